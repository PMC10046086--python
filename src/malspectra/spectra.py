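"""Base-substitution spectra: 6-class and 96-channel trinucleotide profiles.

Single-nucleotide variants are normalised to the pyrimidine strand: a
substitution whose reference base is a purine (A or G) is reported as the
reverse complement, so every SNV falls into one of six classes
(C>A, C>G, C>T, T>A, T>C, T>G). With the two flanking reference bases this
expands to 96 channels in the canonical COSMIC ordering (class-major,
then 5' flank, then 3' flank: A[C>A]A ... T[T>G]T), the row order expected
by SBS signature matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The six pyrimidine-strand substitution classes, in canonical order.
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Transitions on the pyrimidine strand (C>T covers C>T and G>A, etc.).
TRANSITIONS = frozenset({"C>T", "T>C"})

#: The 96 trinucleotide channels, class-major then 5' then 3' flank.
CHANNELS_96 = tuple(
    f"{five}[{cls}]{three}" for cls in SUB_CLASSES for five in BASES for three in BASES
)

_CLASS_INDEX = {c: i for i, c in enumerate(SUB_CLASSES)}
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

#: class index of each channel (channel -> one class; marginalisation map)
CHANNEL_CLASS = np.array(
    [_CLASS_INDEX[ch.split("[")[1].split("]")[0]] for ch in CHANNELS_96]
)


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def normalize_substitution(ref: str, alt: str, context: str | None = None):
    """Fold an SNV (and optionally its trinucleotide context) onto the
    pyrimidine strand.

    Returns ``(class_label, context)`` where ``class_label`` is one of
    :data:`SUB_CLASSES` and ``context`` is the reverse-complemented
    trinucleotide when the reference base was a purine.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context = revcomp(context.upper()) if context is not None else None
    elif context is not None:
        context = context.upper()
    label = f"{ref}>{alt}"
    if label not in _CLASS_INDEX:
        raise ValueError(f"invalid substitution {label}")
    if context is not None:
        if len(context) != 3 or context[1] != ref:
            raise ValueError(f"context {context!r} inconsistent with ref {ref}")
    return label, context


def channel_name(cls: str, context: str) -> str:
    return f"{context[0]}[{cls}]{context[2]}"


class MutationSpectrum:
    """A configured substitution spectrum used by the simulator.

    Holds a probability vector over the six pyrimidine-strand classes and,
    optionally, over the 96 trinucleotide channels (when built from a
    signature mixture). Class probabilities always marginalise the channel
    probabilities when both are present.
    """

    def __init__(self, class_probs, channel_probs=None):
        class_probs = np.asarray(class_probs, dtype=float)
        if class_probs.shape != (6,):
            raise ValueError("class probability vector must have 6 entries")
        if np.any(class_probs < 0) or abs(class_probs.sum() - 1.0) > 1e-9:
            raise ValueError("class probabilities must be >=0 and sum to 1")
        self.class_probs = class_probs
        if channel_probs is not None:
            channel_probs = np.asarray(channel_probs, dtype=float)
            if channel_probs.shape != (96,):
                raise ValueError("channel probability vector must have 96 entries")
            if np.any(channel_probs < 0) or abs(channel_probs.sum() - 1.0) > 1e-9:
                raise ValueError("channel probabilities must be >=0 and sum to 1")
        self.channel_probs = channel_probs

    @classmethod
    def uniform(cls) -> "MutationSpectrum":
        """Uniform over the 12 raw substitution types (Ts/Tv = 0.5)."""
        return cls(np.full(6, 1.0 / 6.0))

    @classmethod
    def from_ts_tv(cls, ts_tv: float, gc_at_bias: float = 1.0) -> "MutationSpectrum":
        """Spectrum with a given transition/transversion ratio and G/C→A/T bias.

        The transition mass ``p = ts_tv / (1 + ts_tv)`` is split between C>T
        and T>C by the bias ``b`` (weight b/(1+b) on the G/C→A/T member);
        the GC-changing transversions C>A and T>G share half the remaining
        mass with the same split, and the GC-neutral C>G / T>A split the
        other half evenly. This makes both summary statistics exact:
        Ts/Tv = ts_tv and (C>A + C>T)/(T>C + T>G) = gc_at_bias.
        """
        if ts_tv < 0 or gc_at_bias < 0:
            raise ValueError("ratios must be nonnegative")
        p = ts_tv / (1.0 + ts_tv)
        w = gc_at_bias / (1.0 + gc_at_bias)
        probs = {
            "C>T": p * w,
            "T>C": p * (1 - w),
            "C>A": (1 - p) / 2 * w,
            "T>G": (1 - p) / 2 * (1 - w),
            "C>G": (1 - p) / 4,
            "T>A": (1 - p) / 4,
        }
        return cls(np.array([probs[c] for c in SUB_CLASSES]))

    @classmethod
    def from_signature_mixture(cls, matrix, weights) -> "MutationSpectrum":
        """Mixture of signature columns (a 96-channel distribution)."""
        weights = np.asarray(weights, dtype=float)
        values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix)
        if values.shape[0] != 96 or values.shape[1] != len(weights):
            raise ValueError("matrix must be 96 x k with one weight per column")
        if np.any(weights < 0):
            raise ValueError("mixture weights must be nonnegative")
        channel = values @ weights
        total = channel.sum()
        if total <= 0:
            raise ValueError("mixture has zero total mass")
        channel = channel / total
        class_probs = np.zeros(6)
        np.add.at(class_probs, CHANNEL_CLASS, channel)
        return cls(class_probs, channel)

    @property
    def transition_fraction(self) -> float:
        return float(sum(self.class_probs[_CLASS_INDEX[c]] for c in TRANSITIONS))

    @property
    def ts_tv(self) -> float:
        p = self.transition_fraction
        return p / (1.0 - p) if p < 1.0 else float("inf")


@dataclass
class SpectrumSummary:
    """Six-class summary of an SNV set (pyrimidine-strand normalised).

    ``ts_tv`` and ``gc_to_at`` are ``None`` when their denominator is zero
    (reported as undefined, never silently as 0 or infinity).
    """

    class_counts: dict
    n: int
    ts_tv: float | None
    gc_to_at: float | None

    @property
    def class_proportions(self) -> dict:
        if self.n == 0:
            return {c: float("nan") for c in SUB_CLASSES}
        return {c: v / self.n for c, v in self.class_counts.items()}


def spectrum_summary(variants) -> SpectrumSummary:
    """Six-class spectrum, Ts/Tv and G/C→A/T bias of a curated SNV set.

    Ts/Tv = (C>T + T>C) / (C>A + C>G + T>A + T>G);
    gc_to_at = (C>A + C>T) / (T>C + T>G). Raises on non-SNV input.
    """
    counts = {c: 0 for c in SUB_CLASSES}
    for v in variants:
        if getattr(v, "var_class", "SNV") != "SNV":
            raise ValueError(f"non-SNV in spectrum input: {v}")
        label, _ = normalize_substitution(v.ref_allele, v.alt_allele)
        counts[label] += 1
    n = sum(counts.values())
    ts = counts["C>T"] + counts["T>C"]
    tv = n - ts
    gc_at = counts["C>A"] + counts["C>T"]
    at_gc = counts["T>C"] + counts["T>G"]
    return SpectrumSummary(
        class_counts=counts,
        n=n,
        ts_tv=(ts / tv) if tv > 0 else None,
        gc_to_at=(gc_at / at_gc) if at_gc > 0 else None,
    )


@dataclass
class SpectrumProfile:
    """Joint 6-class / 96-channel counts for a variant set.

    Invariant: ``class_counts`` equals ``context_counts`` marginalised over
    flanking bases, and both sum to ``total``.
    """

    class_counts: np.ndarray
    context_counts: np.ndarray
    total: int
    skipped: int = 0

    def __post_init__(self):
        self.class_counts = np.asarray(self.class_counts)
        self.context_counts = np.asarray(self.context_counts)

    @property
    def channels(self):
        return CHANNELS_96

    def collapse_to_classes(self) -> np.ndarray:
        """Marginalise the 96 channels over flanks back to the 6 classes."""
        out = np.zeros(6, dtype=self.context_counts.dtype)
        np.add.at(out, CHANNEL_CLASS, self.context_counts)
        return out

    def to_series(self) -> pd.Series:
        return pd.Series(self.context_counts, index=list(CHANNELS_96), name="count")

    def plot(self, ax=None):
        """Bar plot of the 96-channel profile, coloured by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(14, 3))
        colors = ["#03BCEE", "#010101", "#E32926", "#CAC9C9", "#A1CE63", "#EBC6C4"]
        ax.bar(
            np.arange(96),
            self.context_counts,
            color=[colors[c] for c in CHANNEL_CLASS],
        )
        ax.set_xticks(np.arange(96))
        ax.set_xticklabels(list(CHANNELS_96), rotation=90, fontsize=4)
        ax.set_ylabel("count")
        return ax


def trinucleotide_profile(variants, genome) -> SpectrumProfile:
    """Assign each SNV to one of the 96 trinucleotide channels.

    The flanking bases are read from the reference; a variant whose
    reference allele disagrees with the genome raises, and
    chromosome-terminal SNVs (no flank available) are skipped with a
    warning.
    """
    class_counts = np.zeros(6, dtype=np.int64)
    context_counts = np.zeros(96, dtype=np.int64)
    total = 0
    skipped = 0
    for v in variants:
        if getattr(v, "var_class", "SNV") != "SNV":
            raise ValueError(f"non-SNV in profile input: {v}")
        ref_base = genome.base(v.chromosome, v.position)
        if ref_base != v.ref_allele.upper():
            raise ValueError(
                f"reference mismatch at {v.chromosome}:{v.position}: "
                f"variant ref {v.ref_allele}, genome {ref_base}"
            )
        context = genome.trinucleotide(v.chromosome, v.position)
        if context is None:
            warnings.warn(
                f"skipping chromosome-terminal SNV at {v.chromosome}:{v.position}",
                stacklevel=2,
            )
            skipped += 1
            continue
        label, ctx = normalize_substitution(v.ref_allele, v.alt_allele, context)
        class_counts[_CLASS_INDEX[label]] += 1
        context_counts[_CHANNEL_INDEX[channel_name(label, ctx)]] += 1
        total += 1
    return SpectrumProfile(class_counts, context_counts, total, skipped)
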