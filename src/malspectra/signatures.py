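"""Nonnegative signature refitting of 96-channel mutation profiles.

A mutation profile (96 trinucleotide-channel counts) is decomposed as a
nonnegative combination of reference single-base-substitution (SBS)
signatures by nonnegative least squares. The strict refit then prunes
weakly supported signatures by backward elimination: repeatedly drop the
signature with the smallest fitted contribution and accept the removal as
long as the cosine similarity between the profile and its reconstruction
falls by less than ``max_delta`` (default 0.004) relative to the previously
accepted fit; the first rejected removal is restored and the loop stops.
This guards against the well-known over-assignment of NNLS with large
signature catalogues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls


def cosine_similarity(a, b) -> float:
    """Cosine similarity on raw count vectors; 0 when either vector is 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


class SignatureMatrix:
    """Reference signatures: 96 canonical channels x named columns.

    Columns are probability vectors (nonnegative, sum 1); rows are
    reindexed to the canonical channel order on construction so that any
    COSMIC-style tab-separated file can be consumed directly.
    """

    def __init__(self, data: pd.DataFrame):
        from .spectra import CHANNELS_96

        missing = set(CHANNELS_96) - set(data.index)
        if missing:
            raise ValueError(f"matrix is missing {len(missing)} channels")
        data = data.loc[list(CHANNELS_96)].astype(float)
        if (data.values < 0).any():
            raise ValueError("signature weights must be nonnegative")
        sums = data.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("signature columns must have positive mass")
        if (np.abs(sums - 1.0) > 1e-4).any():
            raise ValueError("signature columns must sum to 1")
        self.data = data / sums  # exact normalisation
        if not self.names:
            raise ValueError("signature matrix has no columns")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        """Read a COSMIC v3 SBS tab-separated file (Type column with
        'A[C>A]A'-style channels, one column per signature)."""
        df = pd.read_csv(path, sep="\t")
        type_col = df.columns[0]
        return cls(df.set_index(type_col))

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    def subset(self, names) -> "SignatureMatrix":
        out = SignatureMatrix.__new__(SignatureMatrix)
        out.data = self.data[list(names)]
        return out

    def to_tsv(self, path) -> None:
        self.data.rename_axis("Type").to_csv(path, sep="\t")


def _as_profile_vector(profile) -> np.ndarray:
    if hasattr(profile, "context_counts"):
        vec = np.asarray(profile.context_counts, dtype=float)
    else:
        vec = np.asarray(profile, dtype=float)
    if vec.shape != (96,):
        raise ValueError("profile must be a 96-channel vector")
    if (vec < 0).any():
        raise ValueError("profile counts must be nonnegative")
    if vec.sum() == 0:
        raise ValueError("profile is all zero")
    return vec


@dataclass
class NNLSFit:
    """Plain NNLS decomposition of a profile over all given signatures."""

    contributions: pd.Series
    reconstruction: np.ndarray
    residual_norm: float
    similarity: float


def nnls_fit(profile, matrix: SignatureMatrix) -> NNLSFit:
    """Nonnegative least squares: minimise ||profile - M c|| over c >= 0.

    Contributions are on the mutation-count scale (each column of M sums
    to 1, so a contribution is the number of mutations attributed to that
    signature in the reconstruction).
    """
    vec = _as_profile_vector(profile)
    coefs, residual = nnls(matrix.values, vec)
    recon = matrix.values @ coefs
    return NNLSFit(
        contributions=pd.Series(coefs, index=matrix.names, name="contribution"),
        reconstruction=recon,
        residual_norm=float(residual),
        similarity=cosine_similarity(vec, recon),
    )


@dataclass
class SignatureRefit:
    """Result of the strict backward-elimination refit."""

    contributions: pd.Series
    dropped: list
    reconstruction: np.ndarray
    reconstruction_similarity: float
    residual_norm: float
    max_delta: float
    trace: list  # (signature removed, similarity after its removal)

    @property
    def retained(self) -> list[str]:
        return list(self.contributions.index)

    def summary(self) -> str:
        lines = [
            f"Strict signature refit (max similarity drop per removal "
            f"{self.max_delta})",
            f"  reconstruction cosine similarity = "
            f"{self.reconstruction_similarity:.4f}",
            f"  residual norm = {self.residual_norm:.3f}",
            "  retained contributions (mutation counts):",
        ]
        for name, value in self.contributions.sort_values(ascending=False).items():
            lines.append(f"    {name:>10s}  {value:10.2f}")
        if self.dropped:
            lines.append("  dropped (in order): " + ", ".join(self.dropped))
        return "\n".join(lines)


class SignatureRefitModel:
    """Strict refitting of one 96-channel profile against a signature matrix.

    ``fit(max_delta)`` runs NNLS over all signatures, then iteratively
    removes the signature with the smallest current contribution (ties
    broken by name) and refits; a removal is accepted while the cosine
    similarity to the profile drops by less than ``max_delta`` relative to
    the previous accepted fit. The procedure is deterministic and never
    eliminates the last remaining signature.
    """

    def __init__(self, profile, matrix: SignatureMatrix):
        self.profile = _as_profile_vector(profile)
        self.matrix = matrix

    def fit(self, max_delta: float = 0.004) -> SignatureRefit:
        if not 0 <= max_delta < 1:
            raise ValueError("max_delta must be in [0, 1)")
        current = list(self.matrix.names)
        fit = nnls_fit(self.profile, self.matrix)
        accepted_sim = fit.similarity
        dropped: list[str] = []
        trace: list[tuple[str, float]] = []
        # tolerance absorbs solver noise so max_delta=0 still allows removals
        # that leave the similarity numerically unchanged
        eps = 1e-12
        while len(current) > 1:
            # smallest contribution, ties broken by signature name
            candidate = min(
                current, key=lambda s: (fit.contributions[s], s)
            )
            reduced = [s for s in current if s != candidate]
            trial = nnls_fit(self.profile, self.matrix.subset(reduced))
            if accepted_sim - trial.similarity < max_delta + eps:
                current = reduced
                fit = trial
                accepted_sim = trial.similarity
                dropped.append(candidate)
                trace.append((candidate, trial.similarity))
            else:
                break
        return SignatureRefit(
            contributions=fit.contributions,
            dropped=dropped,
            reconstruction=fit.reconstruction,
            reconstruction_similarity=accepted_sim,
            residual_norm=fit.residual_norm,
            max_delta=max_delta,
            trace=trace,
        )


def fit_signatures_strict(
    profile, matrix: SignatureMatrix, max_delta: float = 0.004
) -> SignatureRefit:
    """Functional wrapper around :class:`SignatureRefitModel`."""
    return SignatureRefitModel(profile, matrix).fit(max_delta)
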