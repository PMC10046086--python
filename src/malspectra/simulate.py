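"""Synthetic mutation-accumulation-line (MAL) experiments with known truth.

A MAL propagates a single clone through repeated single-cell bottlenecks so
that spontaneous mutations accumulate nearly free of selection. The
simulator emulates the whole observable layer of such an experiment on a
toy reference genome:

* per-replicate de novo mutations — Poisson counts at a configured
  per-base per-generation rate over the callable genome, substitution
  types drawn from a configured spectrum at matching reference sites
  (infinite-sites: one mutation per site per replicate);
* two imperfect variant callers per replicate, each dropping true calls
  (false negatives) and adding caller-specific spurious calls (false
  positives) at independent uniform positions;
* variants already present in the ancestor clone, which therefore appear
  in every replicate's call sets;
* windowed sequencing-depth tracks with negative-binomial noise, an
  elevated mitochondrial copy ratio, and whole-chromosome or segmental
  copy events.

Everything is driven by one integer seed; the returned
:class:`SimulatedExperiment` carries the ground truth needed to test the
downstream curation, rate, spectrum and copy-number stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Genome
from .spectra import COMPLEMENT, MutationSpectrum, SUB_CLASSES
from .variants import VariantCall

CALLERS = ("callerA", "callerB")

_MAX_SITE_TRIES = 100_000


@dataclass(frozen=True)
class MALDesign:
    """Experimental design of one strain's mutation accumulation lines.

    ``generations_total`` is the total number of cell divisions over the
    whole propagation (e.g. ~2520 for normal growers bottlenecked 120
    times, ~1260 for slow growers bottlenecked 60 times). When
    ``bottleneck_count`` is given, ``generations_total`` must be an exact
    multiple of it (a constant number of divisions per bottleneck).
    """

    strain_id: str
    generations_total: int
    replicate_count: int = 4
    bottleneck_count: int | None = None
    ploidy: int = 1
    mito_present: bool = True

    def __post_init__(self):
        if self.generations_total <= 0:
            raise ValueError("generations_total must be positive")
        if self.replicate_count < 1:
            raise ValueError("need at least one replicate")
        if self.ploidy < 1:
            raise ValueError("ploidy must be positive")
        if self.bottleneck_count is not None:
            if self.bottleneck_count <= 0:
                raise ValueError("bottleneck_count must be positive")
            if self.generations_total % self.bottleneck_count != 0:
                raise ValueError(
                    "generations_total must be a multiple of bottleneck_count"
                )

    @property
    def replicate_ids(self) -> list[str]:
        return [f"{self.strain_id}_r{i + 1}" for i in range(self.replicate_count)]


def _as_caller_dict(value) -> dict[str, float]:
    if isinstance(value, dict):
        missing = set(CALLERS) - set(value)
        if missing:
            raise ValueError(f"missing caller rates for {sorted(missing)}")
        return {c: float(value[c]) for c in CALLERS}
    return {c: float(value) for c in CALLERS}


@dataclass
class SimParams:
    """All simulated quantities of one strain's experiment.

    Rates are per base per generation. ``spectrum`` defaults to uniform
    over the 12 raw substitution types (Ts/Tv = 0.5). ``caller_fp_rate``
    is a per-base probability of a spurious call per replicate (so the
    expected FP count is rate x genome length); caller rates may be one
    number for both callers or a dict per caller. ``seed`` fixes every
    source of randomness.
    """

    snv_rate: float
    indel_rate: float = 0.0
    mito_snv_rate: float = 0.0
    mito_indel_rate: float = 0.0
    spectrum: MutationSpectrum = field(default_factory=MutationSpectrum.uniform)
    caller_fp_rate: dict | float = 0.0
    caller_fn_rate: dict | float = 0.0
    ancestor_variant_count: int = 0
    mean_depth: float = 88.0
    depth_dispersion: float = 2.0
    mito_copy_ratio: float = 14.0
    ploidy_events: tuple = ()
    seed: int = 0

    def __post_init__(self):
        for name in ("snv_rate", "indel_rate", "mito_snv_rate", "mito_indel_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.mito_copy_ratio < 0:
            raise ValueError("mito_copy_ratio must be >= 0")
        if self.depth_dispersion < 1.0:
            raise ValueError("depth_dispersion is variance/mean, must be >= 1")
        self.caller_fp_rate = _as_caller_dict(self.caller_fp_rate)
        self.caller_fn_rate = _as_caller_dict(self.caller_fn_rate)


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    Every call emitted for a replicate is either in that replicate's truth
    list, the ancestor list, or the corresponding false-positive list.
    """

    design: MALDesign
    params: SimParams
    truth: dict[str, list[VariantCall]]
    ancestor: list[VariantCall]
    false_positives: dict[tuple[str, str], list[VariantCall]]
    callable_nuclear: int
    callable_mito: int

    def truth_count(self, replicate_id: str, var_class: str, compartment: str) -> int:
        return sum(
            1
            for v in self.truth[replicate_id]
            if v.var_class == var_class
            and (
                (compartment == "mito") == (v.chromosome == self._mito_id)
            )
        )

    _mito_id: str | None = None


@dataclass
class SimulatedExperiment:
    """Caller outputs plus ground truth for one strain."""

    truth: SimTruth
    caller_calls: dict[str, dict[str, list[VariantCall]]]
    ancestor_calls: list[VariantCall]


def _draw_depth(rng, mean: float, dispersion: float, size=None):
    """Negative-binomial depths with variance = dispersion x mean."""
    if mean <= 0:
        return np.zeros(size if size is not None else 1, dtype=int) if size else 0
    if dispersion <= 1.0 + 1e-12:
        return rng.poisson(mean, size=size)
    p = 1.0 / dispersion
    n = mean * p / (1.0 - p)
    return rng.negative_binomial(n, p, size=size)


class _SiteChooser:
    """Uniform 1-based site over the concatenated compartment."""

    def __init__(self, genome: Genome, chroms):
        self.chroms = list(chroms)
        lengths = np.array([genome.lengths[c] for c in self.chroms], dtype=np.int64)
        self.cum = np.cumsum(lengths)
        self.total = int(self.cum[-1])

    def draw(self, rng) -> tuple[str, int]:
        r = int(rng.integers(self.total))
        i = int(np.searchsorted(self.cum, r, side="right"))
        offset = r - (int(self.cum[i - 1]) if i else 0)
        return self.chroms[i], offset + 1


def _sample_snv_site(genome: Genome, chooser: _SiteChooser, cls: str, used, rng):
    """Uniform site among callable sites whose (pyrimidine-strand) base
    matches the class, by rejection sampling; resamples sites already used
    in this replicate (infinite-sites approximation)."""
    pyr = cls[0]  # C or T
    wanted = {pyr, COMPLEMENT[pyr]}
    for _ in range(_MAX_SITE_TRIES):
        chrom, pos = chooser.draw(rng)
        if (chrom, pos) in used:
            continue
        base = genome.base(chrom, pos)
        if base in wanted:
            return chrom, pos, base
    raise RuntimeError(f"no site found for class {cls}; genome too small or skewed")


def _make_snv(base, cls) -> tuple[str, str]:
    """Reference/alt alleles realising a pyrimidine-strand class at a site."""
    ref_pyr, alt_pyr = cls[0], cls[2]
    if base == ref_pyr:
        return base, alt_pyr
    return base, COMPLEMENT[alt_pyr]


def _sample_channel_site(genome, chooser, channel_idx, used, rng):
    """Rejection-sample a site whose pyrimidine-normalised trinucleotide
    matches a 96-channel context."""
    from .spectra import CHANNELS_96, revcomp

    ch = CHANNELS_96[channel_idx]
    context = ch[0] + ch[2] + ch[6]  # five, ref, three
    rc = revcomp(context)
    for _ in range(_MAX_SITE_TRIES):
        chrom, pos = chooser.draw(rng)
        if (chrom, pos) in used:
            continue
        tri = genome.trinucleotide(chrom, pos)
        if tri is None:
            continue
        if tri == context or tri == rc:
            return chrom, pos, genome.base(chrom, pos)
    raise RuntimeError(f"no site found for channel {ch}")


def sample_snvs(
    genome: Genome,
    n: int,
    spectrum: MutationSpectrum,
    rng: np.random.Generator,
    compartment: str = "nuclear",
    replicate_id: str = "",
    used: set | None = None,
) -> list[VariantCall]:
    """Draw ``n`` de novo SNVs from a spectrum onto matching reference sites.

    The substitution class (or, for a signature-mixture spectrum, the
    96-channel context) is drawn first, then a uniformly random site with a
    matching reference base/trinucleotide, so the realised spectrum matches
    the configured one in expectation regardless of base composition.
    """
    chroms = genome.nuclear_ids if compartment == "nuclear" else [genome.mito_id]
    if chroms == [None]:
        raise ValueError("genome has no mitochondrial chromosome")
    chooser = _SiteChooser(genome, chroms)
    used = set() if used is None else used
    calls = []
    if spectrum.channel_probs is not None:
        from .spectra import CHANNELS_96

        channels = rng.choice(96, size=n, p=spectrum.channel_probs)
        for idx in channels:
            chrom, pos, base = _sample_channel_site(
                genome, chooser, int(idx), used, rng
            )
            cls = CHANNELS_96[int(idx)].split("[")[1].split("]")[0]
            ref, alt = _make_snv(base, cls)
            used.add((chrom, pos))
            calls.append(
                VariantCall(chrom, pos, ref, alt, replicate_id=replicate_id)
            )
    else:
        classes = rng.choice(6, size=n, p=spectrum.class_probs)
        for idx in classes:
            cls = SUB_CLASSES[int(idx)]
            chrom, pos, base = _sample_snv_site(genome, chooser, cls, used, rng)
            ref, alt = _make_snv(base, cls)
            used.add((chrom, pos))
            calls.append(
                VariantCall(chrom, pos, ref, alt, replicate_id=replicate_id)
            )
    return calls


def sample_indels(
    genome: Genome,
    n: int,
    rng: np.random.Generator,
    compartment: str = "nuclear",
    replicate_id: str = "",
    used: set | None = None,
) -> list[VariantCall]:
    """Draw ``n`` short INDELs: geometric(0.5) length in 1..10 bp,
    insertion/deletion equiprobable, VCF anchor-base representation."""
    chroms = genome.nuclear_ids if compartment == "nuclear" else [genome.mito_id]
    chooser = _SiteChooser(genome, chroms)
    used = set() if used is None else used
    alphabet = "ACGT"
    calls = []
    for _ in range(n):
        for _try in range(_MAX_SITE_TRIES):
            chrom, pos = chooser.draw(rng)
            clen = genome.lengths[chrom]
            size = min(int(rng.geometric(0.5)), 10)
            is_del = bool(rng.integers(2))
            # anchor base before the event; deletions need room to the right
            if pos >= clen - size:
                continue
            if (chrom, pos) in used:
                continue
            anchor = genome.base(chrom, pos)
            if is_del:
                ref = genome.slice(chrom, pos - 1, pos + size)
                alt = anchor
            else:
                ref = anchor
                alt = anchor + "".join(
                    alphabet[int(b)] for b in rng.integers(0, 4, size=size)
                )
            used.add((chrom, pos))
            calls.append(VariantCall(chrom, pos, ref, alt, replicate_id=replicate_id))
            break
        else:
            raise RuntimeError("could not place INDEL")
    return calls


def simulate_mal_experiment(
    genome: Genome, design: MALDesign, params: SimParams
) -> SimulatedExperiment:
    """Simulate one strain's MAL experiment end to end.

    Per replicate the nuclear SNV count is Poisson(snv_rate x callable
    length x generations), and likewise for INDELs and the mitochondrial
    compartment (when the design retains mtDNA). Each caller's output is
    the truth minus false-negative draws plus caller-specific false
    positives; ancestor variants appear in the ancestor call set and in
    every replicate's caller sets.
    """
    rng = np.random.default_rng(params.seed)
    L_nuc = genome.compartment_length("nuclear")
    L_mito = genome.compartment_length("mito")
    T = design.generations_total

    ancestor = sample_snvs(
        genome, params.ancestor_variant_count, params.spectrum, rng,
        replicate_id="ancestor",
    )
    ancestor_keys = {v.key for v in ancestor}

    truth: dict[str, list[VariantCall]] = {}
    caller_calls: dict[str, dict[str, list[VariantCall]]] = {}
    false_positives: dict[tuple[str, str], list[VariantCall]] = {}

    for rep in design.replicate_ids:
        used: set = {(v.chromosome, v.position) for v in ancestor}
        muts: list[VariantCall] = []
        n_snv = rng.poisson(params.snv_rate * L_nuc * T)
        muts += sample_snvs(
            genome, n_snv, params.spectrum, rng, "nuclear", rep, used
        )
        n_indel = rng.poisson(params.indel_rate * L_nuc * T)
        muts += sample_indels(genome, n_indel, rng, "nuclear", rep, used)
        if design.mito_present and genome.mito_id is not None and params.mito_copy_ratio > 0:
            n_msnv = rng.poisson(params.mito_snv_rate * L_mito * T)
            muts += sample_snvs(
                genome, n_msnv, params.spectrum, rng, "mito", rep, used
            )
            n_mindel = rng.poisson(params.mito_indel_rate * L_mito * T)
            muts += sample_indels(genome, n_mindel, rng, "mito", rep, used)
        truth[rep] = muts

        caller_calls[rep] = {}
        for caller in CALLERS:
            fn = params.caller_fn_rate[caller]
            kept = []
            for v in muts + ancestor:
                if v.key in ancestor_keys or rng.random() >= fn:
                    depth = int(
                        _draw_depth(rng, params.mean_depth, params.depth_dispersion)
                    )
                    kept.append(
                        VariantCall(
                            v.chromosome, v.position, v.ref_allele, v.alt_allele,
                            depth=depth, replicate_id=rep,
                            caller_flags=frozenset({caller}),
                        )
                    )
            fp_rate = params.caller_fp_rate[caller]
            n_fp = rng.poisson(fp_rate * (L_nuc + L_mito))
            fps = []
            fp_used = set(used)
            for v in sample_snvs(
                genome, n_fp, MutationSpectrum.uniform(), rng, "nuclear", rep, fp_used
            ):
                depth = int(
                    _draw_depth(rng, params.mean_depth, params.depth_dispersion)
                )
                fps.append(
                    VariantCall(
                        v.chromosome, v.position, v.ref_allele, v.alt_allele,
                        depth=depth, replicate_id=rep,
                        caller_flags=frozenset({caller}),
                    )
                )
            false_positives[(rep, caller)] = fps
            caller_calls[rep][caller] = sorted(
                kept + fps, key=lambda c: (c.chromosome, c.position, c.alt_allele)
            )

    ancestor_depth = [
        VariantCall(
            v.chromosome, v.position, v.ref_allele, v.alt_allele,
            depth=int(_draw_depth(rng, params.mean_depth, params.depth_dispersion)),
            replicate_id="ancestor",
        )
        for v in ancestor
    ]

    sim_truth = SimTruth(
        design=design,
        params=params,
        truth=truth,
        ancestor=ancestor,
        false_positives=false_positives,
        callable_nuclear=L_nuc,
        callable_mito=L_mito,
    )
    sim_truth._mito_id = genome.mito_id
    return SimulatedExperiment(
        truth=sim_truth, caller_calls=caller_calls, ancestor_calls=ancestor_depth
    )


def simulate_depth_tracks(
    genome: Genome,
    params: SimParams,
    window_size: int = 1000,
    noise: bool = True,
    ploidy: int = 1,
    rng: np.random.Generator | None = None,
):
    """Windowed depth tracks around ``mean_depth`` with copy structure.

    Mitochondrial windows are scaled by ``mito_copy_ratio / ploidy``;
    ``ploidy_events`` — tuples ``(chromosome, copy)`` or
    ``(chromosome, start, end, copy)`` with 0-based half-open intervals —
    scale the affected windows by ``copy / ploidy``. With ``noise`` the
    window depth is negative-binomial with variance = dispersion x mean;
    without it every window sits exactly at its expected depth. A window
    larger than its chromosome becomes a single truncated window.
    """
    from .cnv import DepthTrack

    if window_size < 1:
        raise ValueError("window size must be >= 1")
    if params.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    events = []
    for ev in params.ploidy_events:
        if len(ev) == 2:
            events.append((ev[0], 0, genome.lengths[ev[0]], float(ev[1])))
        elif len(ev) == 4:
            events.append((ev[0], int(ev[1]), int(ev[2]), float(ev[3])))
        else:
            raise ValueError(f"bad ploidy event {ev!r}")

    tracks = []
    for chrom, length in genome.lengths.items():
        starts = np.arange(0, length, window_size)
        ends = np.minimum(starts + window_size, length)
        mult = np.ones(len(starts))
        if chrom == genome.mito_id:
            mult[:] = params.mito_copy_ratio / ploidy
        for echrom, estart, eend, copy in events:
            if echrom != chrom:
                continue
            hit = (starts < eend) & (ends > estart)
            mult[hit] = copy / ploidy
        means = params.mean_depth * mult
        if noise:
            depths = np.array(
                [
                    float(_draw_depth(rng, m, params.depth_dispersion))
                    for m in means
                ]
            )
        else:
            depths = means.astype(float)
        tracks.append(DepthTrack(chrom, starts, ends, depths, window_size))
    return tracks


def random_gene_models(
    genome: Genome,
    genic_fraction: float = 0.7,
    mean_cds_codons: int = 450,
    seed: int | np.random.Generator = 0,
):
    """Non-overlapping single-exon gene models covering roughly a target
    fraction of the nuclear genome (yeast-like gene density), random strand,
    CDS length a multiple of 3."""
    from .annotation import GeneModel

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    models = []
    n = 0
    for chrom in genome.nuclear_ids:
        length = genome.lengths[chrom]
        pos = int(rng.integers(0, 200))
        while pos < length - 300:
            codons = max(30, int(rng.exponential(mean_cds_codons)))
            span = codons * 3
            if pos + span > length:
                break
            n += 1
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(
                GeneModel(
                    gene_id=f"G{n:05d}",
                    chromosome=chrom,
                    strand=strand,
                    cds_intervals=((pos, pos + span),),
                )
            )
            # intergenic gap sized to hit the target genic fraction
            gap = max(3, int(rng.exponential(span * (1 - genic_fraction) / max(genic_fraction, 1e-6))))
            pos += span + gap
    return models
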