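"""Depth-based copy number: mtDNA copy, aneuploidy, segmental CNV.

All estimates are ratios of median window depths, so they are invariant to
the overall sequencing depth. The mitochondrial copy number per haploid
nuclear genome is the mito/nuclear median-depth ratio times ploidy; a
whole-chromosome call is ploidy times the chromosome's median depth over
the genome-wide baseline (median of per-chromosome medians); segmental
events are found by binary segmentation of normalised window depths with a
BIC-style stopping rule and reported when they deviate from the chromosome
baseline by at least ``copy_threshold`` copies over at least
``min_windows`` windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class DepthTrack:
    """Windowed mean depth along one chromosome (0-based half-open windows)."""

    chromosome: str
    starts: np.ndarray
    ends: np.ndarray
    depths: np.ndarray
    window_size: int = 0

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        self.depths = np.asarray(self.depths, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.depths)):
            raise ValueError("starts, ends and depths must align")
        if np.any(self.ends <= self.starts):
            raise ValueError("windows must be non-empty")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("windows must be sorted and non-overlapping")
        if np.any(self.depths < 0):
            raise ValueError("depths must be >= 0")

    def __len__(self):
        return len(self.depths)

    @property
    def median_depth(self) -> float:
        return float(np.median(self.depths))


@dataclass
class CopyNumberCall:
    """One whole-chromosome or segmental copy-number call.

    ``estimated_copy`` is the raw depth-ratio estimate; ``integer_copy``
    rounds half away from zero (half-up for the nonnegative estimates here)
    so borderline calls remain auditable from the estimate itself.
    """

    scope: str  # "chromosome" or "segment"
    chromosome: str
    start: int
    end: int
    estimated_copy: float
    integer_copy: int
    baseline_depth: float
    breakpoint_repeat_distances: tuple | None = None
    flagged: str | None = None

    @property
    def is_aneuploid(self) -> bool:
        return self.scope == "chromosome" and self.flagged is None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mtdna_copy_number(
    tracks,
    mito_id: str,
    ploidy: int = 1,
    rho0_ratio_threshold: float = 0.01,
) -> float:
    """Mitochondrial genomes per haploid nuclear genome.

    copy = (median mito window depth / nuclear baseline depth) x ploidy,
    with ratios below ``rho0_ratio_threshold`` reported as exactly 0
    (complete mtDNA loss, rho0). The nuclear baseline is the median of
    per-chromosome median depths so that an aneuploid chromosome's windows
    do not drag the baseline.
    """
    mito_depths = []
    nuclear_medians = []
    for t in tracks:
        if t.chromosome == mito_id:
            mito_depths.append(t.depths)
        else:
            nuclear_medians.append(t.median_depth)
    if not nuclear_medians:
        raise ValueError("no nuclear windows present")
    if not mito_depths:
        raise ValueError(f"no windows for mitochondrial chromosome {mito_id!r}")
    nuc = float(np.median(nuclear_medians))
    if nuc <= 0:
        raise ValueError("nuclear median depth is zero")
    ratio = float(np.median(np.concatenate(mito_depths))) / nuc
    if ratio < rho0_ratio_threshold:
        return 0.0
    return ratio * ploidy


def call_aneuploidy(tracks, ploidy: int = 1, mito_id: str | None = None):
    """Whole-chromosome copy calls from per-chromosome median depths.

    The baseline is the median of per-chromosome median depths (robust as
    long as most chromosomes are euploid); each chromosome's estimated copy
    is ploidy x (chromosome median / baseline). With a single nuclear
    chromosome the baseline collapses onto it and the call is flagged
    undecidable.
    """
    nuclear = [t for t in tracks if t.chromosome != mito_id]
    if not nuclear:
        raise ValueError("no nuclear depth tracks")
    medians = {t.chromosome: t.median_depth for t in nuclear}
    baseline = float(np.median(list(medians.values())))
    if baseline <= 0:
        raise ValueError("baseline depth is zero")
    single = len(nuclear) < 2
    calls = []
    for t in nuclear:
        est = ploidy * medians[t.chromosome] / baseline
        calls.append(
            CopyNumberCall(
                scope="chromosome",
                chromosome=t.chromosome,
                start=int(t.starts[0]),
                end=int(t.ends[-1]),
                estimated_copy=float(est),
                integer_copy=_round_half_up(est),
                baseline_depth=baseline,
                flagged=(
                    "single-chromosome genome: aneuploidy undecidable"
                    if single
                    else None
                ),
            )
        )
    return calls


def _best_split(x: np.ndarray):
    """Best change point of a sequence by squared-error cost; returns
    (index, cost reduction). Index k splits into x[:k], x[k:]."""
    n = len(x)
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    total_sse = css[-1] - cs[-1] ** 2 / n
    k = np.arange(1, n)
    left = css[:-1] - cs[:-1] ** 2 / k
    right = (css[-1] - css[:-1]) - (cs[-1] - cs[:-1]) ** 2 / (n - k)
    reduction = total_sse - (left + right)
    best = int(np.argmax(reduction))
    return best + 1, float(reduction[best])


def _segment_boundaries(x: np.ndarray, penalty: float, min_size: int = 2):
    """Recursive binary segmentation; split accepted while the SSE reduction
    exceeds the penalty. Deterministic. Returns sorted interior boundaries."""
    out = []

    def recurse(lo: int, hi: int):
        if hi - lo < 2 * min_size:
            return
        k, reduction = _best_split(x[lo:hi])
        if reduction <= penalty:
            return
        if k < min_size or (hi - lo) - k < min_size:
            return
        out.append(lo + k)
        recurse(lo, lo + k)
        recurse(lo + k, hi)

    recurse(0, len(x))
    return sorted(out)


def _noise_scale(x: np.ndarray) -> float:
    """Robust per-window noise SD from first differences (change points are
    sparse, so differences are dominated by noise)."""
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


def detect_segmental_cnv(
    track: DepthTrack,
    min_windows: int = 5,
    copy_threshold: float = 0.5,
    ploidy: int = 1,
    repeats=None,
    baseline_depth: float | None = None,
):
    """Segmental copy-number calls on one chromosome's depth track.

    Window depths are normalised to copy units against the chromosome
    baseline (its median depth, or ``baseline_depth`` when the expected
    euploid depth is known, e.g. on an aneuploid chromosome). Binary
    segmentation with a BIC-style penalty finds change points; adjacent
    segments with equal rounded copy are merged and segments deviating from
    ploidy by >= ``copy_threshold`` copies over >= ``min_windows`` windows
    are reported. When ``repeats`` (0-based half-open intervals on this
    chromosome) is given, each breakpoint is annotated with its distance to
    the nearest repeat interval.
    """
    if len(track) < min_windows:
        raise ValueError("track shorter than min_windows")
    scale = track.median_depth if baseline_depth is None else float(baseline_depth)
    if scale <= 0:
        if np.all(track.depths == 0):
            return []
        scale = float(track.depths.mean())
    normed = track.depths / scale
    sigma = _noise_scale(normed)
    penalty = 3.0 * sigma**2 * math.log(max(len(normed), 2))
    bounds = _segment_boundaries(normed, penalty)
    edges = [0] + bounds + [len(normed)]
    pieces = [(lo, hi, float(track.depths[lo:hi].mean())) for lo, hi in zip(edges[:-1], edges[1:])]

    if baseline_depth is not None:
        baseline = float(baseline_depth)
    else:
        # euploid baseline = mean depth of the majority segment; on a tie
        # the lower-depth state is taken as euploid (duplications are the
        # common event)
        baseline = min(
            pieces, key=lambda p: (-(p[1] - p[0]), p[2])
        )[2]
    if baseline <= 0:
        raise ValueError("chromosome baseline depth is zero")
    copies = ploidy * track.depths / baseline

    # merge adjacent segments with the same rounded copy
    segments = []
    for lo, hi, _mean in pieces:
        mean_copy = float(copies[lo:hi].mean())
        rounded = _round_half_up(mean_copy)
        if segments and segments[-1][2] == rounded:
            plo, phi, _ = segments[-1]
            merged_mean = float(copies[plo:hi].mean())
            segments[-1] = (plo, hi, _round_half_up(merged_mean))
        else:
            segments.append((lo, hi, rounded))

    calls = []
    for lo, hi, _rounded in segments:
        mean_copy = float(copies[lo:hi].mean())
        if abs(mean_copy - ploidy) < copy_threshold:
            continue
        if hi - lo < min_windows:
            continue
        start = int(track.starts[lo])
        end = int(track.ends[hi - 1])
        distances = None
        if repeats is not None:
            distances = tuple(
                _distance_to_repeats(bp, repeats) for bp in (start, end)
            )
        calls.append(
            CopyNumberCall(
                scope="segment",
                chromosome=track.chromosome,
                start=start,
                end=end,
                estimated_copy=mean_copy,
                integer_copy=_round_half_up(mean_copy),
                baseline_depth=baseline,
                breakpoint_repeat_distances=distances,
            )
        )
    return calls


def _distance_to_repeats(position: int, repeats) -> int:
    """Distance from a breakpoint to the nearest repeat interval (0 inside)."""
    best = None
    for start, end in repeats:
        if start <= position < end:
            return 0
        d = start - position if position < start else position - (end - 1)
        best = d if best is None else min(best, d)
    if best is None:
        raise ValueError("empty repeat interval set")
    return int(best)
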