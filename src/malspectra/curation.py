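"""De novo variant curation: caller consensus, filters, contamination screen.

Raw per-replicate calls from two independent callers are reduced to curated
de novo variants in three steps: intersection of the two call sets (a call
must be reported identically by both callers), subtraction of variants
already present in the ancestor clone, and removal of calls inside
excluded complex regions (e.g. subtelomeres) or with poor mapping depth
(<= 10 by default). Replicate pairs sharing an implausibly high fraction of
mutations are flagged as potential cross-contamination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from intervaltree import IntervalTree

from .variants import VariantCall, by_key, normalize_indel

logger = logging.getLogger(__name__)


@dataclass
class ExclusionSet:
    """Genomic intervals excluded from calling, 0-based half-open."""

    intervals: list  # (chromosome, start, end)
    label: str = "excluded"

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
        self._trees = {}
        for chrom, start, end in self.intervals:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def contains(self, chromosome: str, position: int) -> bool:
        """Whether a 1-based position falls in an excluded interval."""
        tree = self._trees.get(chromosome)
        return bool(tree is not None and tree.overlaps_point(position - 1))

    def excluded_length(self, chromosome: str | None = None) -> int:
        """Total excluded bases (overlaps merged)."""
        total = 0
        for chrom, tree in self._trees.items():
            if chromosome is not None and chrom != chromosome:
                continue
            merged = IntervalTree(tree)
            merged.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in merged)
        return total

    @property
    def chromosomes(self):
        return set(self._trees)


def consensus_intersect(calls_a, calls_b, genome=None) -> list[VariantCall]:
    """Calls reported by both callers with an identical
    (chromosome, position, ref, alt) key.

    INDELs are left-normalised on both sides before comparison since
    callers pad and anchor the same event differently (full left-alignment
    when a reference ``genome`` is supplied, parsimony trimming otherwise).
    The surviving call carries both caller flags and the minimum of the two
    reported depths.
    """
    a = by_key(normalize_indel(c, genome) for c in calls_a)
    b = by_key(normalize_indel(c, genome) for c in calls_b)
    out = []
    for key in a.keys() & b.keys():
        ca, cb = a[key], b[key]
        depths = [d for d in (ca.depth, cb.depth) if d is not None]
        out.append(
            VariantCall(
                ca.chromosome,
                ca.position,
                ca.ref_allele,
                ca.alt_allele,
                depth=min(depths) if depths else None,
                replicate_id=ca.replicate_id or cb.replicate_id,
                caller_flags=ca.caller_flags | cb.caller_flags,
            )
        )
    out.sort(key=lambda c: (c.chromosome, c.position, c.ref_allele, c.alt_allele))
    return out


@dataclass
class FilterLog:
    """Counts of calls removed by each filter, for the curation log."""

    input: int = 0
    ancestor: int = 0
    excluded_region: int = 0
    low_depth: int = 0
    kept: int = 0

    def as_dict(self):
        return dict(self.__dict__)


def apply_filters(
    calls,
    ancestor=(),
    excluded: ExclusionSet | None = None,
    min_depth: int = 11,
    known_chromosomes=None,
) -> tuple[list[VariantCall], FilterLog]:
    """Remove ancestor-shared calls, calls in excluded regions, and calls
    with depth below ``min_depth`` (default keeps depth >= 11, i.e. rejects
    the poor-depth <= 10 calls).

    A call without a recorded depth is kept with a warning. Excluded
    intervals on chromosomes absent from ``known_chromosomes`` (when given)
    are ignored with a warning. The three filters commute, so the result is
    order-independent.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    if excluded is not None and known_chromosomes is not None:
        unknown = excluded.chromosomes - set(known_chromosomes)
        if unknown:
            logger.warning(
                "exclusion intervals on unknown chromosomes ignored: %s",
                sorted(unknown),
            )
    ancestor_keys = {normalize_indel(c).key for c in ancestor}
    log = FilterLog()
    kept = []
    for call in calls:
        log.input += 1
        if normalize_indel(call).key in ancestor_keys:
            log.ancestor += 1
            continue
        if excluded is not None and excluded.contains(call.chromosome, call.position):
            log.excluded_region += 1
            continue
        if call.depth is None:
            logger.warning(
                "call %s:%d has no depth record; kept unfiltered",
                call.chromosome,
                call.position,
            )
        elif call.depth < min_depth:
            log.low_depth += 1
            continue
        kept.append(call)
    log.kept = len(kept)
    return kept, log


@dataclass
class ContaminationFlag:
    """Shared-mutation fraction for one replicate pair."""

    replicate_a: str
    replicate_b: str
    shared: int
    shared_fraction: float
    flagged: bool


def detect_cross_contamination(
    replicate_sets: dict[str, list], threshold: float = 0.2
) -> list[ContaminationFlag]:
    """Screen replicate pairs for cross-contamination.

    The shared fraction is |intersection| / min(|A|, |B|) of the curated
    mutation keys (0 when either set is empty); pairs at or above
    ``threshold`` are flagged for exclusion. MAL replicates accumulate
    mutations independently, so any appreciable sharing indicates mixing.
    """
    if len(replicate_sets) < 2:
        raise ValueError("need at least two replicates")
    keysets = {rep: {c.key for c in calls} for rep, calls in replicate_sets.items()}
    flags = []
    for rep_a, rep_b in combinations(sorted(keysets), 2):
        a, b = keysets[rep_a], keysets[rep_b]
        shared = len(a & b)
        denom = min(len(a), len(b))
        frac = shared / denom if denom > 0 else 0.0
        flags.append(
            ContaminationFlag(rep_a, rep_b, shared, frac, frac >= threshold)
        )
    return flags


def curate_replicate(
    calls_a,
    calls_b,
    ancestor=(),
    excluded: ExclusionSet | None = None,
    min_depth: int = 11,
    genome=None,
) -> tuple[list[VariantCall], FilterLog]:
    """Consensus intersection followed by the full filter stack."""
    consensus = consensus_intersect(calls_a, calls_b, genome)
    return apply_filters(consensus, ancestor, excluded, min_depth)
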