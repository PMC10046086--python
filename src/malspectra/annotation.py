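"""Minimal variant effect classification against gene models.

Classifies curated SNVs as intergenic / genic-noncoding / synonymous /
missense / nonsense by reconstructing the affected codon from the reference
(reverse-complemented for minus-strand genes) and translating with the
standard nuclear genetic code. "Genic" means within the gene span; "coding"
means within a CDS interval. INDELs and mitochondrial variants are
annotated genic/intergenic only (no codon logic). The impact mapping is
fixed: synonymous -> low, missense -> moderate, nonsense -> high; noncoding
categories are reported as low impact.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .spectra import COMPLEMENT

CATEGORIES = ("intergenic", "genic_noncoding", "synonymous", "missense", "nonsense")
_SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}
IMPACT = {
    "intergenic": "low",
    "genic_noncoding": "low",
    "synonymous": "low",
    "missense": "moderate",
    "nonsense": "high",
}


@dataclass(frozen=True)
class GeneModel:
    """A gene with ordered CDS intervals (0-based half-open, genome order).

    The reading frame follows the interval order 5'->3' on the coding
    strand; for minus-strand genes the last genomic interval is read first.
    For complete models the total CDS length is a multiple of 3.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_intervals: tuple
    gene_start: int | None = None
    gene_end: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev_end = -1
        for start, end in self.cds_intervals:
            if start >= end:
                raise ValueError("empty CDS interval")
            if start < prev_end:
                raise ValueError("CDS intervals must be sorted and non-overlapping")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        start = self.gene_start
        end = self.gene_end
        if self.cds_intervals:
            cds_start = self.cds_intervals[0][0]
            cds_end = self.cds_intervals[-1][1]
            start = cds_start if start is None else min(start, cds_start)
            end = cds_end if end is None else max(end, cds_end)
        return start, end

    @property
    def coding_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    def coding_offset(self, pos0: int) -> int | None:
        """Offset of a 0-based genomic position within the coding sequence
        (5'->3' on the coding strand), or None outside the CDS."""
        offset = 0
        if self.strand == "+":
            for start, end in self.cds_intervals:
                if start <= pos0 < end:
                    return offset + (pos0 - start)
                offset += end - start
        else:
            for start, end in reversed(self.cds_intervals):
                if start <= pos0 < end:
                    return offset + (end - 1 - pos0)
                offset += end - start
        return None

    def coding_sequence(self, genome) -> str:
        from .spectra import revcomp

        parts = [
            genome.slice(self.chromosome, start, end)
            for start, end in self.cds_intervals
        ]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class EffectAnnotation:
    variant_key: tuple
    gene_id: str | None
    category: str
    impact: str
    aa_change: str | None = None


def _classify_coding_snv(variant, gene: GeneModel, genome) -> EffectAnnotation:
    offset = gene.coding_offset(variant.position - 1)
    assert offset is not None
    cds = gene.coding_sequence(genome)
    codon_i, within = divmod(offset, 3)
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    if len(codon) < 3:  # incomplete terminal codon in a truncated model
        return EffectAnnotation(
            variant.key, gene.gene_id, "genic_noncoding", IMPACT["genic_noncoding"]
        )
    ref_coding = (
        variant.ref_allele if gene.strand == "+" else COMPLEMENT[variant.ref_allele]
    )
    alt_coding = (
        variant.alt_allele if gene.strand == "+" else COMPLEMENT[variant.alt_allele]
    )
    if codon[within] != ref_coding:
        raise ValueError(
            f"reference mismatch in {gene.gene_id} at "
            f"{variant.chromosome}:{variant.position}"
        )
    new_codon = codon[:within] + alt_coding + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new_codon).translate())
    if aa_alt == aa_ref:
        category = "synonymous"
    elif aa_alt == "*":
        category = "nonsense"
    else:
        # includes stop-loss, reported as missense (moderate impact)
        category = "missense"
    change = f"{aa_ref}{codon_i + 1}{aa_alt}"
    return EffectAnnotation(
        variant.key, gene.gene_id, category, IMPACT[category], change
    )


def classify_variant_effect(variant, models, genome) -> EffectAnnotation:
    """Classify one variant against a set of gene models.

    SNVs whose reference allele disagrees with the genome raise (guards
    corrupted inputs). When a variant lies in overlapping genes it is
    annotated per gene and the most severe category is reported.
    """
    if variant.var_class == "SNV":
        ref_base = genome.base(variant.chromosome, variant.position)
        if ref_base != variant.ref_allele.upper():
            raise ValueError(
                f"variant ref {variant.ref_allele} disagrees with genome "
                f"{ref_base} at {variant.chromosome}:{variant.position}"
            )
    pos0 = variant.position - 1
    hits = [
        g
        for g in models
        if g.chromosome == variant.chromosome and g.span[0] <= pos0 < g.span[1]
    ]
    if not hits:
        return EffectAnnotation(variant.key, None, "intergenic", IMPACT["intergenic"])

    mito = genome.mito_id is not None and variant.chromosome == genome.mito_id
    best = None
    for gene in hits:
        in_cds = gene.coding_offset(pos0) is not None
        if variant.var_class == "SNV" and in_cds and not mito:
            ann = _classify_coding_snv(variant, gene, genome)
        else:
            ann = EffectAnnotation(
                variant.key, gene.gene_id, "genic_noncoding",
                IMPACT["genic_noncoding"],
            )
        if best is None or _SEVERITY[ann.category] > _SEVERITY[best.category]:
            best = ann
    return best


def annotate_variants(variants, models, genome) -> list[EffectAnnotation]:
    return [classify_variant_effect(v, models, genome) for v in variants]


@dataclass
class EffectFractions:
    """Non-synonymous fraction over coding SNVs and genic fraction over all
    annotated variants, with their denominators. Fractions are None
    (``defined`` False) when the denominator is zero, never silently 0."""

    nonsyn_fraction: float | None
    genic_fraction: float | None
    coding_count: int
    nonsyn_count: int
    genic_count: int
    total: int

    @property
    def defined(self) -> bool:
        return self.nonsyn_fraction is not None and self.genic_fraction is not None


def effect_fractions(annotations) -> EffectFractions:
    annotations = list(annotations)
    total = len(annotations)
    coding = [a for a in annotations if a.category in ("synonymous", "missense", "nonsense")]
    nonsyn = [a for a in coding if a.category in ("missense", "nonsense")]
    genic = [a for a in annotations if a.category != "intergenic"]
    return EffectFractions(
        nonsyn_fraction=len(nonsyn) / len(coding) if coding else None,
        genic_fraction=len(genic) / total if total else None,
        coding_count=len(coding),
        nonsyn_count=len(nonsyn),
        genic_count=len(genic),
        total=total,
    )
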