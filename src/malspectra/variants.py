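"""Variant call records shared by the simulator and the curation stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class VariantCall:
    """One raw or curated call.

    Identity is keyed on (chromosome, position, ref, alt); depth, replicate
    and caller provenance travel alongside but do not affect identity.
    Positions are 1-based (VCF convention).
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    depth: int | None = None
    replicate_id: str = ""
    caller_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        if self.position < 1:
            raise ValueError("positions are 1-based")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")

    @property
    def var_class(self) -> str:
        """SNV iff both alleles are single differing bases, else INDEL."""
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNV"
        return "INDEL"

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


def normalize_indel(call: VariantCall, genome=None) -> VariantCall:
    """Left-normalise an INDEL representation.

    Callers represent the same INDEL with different padding and anchors;
    normalising both sides before intersection makes the
    (chrom, pos, ref, alt) key comparable. Without a reference, shared
    trailing then leading bases are trimmed (parsimony). With ``genome``
    the variant is fully left-aligned: trailing shared bases are trimmed
    and the alleles re-anchored by extending leftwards through the
    reference until the representation is minimal, which canonicalises
    homopolymer/repeat INDELs regardless of the caller's anchor choice.
    SNVs pass through unchanged.
    """
    ref, alt, pos = call.ref_allele, call.alt_allele, call.position
    if len(ref) == 1 and len(alt) == 1:
        return call
    if genome is not None:
        while True:
            if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
                ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos <= 1:
                    break
                base = genome.base(call.chromosome, pos - 1)
                ref, alt = base + ref, base + alt
                pos -= 1
                continue
            if not (ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1)):
                break
    else:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (call.ref_allele, call.alt_allele, call.position):
        return call
    return replace(call, ref_allele=ref, alt_allele=alt, position=pos)


def by_key(calls) -> dict:
    """Index a call iterable by identity key (last call wins on duplicates)."""
    return {c.key: c for c in calls}
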