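"""Reference genome container and toy-genome generation.

A :class:`Genome` is an ordered mapping of chromosome name to sequence with
an optional designated mitochondrial chromosome; positions are 1-based in
the accessors, matching VCF convention.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np


class Genome(Mapping):
    """In-memory reference genome.

    Parameters
    ----------
    sequences
        Mapping of chromosome id to uppercase DNA sequence.
    mito_id
        Name of the mitochondrial chromosome, if present; everything else
        is treated as nuclear.
    """

    def __init__(self, sequences: dict[str, str], mito_id: str | None = None):
        if not sequences:
            raise ValueError("genome has no chromosomes")
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        for name, seq in self._seqs.items():
            if len(seq) == 0:
                raise ValueError(f"zero-length chromosome {name!r}")
        if mito_id is not None and mito_id not in self._seqs:
            raise ValueError(f"mito_id {mito_id!r} not among chromosomes")
        self.mito_id = mito_id
        if not self.nuclear_ids:
            raise ValueError("genome needs at least one nuclear chromosome")

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self):
        return len(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    @property
    def nuclear_ids(self) -> list[str]:
        return [c for c in self._seqs if c != self.mito_id]

    def compartment_length(self, compartment: str = "nuclear") -> int:
        """Total bases in the nuclear or mitochondrial compartment."""
        if compartment == "nuclear":
            return sum(len(self._seqs[c]) for c in self.nuclear_ids)
        if compartment == "mito":
            return len(self._seqs[self.mito_id]) if self.mito_id else 0
        raise ValueError(f"unknown compartment {compartment!r}")

    def base(self, chromosome: str, position: int) -> str:
        """Reference base at a 1-based position."""
        seq = self._seqs[chromosome]
        if not 1 <= position <= len(seq):
            raise IndexError(f"{chromosome}:{position} outside chromosome")
        return seq[position - 1]

    def slice(self, chromosome: str, start: int, end: int) -> str:
        """0-based half-open slice of a chromosome."""
        return self._seqs[chromosome][start:end]

    def trinucleotide(self, chromosome: str, position: int) -> str | None:
        """Trinucleotide centred on a 1-based position, None at chromosome ends."""
        seq = self._seqs[chromosome]
        if position < 2 or position > len(seq) - 1:
            return None
        return seq[position - 2 : position + 1]

    def reverse_complement(self) -> "Genome":
        """Mirror genome with every chromosome reverse-complemented."""
        from .spectra import revcomp

        return Genome(
            {name: revcomp(seq) for name, seq in self._seqs.items()},
            mito_id=self.mito_id,
        )

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path, mito_id: str | None = None) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()}, mito_id=mito_id)


def random_genome(
    lengths: dict[str, int],
    gc: float = 0.38,
    seed: int | np.random.Generator = 0,
    mito_id: str | None = None,
) -> Genome:
    """Random toy genome with a given GC content (yeast-like default 0.38)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for name, length in lengths.items():
        codes = rng.choice(alphabet, size=int(length), p=probs)
        seqs[name] = codes.tobytes().decode("ascii")
    return Genome(seqs, mito_id=mito_id)
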