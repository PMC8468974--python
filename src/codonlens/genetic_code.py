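"""Genetic-code tables, synonymous-family structure, and translation.

Codons are handled internally in the RNA alphabet (``ACGU``); DNA input is
normalized on entry (``T`` -> ``U``).  The standard code (NCBI table 1) is the
default everywhere; other tables can be loaded by id but none of the shipped
analyses use them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, Mapping, Tuple

from Bio.Data import CodonTable

STOP = "*"
RNA_BASES = "ACGU"
#: IUPAC ambiguity letters tolerated by QC (flagged, never counted).
AMBIGUOUS_BASES = frozenset("RYSWKMBDHVN")

ALL_CODONS: Tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(RNA_BASES, repeat=3)
)


class CodonError(ValueError):
    """Invalid codon or nucleotide input."""


class FrameError(CodonError):
    """Sequence length is not a multiple of three."""


class AmbiguityError(CodonError):
    """Ambiguous base encountered under the ``error`` policy."""


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert DNA ``T`` to RNA ``U``."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Convert an internal RNA string back to DNA for output."""
    return seq.upper().replace("U", "T")


def validate_codon(codon: str) -> str:
    """Normalize and validate a single codon; raise :class:`CodonError` if bad."""
    c = normalize_rna(codon)
    if len(c) != 3:
        raise CodonError(f"codon {codon!r} has length {len(c)}, expected 3")
    if any(b not in RNA_BASES for b in c):
        raise CodonError(f"codon {codon!r} contains characters outside ACGU/T")
    return c


def split_codons(seq: str) -> Tuple[str, ...]:
    """Split an in-frame RNA string into consecutive triplets."""
    if len(seq) % 3:
        raise FrameError(f"length {len(seq)} is not a multiple of 3")
    return tuple(seq[i : i + 3] for i in range(0, len(seq), 3))


def codon_gc(codon: str) -> float:
    """G+C fraction of one codon (0, 1/3, 2/3 or 1)."""
    c = validate_codon(codon)
    return sum(b in "GC" for b in c) / 3.0


@dataclass(frozen=True)
class GeneticCode:
    """A translation table plus its synonymous-family partition.

    Attributes
    ----------
    table_id:
        NCBI translation-table number (1 = standard code).
    codon_to_aa:
        Maps each of the 64 RNA codons to a one-letter amino acid or ``"*"``.
    families:
        Partition of the coding codons into synonymous families keyed by
        amino acid; stop codons form the ``"*"`` family kept separately in
        :attr:`stop_codons`.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    families: Mapping[str, FrozenSet[str]]
    stop_codons: FrozenSet[str]

    @classmethod
    def from_table(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_rna_by_id[table_id]
        codon_to_aa: Dict[str, str] = dict(table.forward_table)
        for c in table.stop_codons:
            codon_to_aa[c] = STOP
        if set(codon_to_aa) != set(ALL_CODONS):
            raise CodonError(f"table {table_id} does not cover all 64 codons")
        fams: Dict[str, set] = {}
        for codon, aa in codon_to_aa.items():
            if aa != STOP:
                fams.setdefault(aa, set()).add(codon)
        families = {aa: frozenset(cs) for aa, cs in fams.items()}
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            families=families,
            stop_codons=frozenset(table.stop_codons),
        )

    @property
    def coding_codons(self) -> Tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c not in self.stop_codons)

    def aa_of(self, codon: str) -> str:
        return self.codon_to_aa[validate_codon(codon)]

    def family_of(self, codon: str) -> FrozenSet[str]:
        """All codons encoding the same amino acid as ``codon`` (incl. itself).

        Stop codons return the full stop family.
        """
        c = validate_codon(codon)
        aa = self.codon_to_aa[c]
        if aa == STOP:
            return self.stop_codons
        return self.families[aa]

    def degenerate_amino_acids(self) -> Tuple[str, ...]:
        """Amino acids with more than one codon, sorted (18 in the standard code)."""
        return tuple(sorted(aa for aa, f in self.families.items() if len(f) > 1))

    def translate(self, cds: str, ambiguous: str = "error") -> str:
        """Translate an in-frame nucleotide string to amino acids.

        Stop codons render as ``"*"`` wherever they occur; use
        :meth:`internal_stop_positions` to locate premature ones.  Codons
        containing IUPAC ambiguity letters raise :class:`AmbiguityError`
        under ``ambiguous="error"`` or are dropped under ``"skip"``.
        """
        if ambiguous not in ("error", "skip"):
            raise ValueError(f"unknown ambiguity policy {ambiguous!r}")
        seq = normalize_rna(cds)
        out = []
        for i, codon in enumerate(split_codons(seq)):
            if any(b not in RNA_BASES for b in codon):
                if ambiguous == "error":
                    raise AmbiguityError(
                        f"ambiguous codon {codon!r} at codon position {i}"
                    )
                continue
            out.append(self.codon_to_aa[codon])
        return "".join(out)

    def internal_stop_positions(self, cds: str) -> Tuple[int, ...]:
        """Codon indices (0-based) of stop codons before the final codon."""
        codons = split_codons(normalize_rna(cds))
        return tuple(
            i for i, c in enumerate(codons[:-1]) if self.codon_to_aa.get(c) == STOP
        )


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard genetic code (NCBI table 1), cached."""
    return GeneticCode.from_table(1)
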