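"""Genetic-code binding.

Thin wrapper over Biopython's NCBI translation tables.  The default for
anthozoan mitochondrial data is table 4 (mold/protozoan/coelenterate
mitochondrial), under which TGA encodes tryptophan; the table id is a
required, logged configuration field wherever codon data enter the
pipeline because the choice changes both translation and the synonymous
family structure used by codon-usage statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

STOP = "*"
NUCLEOTIDES = "ACGT"

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table with precomputed codon partitions."""

    table_id: int
    codon_to_aa: dict[str, str] = field(repr=False)
    sense_codons: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map exactly 64 codons")
        for codon in self.sense_codons:
            if self.codon_to_aa[codon] == STOP:
                raise ValueError(f"stop codon {codon} listed as sense")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == STOP)

    def translate_codon(self, codon: str) -> str:
        """One-letter amino acid, or '*' for a stop codon."""
        return self.codon_to_aa[codon.upper()]

    def synonymous_families(self) -> dict[str, tuple[str, ...]]:
        """Amino acid -> its sense codons, ordered."""
        fams: dict[str, list[str]] = {}
        for codon in self.sense_codons:
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        return {aa: tuple(cods) for aa, cods in fams.items()}


def get_code(table_id: int = 4) -> GeneticCode:
    """Load an NCBI translation table (default 4, coelenterate mitochondrial)."""
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise ValueError(f"no NCBI translation table with id {table_id}") from exc
    codon_to_aa = {c: table.forward_table.get(c, STOP) for c in ALL_CODONS}
    sense = tuple(c for c in ALL_CODONS if codon_to_aa[c] != STOP)
    return GeneticCode(table_id=table_id, codon_to_aa=codon_to_aa, sense_codons=sense)
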