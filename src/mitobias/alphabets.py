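"""Symbol alphabets shared across the package.

Five alphabets are used throughout: plain nucleotides (``nt4``), the 20
amino acids (``aa20``), purine/pyrimidine recoded nucleotides (``ry2``),
the six-class amino-acid reduction (``aa6``) and the four-class reduction
(``aa4``).  The aa4 states are deliberately labelled A, T, G and C so that
four-state nucleotide machinery (GTR and friends) applies unchanged.
"""

from __future__ import annotations

GAP = "-"
MISSING = "?"

ALPHABETS: dict[str, str] = {
    "nt4": "ACGT",
    "aa20": "ARNDCQEGHILKMFPSTWYV",
    "ry2": "RY",
    "aa6": "123456",
    "aa4": "ATGC",
}

#: Amino acids encoded by A+T-rich codons (Phe, Tyr, Met, Ile, Asn, Lys).
FYMINK = "FYMINK"
#: Amino acids encoded by G+C-rich codons (Gly, Ala, Arg, Pro).
GARP = "GARP"


def resolve(name: str) -> str:
    """Return the symbol string for an alphabet name (case-insensitive)."""
    key = name.lower()
    if key not in ALPHABETS:
        raise ValueError(f"unknown alphabet {name!r}; choose from {sorted(ALPHABETS)}")
    return ALPHABETS[key]


def symbol_index(name: str) -> dict[str, int]:
    """Mapping symbol -> state index for an alphabet."""
    return {s: i for i, s in enumerate(resolve(name))}
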