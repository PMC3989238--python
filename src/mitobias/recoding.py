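"""Alphabet reductions and residue masking.

The reductions implemented here target compositional bias: RY coding
collapses nucleotides to purine/pyrimidine, neutralising within-class
(A<->G, C<->T) frequency differences; the six-class and four-class
amino-acid recodings pool residues that commonly replace one another; and
residue masking removes the signal carried by individual composition-
sensitive amino acids (e.g. Phe, Ala, Thr, Tyr).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .alphabets import GAP, MISSING, resolve
from .seq_data import Alignment, CodonAlignment


@dataclass(frozen=True)
class RecodingScheme:
    name: str
    symbol_map: dict[str, str]
    target_alphabet: str

    def apply(self, alignment: Alignment) -> Alignment:
        table = dict(self.symbol_map)
        table.setdefault(GAP, GAP)
        table.setdefault(MISSING, MISSING)
        missing_src = set(resolve(alignment.alphabet)) - set(self.symbol_map)
        if missing_src:
            raise ValueError(f"scheme {self.name!r} leaves {sorted(missing_src)} unmapped")
        out = np.empty_like(alignment.data)
        for src, dst in table.items():
            out[alignment.data == src] = dst
        return Alignment(alignment.taxon_ids, out, self.target_alphabet)


RY_SCHEME = RecodingScheme(
    "ry", {"A": "R", "G": "R", "C": "Y", "T": "Y"}, "ry2"
)

# Six classes of amino acids that usually replace one another:
# MVIL -> 1, FYW -> 2, ASTGP -> 3, DNEQ -> 4, RKH -> 5, C -> 6.
_AA6_CLASSES = {"1": "MVIL", "2": "FYW", "3": "ASTGP", "4": "DNEQ", "5": "RKH", "6": "C"}
AA6_SCHEME = RecodingScheme(
    "aa6",
    {aa: cls for cls, aas in _AA6_CLASSES.items() for aa in aas},
    "aa6",
)

# Four classes (aromatic+hydrophobic pooled, Cys treated as missing),
# labelled A/T/G/C so nucleotide GTR machinery applies unchanged.
_AA4_CLASSES = {"A": "FYWMVIL", "T": "ASTGP", "G": "DNEQ", "C": "RKH"}
AA4_SCHEME = RecodingScheme(
    "aa4",
    {**{aa: cls for cls, aas in _AA4_CLASSES.items() for aa in aas}, "C": MISSING},
    "aa4",
)


def ry_recode(nt_alignment: Alignment) -> Alignment:
    """Recode A,G -> R and C,T -> Y; gaps and missing are preserved."""
    if nt_alignment.alphabet != "nt4":
        raise ValueError("RY recoding requires an nt4 alignment")
    return RY_SCHEME.apply(nt_alignment)


def aa6_recode(aa_alignment: Alignment) -> Alignment:
    """Six-class amino-acid recoding (states '1'..'6')."""
    if aa_alignment.alphabet != "aa20":
        raise ValueError("aa6 recoding requires an aa20 alignment")
    return AA6_SCHEME.apply(aa_alignment)


def aa4_recode(aa_alignment: Alignment) -> Alignment:
    """Four-class recoding; cysteine becomes missing data."""
    if aa_alignment.alphabet != "aa20":
        raise ValueError("aa4 recoding requires an aa20 alignment")
    return AA4_SCHEME.apply(aa_alignment)


def drop_codon_positions(
    codon_alignment: CodonAlignment, drop_set: Iterable[int]
) -> Alignment:
    """Remove all columns at the given codon positions (subset of {1,2,3}).

    Returns a plain nt4 alignment (the result is generally out of frame).
    """
    drop = set(drop_set)
    if not drop <= {1, 2, 3}:
        raise ValueError("drop_set must be a subset of {1, 2, 3}")
    keep_pattern = [p not in drop for p in (1, 2, 3)]
    keep = np.tile(keep_pattern, codon_alignment.n_codons)
    return Alignment(
        codon_alignment.taxon_ids,
        codon_alignment.data[:, keep],
        "nt4",
    )


def mask_residues(
    aa_alignment: Alignment, residues: Iterable[str], mode: str = "mask"
) -> Alignment:
    """Exclude the listed residues from an amino-acid alignment.

    ``mode='mask'`` (default) replaces each occurrence with '?', keeping
    the column structure; ``mode='drop_columns'`` removes every column in
    which any taxon carries one of the residues, a far more destructive
    variant kept for sensitivity analysis.
    """
    residues = set(r.upper() for r in residues)
    if not residues <= set(resolve("aa20")):
        raise ValueError("residues must be one-letter amino acids")
    hit = np.isin(aa_alignment.data, sorted(residues))
    if mode == "mask":
        out = aa_alignment.data.copy()
        out[hit] = MISSING
        return Alignment(aa_alignment.taxon_ids, out, "aa20")
    if mode == "drop_columns":
        keep = ~hit.any(axis=0)
        return aa_alignment.take_columns(np.nonzero(keep)[0])
    raise ValueError("mode must be 'mask' or 'drop_columns'")
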