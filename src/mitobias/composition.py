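"""Nucleotide and amino-acid composition statistics.

Per-taxon composition is computed on protein-coding sequence on the
annotated coding strand.  The statistics here are the ones that diagnose
the "Robust"-coral style bias: per-codon-position base frequencies, AT/GC
content and skews, the FYMINK/GARP amino-acid ratio (A+T-rich versus
G+C-rich residues), Wright's effective number of codons (NC) and the
codon adaptation index (CAI).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabets import FYMINK, GAP, GARP, MISSING, resolve
from .codes import ALL_CODONS, GeneticCode
from .seq_data import Alignment, CodonAlignment, translate

logger = logging.getLogger(__name__)

NT_ORDER = "ACGT"
AA_ORDER = resolve("aa20")


def nt_composition(
    codon_alignment: CodonAlignment, taxon: str, position_set: Iterable[int] = (1, 2, 3)
) -> np.ndarray:
    """(A, C, G, T) proportions over the selected codon positions of one row.

    Gaps and missing symbols are excluded from the denominator.
    """
    positions = set(position_set)
    if not positions or not positions <= {1, 2, 3}:
        raise ValueError("position_set must be a nonempty subset of {1, 2, 3}")
    row = codon_alignment.data[codon_alignment.taxon_ids.index(taxon)]
    mask = np.tile([p in positions for p in (1, 2, 3)], codon_alignment.n_codons)
    sub = row[mask]
    counts = np.array([(sub == b).sum() for b in NT_ORDER], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no countable symbols for taxon {taxon!r}")
    return counts / total


def skews(freq_vector: Sequence[float]) -> tuple[float, float]:
    """AT skew (A-T)/(A+T) and GC skew (G-C)/(G+C) from (A,C,G,T) proportions.

    A zero denominator yields NaN rather than an error.
    """
    a, c, g, t = freq_vector
    at = (a - t) / (a + t) if (a + t) > 0 else math.nan
    gc = (g - c) / (g + c) if (g + c) > 0 else math.nan
    return at, gc


def aa_frequencies(aa_alignment: Alignment, taxon: str) -> np.ndarray:
    """20-vector of residue proportions (gaps/missing excluded)."""
    row = aa_alignment.data[aa_alignment.taxon_ids.index(taxon)]
    counts = np.array([(row == a).sum() for a in AA_ORDER], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no countable residues for taxon {taxon!r}")
    return counts / total


def fymink_garp(aa_freqs: Sequence[float]) -> tuple[float, float, float]:
    """FYMINK and GARP proportions and their ratio (NaN when GARP is 0)."""
    freqs = {aa: aa_freqs[i] for i, aa in enumerate(AA_ORDER)}
    fy = sum(freqs[a] for a in FYMINK)
    ga = sum(freqs[a] for a in GARP)
    ratio = fy / ga if ga > 0 else math.nan
    return fy, ga, ratio


# ----------------------------------------------------------------------
# Codon usage
# ----------------------------------------------------------------------

def codon_counts(codon_alignment: CodonAlignment, taxon: str) -> dict[str, int]:
    """Counts of complete (gap-free) codons in one row, over all 64 codons."""
    i = codon_alignment.taxon_ids.index(taxon)
    row = codon_alignment.data[i]
    counts = dict.fromkeys(ALL_CODONS, 0)
    for c in range(codon_alignment.n_codons):
        codon = "".join(row[3 * c : 3 * c + 3])
        if GAP in codon or MISSING in codon:
            continue
        counts[codon] += 1
    return counts


def effective_number_of_codons(
    counts: Mapping[str, int], code: GeneticCode
) -> float:
    """Wright's NC computed from the bound code's synonymous families.

    For each family the codon homozygosity is F-hat = (n*sum(p^2) - 1)/(n - 1);
    families are grouped into size classes derived from the code (so table 4's
    two-codon Trp family is handled correctly), and NC = sum over classes of
    K_s / Fbar_s with K_s the number of families of size s.  A size class
    with no estimable family borrows the mean of the nearest available
    classes (Wright's averaging fallback, logged).  The result is clipped
    to [20, number of sense codons].
    """
    families = code.synonymous_families()
    total = sum(counts.get(c, 0) for c in code.sense_codons)
    if total == 0:
        raise ValueError("all codon counts are zero")
    size_classes: dict[int, list[float]] = {}
    class_sizes: dict[int, int] = {}
    for aa, fam in families.items():
        s = len(fam)
        class_sizes[s] = class_sizes.get(s, 0) + 1
        if s == 1:
            continue
        n = sum(counts.get(c, 0) for c in fam)
        if n < 2:
            continue
        p = np.array([counts.get(c, 0) / n for c in fam])
        f_hat = (n * float((p**2).sum()) - 1.0) / (n - 1.0)
        if f_hat > 0:
            size_classes.setdefault(s, []).append(f_hat)
    means = {s: float(np.mean(v)) for s, v in size_classes.items() if v}
    nc = 0.0
    for s, k_s in sorted(class_sizes.items()):
        if s == 1:
            nc += k_s  # single-codon families have F = 1 identically
            continue
        if s in means:
            fbar = means[s]
        else:
            lower = [t for t in means if t < s]
            upper = [t for t in means if t > s]
            neighbours = ([means[max(lower)]] if lower else []) + (
                [means[min(upper)]] if upper else []
            )
            if not neighbours:
                raise ValueError("no estimable synonymous family in any size class")
            fbar = float(np.mean(neighbours))
            logger.info(
                "NC: size class %d has no estimable family; using neighbour mean %.4f",
                s,
                fbar,
            )
        nc += k_s / fbar
    return float(np.clip(nc, 20.0, len(code.sense_codons)))


def reference_weights(
    counts: Mapping[str, int], code: GeneticCode, floor: float = 0.01
) -> dict[str, float]:
    """Relative adaptiveness w = count / max-count within each family.

    Codons unobserved in the reference usage are floored at 0.01 so the
    geometric mean stays finite.
    """
    weights: dict[str, float] = {}
    for fam in code.synonymous_families().values():
        mx = max(counts.get(c, 0) for c in fam)
        for c in fam:
            w = counts.get(c, 0) / mx if mx > 0 else 1.0
            weights[c] = max(w, floor)
    return weights


def codon_adaptation_index(
    counts: Mapping[str, int], weights: Mapping[str, float], code: GeneticCode
) -> float:
    """CAI: count-weighted geometric mean of relative adaptiveness.

    Only codons of multi-codon families are eligible (single-codon families
    carry no usage information).
    """
    log_sum = 0.0
    n = 0
    for aa, fam in code.synonymous_families().items():
        if len(fam) < 2:
            continue
        for c in fam:
            k = counts.get(c, 0)
            if k == 0:
                continue
            w = weights[c]
            if not 0 < w <= 1:
                raise ValueError(f"weight for {c} must be in (0, 1], got {w}")
            log_sum += k * math.log(w)
            n += k
    if n == 0:
        raise ValueError("no codons from multi-codon families observed")
    return math.exp(log_sum / n)


# ----------------------------------------------------------------------
# Profiles and group summaries
# ----------------------------------------------------------------------

@dataclass
class CompositionProfile:
    """Per-taxon composition summary over protein-coding sequence."""

    taxon_id: str
    freq_by_position: dict[str, np.ndarray]  # keys '1','2','3','all'; (A,C,G,T)
    at_content: float
    gc_content: float
    at_skew: float
    gc_skew: float
    aa_freqs: np.ndarray
    fymink: float
    garp: float
    fymink_garp_ratio: float

    def as_series(self) -> pd.Series:
        d = {
            "taxon": self.taxon_id,
            "at_content": self.at_content,
            "gc_content": self.gc_content,
            "at_skew": self.at_skew,
            "gc_skew": self.gc_skew,
            "fymink": self.fymink,
            "garp": self.garp,
            "fymink_garp_ratio": self.fymink_garp_ratio,
        }
        for pos, vec in self.freq_by_position.items():
            for base, v in zip(NT_ORDER, vec):
                d[f"{base}{pos}"] = v
        return pd.Series(d)


def composition_profile(
    codon_alignment: CodonAlignment, taxon: str, aa_alignment: Alignment | None = None
) -> CompositionProfile:
    """Build the full per-taxon profile; translates on the fly if needed."""
    freq_by_position = {
        "1": nt_composition(codon_alignment, taxon, {1}),
        "2": nt_composition(codon_alignment, taxon, {2}),
        "3": nt_composition(codon_alignment, taxon, {3}),
        "all": nt_composition(codon_alignment, taxon, {1, 2, 3}),
    }
    overall = freq_by_position["all"]
    at = float(overall[0] + overall[3])
    at_skew, gc_skew = skews(overall)
    if aa_alignment is None:
        aa_alignment = translate(codon_alignment)
    aaf = aa_frequencies(aa_alignment, taxon)
    fy, ga, ratio = fymink_garp(aaf)
    return CompositionProfile(
        taxon_id=taxon,
        freq_by_position=freq_by_position,
        at_content=at,
        gc_content=1.0 - at,
        at_skew=at_skew,
        gc_skew=gc_skew,
        aa_freqs=aaf,
        fymink=fy,
        garp=ga,
        fymink_garp_ratio=ratio,
    )


def profiles_table(profiles: Sequence[CompositionProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.as_series() for p in profiles]).set_index("taxon")


def group_summary(
    profiles: Sequence[CompositionProfile], group_map: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic mean of each per-taxon statistic within groups.

    Ratios are averaged per taxon (a mean of ratios), matching summaries
    reported as averages across species rather than statistics of pooled
    counts.
    """
    unmapped = [p.taxon_id for p in profiles if p.taxon_id not in group_map]
    if unmapped:
        raise ValueError(f"taxa missing from group map: {unmapped}")
    table = profiles_table(profiles)
    table["group"] = [group_map[t] for t in table.index]
    return table.groupby("group").mean(numeric_only=True)
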