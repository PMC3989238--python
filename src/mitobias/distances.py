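"""Composition-based and composition-robust distances, trees and quartets.

Two complementary distances are provided.  The base-frequencies (BF)
distance between two taxa is half the summed absolute differences of
their symbol-frequency vectors (the total-variation distance), so trees
built from it reflect composition alone.  The LogDet/paralinear distance
is consistent under the general (non-stationary, non-homogeneous) Markov
model and therefore robust to exactly the compositional heterogeneity
that the BF trees are designed to expose.

Note: the BF formula is sometimes printed without absolute-value bars,
in which case it is identically zero for frequency vectors; the
absolute-value (half-L1) form of Phillips et al. is what is implemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .alphabets import GAP, MISSING, resolve
from .seq_data import Alignment
from .treeutils import floor_negative_lengths, from_newick


@dataclass
class DistanceMatrix:
    taxon_ids: list[str]
    values: np.ndarray
    flags: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxon_ids), len(self.taxon_ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.nan_to_num(v, posinf=1.0), np.nan_to_num(v.T, posinf=1.0)):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.taxon_ids.index(a), self.taxon_ids.index(b)]
        )

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxon_ids)}\n")
            for i, t in enumerate(self.taxon_ids):
                row = " ".join(f"{x:.6f}" for x in self.values[i])
                fh.write(f"{t}  {row}\n")


def bf_distance(profile_i: Sequence[float], profile_j: Sequence[float]) -> float:
    """Half the L1 distance between two frequency vectors."""
    p = np.asarray(profile_i, dtype=float)
    q = np.asarray(profile_j, dtype=float)
    if p.shape != q.shape:
        raise ValueError("mismatched frequency-vector alphabets")
    return float(np.abs(p - q).sum() / 2.0)


def bf_distance_matrix(profiles: Mapping[str, Sequence[float]]) -> DistanceMatrix:
    """Pairwise BF distances; works for nucleotide and amino-acid vectors."""
    taxa = list(profiles)
    if len(taxa) < 3:
        raise ValueError("need at least 3 profiles for a distance tree")
    n = len(taxa)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = bf_distance(profiles[taxa[i]], profiles[taxa[j]])
    return DistanceMatrix(taxa, vals)


def logdet_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Pairwise LogDet (paralinear) distances.

    For each pair the joint proportion matrix J over shared non-missing
    columns gives d = -(1/k) [ln det J - 0.5 * sum_i ln(f_i g_i)], with f
    and g the marginal frequencies.  Pairs with a singular joint matrix
    are flagged infinite; pairs with fewer than k shared columns are
    flagged undefined (NaN).
    """
    symbols = resolve(alignment.alphabet)
    k = len(symbols)
    index = {s: i for i, s in enumerate(symbols)}
    enc = np.array(
        [[index.get(ch, -1) for ch in alignment.data[i]] for i in range(alignment.n_taxa)],
        dtype=np.int32,
    )
    taxa = alignment.taxon_ids
    n = len(taxa)
    vals = np.zeros((n, n))
    flags: dict[tuple[str, str], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            shared = (enc[i] >= 0) & (enc[j] >= 0)
            m = int(shared.sum())
            if m < k:
                vals[i, j] = vals[j, i] = np.nan
                flags[(taxa[i], taxa[j])] = "undefined"
                continue
            J = np.zeros((k, k))
            np.add.at(J, (enc[i][shared], enc[j][shared]), 1.0)
            J /= m
            f = J.sum(axis=1)
            g = J.sum(axis=0)
            sign, logdet = np.linalg.slogdet(J)
            if sign <= 0 or (f <= 0).any() or (g <= 0).any():
                vals[i, j] = vals[j, i] = np.inf
                flags[(taxa[i], taxa[j])] = "singular"
                continue
            d = -(logdet - 0.5 * (np.log(f).sum() + np.log(g).sum())) / k
            vals[i, j] = vals[j, i] = max(d, 0.0)
    return DistanceMatrix(taxa, vals, flags)


def jc_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Jukes-Cantor-corrected distances (stationarity-assuming baseline)."""
    symbols = resolve(alignment.alphabet)
    k = len(symbols)
    index = {s: i for i, s in enumerate(symbols)}
    enc = np.array(
        [[index.get(ch, -1) for ch in alignment.data[i]] for i in range(alignment.n_taxa)],
        dtype=np.int32,
    )
    taxa = alignment.taxon_ids
    n = len(taxa)
    vals = np.zeros((n, n))
    flags: dict[tuple[str, str], str] = {}
    b = (k - 1) / k
    for i in range(n):
        for j in range(i + 1, n):
            shared = (enc[i] >= 0) & (enc[j] >= 0)
            m = int(shared.sum())
            if m == 0:
                vals[i, j] = vals[j, i] = np.nan
                flags[(taxa[i], taxa[j])] = "undefined"
                continue
            p = float((enc[i][shared] != enc[j][shared]).mean())
            if p >= b:
                vals[i, j] = vals[j, i] = np.inf
                flags[(taxa[i], taxa[j])] = "saturated"
                continue
            vals[i, j] = vals[j, i] = -b * np.log(1 - p / b)
    return DistanceMatrix(taxa, vals, flags)


def ml_distance_matrix(alignment: Alignment, model) -> DistanceMatrix:
    """Pairwise maximum-likelihood distances under a reversible model.

    For each pair the site data reduce to a symbol-pair count matrix N;
    lnL(t) = sum_ij N_ij log(pi_i P_ij(t)) is maximised by bounded Brent.
    Mixture (gamma/invariant) categories are averaged into P. Saturated
    pairs simply hit the upper bound instead of diverging, which makes
    these distances a robust initialiser for branch-length fitting.
    """
    from scipy.optimize import minimize_scalar

    symbols = resolve(alignment.alphabet)
    k = len(symbols)
    index = {s: i for i, s in enumerate(symbols)}
    enc = np.array(
        [[index.get(ch, -1) for ch in alignment.data[i]] for i in range(alignment.n_taxa)],
        dtype=np.int32,
    )
    taxa = alignment.taxon_ids
    n = len(taxa)
    rates, weights, p_inv = model.mixture()
    if p_inv > 0:
        rates = np.concatenate([rates, [0.0]])
        weights = np.concatenate([weights, [p_inv]])
    log_pi = np.log(np.maximum(model.equilibrium_freqs, 1e-300))
    vals = np.zeros((n, n))
    flags: dict[tuple[str, str], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            shared = (enc[i] >= 0) & (enc[j] >= 0)
            if not shared.any():
                vals[i, j] = vals[j, i] = np.nan
                flags[(taxa[i], taxa[j])] = "undefined"
                continue
            N = np.zeros((k, k))
            np.add.at(N, (enc[i][shared], enc[j][shared]), 1.0)

            def neg(t):
                P = model.transition_matrices(t, rates)
                P_mix = np.tensordot(weights, P, axes=1)
                return -float(
                    (N * (log_pi[:, None] + np.log(np.maximum(P_mix, 1e-300)))).sum()
                )

            res = minimize_scalar(
                neg, bounds=(1e-8, 10.0), method="bounded",
                options={"xatol": 1e-5, "maxiter": 40},
            )
            vals[i, j] = vals[j, i] = float(res.x)
    return DistanceMatrix(taxa, vals, flags)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """NJ tree (the standard minimum-evolution heuristic).

    Negative branch lengths are floored at zero.  Requires finite entries.
    """
    import skbio

    if len(dm.taxon_ids) < 3:
        raise ValueError("need at least 3 taxa")
    if not np.isfinite(dm.values).all():
        bad = [p for p, f in dm.flags.items()]
        raise ValueError(f"non-finite distances for pairs: {bad}")
    import io

    sk = skbio.DistanceMatrix(dm.values, ids=dm.taxon_ids)
    buf = io.StringIO()
    skbio.tree.nj(sk).write(buf)
    tree = from_newick(buf.getvalue())
    floor_negative_lengths(tree)
    return tree


# ----------------------------------------------------------------------
# Quartet analyses
# ----------------------------------------------------------------------

@dataclass
class QuartetTally:
    """Counts of the three unrooted groupings over sampled quartets.

    Pattern keys name the pair grouped with the first sampled group, e.g.
    for groups (a, b, c, d): 'ab|cd', 'ac|bd', 'ad|bc', plus 'unresolved'.
    """

    n_quartets: int
    counts: dict[str, int]

    @property
    def proportions(self) -> dict[str, float]:
        if self.n_quartets == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.n_quartets for k, v in self.counts.items()}


def sample_quartets(
    group_map: Mapping[str, str],
    pattern: Sequence[str],
    n: int,
    seed: int,
) -> list[tuple[str, ...]]:
    """Draw n quartets uniformly with replacement, one taxon per group."""
    if len(pattern) != 4:
        raise ValueError("pattern must name exactly 4 groups")
    pools = {}
    for g in pattern:
        pool = sorted(t for t, grp in group_map.items() if grp == g)
        if not pool:
            raise ValueError(f"group {g!r} has no taxa")
        pools[g] = pool
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(tuple(pools[g][rng.integers(len(pools[g]))] for g in pattern))
    return out


def _quartet_keys(pattern: Sequence[str]) -> list[str]:
    a, b, c, d = pattern
    return [f"{a},{b}|{c},{d}", f"{a},{c}|{b},{d}", f"{a},{d}|{b},{c}"]


def _distance_quartet_grouping(d: np.ndarray) -> int:
    """Four-point condition: index of the best grouping, -1 on ties.

    d is the 4x4 distance matrix in pattern order (a,b,c,d); groupings are
    ab|cd, ac|bd, ad|bc.
    """
    sums = np.array(
        [d[0, 1] + d[2, 3], d[0, 2] + d[1, 3], d[0, 3] + d[1, 2]]
    )
    best = sums.min()
    winners = np.nonzero(np.isclose(sums, best, rtol=0, atol=1e-12))[0]
    return int(winners[0]) if len(winners) == 1 else -1


def _ml_quartet_grouping(sub: Alignment, model_alphabet: str) -> int:
    """Best of the 3 unrooted quartet topologies by maximised likelihood."""
    from .likelihood import PruningEngine, empirical_frequencies, gtr_model

    t = sub.taxon_ids
    model = gtr_model(sub.alphabet, freqs=empirical_frequencies(sub, pseudocount=0.5))
    tops = [
        f"(({t[0]},{t[1]}),({t[2]},{t[3]}));",
        f"(({t[0]},{t[2]}),({t[1]},{t[3]}));",
        f"(({t[0]},{t[3]}),({t[1]},{t[2]}));",
    ]
    scores = []
    for nwk in tops:
        tree = from_newick(nwk)
        for e in tree.preorder_edge_iter():
            if e.length is None:
                e.length = 0.1
        eng = PruningEngine(sub, tree, model)
        scores.append(eng.optimize_branch_lengths(max_sweeps=2, maxiter=16))
    scores = np.array(scores)
    best = scores.max()
    winners = np.nonzero(np.isclose(scores, best, rtol=0, atol=1e-6))[0]
    return int(winners[0]) if len(winners) == 1 else -1


def tally_quartet_topologies(
    alignment: Alignment,
    quartets: Sequence[tuple[str, ...]],
    method: str = "logdet_nj",
    pattern: Sequence[str] = ("a", "b", "c", "d"),
) -> QuartetTally:
    """Tally the supported grouping for each sampled quartet.

    ``method``: 'logdet_nj' (four-point condition on LogDet distances),
    'jc_nj' (same on Jukes-Cantor distances) or 'ml_gtr' (maximised
    likelihood over the three topologies).  Ties and undefined distances
    count as unresolved.
    """
    keys = _quartet_keys(pattern)
    counts = {k: 0 for k in keys}
    counts["unresolved"] = 0
    for quartet in quartets:
        rows = [alignment.row(t) for t in quartet]
        sub = Alignment([f"q{i}" for i in range(4)], rows, alignment.alphabet)
        if method in ("logdet_nj", "jc_nj"):
            dm = (
                logdet_distance_matrix(sub)
                if method == "logdet_nj"
                else jc_distance_matrix(sub)
            )
            if not np.isfinite(dm.values).all():
                counts["unresolved"] += 1
                continue
            g = _distance_quartet_grouping(dm.values)
        elif method == "ml_gtr":
            g = _ml_quartet_grouping(sub, sub.alphabet)
        else:
            raise ValueError(f"unknown quartet method {method!r}")
        if g < 0:
            counts["unresolved"] += 1
        else:
            counts[keys[g]] += 1
    return QuartetTally(n_quartets=len(quartets), counts=counts)
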