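"""Topology comparison (RELL-based KH and SH tests) and the Goldman
goodness-of-fit test.

The KH and SH tests resample per-site log-likelihood vectors (RELL) to
ask whether the likelihood difference between competing topologies
exceeds what resampling noise would produce.  The Goldman (Cox) test asks
an absolute question instead: it compares the fitted model's likelihood
against the unconstrained multinomial likelihood of the site-pattern
frequencies, calibrating the gap by parametric bootstrap under the
fitted model.  All Monte Carlo p-values use the add-one convention
(1 + hits) / (1 + n) and are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .likelihood import (
    PruningEngine,
    SiteLogLikelihoods,
    SubstitutionModel,
    simulate_under_model,
)
from .seq_data import Alignment


def unconstrained_log_likelihood(alignment: Alignment) -> float:
    """Best-possible lnL: sum over patterns p of n_p * ln(n_p / N)."""
    if alignment.n_columns == 0:
        raise ValueError("empty alignment")
    _, counts = np.unique(alignment.data, axis=1, return_counts=True)
    n = counts.astype(float)
    total = n.sum()
    return float((n * (np.log(n) - np.log(total))).sum())


def rell_bootstrap(
    site_lnl_set: Sequence[np.ndarray], b: int, seed: int
) -> np.ndarray:
    """RELL replicate totals, shape (B, n_topologies).

    Resamples site indices with replacement; all topologies share each
    replicate's index draw.
    """
    mat = np.asarray([np.asarray(v, dtype=float) for v in site_lnl_set])
    if mat.ndim != 2:
        raise ValueError("site lnL vectors must share a common length")
    n_top, n_sites = mat.shape
    rng = np.random.default_rng(seed)
    out = np.empty((b, n_top))
    for r in range(b):
        idx = rng.integers(0, n_sites, size=n_sites)
        out[r] = mat[:, idx].sum(axis=1)
    return out


def kh_test(
    site_lnl_a: np.ndarray, site_lnl_b: np.ndarray, b: int = 10000, seed: int = 0
) -> float:
    """Two-sided Kishino-Hasegawa p-value from the centred RELL distribution."""
    a = np.asarray(site_lnl_a, dtype=float)
    bb = np.asarray(site_lnl_b, dtype=float)
    if a.shape != bb.shape:
        raise ValueError("site lnL vectors must have equal length")
    d = a - bb
    observed = d.sum()
    reps = rell_bootstrap([d], b, seed)[:, 0]
    centred = reps - reps.mean()
    return float((np.abs(centred) >= abs(observed)).mean())


def sh_test(
    site_lnl_set: Sequence[np.ndarray], b: int = 10000, seed: int = 0
) -> np.ndarray:
    """Shimodaira-Hasegawa p-value per topology (centred across the set)."""
    mat = np.asarray([np.asarray(v, dtype=float) for v in site_lnl_set])
    if mat.shape[0] < 2:
        raise ValueError("SH test needs at least 2 topologies")
    totals = mat.sum(axis=1)
    delta_obs = totals.max() - totals
    reps = rell_bootstrap(list(mat), b, seed)  # (B, T)
    centred = reps - reps.mean(axis=0, keepdims=True)
    delta_rep = centred.max(axis=1, keepdims=True) - centred  # (B, T)
    return (delta_rep >= delta_obs[None, :]).mean(axis=0)


@dataclass
class TopologyComparison:
    topology_ids: list[str]
    totals: np.ndarray
    kh_p: dict[tuple[str, str], float]
    sh_p: dict[str, float]
    b: int
    seed: int


def compare_topologies(
    site_lnl_set: Sequence[SiteLogLikelihoods], b: int = 10000, seed: int = 0
) -> TopologyComparison:
    """KH (all pairs) and SH (across the set) from per-site lnL vectors."""
    ids = [s.topology_id or f"t{i}" for i, s in enumerate(site_lnl_set)]
    vecs = [s.values for s in site_lnl_set]
    kh = {}
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            kh[(ids[i], ids[j])] = kh_test(vecs[i], vecs[j], b=b, seed=seed)
    sh = dict(zip(ids, sh_test(vecs, b=b, seed=seed)))
    return TopologyComparison(
        topology_ids=ids,
        totals=np.array([v.sum() for v in vecs]),
        kh_p=kh,
        sh_p=sh,
        b=b,
        seed=seed,
    )


@dataclass
class GoldmanResult:
    delta: float
    n_sim: int
    p_value: float
    seed: int
    delta_null: np.ndarray


def _refit_delta(
    alignment: Alignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    refit: str,
    bl_sweeps: int,
    brent_maxiter: int = 10,
) -> tuple[float, SubstitutionModel, dendropy.Tree]:
    """Fit (branch lengths, optionally alpha) and return delta = L_uncon - L_model.

    The optimisation budget is deliberately bounded; the Goldman test
    applies this exact schedule to the observed data and to every
    simulated replicate, so the test statistic is well defined even
    short of full convergence.
    """
    from dataclasses import replace
    from scipy.optimize import minimize_scalar

    eng = PruningEngine(alignment, tree, model)
    lnl = eng.optimize_branch_lengths(
        max_sweeps=bl_sweeps, maxiter=brent_maxiter, xatol=1e-4
    )
    if refit == "bl+alpha" and model.gamma_shape is not None:
        def neg(log_alpha):
            eng.model = replace(eng.model, gamma_shape=float(np.exp(log_alpha)))
            return -eng.log_likelihood()

        res = minimize_scalar(
            neg, bounds=(np.log(0.02), np.log(50.0)), method="bounded",
            options={"xatol": 5e-3, "maxiter": 10},
        )
        eng.model = replace(eng.model, gamma_shape=float(np.exp(res.x)))
        lnl = -float(res.fun)
    delta = unconstrained_log_likelihood(alignment) - lnl
    return delta, eng.model, eng.tree_with_lengths()


def goldman_test(
    alignment: Alignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sim: int = 200,
    seed: int = 0,
    refit: str = "bl+alpha",
    bl_sweeps: int = 1,
) -> GoldmanResult:
    """Parametric-bootstrap goodness-of-fit test of a fitted model.

    delta_obs is the gap between the unconstrained multinomial lnL and the
    model lnL after fitting (branch lengths, and alpha when
    ``refit='bl+alpha'``).  n_sim datasets are simulated under the fitted
    (tree, model), each refitted with the identical schedule, and
    p = (1 + #{delta* >= delta_obs}) / (n_sim + 1).  Applying the same
    bounded fitting schedule to the observed and every simulated dataset
    is what keeps the Monte Carlo p-value calibrated.
    """
    if refit not in ("bl", "bl+alpha"):
        raise ValueError("refit must be 'bl' or 'bl+alpha'")
    delta_obs, fitted_model, fitted_tree = _refit_delta(
        alignment, tree, model, refit, bl_sweeps
    )
    rng = np.random.default_rng(seed)
    taxa = alignment.taxon_ids
    n_sites = alignment.n_columns
    deltas = np.empty(n_sim)
    for s in range(n_sim):
        for attempt in range(5):
            sim = simulate_under_model(fitted_tree, fitted_model, n_sites, rng, taxa=taxa)
            if sim.n_columns > 0:
                break
        d_star, _, _ = _refit_delta(sim, fitted_tree, fitted_model, refit, bl_sweeps)
        deltas[s] = d_star
    p = (1.0 + float((deltas >= delta_obs).sum())) / (n_sim + 1.0)
    return GoldmanResult(
        delta=float(delta_obs), n_sim=n_sim, p_value=p, seed=seed, delta_null=deltas
    )


# ----------------------------------------------------------------------
# Consel-compatible site-lnL export
# ----------------------------------------------------------------------

def write_site_lnl(site_lnl_set: Sequence[SiteLogLikelihoods], path) -> None:
    """Write a topologies x sites matrix in Consel ``.mt``-style text."""
    mat = np.asarray([s.values for s in site_lnl_set])
    with open(path, "w") as fh:
        fh.write(f"{mat.shape[0]} {mat.shape[1]}\n")
        for i, s in enumerate(site_lnl_set):
            fh.write(f"# {s.topology_id or f't{i}'}\n")
            fh.write(" ".join(f"{x:.8f}" for x in mat[i]) + "\n")


def read_site_lnl(path) -> list[SiteLogLikelihoods]:
    with open(path) as fh:
        header = fh.readline().split()
        n_top, n_sites = int(header[0]), int(header[1])
        out = []
        name = ""
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                name = line[1:].strip()
                continue
            vals = np.array([float(x) for x in line.split()])
            if len(vals) != n_sites:
                raise ValueError("site count mismatch in site-lnL file")
            out.append(SiteLogLikelihoods(name or f"t{len(out)}", vals))
            name = ""
    if len(out) != n_top:
        raise ValueError("topology count mismatch in site-lnL file")
    return out
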