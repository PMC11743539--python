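"""Monte-Carlo validation studies: null calibration and effect recovery.

These routines run the full analysis path (simulation -> connectivity ->
edgewise statistics -> permutation inference) many times over to measure
its operating characteristics: type-I error of the edgewise permutation
test, family-wise error of the network-based statistic, and sensitivity to
planted effects.  They exist so the package can demonstrate, on demand,
that its inference machinery is calibrated under the null and powerful
under the designs it targets.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .connectivity import connectome
from .inference import (
    _freedman_lane_ts,
    _max_component_edges,
    _components,
    _ols_group_t,
    build_design,
    bh_adjust,
    perm_pvalues,
    permutation_indices,
    upper_triangle,
)
from .simulate import SimulationSpec, simulate_group_timeseries

#: three disjoint between-block effect edges (20-region, 4-block layout)
DISJOINT_EFFECT_EDGES = ((0, 5), (1, 6), (2, 7))
#: a connected 5-edge path crossing community blocks (20-region layout)
PATH_COMPONENT_EDGES = ((0, 5), (5, 1), (1, 6), (6, 2), (2, 7))


def _edge_stats_and_null(panels, covariates, n_perm: int,
                         rng: np.random.Generator):
    """Observed group t per edge plus the Freedman-Lane permutation nulls."""
    z_stack = np.stack([connectome(p).z for p in panels])
    X, _, _ = build_design(covariates)
    Y, iu, ju = upper_triangle(z_stack)
    t_obs, _ = _ols_group_t(Y, X)
    perms = permutation_indices(len(Y), n_perm, rng)
    null_t = _freedman_lane_ts(Y, X, perms)
    return t_obs, null_t, iu, ju, X.shape


def null_calibration(n_reps: int = 200, n_per_group: tuple[int, int] = (20, 20),
                     n_regions: int = 20, n_timepoints: int = 240,
                     n_perm: int = 200, alpha: float = 0.05,
                     nbs_primary_p: float = 0.1, seed: int = 0) -> dict:
    """Type-I error of edgewise permutation tests and NBS FWE under the null.

    Simulates ``n_reps`` studies with no group effect and returns the mean
    edgewise rejection rate at ``alpha`` and the fraction of replicates in
    which any NBS component reaches FWE significance at ``alpha`` — both
    should sit near ``alpha`` for a calibrated procedure.
    """
    rng = np.random.default_rng(seed)
    spec = SimulationSpec(n_per_group=n_per_group, n_regions=n_regions,
                          n_timepoints=n_timepoints, seed=seed)
    edge_rates = []
    nbs_hits = []
    for _ in range(n_reps):
        panels, cov = simulate_group_timeseries(
            spec, seed=np.random.SeedSequence(rng.integers(2**31)))
        t_obs, null_t, iu, ju, (n, p) = _edge_stats_and_null(
            panels, cov, n_perm, rng)
        p_perm = perm_pvalues(np.abs(t_obs), np.abs(null_t))
        edge_rates.append(float((p_perm <= alpha).mean()))
        t_crit = stats.t.ppf(1.0 - nbs_primary_p / 2.0, n - p)
        null_max = np.array([
            _max_component_edges(np.abs(row) > t_crit, iu, ju, n_regions)
            for row in null_t])
        obs_max = _max_component_edges(np.abs(t_obs) > t_crit, iu, ju, n_regions)
        p_fwe = (1.0 + (null_max >= max(obs_max, 1)).sum()) / (1.0 + n_perm)
        nbs_hits.append(obs_max > 0 and p_fwe <= alpha)
    return {
        "edgewise_rejection_rate": float(np.mean(edge_rates)),
        "nbs_fwe_rate": float(np.mean(nbs_hits)),
        "n_reps": n_reps,
        "alpha": alpha,
    }


def fdr_recovery(n_reps: int = 50, n_per_group: tuple[int, int] = (40, 40),
                 n_regions: int = 20, n_timepoints: int = 500,
                 effect_edges: tuple = DISJOINT_EFFECT_EDGES,
                 effect_delta: float = 0.3, n_perm: int = 2000,
                 q: float = 0.05, seed: int = 0) -> dict:
    """Sensitivity and false-discovery proportion of edgewise permutation FDR.

    Plants ``effect_delta`` on ``effect_edges`` and measures, across
    replicates, the fraction of planted edges recovered (sensitivity) and
    the observed false-discovery proportion among rejections.

    Note: with permutation p-values floored at 1/(1+n_perm), Benjamini-
    Hochberg over E edges can only reject k edges if 1/(1+n_perm) <=
    k*q/E; ``n_perm`` must be chosen accordingly (2000 for 3 effects
    among 190 edges at q=0.05).
    """
    rng = np.random.default_rng(seed)
    spec = SimulationSpec(n_per_group=n_per_group, n_regions=n_regions,
                          n_timepoints=n_timepoints, effect_edges=effect_edges,
                          effect_delta=effect_delta, seed=seed)
    truth = {tuple(sorted(e)) for e in effect_edges}
    sens, fdp = [], []
    for _ in range(n_reps):
        panels, cov = simulate_group_timeseries(
            spec, seed=np.random.SeedSequence(rng.integers(2**31)))
        t_obs, null_t, iu, ju, _ = _edge_stats_and_null(panels, cov, n_perm, rng)
        p_perm = perm_pvalues(np.abs(t_obs), np.abs(null_t))
        reject, _ = bh_adjust(p_perm, q)
        rejected = {(int(iu[e]), int(ju[e])) for e in np.flatnonzero(reject)}
        hits = len(rejected & truth)
        sens.append(hits / len(truth))
        fdp.append((len(rejected) - hits) / max(len(rejected), 1))
    return {
        "sensitivity": float(np.mean(sens)),
        "false_discovery_proportion": float(np.mean(fdp)),
        "n_reps": n_reps,
    }


def nbs_recovery(n_reps: int = 50, n_per_group: tuple[int, int] = (40, 40),
                 n_regions: int = 20, n_timepoints: int = 500,
                 effect_edges: tuple = PATH_COMPONENT_EDGES,
                 effect_delta: float = 0.3, primary_p: float = 0.001,
                 n_perm: int = 200, alpha: float = 0.05, seed: int = 0) -> dict:
    """Recovery rate of a planted connected component by the NBS FWE test.

    A replicate counts as recovered when some FWE-significant component
    (p <= alpha) contains every planted edge.
    """
    rng = np.random.default_rng(seed)
    spec = SimulationSpec(n_per_group=n_per_group, n_regions=n_regions,
                          n_timepoints=n_timepoints, effect_edges=effect_edges,
                          effect_delta=effect_delta, seed=seed)
    truth = {tuple(sorted(e)) for e in effect_edges}
    recovered = []
    for _ in range(n_reps):
        panels, cov = simulate_group_timeseries(
            spec, seed=np.random.SeedSequence(rng.integers(2**31)))
        t_obs, null_t, iu, ju, (n, p) = _edge_stats_and_null(
            panels, cov, n_perm, rng)
        t_crit = stats.t.ppf(1.0 - primary_p / 2.0, n - p)
        null_max = np.array([
            _max_component_edges(np.abs(row) > t_crit, iu, ju, n_regions)
            for row in null_t])
        hit = False
        for edge_idx in _components(np.abs(t_obs) > t_crit, iu, ju, n_regions):
            p_fwe = (1.0 + (null_max >= len(edge_idx)).sum()) / (1.0 + n_perm)
            edges = {(int(iu[e]), int(ju[e])) for e in edge_idx}
            if p_fwe <= alpha and truth <= edges:
                hit = True
        recovered.append(hit)
    return {"recovery_rate": float(np.mean(recovered)), "n_reps": n_reps}
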