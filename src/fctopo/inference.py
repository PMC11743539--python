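"""Group-difference inference on connectomes and AUC metrics.

Three complementary procedures, all permutation-based:

* **edgewise FDR** — a per-edge statistic for the group effect (OLS t with
  age and mean FD as nuisance covariates), a permutation p-value per edge
  (the same label shuffles reused across edges, preserving the joint null
  dependence), and Benjamini–Hochberg adjustment across edges;
* **NBS** (network-based statistic) — suprathreshold edges at a primary
  cluster-forming threshold are decomposed into connected components and
  each component's extent (edge count) is referred to the permutation
  distribution of the *maximum* component extent, giving family-wise error
  control;
* **AUC group tests** — two-sample two-tailed t-tests on each (metric,
  node) AUC, permutation p-values, and BH-FDR across the family.

With covariates present, permutations follow the Freedman–Lane scheme:
residuals of the reduced (nuisance-only) model are shuffled, the reduced
fit is added back, and the full-model statistic recomputed.  Permutation
p-values use the (1 + count) / (1 + n_perm) estimator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------- design

def build_design(covariates: pd.DataFrame,
                 group_col: str = "group",
                 covariate_cols: tuple[str, ...] = ("age", "mean_fd"),
                 treatment_label: str | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix [intercept, group, covariates...] and the group vector.

    Returns (X, y, column_names) where y is the 0/1 group indicator.
    Raises if the design is rank-deficient, naming the collinear columns.
    """
    groups = covariates[group_col].to_numpy()
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    if treatment_label is None:
        treatment_label = "treatment" if "treatment" in levels else levels[0]
    y = (groups == treatment_label).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both groups must be non-empty")
    cols = [np.ones(len(y)), y]
    names = ["intercept", "group"]
    for c in covariate_cols:
        cols.append(covariates[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    return X, y, names


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(X[:, j])):
            bad.append(names[j])
    return bad or names[1:]


def upper_triangle(z_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorize symmetric matrices: (S, N, N) -> (S, E) plus (i, j) indices."""
    n = z_stack.shape[-1]
    iu, ju = np.triu_indices(n, k=1)
    return z_stack[..., iu, ju], iu, ju


# ------------------------------------------------------------ edgewise GLM

def _ols_group_t(Y: np.ndarray, X: np.ndarray,
                 group_idx: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-column OLS of Y on X; t statistic and estimate for one coefficient.

    Y: (n_subjects, n_responses); X: (n_subjects, p).  Vectorized across
    responses.  Columns with zero residual variance get t = inf * sign.
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)                       # (p, E)
    resid = Y - X @ beta
    dof = n - p
    s2 = (resid ** 2).sum(axis=0) / dof              # (E,)
    se = np.sqrt(np.maximum(s2, 0.0) * xtx_inv[group_idx, group_idx])
    b = beta[group_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, np.sign(b) * np.inf)
    t = np.where((se == 0) & (b == 0), 0.0, t)
    return t, b


def edgewise_glm(z_stack: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS t statistic (and effect estimate) for the group coefficient, per edge.

    ``z_stack`` is (n_subjects, N, N); the response for each edge is its
    Fisher-z value across subjects.  With no covariate columns the t equals
    the pooled-variance two-sample t exactly.
    """
    Y, _, _ = upper_triangle(np.asarray(z_stack, dtype=float))
    if Y.shape[0] != design.shape[0]:
        raise ValueError("subjects in z_stack and design do not align")
    return _ols_group_t(Y, design)


def _freedman_lane_ts(Y: np.ndarray, X: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Group-coefficient t under each row-permutation, Freedman–Lane style.

    perms: (n_perm, n_subjects) integer index rows.  Returns (n_perm, E).
    With an intercept-only reduced model this reduces to plain label
    permutation of the responses.
    """
    X0 = np.delete(X, 1, axis=1)  # reduced model: drop the group column
    beta0 = np.linalg.lstsq(X0, Y, rcond=None)[0]
    fitted0 = X0 @ beta0
    resid0 = Y - fitted0
    out = np.empty((perms.shape[0], Y.shape[1]))
    for b, pi in enumerate(perms):
        Ystar = fitted0 + resid0[pi]
        out[b], _ = _ols_group_t(Ystar, X)
    return out


def permutation_indices(n_subjects: int, n_perm: int,
                        rng: np.random.Generator) -> np.ndarray:
    """The shared shuffle log: one permutation of subject rows per iteration."""
    return np.stack([rng.permutation(n_subjects) for _ in range(n_perm)])


def perm_pvalues(obs_abs: np.ndarray, null_abs: np.ndarray) -> np.ndarray:
    """(1 + #{null >= obs}) / (1 + n_perm), columnwise two-sided."""
    n_perm = null_abs.shape[0]
    count = (null_abs >= obs_abs[None, :]).sum(axis=0)
    return (1.0 + count) / (1.0 + n_perm)


def bh_adjust(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg: (reject flags, adjusted p)."""
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


# ------------------------------------------------------------- NBS helpers

def _max_component_edges(supra: np.ndarray, iu: np.ndarray, ju: np.ndarray,
                         n_nodes: int) -> int:
    """Largest connected-component extent (edge count) of a suprathreshold set."""
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return 0
    parent = list(range(n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in idx:
        ra, rb = find(int(iu[e])), find(int(ju[e]))
        if ra != rb:
            parent[ra] = rb
    counts: dict[int, int] = {}
    for e in idx:
        r = find(int(iu[e]))
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


def _components(supra: np.ndarray, iu: np.ndarray, ju: np.ndarray,
                n_nodes: int) -> list[np.ndarray]:
    """Connected components of the suprathreshold edge set, as edge-index arrays."""
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return []
    parent = list(range(n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in idx:
        ra, rb = find(int(iu[e])), find(int(ju[e]))
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, list[int]] = {}
    for e in idx:
        comps.setdefault(find(int(iu[e])), []).append(int(e))
    return [np.array(v) for v in comps.values()]


@dataclass
class NBSComponent:
    edges: list[tuple[int, int]]
    size: int
    p_fwe: float


# ------------------------------------------------------------- estimators

class EdgewisePermutationFDR(BaseEstimator):
    """Edgewise group inference: OLS t, permutation p, BH-FDR decisions.

    Parameters
    ----------
    n_perm : int
        Number of group-label permutations (Freedman–Lane with covariates).
    q : float
        FDR level for Benjamini–Hochberg.
    seed : int
        Seed for the shared shuffle log.

    Attributes (after fit)
    ----------------------
    t_, effect_ : ndarray of shape (n_edges,)
    p_perm_, p_fdr_ : ndarray of shape (n_edges,)
    reject_ : boolean ndarray
    edge_index_ : (i, j) arrays of the upper-triangle order
    """

    def __init__(self, n_perm: int = 1000, q: float = 0.05, seed: int = 0):
        self.n_perm = n_perm
        self.q = q
        self.seed = seed

    def fit(self, z_stack: np.ndarray, covariates: pd.DataFrame,
            covariate_cols: tuple[str, ...] = ("age", "mean_fd")) -> "EdgewisePermutationFDR":
        X, _, _ = build_design(covariates, covariate_cols=covariate_cols)
        Y, iu, ju = upper_triangle(np.asarray(z_stack, dtype=float))
        self.t_, self.effect_ = _ols_group_t(Y, X)
        rng = np.random.default_rng(self.seed)
        perms = permutation_indices(len(Y), self.n_perm, rng)
        null_t = _freedman_lane_ts(Y, X, perms)
        self.p_perm_ = perm_pvalues(np.abs(self.t_), np.abs(null_t))
        self.reject_, self.p_fdr_ = bh_adjust(self.p_perm_, self.q)
        self.edge_index_ = (iu, ju)
        return self

    def result_table(self, region_names: list[str] | None = None) -> pd.DataFrame:
        iu, ju = self.edge_index_
        name = (lambda k: region_names[k]) if region_names else (lambda k: k + 1)
        return pd.DataFrame({
            "i": [name(a) for a in iu], "j": [name(b) for b in ju],
            "t": self.t_, "effect": self.effect_,
            "p_perm": self.p_perm_, "p_fdr": self.p_fdr_,
            "reject": self.reject_,
        })


class NetworkBasedStatistic(BaseEstimator):
    """NBS: component-extent FWE inference on suprathreshold edges.

    The primary (cluster-forming) threshold is the two-sided parametric
    critical t at ``primary_p``; component extent is its edge count; the
    FWE p of each observed component is the fraction of permutations whose
    *maximum* extent reaches it, with the (1+count)/(1+n_perm) estimator.

    Attributes (after fit)
    ----------------------
    components_ : list of NBSComponent
    t_, t_crit_ : edge statistics and the primary threshold used
    null_max_size_ : permutation distribution of the maximum extent
    """

    def __init__(self, primary_p: float = 0.001, n_perm: int = 1000,
                 q: float = 0.05, seed: int = 0):
        self.primary_p = primary_p
        self.n_perm = n_perm
        self.q = q
        self.seed = seed

    def fit(self, z_stack: np.ndarray, covariates: pd.DataFrame,
            covariate_cols: tuple[str, ...] = ("age", "mean_fd")) -> "NetworkBasedStatistic":
        if not (0.0 < self.primary_p < 1.0):
            raise ValueError("primary_p must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for a usable FWE estimate")
        X, _, _ = build_design(covariates, covariate_cols=covariate_cols)
        Y, iu, ju = upper_triangle(np.asarray(z_stack, dtype=float))
        n_nodes = z_stack.shape[-1]
        self.t_, self.effect_ = _ols_group_t(Y, X)
        dof = len(Y) - X.shape[1]
        self.t_crit_ = float(stats.t.ppf(1.0 - self.primary_p / 2.0, dof))
        rng = np.random.default_rng(self.seed)
        perms = permutation_indices(len(Y), self.n_perm, rng)
        null_t = _freedman_lane_ts(Y, X, perms)
        self.null_max_size_ = np.array([
            _max_component_edges(np.abs(row) > self.t_crit_, iu, ju, n_nodes)
            for row in null_t])
        comps = _components(np.abs(self.t_) > self.t_crit_, iu, ju, n_nodes)
        self.components_ = []
        for edge_idx in comps:
            size = len(edge_idx)
            p = (1.0 + (self.null_max_size_ >= size).sum()) / (1.0 + self.n_perm)
            self.components_.append(NBSComponent(
                edges=[(int(iu[e]), int(ju[e])) for e in edge_idx],
                size=size, p_fwe=float(p)))
        self.components_.sort(key=lambda c: c.p_fwe)
        self.edge_index_ = (iu, ju)
        return self

    def result_table(self, region_names: list[str] | None = None) -> pd.DataFrame:
        rows = []
        for cid, c in enumerate(self.components_, start=1):
            if region_names:
                edges = ";".join(f"{region_names[i]}-{region_names[j]}"
                                 for i, j in c.edges)
            else:
                edges = ";".join(f"{i + 1}-{j + 1}" for i, j in c.edges)
            rows.append((cid, edges, c.size, c.p_fwe, c.p_fwe <= self.q))
        return pd.DataFrame(rows, columns=["component", "edges", "size",
                                           "p_fwe", "significant"])


class AUCGroupTest(BaseEstimator):
    """Two-sample t-tests with permutation p and BH-FDR on AUC features.

    Fit on a wide AUC table (subjects x ``metric|node`` columns) and the
    covariate table (aligned by row order).  Features with zero variance in
    both groups get NaN statistics and are excluded from the FDR family.

    Attributes (after fit)
    ----------------------
    t_, p_perm_, p_fdr_, reject_ : per-feature arrays (NaN where undefined)
    effect_ : group mean difference per feature
    pointbiserial_ : point-biserial correlation of feature with group label
    feature_names_ : list of str
    """

    def __init__(self, n_perm: int = 1000, q: float = 0.05, seed: int = 0,
                 equal_var: bool = False):
        self.n_perm = n_perm
        self.q = q
        self.seed = seed
        self.equal_var = equal_var

    def fit(self, auc_wide: pd.DataFrame, covariates: pd.DataFrame) -> "AUCGroupTest":
        _, y, _ = build_design(covariates, covariate_cols=())
        if len(y) != len(auc_wide):
            raise ValueError("AUC table and covariates do not align")
        g1, g2 = y == 1, y == 0
        if g1.sum() < 2 or g2.sum() < 2:
            raise ValueError("both groups need >= 2 subjects")
        V = auc_wide.to_numpy(dtype=float)
        self.feature_names_ = list(auc_wide.columns)
        t_obs = self._tstat(V, g1, g2)
        rng = np.random.default_rng(self.seed)
        perms = permutation_indices(len(y), self.n_perm, rng)
        null = np.empty((self.n_perm, V.shape[1]))
        for b, pi in enumerate(perms):
            yb = y[pi] == 1
            null[b] = self._tstat(V, yb, ~yb)
        defined = np.isfinite(t_obs)
        p_perm = np.full(V.shape[1], np.nan)
        with np.errstate(invalid="ignore"):
            p_perm[defined] = perm_pvalues(np.abs(t_obs[defined]),
                                           np.abs(null[:, defined]))
        reject = np.zeros(V.shape[1], dtype=bool)
        p_fdr = np.full(V.shape[1], np.nan)
        if defined.any():
            reject[defined], p_fdr[defined] = bh_adjust(p_perm[defined], self.q)
        self.t_, self.p_perm_, self.p_fdr_, self.reject_ = t_obs, p_perm, p_fdr, reject
        self.effect_ = V[g1].mean(axis=0) - V[g2].mean(axis=0)
        self.pointbiserial_ = self._pointbiserial(V, y)
        self.n_excluded_ = int((~defined).sum())
        return self

    def _tstat(self, V: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        n1, n2 = g1.sum(), g2.sum()
        m1, m2 = V[g1].mean(axis=0), V[g2].mean(axis=0)
        v1, v2 = V[g1].var(axis=0, ddof=1), V[g2].var(axis=0, ddof=1)
        if self.equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        else:
            se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m1 - m2) / np.sqrt(se2)
        return np.where(se2 == 0, np.nan, t)

    @staticmethod
    def _pointbiserial(V: np.ndarray, y: np.ndarray) -> np.ndarray:
        yc = y - y.mean()
        Vc = V - V.mean(axis=0)
        denom = np.sqrt((yc ** 2).sum() * (Vc ** 2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (yc @ Vc) / denom
        return np.where(denom == 0, np.nan, r)

    def result_table(self) -> pd.DataFrame:
        metric = [f.split("|")[0] for f in self.feature_names_]
        node = [f.split("|")[1] if "|" in f else GLOBAL_LABEL
                for f in self.feature_names_]
        return pd.DataFrame({
            "metric": metric, "node": node, "t": self.t_,
            "effect": self.effect_, "r_pointbiserial": self.pointbiserial_,
            "p_perm": self.p_perm_, "p_fdr": self.p_fdr_, "reject": self.reject_,
        })


GLOBAL_LABEL = "GLOBAL"


# ------------------------------------------------------------ summary t

def summary_t(mean1: float, sd1: float, n1: int, mean2: float, sd2: float,
              n2: int, equal_var: bool = False) -> float:
    """Two-sample t from printed summary statistics (Welch by default).

    Lets printed group summaries (mean +/- SD, n) be checked against their
    printed t-values.  Both SDs zero with equal means is undefined (NaN).
    """
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    diff = mean1 - mean2
    if equal_var:
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se = np.sqrt(sd1 ** 2 / n1 + sd2 ** 2 / n2)
    if se == 0:
        return float("nan") if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / se)


# ----------------------------------------------------- functional wrappers

def edgewise_fdr(z_stack: np.ndarray, covariates: pd.DataFrame,
                 n_perm: int = 1000, seed: int = 0, q: float = 0.05,
                 covariate_cols: tuple[str, ...] = ("age", "mean_fd")) -> pd.DataFrame:
    est = EdgewisePermutationFDR(n_perm=n_perm, q=q, seed=seed)
    return est.fit(z_stack, covariates, covariate_cols).result_table()


def nbs_fwe(z_stack: np.ndarray, covariates: pd.DataFrame,
            primary_p: float = 0.001, n_perm: int = 1000, seed: int = 0,
            q: float = 0.05,
            covariate_cols: tuple[str, ...] = ("age", "mean_fd")) -> pd.DataFrame:
    est = NetworkBasedStatistic(primary_p=primary_p, n_perm=n_perm, q=q, seed=seed)
    return est.fit(z_stack, covariates, covariate_cols).result_table()


def auc_group_test(auc_wide: pd.DataFrame, covariates: pd.DataFrame,
                   n_perm: int = 1000, seed: int = 0, q: float = 0.05) -> pd.DataFrame:
    est = AUCGroupTest(n_perm=n_perm, q=q, seed=seed)
    return est.fit(auc_wide, covariates).result_table()
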