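"""Synthetic study generator and toy-graph fixtures.

No subject-level fMRI data accompany the study design this package
implements, so the generator emulates its statistical structure instead:
two treatment arms of region-wise BOLD-like series (default 67 vs 72
subjects, 116 regions, 240 time points), drawn as zero-mean Gaussian
innovations with a community-structured covariance, temporally colored by
a first-order autoregression, with an optional group effect planted on a
chosen edge set of the correlation matrix.  Marginal stationary variances
are 1, so covariance-scale and correlation-scale effects coincide.

Covariates (age, mean framewise displacement) are drawn to mimic the
study's matched arms: age ~ Normal(22.09, 2.44) / Normal(21.69, 2.57)
years, FD half-normal with scale 0.15 mm in both arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import TimeSeriesPanel
from .graph import BinaryGraph

#: per-group (treatment, control) covariate model defaults
DEFAULT_COVARIATE_MODEL = {
    "age_mean": (22.09, 21.69),
    "age_sd": (2.44, 2.57),
    "fd_scale": (0.15, 0.15),
}


def block_covariance(n_regions: int, n_blocks: int = 4, rho_in: float = 0.4,
                     rho_out: float = 0.1) -> np.ndarray:
    """Community-structured correlation matrix: unit diagonal, rho_in within
    contiguous blocks, rho_out between blocks.

    With rho_out < rho_in < 1 this is positive-definite (its smallest
    eigenvalue is 1 - rho_in) and yields small-world-like graphs once
    proportionally thresholded.
    """
    if n_blocks < 1 or n_blocks > n_regions:
        raise ValueError("need 1 <= n_blocks <= n_regions")
    labels = np.arange(n_regions) * n_blocks // n_regions
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, rho_in, rho_out).astype(float)
    np.fill_diagonal(cov, 1.0)
    return cov


@dataclass
class SimulationSpec:
    """Design of a synthetic two-group connectome study.

    ``effect_edges`` lists (i, j) region pairs whose correlation is shifted
    by ``effect_delta`` in the treatment group relative to control; the
    perturbed covariance must remain positive-definite (checked here).
    """

    n_per_group: tuple[int, int] = (67, 72)
    n_regions: int = 116
    n_timepoints: int = 240
    base_covariance: np.ndarray | None = None
    effect_edges: tuple[tuple[int, int], ...] = ()
    effect_delta: float = 0.0
    ar_coefficient: float = 0.3
    covariate_model: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MODEL))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_covariance is None:
            self.base_covariance = block_covariance(self.n_regions)
        self.base_covariance = np.asarray(self.base_covariance, dtype=float)
        if self.base_covariance.shape != (self.n_regions, self.n_regions):
            raise ValueError("base_covariance shape does not match n_regions")
        if not np.allclose(self.base_covariance, self.base_covariance.T):
            raise ValueError("base_covariance must be symmetric")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ValueError("ar_coefficient must be in [0, 1)")
        if min(self.n_per_group) < 1:
            raise ValueError("both groups must be non-empty")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        for (i, j) in self.effect_edges:
            if i == j or not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError(f"effect edge ({i}, {j}) is not an off-diagonal pair")
        self._chol_base = _checked_cholesky(self.base_covariance, "base_covariance")
        self._chol_effect = _checked_cholesky(
            self.effect_covariance(),
            f"base_covariance perturbed by effect_delta={self.effect_delta}")

    def effect_covariance(self) -> np.ndarray:
        """Treatment-group covariance: base plus delta on the effect edges."""
        cov = self.base_covariance.copy()
        for (i, j) in self.effect_edges:
            cov[i, j] += self.effect_delta
            cov[j, i] = cov[i, j]
        return cov


def _checked_cholesky(cov: np.ndarray, what: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(f"{what} is not positive-definite") from None


def _ar1_panel(chol: np.ndarray, n_timepoints: int, phi: float,
               rng: np.random.Generator) -> np.ndarray:
    """AR(1)-colored Gaussian series whose stationary covariance is chol@chol.T.

    x_0 ~ N(0, S); x_t = phi x_{t-1} + sqrt(1 - phi^2) e_t, e_t ~ N(0, S).
    The stationary marginal covariance then equals S exactly and every
    region's lag-1 autocorrelation is phi.
    """
    n_regions = chol.shape[0]
    innov = rng.standard_normal((n_timepoints, n_regions)) @ chol.T
    x = np.empty_like(innov)
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi ** 2)
    for t in range(1, n_timepoints):
        x[t] = phi * x[t - 1] + scale * innov[t]
    return x


def simulate_group_timeseries(
        spec: SimulationSpec,
        seed: int | np.random.SeedSequence | None = None,
) -> tuple[list[TimeSeriesPanel], pd.DataFrame]:
    """Draw both groups' panels and the covariate table.

    Group labels are ``treatment`` (perturbed covariance) and ``control``
    (base covariance).  Fully deterministic given the spec and seed; when
    ``seed`` is None the spec's own seed is used.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    region_names = [f"R{i + 1}" for i in range(spec.n_regions)]
    chols = (spec._chol_effect, spec._chol_base)
    groups = ("treatment", "control")
    panels: list[TimeSeriesPanel] = []
    cov_rows = []
    cm = spec.covariate_model
    for gi, (group, chol) in enumerate(zip(groups, chols)):
        for k in range(spec.n_per_group[gi]):
            sid = f"{group[:3]}-{k + 1:03d}"
            values = _ar1_panel(chol, spec.n_timepoints, spec.ar_coefficient, rng)
            panels.append(TimeSeriesPanel(values=values,
                                          region_names=region_names,
                                          subject_id=sid))
            age = rng.normal(cm["age_mean"][gi], cm["age_sd"][gi])
            fd = abs(rng.normal(0.0, cm["fd_scale"][gi]))
            cov_rows.append((sid, group, age, fd))
    covariates = pd.DataFrame(cov_rows,
                              columns=["subject_id", "group", "age", "mean_fd"])
    return panels, covariates


def make_toy_graph(kind: str, n: int, seed: int | None = None,
                   **params) -> BinaryGraph:
    """Named graph families with known metric values, for validation.

    kind: complete | path | star | ring_lattice(k) | watts_strogatz(k, p)
          | erdos_renyi(m or p)
    """
    if n < 2:
        raise ValueError("need n >= 2 nodes")
    try:
        if kind == "complete":
            g = nx.complete_graph(n)
        elif kind == "path":
            g = nx.path_graph(n)
        elif kind == "star":
            g = nx.star_graph(n - 1)
        elif kind == "ring_lattice":
            g = nx.watts_strogatz_graph(n, params["k"], 0.0)
        elif kind == "watts_strogatz":
            g = nx.watts_strogatz_graph(n, params["k"], params["p"], seed=seed)
        elif kind == "erdos_renyi":
            if "m" in params:
                g = nx.gnm_random_graph(n, params["m"], seed=seed)
            else:
                g = nx.gnp_random_graph(n, params["p"], seed=seed)
        else:
            raise ValueError(f"unknown toy-graph kind {kind!r}")
    except (nx.NetworkXError, KeyError) as exc:
        raise ValueError(f"invalid parameters for {kind!r}: {exc}") from exc
    a = nx.to_numpy_array(g, nodelist=range(n), dtype=np.uint8)
    density = a.sum() / (n * (n - 1)) if n > 1 else 0.0
    return BinaryGraph(adjacency=a, sparsity=float(density))
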