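"""Functional connectivity: region-wise BOLD series -> Fisher-z connectomes.

Each subject contributes a time x region matrix of cleaned BOLD signals.
The functional connectome is the matrix of pairwise Pearson correlations
between regional series, variance-stabilized by the Fisher r-to-z transform
(z = arctanh r) with the diagonal fixed at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class TimeSeriesPanel:
    """One subject's region-wise time series (time in rows, regions in columns)."""

    values: np.ndarray
    region_names: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time-series panel must be 2-D (time x region)")
        if self.values.shape[1] != len(self.region_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.region_names)} region names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"panel {self.subject_id!r} contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ZMatrix:
    """Symmetric Fisher-z connectivity matrix with a zero diagonal."""

    z: np.ndarray
    region_names: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != n:
            raise ValueError("z matrix must be square")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("z matrix must be symmetric")
        if np.any(np.diag(self.z) != 0.0):
            raise ValueError("z matrix diagonal must be exactly 0")
        off = self.z[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal z values must be finite")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


def pearson_fc(panel: TimeSeriesPanel) -> np.ndarray:
    """Pearson correlation between every pair of regional mean time series.

    Returns a symmetric matrix with unit diagonal and entries in [-1, 1].
    A region with zero temporal variance makes its correlations undefined
    and raises, naming the region.
    """
    x = panel.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points to correlate")
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        names = [panel.region_names[i] for i in bad]
        raise ValueError(f"constant (zero-variance) region(s): {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # symmetrize fp noise, bound overshoot
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: np.ndarray, region_names: Sequence[str] | None = None,
             subject_id: str = "") -> ZMatrix:
    """Fisher r-to-z transform of a correlation matrix, diagonal set to 0.

    Off-diagonal correlations at exactly +/-1 have infinite z; they indicate
    duplicated regions and raise (identifying the offending pair) rather
    than being clipped.
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if region_names is None:
        region_names = [f"R{i + 1}" for i in range(n)]
    offdiag = ~np.eye(n, dtype=bool)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    sat = np.argwhere((np.abs(r) == 1.0) & offdiag)
    if sat.size:
        i, j = sat[0]
        raise ValueError(
            f"|r| = 1 between regions {region_names[i]!r} and {region_names[j]!r}: "
            "infinite Fisher z (duplicated series?)"
        )
    z = np.zeros_like(r)
    z[offdiag] = np.arctanh(r[offdiag])
    z = (z + z.T) / 2.0
    return ZMatrix(z=z, region_names=list(region_names), subject_id=subject_id)


def connectome(panel: TimeSeriesPanel) -> ZMatrix:
    """Pearson FC followed by the Fisher transform: the subject's connectome."""
    return fisher_z(pearson_fc(panel), panel.region_names, panel.subject_id)


def screen_outliers(z_matrices: Sequence[ZMatrix], sd_limit: float = 3.0) -> dict[str, bool]:
    """Flag subjects whose mean off-diagonal z deviates from the cohort.

    A subject is flagged when its mean off-diagonal z lies more than
    ``sd_limit`` standard deviations from the cohort mean, both computed
    leaving that subject out (so a gross outlier cannot mask itself by
    inflating the reference spread).  Flags are reported, never acted on:
    exclusion is the analyst's decision.
    """
    if len(z_matrices) < 3:
        raise ValueError("outlier screening needs at least 3 subjects")
    n = z_matrices[0].n_regions
    mask = ~np.eye(n, dtype=bool)
    means = np.array([zm.z[mask].mean() for zm in z_matrices])
    flags = np.zeros(len(means), dtype=bool)
    for i in range(len(means)):
        rest = np.delete(means, i)
        sd = rest.std(ddof=1)
        if sd > 0.0:
            flags[i] = abs(means[i] - rest.mean()) > sd_limit * sd
    return {
        zm.subject_id or str(i): bool(f)
        for i, (zm, f) in enumerate(zip(z_matrices, flags))
    }


def zmatrix_normality_summary(z_matrices: Sequence[ZMatrix]) -> dict[str, float]:
    """Descriptive skew/kurtosis of pooled off-diagonal z values.

    Reported for inspection only; nothing downstream gates on it.
    """
    from scipy import stats

    n = z_matrices[0].n_regions
    iu = np.triu_indices(n, k=1)
    pooled = np.concatenate([zm.z[iu] for zm in z_matrices])
    return {
        "skew": float(stats.skew(pooled)),
        "excess_kurtosis": float(stats.kurtosis(pooled)),
        "n_values": int(pooled.size),
    }


class PearsonConnectivity(BaseEstimator, TransformerMixin):
    """Transformer from time-series panels to stacked Fisher-z connectomes.

    Parameters
    ----------
    apply_fisher : bool, default True
        If False, transform returns raw Pearson correlation matrices
        (diagonal 1) instead of Fisher-z matrices (diagonal 0).

    Attributes
    ----------
    n_regions_ : int
        Number of regions seen during fit.
    region_names_ : list of str
        Region labels taken from the first panel.
    """

    def __init__(self, apply_fisher: bool = True):
        self.apply_fisher = apply_fisher

    def fit(self, X: Sequence[TimeSeriesPanel], y=None) -> "PearsonConnectivity":
        if len(X) == 0:
            raise ValueError("no panels given")
        n = X[0].n_regions
        for p in X:
            if p.n_regions != n:
                raise ValueError(
                    f"panel {p.subject_id!r} has {p.n_regions} regions, expected {n}"
                )
        self.n_regions_ = n
        self.region_names_ = list(X[0].region_names)
        return self

    def transform(self, X: Sequence[TimeSeriesPanel]) -> np.ndarray:
        """Return an (n_subjects, n_regions, n_regions) array."""
        mats = []
        for p in X:
            r = pearson_fc(p)
            mats.append(fisher_z(r, p.region_names, p.subject_id).z
                        if self.apply_fisher else r)
        return np.stack(mats)
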