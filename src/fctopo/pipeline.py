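"""End-to-end pipeline: time series -> connectomes -> graphs -> inference.

The run is a pure function of (inputs, config, seed): per-stage random
generators are derived deterministically from the master seed, and the
manifest records the config plus a checksum of every emitted table, so a
rerun with identical inputs reproduces every output byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .config import StudyConfig, child_seed
from .connectivity import PearsonConnectivity, screen_outliers, fisher_z, pearson_fc
from .graph import ProportionalThresholdSweep
from .inference import AUCGroupTest, EdgewisePermutationFDR, NetworkBasedStatistic
from .metrics import GraphMetricsAUC, auc_table, sweep_metrics
from .smallworld import NodalSmallWorldPropensity


def _load_cohort(timeseries_dir: Path, covariates: pd.DataFrame,
                 region_names: list[str] | None):
    panels = []
    missing = []
    for sid in covariates["subject_id"]:
        f = timeseries_dir / f"{sid}.tsv"
        if not f.exists():
            missing.append(sid)
            continue
        panels.append(fio.read_timeseries(f, region_names=region_names,
                                          subject_id=sid))
    if missing:
        raise FileNotFoundError(
            f"no time-series file for subject(s): {missing} in {timeseries_dir}")
    return panels


def run_pipeline(config: StudyConfig, timeseries_dir: str | Path,
                 covariates: pd.DataFrame | str | Path,
                 out_dir: str | Path,
                 node_labels: list[str] | None = None) -> Path:
    """Run every stage and write all result tables under ``out_dir``.

    Emits per-subject z-matrices, the outlier report, long per-sparsity
    metric tables, AUC tables (plain metrics and small-world propensity),
    edgewise FDR / NBS component / AUC group-test tables, and a manifest.
    Returns the manifest path.
    """
    timeseries_dir = Path(timeseries_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(covariates, pd.DataFrame):
        covariates = fio.read_covariates(covariates)

    panels = _load_cohort(timeseries_dir, covariates, node_labels)
    region_names = panels[0].region_names
    outputs: list[str] = []

    # --- connectivity
    PearsonConnectivity().fit(panels)  # validates region alignment
    zmats = [fisher_z(pearson_fc(p), p.region_names, p.subject_id) for p in panels]
    z_stack = np.stack([zm.z for zm in zmats])
    zdir = out_dir / "zmatrices"
    zdir.mkdir(exist_ok=True)
    for zm in zmats:
        name = f"zmatrices/{zm.subject_id}.tsv"
        fio.write_zmatrix(zm, out_dir / name)
        outputs.append(name)
    flags = screen_outliers(zmats)
    pd.DataFrame({"subject_id": list(flags), "outlier": list(flags.values())}
                 ).to_csv(out_dir / "outliers.tsv", sep="\t", index=False)
    outputs.append("outliers.tsv")

    # --- sparsity sweep and metrics
    sweeper = ProportionalThresholdSweep(
        lo=config.sparsity_lo, hi=config.sparsity_hi,
        step=config.sparsity_step, mode=config.threshold_mode).fit(z_stack)
    sweeps = sweeper.transform(z_stack)
    long_frames = [sweep_metrics(sw, region_names, subject_id=sid)
                   for sw, sid in zip(sweeps, covariates["subject_id"])]
    metric_long = pd.concat(long_frames, ignore_index=True)
    metric_long.to_csv(out_dir / "metrics_by_sparsity.tsv", sep="\t",
                       index=False, float_format=fio.FLOAT_FMT)
    outputs.append("metrics_by_sparsity.tsv")
    aucs = auc_table(metric_long)
    aucs.to_csv(out_dir / "metrics_auc.tsv", sep="\t", index=False,
                float_format=fio.FLOAT_FMT)
    outputs.append("metrics_auc.tsv")

    # --- nodal small-world propensity (gamma and sigma AUCs)
    swp_seed = int(child_seed(config.seed, "swp_null").generate_state(1)[0] % (2 ** 31))
    swp = NodalSmallWorldPropensity(
        null_model=config.null_model,
        n_realizations=config.n_null_realizations,
        seed=swp_seed, node_names=region_names).fit(sweeps)
    swp_wide = swp.transform(sweeps)
    swp_wide.insert(0, "subject_id", covariates["subject_id"].to_numpy())
    swp_wide.to_csv(out_dir / "swp_auc.tsv", sep="\t", index=False,
                    float_format=fio.FLOAT_FMT)
    outputs.append("swp_auc.tsv")

    # --- inference
    def seed_for(stage: str) -> int:
        return int(child_seed(config.seed, stage).generate_state(1)[0] % (2 ** 31))

    edge = EdgewisePermutationFDR(n_perm=config.n_permutations, q=config.fdr_q,
                                  seed=seed_for("edgewise_fdr"))
    edge.fit(z_stack, covariates)
    edge.result_table(region_names).to_csv(
        out_dir / "edgewise_fdr.tsv", sep="\t", index=False,
        float_format=fio.FLOAT_FMT)
    outputs.append("edgewise_fdr.tsv")

    nbs = NetworkBasedStatistic(primary_p=config.nbs_primary_p,
                                n_perm=max(config.n_permutations, 100),
                                q=config.fdr_q, seed=seed_for("nbs"))
    nbs.fit(z_stack, covariates)
    nbs.result_table(region_names).to_csv(
        out_dir / "nbs_components.tsv", sep="\t", index=False,
        float_format=fio.FLOAT_FMT)
    outputs.append("nbs_components.tsv")

    metric_wide = GraphMetricsAUC(node_names=region_names).fit(sweeps).transform(sweeps)
    feature_table = pd.concat(
        [metric_wide.reset_index(drop=True),
         swp_wide.drop(columns="subject_id").reset_index(drop=True)], axis=1)
    auct = AUCGroupTest(n_perm=config.n_permutations, q=config.fdr_q,
                        seed=seed_for("auc_group_test"))
    auct.fit(feature_table, covariates)
    auct.result_table().to_csv(out_dir / "auc_group_tests.tsv", sep="\t",
                               index=False, float_format=fio.FLOAT_FMT)
    outputs.append("auc_group_tests.tsv")

    extra = {
        "nbs_primary_p": config.nbs_primary_p,  # cluster-forming threshold, always logged
        "n_subjects": int(len(covariates)),
        "n_regions": int(len(region_names)),
    }
    return fio.write_manifest(out_dir, config.to_dict(), outputs, extra=extra)
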