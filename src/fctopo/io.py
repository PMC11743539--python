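"""Readers and writers for every on-disk artifact.

All tables are tab-separated text with a mandatory header row; matrices
carry region labels on both axes; node indexing is 1-based with names in
emitted files.  Every writer/reader pair round-trips within 1e-12.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import TimeSeriesPanel, ZMatrix

#: printed recruitment figures carried into every manifest (see cohort_accounting)
RECRUITED_ABSTRACT = 142
RECRUITED_PARTICIPANTS = 139
EXCLUDED = 3

FLOAT_FMT = "%.17g"


def read_timeseries(path: str | Path, delimiter: str = "\t",
                    region_names: list[str] | None = None,
                    subject_id: str | None = None) -> TimeSeriesPanel:
    """Read one subject's time x region table.

    The first line is a header of region names (overridden by
    ``region_names`` from a node-label file, if given).  Ragged rows and
    non-numeric cells raise with the offending line / coordinates.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: no data rows")
    header = lines[0].split(delimiter)
    n_cols = len(header)
    if n_cols < 2:
        raise ValueError(f"{path}: need at least 2 regions, found {n_cols}")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(delimiter)
        if len(cells) != n_cols:
            raise ValueError(
                f"{path}: line {lineno} has {len(cells)} fields, expected {n_cols}")
        row = []
        for col, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at line {lineno}, "
                    f"column {col}") from None
        rows.append(row)
    if len(rows) < 3:
        raise ValueError(f"{path}: need at least 3 time points, found {len(rows)}")
    names = list(region_names) if region_names is not None else header
    if len(names) != n_cols:
        raise ValueError(f"{path}: {len(names)} region names for {n_cols} columns")
    return TimeSeriesPanel(values=np.array(rows),
                           region_names=names,
                           subject_id=subject_id or path.stem)


def write_timeseries(panel: TimeSeriesPanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.values, columns=panel.region_names)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_matrix(matrix: np.ndarray, path: str | Path,
                 labels: list[str] | None = None) -> None:
    """Write a square symmetric matrix as labeled TSV."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric within 1e-10")
    if labels is None:
        labels = [f"R{i + 1}" for i in range(m.shape[0])]
    df = pd.DataFrame(m, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="region")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_zmatrix(zm: ZMatrix, path: str | Path) -> None:
    write_matrix(zm.z, path, labels=zm.region_names)


def read_zmatrix(path: str | Path, subject_id: str | None = None) -> ZMatrix:
    m, labels = read_matrix(path)
    return ZMatrix(z=m, region_names=labels,
                   subject_id=subject_id or Path(path).stem)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "group", "age", "mean_fd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing covariate columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dups}")
    return df


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_node_labels(path: str | Path) -> list[str]:
    """Two-column TSV (1-based index, name) -> names in index order."""
    df = pd.read_csv(path, sep="\t", header=None, names=["index", "name"],
                     dtype={"index": int, "name": str}, comment="#")
    df = df.sort_values("index")
    if not (df["index"].to_numpy() == np.arange(1, len(df) + 1)).all():
        raise ValueError(f"{path}: node indices must be 1..n without gaps")
    return df["name"].tolist()


def write_node_labels(names: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(names, start=1):
            fh.write(f"{i}\t{name}\n")


def cohort_accounting(n_recruited: int = RECRUITED_ABSTRACT,
                      n_excluded: int = EXCLUDED) -> dict:
    """Raw and analyzed sample counts, recorded verbatim in the manifest.

    The source study reports two recruitment figures (142 in one place,
    139 in another) alongside 3 exclusions; both raw figures are carried
    through unresolved, and the analyzed count is recruited - excluded.
    """
    return {
        "n_recruited": int(n_recruited),
        "n_recruited_reported_elsewhere": RECRUITED_PARTICIPANTS,
        "n_excluded": int(n_excluded),
        "n_analyzed": int(n_recruited) - int(n_excluded),
    }


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir: str | Path, config_dict: dict,
                   outputs: list[str], extra: dict | None = None) -> Path:
    """Run manifest: config, seed, sample accounting, output checksums."""
    out_dir = Path(out_dir)
    manifest = {
        "config": config_dict,
        "sample_accounting": cohort_accounting(),
        "outputs": {
            name: file_checksum(out_dir / name) for name in sorted(outputs)
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
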