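"""Delimited-text I/O: time-series tables, manifests, matrices, BrainNet files.

Every on-disk artifact is plain text. Time series are tab-separated
regions x time matrices with a header row of region labels (one file per
subject); the cohort manifest is a TSV of (subject_id, group, path);
connectivity and adjacency matrices are square TSV tables with a label
header. Thresholded networks can be exported as BrainNet-Viewer-compatible
``.edge`` (square matrix) and ``.node`` (coordinates/colour/size/label)
files for surface rendering in external tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .network import ConnectivityMatrix
from .synthetic import SubjectTimeSeries

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_manifest",
    "read_manifest",
    "write_matrix",
    "read_matrix",
    "write_brainnet",
    "write_cohort",
    "read_cohort",
]


def write_timeseries(ts: SubjectTimeSeries, path: str | Path) -> None:
    """One subject as a regions x time TSV with a region-label header."""
    df = pd.DataFrame(ts.data.T, columns=ts.region_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries(
    path: str | Path, subject_id: str, group: str
) -> SubjectTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return SubjectTimeSeries(
        subject_id=subject_id,
        group=group,
        data=df.to_numpy().T,
        region_labels=list(df.columns),
    )


def write_manifest(rows: list[tuple[str, str, str]], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["subject_id", "group", "path"]).to_csv(
        path, sep="\t", index=False
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"subject_id", "group", "path"}
    if not expected.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(expected)}")
    return df


def write_matrix(
    M: np.ndarray, labels: list[str], path: str | Path
) -> None:
    pd.DataFrame(M, columns=labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(z=df.to_numpy(), region_labels=list(df.columns))


def write_brainnet(
    W: np.ndarray,
    labels: list[str],
    stem: str | Path,
    coords: np.ndarray | None = None,
    colors: np.ndarray | None = None,
    sizes: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Export a network as BrainNet Viewer ``.node`` / ``.edge`` files.

    Without an atlas the coordinates default to points on a sphere, which
    is sufficient for schematic rendering; colour (e.g. significance flag)
    and size (e.g. a nodal measure) columns default to 1.
    """
    stem = Path(stem)
    n = W.shape[0]
    if coords is None:
        t = np.arange(n)
        phi = np.arccos(1 - 2 * (t + 0.5) / n)
        theta = np.pi * (1 + 5**0.5) * t
        coords = 70 * np.column_stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
    colors = np.ones(n) if colors is None else np.asarray(colors)
    sizes = np.ones(n) if sizes is None else np.asarray(sizes)
    node_path = stem.with_suffix(".node")
    edge_path = stem.with_suffix(".edge")
    with open(node_path, "w") as fh:
        for i in range(n):
            x, y, z = coords[i]
            fh.write(
                f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{colors[i]:g}\t{sizes[i]:g}\t{labels[i]}\n"
            )
    np.savetxt(edge_path, W, fmt="%.6g", delimiter="\t")
    return node_path, edge_path


def write_cohort(
    cohort: list[SubjectTimeSeries], out_dir: str | Path
) -> Path:
    """Write every subject's time series plus the manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in cohort:
        p = out_dir / f"{ts.subject_id}.tsv"
        write_timeseries(ts, p)
        rows.append((ts.subject_id, ts.group, str(p)))
    manifest = out_dir / "manifest.tsv"
    write_manifest(rows, manifest)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SubjectTimeSeries]:
    df = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    out = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        out.append(read_timeseries(p, row["subject_id"], row["group"]))
    return out
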