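"""Readers and writers for the pipeline's plain-text formats.

Counts CSV (one row per observed grid point, 0-based cell index):

    time_min,cell_index,n_samples,n_labelled

Lines starting with ``#`` are header comments carrying the tool version and the
resolved seed, so every output is self-describing and reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import PosteriorSamples, ReplicatedDataset
from .measurement import CountData, SpaceTimeGrid

__all__ = [
    "read_counts",
    "write_counts",
    "write_posterior",
    "read_posterior",
    "write_replicates",
    "write_matrix",
    "write_truth",
]

COUNTS_COLUMNS = ["time_min", "cell_index", "n_samples", "n_labelled"]


def _header(seed) -> str:
    return f"# cryptdrift {__version__} seed={seed}\n"


def read_counts(path, n_cells: int | None = None) -> CountData:
    """Parse a Counts CSV into validated :class:`CountData`.

    Missing grid points are treated as n = 0; duplicate (time, cell) rows and
    rows with y > n are rejected with the offending location named.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != COUNTS_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(COUNTS_COLUMNS)}, got {','.join(df.columns)}")
    if len(df) == 0:
        grid = SpaceTimeGrid(n_cells=n_cells or 2, times=np.array([0.0]))
        zeros = np.zeros((1, grid.n_cells), dtype=np.int64)
        return CountData(grid=grid, n=zeros, y=zeros.copy())
    for col in COUNTS_COLUMNS[1:]:
        if not pd.api.types.is_integer_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() |
                     (pd.to_numeric(df[col], errors="coerce") % 1 != 0)]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-integer value in column {col} (line {line})")
    dup = df.duplicated(subset=["time_min", "cell_index"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicate (time, cell) row at line {line}")
    if (df["n_labelled"] > df["n_samples"]).any():
        line = int(df.index[df["n_labelled"] > df["n_samples"]][0]) + 2
        raise ValueError(f"{path}: n_labelled > n_samples at line {line}")
    if (df[COUNTS_COLUMNS[1:]] < 0).any().any():
        raise ValueError(f"{path}: negative count entries")

    times = np.sort(df["time_min"].unique()).astype(float)
    if times.size == 0:
        times = np.array([0.0])
    if n_cells is None:
        n_cells = int(df["cell_index"].max()) + 1 if len(df) else 2
        n_cells = max(n_cells, 2)
    grid = SpaceTimeGrid(n_cells=n_cells, times=times)
    n = np.zeros((grid.n_times, n_cells), dtype=np.int64)
    y = np.zeros_like(n)
    for _, row in df.iterrows():
        j = grid.time_index(float(row["time_min"]))
        i = int(row["cell_index"])
        if i >= n_cells:
            raise ValueError(f"{path}: cell_index {i} outside grid of {n_cells} cells")
        n[j, i] = row["n_samples"]
        y[j, i] = row["n_labelled"]
    return CountData(grid=grid, n=n, y=y)


def write_counts(data: CountData, path, seed="none") -> None:
    """Write observed grid points (n > 0) in the Counts CSV dialect."""
    path = Path(path)
    rows = []
    for j, t in enumerate(data.grid.times):
        for i in np.flatnonzero(data.n[j] > 0):
            rows.append((int(t) if float(t).is_integer() else float(t), int(i),
                         int(data.n[j, i]), int(data.y[j, i])))
    df = pd.DataFrame(rows, columns=COUNTS_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, index=False)


def write_posterior(post: PosteriorSamples, path, seed="none") -> None:
    """Posterior CSV: ``draw,k_0,...,k_{m-1},log_post``."""
    m = post.draws.shape[1]
    df = pd.DataFrame(post.draws, columns=[f"k_{d}" for d in range(m)])
    df.insert(0, "draw", np.arange(len(df)))
    df["log_post"] = post.log_post
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, index=False)


def read_posterior(path) -> np.ndarray:
    """Read back the draw matrix (n_draws, m) of a posterior CSV."""
    df = pd.read_csv(path, comment="#")
    kcols = [c for c in df.columns if c.startswith("k_")]
    if not kcols or "draw" not in df.columns:
        raise ValueError(f"{path}: not a posterior CSV")
    return df[kcols].to_numpy(dtype=float)


def write_replicates(reps: ReplicatedDataset, path, seed="none") -> None:
    """Replicates CSV: Counts dialect with a leading ``replicate`` column."""
    rows = []
    tmpl = reps.template
    for r in range(reps.ys.shape[0]):
        for j, t in enumerate(tmpl.grid.times):
            for i in np.flatnonzero(tmpl.n[j] > 0):
                rows.append((r, int(t) if float(t).is_integer() else float(t),
                             int(i), int(tmpl.n[j, i]), int(reps.ys[r, j, i])))
    df = pd.DataFrame(rows, columns=["replicate"] + COUNTS_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, index=False)


def write_matrix(values: np.ndarray, times, path, seed="none") -> None:
    """Dense text matrix (rows = times, columns = cell index), for heatmaps."""
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.insert(0, "time_min", np.asarray(times, dtype=float))
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, index=False)


def write_truth(truth, out_dir, seed="none") -> None:
    """Sidecar ground-truth files for recovery tests (synthetic bookkeeping)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sc = truth.scenario
    rows = {
        "condition": sc.condition,
        "scale": sc.scale,
        "seed": sc.seed,
        "variant": truth.variant,
        **{f"k_region_{r}": v for r, v in enumerate(truth.rates.base_regions)},
    }
    with open(out_dir / "truth.csv", "w") as fh:
        fh.write(_header(seed))
        pd.DataFrame([rows]).to_csv(fh, index=False)
    write_matrix(truth.latent.values, truth.latent.times, out_dir / "latent_L.csv",
                 seed=seed)
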