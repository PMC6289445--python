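"""Readers and writers for the repo-wide plain-text formats.

Time series use one CSV dialect throughout: a ``time_s`` column followed by
``ch01_hbo, ch01_hbr, ch02_hbo, ...`` (concentrations, µM) or
``ch01_od760, ch01_od830, ...`` (optical-density changes); one row per
sample, UTF-8, decimal point.  Sidecars are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .activation import ActivationMap
from .containers import ConcentrationSeries, EpochSet
from .synthetic import GroundTruth

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "write_od_csv",
    "read_od_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_epochs",
    "write_activation_map",
    "plot_activation_grid",
    "write_accuracy_grid",
]


def _ch_name(label) -> str:
    return f"ch{int(label):02d}" if str(label).isdigit() or isinstance(label, (int, np.integer)) else str(label)


def write_series_csv(series: ConcentrationSeries, path: str | Path) -> None:
    """Write a concentration series in the ``time_s,ch01_hbo,ch01_hbr,...`` dialect."""
    cols: dict[str, np.ndarray] = {"time_s": series.times}
    for i, lab in enumerate(series.channel_labels):
        cols[f"{_ch_name(lab)}_hbo"] = series.hbo[i]
        cols[f"{_ch_name(lab)}_hbr"] = series.hbr[i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> ConcentrationSeries:
    """Read the concentration CSV dialect back into a ConcentrationSeries."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("missing time_s column")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("need at least two samples to infer the sampling rate")
    fs = 1.0 / np.median(np.diff(t))
    hbo_cols = [c for c in df.columns if c.endswith("_hbo")]
    labels = []
    hbo, hbr = [], []
    for c in hbo_cols:
        base = c[: -len("_hbo")]
        labels.append(int(base[2:]) if base.startswith("ch") and base[2:].isdigit() else base)
        hbo.append(df[c].to_numpy())
        hbr.append(df[f"{base}_hbr"].to_numpy())
    return ConcentrationSeries(
        hbo=np.vstack(hbo), hbr=np.vstack(hbr), sampling_hz=float(fs),
        channel_labels=tuple(labels),
    )


def write_od_csv(od: np.ndarray, sampling_hz: float, wavelengths: tuple[float, float],
                 path: str | Path, channel_labels=None) -> None:
    """Write a two-wavelength ΔA series (n_ch, n_t, 2) as CSV."""
    od = np.asarray(od, dtype=float)
    n_ch, n_t, _ = od.shape
    labels = channel_labels or range(1, n_ch + 1)
    cols: dict[str, np.ndarray] = {"time_s": np.arange(n_t) / sampling_hz}
    for i, lab in enumerate(labels):
        for w, wl in enumerate(wavelengths):
            cols[f"{_ch_name(lab)}_od{int(wl)}"] = od[i, :, w]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_od_csv(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Read an OD CSV → (array (n_ch, n_t, 2), sampling_hz, wavelengths)."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    od_cols = [c for c in df.columns if "_od" in c]
    wls = sorted({float(c.split("_od")[1]) for c in od_cols})
    bases = sorted({c.split("_od")[0] for c in od_cols})
    od = np.stack(
        [
            np.stack([df[f"{b}_od{int(w)}"].to_numpy() for w in wls], axis=-1)
            for b in bases
        ]
    )
    return od, float(fs), (wls[0], wls[1])


def write_ground_truth_json(truth: GroundTruth, path: str | Path, seed: int | None = None) -> None:
    d = truth.to_dict()
    if seed is not None:
        d["seed"] = int(seed)
    Path(path).write_text(json.dumps(d, indent=1))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    beta = {}
    for key, b in d["beta"].items():
        ch, v = key.split("|")
        beta[(int(ch) if ch.isdigit() else ch, v)] = float(b)
    return GroundTruth(beta=beta, channels=tuple(d["channels"]))


def write_epochs(epochs: EpochSet, directory: str | Path, prefix: str = "epochs") -> None:
    """One CSV per valence (rows = trials of the channel-averaged signal,
    columns = time samples) plus a JSON sidecar with window/fs/labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for valence in sorted(set(epochs.labels)):
        sub = epochs.select(valence)
        avg = sub.roi_average()
        pd.DataFrame(avg).to_csv(directory / f"{prefix}_{valence}.csv", index=False)
    sidecar = {
        "window_s": list(epochs.window),
        "sampling_hz": epochs.sampling_hz,
        "labels": list(epochs.labels),
        "channel_labels": [str(c) for c in epochs.channel_labels],
    }
    (directory / f"{prefix}.json").write_text(json.dumps(sidecar, indent=1))


def write_activation_map(amap: ActivationMap, path: str | Path) -> None:
    """CSV with columns channel,beta,se,t,p,active."""
    amap.to_frame().to_csv(path, index=False)


def plot_activation_grid(amap: ActivationMap, path: str | Path, shape=(4, 4)) -> None:
    """Channel-grid t-value heatmap (4×4, labelled 1–16) — the flat stand-in
    for scalp-interpolated activation maps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = amap.t_values
    n = shape[0] * shape[1]
    grid = np.full(n, np.nan)
    grid[: len(t)] = t[:n]
    grid = grid.reshape(shape)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid, cmap="RdBu_r", vmin=-max(3, np.nanmax(np.abs(grid))),
                   vmax=max(3, np.nanmax(np.abs(grid))))
    for idx, ch in enumerate(amap.channels[:n]):
        r, c = divmod(idx, shape[1])
        ax.text(c, r, str(ch), ha="center", va="center", fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"t-map ({amap.valence}), t_crt = {amap.t_crt:.2f}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def write_accuracy_grid(grid, directory: str | Path, prefix: str = "accuracy") -> None:
    """Accuracy grid as CSV (pairs × subjects with aggregates) + JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid.to_frame().to_csv(directory / f"{prefix}_grid.csv")
    meta = {
        "problem": grid.problem,
        "scheme": list(grid.scheme) if isinstance(grid.scheme, tuple) else grid.scheme,
        "best_pair": list(grid.best_pair),
        "best_accuracy": grid.best_accuracy,
    }
    (directory / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=1))
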