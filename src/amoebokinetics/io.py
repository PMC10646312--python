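"""File formats shared by the analysis modules.

Canonical units are micrometres and seconds everywhere; trajectory tables use
columns ``cell_id, t_s, x_um, y_um``, kymographs are CSV matrices with rows =
boundary index and columns = frames, parameter sets and reports are JSON.
Mask movies are multi-page TIFF (or a directory of PNG frames) of a single
binary cell per frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gle_model import GLEParams, Trajectory

TRAJ_COLUMNS = ["cell_id", "t_s", "x_um", "y_um"]


def write_trajectories(trajs: list[Trajectory], path) -> None:
    frames = [pd.DataFrame({"cell_id": i, "t_s": t.times,
                            "x_um": t.positions[:, 0],
                            "y_um": t.positions[:, 1]})
              for i, t in enumerate(trajs)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory CSV; the sampling interval is inferred and validated."""
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table misses columns {missing}")
    out = []
    for _, grp in df.groupby("cell_id", sort=True):
        times = grp["t_s"].to_numpy(float)
        steps = np.diff(times)
        if len(steps) == 0:
            raise ValueError("trajectory with a single sample")
        dt = float(np.median(steps))
        if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform sampling in trajectory table")
        out.append(Trajectory(times=times,
                              positions=grp[["x_um", "y_um"]].to_numpy(float),
                              dt=dt))
    return out


def write_params(params: GLEParams, path, extra: dict | None = None) -> None:
    payload = params.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_params(path) -> GLEParams:
    d = json.loads(Path(path).read_text())
    return GLEParams(alpha=d["alpha"], beta=d["beta"], gamma=d["gamma"],
                     sigma=d["sigma"], sigma_x=d.get("sigma_x", 0.0))


def write_vac(lags: np.ndarray, vac: np.ndarray, path,
              n_samples=None) -> None:
    df = pd.DataFrame({"lag_s": lags, "vac_um2_s2": vac})
    if n_samples is not None:
        df["n_samples"] = n_samples
    df.to_csv(path, index=False)


def read_vac(path):
    df = pd.read_csv(path)
    return df["lag_s"].to_numpy(float), df["vac_um2_s2"].to_numpy(float)


def read_masks(path) -> np.ndarray:
    """Binary mask movie from a multi-page TIFF or a directory of PNG frames."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio
        frames = sorted(path.glob("*.png"))
        if not frames:
            raise ValueError(f"no PNG frames in {path}")
        stack = np.stack([iio.imread(f) for f in frames])
    else:
        import tifffile
        stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim == 4:  # drop a trailing color channel
        stack = stack[..., 0]
    return stack > 0


def write_masks(masks: np.ndarray, path) -> None:
    import tifffile
    tifffile.imwrite(path, (np.asarray(masks) > 0).astype(np.uint8) * 255,
                     photometric='minisblack')


def write_kymograph(array: np.ndarray, path) -> None:
    """Rows = boundary index (1-based in the header), columns = frames."""
    df = pd.DataFrame(array)
    df.index = np.arange(1, array.shape[0] + 1)
    df.index.name = "boundary_index"
    df.to_csv(path)


def read_kymograph(path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy(float)


def render_kymograph(array: np.ndarray, path, cmap: str = "RdBu_r") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, 4))
    lim = np.nanmax(np.abs(array))
    im = ax.imshow(array, aspect="auto", origin="lower", cmap=cmap,
                   vmin=-lim, vmax=lim, interpolation="nearest")
    ax.set_xlabel("frame")
    ax.set_ylabel("boundary index")
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True,
                                     default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
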