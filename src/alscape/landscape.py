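"""Potency hyper-surface interpolation and potency color coding.

Given a 2D embedding of an activity class, the third dimension (compound
potency, pKi) is interpolated into a coherent hyper-surface by Gaussian
process regression with a squared-exponential kernel plus white noise. The
surface is evaluated on a regular grid over the padded embedding bounding box
and colored by a fixed green→yellow→red potency gradient anchored at
pKi 5.75 (green, and below) and pKi 8.75 (red, and above).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

__all__ = [
    "ColorMap",
    "GPModel",
    "SurfaceGrid",
    "gpr_fit",
    "gpr_surface",
    "potency_to_color",
    "potencies_to_colors",
    "surface_roughness",
    "write_surface_csv",
    "read_surface_csv",
]

_GREEN = np.array([0.0, 1.0, 0.0])
_YELLOW = np.array([1.0, 1.0, 0.0])
_RED = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class ColorMap:
    """Potency → RGB gradient.

    ``gradient`` mode (default) interpolates green→yellow over
    [green_anchor, midpoint] and yellow→red over [midpoint, red_anchor];
    ``band`` mode paints the whole interior range flat yellow. Values outside
    the anchors are clamped.
    """

    green_anchor: float = 5.75
    red_anchor: float = 8.75
    mode: str = "gradient"

    def __post_init__(self) -> None:
        if self.green_anchor >= self.red_anchor:
            raise ValueError("green_anchor must be below red_anchor")
        if self.mode not in ("gradient", "band"):
            raise ValueError(f"unknown color mode {self.mode!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.green_anchor + self.red_anchor)


def potencies_to_colors(p: np.ndarray, cmap: ColorMap | None = None) -> np.ndarray:
    """Vectorized potency → RGB mapping; output shape p.shape + (3,)."""
    cmap = cmap if cmap is not None else ColorMap()
    p = np.asarray(p, dtype=float)
    out = np.empty(p.shape + (3,))
    if cmap.mode == "band":
        out[...] = _YELLOW
        out[p <= cmap.green_anchor] = _GREEN
        out[p >= cmap.red_anchor] = _RED
        return out
    lo, mid, hi = cmap.green_anchor, cmap.midpoint, cmap.red_anchor
    t1 = np.clip((p - lo) / (mid - lo), 0.0, 1.0)[..., None]
    t2 = np.clip((p - mid) / (hi - mid), 0.0, 1.0)[..., None]
    lower = (1.0 - t1) * _GREEN + t1 * _YELLOW
    upper = (1.0 - t2) * _YELLOW + t2 * _RED
    out = np.where((p <= mid)[..., None], lower, upper)
    return out


def potency_to_color(p: float, cmap: ColorMap | None = None) -> tuple[float, float, float]:
    """RGB triple in [0,1] for a single pKi value."""
    if not np.isfinite(p):
        raise ValueError("potency must be finite")
    return tuple(potencies_to_colors(np.array(p), cmap))


@dataclass
class GPModel:
    """Fitted GP: squared-exponential kernel + white noise, zero-mean on centered y."""

    gp: GaussianProcessRegressor
    coords: np.ndarray
    potencies: np.ndarray
    signal_variance: float
    length_scale: float
    noise_variance: float

    def predict(self, xy: np.ndarray) -> np.ndarray:
        return self.gp.predict(np.asarray(xy, dtype=float))

    def hyperparameters(self) -> dict:
        return {
            "signal_variance": self.signal_variance,
            "length_scale": self.length_scale,
            "noise_variance": self.noise_variance,
        }


def gpr_fit(
    coords: np.ndarray,
    potencies: np.ndarray,
    seed: int = 0,
    n_restarts: int = 3,
    noise_bounds: tuple[float, float] = (1e-8, 1.0),
) -> GPModel:
    """Fit the potency surface GP by marginal-likelihood maximization.

    Length-scale bounds are set relative to the coordinate span (1e-2 to 1e2
    of the bounding-box diagonal) so hyperparameter search is scale-free.
    """
    coords = np.asarray(coords, dtype=float)
    potencies = np.asarray(potencies, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2)")
    if coords.shape[0] != potencies.shape[0]:
        raise ValueError("coords and potencies disagree in length")
    if coords.shape[0] < 3:
        raise ValueError("GP fit needs at least 3 points")
    if not (np.all(np.isfinite(coords)) and np.all(np.isfinite(potencies))):
        raise ValueError("coords and potencies must be finite")

    span = np.linalg.norm(coords.max(axis=0) - coords.min(axis=0))
    span = span if span > 0 else 1.0
    y_var = float(potencies.var())
    amp = max(y_var, 1e-4)
    kernel = (
        ConstantKernel(amp, (amp * 1e-3, amp * 1e3 + 1.0))
        * RBF(span / 10.0, (span * 1e-2, span * 1e2))
        + WhiteKernel(1e-4, noise_bounds)
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
    )
    gp.fit(coords, potencies)
    k = gp.kernel_
    return GPModel(
        gp=gp,
        coords=coords,
        potencies=potencies,
        signal_variance=float(k.k1.k1.constant_value),
        length_scale=float(k.k1.k2.length_scale),
        noise_variance=float(k.k2.noise_level),
    )


@dataclass
class SurfaceGrid:
    """Regular surface grid: xs (W,), ys (H,), z (H, W) pKi, colors (H, W, 3)."""

    xs: np.ndarray
    ys: np.ndarray
    z: np.ndarray
    colors: np.ndarray
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.z.shape != (self.ys.size, self.xs.size):
            raise ValueError("z shape must be (len(ys), len(xs))")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("surface contains non-finite values")


def gpr_surface(
    model: GPModel,
    resolution: int = 100,
    padding: float = 0.05,
    cmap: ColorMap | None = None,
) -> SurfaceGrid:
    """Posterior-mean surface on a regular grid over the padded bounding box."""
    if resolution < 8:
        raise ValueError("resolution must be ≥ 8")
    lo = model.coords.min(axis=0)
    hi = model.coords.max(axis=0)
    extent = np.maximum(hi - lo, 1e-9)
    lo = lo - padding * extent
    hi = hi + padding * extent
    xs = np.linspace(lo[0], hi[0], resolution)
    ys = np.linspace(lo[1], hi[1], resolution)
    X, Y = np.meshgrid(xs, ys)
    z = model.predict(np.column_stack([X.ravel(), Y.ravel()])).reshape(resolution, resolution)
    cmap = cmap if cmap is not None else ColorMap()
    return SurfaceGrid(
        xs=xs, ys=ys, z=z, colors=potencies_to_colors(z, cmap),
        hyperparameters=model.hyperparameters(),
    )


def surface_roughness(grid: SurfaceGrid) -> float:
    """Mean gradient magnitude of z — a scalar ruggedness summary."""
    gy, gx = np.gradient(grid.z, grid.ys, grid.xs)
    return float(np.mean(np.hypot(gx, gy)))


def write_surface_csv(grid: SurfaceGrid, path, sidecar_path=None) -> None:
    """Serialize to long-format CSV (x, y, z) plus a JSON hyperparameter sidecar."""
    X, Y = np.meshgrid(grid.xs, grid.ys)
    pd.DataFrame({"x": X.ravel(), "y": Y.ravel(), "z": grid.z.ravel()}).to_csv(path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(grid.hyperparameters, fh, indent=2)


def read_surface_csv(path, cmap: ColorMap | None = None) -> SurfaceGrid:
    df = pd.read_csv(path)
    xs = np.unique(df["x"].to_numpy())
    ys = np.unique(df["y"].to_numpy())
    z = df["z"].to_numpy().reshape(ys.size, xs.size)
    return SurfaceGrid(xs=xs, ys=ys, z=z, colors=potencies_to_colors(z, cmap or ColorMap()))
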