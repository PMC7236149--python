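"""Landscape rendering, reduced-information image variants, and collections.

Surfaces are rendered off-screen as 3D plots at 1200×800 (axes suppressed,
white background) from a grid of viewpoints: azimuth ∈ {0°, 90°, 180°, 270°}
× elevation ∈ {0°, 35°, 65°, 90°}. Each rendering is cropped to its content,
resized to 360×220, and optionally reduced to grayscale (0.299 R + 0.587 G +
0.114 B), black/white (Otsu), Sobel-edge, or Canny-edge variants. A
single-channel 360×220 image flattens row-wise into a 79,200-feature vector.

Collections group the (projection × elevation × azimuth) combinations used
for model training; the seven standard collections are available by name in
``STANDARD_COLLECTIONS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from scipy.ndimage import convolve
from skimage import feature as _skfeature
from skimage.transform import resize as _skresize

from .landscape import SurfaceGrid

__all__ = [
    "AZIMUTHS",
    "ELEVATIONS",
    "ENCODINGS",
    "STANDARD_COLLECTIONS",
    "SOBEL_GX",
    "SOBEL_GY",
    "ViewSpec",
    "RenderedImage",
    "CollectionSpec",
    "render_landscape",
    "crop_resize",
    "to_grayscale",
    "otsu_binarize",
    "sobel_edges",
    "canny_edges",
    "encode_variant",
    "normalize_and_flatten",
    "build_collection",
    "collection_size",
]

AZIMUTHS = (0, 90, 180, 270)
ELEVATIONS = (0, 35, 65, 90)
ENCODINGS = ("color", "grayscale", "bw", "sobel", "canny")

#: Sobel convolution matrices (the vertical filter G_y is the one applied).
SOBEL_GX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_GY = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)

RENDER_SIZE = (1200, 800)  # (width, height)
CROP_SIZE = (220, 360)  # (height, width) → 79,200 features


@dataclass(frozen=True)
class ViewSpec:
    """Viewpoint: azimuth (horizontal rotation) and elevation (tilt), degrees."""

    azimuth: float
    elevation: float
    strict: bool = True

    def __post_init__(self) -> None:
        if self.strict and (self.azimuth not in AZIMUTHS or self.elevation not in ELEVATIONS):
            raise ValueError(
                f"view ({self.azimuth}, {self.elevation}) outside the standard grids "
                f"{AZIMUTHS} × {ELEVATIONS}; pass strict=False to extend"
            )


@dataclass
class RenderedImage:
    """Pixel array in [0, 1] (H×W grayscale or H×W×3 color) plus provenance."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be H×W or H×W×C")
        if self.pixels.min() < -1e-6 or self.pixels.max() > 1 + 1e-6:
            raise ValueError("pixel intensities must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def with_pixels(self, pixels: np.ndarray, **meta_updates) -> "RenderedImage":
        return RenderedImage(pixels=pixels, meta={**self.meta, **meta_updates})


@dataclass(frozen=True)
class CollectionSpec:
    """Subset of projections × elevations × azimuths plus an encoding."""

    projections: tuple[str, ...] = ("MDS", "Neuroscale")
    elevations: tuple[float, ...] = ELEVATIONS
    azimuths: tuple[float, ...] = AZIMUTHS
    encoding: str = "color"

    def __post_init__(self) -> None:
        if not (self.projections and self.elevations and self.azimuths):
            raise ValueError("projections, elevations and azimuths must be nonempty")
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")

    def n_views(self) -> int:
        return len(self.projections) * len(self.elevations) * len(self.azimuths)


#: The seven standard collections: 1–3 vary the projection over all views,
#: 4–7 fix a single elevation and combine both projections.
STANDARD_COLLECTIONS: dict[str, CollectionSpec] = {
    "1": CollectionSpec(),
    "2": CollectionSpec(projections=("MDS",)),
    "3": CollectionSpec(projections=("Neuroscale",)),
    "4": CollectionSpec(elevations=(90,)),
    "5": CollectionSpec(elevations=(65,)),
    "6": CollectionSpec(elevations=(35,)),
    "7": CollectionSpec(elevations=(0,)),
}


def collection_size(n_classes: int, spec: CollectionSpec, n_variants: int = 3) -> int:
    """Number of images a collection yields: classes × variants × views."""
    return n_classes * n_variants * spec.n_views()


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_landscape(
    surface: SurfaceGrid,
    view: ViewSpec,
    size: tuple[int, int] = RENDER_SIZE,
    dpi: int = 100,
    zlim: tuple[float, float] | None = None,
) -> RenderedImage:
    """Off-screen 3D surface render: white background, no axes, potency colors.

    ``zlim`` fixes the vertical (pKi) axis range; rendering a set of
    landscapes with a common ``zlim`` keeps their altitudes comparable, so a
    flat landscape stays visually flat instead of being stretched to fill
    the frame. Rasterization via the Agg backend is bit-reproducible for
    identical inputs and configuration.
    """
    width, height = size
    fig = Figure(figsize=(width / dpi, height / dpi), dpi=dpi)
    FigureCanvasAgg(fig)
    ax = fig.add_axes([0, 0, 1, 1], projection="3d")
    try:
        X, Y = np.meshgrid(surface.xs, surface.ys)
        ax.plot_surface(
            X, Y, surface.z,
            facecolors=surface.colors, shade=False,
            antialiased=False, rstride=1, cstride=1, linewidth=0,
        )
        ax.view_init(elev=view.elevation, azim=view.azimuth)
        if zlim is not None:
            ax.set_zlim(*zlim)
        ax.set_axis_off()
        ax.set_facecolor("white")
        fig.patch.set_facecolor("white")
        fig.canvas.draw()
        buf = np.asarray(fig.canvas.buffer_rgba())[:, :, :3]
    finally:
        fig.clf()
    pixels = buf.astype(np.float32) / 255.0
    return RenderedImage(
        pixels=pixels,
        meta={"azimuth": view.azimuth, "elevation": view.elevation, "encoding": "color"},
    )


# ---------------------------------------------------------------------------
# Pre-processing variants
# ---------------------------------------------------------------------------

def crop_resize(
    img: RenderedImage,
    target: tuple[int, int] = CROP_SIZE,
    pad: float = 0.02,
    crop_box: tuple[int, int, int, int] | None = None,
    background_tol: float = 2.0 / 255.0,
) -> RenderedImage:
    """Crop away the white background, then resize to 360×220 (bilinear).

    The default crop is the tight bounding box of non-background pixels
    padded by 2 % of its extent; a fixed ``crop_box`` (r0, r1, c0, c1) can be
    supplied instead. Aspect ratio is not preserved.
    """
    px = img.pixels
    if crop_box is None:
        nonbg = px < 1.0 - background_tol
        if px.ndim == 3:
            nonbg = nonbg.any(axis=2)
        rows = np.flatnonzero(nonbg.any(axis=1))
        cols = np.flatnonzero(nonbg.any(axis=0))
        if rows.size == 0:
            raise ValueError("cannot crop a fully-background image")
        pr = int(round(pad * (rows[-1] - rows[0] + 1)))
        pc = int(round(pad * (cols[-1] - cols[0] + 1)))
        r0 = max(rows[0] - pr, 0)
        r1 = min(rows[-1] + pr + 1, px.shape[0])
        c0 = max(cols[0] - pc, 0)
        c1 = min(cols[-1] + pc + 1, px.shape[1])
    else:
        r0, r1, c0, c1 = crop_box
    cropped = px[r0:r1, c0:c1]
    out_shape = target if cropped.ndim == 2 else (*target, cropped.shape[2])
    resized = _skresize(cropped, out_shape, order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    return img.with_pixels(np.clip(resized, 0.0, 1.0))


def to_grayscale(img: RenderedImage) -> RenderedImage:
    """Weighted channel sum: 0.299 R + 0.587 G + 0.114 B."""
    if img.n_channels != 3:
        raise ValueError(f"grayscale conversion needs 3 channels, got {img.n_channels}")
    gray = (img.pixels * np.array([0.299, 0.587, 0.114], dtype=np.float32)).sum(axis=2)
    return img.with_pixels(np.clip(gray, 0.0, 1.0), encoding="grayscale")


def otsu_binarize(img: RenderedImage) -> tuple[int, RenderedImage]:
    """Binary Otsu thresholding on the 8-bit-quantized histogram.

    Scans all 256 candidate thresholds and keeps the one maximizing the
    between-class variance (ties resolved to the mean tied threshold, which
    places the cut midway between well-separated modes); pixels strictly
    above it map to 1. A constant image degenerates to an all-zero output
    with the threshold at its level.
    """
    if img.n_channels != 1:
        raise ValueError("Otsu binarization needs a single-channel image")
    q = np.round(img.pixels * 255.0).astype(np.int64)
    if q.min() == q.max():
        return int(q.flat[0]), img.with_pixels(np.zeros_like(img.pixels), encoding="bw")
    hist = np.bincount(q.ravel(), minlength=256).astype(float)
    total = hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)
    sum0 = np.cumsum(hist * levels)
    w1 = total - w0
    mu0 = np.divide(sum0, w0, out=np.zeros(256), where=w0 > 0)
    mu1 = np.divide(sum0[-1] - sum0, w1, out=np.zeros(256), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    ties = np.flatnonzero(between == between.max())
    t = int(np.round(ties.mean()))
    bw = (q > t).astype(np.float32)
    return t, img.with_pixels(bw, encoding="bw")


def sobel_edges(img: RenderedImage) -> RenderedImage:
    """Vertical Sobel filter G_y: convolution, absolute value, rescale to [0,1].

    Borders are handled by edge replication. G_y responds to row-wise
    (vertical) intensity changes, i.e. horizontal edges.
    """
    if img.n_channels != 1:
        raise ValueError("Sobel filtering needs a single-channel image")
    if min(img.pixels.shape[:2]) < 3:
        raise ValueError("image smaller than the 3×3 Sobel kernel")
    resp = np.abs(convolve(img.pixels.astype(float), SOBEL_GY, mode="nearest"))
    peak = resp.max()
    if peak > 0:
        resp = resp / peak
    return img.with_pixels(resp.astype(np.float32), encoding="sobel")


def canny_edges(img: RenderedImage, low: float = 100.0, high: float = 200.0) -> RenderedImage:
    """Binary Canny edge map with hysteresis thresholds in 8-bit gradient units.

    Gaussian smoothing, Sobel gradient, non-maximum suppression and
    hysteresis are delegated to scikit-image; thresholds apply to the
    unnormalized gradient magnitude of the 0–255 image, matching the common
    8-bit convention.
    """
    if img.n_channels != 1:
        raise ValueError("Canny filtering needs a single-channel image")
    if low >= high:
        raise ValueError("Canny requires low < high hysteresis thresholds")
    q = np.round(img.pixels * 255.0).astype(float)
    edges = _skfeature.canny(q, sigma=1.0, low_threshold=low, high_threshold=high)
    return img.with_pixels(edges.astype(np.float32), encoding="canny")


def content_bbox(img: RenderedImage, background_tol: float = 2.0 / 255.0):
    """(r0, r1, c0, c1) bounding box of non-background pixels."""
    px = img.pixels
    nonbg = px < 1.0 - background_tol
    if px.ndim == 3:
        nonbg = nonbg.any(axis=2)
    rows = np.flatnonzero(nonbg.any(axis=1))
    cols = np.flatnonzero(nonbg.any(axis=0))
    if rows.size == 0:
        raise ValueError("fully-background image has no content box")
    return int(rows[0]), int(rows[-1] + 1), int(cols[0]), int(cols[-1] + 1)


def encode_variant(
    color_img: RenderedImage,
    encoding: str,
    canny_low: float = 100.0,
    canny_high: float = 200.0,
    crop: bool = True,
    crop_box: tuple[int, int, int, int] | None = None,
) -> RenderedImage:
    """Fixed pipeline: crop/resize → grayscale → {bw | sobel | canny}."""
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}")
    img = crop_resize(color_img, crop_box=crop_box) if crop else color_img
    if encoding == "color":
        return img
    gray = to_grayscale(img)
    if encoding == "grayscale":
        return gray
    if encoding == "bw":
        return otsu_binarize(gray)[1]
    if encoding == "sobel":
        return sobel_edges(gray)
    return canny_edges(gray, canny_low, canny_high)


def normalize_and_flatten(img: RenderedImage) -> np.ndarray:
    """Row-major flattening of a single-channel 360×220 image → 79,200 floats.

    Pixel (r, c) lands at index r·W + c with W = 360; intensities are float32
    in [0, 1].
    """
    if img.n_channels != 1:
        raise ValueError("feature extraction needs a single-channel image")
    if img.pixels.shape != CROP_SIZE:
        raise ValueError(f"expected {CROP_SIZE} image, got {img.pixels.shape}")
    return np.clip(img.pixels, 0.0, 1.0).astype(np.float32).ravel(order="C")


# ---------------------------------------------------------------------------
# Collections
# ---------------------------------------------------------------------------

def build_collection(
    surfaces: dict[tuple[str, str, str], SurfaceGrid],
    spec: CollectionSpec,
    size: tuple[int, int] = RENDER_SIZE,
    render: bool = True,
    canny_low: float = 100.0,
    canny_high: float = 200.0,
    zlim: tuple[float, float] | None = None,
) -> tuple[list[RenderedImage] | None, pd.DataFrame]:
    """Render one image per (class × variant × projection × elevation × azimuth).

    ``surfaces`` maps (class name, variant, projection) to the corresponding
    surface grid; every class must provide all three topology variants for
    each requested projection. ``zlim`` defaults to the common z-range of
    all surfaces so altitudes stay comparable across images. With
    ``render=False`` only the manifest is produced (the combinatorial
    contract is resolution- and pixel-free).
    """
    class_names = sorted({k[0] for k in surfaces})
    variants = ("heterogeneous", "smooth", "rugged")
    for name in class_names:
        for variant in variants:
            for proj in spec.projections:
                if (name, variant, proj) not in surfaces:
                    raise ValueError(
                        f"class {name!r}: missing surface for variant {variant!r}, "
                        f"projection {proj!r}"
                    )
    if render and zlim is None and surfaces:
        zmin = min(s.z.min() for s in surfaces.values())
        zmax = max(s.z.max() for s in surfaces.values())
        margin = 0.05 * max(zmax - zmin, 1e-9)
        zlim = (float(zmin - margin), float(zmax + margin))
    rows = []
    raws: list[RenderedImage] = []
    for name in class_names:
        for variant in variants:
            for proj in spec.projections:
                for elev in spec.elevations:
                    for azim in spec.azimuths:
                        rows.append({
                            "class": name, "variant": variant, "projection": proj,
                            "azimuth": azim, "elevation": elev, "encoding": spec.encoding,
                        })
                        if render:
                            raw = render_landscape(
                                surfaces[(name, variant, proj)],
                                ViewSpec(azim, elev), size=size, zlim=zlim,
                            )
                            raw.meta.update(rows[-1])
                            raws.append(raw)
    manifest = pd.DataFrame(rows)
    if not render:
        return None, manifest
    # shared crop box (union of content boxes, padded 2 %): keeps relative
    # altitude comparable across images instead of stretching each to fill
    boxes = np.array([content_bbox(r) for r in raws])
    r0, c0 = boxes[:, 0].min(), boxes[:, 2].min()
    r1, c1 = boxes[:, 1].max(), boxes[:, 3].max()
    pr = int(round(0.02 * (r1 - r0)))
    pc = int(round(0.02 * (c1 - c0)))
    h, w = raws[0].pixels.shape[:2]
    box = (max(r0 - pr, 0), min(r1 + pr, h), max(c0 - pc, 0), min(c1 + pc, w))
    images = [
        encode_variant(raw, spec.encoding, canny_low, canny_high, crop_box=box)
        for raw in raws
    ]
    return images, manifest
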