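"""Synthetic activity classes and analytic surface fixtures.

Real activity classes pair clustered chemical neighborhoods (analog series)
with potency values whose local behavior encodes SAR continuity (smooth
gradients) or discontinuity (activity cliffs: highly similar compound pairs
with a large pKi gap). The generator emulates exactly that statistical
structure on random bit-vector fingerprints:

* each class is a set of clusters, one prototype fingerprint per cluster,
  members obtained by independent per-bit flips of the prototype;
* each cluster owns a latent 2D coordinate and each member a jittered copy;
* ``smooth`` topology assigns potency as a linear ramp over the latent plane
  plus bounded noise, ``rugged`` splits each cluster into two potency modes a
  guaranteed ΔpKi apart (planted cliffs), and ``heterogeneous`` applies the
  smooth rule to half of the clusters and the rugged rule to the other half.
  The two modes of a cliff cluster additionally differ by a small dedicated
  set of fingerprint bits, mirroring real activity cliffs, which are formed
  by distinct (if highly similar) analogs rather than identical structures.

Noise and latent jitter are truncated at 1.5 standard deviations, so the
construction carries hard guarantees: smooth classes contain no cliff pairs
and every rugged cluster contains at least one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compound_data import ActivityClass, Compound, Fingerprint, pairwise_tanimoto
from .landscape import ColorMap, SurfaceGrid, potencies_to_colors

__all__ = [
    "SyntheticClassSpec",
    "SurfaceFixtureSpec",
    "generate_activity_class",
    "generate_surface_fixture",
    "planted_cliff_count",
]


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Parameters of one synthetic activity class.

    Defaults are desk-scale: 150 compounds in 6 clusters with pKi spanning
    5–10 log units and cliffs of 2.5 pKi, echoing the size envelope and
    multi-log-unit potency spreads of curated public activity classes.
    """

    n_compounds: int = 150
    n_clusters: int = 6
    fp_length: int = 1024
    bit_density: float = 0.08
    flip_rate: float = 0.01
    topology: str = "heterogeneous"
    pki_range: tuple[float, float] = (5.0, 10.0)
    cliff_delta: float = 2.5
    mode_shift: float = 0.02  # fraction of bits separating the two cliff modes
    noise_sigma: float = 0.2
    latent_jitter: float = 0.015
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0.0 < self.flip_rate < 0.5):
            raise ValueError("flip_rate must be in (0, 0.5)")
        if self.pki_range[0] >= self.pki_range[1]:
            raise ValueError("pki_range must satisfy min < max")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")
        if self.n_clusters > self.n_compounds:
            raise ValueError("n_clusters may not exceed n_compounds")
        if self.topology not in ("smooth", "rugged", "heterogeneous"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass(frozen=True)
class SurfaceFixtureSpec:
    """Analytic surface: base level plus Gaussian bumps on the unit square."""

    grid_size: int = 64
    n_peaks: int = 1
    amplitude: float = 2.5
    width: float = 0.06
    base_level: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be ≥ 0")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


def _truncnorm(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Normal noise truncated (clipped) at ±1.5 σ — bounded measurement noise."""
    if sigma == 0:
        return np.zeros(size)
    return np.clip(rng.normal(0.0, sigma, size), -1.5 * sigma, 1.5 * sigma)


def generate_activity_class(spec: SyntheticClassSpec) -> ActivityClass:
    """Generate one synthetic activity class; deterministic per spec.seed."""
    rng = np.random.default_rng(spec.seed)
    k, n = spec.n_clusters, spec.n_compounds

    # cluster prototypes; re-draw all-zero prototypes (possible at low density)
    protos = rng.random((k, spec.fp_length)) < spec.bit_density
    for i in range(k):
        while not protos[i].any():
            protos[i] = rng.random(spec.fp_length) < spec.bit_density

    # latent cluster centers: jittered latin-hypercube grid so the latent
    # spread is bounded away from zero (keeps the smooth ramp slope bounded)
    cx = (rng.permutation(k) + rng.random(k)) / k
    cy = (rng.permutation(k) + rng.random(k)) / k
    centers = np.column_stack([cx, cy])

    # near-equal cluster sizes, remainder to earliest clusters
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]

    # per-cluster potency rule: smooth ramp over latent x+y, or bimodal cliffs
    ramp_pos = centers.sum(axis=1) / 2.0  # in [0, 1]
    lo, hi = spec.pki_range
    if spec.topology == "smooth":
        rugged_clusters: set[int] = set()
    elif spec.topology == "rugged":
        rugged_clusters = set(range(k))
    else:
        rugged_clusters = set(rng.choice(k, size=k // 2, replace=False))

    # half-separation that guarantees a ≥ cliff_delta gap after truncated noise
    half_gap = spec.cliff_delta / 2.0 + 1.5 * spec.noise_sigma

    compounds: list[Compound] = []
    width = len(str(n - 1))
    idx = 0
    for ci in range(k):
        m = sizes[ci]
        flips = rng.random((m, spec.fp_length)) < spec.flip_rate
        bits = protos[ci][None, :] ^ flips
        latent = centers[ci][None, :] + np.column_stack(
            [_truncnorm(rng, spec.latent_jitter, m), _truncnorm(rng, spec.latent_jitter, m)]
        )
        if ci in rugged_clusters:
            # cluster base potency kept inside the range by the half-gap margin
            span = (hi - lo) - 2.0 * half_gap
            span = max(span, 0.0)
            center_p = lo + half_gap + span * ramp_pos[ci]
            signs = np.where(np.arange(m) % 2 == 0, -1.0, 1.0)
            pot = center_p + signs * half_gap + _truncnorm(rng, spec.noise_sigma, m)
            # high-potency mode carries a dedicated bit-set shift: cliff
            # partners are distinct analogs, not identical structures
            n_shift = int(round(spec.mode_shift * spec.fp_length))
            if n_shift:
                shift_bits = rng.choice(spec.fp_length, size=n_shift, replace=False)
                bits[signs > 0] = bits[signs > 0] ^ np.isin(
                    np.arange(spec.fp_length), shift_bits
                )
        else:
            pos = latent.sum(axis=1) / 2.0
            pot = lo + (hi - lo) * np.clip(pos, 0.0, 1.0) + _truncnorm(rng, spec.noise_sigma, m)
        for j in range(m):
            b = bits[j]
            if not b.any():
                b = protos[ci].copy()
            compounds.append(
                Compound(f"{spec.name}_{idx:0{width}d}", Fingerprint(b), float(pot[j]))
            )
            idx += 1
    return ActivityClass(name=spec.name, compounds=compounds)


def generate_surface_fixture(spec: SurfaceFixtureSpec, cmap: ColorMap | None = None) -> SurfaceGrid:
    """Analytic surface grid with exactly ``n_peaks`` well-separated bumps."""
    rng = np.random.default_rng(spec.seed)
    g = spec.grid_size
    xs = np.linspace(0.0, 1.0, g)
    ys = np.linspace(0.0, 1.0, g)
    X, Y = np.meshgrid(xs, ys)
    z = np.full((g, g), float(spec.base_level))

    if spec.n_peaks > 0:
        # peak centers on a coarse sub-grid with jitter: enforced separation
        side = int(np.ceil(np.sqrt(spec.n_peaks)))
        cells = rng.permutation(side * side)[: spec.n_peaks]
        cw = 1.0 / side
        for c in cells:
            r, q = divmod(int(c), side)
            px = (q + 0.35 + 0.3 * rng.random()) * cw
            py = (r + 0.35 + 0.3 * rng.random()) * cw
            z += spec.amplitude * np.exp(-((X - px) ** 2 + (Y - py) ** 2) / (2 * spec.width**2))

    cmap = cmap if cmap is not None else ColorMap()
    return SurfaceGrid(xs=xs, ys=ys, z=z, colors=potencies_to_colors(z, cmap))


def planted_cliff_count(cls: ActivityClass, tc_min: float = 0.6, dp_min: float = 2.0) -> int:
    """Number of unordered activity-cliff pairs: Tc ≥ tc_min and |ΔpKi| ≥ dp_min."""
    n = len(cls)
    if n < 2:
        return 0
    tc = pairwise_tanimoto(cls)
    p = cls.potencies
    dp = np.abs(p[:, None] - p[None, :])
    mask = (tc >= tc_min) & (dp >= dp_min)
    return int(np.triu(mask, k=1).sum())
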