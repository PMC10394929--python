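"""Synthetic wheat-ear fixtures: images, masks and exact per-side grain counts.

One generated sample emulates a photograph of one side of a wheat ear at the
grain-filling stage: grain-shaped ellipses arranged in two staggered columns
along a vertical rachis, on either a field-like (low-frequency green-brown
noise) or white-paper background, with radial grain shading, a lateral
illumination ramp and pixel noise.  The binary mask is exactly the union of
the rendered ellipses and the true per-side count is the number of ellipses
placed, so the sample doubles as a counting oracle.

``adhesion`` controls how deeply vertically neighboring grains interpenetrate,
as a fraction of the mean minor axis: at 0 all grains are disjoint (separated
by a small gap); as it grows, within-column necks appear and widen — exactly
the failure mode the distance-transform counting pipeline must resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import draw

__all__ = ["EarSpec", "SyntheticSample", "PlacementError", "generate_ear", "generate_dataset"]

_BACKGROUNDS = ("field", "white")


class PlacementError(ValueError):
    pass


@dataclass(frozen=True)
class EarSpec:
    """Geometry and rendering ranges for one synthetic ear side (480 x 480 default).

    Axis ranges are full ellipse axes in pixels; ``adhesion`` is the overlap
    fraction of the mean minor axis between vertical neighbors in a column.
    """

    grains_per_side: tuple = (16, 24)
    major_axis: tuple = (18.0, 30.0)
    minor_axis: tuple = (10.0, 16.0)
    adhesion: float = 0.0
    background: str = "field"
    noise_level: float = 3.0
    illumination: float = 10.0
    edge: int = 480
    gap: float = 3.0

    def __post_init__(self):
        if not 0 <= self.adhesion < 1:
            raise ValueError("adhesion must lie in [0, 1)")
        if self.background not in _BACKGROUNDS:
            raise ValueError(f"background must be one of {_BACKGROUNDS}")
        lo, hi = self.grains_per_side
        if lo < 0 or hi < lo:
            raise ValueError("grains_per_side must be a non-negative lo <= hi range")
        for lo, hi in (self.major_axis, self.minor_axis):
            if lo <= 0 or hi < lo:
                raise ValueError("axis ranges must be positive with lo <= hi")
        if self.edge < 64:
            raise ValueError("edge must be >= 64")


@dataclass
class SyntheticSample:
    image: np.ndarray  # (edge, edge, 3) uint8
    mask: np.ndarray  # (edge, edge) in {0, 1}
    true_side_count: int
    spec: EarSpec
    seed: int


def _field_background(rng, edge, noise_level):
    base = np.array([72.0, 96.0, 52.0])
    coarse = rng.normal(0.0, 22.0, size=(edge // 16 + 1, edge // 16 + 1, 3))
    coarse = np.kron(coarse, np.ones((16, 16, 1)))[:edge, :edge]
    img = base[None, None, :] + coarse
    img += rng.normal(0.0, noise_level, size=img.shape)
    return img


def _white_background(rng, edge, noise_level):
    img = np.full((edge, edge, 3), 240.0)
    img += rng.normal(0.0, max(noise_level, 1.7), size=img.shape)
    return img


def _place_grains(rng, spec):
    """Ellipse parameters (cy, cx, semi_major, semi_minor, angle) for both columns."""
    n = int(rng.integers(spec.grains_per_side[0], spec.grains_per_side[1] + 1))
    semi_major = rng.uniform(*spec.major_axis, size=n) / 2.0
    semi_minor = rng.uniform(*spec.minor_axis, size=n) / 2.0
    angles = rng.normal(0.0, np.deg2rad(5.0), size=n)
    if n == 0:
        return 0, np.empty(0), np.empty(0), semi_major, semi_minor, angles
    mean_minor = 2.0 * semi_minor.mean()
    n_left = (n + 1) // 2
    dx = spec.minor_axis[1] / 2.0 + 3.0  # column offset from the rachis
    cx_col = {0: spec.edge / 2.0 - dx, 1: spec.edge / 2.0 + dx}
    # stagger the right column by roughly half a step so grains alternate
    stagger = semi_major.mean() * (1.0 - spec.adhesion)
    cy, cx = np.empty(n), np.empty(n)
    for col, idx in ((0, list(range(n_left))), (1, list(range(n_left, n)))):
        if not idx:
            continue
        ys = [0.0]
        for prev, cur in zip(idx[:-1], idx[1:]):
            step = semi_major[prev] + semi_major[cur] + spec.gap - spec.adhesion * (
                mean_minor + spec.gap
            )
            ys.append(ys[-1] + step)
        ys = np.asarray(ys)
        span = ys[-1] + semi_major[idx[0]] + semi_major[idx[-1]] + stagger
        if span > spec.edge - 4:
            raise PlacementError(
                f"{n} grains (column height {span:.0f}px) do not fit in a "
                f"{spec.edge}px frame"
            )
        cy[idx] = ys - ys.mean() + spec.edge / 2.0 + (stagger if col == 1 else 0.0)
        cx[idx] = cx_col[col] + rng.uniform(-1.0, 1.0, size=len(idx))
    return n, cy, cx, semi_major, semi_minor, angles


def _render_grain(img, mask, cy, cx, a, b, angle, color, edge):
    rr, cc = draw.ellipse(cy, cx, a, b, shape=(edge, edge), rotation=angle)
    if rr.size == 0:
        return
    mask[rr, cc] = 1
    # elliptical radial fraction for a simple dome shading
    dy, dx_ = rr - cy, cc - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (dy * ca + dx_ * sa) / a
    v = (-dy * sa + dx_ * ca) / b
    frac2 = np.clip(u**2 + v**2, 0.0, 1.0)
    shade = 1.0 - 0.25 * frac2
    img[rr, cc] = color[None, :] * shade[:, None]


def generate_ear(spec: EarSpec, seed: int) -> SyntheticSample:
    """Render one ear side; deterministic in (spec, seed)."""
    rng = np.random.default_rng(seed)
    edge = spec.edge
    if spec.background == "field":
        img = _field_background(rng, edge, spec.noise_level)
    else:
        img = _white_background(rng, edge, spec.noise_level)
    # rachis: a thin straw-colored vertical band behind the grains
    half_w = 3
    c0 = edge // 2 - half_w
    img[:, c0 : c0 + 2 * half_w] = np.array([150.0, 132.0, 72.0]) + rng.normal(
        0.0, 4.0, size=(edge, 2 * half_w, 3)
    )
    n, cy, cx, semi_a, semi_b, angles = _place_grains(rng, spec)
    mask = np.zeros((edge, edge), dtype=np.uint8)
    for i in range(n):
        color = np.array([205.0, 175.0, 100.0]) + rng.normal(0.0, 8.0, size=3)
        _render_grain(img, mask, cy[i], cx[i], semi_a[i], semi_b[i], angles[i], color, edge)
    ramp = np.linspace(-1.0, 1.0, edge)[None, :, None] * spec.illumination
    img = img + ramp
    img += rng.normal(0.0, spec.noise_level * 0.5, size=img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticSample(
        image=image, mask=mask, true_side_count=n, spec=spec, seed=int(seed)
    )


def derive_seed(master_seed: int, index: int) -> int:
    """Counter-based per-sample seed derivation from one master seed."""
    return int((int(master_seed) * 1_000_003 + 7919 * int(index) + 1) % (2**31 - 1))


def generate_dataset(
    n: int,
    spec: EarSpec | None = None,
    seed: int = 0,
    adhesion_range: tuple | None = None,
    backgrounds: tuple = ("field", "white"),
) -> list[SyntheticSample]:
    """Generate *n* samples with per-sample seeds derived from ``seed``.

    When ``adhesion_range`` is given, each sample's adhesion is drawn uniformly
    from it; backgrounds alternate through ``backgrounds``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or EarSpec()
    samples = []
    for i in range(n):
        child = derive_seed(seed, i)
        rng = np.random.default_rng(child)
        s = replace(spec, background=backgrounds[i % len(backgrounds)])
        if adhesion_range is not None:
            s = replace(s, adhesion=float(rng.uniform(*adhesion_range)))
        samples.append(generate_ear(s, derive_seed(child, 1)))
    return samples
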