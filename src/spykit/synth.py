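"""Synthetic scanner scenes with exact ground truth.

The generator emulates flatbed scans of two-ranked unilateral grass
inflorescences (e.g. perennial ryegrass): a near-black noisy background, and
elongated, possibly curved spikes built from a rachis (central axis) with
ellipsoidal spikelets attached alternately left/right along it. Every scene
carries analytic ground truth (spike count, per-spike centerline arc length,
spikelet count and centers), so segmentation, length estimation and spikelet
counting are testable without external image data.

Geometry is expressed in image coordinates: origin at the top-left corner,
x = columns rightward, y = rows downward, angles in degrees from +x toward +y.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, PlacementError, ValidationError

# Default appearance. Scenes are rendered at roughly half the paper's 600-dpi
# working scale: a mature ryegrass spike of ~10 cm maps to ~900 px, a spikelet
# of ~1 cm to a ~55 px semi-major axis.
DEFAULT_BASE_COLOR = (95, 115, 60)   # olive green
DEFAULT_TIP_COLOR = (150, 130, 70)   # senescing tan toward the tip
BACKGROUND_LEVEL = 10                # "black velvet" scanner background
BACKGROUND_NOISE_SD = 3.0
SPIKE_MIN_CHANNEL = 40               # spikes stay well above the background
SEPARATION_PX = 12                   # enforced clearance between spikes


@dataclass(frozen=True)
class SpikeSpec:
    """Parametric description of one spike.

    The centerline starts at a local origin with tangent ``orientation`` and
    is either a straight segment (``radius is None``) or a circular arc of
    signed ``radius`` (positive bends toward +y of the local frame).
    ``attach_angle`` is the angle between a spikelet's major axis and the
    rachis tangent; the sign alternates so spikelets form two opposite rows.
    """

    arc_length: float = 900.0
    radius: float | None = None
    orientation: float = 90.0
    rachis_width: float = 12.0
    n_spikelets: int = 14
    spikelet_spacing: float = 60.0
    spikelet_axes: tuple[float, float] = (55.0, 20.0)
    attach_angle: float = 35.0
    base_color: tuple[int, int, int] = DEFAULT_BASE_COLOR
    tip_color: tuple[int, int, int] | None = DEFAULT_TIP_COLOR
    color_jitter: float = 12.0

    def validate(self) -> None:
        if not self.arc_length > 0:
            raise ValidationError("arc_length must be > 0")
        if self.rachis_width < 3:
            raise ValidationError("rachis_width must be >= 3 px")
        if self.n_spikelets < 0:
            raise ValidationError("n_spikelets must be >= 0")
        if not self.spikelet_spacing > 0:
            raise ValidationError("spikelet_spacing must be > 0")
        if self.radius is not None and self.radius == 0:
            raise ValidationError("arc radius must be nonzero")
        if any(not (0 <= c <= 255) for c in self.base_color):
            raise ValidationError("base_color must be 8-bit RGB")
        a, b = self.spikelet_axes
        if self.n_spikelets and (a <= 0 or b <= 0 or b > a):
            raise ValidationError("spikelet_axes must satisfy 0 < minor <= major")
        if self.n_spikelets:
            smax = (self.n_spikelets - 0.5) * self.spikelet_spacing
            if smax > self.arc_length:
                raise ValidationError(
                    f"{self.n_spikelets} spikelets at spacing "
                    f"{self.spikelet_spacing} px do not fit on a "
                    f"{self.arc_length} px centerline"
                )

    # -- centerline geometry -------------------------------------------------
    def centerline(self, s: np.ndarray) -> np.ndarray:
        """(x, y) points of the centerline at arc-length positions ``s``."""
        s = np.asarray(s, dtype=float)
        th0 = np.radians(self.orientation)
        if self.radius is None:
            x = s * np.cos(th0)
            y = s * np.sin(th0)
        else:
            k = 1.0 / self.radius
            th = th0 + k * s
            x = (np.sin(th) - np.sin(th0)) / k
            y = -(np.cos(th) - np.cos(th0)) / k
        return np.stack([x, y], axis=-1)

    def tangent_angle(self, s: np.ndarray) -> np.ndarray:
        """Tangent direction (radians) at arc-length positions ``s``."""
        s = np.asarray(s, dtype=float)
        th0 = np.radians(self.orientation)
        if self.radius is None:
            return np.full_like(s, th0)
        return th0 + s / self.radius

    def spikelet_positions(self) -> np.ndarray:
        """Arc-length positions of spikelet attachment points."""
        return (np.arange(self.n_spikelets) + 0.5) * self.spikelet_spacing


@dataclass(frozen=True)
class SceneSpec:
    """A scanner scene: canvas, background statistics and spike placement.

    ``anchors`` holds one (row, col) top-left patch position per spike, or
    None for random rejection-sampled placement.
    """

    image_height: int = 1200
    image_width: int = 1600
    background_level: int = BACKGROUND_LEVEL
    background_noise_sd: float = BACKGROUND_NOISE_SD
    spikes: tuple[SpikeSpec, ...] = ()
    anchors: tuple[tuple[int, int] | None, ...] | None = None
    seed: int = 0
    separation: int = SEPARATION_PX

    def validate(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValidationError("scene dimensions must be positive")
        if not (0 <= self.background_level <= 255):
            raise ValidationError("background_level must be 8-bit")
        if self.background_level >= SPIKE_MIN_CHANNEL:
            raise ValidationError(
                "background_level must stay below the spike channel floor "
                f"({SPIKE_MIN_CHANNEL})"
            )
        if self.anchors is not None and len(self.anchors) != len(self.spikes):
            raise ValidationError("anchors must match spikes one-to-one")
        for sp in self.spikes:
            sp.validate()


@dataclass
class SpikeTruth:
    """Ground truth for one rendered spike (patch-local or scene coords)."""

    arc_length: float
    spikelet_count: int
    centers: np.ndarray          # (n, 2) spikelet centers as (row, col)
    arc_positions: np.ndarray    # (n,) arc-length position of each spikelet
    mask: np.ndarray             # boolean footprint
    offset: tuple[int, int] = (0, 0)   # top-left of mask within the scene

    def to_json_dict(self) -> dict:
        return {
            "arc_length": float(self.arc_length),
            "spikelet_count": int(self.spikelet_count),
            "centers": [[float(r), float(c)] for r, c in self.centers],
        }


@dataclass
class SceneTruth:
    """Ground truth for a rendered scene."""

    n_spikes: int
    spikes: list[SpikeTruth] = field(default_factory=list)

    def spike_mask(self, i: int, shape: tuple[int, int]) -> np.ndarray:
        """Footprint of spike ``i`` on a canvas of ``shape``."""
        st = self.spikes[i]
        out = np.zeros(shape, dtype=bool)
        r0, c0 = st.offset
        h, w = st.mask.shape
        out[r0:r0 + h, c0:c0 + w] = st.mask
        return out

    def union_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for i in range(self.n_spikes):
            out |= self.spike_mask(i, shape)
        return out

    def to_json_dict(self) -> dict:
        return {
            "n_spikes": self.n_spikes,
            "spikes": [s.to_json_dict() for s in self.spikes],
        }


def _fill_rotated_ellipse(canvas: np.ndarray, center_xy, a: float, b: float,
                          phi: float) -> None:
    """Set pixels of ``canvas`` inside an ellipse with semi-axes (a, b),
    major axis at angle ``phi`` (radians, image frame)."""
    cx, cy = center_xy
    h, w = canvas.shape
    r0 = max(int(np.floor(cy - a - 2)), 0)
    r1 = min(int(np.ceil(cy + a + 2)), h - 1)
    c0 = max(int(np.floor(cx - a - 2)), 0)
    c1 = min(int(np.ceil(cx + a + 2)), w - 1)
    if r1 < r0 or c1 < c0:
        return
    yy, xx = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    dx = xx - cx
    dy = yy - cy
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    canvas[r0:r1 + 1, c0:c1 + 1] |= inside


def render_spike(spec: SpikeSpec, seed: int = 0):
    """Rasterize one spike on a tight local canvas.

    Returns ``(mask, patch, truth)``: a boolean footprint (single
    8-connected component), an RGB uint8 patch (zero outside the mask), and
    a :class:`SpikeTruth` in patch coordinates.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    step = max(min(spec.rachis_width / 4.0, 1.0), 0.25)
    s_grid = np.arange(0.0, spec.arc_length + step, step)
    s_grid[-1] = spec.arc_length
    pts = spec.centerline(s_grid)

    a, b = spec.spikelet_axes
    s_sp = spec.spikelet_positions()
    attach = np.radians(spec.attach_angle)
    tang = spec.tangent_angle(s_sp)
    sides = np.where(np.arange(spec.n_spikelets) % 2 == 0, 1.0, -1.0)
    phis = tang + sides * attach
    bases = spec.centerline(s_sp)
    centers_xy = bases + 0.55 * a * np.stack([np.cos(phis), np.sin(phis)], -1)

    reach = a + spec.rachis_width
    all_x = np.concatenate([pts[:, 0], centers_xy[:, 0]] if len(s_sp)
                           else [pts[:, 0]])
    all_y = np.concatenate([pts[:, 1], centers_xy[:, 1]] if len(s_sp)
                           else [pts[:, 1]])
    margin = reach + 3
    x0, y0 = all_x.min() - margin, all_y.min() - margin
    w = int(np.ceil(all_x.max() + margin - x0)) + 1
    h = int(np.ceil(all_y.max() + margin - y0)) + 1

    mask = np.zeros((h, w), dtype=bool)
    rr = np.clip(np.round(pts[:, 1] - y0).astype(int), 0, h - 1)
    cc = np.clip(np.round(pts[:, 0] - x0).astype(int), 0, w - 1)
    mask[rr, cc] = True
    rad = max(int(round(spec.rachis_width / 2)), 1)
    yk, xk = np.mgrid[-rad:rad + 1, -rad:rad + 1]
    disk = (xk ** 2 + yk ** 2) <= rad ** 2
    mask = ndi.binary_dilation(mask, structure=disk)

    for (cx, cy), phi in zip(centers_xy, phis):
        _fill_rotated_ellipse(mask, (cx - x0, cy - y0), a, b, phi)

    n_comp = ndi.label(mask, structure=np.ones((3, 3)))[1]
    if n_comp != 1:  # pragma: no cover - guarded by spec.validate
        raise DegenerateInputError("rendered spike is not a single component")

    # color: base -> tip gradient by arc position of the nearest centerline
    # sample, plus independent per-pixel Gaussian jitter
    fg_r, fg_c = np.nonzero(mask)
    patch = np.zeros((h, w, 3), dtype=np.uint8)
    base = np.asarray(spec.base_color, dtype=float)
    if spec.tip_color is not None:
        tree = cKDTree(np.stack([pts[:, 1] - y0, pts[:, 0] - x0], axis=1))
        _, idx = tree.query(np.stack([fg_r, fg_c], axis=1).astype(float))
        frac = (s_grid[idx] / spec.arc_length)[:, None]
        color = base[None, :] * (1 - frac) + np.asarray(spec.tip_color,
                                                        float)[None, :] * frac
    else:
        color = np.repeat(base[None, :], fg_r.size, axis=0)
    color = color + rng.normal(0.0, spec.color_jitter, size=color.shape)
    color = np.clip(color, SPIKE_MIN_CHANNEL, 255)
    patch[fg_r, fg_c] = np.round(color).astype(np.uint8)

    centers_rc = np.stack([centers_xy[:, 1] - y0, centers_xy[:, 0] - x0],
                          axis=1) if len(s_sp) else np.zeros((0, 2))
    truth = SpikeTruth(arc_length=float(spec.arc_length),
                       spikelet_count=int(spec.n_spikelets),
                       centers=centers_rc, arc_positions=s_sp, mask=mask)
    return mask, patch, truth


def render_scene(spec: SceneSpec):
    """Render a full scene.

    Deterministic for a fixed spec (including its seed). Spike footprints
    are kept pairwise disjoint with at least ``spec.separation`` px
    clearance; random placement is retried up to 100 times per spike before
    raising :class:`PlacementError`.

    Returns ``(image, truth)`` with ``image`` an (H, W, 3) uint8 raster and
    ``truth`` a :class:`SceneTruth` whose spikes are ordered left-to-right
    (matching the segmentation module's enumeration order).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width

    image = np.clip(
        rng.normal(spec.background_level, spec.background_noise_sd,
                   size=(H, W, 3)),
        0, 255,
    ).astype(np.uint8)

    occupied = np.zeros((H, W), dtype=bool)
    placed: list[tuple[SpikeTruth, np.ndarray]] = []
    anchors = spec.anchors or (None,) * len(spec.spikes)

    for sp, anchor in zip(spec.spikes, anchors):
        patch_seed = int(rng.integers(0, 2 ** 31 - 1))
        mask, patch, truth = render_spike(sp, seed=patch_seed)
        ph, pw = mask.shape
        if ph > H or pw > W:
            raise PlacementError(
                f"spike patch {ph}x{pw} exceeds scene {H}x{W}")
        grown = ndi.binary_dilation(mask, structure=np.ones((3, 3)),
                                    iterations=max(spec.separation, 1))
        placed_ok = False
        tries = 1 if anchor is not None else 100
        for _ in range(tries):
            if anchor is not None:
                r0, c0 = anchor
            else:
                r0 = int(rng.integers(0, H - ph + 1))
                c0 = int(rng.integers(0, W - pw + 1))
            if r0 < 0 or c0 < 0 or r0 + ph > H or c0 + pw > W:
                continue
            if not (occupied[r0:r0 + ph, c0:c0 + pw] & grown).any():
                placed_ok = True
                break
        if not placed_ok:
            raise PlacementError(
                "could not place spike disjointly after bounded retries")
        occupied[r0:r0 + ph, c0:c0 + pw] |= grown
        image[r0:r0 + ph, c0:c0 + pw][mask] = patch[mask]
        truth.offset = (r0, c0)
        truth.centers = truth.centers + np.array([r0, c0], dtype=float)
        placed.append((truth, mask))

    placed.sort(key=lambda t: (t[0].offset[1], t[0].offset[0]))
    truth = SceneTruth(n_spikes=len(placed), spikes=[t for t, _ in placed])
    return image, truth


# -- randomized scene helpers -------------------------------------------------

def random_spike_spec(rng: np.random.Generator, *,
                      curved: bool = False,
                      n_spikelets: int | None = None,
                      spacing: float | None = None,
                      base_color: tuple[int, int, int] | None = None,
                      tip_color: tuple[int, int, int] | None = DEFAULT_TIP_COLOR,
                      color_jitter: float = 12.0) -> SpikeSpec:
    """Draw one realistic :class:`SpikeSpec` from mild parameter jitter."""
    n = int(rng.integers(8, 15)) if n_spikelets is None else int(n_spikelets)
    spc = float(rng.uniform(55, 70)) if spacing is None else float(spacing)
    arc = (n + 0.5) * spc
    radius = None
    if curved:
        radius = float(rng.choice([-1, 1]) * rng.uniform(arc / np.pi, 2 * arc))
    return SpikeSpec(
        arc_length=arc,
        radius=radius,
        orientation=float(rng.uniform(75, 105)),
        rachis_width=float(rng.uniform(10, 14)),
        n_spikelets=n,
        spikelet_spacing=spc,
        spikelet_axes=(float(rng.uniform(48, 60)), float(rng.uniform(17, 23))),
        attach_angle=float(rng.uniform(30, 42)),
        base_color=base_color or DEFAULT_BASE_COLOR,
        tip_color=tip_color,
        color_jitter=color_jitter,
    )


def random_scene_spec(n_spikes: int, seed: int, *,
                      curved: bool = False) -> SceneSpec:
    """Scene with ``n_spikes`` randomly drawn, randomly placed spikes."""
    rng = np.random.default_rng(seed)
    spikes = tuple(random_spike_spec(rng, curved=curved)
                   for _ in range(n_spikes))
    width = max(900, 260 * n_spikes + 300)
    return SceneSpec(image_height=1350, image_width=width, spikes=spikes,
                     seed=seed)


# -- I/O ----------------------------------------------------------------------

def save_scene(image: np.ndarray, truth: SceneTruth, out_dir: str | Path,
               stem: str = "scene") -> dict:
    """Write the scene PNG, per-spike 0/255 mask PNGs and the truth JSON."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{stem}.png"
    iio.imwrite(img_path, image)
    for i, st in enumerate(truth.spikes, start=1):
        iio.imwrite(out / f"{stem}_spike{i}_mask.png",
                    (st.mask.astype(np.uint8) * 255))
    truth_path = out / f"{stem}_truth.json"
    truth_path.write_text(json.dumps(truth.to_json_dict(), indent=2))
    return {"image": img_path, "truth": truth_path}
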