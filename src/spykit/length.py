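"""Spike length estimation.

Four estimators mirror the practice in inflorescence phenotyping:

* ``ellipse`` — full major-axis length of the moment ellipse of the mask;
* ``convex_hull`` — same rule on the filled convex hull;
* ``skeleton`` — Zhang–Suen thinning of the blurred mask, then the longest
  endpoint-to-endpoint geodesic along the skeleton;
* ``medial_axis`` — identical pipeline with the medial-axis transform as the
  thinning operator.

The ellipse-based estimators are fast but underestimate curved spikes; the
thinning estimators follow the rachis. ``blur_sigma`` and ``prune_px`` are
scale parameters: the low-pass blur must exceed the scallop scale of the
spikelets for the skeleton to track the rachis, and ``prune_px`` should be
of the order of the spikelet major axis so lateral spurs are removed.
"""
from __future__ import annotations

import time
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from ._moments import ellipse_from_mask
from .errors import DegenerateInputError, ValidationError

METHODS = ("ellipse", "convex_hull", "skeleton", "medial_axis")
DEFAULT_BLUR_SIGMA = 2.0
DEFAULT_PRUNE_PX = 15.0

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class LengthResult:
    method: str
    length: float
    elapsed_time: float
    overlay: np.ndarray | None = None


def _require_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValidationError("empty mask")
    return mask


def length_ellipse(mask: np.ndarray) -> LengthResult:
    """Full major-axis length (2x semi-major) of the mask's moment ellipse."""
    t0 = time.perf_counter()
    mask = _require_mask(mask)
    semi_major, _, _, _ = ellipse_from_mask(mask)
    return LengthResult("ellipse", 2.0 * semi_major, time.perf_counter() - t0)


def length_convex_hull(mask: np.ndarray) -> LengthResult:
    """Ellipse rule applied to the filled convex hull of the mask."""
    t0 = time.perf_counter()
    mask = _require_mask(mask)
    hull = morphology.convex_hull_image(mask)
    semi_major, _, _, _ = ellipse_from_mask(hull)
    return LengthResult("convex_hull", 2.0 * semi_major,
                        time.perf_counter() - t0)


def thin_mask(mask: np.ndarray, method: str = "skeleton",
              blur_sigma: float = DEFAULT_BLUR_SIGMA) -> np.ndarray:
    """Low-pass blur, re-binarize at 0.5, then thin to one pixel width.

    ``blur_sigma=0`` skips the blur (the operation is then idempotent on an
    already one-pixel-wide input).
    """
    mask = _require_mask(mask)
    if method not in ("skeleton", "medial_axis"):
        raise ValidationError(f"unknown thinning method {method!r}")
    if blur_sigma > 0:
        work = ndi.gaussian_filter(mask.astype(float), blur_sigma) > 0.5
    else:
        work = mask
    if not work.any():
        raise DegenerateInputError("mask vanished after blurring")
    if method == "skeleton":
        return morphology.skeletonize(work, method="zhang")
    # medial_axis breaks pixel-order ties randomly; seed for determinism
    return morphology.medial_axis(work, rng=0)


def _skeleton_graph(skeleton: np.ndarray) -> nx.Graph:
    coords = np.argwhere(skeleton)
    nodes = {tuple(rc) for rc in coords}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for r, c in coords:
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
            nb = (r + dr, c + dc)
            if nb in nodes:
                w = 1.0 if dr == 0 or dc == 0 else _SQRT2
                g.add_edge((r, c), nb, weight=w)
    return g


def _prune_spurs(g: nx.Graph, prune_px: float) -> None:
    """Iteratively remove leaf branches shorter than ``prune_px``.

    A branch runs from a leaf to the first junction (degree >= 3); branches
    ending at another leaf form the backbone and are never removed.
    """
    while True:
        removed = False
        for leaf in [n for n in g.nodes if g.degree(n) == 1]:
            if leaf not in g or g.degree(leaf) != 1:
                continue
            path = [leaf]
            length = 0.0
            node, prev = leaf, None
            while True:
                nbrs = [n for n in g.neighbors(node) if n != prev]
                if g.degree(node) >= 3 or not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[node, nxt]["weight"]
                prev, node = node, nxt
                if g.degree(node) >= 3:
                    break
                path.append(node)
            if g.degree(node) >= 3 and length < prune_px:
                g.remove_nodes_from(path)
                removed = True
        if not removed:
            break


def _longest_geodesic(g: nx.Graph):
    """Longest endpoint-to-endpoint shortest path; returns (length, path)."""
    if g.number_of_nodes() == 0:
        return 0.0, []
    components = list(nx.connected_components(g))
    giant = max(components, key=len)
    sub = g.subgraph(giant)
    endpoints = [n for n in sub.nodes if sub.degree(n) <= 1]
    if not endpoints:
        # pure cycle: double-sweep from an arbitrary node
        start = next(iter(sub.nodes))
        dist = nx.single_source_dijkstra_path_length(sub, start)
        endpoints = [max(dist, key=dist.get)]
    best = (0.0, [next(iter(sub.nodes))])
    for src in endpoints:
        dist, paths = nx.single_source_dijkstra(sub, src)
        far = max(dist, key=dist.get)
        if dist[far] > best[0]:
            best = (dist[far], paths[far])
    return best


def skeleton_path_length(skeleton: np.ndarray,
                         prune_px: float = DEFAULT_PRUNE_PX):
    """Length of the longest geodesic on the skeleton graph.

    Steps cost 1 (orthogonal) or sqrt(2) (diagonal); spur branches shorter
    than ``prune_px`` are removed first. Returns ``(length, path)`` with
    ``path`` the list of (row, col) pixels of the measured geodesic.
    """
    skeleton = np.asarray(skeleton).astype(bool)
    if not skeleton.any():
        raise ValidationError("empty skeleton")
    g = _skeleton_graph(skeleton)
    if prune_px > 0:
        _prune_spurs(g, prune_px)
    return _longest_geodesic(g)


def polyline_length(path, step: float = 0.0) -> float:
    """Length of a pixel path, optionally chord-resampled at ``step`` px.

    Digitized centerlines are jagged at the pixel scale, which inflates
    their chain length relative to the underlying smooth curve; resampling
    the path at chords of ``step`` pixels (endpoints preserved) is a
    standard digital arc-length correction. ``step=0`` sums raw segments.
    """
    pts = np.asarray(path, dtype=float)
    if pts.shape[0] < 2:
        return 0.0
    seg = np.hypot(*np.diff(pts, axis=0).T)
    if step <= 0:
        return float(seg.sum())
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, cum[-1], step)
    targets = np.append(targets, cum[-1])
    idx = np.searchsorted(cum, targets)
    idx = np.clip(idx, 0, len(cum) - 1)
    sampled = pts[np.unique(idx)]
    return float(np.hypot(*np.diff(sampled, axis=0).T).sum())


DEFAULT_RESAMPLE_PX = 25.0
MEDIAL_TRIM_FRACTION = 0.65


def _medial_path_length(path, dist: np.ndarray, resample_px: float,
                        fraction: float = MEDIAL_TRIM_FRACTION) -> float:
    """Path length with corner-branch trimming for the medial axis.

    The medial axis of an elongated band keeps an EDT radius near the band
    half-width along the true centerline, but at the tips it also runs into
    boundary corners, where the radius collapses. End runs whose radius
    stays below ``fraction`` of the path's median radius are trimmed before
    the chord-resampled length is taken.
    """
    pts = np.asarray(path, dtype=float)
    if pts.shape[0] < 5:
        return polyline_length(path, resample_px)
    radii = np.array([dist[r, c] for r, c in path])
    cutoff = fraction * float(np.median(radii))

    def run_len(rr):
        k = 0
        while k < len(rr) - 2 and rr[k] < cutoff:
            k += 1
        return k if k >= 2 else 0

    k0 = run_len(radii)
    k1 = run_len(radii[::-1])
    core = pts[k0:len(pts) - k1]
    if core.shape[0] < 2:
        return polyline_length(path, resample_px)
    return polyline_length(core, resample_px)


def _thinning_length(mask: np.ndarray, method: str, blur_sigma: float,
                     prune_px: float, overlay: bool,
                     resample_px: float = DEFAULT_RESAMPLE_PX) -> LengthResult:
    t0 = time.perf_counter()
    mask_b = _require_mask(mask)
    if blur_sigma > 0:
        work = ndi.gaussian_filter(mask_b.astype(float), blur_sigma) > 0.5
        if not work.any():
            raise DegenerateInputError("mask vanished after blurring")
    else:
        work = mask_b
    if method == "skeleton":
        skel = morphology.skeletonize(work, method="zhang")
        _, path = skeleton_path_length(skel, prune_px=prune_px)
        length = polyline_length(path, resample_px)
    else:
        skel, dist = morphology.medial_axis(work, return_distance=True,
                                            rng=0)
        _, path = skeleton_path_length(skel, prune_px=prune_px)
        length = _medial_path_length(path, dist, resample_px)
    elapsed = time.perf_counter() - t0
    img = None
    if overlay:
        img = np.zeros(mask.shape + (3,), dtype=np.uint8)
        img[np.asarray(mask, bool)] = (90, 90, 90)
        if path:
            rr, cc = zip(*path)
            img[list(rr), list(cc)] = (255, 0, 0)
    return LengthResult(method, length, elapsed, overlay=img)


def spk_length(mask: np.ndarray, methods=METHODS, *,
               blur_sigma: float = DEFAULT_BLUR_SIGMA,
               prune_px: float = DEFAULT_PRUNE_PX,
               resample_px: float = DEFAULT_RESAMPLE_PX,
               overlay: bool = False) -> list[LengthResult]:
    """Estimate spike length with any subset of the four methods.

    Results are returned in the canonical method order; overlays (the mask
    with the measured centerline in red) are rendered for the thinning
    methods when ``overlay`` is set. Thinning lengths are measured on the
    longest skeleton geodesic, chord-resampled at ``resample_px``.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown length methods: {sorted(unknown)}")
    results = []
    for m in METHODS:
        if m not in methods:
            continue
        if m == "ellipse":
            results.append(length_ellipse(mask))
        elif m == "convex_hull":
            results.append(length_convex_hull(mask))
        else:
            results.append(_thinning_length(mask, m, blur_sigma, prune_px,
                                            overlay, resample_px))
    return results
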