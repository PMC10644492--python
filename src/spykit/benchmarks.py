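"""Reproducible synthetic evaluation studies.

Each study renders its own scenes from the generator's standard conditions
and measures one pipeline property end to end: spike-count recovery under
the default red-channel threshold, length-estimator accuracy on
semicircular spikes, spikelet-count recovery at the default minimum peak
distance, and color-descriptor separability of latent (PC) phenotypes.
The same functions back the test suite and the acceptance script, so the
numbers reported in both are computed identically.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import synth
from .color import channel_percentiles
from .latent import mean_pairwise_ed, pca_project
from .length import spk_length
from .segment import (SegmentationParams, SpikeRecord, count_rmse,
                      segment_image)
from .spikelets import SpikeletParams, spikelet_segm

# Scale-matched thinning parameters for the generator's default spikelet
# size: the low-pass blur must reach the scallop amplitude (~ the spikelet
# semi-minor axis) so the skeleton tracks the rachis; pruning then only has
# residual spurs to remove and must stay well below the tip-to-last-spikelet
# distance (~ the spikelet spacing) to avoid cutting genuine tips.
CURVED_BLUR_SIGMA = 16.0
CURVED_PRUNE_PX = 30.0
CURVED_RESAMPLE_PX = 25.0


def spike_count_study(n_scenes: int = 20, seed: int = 0,
                      params: SegmentationParams = SegmentationParams()):
    """Spike-count RMSE over randomized scenes with 1-10 disjoint spikes."""
    rng = np.random.default_rng(seed)
    predicted, observed = [], []
    for i in range(n_scenes):
        n = int(rng.integers(1, 11))
        scene_seed = int(rng.integers(0, 2 ** 31 - 1))
        image, truth = synth.render_scene(
            synth.random_scene_spec(n, seed=scene_seed))
        _, labeled, _ = segment_image(image, params)
        predicted.append(labeled.k)
        observed.append(truth.n_spikes)
    rmse, sd = count_rmse(predicted, observed)
    return {"rmse": rmse, "sd": sd, "n_scenes": n_scenes,
            "predicted": predicted, "observed": observed}


def semicircular_spike(rng: np.random.Generator) -> synth.SpikeSpec:
    """A semicircular spike (arc spanning pi) at standard appearance."""
    n = int(rng.integers(8, 13))
    spacing = float(rng.uniform(55, 65))
    arc = (n + 0.5) * spacing
    return synth.SpikeSpec(
        arc_length=arc,
        radius=float(rng.choice([-1, 1])) * arc / np.pi,
        orientation=float(rng.uniform(0, 360)),
        n_spikelets=n,
        spikelet_spacing=spacing,
    )


def curved_length_study(n_spikes: int = 20, seed: int = 0):
    """Length-estimator errors on semicircular spikes.

    Returns per-method absolute percentage errors against the analytic arc
    length, using thinning parameters matched to the spikelet scale.
    """
    rng = np.random.default_rng(seed)
    errors = {m: [] for m in ("ellipse", "convex_hull", "skeleton",
                              "medial_axis")}
    for i in range(n_spikes):
        spec = semicircular_spike(rng)
        mask, _, truth = synth.render_spike(
            spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
        for res in spk_length(mask, blur_sigma=CURVED_BLUR_SIGMA,
                              prune_px=CURVED_PRUNE_PX,
                              resample_px=CURVED_RESAMPLE_PX):
            errors[res.method].append(
                abs(res.length - truth.arc_length) / truth.arc_length * 100.0)
    return {m: np.asarray(v) for m, v in errors.items()}


# Morphological cleaning matched to the generator's working scale (about
# half the 600-dpi scanner scale): disconnecting spikelets requires eroding
# roughly the rachis half-width (~6 px full scale = 3 iterations at 20%)
# while the coarser default rescale would also erase spikelet cores.
RECOVERY_PARAMS = SpikeletParams(morph_rescale=0.2, erosion_iter=3)


def spikelet_recovery_study(n_spikes: int = 50, seed: int = 0,
                            params: SpikeletParams = RECOVERY_PARAMS):
    """Spikelet-count recovery on spikes with 5-15 spikelets, spacing >= 50.

    Returns per-spike predicted/true counts and the fraction of spikes with
    |predicted - true| <= 1.
    """
    rng = np.random.default_rng(seed)
    predicted, observed = [], []
    for i in range(n_spikes):
        n = int(rng.integers(5, 16))
        spacing = float(rng.uniform(50, 70))
        spec = synth.SpikeSpec(arc_length=(n + 0.5) * spacing,
                               radius=None if rng.random() < 0.5 else
                               float(rng.choice([-1, 1]) * rng.uniform(
                                   (n + 0.5) * spacing / np.pi,
                                   2 * (n + 0.5) * spacing)),
                               orientation=float(rng.uniform(0, 360)),
                               n_spikelets=n, spikelet_spacing=spacing)
        mask, _, truth = synth.render_spike(
            spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
        predicted.append(spikelet_segm(mask, params).count)
        observed.append(truth.spikelet_count)
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    within_one = float(np.mean(np.abs(predicted - observed) <= 1))
    return {"predicted": predicted, "observed": observed,
            "fraction_within_one": within_one,
            "rmse": count_rmse(predicted, observed)[0]}


# -- color separability -------------------------------------------------------

COLOR_RECIPES = (
    # (base mean RGB, tip mean RGB): green, green-tan, tan maturity classes
    ((80, 120, 55), (110, 125, 60)),
    ((100, 115, 58), (150, 130, 70)),
    ((135, 120, 62), (175, 140, 80)),
)


def _recipe_spike(rng: np.random.Generator, recipe) -> synth.SpikeSpec:
    base, tip = recipe
    jitter = rng.normal(0, 6, size=3)
    base = tuple(int(np.clip(b + j, 45, 250)) for b, j in zip(base, jitter))
    tip = tuple(int(np.clip(t + j, 45, 250))
                for t, j in zip(tip, rng.normal(0, 6, size=3)))
    n = int(rng.integers(6, 9))
    return synth.SpikeSpec(arc_length=(n + 0.5) * 55.0, n_spikelets=n,
                           spikelet_spacing=55.0,
                           orientation=float(rng.uniform(80, 100)),
                           base_color=base, tip_color=tip,
                           color_jitter=float(rng.uniform(8, 16)))


def color_descriptor_table(n_per_recipe: int = 20, seed: int = 0) -> pd.DataFrame:
    """Canonical color records for spikes drawn from the three recipes."""
    rng = np.random.default_rng(seed)
    rows = []
    for recipe in COLOR_RECIPES:
        for _ in range(n_per_recipe):
            spec = _recipe_spike(rng, recipe)
            mask, patch, _ = synth.render_spike(
                spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
            record = _record_from_patch(mask, patch)
            rows.append(channel_percentiles(record))
    return pd.DataFrame(rows)


def _record_from_patch(mask: np.ndarray, patch: np.ndarray) -> SpikeRecord:
    """Wrap a rendered spike patch as a SpikeRecord without re-segmenting."""
    from skimage import color as skcolor

    rgb_f = patch.astype(float) / 255.0
    hsv = skcolor.rgb2hsv(rgb_f)
    hsv[..., 0] *= 360.0
    hsv[..., 1] *= 255.0
    hsv[..., 2] *= 255.0
    lab = skcolor.rgb2lab(rgb_f)
    return SpikeRecord(label=1, bbox=(0, 0, mask.shape[0], mask.shape[1]),
                       pad_px=0, mask=mask, rgb=patch, hsv=hsv, lab=lab)


def color_separability_study(n_replicates: int = 20, n_per_recipe: int = 20,
                             seed: int = 0):
    """Latent-space separability: full canonical set vs mean-RGB-only.

    For each replicate, spikes from the three color recipes are projected
    onto two principal components (of the centered/scaled descriptors) and
    the mean pairwise Euclidean distance between spikes is compared between
    the full 77-descriptor set and the three RGB channel means alone.
    """
    rng = np.random.default_rng(seed)
    full_eds, rgb_eds = [], []
    for _ in range(n_replicates):
        table = color_descriptor_table(
            n_per_recipe, seed=int(rng.integers(0, 2 ** 31 - 1)))
        full = pca_project(table, k=2)
        rgb = pca_project(table[["R_mean", "G_mean", "B_mean"]], k=2)
        full_eds.append(mean_pairwise_ed(full.raw_scores)[0])
        rgb_eds.append(mean_pairwise_ed(rgb.raw_scores)[0])
    full_eds = np.asarray(full_eds)
    rgb_eds = np.asarray(rgb_eds)
    return {"full_ed": full_eds, "rgb_ed": rgb_eds,
            "win_fraction": float(np.mean(full_eds > rgb_eds))}
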