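"""Distributional color descriptors per spike.

Color is summarized distribution-wise — not just by channel means — over
nine channels in three color spaces (R, G, B; H, S, V; L*, a*, b*), using
the pixels inside the spike mask. The canonical record holds exactly 77
descriptors: the seven always-positive channels get
{min, max, mean, sd, p5, p25, p50, p75, p95} and the signed a*/b* channels
get {mean, sd, p5, p25, p50, p75, p95}. The extended block appends the
coefficient of variation (CV = sd/mean) and the quartile coefficient of
variation (QCV = (p75 - p25)/(p75 + p25)) per channel, plus the same
battery restricted to the strictly negative / strictly positive values of
a* and b* (green-red and blue-yellow opponent signs track maturity).
"""
from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .errors import ValidationError
from .segment import SpikeRecord

CHANNELS = ("R", "G", "B", "H", "S", "V", "L", "aStar", "bStar")
FULL_STATS = ("min", "max", "mean", "sd", "p5", "p25", "p50", "p75", "p95")
SIGNED_STATS = ("mean", "sd", "p5", "p25", "p50", "p75", "p95")
CANONICAL_WIDTH = 77  # 7 channels x 9 stats + 2 signed channels x 7 stats


def channel_values(record: SpikeRecord) -> "OrderedDict[str, np.ndarray]":
    """Per-channel value vectors over the spike's foreground pixels."""
    mask = record.mask
    if not mask.any():
        raise ValidationError("spike record has no foreground pixels")
    out: OrderedDict[str, np.ndarray] = OrderedDict()
    rgb = record.rgb.astype(float)
    for i, name in enumerate(("R", "G", "B")):
        out[name] = rgb[..., i][mask]
    for i, name in enumerate(("H", "S", "V")):
        out[name] = record.hsv[..., i][mask]
    for i, name in enumerate(("L", "aStar", "bStar")):
        out[name] = record.lab[..., i][mask]
    return out


def channel_stats(values: np.ndarray) -> "OrderedDict[str, float]":
    """Distribution statistics of one channel vector.

    sd is the population standard deviation; percentiles use linear
    interpolation between order statistics. CV is undefined (NaN) at zero
    mean, QCV at p75 + p25 == 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("empty value vector")
    p5, p25, p50, p75, p95 = np.percentile(v, [5, 25, 50, 75, 95])
    mean = float(v.mean())
    sd = float(v.std())
    cv = sd / mean if mean != 0 else float("nan")
    qcv = (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else float("nan")
    return OrderedDict(
        min=float(v.min()), max=float(v.max()), mean=mean, sd=sd,
        p5=float(p5), p25=float(p25), p50=float(p50), p75=float(p75),
        p95=float(p95), cv=float(cv), qcv=float(qcv),
    )


def sign_split_stats(a_values: np.ndarray, b_values: np.ndarray) -> dict:
    """The full statistic battery on the strictly negative / strictly
    positive subsets of a* and b*, with the subset pixel fraction.

    Empty subsets report NaN statistics and fraction 0.
    """
    out = {}
    for channel, vec in (("aStar", np.asarray(a_values, float)),
                         ("bStar", np.asarray(b_values, float))):
        for sign, sub in (("Neg", vec[vec < 0]), ("Pos", vec[vec > 0])):
            key = f"{channel}{sign}"
            if sub.size:
                stats = channel_stats(sub)
                stats["frac"] = sub.size / vec.size if vec.size else 0.0
            else:
                stats = OrderedDict((s, float("nan"))
                                    for s in FULL_STATS + ("cv", "qcv"))
                stats["frac"] = 0.0
            out[key] = stats
    return out


def channel_percentiles(record: SpikeRecord,
                        extended: bool = False) -> "OrderedDict[str, float]":
    """The canonical 77-descriptor color record (or the extended set).

    Canonical mode emits ``<channel>_<stat>`` fields in a fixed order;
    extended mode appends per-channel CV/QCV and the a*/b* sign-split
    blocks (``aStarNeg_mean`` ... ``bStarPos_frac``).
    """
    vals = channel_values(record)
    stats = {ch: channel_stats(v) for ch, v in vals.items()}
    out: OrderedDict[str, float] = OrderedDict()
    for ch in CHANNELS:
        battery = SIGNED_STATS if ch in ("aStar", "bStar") else FULL_STATS
        for s in battery:
            out[f"{ch}_{s}"] = stats[ch][s]
    if extended:
        for ch in CHANNELS:
            out[f"{ch}_cv"] = stats[ch]["cv"]
            out[f"{ch}_qcv"] = stats[ch]["qcv"]
        split = sign_split_stats(vals["aStar"], vals["bStar"])
        for key in ("aStarNeg", "aStarPos", "bStarNeg", "bStarPos"):
            for s, value in split[key].items():
                out[f"{key}_{s}"] = value
    return out
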