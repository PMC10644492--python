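"""Second-central-moment ellipse fits for binary regions.

A single implementation backs spike-length estimation and spikelet ellipse
fitting so the orientation convention is identical everywhere: angles are
measured in the image frame (origin top-left, x = columns rightward,
y = rows downward), from the +x axis toward +y, in degrees in [0, 180).
"""
from __future__ import annotations

import numpy as np


def ellipse_from_coords(rows: np.ndarray, cols: np.ndarray):
    """Moment ellipse of a pixel set.

    Returns (semi_major, semi_minor, angle_deg, centroid_rc).
    The ellipse has the same normalized second central moments as the
    region; its semi-axis along eigenvalue ``lam`` is ``2*sqrt(lam)``.
    Degenerate sets (< 2 pixels, or zero variance) return zero axes and
    NaN angle.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    n = rows.size
    cr, cc = rows.mean(), cols.mean()
    if n < 2:
        return 0.0, 0.0, float("nan"), (cr, cc)
    x = cols - cc
    y = rows - cr
    mxx = float(np.mean(x * x))
    myy = float(np.mean(y * y))
    mxy = float(np.mean(x * y))
    # eigenvalues of [[mxx, mxy], [mxy, myy]]
    tr, det = mxx + myy, mxx * myy - mxy * mxy
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + np.sqrt(disc)
    lam2 = tr / 2.0 - np.sqrt(disc)
    semi_major = 2.0 * np.sqrt(max(lam1, 0.0))
    semi_minor = 2.0 * np.sqrt(max(lam2, 0.0))
    if semi_major <= 0 or (abs(mxy) < 1e-12 and abs(mxx - myy) < 1e-12):
        angle = float("nan") if semi_major <= 0 else 0.0
        return semi_major, semi_minor, angle, (cr, cc)
    theta = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)
    angle = float(np.degrees(theta) % 180.0)
    return semi_major, semi_minor, angle, (cr, cc)


def ellipse_from_mask(mask: np.ndarray):
    """Moment ellipse of a boolean mask (see :func:`ellipse_from_coords`)."""
    rr, cc = np.nonzero(mask)
    return ellipse_from_coords(rr, cc)
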