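"""Independent reference implementations used only by the tests."""
from __future__ import annotations

import numpy as np


def otsu_brute_force(gray: np.ndarray) -> int:
    """Otsu threshold by direct per-candidate class statistics."""
    g = np.asarray(gray).ravel().astype(float)
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = g[g <= t]
        hi = g[g > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def edt_brute_force(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance transform by exhaustive nearest-background scan."""
    mask = np.asarray(mask).astype(bool)
    out = np.zeros(mask.shape, dtype=float)
    bg = np.argwhere(~mask)
    if bg.size == 0:
        out[:] = np.inf
        return out
    for r, c in np.argwhere(mask):
        d2 = (bg[:, 0] - r) ** 2 + (bg[:, 1] - c) ** 2
        out[r, c] = np.sqrt(d2.min())
    return out


def efd_brute_force(contour: np.ndarray, n_harmonics: int):
    """Elliptic Fourier coefficients by per-segment closed-form integration.

    Treats x(t), y(t) as piecewise linear in the cumulative chord-length
    parameter and evaluates a_n = (2/T) int x(t) cos(2 pi n t / T) dt (and
    the sin / y analogues) with the exact antiderivative of
    (alpha + beta t) cos(omega t) on each segment.
    """
    pts = np.asarray(contour, dtype=float)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    d = np.diff(pts, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    starts = pts[:-1][keep]
    t0 = np.concatenate([[0.0], np.cumsum(dt)])[:-1]
    t1 = t0 + dt
    T = t1[-1]

    def seg_integrals(x0, beta, omega):
        # int (x0 + beta (t - t0)) cos(omega t) dt and the sin analogue
        def val_cos(t, tt0):
            return ((x0 + beta * (t - tt0)) * np.sin(omega * t) / omega
                    + beta * np.cos(omega * t) / omega ** 2)

        def val_sin(t, tt0):
            return (-(x0 + beta * (t - tt0)) * np.cos(omega * t) / omega
                    + beta * np.sin(omega * t) / omega ** 2)

        icos = val_cos(t1, t0) - val_cos(t0, t0)
        isin = val_sin(t1, t0) - val_sin(t0, t0)
        return icos.sum(), isin.sum()

    coeffs = np.zeros((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        omega = 2.0 * np.pi * n / T
        ax, bx = seg_integrals(starts[:, 0], d[:, 0] / dt, omega)
        cy, dy = seg_integrals(starts[:, 1], d[:, 1] / dt, omega)
        coeffs[n - 1] = (2.0 / T) * np.array([ax, bx, cy, dy])
    a0 = float(np.sum((starts[:, 0] + pts[1:][keep][:, 0]) / 2 * dt) / T)
    c0 = float(np.sum((starts[:, 1] + pts[1:][keep][:, 1]) / 2 * dt) / T)
    return coeffs, a0, c0


def ellipse_contour(a: float, b: float, cx: float = 0.0, cy: float = 0.0,
                    phi: float = 0.0, n: int = 400) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    xr = cx + x * np.cos(phi) - y * np.sin(phi)
    yr = cy + x * np.sin(phi) + y * np.cos(phi)
    return np.stack([xr, yr], axis=1)


def star_contour(n_points: int = 7, r_out: float = 60.0, r_in: float = 28.0):
    ang = np.linspace(0, 2 * np.pi, 2 * n_points, endpoint=False)
    r = np.where(np.arange(2 * n_points) % 2 == 0, r_out, r_in)
    return np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)


def fourier_blob_contour(seed: int = 0, n: int = 360) -> np.ndarray:
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 50.0 + sum(rng.normal(0, 4) * np.cos(k * t + rng.uniform(0, 2 * np.pi))
                   for k in range(2, 7))
    return np.stack([r * np.cos(t), r * np.sin(t)], axis=1)
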