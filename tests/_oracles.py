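"""Independent reference implementations used to check the package.

Everything here is deliberately written from the definitions (scalar loops,
no imports from edemaseg's numerics) so that agreement with the package is a
two-route check, not a tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_edt


def ncc_brute(counts1, counts2) -> float:
    """Normalized correlation of two count vectors, by scalar loops."""
    c1 = [float(v) for v in counts1]
    c2 = [float(v) for v in counts2]
    n = len(c1)
    m1 = sum(c1) / n
    m2 = sum(c2) / n
    num = sum((a - m1) * (b - m2) for a, b in zip(c1, c2))
    s1 = sum((a - m1) ** 2 for a in c1)
    s2 = sum((b - m2) ** 2 for b in c2)
    return num / np.sqrt(s1 * s2)


def hist_brute(values, n_bins: int, lo: float, hi: float) -> np.ndarray:
    """Clipped half-open binning (last bin closed), by scalar loops."""
    counts = np.zeros(n_bins)
    width = (hi - lo) / n_bins
    for v in np.asarray(values, float).ravel():
        v = min(max(v, lo), hi)
        idx = min(int((v - lo) / width), n_bins - 1)
        counts[idx] += 1
    return counts


def region_means_brute(values, phi, supp, epsilon=None):
    """Sharp (or smoothed-H weighted) region means over the support."""
    num1 = den1 = num2 = den2 = 0.0
    rows, cols = np.asarray(values).shape
    for i in range(rows):
        for j in range(cols):
            if not supp[i, j]:
                continue
            if epsilon is None:
                h = 1.0 if phi[i, j] >= 0 else 0.0
            else:
                h = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi[i, j] / epsilon))
            num1 += values[i, j] * h
            den1 += h
            num2 += values[i, j] * (1.0 - h)
            den2 += 1.0 - h
    return num1 / den1, num2 / den2


def _pad_edge_get(f, i, j):
    rows, cols = f.shape
    return f[min(max(i, 0), rows - 1), min(max(j, 0), cols - 1)]


def curvature_brute(phi: np.ndarray, eta: float = 1e-8) -> np.ndarray:
    """div(grad phi / |grad phi|): central differences, edge replication."""
    phi = np.asarray(phi, float)
    rows, cols = phi.shape
    gy = np.zeros_like(phi)
    gx = np.zeros_like(phi)
    for i in range(rows):
        for j in range(cols):
            gy[i, j] = 0.5 * (_pad_edge_get(phi, i + 1, j) - _pad_edge_get(phi, i - 1, j))
            gx[i, j] = 0.5 * (_pad_edge_get(phi, i, j + 1) - _pad_edge_get(phi, i, j - 1))
    norm = np.sqrt(gy ** 2 + gx ** 2) + eta
    ny, nx = gy / norm, gx / norm
    kappa = np.zeros_like(phi)
    for i in range(rows):
        for j in range(cols):
            dyy = 0.5 * (_pad_edge_get(ny, i + 1, j) - _pad_edge_get(ny, i - 1, j))
            dxx = 0.5 * (_pad_edge_get(nx, i, j + 1) - _pad_edge_get(nx, i, j - 1))
            kappa[i, j] = dyy + dxx
    return kappa


def evolve_step_brute(phi, values, supp, C1, C2, prior_counts, n_bins, lo, hi,
                      alpha, beta, dt, epsilon, prior_mode="dissimilarity"):
    """One explicit step of the evolution PDE, from the definitions."""
    phi = np.asarray(phi, float)
    bg_vals = [values[i, j] for i in range(phi.shape[0])
               for j in range(phi.shape[1]) if supp[i, j] and phi[i, j] < 0]
    h_bg = hist_brute(bg_vals, n_bins, lo, hi)
    r = ncc_brute(h_bg, prior_counts)
    r = min(max(r, -1.0), 1.0)
    F = 1.0 - r if prior_mode == "dissimilarity" else r
    kappa = curvature_brute(phi)
    out = phi.copy()
    for i in range(phi.shape[0]):
        for j in range(phi.shape[1]):
            if not supp[i, j]:
                continue
            force = (-(values[i, j] - C1) ** 2 + (values[i, j] - C2) ** 2
                     + alpha * F + beta * kappa[i, j])
            delta = (epsilon / np.pi) / (epsilon ** 2 + phi[i, j] ** 2)
            out[i, j] = phi[i, j] + dt * delta * force
    return out, F


def plain_chanvese(values, supp, beta, dt, epsilon, max_iter, reinit_every,
                   converge_tol, seed_window=(-50.0, 50.0)):
    """A self-contained classic Chan-Vese run (no density prior).

    Threshold-window initialization, signed-distance maintenance from the
    Euclidean distance transform, sharp-H region means, arctan delta in the
    explicit update, sign-change convergence. Returns the binary mask.
    """
    values = np.asarray(values, float)
    supp = np.asarray(supp, bool)
    clamp = -float(np.hypot(*values.shape))

    def sdist(inside):
        return distance_transform_edt(inside) - distance_transform_edt(~inside)

    seed = (values >= seed_window[0]) & (values <= seed_window[1]) & supp
    phi = sdist(seed)
    phi[~supp] = clamp
    prev_sign = phi[supp] >= 0
    n_supp = int(supp.sum())

    def grad(f):
        p = np.pad(f, 1, mode="edge")
        return (0.5 * (p[2:, 1:-1] - p[:-2, 1:-1]),
                0.5 * (p[1:-1, 2:] - p[1:-1, :-2]))

    for it in range(1, max_iter + 1):
        s = phi[supp] >= 0
        if s.all() or not s.any():
            break
        inside = (phi >= 0) & supp
        outside = (phi < 0) & supp
        C1 = values[inside].mean()
        C2 = values[outside].mean()
        gy, gx = grad(phi)
        norm = np.sqrt(gy ** 2 + gx ** 2) + 1e-8
        dyy, _ = grad(gy / norm)
        _, dxx = grad(gx / norm)
        kappa = dyy + dxx
        force = (-(values - C1) ** 2 + (values - C2) ** 2 + 0.0 + beta * kappa)
        delta = (epsilon / np.pi) / (epsilon ** 2 + phi ** 2)
        phi_new = phi.copy()
        phi_new[supp] = phi[supp] + dt * delta[supp] * force[supp]
        phi = phi_new
        sign = phi[supp] >= 0
        changed = float(np.mean(sign != prev_sign))
        prev_sign = sign
        if it % reinit_every == 0:
            s = phi[supp] >= 0
            if s.all() or not s.any():
                break
            phi = sdist(phi >= 0)
            phi[~supp] = clamp
        if changed < converge_tol:
            break
    return ((phi >= 0) & supp).astype(np.uint8)
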