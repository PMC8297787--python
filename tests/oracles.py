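"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own solver paths: diffusion is
integrated by explicit Euler at tiny steps, linear programs by
enumerating basic feasible points, and hard-sphere availability by
Monte-Carlo probe insertion.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def explicit_euler_diffusion(
    rho: np.ndarray, d_eff: np.ndarray, dx: float, dt: float, n_steps: int,
    periodic: bool = False,
) -> np.ndarray:
    """Explicit finite-volume integration of drho/dt = div(D grad rho)
    on a 2D grid with harmonic-mean interface diffusivities and
    zero-flux (or periodic) boundaries."""
    rho = rho.astype(float).copy()
    d = d_eff.astype(float)

    def harm(a, b):
        s = a + b
        out = np.zeros_like(s)
        nz = s > 0
        out[nz] = 2 * a[nz] * b[nz] / s[nz]
        return out

    for _ in range(n_steps):
        flux = np.zeros_like(rho)
        for ax in range(rho.ndim):
            if rho.shape[ax] == 1:
                continue
            lo = [slice(None)] * rho.ndim
            hi = [slice(None)] * rho.ndim
            lo[ax] = slice(0, -1)
            hi[ax] = slice(1, None)
            c = harm(d[tuple(lo)], d[tuple(hi)]) / dx**2
            f = c * (rho[tuple(hi)] - rho[tuple(lo)])
            flux[tuple(lo)] += f
            flux[tuple(hi)] -= f
            if periodic:
                first = [slice(None)] * rho.ndim
                last = [slice(None)] * rho.ndim
                first[ax] = 0
                last[ax] = rho.shape[ax] - 1
                c = harm(d[tuple(first)], d[tuple(last)]) / dx**2
                f = c * (rho[tuple(last)] - rho[tuple(first)])
                flux[tuple(first)] += f
                flux[tuple(last)] -= f
        rho += dt * flux
    return rho


def lp_vertex_maximize(c, a_eq, b_eq, lb, ub, tol=1e-9):
    """Maximize c.v subject to A_eq v = b_eq, lb <= v <= ub, by
    enumerating basic feasible points (variables not in the basis are
    pinned at a bound).  Intended for <= ~10 variables."""
    c = np.asarray(c, float)
    a_eq = np.atleast_2d(np.asarray(a_eq, float))
    b_eq = np.asarray(b_eq, float)
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    n = c.size
    m = a_eq.shape[0]
    best = None
    for basis in itertools.combinations(range(n), min(m, n)):
        nonbasis = [j for j in range(n) if j not in basis]
        a_b = a_eq[:, basis]
        if np.linalg.matrix_rank(a_b) < len(basis):
            continue
        for corners in itertools.product(*[(lb[j], ub[j]) for j in nonbasis]):
            corners = np.asarray(corners)
            if not np.all(np.isfinite(corners)):
                continue
            rhs = b_eq - a_eq[:, nonbasis] @ corners
            try:
                vb = np.linalg.lstsq(a_b, rhs, rcond=None)[0]
            except np.linalg.LinAlgError:
                continue
            if np.max(np.abs(a_b @ vb - rhs)) > tol:
                continue
            v = np.empty(n)
            v[list(basis)] = vb
            v[nonbasis] = corners
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                val = c @ v
                if best is None or val > best[0]:
                    best = (val, v)
    if best is None:
        return None
    return best


def widom_insertion(radii, centers, box, r_probe, n_trials, rng):
    """Monte-Carlo probe-insertion acceptance probability in a periodic
    box of hard spheres; returns (p_accept, standard error)."""
    centers = np.asarray(centers, float)
    radii = np.asarray(radii, float)
    pts = rng.uniform(0, box, size=(n_trials, 3))
    hits = 0
    for p in pts:
        d = np.abs(centers - p)
        d = np.minimum(d, box - d)
        if np.all(np.sqrt((d**2).sum(axis=1)) >= radii + r_probe):
            hits += 1
    p_acc = hits / n_trials
    se = math.sqrt(max(p_acc * (1 - p_acc), 1e-12) / n_trials)
    return p_acc, se


def rsa_sphere_packing(phi, radius, box, rng, max_tries=200000):
    """Random sequential addition of equal hard spheres (periodic box)."""
    v_one = 4 / 3 * math.pi * radius**3
    n = int(round(phi * box**3 / v_one))
    centers = []
    for _ in range(max_tries):
        if len(centers) == n:
            break
        p = rng.uniform(0, box, size=3)
        ok = True
        for c in centers:
            d = np.abs(np.asarray(c) - p)
            d = np.minimum(d, box - d)
            if (d**2).sum() < (2 * radius) ** 2:
                ok = False
                break
        if ok:
            centers.append(p)
    assert len(centers) == n, f"packing failed at phi={phi}"
    return np.asarray(centers)
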