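"""Binding-radius calibration.

Association in the particle simulation is geometric: at the end of every
timestep, any open pair closer than the binding radius ``r_b`` forms a
dimer.  ``r_b`` is chosen so that this per-step capture rule reproduces a
target mass-action association rate ``k_on`` (a 2D rate, um^2/s) for the
pair's mutual diffusion coefficient and the timestep in use — the
construction introduced for Smoldyn-style particle simulators.

The effective rate of the capture rule is computed deterministically by
iterating the radial pair-distribution function to its steady state: each
iteration convolves the pair density with the Gaussian displacement kernel
of one relative-diffusion step and then absorbs the mass inside ``r_b``.
The absorbed mass per step (with unit far-field concentration) divided by
``dt`` is the effective association rate.  ``compute_binding_radius``
root-finds on ``r_b`` against this evaluation.

With the rates and timesteps used here the binding radius is far smaller
than the rms step, so capture is nearly "activation-limited" and
``r_b ~ sqrt(k_on * dt / pi)``; the solver supplies the (small)
diffusion-limited correction and remains valid outside this regime.

``mc_association_rate`` provides an independent brute-force oracle: a
well-mixed two-species Brownian simulation in a small periodic box that
counts capture events directly.
"""

from __future__ import annotations

import functools
import math

import numpy as np
from numba import njit
from scipy.optimize import brentq
from scipy.special import ive

#: upper physical bound on a binding radius (um); anything larger than this
#: is no longer small compared with the simulation box.
MAX_BINDING_RADIUS = 0.05


def _radial_grid(r_b: float, sigma: float) -> np.ndarray:
    """Grid refined near the absorbing radius, coarsening outward.

    ``r_b`` is an exact grid point (the captured-flux integral runs over
    ``[0, r_b]``).  Spacing is ``r_b/12`` inside ``[0, 3*r_b]`` and grows
    geometrically, capped at ``sigma/4`` (the kernel width must stay
    resolved), out to ``r_b + 12*sigma`` where the far field is taken as
    unperturbed.
    """
    r_max = r_b + 12.0 * sigma
    pts = list(np.linspace(0.0, r_b, 13))
    h = r_b / 12.0
    cap = sigma / 4.0
    r = r_b
    while r < r_max:
        r += h
        pts.append(r)
        if r > 3.0 * r_b:
            h = min(h * 1.25, cap)
    return np.asarray(pts)


def effective_association_rate(
    r_b: float,
    D_mutual: float,
    dt: float,
    *,
    rtol: float = 1e-7,
    max_iter: int = 2000,
) -> float:
    """Steady-state mass-action rate (um^2/s) of the end-of-step capture
    rule for binding radius ``r_b``.

    Evolves the deficit field ``u = 1 - rho`` of the radial pair density
    under the step kernel with absorption inside ``r_b`` until the
    captured flux per step converges.
    """
    if r_b < 0 or D_mutual <= 0 or dt <= 0:
        raise ValueError("need r_b >= 0, D_mutual > 0, dt > 0")
    if r_b == 0.0:
        return 0.0
    sigma2 = 2.0 * D_mutual * dt  # per-axis variance of the relative step
    sigma = math.sqrt(sigma2)
    r = _radial_grid(r_b, sigma)
    n = r.size
    # trapezoid weights
    w = np.empty(n)
    w[0] = 0.5 * (r[1] - r[0])
    w[-1] = 0.5 * (r[-1] - r[-2])
    w[1:-1] = 0.5 * (r[2:] - r[:-2])
    # radial transition kernel of one 2D Gaussian step:
    #   T(r -> r') = (r'/s2) exp(-(r^2 + r'^2)/(2 s2)) I0(r r'/s2)
    # assembled with the exponentially scaled Bessel function for stability
    rp = r[:, None]  # destination
    r0 = r[None, :]  # source
    T = (rp / sigma2) * np.exp(-((rp - r0) ** 2) / (2.0 * sigma2)) * ive(
        0, rp * r0 / sigma2
    )
    A = T * w[None, :]
    inside = r <= r_b * (1.0 + 1e-12)
    n_in = int(inside.sum())
    # trapezoid for the flux integral over [0, r_b] only (half-weight at r_b)
    w_in = np.empty(n_in)
    w_in[0] = 0.5 * (r[1] - r[0])
    w_in[-1] = 0.5 * (r[n_in - 1] - r[n_in - 2])
    w_in[1:-1] = 0.5 * (r[2:n_in] - r[: n_in - 2])
    area_w_in = 2.0 * math.pi * r[:n_in] * w_in
    u = np.where(inside, 1.0, 0.0)
    flux_prev = np.inf
    for _ in range(max_iter):
        u = A @ u
        np.clip(u, 0.0, 1.0, out=u)
        flux = float(area_w_in @ (1.0 - u[:n_in]))
        u[inside] = 1.0
        if abs(flux - flux_prev) <= rtol * max(flux, 1e-300):
            break
        flux_prev = flux
    return flux / dt


@functools.lru_cache(maxsize=64)
def compute_binding_radius(k_on: float, D_mutual: float, dt: float) -> float:
    """Binding radius (um) whose end-of-step capture rule reproduces the
    association rate ``k_on`` (um^2/s) at mutual diffusion ``D_mutual``
    (um^2/s) and timestep ``dt`` (s).

    ``k_on = 0`` returns 0.  Raises if no radius below
    ``MAX_BINDING_RADIUS`` achieves the requested rate.
    """
    if k_on < 0 or D_mutual <= 0 or dt <= 0:
        raise ValueError(
            f"need k_on >= 0, D_mutual > 0, dt > 0 "
            f"(got k_on={k_on}, D_mutual={D_mutual}, dt={dt})"
        )
    if k_on == 0.0:
        return 0.0
    # activation-limited guess; the true root is >= this value
    r_guess = math.sqrt(k_on * dt / math.pi)
    lo, hi = 0.5 * r_guess, 2.0 * r_guess
    f = lambda r: effective_association_rate(r, D_mutual, dt) - k_on
    while f(hi) < 0.0:
        lo, hi = hi, hi * 2.0
        if hi > MAX_BINDING_RADIUS:
            raise ValueError(
                f"no binding radius below {MAX_BINDING_RADIUS} um reproduces "
                f"k_on={k_on} um^2/s at D_mutual={D_mutual}, dt={dt}; "
                "the requested rate is too fast for this timestep"
            )
    return brentq(f, lo, hi, xtol=r_guess * 1e-6, rtol=1e-12)


@njit(cache=True)
def _mc_capture_count(seed, n_each, box, std_a, std_b, r_b, n_steps):  # pragma: no cover
    np.random.seed(seed)
    xa = np.random.random(n_each) * box
    ya = np.random.random(n_each) * box
    xb = np.random.random(n_each) * box
    yb = np.random.random(n_each) * box
    captures = 0
    rb2 = r_b * r_b
    half = 0.5 * box
    for _ in range(n_steps):
        for i in range(n_each):
            xa[i] = (xa[i] + np.random.normal(0.0, std_a)) % box
            ya[i] = (ya[i] + np.random.normal(0.0, std_a)) % box
            xb[i] = (xb[i] + np.random.normal(0.0, std_b)) % box
            yb[i] = (yb[i] + np.random.normal(0.0, std_b)) % box
        for i in range(n_each):
            xi = xa[i]
            yi = ya[i]
            for j in range(n_each):
                dx = xb[j] - xi
                if dx > half:
                    dx -= box
                elif dx < -half:
                    dx += box
                if dx > r_b or dx < -r_b:
                    continue
                dy = yb[j] - yi
                if dy > half:
                    dy -= box
                elif dy < -half:
                    dy += box
                if dx * dx + dy * dy < rb2:
                    captures += 1
    return captures


def mc_association_rate(
    r_b: float,
    D_mutual: float,
    dt: float,
    *,
    n_each: int = 64,
    box: float = 0.005,
    n_steps: int = 200_000,
    seed: int = 0,
) -> float:
    """Brute-force measurement of the capture rule's mass-action rate.

    Two well-mixed species (``n_each`` particles each, half the mutual
    diffusion per species) diffuse in a periodic ``box`` x ``box``; pairs
    within ``r_b`` at the end of a step are counted as capture events
    (without removal — occupation of the capture disk is renewed every
    step because the rms step is much larger than ``r_b``).  Returns
    events * area / (N_A * N_B * T).
    """
    std = math.sqrt(2.0 * (D_mutual / 2.0) * dt)
    captures = _mc_capture_count(seed, n_each, box, std, std, r_b, n_steps)
    return captures * box * box / (n_each * n_each * n_steps * dt)
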