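"""Monte-Carlo random-walk oracle for the closed-form signal models.

Simulates spins as fixed-length random walkers in free space, inside an
impermeable sphere, along isotropically oriented sticks, or inside
isotropically oriented cylinders, under narrow-pulse encoding: the phase of
a walker is φ = q·(x(t_d) − x(0)) with q = √(b/t_d), and the signal is
⟨cos φ⟩.  Boundaries are reflecting (specular).

This module is a validation tool: it is unbiased (up to step-size
discretization) where the GPD closed forms are approximate, so agreement
within a small absolute tolerance — not to arbitrary precision — is the
expected outcome at strong weighting.
"""

from __future__ import annotations

import warnings

import numpy as np

from .scheme import AcquisitionScheme

_GEOMETRIES = ("free", "sphere", "stick", "cylinder")


def _unit_vectors(rng: np.random.Generator, n: int, ndim: int = 3) -> np.ndarray:
    v = rng.standard_normal((n, ndim))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def _uniform_in_ball(rng: np.random.Generator, n: int, radius: float, ndim: int) -> np.ndarray:
    v = _unit_vectors(rng, n, ndim)
    u = rng.random(n) ** (1.0 / ndim)
    return v * (radius * u)[:, None]


def _reflect_in_ball(pos: np.ndarray, step: np.ndarray, radius: float) -> np.ndarray:
    """Advance walkers by one step with specular reflection at |x| = radius.

    Works in 2 or 3 dimensions (disk cross-section or sphere).  Steps are
    short relative to the radius, so a few reflection passes suffice; any
    residual outlier is projected back onto the boundary.
    """
    new = pos + step
    for _ in range(4):
        out = np.einsum("ij,ij->i", new, new) > radius * radius
        if not out.any():
            return new
        p, s = pos[out], step[out]
        # fraction t of the step at which the boundary is crossed
        ss = np.einsum("ij,ij->i", s, s)
        ps = np.einsum("ij,ij->i", p, s)
        pp = np.einsum("ij,ij->i", p, p)
        disc = np.sqrt(np.maximum(ps * ps + ss * (radius * radius - pp), 0.0))
        t = np.clip((-ps + disc) / np.maximum(ss, 1e-300), 0.0, 1.0)
        hit = p + t[:, None] * s
        normal = hit / radius
        remainder = (1.0 - t)[:, None] * s
        reflected = remainder - 2.0 * np.einsum("ij,ij->i", remainder, normal)[:, None] * normal
        pos = pos.copy()
        step = step.copy()
        pos[out] = hit
        step[out] = reflected
        new = pos + step
    # pathological multi-bounce leftovers: clamp radially
    norm = np.sqrt(np.einsum("ij,ij->i", new, new))
    bad = norm > radius
    if bad.any():
        new[bad] *= (radius / norm[bad])[:, None]
    return new


def mc_random_walk_signal(
    geometry: str,
    geom_params: dict,
    scheme: AcquisitionScheme,
    b,
    n_walkers: int = 100_000,
    n_steps: int = 2000,
    seed: int = 0,
):
    """Estimate the narrow-pulse attenuation ⟨cos φ⟩ by random walk.

    Parameters
    ----------
    geometry
        ``"free"``, ``"sphere"``, ``"stick"`` or ``"cylinder"``.
    geom_params
        ``{"D": ...}`` plus ``{"r": ...}`` for sphere/cylinder.  Sticks and
        cylinders are powder-averaged by drawing an isotropic orientation
        per walker.
    b
        Scalar or array of diffusion weightings, ms/µm².  All b-values are
        evaluated on the same trajectory ensemble, so estimates across b
        share their Monte-Carlo noise.
    n_walkers, n_steps, seed
        Ensemble size (≥1e4 recommended for quantitative use), number of
        fixed-duration steps over t_d, and RNG seed (reproducible).

    Returns
    -------
    (signal, standard_error), each scalar or array matching ``b``.
    """
    if geometry not in _GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; expected one of {_GEOMETRIES}")
    if n_walkers < 1 or n_steps < 1:
        raise ValueError("n_walkers and n_steps must be positive")
    D = float(geom_params.get("D", np.nan))
    if not D > 0:
        raise ValueError("geom_params must contain D > 0")
    b_arr = np.atleast_1d(np.asarray(b, dtype=float))
    if np.any(b_arr < 0):
        raise ValueError("b must be nonnegative")

    rng = np.random.default_rng(seed)
    td = scheme.t_d
    dt = td / n_steps
    q = np.sqrt(b_arr / td)  # 1/µm

    if geometry in ("sphere", "cylinder"):
        r = float(geom_params.get("r", np.nan))
        if not r > 0:
            raise ValueError("geom_params must contain r > 0 for bounded geometries")
        step_len = np.sqrt(6.0 * D * dt)
        if step_len > r / 10.0:
            warnings.warn(
                f"step length {step_len:.3g} µm exceeds r/10 = {r / 10:.3g} µm; "
                "increase n_steps for a quantitative estimate",
                stacklevel=2,
            )

    if geometry == "free":
        # only the net displacement along the gradient matters
        step_len = np.sqrt(6.0 * D * dt)
        disp = np.zeros(n_walkers)
        for _ in range(n_steps):
            disp += step_len * _unit_vectors(rng, n_walkers)[:, 2]
        phase_per_q = disp

    elif geometry == "stick":
        # 1-D free walk along the stick axis; powder average via random
        # orientation cosine per walker (isotropic axes)
        step_len = np.sqrt(2.0 * D * dt)
        disp = np.zeros(n_walkers)
        for _ in range(n_steps):
            disp += step_len * rng.choice((-1.0, 1.0), size=n_walkers)
        cos_theta = rng.uniform(-1.0, 1.0, n_walkers)
        phase_per_q = disp * cos_theta

    elif geometry == "sphere":
        pos = _uniform_in_ball(rng, n_walkers, r, 3)
        z0 = pos[:, 2].copy()
        for _ in range(n_steps):
            step = step_len * _unit_vectors(rng, n_walkers)
            pos = _reflect_in_ball(pos, step, r)
        phase_per_q = pos[:, 2] - z0

    else:  # cylinder: restricted disk cross-section + free axis, powder avg
        pos_xy = _uniform_in_ball(rng, n_walkers, r, 2)
        x0 = pos_xy[:, 0].copy()
        disp_z = np.zeros(n_walkers)
        for _ in range(n_steps):
            step3 = step_len * _unit_vectors(rng, n_walkers, 3)
            pos_xy = _reflect_in_ball(pos_xy, step3[:, :2], r)
            disp_z += step3[:, 2]
        cos_theta = rng.uniform(-1.0, 1.0, n_walkers)
        sin_theta = np.sqrt(1.0 - cos_theta**2)
        # gradient at angle θ to the cylinder axis: axial (free) component
        # plus one transverse (restricted) component
        phase_per_q = cos_theta * disp_z + sin_theta * (pos_xy[:, 0] - x0)

    phases = q[:, None] * phase_per_q[None, :]
    cosines = np.cos(phases)
    sig = cosines.mean(axis=1)
    se = cosines.std(axis=1, ddof=1) / np.sqrt(n_walkers)
    if np.ndim(b) == 0:
        return float(sig[0]), float(se[0])
    return sig, se
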