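"""Multi-start bounded nonlinear least squares shared by all model fits.

Attenuation fits here are small (≤10 data points, 2–3 parameters) but the
cost surfaces have local minima (e.g. sphere radius vs diffusivity
trade-off), so every fit restarts from a fixed deterministic grid over the
bounds and keeps the best converged solution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitFailureError


@dataclass
class FitOptions:
    """Options shared by the microstructure and two-pool fits.

    Parameters
    ----------
    n_starts
        Starting points per free parameter; the multi-start grid is the
        Cartesian product of ``n_starts`` interior quantiles of each bound
        interval (default 3, i.e. a 3×3×3 grid for a 3-parameter fit).
    weighted
        Use 1/sd² weights when the curve carries per-point SDs (points with
        sd = 0 fall back to the smallest positive weight present).
    fix_f_sphere
        Fix the sphere signal fraction at this value instead of fitting it
        (microstructure fit only).
    bootstrap_draws
        Residual-bootstrap draws for confidence half-widths; 0 disables.
    seed
        Seed for the bootstrap resampling only (the fit itself is
        deterministic).
    ftol, xtol
        Optimizer tolerances passed to :func:`scipy.optimize.least_squares`.
    """

    n_starts: int = 3
    weighted: bool = True
    fix_f_sphere: float | None = None
    bootstrap_draws: int = 0
    seed: int = 0
    ftol: float = 1e-12
    xtol: float = 1e-12

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.fix_f_sphere is not None and not 0.0 <= self.fix_f_sphere <= 1.0:
            raise ValueError("fix_f_sphere must lie in [0, 1]")
        if self.bootstrap_draws < 0:
            raise ValueError("bootstrap_draws must be >= 0")


def start_grid(bounds: list[tuple[float, float]], n_starts: int) -> np.ndarray:
    """Deterministic multi-start grid: interior quantiles of each interval."""
    axes = []
    for lo, hi in bounds:
        q = np.linspace(0.0, 1.0, n_starts + 2)[1:-1]
        axes.append(lo + q * (hi - lo))
    return np.array(list(itertools.product(*axes)))


@dataclass
class LeastSquaresFit:
    params: np.ndarray
    cost: float  # sum of squared weighted residuals
    at_bound: list[bool]
    n_converged: int
    diagnostics: list = field(default_factory=list)


def multistart_least_squares(
    residual_fn,
    bounds: list[tuple[float, float]],
    n_starts: int,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
) -> LeastSquaresFit:
    """Run bounded least squares from a fixed grid of starts; keep the best.

    Raises :class:`FitFailureError` with per-start diagnostics if no start
    converges.
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    diagnostics = []
    n_converged = 0
    for x0 in start_grid(bounds, n_starts):
        try:
            res = least_squares(
                residual_fn, x0, bounds=(lo, hi), method="trf",
                ftol=ftol, xtol=xtol, gtol=1e-12,
            )
        except Exception as exc:  # noqa: BLE001 - keep per-start diagnostics
            diagnostics.append({"x0": x0.tolist(), "error": repr(exc)})
            continue
        diagnostics.append({"x0": x0.tolist(), "cost": 2.0 * res.cost, "status": res.status})
        if res.status <= 0 or not np.all(np.isfinite(res.x)):
            continue
        n_converged += 1
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError("no optimizer start converged", diagnostics)
    span = hi - lo
    at_bound = [
        bool(best.x[i] - lo[i] < 1e-6 * span[i] or hi[i] - best.x[i] < 1e-6 * span[i])
        for i in range(len(bounds))
    ]
    return LeastSquaresFit(
        params=best.x, cost=float(2.0 * best.cost), at_bound=at_bound,
        n_converged=n_converged, diagnostics=diagnostics,
    )


def residual_weights(sd: np.ndarray | None, n: int, weighted: bool) -> np.ndarray:
    """Per-point weights for the residual vector (√ of the 1/sd² weights).

    Empirical per-point SDs from a handful of curves are themselves noisy,
    so sd is floored at its median positive value before inversion: points
    with an accidentally tiny SD cannot dominate the fit.
    """
    if not weighted or sd is None:
        return np.ones(n)
    sd = np.asarray(sd, dtype=float)
    pos = sd[sd > 0]
    if pos.size == 0:
        return np.ones(n)
    floor = float(np.median(pos))
    return 1.0 / np.maximum(sd, floor)


def bootstrap_half_widths(
    fit_once,
    fitted: np.ndarray,
    model_values: np.ndarray,
    data_values: np.ndarray,
    draws: int,
    seed: int,
) -> np.ndarray:
    """Residual-bootstrap 95% half-widths (1.96 × SD of refitted params).

    ``fit_once(y)`` must refit the model to surrogate data ``y`` and return
    a parameter vector.  Surrogates are model + resampled residuals.
    """
    rng = np.random.default_rng(seed)
    residuals = data_values - model_values
    samples = []
    for _ in range(draws):
        y = model_values + rng.choice(residuals, size=residuals.size, replace=True)
        y = np.maximum(y, 1e-6)
        try:
            samples.append(fit_once(y))
        except FitFailureError:
            continue
    if len(samples) < max(10, draws // 4):
        return np.full(fitted.shape, np.nan)
    return 1.96 * np.std(np.asarray(samples), axis=0, ddof=1)
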