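"""Diffusion acquisition scheme: b-values and pulse timing.

Units are fixed package-wide: b in ms/µm², diffusivities in µm²/ms,
lengths in µm, times in ms, so that b·D is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default diffusion weightings, ms/µm².  The acquisition spans 0.02–20
#: ms/µm² at a single diffusion time; the shell spacing is a package choice
#: (roughly geometric, denser at low b where the extracellular pool decays).
DEFAULT_B_GRID: tuple[float, ...] = (0.02, 1.0, 2.0, 3.5, 5.0, 7.0, 10.0, 13.0, 16.0, 20.0)

#: Diffusion time of the in-vivo protocol, ms.
DEFAULT_DIFFUSION_TIME: float = 53.2


@dataclass
class AcquisitionScheme:
    """b-values and timing of a single-diffusion-time experiment.

    Parameters
    ----------
    b_values
        Diffusion weightings in ms/µm², strictly positive and strictly
        increasing.  At least four distinct values are required for any fit.
    t_d
        Effective diffusion time in ms.
    delta, Delta
        Gradient pulse duration and separation in ms; required when
        ``pulse_model="finite_pulse"``, in which case ``t_d`` must equal
        ``Delta - delta/3`` (the standard PGSE effective time).
    pulse_model
        ``"narrow_pulse"`` (default; the only model fully determined by the
        printed protocol numbers) or ``"finite_pulse"``.
    """

    b_values: np.ndarray
    t_d: float = DEFAULT_DIFFUSION_TIME
    delta: float | None = None
    Delta: float | None = None
    pulse_model: str = "narrow_pulse"

    def __post_init__(self):
        self.b_values = np.atleast_1d(np.asarray(self.b_values, dtype=float))
        if self.b_values.ndim != 1 or self.b_values.size == 0:
            raise ValueError("b_values must be a non-empty 1-D array")
        if np.any(self.b_values <= 0):
            raise ValueError("b_values must be strictly positive")
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if not self.t_d > 0:
            raise ValueError(f"t_d must be positive, got {self.t_d}")
        if self.pulse_model not in ("narrow_pulse", "finite_pulse"):
            raise ValueError(f"unknown pulse_model {self.pulse_model!r}")
        if self.pulse_model == "finite_pulse":
            if self.delta is None or self.Delta is None:
                raise ValueError("finite_pulse requires delta and Delta")
            if not (self.Delta >= self.delta > 0):
                raise ValueError("need Delta >= delta > 0")
            t_eff = self.Delta - self.delta / 3.0
            if abs(self.t_d - t_eff) > 1e-6 * max(1.0, t_eff):
                raise ValueError(
                    f"t_d={self.t_d} inconsistent with Delta - delta/3 = {t_eff}"
                )

    @property
    def b_min(self) -> float:
        return float(self.b_values[0])

    def validate_for_fit(self) -> None:
        """Raise if the scheme cannot support a nonlinear fit."""
        if np.unique(self.b_values).size < 4:
            raise ValueError(
                f"need at least 4 distinct b-values for a fit, got {np.unique(self.b_values).size}"
            )


def default_scheme(b_values=None, t_d: float = DEFAULT_DIFFUSION_TIME) -> AcquisitionScheme:
    """The study's acquisition: b from 0.02 to 20 ms/µm² at t_d = 53.2 ms."""
    if b_values is None:
        b_values = DEFAULT_B_GRID
    return AcquisitionScheme(b_values=np.asarray(b_values, dtype=float), t_d=t_d)
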