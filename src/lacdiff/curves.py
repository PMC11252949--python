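"""Attenuation curves: one metabolite's normalized signal vs b.

The curve is the pipeline's unit of data — one metabolite, one subject (or
one group mean), signal S(b) normalized to the lowest b.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Metabolite labels the pipeline recognises.  NAA and Ins are the purely
#: intracellular references; Lac is the metabolite whose intra/extracellular
#: split is estimated; "pooled" marks the NAA+Ins average.
KNOWN_METABOLITES = ("NAA", "Ins", "tCr", "tCho", "Lac", "pooled")


@dataclass
class AttenuationCurve:
    """Diffusion-weighted signal attenuation of one metabolite.

    Parameters
    ----------
    metabolite
        One of :data:`KNOWN_METABOLITES`.
    subject_id, group
        Free-form labels ("control", "APP/PS1", "synthetic", ...).
    b
        Diffusion weightings, ms/µm², strictly increasing.
    S
        Dimensionless signal, same length as ``b``, strictly positive.
    sd
        Optional nonnegative per-point SD (across animals, or the noise SD).
    """

    metabolite: str
    subject_id: str
    group: str
    b: np.ndarray
    S: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        if self.metabolite not in KNOWN_METABOLITES:
            raise ValueError(
                f"unknown metabolite {self.metabolite!r}; expected one of {KNOWN_METABOLITES}"
            )
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.S = np.atleast_1d(np.asarray(self.S, dtype=float))
        if self.b.shape != self.S.shape:
            raise ValueError(f"b and S lengths differ: {self.b.size} vs {self.S.size}")
        if np.any(np.diff(self.b) <= 0):
            raise ValueError("b must be strictly increasing")
        if np.any(self.S <= 0):
            raise ValueError("signal must be strictly positive")
        if self.sd is not None:
            self.sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
            if self.sd.shape != self.b.shape:
                raise ValueError("sd must have the same length as b")
            if np.any(self.sd < 0):
                raise ValueError("sd must be nonnegative")

    @property
    def n_points(self) -> int:
        return int(self.b.size)

    @property
    def is_normalized(self) -> bool:
        """True when S equals 1 at the lowest b (to float rounding)."""
        return bool(abs(self.S[0] - 1.0) < 1e-9)

    def normalized(self) -> "AttenuationCurve":
        """Return a copy with S (and sd) divided by S at the lowest b."""
        s0 = self.S[0]
        sd = None if self.sd is None else self.sd / s0
        return replace(self, S=self.S / s0, sd=sd)

    def same_grid(self, other: "AttenuationCurve", rtol: float = 1e-9) -> bool:
        return self.b.size == other.b.size and bool(np.allclose(self.b, other.b, rtol=rtol))


def require_shared_grid(curves: list[AttenuationCurve]) -> np.ndarray:
    """Return the common b-grid, raising if any curve deviates (no silent
    interpolation)."""
    if not curves:
        raise ValueError("no curves supplied")
    ref = curves[0]
    for c in curves[1:]:
        if not ref.same_grid(c):
            raise ValueError(
                f"b-grid mismatch between {ref.metabolite}/{ref.subject_id} "
                f"and {c.metabolite}/{c.subject_id}; resample explicitly before pooling"
            )
    return ref.b.copy()
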