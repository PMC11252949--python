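"""Synthetic two-group dMRS cohorts.

Generates per-animal attenuation curves for NAA, Ins and lactate in two
groups — "control" and "APP/PS1" — with the statistical structure the
pipeline assumes: a shared intracellular geometry across groups, group
differences confined to the extracellular lactate fraction, between-animal
parameter jitter, and multiplicative measurement noise per (metabolite, b)
point.  Default ground truth matches the in-vivo study's reported values:
D_intra = 0.40 µm²/ms, r_soma = 3.1 µm, f_extra = 0.36 (control) vs 0.23
(APP/PS1), λ = 1.3.

This stands in for the deposited in-vivo tables; it emulates quantified
attenuation curves only, not spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curves import AttenuationCurve
from .lactate import LactateScaling, two_pool_signal
from .microstructure import MicrostructureParams
from .models import sticks_spheres_signal
from .scheme import AcquisitionScheme, default_scheme

CONTROL = "control"
APPPS1 = "APP/PS1"


def _default_micro() -> MicrostructureParams:
    # f_sphere 0.5: the sticks/spheres ratio is not printed; equal signal
    # fractions, with robustness to this choice checked downstream
    return MicrostructureParams(D_intra=0.40, r_soma=3.1, f_sphere=0.5)


@dataclass
class GroupTruth:
    """Ground-truth parameters of one synthetic group."""

    micro: MicrostructureParams
    f_extra: float
    D_extra: float = 1.3

    def __post_init__(self):
        if not 0.0 <= self.f_extra <= 1.0:
            raise ValueError("f_extra must lie in [0, 1]")
        if not self.D_extra > 0:
            raise ValueError("D_extra must be positive")


@dataclass
class SyntheticCohortConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the study design: 5 animals per group, b spanning
    0.02–20 ms/µm² at t_d = 53.2 ms, control f_extra = 0.36 vs APP/PS1
    0.23 with shared D_extra, λ = 1.3.  ``noise_sigma`` is the relative SD
    of multiplicative Gaussian noise per (metabolite, b) measurement;
    ``between_animal_cv`` the relative SD of per-animal jitter on
    (D_intra, r_soma, f_extra).  The same seed yields bit-identical output.
    """

    n_per_group: int = 5
    scheme: AcquisitionScheme = field(default_factory=default_scheme)
    truth: dict[str, GroupTruth] = field(default_factory=lambda: {
        CONTROL: GroupTruth(micro=_default_micro(), f_extra=0.36),
        APPPS1: GroupTruth(micro=_default_micro(), f_extra=0.23),
    })
    scaling: LactateScaling = field(default_factory=LactateScaling)
    noise_sigma: float = 0.02
    between_animal_cv: float = 0.11
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.between_animal_cv < 0:
            raise ValueError("between_animal_cv must be >= 0")
        if not self.truth:
            raise ValueError("truth must name at least one group")


def _jitter(rng: np.random.Generator, value: float, cv: float,
            lo: float, hi: float) -> float:
    if cv == 0.0:
        return value
    return float(np.clip(value * (1.0 + cv * rng.standard_normal()), lo, hi))


def animal_truth(config: SyntheticCohortConfig, group: str,
                 rng: np.random.Generator) -> GroupTruth:
    """Draw one animal's parameters around the group truth."""
    g = config.truth[group]
    cv = config.between_animal_cv
    micro = MicrostructureParams(
        D_intra=_jitter(rng, g.micro.D_intra, cv, 0.01, 1.5),
        r_soma=_jitter(rng, g.micro.r_soma, cv, 0.1, 15.0),
        f_sphere=g.micro.f_sphere,
    )
    f_extra = _jitter(rng, g.f_extra, cv, 0.0, 1.0)
    return GroupTruth(micro=micro, f_extra=f_extra, D_extra=g.D_extra)


def _noisy_normalized(rng, S, sigma):
    if sigma > 0:
        S = S * (1.0 + sigma * rng.standard_normal(S.shape))
        S = np.maximum(S, 1e-6)
    return S / S[0]


def generate_cohort(config: SyntheticCohortConfig) -> list[AttenuationCurve]:
    """Generate per-animal NAA, Ins and Lac attenuation curves.

    Per animal: draw jittered parameters, evaluate the forward models
    (intracellular metabolites via sticks-and-spheres; lactate via the
    two-pool mixture with the intracellular part at λ·D_intra), apply
    multiplicative noise independently per metabolite and b, renormalize at
    the lowest b.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme
    b = scheme.b_values
    curves: list[AttenuationCurve] = []
    for group in config.truth:
        for i in range(config.n_per_group):
            truth = animal_truth(config, group, rng)
            m = truth.micro
            subject = f"{group.replace('/', '')}-{i + 1:02d}"
            s_cell = sticks_spheres_signal(scheme, b, m.D_intra, m.r_soma, m.f_sphere)
            s_cell = np.atleast_1d(s_cell)
            s_intra_lac = np.atleast_1d(sticks_spheres_signal(
                scheme, b, config.scaling.lam * m.D_intra, m.r_soma, m.f_sphere))
            s_lac = two_pool_signal(b, truth.f_extra, truth.D_extra, s_intra_lac)
            for metabolite, signal in (("NAA", s_cell), ("Ins", s_cell), ("Lac", s_lac)):
                noisy = _noisy_normalized(rng, signal.copy(), config.noise_sigma)
                curves.append(AttenuationCurve(
                    metabolite=metabolite, subject_id=subject, group=group,
                    b=b.copy(), S=noisy,
                    sd=np.full(b.size, config.noise_sigma) if config.noise_sigma > 0 else None,
                ))
    return curves


def noiseless_config(config: SyntheticCohortConfig) -> SyntheticCohortConfig:
    """Copy of ``config`` with all randomness switched off."""
    return replace(config, noise_sigma=0.0, between_animal_cv=0.0)
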