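"""Group-level statistics: unpaired t-tests and percent changes.

The two-group comparisons mirror the study's analysis: unpaired Student's
t-tests (equal-variance by default, Welch as an option) on per-animal
quantities, and per-b-value tests on normalized attenuations.  The t-test
is computed from first principles (means, pooled variance, t statistic,
p from the t-distribution CDF); scipy supplies only the CDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .curves import AttenuationCurve, require_shared_grid


@dataclass
class GroupComparison:
    """Two-sample comparison of one scalar quantity."""

    quantity: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_stat: float
    p_value: float
    df: float
    degenerate: bool = False

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def compare_groups(values_a, values_b, quantity: str = "",
                   equal_var: bool = True) -> GroupComparison:
    """Two-sided unpaired t-test between two groups of per-animal values.

    Equal-variance (Student) by default; ``equal_var=False`` gives the
    Welch test with Satterthwaite degrees of freedom.  With zero variance
    in both groups the test is degenerate: p → 0 if the means differ
    (flagged with a warning), p = 1 if they coincide.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = ma - mb

    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        sem = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    else:
        sem = np.sqrt(va / na + vb / nb)
        if va == 0 and vb == 0:
            df = float(na + nb - 2)
        else:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )

    degenerate = sem == 0.0
    if degenerate:
        if diff == 0.0:
            t, p = 0.0, 1.0
        else:
            t = np.inf if diff > 0 else -np.inf
            p = 0.0
            warnings.warn(
                f"zero within-group variance for {quantity or 'quantity'}; p -> 0",
                stacklevel=2,
            )
    else:
        t = diff / sem
        p = 2.0 * sps.t.sf(abs(t), df)

    return GroupComparison(
        quantity=quantity, mean_a=float(ma), mean_b=float(mb),
        sd_a=float(np.sqrt(va)), sd_b=float(np.sqrt(vb)),
        n_a=int(na), n_b=int(nb), t_stat=float(t), p_value=float(min(p, 1.0)),
        df=float(df), degenerate=bool(degenerate),
    )


def percent_decrease(reference: float, test: float) -> float:
    """Percent decrease of ``test`` relative to ``reference``.

    100·(reference − test)/reference; an increase comes out negative.
    """
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (reference - test) / reference


def per_b_group_tests(curves_a: list[AttenuationCurve],
                      curves_b: list[AttenuationCurve],
                      equal_var: bool = True) -> list[GroupComparison]:
    """Unpaired t-test at every b-value on normalized per-animal signals.

    This reproduces per-shell significance marks on attenuation plots; no
    multiple-testing correction is applied, matching how such plots are
    annotated.
    """
    b = require_shared_grid(curves_a + curves_b)
    sa = np.array([c.normalized().S for c in curves_a])
    sb = np.array([c.normalized().S for c in curves_b])
    out = []
    for j, bj in enumerate(b):
        out.append(compare_groups(sa[:, j], sb[:, j],
                                  quantity=f"S(b={bj:g})", equal_var=equal_var))
    return out
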