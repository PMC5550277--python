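"""Binomial dimer-exchange activity deconvolution.

Mixing wild-type and hydrolysis-dead (E115A) TRAP1 at varying ratios and
letting the dimers re-assort produces a binomial mixture of wild-type,
mutant and heterodimeric species.  Measured total steady-state ATPase
activity then decomposes as

    V_total = v_wt * f^2 + v_mut * (1-f)^2 + v_het * 2 f (1-f)

with f the wild-type subunit fraction.  Solving for the single unknown
v_het (the homodimer activities are anchored by the pure f=0 and f=1
measurements) tests whether the two protomers hydrolyze independently:
under independence v_het = (v_wt + v_mut)/2 and the mixing curve is a
straight line between the endpoints; sub-additive heterodimer activity
bends the curve below that line.

A convention flag controls whether the binomial factor 2 multiplies the
heterodimer term.  The default includes it, which is the form consistent
with the independence expectation being the average of the two homodimer
activities; the literal no-factor-2 form is available behind the flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class MixTable:
    """Mixing-ratio activity data: wild-type subunit fraction vs total activity."""

    f_wildtype: np.ndarray
    v_total: np.ndarray
    sd: Optional[np.ndarray] = None

    def __post_init__(self):
        self.f_wildtype = np.asarray(self.f_wildtype, dtype=float)
        self.v_total = np.asarray(self.v_total, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if len(self.sd) != len(self.f_wildtype):
                raise ValueError("sd must match the number of rows")
        if len(self.f_wildtype) != len(self.v_total):
            raise ValueError("f_wildtype and v_total must have the same length")
        if np.any((self.f_wildtype < 0) | (self.f_wildtype > 1)):
            raise ValueError("wild-type fractions must lie in [0, 1]")
        if len(np.unique(self.f_wildtype)) < 3:
            raise ValueError("need at least 3 distinct mixing fractions")


@dataclass
class MixFitResult:
    v_wildtype: float
    v_mutant: float
    v_heterodimer: float
    v_heterodimer_se: float
    fixed_wildtype: bool
    fixed_mutant: bool
    includes_factor_2: bool
    rss: float
    sub_additive: bool  # v_het below the independence value (v_wt+v_mut)/2


def species_fractions(f_wildtype: float) -> tuple[float, float, float]:
    """Binomial dimer-species fractions (wt:wt, mut:mut, het) at wt fraction f."""
    f = float(f_wildtype)
    if not 0.0 <= f <= 1.0:
        raise ValueError("wild-type fraction must lie in [0, 1]")
    return f * f, (1.0 - f) * (1.0 - f), 2.0 * f * (1.0 - f)


def total_activity(
    f_wildtype,
    v_wt: float,
    v_mut: float,
    v_het: float,
    includes_factor_2: bool = True,
):
    """Total activity of a binomially re-assorted mixture at wt fraction f."""
    f = np.asarray(f_wildtype, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("wild-type fraction must lie in [0, 1]")
    if min(v_wt, v_mut, v_het) < 0:
        raise ValueError("activities must be >= 0")
    het_weight = 2.0 * f * (1.0 - f) if includes_factor_2 else f * (1.0 - f)
    out = v_wt * f**2 + v_mut * (1.0 - f) ** 2 + v_het * het_weight
    return float(out) if np.isscalar(f_wildtype) else out


def independent_expectation(f_wildtype, v_wt: float, v_mut: float):
    """Expected activity if the two protomers hydrolyze independently.

    Equals the binomial mixture with v_het = (v_wt+v_mut)/2 and reduces to
    the straight line v_wt*f + v_mut*(1-f).
    """
    f = np.asarray(f_wildtype, dtype=float)
    out = v_wt * f + v_mut * (1.0 - f)
    return float(out) if np.isscalar(f_wildtype) else out


def fit_heterodimer_activity(
    table: MixTable,
    v_wt: float,
    v_mut: float,
    includes_factor_2: bool = True,
) -> MixFitResult:
    """One-parameter least squares for the heterodimer activity.

    The homodimer activities are fixed (measured anchors at f=1 and f=0);
    only v_het is estimated, in closed form since the model is linear in it.
    The standard error comes from the residual variance.
    """
    f = table.f_wildtype
    interior = (f > 0) & (f < 1)
    if not np.any(interior):
        raise ValueError("mixing table has no interior fractions to constrain v_het")
    w = 2.0 * f * (1.0 - f) if includes_factor_2 else f * (1.0 - f)
    resid0 = table.v_total - v_wt * f**2 - v_mut * (1.0 - f) ** 2
    sww = float(np.sum(w * w))
    v_het = float(np.sum(w * resid0) / sww)
    resid = resid0 - v_het * w
    rss = float(np.sum(resid**2))
    dof = max(len(f) - 1, 1)
    se = math.sqrt(rss / dof / sww)
    return MixFitResult(
        v_wildtype=v_wt,
        v_mutant=v_mut,
        v_heterodimer=v_het,
        v_heterodimer_se=se,
        fixed_wildtype=True,
        fixed_mutant=True,
        includes_factor_2=includes_factor_2,
        rss=rss,
        sub_additive=v_het < 0.5 * (v_wt + v_mut) - 1e-9 * max(1.0, abs(v_wt) + abs(v_mut)),
    )
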