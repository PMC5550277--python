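"""Two-conformer decomposition of DEER spin-label distance distributions.

The MD:CTD spin-label distance of a closed TRAP1 protomer reports its arm
conformation: the buckled arm gives a short distance (~22 Å reference) and
the straight arm a long one (~41 Å).  Starting from a processed distance
distribution P(r), this module fits a two-Gaussian mixture

    P(r) = w1 N(r; µ1, σ1) + w2 N(r; µ2, σ2),   w1 + w2 = 1,  µ1 <= µ2

and assigns each component to the nearer reference distance to obtain the
buckled/straight conformer fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np
from scipy.signal import find_peaks


@dataclass
class DistanceDistribution:
    """A normalized P(r) on a uniform, strictly increasing r grid (Å)."""

    r: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.r) != len(self.p):
            raise ValueError("r and p must have the same length")
        if len(self.r) < 3:
            raise ValueError("distance grid too short")
        dr = np.diff(self.r)
        if np.any(dr <= 0):
            raise ValueError("r grid must be strictly increasing")
        if not np.allclose(dr, dr[0], rtol=1e-6):
            raise ValueError("r grid must be uniformly spaced")
        if np.any(self.p < 0):
            raise ValueError("densities must be >= 0")
        integral = np.trapezoid(self.p, self.r)
        if abs(integral - 1.0) > 1e-6:
            raise ValueError(
                f"P(r) must integrate to 1 (got {integral:.6g}); "
                "use DistanceDistribution.from_unnormalized"
            )

    @classmethod
    def from_unnormalized(cls, r, p) -> "DistanceDistribution":
        r = np.asarray(r, dtype=float)
        p = np.clip(np.asarray(p, dtype=float), 0.0, None)
        integral = np.trapezoid(p, r)
        if integral <= 0:
            raise ValueError("cannot normalize an all-zero density")
        return cls(r, p / integral)


@dataclass
class TwoStateFit:
    """Two-Gaussian decomposition with centers ordered µ1 <= µ2."""

    centers: tuple  # (µ1, µ2), Å
    widths: tuple  # (σ1, σ2), Å
    weights: tuple  # (w1, w2), on the simplex
    rss: float
    converged: bool
    degenerate: bool  # centers closer than 2 Å


def _gauss(r, mu, sigma):
    return np.exp(-0.5 * ((r - mu) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def _default_init(dist: DistanceDistribution):
    """Initial centers from the two highest well-separated local maxima."""
    dr = dist.r[1] - dist.r[0]
    min_sep = max(int(round(4.0 / dr)), 2)
    peaks, props = find_peaks(dist.p, distance=min_sep, height=0.0)
    if len(peaks) >= 2:
        top = peaks[np.argsort(props["peak_heights"])[-2:]]
        mu = np.sort(dist.r[top])
    else:
        # unimodal: seed from the 25% / 75% quantiles of the distribution
        cdf = np.cumsum(dist.p)
        cdf /= cdf[-1]
        mu = np.array([np.interp(0.25, cdf, dist.r), np.interp(0.75, cdf, dist.r)])
    return float(mu[0]), float(mu[1])


def fit_two_gaussians(
    dist: DistanceDistribution, init: Optional[dict] = None
) -> TwoStateFit:
    """Least-squares two-Gaussian mixture fit on the P(r) grid.

    ``init`` may provide ``mu1, mu2, sigma1, sigma2, w1`` starting values;
    otherwise centers are seeded from the two highest well-separated local
    maxima.  Component order is fixed to µ1 <= µ2 after the fit; a fit whose
    centers land within 2 Å of each other is flagged degenerate (effectively
    unimodal input).
    """
    if len(dist.r) < 50:
        raise ValueError("distance grid too coarse: need >= 50 points across the support")
    mu1_0, mu2_0 = _default_init(dist)
    defaults = {"mu1": mu1_0, "mu2": mu2_0, "sigma1": 3.0, "sigma2": 3.0, "w1": 0.5}
    if init:
        defaults.update(init)

    def model(r, mu1, mu2, sigma1, sigma2, w1):
        return w1 * _gauss(r, mu1, sigma1) + (1.0 - w1) * _gauss(r, mu2, sigma2)

    params = lmfit.Parameters()
    r_lo, r_hi = float(dist.r[0]), float(dist.r[-1])
    params.add("mu1", value=defaults["mu1"], min=r_lo, max=r_hi)
    params.add("mu2", value=defaults["mu2"], min=r_lo, max=r_hi)
    params.add("sigma1", value=defaults["sigma1"], min=1e-3)
    params.add("sigma2", value=defaults["sigma2"], min=1e-3)
    params.add("w1", value=defaults["w1"], min=0.0, max=1.0)
    result = lmfit.Model(model, independent_vars=["r"]).fit(dist.p, params=params, r=dist.r)
    p = result.params
    mu = [float(p["mu1"].value), float(p["mu2"].value)]
    sigma = [float(p["sigma1"].value), float(p["sigma2"].value)]
    w = [float(p["w1"].value), 1.0 - float(p["w1"].value)]
    if mu[0] > mu[1]:
        mu.reverse()
        sigma.reverse()
        w.reverse()
    return TwoStateFit(
        centers=tuple(mu),
        widths=tuple(sigma),
        weights=tuple(w),
        rss=float(np.sum(result.residual**2)),
        converged=bool(result.success),
        degenerate=abs(mu[1] - mu[0]) < 2.0,
    )


@dataclass
class ConformerFractions:
    f_buckled: float
    f_straight: float
    ambiguous: bool


def conformer_fractions(
    fit: TwoStateFit,
    ref_buckled: float = 22.0,
    ref_straight: float = 41.0,
) -> ConformerFractions:
    """Assign mixture components to conformers by nearest reference distance.

    The reference distances default to the short (buckled) and long
    (straight) MD:CTD spin-label separations; each fitted component takes the
    weight of the conformer whose reference it is closer to.  If both
    components fall nearer the same reference the assignment is flagged
    ambiguous; a degenerate fit is rejected.
    """
    if fit.degenerate:
        raise ValueError("degenerate fit: conformer fractions are undefined")
    assign = [
        "buckled" if abs(mu - ref_buckled) <= abs(mu - ref_straight) else "straight"
        for mu in fit.centers
    ]
    if assign[0] == assign[1]:
        # both components nearest the same conformer: report its total weight
        f_b = 1.0 if assign[0] == "buckled" else 0.0
        return ConformerFractions(f_b, 1.0 - f_b, ambiguous=True)
    f_buckled = fit.weights[assign.index("buckled")]
    return ConformerFractions(f_buckled, 1.0 - f_buckled, ambiguous=False)
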