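"""Seeded generators for every input the analysis modules consume.

The generators emulate the study's assays with the statistical structure the
analyses assume — two-state closure/reopening FRET kinetics, Mg2+-free
phosphate-release time courses rendered through a linear sensor standard
curve with a detector-linearity cap, single-turnover hydrolyzed-fraction
traces, binomially re-assorted dimer mixing tables, two-Gaussian DEER
distance distributions, and toy box-water trajectories with site-specific
telegraph (on/off) exchange kinetics around the two ATP pockets.

Default parameters are the study conditions: closure 0.16/min (with Mg) or
6.95/hr (Mg-free), per-site Mg-free hydrolysis 0.5808/hr on top of a
spontaneous 0.00155/hr background, 500 µM initial ATP, distance-peak centers
22/41 Å, frames every 3 ns.  Identical spec (seed + parameters) reproduces
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cycle_model import CycleRates, SimResult, Variant, simulate_master
from .deer_conformers import DistanceDistribution
from .kinetics import Calibration, KineticTrace
from .mixing_model import MixTable, total_activity
from .water_dynamics import ROLE_SITE, ROLE_WATER, TrajectoryFrames


@dataclass
class GeneratorSpec:
    """Seed and noise model shared by all generators.

    ``noise_frac`` is the Gaussian noise sigma as a fraction of the signal
    scale (homoscedastic).  Scenario parameters are passed to the individual
    generators and echoed back in each generator's ``params`` dict.
    """

    seed: int = 0
    noise_frac: float = 0.02

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))


_VARIANTS = {
    "wild_type": Variant.wild_type,
    "het_E115A": Variant.het_hydrolysis_dead,
    "het_R402A": Variant.het_sensor_broken,
    "dead_dead": Variant.dead_dead,
}


def _resolve_variant(variant) -> Variant:
    if isinstance(variant, Variant):
        return variant
    try:
        return _VARIANTS[variant]()
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(_VARIANTS)}")


def gen_fret_traces(
    spec: GeneratorSpec,
    variant="het_E115A",
    rates: Optional[CycleRates] = None,
    t_max: float = 40.0,
    n_points: int = 120,
    donor0: float = 100.0,
    acceptor0: float = 60.0,
    eta: float = 0.1,
    kappa: float = 0.1,
    initial: str = "open_tt",
):
    """Donor/acceptor fluorescence channels driven by the cycle model.

    The master-equation closed fraction f(t) maps to the channels as
    donor = donor0*(1 - eta*f) and acceptor = acceptor0*(1 + kappa*f), plus
    Gaussian noise.  Returns (donor trace, acceptor trace, params).
    """
    rates = rates or CycleRates.mg()
    var = _resolve_variant(variant)
    t = np.linspace(0.0, t_max, n_points)
    res = simulate_master(rates, var, t, mode="multiple", initial=initial)
    f = res.fraction_closed
    rng = spec.rng(1)
    donor = donor0 * (1.0 - eta * f)
    acceptor = acceptor0 * (1.0 + kappa * f)
    donor = donor + rng.normal(0.0, spec.noise_frac * donor0, n_points)
    acceptor = acceptor + rng.normal(0.0, spec.noise_frac * acceptor0, n_points)
    unit = rates.time_unit
    params = {
        "seed": spec.seed, "noise_frac": spec.noise_frac, "variant": variant,
        "t_max": t_max, "n_points": n_points, "donor0": donor0,
        "acceptor0": acceptor0, "eta": eta, "kappa": kappa, "initial": initial,
    }
    return (
        KineticTrace(t, donor, time_unit=unit, kind="rfu", label="donor"),
        KineticTrace(t, acceptor, time_unit=unit, kind="rfu", label="acceptor"),
        params,
    )


def default_calibration() -> Calibration:
    """The generator's phosphate-sensor standard curve (RFU = 500 + 1950*[Pi])."""
    return Calibration(slope=1950.0, intercept=500.0, linear_cap=20000.0, points_used=0)


def gen_phosphate_release(
    spec: GeneratorSpec,
    dimer_concs=(0.0, 0.5, 1.0, 2.0),
    k_cat_site: float = 0.5808,
    k_spont: float = 0.00155,
    atp0: float = 500.0,
    t_max: float = 2.0,
    n_points: int = 60,
    calibration: Optional[Calibration] = None,
    closed_efficiency: float = 1.0,
    inhibited: bool = False,
):
    """Mg2+-free phosphate-release assay: RFU traces plus a standards table.

    Free phosphate follows first-order depletion of the ATP pool,
    Pi(t) = atp0*(1 - exp(-k_tot t)) with
    k_tot = k_spont + 2*k_cat_site*eff*[dimer]/atp0 (all sites closed and
    loaded; ``closed_efficiency`` scales the catalyzed term for partial
    closure, and ``inhibited`` zeroes it — the ATPase-inhibitor control).
    Pi maps to RFU through the linear standard curve; readings at or above
    the detector cap respond with a compressed (non-linear) slope and must be
    excluded by the analysis-side calibration rule.  Times are in hours.
    """
    cal = calibration or default_calibration()
    rng = spec.rng(2)
    t = np.linspace(0.0, t_max, n_points)
    traces = {}
    for conc in dimer_concs:
        catalyzed = 0.0 if inhibited else 2.0 * k_cat_site * closed_efficiency * conc / atp0
        k_tot = k_spont + catalyzed
        pi = atp0 * (-np.expm1(-k_tot * t))
        rfu = cal.intercept + cal.slope * pi
        over = rfu >= cal.linear_cap
        rfu[over] = cal.linear_cap + 0.2 * (rfu[over] - cal.linear_cap)
        rfu = rfu + rng.normal(0.0, spec.noise_frac * cal.slope, n_points)
        traces[conc] = KineticTrace(
            t, rfu, time_unit="hr", kind="rfu", label=f"dimer {conc} uM"
        )
    pi_std = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0])
    rfu_std = cal.intercept + cal.slope * pi_std
    over = rfu_std >= cal.linear_cap
    rfu_std[over] = cal.linear_cap + 0.2 * (rfu_std[over] - cal.linear_cap)
    rfu_std = rfu_std + rng.normal(0.0, spec.noise_frac * cal.slope, len(pi_std))
    standards = pd.DataFrame({"pi_uM": pi_std, "rfu": rfu_std})
    params = {
        "seed": spec.seed, "noise_frac": spec.noise_frac,
        "dimer_concs": list(dimer_concs), "k_cat_site": k_cat_site,
        "k_spont": k_spont, "atp0": atp0, "t_max": t_max, "n_points": n_points,
        "cal_slope": cal.slope, "cal_intercept": cal.intercept,
        "linear_cap": cal.linear_cap, "closed_efficiency": closed_efficiency,
        "inhibited": inhibited,
    }
    return traces, standards, params


def gen_single_turnover(
    spec: GeneratorSpec,
    variant="het_E115A",
    rates: Optional[CycleRates] = None,
    t_max: float = 60.0,
    n_points: int = 80,
):
    """Single-turnover hydrolyzed-fraction time course from the cycle model.

    With ``rates.k_open_leak > 0`` the +/hydrolysis-dead trace gains the slow
    second phase of leak-driven re-closure on the dimer's own nucleotides.
    Returns (trace, params).
    """
    rates = rates or CycleRates.mg()
    var = _resolve_variant(variant)
    t = np.linspace(0.0, t_max, n_points)
    res = simulate_master(rates, var, t, mode="single")
    rng = spec.rng(3)
    frac = res.hydrolyzed_fraction + rng.normal(0.0, spec.noise_frac, n_points)
    params = {
        "seed": spec.seed, "noise_frac": spec.noise_frac, "variant": variant,
        "t_max": t_max, "n_points": n_points, "k_open_leak": rates.k_open_leak,
    }
    return (
        KineticTrace(t, frac, time_unit=rates.time_unit,
                     kind="fraction_hydrolyzed", label=str(variant)),
        params,
    )


def gen_mixing_table(
    spec: GeneratorSpec,
    v_wt: float = 1.0,
    v_mut: float = 0.0,
    v_het: float = 0.2,
    f_grid=None,
    n_replicates: int = 3,
    includes_factor_2: bool = True,
):
    """Binomially mixed dimer activity table with replicate noise.

    Each fraction is measured ``n_replicates`` times with Gaussian noise of
    sigma = noise_frac * v_wt; the table holds replicate means and SDs.
    Returns (MixTable, params).
    """
    f = np.linspace(0.0, 1.0, 11) if f_grid is None else np.asarray(f_grid, dtype=float)
    rng = spec.rng(4)
    truth = total_activity(f, v_wt, v_mut, v_het, includes_factor_2)
    reps = truth[:, None] + rng.normal(0.0, spec.noise_frac * v_wt, (len(f), n_replicates))
    params = {
        "seed": spec.seed, "noise_frac": spec.noise_frac, "v_wt": v_wt,
        "v_mut": v_mut, "v_het": v_het, "n_replicates": n_replicates,
        "includes_factor_2": includes_factor_2,
    }
    return (
        MixTable(f, reps.mean(axis=1), sd=reps.std(axis=1, ddof=1)),
        params,
    )


def gen_pr(
    spec: GeneratorSpec,
    centers=(22.0, 41.0),
    widths=(3.0, 4.0),
    weights=(0.5, 0.5),
    r_min: float = 10.0,
    r_max: float = 60.0,
    dr: float = 0.25,
    noise: Optional[float] = None,
):
    """Two-Gaussian distance distribution on a uniform r grid, renormalized.

    ``noise`` (default the spec's noise_frac) adds Gaussian grid noise scaled
    to the peak density before clipping at zero and renormalizing.
    Returns (DistanceDistribution, params).
    """
    if len(centers) != len(widths) or len(centers) != len(weights):
        raise ValueError("centers, widths and weights must have equal length")
    r = np.arange(r_min, r_max + 0.5 * dr, dr)
    p = np.zeros_like(r)
    wsum = float(np.sum(weights))
    for mu, sig, w in zip(centers, widths, weights):
        p += (w / wsum) * np.exp(-0.5 * ((r - mu) / sig) ** 2) / (sig * math.sqrt(2 * math.pi))
    level = spec.noise_frac if noise is None else noise
    if level > 0:
        rng = spec.rng(5)
        p = p + rng.normal(0.0, level * p.max(), len(r))
    params = {
        "seed": spec.seed, "centers": list(centers), "widths": list(widths),
        "weights": list(weights), "r_min": r_min, "r_max": r_max, "dr": dr,
        "noise": level,
    }
    return DistanceDistribution.from_unnormalized(r, p), params


#: default telegraph kinetics (per ns): the buckled pocket holds fewer,
#: shorter-lived waters than the straight pocket
DEFAULT_SITE_KINETICS = {
    "buckled": {"k_on": 0.02, "k_off": 0.18},
    "straight": {"k_on": 0.015, "k_off": 0.06},
}


def gen_trajectory(
    spec: GeneratorSpec,
    n_waters_per_site: int = 40,
    site_centers=((15.0, 15.0, 15.0), (35.0, 35.0, 35.0)),
    site_kinetics: Optional[dict] = None,
    frame_interval: float = 3.0,
    n_frames: int = 200,
    box_size: float = 50.0,
    cutoff: float = 5.0,
    bound_radius: float = 3.0,
):
    """Toy box-water trajectory with two-state exchange at two ATP pockets.

    Each pocket is marked by two site atoms 1 Å either side of its center.
    Every water belongs to one pocket and follows an exact two-state
    telegraph process sampled at the frame interval (stationary occupancy
    k_on/(k_on+k_off)); when bound it sits within ``bound_radius`` of the
    pocket center (inside the cutoff), when unbound it is uniform in the box
    but excluded from both cutoff shells.  Returns (TrajectoryFrames, params).
    """
    kin = site_kinetics or DEFAULT_SITE_KINETICS
    labels = list(kin)
    centers = np.asarray(site_centers, dtype=float)
    if len(labels) != len(centers):
        raise ValueError("one center per site required")
    if len(centers) == 2 and np.linalg.norm(centers[0] - centers[1]) <= 2.0 * (cutoff + 1.0):
        raise ValueError("site shells overlap; move the site centers apart")
    rng = spec.rng(6)
    site_offsets = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
    atoms = []
    site_atom_coords = []
    for lbl, c in zip(labels, centers):
        for k, off in enumerate(site_offsets):
            atoms.append({"id": f"site_{lbl}_{k}", "role": ROLE_SITE, "site": lbl})
            site_atom_coords.append(c + off)
    n_sites = len(labels)
    n_waters = n_waters_per_site * n_sites
    for w in range(n_waters):
        atoms.append({"id": f"W{w}", "role": ROLE_WATER, "site": ""})
    atoms = pd.DataFrame(atoms)
    site_atom_coords = np.asarray(site_atom_coords)

    times = np.arange(n_frames) * frame_interval
    coords = np.zeros((n_frames, len(atoms), 3))
    coords[:, : len(site_atom_coords)] = site_atom_coords[None, :, :]

    def bound_position(center):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        radius = bound_radius * rng.random() ** (1.0 / 3.0)
        return center + radius * v

    def unbound_position():
        while True:
            pos = rng.random(3) * box_size
            d = np.linalg.norm(site_atom_coords - pos, axis=1)
            if np.min(d) > cutoff + 0.5:
                return pos

    offset = len(site_atom_coords)
    for s, lbl in enumerate(labels):
        k_on, k_off = kin[lbl]["k_on"], kin[lbl]["k_off"]
        lam = k_on + k_off
        pi_on = k_on / lam if lam > 0 else 0.0
        decay = math.exp(-lam * frame_interval)
        p_on_given_on = pi_on + (1.0 - pi_on) * decay
        p_on_given_off = pi_on * (1.0 - decay)
        center = centers[s]
        for w in range(n_waters_per_site):
            col = offset + s * n_waters_per_site + w
            bound = rng.random() < pi_on
            for f in range(n_frames):
                if f > 0:
                    p_on = p_on_given_on if bound else p_on_given_off
                    bound = rng.random() < p_on
                coords[f, col] = bound_position(center) if bound else unbound_position()
    traj = TrajectoryFrames(coords, atoms, times, box=None)
    params = {
        "seed": spec.seed, "n_waters_per_site": n_waters_per_site,
        "site_centers": centers.tolist(), "site_kinetics": {k: dict(v) for k, v in kin.items()},
        "frame_interval": frame_interval, "n_frames": n_frames,
        "box_size": box_size, "cutoff": cutoff, "bound_radius": bound_radius,
    }
    return traj, params
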