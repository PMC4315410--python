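"""Synthetic sandwich-plate data with the kinetic structure of the assay.

The generator solves a linear compartment model of one well pair.  The
lipid-filled filter is split into two exchanging pools:

* a *transport pool* (water-equivalent capacity ``phi * K * Vm``) through
  which donor and acceptor communicate, each face with interface
  permeability ``2 * true_pe`` so that the quasi-steady series resistance
  reproduces ``true_pe`` exactly;
* a *binding pool* (capacity ``(1 - phi) * K * Vm``) exchanging with the
  transport pool at the slower ``binding_permeability``, standing in for
  hydrogen-bond sequestration of drug by the immobilised lipid.

Here ``K`` is the membrane/water partition ratio and ``Vm`` the physical
membrane volume, so the membrane holds ``K * Vm * C`` at equilibrium with
wells at concentration ``C``.  Nothing moves before the steady-state lag
t_0; afterwards the system evolves by matrix exponential, conserving mass
to machine precision.  As the membrane capacity vanishes, the model
collapses exactly onto the closed-form two-compartment solution of
:func:`pampakit.permeability.forward_concentrations`.

Filling the transport pool delays acceptor flux (apparent P_e rises over
the first hours); once the wells have nearly equalised, the still-hungry
binding pool keeps draining both — the acceptor faster, having the
smaller volume — so the apparent P_e passes a maximum and declines
slightly, reproducing the parabola-shaped time course seen in sandwich
assays with retentive membranes.

Read noise is multiplicative lognormal (UV quantification error scales
with signal), with the mean-one parameterisation so ``noise_cv`` is the
coefficient of variation exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .permeability import effective_permeability, forward_concentrations
from .plate import ConcentrationRecord, SandwichGeometry, write_plate_table
from .reference import PHProfilePoint
from . import phmodel

__all__ = [
    "SimParams",
    "SimTrajectory",
    "simulate_sandwich",
    "apparent_pe_time_course",
    "generate_ph_dataset",
    "generate_plate_csv",
]

DEFAULT_TIME_GRID_S = tuple(float(h) * 3600.0 for h in range(4, 21))


@dataclass(frozen=True)
class SimParams:
    """Physical and statistical parameters of one simulated well pair.

    ``membrane_capacity`` is the physical membrane volume in cm^3 and
    ``membrane_partition_ratio`` the membrane/water affinity, so the
    membrane's water-equivalent capacity is their product.
    ``binding_permeability_cm_per_s`` (default ``true_pe / 2``) sets how
    fast the sequestered pool fills; ``transport_pool_fraction`` is the
    capacity share of the conductive pool.
    """

    true_pe_cm_per_s: float = 2e-5
    membrane_capacity: float = 0.01
    membrane_partition_ratio: float = 50.0
    geometry: SandwichGeometry = field(default_factory=SandwichGeometry)
    noise_cv: float = 0.0
    seed: int = 0
    time_grid_s: tuple[float, ...] = DEFAULT_TIME_GRID_S
    donor_conc_initial: float = 1.0
    binding_permeability_cm_per_s: float | None = None
    transport_pool_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.true_pe_cm_per_s < 0:
            raise ValueError("true_pe_cm_per_s must be non-negative")
        if self.membrane_capacity <= 0 or self.membrane_partition_ratio <= 0:
            raise ValueError("membrane capacity and partition ratio must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0 < self.transport_pool_fraction < 1:
            raise ValueError("transport_pool_fraction must lie in (0, 1)")
        if len(self.time_grid_s) == 0 or min(self.time_grid_s) <= 0:
            raise ValueError("time_grid_s must hold positive times")

    @property
    def binding_permeability(self) -> float:
        if self.binding_permeability_cm_per_s is not None:
            return self.binding_permeability_cm_per_s
        return 0.5 * self.true_pe_cm_per_s


@dataclass(frozen=True)
class SimTrajectory:
    """Noise-free donor/membrane/acceptor state along the time grid.

    ``membrane_amount`` is the total drug amount in the membrane
    (transport plus binding pool, concentration x volume units), so
    V_d C_d + membrane_amount + V_a C_a is conserved.
    """

    times_s: np.ndarray
    donor_conc: np.ndarray
    membrane_amount: np.ndarray
    acceptor_conc: np.ndarray
    params: SimParams


def _rate_matrix(params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Linear generator for amounts (n_d, n_f, n_a, n_b) and capacities."""
    g = params.geometry
    va, vd, area = g.acceptor_volume_cm3, g.donor_volume_cm3, g.filter_area_cm2
    k_vm = params.membrane_partition_ratio * params.membrane_capacity
    vf = params.transport_pool_fraction * k_vm
    vb = (1.0 - params.transport_pool_fraction) * k_vm
    p = 2.0 * params.true_pe_cm_per_s  # per-face interface permeability
    pb = params.binding_permeability
    caps = np.array([vd, vf, va, vb])
    m = np.zeros((4, 4))
    # donor <-> transport pool
    m[0, 0] -= area * p / vd
    m[0, 1] += area * p / vf
    m[1, 0] += area * p / vd
    m[1, 1] -= area * p / vf
    # acceptor <-> transport pool
    m[2, 2] -= area * p / va
    m[2, 1] += area * p / vf
    m[1, 2] += area * p / va
    m[1, 1] -= area * p / vf
    # transport pool <-> binding pool
    m[1, 1] -= area * pb / vf
    m[1, 3] += area * pb / vb
    m[3, 1] += area * pb / vf
    m[3, 3] -= area * pb / vb
    return m, caps


def simulate_sandwich(params: SimParams) -> SimTrajectory:
    """Deterministic (pre-noise) trajectory of the compartment model.

    The initial dose sits entirely in the donor well and nothing moves
    until the steady-state lag t_0; identical parameters give identical
    output.  Zero permeability leaves all concentrations constant.
    """
    g = params.geometry
    times = np.asarray(sorted(params.time_grid_s), dtype=float)
    vd, va = g.donor_volume_cm3, g.acceptor_volume_cm3
    x0 = np.array([vd * params.donor_conc_initial, 0.0, 0.0, 0.0])
    if params.true_pe_cm_per_s == 0.0:
        states = np.tile(x0, (len(times), 1))
    else:
        m, _ = _rate_matrix(params)
        states = np.empty((len(times), 4))
        for i, t in enumerate(times):
            tau = max(t - g.steady_state_lag_s, 0.0)
            states[i] = expm(m * tau) @ x0
    if not np.all(np.isfinite(states)):
        raise FloatingPointError("compartment integration produced non-finite state")
    return SimTrajectory(
        times_s=times,
        donor_conc=states[:, 0] / vd,
        membrane_amount=states[:, 1] + states[:, 3],
        acceptor_conc=states[:, 2] / va,
        params=params,
    )


def apparent_pe_time_course(
    traj: SimTrajectory, geometry: SandwichGeometry | None = None
) -> list[tuple[float, float]]:
    """Apparent P_e at each sampled time past the lag.

    Runs each (t, C_d, C_a) snapshot through the mass-balance equation,
    exactly as a plate reader time series would be analysed.  Requires at
    least five usable times for a meaningful course.
    """
    g = geometry if geometry is not None else traj.params.geometry
    cd0 = traj.params.donor_conc_initial
    out = []
    for t, cd, ca in zip(traj.times_s, traj.donor_conc, traj.acceptor_conc):
        if t <= g.steady_state_lag_s:
            continue
        rec = ConcentrationRecord(
            compound_name="sim",
            lipid_label="sim",
            donor_pH=7.4,
            acceptor_pH=7.4,
            incubation_time_s=float(t),
            donor_conc_initial=cd0,
            donor_conc_final=float(cd),
            acceptor_conc_final=float(ca),
        )
        res = effective_permeability(rec, g)
        if res.quality_flag in ("ok", "no_transport"):
            out.append((float(t), res.pe_cm_per_s))
    if len(out) < 5:
        raise ValueError("need at least five sampled times beyond the lag t_0")
    return out


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=size)


def generate_ph_dataset(
    P_o: float,
    P_u: float,
    pKa,
    ionization_class: str,
    ph_grid: Sequence[float],
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[PHProfilePoint]:
    """Noisy P_e-pH profile drawn from the pH-partition model.

    Each grid point is the mean of ``n_replicates`` lognormal multiplicative
    draws around the model curve, with the replicate SD attached (the SD is
    0 for a single replicate or zero noise).  ``pKa`` is a scalar for
    monoprotic classes or an (acidic, basic) pair for ampholytes.
    """
    rng = np.random.default_rng(seed)
    pkas = tuple(np.atleast_1d(np.asarray(pKa, dtype=float)))
    points = []
    for ph in ph_grid:
        if ionization_class == "ampholyte":
            true = phmodel.predict_pe_ampholyte(ph, P_o, P_u, pkas[0], pkas[-1])
        else:
            true = phmodel.predict_pe_monoprotic(ph, P_o, P_u, pkas[0], ionization_class)
        reps = true * _lognormal_factors(rng, noise_cv, n_replicates)
        mean = float(np.mean(reps))
        sd = float(np.std(reps, ddof=1)) if n_replicates > 1 else 0.0
        # guard against pure rounding scatter of identical replicates
        if sd <= 1e-12 * mean:
            sd = 0.0
        points.append(
            PHProfilePoint(
                pH=float(ph),
                pe_cm_per_s=mean,
                sd_cm_per_s=sd if sd > 0 else None,
            )
        )
    return points


def generate_plate_csv(
    true_pe: dict[tuple[str, str], float],
    path: str | Path,
    times_s: Sequence[float] = (57600.0,),
    retention: float = 0.0,
    cd0: float = 1.0,
    donor_pH: float = 7.4,
    acceptor_pH: float = 7.4,
    noise_cv: float = 0.0,
    seed: int = 0,
    geometry: SandwichGeometry | None = None,
) -> list[ConcentrationRecord]:
    """Write a plate-schema CSV over a (drug, lipid) x time grid.

    ``true_pe`` maps (compound, lipid) to its true permeability; wells are
    produced by the closed-form forward model, then each measured
    concentration gets independent multiplicative read noise.  The file
    round-trips through :func:`pampakit.plate.read_plate_table`, and with
    ``noise_cv=0`` the batch permeability pipeline recovers the true
    values exactly.
    """
    g = geometry if geometry is not None else SandwichGeometry()
    rng = np.random.default_rng(seed)
    records = []
    for (compound, lipid), pe in sorted(true_pe.items()):
        for t in times_s:
            cd, ca = forward_concentrations(pe, retention, g, cd0, float(t))
            f_cd0, f_cd, f_ca = _lognormal_factors(rng, noise_cv, 3)
            records.append(
                ConcentrationRecord(
                    compound_name=compound,
                    lipid_label=lipid,
                    donor_pH=donor_pH,
                    acceptor_pH=acceptor_pH,
                    incubation_time_s=float(t),
                    donor_conc_initial=cd0 * f_cd0,
                    donor_conc_final=cd * f_cd,
                    acceptor_conc_final=ca * f_ca,
                )
            )
    write_plate_table(records, path)
    return records
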