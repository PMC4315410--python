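"""Effective permeability from sandwich-plate mass balance.

The acceptor well fills toward the joint-equilibrium concentration of the
two wells; the effective permeability P_e (cm/s) is the rate constant of
that approach, corrected for the dose fraction lost to the membrane.  With
V_a, V_d the well volumes, A the filter area, t_0 the steady-state lag and
S the fraction of the dose still recoverable from the two wells,

    P_e = - V_a V_d / ((V_a + V_d) A (t - t_0)) * ln(1 - (V_a + V_d) C_a(t) / (V_d S C_d(0)))
    S   = V_a C_a(t) / (V_d C_d(0)) + C_d(t) / C_d(0)

The natural log is used directly: the conventional prefactor
2.303 * log10 is a rounded rendering of ln and would introduce a 0.013%
systematic bias.

``forward_concentrations`` is the exact closed-form inverse (the
two-compartment solution with an instantaneous membrane uptake at t_0),
used by the synthetic generator and by round-trip tests.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

from .plate import ConcentrationRecord, PermeabilityResult, SandwichGeometry

__all__ = [
    "LagTimeError",
    "mass_fraction_remaining",
    "effective_permeability",
    "forward_concentrations",
    "batch_permeability",
    "aggregate_replicates",
    "AggregatedPermeability",
]

logger = logging.getLogger(__name__)

#: S values in (1, 1 + S_TOLERANCE] are treated as read noise and clipped to 1.
S_TOLERANCE = 0.02
#: Log arguments in (0, EQUILIBRIUM_EPS] are flagged at_equilibrium: so close
#: to the joint equilibrium that noise makes P_e unidentifiable.
EQUILIBRIUM_EPS = 1e-12


class LagTimeError(ValueError):
    """The sampling time does not exceed the steady-state lag t_0."""


def mass_fraction_remaining(
    record: ConcentrationRecord, geometry: SandwichGeometry
) -> float:
    """S factor: fraction of the dose recoverable from donor plus acceptor."""
    if record.donor_conc_initial <= 0:
        raise ValueError("C_d(0) must be > 0 for the mass balance")
    va, vd = geometry.acceptor_volume_cm3, geometry.donor_volume_cm3
    cd0 = record.donor_conc_initial
    return (va * record.acceptor_conc_final) / (vd * cd0) + record.donor_conc_final / cd0


def effective_permeability(
    record: ConcentrationRecord, geometry: SandwichGeometry
) -> PermeabilityResult:
    """Compute P_e for one well, with mass-balance quality flags.

    Flags: ``no_transport`` (C_a = 0, P_e = 0), ``at_equilibrium`` (the
    acceptor has reached the joint equilibrium; no finite P_e, NaN),
    ``mass_balance_violation`` (S > 1 beyond read-noise tolerance, NaN).
    """
    t, t0 = record.incubation_time_s, geometry.steady_state_lag_s
    if t <= t0:
        raise LagTimeError(
            f"incubation time {t} s does not exceed the steady-state lag {t0} s"
        )
    va, vd = geometry.acceptor_volume_cm3, geometry.donor_volume_cm3
    area = geometry.filter_area_cm2
    cd0 = record.donor_conc_initial
    ca = record.acceptor_conc_final

    s = mass_fraction_remaining(record, geometry)
    name, lipid = record.compound_name, record.lipid_label

    if s > 1.0 + S_TOLERANCE:
        return PermeabilityResult(
            name, lipid, math.nan, s, 1.0 - s, "mass_balance_violation"
        )
    if s > 1.0:
        logger.warning(
            "%s/%s: S=%.4f slightly above 1, clipping to 1 (read noise)", name, lipid, s
        )
        s = 1.0
    if ca == 0.0:
        return PermeabilityResult(name, lipid, 0.0, s, 1.0 - s, "no_transport")
    if s <= 0.0:
        # unreachable for non-negative concentrations, kept as a guard
        return PermeabilityResult(
            name, lipid, math.nan, s, 1.0 - s, "mass_balance_violation"
        )

    log_arg = 1.0 - (va + vd) * ca / (vd * s * cd0)
    if log_arg <= EQUILIBRIUM_EPS:
        return PermeabilityResult(name, lipid, math.nan, s, 1.0 - s, "at_equilibrium")

    pe = -(va * vd) / ((va + vd) * area * (t - t0)) * math.log(log_arg)
    return PermeabilityResult(name, lipid, pe, s, 1.0 - s, "ok")


def forward_concentrations(
    pe: float,
    retention: float,
    geometry: SandwichGeometry,
    cd0: float,
    t: float,
) -> tuple[float, float]:
    """Closed-form (C_d(t), C_a(t)) for a true P_e and membrane retention.

    The membrane takes up the retained fraction at t_0; thereafter donor
    and acceptor exchange as a two-compartment system with rate
    k = pe * A * (V_a + V_d) / (V_a V_d).  Exact inverse of
    :func:`effective_permeability`.
    """
    if pe < 0:
        raise ValueError("pe must be non-negative")
    if not 0 <= retention < 1:
        raise ValueError("retention must lie in [0, 1)")
    t0 = geometry.steady_state_lag_s
    if t <= t0:
        raise LagTimeError(f"t={t} s must exceed the steady-state lag {t0} s")
    va, vd = geometry.acceptor_volume_cm3, geometry.donor_volume_cm3
    s = 1.0 - retention
    c_eq = s * vd * cd0 / (va + vd)
    k = pe * geometry.filter_area_cm2 * (va + vd) / (va * vd)
    ca = c_eq * (1.0 - math.exp(-k * (t - t0)))
    cd = s * cd0 - (va / vd) * ca
    return cd, ca


def batch_permeability(
    records: Sequence[ConcentrationRecord], geometry: SandwichGeometry
) -> list[PermeabilityResult]:
    """Per-record P_e results in input order."""
    if not records:
        raise ValueError("batch_permeability needs at least one record")
    return [effective_permeability(r, geometry) for r in records]


@dataclass(frozen=True)
class AggregatedPermeability:
    """Replicate wells of one condition reduced to mean +/- sd of P_e."""

    compound_name: str
    lipid_label: str
    donor_pH: float
    acceptor_pH: float
    incubation_time_s: float
    n_replicates: int
    n_valid: int
    pe_mean_cm_per_s: float
    pe_sd_cm_per_s: float
    flags: tuple[str, ...]


def aggregate_replicates(
    records: Sequence[ConcentrationRecord],
    geometry: SandwichGeometry,
) -> list[AggregatedPermeability]:
    """Group replicate wells and aggregate P_e after the transform.

    Wells sharing (compound, lipid, donor pH, acceptor pH, time) form one
    group, mirroring triplicate assays reported as mean +/- SD.  Replicates
    whose flag is not ``ok``/``no_transport`` are excluded from the mean
    but their flags are propagated; a group with no valid replicate is
    dropped with a logged warning.
    """
    groups: dict[tuple, list[ConcentrationRecord]] = {}
    for rec in records:
        key = (
            rec.compound_name,
            rec.lipid_label,
            rec.donor_pH,
            rec.acceptor_pH,
            rec.incubation_time_s,
        )
        groups.setdefault(key, []).append(rec)

    out: list[AggregatedPermeability] = []
    for key, group in groups.items():
        results = [effective_permeability(r, geometry) for r in group]
        valid = [r.pe_cm_per_s for r in results if r.quality_flag in ("ok", "no_transport")]
        flags = tuple(sorted({r.quality_flag for r in results}))
        if not valid:
            logger.warning("condition %s: no valid replicate, excluded from output", key)
            continue
        mean = statistics.fmean(valid)
        sd = statistics.stdev(valid) if len(valid) > 1 else 0.0
        out.append(
            AggregatedPermeability(
                compound_name=key[0],
                lipid_label=key[1],
                donor_pH=key[2],
                acceptor_pH=key[3],
                incubation_time_s=key[4],
                n_replicates=len(group),
                n_valid=len(valid),
                pe_mean_cm_per_s=mean,
                pe_sd_cm_per_s=sd,
                flags=flags,
            )
        )
    return out
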