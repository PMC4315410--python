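"""UWL-corrected pH-partition permeability model and profile fitting.

Only the un-ionized species crosses the lipid membrane; its fraction
follows the Henderson-Hasselbalch relation, and the unstirred water layer
(UWL) adds a pH-independent series resistance.  For a monoprotic compound

    1/P_e = 1/P_u + (10^{+/-(pH - pKa)} + 1) / P_o

with '+' for acids and '-' for bases; P_o is the intrinsic membrane
permeability of the neutral species and P_u the UWL permeability.  An
ampholyte (acidic pKa and basic pKa) gets the natural two-term extension

    1/P_e = 1/P_u + (10^{-(pH - pKa_b)} + 10^{+(pH - pKa_a)} + 1) / P_o

which reduces to the monoprotic form whenever one pKa leaves the pH
window and is unimodal with its maximum midway between the two pKa values.

Profiles are fitted by weighted least squares on the P_e scale (weights
1/sd^2 when SDs are available) with P_o, P_u optimised as base-10 logs so
they stay positive; an optional reciprocal mode fits 1/P_e instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .plate import DrugInfo
from .reference import PHProfilePoint

__all__ = [
    "PHProfileFit",
    "UnderdeterminedFitError",
    "fraction_unionized",
    "predict_pe_monoprotic",
    "predict_pe_ampholyte",
    "select_pka",
    "fit_ph_profile",
    "ph_of_max_permeability",
]

_LOG_BOUNDS = (-9.0, 0.0)  # log10 cm/s; 1 cm/s is far above any aqueous layer


class UnderdeterminedFitError(ValueError):
    """Fewer profile points than free parameters."""


def fraction_unionized(pH, pKa: float, ionization_class: str):
    """Henderson-Hasselbalch neutral fraction; exactly 1 for neutral drugs."""
    pH = np.asarray(pH, dtype=float)
    if ionization_class == "acid":
        frac = 1.0 / (1.0 + 10.0 ** (pH - pKa))
    elif ionization_class == "base":
        frac = 1.0 / (1.0 + 10.0 ** (pKa - pH))
    elif ionization_class == "neutral":
        frac = np.ones_like(pH)
    else:
        raise ValueError(f"fraction_unionized undefined for class {ionization_class!r}")
    return frac if frac.ndim else float(frac)


def _ionization_denominator(pH, pKas: Sequence[float], ionization_class: str):
    """The (10^... + 1) factor multiplying 1/P_o, i.e. 1/fraction-neutral."""
    pH = np.asarray(pH, dtype=float)
    if ionization_class == "acid":
        return 10.0 ** (pH - pKas[0]) + 1.0
    if ionization_class == "base":
        return 10.0 ** (pKas[0] - pH) + 1.0
    if ionization_class == "ampholyte":
        pka_acidic, pka_basic = pKas
        return 10.0 ** (-(pH - pka_basic)) + 10.0 ** (pH - pka_acidic) + 1.0
    if ionization_class == "neutral":
        return np.ones_like(pH)
    raise ValueError(f"unknown ionization class {ionization_class!r}")


def predict_pe_monoprotic(pH, P_o: float, P_u: float, pKa: float, ionization_class: str):
    """P_e of a monoprotic acid or base; always below min(P_u, P_o)."""
    if P_o <= 0 or P_u <= 0:
        raise ValueError("P_o and P_u must be positive")
    denom = _ionization_denominator(pH, (pKa,), ionization_class)
    pe = 1.0 / (1.0 / P_u + denom / P_o)
    return pe if np.ndim(pe) else float(pe)


def predict_pe_ampholyte(pH, P_o: float, P_u: float, pKa_acidic: float, pKa_basic: float):
    """P_e of an ampholyte; unimodal, peaking at (pKa_acidic + pKa_basic)/2."""
    if P_o <= 0 or P_u <= 0:
        raise ValueError("P_o and P_u must be positive")
    denom = _ionization_denominator(pH, (pKa_acidic, pKa_basic), "ampholyte")
    pe = 1.0 / (1.0 / P_u + denom / P_o)
    return pe if np.ndim(pe) else float(pe)


def select_pka(drug: DrugInfo, ph_window: tuple[float, float]) -> tuple[float, ...]:
    """Choose the pKa value(s) entering the profile model for a drug.

    Monoprotic classes use the pKa closest to the centre of the observed
    pH window (drugs tabulated with a second, far-off pKa keep only the
    relevant one).  Ampholytes use the outermost pair, the two pKa values
    bracketing the pH window; the lower is taken as the acidic centre and
    the upper as the basic one.
    """
    if drug.ionization_class == "neutral":
        return ()
    if drug.ionization_class == "ampholyte":
        if len(drug.pKa_values) < 2:
            raise ValueError("ampholyte needs two pKa values")
        return (drug.pKa_values[0], drug.pKa_values[-1])
    centre = 0.5 * (ph_window[0] + ph_window[1])
    return (min(drug.pKa_values, key=lambda p: abs(p - centre)),)


@dataclass(frozen=True)
class PHProfileFit:
    """Fitted UWL-corrected pH-partition model for one drug/lipid profile."""

    ionization_class: str
    pKa_used: tuple[float, ...]
    intrinsic_permeability: float  # P_o, cm/s
    uwl_permeability: float  # P_u, cm/s
    residual_sum_of_squares: float
    converged: bool
    n_points: int
    ph_window: tuple[float, float]
    pKa_fitted: bool = False

    def predict(self, pH):
        """Model P_e at the given pH value(s)."""
        denom = _ionization_denominator(pH, self.pKa_used, self.ionization_class)
        pe = 1.0 / (1.0 / self.uwl_permeability + denom / self.intrinsic_permeability)
        return pe if np.ndim(pe) else float(pe)

    def membrane_permeability_at(self, pH):
        """P_m(pH) = P_o scaled by the neutral fraction (UWL removed)."""
        denom = _ionization_denominator(pH, self.pKa_used, self.ionization_class)
        pm = self.intrinsic_permeability / denom
        return pm if np.ndim(pm) else float(pm)


def _weights(points: Sequence[PHProfilePoint]) -> np.ndarray:
    """1/sd^2 weights; printed sd of 0 borrows the smallest positive sd."""
    sds = np.array(
        [p.sd_cm_per_s if p.sd_cm_per_s is not None else np.nan for p in points]
    )
    if np.all(np.isnan(sds)):
        return np.ones(len(points))
    positive = sds[np.isfinite(sds) & (sds > 0)]
    fallback = positive.min() if positive.size else 1.0
    sds = np.where(np.isfinite(sds) & (sds > 0), sds, fallback)
    return 1.0 / sds**2


def fit_ph_profile(
    points: Sequence[PHProfilePoint],
    drug: DrugInfo,
    fit_pKa: bool = False,
    weighting: str = "pe",
) -> PHProfileFit:
    """Least-squares fit of (P_o, P_u) [and optionally pKa] to a profile.

    ``weighting='pe'`` (default) minimises sum w_i (pred_i - obs_i)^2 on
    the P_e scale; ``'reciprocal'`` fits 1/P_e instead (over-weights the
    smallest P_e values, offered for comparison).  Parameters are
    optimised as base-10 logs from a deterministic initial guess
    (P_u = 2 max observed P_e; P_o from the most-unionized point) plus a
    coarse log-grid multistart.
    """
    if weighting not in ("pe", "reciprocal"):
        raise ValueError("weighting must be 'pe' or 'reciprocal'")
    klass = drug.ionization_class
    if klass == "neutral":
        raise ValueError("a neutral drug has no pH profile to fit")
    n_params = 2 + (fit_pKa * (2 if klass == "ampholyte" else 1))
    if len(points) < max(3, n_params) or (fit_pKa and len(points) < n_params + 1):
        raise UnderdeterminedFitError(
            f"{len(points)} points cannot determine {n_params} parameters"
        )

    ph = np.array([p.pH for p in points])
    pe_obs = np.array([p.pe_cm_per_s for p in points])
    w = np.sqrt(_weights(points))
    window = (float(ph.min()), float(ph.max()))
    pkas0 = select_pka(drug, window)

    def unpack(x):
        po, pu = 10.0 ** x[0], 10.0 ** x[1]
        pkas = tuple(x[2:]) if fit_pKa else pkas0
        return po, pu, pkas

    def residuals(x):
        po, pu, pkas = unpack(x)
        denom = _ionization_denominator(ph, pkas, klass)
        pred = 1.0 / (1.0 / pu + denom / po)
        if weighting == "reciprocal":
            return w * (1.0 / pred - 1.0 / pe_obs)
        return w * (pred - pe_obs)

    # Deterministic initial guess.
    pu0 = 2.0 * pe_obs.max()
    denom0 = _ionization_denominator(ph, pkas0, klass)
    i_best = int(np.argmin(denom0))  # most-unionized observation
    inv_po = max(1.0 / pe_obs[i_best] - 1.0 / pu0, 1e-3 / pe_obs[i_best])
    po0 = denom0[i_best] / inv_po

    lo, hi = _LOG_BOUNDS
    starts = []
    for shift in (0.0, 2.0, -2.0, 4.0):
        x0 = [np.clip(np.log10(po0) + shift, lo, hi), np.clip(np.log10(pu0), lo, hi)]
        if fit_pKa:
            x0 += list(pkas0)
        starts.append(np.array(x0))

    bounds_lo = [lo, lo] + ([0.0] * (n_params - 2) if fit_pKa else [])
    bounds_hi = [hi, hi] + ([14.0] * (n_params - 2) if fit_pKa else [])

    best = None
    for x0 in starts:
        sol = least_squares(
            residuals,
            x0,
            bounds=(bounds_lo, bounds_hi),
            method="trf",
            x_scale="jac",
            ftol=1e-15,
            xtol=1e-15,
            gtol=1e-15,
            max_nfev=2000,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    po, pu, pkas = unpack(best.x)
    rss = float(np.sum(residuals(best.x) ** 2))
    return PHProfileFit(
        ionization_class=klass,
        pKa_used=tuple(float(p) for p in pkas),
        intrinsic_permeability=float(po),
        uwl_permeability=float(pu),
        residual_sum_of_squares=rss,
        converged=bool(best.success),
        n_points=len(points),
        ph_window=window,
        pKa_fitted=fit_pKa,
    )


def ph_of_max_permeability(
    fit: PHProfileFit, ph_range: tuple[float, float] | None = None
) -> float:
    """pH at which the fitted profile predicts its maximum P_e.

    Monotone classes peak at a boundary of the evaluated range (acids at
    the low end, bases at the high end); ampholytes peak in the interior,
    midway between the two pKa values.
    """
    if not fit.converged:
        raise ValueError("cannot locate the maximum of a non-converged fit")
    lo, hi = ph_range if ph_range is not None else fit.ph_window
    if fit.ionization_class == "acid":
        return float(lo)
    if fit.ionization_class == "base":
        return float(hi)
    grid = np.linspace(lo, hi, 20001)
    return float(grid[int(np.argmax(fit.predict(grid)))])
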