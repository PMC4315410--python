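"""Correlation between effective permeability and human fraction absorbed.

Reports both the Pearson product-moment r (which reproduces the published
correlation figures on the 16 h screen) and Spearman's rank rho with
mid-rank ties, each with its square, so either convention can be read off.
The exclusion analysis re-runs the correlation with a named subset of
drugs removed — in the source study amoxicillin, cimetidine and
ranitidine, whose absorption is thought to be carrier-mediated rather
than passive — on otherwise identical settings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .plate import DrugInfo

__all__ = [
    "CorrelationResult",
    "correlate_pe_fa",
    "exclusion_analysis",
    "DEVIATING_DRUGS",
]

#: Drugs excluded in the published subset analysis.
DEVIATING_DRUGS = ("Amoxicillin", "Cimetidine", "Ranitidine")


@dataclass(frozen=True)
class CorrelationResult:
    """All four P_e-%FA correlation statistics for one drug panel."""

    lipid_label: str
    n: int
    pearson_r: float
    pearson_r_squared: float
    spearman_rho: float
    spearman_rho_squared: float
    excluded_names: tuple[str, ...] = ()


def correlate_pe_fa(
    pairs: Sequence[tuple[float, float]], lipid_label: str = ""
) -> CorrelationResult:
    """Correlate (P_e, %FA) pairs; needs n >= 3 finite points."""
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(pairs)}")
    pe = np.array([p[0] for p in pairs], dtype=float)
    fa = np.array([p[1] for p in pairs], dtype=float)
    if not (np.all(np.isfinite(pe)) and np.all(np.isfinite(fa))):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(pe) == 0 or np.ptp(fa) == 0:
        raise ValueError("zero variance in P_e or %FA: correlation undefined")
    r = float(stats.pearsonr(pe, fa).statistic)
    rho = float(stats.spearmanr(pe, fa).statistic)
    return CorrelationResult(
        lipid_label=lipid_label,
        n=len(pairs),
        pearson_r=r,
        pearson_r_squared=r * r,
        spearman_rho=rho,
        spearman_rho_squared=rho * rho,
    )


def exclusion_analysis(
    entries: Sequence[tuple[DrugInfo, float]],
    excluded_names: Sequence[str] = DEVIATING_DRUGS,
    lipid_label: str = "",
) -> tuple[CorrelationResult, CorrelationResult]:
    """Correlations for the full panel and for the panel minus named drugs.

    Returns ``(all_drugs, subset)`` computed with identical settings.
    Unknown excluded names raise a ValueError listing the known drugs.
    """
    known = [drug.name for drug, _ in entries]
    unknown = [n for n in excluded_names if n not in known]
    if unknown:
        raise ValueError(f"excluded drug(s) {unknown} not found; known drugs: {known}")
    full = correlate_pe_fa(
        [(pe, drug.fraction_absorbed_percent) for drug, pe in entries], lipid_label
    )
    subset_pairs = [
        (pe, drug.fraction_absorbed_percent)
        for drug, pe in entries
        if drug.name not in excluded_names
    ]
    subset = correlate_pe_fa(subset_pairs, lipid_label)
    return full, replace(subset, excluded_names=tuple(excluded_names))
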