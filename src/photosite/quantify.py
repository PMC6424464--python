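"""Labeling-efficiency and competition (protection) quantification.

Labeling efficiency is the XIC area of the photolabeled peptide expressed
as a percentage of the unlabeled peptide's XIC area, compared at the same
charge state.  Competition is the percent reduction of that efficiency
when labeling proceeds in the presence of excess unmodified ligand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import (
    AdductSpec,
    Peptide,
    ResidueMassTable,
    default_mass_table,
    mz_from_mass,
    peptide_mass,
)
from .io import Run, extract_xic, integrate_area
from .screen import SearchParams, detect_features

__all__ = [
    "EfficiencyResult",
    "CompetitionResult",
    "labeling_efficiency",
    "efficiency_from_run",
    "competition_reduction",
]


@dataclass
class EfficiencyResult:
    peptide_id: str
    site_interval: tuple[int, int] | None
    labeled_area: float
    unlabeled_area: float
    efficiency_pct: float
    charge: int | None = None
    condition: str = ""
    replicate: str | None = None
    not_detected: bool = False


@dataclass
class CompetitionResult:
    control_mean: float
    control_sd: float
    control_n: int
    competitor_mean: float
    competitor_sd: float
    competitor_n: int
    percent_reduction: float
    per_replicate_reduction: list[float]


def labeling_efficiency(labeled_area: float, unlabeled_area: float) -> float:
    """Labeled XIC area as a percentage of the unlabeled area."""
    if unlabeled_area <= 0:
        raise ValueError("unlabeled area must be > 0 (undefined denominator)")
    return 100.0 * labeled_area / unlabeled_area


def _feature_area(run: Run, mz: float, z: int, params: SearchParams) -> float:
    """Area of the largest feature at a theoretical m/z (0 if none)."""
    feats = detect_features(run, [(mz, z)], params)
    return max((f.area for f in feats), default=0.0)


def efficiency_from_run(
    run: Run,
    peptide: Peptide,
    adduct: AdductSpec,
    params: SearchParams | None = None,
    table: ResidueMassTable | None = None,
    site_interval: tuple[int, int] | None = None,
    condition: str = "",
    replicate: str | None = None,
) -> EfficiencyResult:
    """Measure labeling efficiency for one peptide x adduct in one run.

    Both XICs are extracted at every charge in the search range; the charge
    with the largest unlabeled feature area is used for the ratio.  An
    absent labeled feature gives 0% flagged ``not_detected``; an absent
    unlabeled feature is an error (no denominator reference).
    """
    params = params or SearchParams()
    table = table or default_mass_table()
    base_mass = peptide_mass(peptide, table)
    labeled_mass = base_mass + adduct.adduct_mass
    zlo, zhi = params.charge_range
    best_z, best_unlabeled = None, 0.0
    for z in range(zlo, zhi + 1):
        area = _feature_area(run, mz_from_mass(base_mass, z, table), z, params)
        if area > best_unlabeled:
            best_z, best_unlabeled = z, area
    if best_z is None:
        raise ValueError(
            f"unlabeled peptide {peptide.sequence!r} not detected at any charge "
            f"{zlo}..{zhi}; efficiency denominator unavailable"
        )
    labeled_area = _feature_area(
        run, mz_from_mass(labeled_mass, best_z, table), best_z, params
    )
    not_detected = labeled_area <= 0.0
    return EfficiencyResult(
        peptide_id=f"{peptide.protein_id}:{peptide.start}-{peptide.end}",
        site_interval=site_interval,
        labeled_area=labeled_area,
        unlabeled_area=best_unlabeled,
        efficiency_pct=labeling_efficiency(labeled_area, best_unlabeled),
        charge=best_z,
        condition=condition,
        replicate=replicate,
        not_detected=not_detected,
    )


def _arm_stats(arm: list[EfficiencyResult]) -> tuple[float, float, int]:
    vals = np.array([r.efficiency_pct for r in arm], dtype=float)
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, int(vals.size)


def competition_reduction(
    control: list[EfficiencyResult], competitor: list[EfficiencyResult]
) -> CompetitionResult:
    """Percent reduction of labeling by a competitor, from arm means.

    Per-replicate reductions (pairing replicates in list order up to the
    shorter arm) are also reported.
    """
    if not control:
        raise ValueError("control arm is empty")
    c_mean, c_sd, c_n = _arm_stats(control)
    if c_mean <= 0:
        raise ValueError("control arm mean efficiency must be > 0")
    k_mean, k_sd, k_n = _arm_stats(competitor) if competitor else (0.0, 0.0, 0)
    reduction = 100.0 * (c_mean - k_mean) / c_mean
    per_rep = [
        100.0 * (c.efficiency_pct - k.efficiency_pct) / c.efficiency_pct
        for c, k in zip(control, competitor)
        if c.efficiency_pct > 0
    ]
    return CompetitionResult(c_mean, c_sd, c_n, k_mean, k_sd, k_n, reduction, per_rep)
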