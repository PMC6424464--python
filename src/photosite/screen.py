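"""MS1-level screening for photolabeled peptide candidates.

Three criteria drive the screen, mirroring how labeled transmembrane
peptides behave chromatographically: (1) precursor mass match within a ppm
tolerance, (2) a retention delay of the labeled form relative to its
unlabeled counterpart (the covalent sterol adduct increases hydrophobicity,
so labeled peptides elute later), and (3) for click-tagged reagents, a
co-eluting heavy/light doublet at a fixed neutral-mass offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .chem import (
    AdductSpec,
    ModifiedPeptide,
    Peptide,
    ResidueMassTable,
    default_mass_table,
    mass_from_mz,
    mz_from_mass,
    peptide_mass,
    ppm_error,
)
from .io import Chromatogram, Feature, Run, extract_xic

__all__ = [
    "SearchParams",
    "CandidateHit",
    "DoubletPair",
    "detect_features",
    "screen_labeled",
    "find_doublets",
]


@dataclass(frozen=True)
class SearchParams:
    """Search tolerances for MS1 screening and MS2 fragment matching."""

    precursor_tol_ppm: float = 30.0
    fragment_tol_da: float = 0.1
    coelution_tol_min: float = 0.2
    min_retention_delay_min: float = 1.0
    charge_range: tuple[int, int] = (2, 6)
    pair_abs_floor_da: float = 0.01  # absolute floor on doublet mass-difference tolerance
    intensity_floor_factor: float = 5.0  # x median nonzero XIC intensity
    max_fragment_charge: int = 3

    def __post_init__(self) -> None:
        for name in ("precursor_tol_ppm", "fragment_tol_da", "coelution_tol_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.charge_range[0] < 1 or self.charge_range[1] < self.charge_range[0]:
            raise ValueError("invalid charge range")


@dataclass
class CandidateHit:
    """A peptide x adduct x charge candidate matched to an MS1 feature."""

    peptide: Peptide
    adduct: AdductSpec
    charge: int
    feature: Feature
    mass_error_ppm: float
    retention_delay_min: float | None = None
    no_reference: bool = False
    paired: bool = False


@dataclass
class DoubletPair:
    """Co-eluting heavy/light features of one click-tagged labeled peptide."""

    light: Feature
    heavy: Feature
    charge: int
    mass_difference: float  # neutral-mass difference, Da
    rt_offset: float  # heavy apex - light apex, min
    intensity_ratio: float | None = None  # light area / heavy area; recorded, not filtered


def _feature_from_window(
    xic: Chromatogram, run: Run, apex_idx: int, left: int, right: int, charge: int
) -> Feature:
    """Build a Feature from XIC indices, measuring the apex-scan observed m/z."""
    rt = xic.rt
    # observed m/z: intensity-weighted mean of peaks in the tolerance window
    # at the apex scan (falls back to the target when the scan is gone)
    lo = xic.target_mz * (1 - xic.tol_ppm * 1e-6)
    hi = xic.target_mz * (1 + xic.tol_ppm * 1e-6)
    observed = xic.target_mz
    apex_rt = rt[apex_idx]
    for scan_rt, peaks in run.ms1:
        if scan_rt == apex_rt:
            i, j = np.searchsorted(peaks.mz, [lo, hi])
            if j > i and peaks.intensity[i:j].sum() > 0:
                observed = float(
                    np.average(peaks.mz[i:j], weights=peaks.intensity[i:j])
                )
            break
    area = float(np.trapezoid(xic.intensity[left : right + 1], rt[left : right + 1]))
    return Feature(
        mz=observed,
        charge=charge,
        rt_apex=float(apex_rt),
        rt_start=float(rt[left]),
        rt_end=float(rt[right]),
        area=area,
        apex_intensity=float(xic.intensity[apex_idx]),
    )


def detect_features(
    run: Run,
    targets: list[tuple[float, int]],
    params: SearchParams | None = None,
    intensity_floor: float | None = None,
) -> list[Feature]:
    """Targeted feature detection: XIC local maxima above an intensity floor.

    The floor defaults to ``intensity_floor_factor`` x the median nonzero
    XIC intensity (scale-free).  Feature bounds sit at the nearest local
    minima around each apex; the area is the trapezoidal integral between
    the bounds.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    params = params or SearchParams()
    features: list[Feature] = []
    for target_mz, charge in targets:
        xic = extract_xic(run, target_mz, params.precursor_tol_ppm, charge=charge)
        y = xic.intensity
        if len(xic) == 0 or not np.any(y > 0):
            continue
        floor = intensity_floor
        if floor is None:
            floor = params.intensity_floor_factor * float(np.median(y[y > 0]))
        peaks, _ = find_peaks(y, height=min(floor, y.max()))
        if peaks.size == 0 and y.max() >= floor:
            peaks = np.array([int(np.argmax(y))])  # apex at a series edge
        for apex in peaks:
            left = apex
            while left > 0 and y[left - 1] < y[left]:
                left -= 1
            right = apex
            while right < y.size - 1 and y[right + 1] < y[right]:
                right += 1
            features.append(_feature_from_window(xic, run, int(apex), left, right, charge))
    return features


def screen_labeled(
    run: Run,
    digest_peptides: list[Peptide],
    adducts: list[AdductSpec],
    params: SearchParams | None = None,
    table: ResidueMassTable | None = None,
) -> list[CandidateHit]:
    """Screen a digest against a run for retention-delayed labeled peptides.

    Enumerates (peptide x adduct x charge) theoretical precursors, finds
    matching MS1 features, and keeps those eluting at least
    ``min_retention_delay_min`` after the unlabeled peptide's apex.  When no
    unlabeled reference feature exists the hit is kept but flagged
    ``no_reference``.
    """
    params = params or SearchParams()
    table = table or default_mass_table()
    zlo, zhi = params.charge_range
    hits: list[CandidateHit] = []
    for pep in digest_peptides:
        base_mass = peptide_mass(pep, table)
        unlabeled = detect_features(
            run, [(mz_from_mass(base_mass, z, table), z) for z in range(zlo, zhi + 1)], params
        )
        reference = max(unlabeled, key=lambda f: f.area, default=None)
        for adduct in adducts:
            labeled_mass = base_mass + adduct.adduct_mass
            for z in range(zlo, zhi + 1):
                theo = mz_from_mass(labeled_mass, z, table)
                for feat in detect_features(run, [(theo, z)], params):
                    err = ppm_error(feat.mz, theo)
                    if abs(err) > params.precursor_tol_ppm:
                        continue
                    if reference is None:
                        hits.append(
                            CandidateHit(pep, adduct, z, feat, err, None, no_reference=True)
                        )
                        continue
                    delay = feat.rt_apex - reference.rt_apex
                    if delay >= params.min_retention_delay_min:
                        hits.append(CandidateHit(pep, adduct, z, feat, err, delay))
    return hits


def find_doublets(
    features: list[Feature],
    pair_delta: float,
    params: SearchParams | None = None,
    table: ResidueMassTable | None = None,
) -> list[DoubletPair]:
    """Pair co-eluting equal-charge features separated by ``pair_delta`` Da.

    The neutral-mass difference must match ``pair_delta`` within the
    precursor ppm tolerance (with an absolute floor) and the apexes must
    co-elute within the co-elution tolerance.  Each feature joins at most
    one pair; candidate pairs are accepted greedily by smallest combined
    normalized mass + rt error, ties broken by ascending light m/z.
    """
    if pair_delta <= 0:
        raise ValueError("pair_delta must be > 0")
    params = params or SearchParams()
    table = table or default_mass_table()
    order = sorted(range(len(features)), key=lambda i: (features[i].mz, features[i].rt_apex))
    candidates = []
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1 :]:
            light, heavy = features[i], features[j]
            if light.charge != heavy.charge:
                continue
            dm = mass_from_mz(heavy.mz, heavy.charge, table) - mass_from_mz(
                light.mz, light.charge, table
            )
            mass_tol = max(
                params.pair_abs_floor_da,
                params.precursor_tol_ppm * 1e-6 * mass_from_mz(light.mz, light.charge, table),
            )
            mass_err = abs(dm - pair_delta)
            rt_err = abs(heavy.rt_apex - light.rt_apex)
            if mass_err > mass_tol or rt_err > params.coelution_tol_min:
                continue
            score = mass_err / mass_tol + rt_err / max(params.coelution_tol_min, 1e-12)
            candidates.append((score, light.mz, heavy.mz, i, j, dm, rt_err))
    candidates.sort()
    used: set[int] = set()
    pairs: list[DoubletPair] = []
    for _score, _lmz, _hmz, i, j, dm, _rt in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        light, heavy = features[i], features[j]
        ratio = light.area / heavy.area if heavy.area > 0 else None
        pairs.append(
            DoubletPair(
                light=light,
                heavy=heavy,
                charge=light.charge,
                mass_difference=dm,
                rt_offset=heavy.rt_apex - light.rt_apex,
                intensity_ratio=ratio,
            )
        )
    pairs.sort(key=lambda p: (p.light.mz, p.light.rt_apex))
    return pairs
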