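"""Residue-level localization of a photoreagent adduct from MS2 spectra.

The adduct site is inferred from b/y fragment-ion ladders.  A fragment that
retains the adduct places the labeled residue inside that fragment's span;
a fragment observed at its unmodified mass excludes its span — unless the
same fragment is also seen with the adduct, in which case the unmodified
peak is the adduct's neutral loss, which supports peptide identity but says
nothing about the site.  The bracketing "site-defining" pair (adjacent
ladder ions whose adduct status flips) pins the site to a single residue;
incomplete ladders yield a minimal residue interval instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import (
    AdductSpec,
    ModificationSpec,
    ModifiedPeptide,
    Peptide,
    ResidueMassTable,
    default_mass_table,
)
from .io import MS2Spectrum
from .screen import SearchParams

__all__ = [
    "FragmentIon",
    "MatchedIon",
    "LocalizationResult",
    "OverlayResult",
    "theoretical_ladder",
    "match_fragments",
    "localize",
    "overlay_verify",
]


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical b or y ion, optionally adduct-bearing or its neutral loss."""

    series: str  # "b" | "y"
    index: int  # 1 .. L-1
    charge: int
    carries_adduct: bool
    neutral_loss: bool
    mz: float

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError(f"unknown ion series {self.series!r}")
        if self.neutral_loss and self.carries_adduct:
            raise ValueError("a neutral-loss ion is observed without its adduct")

    def span(self, peptide_length: int) -> tuple[int, int]:
        """1-based inclusive residue span covered by this fragment."""
        if self.series == "b":
            return (1, self.index)
        return (peptide_length - self.index + 1, peptide_length)


@dataclass(frozen=True)
class MatchedIon:
    ion: FragmentIon
    observed_mz: float
    error_da: float
    peak_index: int


@dataclass
class LocalizationResult:
    """Minimal residue interval consistent with the site-defining ions."""

    peptide: Peptide
    adduct: AdductSpec
    interval: tuple[int, int]  # protein coordinates, inclusive; a == b for a unique site
    interval_local: tuple[int, int]  # within-peptide coordinates
    matched_ions: list[MatchedIon]
    n_adduct_bearing: int
    n_adduct_free: int
    n_neutral_loss: int
    placement_score: np.ndarray  # score per candidate residue, length L
    site_defining_pairs: list[tuple[MatchedIon, MatchedIon]] = field(default_factory=list)
    precursor_warning: str | None = None

    @property
    def is_unique(self) -> bool:
        return self.interval[0] == self.interval[1]


@dataclass
class OverlayResult:
    """Heavy/light fragment-overlay verification of an adduct assignment."""

    pairs: list[tuple[FragmentIon, float, float, float]]  # ion, light m/z, heavy m/z, diff
    verdict: str  # "verified" | "inconsistent"
    expected_shift: float  # pair_delta (per unit charge applies as delta/z)


def _positioned_mods(p: ModifiedPeptide) -> list[tuple[int, float]]:
    """(position, delta) for non-adduct modifications."""
    return [
        (pos, mod.delta_mass)
        for pos, mod in p.modifications
        if not isinstance(mod, AdductSpec)
    ]


def theoretical_ladder(
    p: ModifiedPeptide | Peptide | str,
    placement: int,
    charges: tuple[int, ...] = (1,),
    include_neutral_loss: bool = False,
    adduct: AdductSpec | None = None,
    table: ResidueMassTable | None = None,
) -> list[FragmentIon]:
    """b/y ladder for the adduct placed at ``placement`` (1-based).

    ``adduct`` defaults to the one carried by ``p``; pass ``adduct=None``
    with an unmodified peptide for a plain ladder.  Fixed modifications on
    ``p`` are included whenever their residue falls inside the fragment
    span.  With ``include_neutral_loss``, every adduct-bearing ion is also
    emitted at its adduct-stripped mass.
    """
    table = table or default_mass_table()
    if isinstance(p, str):
        p = ModifiedPeptide(Peptide(p))
    elif isinstance(p, Peptide):
        p = ModifiedPeptide(p)
    if adduct is None and p.adduct_placement is not None:
        adduct = p.adduct_placement[1]
    L = len(p.peptide)
    if not 1 <= placement <= L:
        raise ValueError(f"placement {placement} outside peptide 1..{L}")
    residue_masses = [table.mass(r, i + 1) for i, r in enumerate(p.sequence)]
    mods = _positioned_mods(p)
    ions: list[FragmentIon] = []
    for series in ("b", "y"):
        for index in range(1, L):
            if series == "b":
                span = (1, index)
                frag = sum(residue_masses[:index])
            else:
                span = (L - index + 1, L)
                frag = sum(residue_masses[L - index :]) + table.water
            frag += sum(d for pos, d in mods if span[0] <= pos <= span[1])
            carries = adduct is not None and span[0] <= placement <= span[1]
            for z in charges:
                base_mz = (frag + z * table.proton) / z
                if carries:
                    ions.append(
                        FragmentIon(series, index, z, True, False,
                                    base_mz + adduct.adduct_mass / z)
                    )
                    if include_neutral_loss:
                        ions.append(FragmentIon(series, index, z, False, True, base_mz))
                else:
                    ions.append(FragmentIon(series, index, z, False, False, base_mz))
    return ions


def match_fragments(
    spec: MS2Spectrum, ions: list[FragmentIon], tol_da: float
) -> list[MatchedIon]:
    """Match each theoretical ion to the nearest peak within ``tol_da``.

    One peak may satisfy several isobaric ions; matches are recorded per
    ion, and downstream scoring counts distinct peaks so they are never
    double-counted.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be > 0")
    mz = spec.peaks.mz
    if mz.size == 0:
        return []
    out: list[MatchedIon] = []
    for ion in ions:
        idx = int(np.searchsorted(mz, ion.mz))
        best, best_err = -1, tol_da
        for j in (idx - 1, idx):
            if 0 <= j < mz.size and abs(mz[j] - ion.mz) <= best_err:
                best, best_err = j, abs(mz[j] - ion.mz)
        if best >= 0:
            out.append(MatchedIon(ion, float(mz[best]), float(mz[best] - ion.mz), best))
    return out


def _fragment_charges(precursor_charge: int, params: SearchParams) -> tuple[int, ...]:
    top = min(max(precursor_charge - 1, 1), params.max_fragment_charge)
    return tuple(range(1, top + 1))


def localize(
    spec: MS2Spectrum,
    p: ModifiedPeptide | Peptide | str,
    adduct: AdductSpec,
    params: SearchParams | None = None,
    table: ResidueMassTable | None = None,
) -> LocalizationResult:
    """Locate the adduct on ``p`` from one MS2 spectrum.

    Every candidate placement 1..L is scored by the number of distinct
    peaks matching ions consistent with it: an adduct-bearing match is
    consistent when the placement falls in its span; an unmodified-mass
    match whose adduct-bearing counterpart is absent is adduct-free and
    consistent when the placement falls outside its span; an
    unmodified-mass match whose counterpart is present is the adduct's
    neutral loss and never constrains.  If no adduct-bearing ion matches at
    all, the spectrum carries no positional evidence and the whole peptide
    is returned.  The result is the minimal interval covering all
    placements of maximal score (ties widen the interval; a site is never
    forced).
    """
    params = params or SearchParams()
    table = table or default_mass_table()
    if isinstance(p, str):
        p = ModifiedPeptide(Peptide(p))
    elif isinstance(p, Peptide):
        p = ModifiedPeptide(p)
    L = len(p.peptide)
    if L < 2:
        raise ValueError("peptide must have at least 2 residues to localize")

    charges = _fragment_charges(spec.precursor_charge, params)
    # placement-independent candidate forms: plain and adduct-bearing m/z per ion
    plain = theoretical_ladder(p, 1, charges, include_neutral_loss=False,
                               adduct=None, table=table)
    matched_plain = {
        (m.ion.series, m.ion.index, m.ion.charge): m
        for m in match_fragments(spec, plain, params.fragment_tol_da)
    }
    shifted = [
        FragmentIon(i.series, i.index, i.charge, True, False,
                    i.mz + adduct.adduct_mass / i.charge)
        for i in plain
    ]
    matched_adduct = {
        (m.ion.series, m.ion.index, m.ion.charge): m
        for m in match_fragments(spec, shifted, params.fragment_tol_da)
    }

    # competitive peak assignment: a peak supports only the ion form(s) that
    # explain it with the smallest mass error, so an ion coincidentally
    # isobaric with another fragment's peak does not manufacture evidence
    best_err: dict[int, float] = {}
    for m in list(matched_plain.values()) + list(matched_adduct.values()):
        err = abs(m.error_da)
        if m.peak_index not in best_err or err < best_err[m.peak_index]:
            best_err[m.peak_index] = err
    keep = lambda m: abs(m.error_da) <= best_err[m.peak_index] + 1e-9  # noqa: E731
    matched_plain = {k: m for k, m in matched_plain.items() if keep(m)}
    matched_adduct = {k: m for k, m in matched_adduct.items() if keep(m)}

    # precursor consistency check (warning only)
    from .chem import mz_from_mass, peptide_mass, ppm_error

    theo_prec = mz_from_mass(
        peptide_mass(p, table) + adduct.adduct_mass, spec.precursor_charge, table
    )
    warn = None
    prec_err = ppm_error(spec.precursor_mz, theo_prec)
    if abs(prec_err) > params.precursor_tol_ppm:
        warn = (
            f"precursor m/z {spec.precursor_mz:.4f} deviates {prec_err:.1f} ppm "
            f"from peptide+adduct ({theo_prec:.4f})"
        )

    adduct_bearing: list[MatchedIon] = []
    adduct_free: list[MatchedIon] = []
    neutral_loss: list[MatchedIon] = []
    for key, m in matched_adduct.items():
        adduct_bearing.append(m)
    for key, m in matched_plain.items():
        if key in matched_adduct:
            ion = m.ion
            neutral_loss.append(
                MatchedIon(
                    FragmentIon(ion.series, ion.index, ion.charge, False, True, ion.mz),
                    m.observed_mz, m.error_da, m.peak_index,
                )
            )
        else:
            adduct_free.append(m)

    matched_ions = adduct_bearing + adduct_free + neutral_loss

    scores = np.zeros(L)
    if not adduct_bearing:
        # no adduct-retaining fragment: positional evidence is absent
        interval_local = (1, L)
    else:
        for s in range(1, L + 1):
            peaks_seen: set[int] = set()
            for m in adduct_bearing:
                a, b = m.ion.span(L)
                if a <= s <= b:
                    peaks_seen.add(m.peak_index)
            for m in adduct_free:
                a, b = m.ion.span(L)
                if not a <= s <= b:
                    peaks_seen.add(m.peak_index)
            scores[s - 1] = len(peaks_seen)
        best = np.flatnonzero(scores == scores.max()) + 1
        interval_local = (int(best.min()), int(best.max()))

    # bracketing site-defining pairs: adjacent same-series ions whose adduct
    # status flips between index i and i+1
    by_key_status: dict[tuple[str, int], dict[bool, MatchedIon]] = {}
    for m in adduct_bearing:
        by_key_status.setdefault((m.ion.series, m.ion.index), {})[True] = m
    for m in adduct_free:
        by_key_status.setdefault((m.ion.series, m.ion.index), {})[False] = m
    pairs: list[tuple[MatchedIon, MatchedIon]] = []
    for (series, index), status in sorted(by_key_status.items()):
        nxt = by_key_status.get((series, index + 1), {})
        if False in status and True in nxt:
            pairs.append((status[False], nxt[True]))

    interval = (
        p.peptide.to_protein(interval_local[0]),
        p.peptide.to_protein(interval_local[1]),
    )
    return LocalizationResult(
        peptide=p.peptide,
        adduct=adduct,
        interval=interval,
        interval_local=interval_local,
        matched_ions=matched_ions,
        n_adduct_bearing=len(adduct_bearing),
        n_adduct_free=len(adduct_free),
        n_neutral_loss=len(neutral_loss),
        placement_score=scores,
        site_defining_pairs=pairs,
        precursor_warning=warn,
    )


def overlay_verify(
    light: MS2Spectrum,
    heavy: MS2Spectrum,
    p: ModifiedPeptide,
    adduct: AdductSpec,
    params: SearchParams | None = None,
    table: ResidueMassTable | None = None,
) -> OverlayResult:
    """Verify an assignment by overlaying light- and heavy-tag spectra.

    ``p`` must carry the adduct placement; ``adduct`` is the light form and
    must define ``pair_delta``.  Verified requires every common
    adduct-bearing fragment to shift by pair_delta/charge within the
    fragment tolerance and every common adduct-free fragment to stay put.
    """
    params = params or SearchParams()
    table = table or default_mass_table()
    if adduct.pair_delta is None:
        raise ValueError("adduct has no heavy/light pair_delta")
    if p.adduct_placement is None:
        raise ValueError("peptide must carry a placed adduct")
    placement = p.adduct_placement[0]
    charges = _fragment_charges(light.precursor_charge, params)
    ladder = theoretical_ladder(p, placement, charges, include_neutral_loss=False,
                                adduct=adduct, table=table)
    light_matches = match_fragments(light, ladder, params.fragment_tol_da)

    def nearest(mz_target: float) -> float | None:
        hits = match_fragments(
            heavy,
            [FragmentIon("b", 1, 1, False, False, mz_target)],
            params.fragment_tol_da,
        )
        return hits[0].observed_mz if hits else None

    pairs = []
    ok = True
    for lm in light_matches:
        expected = adduct.pair_delta / lm.ion.charge if lm.ion.carries_adduct else 0.0
        # look for the counterpart at its expected position; failing that,
        # at the "wrong" (unshifted vs shifted) position, which falsifies
        heavy_obs = nearest(lm.observed_mz + expected)
        if heavy_obs is None:
            wrong = adduct.pair_delta / lm.ion.charge - expected  # the other offset
            heavy_obs = nearest(lm.observed_mz + wrong)
            if heavy_obs is None:
                continue  # fragment absent from the heavy spectrum
        diff = heavy_obs - lm.observed_mz
        if abs(diff - expected) > params.fragment_tol_da:
            ok = False
        pairs.append((lm.ion, lm.observed_mz, heavy_obs, diff))
    if not pairs:
        return OverlayResult([], "inconsistent", adduct.pair_delta)
    return OverlayResult(pairs, "verified" if ok else "inconsistent", adduct.pair_delta)
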