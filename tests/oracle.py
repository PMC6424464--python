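"""Brute-force localization oracle, independent of the package internals.

Enumerates every candidate adduct placement explicitly, computes fragment
masses by direct summation over the printed 5-decimal residue constants,
matches peaks by linear scan with competitive assignment (a peak supports
only the ion forms explaining it with minimal mass error), and applies the
classification rules — adduct-retaining constrains, adduct-free excludes,
neutral loss (a plain-mass match shadowed by its adduct-bearing
counterpart) never constrains, and a spectrum with no adduct-retaining
match carries no positional evidence — with plain set arithmetic.
"""

from pyteomics.mass import std_aa_mass

AA = {a: round(m, 5) for a, m in std_aa_mass.items() if len(a) == 1}
WATER = 18.01056
PROTON = 1.00728


def _fragment_mass(seq: str, series: str, index: int) -> float:
    if series == "b":
        return sum(AA[a] for a in seq[:index])
    return sum(AA[a] for a in seq[len(seq) - index:]) + WATER


def _nearest_peak(peaks, target, tol):
    """(index, error) of the nearest peak within tol, else None (linear scan)."""
    best, best_d = None, tol
    for i, mz in enumerate(peaks):
        d = abs(mz - target)
        if d <= best_d:
            best, best_d = i, d
    return None if best is None else (best, best_d)


def oracle_localize(peaks, sequence, adduct_mass, precursor_charge, tol=0.1,
                    max_fragment_charge=3):
    """Return (interval, scores list) for an unmodified peptide + one adduct."""
    L = len(sequence)
    charges = range(1, min(max(precursor_charge - 1, 1), max_fragment_charge) + 1)
    keys = [
        (series, index, z)
        for series in ("b", "y")
        for index in range(1, L)
        for z in charges
    ]
    spans = {
        (series, index): (1, index) if series == "b" else (L - index + 1, L)
        for series in ("b", "y")
        for index in range(1, L)
    }
    plain_hit, adduct_hit = {}, {}
    for series, index, z in keys:
        frag = _fragment_mass(sequence, series, index)
        plain_mz = (frag + z * PROTON) / z
        adduct_mz = plain_mz + adduct_mass / z
        p = _nearest_peak(peaks, plain_mz, tol)
        a = _nearest_peak(peaks, adduct_mz, tol)
        if p is not None:
            plain_hit[(series, index, z)] = p
        if a is not None:
            adduct_hit[(series, index, z)] = a

    # competitive assignment: keep only minimal-error explanations per peak
    best = {}
    for peak, err in list(plain_hit.values()) + list(adduct_hit.values()):
        if peak not in best or err < best[peak]:
            best[peak] = err
    plain_hit = {k: (p, e) for k, (p, e) in plain_hit.items() if e <= best[p] + 1e-9}
    adduct_hit = {k: (p, e) for k, (p, e) in adduct_hit.items() if e <= best[p] + 1e-9}

    if not adduct_hit:
        return (1, L), [0.0] * L

    free_hit = {k: v for k, v in plain_hit.items() if k not in adduct_hit}
    scores = []
    for s in range(1, L + 1):
        consistent_peaks = set()
        for (series, index, _z), (peak, _e) in adduct_hit.items():
            a, b = spans[(series, index)]
            if a <= s <= b:
                consistent_peaks.add(peak)
        for (series, index, _z), (peak, _e) in free_hit.items():
            a, b = spans[(series, index)]
            if not (a <= s <= b):
                consistent_peaks.add(peak)
        scores.append(float(len(consistent_peaks)))
    top = max(scores)
    winners = [s for s, score in enumerate(scores, start=1) if score == top]
    return (min(winners), max(winners)), scores
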