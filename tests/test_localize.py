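"""Fragment ladders, matching, adduct-site localization and heavy/light overlay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import photosite as ps
from photosite.io import PeakList
from photosite.localize import FragmentIon

from oracle import oracle_localize

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def _spectrum(mzs, precursor_mz=1000.0, charge=2, intensity=100.0):
    pl = PeakList.from_pairs([(m, intensity) for m in mzs])
    return ps.MS2Spectrum(precursor_mz, charge, 10.0, pl)


def _ion_mz(ladder, series, index, charge, carries):
    for ion in ladder:
        if (ion.series, ion.index, ion.charge, ion.carries_adduct) == (
            series, index, charge, carries
        ) and not ion.neutral_loss:
            return ion.mz
    raise KeyError((series, index, charge, carries))


class TestTheoreticalLadder:
    def test_plain_b2_y1(self, table):
        ladder = ps.theoretical_ladder("AGK", 1, charges=(1,), table=table)
        assert _ion_mz(ladder, "b", 2, 1, False) == pytest.approx(129.066, abs=1e-3)
        assert _ion_mz(ladder, "y", 1, 1, False) == pytest.approx(147.113, abs=1e-3)

    def test_adduct_span_membership(self, table):
        adduct = ps.AdductSpec("x", 100.0)
        ladder = ps.theoretical_ladder("AGK", 3, charges=(1,), adduct=adduct,
                                       include_neutral_loss=True, table=table)
        assert _ion_mz(ladder, "y", 1, 1, True) == pytest.approx(247.113, abs=1e-3)
        assert _ion_mz(ladder, "b", 2, 1, False) == pytest.approx(129.066, abs=1e-3)
        nl = [i for i in ladder if i.neutral_loss and i.series == "y" and i.index == 1]
        assert len(nl) == 1 and nl[0].mz == pytest.approx(147.113, abs=1e-3)

    def test_fixed_mod_included_in_span(self, table):
        mod = ps.ModificationSpec("NEM(C)", 125.04768, frozenset("C"))
        p = ps.ModifiedPeptide(ps.Peptide("ACK"), ((2, mod),))
        ladder = ps.theoretical_ladder(p, 1, charges=(1,), table=table)
        plain = ps.theoretical_ladder("ACK", 1, charges=(1,), table=table)
        assert _ion_mz(ladder, "b", 2, 1, False) - _ion_mz(plain, "b", 2, 1, False) == (
            pytest.approx(125.04768, abs=1e-9)
        )
        assert _ion_mz(ladder, "b", 1, 1, False) == _ion_mz(plain, "b", 1, 1, False)

    def test_invalid_placement_rejected(self):
        with pytest.raises(ValueError):
            ps.theoretical_ladder("AGK", 4)


class TestMatchFragments:
    def test_exact_peaks_all_match(self, table):
        ladder = ps.theoretical_ladder("PEPTIDEK", 1, charges=(1,), table=table)
        spec = _spectrum([i.mz for i in ladder])
        matches = ps.match_fragments(spec, ladder, 0.1)
        assert len(matches) == len(ladder)
        assert all(m.error_da == pytest.approx(0.0, abs=1e-9) for m in matches)

    def test_displaced_peak_unmatched(self):
        ion = FragmentIon("b", 1, 1, False, False, 400.0)
        spec = _spectrum([400.2])
        assert ps.match_fragments(spec, [ion], 0.1) == []

    def test_partial_ladder_matched_fraction(self, table, beta3_tm4, adducts):
        sp = ps.SpeciesConfig(beta3_tm4, adducts["KK123"], true_site=17,
                              efficiency_pct=1.0, charges=(3,))
        cfg = ps.SyntheticRunConfig([sp], seed=21, ladder_completeness=0.8,
                                    noise_peaks=0, neutral_loss_fraction=0.0)
        run, truth = ps.generate_run(cfg)
        ladder = ps.theoretical_ladder(beta3_tm4, 17, charges=(1, 2),
                                       adduct=adducts["KK123"], table=table)
        matched = ps.match_fragments(run.ms2[0], ladder, 0.1)
        frac = len(matched) / len(ladder)
        assert 0.6 <= frac <= 0.95  # binomial tolerance around 0.8


class TestLocalize:
    def _ladder_peaks(self, seq, placement, adduct, table, charges=(1,)):
        return [
            i.mz
            for i in ps.theoretical_ladder(seq, placement, charges=charges,
                                           adduct=adduct, table=table)
        ]

    def test_full_ladder_unique_site(self, table):
        adduct = ps.AdductSpec("x", 300.0)
        spec = _spectrum(self._ladder_peaks("ACDEFGK", 3, adduct, table))
        r = ps.localize(spec, "ACDEFGK", adduct)
        assert r.interval_local == (3, 3) and r.is_unique

    def test_neutral_loss_only_no_evidence(self, table):
        adduct = ps.AdductSpec("x", 300.0)
        ladder = ps.theoretical_ladder("ACDEFGK", 3, charges=(1,), adduct=adduct,
                                       include_neutral_loss=True, table=table)
        nl_only = [i.mz for i in ladder if i.neutral_loss]
        r = ps.localize(_spectrum(nl_only), "ACDEFGK", adduct)
        assert r.interval_local == (1, 7)
        assert r.n_adduct_bearing == 0

    def test_one_sided_evidence_interval(self, table):
        adduct = ps.AdductSpec("x", 300.0)
        ladder = ps.theoretical_ladder("ACDEFGK", 3, charges=(1,), adduct=adduct,
                                       table=table)
        peaks = [
            _ion_mz(ladder, "b", 2, 1, False),  # adduct-free, excludes 1-2
            _ion_mz(ladder, "y", 5, 1, True),  # adduct-bearing, constrains 3-7
        ]
        r = ps.localize(_spectrum(peaks), "ACDEFGK", adduct)
        assert r.interval_local == (3, 7)

    def test_site_defining_pair_reported(self, table):
        adduct = ps.AdductSpec("x", 300.0)
        spec = _spectrum(self._ladder_peaks("ACDEFGK", 3, adduct, table))
        r = ps.localize(spec, "ACDEFGK", adduct)
        assert any(
            (a.ion.series, a.ion.index, b.ion.index) == ("b", 2, 3)
            for a, b in r.site_defining_pairs
        )

    def test_protein_coordinates(self, table, alpha1_tm4, adducts):
        spec = _spectrum(
            self._ladder_peaks(alpha1_tm4.sequence, 18, adducts["KK123"], table),
            precursor_mz=875.475, charge=4,
        )
        r = ps.localize(spec, alpha1_tm4, adducts["KK123"])
        assert r.interval == (415, 415)  # Y415 in protein numbering

    def test_noise_peaks_matching_nothing_are_inert(self, table):
        adduct = ps.AdductSpec("x", 300.0)
        peaks = self._ladder_peaks("ACDEFGK", 3, adduct, table)
        r0 = ps.localize(_spectrum(peaks), "ACDEFGK", adduct)
        noisy = peaks + [1500.123, 1600.456, 1700.789]
        r1 = ps.localize(_spectrum(noisy), "ACDEFGK", adduct)
        assert r1.interval_local == r0.interval_local
        assert np.array_equal(r1.placement_score, r0.placement_score)

    def test_adding_adduct_ion_never_widens(self, table):
        adduct = ps.AdductSpec("x", 300.0)
        ladder = ps.theoretical_ladder("ACDEFGK", 3, charges=(1,), adduct=adduct,
                                       table=table)
        peaks = [_ion_mz(ladder, "y", 5, 1, True)]
        r0 = ps.localize(_spectrum(peaks), "ACDEFGK", adduct)
        peaks.append(_ion_mz(ladder, "b", 4, 1, True))  # constrains 3..4
        r1 = ps.localize(_spectrum(peaks), "ACDEFGK", adduct)
        w0 = r0.interval_local[1] - r0.interval_local[0]
        w1 = r1.interval_local[1] - r1.interval_local[0]
        assert w1 <= w0

    def test_short_peptide_rejected(self, table):
        with pytest.raises(ValueError):
            ps.localize(_spectrum([100.0]), "A", ps.AdductSpec("x", 300.0))

    def test_precursor_mismatch_warns_not_rejects(self, table):
        adduct = ps.AdductSpec("x", 300.0)
        spec = _spectrum(self._ladder_peaks("ACDEFGK", 3, adduct, table),
                         precursor_mz=555.0, charge=2)
        r = ps.localize(spec, "ACDEFGK", adduct)
        assert r.precursor_warning is not None

    @settings(max_examples=40)
    @given(
        seq=st.text(alphabet=RESIDUES, min_size=4, max_size=12),
        site_frac=st.floats(0, 1),
    )
    def test_complete_ladder_always_unique(self, seq, site_frac):
        """With every ladder ion present the site interval collapses to one residue."""
        table = ps.default_mass_table()
        site = 1 + int(site_frac * (len(seq) - 1))
        adduct = ps.AdductSpec("x", 287.5)
        peaks = sorted(
            i.mz
            for i in ps.theoretical_ladder(seq, site, charges=(1,), adduct=adduct,
                                           table=table)
        )
        r = ps.localize(_spectrum(peaks, charge=2), seq, adduct)
        assert r.interval_local == (site, site)

    def test_agrees_with_bruteforce_oracle_sample(self):
        """Spot-check oracle equivalence (full sweep in the acceptance suite)."""
        rng = np.random.default_rng(42)
        table = ps.default_mass_table()
        adduct = ps.AdductSpec("x", 287.5)
        for _ in range(60):
            L = int(rng.integers(4, 13))
            seq = "".join(rng.choice(list(RESIDUES), L))
            site = int(rng.integers(1, L + 1))
            z = int(rng.integers(2, 5))
            ladder = ps.theoretical_ladder(seq, site, charges=(1, 2), adduct=adduct,
                                           include_neutral_loss=True, table=table)
            keep = [i.mz for i in ladder if rng.random() < 0.7]
            keep += list(rng.uniform(100, 2000, rng.integers(0, 6)))
            spec = _spectrum(sorted(keep), charge=z)
            r = ps.localize(spec, seq, adduct)
            expected, scores = oracle_localize(
                list(spec.peaks.mz), seq, adduct.adduct_mass, z
            )
            assert r.interval_local == expected
            assert list(r.placement_score) == scores


class TestOverlay:
    @pytest.fixture()
    def paired_spectra(self, beta3_tm4, adducts):
        light = adducts["KK123-FLI-light"]
        sp = ps.SpeciesConfig(beta3_tm4, light, true_site=17, efficiency_pct=2.0,
                              charges=(3,), paired=True)
        run, _ = ps.generate_run(
            ps.SyntheticRunConfig([sp], seed=9, noise_peaks=5)
        )
        mp = ps.ModifiedPeptide(beta3_tm4, ((17, light),))
        return run.ms2[0], run.ms2[1], mp, light

    def test_generator_pair_verified(self, paired_spectra):
        light_spec, heavy_spec, mp, adduct = paired_spectra
        result = ps.overlay_verify(light_spec, heavy_spec, mp, adduct)
        assert result.verdict == "verified"
        assert result.pairs

    def test_identical_spectra_inconsistent(self, paired_spectra):
        light_spec, _heavy, mp, adduct = paired_spectra
        assert ps.overlay_verify(light_spec, light_spec, mp, adduct).verdict == (
            "inconsistent"
        )

    def test_shift_on_adduct_free_ions_inconsistent(self, paired_spectra, table):
        light_spec, _heavy, mp, adduct = paired_spectra
        shifted_all = ps.MS2Spectrum(
            light_spec.precursor_mz, light_spec.precursor_charge, light_spec.rt,
            PeakList(light_spec.peaks.mz + adduct.pair_delta,
                     light_spec.peaks.intensity),
        )
        assert ps.overlay_verify(light_spec, shifted_all, mp, adduct).verdict == (
            "inconsistent"
        )

    def test_disjoint_spectra_inconsistent(self, paired_spectra):
        light_spec, _heavy, mp, adduct = paired_spectra
        empty = ps.MS2Spectrum(light_spec.precursor_mz, light_spec.precursor_charge,
                               light_spec.rt, PeakList(np.array([55.0]),
                                                       np.array([1.0])))
        result = ps.overlay_verify(light_spec, empty, mp, adduct)
        assert result.verdict == "inconsistent" and result.pairs == []
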