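"""Mass bookkeeping, charge arithmetic and tryptic digestion."""

import pytest
from hypothesis import given, strategies as st

import photosite as ps
from photosite.chem import load_chemistry_config

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class TestPeptideMass:
    def test_tm4_peptide_mass(self, table):
        assert ps.peptide_mass("IAFPLLFGIFNLVYWATYLNREPQLK", table) == pytest.approx(
            3125.711, abs=0.01
        )

    def test_single_glycine(self, table):
        assert ps.peptide_mass("G", table) == pytest.approx(57.02146 + 18.01056, abs=1e-4)

    def test_adduct_addition(self, table, adducts, beta3_tm4):
        light = adducts["KK123-FLI-light"]
        modified = ps.ModifiedPeptide(beta3_tm4, ((17, light),))
        assert ps.peptide_mass(modified, table) == pytest.approx(
            2544.313 + 672.4322, abs=0.01
        )

    def test_unknown_residue_reports_position(self, table):
        with pytest.raises(KeyError, match="position 3"):
            ps.peptide_mass("AAZAA", table)

    def test_mod_position_out_of_range(self, adducts):
        with pytest.raises(ValueError, match="position"):
            ps.ModifiedPeptide(ps.Peptide("AGK"), ((4, adducts["KK123"]),))

    def test_at_most_one_adduct(self, adducts):
        with pytest.raises(ValueError, match="one photoreagent adduct"):
            ps.ModifiedPeptide(
                ps.Peptide("AGKL"), ((1, adducts["KK123"]), (2, adducts["KK200"]))
            )

    @given(
        seq=st.text(alphabet=RESIDUES, min_size=1, max_size=30),
        pos_frac=st.floats(0, 1),
        delta=st.floats(1.0, 1000.0),
    )
    def test_mass_additivity(self, seq, pos_frac, delta):
        """Modifying a peptide adds exactly the delta mass."""
        table = ps.default_mass_table()
        pos = 1 + int(pos_frac * (len(seq) - 1))
        mod = ps.ModificationSpec("x", delta)
        base = ps.peptide_mass(seq, table)
        modified = ps.peptide_mass(
            ps.ModifiedPeptide(ps.Peptide(seq), ((pos, mod),)), table
        )
        assert modified - base == pytest.approx(delta, abs=1e-9)

    def test_cross_check_against_pyteomics(self, table):
        """Independent route: full-precision residue masses agree to ~1e-4/residue."""
        from pyteomics import mass as pmass

        for seq in ("IAFPLLFGIFNLVYWATYLNREPQLK", "AGK", "WWWW", "PEPTIDE"):
            assert ps.peptide_mass(seq, table) == pytest.approx(
                pmass.calculate_mass(sequence=seq), abs=2e-4 * len(seq)
            )


class TestChargeArithmetic:
    def test_simple_mz(self, table):
        assert ps.mz_from_mass(1000.0, 2, table) == pytest.approx(501.00728, abs=1e-6)

    def test_printed_precursor(self, table):
        mass = ps.peptide_mass("IAFPLLFGIFNLVYWATYLNREPQLK", table) + 462.27
        assert ps.mz_from_mass(mass, 4, table) == pytest.approx(898.002, abs=0.01)

    def test_mass_from_printed_mz(self, table):
        assert ps.mass_from_mz(875.503, 4, table) == pytest.approx(3497.98, abs=0.01)

    def test_bare_proton(self, table):
        assert ps.mass_from_mz(1.00728, 1, table) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("z", range(1, 9))
    def test_round_trip(self, table, z):
        m = 2544.3133
        assert ps.mass_from_mz(ps.mz_from_mass(m, z, table), z, table) == pytest.approx(
            m, abs=1e-9
        )

    @pytest.mark.parametrize("z", [0, -1])
    def test_invalid_charge_rejected(self, table, z):
        with pytest.raises(ValueError):
            ps.mz_from_mass(1000.0, z, table)
        with pytest.raises(ValueError):
            ps.mass_from_mz(500.0, z, table)


class TestPpmError:
    def test_thirty_ppm(self):
        assert ps.ppm_error(500.015, 500.0) == pytest.approx(30.0)

    def test_identity_and_inversion(self):
        assert ps.ppm_error(898.002, 898.002) == 0.0
        theo = 898.002 * (1 - 30e-6)
        assert ps.ppm_error(898.002, theo) == pytest.approx(30.0, abs=1e-3)

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            ps.ppm_error(500.0, 0.0)


class TestDigest:
    def test_proline_exception(self):
        peps = ps.digest("AAKRPCCK", ps.DigestParams(max_missed_cleavages=0))
        assert [(p.sequence, p.start, p.end) for p in peps] == [
            ("AAK", 1, 3),
            ("RPCCK", 4, 8),
        ]

    def test_one_missed_cleavage(self):
        peps = ps.digest("AAKRPCCK", ps.DigestParams(max_missed_cleavages=1))
        assert ("AAKRPCCK", 1, 8, 1) in [
            (p.sequence, p.start, p.end, p.missed_cleavages) for p in peps
        ]

    def test_no_cleavage_sites(self):
        peps = ps.digest("GGG", ps.DigestParams(max_missed_cleavages=3))
        assert [p.sequence for p in peps] == ["GGG"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ps.digest("")

    @given(seq=st.text(alphabet=RESIDUES, min_size=1, max_size=60))
    def test_conservation_and_closure(self, seq):
        """Zero-missed peptides tile the protein; k-missed ones concatenate k+1 tiles."""
        params = ps.DigestParams(max_missed_cleavages=2)
        peps = ps.digest(seq, params)
        zero = sorted((p for p in peps if p.missed_cleavages == 0), key=lambda p: p.start)
        assert "".join(p.sequence for p in zero) == seq
        starts = {p.start: i for i, p in enumerate(zero)}
        for p in peps:
            i = starts[p.start]
            tiles = zero[i : i + p.missed_cleavages + 1]
            assert "".join(t.sequence for t in tiles) == p.sequence

    def test_tm4_peptide_in_digest(self, alpha1_tm4):
        """A K.xxx.K tryptic window around the TM4 region is produced."""
        context = "K" + alpha1_tm4.sequence + "A"
        peps = ps.digest(context, ps.DigestParams(max_missed_cleavages=1))
        assert alpha1_tm4.sequence in [p.sequence for p in peps]


class TestRegistries:
    def test_adduct_masses(self, adducts):
        assert adducts["KK123"].adduct_mass == 372.16
        assert adducts["KK200"].adduct_mass == 462.27
        assert adducts["KK202"].adduct_mass == 500.31

    def test_pair_delta_from_tag_masses(self, adducts):
        light = adducts["KK123-FLI-light"]
        assert light.pair_delta == pytest.approx(682.44 - 672.4322, abs=1e-9)

    def test_inconsistent_pair_delta_rejected(self):
        with pytest.raises(ValueError, match="pair_delta"):
            ps.AdductSpec("x", 100.0, light_tag_mass=100.0, heavy_tag_mass=110.0,
                          pair_delta=9.0)

    def test_nominal_pair_delta_override(self):
        spec = ps.AdductSpec("x", 100.0, light_tag_mass=100.0, heavy_tag_mass=110.008,
                             pair_delta=10.07, allow_pair_delta_override=True)
        assert spec.pair_delta == 10.07

    def test_config_overrides(self):
        config = {
            "chemistry": {
                "adducts": {"ZCM42": {"adduct_mass": 330.0}},
                "modifications": {
                    "Ox2": {"delta_mass": 31.99, "specificity": "MW"}
                },
            }
        }
        table, mods, adducts = load_chemistry_config(config)
        assert adducts["ZCM42"].adduct_mass == 330.0
        assert mods["Ox2"].specificity == frozenset("MW")
        assert adducts["KK123"].adduct_mass == 372.16  # defaults retained
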