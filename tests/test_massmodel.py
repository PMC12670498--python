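"""Mass arithmetic and fragment enumeration of the lasso model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lassokit import massmodel as mm
from lassokit.massmodel import (
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
    FragmentConfig,
    IonKind,
    LassoTopology,
    MassConstants,
)

from conftest import random_topology


class TestScalarMasses:
    @pytest.mark.parametrize(
        "seq,expected",
        [("G", 57.02146), ("GG", 114.04292), ("NAD", 300.10698)],
    )
    def test_residue_mass_sum(self, seq, expected):
        assert mm.residue_mass_sum(seq) == pytest.approx(expected, abs=1e-4)

    def test_unknown_letter_reported(self):
        with pytest.raises(ValueError, match="'B'"):
            mm.residue_mass_sum("GAB")
        with pytest.raises(ValueError):
            mm.residue_mass_sum("")

    def test_residue_table_matches_independent_calculator(self):
        """The frozen residue-mass table agrees with pyteomics' calculator."""
        from pyteomics import mass as pmass

        for aa, m in RESIDUE_MASSES.items():
            ref = pmass.calculate_mass(sequence=aa) - pmass.calculate_mass(formula="H2O")
            assert m == pytest.approx(ref, abs=1e-5)

    def test_neutral_mass_linear(self):
        assert mm.neutral_mass("GG", "linear") == pytest.approx(132.05349, abs=1e-4)

    def test_lasso_loses_one_water(self):
        diff = mm.neutral_mass("GG", "linear") - mm.neutral_mass("GG", "lasso")
        assert diff == pytest.approx(WATER_MASS, abs=1e-12)

    def test_neutral_mass_lasso_vs_residue_sum(self):
        assert mm.neutral_mass("NADGG", "lasso") == pytest.approx(
            mm.residue_mass_sum("NADGG"), abs=1e-12
        )
        assert mm.neutral_mass("NADGG", "lasso") == pytest.approx(414.14990, abs=1e-4)

    def test_neutral_mass_rejects(self):
        with pytest.raises(ValueError):
            mm.neutral_mass("GG", "cyclic")
        with pytest.raises(ValueError):
            mm.neutral_mass("G", "lasso")

    def test_mass_constants_immutable_and_complete(self):
        const = MassConstants()
        assert set(const.residue_masses) == set("ACDEFGHIKLMNPQRSTVWY")
        with pytest.raises(TypeError):
            const.residue_masses["G"] = 0.0


class TestChargeAlgebra:
    def test_mass_from_mz_printed_precursor(self):
        assert mm.mass_from_mz(1050.9996, 2) == pytest.approx(2099.98465, abs=1e-4)

    def test_z1_identity(self):
        assert mm.mass_from_mz(PROTON_MASS + 500.0, 1) == pytest.approx(500.0, abs=1e-12)
        assert mm.mz_from_mass(100.0, 1) == pytest.approx(101.00728, abs=1e-5)

    @pytest.mark.parametrize("z", [1, 2, 3, 4, 5])
    def test_round_trip(self, z):
        for mass in (300.0, 2099.98465, 12345.6789):
            assert mm.mass_from_mz(mm.mz_from_mass(mass, z), z) == pytest.approx(
                mass, abs=1e-9
            )

    def test_observed_charge_states_consistent(self):
        """The 2+ and 3+ m/z values of the same ~2.1 kDa peptide agree."""
        neutral = mm.mass_from_mz(1050.9996, 2)
        assert mm.mz_from_mass(neutral, 3) == pytest.approx(701.0022, abs=0.0005)
        assert mm.mz_from_mass(neutral, 2) == pytest.approx(1050.9996, abs=0.0005)

    @pytest.mark.parametrize("fn", [mm.mass_from_mz, mm.mz_from_mass])
    def test_nonpositive_charge_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(100.0, 0)
        with pytest.raises(ValueError):
            fn(100.0, -2)


class TestTopology:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LassoTopology("GGGGG", 5)  # r = N
        with pytest.raises(ValueError):
            LassoTopology("GGDGG", 2)  # acceptor not D/E
        with pytest.raises(ValueError):
            LassoTopology("GGDGG", 3, loop_window=(3, 5))  # window inside ring
        top = LassoTopology("GGDGG", 3, loop_window=(4, 5))
        assert top.ring_seq == "GGD" and top.tail_seq == "GG"
        assert top.acceptor_pos == 3


class TestTailIons:
    def test_hand_checked_values(self, small_top):
        ions = {
            (ion.label, ion.z): ion for ion in mm.tail_by_ions(small_top, [1])
        }
        assert ions[("b3", 1)].mz == pytest.approx(283.10369, abs=1e-4)
        assert ions[("y2", 1)].mz == pytest.approx(133.06076, abs=1e-4)

    def test_b_series_bounds(self, lasso20_top):
        labels = {ion.label for ion in mm.tail_by_ions(lasso20_top, [1])}
        assert labels == {f"b{i}" for i in range(10, 20)} | {
            f"y{j}" for j in range(1, 11)
        }

    def test_complementarity_identity(self, rng):
        """neutral(b_i) + neutral(y_{N-i}) = M(lasso) for every cleavage."""
        for _ in range(50):
            top = random_topology(rng)
            total = top.neutral_mass()
            ions = {
                (ion.kind, ion.i, ion.j): ion.neutral_mass
                for ion in mm.tail_by_ions(top, [1])
            }
            for i in range(top.ring_size, top.n):
                b = ions[(IonKind.B_TAIL, i, None)]
                y = ions[(IonKind.Y_TAIL, None, top.n - i)]
                assert b + y == pytest.approx(total, abs=1e-9)

    def test_b_mz_strictly_increasing(self, lasso20_top):
        for z in (1, 2):
            bs = [
                ion.mz
                for ion in sorted(
                    (i for i in mm.tail_by_ions(lasso20_top, [z]) if i.kind == IonKind.B_TAIL),
                    key=lambda i: i.i,
                )
            ]
            assert all(a < b for a, b in zip(bs, bs[1:]))

    def test_empty_charges_rejected(self, small_top):
        with pytest.raises(ValueError):
            mm.tail_by_ions(small_top, [])


class TestRingOpenings:
    @pytest.mark.parametrize("r", range(2, 13))
    def test_count_is_r_minus_1(self, r):
        core = "G" * (r - 1) + "D" + "GG"
        top = LassoTopology(core, r)
        assert len(mm.enumerate_ring_openings(top)) == r - 1

    def test_rotations_exhaustive_small(self, small_top):
        assert mm.enumerate_ring_openings(small_top) == [(1, "ADN"), (2, "DNA")]

    def test_rotation_excludes_isopeptide_bond(self, lasso20_top):
        # 10-residue ring -> nine linearized forms, never opened at the
        # isopeptide bond (every rotation is a true backbone rotation)
        rotations = mm.enumerate_ring_openings(lasso20_top)
        assert len(rotations) == 9
        ring = lasso20_top.ring_seq
        for k, rot in rotations:
            assert rot == ring[k:] + ring[:k]

    def test_secondary_b_value(self, small_top):
        ions = {
            (ion.opening_site, ion.rotation_pos, ion.z): ion
            for ion in mm.ring_opened_b_ions(small_top, [1])
            if ion.kind == IonKind.B_RING_OPENED and ion.opening_site is not None
        }
        # rotation [A, D, N], prefix A: 71.03711 - water + proton
        assert ions[(1, 1, 1)].mz == pytest.approx(54.03382, abs=1e-4)

    def test_label_count_ring10(self, lasso20_top):
        ions = mm.ring_opened_b_ions(lasso20_top, [1])
        assert len(ions) == 9 * 9 + 1  # rotations x prefixes + intact-ring ion

    def test_water_offset_switch(self, small_top):
        default = mm.ring_opened_b_ions(small_top, [1])
        no_loss = mm.ring_opened_b_ions(small_top, [1], water_offset=0.0)
        for a, b in zip(default, no_loss):
            if a.opening_site is not None:
                assert b.neutral_mass - a.neutral_mass == pytest.approx(
                    WATER_MASS, abs=1e-9
                )
        with pytest.raises(ValueError):
            mm.ring_opened_b_ions(small_top, [1], water_offset=-1.0)

    def test_full_prefixes_differ_across_rotations(self, rng):
        """m = r-1 prefixes have distinct masses unless the ring composition
        is rotationally degenerate."""
        top = LassoTopology("NAWDGG", 4, None)
        full = [
            ion.neutral_mass
            for ion in mm.ring_opened_b_ions(top, [1])
            if ion.rotation_pos == 3
        ]
        assert len(set(round(m, 6) for m in full)) == 3


def brute_force_interlocked(top):
    """Independent double loop over all (i, j) applying the window rule."""
    lo, hi = top.loop_window
    out = set()
    for i in range(1, top.n):
        for j in range(1, top.n):
            if lo <= i <= hi and lo <= top.n - j <= hi and i + j <= top.n - 1:
                out.add((i, j))
    return out


class TestInterlocked:
    def test_observed_pairs_present(self, lasso20_top):
        labels = {ion.label for ion in mm.enumerate_interlocked(lasso20_top, [2])}
        assert {"[(b17)*(y2)]", "[(b15)*(y4)]", "[(b15)*(y2)]"} <= labels

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            top = random_topology(rng, n_min=5, n_max=12)
            if top.loop_window is None:
                continue
            got = {(ion.i, ion.j) for ion in mm.enumerate_interlocked(top, [1])}
            assert got == brute_force_interlocked(top)

    def test_mass_conservation(self, lasso20_top):
        total = lasso20_top.neutral_mass()
        for ion in mm.enumerate_interlocked(lasso20_top, [1]):
            eliminated = mm.residue_mass_sum(
                lasso20_top.core[ion.i : lasso20_top.n - ion.j]
            )
            assert ion.neutral_mass == pytest.approx(total - eliminated, abs=1e-9)
            assert ion.neutral_mass < total

    def test_unset_window_rejected(self):
        top = LassoTopology("NADGG", 3, None)
        with pytest.raises(ValueError, match="loop_window"):
            mm.enumerate_interlocked(top, [1])


class TestInternalFragments:
    def test_span_and_mass(self, lasso20_top):
        (ion,) = mm.internal_by_fragments(lasso20_top, [(18, 5)], [1])
        # spans residues 16..18 (3 residues)
        span = lasso20_top.core[15:18]
        assert len(span) == 3
        assert ion.neutral_mass == pytest.approx(mm.residue_mass_sum(span), abs=1e-9)
        assert ion.mz == pytest.approx(ion.neutral_mass + PROTON_MASS, abs=1e-9)

    def test_single_residue_span(self, small_top):
        (ion,) = mm.internal_by_fragments(small_top, [(4, 2)], [1])
        assert ion.neutral_mass == pytest.approx(57.02146, abs=1e-4)

    def test_degenerate_pair_rejected(self, small_top):
        with pytest.raises(ValueError):
            mm.internal_by_fragments(small_top, [(3, 2)], [1])  # x = N - j

    def test_complementary_pair_of_interlocked(self, lasso20_top):
        assert mm.complementary_internal_pair(lasso20_top, 15, 2) == (18, 5)


class TestTheoreticalSpectrum:
    def test_contains_tail_series(self, lasso20_top):
        labels = {ion.label for ion in mm.theoretical_spectrum(lasso20_top)}
        assert {f"b{i}" for i in range(10, 20)} <= labels
        assert {f"y{j}" for j in range(1, 11)} <= labels
        assert "[M+2H]2+" in labels

    def test_sorted_and_deterministic(self, lasso20_top):
        a = mm.theoretical_spectrum(lasso20_top)
        b = mm.theoretical_spectrum(lasso20_top)
        assert a == b
        mzs = [ion.mz for ion in a]
        assert mzs == sorted(mzs)

    def test_empty_charges_rejected(self, lasso20_top):
        with pytest.raises(ValueError):
            mm.theoretical_spectrum(lasso20_top, FragmentConfig(charges=()))

    def test_mz_consistency_invariant(self, lasso20_top):
        for ion in mm.theoretical_spectrum(lasso20_top):
            assert ion.mz == pytest.approx(
                (ion.neutral_mass + ion.z * PROTON_MASS) / ion.z, abs=1e-9
            )

    def test_table_round_trip(self, lasso20_top, tmp_path):
        import pandas as pd

        ions = mm.theoretical_spectrum(lasso20_top)
        path = tmp_path / "frags.tsv"
        mm.write_fragment_table(ions, path)
        table = pd.read_csv(path, sep="\t")
        assert list(table.columns) == [
            "label", "kind", "i", "j", "opening_site", "z", "neutral_mass", "mz",
        ]
        assert len(table) == len(ions)
        assert table["mz"].is_monotonic_increasing


@settings(max_examples=50, derandomize=True)
@given(
    mass=st.floats(min_value=50.0, max_value=5000.0),
    z=st.integers(min_value=1, max_value=5),
)
def test_charge_algebra_property(mass, z):
    assert mm.mass_from_mz(mm.mz_from_mass(mass, z), z) == pytest.approx(mass, abs=1e-9)
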