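"""Digestion, elemental composition, and isotope-envelope correctness.

The envelope convolution is checked against an independent brute-force
isotopologue enumeration (multinomial count vectors) for short peptides,
plus closed-form invariants: normalization, centroid linearity in
enrichment, and the no-nitrogen degeneracy.
"""

import numpy as np
import pytest
from helpers import enumerate_isotopologues
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pt_mass

from riboqms.isotope import (
    N15_N14_DELTA,
    NATURAL_N15_ABUNDANCE,
    NEUTRON_MASS,
    PROTON_MASS,
    ElementalComposition,
    EmptyCompositionError,
    InvalidSequenceError,
    UnknownModificationError,
    elemental_composition,
    isotope_distribution,
    tryptic_digest,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestTrypticDigest:
    @pytest.mark.parametrize(
        "seq, mc, expected",
        [
            ("AAAKGGGR", 0, ["AAAK", "GGGR"]),
            ("AAKPGGR", 0, ["AAKPGGR"]),  # no cleavage before proline
            ("AKGR", 1, {"AK", "GR", "AKGR"}),
            ("GGGG", 0, ["GGGG"]),  # no cleavage site at all
            ("KKK", 0, ["K", "K", "K"]),
        ],
    )
    def test_examples(self, seq, mc, expected):
        result = tryptic_digest(seq, mc)
        if isinstance(expected, set):
            assert set(result) == expected
        else:
            assert result == expected

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(InvalidSequenceError):
            tryptic_digest("AAXK")

    @given(st.text(alphabet=AA, min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_zero_missed_cleavage_partition(self, seq):
        """0-missed-cleavage peptides concatenate back to the protein."""
        assert "".join(tryptic_digest(seq, 0)) == seq

    @given(st.text(alphabet=AA, min_size=1, max_size=40), st.integers(0, 3))
    @settings(max_examples=100, deadline=None)
    def test_missed_cleavage_superset(self, seq, mc):
        """Raising the missed-cleavage allowance only adds peptides."""
        base = set(tryptic_digest(seq, 0))
        assert base.issubset(set(tryptic_digest(seq, mc)))


class TestElementalComposition:
    @pytest.mark.parametrize(
        "pep, mods, expected",
        [
            ("G", frozenset(), dict(C=2, H=5, N=1, O=2)),
            ("GG", frozenset(), dict(C=4, H=8, N=2, O=3)),
            ("C", frozenset({"carbamidomethyl"}), dict(C=5, H=10, N=2, O=3, S=1)),
        ],
    )
    def test_examples(self, pep, mods, expected):
        assert elemental_composition(pep, mods).as_dict() == expected

    def test_monoisotopic_mass_matches_pyteomics(self):
        """Cross-check masses against an independent calculator."""
        for pep in ("GASPK", "WWNQR", "ACDEFGHIK"):
            ours = elemental_composition(pep, frozenset()).monoisotopic_mass()
            theirs = pt_mass.calculate_mass(sequence=pep)
            assert ours == pytest.approx(theirs, abs=1e-6)

    def test_carbamidomethyl_only_on_cys(self):
        with_mod = elemental_composition("ACK")
        without = elemental_composition("ACK", frozenset())
        assert with_mod.C - without.C == 2 and with_mod.N - without.N == 1
        assert elemental_composition("AGK") == elemental_composition("AGK", frozenset())

    def test_errors(self):
        with pytest.raises(InvalidSequenceError):
            elemental_composition("AZ")
        with pytest.raises(InvalidSequenceError):
            elemental_composition("")
        with pytest.raises(UnknownModificationError):
            elemental_composition("A", {"phospho"})

    @given(
        st.text(alphabet=AA, min_size=1, max_size=20),
        st.text(alphabet=AA, min_size=1, max_size=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_concatenation_adds_one_water(self, a, b):
        joint = elemental_composition(a + b, frozenset())
        parts = elemental_composition(a, frozenset()) + elemental_composition(b, frozenset())
        assert joint.H == parts.H - 2 and joint.O == parts.O - 1
        assert joint.C == parts.C and joint.N == parts.N and joint.S == parts.S


class TestIsotopeDistribution:
    def test_no_nitrogen_is_enrichment_independent(self):
        comp = ElementalComposition(C=10, H=16, O=4)
        envs = [isotope_distribution(comp, e, truncation=0) for e in (0.0, 0.3, 1.0)]
        for env in envs[1:]:
            np.testing.assert_allclose(env.intensity, envs[0].intensity, atol=1e-12)
            np.testing.assert_allclose(env.mz, envs[0].mz, atol=1e-12)

    def test_single_nitrogen_binomial(self):
        """One N, no other polyisotopic atoms: two peaks of (1-e, e)."""
        comp = ElementalComposition(N=1)
        env = isotope_distribution(comp, 0.5, truncation=0)
        np.testing.assert_allclose(env.intensity, [0.5, 0.5], atol=1e-12)
        assert env.mz[1] - env.mz[0] == pytest.approx(N15_N14_DELTA, abs=1e-9)

    @pytest.mark.parametrize("pep", ["AKG", "GGR", "CCK", "WNQTK"])
    @pytest.mark.parametrize("e", [0.0, 0.00364, 0.5, 0.99])
    def test_matches_brute_force_enumeration(self, pep, e):
        """Convolution equals multinomial isotopologue enumeration exactly."""
        comp = elemental_composition(pep, frozenset())
        env = isotope_distribution(comp, e, charge=1, truncation=0)
        oracle = enumerate_isotopologues(comp.as_dict(), e)
        probs = np.array([p for p, _ in oracle.values()])
        masses = np.array([pm / p for p, pm in oracle.values()])
        assert len(env) == len(probs)
        np.testing.assert_allclose(env.intensity, probs / probs.sum(), atol=1e-9)
        np.testing.assert_allclose(env.mz, masses + PROTON_MASS, atol=1e-9)

    def test_normalization_before_truncation(self):
        comp = elemental_composition("ACDEFGHIK")
        env = isotope_distribution(comp, 0.5, truncation=0)
        assert env.intensity.sum() == pytest.approx(1.0, abs=1e-9)

    def test_truncation_renormalizes(self):
        comp = elemental_composition("ACDEFGHIK")
        env = isotope_distribution(comp, 0.5, truncation=1e-4)
        assert env.intensity.sum() == pytest.approx(1.0, abs=1e-12)
        assert env.intensity.min() >= 1e-4 * 0.9  # cutoff is pre-renormalization

    def test_peak_spacing_near_one_neutron(self):
        comp = elemental_composition("ACDEFGHIK")
        for e in (0.00364, 0.5, 1.0):
            env = isotope_distribution(comp, e, charge=2, truncation=1e-4)
            spacing = np.diff(env.mz)
            # mass-weighted centers: 13C / 15N spacings straddle 1 Da but
            # stay within 15 mTh of the free-neutron mass per charge
            assert np.all(np.abs(spacing - NEUTRON_MASS / 2) < 0.015)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_centroid_linear_in_enrichment(self, e1, e2):
        """Mean neutral mass shifts by (e2-e1) * nN * dM(15N,14N)."""
        comp = elemental_composition("WNQTK", frozenset())
        m1 = isotope_distribution(comp, e1, truncation=0).centroid_neutral_mass()
        m2 = isotope_distribution(comp, e2, truncation=0).centroid_neutral_mass()
        assert m2 - m1 == pytest.approx((e2 - e1) * comp.N * N15_N14_DELTA, abs=1e-6)

    def test_natural_enrichment_reproduces_natural_nitrogen(self):
        comp = elemental_composition("AKG", frozenset())
        env = isotope_distribution(comp, NATURAL_N15_ABUNDANCE, truncation=0)
        theirs = pt_mass.calculate_mass(sequence="AKG")
        assert env.mz[0] - PROTON_MASS == pytest.approx(theirs, abs=1e-6)

    def test_errors(self):
        with pytest.raises(EmptyCompositionError):
            isotope_distribution(ElementalComposition())
        comp = ElementalComposition(C=1, N=1)
        with pytest.raises(ValueError):
            isotope_distribution(comp, -0.1)
        with pytest.raises(ValueError):
            isotope_distribution(comp, 0.5, charge=0)
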