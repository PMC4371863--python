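"""Amplitude fitting, ratio arithmetic, and abundance-matrix rollup."""

import numpy as np
import pandas as pd
import pytest
from helpers import grid_search_amplitudes

from riboqms.quantitation import (
    EnvelopeFitResult,
    EnvelopeMixtureModel,
    MissingValue,
    PeakList,
    RatioMode,
    fit_envelope_amplitudes,
    peptide_ratio,
    protein_abundance_matrix,
    quantify_peaklists,
    species_envelopes,
)


@pytest.fixture(scope="module")
def designs_akgildk():
    return species_envelopes("AGILDK", 1, e_post=0.5)


def synth_peaklist(envs, a_pre, a_post, a_ref, fraction="F1"):
    mzs, intens = [], []
    for sp, a in zip(("pre", "post", "ref"), (a_pre, a_post, a_ref)):
        if a:
            mzs.extend(envs[sp].mz.tolist())
            intens.extend((a * envs[sp].intensity).tolist())
    return PeakList(fraction, np.array(mzs), np.array(intens))


class TestEnvelopeFit:
    def test_exact_recovery(self, designs_akgildk):
        pl = synth_peaklist(designs_akgildk, 1.0, 0.5, 1.0)
        fit = fit_envelope_amplitudes(pl, designs_akgildk)
        assert fit.amplitudes == pytest.approx((1.0, 0.5, 1.0), abs=1e-9)
        assert fit.residual_rms < 1e-12
        assert fit.snr > 1e6  # effectively noiseless

    def test_empty_peaklist(self, designs_akgildk):
        pl = PeakList("F1", np.array([]), np.array([]))
        fit = fit_envelope_amplitudes(pl, designs_akgildk)
        assert fit.amplitudes == (0.0, 0.0, 0.0)
        assert fit.snr == 0.0

    def test_scale_invariance_of_ratios(self, designs_akgildk):
        """Multiplying all intensities by a constant rescales amplitudes
        uniformly, leaving every ratio unchanged."""
        pl = synth_peaklist(designs_akgildk, 0.8, 0.3, 1.0)
        pl10 = PeakList("F1", pl.mz, 10.0 * pl.intensity)
        f1 = fit_envelope_amplitudes(pl, designs_akgildk)
        f10 = fit_envelope_amplitudes(pl10, designs_akgildk)
        for mode in RatioMode:
            assert peptide_ratio(f1, mode) == pytest.approx(peptide_ratio(f10, mode), abs=1e-9)

    def test_noisy_fit_matches_grid_search_oracle(self, designs_akgildk, rng):
        """NNLS equals a dense grid search on the same objective, within
        a 3-sigma-equivalent tolerance at 1% noise."""
        model = EnvelopeMixtureModel(
            synth_peaklist(designs_akgildk, 1.0, 0.5, 1.0), designs_akgildk
        )
        y, _ = model._observed_vector()
        noise = rng.normal(0, 0.01 * y.max(), size=len(y))
        y_noisy = np.clip(y + noise, 0, None)
        from scipy.optimize import nnls

        amps, _ = nnls(model.design_, y_noisy)
        oracle = grid_search_amplitudes(model.design_, y_noisy)
        assert amps == pytest.approx(oracle, abs=0.03)
        # NNLS objective is no worse than the oracle's
        def obj(a):
            r = y_noisy - model.design_ @ a
            return r @ r

        assert obj(amps) <= obj(oracle) + 1e-12

    def test_overlap_collapse_flagged(self):
        envs = species_envelopes("GGFGGK", 1, e_post=0.5)
        pl = synth_peaklist(envs, 1.0, 0.0, 1.0)
        fit = fit_envelope_amplitudes(pl, envs)
        # pre A+1 (13C) and post A+1 (15N) columns fall within 15 ppm here
        assert fit.overlap_collapsed
        assert fit.a_pre == pytest.approx(1.0, abs=1e-9)

    def test_out_of_window_peaks_ignored(self, designs_akgildk):
        pl = synth_peaklist(designs_akgildk, 1.0, 0.0, 1.0)
        spiked = PeakList(
            "F1", np.append(pl.mz, 2000.0), np.append(pl.intensity, 99.0)
        )
        fit = fit_envelope_amplitudes(spiked, designs_akgildk)
        assert fit.a_pre == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_envelopes_rejected(self, designs_akgildk):
        other = species_envelopes("WNQTK", 2)
        mixed = dict(designs_akgildk, ref=other["ref"])
        with pytest.raises(ValueError):
            EnvelopeMixtureModel(PeakList("F1", np.array([300.0]), np.array([1.0])), mixed)


class TestPeptideRatio:
    def make_fit(self, a_pre, a_post, a_ref):
        return EnvelopeFitResult("p/1", 1, a_pre, a_post, a_ref, 0.0, 10.0)

    @pytest.mark.parametrize(
        "amps, mode, expected",
        [
            ((3, 0, 1), "relative_abundance", 0.75),
            ((1, 1, 0), "fraction_labeled", 0.5),
            ((0, 0, 5), "relative_abundance", 0.0),
            ((0, 2, 2), "strain_ratio", 0.5),
            ((0, 0.3, 0.9), "strain_ratio", 0.25),
        ],
    )
    def test_formulas(self, amps, mode, expected):
        assert peptide_ratio(self.make_fit(*amps), mode) == pytest.approx(expected)

    def test_zero_denominator_is_missing(self):
        r = peptide_ratio(self.make_fit(0, 0, 0), "relative_abundance")
        assert isinstance(r, MissingValue) and not r
        assert "zero denominator" in r.reason

    def test_monotone_in_a_pre(self):
        vals = [
            peptide_ratio(self.make_fit(a, 0, 1.0), "relative_abundance")
            for a in (0.1, 0.5, 1.0, 2.0)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_always_in_unit_interval(self, rng):
        for _ in range(200):
            a = rng.uniform(0, 5, size=3)
            for mode in RatioMode:
                r = peptide_ratio(self.make_fit(*a), mode)
                if not isinstance(r, MissingValue):
                    assert 0.0 <= r <= 1.0


class TestAbundanceMatrix:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["protein", "fraction", "ratio", "snr"])

    def test_reference_row_is_one(self):
        table = self.make_table(
            [("S4", "F1", 0.5, 10), ("S4", "F2", 0.4, 10), ("S5", "F1", 0.25, 10)]
        )
        mat = protein_abundance_matrix(table, snr_min=5, reference_protein="S4")
        assert mat.values.loc["S4"].tolist() == pytest.approx([1.0, 1.0])
        assert mat.values.loc["S5", "F1"] == pytest.approx(0.5)

    def test_median_rollup(self):
        table = self.make_table(
            [("S4", "F1", 0.5, 10)]
            + [("S5", "F1", r, 10) for r in (0.2, 0.25, 0.3)]
        )
        mat = protein_abundance_matrix(table, snr_min=5)
        assert mat.values.loc["S5", "F1"] == pytest.approx(0.25 / 0.5)
        assert mat.n_peptides.loc["S5", "F1"] == 3
        assert mat.mad.loc["S5", "F1"] == pytest.approx(0.05)

    def test_low_snr_excluded_and_missing_marked(self):
        table = self.make_table(
            [("S4", "F1", 0.5, 10), ("S5", "F1", 0.9, 1.0)]  # snr below cutoff
        )
        mat = protein_abundance_matrix(table, snr_min=5)
        assert mat.is_missing("S5", "F1")

    def test_reference_missing_flags_fraction(self):
        table = self.make_table(
            [("S4", "F1", 0.5, 10), ("S5", "F2", 0.3, 10), ("S4", "F2", 0.4, 1.0)]
        )
        mat = protein_abundance_matrix(table, snr_min=5)
        assert mat.unnormalizable_fractions == ["F2"]
        assert mat.values["F2"].isna().all()

    def test_exclusion_list(self):
        table = self.make_table([("S4", "F1", 0.5, 10), ("S17", "F1", 0.9, 10)])
        mat = protein_abundance_matrix(table, exclude_proteins={"S17"})
        assert "S17" not in mat.proteins


class TestFullPipelineRoundTrip:
    def test_zero_noise_truth_recovery(self, noiseless_spectra, assembly_truth):
        """Simulated spectra at zero noise reproduce the expected
        reference-normalized matrix to 1e-6."""
        peaklists, designs, _ = noiseless_spectra
        table = quantify_peaklists(peaklists, designs)
        mat = protein_abundance_matrix(table, snr_min=5, reference_protein="S4")
        expected = assembly_truth.expected_ratio_matrix("S4")
        err = (
            (mat.values - expected.loc[mat.values.index, mat.values.columns]).abs().max().max()
        )
        assert err < 1e-6

    def test_global_intensity_scaling_leaves_matrix_unchanged(self, noiseless_spectra):
        peaklists, designs, _ = noiseless_spectra
        scaled = [PeakList(pl.fraction_id, pl.mz, 7.5 * pl.intensity) for pl in peaklists]
        m1 = protein_abundance_matrix(quantify_peaklists(peaklists, designs))
        m2 = protein_abundance_matrix(quantify_peaklists(scaled, designs))
        pd.testing.assert_frame_equal(m1.values, m2.values, atol=1e-9, rtol=0)
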