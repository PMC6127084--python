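"""Genotype calling: duplicate concordance, ΔCt banding, QC, round trips."""

import numpy as np
import pandas as pd
import pytest

import talclone as tc
from talclone.genotyping import (
    CallThresholds,
    build_genotype_matrix,
    call_copy_number,
    call_mutation_assay,
    qc_filter_cells,
)
from talclone.markers import ValidationError

from conftest import simulate_called_matrix

SENT = -1.0


class TestMutationCall:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ((24.1, 24.9), "positive"),
            ((SENT, SENT), "negative"),
            ((24.1, SENT), "missing"),
            ((SENT, 24.1), "missing"),
            ((39.0, 39.5), "negative"),  # beyond ct_max is not amplification
            ((37.9, 39.0), "missing"),
        ],
    )
    def test_duplicate_concordance_rule(self, cts, expected):
        assert call_mutation_assay(cts, CallThresholds(ct_max=38)) == expected

    def test_lowering_ct_max_never_creates_positives(self):
        """Monotonicity: stricter ct_max moves calls only toward
        negative/missing, never toward positive."""
        rank = {"negative": 0, "missing": 1, "positive": 2}
        rng = np.random.default_rng(0)
        pairs = [
            tuple(np.where(rng.random(2) < 0.3, SENT, rng.uniform(20, 45, 2)))
            for _ in range(200)
        ]
        for strict, lax in [(30.0, 38.0), (25.0, 35.0)]:
            for cts in pairs:
                a = call_mutation_assay(cts, CallThresholds(ct_max=strict))
                b = call_mutation_assay(cts, CallThresholds(ct_max=lax))
                assert rank[a] <= rank[b]


class TestCopyNumberCall:
    def test_delta_ct_banding(self):
        thr = CallThresholds(delta_ct_bands=(0.5, 1.5))
        assert call_copy_number((24.0, 24.0), (24.0, 24.0), thr) == 2
        assert call_copy_number((25.0, 25.0), (24.0, 24.0), thr) == 1
        assert call_copy_number((26.5, 26.5), (24.0, 24.0), thr) == 0

    def test_biallelic_loss_requires_silent_locus_with_passing_controls(self):
        thr = CallThresholds()
        assert call_copy_number((SENT, SENT), (24.0, 24.0), thr) == 0

    def test_control_failure_gives_na(self):
        thr = CallThresholds()
        assert call_copy_number((24.0, 24.0), (SENT, 24.0), thr) is pd.NA

    def test_discordant_locus_duplicate_gives_na(self):
        thr = CallThresholds()
        assert call_copy_number((24.0, SENT), (24.0, 24.0), thr) is pd.NA

    def test_bands_must_increase(self):
        with pytest.raises(ValidationError):
            CallThresholds(delta_ct_bands=(1.5, 0.5))


class TestBuildGenotypeMatrix:
    def test_zero_noise_round_trip_equals_truth(self, case6030_truth, zero_noise):
        gm_true, gm, _ = simulate_called_matrix(case6030_truth, 300, zero_noise, seed=5)
        assert not gm.calls.isna().any().any()
        assert (gm.calls.to_numpy(dtype=int) == gm_true.to_numpy()).all()

    def test_all_sentinel_cell_is_fully_na_and_flagged(self, case6116_truth, zero_noise):
        gm_true, _ = tc.sample_cells(case6116_truth, 3, seed=0)
        panel = tc.AssayPanel.default_for(case6116_truth.markers)
        ct = tc.simulate_ct_readout(gm_true, panel, zero_noise, seed=0)
        ct.iloc[1] = SENT
        gm = build_genotype_matrix(ct, panel)
        assert gm.calls.iloc[1].isna().all()
        assert not gm.qc["controls_passed"].iloc[1]
        assert gm.qc["controls_passed"].iloc[0]

    def test_homozygosity_needs_negative_wildtype_assay(self, zero_noise):
        from talclone.cases import case_6030_c7_zygosity

        truth = case_6030_c7_zygosity("diagnostic")
        gm_true, gm, _ = simulate_called_matrix(
            truth, 200, zero_noise, seed=1, wildtype_assays=True
        )
        assert (gm.calls.to_numpy(dtype=int) == gm_true.to_numpy()).all()
        assert set(gm.calls["PTEN_ex8"].unique()) == {1, 2}

    def test_without_wildtype_assay_zygosity_caps_at_het(self, zero_noise):
        from talclone.cases import case_6030_c7_zygosity

        truth = case_6030_c7_zygosity("diagnostic")
        _, gm, _ = simulate_called_matrix(truth, 100, zero_noise, seed=1)
        assert set(gm.calls["PTEN_ex8"].unique()) == {1}

    def test_row_order_never_changes_calls(self, case6116_truth, noisy):
        gm_true, _ = tc.sample_cells(case6116_truth, 50, seed=2)
        panel = tc.AssayPanel.default_for(case6116_truth.markers)
        ct = tc.simulate_ct_readout(gm_true, panel, noisy, seed=3)
        gm_fwd = build_genotype_matrix(ct, panel)
        perm = np.random.default_rng(0).permutation(len(ct))
        gm_perm = build_genotype_matrix(ct.iloc[perm], panel)
        pd.testing.assert_frame_equal(
            gm_perm.calls.sort_index(), gm_fwd.calls.sort_index()
        )


class TestQCFilter:
    def test_identity_when_everything_passes(self, case6116_truth, zero_noise):
        _, gm, _ = simulate_called_matrix(case6116_truth, 100, zero_noise, seed=4)
        kept, report = qc_filter_cells(gm, max_missing_frac=1.0)
        assert kept.n_cells == 100
        assert report.removed == {"control_failure": 0, "too_many_missing": 0}

    def test_control_failure_reason_counted(self, case6116_truth, zero_noise):
        gm_true, _ = tc.sample_cells(case6116_truth, 10, seed=0)
        panel = tc.AssayPanel.default_for(case6116_truth.markers)
        ct = tc.simulate_ct_readout(gm_true, panel, zero_noise, seed=0)
        ct.loc[ct.index[:3], ["CTRL_diploid__rep1", "CTRL_diploid__rep2"]] = SENT
        gm = build_genotype_matrix(ct, panel)
        kept, report = qc_filter_cells(gm, max_missing_frac=1.0)
        assert report.removed["control_failure"] == 3
        assert kept.n_cells == 7

    def test_kept_fraction_matches_independent_recount(self, case6030_truth, noisy):
        _, gm, _ = simulate_called_matrix(case6030_truth, 1000, noisy, seed=8)
        kept, report = qc_filter_cells(gm, max_missing_frac=0.3)
        # independent recount straight off the call matrix
        ctrl_ok = gm.qc["controls_passed"].to_numpy()
        frac = gm.calls.isna().mean(axis=1).to_numpy()
        expected_keep = int((ctrl_ok & (frac <= 0.3)).sum())
        assert report.n_kept == expected_keep
        assert report.n_kept + sum(report.removed.values()) == report.n_input
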