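"""Ground-truth generator: determinism, irreversibility, sampling noise."""

import numpy as np
import pytest

import talclone as tc
from talclone.markers import Marker, ValidationError, genotype_to_units
from talclone.simdata import make_breakpoint_sequences, _revcomp


def truncal_ids():
    return ["F", "CDKN2A_del"]


def build_truth(n_subclones, seed, n_snvs=4, **kw):
    markers = [
        Marker("F", "STIL_TAL1", "fusion"),
        Marker("CDKN2A_del", "CDKN2A", "cn_loss"),
    ] + [Marker(f"snv{j}", f"G{j}", "snv") for j in range(n_snvs)]
    return tc.make_truth(n_subclones, markers, truncal_ids(), seed=seed, **kw)


class TestMakeTruth:
    def test_single_clone_degenerate(self):
        truth = build_truth(1, seed=0, n_snvs=0)
        assert truth.clones() == ["C1"]
        assert truth.frequencies["C1"] == 1.0
        # truncal fusion het, CDKN2A bi-allelic loss
        assert truth.genotypes["C1"] == (1, 0)

    def test_deterministic_for_fixed_seed(self):
        a, b = build_truth(5, seed=7), build_truth(5, seed=7)
        assert a.parents == b.parents
        assert a.genotypes == b.genotypes
        assert a.frequencies == b.frequencies

    @pytest.mark.parametrize("seed", range(10))
    def test_irreversibility_along_every_lineage(self, seed):
        truth = build_truth(6, seed=seed, n_snvs=8)
        for clone in truth.clones():
            path = truth.path_to_root(clone)[::-1]  # root .. clone
            prev = genotype_to_units(truth.genotypes[path[0]], truth.markers)
            for node in path[1:]:
                cur = genotype_to_units(truth.genotypes[node], truth.markers)
                assert all(c >= p for p, c in zip(prev, cur))
                prev = cur

    def test_first_node_carries_all_truncal_markers(self):
        truth = build_truth(4, seed=3)
        units = genotype_to_units(truth.genotypes["C1"], truth.markers)
        idx = {m.id: j for j, m in enumerate(truth.markers)}
        assert units[idx["F"]] == 1
        assert units[idx["CDKN2A_del"]] == 2  # bi-allelic

    def test_reiterative_hits_are_distinct_and_divergent(self):
        truth = build_truth(5, seed=11, reiterative_spec=[("PTEN", 3)])
        pten = [m.id for m in truth.markers if m.gene == "PTEN"]
        assert len(pten) == 3
        carriers = {
            mid: [
                c for c in truth.clones()
                if genotype_to_units(truth.genotypes[c], truth.markers)[
                    [m.id for m in truth.markers].index(mid)
                ] > 0
            ]
            for mid in pten
        }
        # originating clones are pairwise non-ancestral
        origins = [min(v, key=lambda c: len(truth.path_to_root(c))) for v in carriers.values()]
        for a in origins:
            for b in origins:
                if a != b:
                    assert a not in truth.path_to_root(b)[1:]

    def test_bad_frequency_vector_rejected(self):
        with pytest.raises(ValidationError):
            build_truth(3, seed=0, frequencies=[0.5, 0.5])
        with pytest.raises(ValidationError):
            build_truth(2, seed=0, frequencies=[0.7, 0.7])


class TestSampleCells:
    def test_single_clone_identical_rows(self):
        truth = build_truth(1, seed=0, n_snvs=0)
        gm, labels = tc.sample_cells(truth, 10, seed=1)
        assert len(gm) == 10
        assert (gm.nunique() == 1).all()
        assert (labels == "C1").all()

    def test_multinomial_counts_within_three_sigma(self):
        truth = build_truth(2, seed=0, frequencies=[0.5, 0.5])
        n = 10_000
        _, labels = tc.sample_cells(truth, n, seed=42)
        count = (labels == "C1").sum()
        sigma = np.sqrt(n * 0.25)
        assert abs(count - n / 2) <= 3 * sigma

    def test_zero_cells_rejected(self):
        truth = build_truth(1, seed=0, n_snvs=0)
        with pytest.raises(ValidationError):
            tc.sample_cells(truth, 0)


class TestCtReadout:
    def test_wildtype_cell_mutation_assay_silent(self, zero_noise, small_markers):
        truth = tc.make_truth(1, small_markers[:2], truncal_ids(), seed=0)
        gm, _ = tc.sample_cells(truth, 5, seed=0)
        gm[:] = [[0, 2]] * 5  # force germline cells
        panel = tc.AssayPanel.default_for(truth.markers)
        ct = tc.simulate_ct_readout(gm, panel, zero_noise, seed=0)
        assert (ct["F__mut__rep1"] == zero_noise.no_amp_sentinel).all()
        assert (ct["F__mut__rep2"] == zero_noise.no_amp_sentinel).all()

    def test_one_copy_ct_is_baseline_plus_shift(self, zero_noise, small_markers):
        truth = tc.make_truth(1, small_markers[:2], truncal_ids(), seed=0)
        gm, _ = tc.sample_cells(truth, 4, seed=0)
        gm[:] = [[1, 1]] * 4  # one CDKN2A copy retained
        panel = tc.AssayPanel.default_for(truth.markers)
        ct = tc.simulate_ct_readout(gm, panel, zero_noise, seed=0)
        expected = zero_noise.ct_baseline + zero_noise.ct_per_copy_shift
        assert np.allclose(ct["CDKN2A_del__cn__rep1"], expected)
        assert np.allclose(ct["CDKN2A_del__cn__rep2"], expected)

    def test_total_dropout_silences_allele_dependent_assays(self, small_markers):
        noise = tc.NoiseConfig(allelic_dropout_rate=1.0)
        truth = tc.make_truth(2, small_markers, truncal_ids(), seed=0)
        gm, _ = tc.sample_cells(truth, 20, seed=0)
        panel = tc.AssayPanel.default_for(truth.markers)
        ct = tc.simulate_ct_readout(gm, panel, noise, seed=0)
        for col in ct.columns:
            if col.startswith("CTRL"):
                continue
            assert (ct[col] == noise.no_amp_sentinel).all()


class TestXenograft:
    def test_single_clone_sweep(self, case6030_truth):
        gm, labels = tc.simulate_xenograft(
            case6030_truth, 100, engrafting_clones={"C7": 1.0}, seed=0
        )
        assert (labels == "C7").all()
        assert (gm.nunique() == 1).all()

    def test_equal_weights_indistinguishable_from_diagnosis(self, case6030_truth):
        from scipy.stats import chi2_contingency

        n = 5000
        _, diag = tc.sample_cells(case6030_truth, n, seed=1)
        _, xeno = tc.simulate_xenograft(
            case6030_truth, n,
            engrafting_clones=dict(case6030_truth.frequencies), seed=2,
        )
        clones = case6030_truth.clones()
        table = np.array([
            [(diag == c).sum() for c in clones],
            [(xeno == c).sum() for c in clones],
        ])
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_unknown_or_empty_engrafting_set_rejected(self, case6030_truth):
        with pytest.raises(ValidationError):
            tc.simulate_xenograft(case6030_truth, 10, engrafting_clones={"C99": 1.0})
        with pytest.raises(ValidationError):
            tc.simulate_xenograft(case6030_truth, 10, engrafting_clones={})


class TestBreakpointSequences:
    def test_planted_consensus_scores_at_pwm_maximum(self):
        from talclone.rss import default_matrix, scan_rss

        mat = default_matrix()
        recs = make_breakpoint_sequences(5, 80, embed="consensus_rss", spacer=23, seed=3)
        for r in recs:
            best = scan_rss(r.seq, matrix=mat)["global_best"]
            assert best.total == mat.max_heptamer() + mat.max_nonamer()

    def test_background_heptamer_count_matches_closed_form(self):
        n, L = 100, 500
        total = 0
        for seed in range(5):
            recs = make_breakpoint_sequences(n, L, embed="none", seed=seed)
            for r in recs:
                # brute-force sliding window count
                total += sum(
                    r.seq[i:i + 7] == "CACAGTG" for i in range(L - 6)
                )
        expected = 5 * n * (L - 6) / 4 ** 7
        sigma = np.sqrt(expected)
        assert abs(total - expected) <= 4 * sigma

    def test_same_seed_identical_output(self, tmp_path):
        from talclone.io import write_fasta

        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(make_breakpoint_sequences(10, 60, embed="consensus_rss", seed=9), p1)
        write_fasta(make_breakpoint_sequences(10, 60, embed="consensus_rss", seed=9), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_length_too_small_rejected(self):
        with pytest.raises(ValidationError):
            make_breakpoint_sequences(1, 30, embed="consensus_rss", spacer=23)

    def test_strand_recorded_matches_planted_element(self):
        recs = make_breakpoint_sequences(20, 100, embed="consensus_rss", spacer=12, seed=4)
        for r in recs:
            window = r.seq[r.offset_start:r.offset_end]
            if r.strand == "-":
                window = _revcomp(window)
            assert window.startswith("CACAGTG")
            assert window.endswith("ACAAAAACC")
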