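"""Matching and scaled-AUC estimator, checked against naive oracles."""

import numpy as np
import pytest

from conftest import oracle_auc, oracle_match, random_instance
from txadvise.errors import ValidationError
from txadvise.evaluation import (
    MatchLabel,
    auc,
    match_transcripts,
    roc_curve,
)
from txadvise.gtf_io import Exon, Transcript, Transcriptome
from txadvise.synthetic import ReferenceModel, generate_assembly, generate_reference


def _labels(pairs):
    return [
        MatchLabel(f"p{i}", cov, rid is not None, rid)
        for i, (cov, rid) in enumerate(pairs)
    ]


class TestMatchTranscripts:
    def test_identical_prediction_matches(self, tiny_reference):
        pred = Transcriptome([
            Transcript("p1", "g", "chr1", "+",
                       [Exon(100, 200), Exon(300, 400)], 5.0)
        ])
        (lab,) = match_transcripts(pred, tiny_reference)
        assert lab.matched and lab.matched_ref_id == "r1"

    def test_same_chain_opposite_strand_unmatched(self, tiny_reference):
        pred = Transcriptome([
            Transcript("p1", "g", "chr1", "-",
                       [Exon(100, 200), Exon(300, 400)], 5.0)
        ])
        (lab,) = match_transcripts(pred, tiny_reference)
        assert not lab.matched

    def test_unknown_strand_matches_either(self, tiny_reference):
        pred = Transcriptome([
            Transcript("p1", "g", "chr1", ".",
                       [Exon(100, 200), Exon(300, 400)], 5.0)
        ])
        (lab,) = match_transcripts(pred, tiny_reference)
        assert lab.matched

    def test_intron_chain_not_exon_boundaries_decides(self, tiny_reference):
        # different first-exon start, same introns -> still a match
        pred = Transcriptome([
            Transcript("p1", "g", "chr1", "+",
                       [Exon(150, 200), Exon(300, 390)], 5.0)
        ])
        (lab,) = match_transcripts(pred, tiny_reference)
        assert lab.matched and lab.matched_ref_id == "r1"

    @pytest.mark.parametrize("start,end,expect", [
        (1000, 1500, True),    # exact
        (1050, 1500, True),    # overlap 451/501 ~ 0.90
        (1200, 1500, False),   # overlap 301/501 ~ 0.60
    ])
    def test_single_exon_reciprocal_overlap(self, tiny_reference, start, end, expect):
        pred = Transcriptome([
            Transcript("p1", "g", "chr1", "-", [Exon(start, end)], 1.0)
        ])
        (lab,) = match_transcripts(pred, tiny_reference, single_exon_overlap=0.8)
        assert lab.matched is expect

    def test_single_exon_never_matches_multi_exon(self, tiny_reference):
        pred = Transcriptome([
            Transcript("p1", "g", "chr1", "+", [Exon(100, 400)], 1.0)
        ])
        (lab,) = match_transcripts(pred, tiny_reference)
        assert not lab.matched

    def test_chromosome_absent_from_reference_unmatched(self, tiny_reference):
        pred = Transcriptome([
            Transcript("p1", "g", "chr9", "+",
                       [Exon(100, 200), Exon(300, 400)], 1.0)
        ])
        (lab,) = match_transcripts(pred, tiny_reference)
        assert not lab.matched

    def test_tie_broken_by_smallest_reference_id(self):
        ref = Transcriptome([
            Transcript("rB", "g", "chr1", "+", [Exon(1, 10), Exon(20, 30)]),
            Transcript("rA", "g2", "chr1", "+", [Exon(3, 10), Exon(20, 33)]),
        ])
        pred = Transcriptome([
            Transcript("p", "g", "chr1", "+", [Exon(1, 10), Exon(20, 30)], 1.0)
        ])
        (lab,) = match_transcripts(pred, ref)
        assert lab.matched_ref_id == "rA"

    def test_empty_reference_is_an_error(self):
        pred = Transcriptome([Transcript("p", "g", "chr1", "+", [Exon(1, 9)], 1.0)])
        with pytest.raises(ValidationError):
            match_transcripts(pred, Transcriptome())

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred, ref = random_instance(rng, n_ref=30, n_pred=50)
        labels = {l.transcript_id: l.matched_ref_id
                  for l in match_transcripts(pred, ref)}
        assert labels == oracle_match(pred, ref)


class TestRocCurve:
    def test_empty_labels(self):
        c = roc_curve([], reference_size=10)
        assert c.points == [] and c.auc_scaled == 0.0

    def test_constant_precision_rectangle(self):
        # 5 matched predictions of 5 distinct references, reference of 100
        labels = _labels([(float(c), f"r{c}") for c in (9, 7, 5, 3, 1)])
        c = roc_curve(labels, reference_size=100)
        assert c.auc_scaled == pytest.approx(500.0)

    def test_hand_worked_threshold_sweep(self):
        labels = _labels([(10.0, "r1"), (8.0, "r2"), (5.0, None), (2.0, "r3")])
        c = roc_curve(labels, reference_size=1000)
        got = [(p.sensitivity, p.precision) for p in c.points]
        assert got == pytest.approx(
            [(0.001, 1.0), (0.002, 1.0), (0.002, 2 / 3), (0.003, 0.75)]
        )
        assert c.auc_scaled == pytest.approx(27.0833333333, abs=1e-8)

    def test_duplicate_reference_matches_count_once_for_sensitivity(self):
        labels = _labels([(10.0, "r1"), (9.0, "r1")])
        c = roc_curve(labels, reference_size=10)
        last = c.points[-1]
        assert last.matched_kept == 2
        assert last.distinct_ref_matched == 1
        assert last.precision == 1.0 and last.sensitivity == 0.1

    def test_invalid_reference_size(self):
        with pytest.raises(ValidationError):
            roc_curve([], reference_size=0)

    def test_sensitivity_nondecreasing_and_bounds(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 60))
            pairs = [
                (float(rng.integers(0, 15)),
                 f"r{rng.integers(0, 20)}" if rng.random() < 0.5 else None)
                for _ in range(n)
            ]
            c = roc_curve(_labels(pairs), reference_size=100)
            sens = [p.sensitivity for p in c.points]
            assert sens == sorted(sens)
            assert 0.0 <= c.auc_scaled <= 1e4
            assert c.auc_scaled <= 1e4 * c.max_sensitivity + 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_threshold_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(1, 100))
        pairs = [
            (float(np.round(rng.lognormal(1, 1), 2)),
             f"r{rng.integers(0, 30)}" if rng.random() < 0.6 else None)
            for _ in range(n)
        ]
        c = roc_curve(_labels(pairs), reference_size=200)
        assert c.auc_scaled == pytest.approx(oracle_auc(pairs, 200), abs=1e-9)

    def test_adding_high_coverage_match_never_decreases_auc(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            pairs = [
                (float(r.integers(1, 10)),
                 f"r{r.integers(0, 10)}" if r.random() < 0.5 else None)
                for _ in range(30)
            ]
            base = roc_curve(_labels(pairs), reference_size=100).auc_scaled
            grown = pairs + [(100.0, "r_new")]
            assert roc_curve(_labels(grown), 100).auc_scaled >= base - 1e-12

    def test_adding_lowest_coverage_unmatched_never_increases_auc(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            pairs = [
                (float(r.integers(1, 10)),
                 f"r{r.integers(0, 10)}" if r.random() < 0.5 else None)
                for _ in range(30)
            ]
            base = roc_curve(_labels(pairs), reference_size=100).auc_scaled
            grown = pairs + [(0.5, None)]
            assert roc_curve(_labels(grown), 100).auc_scaled <= base + 1e-12


class TestAucComposition:
    def test_perfect_assembly_scores_ten_thousand(self, tmp_path):
        ref = generate_reference(ReferenceModel(n_genes=10, seed=4))
        pred = generate_assembly(ref, tp_fraction=1.0, fp_count=0, seed=4)
        from txadvise.gtf_io import write_gtf
        write_gtf(ref, tmp_path / "ref.gtf")
        write_gtf(pred, tmp_path / "pred.gtf")
        assert auc(tmp_path / "pred.gtf", tmp_path / "ref.gtf") == pytest.approx(1e4)

    def test_disjoint_chromosomes_score_zero(self):
        ref = Transcriptome([Transcript("r", "g", "chr1", "+", [Exon(1, 99)])])
        pred = Transcriptome([Transcript("p", "g", "chr7", "+", [Exon(1, 99)], 1.0)])
        assert auc(pred, ref) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_end_to_end_matches_scripted_oracle(self, seed):
        """Full path (match + sweep + area) vs oracle matcher + oracle area."""
        rng = np.random.default_rng(500 + seed)
        pred, ref = random_instance(rng, n_ref=25, n_pred=40)
        expected = oracle_auc(
            [(p.coverage, oracle_match(pred, ref)[p.transcript_id]) for p in pred],
            reference_size=len(ref),
        )
        assert auc(pred, ref) == pytest.approx(expected, abs=1e-9)
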