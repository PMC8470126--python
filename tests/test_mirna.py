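"""Prediction gating, exon-9 target screening, and feedback detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from il6_episcreen.data import (
    MirdipClass,
    PredictionSource,
    SiteRegion,
    TargetPrediction,
)
from il6_episcreen.mirna import (
    candidate_mirnas,
    detect_feedback,
    exon9_target_screen,
    filter_predicted,
)


def mirdip(mirna, gene, cls):
    return TargetPrediction(mirna, gene, PredictionSource.MIRDIP,
                            class_score=MirdipClass.parse(cls))


def starmir(mirna, exon, prob):
    return TargetPrediction(mirna, exon, PredictionSource.STARMIR,
                            logit_prob=prob, site_region=SiteRegion.CDS_SEED)


def corr_records(entries):
    return pd.DataFrame(
        entries, columns=["feature_id", "target_id", "cohort", "r", "p_value", "n"]
    )


class TestFilterPredicted:
    def test_class_gate(self):
        preds = [mirdip("m1", "G", "high"), mirdip("m2", "G", "low")]
        assert filter_predicted(preds, "G", "high") == {"m1"}

    def test_ordinal_ordering(self):
        preds = [mirdip("m1", "G", "high"), mirdip("m2", "G", "medium"),
                 mirdip("m3", "G", "low"), mirdip("m4", "G", "very high")]
        assert filter_predicted(preds, "G", "medium") == {"m1", "m2", "m4"}

    def test_matches_brute_force(self, rng):
        classes = ["low", "medium", "high", "very_high"]
        preds = [mirdip(f"m{i}", "G", classes[rng.integers(0, 4)]) for i in range(30)]
        for min_class in classes:
            expected = {
                p.mirna_id for p in preds
                if p.class_score >= MirdipClass.parse(min_class)
            }
            assert filter_predicted(preds, "G", min_class) == expected

    def test_unknown_gene_empty(self):
        assert filter_predicted([mirdip("m1", "G", "high")], "OTHER") == set()


class TestCandidateMirnas:
    def records_for(self, mirna, n_cohorts, r):
        return [(mirna, "G", f"C{i:02d}", r, 0.01, 200) for i in range(n_cohorts)]

    def test_min_cohorts_boundary(self):
        preds = [mirdip("m5", "G", "very_high"), mirdip("m4", "G", "very_high")]
        records = corr_records(
            self.records_for("m5", 5, -0.5) + self.records_for("m4", 4, -0.5)
        )
        cands = candidate_mirnas(records, preds, "G", min_cohorts=5)
        assert [c.mirna_id for c in cands] == ["m5"]
        assert cands[0].direction_profile == "always_negative"

    def test_prediction_class_gate_excludes(self):
        preds = [mirdip("m1", "G", "medium")]
        records = corr_records(self.records_for("m1", 6, -0.5))
        assert candidate_mirnas(records, preds, "G", min_class="high") == []

    def test_gating_monotonicity_min_cohorts(self, rng):
        preds = [mirdip(f"m{i}", "G", "high") for i in range(10)]
        rows = []
        for i in range(10):
            for c in range(int(rng.integers(1, 9))):
                rows.append((f"m{i}", "G", f"C{c}", float(rng.choice([-0.5, 0.5])),
                             0.01, 100))
        records = corr_records(rows)
        previous = None
        for k in (1, 3, 5, 7):
            ids = {c.mirna_id for c in candidate_mirnas(records, preds, "G",
                                                        min_cohorts=k)}
            if previous is not None:
                assert ids <= previous
            previous = ids

    @given(r_thr=st.sampled_from([0.3, 0.4, 0.5, 0.6]))
    @settings(max_examples=4, deadline=None)
    def test_gating_monotonicity_r_threshold(self, r_thr):
        preds = [mirdip("m1", "G", "high")]
        rows = [("m1", "G", f"C{i}", -0.45, 0.01, 100) for i in range(6)]
        records = corr_records(rows)
        loose = {c.mirna_id for c in candidate_mirnas(records, preds, "G",
                                                      r_threshold=0.3)}
        tight = {c.mirna_id for c in candidate_mirnas(records, preds, "G",
                                                      r_threshold=r_thr)}
        assert tight <= loose


class TestExon9Screen:
    def test_gate_satisfied(self):
        preds = [starmir("m", "Exon9", 0.73)]
        records = corr_records([("m", "Exon9", "C01", -0.4, 0.01, 100)])
        (cand,) = exon9_target_screen(preds, records, "Exon9")
        assert cand.consensus.n_sig_neg == 1

    def test_logit_prob_boundary(self):
        records = corr_records([("m", "Exon9", "C01", -0.4, 0.01, 100)])
        assert exon9_target_screen([starmir("m", "Exon9", 0.49)], records, "Exon9") == []
        assert len(exon9_target_screen([starmir("m", "Exon9", 0.5)], records, "Exon9")) == 1

    def test_needs_significant_cohort(self):
        preds = [starmir("m", "Exon9", 0.9)]
        records = corr_records([("m", "Exon9", "C01", -0.2, 0.01, 100)])
        assert exon9_target_screen(preds, records, "Exon9") == []


class TestDetectFeedback:
    def build(self, pos_cohorts, neg_cohorts, mirna="mFB"):
        ligand = corr_records(
            [(mirna, "IL6", c, 0.5, 0.01, 200) for c in pos_cohorts]
        )
        receptor = corr_records(
            [(mirna, "IL6R", c, -0.5, 0.01, 200) for c in neg_cohorts]
        )
        preds = [mirdip(mirna, "IL6R", "medium")]
        return ligand, receptor, preds

    def test_boundary_five_and_four(self):
        cohorts = [f"C{i}" for i in range(5)]
        ligand, receptor, preds = self.build(cohorts, cohorts[:4])
        assert detect_feedback(ligand, receptor, preds) == []
        ligand, receptor, preds = self.build(cohorts, cohorts)
        (cand,) = detect_feedback(ligand, receptor, preds)
        assert cand.n_pos == 5 and cand.n_neg == 5
        assert cand.both_satisfied_cohorts == frozenset(cohorts)

    def test_prediction_gate_on_receptor_arm(self):
        cohorts = [f"C{i}" for i in range(6)]
        ligand, receptor, _ = self.build(cohorts, cohorts)
        preds = [mirdip("mFB", "IL6R", "low")]
        assert detect_feedback(ligand, receptor, preds, min_class="medium") == []

    def test_ordering_invariance(self, rng):
        cohorts = [f"C{i}" for i in range(8)]
        ligand, receptor, preds = self.build(cohorts, cohorts)
        lig_shuffled = ligand.sample(frac=1, random_state=1).reset_index(drop=True)
        rec_shuffled = receptor.sample(frac=1, random_state=2).reset_index(drop=True)
        assert detect_feedback(ligand, receptor, preds) == detect_feedback(
            lig_shuffled, rec_shuffled, preds
        )

    def test_planted_motif_recovered_against_decoys(self, small_bundle,
                                                    small_predictions):
        from il6_episcreen.correlation import correlate_layer

        ligand = correlate_layer(small_bundle.mirna,
                                 small_bundle.expression.row("IL6"),
                                 small_bundle.sample_annotations, target_id="IL6")
        receptor = correlate_layer(small_bundle.mirna,
                                   small_bundle.expression.row("IL6R"),
                                   small_bundle.sample_annotations, target_id="IL6R")
        cands = detect_feedback(ligand, receptor, small_predictions,
                                min_cohorts=5)
        assert [c.mirna_id for c in cands] == ["miR-FB"]
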