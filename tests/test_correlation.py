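"""Pearson screens, consensus counting, probe selection, and region means."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from il6_episcreen.correlation import (
    ConsensusSummary,
    consensus,
    correlate_layer,
    pearson_with_p,
    region_methylation_means,
    select_probes_for_survival,
)
from il6_episcreen.data import OmicsMatrix
from il6_episcreen.exceptions import DegenerateDataError, InsufficientDataError


def t_cdf_oracle_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via independent integration of the t density."""
    df = n - 2
    t = abs(r) * math.sqrt(df / (1 - r * r))

    def density(x):
        c = math.exp(math.lgamma((df + 1) / 2) - math.lgamma(df / 2)) / math.sqrt(
            df * math.pi
        )
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(density, t, np.inf)
    return 2 * tail


class TestPearson:
    def test_perfect_positive(self):
        r, p, n = pearson_with_p([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == 1.0
        assert p == 0.0

    def test_perfect_negative(self):
        r, p, _ = pearson_with_p([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == -1.0
        assert p == 0.0

    def test_p_matches_t_density_oracle(self):
        x = [0.1, 0.9, 0.3, 0.7, 0.2, 0.8]
        y = [1.2, 0.4, 0.9, 0.5, 1.1, 0.2]
        r, p, n = pearson_with_p(x, y)
        assert n == 6
        assert p == pytest.approx(t_cdf_oracle_p(r, n), abs=1e-9)

    def test_affine_invariance_and_sign_flip(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        r0, _, _ = pearson_with_p(x, y)
        r_scaled, _, _ = pearson_with_p(2.5 * x + 7, y)
        r_neg, _, _ = pearson_with_p(-1.5 * x + 2, y)
        assert r_scaled == pytest.approx(r0, abs=1e-12)
        assert r_neg == pytest.approx(-r0, abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(DegenerateDataError):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_missing_pairs_dropped_then_floor_enforced(self):
        with pytest.raises(InsufficientDataError):
            pearson_with_p([1, 2, np.nan, np.nan], [1, np.nan, 3, 4])


def make_records(entries):
    return pd.DataFrame(
        entries, columns=["feature_id", "target_id", "cohort", "r", "p_value", "n"]
    )


class TestConsensus:
    def test_all_negative(self):
        records = make_records(
            [("f", "g", f"C{i}", -0.5, 0.01, 50) for i in range(10)]
        )
        (s,) = consensus(records)
        assert s.n_sig_neg == 10
        assert s.always_negative and not s.always_positive

    def test_one_positive_breaks_always_negative(self):
        rows = [("f", "g", f"C{i}", -0.5, 0.01, 50) for i in range(5)]
        rows.append(("f", "g", "C9", 0.5, 0.01, 50))
        (s,) = consensus(make_records(rows))
        assert s.n_sig_neg == 5 and s.n_sig_pos == 1
        assert not s.always_negative

    def test_neutral_cohorts_do_not_count(self):
        rows = [
            ("f", "g", "C1", -0.5, 0.01, 50),
            ("f", "g", "C2", -0.2, 0.01, 50),   # weak
            ("f", "g", "C3", -0.6, 0.20, 50),   # non-significant
        ]
        (s,) = consensus(make_records(rows))
        assert s.n_sig_neg == 1
        assert s.always_negative

    def test_counts_match_brute_force(self, rng):
        rows = []
        for f in range(4):
            for c in range(12):
                rows.append(
                    (f"f{f}", "g", f"C{c:02d}",
                     float(rng.uniform(-1, 1)), float(rng.uniform(0, 0.2)), 30)
                )
        records = make_records(rows)
        for s in consensus(records):
            sub = records[records.feature_id == s.feature_id]
            neg = sum(1 for _, r in sub.iterrows() if r.r <= -0.3 and r.p_value <= 0.05)
            pos = sum(1 for _, r in sub.iterrows() if r.r >= 0.3 and r.p_value <= 0.05)
            assert (s.n_sig_neg, s.n_sig_pos) == (neg, pos)

    def test_order_invariance(self, rng):
        rows = [
            (f"f{f}", "g", f"C{c}", float(rng.uniform(-1, 1)),
             float(rng.uniform(0, 0.1)), 30)
            for f in range(3) for c in range(6)
        ]
        records = make_records(rows)
        shuffled = records.sample(frac=1, random_state=3).reset_index(drop=True)
        assert consensus(records) == consensus(shuffled)


class TestProbeSelection:
    def summary(self, probe, gene, n_neg):
        return ConsensusSummary(probe, gene, n_neg, 0, n_neg > 0, False, ())

    def test_threshold_is_strict(self):
        summaries = [self.summary("cgA", "IL6R", 11), self.summary("cgB", "IL6R", 10)]
        assert select_probes_for_survival(summaries, "IL6R", 10) == ["cgA"]

    def test_tie_broken_by_probe_id(self):
        summaries = [self.summary("cgB", "G", 6), self.summary("cgA", "G", 6)]
        assert select_probes_for_survival(summaries, "G", 0) == ["cgA", "cgB"]

    def test_empty_summaries_empty_result(self):
        assert select_probes_for_survival([], "G", 0) == []


class TestRegionMeans:
    def test_constant_beta(self, small_bundle):
        from il6_episcreen.data import ProbeAnnotation, ProbeRegion

        meth = OmicsMatrix(
            pd.DataFrame(0.8, index=["cg1"], columns=small_bundle.tumor_samples()),
            "beta",
        )
        ann = [ProbeAnnotation("cg1", "IL6", ProbeRegion.BODY, 10)]
        out = region_methylation_means(meth, ann, small_bundle.sample_annotations)
        cohort_cols = [c for c in out.columns if c.startswith("C")]
        assert np.allclose(out.loc["cg1", cohort_cols].astype(float), 0.8)

    def test_means_match_brute_force(self, small_bundle):
        out = region_methylation_means(
            small_bundle.methylation,
            small_bundle.probe_annotations,
            small_bundle.sample_annotations,
        )
        samples = small_bundle.tumor_samples("C02")
        expected = small_bundle.methylation.values.loc["cg00000001", samples].mean()
        assert out.loc["cg00000001", "C02"] == pytest.approx(expected)

    def test_position_ordering(self, small_bundle):
        out = region_methylation_means(
            small_bundle.methylation,
            small_bundle.probe_annotations,
            small_bundle.sample_annotations,
        )
        assert list(out["position"]) == sorted(out["position"])


class TestCorrelateLayer:
    def test_planted_negative_coupling_detected(self, small_bundle):
        records = correlate_layer(
            small_bundle.methylation,
            small_bundle.expression.row("IL6R"),
            small_bundle.sample_annotations,
            target_id="IL6R",
        )
        planted = records[records.feature_id == "cg00000001"]
        assert len(planted) == 6  # one record per cohort
        assert (planted.r < 0).all()

    def test_single_cohort_one_record_per_feature(self, small_bundle):
        anns = [a for a in small_bundle.sample_annotations if a.cohort.code == "C01"]
        records = correlate_layer(
            small_bundle.methylation,
            small_bundle.expression.row("IL6"),
            anns,
            target_id="IL6",
        )
        assert sorted(records.feature_id) == sorted(small_bundle.methylation.feature_ids)
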