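"""Repeatability/reproducibility statistics: oracles and calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from natsc import (
    bland_altman_ratio,
    default_landmarks,
    ks_normality,
    laterality_test,
    max_pct_diff,
    measure_all,
    paired_visit_test,
    pearson_r2,
    signflip_pvalue,
    simulate_cohort,
    spearman_rho,
    summarize,
)
from natsc.phantom import zero_variability
from natsc.stats import family_visit_test


def make_measurements(values, readers=("r1", "r2")):
    """Measurement table from {(subject, visit, region, side): conc}."""
    rows = []
    for (subject, visit, region, side), conc in values.items():
        for reader in readers:
            rows.append(
                dict(
                    subject=subject,
                    visit=visit,
                    reader=reader,
                    region=region,
                    side=side,
                    mean_signal=conc,
                    concentration=conc,
                    n_voxels=12,
                )
            )
    return pd.DataFrame(rows)


class TestPearsonR2:
    def test_perfect_and_affine(self, rng):
        x = rng.normal(size=20)
        assert pearson_r2(x, x) == pytest.approx(1.0)
        assert pearson_r2(x, -2 * x + 7) == pytest.approx(1.0)

    def test_five_point_hand_sums(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # brute-force expanded sums
        n = 5
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x * x).sum() - x.sum() ** 2) * np.sqrt(
            n * (y * y).sum() - y.sum() ** 2
        )
        assert pearson_r2(x, y) == pytest.approx((num / den) ** 2, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r2([1, 1, 1, 1], [1, 2, 3, 4])


class TestMaxPctDiff:
    @pytest.mark.parametrize(
        "pair, printed",
        [
            ((65.4, 42.4), 35.1),  # gray matter
            ((52.9, 34.5), 34.7),  # white matter
            ((81.5, 49.5), 39.3),  # caudate head
            ((58.4, 33.2), 43.0),  # pons
            ((52.3, 33.0), 36.9),  # cerebellum
        ],
    )
    def test_reported_fluctuations(self, pair, printed):
        assert max_pct_diff(pair) == pytest.approx(printed, abs=0.2)

    def test_equal_values_and_scale_invariance(self, rng):
        assert max_pct_diff([7.0, 7.0, 7.0]) == 0.0
        v = rng.uniform(10, 90, 8)
        assert max_pct_diff(3.7 * v) == pytest.approx(max_pct_diff(v), rel=1e-12)

    def test_positive_input_required(self):
        with pytest.raises(ValueError):
            max_pct_diff([5.0, -1.0])


class TestSignFlip:
    def test_identical_data_p_one(self):
        assert signflip_pvalue(np.zeros(12)) == 1.0

    def test_constant_offset_exact_enumeration(self):
        # only the all-plus and all-minus sign patterns reach |sum| = n*c
        assert signflip_pvalue(np.full(12, 3.0)) == pytest.approx(2 / 4096)

    def test_matches_explicit_enumeration(self, rng):
        d = rng.normal(size=6)
        obs = abs(d.sum())
        count = sum(
            abs(np.dot(signs, d)) >= obs - 1e-12
            for signs in itertools.product([-1, 1], repeat=6)
        )
        assert signflip_pvalue(d) == pytest.approx(count / 64)

    def test_large_n_uses_sampling(self, rng):
        d = rng.normal(0.8, 1.0, size=30)
        p = signflip_pvalue(d, n_perm=10_000, seed=0)
        assert 0 < p < 0.01

    def test_type_one_error_calibrated(self, rng):
        # 1000 simulated null cohorts of n = 12: rejection rate ~ alpha
        n_rep, n = 1000, 12
        diffs = rng.normal(size=(n_rep, n))
        codes = np.arange(2**n, dtype=np.int64)[:, None]
        signs = ((codes >> np.arange(n)) & 1) * 2 - 1
        sums = np.abs(signs @ diffs.T)  # (4096, n_rep)
        obs = np.abs(diffs.sum(axis=1))
        pvals = (sums >= obs * (1 - 1e-12)).mean(axis=0)
        rate = (pvals <= 0.05).mean()
        assert abs(rate - 0.05) < 0.02


class TestVisitAndLateralityTests:
    def test_identical_visits_p_one(self):
        values = {}
        for s in range(6):
            for visit in ("V1", "V2"):
                values[(f"s{s}", visit, "GM", "left")] = 50.0 + s
        m = make_measurements(values)
        assert paired_visit_test(m, ("V1", "V2"), "GM") == 1.0

    def test_large_shift_detected_exactly(self):
        values = {}
        for s in range(12):
            base = 50.0 + s
            values[(f"s{s:02d}", "V1", "GM", "left")] = base
            values[(f"s{s:02d}", "V2", "GM", "left")] = base + 20.0
        m = make_measurements(values)
        assert paired_visit_test(m, ("V1", "V2"), "GM") <= 0.001

    def test_family_maxt_null_and_alternative(self):
        values = {}
        for s in range(10):
            base = 50.0 + s
            for visit in ("V1", "V2", "V3"):
                values[(f"s{s:02d}", visit, "GM", "left")] = base
        m = make_measurements(values)
        assert family_visit_test(m, "GM") == 1.0
        for s in range(10):
            values[(f"s{s:02d}", "V3", "GM", "left")] += 15.0
        m = make_measurements(values)
        assert family_visit_test(m, "GM") < 0.01

    def test_laterality_enumeration_oracle(self):
        left = np.array([50.0 + i for i in range(12)])
        right = left - 4.0
        lm, rm, p = laterality_test(left, right)
        assert lm == pytest.approx(right.mean() + 4.0)
        assert p == pytest.approx(2 / 4096)
        _, _, p_same = laterality_test(left, left)
        assert p_same == 1.0

    def test_laterality_power_on_synthetic_cohort(self, lib, phantom_config):
        # configured +4 left HCN offset: detected at n = 12 under default
        # noise in most seeds
        from dataclasses import replace

        cfg = replace(phantom_config, laterality_offset={"HCN": 4.0})
        hits = 0
        seeds = (101, 102, 103, 104, 105)
        for seed in seeds:
            cohort = simulate_cohort(
                12, seed=seed, config=cfg, lib=lib, visits=("V1",)
            )
            m = measure_all(
                cohort, default_landmarks(cfg), jitter_sd_mm=1.0, seed=seed
            )
            hcn = m[m.region == "HCN"]
            piv = (
                hcn.groupby(["subject", "side"])["concentration"].mean().unstack()
            )
            lm, rm, p = laterality_test(piv["left"], piv["right"])
            if p < 0.05 and lm > rm:
                hits += 1
        assert hits >= 0.8 * len(seeds)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            laterality_test([1.0, 2.0], [1.0, 2.0])


class TestSpearman:
    def test_monotone_agreement(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_rho(a, [10, 20, 30, 40, 50]) == pytest.approx(1.0)
        assert spearman_rho(a, [50, 40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_ties_equal_midrank_pearson(self):
        a = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        ranks_a = pd.Series(a).rank().to_numpy()
        ranks_b = pd.Series(b).rank().to_numpy()
        expected = np.corrcoef(ranks_a, ranks_b)[0, 1]
        assert spearman_rho(a, b) == pytest.approx(expected, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_readers(self):
        a = np.array([40.0, 50.0, 60.0])
        assert bland_altman_ratio(a, a) == pytest.approx((1.0, 1.0, 1.0))

    def test_constant_ratio(self):
        b = np.array([40.0, 50.0, 60.0])
        m, lo, hi = bland_altman_ratio(1.1 * b, b)
        assert (m, lo, hi) == pytest.approx((1.1, 1.1, 1.1))

    def test_six_pair_hand_computation(self):
        a = np.array([52.0, 48.0, 61.0, 40.0, 44.0, 55.0])
        b = np.array([50.0, 50.0, 58.0, 42.0, 43.0, 53.0])
        r = a / b
        mean = r.sum() / 6
        sd = np.sqrt(((r - mean) ** 2).sum() / 5)
        m, lo, hi = bland_altman_ratio(a, b)
        assert m == pytest.approx(mean, rel=1e-12)
        assert lo == pytest.approx(mean - 1.96 * sd, rel=1e-12)
        assert hi == pytest.approx(mean + 1.96 * sd, rel=1e-12)
        assert lo <= m <= hi

    def test_limits_cover_ratios(self, rng):
        b = rng.uniform(40, 60, 2000)
        a = b * rng.normal(1.05, 0.05, 2000)
        m, lo, hi = bland_altman_ratio(a, b)
        cover = np.mean((a / b >= lo) & (a / b <= hi))
        assert cover >= 0.90

    def test_positive_values_required(self):
        with pytest.raises(ValueError):
            bland_altman_ratio([1.0, -2.0, 1.0], [1.0, 1.0, 1.0])


class TestKsNormality:
    def test_rejection_rate_near_alpha(self, rng):
        # repeated normal samples: Lilliefors-style p rejects at ~alpha
        n_rep = 200
        rejections = 0
        for i in range(n_rep):
            x = rng.normal(3.0, 2.0, 30)
            if ks_normality(x, n_sim=400, seed=i) <= 0.05 :
                rejections += 1
        rate = rejections / n_rep
        assert 0.01 <= rate <= 0.10

    def test_heavy_tail_detected(self, rng):
        x = rng.standard_t(df=2, size=1000)
        assert ks_normality(x, seed=0) < 0.01

    def test_agrees_with_statsmodels_lilliefors(self, rng):
        from statsmodels.stats.diagnostic import lilliefors

        x = rng.normal(size=80) + 0.3 * rng.normal(size=80) ** 2
        p_sm = lilliefors(x, dist="norm", pvalmethod="table")[1]
        p = ks_normality(x, n_sim=2000, seed=1)
        assert p == pytest.approx(np.clip(p_sm, 0.001, 0.99), abs=0.08)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([5.0, 5.0, 5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])


class TestSummarize:
    def test_degenerate_cohort_all_null(self):
        regions = {"GM": 51.5, "WM": 40.9, "CSF": 102.1}
        values = {}
        for s in range(4):
            for visit in ("V1", "V2", "V3"):
                for region, conc in regions.items():
                    values[(f"s{s}", visit, region, "left")] = conc
                    values[(f"s{s}", visit, region, "right")] = conc
        report = summarize(make_measurements(values))
        assert report.r2["repeatability"] == pytest.approx(1.0)
        assert report.r2["reproducibility"] == pytest.approx(1.0)
        p_cols = [c for c in report.table.columns if c.startswith("p_")]
        assert (report.table[p_cols] == 1.0).all().all()
        assert (report.fluctuation["max_pct_diff"] == 0.0).all()
        assert (report.laterality["p"] == 1.0).all()

    def test_report_deterministic(self, default_cohort):
        m = measure_all(
            default_cohort, default_landmarks(default_cohort.config), seed=7
        )
        a = summarize(m, seed=1)
        b = summarize(m, seed=1)
        assert a.table.equals(b.table)
        assert a.to_flat_dict() == b.to_flat_dict()

    def test_recovers_configured_between_subject_sd(self, lib, phantom_config):
        # measurement table built from the truth of a 200-subject cohort
        cohort = simulate_cohort(
            200, seed=21, config=phantom_config, lib=lib, render=False
        )
        truth = cohort.truth[cohort.truth.region != "reference"]
        values = {}
        for row in truth.itertuples():
            side = row.side or "left"
            for visit in ("V1", "V2"):
                values[(row.subject, visit, row.region, side)] = row.true_conc
        report = summarize(make_measurements(values))
        for region, sd in phantom_config.between_subject_sd.items():
            got = report.table.loc[
                report.table.region == region, "v1_sd"
            ].item()
            se = sd / np.sqrt(2 * 199)
            assert abs(got - sd) < 3 * se, region

    def test_missing_visit_reported_as_gap(self):
        values = {}
        for s in range(5):
            for visit in ("V1", "V2"):
                values[(f"s{s}", visit, "GM", "left")] = 50.0 + s + (visit == "V2")
        report = summarize(make_measurements(values))
        row = report.table[report.table.region == "GM"].iloc[0]
        assert np.isnan(row["v3_mean"])
        assert np.isnan(row["p_v1_v3"])
        assert not np.isnan(row["p_v1_v2"])

    def test_inter_reader_statistics(self, rng):
        rows = []
        for s in range(10):
            base = 50.0 + rng.normal(0, 5)
            for visit in ("V1", "V2"):
                r1 = base + rng.normal(0, 1)
                r2 = 1.1 * base + rng.normal(0, 1)
                for reader, conc in (("r1", r1), ("r2", r2)):
                    rows.append(
                        dict(
                            subject=f"s{s}",
                            visit=visit,
                            reader=reader,
                            region="GM",
                            side="left",
                            mean_signal=conc,
                            concentration=conc,
                            n_voxels=12,
                        )
                    )
        report = summarize(pd.DataFrame(rows))
        assert report.inter_reader_rho["GM"] > 0.8
        m, lo, hi = report.bland_altman
        assert lo <= m <= hi
        assert m < 1.0  # reader 2 reads systematically higher
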