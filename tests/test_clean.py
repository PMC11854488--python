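"""Tests of the data-selection (cleaning) stage."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from hcgrowth import clean, synth

from conftest import with_age


class TestAgeComputation:
    @pytest.mark.parametrize(
        "birth,meas,expected",
        [
            ("2020-01-01", "2020-01-01", 0),
            ("2020-01-01", "2020-01-31", 30),
            ("2019-12-31", "2020-03-01", 61),  # spans the 2020 leap February
        ],
    )
    def test_calendar_day_difference(self, birth, meas, expected):
        assert clean.compute_age_days(birth, meas) == expected
        # cross-check against datetime arithmetic
        oracle = (dt.date.fromisoformat(meas) - dt.date.fromisoformat(birth)).days
        assert oracle == expected

    def test_measurement_before_birth_rejected(self):
        with pytest.raises(ValueError, match="precedes birth"):
            clean.compute_age_days("2020-05-01", "2020-04-30")
        s = pd.DataFrame(
            {"b": ["2020-01-01", "2020-06-01"], "m": ["2020-02-01", "2020-05-01"]}
        )
        with pytest.raises(ValueError, match="rows \\[1\\]"):
            clean.compute_age_days(s["b"], s["m"])


class TestUnits:
    @pytest.mark.parametrize("raw,unit,expected", [(47.0, "cm", 47.0), (470, "mm", 47.0)])
    def test_conversion(self, raw, unit, expected):
        assert clean.standardize_units(raw, unit) == expected

    @pytest.mark.parametrize("raw,unit", [(0, "cm"), (-3, "cm"), ("abc", "cm"), (47, "inch")])
    def test_invalid_inputs(self, raw, unit):
        with pytest.raises(ValueError):
            clean.standardize_units(raw, unit)


class TestHealthAndDuplicates:
    def _frame(self, flags):
        return pd.DataFrame({"hc_cm": np.arange(len(flags)) + 40.0, "health_flag": flags})

    def test_all_healthy(self):
        kept, removed = clean.filter_health(self._frame(["healthy"] * 4))
        assert len(kept) == 4 and removed.empty

    def test_excluded_conditions_removed(self):
        flags = ["healthy"] * 7 + ["excluded_condition"] * 3
        kept, removed = clean.filter_health(self._frame(flags))
        assert len(kept) == 7 and len(removed) == 3

    def test_missing_flag_conservatively_excluded(self):
        kept, removed = clean.filter_health(self._frame(["healthy", None, "healthy"]))
        assert len(kept) == 2 and len(removed) == 1

    def test_exact_duplicates_reduced_to_first(self):
        row = {"child_id": "C1", "measurement_date": "2020-01-01", "hc_cm": 40.0}
        df = pd.DataFrame([row, row, row])
        kept, removed = clean.deduplicate(df)
        assert len(kept) == 1 and len(removed) == 2
        assert kept.index[0] == 0

    def test_same_visit_different_hc_both_kept(self):
        df = pd.DataFrame(
            [
                {"child_id": "C1", "measurement_date": "2020-01-01", "hc_cm": 40.0},
                {"child_id": "C1", "measurement_date": "2020-01-01", "hc_cm": 41.0},
            ]
        )
        kept, removed = clean.deduplicate(df)
        assert len(kept) == 2 and removed.empty


class TestOutlierFlags:
    def test_strict_boundary_semantics(self):
        """z exactly +/-5 is retained; strictly beyond is removed.

        The reference uses binary-exact coefficients (M=40, S=1/16, L=1) so
        the z of each constructed measurement is float-exact: 52.5 -> +5,
        27.5 -> -5, 55.0 -> +6, 27.0 -> -5.2, 40.0 -> 0.
        """
        from hcgrowth.charts import ReferenceChart

        ref = ReferenceChart(
            data=pd.DataFrame(
                {
                    "sex": ["male", "male"],
                    "age_days": [0.0, 1800.0],
                    "L": [1.0, 1.0],
                    "M": [40.0, 40.0],
                    "S": [0.0625, 0.0625],
                }
            )
        )
        df = pd.DataFrame(
            {
                "sex": "male",
                "age_days": 600.0,
                "hc_cm": [52.5, 27.5, 55.0, 27.0, 40.0],
            }
        )
        zs = ref.zscore(df["hc_cm"].to_numpy(), df["age_days"].to_numpy(), "male")
        assert list(zs[[0, 1, 2, 4]]) == [5.0, -5.0, 6.0, 0.0]  # float-exact
        assert zs[3] == pytest.approx(-5.2)
        kept, removed = clean.flag_outliers(df, ref)
        assert set(removed.index) == {2, 3}  # only |z| strictly beyond 5
        assert len(kept) == 3

    def test_age_outside_coverage_is_an_error(self, reference):
        df = pd.DataFrame({"sex": ["male"], "age_days": [5000.0], "hc_cm": [50.0]})
        with pytest.raises(ValueError, match="coverage"):
            clean.flag_outliers(df, reference)

    def test_agrees_with_per_record_bruteforce(self, truth_pair, reference):
        """On a small cohort, vectorized flagging equals a per-record z
        computed by hand from the tabulated reference via interpolation."""
        cfg = synth.CohortConfig(n_children=50, visit_count_distribution={1: 1.0}, seed=13)
        df = with_age(synth.records_to_frame(synth.simulate_cohort(truth_pair, cfg)))
        # make some rows extreme so both dispositions occur
        df.loc[::7, "hc_cm"] = df.loc[::7, "hc_cm"] * 1.4
        kept, removed = clean.flag_outliers(df, reference)
        tab = reference.data
        removed_brute = []
        for i, row in df.iterrows():
            t = tab[tab["sex"] == row["sex"]]
            ages = t["age_days"].to_numpy()
            mu = np.interp(row["age_days"], ages, t["mu"])
            sg = np.interp(row["age_days"], ages, t["sigma"])
            nu = np.interp(row["age_days"], ages, t["nu"])
            z = ((row["hc_cm"] / mu) ** nu - 1.0) / (nu * sg)
            if z > 5.0 or z < -5.0:
                removed_brute.append(i)
        assert list(removed.index) == removed_brute
        assert len(kept) + len(removed) == len(df)


class TestBinning:
    @pytest.mark.parametrize("age,expected_bin", [(0, 0), (119, 0), (120, 1), (1799, 14), (1800, 14)])
    def test_half_open_bins_with_closing_day(self, age, expected_bin):
        df = pd.DataFrame({"sex": ["male"], "age_days": [age], "hc_cm": [45.0]})
        out = clean.bin_and_summarize(df)
        assert out.loc[0, "bin"] == expected_bin

    def test_bin_mean(self):
        df = pd.DataFrame(
            {"sex": ["male", "male"], "age_days": [10, 20], "hc_cm": [40.0, 42.0]}
        )
        out = clean.bin_and_summarize(df)
        assert out.loc[0, "n"] == 2
        assert out.loc[0, "mean_hc_cm"] == pytest.approx(41.0)


class TestRanksum:
    def test_separated_groups_exact(self):
        df = pd.DataFrame(
            {"sex": ["male"] * 3 + ["female"] * 3, "hc_cm": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}
        )
        u, p = clean.ranksum_sex_test(df)
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_not_significant(self):
        df = pd.DataFrame(
            {"sex": ["male"] * 3 + ["female"] * 3, "hc_cm": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}
        )
        _, p = clean.ranksum_sex_test(df)
        assert p >= 0.99

    def test_missing_sex_rejected(self):
        df = pd.DataFrame({"sex": ["male"] * 3, "hc_cm": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            clean.ranksum_sex_test(df)

    def test_statistic_in_range_large_sample(self, cohort_df):
        u, p = clean.ranksum_sex_test(cohort_df)
        n1 = int((cohort_df["sex"] == "male").sum())
        n2 = int((cohort_df["sex"] == "female").sum())
        assert 0.0 <= u <= n1 * n2
        assert 0.0 <= p <= 1.0

    def test_exact_branch_matches_independent_enumeration(self):
        """All (n1, n2) splits with combined n <= 8, several datasets each,
        against an enumeration oracle built from rank sums."""
        rng = np.random.default_rng(99)
        for n1, n2 in [(a, b) for a in range(1, 8) for b in range(1, 8) if a + b <= 8]:
            for rep in range(3):
                pooled = np.round(rng.normal(size=n1 + n2), 1)  # rounding makes ties
                x, y = pooled[:n1], pooled[n1:]
                df = pd.DataFrame(
                    {"sex": ["male"] * n1 + ["female"] * n2, "hc_cm": pooled}
                )
                u, p = clean.ranksum_sex_test(df)
                u_or, p_or = _oracle_exact(x, y)
                assert u == pytest.approx(u_or)
                assert p == pytest.approx(p_or)


def _oracle_exact(x, y):
    """Independent exact Mann-Whitney: U from midranks, p by enumerating
    index subsets."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = rankdata(pooled)

    def u_of(idx_set):
        r1 = ranks[list(idx_set)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    center = n1 * (n - n1) / 2.0
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_of(comb) - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return u_obs, hits / total


class TestPipeline:
    def test_dispositions_partition_input(self, truth_pair, reference):
        cfg = synth.CohortConfig(
            n_children=400, seed=21, duplicate_rate=0.03, outlier_rate=0.02,
            unhealthy_rate=0.05, max_abs_z=4.0,
        )
        recs = synth.simulate_cohort(truth_pair, cfg)
        recs, _ = synth.inject_artifacts(recs, cfg, truth_pair)
        df = synth.records_to_frame(recs)
        kept, report = clean.clean_pipeline(df, reference)
        assert report.total == len(df)
        assert report.retained == len(kept)

    def test_order_independence(self, truth_pair, reference):
        cfg = synth.CohortConfig(
            n_children=300, seed=8, duplicate_rate=0.02, outlier_rate=0.02, max_abs_z=4.0
        )
        recs = synth.simulate_cohort(truth_pair, cfg)
        recs, _ = synth.inject_artifacts(recs, cfg, truth_pair)
        df = synth.records_to_frame(recs)
        _, rep_a = clean.clean_pipeline(df, reference)
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        _, rep_b = clean.clean_pipeline(shuffled, reference)
        assert rep_a.counts() == rep_b.counts()
        pd.testing.assert_frame_equal(
            rep_a.bin_summary, rep_b.bin_summary, check_exact=False, atol=1e-9
        )

    def test_roundtrip_with_manifest(self, truth_pair, reference):
        """Truth confined to |z| < 4, artifacts at |z| = 8: cleaning removes
        exactly the manifest's artifacts."""
        cfg = synth.CohortConfig(
            n_children=500, visit_count_distribution={1: 1.0}, seed=31,
            duplicate_rate=0.02, outlier_rate=0.03, max_abs_z=4.0,
        )
        recs = synth.simulate_cohort(truth_pair, cfg)
        recs, manifest = synth.inject_artifacts(recs, cfg, truth_pair)
        kinds = list(manifest.values())
        _, report = clean.clean_pipeline(synth.records_to_frame(recs), reference)
        assert report.removed_duplicate == kinds.count("duplicate") == 10
        assert report.removed_outlier == kinds.count("outlier") == 15

    def test_report_yaml(self, tmp_path, truth_pair, reference):
        cfg = synth.CohortConfig(n_children=60, seed=3)
        df = synth.records_to_frame(synth.simulate_cohort(truth_pair, cfg))
        _, report = clean.clean_pipeline(df, reference)
        out = tmp_path / "report.yaml"
        report.to_yaml(out)
        assert "retained" in out.read_text()
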