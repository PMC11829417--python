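"""Pair matching, BH-FDR against a brute-force oracle, families, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striocomp.cohort_stats import (
    SubjectRecord,
    age_window_months,
    bh_fdr,
    match_pairs,
    paired_t,
    regression_harness,
    run_test_families,
)


def subject(sid, age, sex="M", race="White", study="s1", diagnosis="TD", css=None):
    return SubjectRecord(
        subject_id=sid, age_months=age, sex=sex, race_label=race,
        study_id=study, diagnosis=diagnosis, css=css,
    )


class TestAgeWindows:
    @pytest.mark.parametrize(
        "age, window",
        [(100, 12), (240, 12), (241, 24), (360, 24), (361, 48), (500, 48)],
    )
    def test_band_boundaries(self, age, window):
        assert age_window_months(age) == window


class TestMatchPairs:
    def test_sex_is_obligatory(self):
        subjects = [
            subject("case", 100, sex="M", diagnosis="ADOS-high"),
            subject("ctlM", 111, sex="M"),
            subject("ctlF", 100, sex="F"),
        ]
        pairs, unmatched = match_pairs(subjects)
        assert len(pairs) == 1
        assert pairs[0].control_id == "ctlM"
        assert "ctlF" in unmatched

    def test_window_excludes_30_month_gap_in_middle_band(self):
        subjects = [
            subject("case", 250, diagnosis="ADOS-mid"),
            subject("ctl", 280),
        ]
        pairs, unmatched = match_pairs(subjects)
        assert pairs == []
        assert set(unmatched) == {"case", "ctl"}

    def test_oldest_band_allows_40_month_gap(self):
        subjects = [
            subject("case", 400, diagnosis="ADOS-high"),
            subject("ctl", 440),
        ]
        pairs, _ = match_pairs(subjects)
        assert len(pairs) == 1
        assert pairs[0].age_gap_months == pytest.approx(40)

    def test_same_study_preferred_over_closer_age(self):
        subjects = [
            subject("case", 100, study="sA", diagnosis="ADOS-high"),
            subject("ctl_same_study", 108, study="sA"),
            subject("ctl_closer_age", 101, study="sB"),
        ]
        pairs, _ = match_pairs(subjects)
        assert pairs[0].control_id == "ctl_same_study"

    def test_race_breaks_age_ties(self):
        subjects = [
            subject("case", 100, race="Asian", diagnosis="ADOS-high"),
            subject("ctl_other_race", 104, race="White"),
            subject("ctl_same_race", 104, race="Asian"),
        ]
        pairs, _ = match_pairs(subjects)
        assert pairs[0].control_id == "ctl_same_race"

    def test_emitted_pairs_satisfy_constraints_and_uniqueness(self):
        rng = np.random.default_rng(0)
        subjects = []
        for i in range(120):
            subjects.append(
                subject(
                    f"s{i:03d}",
                    float(rng.integers(78, 500)),
                    sex=rng.choice(["M", "F"]),
                    race=rng.choice(["White", "Black", "Asian"]),
                    study=rng.choice(["s1", "s2", "s3"]),
                    diagnosis=rng.choice(["TD", "ADOS-mid", "ADOS-high"]),
                )
            )
        by_id = {s.subject_id: s for s in subjects}
        pairs, unmatched = match_pairs(subjects)
        used = [p.case_id for p in pairs] + [p.control_id for p in pairs]
        assert len(used) == len(set(used))
        assert len(used) + len(unmatched) == len(subjects)
        for p in pairs:
            case, ctl = by_id[p.case_id], by_id[p.control_id]
            assert case.sex == ctl.sex
            assert p.age_gap_months <= age_window_months(case.age_months)

    def test_deterministic_given_sorted_input(self):
        rng = np.random.default_rng(1)
        subjects = [
            subject(
                f"s{i}", float(rng.integers(80, 480)),
                sex=rng.choice(["M", "F"]),
                diagnosis=rng.choice(["TD", "ADOS-high"]),
            )
            for i in range(60)
        ]
        p1, _ = match_pairs(subjects)
        p2, _ = match_pairs(list(reversed(subjects)))
        assert [(p.case_id, p.control_id) for p in p1] == [
            (p.case_id, p.control_id) for p in p2
        ]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            match_pairs([subject("a", 100)])


def bh_oracle(p_values, q):
    """Exhaustive step-up: largest k over all ranks with p_(k) <= qk/m."""
    s = sorted(p_values)
    m = len(s)
    k_star = 0
    for k in range(1, m + 1):
        if s[k - 1] <= q * k / m:
            k_star = k
    if k_star == 0:
        return None, [False] * m
    thr = q * k_star / m
    return thr, [p <= thr for p in p_values]


class TestBhFdr:
    def test_rank1_critical_value_for_seven_tests(self):
        # only the smallest p passes -> threshold 0.05/7 ~ 7.1e-3
        thr, rej = bh_fdr([0.001, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95], q=0.05)
        assert thr == pytest.approx(7.1e-3, abs=2e-4)
        assert rej.sum() == 1

    def test_rank1_critical_value_for_ten_tests(self):
        thr, rej = bh_fdr([0.001] + [0.9] * 9, q=0.05)
        assert thr == pytest.approx(5.0e-3)
        assert rej.sum() == 1

    def test_step_up_promotes_larger_p(self):
        thr, rej = bh_fdr([0.001, 0.02, 0.03, 0.04, 0.06], q=0.05)
        assert thr == pytest.approx(0.04)
        assert rej.sum() == 4

    def test_no_rejections_reports_none(self):
        thr, rej = bh_fdr([0.5, 0.9], q=0.05)
        assert thr is None
        assert not rej.any()

    @given(
        st.lists(
            st.integers(0, 100).map(lambda i: i / 100.0), min_size=1, max_size=10
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_oracle_on_p_grid(self, p_values):
        thr, rej = bh_fdr(p_values, q=0.05)
        thr_o, rej_o = bh_oracle(p_values, q=0.05)
        assert (thr is None) == (thr_o is None)
        if thr is not None:
            assert thr == pytest.approx(thr_o)
        assert list(rej) == rej_o

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bh_fdr([], q=0.05)


class TestTestFamilies:
    def _measurements(self, n_pairs=10, delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        specs = {
            1: [f"volume_{i}" for i in range(12)],
            2: [f"top_bin_{i}" for i in range(5)],
            3: [f"bait_{i}" for i in range(10)],
            4: [f"zone_{i}" for i in range(10)],
        }
        for family, labels in specs.items():
            for label in labels:
                ctrl = rng.normal(100, 10, n_pairs)
                case = ctrl + delta + rng.normal(0, 1, n_pairs)
                for i in range(n_pairs):
                    rows.append(
                        {
                            "family": family,
                            "test_label": label,
                            "pair_id": f"p{i}",
                            "case": case[i],
                            "control": ctrl[i],
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_tables_reject_nothing(self, config):
        table = self._measurements()
        table["case"] = table["control"]
        families = run_test_families(table, config)
        assert set(families) == {1, 2, 3, 4}
        for fam in families.values():
            assert (fam.results["p_value"] >= 0.99).all()
            assert fam.rejections == []
            assert fam.threshold is None

    def test_family_two_holds_five_bin_tests(self, config):
        families = run_test_families(self._measurements(), config)
        assert len(families[2].results) == 5

    def test_large_shift_is_rejected_in_every_family(self, config):
        families = run_test_families(self._measurements(delta=30.0), config)
        for fam in families.values():
            assert len(fam.rejections) == len(fam.results)

    def test_single_pair_family_rejected(self, config):
        table = self._measurements(n_pairs=1)
        with pytest.raises(ValueError, match="<2 pairs"):
            run_test_families(table, config)

    def test_one_tailed_halves_p_in_observed_direction(self):
        rng = np.random.default_rng(5)
        ctrl = rng.normal(0, 1, 30)
        case = ctrl + 0.5
        _, p_two = paired_t(case, ctrl)
        _, p_one = paired_t(case, ctrl, one_tailed=True)
        assert p_one == pytest.approx(p_two / 2)


class TestRegression:
    def _table(self, n=300, coeff=0.373, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        striatal = rng.normal(900, 60, n)
        return pd.DataFrame(
            {
                "matrix_volume": coeff * striatal + rng.normal(0, sigma, n),
                "striatal_volume_voxels": striatal,
                "diagnosis": rng.choice(["TD", "ADOS-mid", "ADOS-high"], n),
                "study_id": rng.choice(["s1", "s2"], n),
                "hemisphere": rng.choice(["L", "R"], n),
                "sex": rng.choice(["M", "F"], n),
                "race_label": rng.choice(["White", "Black"], n),
            }
        )

    def test_constant_response_has_zero_slopes(self):
        table = self._table(coeff=0.0)
        table["matrix_volume"] = 42.0
        report = regression_harness(table)
        assert report["r_squared"] == pytest.approx(0.0, abs=1e-10)
        slopes = {k: v for k, v in report["coefficients"].items() if k != "Intercept"}
        assert all(abs(v) < 1e-8 for v in slopes.values())

    def test_recovers_injected_striatal_volume_coefficient(self):
        report = regression_harness(self._table(sigma=1e-8))
        assert report["coefficients"]["striatal_volume_voxels"] == pytest.approx(
            0.373, rel=1e-4
        )

    def test_null_css_effect_ci_covers_zero(self):
        rng = np.random.default_rng(3)
        table = self._table(sigma=20.0)
        table["css"] = np.clip(np.rint(rng.normal(7, 1.4, len(table))), 3, 10)
        report = regression_harness(table)
        lo, hi = report["css_model"]["conf_int"]
        assert lo < 0 < hi
        assert report["css_model"]["r_squared"] < 0.05
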