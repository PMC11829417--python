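"""Pair matching, family-wise paired testing with BH-FDR, and regressions.

Cases and controls are matched one-to-one under a criterion hierarchy:
sex is an obligatory match; the age gap must fall within an age-dependent
window (12 months for cases aged <= 240 months, 24 months for 241-360,
48 months above 360); among admissible controls the matcher prefers
same-study candidates, then the minimal age gap, then a race match, then
subject-id order.  The matcher is greedy over cases sorted by age and fully
deterministic.

Hypothesis tests are organized into four pre-declared families (compartment
volumetry; top-five histogram bins; per-bait-region extra-striate bias;
per-zone matrix-like volume), each corrected independently with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .io_core import AnalysisConfig

#: (upper age bound in months, matching window in months); boundary ages
#: belong to the younger band.
AGE_WINDOWS = ((240, 12), (360, 24), (np.inf, 48))


def age_window_months(age_months: float) -> int:
    """Maximum admissible |age gap| for a case of the given age."""
    if age_months <= 0:
        raise ValueError(f"age must be positive, got {age_months}")
    for bound, window in AGE_WINDOWS:
        if age_months <= bound:
            return window
    raise AssertionError("unreachable")


@dataclass
class SubjectRecord:
    subject_id: str
    age_months: float
    sex: str
    race_label: str
    study_id: str
    diagnosis: str  # TD | ADOS-mid | ADOS-high
    css: float | None = None  # calibrated severity score, ASD sub-cohort only
    striatal_volume_voxels: float | None = None

    def __post_init__(self) -> None:
        if self.age_months <= 0:
            raise ValueError(f"{self.subject_id}: age must be positive")
        if self.diagnosis not in ("TD", "ADOS-mid", "ADOS-high"):
            raise ValueError(f"{self.subject_id}: unknown diagnosis {self.diagnosis!r}")
        if self.diagnosis == "TD" and self.css is not None:
            raise ValueError(f"{self.subject_id}: CSS present for a TD subject")
        if self.css is not None and not (3 <= self.css <= 10):
            raise ValueError(f"{self.subject_id}: CSS {self.css} outside [3, 10]")

    @property
    def is_case(self) -> bool:
        return self.diagnosis != "TD"


@dataclass
class MatchedPair:
    case_id: str
    control_id: str
    age_gap_months: float
    same_study: bool
    same_race: bool


@dataclass
class TestFamily:
    """One family of paired tests with its BH correction."""

    family_id: int
    results: pd.DataFrame  # columns: test_label, p_value, effect
    q: float
    threshold: float | None = None  # q*k*/m; None when nothing rejected
    rejections: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pair matching
# ---------------------------------------------------------------------------


def match_pairs(
    subjects: list[SubjectRecord],
) -> tuple[list[MatchedPair], list[str]]:
    """Greedy deterministic case-control matching.

    Returns the matched pairs and the ids of unmatched subjects.  Criterion
    hierarchy: sex obligatory; age window by the case's age band; prefer
    intra-study candidates; among those minimize |age gap|; break ties by
    race match then control subject-id order.  When a cross-study pair is
    unavoidable, the matcher prefers controls from studies that have so far
    donated fewer controls to cross-study pairs than they have contributed
    cases, balancing the direction of cross-study borrowing.
    """
    cases = sorted((s for s in subjects if s.is_case), key=lambda s: (s.age_months, s.subject_id))
    controls = [s for s in subjects if not s.is_case]
    if not cases or not controls:
        raise ValueError("both cohorts must be nonempty")
    available: dict[str, SubjectRecord] = {c.subject_id: c for c in controls}
    # net cross-study borrowing per study: +1 when a study's case was matched
    # across studies, -1 when the study donated a control across studies
    cross_balance: dict[str, int] = {}
    pairs: list[MatchedPair] = []

    for case in cases:
        window = age_window_months(case.age_months)
        candidates = [
            c
            for c in available.values()
            if c.sex == case.sex and abs(c.age_months - case.age_months) <= window
        ]
        if not candidates:
            continue
        intra = [c for c in candidates if c.study_id == case.study_id]
        pool = intra if intra else candidates

        def sort_key(c: SubjectRecord):
            gap = abs(c.age_months - case.age_months)
            race_mismatch = 0 if c.race_label == case.race_label else 1
            if intra:
                balance = 0
            else:
                # prefer donors whose study owes controls (positive balance)
                balance = -cross_balance.get(c.study_id, 0)
            return (gap, balance, race_mismatch, c.subject_id)

        chosen = min(pool, key=sort_key)
        del available[chosen.subject_id]
        if chosen.study_id != case.study_id:
            cross_balance[case.study_id] = cross_balance.get(case.study_id, 0) + 1
            cross_balance[chosen.study_id] = cross_balance.get(chosen.study_id, 0) - 1
        pairs.append(
            MatchedPair(
                case_id=case.subject_id,
                control_id=chosen.subject_id,
                age_gap_months=abs(chosen.age_months - case.age_months),
                same_study=chosen.study_id == case.study_id,
                same_race=chosen.race_label == case.race_label,
            )
        )

    matched_ids = {p.case_id for p in pairs} | {p.control_id for p in pairs}
    unmatched = sorted(s.subject_id for s in subjects if s.subject_id not in matched_ids)
    return pairs, unmatched


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_fdr(p_values, q: float = 0.05) -> tuple[float | None, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(threshold, rejections)`` where ``threshold = q * k / m`` for
    the largest rank k with ``p_(k) <= q * k / m``, and ``rejections`` flags
    the hypotheses with ``p <= threshold``.  With zero rejections the
    threshold is reported as ``None`` ("none"), never as ``q/m``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ranks = np.arange(1, m + 1)
    passing = sorted_p <= q * ranks / m
    if not passing.any():
        return None, np.zeros(m, dtype=bool)
    k_star = int(ranks[passing].max())
    threshold = q * k_star / m
    return threshold, p <= threshold


# ---------------------------------------------------------------------------
# test families
# ---------------------------------------------------------------------------


def paired_t(case: np.ndarray, control: np.ndarray, one_tailed: bool = False) -> tuple[float, float]:
    """Two-tailed (default) paired t-test; returns (t, p).

    Identical samples give t = 0, p = 1 rather than NaN.  The one-tailed
    variant halves the p-value in the direction of the observed mean
    difference (used for the caudate/putamen follow-up contrasts).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.shape != control.shape:
        raise ValueError("paired samples differ in length")
    if case.size < 2:
        raise ValueError("paired test needs at least 2 pairs")
    diffs = case - control
    if np.allclose(diffs, diffs[0]) and np.isclose(diffs[0], 0):
        return 0.0, 1.0
    res = stats.ttest_rel(case, control)
    t, p = float(res.statistic), float(res.pvalue)
    if one_tailed:
        p = p / 2 if t > 0 else 1 - p / 2
    return t, p


def run_test_families(
    measurements: pd.DataFrame, config: AnalysisConfig
) -> dict[int, TestFamily]:
    """Run the four pre-declared families of paired tests with BH per family.

    ``measurements`` is long-form with columns
    ``family (1-4), test_label, pair_id, case, control`` and optionally
    ``one_tailed`` (bool, default False).  Family membership is declared by
    the caller (config-driven), not hard-coded, because the exact contrast
    roster per family is an experimental-design choice.
    """
    required = {"family", "test_label", "pair_id", "case", "control"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    families: dict[int, TestFamily] = {}
    for fam_id, fam in measurements.groupby("family", sort=True):
        rows = []
        for label, sub in fam.groupby("test_label", sort=True):
            if len(sub) < 2:
                raise ValueError(f"family {fam_id} test {label!r} has <2 pairs")
            one_tailed = bool(sub["one_tailed"].iloc[0]) if "one_tailed" in sub else False
            t, p = paired_t(
                sub["case"].to_numpy(), sub["control"].to_numpy(), one_tailed=one_tailed
            )
            rows.append(
                {
                    "test_label": label,
                    "t_statistic": t,
                    "p_value": p,
                    "effect": float((sub["case"] - sub["control"]).mean()),
                    "n_pairs": len(sub),
                }
            )
        table = pd.DataFrame(rows)
        threshold, reject = bh_fdr(table["p_value"].to_numpy(), q=config.fdr_q)
        families[int(fam_id)] = TestFamily(
            family_id=int(fam_id),
            results=table.assign(rejected=reject),
            q=config.fdr_q,
            threshold=threshold,
            rejections=sorted(table.loc[reject, "test_label"]),
        )
    return families


# ---------------------------------------------------------------------------
# regression harness
# ---------------------------------------------------------------------------


def regression_harness(
    table: pd.DataFrame,
    response: str = "matrix_volume",
    alpha: float = 0.05,
) -> dict:
    """Multiple linear regression of matrix-like volume on cohort covariates.

    Primary model: response ~ diagnosis + study + hemisphere + striatal
    volume + sex + race (age excluded for collinearity with striatal
    volume).  A secondary model refits only the covariates significant in
    the primary model plus their pairwise interactions.  When a ``css``
    column is present, a separate simple regression of the response on CSS
    is run for the severity sub-cohort.  Rank deficiency is reported, never
    silently dropped.
    """
    candidates = [
        c
        for c in ("diagnosis", "study_id", "hemisphere", "striatal_volume_voxels", "sex", "race_label")
        if c in table.columns
    ]
    if not candidates:
        raise ValueError("no candidate covariates present in the table")
    categorical = {"diagnosis", "study_id", "hemisphere", "sex", "race_label"}

    def term(c: str) -> str:
        return f"C({c})" if c in categorical else c

    formula = f"{response} ~ " + " + ".join(term(c) for c in candidates)
    model = smf.ols(formula, data=table).fit()
    r_squared = float(model.rsquared)
    if not np.isfinite(r_squared):  # constant response: zero total variance
        r_squared = 0.0
    design_rank = np.linalg.matrix_rank(model.model.exog)
    report = {
        "formula": formula,
        "coefficients": model.params.to_dict(),
        "t_statistics": model.tvalues.to_dict(),
        "p_values": model.pvalues.to_dict(),
        "conf_int": {k: list(v) for k, v in model.conf_int(alpha).iterrows()},
        "r_squared": r_squared,
        "rank_deficient": bool(design_rank < model.model.exog.shape[1]),
        "model": model,
    }

    # secondary model: significant covariates + interactions
    sig = [
        c
        for c in candidates
        if any(
            name == c or name.startswith(f"C({c})")
            for name, p in model.pvalues.items()
            if name != "Intercept" and p < alpha
        )
    ]
    if len(sig) >= 2:
        inter = f"{response} ~ (" + " + ".join(term(c) for c in sig) + ") ** 2"
        report["secondary"] = smf.ols(inter, data=table).fit()
    elif sig:
        report["secondary"] = smf.ols(
            f"{response} ~ {term(sig[0])}", data=table
        ).fit()
    else:
        report["secondary"] = None

    if "css" in table.columns and table["css"].notna().any():
        sub = table.dropna(subset=["css"])
        css_model = smf.ols(f"{response} ~ css", data=sub).fit()
        report["css_model"] = {
            "coefficient": float(css_model.params["css"]),
            "conf_int": list(css_model.conf_int(alpha).loc["css"]),
            "r_squared": float(css_model.rsquared),
            "p_value": float(css_model.pvalues["css"]),
            "model": css_model,
        }
    return report
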