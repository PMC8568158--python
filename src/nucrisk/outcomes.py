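"""Cohort description and survival analysis.

Descriptive comparisons between nodal groups use Pearson chi-square (no
continuity correction) for categorical variables and the Wilcoxon rank-sum
test for continuous ones.  Time-to-event endpoints — time to regional
recurrence (RR) and disease-specific survival (DSS) — are analyzed with the
Kaplan–Meier product-limit estimator and the log-rank test.  Because nodal
status is not fixed at surgery, DSS between nodal groups uses a 2-year
landmark: only patients alive and in follow-up at the landmark enter the
comparison (time origin stays at surgery).  RR-free comparison between
*predicted* risk groups (fixed at surgery) is done without the landmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

LANDMARK_YEARS = 2.0


# ---------------------------------------------------------------------------
# descriptive table


def _fmt_pct(n: int, total: int) -> str:
    return f"{n} ({100.0 * n / total:.1f})" if total else "0"


def cohort_table(
    patients: pd.DataFrame,
    variables: dict[str, str],
    group_col: str = "ln_status",
) -> pd.DataFrame:
    """Descriptive table by nodal group.

    ``variables`` maps column name -> "categorical" | "continuous".
    Categorical: per-level counts (percent) and a Pearson chi-square test
    without continuity correction.  Continuous: mean (SD), median (Q1, Q3)
    and a Wilcoxon rank-sum test.  Single-level variables are reported with
    the test skipped."""
    groups = sorted(patients[group_col].dropna().unique())
    rows = []
    for var, kind in variables.items():
        if kind == "categorical":
            tab = pd.crosstab(patients[var], patients[group_col])
            if tab.shape[0] < 2:
                p = np.nan
                note = "single level; test skipped"
            else:
                chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
                note = ""
            rows.append({"variable": var, "level": "", "test": "chi-square", "p": p, "note": note,
                         **{g: "" for g in groups}})
            totals = tab.sum(axis=0)
            for level in tab.index:
                rows.append({
                    "variable": var, "level": str(level), "test": "", "p": np.nan, "note": "",
                    **{g: _fmt_pct(int(tab.loc[level, g]), int(totals[g])) for g in groups},
                })
        elif kind == "continuous":
            arms = [patients.loc[patients[group_col] == g, var].dropna() for g in groups]
            if len(arms) == 2 and all(len(a) for a in arms):
                p = stats.mannwhitneyu(arms[0], arms[1], alternative="two-sided").pvalue
            else:
                p = np.nan
            rows.append({"variable": var, "level": "", "test": "rank-sum", "p": p, "note": "",
                         **{g: "" for g in groups}})
            rows.append({
                "variable": var, "level": "mean (SD)", "test": "", "p": np.nan, "note": "",
                **{g: f"{a.mean():.1f} ({a.std(ddof=1):.1f})" for g, a in zip(groups, arms)},
            })
            rows.append({
                "variable": var, "level": "median (Q1, Q3)", "test": "", "p": np.nan, "note": "",
                **{g: f"{a.median():.1f} ({a.quantile(.25):.1f}, {a.quantile(.75):.1f})"
                   for g, a in zip(groups, arms)},
            })
        else:
            raise ValueError(f"variable kind must be categorical/continuous, got {kind!r}")
    return pd.DataFrame(rows)


def chi_square_p(table: np.ndarray) -> float:
    """Pearson chi-square p-value on a contingency table, no continuity
    correction (the convention that reproduces printed cohort tables)."""
    return float(stats.chi2_contingency(np.asarray(table), correction=False)[1])


# ---------------------------------------------------------------------------
# survival


def _check_records(records: pd.DataFrame) -> None:
    if len(records) == 0:
        raise ValueError("empty survival input")
    if (records["time"] < 0).any():
        raise ValueError("negative survival times")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve with right censoring.

    Returns a step table (time, survival, n_at_risk); survival is 1 before
    the first event."""
    _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    table = kmf.event_table
    surv = kmf.survival_function_
    out = pd.DataFrame({
        "time": surv.index.to_numpy(dtype=float),
        "survival": surv.iloc[:, 0].to_numpy(),
        "n_at_risk": table["at_risk"].to_numpy(dtype=float),
    })
    return out


def km_survival_at(records: pd.DataFrame, t: float) -> float:
    curve = km_estimate(records)
    past = curve[curve["time"] <= t]
    return float(past["survival"].iloc[-1]) if len(past) else 1.0


def logrank_test(records: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across >= 2 groups."""
    _check_records(records)
    if records[group_col].nunique() < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if records["event"].sum() == 0:
        raise ValueError("log-rank needs >= 1 event")
    res = multivariate_logrank_test(records["time"], records[group_col], records["event"])
    return float(res.test_statistic), float(res.p_value)


def landmark_filter(records: pd.DataFrame, landmark: float = LANDMARK_YEARS) -> pd.DataFrame:
    """Landmark conditioning: keep patients alive and in follow-up at the
    landmark (observation time ≥ landmark); time origin stays at surgery and
    group labels are frozen at the landmark."""
    if landmark < 0:
        raise ValueError("landmark must be >= 0")
    out = records[records["time"] >= landmark].copy()
    if len(out) == 0:
        raise ValueError("empty landmark cohort")
    return out


def landmark_dss_analysis(records: pd.DataFrame, landmark: float = LANDMARK_YEARS) -> dict:
    """2-year-landmark DSS comparison between nodal groups."""
    filtered = landmark_filter(records, landmark)
    stat, p = logrank_test(filtered)
    curves = {g: km_estimate(grp) for g, grp in filtered.groupby("group")}
    return {"statistic": stat, "p": p, "n": len(filtered),
            "n_events": int(filtered["event"].sum()), "curves": curves}


def rr_free_analysis(records: pd.DataFrame, risk_groups: pd.DataFrame) -> dict:
    """RR-free Kaplan–Meier + log-rank by *predicted* risk group, no landmark.

    ``risk_groups`` carries patient_id and risk_group (and optionally a
    ``partition`` column: results are then reported per partition, training
    and test separately)."""
    merged = records.merge(risk_groups, on="patient_id", how="inner")
    results = {}
    partitions = (
        merged.groupby("partition") if "partition" in merged.columns else [("all", merged)]
    )
    for name, part in partitions:
        counts = part["risk_group"].value_counts()
        if (counts == 0).any() or len(counts) < 2:
            raise ValueError(f"partition {name}: need both risk groups populated")
        stat, p = logrank_test(part, group_col="risk_group")
        results[name] = {
            "statistic": stat, "p": p,
            "n": len(part), "n_events": int(part["event"].sum()),
            "curves": {g: km_estimate(grp) for g, grp in part.groupby("risk_group")},
        }
    return results
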