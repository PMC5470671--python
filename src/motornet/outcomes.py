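"""Clinical outcome labeling and cohort statistics.

A patient has a favorable rehabilitation outcome when the improvement
on any scale reaches 10% of that scale's maximum: 6.6 points on the
Fugl-Meyer Assessment (max 66), 7.5 on the Wolf Motor Function Test, or
16.2 on the TEMPA (negative-scored, so improvement is post - pre on
both scales).  The shipped clinical table carries the study labels as
printed; re-derived labels that disagree are reported as discrepancies,
never overwritten.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutcomeRule", "load_table1", "label_outcome", "label_table",
    "label_discrepancies", "cohort_stats", "improvement_summary",
    "subgroup_accuracy", "anova_features", "spectral_difference",
]

SCALES = ("fma", "tempa", "wmft")


@dataclass(frozen=True)
class OutcomeRule:
    """Improvement thresholds, each 10% of the scale maximum."""

    fma: float = 6.6
    wmft: float = 7.5
    tempa: float = 16.2

    def __post_init__(self) -> None:
        if min(self.fma, self.wmft, self.tempa) <= 0:
            raise ValueError("thresholds must be positive")

    def threshold(self, scale: str) -> float:
        return getattr(self, scale)


def load_table1() -> pd.DataFrame:
    """The packaged clinical table (37 training + 16 validation rows)."""
    with resources.files("motornet.data").joinpath("table1.csv").open() as f:
        df = pd.read_csv(f, dtype={"prediction": "string"})
    return df


def label_outcome(rec, rule: OutcomeRule = OutcomeRule()) -> str:
    """'F' (favorable) if any scale improvement reaches its threshold.

    Comparisons use >= : reaching the 10% level counts.  ``rec`` is a
    mapping or Series with ``{scale}_pre`` / ``{scale}_post`` entries.
    """
    deltas = {}
    for s in SCALES:
        pre, post = rec[f"{s}_pre"], rec[f"{s}_post"]
        if pre is None or post is None or (
            isinstance(pre, float) and np.isnan(pre)
        ) or (isinstance(post, float) and np.isnan(post)):
            raise ValueError(f"missing {s} score; cannot label outcome")
        deltas[s] = post - pre
    return "F" if any(deltas[s] >= rule.threshold(s) for s in SCALES) else "P"


def label_table(df: pd.DataFrame, rule: OutcomeRule = OutcomeRule()) -> pd.Series:
    """Re-derived outcome label per row."""
    return df.apply(lambda r: label_outcome(r, rule), axis=1)


def label_discrepancies(df: pd.DataFrame, rule: OutcomeRule = OutcomeRule()) -> pd.DataFrame:
    """Rows whose printed label disagrees with the re-applied rule.

    The printed label stays authoritative; this reports, per mismatch,
    the improvements and the derived label.
    """
    derived = label_table(df, rule)
    bad = df["true_condition"] != derived
    out = df.loc[bad, ["dataset", "id", "true_condition"]].copy()
    out["derived_condition"] = derived[bad]
    for s in SCALES:
        out[f"{s}_delta"] = df.loc[bad, f"{s}_post"] - df.loc[bad, f"{s}_pre"]
    return out.reset_index(drop=True)


_NUMERIC_VARS = [
    "age", "time_poststroke", "brunnstrom_proximal", "brunnstrom_distal",
    "fma_pre", "tempa_pre", "wmft_pre",
]
_CATEGORICAL_VARS = [
    "gender", "affected_hemisphere", "lesion_level", "stroke_type", "hand_dominance",
]


def _two_sample_tests(a: np.ndarray, b: np.ndarray) -> dict:
    pooled = stats.ttest_ind(a, b, equal_var=True)
    welch = stats.ttest_ind(a, b, equal_var=False)
    return {
        "t_pooled": float(pooled.statistic),
        "p_pooled_two_tailed": float(pooled.pvalue),
        "p_pooled_one_tailed": float(pooled.pvalue / 2.0),
        "t_welch": float(welch.statistic),
        "p_welch_two_tailed": float(welch.pvalue),
        "p_welch_one_tailed": float(welch.pvalue / 2.0),
    }


def cohort_stats(
    table: pd.DataFrame,
    grouping: str,
    numeric_vars=None,
    categorical_vars=None,
    include_improvements: bool = True,
) -> dict:
    """Group means, SDs and two-sample t-tests per clinical variable.

    Splits ``table`` by the two levels of ``grouping``; numeric
    variables get group mean/SD plus pooled and Welch t-tests (one- and
    two-tailed p both reported, since tail conventions vary);
    categorical variables get per-level counts.  Groups with fewer than
    2 rows skip the variable with a note.
    """
    levels = list(pd.unique(table[grouping]))
    if len(levels) != 2:
        raise ValueError(f"grouping column {grouping!r} must have two levels")
    ga = table[table[grouping] == levels[0]]
    gb = table[table[grouping] == levels[1]]
    numeric = list(numeric_vars) if numeric_vars is not None else list(_NUMERIC_VARS)
    if include_improvements:
        numeric += [f"{s}_improvement" for s in SCALES]
    work = table.copy()
    for s in SCALES:
        work[f"{s}_improvement"] = work[f"{s}_post"] - work[f"{s}_pre"]
    ga, gb = work[work[grouping] == levels[0]], work[work[grouping] == levels[1]]

    report: dict = {"grouping": grouping, "levels": levels,
                    "n": {str(levels[0]): len(ga), str(levels[1]): len(gb)},
                    "numeric": {}, "categorical": {}, "skipped": []}
    for var in numeric:
        if var not in work.columns:
            report["skipped"].append({"variable": var, "reason": "missing column"})
            continue
        a, b = ga[var].dropna().to_numpy(float), gb[var].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            report["skipped"].append({"variable": var, "reason": "group with n < 2"})
            continue
        entry = {
            str(levels[0]): {"mean": float(a.mean()), "sd": float(a.std(ddof=1)), "n": len(a)},
            str(levels[1]): {"mean": float(b.mean()), "sd": float(b.std(ddof=1)), "n": len(b)},
        }
        entry.update(_two_sample_tests(a, b))
        report["numeric"][var] = entry
    cats = list(categorical_vars) if categorical_vars is not None else list(_CATEGORICAL_VARS)
    for var in cats:
        if var not in work.columns:
            continue
        report["categorical"][var] = {
            str(levels[0]): ga[var].value_counts().to_dict(),
            str(levels[1]): gb[var].value_counts().to_dict(),
        }
    return report


def improvement_summary(
    table: pd.DataFrame,
    scale: str,
    dataset: str | None = None,
    condition: str | None = None,
) -> tuple[float, float, int]:
    """Mean and SD of post - pre improvement over the selected rows."""
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}")
    sel = table
    if dataset is not None:
        sel = sel[sel["dataset"] == dataset]
    if condition is not None:
        sel = sel[sel["true_condition"] == condition]
    if len(sel) == 0:
        raise ValueError("empty selection")
    delta = (sel[f"{scale}_post"] - sel[f"{scale}_pre"]).to_numpy(float)
    sd = float(delta.std(ddof=1)) if delta.size > 1 else 0.0
    return float(delta.mean()), sd, int(delta.size)


def subgroup_accuracy(
    table: pd.DataFrame,
    variable: str,
    bins: list[tuple],
    prediction_col: str = "prediction",
    truth_col: str = "true_condition",
) -> pd.DataFrame:
    """Prediction accuracy within bins of a clinical variable.

    ``bins`` is a list of (label, low, high) with inclusive bounds
    (use -inf/inf for open ends) or, for a categorical variable,
    (label, value).  Empty bins are reported with n = 0.
    """
    rows = []
    have = table.dropna(subset=[prediction_col])
    for spec in bins:
        if len(spec) == 3:
            label, lo, hi = spec
            sel = have[(have[variable] >= lo) & (have[variable] <= hi)]
        else:
            label, value = spec
            sel = have[have[variable] == value]
        n = len(sel)
        correct = int((sel[prediction_col] == sel[truth_col]).sum()) if n else 0
        rows.append({
            "bin": label, "n": n, "n_correct": correct,
            "accuracy_%": 100.0 * correct / n if n else np.nan,
        })
    return pd.DataFrame(rows)


def anova_features(
    features: pd.DataFrame,
    labels,
    correction: str | None = None,
) -> pd.DataFrame:
    """One-way ANOVA per feature across the two outcome groups.

    No multiple-testing correction by default; pass
    ``correction='fdr_bh'`` (or any statsmodels method name) to adjust.
    Features with zero within-group variance get NaN p with a flag.
    """
    y = np.asarray(labels)
    groups = pd.unique(y)
    if len(groups) != 2 or min((y == g).sum() for g in groups) < 2:
        raise ValueError("need two groups with >= 2 members each")
    rows = []
    for col in features.columns:
        a = features.loc[y == groups[0], col].to_numpy(float)
        b = features.loc[y == groups[1], col].to_numpy(float)
        if a.var() == 0 and b.var() == 0:
            rows.append({"feature": col, "F": np.nan, "p": np.nan, "degenerate": True})
            continue
        f, p = stats.f_oneway(a, b)
        rows.append({"feature": col, "F": float(f), "p": float(p), "degenerate": False})
    out = pd.DataFrame(rows)
    if correction is not None:
        from statsmodels.stats.multitest import multipletests
        ok = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method=correction)[1]
        out["p_adjusted"] = adj
    return out


def spectral_difference(specs_a, specs_b) -> dict:
    """Mean spectral difference between two sources across subjects.

    For each subject the difference of the two sources' spectrograms is
    averaged over frequency and time and expressed as a percentage of
    the subjects' mean power magnitude; a paired t-test across subjects
    tests whether the difference is systematic.  ``specs_a`` / ``specs_b``
    are per-subject (frequencies x time) power arrays for the two
    sources.
    """
    if len(specs_a) != len(specs_b) or len(specs_a) == 0:
        raise ValueError("need matched per-subject spectrogram lists")
    msd = []
    for a, b in zip(specs_a, specs_b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        denom = np.mean(np.abs((a + b) / 2.0))
        if denom < 1e-12:
            raise ZeroDivisionError("mean power is zero; percentage undefined")
        msd.append(100.0 * np.mean(a - b) / denom)
    msd = np.asarray(msd)
    if msd.size < 2:
        return {"msd_percent": float(msd.mean()), "t": None, "p": None,
                "per_subject": msd}
    t, p = stats.ttest_1samp(msd, 0.0)
    return {"msd_percent": float(msd.mean()), "t": float(t), "p": float(p),
            "per_subject": msd}
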