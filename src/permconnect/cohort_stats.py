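"""Cohort-level descriptive and inferential statistics.

Group comparisons of phenotype variables: one-way ANOVA for continuous
measures, Pearson chi-square (no continuity correction) for categorical ones,
ANCOVA group F-tests controlling for age and vascular-risk-factor count, the
Trail Making Test difference score, and reclassification bookkeeping for the
clinical-diagnosis x MRI-finding table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "pearson_chi_square",
    "one_way_anova",
    "ancova_group_effect",
    "tmt_difference",
    "reclassification_totals",
    "group_summary_table",
]


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table, no Yates correction.

    Returns (chi2, df, p).  Rejects tables with a zero row or column margin
    (expected counts undefined).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(obs < 0) or obs.sum() == 0:
        raise ValueError("counts must be nonnegative with positive total")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way between-groups ANOVA; returns (F, df_between, df_within, p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(a.std() == 0 for a in arrays):
        raise ValueError("zero within-group variance everywhere")
    F, p = stats.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)
    return float(F), df1, df2, float(p)


def ancova_group_effect(
    score: np.ndarray,
    group,
    covariates: pd.DataFrame | np.ndarray,
) -> tuple[float, float]:
    """Group F-test with covariates held in the model.

    Compares the least-squares fit of ``score ~ covariates + group`` against
    ``score ~ covariates`` (Type-III-style single-factor comparison).
    Exactly collinear covariate columns are pruned with a warning.
    Returns (F_group, p).
    """
    y = np.asarray(score, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("score is constant across subjects")
    C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else (
        np.asarray(covariates, dtype=float)
    )
    if C.ndim == 1:
        C = C[:, None]
    if np.isnan(C).any() or np.isnan(y).any():
        raise ValueError("missing values in score or covariates")
    # prune exactly dependent covariate columns, in input order
    keep: list[int] = []
    X = np.ones((y.size, 1))
    for j in range(C.shape[1]):
        trial = np.column_stack([X, C[:, j]])
        if np.linalg.matrix_rank(trial) > X.shape[1]:
            keep.append(j)
            X = trial
    if len(keep) < C.shape[1]:
        warnings.warn(f"dropping {C.shape[1] - len(keep)} collinear covariate(s)",
                      stacklevel=2)
    dummies = pd.get_dummies(pd.Series(np.asarray(group)), drop_first=True).to_numpy(float)
    reduced = sm.OLS(y, X).fit()
    full = sm.OLS(y, np.column_stack([X, dummies])).fit()
    F, p, _ = full.compare_f_test(reduced)
    return float(F), float(p)


def tmt_difference(part_a_seconds: float, part_b_seconds: float) -> float:
    """Trail Making Test difference score: Part B time minus Part A time.

    Higher values indicate poorer set-shifting performance.
    """
    a = np.asarray(part_a_seconds, dtype=float)
    b = np.asarray(part_b_seconds, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("completion times must be > 0")
    out = b - a
    return float(out) if out.ndim == 0 else out


def reclassification_totals(matrix) -> tuple[int, int]:
    """Final group sizes from a clinical-diagnosis x MRI-finding count table.

    Rows are the prior clinical diagnoses, columns the MRI outcome
    (infarct, no infarct); returns the column sums
    (n_minor_stroke_final, n_tia_final).
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[1] != 2 or np.any(m < 0):
        raise ValueError("expected an r x 2 table of nonnegative counts")
    infarct, no_infarct = m.sum(axis=0)
    return int(infarct), int(no_infarct)


def group_summary_table(
    phenotypes: pd.DataFrame,
    score_columns: list[str] | None = None,
    covariate_columns: tuple[str, str] = ("age", "vrf_count"),
) -> pd.DataFrame:
    """Per-group mean +/- SD with ANOVA and ANCOVA tests for each score.

    One row per continuous variable: group means and SDs, the one-way ANOVA
    F/p over the three groups, and the ANCOVA group F/p controlling for age
    and vascular-risk-factor count.
    """
    if score_columns is None:
        reserved = {"subject_id", "group", *covariate_columns}
        score_columns = [
            c for c in phenotypes.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(phenotypes[c])
        ]
    groups = list(pd.unique(phenotypes["group"]))
    rows = []
    covs = phenotypes[list(covariate_columns)]
    for col in [*covariate_columns, *score_columns]:
        vals = [phenotypes.loc[phenotypes["group"] == g, col].to_numpy(float)
                for g in groups]
        row: dict[str, object] = {"variable": col}
        for g, v in zip(groups, vals):
            row[f"{g}_mean"] = v.mean()
            row[f"{g}_sd"] = v.std(ddof=1)
        try:
            F, df1, df2, p = one_way_anova(vals)
            row.update(anova_F=F, anova_df1=df1, anova_df2=df2, anova_p=p)
        except ValueError:
            row.update(anova_F=np.nan, anova_df1=np.nan, anova_df2=np.nan, anova_p=np.nan)
        if col not in covariate_columns:
            try:
                F, p = ancova_group_effect(
                    phenotypes[col].to_numpy(float), phenotypes["group"], covs
                )
                row.update(ancova_F=F, ancova_p=p)
            except ValueError:
                row.update(ancova_F=np.nan, ancova_p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
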