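"""Group-level statistics for SN measurements.

Implements the study's statistical program on a tidy subject-visit table:

* demographics tests (pooled-variance t test, Pearson chi-square on sex
  proportions) and a Shapiro–Wilk normality gate;
* cross-sectional factorial ANOVA (group x sex with age as a covariate,
  Type-III sums of squares with sum-to-zero coding);
* longitudinal mixed-design ANOVA with visit as the within-subject factor,
  computed by the exact split-plot decomposition for a 2-level within
  factor: between-subject terms are tested on subject means, visit and its
  interactions on the V2 - V1 differences;
* one-way scanner-effect ANOVA on healthy-volunteer baselines;
* ROC diagnostics (empirical AUC, ties at 0.5);
* Pearson correlations between SN measures and clinical scores with a
  max-|r| multivariate permutation correction for the measurement family.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.anova import anova_lm

__all__ = [
    "chi_square_proportions",
    "two_sample_t",
    "normality_gate",
    "cross_sectional_model",
    "longitudinal_model",
    "scanner_effect",
    "roc_auc",
    "ROCResult",
    "correlation_with_permutation",
]

ALPHA = 0.05


def chi_square_proportions(counts) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("cell counts must be nonnegative")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("both margins must be positive")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def two_sample_t(values_a, values_b) -> tuple[float, float]:
    """Two-sided Student t test with pooled variance."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def normality_gate(values, alpha_gate: float = ALPHA) -> tuple[float, float, bool]:
    """Shapiro–Wilk test; ``parametric_ok`` is True when p > ``alpha_gate``."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro–Wilk needs 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p), bool(p > alpha_gate)


def _check_full_rank(model) -> None:
    exog = model.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        # name which design columns are aliased
        _, r = np.linalg.qr(exog)
        aliased = [
            model.model.exog_names[j]
            for j in range(exog.shape[1])
            if abs(r[j, j]) < 1e-8
        ]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def _type3_table(df: pd.DataFrame, formula: str) -> pd.DataFrame:
    fit = smf.ols(formula, data=df).fit()
    _check_full_rank(fit)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(fit, typ=3)
    return table


_TERM_CLEANUP = {
    "C(group, Sum)": "group",
    "C(sex, Sum)": "sex",
    "C(group, Sum):C(sex, Sum)": "group:sex",
    "age_c": "age",
}


def _tidy(table: pd.DataFrame, rename: dict[str, str], direction: dict[str, float]) -> pd.DataFrame:
    df_den = float(table.loc["Residual", "df"])
    rows = []
    for raw, term in rename.items():
        if raw not in table.index:
            continue
        rows.append(
            dict(
                term=term,
                f_stat=float(table.loc[raw, "F"]),
                df_num=float(table.loc[raw, "df"]),
                df_den=df_den,
                p_value=float(table.loc[raw, "PR(>F)"]),
                effect_direction=direction.get(term, np.nan),
            )
        )
    return pd.DataFrame(rows)


def _group_direction(df: pd.DataFrame, value_col: str) -> float:
    means = df.groupby("group")[value_col].mean()
    if {"PD", "HV"} <= set(means.index):
        return float(np.sign(means["PD"] - means["HV"]))
    return np.nan


def cross_sectional_model(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Baseline group x sex ANOVA with age as covariate for one measure.

    Type-III sums of squares with sum-to-zero factor coding; age is
    centered before entering the model. ``effect_direction`` on the group
    row is the sign of the PD - HV mean difference.
    """
    required = {"group", "sex", "age", measure}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    df = table.dropna(subset=list(required)).copy()
    for factor in ("group", "sex"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs 2 levels")
    df["age_c"] = df["age"] - df["age"].mean()
    df = df.rename(columns={measure: "_y"})
    anova = _type3_table(df, "_y ~ C(group, Sum) * C(sex, Sum) + age_c")
    return _tidy(anova, _TERM_CLEANUP, {"group": _group_direction(df, "_y")})


def longitudinal_model(
    table: pd.DataFrame, measure: str, design: str = "cohort1"
) -> tuple[pd.DataFrame, int]:
    """Mixed-design ANOVA with visit (V1, V2) as the within-subject factor.

    ``design='cohort1'`` fits visit x group x sex with age as covariate;
    ``design='cohort2'`` fits visit x sex with age (single-group follow-up).
    Subjects missing a visit are excluded; the count is returned alongside
    the tidy results. For the 2-level within factor the split-plot
    decomposition is exact: between-subject terms are Type-III F tests on
    the per-subject visit means, the visit main effect is the Type-III
    intercept test on the V2 - V1 differences, and each visit:X interaction
    is the X term of that difference model.
    """
    if design not in ("cohort1", "cohort2"):
        raise ValueError("design must be 'cohort1' or 'cohort2'")
    required = {"subject_id", "visit", "sex", measure}
    if design == "cohort1":
        required.add("group")
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    with_age = "age" in table.columns  # covariate omitted when not recorded

    df = table.dropna(subset=list(required)).copy()
    if not with_age:
        df["age"] = 0.0
    wide = df.pivot_table(index="subject_id", columns="visit", values=measure, aggfunc="first")
    for v in ("V1", "V2"):
        if v not in wide.columns:
            wide[v] = np.nan
    complete_ids = wide.dropna().index
    n_excluded = wide.shape[0] - len(complete_ids)

    baseline_cols = ["subject_id", "sex", "age"] + (["group"] if design == "cohort1" else [])
    base = (
        df[df["visit"] == "V1"][baseline_cols]
        .drop_duplicates("subject_id")
        .set_index("subject_id")
        .loc[complete_ids]
        .copy()
    )
    base["_mean"] = (wide.loc[complete_ids, "V1"] + wide.loc[complete_ids, "V2"]) / 2.0
    base["_diff"] = wide.loc[complete_ids, "V2"] - wide.loc[complete_ids, "V1"]
    base["age_c"] = base["age"] - base["age"].mean()

    cell_factors = ["group", "sex"] if design == "cohort1" else ["sex"]
    cells = base.groupby(cell_factors).size()
    n_expected = int(np.prod([df[f].nunique() for f in cell_factors]))
    if len(base) < 4 or len(cells) < n_expected or cells.min() < 2:
        raise ValueError(
            f"need >= 2 complete subjects in each of {n_expected} design cells; "
            f"observed cell sizes {cells.to_dict()}"
        )

    if design == "cohort1":
        rhs = "C(group, Sum) * C(sex, Sum)"
        between_rename = dict(_TERM_CLEANUP)
        within_rename = {
            "Intercept": "visit",
            "C(group, Sum)": "visit:group",
            "C(sex, Sum)": "visit:sex",
            "C(group, Sum):C(sex, Sum)": "visit:group:sex",
            "age_c": "visit:age",
        }
    else:
        rhs = "C(sex, Sum)"
        between_rename = {"C(sex, Sum)": "sex", "age_c": "age"}
        within_rename = {
            "Intercept": "visit",
            "C(sex, Sum)": "visit:sex",
            "age_c": "visit:age",
        }
    if with_age:
        rhs += " + age_c"

    directions = {"visit": float(np.sign(base["_diff"].mean()))}
    if design == "cohort1":
        directions["group"] = _group_direction(base.reset_index(), "_mean")
        gdiff = base.groupby("group")["_diff"].mean()
        if {"PD", "HV"} <= set(gdiff.index):
            directions["visit:group"] = float(np.sign(gdiff["PD"] - gdiff["HV"]))

    between = _tidy(_type3_table(base, f"_mean ~ {rhs}"), between_rename, directions)
    if np.allclose(base["_diff"], 0.0):
        # identical visits: no within-subject variation, nothing to test
        within = pd.DataFrame(
            [dict(term=t, f_stat=0.0, df_num=1.0, df_den=float(len(base) - 1),
                  p_value=1.0, effect_direction=directions.get(t, np.nan))
             for t in within_rename.values()]
        )
    else:
        within = _tidy(_type3_table(base, f"_diff ~ {rhs}"), within_rename, directions)
    result = pd.concat([between, within], ignore_index=True)
    return result, int(n_excluded)


def scanner_effect(table_hv_baseline: pd.DataFrame, measure: str) -> pd.DataFrame:
    """One-way ANOVA of ``measure`` across scanners (HV baseline rows)."""
    df = table_hv_baseline.dropna(subset=["scanner", measure])
    groups = [g[measure].to_numpy() for _, g in df.groupby("scanner")]
    if len(groups) < 2:
        raise ValueError("scanner effect needs at least 2 scanners")
    f, p = sps.f_oneway(*groups)
    return pd.DataFrame(
        [
            dict(
                term="scanner",
                f_stat=float(f),
                df_num=float(len(groups) - 1),
                df_den=float(len(df) - len(groups)),
                p_value=float(p),
                effect_direction=np.nan,
            )
        ]
    )


class ROCResult(NamedTuple):
    auc: float
    flipped: bool


def roc_auc(scores, labels, positive_group) -> ROCResult:
    """Empirical AUC for separating ``positive_group`` from the rest.

    Ties count 0.5 (Mann–Whitney convention). The score orientation is
    chosen so the AUC is >= 0.5 — PD shows *lower* SN measurements, so raw
    measures would otherwise yield AUC < 0.5; ``flipped`` discloses when
    the sign was inverted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive_group
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, scores))
    if auc < 0.5:
        return ROCResult(1.0 - auc, True)
    return ROCResult(auc, False)


def correlation_with_permutation(
    table: pd.DataFrame,
    measures: Sequence[str],
    clinical_vars: Sequence[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlations with a max-|r| family-wise permutation correction.

    For each clinical variable, its values are permuted jointly across the
    family of SN measures; each permutation's maximum |r| over the family
    builds the null. The corrected p for a pair is the add-one estimator
    (1 + #{max|r| >= |r_obs|}) / (1 + n_perm), which is never smaller than
    the raw p up to permutation noise. When n! <= n_perm the permutation
    distribution is enumerated exactly and the corrected p is the exact
    proportion over all n! permutations.
    """
    if n_perm < 1000:
        raise ValueError("use at least 1000 permutations")
    rng = np.random.default_rng(seed)
    rows = []
    for var in clinical_vars:
        sub = table.dropna(subset=list(measures) + [var])
        n = len(sub)
        if n < 3:
            warnings.warn(f"too few complete cases for {var!r}; skipped")
            continue
        y = sub[var].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"constant clinical column {var!r}; skipped")
            continue
        usable, obs_r, raw_p, X = [], [], [], []
        for m in measures:
            x = sub[m].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                warnings.warn(f"constant measurement column {m!r}; pair skipped")
                continue
            r, p = sps.pearsonr(x, y)
            usable.append(m)
            obs_r.append(r)
            raw_p.append(p)
            X.append((x - x.mean()) / x.std())
        if not usable:
            continue
        Xs = np.stack(X)  # (m, n), standardized
        ys = (y - y.mean()) / y.std()
        exhaustive = math.factorial(n) <= n_perm
        if exhaustive:
            perms = np.array(list(itertools.permutations(range(n))))
            perm_max = np.max(np.abs(Xs @ ys[perms].T) / n, axis=0)
        else:
            perm_max = np.empty(n_perm)
            for b in range(n_perm):
                yp = ys[rng.permutation(n)]
                perm_max[b] = np.max(np.abs(Xs @ yp) / n)
        for m, r, p in zip(usable, obs_r, raw_p):
            hits = np.sum(perm_max >= abs(r) - 1e-12)
            if exhaustive:
                p_corr = hits / len(perm_max)
            else:
                p_corr = (1.0 + hits) / (1.0 + n_perm)
            rows.append(
                dict(
                    measure=m, clinical_var=var, r=float(r),
                    p_raw=float(p), p_corrected=float(p_corr), n=n,
                )
            )
    return pd.DataFrame(rows)
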