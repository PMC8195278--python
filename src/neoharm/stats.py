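"""Regression-based validation of harmonization.

The logic mirrors the validation design used for scanner-harmonization
studies: build GA/PMA-matched cohort subsets, regress each measurement on
``cohort + PMA + GA + sex``, and read the cohort coefficient.  If anatomy is
matched, a significant cohort effect can only be acquisition-induced, so a
successful harmonization renders it non-significant.  A pooled-variance
two-sample t-test provides the headline group comparison, and an
outcome-association analysis demonstrates how an un-harmonized pooled
analysis manufactures a spurious brain-behaviour correlation.

Model fitting is ordinary least squares through statsmodels; coefficients,
standard errors, t statistics and two-sided p values are exposed per term.
Cohort and sex enter as 0/1 indicators with source/F as reference, so a
positive cohort coefficient means "larger in the target cohort".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "match_cohorts",
    "fit_lm",
    "two_sample_t",
    "harmonization_report",
    "outcome_association",
]

_INDICATORS = {"cohort": ("source", "target"), "sex": ("F", "M")}


@dataclass
class RegressionResult:
    """One OLS fit: per-term coefficient, SE, t, two-sided p."""

    terms: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    tstat: dict[str, float]
    pvalue: dict[str, float]
    n: int
    df_resid: int
    model: str

    def __getitem__(self, term: str) -> dict[str, float]:
        return {"coef": self.coef[term], "se": self.se[term],
                "t": self.tstat[term], "p": self.pvalue[term]}

    def significant(self, term: str, alpha: float = 0.05) -> bool:
        return self.pvalue[term] < alpha


def _encode(table: pd.DataFrame, term: str) -> np.ndarray:
    """Numeric column for a model term; categorical terms become 0/1."""
    if ":" in term:  # interaction
        parts = term.split(":")
        col = np.ones(len(table))
        for p in parts:
            col = col * _encode(table, p)
        return col
    vals = table[term]
    if term in _INDICATORS:
        ref, other = _INDICATORS[term]
        bad = set(vals.unique()) - {ref, other}
        if bad:
            raise ValueError(f"unknown level(s) {bad} in {term}")
        return (vals == other).astype(float).to_numpy()
    out = pd.to_numeric(vals).to_numpy(dtype=float)
    if np.any(~np.isfinite(out)):
        raise ValueError(f"missing values in model variable {term!r}")
    return out


def fit_lm(table: pd.DataFrame, response: str, terms: list[str]) -> RegressionResult:
    """OLS of `response` on `terms` (+ intercept).

    Terms may be numeric columns, the categorical columns cohort/sex
    (encoded 0/1 against source/F), or interactions written "a:b".
    """
    y = pd.to_numeric(table[response]).to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"missing values in response {response!r}")
    cols = [np.ones(len(table))] + [_encode(table, t) for t in terms]
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        names = ["intercept"] + list(terms)
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    res = sm.OLS(y, X).fit()
    names = ["intercept"] + list(terms)
    return RegressionResult(
        terms=names,
        coef=dict(zip(names, map(float, res.params))),
        se=dict(zip(names, map(float, res.bse))),
        tstat=dict(zip(names, map(float, res.tvalues))),
        pvalue=dict(zip(names, map(float, res.pvalues))),
        n=len(table),
        df_resid=int(res.df_resid),
        model=f"{response} ~ " + " + ".join(terms),
    )


def two_sample_t(group_a, group_b) -> dict:
    """Pooled-variance two-sample t-test (df = nA + nB - 2)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("degenerate variance in both groups")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return {
        "t": float(t), "df": int(a.size + b.size - 2), "p": float(p),
        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)), "sd_b": float(b.std(ddof=1)),
    }


def match_cohorts(meta_a, meta_b, n: int) -> dict:
    """Greedy nearest-neighbour matching on standardized (GA, PMA).

    Returns n index pairs (into meta_a / meta_b) plus balance diagnostics
    (standardized mean differences of GA and PMA over the matched sets).
    """
    if len(meta_a) < n or len(meta_b) < n:
        raise ValueError("not enough subjects to match")

    def xy(ms):
        return np.array([[m.ga_weeks, m.pma_weeks] for m in ms], dtype=float)

    a, b = xy(meta_a), xy(meta_b)
    allv = np.vstack([a, b])
    mu, sd = allv.mean(axis=0), allv.std(axis=0)
    sd[sd == 0] = 1.0
    az, bz = (a - mu) / sd, (b - mu) / sd
    d = np.linalg.norm(az[:, None, :] - bz[None, :, :], axis=2)
    pairs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    flat = np.argsort(d, axis=None)
    for idx in flat:
        i, j = np.unravel_index(idx, d.shape)
        if i in used_a or j in used_b:
            continue
        pairs.append((int(i), int(j)))
        used_a.add(int(i))
        used_b.add(int(j))
        if len(pairs) == n:
            break
    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    if n > 1:
        pooled_sd = np.sqrt(0.5 * (a[ia].var(axis=0, ddof=1)
                                   + b[ib].var(axis=0, ddof=1)))
        pooled_sd[pooled_sd == 0] = 1.0
    else:
        pooled_sd = np.ones(2)  # one pair: report the raw difference
    smd = (a[ia].mean(axis=0) - b[ib].mean(axis=0)) / pooled_sd
    return {"pairs": pairs, "smd_ga": float(smd[0]), "smd_pma": float(smd[1])}


VOLUME_MEASURES = ["csf", "cgm", "wm", "dgm", "cerebellum", "brainstem"]


def harmonization_report(tables: dict[str, pd.DataFrame],
                         alpha: float = 0.05) -> pd.DataFrame:
    """Cohort-effect summary across harmonization conditions.

    For every condition (a named AnalysisTable) and every measure — the six
    non-background tissue volumes plus global cortical thickness — fits
    ``measure ~ cohort + PMA + GA + sex`` and flags a significant cohort
    effect, mirroring the per-tissue asterisk tables of harmonization
    validation figures.
    """
    rows = []
    for condition, table in tables.items():
        if set(table["cohort"].unique()) != {"source", "target"}:
            raise ValueError(f"condition {condition!r} must contain both cohorts")
        measures = [(f"vol_{t}_mm3", t) for t in VOLUME_MEASURES]
        measures.append(("thickness_mm", "cortical_thickness"))
        for col, label in measures:
            if col not in table.columns:
                continue
            fit = fit_lm(table, col, ["cohort", "pma_weeks", "ga_weeks", "sex"])
            rows.append({
                "condition": condition,
                "measure": label,
                "cohort_beta": fit.coef["cohort"],
                "cohort_p": fit.pvalue["cohort"],
                "significant": fit.pvalue["cohort"] < alpha,
                "pma_beta": fit.coef["pma_weeks"],
                "pma_p": fit.pvalue["pma_weeks"],
                "n": fit.n,
            })
    return pd.DataFrame(rows)


def outcome_association(table: pd.DataFrame, ct_column: str,
                        outcome_column: str = "outcome_score") -> dict:
    """Outcome ~ cortical thickness, per cohort and pooled.

    Controls for PMA, GA, sex and intracranial volume (sum of non-background
    tissue volumes, computed if an `icv_mm3` column is absent).  Returns the
    three fits; comparing the pooled fit on un-harmonized measures with the
    per-cohort fits exposes the spurious association created by pooling
    biased measurements.
    """
    t = table.copy()
    if t[outcome_column].std(ddof=0) == 0:
        raise ValueError("outcome has zero variance; degenerate fit")
    if "icv_mm3" not in t.columns:
        vol_cols = [c for c in t.columns
                    if c.startswith("vol_") and not c.startswith("vol_background")]
        if not vol_cols:
            raise ValueError("no volume columns to form intracranial volume")
        t["icv_mm3"] = t[vol_cols].sum(axis=1)
    terms = [ct_column, "pma_weeks", "ga_weeks", "sex", "icv_mm3"]
    out = {}
    for name, sub in (("source", t[t.cohort == "source"]),
                      ("target", t[t.cohort == "target"]),
                      ("pooled", t)):
        out[name] = fit_lm(sub, outcome_column, terms)
    return out
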