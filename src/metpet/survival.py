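"""Overall-survival analysis: Kaplan–Meier, log-rank, and Cox regression.

Subjects are rows of a DataFrame with at least ``time_months`` (> 0, months
from surgery) and ``event`` (1 = all-cause death, 0 = censored), plus
clinical covariates (age, sex, who_grade, genetic_status) and feature
columns.  Estimation is delegated to lifelines: the Kaplan–Meier
product-limit estimator, the k-group log-rank test, and the Cox
proportional-hazards partial likelihood (ties by Efron's approximation —
the lifelines convention — Wald 95% confidence intervals exp(β ± 1.96·SE)).

Texture features enter the Cox models on their raw scale by default (use
``standardize_covariates`` for per-SD hazard ratios); WHO grade is ordinal
numeric (II=2, III=3, IV=4) and genetic status is encoded as two indicator
columns against a configurable reference level.  α = 0.05 two-sided, no
multiple-testing correction — a deliberate caveat, not an oversight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMEstimate",
    "LogRankResult",
    "CoxFit",
    "CoxConvergenceError",
    "km_estimate",
    "log_rank",
    "cox_fit",
    "dichotomize",
    "encode_clinical",
    "univariate_screen",
    "multivariate_models",
    "plot_km",
]

TIME_COL = "time_months"
EVENT_COL = "event"


class CoxConvergenceError(RuntimeError):
    """Cox partial likelihood failed to converge (e.g. monotone likelihood)."""

    def __init__(self, covariates, detail: str):
        self.covariates = list(covariates)
        super().__init__(
            f"Cox model with covariates {list(covariates)} did not converge: {detail}"
        )


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_subjects: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass
class CoxFit:
    """Per-covariate estimates plus the model likelihood-ratio test."""

    summary: pd.DataFrame  # index: covariate; columns: coef, hr, ci_lower, ci_upper, se, p
    lr_chi2: float
    lr_df: int
    lr_p: float
    ties: str = "efron"
    n_subjects: int = 0
    n_events: int = 0

    def coef(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "coef"])

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def _check_records(df: pd.DataFrame) -> None:
    for col in (TIME_COL, EVENT_COL):
        if col not in df.columns:
            raise ValueError(f"records must contain a '{col}' column")
    if (df[TIME_COL] <= 0).any():
        raise ValueError("all survival times must be strictly positive")


def _grouping_series(df: pd.DataFrame, grouping) -> pd.Series:
    if isinstance(grouping, str):
        if grouping not in df.columns:
            raise KeyError(f"unknown grouping column '{grouping}'")
        g = df[grouping]
    else:
        g = pd.Series(np.asarray(grouping), index=df.index)
        if len(g) != len(df):
            raise ValueError("grouping length does not match records")
    if g.isna().any():
        raise ValueError("grouping contains missing labels")
    return g.astype(str)


def km_estimate(df: pd.DataFrame, grouping) -> list[KMEstimate]:
    """Kaplan–Meier estimate per group (groups ordered by label)."""
    _check_records(df)
    g = _grouping_series(df, grouping)
    out = []
    for label in sorted(g.unique()):
        sub = df[g == label]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[TIME_COL], event_observed=sub[EVENT_COL])
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
        out.append(
            KMEstimate(
                group=label,
                times=times,
                survival=surv,
                at_risk=at_risk,
                n_subjects=len(sub),
                n_events=int(sub[EVENT_COL].sum()),
            )
        )
    return out


def log_rank(df: pd.DataFrame, grouping) -> LogRankResult:
    """k-group log-rank test (k−1 degrees of freedom)."""
    _check_records(df)
    g = _grouping_series(df, grouping)
    k = g.nunique()
    if k < 2:
        raise ValueError("log-rank test requires at least two groups")
    if df[EVENT_COL].sum() < 1:
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(df[TIME_COL], g, df[EVENT_COL])
    return LogRankResult(chi2=float(res.test_statistic), df=k - 1, p=float(res.p_value))


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    standardize_covariates: bool = False,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Wald 95% CI).

    Raises on constant covariates, collinear designs, and non-convergence
    (monotone likelihood / perfect separation).
    """
    _check_records(df)
    if df[EVENT_COL].sum() < 1:
        raise ValueError("Cox model requires at least one event")
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise KeyError(f"covariates not present in records: {missing}")
    x = df[list(covariates)].astype(float)
    constant = [c for c in covariates if x[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    if len(covariates) > 1:
        centered = x - x.mean(axis=0)
        if np.linalg.matrix_rank(centered.to_numpy()) < len(covariates):
            raise ValueError(f"collinear covariates: {list(covariates)}")
    if standardize_covariates:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    data = pd.concat([df[[TIME_COL, EVENT_COL]].reset_index(drop=True),
                      x.reset_index(drop=True)], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=TIME_COL, event_col=EVENT_COL)
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise CoxConvergenceError(covariates, str(exc)) from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
    lr = cph.log_likelihood_ratio_test()
    return CoxFit(
        summary=summary,
        lr_chi2=float(lr.test_statistic),
        lr_df=int(lr.degrees_freedom),
        lr_p=float(lr.p_value),
        ties="efron",
        n_subjects=len(df),
        n_events=int(df[EVENT_COL].sum()),
    )


def dichotomize(df: pd.DataFrame, feature: str, cutoff: float) -> pd.Series:
    """Two groups: feature < cutoff ("low") vs >= cutoff ("high").

    An empty group triggers a warning; the log-rank test will then refuse
    the single remaining group.
    """
    if feature not in df.columns:
        raise KeyError(f"feature '{feature}' not present")
    if df[feature].isna().any():
        raise ValueError(f"feature '{feature}' has missing values")
    labels = pd.Series(
        np.where(df[feature] < cutoff, f"low (<{cutoff:g})", f"high (>={cutoff:g})"),
        index=df.index,
    )
    counts = labels.value_counts()
    if len(counts) < 2:
        warnings.warn(
            f"cutoff {cutoff:g} leaves an empty group for '{feature}' "
            f"(all subjects are '{counts.index[0]}')",
            stacklevel=2,
        )
    return labels


def encode_clinical(df: pd.DataFrame, genetic_reference: str = "codel") -> pd.DataFrame:
    """Add model-ready encodings: sex_male, genetic indicator columns.

    who_grade is kept ordinal numeric.  Genetic status becomes one indicator
    per non-reference level (columns ``genetic_<level>``).
    """
    out = df.copy()
    if "sex" in out.columns and "sex_male" not in out.columns:
        out["sex_male"] = (out["sex"].astype(str) == "male").astype(int)
    if "genetic_status" in out.columns:
        levels = sorted(out["genetic_status"].astype(str).unique())
        if genetic_reference not in levels and len(levels) > 1:
            genetic_reference = levels[0]
        for level in levels:
            if level != genetic_reference:
                out[f"genetic_{level}"] = (out["genetic_status"].astype(str) == level).astype(int)
    return out


def _genetic_indicator_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("genetic_") and c != "genetic_status"]


def univariate_screen(df: pd.DataFrame, candidates: list[str]) -> pd.DataFrame:
    """One single-covariate Cox fit per candidate, as a result table.

    ``sex`` and ``genetic_status`` are handled categorically.  A categorical
    level with zero events makes the hazard ratio non-estimable (monotone
    likelihood): the row is flagged NA with the log-rank p-value across
    levels instead — the convention used when reporting such covariates.
    Per-candidate failures are recorded, not raised.
    """
    _check_records(df)
    df = encode_clinical(df)
    rows = []
    for cand in candidates:
        row = {"covariate": cand, "hr": np.nan, "ci_lower": np.nan,
               "ci_upper": np.nan, "p": np.nan, "note": ""}
        try:
            if cand == "genetic_status":
                by_level_events = df.groupby("genetic_status")[EVENT_COL].sum()
                if (by_level_events == 0).any():
                    row["note"] = (
                        "NA: level(s) with no events "
                        f"({', '.join(by_level_events[by_level_events == 0].index)}); "
                        "p from log-rank"
                    )
                    row["p"] = log_rank(df, "genetic_status").p
                else:
                    fit = cox_fit(df, _genetic_indicator_cols(df))
                    row["p"] = fit.lr_p
                    row["note"] = "joint LR p over indicator levels"
            else:
                col = "sex_male" if cand == "sex" else cand
                fit = cox_fit(df, [col])
                row.update(
                    hr=fit.hr(col),
                    ci_lower=float(fit.summary.loc[col, "ci_lower"]),
                    ci_upper=float(fit.summary.loc[col, "ci_upper"]),
                    p=fit.p(col),
                )
        except (ValueError, KeyError, CoxConvergenceError) as exc:
            row["note"] = f"not estimable: {exc}"
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")


def multivariate_models(df: pd.DataFrame, texture: str) -> dict[str, CoxFit]:
    """Three adjusted Cox models for one texture feature.

    model1 adjusts for age, model2 for WHO grade (ordinal), model3 for
    genetic status (indicator-coded); each model is the adjuster plus the
    texture feature.
    """
    df = encode_clinical(df)
    models = {
        "model1_age": ["age", texture],
        "model2_grade": ["who_grade", texture],
        "model3_genetic": _genetic_indicator_cols(df) + [texture],
    }
    return {name: cox_fit(df, covs) for name, covs in models.items()}


def plot_km(df: pd.DataFrame, grouping, path: str | Path, title: str = "") -> Path:
    """Kaplan–Meier curves per group, with the log-rank p in the title."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _check_records(df)
    g = _grouping_series(df, grouping)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label in sorted(g.unique()):
        sub = df[g == label]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[TIME_COL], event_observed=sub[EVENT_COL], label=f"{label} (n={len(sub)})")
        kmf.plot_survival_function(ax=ax, ci_show=False)
    try:
        p = log_rank(df, g).p
        extra = f" (log-rank p = {p:.3g})"
    except ValueError:
        extra = ""
    ax.set_title((title or "Overall survival") + extra)
    ax.set_xlabel("months from surgery")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
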