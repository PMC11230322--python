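"""Cox proportional-hazards fits on the age time scale, and their summaries.

Age is the time scale: entry age is the left-truncation (delayed entry)
time and exit age the event/censoring time, so each participant
contributes risk only over the ages actually observed.  Ties are handled
with the Efron approximation (the lifelines default).  Confidence
intervals are Wald intervals on the log-hazard scale with +/-1.96
standard errors; p-values are two-sided Wald tests.

Gender-stratified fits are combined with a fixed-effects (inverse-
variance) meta-analysis of the stratum log hazard ratios, mirroring how
sex-specific cohorts are usually pooled in this literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .index import quantile_bin
from .simulate import covariate_columns

__all__ = [
    "CoxFit",
    "MetaResult",
    "fit_cox",
    "hr_per_10_units",
    "extreme_decile_contrast",
    "p_for_trend",
    "meta_fixed_effects",
    "add_quintile_covariates",
    "default_covariates",
    "TermEstimate",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TermEstimate:
    """One model term on the hazard-ratio scale."""

    beta: float
    se: float

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        with np.errstate(over="ignore"):
            return (
                float(np.exp(self.beta - Z95 * self.se)),
                float(np.exp(self.beta + Z95 * self.se)),
            )

    @property
    def p(self) -> float:
        if self.se == 0:
            return float(np.nan)
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))


@dataclass
class CoxFit:
    """A fitted Cox model: per-term estimates plus metadata."""

    terms: pd.DataFrame  # index: term; columns: beta, se, hr, hr_lcl, hr_ucl, p
    exposure_term: str
    form: str  # continuous | deciles | trend
    stratum: str  # female | male | all
    n: int
    n_events: int
    converged: bool = True
    message: str = ""

    def term(self, name: str) -> TermEstimate:
        row = self.terms.loc[name]
        return TermEstimate(beta=float(row["beta"]), se=float(row["se"]))


def default_covariates(stratum: str | None = None) -> list[str]:
    """The full adjustment set: binary/categorical covariates entered as
    numeric codes plus within-gender margarine and energy quintiles.
    Hormone-use terms are included only in the female stratum."""
    cols = [c for c in covariate_columns("male") if c != "margarine"]
    cols += ["margarine_q", "energy_q"]
    if stratum == "female":
        cols += ["hormone_use", "oral_contraceptive"]
    return cols


def add_quintile_covariates(resolved: pd.DataFrame) -> pd.DataFrame:
    """Attach within-gender quintile codes for margarine and resolved
    energy intake (``margarine_q``, ``energy_q``)."""
    df = resolved.copy()
    for src, dst in (("margarine", "margarine_q"), ("energy", "energy_q")):
        if src not in df.columns:
            raise ValueError(f"column {src!r} not present")
        q = np.empty(len(df), dtype=int)
        for _, idx in df.groupby("gender").groups.items():
            loc = df.index.get_indexer(idx)
            q[loc] = quantile_bin(df[src].to_numpy(dtype=float)[loc], 5)
        df[dst] = q
    df.attrs = dict(resolved.attrs)
    return df


def _decile_design(bins: pd.Series) -> pd.DataFrame:
    b = bins.astype(int)
    if (b == 1).sum() == 0:
        raise ValueError("decile reference bin (bin 1) is empty")
    cols = {}
    for k in range(2, 11):
        if (b == k).any():
            cols[f"decile_{k}"] = (b == k).astype(float)
    return pd.DataFrame(cols, index=bins.index)


def fit_cox(
    data: pd.DataFrame,
    exposure_col: str,
    form: str = "continuous",
    covariates: list[str] | tuple[str, ...] = (),
    stratum: str | None = None,
    entry_col: str = "entry_age",
    duration_col: str = "exit_age",
    event_col: str = "event",
    robust: bool = False,
) -> CoxFit:
    """Fit a Cox model of the event on an exposure plus covariates.

    Parameters
    ----------
    exposure_col
        Continuous index column (``form="continuous"``), decile-bin
        column (``form="deciles"``; indicators for bins 2-10 are built
        with bin 1 as reference), or decile-median column
        (``form="trend"``).
    stratum
        ``"female"``/``"male"`` restricts to that gender; ``None`` uses
        everyone.

    Raises on zero events or on an exposure with no variation; a
    non-converged optimisation returns a flagged (``converged=False``)
    fit rather than raising, so multiverse sweeps can log and continue.
    """
    if form not in ("continuous", "deciles", "trend"):
        raise ValueError(f"unknown exposure form {form!r}")
    df = data if stratum is None else data[data["gender"] == stratum]
    stratum_label = stratum or "all"
    n = len(df)
    n_events = int(df[event_col].sum()) if n else 0
    if n_events == 0:
        raise ValueError(f"no events in analysis set (stratum={stratum_label})")

    if form == "deciles":
        design = _decile_design(df[exposure_col])
        exposure_term = "decile_10"
    else:
        vals = df[exposure_col].to_numpy(dtype=float)
        if np.nanstd(vals) == 0:
            raise ValueError(
                f"exposure {exposure_col!r} is constant; term inestimable"
            )
        design = pd.DataFrame({exposure_col: vals}, index=df.index)
        exposure_term = exposure_col
    for c in covariates:
        if c not in df.columns:
            raise ValueError(f"covariate {c!r} not present")
        design[c] = df[c].to_numpy(dtype=float)
    # drop covariates with no variation in this stratum (inestimable)
    dropped = [c for c in covariates if np.nanstd(design[c].to_numpy()) == 0]
    design = design.drop(columns=dropped)

    fit_df = design.copy()
    fit_df[duration_col] = df[duration_col].to_numpy(dtype=float)
    fit_df[entry_col] = df[entry_col].to_numpy(dtype=float)
    fit_df[event_col] = df[event_col].to_numpy(dtype=int)
    if fit_df.isna().any().any():
        fit_df = fit_df.dropna()
        n = len(fit_df)
        n_events = int(fit_df[event_col].sum())
        if n_events == 0:
            raise ValueError(f"no events after dropping incomplete rows (stratum={stratum_label})")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                fit_df,
                duration_col=duration_col,
                event_col=event_col,
                entry_col=entry_col,
                robust=robust,
            )
        betas = cph.params_
        ses = cph.standard_errors_
        converged, message = True, ""
    except (ConvergenceError, np.linalg.LinAlgError) as err:
        betas = pd.Series(np.nan, index=design.columns)
        ses = pd.Series(np.nan, index=design.columns)
        converged, message = False, f"{type(err).__name__}: {err}"

    terms = pd.DataFrame({"beta": betas, "se": ses})
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        terms["hr"] = np.exp(terms["beta"])
        terms["hr_lcl"] = np.exp(terms["beta"] - Z95 * terms["se"])
        terms["hr_ucl"] = np.exp(terms["beta"] + Z95 * terms["se"])
        terms["p"] = 2.0 * stats.norm.sf(np.abs(terms["beta"] / terms["se"]))
    return CoxFit(
        terms=terms,
        exposure_term=exposure_term,
        form=form,
        stratum=stratum_label,
        n=int(n),
        n_events=n_events,
        converged=converged,
        message=message,
    )


def hr_per_10_units(fit: CoxFit) -> TermEstimate:
    """Hazard ratio for a 10-unit increment of a continuous index.

    ``HR = exp(10 * beta)`` with Wald CI ``exp(10 * (beta +/- 1.96 se))``;
    the p-value is unchanged by the linear rescaling.
    """
    if fit.form != "continuous":
        raise ValueError(f"fit has form {fit.form!r}, need a continuous exposure")
    t = fit.term(fit.exposure_term)
    return TermEstimate(beta=10.0 * t.beta, se=10.0 * t.se)


def extreme_decile_contrast(fit: CoxFit) -> TermEstimate:
    """Hazard ratio for the highest vs lowest decile bin."""
    if fit.form != "deciles":
        raise ValueError(f"fit has form {fit.form!r}, need a decile-indicator exposure")
    if "decile_10" not in fit.terms.index:
        raise ValueError("top decile bin is empty; extreme contrast undefined")
    return fit.term("decile_10")


def p_for_trend(
    data: pd.DataFrame,
    median_col: str = "bin_median",
    covariates: list[str] | tuple[str, ...] = (),
    stratum: str | None = None,
    **kwargs,
) -> float:
    """Trend test: each participant carries their decile bin's median
    index value; returns the two-sided Wald p of that single term."""
    fit = fit_cox(
        data, median_col, form="trend", covariates=covariates, stratum=stratum, **kwargs
    )
    if not fit.converged:
        return float(np.nan)
    return fit.term(fit.exposure_term).p


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance fixed-effects combination of log hazard ratios."""

    beta: float
    se: float
    n_strata: int

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - Z95 * self.se)),
            float(np.exp(self.beta + Z95 * self.se)),
        )

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))


def meta_fixed_effects(estimates: list[TermEstimate]) -> MetaResult:
    """Fixed-effects meta-analysis: weighted mean of log HRs with
    weights ``1/se**2``; combined variance ``1 / sum(weights)``."""
    if not estimates:
        raise ValueError("no stratum estimates to combine")
    betas = np.array([e.beta for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    if (ses <= 0).any() or np.isnan(ses).any():
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    return MetaResult(beta=beta, se=se, n_strata=len(estimates))
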