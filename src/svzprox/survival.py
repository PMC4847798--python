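"""Survival workflow: Kaplan–Meier / log-rank, and the Cox screening cascade.

The study design this implements: group comparisons (SVZ-involved vs not,
CS ≤30 vs >30 mm, frontal horn vs other dominant regions) use Kaplan–Meier
curves with the unweighted two-group log-rank test; prognostic modelling
within the SVZ-involved subcohort runs a univariate Cox proportional-hazards
screen over candidate binary covariates, then fits one multivariate Cox
model on the covariates whose univariate p < alpha (default 0.05).

Estimation is delegated to lifelines (Efron handling of tied event times;
Wald 95% confidence intervals on the log-hazard scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "ENDPOINTS",
    "KMResult",
    "EffectEstimate",
    "ModelReport",
    "ZeroVarianceError",
    "CollinearityError",
    "FitError",
    "km_logrank",
    "cox_univariate",
    "cox_multivariate",
    "screen_then_multivariate",
]

#: endpoint tag → (duration column, event column)
ENDPOINTS = {"os": ("os_days", "os_event"), "pfs": ("pfs_days", "pfs_event")}

TIE_METHOD = "efron"  # lifelines' partial-likelihood tie handling


class ZeroVarianceError(ValueError):
    """A covariate takes a single value; no hazard ratio is estimable."""


class CollinearityError(ValueError):
    """The covariate matrix is rank-deficient."""


class FitError(RuntimeError):
    """Model fitting failed; message carries diagnostics."""


@dataclass(frozen=True)
class KMResult:
    """Per-group product-limit curves plus the two-sided log-rank test."""

    curves: dict  # group label -> DataFrame(time, survival, at_risk)
    chi_square: float
    p_value: float
    group_labels: tuple
    group_sizes: dict

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for label, curve in self.curves.items():
            part = curve.copy()
            part.insert(0, "group", label)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class EffectEstimate:
    """One covariate's hazard ratio with Wald 95% CI and p-value."""

    covariate: str
    endpoint: str  # "os" | "pfs"
    model: str  # "univariate" | "multivariate"
    hr: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if not (0 < self.ci_lower < self.hr < self.ci_upper) and np.isfinite(self.hr):
            # Wald CIs on the log scale always bracket the HR; anything else
            # signals a numerically broken fit worth surfacing.
            raise FitError(
                f"{self.covariate} ({self.endpoint}/{self.model}): CI "
                f"[{self.ci_lower}, {self.ci_upper}] does not bracket HR {self.hr}"
            )

    def to_row(self) -> dict:
        return {
            "covariate": self.covariate,
            "endpoint": self.endpoint.upper(),
            "model": self.model,
            "hr": self.hr,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p": self.p_value,
            "n": self.n,
            "events": self.n_events,
        }


@dataclass(frozen=True)
class ModelReport:
    """Result of the univariate screen and the gated multivariate fit."""

    endpoint: str
    alpha: float
    univariate: list = field(default_factory=list)
    selected: list = field(default_factory=list)  # covariate names, p < alpha
    multivariate: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [e.to_row() for e in self.univariate] + [e.to_row() for e in self.multivariate]
        return pd.DataFrame(rows)


def _as_arrays(times, events, group=None):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    if group is not None:
        group = np.asarray(group)
        if group.shape != times.shape:
            raise ValueError("group labels must match times")
    return times, events, group


def km_logrank(times, events, group, group_labels: dict | None = None) -> KMResult:
    """Kaplan–Meier curves per group plus the unweighted two-sided log-rank test.

    Parameters
    ----------
    times, events
        Durations and event indicators (1 = event, 0 = censored).
    group
        Group membership labels (two or more non-empty groups).
    group_labels
        Optional mapping of raw group values to display names.
    """
    times, events, group = _as_arrays(times, events, group)
    levels = np.unique(group)
    if len(levels) < 2:
        raise ValueError("log-rank comparison needs at least two non-empty groups")
    if events.sum() == 0:
        raise ValueError("no events observed in any group")

    curves: dict = {}
    sizes: dict = {}
    for level in levels:
        sel = group == level
        label = (group_labels or {}).get(level, level)
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        table = kmf.event_table
        curve = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
        curves[label] = curve
        sizes[label] = int(sel.sum())

    res = multivariate_logrank_test(times, group, events)
    return KMResult(
        curves=curves,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        group_labels=tuple(curves.keys()),
        group_sizes=sizes,
    )


def _prepare(rows: pd.DataFrame, endpoint: str, covariates: list[str]) -> tuple[pd.DataFrame, str, str]:
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {sorted(ENDPOINTS)}, got {endpoint!r}")
    dur_col, ev_col = ENDPOINTS[endpoint]
    cols = [dur_col, ev_col] + covariates
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise ValueError(f"analysis table missing columns: {missing}")
    sub = rows[cols].dropna().astype(float).reset_index(drop=True)
    if sub[ev_col].sum() < 1:
        raise ValueError(f"no {endpoint.upper()} events among complete cases")
    return sub, dur_col, ev_col


def _fit_cox(sub: pd.DataFrame, dur_col: str, ev_col: str, endpoint: str, model: str) -> list[EffectEstimate]:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(sub, duration_col=dur_col, event_col=ev_col)
    except Exception as exc:
        raise FitError(f"Cox fit failed ({endpoint}/{model}): {exc}") from exc
    summary = cph.summary
    n, n_events = int(len(sub)), int(sub[ev_col].sum())
    return [
        EffectEstimate(
            covariate=str(name),
            endpoint=endpoint,
            model=model,
            hr=float(row["exp(coef)"]),
            ci_lower=float(row["exp(coef) lower 95%"]),
            ci_upper=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
            n=n,
            n_events=n_events,
        )
        for name, row in summary.iterrows()
    ]


def cox_univariate(rows: pd.DataFrame, endpoint: str, covariate: str) -> EffectEstimate:
    """Single-covariate Cox proportional-hazards fit.

    HR = exp(coefficient) for the binary indicator, with Wald 95% CI and
    two-sided p-value. Complete cases only.
    """
    sub, dur_col, ev_col = _prepare(rows, endpoint, [covariate])
    if sub[covariate].nunique() < 2:
        raise ZeroVarianceError(f"covariate {covariate!r} is constant across patients")
    return _fit_cox(sub, dur_col, ev_col, endpoint, "univariate")[0]


def cox_multivariate(rows: pd.DataFrame, endpoint: str, covariates: list[str]) -> list[EffectEstimate]:
    """Joint Cox fit over the given covariates (one EffectEstimate each)."""
    if len(covariates) == 0:
        raise ValueError("empty covariate list")
    if len(set(covariates)) < len(covariates):
        raise CollinearityError("duplicated covariate names")
    sub, dur_col, ev_col = _prepare(rows, endpoint, list(covariates))
    X = sub[list(covariates)].to_numpy()
    for cov in covariates:
        if sub[cov].nunique() < 2:
            raise ZeroVarianceError(f"covariate {cov!r} is constant across patients")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < len(covariates):
        raise CollinearityError(f"collinear covariates among {covariates}")
    if sub[ev_col].sum() < len(covariates):
        raise ValueError(
            f"{int(sub[ev_col].sum())} events cannot support {len(covariates)} covariates"
        )
    return _fit_cox(sub, dur_col, ev_col, endpoint, "multivariate")


def screen_then_multivariate(
    rows: pd.DataFrame,
    endpoint: str,
    candidates: list[str],
    alpha: float = 0.05,
) -> ModelReport:
    """Univariate Cox screen over candidates, then one multivariate model.

    Every candidate is screened univariately; those with p < ``alpha`` enter a
    single joint Cox model. Per-covariate fit failures are recorded as notes
    without aborting the screen; an empty selection yields a report with no
    multivariate section.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    univariate: list[EffectEstimate] = []
    notes: list[str] = []
    for cov in candidates:
        try:
            univariate.append(cox_univariate(rows, endpoint, cov))
        except (ZeroVarianceError, ValueError, FitError) as exc:
            notes.append(f"{cov}: {exc}")
    selected = [e.covariate for e in univariate if e.p_value < alpha]
    multivariate: list[EffectEstimate] = []
    if not selected:
        notes.append("no candidate passed the univariate screen; no multivariate model")
    elif len(selected) == 1:
        # single survivor: the joint model is the univariate model
        multivariate = [
            EffectEstimate(**{**vars(e), "model": "multivariate"})
            for e in univariate
            if e.covariate == selected[0]
        ]
    else:
        try:
            multivariate = cox_multivariate(rows, endpoint, selected)
        except (CollinearityError, ValueError, FitError) as exc:
            notes.append(f"multivariate fit failed: {exc}")
    return ModelReport(
        endpoint=endpoint,
        alpha=alpha,
        univariate=univariate,
        selected=selected,
        multivariate=multivariate,
        notes=notes,
    )
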