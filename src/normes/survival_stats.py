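"""Censored-survival evaluation of imaging markers under case-control sampling.

A screening cohort is analysed as right-censored survival data: each subject
has a follow-up time in days, an all-cause death indicator, a lung-cancer
death indicator, a sampling weight and one or more marker values. Cohorts
built by keeping every death and a known fraction of survivors are handled
by inverse-sampling weights (survivor weight = 1/fraction) so every
estimator targets the full-cohort quantity.

Provided estimators:

* weighted Kaplan-Meier product-limit curves and the censoring-distribution
  Kaplan-Meier (the IPCW ingredient);
* weighted pairwise log-rank tests with a Bonferroni threshold;
* cumulative/dynamic time-dependent AUC at a horizon t: the weighted
  probability that a subject who died by t outranks a subject still in
  follow-up at t, with inverse-probability-of-censoring weights;
* stratified-bootstrap confidence intervals for AUC differences;
* a univariate weighted Cox proportional-hazards fit (Newton iteration on
  the partial likelihood, Breslow tie handling and baseline hazard), used
  to map marker values onto predicted event risks;
* the continuous net reclassification improvement (NRI) for censored data,
  with Kaplan-Meier estimates of the event probabilities inside the
  "risk up" / "risk down" subgroups;
* a driver assembling per-horizon AUC / diffAUC / NRI tables for two
  markers and one or two causes of death.

Cause-specific analyses (lung-cancer mortality) censor other-cause deaths
at their death time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

_CAUSES = ("all_cause", "lung_cancer")
_REQUIRED_COLUMNS = ["id", "time_days", "event_all_cause", "event_lung_cancer", "weight"]


class ConvergenceError(RuntimeError):
    """Raised when the proportional-hazards Newton iteration fails."""


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class SubjectRecord:
    """One subject: follow-up, outcome flags, sampling weight, markers."""

    id: str
    time_days: float
    event_all_cause: int
    event_lung_cancer: int = 0
    weight: float = 1.0
    markers: dict = field(default_factory=dict)


class Cohort:
    """A survival cohort backed by a pandas DataFrame.

    Required columns: ``id, time_days, event_all_cause, event_lung_cancer,
    weight``; every further numeric column is a marker. ``design`` is
    ``"full"`` or ``"case_control"`` (all deaths kept, survivors subsampled
    with weight 1/fraction).
    """

    def __init__(self, frame: pd.DataFrame, design: str = "full",
                 control_fraction: float | None = None):
        frame = frame.copy().reset_index(drop=True)
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns {missing}")
        if frame["id"].duplicated().any():
            raise ValueError("subject ids must be unique")
        if (frame["time_days"] <= 0).any():
            raise ValueError("follow-up times must be > 0")
        for col in ("event_all_cause", "event_lung_cancer"):
            if not frame[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be binary")
        if (frame["event_lung_cancer"] > frame["event_all_cause"]).any():
            raise ValueError("a lung-cancer death must also be an all-cause death")
        if (frame["weight"] < 1.0 - 1e-9).any():
            raise ValueError("sampling weights must be >= 1")
        if design not in ("full", "case_control"):
            raise ValueError("design must be 'full' or 'case_control'")
        if design == "case_control":
            ev = frame["event_all_cause"] == 1
            if not np.allclose(frame.loc[ev, "weight"], 1.0):
                raise ValueError("case-control design requires weight 1 for every death")
        self.frame = frame
        self.design = design
        self.control_fraction = control_fraction

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: list[SubjectRecord], design: str = "full",
                     control_fraction: float | None = None) -> "Cohort":
        rows = []
        for r in records:
            row = {
                "id": r.id,
                "time_days": r.time_days,
                "event_all_cause": int(r.event_all_cause),
                "event_lung_cancer": int(r.event_lung_cancer),
                "weight": r.weight,
            }
            row.update(r.markers)
            rows.append(row)
        return cls(pd.DataFrame(rows), design=design, control_fraction=control_fraction)

    @classmethod
    def read_csv(cls, path) -> "Cohort":
        frame = pd.read_csv(path)
        design = "case_control" if (frame["weight"] > 1.0 + 1e-9).any() else "full"
        return cls(frame, design=design)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # -- access ------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def marker_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in _REQUIRED_COLUMNS]

    def marker(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise KeyError(f"unknown marker {name!r}; have {self.marker_names}")
        return self.frame[name].to_numpy(dtype=float)

    def survival_arrays(self, cause: str = "all_cause"):
        """(time, event, weight) arrays for a cause; for ``lung_cancer``,
        other-cause deaths are censored at their death time."""
        if cause not in _CAUSES:
            raise ValueError(f"cause must be one of {_CAUSES}")
        t = self.frame["time_days"].to_numpy(dtype=float)
        w = self.frame["weight"].to_numpy(dtype=float)
        col = "event_all_cause" if cause == "all_cause" else "event_lung_cancer"
        e = self.frame[col].to_numpy(dtype=int)
        return t, e, w

    def subset(self, index: np.ndarray) -> "Cohort":
        """Row subset/resample by positional index; ids are rewritten to stay
        unique (used by the bootstrap)."""
        frame = self.frame.iloc[index].reset_index(drop=True)
        frame["id"] = [f"b{i}" for i in range(len(frame))]
        return Cohort(frame, design=self.design, control_fraction=self.control_fraction)


# ---------------------------------------------------------------------------
# percentile categories


@dataclass
class CategoryCuts:
    """60th/80th percentile cut points of a marker over the analysis cohort."""

    p60: float
    p80: float

    def __post_init__(self) -> None:
        if self.p60 > self.p80:
            raise ValueError("p60 must not exceed p80")


def weighted_quantile(values: np.ndarray, q, weights: np.ndarray | None = None) -> np.ndarray:
    """Linear-interpolation sample quantiles; with weights, interpolates the
    weighted empirical CDF (reduces to ``np.quantile`` for unit weights on
    distinct values)."""
    values = np.asarray(values, dtype=float)
    if weights is None:
        return np.quantile(values, q)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    # positions of order statistics on [0, 1], midpoint convention
    pos = (cw - 0.5 * w) / cw[-1]
    return np.interp(q, pos, v)


def compute_category_cuts(scores: np.ndarray, weights: np.ndarray | None = None) -> CategoryCuts:
    p60, p80 = weighted_quantile(scores, [0.6, 0.8], weights)
    return CategoryCuts(p60=float(p60), p80=float(p80))


def categorize(scores: np.ndarray, cuts: CategoryCuts) -> np.ndarray:
    """Map scores to ``low`` (< p60), ``medium`` (p60 <= s <= p80) or
    ``high`` (> p80); boundary values fall in ``medium``."""
    scores = np.asarray(scores, dtype=float)
    out = np.full(scores.shape, "medium", dtype=object)
    out[scores < cuts.p60] = "low"
    out[scores > cuts.p80] = "high"
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Weighted product-limit curve: S at each distinct event time, with
    weighted at-risk and event counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t) -> np.ndarray | float:
        """Right-continuous S(t)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx] if np.ndim(t) else float(s[idx])

    def survival_before(self, t) -> np.ndarray | float:
        """Left limit S(t-)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        s = np.concatenate([[1.0], self.survival])
        return s[idx] if np.ndim(t) else float(s[idx])


def product_limit(time: np.ndarray, event: np.ndarray, weight: np.ndarray | None = None) -> KMCurve:
    """Weighted Kaplan-Meier estimator. Weights multiply both the risk-set
    and the event counts, so integer weights reproduce the estimator on the
    correspondingly replicated sample exactly."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("no records")
    w = np.ones_like(time) if weight is None else np.asarray(weight, dtype=float)
    order = np.argsort(time, kind="stable")
    t, e, w = time[order], event[order].astype(bool), w[order]

    uniq, first = np.unique(t, return_index=True)
    total = w.sum()
    # weighted count with time < u, cumulative over unique times
    cum_before = np.concatenate([[0.0], np.cumsum(w)])[first]
    at_risk = total - cum_before
    d = np.zeros(uniq.size)
    np.add.at(d, np.searchsorted(uniq, t[e]), w[e])

    has_event = d > 0
    times = uniq[has_event]
    n_r = at_risk[has_event]
    d_e = d[has_event]
    # clip the step factors: float round-off with non-integer weights can
    # push 1 - d/n a hair below zero when the whole risk set dies
    surv = np.cumprod(np.clip(1.0 - d_e / n_r, 0.0, 1.0))
    return KMCurve(times=times, survival=surv, at_risk=n_r, events=d_e)


def km_curve(cohort: Cohort, cause: str = "all_cause",
             group: np.ndarray | None = None, weighted: bool = True) -> KMCurve:
    """Kaplan-Meier survival curve for a cohort (optionally a boolean
    subgroup), with or without sampling weights."""
    t, e, w = cohort.survival_arrays(cause)
    if group is not None:
        group = np.asarray(group, dtype=bool)
        t, e, w = t[group], e[group], w[group]
    if t.size == 0:
        raise ValueError("no records selected")
    return product_limit(t, e, w if weighted else None)


def censoring_km(cohort: Cohort, cause: str = "all_cause") -> KMCurve:
    """Kaplan-Meier estimate of the censoring distribution G (event
    indicator inverted), the IPCW ingredient."""
    t, e, w = cohort.survival_arrays(cause)
    return product_limit(t, 1 - e, w)


# ---------------------------------------------------------------------------
# log-rank


@dataclass
class LogrankResult:
    pair: tuple[str, str]
    chi2: float
    p: float
    significant: bool


def _two_group_logrank(t1, e1, w1, t2, e2, w2) -> tuple[float, float]:
    """Weighted two-group log-rank chi-square (1 df) via the standard
    observed-minus-expected sums over pooled event times."""
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2]).astype(bool)
    w = np.concatenate([w1, w2])
    g = np.concatenate([np.zeros(t1.size, bool), np.ones(t2.size, bool)])

    uniq = np.unique(t[e])
    o1 = ex1 = var = 0.0
    for u in uniq:
        at = t >= u
        n = w[at].sum()
        n1 = w[at & ~g].sum()
        dead = e & (t == u)
        d = w[dead].sum()
        d1 = w[dead & ~g].sum()
        o1 += d1
        ex1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = (o1 - ex1) ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def pairwise_logrank(cohort: Cohort, categories: np.ndarray, cause: str = "all_cause",
                     pairwise_alpha: float = 0.0167) -> list[LogrankResult]:
    """All pairwise weighted log-rank comparisons between marker categories,
    flagged at the Bonferroni-corrected threshold (0.0167 for 3 groups)."""
    categories = np.asarray(categories)
    t, e, w = cohort.survival_arrays(cause)
    levels = sorted(set(categories.tolist()))
    results = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            sa, sb = categories == a, categories == b
            chi2, p = _two_group_logrank(t[sa], e[sa], w[sa], t[sb], e[sb], w[sb])
            results.append(LogrankResult(pair=(a, b), chi2=chi2, p=p,
                                         significant=p < pairwise_alpha))
    return results


# ---------------------------------------------------------------------------
# time-dependent AUC


@dataclass
class TDAUCResult:
    horizon_days: float
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class AUCDiffResult:
    horizon_days: float
    diff: float
    ci_low: float
    ci_high: float
    n_boot: int


def _weighted_auc(case_m, case_w, ctrl_m, ctrl_w) -> float:
    """Weighted probability that a case outranks a control; ties count 0.5.
    Computed by sorting (exactly equal to the O(n^2) pairwise sum)."""
    order = np.argsort(ctrl_m, kind="stable")
    cm = np.asarray(ctrl_m)[order]
    cw = np.concatenate([[0.0], np.cumsum(np.asarray(ctrl_w)[order])])
    left = np.searchsorted(cm, case_m, side="left")
    right = np.searchsorted(cm, case_m, side="right")
    w_below = cw[left]
    w_equal = cw[right] - cw[left]
    num = float(np.sum(case_w * (w_below + 0.5 * w_equal)))
    denom = float(np.sum(case_w) * cw[-1])
    return num / denom


def _td_auc_arrays(t, e, w, m, horizon: float, g_curve: KMCurve) -> float:
    case = (t <= horizon) & (e == 1)
    ctrl = t > horizon
    if not case.any() or not ctrl.any():
        raise ValueError(f"no cases or no controls at horizon {horizon} days")
    g_case = np.maximum(np.asarray(g_curve.survival_before(t[case])), 1e-12)
    g_at = max(float(g_curve.survival_at(horizon)), 1e-12)
    case_w = w[case] / g_case
    ctrl_w = w[ctrl] / g_at
    return _weighted_auc(m[case], case_w, m[ctrl], ctrl_w)


def td_auc(cohort: Cohort, marker: str, horizon_days: float,
           cause: str = "all_cause") -> TDAUCResult:
    """Cumulative/dynamic time-dependent AUC at a horizon, with IPCW case
    weights ``1/G(T-)`` and control weights ``1/G(t)`` multiplying the
    sampling weights. Subjects censored before the horizon contribute to
    neither set. Confidence limits are filled in by the bootstrap drivers.
    """
    t, e, w = cohort.survival_arrays(cause)
    m = cohort.marker(marker)
    g = product_limit(t, 1 - e, w)
    auc = _td_auc_arrays(t, e, w, m, float(horizon_days), g)
    return TDAUCResult(horizon_days=float(horizon_days), auc=auc)


# ---------------------------------------------------------------------------
# bootstrap machinery


@dataclass
class StatsConfig:
    """Evaluation settings: bootstrap replicates (6000 by default), overall
    and pairwise (Bonferroni, 3 comparisons) significance levels, follow-up
    horizons in years, and the random seed driving all resampling."""

    n_boot: int = 6000
    alpha: float = 0.05
    pairwise_alpha: float = 0.0167
    horizons_years: tuple = (1, 2, 3, 4, 5, 6, 7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def horizons_days(self) -> list[float]:
        return [y * DAYS_PER_YEAR for y in self.horizons_years]


def _stratified_indices(event: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample with replacement within deaths and within survivors, so the
    case-control composition of every replicate matches the original."""
    idx_e = np.flatnonzero(event == 1)
    idx_n = np.flatnonzero(event == 0)
    out = np.concatenate([
        rng.choice(idx_e, size=idx_e.size, replace=True),
        rng.choice(idx_n, size=idx_n.size, replace=True),
    ])
    return out


def auc_difference_bootstrap(cohort: Cohort, marker_a: str, marker_b: str,
                             horizon_days: float, config: StatsConfig | None = None,
                             cause: str = "all_cause") -> AUCDiffResult:
    """Percentile bootstrap CI for AUC(marker_b) - AUC(marker_a) at one
    horizon; replicates are stratified by event status."""
    config = config or StatsConfig()
    t, e, w = cohort.survival_arrays(cause)
    ma, mb = cohort.marker(marker_a), cohort.marker(marker_b)
    g = product_limit(t, 1 - e, w)
    diff = (_td_auc_arrays(t, e, w, mb, horizon_days, g)
            - _td_auc_arrays(t, e, w, ma, horizon_days, g))
    rng = np.random.default_rng(config.seed)
    reps = np.empty(config.n_boot)
    for i in range(config.n_boot):
        idx = _stratified_indices(e, rng)
        tb, eb, wb = t[idx], e[idx], w[idx]
        gb = product_limit(tb, 1 - eb, wb)
        reps[i] = (_td_auc_arrays(tb, eb, wb, mb[idx], horizon_days, gb)
                   - _td_auc_arrays(tb, eb, wb, ma[idx], horizon_days, gb))
    lo, hi = np.quantile(reps, [config.alpha / 2, 1 - config.alpha / 2])
    return AUCDiffResult(horizon_days=float(horizon_days), diff=float(diff),
                         ci_low=float(lo), ci_high=float(hi), n_boot=config.n_boot)


# ---------------------------------------------------------------------------
# univariate proportional hazards


@dataclass
class PHFit:
    """One-covariate weighted Cox fit with Breslow baseline hazard."""

    beta: float
    se: float
    event_times: np.ndarray
    cum_hazard: np.ndarray
    n_iter: int

    def cumulative_hazard_at(self, t) -> np.ndarray | float:
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        h = np.concatenate([[0.0], self.cum_hazard])
        return h[idx] if np.ndim(t) else float(h[idx])


def _fit_ph_arrays(time, event, weight, marker, max_iter: int = 100,
                   tol: float = 1e-8) -> PHFit:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    w = np.asarray(weight, dtype=float)
    m = np.asarray(marker, dtype=float)
    sd = float(np.std(m))
    if sd == 0.0:
        raise ValueError("marker is constant; proportional-hazards fit undefined")
    mu = float(np.mean(m))
    ms = (m - mu) / sd  # standardized for Newton stability

    order = np.argsort(t, kind="stable")
    t, e, w, ms_s = t[order], e[order], w[order], ms[order]
    # first index of each tie group: the risk set for an event at t_i is
    # everything from that index on (Breslow convention)
    first = np.searchsorted(t, t, side="left")

    def _risk_sums(beta):
        r = w * np.exp(beta * ms_s)
        s0 = np.cumsum(r[::-1])[::-1]
        s1 = np.cumsum((r * ms_s)[::-1])[::-1]
        s2 = np.cumsum((r * ms_s**2)[::-1])[::-1]
        return s0[first], s1[first], s2[first]

    beta = 0.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        s0, s1, s2 = _risk_sums(beta)
        mean = s1 / s0
        u = float(np.sum(w[e] * (ms_s[e] - mean[e])))
        info = float(np.sum(w[e] * (s2[e] / s0[e] - mean[e] ** 2)))
        if info <= 0:
            raise ConvergenceError("non-positive information in PH fit")
        step = u / info
        beta += step
        if abs(u) < tol:
            break
    else:
        raise ConvergenceError(f"PH fit did not converge in {max_iter} iterations")

    se_std = 1.0 / np.sqrt(info)
    beta_orig = beta / sd
    se_orig = se_std / sd

    # Breslow baseline cumulative hazard on the original marker scale
    # (uncentered), Lambda0(t) = sum_{u<=t} D_u / S0(u).
    r = w * np.exp(beta_orig * (ms_s * sd + mu))
    s0_full = np.cumsum(r[::-1])[::-1][first]
    uniq, uf = np.unique(t[e], return_index=True)
    d = np.zeros(uniq.size)
    np.add.at(d, np.searchsorted(uniq, t[e]), w[e])
    s0_at = s0_full[e][uf]
    cum = np.cumsum(d / s0_at)
    return PHFit(beta=float(beta_orig), se=float(se_orig), event_times=uniq,
                 cum_hazard=cum, n_iter=n_iter)


def fit_univariate_ph(cohort: Cohort, marker: str, cause: str = "all_cause") -> PHFit:
    """Weighted one-covariate proportional-hazards fit for a marker."""
    t, e, w = cohort.survival_arrays(cause)
    return _fit_ph_arrays(t, e, w, cohort.marker(marker))


def predicted_risk_at(fit: PHFit, marker_value, horizon_days: float):
    """Predicted event probability by the horizon:
    ``1 - exp(-Lambda0(t) * exp(beta * m))``."""
    lam = fit.cumulative_hazard_at(horizon_days)
    return 1.0 - np.exp(-lam * np.exp(fit.beta * np.asarray(marker_value, dtype=float)))


# ---------------------------------------------------------------------------
# continuous NRI


@dataclass
class NRIResult:
    horizon_days: float
    nri_percent: float
    components: tuple  # (p_up_event, p_down_event, p_up_nonevent, p_down_nonevent)
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None


def _nri_point(t, e, w, p_old, p_new, horizon: float, warn: bool = True) -> tuple[float, tuple]:
    up = p_new > p_old
    down = p_new < p_old
    total_w = w.sum()
    s_all = product_limit(t, e, w).survival_at(horizon)
    p_event = 1.0 - s_all
    if p_event <= 0 or s_all <= 0:
        return 0.0, (0.0, 0.0, 0.0, 0.0)

    def group_terms(sel):
        if not sel.any():
            return 0.0, 0.0
        pi = w[sel].sum() / total_w
        s_g = product_limit(t[sel], e[sel], w[sel]).survival_at(horizon)
        # Bayes: P(group | event) = pi * P(event | group) / P(event)
        return pi * (1.0 - s_g) / p_event, pi * s_g / s_all

    if warn and not up.any() and not down.any():
        warnings.warn("markers give identical risks; NRI is 0", stacklevel=3)
    p_up_event, p_up_nonevent = group_terms(up)
    p_down_event, p_down_nonevent = group_terms(down)
    nri = (p_up_event - p_down_event) + (p_down_nonevent - p_up_nonevent)
    return 100.0 * nri, (p_up_event, p_down_event, p_up_nonevent, p_down_nonevent)


def _nri_from_fits(t, e, w, m_old, m_new, horizon: float, warn: bool = True):
    fit_old = _fit_ph_arrays(t, e, w, m_old)
    fit_new = _fit_ph_arrays(t, e, w, m_new)
    p_old = 1.0 - np.exp(-fit_old.cumulative_hazard_at(horizon) * np.exp(fit_old.beta * m_old))
    p_new = 1.0 - np.exp(-fit_new.cumulative_hazard_at(horizon) * np.exp(fit_new.beta * m_new))
    return _nri_point(t, e, w, p_old, p_new, horizon, warn=warn)


def continuous_nri(cohort: Cohort, marker_old: str, marker_new: str,
                   horizon_days: float, config: StatsConfig | None = None,
                   cause: str = "all_cause", ci: bool = True) -> NRIResult:
    """Continuous NRI for censored data at one horizon, in percent.

    Predicted risks come from separate univariate proportional-hazards fits
    of the two markers; subjects are classed "up" (new risk higher) or
    "down" (new risk lower; exact ties in neither), and the event
    probabilities within each class are Kaplan-Meier estimates at the
    horizon, combined by Bayes' rule with the weighted class fractions.
    The CI is a stratified percentile bootstrap.
    """
    config = config or StatsConfig()
    t, e, w = cohort.survival_arrays(cause)
    m_old, m_new = cohort.marker(marker_old), cohort.marker(marker_new)
    h = float(horizon_days)
    nri, comps = _nri_from_fits(t, e, w, m_old, m_new, h)
    lo = hi = None
    n_boot = None
    if ci:
        rng = np.random.default_rng(config.seed)
        reps = np.empty(config.n_boot)
        for i in range(config.n_boot):
            idx = _stratified_indices(e, rng)
            reps[i], _ = _nri_from_fits(t[idx], e[idx], w[idx], m_old[idx],
                                        m_new[idx], h, warn=False)
        lo, hi = (float(q) for q in
                  np.quantile(reps, [config.alpha / 2, 1 - config.alpha / 2]))
        n_boot = config.n_boot
    return NRIResult(horizon_days=h, nri_percent=float(nri), components=comps,
                     ci_low=lo, ci_high=hi, n_boot=n_boot)


# ---------------------------------------------------------------------------
# table driver


def evaluate_markers(cohort: Cohort, marker_old: str = "origES",
                     marker_new: str = "normES",
                     config: StatsConfig | None = None,
                     causes: tuple = _CAUSES) -> pd.DataFrame:
    """Per-horizon discrimination/reclassification table for two markers.

    For each cause and each horizon year the table reports the
    time-dependent AUC of both markers, their difference and the continuous
    NRI, each with a stratified-bootstrap percentile CI. One bootstrap loop
    per cause is shared by every statistic so the whole table is produced
    from ``config.n_boot`` replicates.
    """
    config = config or StatsConfig()
    m_old_all = cohort.marker(marker_old)
    m_new_all = cohort.marker(marker_new)
    rows = []
    for ci_cause, cause in enumerate(causes):
        t, e, w = cohort.survival_arrays(cause)
        horizons = [h for h in config.horizons_days if (t[e == 1] <= h).any() and (t > h).any()]
        g = product_limit(t, 1 - e, w)
        point = {}
        for h in horizons:
            auc_old = _td_auc_arrays(t, e, w, m_old_all, h, g)
            auc_new = _td_auc_arrays(t, e, w, m_new_all, h, g)
            nri, _ = _nri_from_fits(t, e, w, m_old_all, m_new_all, h, warn=False)
            point[h] = (auc_old, auc_new, auc_new - auc_old, nri)

        rng = np.random.default_rng(config.seed + ci_cause)
        reps = {h: [] for h in horizons}
        for _ in range(config.n_boot):
            idx = _stratified_indices(e, rng)
            tb, eb, wb = t[idx], e[idx], w[idx]
            mo, mn = m_old_all[idx], m_new_all[idx]
            gb = product_limit(tb, 1 - eb, wb)
            fit_o = _fit_ph_arrays(tb, eb, wb, mo)
            fit_n = _fit_ph_arrays(tb, eb, wb, mn)
            for h in horizons:
                try:
                    a_o = _td_auc_arrays(tb, eb, wb, mo, h, gb)
                    a_n = _td_auc_arrays(tb, eb, wb, mn, h, gb)
                except ValueError:
                    continue
                p_o = 1.0 - np.exp(-fit_o.cumulative_hazard_at(h) * np.exp(fit_o.beta * mo))
                p_n = 1.0 - np.exp(-fit_n.cumulative_hazard_at(h) * np.exp(fit_n.beta * mn))
                nri_b, _ = _nri_point(tb, eb, wb, p_o, p_n, h, warn=False)
                reps[h].append((a_o, a_n, a_n - a_o, nri_b))

        qs = [config.alpha / 2, 1 - config.alpha / 2]
        for h in horizons:
            arr = np.asarray(reps[h])
            (ao_lo, ao_hi), (an_lo, an_hi), (d_lo, d_hi), (nri_lo, nri_hi) = (
                np.quantile(arr[:, j], qs) for j in range(4)
            )
            auc_old, auc_new, diff, nri = point[h]
            rows.append({
                "cause": cause,
                "year": int(round(h / DAYS_PER_YEAR)),
                "horizon_days": h,
                "auc_old": auc_old, "auc_old_lo": ao_lo, "auc_old_hi": ao_hi,
                "auc_new": auc_new, "auc_new_lo": an_lo, "auc_new_hi": an_hi,
                "diff_auc": diff, "diff_auc_lo": d_lo, "diff_auc_hi": d_hi,
                "nri_percent": nri, "nri_lo": nri_lo, "nri_hi": nri_hi,
                "n_boot": config.n_boot,
            })
    return pd.DataFrame(rows)
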