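"""Claims-based validation of candidate drugs.

Builds a new-user migraine cohort from raw claims tables (enrollment,
ICD-10 diagnoses, prescriptions), lays follow-up out as consecutive
time windows with time-varying exposure and covariates, and estimates each
candidate drug's multiplicative effect on the count of acute migraine
medication prescriptions with a mixed-effects log-linear model

    ln(Y_ij + 1) = b0 + a*t_ij + sum_k b_k x_kij + g_i + ln(time_ij) + e_ij

where Y_ij is the acute-prescription count for patient i in window j, t_ij
the binary drug exposure, g_i ~ N(0, tau^2) a patient random intercept and
ln(time_ij) an offset converting counts to rates.  exp(a) is reported as
the relative risk (RR) of acute-medication use under exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DEFAULT_WINDOW_DAYS = 365
DEFAULT_MIN_PARTIAL_DAYS = 90


def _prefix_range(stem: str, lo: int, hi: int) -> tuple[str, ...]:
    return tuple(f"{stem}{i}" for i in range(lo, hi + 1))


#: ICD-10 prefixes excluded from history and censored on post-index:
#: ischemic heart disease I20-I25, stroke I60-I69, TIA G45.
DEFAULT_EXCLUSION_PREFIXES = (
    _prefix_range("I2", 0, 5) + _prefix_range("I6", 0, 9) + ("G45",)
)
#: Extra censoring codes (heart failure) beyond the exclusion set.
DEFAULT_CENSOR_EXTRA = ("I50",)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ClaimsTables:
    """Raw longitudinal claims: enrollment spans, diagnoses, prescriptions."""

    enrollment: pd.DataFrame  # person_id, start_date, end_date, birth_year, sex
    diagnoses: pd.DataFrame   # person_id, date, icd10_code
    prescriptions: pd.DataFrame  # person_id, date, drug_code, drug_class

    def __post_init__(self) -> None:
        need = {
            "enrollment": ["person_id", "start_date", "end_date", "birth_year", "sex"],
            "diagnoses": ["person_id", "date", "icd10_code"],
            "prescriptions": ["person_id", "date", "drug_code", "drug_class"],
        }
        for name, cols in need.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"claims table {name!r} missing columns {missing}")
        for col in ("start_date", "end_date"):
            self.enrollment[col] = pd.to_datetime(self.enrollment[col])
        self.diagnoses["date"] = pd.to_datetime(self.diagnoses["date"])
        self.prescriptions["date"] = pd.to_datetime(self.prescriptions["date"])
        if self.enrollment["person_id"].duplicated().any():
            raise ValueError("multiple enrollment spans per person are not supported")


@dataclass
class EligibilityConfig:
    """Cohort eligibility rules and censoring code sets."""

    migraine_prefix: str = "G43"
    migraine_specific_codes: tuple[str, ...] = (
        "triptan", "ergotamine", "ditan", "migraine_prophylactic",
    )
    exclusion_prefixes: tuple[str, ...] = DEFAULT_EXCLUSION_PREFIXES
    censor_extra_prefixes: tuple[str, ...] = DEFAULT_CENSOR_EXTRA
    diagnosis_window_start: date = date(2018, 9, 1)
    diagnosis_window_end: date = date(2023, 8, 31)
    study_end: date = date(2033, 12, 31)
    min_enrollment_days: int = 180


@dataclass
class Cohort:
    """Eligible patients with index and censoring dates."""

    table: pd.DataFrame  # person_id, index_date, censor_date, censor_reason
    attrition: pd.DataFrame  # rule, description, n_remaining


@dataclass
class CovariateDef:
    """Window-level covariate: presence of matching codes in the window."""

    name: str
    kind: str  # 'rx' (drug_code match) or 'dx' (icd10 prefix match)
    codes: tuple[str, ...]


@dataclass
class ModelResult:
    drug: str
    alpha: float
    se_alpha: float
    beta0: float
    betas: dict[str, float]
    re_var: float
    resid_var: float
    rr: float
    ci_low: float
    ci_high: float
    n_persons: int
    n_windows: int

    def __post_init__(self) -> None:
        if not (self.ci_low < self.rr < self.ci_high):
            raise ValueError("confidence interval does not bracket the RR")


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

def _matches_prefix(codes: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    return codes.astype(str).str.startswith(prefixes)


def build_cohort(claims: ClaimsTables, config: EligibilityConfig | None = None) -> Cohort:
    """Apply the five eligibility rules in order, recording attrition.

    1. migraine diagnosis (prefix G43) inside the diagnosis window;
       the first such diagnosis is the index date (Day 0);
    2. at least one prescription for a migraine-specific medication;
    3. continuous enrollment covering >= 180 days before the index date;
    4. no exclusion-prefix diagnosis (IHD/stroke/TIA) on or before index;
    5. at least 1 day of follow-up before censoring.

    Censoring is the earliest of enrollment end, study end, and the first
    post-index censoring diagnosis (exclusion prefixes plus heart failure).
    """
    cfg = config or EligibilityConfig()
    enr = claims.enrollment
    dx = claims.diagnoses
    rx = claims.prescriptions
    steps: list[tuple[str, str, int]] = []
    n0 = enr["person_id"].nunique()
    steps.append(("0", "persons in claims", n0))

    win_lo = pd.Timestamp(cfg.diagnosis_window_start)
    win_hi = pd.Timestamp(cfg.diagnosis_window_end)
    mig = dx[_matches_prefix(dx["icd10_code"], (cfg.migraine_prefix,))
             & dx["date"].between(win_lo, win_hi)]
    index_date = mig.groupby("person_id")["date"].min()
    kept = enr[enr["person_id"].isin(index_date.index)].copy()
    steps.append(("1", "migraine diagnosis in window", len(kept)))

    has_med = set(rx.loc[rx["drug_code"].isin(cfg.migraine_specific_codes),
                         "person_id"])
    kept = kept[kept["person_id"].isin(has_med)]
    steps.append(("2", "migraine-specific medication", len(kept)))

    kept = kept.assign(index_date=kept["person_id"].map(index_date))
    pre_days = (kept["index_date"] - kept["start_date"]).dt.days
    kept = kept[(pre_days >= cfg.min_enrollment_days)
                & (kept["index_date"] <= kept["end_date"])]
    steps.append(("3", f">= {cfg.min_enrollment_days} d pre-index enrollment",
                  len(kept)))

    excl = dx[_matches_prefix(dx["icd10_code"], cfg.exclusion_prefixes)]
    excl_idx = excl.merge(kept[["person_id", "index_date"]], on="person_id")
    bad = set(excl_idx.loc[excl_idx["date"] <= excl_idx["index_date"], "person_id"])
    kept = kept[~kept["person_id"].isin(bad)]
    steps.append(("4", "no pre-index IHD/stroke/TIA", len(kept)))

    censor_prefixes = cfg.exclusion_prefixes + cfg.censor_extra_prefixes
    ev = dx[_matches_prefix(dx["icd10_code"], censor_prefixes)]
    ev = ev.merge(kept[["person_id", "index_date"]], on="person_id")
    first_event = (ev[ev["date"] > ev["index_date"]]
                   .groupby("person_id")["date"].min())
    kept = kept.assign(
        event_date=kept["person_id"].map(first_event),
        study_end=pd.Timestamp(cfg.study_end),
    )
    censor = kept[["end_date", "study_end", "event_date"]].min(axis=1)
    reason = np.select(
        [censor.eq(kept["event_date"]), censor.eq(kept["end_date"])],
        ["event", "enrollment end"], default="study end",
    )
    kept = kept.assign(censor_date=censor, censor_reason=reason)
    kept = kept[(kept["censor_date"] - kept["index_date"]).dt.days >= 1]
    steps.append(("5", ">= 1 d follow-up", len(kept)))

    attrition = pd.DataFrame(steps, columns=["rule", "description", "n_remaining"])
    if kept.empty:
        raise ValueError(
            "cohort is empty after eligibility filtering; attrition:\n"
            + attrition.to_string(index=False)
        )
    logger.info("cohort attrition:\n%s", attrition.to_string(index=False))
    table = kept[["person_id", "index_date", "censor_date", "censor_reason"]]
    return Cohort(table.reset_index(drop=True), attrition)


# ---------------------------------------------------------------------------
# Person-period construction
# ---------------------------------------------------------------------------

def make_person_periods(
    cohort: Cohort,
    claims: ClaimsTables,
    acute_codes: tuple[str, ...],
    exposure_codes: dict[str, tuple[str, ...]],
    covariate_defs: list[CovariateDef] | None = None,
    window_days: int = DEFAULT_WINDOW_DAYS,
    min_partial_days: int = DEFAULT_MIN_PARTIAL_DAYS,
    step_days: int | None = None,
) -> pd.DataFrame:
    """Lay follow-up out as rolling windows (non-overlapping by default).

    Window j spans [index + j*step, index + j*step + window_days) clipped at
    censoring; with the default ``step_days = window_days`` the windows are
    consecutive and non-overlapping, while a smaller step gives overlapping
    windows for sensitivity analyses (events then count in every window
    containing them).  A trailing window is kept only if it spans at least
    ``min_partial_days``.  Per window: Y = count of acute-code prescription
    records, one binary exposure column per drug (any exposure-code
    prescription in the window), covariate presence indicators, age at
    window start and sex.  ``time`` is the window length in years and
    enters the model as a ln offset.
    """
    covariate_defs = covariate_defs or []
    step = step_days or window_days
    if step < 1:
        raise ValueError("step_days must be >= 1")
    coh = cohort.table
    followup = (coh["censor_date"] - coh["index_date"]).dt.days.to_numpy()
    # window j is kept while its clipped length >= min_partial_days
    n_win = np.where(followup >= min_partial_days,
                     (followup - min_partial_days) // step + 1, 0)
    empty = n_win == 0
    if empty.any():
        logger.warning("%d persons contribute no window (follow-up < %d d)",
                       int(empty.sum()), min_partial_days)

    person = np.repeat(coh["person_id"].to_numpy(), n_win)
    win = np.concatenate([np.arange(k) for k in n_win]) if len(n_win) else np.array([], int)
    idx_rep = np.repeat(coh["index_date"].to_numpy(), n_win)
    fu_rep = np.repeat(followup, n_win)
    start_off = win * step
    end_off = np.minimum(start_off + window_days, fu_rep)
    periods = pd.DataFrame({
        "person_id": person,
        "window": win,
        "start": pd.to_datetime(idx_rep) + pd.to_timedelta(start_off, unit="D"),
        "end": pd.to_datetime(idx_rep) + pd.to_timedelta(end_off, unit="D"),
        "days": end_off - start_off,
    })
    periods["time"] = periods["days"] / DAYS_PER_YEAR

    def _window_of(events: pd.DataFrame) -> pd.DataFrame:
        """Map per-person event dates to every window containing them."""
        m = events.merge(coh[["person_id", "index_date"]], on="person_id")
        off = (m["date"] - m["index_date"]).dt.days
        m = m.assign(offset=off)
        nw = pd.Series(n_win, index=coh["person_id"]).rename("n_win")
        fu = pd.Series(followup, index=coh["person_id"]).rename("fu")
        m = m.join(nw, on="person_id").join(fu, on="person_id")
        m = m[(m["offset"] >= 0) & (m["offset"] < m["fu"])]
        # windows j with j*step <= offset < j*step + window_days
        j_lo = np.maximum(0, (m["offset"] - window_days) // step + 1)
        j_hi = np.minimum(m["offset"] // step, m["n_win"] - 1)
        reps = np.maximum(0, (j_hi - j_lo + 1).to_numpy())
        m = m.loc[m.index.repeat(reps)]
        window = np.concatenate(
            [np.arange(lo, lo + k) for lo, k in zip(j_lo, reps) if k > 0]
        ) if reps.sum() else np.array([], int)
        m = m.assign(window=window)
        # with step > window_days the layout has gaps; drop misses
        return m[m["offset"] - m["window"] * step < window_days]

    rx = claims.prescriptions
    acute = _window_of(rx[rx["drug_code"].isin(acute_codes)])
    y = acute.groupby(["person_id", "window"]).size().rename("Y")
    periods = periods.join(y, on=["person_id", "window"])
    periods["Y"] = periods["Y"].fillna(0).astype(int)

    for drug, codes in exposure_codes.items():
        hits = _window_of(rx[rx["drug_code"].isin(tuple(codes))])
        flag = hits.groupby(["person_id", "window"]).size().rename("n") > 0
        col = f"exposure_{drug}"
        periods = periods.join(flag.rename(col), on=["person_id", "window"])
        periods[col] = periods[col].eq(True).astype(int)

    dx = claims.diagnoses
    for cov in covariate_defs:
        if cov.kind == "rx":
            ev = rx[rx["drug_code"].isin(cov.codes)]
        elif cov.kind == "dx":
            ev = dx[_matches_prefix(dx["icd10_code"], tuple(cov.codes))]
        else:
            raise ValueError(f"unknown covariate kind {cov.kind!r}")
        ev = ev.rename(columns={"date": "date"})
        hits = _window_of(ev)
        flag = hits.groupby(["person_id", "window"]).size().rename("n") > 0
        periods = periods.join(flag.rename(cov.name), on=["person_id", "window"])
        periods[cov.name] = periods[cov.name].eq(True).astype(int)

    demo = claims.enrollment.set_index("person_id")
    periods["age"] = periods["start"].dt.year - periods["person_id"].map(
        demo["birth_year"])
    periods["sex"] = (periods["person_id"].map(demo["sex"]).astype(str)
                      .str.upper().str.startswith("F")).astype(int)
    return periods.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mixed-effects log-linear model
# ---------------------------------------------------------------------------

@dataclass
class _RandomInterceptREML:
    """Profiled REML fit of y = Xb + g_i + e with one random intercept.

    For variance ratio theta = tau^2/sigma^2 the marginal covariance of a
    group with n_i rows is sigma^2 (I + theta J), whose inverse and
    determinant are closed-form (Woodbury), so beta and sigma^2 profile out
    and REML reduces to a 1-d minimization over theta.  The Wald covariance
    of the fixed effects is sigma^2 (X' (I+theta ZZ')^{-1} X)^{-1}, matching
    the usual linear-mixed-model output.
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    tau2: float
    sigma2: float

    @classmethod
    def fit(cls, y: np.ndarray, x: np.ndarray, groups: np.ndarray
            ) -> "_RandomInterceptREML":
        from scipy.optimize import minimize_scalar

        n, p = x.shape
        _, gidx, gsize = np.unique(groups, return_inverse=True,
                                   return_counts=True)
        xtx = x.T @ x
        # per-group sums of rows of X and of y
        xs = np.zeros((len(gsize), p))
        np.add.at(xs, gidx, x)
        ys = np.zeros(len(gsize))
        np.add.at(ys, gidx, y)
        yty = float(y @ y)
        xty = x.T @ y

        def _solve(theta: float):
            c = theta / (1.0 + theta * gsize)          # per-group shrinkage
            a = xtx - (xs.T * c) @ xs                  # X' (I+th ZZ')^-1 X
            b = xty - xs.T @ (c * ys)
            beta = np.linalg.solve(a, b)
            # r' (I+th ZZ')^-1 r via sufficient statistics
            rss = (yty - 2 * beta @ xty + beta @ xtx @ beta
                   - float(c @ (ys - xs @ beta) ** 2))
            return a, beta, rss

        def neg2_reml(log_theta: float) -> float:
            theta = np.exp(log_theta)
            a, _, rss = _solve(theta)
            s2 = rss / (n - p)
            sign, logdet_a = np.linalg.slogdet(a)
            if sign <= 0 or rss <= 0:
                return np.inf
            return ((n - p) * np.log(s2) + float(np.sum(np.log1p(theta * gsize)))
                    + logdet_a)

        opt = minimize_scalar(neg2_reml, bounds=(-12.0, 8.0), method="bounded",
                              options={"xatol": 1e-8})
        theta = float(np.exp(opt.x))
        if neg2_reml(-30.0) < opt.fun:  # boundary: no between-person variance
            theta = 0.0
        a, beta, rss = _solve(theta)
        sigma2 = rss / (n - p)
        cov_beta = sigma2 * np.linalg.inv(a)
        return cls(beta=beta, cov_beta=cov_beta, tau2=theta * sigma2,
                   sigma2=float(sigma2))


def fit_mixed_loglinear(
    periods: pd.DataFrame,
    drug: str,
    covariates: list[str] | None = None,
) -> ModelResult:
    """Fit ln(Y+1) = b0 + a*exposure + covariates + g_i + ln(time) + e.

    The ln(time) offset is moved to the left side (its coefficient is fixed
    at 1), leaving a linear mixed model with a per-person random intercept,
    estimated by profiled REML (exact 1-d optimization; agrees with a
    general-purpose mixed-model optimizer to numerical precision).
    exp(a) is the exposure RR with a Wald 95% CI.
    """
    covariates = covariates or []
    col = f"exposure_{drug}"
    if col not in periods.columns:
        raise ValueError(f"no exposure column for drug {drug!r}")
    if periods["person_id"].nunique() < 2:
        raise ValueError("need at least 2 persons to fit a mixed model")
    expo = periods[col]
    if expo.nunique() < 2:
        raise ValueError(
            f"drug {drug!r}: no exposed (or no unexposed) windows"
        )
    endog = (np.log(periods["Y"] + 1.0) - np.log(periods["time"])).to_numpy()
    names = ["const", col] + list(covariates)
    exog = np.column_stack(
        [np.ones(len(periods)), expo.to_numpy(dtype=float)]
        + [periods[c].to_numpy(dtype=float) for c in covariates]
    )
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise ValueError(
            f"singular design for drug {drug!r}: rank {rank} < "
            f"{exog.shape[1]} columns {names}"
        )
    res = _RandomInterceptREML.fit(endog, exog, periods["person_id"].to_numpy())
    alpha = float(res.beta[1])
    se = float(np.sqrt(res.cov_beta[1, 1]))
    if not np.isfinite(se) or se <= 0:
        raise ValueError(
            f"singular mixed-model fit for drug {drug!r}: non-finite "
            f"standard error (re_var={res.tau2:.3g}, resid_var={res.sigma2:.3g})"
        )
    rr = float(np.exp(alpha))
    return ModelResult(
        drug=drug, alpha=alpha, se_alpha=se,
        beta0=float(res.beta[0]),
        betas={c: float(res.beta[i + 2]) for i, c in enumerate(covariates)},
        re_var=res.tau2, resid_var=res.sigma2,
        rr=rr, ci_low=float(np.exp(alpha - 1.96 * se)),
        ci_high=float(np.exp(alpha + 1.96 * se)),
        n_persons=int(periods["person_id"].nunique()),
        n_windows=int(len(periods)),
    )


def run_validation(
    periods: pd.DataFrame,
    drugs: list[str],
    covariate_map: dict[str, list[str]] | None = None,
) -> tuple[list[ModelResult], list[tuple[str, str]]]:
    """One independent mixed-model fit per candidate drug.

    ``covariate_map`` supplies each drug's adjustment set (common covariates
    plus drug-specific confounders).  Drugs whose fit preconditions fail are
    reported as skipped rather than aborting the run.  Results are sorted by
    ascending RR.
    """
    covariate_map = covariate_map or {}
    results: list[ModelResult] = []
    skipped: list[tuple[str, str]] = []
    for drug in drugs:
        try:
            results.append(
                fit_mixed_loglinear(periods, drug, covariate_map.get(drug, []))
            )
        except (ValueError, KeyError) as exc:
            logger.warning("drug %s skipped: %s", drug, exc)
            skipped.append((drug, str(exc)))
    results.sort(key=lambda r: r.rr)
    return results, skipped


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


def forest_table(results: list[ModelResult], adjust: bool = False) -> pd.DataFrame:
    """Tabular forest-plot input: drug, RR, CI bounds, sample sizes.

    With ``adjust=True`` two extra columns report the per-drug Wald p-value
    and its Benjamini-Hochberg adjustment across the listed drugs (the
    primary report stays per-drug CIs without multiplicity correction).
    """
    if not results:
        raise ValueError("no model results to tabulate")
    tab = pd.DataFrame(
        [(r.drug, r.rr, r.ci_low, r.ci_high, r.n_persons, r.n_windows)
         for r in results],
        columns=["drug", "RR", "ci_low", "ci_high", "n_persons", "n_windows"],
    )
    if adjust:
        from scipy import stats as _st

        p = np.array([2 * _st.norm.sf(abs(r.alpha / r.se_alpha))
                      for r in results])
        tab["p_value"] = p
        tab["p_bh"] = _bh_adjust(p)
    return tab


def forest_plot(results: list[ModelResult], path: str) -> None:
    """Save a forest plot of per-drug RRs with 95% CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = forest_table(results)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(tab) + 1.5))
    ypos = np.arange(len(tab))[::-1]
    rr = tab["RR"].to_numpy()
    ax.errorbar(
        rr, ypos,
        xerr=[rr - tab["ci_low"].to_numpy(), tab["ci_high"].to_numpy() - rr],
        fmt="o", color="k", ecolor="gray", capsize=3,
    )
    ax.axvline(1.0, color="r", linestyle="--", linewidth=1)
    ax.set_yticks(ypos)
    ax.set_yticklabels(tab["drug"])
    ax.set_xlabel("RR of acute migraine medication use (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
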