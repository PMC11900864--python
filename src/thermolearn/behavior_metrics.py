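"""Model-free behavioral analyses and perceptual indices.

Trial labelling (predicted / neutral / unpredicted / TGI), error rates,
post-prediction-error slowing of response times, and the thermal-grill
indices: perceived TGI quality ratio (cold / (cold + warm)), TGI
responsiveness (TGI burning minus the larger innocuous burning), and
the uncertainty modulation of TGI index (UMTI) coupling second-level
estimation uncertainty to TGI burning ratings.  Ratings are analyzed
with a zero-one-inflated beta (ZOIB) likelihood with logit links,
fitted as a fixed-effects (pooled or per-subject) model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import betaln, expit, logit

from .learning_models import BeliefTrajectory
from .synthetic_data import BehavioralDataset

__all__ = [
    "TrialLabel",
    "ZOIBParams",
    "MetricsReport",
    "label_trials",
    "error_rates",
    "post_pe_slowing",
    "tgi_quality_ratio",
    "tgi_responsiveness",
    "compute_umti",
    "zoib_logpdf",
    "zoib_fit",
    "uncertainty_bins",
    "compute_metrics",
]

LABELS = ("predicted", "neutral", "unpredicted", "tgi")


def label_trials(data: BehavioralDataset) -> pd.Series:
    """Categorize each trial as predicted / neutral / unpredicted / tgi.

    An innocuous trial in a predictive block (nominal probability 82% or
    18%) is ``predicted`` when the delivered stimulus matches the
    subject's prediction and ``unpredicted`` otherwise; innocuous trials
    in chance-level (50%) blocks are ``neutral`` regardless of accuracy;
    TGI trials are ``tgi``.  Trials with a missing prediction in a
    predictive block get the label ``missing``.
    """
    df = data.df
    out = np.empty(len(df), dtype=object)
    stim = df["stimulus"].to_numpy()
    pred = df["prediction"].to_numpy()
    p_nom = df["p_nominal"].to_numpy(dtype=float)
    for i in range(len(df)):
        if stim[i] == "tgi":
            out[i] = "tgi"
        elif abs(p_nom[i] - 0.5) < 1e-9:
            out[i] = "neutral"
        elif not isinstance(pred[i], str):
            out[i] = "missing"
        else:
            out[i] = "predicted" if pred[i] == stim[i] else "unpredicted"
    return pd.Series(out, index=df.index, name="label")


def error_rates(data: BehavioralDataset, labels: pd.Series | None = None,
                by: str = "preceding") -> dict:
    """Prediction error rate per trial category.

    An error is a non-missing prediction that differs from the delivered
    innocuous stimulus; TGI trials have no correct answer and are
    excluded from the error count.  ``by='preceding'`` (default) groups
    each trial's error by the *preceding* trial's label, the sequence
    analysis in which the predicted/unpredicted categories are
    informative (grouping by a trial's own match-based label is
    degenerate).  ``by='block'`` instead groups by the current block
    type (predictive vs neutral).  Categories with no usable trials are
    reported as None rather than zero.
    """
    if by not in ("preceding", "block"):
        raise ValueError("by must be 'preceding' or 'block'")
    labels = label_trials(data) if labels is None else labels
    df = data.df
    stim = df["stimulus"].to_numpy()
    pred = df["prediction"].to_numpy()
    innocuous = stim != "tgi"
    answered = np.array([isinstance(p, str) for p in pred])
    err = np.array([
        isinstance(p, str) and s != "tgi" and p != s for p, s in zip(pred, stim)
    ])

    groups: dict[str, list[int]] = {}
    if by == "preceding":
        lab = labels.to_numpy()
        for i in range(1, len(df)):
            if innocuous[i] and answered[i] and lab[i - 1] in LABELS:
                groups.setdefault(lab[i - 1], []).append(i)
        keys = LABELS
    else:
        p_nom = df["p_nominal"].to_numpy(dtype=float)
        for i in range(len(df)):
            if innocuous[i] and answered[i]:
                key = "neutral" if abs(p_nom[i] - 0.5) < 1e-9 else "predictive"
                groups.setdefault(key, []).append(i)
        keys = ("predictive", "neutral")

    out = {}
    for key in keys:
        idx = groups.get(key)
        out[key] = None if not idx else float(err[idx].mean())
    return out


def post_pe_slowing(data: BehavioralDataset, labels: pd.Series | None = None,
                    fit_glm: bool = True) -> dict:
    """Response times grouped by the preceding trial's label.

    Returns per-category mean RTs (seconds) and, when ``fit_glm`` is
    true and enough categories are populated, coefficients of a gamma
    GLM with logarithmic link regressing RT on the preceding label
    (reference level: predicted) — positive coefficients indicate
    slowing relative to trials that followed confirmed predictions.
    The first trial has no predecessor and is dropped; categories with
    no successor RTs are reported as None.
    """
    labels = label_trials(data) if labels is None else labels
    lab = labels.to_numpy()
    rt = data.df["response_time_s"].to_numpy(dtype=float)
    rows = []
    for i in range(1, len(lab)):
        if lab[i - 1] in LABELS and np.isfinite(rt[i]):
            rows.append((lab[i - 1], rt[i]))
    tab = pd.DataFrame(rows, columns=["prev_label", "rt"])
    means = {
        key: (float(tab.loc[tab["prev_label"] == key, "rt"].mean())
              if (tab["prev_label"] == key).any() else None)
        for key in LABELS
    }
    result = {"means": means, "n": {k: int((tab["prev_label"] == k).sum()) for k in LABELS}}
    present = [k for k in LABELS if means[k] is not None]
    if fit_glm and len(present) >= 2 and "predicted" in present and len(tab) >= 8:
        X = pd.get_dummies(pd.Categorical(tab["prev_label"], categories=present),
                           drop_first=False).astype(float)
        X = X.drop(columns=["predicted"])
        X = sm.add_constant(X)
        glm = sm.GLM(tab["rt"].to_numpy(), X.to_numpy(),
                     family=sm.families.Gamma(sm.families.links.Log()))
        try:
            res = glm.fit()
            result["glm_coefficients"] = dict(zip(["intercept"] + list(X.columns[1:]),
                                                  [float(b) for b in res.params]))
        except Exception as exc:  # singular designs on degenerate inputs
            result["glm_coefficients"] = None
            result["glm_error"] = str(exc)
    else:
        result["glm_coefficients"] = None
    return result


def tgi_quality_ratio(data: BehavioralDataset) -> float | None:
    """Perceived TGI quality: mean over rated TGI trials of
    cold / (cold + warm) rating, in [0, 1]; 0.5 marks thermal ambiguity
    (TGI felt equally warm and cold).  Trials with both ratings zero
    are skipped; returns None when no usable TGI rating exists."""
    df = data.df
    m = (df["stimulus"] == "tgi") & df["vas_cold"].notna() & df["vas_warm"].notna()
    cold = df.loc[m, "vas_cold"].to_numpy(dtype=float)
    warm = df.loc[m, "vas_warm"].to_numpy(dtype=float)
    denom = cold + warm
    ok = denom > 0
    if not ok.any():
        return None
    return float(np.mean(cold[ok] / denom[ok]))


def tgi_responsiveness(data: BehavioralDataset) -> float | None:
    """TGI responsiveness: mean burning rating on TGI trials minus the
    larger of the mean burning ratings on innocuous cold and warm
    trials.  Negative values mark non-responders.  Returns None if any
    of the three per-stimulus burning-rating sets is empty."""
    df = data.df
    means = {}
    for st in ("tgi", "cold", "warm"):
        vals = df.loc[(df["stimulus"] == st) & df["vas_burn"].notna(), "vas_burn"]
        if len(vals) == 0:
            return None
        means[st] = float(vals.mean())
    return means["tgi"] - max(means["cold"], means["warm"])


def compute_umti(data: BehavioralDataset, traj: BeliefTrajectory,
                 min_tgi: int = 3) -> float | None:
    """Uncertainty modulation of TGI index (UMTI).

    Per-subject contrast of estimation-uncertainty slopes on burning
    ratings: an ordinary least-squares fit of vas_burn/100 on
    [1, tgi, eu, eu x tgi] over rated trials returns the interaction
    coefficient — the difference between the slope of burning on
    second-level estimation uncertainty (1/pi2) for TGI trials and that
    slope for innocuous trials.  Positive values mean burning rises
    with estimation uncertainty specifically on TGI trials.  Requires
    an HGF trajectory and at least ``min_tgi`` rated TGI trials (plus
    as many rated innocuous trials); otherwise returns None.
    """
    eu = traj.estimation_uncertainty  # raises for non-HGF trajectories
    df = data.df
    m = df["vas_burn"].notna().to_numpy()
    if m.sum() < 2 * min_tgi:
        return None
    is_tgi = (df["stimulus"] == "tgi").to_numpy(dtype=float)[m]
    if is_tgi.sum() < min_tgi or (1 - is_tgi).sum() < min_tgi:
        return None
    y = df["vas_burn"].to_numpy(dtype=float)[m] / 100.0
    x_eu = eu[m]
    if np.std(x_eu) == 0:
        return None
    X = np.column_stack([np.ones(m.sum()), is_tgi, x_eu, x_eu * is_tgi])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[3])


def uncertainty_bins(values: np.ndarray, n_bins: int = 9) -> np.ndarray:
    """Discretize an uncertainty trajectory into equal-count bins
    (1..n_bins) for binned reports."""
    values = np.asarray(values, dtype=float)
    ranks = pd.Series(values).rank(method="first").to_numpy()
    return np.ceil(ranks / len(values) * n_bins).astype(int)


# --------------------------------------------------------------------------
# Zero-one-inflated beta likelihood

@dataclass
class ZOIBParams:
    """Fitted ZOIB coefficients (all on link scales).

    ``mu_coef`` are logit-scale coefficients of the beta mean over the
    design columns; ``log_phi`` is the log precision; ``logit_p0`` and
    ``logit_p1`` are the zero- and one-inflation intercepts.
    """

    mu_coef: np.ndarray
    log_phi: float
    logit_p0: float
    logit_p1: float
    coef_names: list[str] = field(default_factory=list)
    se: np.ndarray | None = None
    converged: bool = True
    separation_flag: bool = False
    n_obs: int = 0
    loglik: float = np.nan

    @property
    def phi(self) -> float:
        return float(np.exp(self.log_phi))

    @property
    def p0(self) -> float:
        return float(expit(self.logit_p0))

    @property
    def p1(self) -> float:
        return float(expit(self.logit_p1))

    def coefficient(self, name: str) -> float:
        return float(self.mu_coef[self.coef_names.index(name)])

    def coefficient_se(self, name: str) -> float:
        return float(self.se[self.coef_names.index(name)])


def zoib_logpdf(y, mu, phi, p0, p1):
    """Log density of the zero-one-inflated beta distribution.

    Point masses p0 at 0 and p1 at 1; on (0, 1) a Beta with shapes
    (mu * phi, (1 - mu) * phi) scaled by 1 - p0 - p1.  Vectorized over
    y; raises for y outside [0, 1] or p0 + p1 >= 1.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("ratings must lie in [0, 1]")
    p0 = float(p0)
    p1 = float(p1)
    if not (0 <= p0 < 1 and 0 <= p1 < 1 and p0 + p1 < 1):
        raise ValueError("need p0, p1 in [0, 1) with p0 + p1 < 1")
    mu = np.clip(np.asarray(mu, dtype=float), 1e-10, 1 - 1e-10)
    phi = np.asarray(phi, dtype=float)
    a = mu * phi
    b = (1.0 - mu) * phi
    with np.errstate(divide="ignore"):
        out = np.where(
            y == 0.0,
            np.log(p0) if p0 > 0 else -np.inf,
            np.where(
                y == 1.0,
                np.log(p1) if p1 > 0 else -np.inf,
                np.log1p(-(p0 + p1))
                + (a - 1.0) * np.log(np.where((y > 0) & (y < 1), y, 0.5))
                + (b - 1.0) * np.log1p(-np.where((y > 0) & (y < 1), y, 0.5))
                - betaln(a, b),
            ),
        )
    return out if out.ndim else float(out)


def zoib_fit(ratings, design=None, coef_names: list[str] | None = None,
             maxiter: int = 500) -> ZOIBParams:
    """Maximum-likelihood ZOIB regression with logit/log links.

    ``ratings`` live on [0, 1] (rescale VAS by /100 first); ``design``
    is an (n x p) matrix / DataFrame for the beta-mean logit (an
    intercept column is prepended if absent; None means intercept
    only).  Precision and the two inflation probabilities are fitted as
    intercepts.  Standard errors come from the inverse Hessian at the
    optimum.  Complete separation in an inflation component (no mass at
    a bound) is flagged and the corresponding logit capped at -15.
    """
    y = np.asarray(ratings, dtype=float)
    if np.any((y < 0) | (y > 1)) or not np.all(np.isfinite(y)):
        raise ValueError("ratings must be finite and lie in [0, 1]")
    n = len(y)
    if n < 10:
        raise ValueError(f"need >= 10 observations, got {n}")
    if design is None:
        X = np.ones((n, 1))
        names = ["intercept"]
    else:
        if isinstance(design, pd.DataFrame):
            names = list(design.columns)
            X = design.to_numpy(dtype=float)
        else:
            X = np.asarray(design, dtype=float)
            names = coef_names or [f"x{i}" for i in range(X.shape[1])]
        if not np.any(np.all(X == 1.0, axis=0)):
            X = np.column_stack([np.ones(n), X])
            names = ["intercept"] + names
    p = X.shape[1]
    has0 = bool(np.any(y == 0.0))
    has1 = bool(np.any(y == 1.0))

    CAP = 15.0

    def unpack(theta):
        beta = theta[:p]
        log_phi = theta[p]
        l0 = theta[p + 1] if has0 else -CAP
        l1 = theta[p + 1 + has0] if has1 else -CAP
        return beta, log_phi, l0, l1

    def nll(theta):
        beta, log_phi, l0, l1 = unpack(theta)
        if abs(log_phi) > 12 or abs(l0) > 25 or abs(l1) > 25:
            return 1e10
        mu = expit(X @ beta)
        p0 = expit(l0)
        p1 = expit(l1)
        if p0 + p1 >= 1:
            return 1e10
        val = -float(np.sum(zoib_logpdf(y, mu, np.exp(log_phi), p0, p1)))
        return val if np.isfinite(val) else 1e10

    dim = p + 1 + has0 + has1
    theta0 = np.zeros(dim)
    theta0[p] = 1.0  # log phi
    for j in range(p + 1, dim):
        theta0[j] = -2.0
    res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                            options={"maxiter": maxiter})

    from .inversion import _numeric_hessian

    H = _numeric_hessian(nll, res.x)
    se_full = np.full(dim, np.nan)
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            se_full = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        except np.linalg.LinAlgError:
            pass

    beta, log_phi, l0, l1 = unpack(res.x)
    separation = (not has0) or (not has1) or abs(l0) > CAP or abs(l1) > CAP
    l0 = float(np.clip(l0, -CAP, CAP))
    l1 = float(np.clip(l1, -CAP, CAP))
    if not res.success:
        warnings.warn(f"ZOIB fit did not fully converge: {res.message}",
                      RuntimeWarning, stacklevel=2)
    return ZOIBParams(
        mu_coef=np.asarray(beta, dtype=float),
        log_phi=float(log_phi),
        logit_p0=l0,
        logit_p1=l1,
        coef_names=names,
        se=se_full[:p],
        converged=bool(res.success),
        separation_flag=separation,
        n_obs=n,
        loglik=-float(res.fun),
    )


# --------------------------------------------------------------------------
# Per-subject and group report

@dataclass
class MetricsReport:
    """Per-subject metrics with group summaries."""

    per_subject: pd.DataFrame
    group: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"per_subject": self.per_subject.to_dict(orient="records"),
                 "group": self.group},
                fh, indent=1, sort_keys=True, default=_jsonable,
            )


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def compute_metrics(cohort: list[BehavioralDataset],
                    trajectories: list[BeliefTrajectory] | None = None) -> MetricsReport:
    """Compute all indices for a cohort.

    ``trajectories`` (HGF belief trajectories aligned with the cohort)
    enable the UMTI; without them the UMTI column is absent.
    """
    rows = []
    for i, ds in enumerate(cohort):
        labels = label_trials(ds)
        errs = error_rates(ds, labels)
        slow = post_pe_slowing(ds, labels, fit_glm=False)
        row = {
            "subject_id": ds.subject_id,
            "missing_fraction": ds.missing_fraction,
            "excluded": not ds.passes_exclusion(),
            "tgi_quality_ratio": tgi_quality_ratio(ds),
            "tgi_responsiveness": tgi_responsiveness(ds),
        }
        for k, v in errs.items():
            row[f"error_rate_after_{k}"] = v
        for k, v in slow["means"].items():
            row[f"rt_after_{k}"] = v
        if trajectories is not None:
            row["umti"] = compute_umti(ds, trajectories[i])
        rows.append(row)
    per_subject = pd.DataFrame(rows)
    group = {}
    for col in per_subject.columns:
        if col in ("subject_id", "excluded"):
            continue
        vals = pd.to_numeric(per_subject[col], errors="coerce")
        if vals.notna().any():
            group[f"mean_{col}"] = float(vals.mean())
    group["n_subjects"] = len(cohort)
    group["n_excluded"] = int(per_subject["excluded"].sum())
    return MetricsReport(per_subject=per_subject, group=group)
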