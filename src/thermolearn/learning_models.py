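"""Trial-wise perceptual filters for binary cue-outcome learning.

Implements the two-level Hierarchical Gaussian Filter (HGF) for binary
outcomes together with three classical competitors (Rescorla-Wagner,
Sutton's K1 gain-adaptation rule, and Pearce-Hall associability), all
operating on a contingency input sequence ``u`` with values in [0, 1].
Innocuous trials carry ``u`` in {0, 1}; thermal-grill (TGI) trials carry
the intermediate value 0.5, which every filter consumes unchanged (the
prediction error ``u - s_hat`` remains well defined).

Two HGF variants are provided:

* ``canonical`` (default): the standard binary HGF update in which the
  second-level predicted precision is inflated by the volatility step
  ``exp(omega)`` each trial, making omega identifiable from choice data.
* ``paper``: a stripped recursion in which the second-level precision
  only accumulates first-level precision (``pi2 += pi1``) and omega plays
  no role.  Its precision is non-decreasing, so it cannot track
  reversals indefinitely; it is kept for auditing and regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "EPS",
    "HGFParams",
    "RWParams",
    "K1Params",
    "PHParams",
    "BeliefTrajectory",
    "EstimationUncertaintyUnavailable",
    "sigmoid",
    "hgf_filter",
    "rw_filter",
    "k1_filter",
    "ph_filter",
    "extract_uncertainties",
    "run_filter",
]

#: Probability clipping bound keeping likelihoods finite.
EPS = 1e-8


def sigmoid(x):
    """Logistic sigmoid S(x) = 1 / (1 + exp(-x)), overflow-safe.

    Accepts scalars or arrays; the result lies strictly in (0, 1) for
    finite input.
    """
    return expit(x)


class EstimationUncertaintyUnavailable(ValueError):
    """Raised when second-level uncertainty is requested from a model
    that has no second level (RW, K1, PH)."""


@dataclass
class HGFParams:
    """Two-level binary HGF parameters.

    omega is the log-volatility step size of the second-level Gaussian
    random walk: each trial the predicted second-level variance grows by
    exp(omega), so larger omega means faster belief updating.  It is
    only used in ``canonical`` mode.
    """

    omega: float = -3.0
    mu2_init: float = 0.0
    sigma2_init: float = 1.0
    mode: str = "canonical"

    def __post_init__(self) -> None:
        if not self.sigma2_init > 0:
            raise ValueError(f"sigma2_init must be > 0, got {self.sigma2_init}")
        if self.mode not in ("canonical", "paper"):
            raise ValueError(f"mode must be 'canonical' or 'paper', got {self.mode!r}")


@dataclass
class RWParams:
    """Rescorla-Wagner delta rule with fixed learning rate alpha."""

    alpha: float = 0.2
    v_init: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.v_init < 1.0:
            raise ValueError(f"v_init must lie in (0, 1), got {self.v_init}")


@dataclass
class K1Params:
    """Sutton K1 gain-adaptation rule.

    The per-trial gain is k = exp(beta); beta itself is meta-learned at
    rate mu_k1 from the correlation between the current prediction error
    and a trace h of recent updates.
    """

    mu_k1: float = 0.1
    beta_init: float = float(np.log(0.1))
    v_init: float = 0.5

    def __post_init__(self) -> None:
        if not self.mu_k1 > 0:
            raise ValueError(f"mu_k1 must be > 0, got {self.mu_k1}")
        if not 0.0 < self.v_init < 1.0:
            raise ValueError(f"v_init must lie in (0, 1), got {self.v_init}")


@dataclass
class PHParams:
    """Pearce-Hall associability model: the effective learning rate
    kappa * alpha_t tracks the running magnitude of prediction errors."""

    eta: float = 0.3
    kappa: float = 0.5
    alpha_init: float = 1.0
    v_init: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.eta < 1.0:
            raise ValueError(f"eta must lie in (0, 1), got {self.eta}")
        if not 0.0 < self.kappa <= 1.0:
            raise ValueError(f"kappa must lie in (0, 1], got {self.kappa}")
        if not 0.0 < self.alpha_init <= 1.0:
            raise ValueError(f"alpha_init must lie in (0, 1], got {self.alpha_init}")
        if not 0.0 < self.v_init < 1.0:
            raise ValueError(f"v_init must lie in (0, 1), got {self.v_init}")


@dataclass
class BeliefTrajectory:
    """Per-trial belief states produced by a filter.

    For every model, ``s_hat[t]`` is the predictive probability (before
    the trial-t outcome) that the contingency input equals 1, ``pe[t]``
    is the prediction error ``u[t] - s_hat[t]``, and
    ``prediction_uncertainty[t] = s_hat[t] * (1 - s_hat[t])`` is the
    first-level Bernoulli variance (the inverse first-level precision).

    HGF trajectories additionally carry the second-level posterior mean
    ``mu2`` and precision ``pi2``; their inverse ``1/pi2`` is the
    estimation uncertainty about the cue-outcome association strength.
    Non-HGF trajectories carry the value trace ``v`` instead and raise
    :class:`EstimationUncertaintyUnavailable` if second-level
    uncertainty is requested.
    """

    model: str
    u: np.ndarray
    s_hat: np.ndarray
    pe: np.ndarray
    mu2: np.ndarray | None = None
    pi2: np.ndarray | None = None
    v: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.s_hat)

    @property
    def prediction_uncertainty(self) -> np.ndarray:
        return self.s_hat * (1.0 - self.s_hat)

    @property
    def has_estimation_uncertainty(self) -> bool:
        return self.pi2 is not None

    @property
    def estimation_uncertainty(self) -> np.ndarray:
        if self.pi2 is None:
            raise EstimationUncertaintyUnavailable(
                f"model {self.model!r} has no second level; "
                "estimation uncertainty is only defined for the HGF"
            )
        return 1.0 / self.pi2

    def to_frame(self) -> pd.DataFrame:
        """One row per trial, one column per trajectory field."""
        cols = {
            "trial": np.arange(1, self.n_trials + 1),
            "u": self.u,
            "s_hat": self.s_hat,
            "pe": self.pe,
            "prediction_uncertainty": self.prediction_uncertainty,
        }
        if self.mu2 is not None:
            cols["mu2"] = self.mu2
            cols["pi2"] = self.pi2
            cols["estimation_uncertainty"] = self.estimation_uncertainty
        if self.v is not None:
            cols["v"] = self.v
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_inputs(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise ValueError(f"u must be one-dimensional, got shape {u.shape}")
    if not np.all(np.isfinite(u)) or np.any(u < 0.0) or np.any(u > 1.0):
        bad = np.flatnonzero(~((u >= 0.0) & (u <= 1.0)))
        raise ValueError(f"u must lie in [0, 1]; offending trial indices: {bad[:5]}")
    return u


def _clip_prob(p: float) -> float:
    return min(max(p, EPS), 1.0 - EPS)


def hgf_filter(u, params: HGFParams) -> BeliefTrajectory:
    """Run the two-level binary HGF over a contingency input sequence.

    Canonical mode, per trial t (with previous state mu2, pi2)::

        s_hat  = S(mu2)
        pi_hat = 1 / (1/pi2 + exp(omega))          # volatility inflation
        pi2'   = pi_hat + s_hat * (1 - s_hat)
        mu2'   = mu2 + (1/pi2') * (u[t] - s_hat)

    Paper mode drops the volatility inflation: ``pi2' = pi2 + s_hat*(1-s_hat)``
    with the same mean update.  In that variant omega is unused and pi2
    is non-decreasing.

    Raises ``ValueError`` on inputs outside [0, 1] or if the belief
    becomes non-finite (the message names the trial index).
    """
    u = _check_inputs(u)
    n = len(u)
    mu2 = float(params.mu2_init)
    pi2 = 1.0 / float(params.sigma2_init)
    e_omega = float(np.exp(params.omega))
    canonical = params.mode == "canonical"

    s_hat_t = np.empty(n)
    pe_t = np.empty(n)
    mu2_t = np.empty(n)
    pi2_t = np.empty(n)

    for t in range(n):
        s_hat = _clip_prob(float(sigmoid(mu2)))
        pi1_inv = s_hat * (1.0 - s_hat)
        if canonical:
            pi_hat = 1.0 / (1.0 / pi2 + e_omega)
        else:
            pi_hat = pi2
        pi2 = pi_hat + pi1_inv
        delta = u[t] - s_hat
        mu2 = mu2 + delta / pi2
        if not (np.isfinite(mu2) and np.isfinite(pi2) and pi2 > 0.0):
            raise ValueError(f"HGF belief became non-finite at trial {t + 1}")
        s_hat_t[t] = s_hat
        pe_t[t] = delta
        mu2_t[t] = mu2
        pi2_t[t] = pi2

    return BeliefTrajectory(
        model="hgf2",
        u=u,
        s_hat=s_hat_t,
        pe=pe_t,
        mu2=mu2_t,
        pi2=pi2_t,
        params={"omega": params.omega, "mode": params.mode},
    )


def rw_filter(u, params: RWParams) -> BeliefTrajectory:
    """Rescorla-Wagner: v' = v + alpha * (u - v); the prediction for
    trial t is the pre-update value."""
    u = _check_inputs(u)
    n = len(u)
    v = float(params.v_init)
    a = float(params.alpha)
    s_hat_t = np.empty(n)
    pe_t = np.empty(n)
    v_t = np.empty(n)
    for t in range(n):
        s_hat = _clip_prob(v)
        delta = u[t] - v
        v = v + a * delta
        s_hat_t[t] = s_hat
        pe_t[t] = u[t] - s_hat
        v_t[t] = v
    return BeliefTrajectory(
        model="rw", u=u, s_hat=s_hat_t, pe=pe_t, v=v_t, params={"alpha": a}
    )


def k1_filter(u, params: K1Params) -> BeliefTrajectory:
    """Sutton K1 gain adaptation.

    Per trial: delta = u - v; beta += mu_k1 * delta * h; k = exp(beta);
    v = clip(v + k * delta); h = h * max(0, 1 - k) + k * delta, h0 = 0.
    Raises ``ValueError`` (with trial index) if the gain diverges.
    """
    u = _check_inputs(u)
    n = len(u)
    v = float(params.v_init)
    beta = float(params.beta_init)
    h = 0.0
    mu_k1 = float(params.mu_k1)
    s_hat_t = np.empty(n)
    pe_t = np.empty(n)
    v_t = np.empty(n)
    for t in range(n):
        s_hat = _clip_prob(v)
        delta = u[t] - v
        beta = beta + mu_k1 * delta * h
        k = np.exp(beta)
        if not np.isfinite(k):
            raise ValueError(f"K1 gain diverged at trial {t + 1}")
        v = min(max(v + k * delta, EPS), 1.0 - EPS)
        h = h * max(0.0, 1.0 - k) + k * delta
        s_hat_t[t] = s_hat
        pe_t[t] = u[t] - s_hat
        v_t[t] = v
    return BeliefTrajectory(
        model="k1",
        u=u,
        s_hat=s_hat_t,
        pe=pe_t,
        v=v_t,
        params={"mu_k1": mu_k1, "beta_init": params.beta_init},
    )


def ph_filter(u, params: PHParams) -> BeliefTrajectory:
    """Pearce-Hall: v' = v + kappa * assoc * delta with associability
    assoc' = eta * |delta| + (1 - eta) * assoc."""
    u = _check_inputs(u)
    n = len(u)
    v = float(params.v_init)
    assoc = float(params.alpha_init)
    eta = float(params.eta)
    kappa = float(params.kappa)
    s_hat_t = np.empty(n)
    pe_t = np.empty(n)
    v_t = np.empty(n)
    for t in range(n):
        s_hat = _clip_prob(v)
        delta = u[t] - v
        v = v + kappa * assoc * delta
        assoc = eta * abs(delta) + (1.0 - eta) * assoc
        s_hat_t[t] = s_hat
        pe_t[t] = u[t] - s_hat
        v_t[t] = v
    return BeliefTrajectory(
        model="ph",
        u=u,
        s_hat=s_hat_t,
        pe=pe_t,
        v=v_t,
        params={"eta": eta, "kappa": kappa},
    )


_FILTERS = {
    "hgf2": (hgf_filter, HGFParams),
    "rw": (rw_filter, RWParams),
    "k1": (k1_filter, K1Params),
    "ph": (ph_filter, PHParams),
}

SUPPORTED_MODELS = tuple(_FILTERS)


def run_filter(model: str, u, params: dict | None = None, **extra) -> BeliefTrajectory:
    """Dispatch to a filter by model name with keyword parameters.

    ``params`` entries override the model's dataclass defaults; unknown
    model names raise ``ValueError`` listing the supported models.
    """
    if model not in _FILTERS:
        raise ValueError(
            f"unknown model {model!r}; supported models: {sorted(_FILTERS)}"
        )
    fn, cls = _FILTERS[model]
    kwargs = dict(params or {})
    kwargs.update(extra)
    return fn(u, cls(**kwargs))


def extract_uncertainties(traj: BeliefTrajectory, require_estimation: bool = False) -> pd.DataFrame:
    """Tabulate per-trial prediction and estimation uncertainty.

    Prediction uncertainty is the first-level Bernoulli variance
    s_hat * (1 - s_hat); estimation uncertainty is 1/pi2 and is only
    defined for HGF trajectories.  For other models the column is
    omitted; pass ``require_estimation=True`` to raise
    :class:`EstimationUncertaintyUnavailable` instead.
    """
    cols = {
        "trial": np.arange(1, traj.n_trials + 1),
        "prediction_uncertainty": traj.prediction_uncertainty,
    }
    if traj.has_estimation_uncertainty:
        cols["estimation_uncertainty"] = traj.estimation_uncertainty
    elif require_estimation:
        raise EstimationUncertaintyUnavailable(
            f"model {traj.model!r} provides no estimation uncertainty"
        )
    return pd.DataFrame(cols)
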