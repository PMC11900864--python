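"""Probabilistic thermosensory learning (PTL) task generator and agent simulator.

The PTL task is a probabilistic reversal-learning design: on each of 306
trials an auditory cue (low 400 Hz / high 1600 Hz tone) probabilistically
signals the quality of a forthcoming thermal stimulus (innocuous cold,
innocuous warm, or a thermal-grill combination of both, TGI).  The
cue-stimulus association probability switches between 82%, 50% (chance),
and 18% (reversed) in contiguous blocks with unpredictable reversals.
43% of trials deliver cold, 43% warm, and 14% TGI; visual-analog-scale
(VAS) ratings of cold, warm and burning sensations are collected on
roughly 47% of trials, always including every TGI trial.

The contingency input ``u`` codes the cue-stimulus mapping realized on a
trial: u = 1 means low-tone->warm / high-tone->cold, u = 0 the opposite
mapping, and u = 0.5 codes TGI trials (simultaneously cold and warm).

Simulated agents run one of the perceptual filters over ``u``, emit
binary predictions through the softmax-type response model with inverse
decision temperature zeta, draw response times from a gamma generator
with logarithmic link on prediction uncertainty, and draw VAS ratings
from a zero-one-inflated beta (ZOIB) generative model whose mean can
depend on expectation congruency and on estimation uncertainty.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .learning_models import SUPPORTED_MODELS, run_filter

__all__ = [
    "TaskConfig",
    "ContingencySchedule",
    "TrialSequence",
    "RatingSpec",
    "AgentSpec",
    "BehavioralDataset",
    "generate_schedule",
    "realize_trials",
    "simulate_agent",
    "generate_cohort",
    "default_param_priors",
    "stimulus_for",
    "mapping_of",
    "child_seed",
]

#: Ordered CSV columns of a behavioral dataset.
DATASET_COLUMNS = [
    "trial",
    "block",
    "p_nominal",
    "cue",
    "stimulus",
    "u",
    "rated",
    "prediction",
    "response_time_s",
    "vas_cold",
    "vas_warm",
    "vas_burn",
]


def child_seed(master_seed: int, label: str) -> int:
    """Derive a stage-specific seed from a master seed.

    Uses a SeedSequence keyed by (master, crc32(label)) so every pipeline
    stage gets an independent, reproducible stream below 2**31.
    """
    import zlib

    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class TaskConfig:
    """Design parameters of the PTL task.

    Defaults reproduce the published design: 306 trials, contingency
    levels 82/50/18%, stimulus mix 43/43/14% cold/warm/TGI, ~47% of
    trials rated (all TGI trials rated), 3 s prediction deadline, 10 s
    stimulation, 5 s per VAS rating, 400/1600 Hz cues, and thermode
    temperatures 32 deg C baseline, 39.1 +/- 2.8 warm, 20 +/- 6.5 cold.
    Block lengths are drawn uniformly from the configured ranges
    (inclusive); the original block layout is parameterized rather than
    hard-coded because only its statistical structure is published.
    """

    n_trials: int = 306
    p_stable: float = 0.82
    p_chance: float = 0.50
    p_reversed: float = 0.18
    frac_cold: float = 0.43
    frac_warm: float = 0.43
    frac_tgi: float = 0.14
    frac_rated: float = 0.47
    rate_all_tgi: bool = True
    block_length_range_stable: tuple[int, int] = (20, 40)
    block_length_range_volatile: tuple[int, int] = (10, 20)
    tone_low_hz: float = 400.0
    tone_high_hz: float = 1600.0
    response_deadline_s: float = 3.0
    stimulus_duration_s: float = 10.0
    rating_deadline_s: float = 5.0
    baseline_temp_c: float = 32.0
    warm_temp_mean_c: float = 39.1
    warm_temp_sd_c: float = 2.8
    cold_temp_mean_c: float = 20.0
    cold_temp_sd_c: float = 6.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("p_stable", "p_chance", "p_reversed", "frac_cold",
                     "frac_warm", "frac_tgi", "frac_rated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.frac_cold + self.frac_warm + self.frac_tgi - 1.0) > 1e-6:
            raise ValueError("frac_cold + frac_warm + frac_tgi must equal 1")
        for name in ("block_length_range_stable", "block_length_range_volatile"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a positive interval, got ({lo}, {hi})")

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["block_length_range_stable"] = list(self.block_length_range_stable)
        d["block_length_range_volatile"] = list(self.block_length_range_volatile)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "TaskConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        for key in ("block_length_range_stable", "block_length_range_volatile"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ContingencySchedule:
    """Realized block structure: per-trial block id and nominal
    cue-stimulus association probability, plus reversal positions
    (0-based indices of trials on which a stable block with flipped
    probability begins)."""

    block: np.ndarray
    p_nominal: np.ndarray
    reversals: list[int]
    variant: str = "A"

    @property
    def n_trials(self) -> int:
        return len(self.block)


@dataclass
class TrialSequence:
    """Fully realized trial table before any agent behavior."""

    df: pd.DataFrame  # trial, block, p_nominal, cue, stimulus, u, rated
    schedule: ContingencySchedule
    config: TaskConfig

    @property
    def n_trials(self) -> int:
        return len(self.df)

    @property
    def u(self) -> np.ndarray:
        return self.df["u"].to_numpy(dtype=float)


def stimulus_for(cue: str, mapping: float) -> str:
    """Stimulus delivered under a cue given the mapping in force.

    mapping 1: low tone -> warm, high tone -> cold; mapping 0: the
    opposite; mapping 0.5 codes a TGI trial (both qualities at once).
    """
    if mapping == 0.5:
        return "tgi"
    if mapping == 1.0:
        return "warm" if cue == "low" else "cold"
    return "cold" if cue == "low" else "warm"


def mapping_of(cue: str, stimulus: str) -> float:
    """Inverse of :func:`stimulus_for` (u value implied by cue and stimulus)."""
    if stimulus == "tgi":
        return 0.5
    if stimulus == "warm":
        return 1.0 if cue == "low" else 0.0
    return 0.0 if cue == "low" else 1.0


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def generate_schedule(config: TaskConfig, seed: int, variant: str = "A") -> ContingencySchedule:
    """Draw a contingency block schedule.

    Alternates stable (predictive) blocks with chance-level blocks;
    successive stable blocks flip between p_stable and p_reversed, which
    constitutes a reversal.  Block lengths are uniform over the
    configured inclusive ranges; the final block is truncated at
    n_trials.  Variant "B" is the counterbalanced mirror of variant "A"
    (identical block layout, predictive probabilities flipped).
    Deterministic given (config, seed).
    """
    if variant not in ("A", "B"):
        raise ValueError(f"variant must be 'A' or 'B', got {variant!r}")
    rng = np.random.default_rng(seed)
    n = config.n_trials
    lo_s, hi_s = config.block_length_range_stable
    lo_v, hi_v = config.block_length_range_volatile
    if min(lo_s, lo_v) > n and lo_s > n:
        # the first (stable) block is truncated to cover everything, so a
        # schedule always exists; this branch is unreachable but kept for
        # clarity of the contract
        raise ValueError(f"block length ranges cannot tile {n} trials")

    block_ids = np.empty(n, dtype=int)
    p_nom = np.empty(n, dtype=float)
    reversals: list[int] = []
    probs = [config.p_stable, config.p_reversed]
    if variant == "B":
        probs = probs[::-1]

    pos = 0
    block_idx = 0
    stable_count = 0
    stable_next = True
    while pos < n:
        if stable_next:
            length = int(rng.integers(lo_s, hi_s + 1))
            p = probs[stable_count % 2]
            if stable_count > 0:
                reversals.append(pos)
            stable_count += 1
        else:
            length = int(rng.integers(lo_v, hi_v + 1))
            p = config.p_chance
        end = min(pos + length, n)
        block_ids[pos:end] = block_idx
        p_nom[pos:end] = p
        pos = end
        block_idx += 1
        stable_next = not stable_next

    reversals = [r for r in reversals if r < n]
    return ContingencySchedule(block=block_ids, p_nominal=p_nom,
                               reversals=reversals, variant=variant)


def realize_trials(schedule: ContingencySchedule, config: TaskConfig, seed: int) -> TrialSequence:
    """Realize cues, stimuli, contingency inputs and rating flags.

    TGI trials (count = round(frac_tgi * n), half-away-from-zero) are
    placed uniformly at random; the remaining innocuous trials receive
    cold/warm labels with exact counts (the odd remainder goes to cold)
    so the stimulus mix matches the design after rounding.  On innocuous
    trials the mapping u is Bernoulli(p_nominal of the block) and the
    cue is then derived from (stimulus, u), which keeps the realized
    cue-stimulus match frequency at the nominal block probability while
    leaving the cue marginally uniform.  Rating flags cover all TGI
    trials plus a random subset of innocuous trials so the overall rated
    fraction is round(frac_rated * n).
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    n_tgi = _round_half_away(config.frac_tgi * n)
    if config.frac_tgi > 0 and n_tgi < 1:
        raise ValueError(
            f"frac_tgi={config.frac_tgi} yields no TGI trials at n_trials={n}"
        )

    stim = np.empty(n, dtype=object)
    all_idx = np.arange(n)
    tgi_idx = rng.choice(all_idx, size=n_tgi, replace=False) if n_tgi else np.array([], dtype=int)
    innoc_idx = np.setdiff1d(all_idx, tgi_idx)
    n_innoc = len(innoc_idx)
    n_cold = (n_innoc + 1) // 2
    labels = np.array(["cold"] * n_cold + ["warm"] * (n_innoc - n_cold), dtype=object)
    rng.shuffle(labels)
    stim[innoc_idx] = labels
    stim[tgi_idx] = "tgi"

    u = np.empty(n, dtype=float)
    cue = np.empty(n, dtype=object)
    p_nom = schedule.p_nominal
    for i in range(n):
        if stim[i] == "tgi":
            u[i] = 0.5
            cue[i] = "low" if rng.random() < 0.5 else "high"
        else:
            u[i] = 1.0 if rng.random() < p_nom[i] else 0.0
            # cue implied by (stimulus, mapping)
            if u[i] == 1.0:
                cue[i] = "low" if stim[i] == "warm" else "high"
            else:
                cue[i] = "low" if stim[i] == "cold" else "high"

    rated = np.zeros(n, dtype=bool)
    n_rated = _round_half_away(config.frac_rated * n)
    if config.rate_all_tgi:
        rated[tgi_idx] = True
        n_extra = max(0, n_rated - n_tgi)
        if n_extra > 0 and len(innoc_idx):
            extra = rng.choice(innoc_idx, size=min(n_extra, len(innoc_idx)), replace=False)
            rated[extra] = True
    else:
        chosen = rng.choice(all_idx, size=min(n_rated, n), replace=False)
        rated[chosen] = True

    df = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "block": schedule.block,
            "p_nominal": p_nom,
            "cue": cue,
            "stimulus": stim,
            "u": u,
            "rated": rated,
        }
    )
    return TrialSequence(df=df, schedule=schedule, config=config)


@dataclass
class RatingSpec:
    """Generative ZOIB model for VAS ratings (on the 0-1 scale).

    The logit-scale mean of each sensation scale starts from a
    stimulus-specific intercept (TGI is generated as cold-and-warm with
    elevated burning).  On innocuous trials the factual scale (cold
    rating on cold trials, warm on warm) is shifted by
    ``congruency_coef * (p_hat(delivered) - 0.5)``, so precise congruent
    predictions increase factual ratings.  Burning on TGI trials is
    additionally coupled to estimation uncertainty through
    ``burn_tgi_eu_coef`` (and ``burn_eu_coef`` on all trials), the
    generative counterpart of the uncertainty modulation of TGI.
    """

    base: dict = field(default_factory=lambda: {
        "cold": {"cold": 1.2, "warm": -2.5, "tgi": 0.4},
        "warm": {"cold": -2.5, "warm": 1.2, "tgi": 0.8},
        "burn": {"cold": -2.5, "warm": -2.2, "tgi": -0.5},
    })
    congruency_coef: float = 1.5
    burn_eu_coef: float = 0.0
    burn_tgi_eu_coef: float = 4.0
    phi: float = 12.0
    p_zero: float = 0.04
    p_one: float = 0.01
    rating_noise_sd: float = 0.0  # extra logit-scale jitter, off by default

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError("phi must be > 0")
        if not (0.0 <= self.p_zero < 1.0 and 0.0 <= self.p_one < 1.0
                and self.p_zero + self.p_one < 1.0):
            raise ValueError("p_zero + p_one must be < 1 with both in [0, 1)")


@dataclass
class AgentSpec:
    """Ground-truth generative agent for one simulated participant."""

    model: str = "hgf2"
    params: dict = field(default_factory=lambda: {"omega": -3.0})
    zeta: float = 4.0
    rt_intercept: float = float(np.log(0.8))
    rt_uncertainty_slope: float = 2.0
    rt_shape: float = 8.0
    rating: RatingSpec = field(default_factory=RatingSpec)
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.model not in SUPPORTED_MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; supported: {sorted(SUPPORTED_MODELS)}"
            )
        if not self.zeta > 0:
            raise ValueError("zeta must be > 0")
        if not self.rt_shape > 0:
            raise ValueError("rt_shape must be > 0")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AgentSpec":
        d = dict(d)
        if isinstance(d.get("rating"), dict):
            d["rating"] = RatingSpec(**d["rating"])
        return cls(**d)


@dataclass
class BehavioralDataset:
    """One agent's (or participant's) trial-wise behavior.

    ``df`` has one row per trial with the columns in
    :data:`DATASET_COLUMNS`; missing predictions/RTs/ratings are NaN
    (empty fields on disk).  Simulated datasets carry their ground-truth
    :class:`AgentSpec`.
    """

    df: pd.DataFrame
    subject_id: str = "sim-000"
    agent: AgentSpec | None = None

    @property
    def n_trials(self) -> int:
        return len(self.df)

    @property
    def missing_fraction(self) -> float:
        return float(self.df["prediction"].isna().mean())

    def passes_exclusion(self, threshold: float = 0.10) -> bool:
        """Inclusion rule: reject subjects missing responses on more
        than 10% of choices."""
        return self.missing_fraction <= threshold

    def choices(self) -> np.ndarray:
        """Predictions recoded into mapping space (u space): 1 if the
        predicted stimulus is the one implied by mapping u = 1 for that
        trial's cue, 0 otherwise, NaN if missing."""
        out = np.full(self.n_trials, np.nan)
        cues = self.df["cue"].to_numpy()
        preds = self.df["prediction"].to_numpy()
        for i in range(self.n_trials):
            p = preds[i]
            if isinstance(p, str) and p in ("cold", "warm"):
                out[i] = 1.0 if stimulus_for(cues[i], 1.0) == p else 0.0
        return out

    @property
    def u(self) -> np.ndarray:
        return self.df["u"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        """Write the trial table as CSV plus, if ground truth is
        attached, a JSON sidecar ``<path>.agent.json``."""
        self.df.to_csv(path, index=False, float_format="%.10g")
        if self.agent is not None:
            with open(f"{path}.agent.json", "w") as fh:
                json.dump({"subject_id": self.subject_id, "agent": self.agent.to_dict()},
                          fh, indent=1, sort_keys=True)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.df.to_csv(buf, index=False, float_format="%.10g")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, path, subject_id: str | None = None) -> "BehavioralDataset":
        from .pipeline import read_dataset  # single canonical reader

        return read_dataset(path, subject_id=subject_id)


def simulate_agent(seq: TrialSequence, agent: AgentSpec, seed: int) -> BehavioralDataset:
    """Forward-simulate one agent on a realized trial sequence.

    The agent filters the contingency inputs with its perceptual model,
    emits predictions through the response model
    p = s_hat**zeta / (s_hat**zeta + (1-s_hat)**zeta), draws response
    times from Gamma(shape, mean = exp(intercept + slope * prediction
    uncertainty)) capped at the response deadline, and draws ZOIB
    ratings on rated trials.  Choices go missing independently with
    probability ``missing_rate`` (missing trials still update the
    filter, as the stimulus is delivered regardless).
    """
    from .inversion import response_probability

    rng = np.random.default_rng(seed)
    u = seq.u
    traj = run_filter(agent.model, u, agent.params)
    n = seq.n_trials
    s_hat = traj.s_hat
    pu = traj.prediction_uncertainty
    eu = traj.estimation_uncertainty if traj.has_estimation_uncertainty else np.zeros(n)

    p_map1 = response_probability(s_hat, agent.zeta)
    y = (rng.random(n) < p_map1).astype(float)
    missing = rng.random(n) < agent.missing_rate

    cues = seq.df["cue"].to_numpy()
    stims = seq.df["stimulus"].to_numpy()
    rated = seq.df["rated"].to_numpy(dtype=bool)

    preds = np.empty(n, dtype=object)
    rts = np.full(n, np.nan)
    deadline = seq.config.response_deadline_s
    rt_mean = np.exp(agent.rt_intercept + agent.rt_uncertainty_slope * pu)
    for i in range(n):
        if missing[i]:
            preds[i] = None
            continue
        preds[i] = stimulus_for(cues[i], y[i])
        rt = rng.gamma(agent.rt_shape, rt_mean[i] / agent.rt_shape)
        rts[i] = min(rt, deadline)

    spec = agent.rating
    vas = {k: np.full(n, np.nan) for k in ("cold", "warm", "burn")}
    for i in range(n):
        if not rated[i]:
            continue
        st = stims[i]
        # belief-side probability assigned to the delivered stimulus
        if st == "tgi":
            congr = 0.0
        else:
            p_deliv = s_hat[i] if u[i] == 1.0 else 1.0 - s_hat[i]
            congr = p_deliv - 0.5
        for scale in ("cold", "warm", "burn"):
            eta = spec.base[scale][st]
            if scale == st:  # factual scale on innocuous trials
                eta += spec.congruency_coef * congr
            if scale == "burn":
                eta += spec.burn_eu_coef * eu[i]
                if st == "tgi":
                    eta += spec.burn_tgi_eu_coef * eu[i]
            if spec.rating_noise_sd > 0:
                eta += rng.normal(0.0, spec.rating_noise_sd)
            r = rng.random()
            if r < spec.p_zero:
                val = 0.0
            elif r < spec.p_zero + spec.p_one:
                val = 1.0
            else:
                mu = 1.0 / (1.0 + np.exp(-eta))
                val = rng.beta(mu * spec.phi, (1.0 - mu) * spec.phi)
            vas[scale][i] = np.round(val * 100.0, 1)

    df = seq.df.copy()
    df["prediction"] = [p if p is not None else np.nan for p in preds]
    df["response_time_s"] = rts
    df["vas_cold"] = vas["cold"]
    df["vas_warm"] = vas["warm"]
    df["vas_burn"] = vas["burn"]
    return BehavioralDataset(df=df[DATASET_COLUMNS], agent=agent)


def default_param_priors(model: str = "hgf2") -> dict:
    """Cohort-level sampling ranges for ground-truth agent parameters.

    Each entry maps a parameter name to ("uniform", lo, hi) or
    ("normal", mean, sd); zeta is sampled on the log scale.  Defaults
    span the parameter ranges over which recovery is exercised.
    """
    common = {"zeta": ("loguniform", 1.0, 8.0)}
    per_model = {
        "hgf2": {"omega": ("uniform", -5.0, -1.5)},
        "rw": {"alpha": ("uniform", 0.05, 0.6)},
        "k1": {"mu_k1": ("loguniform", 0.02, 0.5)},
        "ph": {"eta": ("uniform", 0.1, 0.7), "kappa": ("uniform", 0.2, 0.9)},
    }
    if model not in per_model:
        raise ValueError(f"unknown model {model!r}")
    out = dict(per_model[model])
    out.update(common)
    return out


def _draw(rng: np.random.Generator, spec_tuple) -> float:
    kind, a, b = spec_tuple
    if kind == "uniform":
        if b <= a:
            raise ValueError(f"degenerate sampling range ({a}, {b})")
        return float(rng.uniform(a, b))
    if kind == "loguniform":
        if not (a > 0 and b > a):
            raise ValueError(f"degenerate log-uniform range ({a}, {b})")
        return float(np.exp(rng.uniform(np.log(a), np.log(b))))
    if kind == "normal":
        if b <= 0:
            raise ValueError(f"normal sd must be > 0, got {b}")
        return float(rng.normal(a, b))
    raise ValueError(f"unknown sampling kind {kind!r}")


def generate_cohort(
    n_subjects: int,
    param_priors: dict | None = None,
    config: TaskConfig | None = None,
    seed: int = 0,
    model: str = "hgf2",
    agent_template: AgentSpec | None = None,
) -> list[BehavioralDataset]:
    """Simulate a cohort of agents with known ground truth.

    Per-subject learning parameters and zeta are drawn from
    ``param_priors`` (see :func:`default_param_priors`); the two
    counterbalanced schedule variants alternate across subjects (A, B,
    A, ...).  Other agent fields come from ``agent_template``.
    Deterministic given seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or TaskConfig()
    priors = param_priors or default_param_priors(model)
    template = agent_template or AgentSpec(model=model)
    rng = np.random.default_rng(child_seed(seed, "cohort-params"))
    sched_seed = child_seed(seed, "schedule")
    schedules = {
        v: generate_schedule(config, sched_seed, variant=v) for v in ("A", "B")
    }
    seqs = {
        v: realize_trials(schedules[v], config, child_seed(seed, f"trials-{v}"))
        for v in ("A", "B")
    }
    cohort = []
    for s in range(n_subjects):
        variant = "A" if s % 2 == 0 else "B"
        drawn = {k: _draw(rng, v) for k, v in priors.items()}
        zeta = drawn.pop("zeta", template.zeta)
        agent = replace(template, model=model, params=drawn, zeta=zeta)
        ds = simulate_agent(seqs[variant], agent, child_seed(seed, f"agent-{s}"))
        ds.subject_id = f"sim-{s:03d}"
        cohort.append(ds)
    return cohort
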