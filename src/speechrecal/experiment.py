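"""Simulated McGurk experiment: stimuli, noise, trial loop, cohorts.

The protocol mirrors a 3-alternative audiovisual categorization experiment:
six stimulus types — acoustic-only /aba/, /ada/, /aga/ and audiovisual
congruent /aba/, incongruent McGurk (acoustic /aba/ with visual /aga/),
congruent /aga/ — each presented 69 times in a uniformly random order
(414 trials per listener).  Stimulus amplitudes are *tailored to the
listener*: they equal the initial category expectations of the perceptual
model and stay frozen while the listener recalibrates, so residual
prediction errors persist.  Each presentation is corrupted by independent
Gaussian sensory noise.

Per trial: add noise → category posterior → MAP percept → learning update
of the perceived category (per rule) → ordering guard → (decay rule only)
inter-trial relaxation.  A cohort is 100 independent listeners sharing the
same perceptual model, each with its own reproducible random substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .perception import CATEGORIES, PerceptualModel, SensoryInput, _log_posterior
from .rules import ListenerState, RuleParams, apply_decay, enforce_order, learning_update_fn

__all__ = [
    "STIM_TYPES",
    "EXPECTED_PERCEPT",
    "N_REPS_DEFAULT",
    "N_LISTENERS_DEFAULT",
    "Stimulus",
    "TrialRecord",
    "ExperimentResult",
    "make_stimuli",
    "add_noise",
    "run_listener",
    "run_cohort",
]

#: Stimulus types in canonical order (codes 0..5).
STIM_TYPES = ("A_aba", "A_ada", "A_aga", "AV_aba", "AV_McGurk", "AV_aga")

#: The percept counted as "correct"/expected per stimulus type; for the
#: McGurk stimulus the expected (fused) percept is /ada/.
EXPECTED_PERCEPT = ("aba", "ada", "aga", "aba", "ada", "aga")

MCGURK_CODE = STIM_TYPES.index("AV_McGurk")
ADA_CODE = CATEGORIES.index("ada")

N_REPS_DEFAULT = 69
N_LISTENERS_DEFAULT = 100


@dataclass(frozen=True)
class Stimulus:
    """True (noise-free) feature amplitudes of one stimulus type."""

    stim_type: str
    C_V: float | None
    C_A: float

    def __post_init__(self) -> None:
        if self.stim_type not in STIM_TYPES:
            raise ValueError(f"unknown stimulus type {self.stim_type!r}")
        acoustic_only = self.stim_type.startswith("A_")
        if acoustic_only != (self.C_V is None):
            raise ValueError("C_V must be absent iff the stimulus is acoustic-only")


@dataclass(frozen=True)
class TrialRecord:
    """One trial: stimulus, noisy input, posterior, percept."""

    index: int
    stim_type: str
    s_V: float | None
    s_A: float
    posterior: tuple[float, float, float]
    percept: str

    @property
    def fused_mcgurk(self) -> bool:
        return self.stim_type == "AV_McGurk" and self.percept == "ada"


def make_stimuli(model0: PerceptualModel) -> tuple[Stimulus, ...]:
    """The six experiment stimuli, tailored to the *initial* model.

    Amplitudes equal the initial category expectations: the three
    acoustic-only stimuli carry only the matching acoustic amplitude, the
    congruent /aba/ and /aga/ carry both, and the McGurk stimulus pairs
    the /aga/ visual amplitude with the /aba/ acoustic amplitude.  They
    are frozen for the whole run (they do not track recalibrated θ).
    """
    thV = {c.category: c.theta_V for c in model0.categories}
    thA = {c.category: c.theta_A for c in model0.categories}
    return (
        Stimulus("A_aba", None, thA["aba"]),
        Stimulus("A_ada", None, thA["ada"]),
        Stimulus("A_aga", None, thA["aga"]),
        Stimulus("AV_aba", thV["aba"], thA["aba"]),
        Stimulus("AV_McGurk", thV["aga"], thA["aba"]),
        Stimulus("AV_aga", thV["aga"], thA["aga"]),
    )


def add_noise(
    stim: Stimulus, model: PerceptualModel, rng: np.random.Generator
) -> SensoryInput:
    """Corrupt a stimulus with the model's sensory noise.

    Independent standard-normal draws scaled by ``sigma_V``/``sigma_A`` per
    present modality.  The visual draw is consumed first on audiovisual
    trials; acoustic-only stimuli yield ``s_V = None``.
    """
    s_V = None
    if stim.C_V is not None:
        s_V = stim.C_V + model.noise_V * rng.standard_normal()
    s_A = stim.C_A + model.noise_A * rng.standard_normal()
    return SensoryInput(s_V=s_V, s_A=s_A)


@dataclass
class ExperimentResult:
    """One listener's full run, stored columnwise.

    Columnar numpy arrays keep a 414-trial run cheap; :attr:`trials`
    materializes :class:`TrialRecord` objects on demand.  ``s_V`` holds
    NaN on acoustic-only trials.  ``theta_trace[t]`` (optional) is the
    working θ table *after* trial ``t`` (post update, guard, and decay).
    """

    listener_id: int
    seed: int | None
    rule_params: RuleParams
    stim_codes: np.ndarray
    s_V: np.ndarray
    s_A: np.ndarray
    posteriors: np.ndarray
    percept_codes: np.ndarray
    final_state: ListenerState
    theta_trace: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return int(self.stim_codes.size)

    @property
    def stim_types(self) -> list[str]:
        return [STIM_TYPES[c] for c in self.stim_codes]

    @property
    def percepts(self) -> list[str]:
        return [CATEGORIES[c] for c in self.percept_codes]

    @property
    def fused(self) -> np.ndarray:
        """Boolean mask of fused McGurk trials (McGurk stimulus, /ada/ percept)."""
        return (self.stim_codes == MCGURK_CODE) & (self.percept_codes == ADA_CODE)

    @property
    def trials(self) -> list[TrialRecord]:
        out = []
        for i in range(self.n_trials):
            sv = self.s_V[i]
            out.append(
                TrialRecord(
                    index=i + 1,
                    stim_type=STIM_TYPES[self.stim_codes[i]],
                    s_V=None if math.isnan(sv) else float(sv),
                    s_A=float(self.s_A[i]),
                    posterior=tuple(self.posteriors[i]),
                    percept=CATEGORIES[self.percept_codes[i]],
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trial table (one row per trial)."""
        return pd.DataFrame(
            {
                "listener_id": self.listener_id,
                "trial": np.arange(1, self.n_trials + 1),
                "stim_type": pd.Categorical.from_codes(
                    self.stim_codes, categories=list(STIM_TYPES)
                ),
                "s_V": self.s_V,
                "s_A": self.s_A,
                "p_aba": self.posteriors[:, 0],
                "p_ada": self.posteriors[:, 1],
                "p_aga": self.posteriors[:, 2],
                "percept": pd.Categorical.from_codes(
                    self.percept_codes, categories=list(CATEGORIES)
                ),
                "fused_mcgurk": self.fused,
            }
        )

    def trace_frame(self) -> pd.DataFrame:
        """Long-format θ trace (trial, category, feature, theta)."""
        if self.theta_trace is None:
            raise ValueError("run with record_trace=True to collect a θ trace")
        rows = []
        for t in range(self.n_trials):
            for k, cat in enumerate(CATEGORIES):
                for f, feat in enumerate(("V", "A")):
                    rows.append((t + 1, cat, feat, self.theta_trace[t, k, f]))
        return pd.DataFrame(rows, columns=["trial", "category", "feature", "theta"])


def _trial_order(rng: np.random.Generator, n_reps: int) -> np.ndarray:
    """Uniformly random permutation of the balanced stimulus multiset."""
    return rng.permutation(np.repeat(np.arange(6, dtype=np.int8), n_reps))


def run_listener(
    model0: PerceptualModel,
    rule_params: RuleParams,
    n_reps: int = N_REPS_DEFAULT,
    rng: np.random.Generator | np.random.SeedSequence | int | None = None,
    listener_id: int = 0,
    record_trace: bool = False,
) -> ExperimentResult:
    """Simulate one listener's full pseudo-random run.

    The random stream drives (in order) the trial permutation, then one
    visual and one acoustic noise draw per trial (the visual draw is
    discarded on acoustic-only trials, which keeps the stream layout
    identical across rules and stimulus orders).
    """
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng)
    stimuli = make_stimuli(model0)
    order = _trial_order(rng, n_reps)
    n = order.size
    eta = rng.standard_normal((n, 2))

    # precompute per-trial noisy amplitudes layout
    amps = [(s.C_V, s.C_A) for s in stimuli]
    sdV, sdA = model0.noise_V, model0.noise_A
    etaV = (eta[:, 0] * sdV).tolist()
    etaA = (eta[:, 1] * sdA).tolist()
    order_list = order.tolist()

    state = ListenerState.initial(model0, rule_params)
    th = state.theta
    s2 = state.sigma2
    nV2 = sdV * sdV
    nA2 = sdA * sdA
    log_prior = [math.log(p) if p > 0 else -math.inf for p in model0.prior]
    update = learning_update_fn(rule_params)
    is_decay = rule_params.rule == "decay"

    s_V_out = np.full(n, np.nan)
    s_A_out = np.empty(n)
    post_out = np.empty((n, 3))
    percept_out = np.empty(n, dtype=np.int8)
    trace = np.empty((n, 3, 2)) if record_trace else None

    exp = math.exp
    for t in range(n):
        code = order_list[t]
        cV, cA = amps[code]
        sA = cA + etaA[t]
        sV = None if cV is None else cV + etaV[t]

        lp = _log_posterior(th, s2, nV2, nA2, log_prior, sV, sA)
        m = lp[0]
        best = 0
        if lp[1] > m:
            m = lp[1]
            best = 1
        if lp[2] > m:
            m = lp[2]
            best = 2
        e0 = exp(lp[0] - m)
        e1 = exp(lp[1] - m)
        e2 = exp(lp[2] - m)
        z = e0 + e1 + e2
        post = (e0 / z, e1 / z, e2 / z)

        if update is not None:
            update(state, best, SensoryInput(sV, sA), post)
            if is_decay:
                apply_decay(state)

        if sV is not None:
            s_V_out[t] = sV
        s_A_out[t] = sA
        post_out[t, 0] = post[0]
        post_out[t, 1] = post[1]
        post_out[t, 2] = post[2]
        percept_out[t] = best
        if trace is not None:
            for k in range(3):
                trace[t, k, 0] = th[k][0]
                trace[t, k, 1] = th[k][1]

    return ExperimentResult(
        listener_id=listener_id,
        seed=seed,
        rule_params=rule_params,
        stim_codes=order,
        s_V=s_V_out,
        s_A=s_A_out,
        posteriors=post_out,
        percept_codes=percept_out,
        final_state=state,
        theta_trace=trace,
    )


def run_cohort(
    model0: PerceptualModel,
    rule_params: RuleParams,
    n_listeners: int = N_LISTENERS_DEFAULT,
    master_seed: int | np.random.SeedSequence = 0,
    n_reps: int = N_REPS_DEFAULT,
    record_trace: bool = False,
) -> list[ExperimentResult]:
    """Simulate independent listeners sharing one perceptual model.

    Each listener gets its own random substream spawned deterministically
    from ``master_seed``, so cohorts are bit-reproducible and listeners
    differ in both trial order and sensory noise.
    """
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    children = ss.spawn(n_listeners)
    return [
        run_listener(
            model0,
            rule_params,
            n_reps=n_reps,
            rng=np.random.default_rng(child),
            listener_id=i,
            record_trace=record_trace,
        )
        for i, child in enumerate(children)
    ]
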