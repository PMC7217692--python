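"""Per-trial recalibration rules for the listener's category representations.

After every perceptual decision the listener adjusts the representation of
the *perceived* category toward the just-experienced sensory features —
recalibration driven by residual prediction error.  Four regimes:

``none``
    Control: the internal model never changes.
``bayes``
    Conjugate Normal–Inverse-χ² sequential updating under a
    stable-environment assumption.  Point estimates of location and spread
    follow an incremental form whose effective learning rate
    ``1/(kappa0 + n(k))`` shrinks with the number of percepts ``n(k)``.
``delta``
    Constant delta rule: ``Δθ = rate · (s − θ) · p(percept | s)``, location
    only, with possibly different rates per modality.
``decay``
    Two-timescale hierarchical rule: a fast working location θ learns with
    constant rate ``R1`` (scaled by the posterior) and relaxes in every
    inter-trial interval toward a slow long-term anchor μ with rate ``D``;
    μ itself may drift toward θ with rate ``R2`` (zero for a session-stable
    long-term memory).

All rules touch only the perceived category at the learning step, and only
the features actually present in the input (acoustic-only trials never move
visual parameters).  An ordering guard restores the empirical relation
θ_/ada/,A ≥ θ_/aba/,A after every learning update by swapping the two
acoustic locations if it is violated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .perception import CATEGORIES, PerceptualModel, SensoryInput, CategoryRepresentation

__all__ = [
    "RULES",
    "RuleParams",
    "BayesHyperState",
    "DecayState",
    "ListenerState",
    "update_bayes",
    "update_delta",
    "update_decay_learn",
    "apply_decay",
    "enforce_order",
    "derive_time_constant",
    "learning_update_fn",
]

RULES = ("none", "bayes", "delta", "decay")

_ABA, _ADA, _AGA = 0, 1, 2
_V, _A = 0, 1


@dataclass(frozen=True)
class RuleParams:
    """Recalibration regime and its parameters.

    Only the parameters belonging to ``rule`` are meaningful; the rest keep
    their defaults.  ``update_variance`` switches the Bayes-rule spread
    update on/off (location-only updating when False).
    """

    rule: str
    kappa0: float = 1.0
    nu0: float = 1.0
    rate_V: float = 0.2
    rate_A: float = 0.2
    R1: float = 0.4
    D: float = 0.14
    R2: float = 0.0
    update_variance: bool = True

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        if self.rule == "bayes" and (self.kappa0 <= 0 or self.nu0 <= 0):
            raise ValueError("kappa0 and nu0 must be positive")
        if self.rule == "delta" and not (
            0 < self.rate_V <= 1 and 0 < self.rate_A <= 1
        ):
            raise ValueError("delta rates must lie in (0, 1]")
        if self.rule == "decay":
            if not (0 < self.R1 <= 1 and 0 < self.D <= 1):
                raise ValueError("R1 and D must lie in (0, 1]")
            if self.R2 < 0:
                raise ValueError("R2 must be non-negative")

    # convenience constructors ------------------------------------------

    @classmethod
    def none(cls) -> "RuleParams":
        return cls(rule="none")

    @classmethod
    def bayes(cls, kappa0: float = 1.0, nu0: float = 1.0,
              update_variance: bool = True) -> "RuleParams":
        return cls(rule="bayes", kappa0=kappa0, nu0=nu0,
                   update_variance=update_variance)

    @classmethod
    def delta(cls, rate_V: float = 0.2, rate_A: float = 0.2) -> "RuleParams":
        return cls(rule="delta", rate_V=rate_V, rate_A=rate_A)

    @classmethod
    def decay(cls, R1: float = 0.4, D: float = 0.14, R2: float = 0.0) -> "RuleParams":
        return cls(rule="decay", R1=R1, D=D, R2=R2)

    def label(self) -> str:
        if self.rule == "bayes":
            return f"bayes(kappa0={self.kappa0:g}, nu0={self.nu0:g})"
        if self.rule == "delta":
            return f"delta(rate_V={self.rate_V:g}, rate_A={self.rate_A:g})"
        if self.rule == "decay":
            return f"decay(R1={self.R1:g}, D={self.D:g}, R2={self.R2:g})"
        return "none"


@dataclass
class BayesHyperState:
    """Conjugate hyperparameters per (category, feature).

    ``ss[k][f]`` accumulates the ν-weighted sum-of-squares scale; it is
    seeded at ``(nu0 + 1) · sigma_init^2`` so the point estimate
    ``ss / (nu + 1)`` starts at the perceptual model's variance and the
    incremental location/spread updates match the batch conjugate forms
    exactly.  ``n_perceived[k][f]`` counts percepts of ``k`` that updated
    feature ``f`` (acoustic-only trials advance the acoustic count only).
    """

    kappa: list[list[float]]
    nu: list[list[float]]
    mu0: list[list[float]]
    ss: list[list[float]]
    n_perceived: list[list[int]]

    @property
    def s0_sq(self) -> list[list[float]]:
        """Hyper scale sigma_{k,f,0}^2 (the accumulator divided by nu)."""
        return [[self.ss[k][f] / self.nu[k][f] for f in (0, 1)] for k in range(3)]


@dataclass
class DecayState:
    """Long-term anchor locations μ_{k,f} for the two-timescale rule."""

    mu_long: list[list[float]]


@dataclass
class ListenerState:
    """Full mutable recalibration state of one simulated listener.

    ``theta``/``sigma2`` are the *working* category locations and variances
    as ``[k][f]`` nested lists (feature order visual, acoustic) — plain
    lists because the trial loop mutates them millions of times.  The
    :attr:`model` property materializes a read-only
    :class:`~speechrecal.perception.PerceptualModel` view.
    """

    theta: list[list[float]]
    sigma2: list[list[float]]
    noise_V: float
    noise_A: float
    prior: tuple[float, float, float]
    rule_params: RuleParams
    bayes: BayesHyperState | None = None
    decay: DecayState | None = None

    @classmethod
    def initial(cls, model: PerceptualModel, rule_params: RuleParams) -> "ListenerState":
        theta = [[c.theta_V, c.theta_A] for c in model.categories]
        sigma2 = [[c.sigma_V**2, c.sigma_A**2] for c in model.categories]
        bayes = None
        decay = None
        if rule_params.rule == "bayes":
            bayes = BayesHyperState(
                kappa=[[rule_params.kappa0] * 2 for _ in range(3)],
                nu=[[rule_params.nu0] * 2 for _ in range(3)],
                mu0=[row[:] for row in theta],
                ss=[[(rule_params.nu0 + 1.0) * v for v in row] for row in sigma2],
                n_perceived=[[0, 0] for _ in range(3)],
            )
        elif rule_params.rule == "decay":
            decay = DecayState(mu_long=[row[:] for row in theta])
        return cls(
            theta=theta,
            sigma2=sigma2,
            noise_V=model.noise_V,
            noise_A=model.noise_A,
            prior=tuple(model.prior),
            rule_params=rule_params,
            bayes=bayes,
            decay=decay,
        )

    @property
    def model(self) -> PerceptualModel:
        cats = tuple(
            CategoryRepresentation(
                category=CATEGORIES[k],
                theta_V=self.theta[k][_V],
                theta_A=self.theta[k][_A],
                sigma_V=math.sqrt(self.sigma2[k][_V]),
                sigma_A=math.sqrt(self.sigma2[k][_A]),
            )
            for k in range(3)
        )
        return PerceptualModel(
            categories=cats, noise_V=self.noise_V, noise_A=self.noise_A,
            prior=self.prior,
        )


def _percept_index(percept: str | int) -> int:
    return percept if isinstance(percept, int) else CATEGORIES.index(percept)


def _present_features(input: SensoryInput):
    if input.s_V is None:
        return ((_A, input.s_A),)
    return ((_V, input.s_V), (_A, input.s_A))


def enforce_order(state: ListenerState) -> ListenerState:
    """Swap the /aba/ and /ada/ acoustic locations if their order reversed.

    Empirically the 2nd formant deflection is larger for /ada/ than /aba/;
    the guard encodes that relational prior.  Only the two acoustic
    locations (and, under the Bayes rule, their hyper-locations, which the
    working values mirror) are exchanged; everything else is untouched.
    """
    th = state.theta
    if th[_ADA][_A] < th[_ABA][_A]:
        th[_ABA][_A], th[_ADA][_A] = th[_ADA][_A], th[_ABA][_A]
        if state.bayes is not None:
            m = state.bayes.mu0
            m[_ABA][_A], m[_ADA][_A] = m[_ADA][_A], m[_ABA][_A]
    return state


def update_bayes(
    state: ListenerState,
    percept: str | int,
    input: SensoryInput,
    posterior: Sequence[float] | None = None,
) -> ListenerState:
    """Conjugate sequential update of the perceived category.

    Hyperparameters advance by one pseudo-observation per present feature;
    the working location and (optionally) variance are set to the matching
    point estimates, equivalent to the incremental forms

        Δθ = (s − θ) / (kappa0 + n(k))
        Δσ² = [ (kappa0+n−1)/(kappa0+n) (s − θ)² − σ² ] / (nu0 + n + 1)

    with ``n(k)`` the per-feature percept count including this trial.
    The posterior is not used: each percept counts as one full observation.
    """
    if state.rule_params.rule != "bayes" or state.bayes is None:
        raise ValueError("update_bayes requires rule='bayes'")
    k = _percept_index(percept)
    h = state.bayes
    for f, s in _present_features(input):
        kap = h.kappa[k][f]
        mu_old = h.mu0[k][f]
        h.mu0[k][f] = mu_old + (s - mu_old) / (kap + 1.0)
        h.ss[k][f] += kap / (kap + 1.0) * (s - mu_old) ** 2
        h.kappa[k][f] = kap + 1.0
        h.nu[k][f] += 1.0
        h.n_perceived[k][f] += 1
        state.theta[k][f] = h.mu0[k][f]
        if state.rule_params.update_variance:
            state.sigma2[k][f] = h.ss[k][f] / (h.nu[k][f] + 1.0)
    return enforce_order(state)


def update_delta(
    state: ListenerState,
    percept: str | int,
    input: SensoryInput,
    posterior: Sequence[float],
) -> ListenerState:
    """Constant delta rule: move the perceived category's locations.

    ``Δθ_{k,f} = rate_f · (s_f − θ_{k,f}) · p(k | s)`` for the percept
    ``k`` only; spreads never change.  On acoustic-only trials the weight
    is the acoustic-marginal posterior and only θ_{k,A} moves.
    """
    if state.rule_params.rule != "delta":
        raise ValueError("update_delta requires rule='delta'")
    k = _percept_index(percept)
    w = posterior[k]
    rp = state.rule_params
    rates = (rp.rate_V, rp.rate_A)
    for f, s in _present_features(input):
        state.theta[k][f] += rates[f] * (s - state.theta[k][f]) * w
    return enforce_order(state)


def update_decay_learn(
    state: ListenerState,
    percept: str | int,
    input: SensoryInput,
    posterior: Sequence[float],
) -> ListenerState:
    """Learning step of the two-timescale rule (the percept's θ and μ).

    ``Δθ = R1 (s − θ) p`` and ``Δμ = R2 (θ − μ) p``, both evaluated at the
    pre-update values and applied together.  With ``R2 = 0`` the long-term
    anchor is constant within a session.  The inter-trial decay is a
    separate step (:func:`apply_decay`).
    """
    if state.rule_params.rule != "decay" or state.decay is None:
        raise ValueError("update_decay_learn requires rule='decay'")
    k = _percept_index(percept)
    w = posterior[k]
    rp = state.rule_params
    mu = state.decay.mu_long
    for f, s in _present_features(input):
        th_old = state.theta[k][f]
        state.theta[k][f] = th_old + rp.R1 * (s - th_old) * w
        if rp.R2 != 0.0:
            mu[k][f] += rp.R2 * (th_old - mu[k][f]) * w
    return enforce_order(state)


def apply_decay(state: ListenerState) -> ListenerState:
    """Inter-trial relaxation: every θ moves toward its long-term anchor.

    ``θ ← θ + D (μ − θ)`` for all categories and both features, applied
    once per inter-trial interval (after the learning step of the current
    trial, before the next stimulus).
    """
    if state.rule_params.rule != "decay" or state.decay is None:
        raise ValueError("apply_decay requires rule='decay'")
    D = state.rule_params.D
    mu = state.decay.mu_long
    th = state.theta
    for k in range(3):
        for f in (_V, _A):
            th[k][f] += D * (mu[k][f] - th[k][f])
    return state


def derive_time_constant(D: float, dt: float = 5.0) -> float:
    """Decay time constant implied by per-interval rate ``D``.

    Matching ``Δθ = D (μ − θ)`` against the continuous-time step
    ``Δθ = (Δt/τ)(μ − θ)`` gives ``τ = Δt / D``; with the 5 s inter-trial
    interval and D = 0.14 this is ≈ 36 s.  ``D = 0`` means no decay,
    reported as an infinite time constant.
    """
    if D < 0 or D > 1:
        raise ValueError("D must lie in [0, 1]")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if D == 0:
        return math.inf
    return dt / D


def learning_update_fn(rule_params: RuleParams) -> Callable | None:
    """Per-trial learning-step dispatcher used by the experiment loop."""
    return {
        "none": None,
        "bayes": update_bayes,
        "delta": update_delta,
        "decay": update_decay_learn,
    }[rule_params.rule]
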