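"""Three-level Gaussian generative model of audiovisual syllable perception.

A listener represents each of the three syllable categories /aba/, /ada/,
/aga/ as a product of two univariate Gaussians over a visual feature (lip
closure amplitude, ``V``) and an acoustic feature (2nd formant transition
amplitude, ``A``).  Given a category ``k``, the hidden feature amplitudes
``C_V, C_A`` are drawn from ``N(theta_{k,f}, sigma_{k,f}^2)``; the sensory
input ``s_V, s_A`` is the hidden amplitude corrupted by sensory noise with
spread ``sigma_f``.  Inverting the model gives the category posterior in
closed form: marginalizing the hidden amplitudes yields

    p(k | s_V, s_A)  ∝  N(s_V; theta_{k,V}, sigma_V^2 + sigma_{k,V}^2)
                      · N(s_A; theta_{k,A}, sigma_A^2 + sigma_{k,A}^2)
                      · p(k)

and the percept is the maximum-a-posteriori category.  Acoustic-only trials
use the acoustic factor alone (the model factorizes over modalities).

Feature amplitudes are unitless, normalized to the largest observed
production per feature (so roughly in [0, 1.5]); noisy inputs outside that
range are tolerated by the Gaussian model and never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "CATEGORIES",
    "FEATURES",
    "CategoryRepresentation",
    "PerceptualModel",
    "SensoryInput",
    "FeatureEstimate",
    "FeaturePosterior",
    "category_posterior",
    "feature_estimate",
    "feature_posterior",
    "choose_percept",
]

#: Fixed category order; also the tie-break order for percept selection.
CATEGORIES: tuple[str, str, str] = ("aba", "ada", "aga")

#: Feature order used throughout: visual first, acoustic second.
FEATURES: tuple[str, str] = ("V", "A")

# Category mean amplitudes: productions of one speaker, normalized per
# feature by the largest mean.  Lip closure is maximal for the bilabial
# /aba/; the 2nd formant deflection is minimal for /aba/ and maximal for
# the velar /aga/.
DEFAULT_THETA_V: dict[str, float] = {"aba": 1.0, "ada": 0.6, "aga": 0.37}
DEFAULT_THETA_A: dict[str, float] = {"aba": 0.1, "ada": 0.4, "aga": 1.0}


class SensoryInput(NamedTuple):
    """One trial's noisy sensory features.

    ``s_V`` is ``None`` on acoustic-only trials; ``s_A`` is always present.
    """

    s_V: float | None
    s_A: float

    @property
    def is_bimodal(self) -> bool:
        return self.s_V is not None


@dataclass(frozen=True)
class CategoryRepresentation:
    """Gaussian feature expectations for one syllable category."""

    category: str
    theta_V: float
    theta_A: float
    sigma_V: float
    sigma_A: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        for name in ("theta_V", "theta_A", "sigma_V", "sigma_A"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.sigma_V <= 0 or self.sigma_A <= 0:
            raise ValueError("category spreads must be strictly positive")


@dataclass(frozen=True)
class PerceptualModel:
    """A listener's internal model: three categories, sensory noise, prior."""

    categories: tuple[
        CategoryRepresentation, CategoryRepresentation, CategoryRepresentation
    ]
    noise_V: float
    noise_A: float
    prior: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if tuple(c.category for c in self.categories) != CATEGORIES:
            raise ValueError(f"categories must be ordered {CATEGORIES}")
        if self.noise_V <= 0 or self.noise_A <= 0:
            raise ValueError("sensory noise spreads must be strictly positive")
        if any(p < 0 for p in self.prior) or not math.isclose(
            sum(self.prior), 1.0, abs_tol=1e-9
        ):
            raise ValueError("prior must be a probability vector summing to 1")

    @classmethod
    def default(
        cls,
        noise_V: float = 0.1,
        noise_A: float = 0.1,
        sigma_kV: float = 0.1,
        sigma_kA: float = 0.1,
    ) -> "PerceptualModel":
        """Model with the normalized mean amplitudes and shared spreads.

        ``sigma_kV``/``sigma_kA`` are the per-category articulation spreads
        (identical across categories initially), ``noise_V``/``noise_A`` the
        sensory noise levels.
        """
        cats = tuple(
            CategoryRepresentation(
                category=k,
                theta_V=DEFAULT_THETA_V[k],
                theta_A=DEFAULT_THETA_A[k],
                sigma_V=sigma_kV,
                sigma_A=sigma_kA,
            )
            for k in CATEGORIES
        )
        return cls(categories=cats, noise_V=noise_V, noise_A=noise_A)

    # -- array views ------------------------------------------------------

    @property
    def theta_V(self) -> np.ndarray:
        return np.array([c.theta_V for c in self.categories])

    @property
    def theta_A(self) -> np.ndarray:
        return np.array([c.theta_A for c in self.categories])

    @property
    def sigma_V(self) -> np.ndarray:
        return np.array([c.sigma_V for c in self.categories])

    @property
    def sigma_A(self) -> np.ndarray:
        return np.array([c.sigma_A for c in self.categories])

    def category_index(self, category: str) -> int:
        return CATEGORIES.index(category)


@dataclass(frozen=True)
class FeatureEstimate:
    """Posterior mean of the hidden amplitudes given input and a category.

    Each present component is the precision-weighted compromise between the
    category expectation and the sensory evidence; an absent modality stays
    ``None``.
    """

    category: str
    C_V: float | None
    C_A: float


@dataclass(frozen=True)
class FeaturePosterior:
    """Mixture posterior over hidden amplitudes, marginalized over category.

    ``weights[k]`` is the category posterior; component ``k`` is Gaussian
    with mean ``mean_f[k]`` and common spread ``sd_f`` per modality
    (``1/sd_f^2 = 1/sigma_f^2 + 1/sigma_{k,f}^2``).  Visual fields are
    ``None`` for acoustic-only input.
    """

    weights: np.ndarray
    mean_V: np.ndarray | None
    sd_V: np.ndarray | None
    mean_A: np.ndarray
    sd_A: np.ndarray

    @property
    def mixture_mean_A(self) -> float:
        return float(np.dot(self.weights, self.mean_A))

    @property
    def mixture_mean_V(self) -> float | None:
        if self.mean_V is None:
            return None
        return float(np.dot(self.weights, self.mean_V))


def _validate_input(input: SensoryInput) -> None:
    if not math.isfinite(input.s_A):
        raise ValueError(f"s_A must be finite, got {input.s_A!r}")
    if input.s_V is not None and not math.isfinite(input.s_V):
        raise ValueError(f"s_V must be finite, got {input.s_V!r}")


def _log_posterior(
    theta: Sequence[Sequence[float]],
    sigma2: Sequence[Sequence[float]],
    noise_V2: float,
    noise_A2: float,
    log_prior: Sequence[float],
    s_V: float | None,
    s_A: float,
) -> list[float]:
    """Unnormalized log category posterior on raw parameter tables.

    ``theta[k] = (theta_V, theta_A)``, ``sigma2[k]`` the matching variances.
    This is the hot path shared with the trial-loop simulator; the public
    :func:`category_posterior` wraps it.  The exact marginal likelihood
    is used, including the ``-0.5 log(var)`` term (it only matters once
    category variances diverge under recalibration).
    """
    out = []
    for k in range(3):
        vA = noise_A2 + sigma2[k][1]
        if vA <= 0:
            raise ValueError("zero total acoustic variance")
        d = s_A - theta[k][1]
        lp = log_prior[k] - 0.5 * (d * d / vA + math.log(vA))
        if s_V is not None:
            vV = noise_V2 + sigma2[k][0]
            if vV <= 0:
                raise ValueError("zero total visual variance")
            d = s_V - theta[k][0]
            lp -= 0.5 * (d * d / vV + math.log(vV))
        out.append(lp)
    return out


def _normalize_log(lp: Sequence[float]) -> np.ndarray:
    m = max(lp)
    e = [math.exp(x - m) for x in lp]
    z = sum(e)
    return np.array([x / z for x in e])


def category_posterior(model: PerceptualModel, input: SensoryInput) -> np.ndarray:
    """Posterior probability of each category given the sensory input.

    Uses the closed-form marginalization over the hidden amplitudes: per
    modality the predictive variance is ``sigma_f^2 + sigma_{k,f}^2``.
    Acoustic-only input drops the visual factor.  Computation is in the
    log domain; the returned vector is normalized to sum to 1.
    """
    _validate_input(input)
    theta = [(c.theta_V, c.theta_A) for c in model.categories]
    sigma2 = [(c.sigma_V**2, c.sigma_A**2) for c in model.categories]
    log_prior = [math.log(p) if p > 0 else -math.inf for p in model.prior]
    lp = _log_posterior(
        theta, sigma2, model.noise_V**2, model.noise_A**2,
        log_prior, input.s_V, input.s_A,
    )
    return _normalize_log(lp)


def feature_estimate(
    model: PerceptualModel, input: SensoryInput, category: str
) -> FeatureEstimate:
    """Hidden-amplitude estimate for one category.

    Per present modality,

        C_{k,f} = theta_{k,f} + sigma_{k,f}^2 / (sigma_f^2 + sigma_{k,f}^2)
                  · (s_f − theta_{k,f}),

    i.e. the category expectation corrected by the precision-weighted
    residual prediction error.  An absent modality yields ``None``.
    """
    _validate_input(input)
    k = model.category_index(category)
    cat = model.categories[k]
    wA = cat.sigma_A**2 / (model.noise_A**2 + cat.sigma_A**2)
    C_A = cat.theta_A + wA * (input.s_A - cat.theta_A)
    C_V: float | None = None
    if input.s_V is not None:
        wV = cat.sigma_V**2 / (model.noise_V**2 + cat.sigma_V**2)
        C_V = cat.theta_V + wV * (input.s_V - cat.theta_V)
    return FeatureEstimate(category=category, C_V=C_V, C_A=C_A)


def feature_posterior(model: PerceptualModel, input: SensoryInput) -> FeaturePosterior:
    """Mixture posterior over hidden amplitudes ``p(C_V, C_A | s_V, s_A)``.

    Component weights are the category posterior, component means the
    per-category feature estimates, and component precisions add sensory
    and category precisions.
    """
    weights = category_posterior(model, input)
    est = [feature_estimate(model, input, k) for k in CATEGORIES]
    mean_A = np.array([e.C_A for e in est])
    sd_A = np.array(
        [
            1.0 / math.sqrt(1.0 / model.noise_A**2 + 1.0 / c.sigma_A**2)
            for c in model.categories
        ]
    )
    if input.s_V is None:
        return FeaturePosterior(weights, None, None, mean_A, sd_A)
    mean_V = np.array([e.C_V for e in est])
    sd_V = np.array(
        [
            1.0 / math.sqrt(1.0 / model.noise_V**2 + 1.0 / c.sigma_V**2)
            for c in model.categories
        ]
    )
    return FeaturePosterior(weights, mean_V, sd_V, mean_A, sd_A)


def choose_percept(posterior: Sequence[float], atol: float = 1e-8) -> str:
    """MAP percept; ties broken by the fixed order aba < ada < aga.

    Raises if the vector is not a normalized probability distribution.
    """
    p = np.asarray(posterior, dtype=float)
    if p.shape != (3,):
        raise ValueError("posterior must have exactly three entries")
    if np.any(p < -atol) or not math.isclose(float(p.sum()), 1.0, abs_tol=atol):
        raise ValueError("posterior must be normalized and non-negative")
    # strict > keeps the earliest category on exact ties
    best = 0
    for k in (1, 2):
        if p[k] > p[best]:
            best = k
    return CATEGORIES[best]
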