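"""Core model types and likelihood contracts.

The model is a variable-dimension logistic regression on paired predictors.
Each of the ``p`` isotope clusters contributes a pair ``(u, v)`` of summary
measures: ``u`` is the intensity summary (primary source) and ``v`` the shape
summary (secondary source).  A cluster may enter the model either as a
*couple* (both ``u`` and ``v`` included) or as an intensity *singleton*
(``u`` only); a shape measure can never be included without its intensity.
With ``k_C`` couples and ``k_I`` singletons, the linear predictor is

    logit(p_i) = beta0 + sum_{j in couples} (a_j u_ij + b_j v_ij)
                       + sum_{l in singletons} a_l u_il

Priors: beta0 ~ N(0, intercept_sd^2); a_j ~ N(0, sigma_a^2) and
b_j ~ N(0, sigma_b^2) with sigma_a^2 = tau_a^2 / s_a, sigma_b^2 = tau_b^2 / s_b,
where tau_a, tau_b are fixed rescaling factors and s_a, s_b carry Gamma(alpha,
beta) priors (shape-rate).  The model dimension k = k_C + k_I has a discrete
uniform prior on {0, ..., kmax}; given k, all configurations (choice of
clusters and couple/singleton composition) are equally likely.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PriorSpec",
    "ModelConfiguration",
    "CoefficientState",
    "ChainSample",
    "ChainSettings",
    "Chain",
    "linear_predictor",
    "bernoulli_loglik",
    "prior_scale_heuristic",
]


@dataclass(frozen=True)
class PriorSpec:
    """Fixed hyperparameters of the prior.

    tau_a, tau_b : rescaling factors for the intensity / shape effect scales.
    alpha, beta  : Gamma(shape, rate) hyperparameters shared by s_a and s_b.
    intercept_sd : prior standard deviation of the intercept (weakly informative).
    kmax         : maximum allowed number of included isotope clusters.
    """

    tau_a: float = 1.0
    tau_b: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    intercept_sd: float = 10.0
    kmax: int = 50

    def __post_init__(self) -> None:
        for name in ("tau_a", "tau_b", "alpha", "beta", "intercept_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not (isinstance(self.kmax, (int, np.integer)) and self.kmax >= 1):
            raise ValueError("kmax must be a positive integer")

    def to_dict(self) -> dict:
        return {
            "tau_a": self.tau_a,
            "tau_b": self.tau_b,
            "alpha": self.alpha,
            "beta": self.beta,
            "intercept_sd": self.intercept_sd,
            "kmax": int(self.kmax),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**{k: d[k] for k in
                      ("tau_a", "tau_b", "alpha", "beta", "intercept_sd", "kmax")
                      if k in d})


@dataclass(frozen=True)
class ModelConfiguration:
    """The current set of included clusters, split by composition.

    ``couples`` lists clusters included with both components, ``singletons``
    those included with intensity only.  Indices are 0-based column positions
    into the design matrices.  Both tuples are kept sorted; the two sets are
    disjoint.
    """

    couples: tuple[int, ...] = ()
    singletons: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "couples", tuple(sorted(self.couples)))
        object.__setattr__(self, "singletons", tuple(sorted(self.singletons)))
        if set(self.couples) & set(self.singletons):
            raise ValueError("a cluster cannot be both couple and singleton")
        if len(set(self.couples)) != len(self.couples) or \
                len(set(self.singletons)) != len(self.singletons):
            raise ValueError("duplicate cluster index in configuration")

    @property
    def k_C(self) -> int:
        return len(self.couples)

    @property
    def k_I(self) -> int:
        return len(self.singletons)

    @property
    def k(self) -> int:
        return self.k_C + self.k_I

    @property
    def included(self) -> tuple[int, ...]:
        """All included cluster indices, couples first (coefficient order)."""
        return self.couples + self.singletons

    def validate(self, p: int, kmax: int | None = None) -> None:
        if self.k and not (0 <= min(self.included) and max(self.included) < p):
            raise ValueError("cluster index out of range")
        if kmax is not None and self.k > kmax:
            raise ValueError(f"configuration dimension {self.k} exceeds kmax={kmax}")


@dataclass
class CoefficientState:
    """Sampled regression coefficients aligned with a ModelConfiguration.

    ``a`` holds the intensity effects for ``config.included`` (couples first,
    then singletons); ``b`` holds the shape effects for ``config.couples``.
    ``s_a`` and ``s_b`` are the positive variance scale factors: the effect
    variances are sigma_a^2 = tau_a^2 / s_a and sigma_b^2 = tau_b^2 / s_b.
    """

    beta0: float
    a: np.ndarray
    b: np.ndarray
    s_a: float
    s_b: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.s_a <= 0 or self.s_b <= 0:
            raise ValueError("variance scale factors must be positive")

    def check_alignment(self, config: ModelConfiguration) -> None:
        if self.a.shape != (config.k,) or self.b.shape != (config.k_C,):
            raise ValueError(
                f"coefficient vectors (a:{self.a.shape}, b:{self.b.shape}) do not "
                f"align with configuration (k={config.k}, k_C={config.k_C})")


@dataclass(frozen=True)
class ChainSample:
    iteration: int
    config: ModelConfiguration
    coeffs: CoefficientState


@dataclass(frozen=True)
class ChainSettings:
    n_iter: int
    burn_in: int
    thin: int
    seed: int
    prior_only: bool = False
    fix_scales: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_iter < 0 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("invalid chain settings")

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter, "burn_in": self.burn_in, "thin": self.thin,
            "seed": self.seed, "prior_only": self.prior_only,
            "fix_scales": list(self.fix_scales) if self.fix_scales else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainSettings":
        fs = d.get("fix_scales")
        return cls(n_iter=d["n_iter"], burn_in=d["burn_in"], thin=d["thin"],
                   seed=d["seed"], prior_only=d.get("prior_only", False),
                   fix_scales=tuple(fs) if fs else None)


@dataclass
class Chain:
    """Thinned post-burn-in samples of the variable-dimension model."""

    samples: list[ChainSample]
    settings: ChainSettings
    prior: PriorSpec
    p: int
    pair_ids: tuple = ()

    def __post_init__(self) -> None:
        its = [s.iteration for s in self.samples]
        if any(b <= a for a, b in zip(its, its[1:])):
            raise ValueError("sample iterations must be strictly increasing")
        if not self.pair_ids:
            self.pair_ids = tuple(range(1, self.p + 1))
        if len(self.pair_ids) != self.p:
            raise ValueError("pair_ids length must equal p")

    def __len__(self) -> int:
        return len(self.samples)

    def k_trace(self) -> np.ndarray:
        return np.array([s.config.k for s in self.samples], dtype=int)

    def kC_trace(self) -> np.ndarray:
        return np.array([s.config.k_C for s in self.samples], dtype=int)

    def kI_trace(self) -> np.ndarray:
        return np.array([s.config.k_I for s in self.samples], dtype=int)


# ---------------------------------------------------------------------------
# Likelihood contracts
# ---------------------------------------------------------------------------

def linear_predictor(config: ModelConfiguration, coeffs: CoefficientState,
                     design) -> np.ndarray:
    """Linear predictor eta_i for every individual in ``design``.

    eta_i = beta0 + sum_{j in couples} (a_j u_ij + b_j v_ij)
                  + sum_{l in singletons} a_l u_il
    """
    coeffs.check_alignment(config)
    n = design.n
    eta = np.full(n, float(coeffs.beta0))
    if config.k:
        idx = np.array(config.included, dtype=int)
        eta += design.U[:, idx] @ coeffs.a
    if config.k_C:
        cidx = np.array(config.couples, dtype=int)
        eta += design.V[:, cidx] @ coeffs.b
    return eta


def bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli-logistic log likelihood sum_i [y_i eta_i - log(1 + exp(eta_i))].

    Overflow-safe: log(1+exp(eta)) is evaluated as eta + log1p(exp(-eta)) for
    positive eta.
    """
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(y)
    if eta.shape != y.shape:
        raise ValueError("eta and y must have the same length")
    # log(1+e^eta) = max(eta,0) + log1p(e^{-|eta|})
    log1pe = np.maximum(eta, 0.0) + np.log1p(np.exp(-np.abs(eta)))
    return float(np.sum(y * eta - log1pe))


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def prior_scale_heuristic(design) -> tuple[float, float]:
    """Data-driven prior guess for the rescaling factors (tau_a, tau_b).

    In logistic regression the coefficient covariance is approximately
    n (X'X)^{-1}, so the typical coefficient scale for a single column x is of
    order n / (x'x).  The heuristic takes the median over columns of the
    reciprocal cross-product 1/(x'x), multiplies by n, and rounds to two
    significant figures, separately for the intensity and the shape columns
    (which live on systematically different scales).  Columns are used as
    supplied, without centering or standardization.
    """
    n = design.n
    out = []
    for name, M in (("u", design.U), ("v", design.V)):
        cross = np.einsum("ij,ij->j", M, M)
        ok = cross > 0
        if not ok.all():
            warnings.warn(
                f"{(~ok).sum()} zero-variance {name} column(s) excluded from the "
                "prior-scale median", stacklevel=2)
        if not ok.any():
            raise ValueError(f"all {name} columns are identically zero")
        out.append(_round_sig(n * float(np.median(1.0 / cross[ok])), 2))
    return out[0], out[1]
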