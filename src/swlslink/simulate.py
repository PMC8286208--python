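"""Seedable synthetic SWLS response matrices.

Real item-level SWLS data from the injury registries the scale was
validated in are not redistributable, so the linking pipeline is exercised
on synthetic respondents instead.  The generator draws a latent
multivariate normal with an exchangeable (or fully specified) inter-item
correlation, then discretizes each latent value to the 7-point response
scale by rounding to the nearest integer and clipping to [1, 7].

Round-and-clip biases the discretized mean away from the latent mean
whenever the latent distribution has appreciable mass outside [0.5, 7.5],
so the latent means are *calibrated*: for each item we solve (by scalar
root-finding on the closed-form expectation of the discretized variable)
for the latent mean whose discretized mean equals the target.  Latent SDs
are left at the target SDs; discretization compresses variance, so the
achieved SD is reported rather than forced — the quantities the linking
method depends on are the item means.

The default profile reproduces the published overall item-level means
(3.76, 3.80, 4.32, 4.53, 3.72) and SDs (2.07, 2.04, 2.07, 2.00, 2.18) of a
combined spinal-cord, brain and burn injury sample of n = 17,897, with an
exchangeable latent correlation of 0.65 — a documented assumption (the
inter-item covariance is not published) chosen to give the high internal
consistency reported for the scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .scoring import LIKERT_MAX, LIKERT_MIN

__all__ = [
    "LikertSimConfig",
    "CalibrationError",
    "CalibrationResult",
    "discretized_moments",
    "calibrate_latent_means",
    "generate_responses",
    "default_swls_profile",
    "DEFAULT_PROFILE_MEANS",
    "DEFAULT_PROFILE_SDS",
    "DEFAULT_PROFILE_RHO",
    "DEFAULT_PROFILE_N",
    "DEFAULT_PROFILE_SEED",
]

DEFAULT_PROFILE_MEANS = (3.76, 3.80, 4.32, 4.53, 3.72)
DEFAULT_PROFILE_SDS = (2.07, 2.04, 2.07, 2.00, 2.18)
DEFAULT_PROFILE_RHO = 0.65
DEFAULT_PROFILE_N = 17_897
DEFAULT_PROFILE_SEED = 20210717


class CalibrationError(ValueError):
    """Raised when a target mean/SD pair cannot exist on the 1-7 grid."""


@dataclass(frozen=True)
class LikertSimConfig:
    """Targets for one synthetic sample of five correlated 7-point items."""

    n: int
    target_means: tuple[float, ...]
    target_sds: tuple[float, ...]
    rho: float | np.ndarray = 0.65
    seed: int = 0

    def __post_init__(self):
        means = tuple(float(m) for m in self.target_means)
        sds = tuple(float(s) for s in self.target_sds)
        if len(means) != 5 or len(sds) != 5:
            raise ValueError("exactly 5 target means and 5 target SDs required")
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if any(not LIKERT_MIN < m < LIKERT_MAX for m in means):
            raise CalibrationError(
                "target means must lie strictly inside the scale range "
                f"({LIKERT_MIN}, {LIKERT_MAX})"
            )
        if any(s <= 0 for s in sds):
            raise ValueError("target SDs must be positive")
        object.__setattr__(self, "target_means", means)
        object.__setattr__(self, "target_sds", sds)
        object.__setattr__(self, "rho", self._check_rho(self.rho))

    @staticmethod
    def _check_rho(rho):
        if np.isscalar(rho):
            r = float(rho)
            if not -0.25 < r <= 1:  # exchangeable 5x5 PSD requires rho > -1/4
                raise ValueError("exchangeable correlation must lie in (-0.25, 1]")
            return r
        m = np.asarray(rho, dtype=float)
        if m.shape != (5, 5) or not np.allclose(m, m.T):
            raise ValueError("correlation matrix must be symmetric 5x5")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        return m

    def correlation_matrix(self) -> np.ndarray:
        if np.isscalar(self.rho):
            m = np.full((5, 5), float(self.rho))
            np.fill_diagonal(m, 1.0)
            return m
        return np.array(self.rho, dtype=float)


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated latent parameters and the moments they achieve."""

    latent_means: np.ndarray
    latent_sds: np.ndarray
    achieved_means: np.ndarray = field(repr=False)
    achieved_sds: np.ndarray = field(repr=False)


def discretized_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Exact mean and SD of round-and-clip(N(mu, sigma^2)) on the 1-7 grid.

    The discretized variable takes value j with probability equal to the
    normal mass on (j-0.5, j+0.5), the end bins absorbing the tails.
    """
    edges = np.arange(LIKERT_MIN, LIKERT_MAX) + 0.5  # 1.5 … 6.5
    cdf = stats.norm.cdf(edges, loc=mu, scale=sigma)
    probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    values = np.arange(LIKERT_MIN, LIKERT_MAX + 1)
    mean = float(probs @ values)
    var = float(probs @ (values - mean) ** 2)
    return mean, float(np.sqrt(var))


def _feasible(mean: float, sd: float) -> bool:
    # a distribution supported on [1, 7] with mean m has variance at most
    # (7 - m)(m - 1) (two-point bound), so some mean/SD pairs cannot exist
    return sd * sd <= (LIKERT_MAX - mean) * (mean - LIKERT_MIN)


def calibrate_latent_means(cfg: LikertSimConfig) -> CalibrationResult:
    """Solve for latent normal means whose discretized means hit the targets.

    Latent SDs are fixed at the target SDs; the achieved post-discretization
    mean and SD per item are returned alongside.  Raises
    :class:`CalibrationError` for targets that no distribution on the 1-7
    grid can attain (boundary means, or SD above the moment bound).
    """
    latent_means = np.empty(5)
    ach_means = np.empty(5)
    ach_sds = np.empty(5)
    for i, (m, s) in enumerate(zip(cfg.target_means, cfg.target_sds)):
        if not _feasible(m, s):
            raise CalibrationError(
                f"item {i + 1}: no distribution on [1, 7] has mean {m} and SD {s} "
                f"(max SD at that mean is {np.sqrt((7 - m) * (m - 1)):.3f})"
            )
        lo = LIKERT_MIN - 8 * s
        hi = LIKERT_MAX + 8 * s
        try:
            mu = optimize.brentq(
                lambda mu: discretized_moments(mu, s)[0] - m, lo, hi, xtol=1e-10
            )
        except ValueError as err:  # pragma: no cover - guarded by _feasible
            raise CalibrationError(f"item {i + 1}: calibration failed ({err})") from err
        latent_means[i] = mu
        ach_means[i], ach_sds[i] = discretized_moments(mu, s)
    return CalibrationResult(
        latent_means=latent_means,
        latent_sds=np.asarray(cfg.target_sds, dtype=float),
        achieved_means=ach_means,
        achieved_sds=ach_sds,
    )


def generate_responses(cfg: LikertSimConfig) -> np.ndarray:
    """Draw an n×5 integer response matrix for the configured sample.

    Identical configs (including seed) produce bitwise-identical matrices.
    """
    cal = calibrate_latent_means(cfg)
    corr = cfg.correlation_matrix()
    cov = corr * np.outer(cal.latent_sds, cal.latent_sds)
    rng = np.random.default_rng(cfg.seed)
    latent = rng.multivariate_normal(cal.latent_means, cov, size=cfg.n, method="svd")
    return np.clip(np.rint(latent), LIKERT_MIN, LIKERT_MAX).astype(np.int64)


def default_swls_profile(
    n: int = DEFAULT_PROFILE_N, seed: int = DEFAULT_PROFILE_SEED
) -> LikertSimConfig:
    """Config reproducing the published overall item means and SDs."""
    return LikertSimConfig(
        n=n,
        target_means=DEFAULT_PROFILE_MEANS,
        target_sds=DEFAULT_PROFILE_SDS,
        rho=DEFAULT_PROFILE_RHO,
        seed=seed,
    )
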