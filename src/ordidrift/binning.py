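"""Equal-interval ordinal scoring of a Gaussian latent trait.

Linear type traits such as stature are recorded on an ordinal 1..k scale by
cutting the continuous measurement axis into k equal-width bins with
open-ended extremes.  When the population mean drifts upward while the bin
boundaries stay put, the score distribution piles up in the top category
(ceiling effect).  This module provides the threshold system, the score
assignment rule, exact category probabilities and score moments under any
threshold offset, and the score-phenotype correlation.

Conventions
-----------
* bins are lower-closed / upper-open: score j iff tau_{j-1} <= y < tau_j;
* a threshold offset ``delta`` > 0 means the interior thresholds lag the
  current mean by that amount, i.e. all interior cut points are shifted
  down by delta (equivalently the mean is shifted up);
* unconditional category probabilities integrate the full phenotypic
  distribution N(mu, sigma_y^2); probabilities conditional on a breeding
  value u use the residual SD sigma_e (see :mod:`ordidrift.projection`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.stats import norm, spearmanr
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CM_PER_INCH",
    "ThresholdSystem",
    "LatentTraitModel",
    "ScoreDistribution",
    "make_equal_interval_thresholds",
    "assign_score",
    "category_probabilities",
    "score_moments",
    "score_phenotype_correlation",
    "EqualIntervalBinner",
]

CM_PER_INCH = 2.54

_UNITS = ("in", "cm")


def _check_unit(unit: str) -> str:
    if unit not in _UNITS:
        raise ValueError(f"unit must be one of {_UNITS}, got {unit!r}")
    return unit


def _check_same_unit(a, b) -> None:
    if a.unit != b.unit:
        raise ValueError(
            f"mixed units: {a.unit!r} vs {b.unit!r}; convert explicitly with "
            ".to_unit() before combining"
        )


@dataclass(frozen=True)
class ThresholdSystem:
    """Ordered interior cut points defining ``k`` ordinal categories.

    Parameters
    ----------
    k : int
        Number of categories (>= 2 for a non-degenerate system).
    tau : ndarray
        Interior thresholds tau_1 < ... < tau_{k-1} in measurement units.
        tau_0 = -inf and tau_k = +inf are implicit.
    unit : str
        Measurement unit tag, ``"in"`` or ``"cm"``.
    delta : float
        Threshold offset Delta >= 0 (same units).  delta > 0 models an
        outdated system whose cut points sit ``delta`` below where the
        current phenotypic mean would place them.
    """

    k: int
    tau: np.ndarray
    unit: str = "in"
    delta: float = 0.0

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        object.__setattr__(self, "tau", tau)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if tau.ndim != 1 or len(tau) != self.k - 1:
            raise ValueError(f"need k-1={self.k - 1} interior thresholds, got {len(tau)}")
        if len(tau) > 1 and not np.all(np.diff(tau) > 0):
            raise ValueError("thresholds must be strictly increasing")
        _check_unit(self.unit)
        if self.delta < 0:
            raise ValueError("delta must be >= 0")

    @property
    def effective_tau(self) -> np.ndarray:
        """Interior thresholds actually applied to phenotypes (tau - delta)."""
        return self.tau - self.delta

    def with_delta(self, delta: float) -> "ThresholdSystem":
        return replace(self, delta=float(delta))

    def to_unit(self, unit: str) -> "ThresholdSystem":
        _check_unit(unit)
        if unit == self.unit:
            return self
        f = CM_PER_INCH if unit == "cm" else 1.0 / CM_PER_INCH
        return ThresholdSystem(self.k, self.tau * f, unit, self.delta * f)

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, stream=None) -> str | None:
        doc = {
            "k": int(self.k),
            "tau": [float(t) for t in self.tau],
            "unit": self.unit,
            "delta": float(self.delta),
        }
        return yaml.safe_dump(doc, stream, sort_keys=False)

    @classmethod
    def from_yaml(cls, source) -> "ThresholdSystem":
        if isinstance(source, str):
            source = io.StringIO(source)
        doc = yaml.safe_load(source)
        return cls(int(doc["k"]), np.asarray(doc["tau"], float),
                   doc.get("unit", "in"), float(doc.get("delta", 0.0)))


@dataclass(frozen=True)
class LatentTraitModel:
    """Gaussian latent trait: y = mu + u + e with u ~ N(0, sigma_u2),
    e ~ N(0, sigma_e2), so y ~ N(mu, sigma_y2), sigma_y2 = sigma_u2 + sigma_e2.
    """

    mu: float
    sigma_u2: float
    sigma_e2: float
    unit: str = "in"

    def __post_init__(self):
        if self.sigma_u2 < 0:
            raise ValueError("sigma_u2 must be >= 0")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be > 0")
        _check_unit(self.unit)

    @property
    def sigma_y2(self) -> float:
        return self.sigma_u2 + self.sigma_e2

    @property
    def sigma_y(self) -> float:
        return float(np.sqrt(self.sigma_y2))

    @property
    def sigma_e(self) -> float:
        return float(np.sqrt(self.sigma_e2))

    @property
    def sigma_u(self) -> float:
        return float(np.sqrt(self.sigma_u2))

    @property
    def h2(self) -> float:
        return self.sigma_u2 / self.sigma_y2

    @classmethod
    def from_h2(cls, mu: float, sigma_y: float, h2: float, unit: str = "in"
                ) -> "LatentTraitModel":
        """Build from phenotypic SD and heritability (sigma_u2 = h2 sigma_y^2)."""
        if not 0 <= h2 < 1:
            raise ValueError("h2 must be in [0, 1)")
        s2 = float(sigma_y) ** 2
        return cls(mu, h2 * s2, (1.0 - h2) * s2, unit)

    def to_unit(self, unit: str) -> "LatentTraitModel":
        _check_unit(unit)
        if unit == self.unit:
            return self
        f = CM_PER_INCH if unit == "cm" else 1.0 / CM_PER_INCH
        return LatentTraitModel(self.mu * f, self.sigma_u2 * f * f,
                                self.sigma_e2 * f * f, unit)


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact distribution of the ordinal score s on {1, ..., k}."""

    p: np.ndarray
    mean: float = field(init=False)
    second_moment: float = field(init=False)
    var: float = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if np.any(p < -1e-15):
            raise ValueError("negative category probability")
        p = np.clip(p, 0.0, None)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "p", p)
        j = np.arange(1, len(p) + 1, dtype=float)
        m = float(j @ p)
        m2 = float((j * j) @ p)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "second_moment", m2)
        object.__setattr__(self, "var", max(m2 - m * m, 0.0))

    @property
    def k(self) -> int:
        return len(self.p)


def make_equal_interval_thresholds(center: float, width: float, k: int,
                                   unit: str = "in", delta: float = 0.0
                                   ) -> ThresholdSystem:
    """Equal-interval thresholds with the central bin straddling ``center``.

    For odd ``k`` the middle category is [center - width/2, center + width/2);
    interior thresholds sit at center +/- (j - 1/2) * width.  The first and
    last categories are open-ended.

    >>> make_equal_interval_thresholds(58, 1, 9).tau
    array([54.5, 55.5, 56.5, 57.5, 58.5, 59.5, 60.5, 61.5])
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if k < 2:
        raise ValueError("k must be >= 2")
    # k-1 cut points symmetric about `center` with spacing `width`
    j = np.arange(k - 1, dtype=float)
    tau = center + (j - (k - 2) / 2.0) * width
    return ThresholdSystem(k, tau, unit, delta)


def assign_score(y, ts: ThresholdSystem):
    """Ordinal score(s) for phenotype(s) ``y`` under (possibly shifted) thresholds.

    Scalar in, scalar out; array in, int array out.  Boundary values go to the
    upper bin (lower-closed / upper-open intervals).
    """
    arr = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("phenotypes must be finite")
    s = 1 + np.searchsorted(ts.effective_tau, arr, side="right")
    if arr.ndim == 0:
        return int(s)
    return s.astype(np.int64)


def category_probabilities(model: LatentTraitModel, ts: ThresholdSystem,
                           u: float | None = None) -> ScoreDistribution:
    """Exact category probabilities of the score.

    Unconditionally (``u is None``) the phenotype is N(mu, sigma_y^2) and

        p_j = Phi((tau_j - mu - delta)/sigma_y) - Phi((tau_{j-1} - mu - delta)/sigma_y).

    Conditional on a breeding value ``u`` the phenotype is N(mu + u, sigma_e^2)
    and sigma_e replaces sigma_y (with mu + u in place of mu).
    """
    _check_same_unit(model, ts)
    if u is None:
        loc, scale = model.mu, model.sigma_y
    else:
        loc, scale = model.mu + u, model.sigma_e
    z = (ts.tau - loc - ts.delta) / scale
    cdf = np.concatenate([[0.0], norm.cdf(z), [1.0]])
    return ScoreDistribution(np.diff(cdf))


def score_moments(dist: ScoreDistribution) -> tuple[float, float, float]:
    """(mean, variance, second moment) of the ordinal score."""
    return dist.mean, dist.var, dist.second_moment


def _stein_cov_score_phenotype(model: LatentTraitModel, ts: ThresholdSystem) -> float:
    """Cov(s, y) = sigma_y * sum_j phi((tau_j - mu - delta)/sigma_y).

    Stein's lemma applied to the full phenotype: s depends on y through the
    step function with unit jumps at the effective thresholds, whose
    distributional derivative is a sum of Dirac masses.
    """
    z = (ts.tau - model.mu - ts.delta) / model.sigma_y
    return model.sigma_y * float(norm.pdf(z).sum())


def score_phenotype_correlation(model: LatentTraitModel, ts: ThresholdSystem,
                                method: str = "closed_form",
                                n_mc: int = 1_000_000,
                                seed: int | None = None,
                                ) -> tuple[float, float | None]:
    """Squared Pearson and (rank) Spearman correlation between score and phenotype.

    closed_form: pearson_sq = Cov(s, y)^2 / (Var(s) sigma_y^2) with the Stein
    covariance; Spearman has no elementary closed form for k > 2 and is
    returned as None.  monte_carlo: both, from ``n_mc`` simulated phenotypes
    (Spearman with average ranks for the heavily tied scores).
    """
    _check_same_unit(model, ts)
    if method == "closed_form":
        dist = category_probabilities(model, ts)
        cov = _stein_cov_score_phenotype(model, ts)
        return cov * cov / (dist.var * model.sigma_y2), None
    if method == "monte_carlo":
        if seed is None:
            raise ValueError("monte_carlo requires a seed")
        rng = np.random.default_rng(seed)
        y = rng.normal(model.mu, model.sigma_y, int(n_mc))
        s = assign_score(y, ts)
        pear = float(np.corrcoef(s, y)[0, 1])
        rho = float(spearmanr(s, y).statistic)
        return pear * pear, rho
    raise ValueError(f"unknown method {method!r}")


class EqualIntervalBinner(TransformerMixin, BaseEstimator):
    """Discretize continuous phenotypes into 1..k ordinal scores.

    A stateless transformer (the bin edges come from parameters, not data)
    so it slots into sklearn pipelines alongside data-driven steps.

    Parameters
    ----------
    center, width, k : the equal-interval grid (central bin straddles center).
    delta : threshold offset; > 0 reproduces an outdated scoring system.
    unit : unit tag carried through to the ThresholdSystem.
    rescale : multiply scores by this constant (e.g. 5 for a 5..45 scale).
    """

    def __init__(self, center: float = 58.0, width: float = 1.0, k: int = 9,
                 delta: float = 0.0, unit: str = "in", rescale: float = 1.0):
        self.center = center
        self.width = width
        self.k = k
        self.delta = delta
        self.unit = unit
        self.rescale = rescale

    def fit(self, X, y=None):
        self.thresholds_ = make_equal_interval_thresholds(
            self.center, self.width, self.k, self.unit, self.delta)
        return self

    def transform(self, X):
        if not hasattr(self, "thresholds_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        flat = assign_score(X.ravel(), self.thresholds_).reshape(X.shape)
        out = flat * self.rescale
        return out if self.rescale != 1.0 else flat
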