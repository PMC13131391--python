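"""Selection-theory consequences of outdated scoring thresholds.

Accuracy of selection on a back-transformed score-scale evaluation is
r(delta) = sqrt(h_s^2(delta)); expected response to truncation selection is
R = i_alpha * r * sigma_u with i_alpha = phi(z_{1-alpha}) / alpha the
selection intensity.  Relative selection accuracy (RSA) compares rankings
produced by an ordinal-scale evaluation with the continuous-scale baseline
within the subset of animals a breeder would actually act on (the tallest,
intermediate or smallest fraction q, chosen on the baseline EBVs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr

__all__ = [
    "selection_accuracy",
    "selection_intensity",
    "expected_response",
    "relative_selection_accuracy",
    "rsa_table",
    "SelectionReport",
]


def selection_accuracy(h_s2: float) -> float:
    """Expected accuracy of phenotype-based selection, r = sqrt(h_s^2)."""
    if not 0.0 <= h_s2 <= 1.0:
        raise ValueError("heritability must lie in [0, 1]")
    return float(np.sqrt(h_s2))


def selection_intensity(alpha: float) -> float:
    """Mean of the selected top-alpha tail of a standard normal:
    i_alpha = phi(z_{1-alpha}) / alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("selected proportion must lie in (0, 1)")
    return float(norm.pdf(norm.ppf(1.0 - alpha)) / alpha)


def expected_response(alpha: float, r: float, sigma_u: float) -> float:
    """Expected genetic gain R = i_alpha * r * sigma_u (units of sigma_u)."""
    return selection_intensity(alpha) * r * sigma_u


def _subset_indices(baseline: np.ndarray, objective: str, proportion: float
                    ) -> np.ndarray:
    n = len(baseline)
    m = max(int(round(proportion * n)), 1)
    order = np.argsort(baseline, kind="stable")  # ascending
    if objective == "top":
        return order[-m:]
    if objective == "bottom":
        return order[:m]
    if objective == "middle":
        lo = (n - m) // 2
        return order[lo:lo + m]
    raise ValueError(f"unknown objective {objective!r}")


def relative_selection_accuracy(ebv_test: np.ndarray, ebv_baseline: np.ndarray,
                                objective: str = "top", proportion: float = 0.05,
                                truth: np.ndarray | None = None) -> float:
    """RSA of a test evaluation against the continuous-scale baseline.

    The subset is picked on the baseline EBVs (top-q, symmetric middle-q or
    bottom-q).  With ``truth`` omitted — the realistic benchmark framing,
    where true breeding values are unknown and the baseline evaluation is
    the reference — RSA is the rank correlation between test and baseline
    EBVs within the subset.  With ``truth`` given (simulations), RSA is the
    ratio Spearman(test, truth | subset) / Spearman(baseline, truth | subset).
    At proportion = 1 all objectives coincide with the full population.
    """
    ebv_test = np.asarray(ebv_test, float)
    ebv_baseline = np.asarray(ebv_baseline, float)
    if ebv_test.shape != ebv_baseline.shape:
        raise ValueError("EBV vectors must cover the same animals")
    if not 0.0 < proportion <= 1.0:
        raise ValueError("proportion must lie in (0, 1]")
    idx = _subset_indices(ebv_baseline, objective, proportion)
    if len(idx) < 3:
        raise ValueError("selected subset too small for a rank correlation")
    if truth is None:
        return float(spearmanr(ebv_test[idx], ebv_baseline[idx]).statistic)
    truth = np.asarray(truth, float)
    num = spearmanr(ebv_test[idx], truth[idx]).statistic
    den = spearmanr(ebv_baseline[idx], truth[idx]).statistic
    return float(num / den)


def rsa_table(ebv_test: np.ndarray, ebv_baseline: np.ndarray,
              proportions=(0.05, 0.10, 0.25, 0.50),
              objectives=("top", "middle", "bottom"),
              truth: np.ndarray | None = None) -> pd.DataFrame:
    """RSA over a grid of objectives and selected proportions."""
    rows = [
        {"objective": ob, "proportion": q,
         "rsa": relative_selection_accuracy(ebv_test, ebv_baseline, ob, q, truth)}
        for ob in objectives for q in proportions
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SelectionReport:
    """Intensity/accuracy/response bundle for one selected proportion."""

    alpha: float
    intensity: float
    accuracy: float
    response: float

    @classmethod
    def from_parameters(cls, alpha: float, h_s2: float, sigma_u: float
                        ) -> "SelectionReport":
        i = selection_intensity(alpha)
        r = selection_accuracy(h_s2)
        return cls(alpha=alpha, intensity=i, accuracy=r, response=i * r * sigma_u)
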