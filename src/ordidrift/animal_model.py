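"""Bayesian animal model: variance components and EBVs by Gibbs sampling.

The pedigree animal model y = 1*mu + Z u + e, u ~ N(0, A sigma_u^2),
e ~ N(0, I sigma_e^2) is fitted by single-site Gibbs sampling with a flat
prior on mu and scaled inverse chi-squared priors on the variances.  The
model is deliberately linear even when the response is an ordinal score —
quantifying what that linear treatment does to variance components and
rankings when scoring thresholds are outdated is the whole point.

Scenario labels used throughout:

====  =======================================================
M0    continuous phenotypes y
M1A   group means of y within delta=0 score classes
M1B   rescaled scores c*s with up-to-date thresholds (delta=0)
M2    rescaled scores with thresholds lagging by 2 inches
M3    rescaled scores with thresholds lagging by 4 inches
====  =======================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

from ._gibbs import gibbs_chain
from .binning import LatentTraitModel, ThresholdSystem, CM_PER_INCH
from .pedsim import Pedigree, PhenotypeSet, inbreeding_coefficients, simulate_phenotypes

__all__ = [
    "GibbsConfig",
    "PosteriorSummary",
    "build_A_inverse",
    "solve_mme",
    "GibbsAnimalModel",
    "gibbs_animal_model",
    "run_scenarios",
    "ScenarioStudy",
    "SCENARIOS",
]

SCENARIOS = ("M0", "M1A", "M1B", "M2", "M3")


def build_A_inverse(ped: Pedigree, use_inbreeding: bool = True) -> sp.csr_matrix:
    """Inverse of the numerator relationship matrix by Henderson's rules.

    Per animal i with Mendelian-sampling variance ratio
    m_i = 0.5 - 0.25 (F_s + F_d)  (both parents known; 0.75 - 0.25 F_p with
    one, 1 with none) the contribution alpha_i = 1/m_i is spread over the
    (i, sire, dam) block.  Sparse symmetric CSR output.
    """
    n = ped.n
    F = inbreeding_coefficients(ped) if use_inbreeding else np.zeros(n)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r); cols.append(c); vals.append(v)

    for i in range(n):
        s, d = int(ped.sire[i]) - 1, int(ped.dam[i]) - 1  # -1 = unknown
        m = 1.0
        if s >= 0:
            m -= 0.25 * (1.0 + F[s])
        if d >= 0:
            m -= 0.25 * (1.0 + F[d])
        a = 1.0 / m
        add(i, i, a)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * a)
                add(p, i, -0.5 * a)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * a)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def solve_mme(y: np.ndarray, phenotyped: np.ndarray, Ainv: sp.spmatrix,
              lam: float) -> tuple[float, np.ndarray]:
    """Direct solve of Henderson's mixed-model equations with known variance
    ratio lam = sigma_e^2 / sigma_u^2.  Returns (mu_hat, BLUP u_hat)."""
    n = Ainv.shape[0]
    w = np.asarray(phenotyped, dtype=float)
    n_rec = w.sum()
    if n_rec == 0:
        raise ValueError("no phenotyped animals")
    yy = np.where(phenotyped, y, 0.0)
    # [[n_rec, w'], [w, diag(w) + lam*Ainv]] @ [mu, u] = [sum y, Z'y]
    top = sp.hstack([sp.csr_matrix([[n_rec]]), sp.csr_matrix(w[None, :])])
    bottom = sp.hstack([sp.csr_matrix(w[:, None]), sp.diags(w) + lam * Ainv])
    lhs = sp.vstack([top, bottom]).tocsc()
    rhs = np.concatenate([[yy.sum()], yy])
    sol = sp.linalg.spsolve(lhs, rhs)
    return float(sol[0]), sol[1:]


@dataclass(frozen=True)
class GibbsConfig:
    """Chain and prior settings for the Gibbs sampler.

    Prior scales default to half the response variance for both components
    (a prior heritability of 0.5) when left as None; nu = 4 keeps the priors
    proper but weak next to thousands of records.
    """

    n_iter: int = 20_000
    burn_in: int = 4_000
    thin: int = 10
    prior_nu_u: float = 4.0
    prior_s2_u: float | None = None
    prior_nu_e: float = 4.0
    prior_s2_e: float | None = None
    seed: int = 0
    n_replicates: int = 10

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_nu_u < 0 or self.prior_nu_e < 0:
            raise ValueError("prior degrees of freedom must be >= 0")


def reduced_config(seed: int = 0, n_replicates: int = 10) -> GibbsConfig:
    """Shorter chains for routine test runs; posterior means of variance
    ratios stabilize quickly at thousands of records."""
    return GibbsConfig(n_iter=2_500, burn_in=500, thin=4, seed=seed,
                       n_replicates=n_replicates)


@dataclass
class PosteriorSummary:
    """Posterior summaries of one chain (or replicate averages)."""

    sigma_u2_mean: float
    sigma_u2_sd: float
    sigma_e2_mean: float
    sigma_e2_sd: float
    sigma_y2_mean: float
    h2_mean: float
    h2_sd: float
    h2_ratio_of_means: float
    mu_mean: float
    ebv: np.ndarray
    sample_var_ebv: float
    sample_var_resid: float
    n_draws: int


class GibbsAnimalModel(BaseEstimator):
    """Sklearn-style estimator around the Gibbs sampler.

    Parameters mirror :class:`GibbsConfig`.  ``fit(y, pedigree)`` takes a
    full-length response vector (NaN marks unphenotyped animals) and leaves
    the posterior in trailing-underscore attributes; ``predict()`` returns
    the EBVs (posterior means of u).
    """

    def __init__(self, n_iter: int = 20_000, burn_in: int = 4_000,
                 thin: int = 10, prior_nu_u: float = 4.0,
                 prior_s2_u: float | None = None, prior_nu_e: float = 4.0,
                 prior_s2_e: float | None = None, seed: int = 0,
                 use_inbreeding: bool = True):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.prior_nu_u = prior_nu_u
        self.prior_s2_u = prior_s2_u
        self.prior_nu_e = prior_nu_e
        self.prior_s2_e = prior_s2_e
        self.seed = seed
        self.use_inbreeding = use_inbreeding

    def fit(self, y, pedigree: Pedigree, Ainv: sp.spmatrix | None = None):
        y = np.asarray(y, dtype=float)
        if len(y) != pedigree.n:
            raise ValueError("response must have one entry per pedigree animal "
                             "(NaN for unphenotyped)")
        phen = np.isfinite(y)
        if phen.sum() < 2:
            raise ValueError("need at least two phenotyped animals")
        if np.ptp(y[phen]) == 0:
            raise ValueError("all phenotypes identical: variance components "
                             "are unidentifiable")
        cfg = GibbsConfig(self.n_iter, self.burn_in, self.thin,
                          self.prior_nu_u, self.prior_s2_u,
                          self.prior_nu_e, self.prior_s2_e, self.seed)
        if Ainv is None:
            Ainv = build_A_inverse(pedigree, self.use_inbreeding)
        self.summary_ = _run_chain(y, phen, Ainv.tocsr(), cfg)
        self.sigma_u2_ = self.summary_.sigma_u2_mean
        self.sigma_e2_ = self.summary_.sigma_e2_mean
        self.h2_ = self.summary_.h2_mean
        self.mu_ = self.summary_.mu_mean
        self.ebv_ = self.summary_.ebv
        return self

    def predict(self):
        return self.ebv_


def _run_chain(y: np.ndarray, phen: np.ndarray, Ainv: sp.csr_matrix,
               cfg: GibbsConfig) -> PosteriorSummary:
    vy = float(np.var(y[phen], ddof=1))
    s2_u = cfg.prior_s2_u if cfg.prior_s2_u is not None else 0.5 * vy
    s2_e = cfg.prior_s2_e if cfg.prior_s2_e is not None else 0.5 * vy
    diag = Ainv.diagonal()
    y_filled = np.where(phen, y, 0.0)
    su2, se2, mu_d, u_mean, n_saved = gibbs_chain(
        Ainv.indptr, Ainv.indices, Ainv.data, diag,
        y_filled, phen.astype(np.uint8),
        int(cfg.n_iter), int(cfg.burn_in), int(cfg.thin),
        float(cfg.prior_nu_u), float(s2_u), float(cfg.prior_nu_e), float(s2_e),
        0.5 * vy, 0.5 * vy, int(cfg.seed) % (2**31 - 1),
    )
    h2 = su2 / (su2 + se2)
    mu_mean = float(mu_d.mean())
    resid = y[phen] - mu_mean - u_mean[phen]
    return PosteriorSummary(
        sigma_u2_mean=float(su2.mean()), sigma_u2_sd=float(su2.std(ddof=1)),
        sigma_e2_mean=float(se2.mean()), sigma_e2_sd=float(se2.std(ddof=1)),
        sigma_y2_mean=float((su2 + se2).mean()),
        h2_mean=float(h2.mean()), h2_sd=float(h2.std(ddof=1)),
        h2_ratio_of_means=float(su2.mean() / (su2.mean() + se2.mean())),
        mu_mean=mu_mean,
        ebv=u_mean,
        sample_var_ebv=float(np.var(u_mean[phen], ddof=1)),
        sample_var_resid=float(np.var(resid, ddof=1)),
        n_draws=int(n_saved),
    )


def gibbs_animal_model(y, ped: Pedigree, config: GibbsConfig,
                       Ainv: sp.spmatrix | None = None) -> PosteriorSummary:
    """Functional wrapper over :class:`GibbsAnimalModel` (single chain)."""
    est = GibbsAnimalModel(config.n_iter, config.burn_in, config.thin,
                           config.prior_nu_u, config.prior_s2_u,
                           config.prior_nu_e, config.prior_s2_e, config.seed)
    est.fit(y, ped, Ainv=Ainv)
    return est.summary_


@dataclass
class ScenarioStudy:
    """Per-replicate results of the M0..M3 scenario comparison."""

    table: pd.DataFrame                     # one row per (replicate, scenario)
    ebv: dict[str, list[np.ndarray]]        # scenario -> EBVs per replicate
    true_u: list[np.ndarray]                # simulated u per replicate
    phenotyped: list[np.ndarray]            # record mask per replicate

    def summary(self) -> pd.DataFrame:
        """Across-replicate means and SDs, one row per scenario."""
        cols = [c for c in self.table.columns if c not in ("replicate", "scenario")]
        g = self.table.groupby("scenario", sort=False)[cols]
        out = g.mean().add_suffix("_mean").join(g.std(ddof=1).add_suffix("_sd"))
        return out.reindex([s for s in SCENARIOS if s in out.index])


def run_scenarios(ped: Pedigree, model: LatentTraitModel, ts: ThresholdSystem,
                  c: float = 5.0, config: GibbsConfig | None = None,
                  scenarios: tuple[str, ...] = SCENARIOS,
                  shift_inches: tuple[float, float] = (2.0, 4.0),
                  phenotyped_fraction: float | None = None,
                  ) -> ScenarioStudy:
    """Simulate and fit the five evaluation scenarios over replicates.

    One phenotype set is simulated per replicate; every scenario reanalyzes
    the same records (continuous, group-mean or rescaled-score response), so
    differences between scenarios are purely the scoring system.  rho_y is
    the rank correlation of each response with the simulated phenotype,
    rho_u of each EBV vector with the simulated breeding values (both over
    phenotyped animals).
    """
    if config is None:
        config = GibbsConfig()
    unit_per_inch = 1.0 if ts.unit == "in" else CM_PER_INCH
    d2, d3 = (s * unit_per_inch for s in shift_inches)
    Ainv = build_A_inverse(ped)
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.generate_state(2 * config.n_replicates) % (2**31 - 1)

    rows, ebvs, true_u, masks = [], {s: [] for s in scenarios}, [], []
    from .pedsim import DEFAULT_PARENT_PHENOTYPED_FRACTION
    frac = (DEFAULT_PARENT_PHENOTYPED_FRACTION
            if phenotyped_fraction is None else phenotyped_fraction)

    for rep in range(config.n_replicates):
        sim_seed = int(rep_seeds[2 * rep])
        chain_seed = int(rep_seeds[2 * rep + 1])
        phe = simulate_phenotypes(ped, model, ts.with_delta(0.0), c=c,
                                  phenotyped_fraction=frac, seed=sim_seed)
        phen = phe.phenotyped
        true_u.append(phe.u)
        masks.append(phen)

        responses = _scenario_responses(phe, ped, model, ts, c, d2, d3, scenarios)
        for sc in scenarios:
            resp = responses[sc]
            yv = np.where(phen, resp, np.nan)
            res = gibbs_animal_model(yv, ped, replace(config, seed=chain_seed),
                                     Ainv=Ainv)
            rho_y = float(spearmanr(resp[phen], phe.y[phen]).statistic)
            rho_u = float(spearmanr(res.ebv[phen], phe.u[phen]).statistic)
            rows.append({
                "replicate": rep, "scenario": sc,
                "sigma_y2": res.sigma_y2_mean,
                "sigma_u2": res.sigma_u2_mean, "sigma_e2": res.sigma_e2_mean,
                "S_u2": res.sample_var_ebv, "S_e2": res.sample_var_resid,
                "h2": res.h2_mean, "rho_y": rho_y, "rho_u": rho_u,
            })
            ebvs[sc].append(res.ebv)
    return ScenarioStudy(pd.DataFrame(rows), ebvs, true_u, masks)


def _scenario_responses(phe: PhenotypeSet, ped: Pedigree,
                        model: LatentTraitModel, ts: ThresholdSystem,
                        c: float, d2: float, d3: float,
                        scenarios) -> dict[str, np.ndarray]:
    from .binning import assign_score
    out = {}
    for sc in scenarios:
        if sc == "M0":
            out[sc] = phe.y
        elif sc == "M1A":
            out[sc] = phe.y_group_mean
        elif sc in ("M1B", "M2", "M3"):
            d = {"M1B": 0.0, "M2": d2, "M3": d3}[sc]
            out[sc] = c * assign_score(phe.y, ts.with_delta(d)).astype(float)
        else:
            raise ValueError(f"unknown scenario {sc!r}")
    return out
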