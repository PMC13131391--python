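"""Presets, run configuration and report tables tying the modules together.

Three canned analyses mirror the package's headline outputs:

* ``bins_table``        — category probabilities and score moments per offset;
* ``projection_table``  — BLP slope, projected variance components and
                          heritability per offset, raw and rescaled;
* ``simulation_study``  — the M0..M3 Gibbs comparison on a synthetic pedigree,
                          with RSA curves against the M0 baseline.

The stature presets: a 9-point, 1-inch grid centred at 58 in (147.32 cm,
the recalibrated system, "EI1") or 56 in (142.24 cm, the previous system,
"EI0"); phenotypic SD 1.87 in (4.75 cm).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .animal_model import GibbsConfig, ScenarioStudy, run_scenarios
from .binning import (CM_PER_INCH, LatentTraitModel, ThresholdSystem,
                      category_probabilities, make_equal_interval_thresholds,
                      score_phenotype_correlation)
from .pedsim import (DEFAULT_N_FOUNDERS, DEFAULT_N_GENERATIONS,
                     DEFAULT_OFFSPRING_PER_MATING,
                     DEFAULT_PARENT_PHENOTYPED_FRACTION, generate_pedigree)
from .projection import projected_components, rescale_components
from .selection import rsa_table

log = logging.getLogger("ordidrift")

__all__ = [
    "stature_thresholds",
    "paper_projection_model",
    "simulation_model",
    "RunConfig",
    "bins_table",
    "projection_table",
    "simulation_study",
    "rsa_curves",
    "run_all",
]


def stature_thresholds(system: str = "EI1", unit: str = "in") -> ThresholdSystem:
    """The 9-category, 1-inch stature grid. EI1 is centred at 58 in
    (147.32 cm); EI0 at 56 in (142.24 cm)."""
    centers = {"EI1": 58.0, "EI0": 56.0}
    if system not in centers:
        raise ValueError("system must be 'EI1' or 'EI0'")
    ts = make_equal_interval_thresholds(centers[system], 1.0, 9, unit="in")
    return ts.to_unit(unit)


def paper_projection_model(unit: str = "cm") -> LatentTraitModel:
    """Worked-example latent model: mu = 147.32 cm, sigma_y = 4.75 cm,
    sigma_u^2 = 10.0 cm^2 (the baseline animal-model estimate)."""
    sy2 = 4.75**2
    m = LatentTraitModel(147.32, 10.0, sy2 - 10.0, unit="cm")
    return m.to_unit(unit)


def simulation_model(unit: str = "cm") -> LatentTraitModel:
    """Simulation-truth latent model: sigma_y = 4.75 cm, h^2 = 0.43."""
    m = LatentTraitModel.from_h2(147.32, 4.75, 0.43, unit="cm")
    return m.to_unit(unit)


@dataclass
class RunConfig:
    """Everything needed for a full, reproducible run (YAML-serializable).

    All stochastic stages draw their streams from ``seed`` deterministically.
    Deltas are in inches regardless of ``unit`` (they name the scenarios);
    they are converted internally when the working unit is cm.
    """

    mu: float = 147.32
    sigma_y: float = 4.75
    h2: float = 0.43
    sigma_u2: float | None = None        # overrides h2*sigma_y^2 when set
    unit: str = "cm"
    system: str = "EI1"
    deltas_in: tuple[float, ...] = (0.0, 2.0, 4.0)
    rescale: float = 5.0
    n_founders: int = DEFAULT_N_FOUNDERS
    n_generations: int = DEFAULT_N_GENERATIONS
    offspring_per_mating: int = DEFAULT_OFFSPRING_PER_MATING
    phenotyped_fraction: float = DEFAULT_PARENT_PHENOTYPED_FRACTION
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    seed: int = 0
    outdir: str = "results"

    def model(self) -> LatentTraitModel:
        if self.sigma_u2 is not None:
            m = LatentTraitModel(147.32, self.sigma_u2,
                                 self.sigma_y**2 - self.sigma_u2, unit="cm")
        else:
            m = LatentTraitModel.from_h2(147.32, self.sigma_y, self.h2, unit="cm")
        m = m.to_unit(self.unit)
        # recentre at the configured mean in the working unit
        return LatentTraitModel(self.mu, m.sigma_u2, m.sigma_e2, self.unit)

    def thresholds(self) -> ThresholdSystem:
        return stature_thresholds(self.system, self.unit)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        gibbs = GibbsConfig(**doc.pop("gibbs", {}))
        deltas = tuple(doc.pop("deltas_in", doc.pop("deltas", (0.0, 2.0, 4.0))))
        return cls(gibbs=gibbs, deltas_in=deltas, **doc)


def _delta_in_unit(delta_in: float, unit: str) -> float:
    return delta_in * (CM_PER_INCH if unit == "cm" else 1.0)


def bins_table(model: LatentTraitModel, ts: ThresholdSystem,
               deltas_in=(0.0, 2.0, 4.0), mc_seed: int | None = None,
               n_mc: int = 1_000_000) -> pd.DataFrame:
    """Per-offset category probabilities, score moments and correlations."""
    rows = []
    for d in deltas_in:
        tsd = ts.with_delta(_delta_in_unit(d, ts.unit))
        dist = category_probabilities(model, tsd)
        r2, _ = score_phenotype_correlation(model, tsd)
        row = {"delta_in": d, **{f"p{j + 1}": p for j, p in enumerate(dist.p)},
               "mean": dist.mean, "var": dist.var,
               "second_moment": dist.second_moment, "pearson_sq": r2}
        if mc_seed is not None:
            _, rho = score_phenotype_correlation(
                model, tsd, "monte_carlo", n_mc=n_mc, seed=mc_seed)
            row["spearman_mc"] = rho
        rows.append(row)
    return pd.DataFrame(rows)


def projection_table(model: LatentTraitModel, ts: ThresholdSystem,
                     deltas_in=(0.0, 2.0, 4.0), c: float = 5.0,
                     method: str = "approx") -> pd.DataFrame:
    """BLP projection table: per offset, beta (per working unit), Var(s),
    projected components on the 1-9 scale, the c-rescaled triple, and h^2."""
    rows = []
    for d in deltas_in:
        tsd = ts.with_delta(_delta_in_unit(d, ts.unit))
        res = projected_components(model, tsd, method=method)
        scaled = rescale_components(res, c)
        rows.append({
            "delta_in": d, "beta": res.beta, "var_s": res.var_s,
            "sigma_us2": res.sigma_us2, "sigma_es2": res.sigma_es2,
            "var_l": scaled.var_s, "sigma_ul2": scaled.sigma_us2,
            "sigma_el2": scaled.sigma_es2, "h2": res.h_s2,
        })
    return pd.DataFrame(rows)


def simulation_study(config: RunConfig) -> ScenarioStudy:
    """Generate the pedigree preset and run the M0..M3 Gibbs comparison."""
    t0 = time.time()
    ped = generate_pedigree(config.n_founders, config.n_generations,
                            config.offspring_per_mating, seed=config.seed)
    log.info("pedigree: %d animals in %d generations (%.1fs)",
             ped.n, ped.generation.max() + 1, time.time() - t0)
    model = config.model()
    gibbs = GibbsConfig(**{**config.gibbs.__dict__, "seed": config.seed})
    study = run_scenarios(ped, model, config.thresholds(), c=config.rescale,
                          config=gibbs,
                          phenotyped_fraction=config.phenotyped_fraction)
    log.info("scenario study done (%.1fs)", time.time() - t0)
    return study


def rsa_curves(study: ScenarioStudy, test_scenarios=("M1B", "M2", "M3"),
               proportions=(0.05, 0.10, 0.25, 0.50),
               objectives=("top", "middle", "bottom")) -> pd.DataFrame:
    """Replicate-averaged RSA of each ordinal scenario against M0."""
    rows = []
    for sc in test_scenarios:
        if sc not in study.ebv:
            continue
        for rep, (test, base) in enumerate(zip(study.ebv[sc], study.ebv["M0"])):
            mask = study.phenotyped[rep]
            tab = rsa_table(test[mask], base[mask], proportions, objectives)
            tab.insert(0, "scenario", sc)
            tab.insert(1, "replicate", rep)
            rows.append(tab)
    out = pd.concat(rows, ignore_index=True)
    return out


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Full pipeline: bins, projection, simulation study, RSA curves.

    Writes bins_delta.csv, projection_table.csv, simulation_table.csv,
    rsa_curves.csv under ``outdir`` and returns the tables."""
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    model, ts = config.model(), config.thresholds()

    bins = bins_table(model, ts, config.deltas_in, mc_seed=config.seed)
    proj = projection_table(model, ts, config.deltas_in, c=config.rescale)
    study = simulation_study(config)
    sim = study.summary().reset_index()
    rsa = rsa_curves(study)

    bins.to_csv(out / "bins_delta.csv", index=False)
    proj.to_csv(out / "projection_table.csv", index=False)
    sim.to_csv(out / "simulation_table.csv", index=False)
    rsa.to_csv(out / "rsa_curves.csv", index=False)
    log.info("wrote 4 tables to %s", out)
    return {"bins": bins, "projection": proj, "simulation": sim, "rsa": rsa,
            "study": study}
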