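"""Synthetic pedigree and phenotype simulation.

Generates discrete-generation pedigrees under random mating, draws breeding
values down the pedigree with Mendelian sampling (inbreeding-adjusted), and
produces continuous phenotypes plus their ordinal scores under any threshold
system.  The default preset emulates a dairy type-classification data set:
three generations totalling 12,909 animals of which about 5,141 carry a
stature record (4.75 cm phenotypic SD, h^2 = 0.43).  Sires are sampled with
replacement (one bull serves many dams, as under AI); each dam is mated once.

Identifiers are 1-based integers; 0 codes an unknown parent — the same
convention the CSV reader/writer uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import LatentTraitModel, ThresholdSystem, assign_score

__all__ = [
    "Pedigree",
    "PhenotypeSet",
    "generate_pedigree",
    "default_pedigree_preset",
    "inbreeding_coefficients",
    "simulate_breeding_values",
    "simulate_phenotypes",
]

# Three equal generations of 4,303 reproduce the reference pedigree size of
# 12,909 ids; phenotyping the whole last generation plus 19.5% of the middle
# one yields ~5,141 records.
DEFAULT_N_FOUNDERS = 4303
DEFAULT_N_GENERATIONS = 2          # descendant generations (3 levels in total)
DEFAULT_OFFSPRING_PER_MATING = 2
DEFAULT_PARENT_PHENOTYPED_FRACTION = 0.195


@dataclass
class Pedigree:
    """Trio-coded pedigree sorted parents-before-offspring.

    animal: 1..n consecutive ids; sire/dam: parent ids (0 = unknown);
    generation: discrete generation index starting at 0 for founders;
    sex: 0 = male, 1 = female (used only to keep sire/dam sets disjoint).
    """

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    sex: np.ndarray | None = None

    def __post_init__(self):
        a = np.asarray(self.animal, dtype=np.int64)
        s = np.asarray(self.sire, dtype=np.int64)
        d = np.asarray(self.dam, dtype=np.int64)
        g = np.asarray(self.generation, dtype=np.int64)
        if not (len(a) == len(s) == len(d) == len(g)):
            raise ValueError("pedigree columns must have equal length")
        if np.any(np.diff(a) != 1) or (len(a) and a[0] != 1):
            raise ValueError("animal ids must be consecutive 1..n")
        if np.any((s >= a) | (d >= a)):
            raise ValueError("parents must precede offspring (id < animal id)")
        if np.any(s < 0) or np.any(d < 0):
            raise ValueError("negative parent id")
        self.animal, self.sire, self.dam, self.generation = a, s, d, g
        if self.sex is not None:
            self.sex = np.asarray(self.sex, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.animal)

    @property
    def n(self) -> int:
        return len(self.animal)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal": self.animal, "sire": self.sire,
                             "dam": self.dam, "generation": self.generation})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\r\n")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(df["animal"].to_numpy(), df["sire"].to_numpy(),
                   df["dam"].to_numpy(), df["generation"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class PhenotypeSet:
    """Simulated effects and records for one pedigree.

    u, e, y are defined for every animal (y = mu + u + e); scores s and
    rescaled scores l only where ``phenotyped`` is True (NaN elsewhere when
    exported).  ``y_group_mean`` replaces each phenotyped y by the mean of
    its delta=0 score group (the group-mean analysis variant).
    """

    u: np.ndarray
    e: np.ndarray
    y: np.ndarray
    s: np.ndarray | None
    l: np.ndarray | None
    phenotyped: np.ndarray
    mu: float
    rescale: float = 1.0
    y_group_mean: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = np.flatnonzero(self.phenotyped)
        out = {"animal": idx + 1, "y": self.y[idx]}
        if self.s is not None:
            out["score"] = self.s[idx]
            out["l"] = self.l[idx]
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\r\n")


def generate_pedigree(n_founders: int = DEFAULT_N_FOUNDERS,
                      n_generations: int = DEFAULT_N_GENERATIONS,
                      offspring_per_mating: int = DEFAULT_OFFSPRING_PER_MATING,
                      seed: int = 0) -> Pedigree:
    """Random-mating pedigree with discrete non-overlapping generations.

    Each generation: every female is mated to one male drawn with
    replacement (paternal half-sib families arise naturally) and produces
    ``offspring_per_mating`` offspring.  Sexes are assigned by balanced
    random split.  Deterministic under ``seed``.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if offspring_per_mating < 1:
        raise ValueError("offspring_per_mating must be >= 1")

    rng = np.random.default_rng(seed)
    animal, sire, dam, gen, sex = [], [], [], [], []

    def add(n_new, sires_of, dams_of, g):
        start = len(animal) + 1
        ids = np.arange(start, start + n_new)
        sx = np.zeros(n_new, dtype=np.int64)
        sx[: n_new // 2] = 1
        rng.shuffle(sx)
        animal.extend(ids); sire.extend(sires_of); dam.extend(dams_of)
        gen.extend([g] * n_new); sex.extend(sx)
        return ids, sx

    cur_ids, cur_sex = add(n_founders, [0] * n_founders, [0] * n_founders, 0)
    for g in range(1, n_generations + 1):
        males = cur_ids[cur_sex == 0]
        females = cur_ids[cur_sex == 1]
        if len(males) == 0 or len(females) == 0:
            raise ValueError(f"generation {g - 1} lacks one sex, cannot mate")
        mates = rng.choice(males, size=len(females))
        n_new = len(females) * offspring_per_mating
        cur_ids, cur_sex = add(
            n_new,
            np.repeat(mates, offspring_per_mating),
            np.repeat(females, offspring_per_mating),
            g,
        )
    return Pedigree(np.array(animal), np.array(sire), np.array(dam),
                    np.array(gen), np.array(sex))


def default_pedigree_preset(seed: int = 0) -> Pedigree:
    """The reference-sized preset: ~12.9k ids over 3 generations."""
    return generate_pedigree(DEFAULT_N_FOUNDERS, DEFAULT_N_GENERATIONS,
                             DEFAULT_OFFSPRING_PER_MATING, seed)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient F per animal via recursive kinship with memoization.

    F_i = f(sire_i, dam_i) where f is the coefficient of kinship; founders
    (unknown parents) are assumed unrelated and non-inbred.  Exact for any
    sorted pedigree; cost is negligible at shallow pedigree depth.
    """
    sire, dam = ped.sire, ped.dam
    cache: dict[tuple[int, int], float] = {}

    def kin(i: int, j: int) -> float:
        # ids are 1-based; 0 = unknown
        if i == 0 or j == 0:
            return 0.0
        if i < j:
            i, j = j, i
        key = (i, j)
        hit = cache.get(key)
        if hit is not None:
            return hit
        if i == j:
            v = 0.5 * (1.0 + kin(sire[i - 1], dam[i - 1]))
        else:
            # i is the later-born: recurse on its parents
            v = 0.5 * (kin(sire[i - 1], j) + kin(dam[i - 1], j))
        cache[key] = v
        return v

    F = np.zeros(ped.n)
    for idx in range(ped.n):
        F[idx] = kin(sire[idx], dam[idx])
    return F


def simulate_breeding_values(ped: Pedigree, sigma_u2: float, seed: int = 0,
                             track_inbreeding: bool = True) -> np.ndarray:
    """Breeding values u ~ N(0, A sigma_u2) simulated down the pedigree.

    Founders are N(0, sigma_u2); a non-founder is the parent average plus a
    Mendelian-sampling deviation with variance
    sigma_u2 * (0.5 - 0.25 (F_sire + F_dam)) (both parents known),
    sigma_u2 * 0.75 (one parent known) or sigma_u2 (none known).
    """
    if sigma_u2 < 0:
        raise ValueError("sigma_u2 must be >= 0")
    n = ped.n
    u = np.zeros(n)
    if sigma_u2 == 0:
        return u
    F = inbreeding_coefficients(ped) if track_inbreeding else np.zeros(n)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == 0 and d == 0:
            u[i] = np.sqrt(sigma_u2) * z[i]
        else:
            pa, msv = 0.0, 1.0
            if s > 0:
                pa += 0.5 * u[s - 1]
                msv -= 0.25 * (1.0 + F[s - 1])
            if d > 0:
                pa += 0.5 * u[d - 1]
                msv -= 0.25 * (1.0 + F[d - 1])
            u[i] = pa + np.sqrt(sigma_u2 * msv) * z[i]
    return u


def simulate_phenotypes(ped: Pedigree, model: LatentTraitModel,
                        ts: ThresholdSystem | None = None,
                        c: float = 1.0,
                        phenotyped_fraction: float = DEFAULT_PARENT_PHENOTYPED_FRACTION,
                        seed: int = 0,
                        track_inbreeding: bool = True) -> PhenotypeSet:
    """Simulate u, e, y (and scores) for a pedigree.

    Phenotypes are recorded on every final-generation animal plus a random
    ``phenotyped_fraction`` of the previous generation.  If ``ts`` is given,
    ordinal scores s = assign_score(y) and rescaled scores l = c*s are
    attached, together with the group-mean phenotype variant.
    """
    rng = np.random.default_rng(seed)
    u = simulate_breeding_values(ped, model.sigma_u2,
                                 seed=rng.integers(2**31 - 1),
                                 track_inbreeding=track_inbreeding)
    e = rng.normal(0.0, model.sigma_e, ped.n)
    y = model.mu + u + e

    last = ped.generation.max()
    phen = ped.generation == last
    prev = np.flatnonzero(ped.generation == last - 1)
    if len(prev) and phenotyped_fraction > 0:
        n_extra = int(round(phenotyped_fraction * len(prev)))
        phen = phen.copy()
        phen[rng.choice(prev, size=n_extra, replace=False)] = True

    s = l = ygm = None
    if ts is not None:
        s = assign_score(y, ts)
        l = c * s.astype(float)
        # group means over the phenotyped records of each score class
        ygm = y.copy()
        idx = np.flatnonzero(phen)
        for j in np.unique(s[idx]):
            grp = idx[s[idx] == j]
            ygm[grp] = y[grp].mean()
    return PhenotypeSet(u=u, e=e, y=y, s=s, l=l, phenotyped=phen,
                        mu=model.mu, rescale=c, y_group_mean=ygm)
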