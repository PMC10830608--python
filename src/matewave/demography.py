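"""Stage-structured two-sex demography with mating systems.

Reproduction happens at the start of the year.  In a patch holding ``f``
potentially reproductive (adult) females and ``m`` adult males, the expected
number of matings follows the harmonic-mean mating function with harem size
``h`` (the maximum number of females one male can fertilize):

    c = min(1, 2 h m / (f + h m)) * f

Each female then reproduces with probability Pr = c / f (a Bernoulli trial),
and a reproducing female's litter is Poisson with mean equal to her effective
fecundity.  For two-sex runs the configured per-female fecundity is doubled
and offspring sex is Bernoulli(1/2), which makes the expected number of
daughters equal to the female-only model's litter and keeps the two model
variants directly comparable.

Survival is density dependent through females only:

    sigma(stage, N_f) = sigma0[stage] * exp(-b * N_f)

where ``N_f`` counts every female currently in the patch (adults plus this
year's juveniles, including immigrant settlers) and ``1/b`` — in units of
females/patch — is read as habitat quality.  Individuals live at most 3
years; survival is applied after dispersal, ages then increment, and anyone
beyond age 3 is removed.

All operations work on per-patch counts: individuals within a patch x sex x
stage class are exchangeable, so binomial and Poisson count draws are
distributionally identical to per-individual Bernoulli/Poisson draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MatingSystem",
    "DemographyParams",
    "FEMALE_ONLY",
    "MONOGAMOUS",
    "POLYGYNOUS",
    "expected_matings",
    "female_reproduction_prob",
    "assign_reproduction",
    "produce_offspring",
    "survival_prob",
    "apply_survival_and_aging",
]

MAX_AGE = 3  # maximum lifespan in years


@dataclass(frozen=True)
class MatingSystem:
    """``female_only`` ignores harem size; h=1 is obligate monogamy, h=100
    the polygynous setting used throughout the experiments."""

    mode: str = "two_sex"  # {"female_only", "two_sex"}
    harem_size: int = 100

    def __post_init__(self) -> None:
        if self.mode not in ("female_only", "two_sex"):
            raise ValueError(f"unknown mating mode {self.mode!r}")
        if self.harem_size < 1:
            raise ValueError("harem size must be >= 1")

    @property
    def two_sex(self) -> bool:
        return self.mode == "two_sex"

    @property
    def label(self) -> str:
        if not self.two_sex:
            return "female_only"
        return "monogamous" if self.harem_size == 1 else "polygynous"


FEMALE_ONLY = MatingSystem(mode="female_only")
MONOGAMOUS = MatingSystem(mode="two_sex", harem_size=1)
POLYGYNOUS = MatingSystem(mode="two_sex", harem_size=100)


@dataclass(frozen=True)
class DemographyParams:
    """Vital rates.

    ``fecundity`` is the female-only-scale mean offspring per reproducing
    female; two-sex runs double it when ``fecundity_doubling_two_sex`` is on.
    ``sigma0_adult`` = 0.3 is the maximum adult survival at low density;
    ``sigma0_juvenile`` defaults to 1.0 so the low-density single-patch
    equilibrium sits near 1/b females, consistent with reading 1/b as habitat
    quality in females/patch.  ``b`` is the per-female strength of density
    dependence (habitat quality = 1/b).
    """

    fecundity: float = 3.0
    b: float = 0.1
    sigma0_adult: float = 0.3
    sigma0_juvenile: float = 1.0
    sex_ratio_at_birth: float = 0.5
    fecundity_doubling_two_sex: bool = True

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive")
        if not (0.0 <= self.sigma0_adult <= 1.0 and 0.0 <= self.sigma0_juvenile <= 1.0):
            raise ValueError("sigma0 values must lie in [0, 1]")
        if self.fecundity < 0:
            raise ValueError("fecundity must be non-negative")

    @property
    def habitat_quality(self) -> float:
        return 1.0 / self.b

    def effective_fecundity(self, two_sex: bool) -> float:
        if two_sex and self.fecundity_doubling_two_sex:
            return 2.0 * self.fecundity
        return self.fecundity


def expected_matings(f, m, h: int = 1):
    """Expected matings c = min(1, 2hm/(f+hm)) * f (harmonic-mean function).

    Accepts scalars or arrays; c is 0 whenever either sex is absent.
    """
    f = np.asarray(f, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    if np.any(f < 0) or np.any(m < 0):
        raise ValueError("counts must be non-negative")
    if h < 1:
        raise ValueError("harem size must be >= 1")
    hm = h * m
    denom = f + hm
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, 2.0 * hm / np.where(denom > 0, denom, 1.0), 0.0)
    c = np.minimum(1.0, ratio) * f
    if c.ndim == 0:
        return float(c)
    return c


def female_reproduction_prob(c, f):
    """Pr = c / f, each female's probability of reproducing this year."""
    c = np.asarray(c, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 1):
        raise ValueError("Pr is undefined for patches without females")
    pr = np.clip(c / f, 0.0, 1.0)
    if pr.ndim == 0:
        return float(pr)
    return pr


def assign_reproduction(
    f,
    m,
    mating_system: MatingSystem,
    rng: np.random.Generator,
):
    """Realize this year's reproducing females per patch.

    Parameters are per-patch adult counts (scalars or arrays).  In
    female-only mode every female reproduces (no mate limitation by
    construction).  In two-sex mode each of the ``f`` females independently
    reproduces with probability Pr from the mating function, so the number
    reproducing is Binomial(f, Pr).

    Returns ``(n_reproducing, n_unmated)``.
    """
    f = np.atleast_1d(np.asarray(f, dtype=np.int64))
    if mating_system.two_sex:
        m = np.atleast_1d(np.asarray(m, dtype=np.int64))
        c = expected_matings(f, m, mating_system.harem_size)
        pr = np.zeros_like(c)
        has_f = f > 0
        pr[has_f] = c[has_f] / f[has_f]
        n_repro = rng.binomial(f, pr)
        n_unmated = f - n_repro
    else:
        n_repro = f.copy()
        n_unmated = np.zeros_like(f)
    return n_repro, n_unmated


def produce_offspring(
    n_mothers,
    params: DemographyParams,
    two_sex: bool,
    rng: np.random.Generator,
):
    """Draw litters for ``n_mothers`` reproducing females per patch.

    Litter sizes are iid Poisson(effective fecundity), so the patch total is
    Poisson(n_mothers * phi_eff); offspring sex is Bernoulli(sex ratio) in
    two-sex mode and all-female otherwise.  Offspring are age-0 juveniles in
    the natal patch.

    Returns ``(n_female_juveniles, n_male_juveniles)``.
    """
    n_mothers = np.atleast_1d(np.asarray(n_mothers, dtype=np.int64))
    phi = params.effective_fecundity(two_sex)
    total = rng.poisson(n_mothers * phi)
    if two_sex:
        females = rng.binomial(total, params.sex_ratio_at_birth)
    else:
        females = total.copy()
    return females, total - females


def survival_prob(stage: str, n_f, params: DemographyParams):
    """sigma = sigma0[stage] * exp(-b * N_f); N_f = females in the patch."""
    n_f = np.asarray(n_f, dtype=np.float64)
    if np.any(n_f < 0):
        raise ValueError("female count must be non-negative")
    if stage == "adult":
        s0 = params.sigma0_adult
    elif stage == "juvenile":
        s0 = params.sigma0_juvenile
    else:
        raise ValueError(f"unknown stage {stage!r}")
    sigma = s0 * np.exp(-params.b * n_f)
    if sigma.ndim == 0:
        return float(sigma)
    return sigma


def apply_survival_and_aging(
    adults: np.ndarray,
    juveniles: np.ndarray,
    params: DemographyParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Density-dependent survival and aging for every patch.

    Parameters
    ----------
    adults : int array, shape (n_patches, 2, MAX_AGE)
        Adult counts by (patch, sex, age class 1..MAX_AGE), end of dispersal.
    juveniles : int array, shape (n_patches, 2)
        Age-0 counts by (patch, sex): natal stayers plus immigrant settlers.

    Each individual survives independently with sigma(stage, N_f) where N_f
    is the total number of females — juvenile and adult — in the patch when
    survival is applied.  Survivors age by one year; age-3 adults leave the
    population even if they survive their Bernoulli trial.

    Returns the next year's adult array (juvenile survivors enter age 1).
    """
    n_f = adults[:, 0, :].sum(axis=1) + juveniles[:, 0]
    decay = np.exp(-params.b * n_f)
    s_juv = params.sigma0_juvenile * decay
    s_ad = params.sigma0_adult * decay
    out = np.zeros_like(adults)
    for sex in (0, 1):
        out[:, sex, 0] = rng.binomial(juveniles[:, sex], s_juv)
        for age in range(MAX_AGE - 1):  # age MAX_AGE survivors are removed
            out[:, sex, age + 1] = rng.binomial(adults[:, sex, age], s_ad)
    return out
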