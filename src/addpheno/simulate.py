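"""Synthetic cohorts with planted vulnerable/resilient structure.

The generator reproduces the population structure reported for outbred rats
screened with the 3-criteria addiction model: the compulsivity dimension
(responding maintained under punishment, expressed as percent resistance to
punishment relative to baseline intake) is bimodal — a log-normal majority
(60-70% of animals) in the 0-30% resistance band abutting a normally
distributed minority centred on 85-100% resistance — while motivation and
drug seeking are log-normal on both sides, and roughly 20% of a population
eventually expresses the fully vulnerable (3-criteria) phenotype.

Animals are emitted as raw response counts (the quantity the pipeline
consumes); percent resistance is an internal latent variable converted to a
count via a per-animal baseline intake. Log-normal dimensions are
parameterised by (median, geometric SD) for interpretability: a draw is
``median * gsd ** z`` with ``z ~ N(0, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import Cohort, cohort_from_arrays

ROLE_VULNERABLE = "vulnerable"
ROLE_RESILIENT = "resilient"
ROLE_INTERMEDIATE = "intermediate"

#: Hard bounds on latent percent resistance to punishment.
RESISTANCE_CLIP = (0.0, 120.0)
#: The resilient (non-compulsive) component lives in the 0-30% resistance band.
RESILIENT_RESISTANCE_BAND = (0.0, 30.0)
#: Baseline draws truncated at median * gsd**±3 to keep counts physiological.
_BASELINE_TRUNC_SIGMA = 3.0


@dataclass(frozen=True)
class LogNormalParams:
    """(median, geometric SD) parameterisation of a log-normal."""

    median: float
    gsd: float

    def validate(self, name: str) -> None:
        if not (self.median > 0):
            raise ConfigError(f"{name}.median must be > 0, got {self.median}")
        if not (self.gsd > 1):
            raise ConfigError(f"{name}.gsd must be > 1, got {self.gsd}")


@dataclass(frozen=True)
class NormalParams:
    mean: float
    sd: float

    def validate(self, name: str) -> None:
        if not (self.sd > 0):
            raise ConfigError(f"{name}.sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of one simulated cohort.

    ``noise_overlap`` is the fraction of intermediate (1-2 criteria-like)
    animals, each drawing a random proper subset of dimensions from the
    vulnerable component; ``rank_corr`` is the within-role Gaussian-copula
    correlation among the three dimensions.
    """

    n_animals: int = 88
    prevalence_vulnerable: float = 0.20
    noise_overlap: float = 0.20
    baseline_intake: LogNormalParams = LogNormalParams(median=100.0, gsd=1.3)
    resilient_resistance: LogNormalParams = LogNormalParams(median=10.0, gsd=1.6)
    vulnerable_resistance: NormalParams = NormalParams(mean=92.5, sd=6.0)
    motivation_params: dict = field(
        default_factory=lambda: {
            ROLE_RESILIENT: LogNormalParams(median=150.0, gsd=1.6),
            ROLE_VULNERABLE: LogNormalParams(median=500.0, gsd=1.6),
        }
    )
    seeking_params: dict = field(
        default_factory=lambda: {
            ROLE_RESILIENT: LogNormalParams(median=30.0, gsd=1.8),
            ROLE_VULNERABLE: LogNormalParams(median=110.0, gsd=1.8),
        }
    )
    rank_corr: float = 0.2
    drug: str = "other"
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 0:
            raise ConfigError(f"n_animals must be >= 0, got {self.n_animals}")
        if not (0 < self.prevalence_vulnerable < 1):
            raise ConfigError(
                f"prevalence_vulnerable must be in (0,1), got {self.prevalence_vulnerable}"
            )
        if not (0 <= self.noise_overlap < 1):
            raise ConfigError(f"noise_overlap must be in [0,1), got {self.noise_overlap}")
        if self.prevalence_vulnerable + self.noise_overlap >= 1:
            raise ConfigError("prevalence_vulnerable + noise_overlap must be < 1")
        if not (-0.99 < self.rank_corr < 0.99):
            raise ConfigError(f"rank_corr must be in (-0.99, 0.99), got {self.rank_corr}")
        self.baseline_intake.validate("baseline_intake")
        self.resilient_resistance.validate("resilient_resistance")
        self.vulnerable_resistance.validate("vulnerable_resistance")
        for role in (ROLE_RESILIENT, ROLE_VULNERABLE):
            if role not in self.motivation_params:
                raise ConfigError(f"motivation_params missing role {role!r}")
            if role not in self.seeking_params:
                raise ConfigError(f"seeking_params missing role {role!r}")
            self.motivation_params[role].validate(f"motivation_params[{role}]")
            self.seeking_params[role].validate(f"seeking_params[{role}]")


def _correlated_normals(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """n x 3 standard normals with pairwise correlation rho (Gaussian copula)."""
    cov = np.full((3, 3), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((n, 3)) @ chol.T


def _lognormal(params: LogNormalParams, z: np.ndarray) -> np.ndarray:
    return params.median * params.gsd ** z


def _draw_role_dims(
    rng: np.random.Generator, config: CohortSimConfig, role: str, n: int
) -> np.ndarray:
    """Latent (motivation, seeking, resistance%) draws for n animals of one role."""
    z = _correlated_normals(rng, n, config.rank_corr)
    motivation = _lognormal(config.motivation_params[role], z[:, 0])
    seeking = _lognormal(config.seeking_params[role], z[:, 1])
    if role == ROLE_VULNERABLE:
        p = config.vulnerable_resistance
        resistance = np.clip(p.mean + p.sd * z[:, 2], *RESISTANCE_CLIP)
    else:
        resistance = np.clip(
            _lognormal(config.resilient_resistance, z[:, 2]), *RESILIENT_RESISTANCE_BAND
        )
    return np.column_stack([motivation, seeking, resistance])


def generate_cohort(
    config: CohortSimConfig, return_latent: bool = False
) -> tuple[Cohort, np.ndarray] | tuple[Cohort, np.ndarray, "pd.DataFrame"]:
    """Generate one cohort plus the planted per-animal truth roles.

    Returns the cohort (raw counts in canonical feature order) and an array
    of roles in {vulnerable, resilient, intermediate}. Intermediate animals
    carry pseudo-crit labels 1 or 2 (the number of dimensions drawn from the
    vulnerable component); resilient and vulnerable animals carry 0 and 3.
    With ``return_latent=True`` a third element exposes the latent percent
    resistance and baseline intake per animal. Output is a pure function of
    the config, including its seed.
    """
    config.validate()
    n = config.n_animals
    rng = np.random.default_rng(config.seed)
    if n == 0:
        empty = cohort_from_arrays(np.empty((0, 3)), drug=config.drug, source="synthetic")
        truth = np.array([], dtype=object)
        if return_latent:
            return empty, truth, pd.DataFrame(columns=["role", "resistance_pct", "baseline"])
        return empty, truth

    u = rng.random(n)
    roles = np.where(
        u < config.prevalence_vulnerable,
        ROLE_VULNERABLE,
        np.where(u < config.prevalence_vulnerable + config.noise_overlap,
                 ROLE_INTERMEDIATE, ROLE_RESILIENT),
    ).astype(object)

    latent = np.empty((n, 3))
    crit = np.zeros(n, dtype=int)
    for i, role in enumerate(roles):
        if role == ROLE_INTERMEDIATE:
            base = _draw_role_dims(rng, config, ROLE_RESILIENT, 1)[0]
            vuln = _draw_role_dims(rng, config, ROLE_VULNERABLE, 1)[0]
            k = int(rng.integers(1, 3))  # 1 or 2 dimensions from the vulnerable side
            dims = rng.choice(3, size=k, replace=False)
            base[dims] = vuln[dims]
            latent[i] = base
            crit[i] = k
        else:
            latent[i] = _draw_role_dims(rng, config, role, 1)[0]
            crit[i] = 3 if role == ROLE_VULNERABLE else 0

    b = config.baseline_intake
    lo, hi = (b.median / b.gsd**_BASELINE_TRUNC_SIGMA, b.median * b.gsd**_BASELINE_TRUNC_SIGMA)
    baseline = np.clip(_lognormal(b, rng.standard_normal(n)), lo, hi)

    features = np.column_stack([
        np.round(latent[:, 0]),
        np.round(latent[:, 1]),
        np.round(latent[:, 2] / 100.0 * baseline),
    ])
    cohort = cohort_from_arrays(
        features, crit_labels=list(crit), drug=config.drug, source="synthetic"
    )
    if return_latent:
        latent_df = pd.DataFrame(
            {"role": roles, "resistance_pct": latent[:, 2], "baseline": baseline}
        )
        return cohort, roles, latent_df
    return cohort, roles


_SCENARIOS = {
    "well_separated",
    "overlapping",
    "paper_like_cocaine",
    "paper_like_alcohol",
}


def make_scenario(name: str, n_animals: int | None = None, seed: int = 0) -> CohortSimConfig:
    """Named study conditions.

    ``well_separated`` has no intermediate animals, at least 4-fold
    between-role separation on every dimension and tight baselines, so the
    planted roles are linearly separable on the punished-responding count
    alone. ``overlapping`` raises the intermediate fraction and narrows the
    separation. The ``paper_like_*`` scenarios use the cohort sizes of the
    pooled cocaine (n=88) and alcohol (n=150) screens with default structure.
    """
    if name not in _SCENARIOS:
        raise ConfigError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    if name == "well_separated":
        cfg = CohortSimConfig(
            n_animals=150,
            noise_overlap=0.0,
            baseline_intake=LogNormalParams(median=100.0, gsd=1.1),
            resilient_resistance=LogNormalParams(median=8.0, gsd=1.5),
            vulnerable_resistance=NormalParams(mean=95.0, sd=4.0),
            motivation_params={
                ROLE_RESILIENT: LogNormalParams(median=120.0, gsd=1.4),
                ROLE_VULNERABLE: LogNormalParams(median=700.0, gsd=1.4),
            },
            seeking_params={
                ROLE_RESILIENT: LogNormalParams(median=25.0, gsd=1.4),
                ROLE_VULNERABLE: LogNormalParams(median=160.0, gsd=1.4),
            },
            seed=seed,
        )
    elif name == "overlapping":
        cfg = CohortSimConfig(
            n_animals=150,
            noise_overlap=0.35,
            resilient_resistance=LogNormalParams(median=14.0, gsd=1.7),
            vulnerable_resistance=NormalParams(mean=88.0, sd=10.0),
            motivation_params={
                ROLE_RESILIENT: LogNormalParams(median=180.0, gsd=1.8),
                ROLE_VULNERABLE: LogNormalParams(median=380.0, gsd=1.8),
            },
            seeking_params={
                ROLE_RESILIENT: LogNormalParams(median=40.0, gsd=1.9),
                ROLE_VULNERABLE: LogNormalParams(median=85.0, gsd=1.9),
            },
            seed=seed,
        )
    elif name == "paper_like_cocaine":
        cfg = CohortSimConfig(n_animals=88, drug="cocaine", seed=seed)
    else:  # paper_like_alcohol
        cfg = CohortSimConfig(n_animals=150, drug="alcohol", seed=seed)
    if n_animals is not None:
        cfg = replace(cfg, n_animals=n_animals)
    return cfg
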