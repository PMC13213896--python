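"""Synthetic multi-site patient-level data with the case study's structure.

The generator emulates a five-jurisdiction primary-care network studying
chronic kidney disease (binary outcome) against hypertension (binary
exposure), sex and age: per-site sample sizes from roughly 1,700 to 24,000,
site-specific exposure prevalence between 0.44 and 0.67, ages drawn from a
truncated normal around 63 years (SD about 12) and rounded to whole years
(age enters models as visit year minus birth year, an integer), and the
outcome drawn from a logistic model

    logit P(Y=1) = b0 + b1*hypertension + b2*sex + b3*age.

Default coefficients are the case study's pooled-data estimates
(-7.0460, 0.2542, -0.0737, 0.0770), which reproduce the ~15% outcome
prevalence.  Sex is coded 1 = male.  Covariates are drawn independently
within site; no within-site covariate correlation is modelled.

Randomness is bit-reproducible: each site's stream is derived from the
master seed and a hash of the site id, so site outputs are independent,
order-insensitive, and unchanged when other sites are added or removed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .glm_core import ModelSpec, SiteDataset

__all__ = [
    "SitePopulationConfig",
    "NetworkConfig",
    "generate_site",
    "generate_network",
    "heterogeneous_network",
    "case_study_spec",
    "case_study_network",
    "write_network",
    "CASE_STUDY_SITES",
    "GLOBAL_COEFFICIENTS",
    "REGIONAL_EXPOSURE_BETAS",
]


@dataclass(frozen=True)
class SitePopulationConfig:
    """Marginal covariate structure of one jurisdiction."""

    site_id: str
    n: int
    exposure_prevalence: float
    male_proportion: float
    age_mean: float
    age_sd: float
    age_bounds: tuple[float, float] = (18.0, 104.0)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"site {self.site_id!r}: n must be >= 1")
        for name in ("exposure_prevalence", "male_proportion"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"site {self.site_id!r}: {name} must be in (0,1)")
        if not self.age_bounds[0] < self.age_bounds[1]:
            raise ValueError(f"site {self.site_id!r}: invalid age bounds")


@dataclass(frozen=True)
class NetworkConfig:
    """A multi-site study: site populations, one common coefficient vector
    (intercept, exposure, sex, age), and a master seed."""

    sites: tuple[SitePopulationConfig, ...]
    coefficients: tuple[float, float, float, float]
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )
        if len(self.coefficients) != 4:
            raise ValueError("coefficients must be (intercept, exposure, sex, age)")


#: Case-study site populations: sizes, exposure (hypertension) prevalence,
#: male proportion, and truncated-normal age parameters per jurisdiction.
CASE_STUDY_SITES: tuple[SitePopulationConfig, ...] = (
    SitePopulationConfig("British Columbia", 1_700, 0.59, 0.54, 63.14, 12.39, (20, 100)),
    SitePopulationConfig("Alberta", 8_002, 0.62, 0.54, 62.66, 12.11, (18, 98)),
    SitePopulationConfig("Manitoba", 6_089, 0.52, 0.55, 63.03, 12.60, (24, 100)),
    SitePopulationConfig("Ontario", 23_946, 0.44, 0.53, 63.58, 12.09, (18, 104)),
    SitePopulationConfig("Maritimes", 2_604, 0.67, 0.51, 64.72, 12.08, (20, 101)),
)

#: Pooled-data (global model) coefficients: intercept, hypertension, sex, age.
GLOBAL_COEFFICIENTS: tuple[float, float, float, float] = (
    -7.0460, 0.2542, -0.0737, 0.0770,
)

#: Site-specific hypertension coefficients exhibiting the case study's
#: regional spread (strongest in British Columbia, weakest in Ontario).
REGIONAL_EXPOSURE_BETAS: tuple[float, ...] = (0.5660, 0.4661, 0.3651, 0.1634, 0.4664)


def case_study_spec() -> ModelSpec:
    """CKD against hypertension, adjusted for sex and age."""
    return ModelSpec(outcome="ckd", covariates=("hypertension", "sex", "age"))


def _site_rng(master_seed: int, site_id: str) -> np.random.Generator:
    # per-site substream keyed by the site id, not its position, so adding or
    # permuting sites never perturbs an existing site's data
    tag = int.from_bytes(hashlib.sha256(site_id.encode()).digest()[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


def generate_site(
    config: SitePopulationConfig, coefficients, seed: int
) -> SiteDataset:
    """Draw one site's records: age ~ rounded truncated normal, sex and
    exposure Bernoulli, outcome Bernoulli through the logit link."""
    beta = np.asarray(coefficients, dtype=float)
    if beta.shape != (4,):
        raise ValueError("coefficients must be (intercept, exposure, sex, age)")
    rng = _site_rng(seed, config.site_id)
    lo, hi = config.age_bounds
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = np.round(
        stats.truncnorm.rvs(
            a, b, loc=config.age_mean, scale=config.age_sd, size=config.n,
            random_state=rng,
        )
    )
    exposure = (rng.random(config.n) < config.exposure_prevalence).astype(np.int64)
    sex = (rng.random(config.n) < config.male_proportion).astype(np.int64)
    eta = beta[0] + beta[1] * exposure + beta[2] * sex + beta[3] * age
    outcome = (rng.random(config.n) < expit(eta)).astype(np.int64)
    data = pd.DataFrame(
        {
            "hypertension": exposure,
            "sex": sex,
            "age": age.astype(np.int64),
            "ckd": outcome,
        }
    )
    return SiteDataset(config.site_id, data)


def generate_network(config: NetworkConfig) -> list[SiteDataset]:
    """One dataset per site, all sharing the common coefficient vector."""
    return [
        generate_site(site, config.coefficients, config.seed)
        for site in config.sites
    ]


def heterogeneous_network(
    config: NetworkConfig, per_site_exposure_betas
) -> list[SiteDataset]:
    """Generate sites with site-specific exposure coefficients (all other
    coefficients common) — the common-effect assumption violated by design,
    to study heterogeneity statistics.  With all betas equal to the common
    value this is bit-identical to :func:`generate_network`."""
    betas = np.asarray(per_site_exposure_betas, dtype=float)
    if betas.shape != (len(config.sites),):
        raise ValueError(
            f"need one exposure beta per site: got {betas.size} for "
            f"{len(config.sites)} sites"
        )
    out = []
    for site, b1 in zip(config.sites, betas):
        coeff = (config.coefficients[0], float(b1), config.coefficients[2],
                 config.coefficients[3])
        out.append(generate_site(site, coeff, config.seed))
    return out


def case_study_network(
    seed: int, scale: float = 1.0, coefficients=GLOBAL_COEFFICIENTS
) -> NetworkConfig:
    """The default five-site study, optionally with sizes scaled down
    (``scale=0.1`` gives a desk-scale network a tenth the size)."""
    sites = tuple(
        SitePopulationConfig(
            s.site_id,
            max(1, round(s.n * scale)),
            s.exposure_prevalence,
            s.male_proportion,
            s.age_mean,
            s.age_sd,
            s.age_bounds,
        )
        for s in CASE_STUDY_SITES
    )
    return NetworkConfig(sites=sites, coefficients=tuple(coefficients), seed=seed)


def write_network(
    datasets: list[SiteDataset], config: NetworkConfig, outdir: str | Path
) -> Path:
    """Write one CSV per site plus a provenance manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for ds in datasets:
        name = ds.site_id.replace(" ", "_").lower() + ".csv"
        ds.data.to_csv(outdir / name, index=False)
        files[ds.site_id] = name
    manifest = {
        "schema": "fedlik.network_manifest/1",
        "seed": config.seed,
        "coefficients": list(config.coefficients),
        "sites": [
            {
                "site_id": s.site_id,
                "n": s.n,
                "exposure_prevalence": s.exposure_prevalence,
                "male_proportion": s.male_proportion,
                "age_mean": s.age_mean,
                "age_sd": s.age_sd,
                "age_bounds": list(s.age_bounds),
                "file": files[s.site_id],
            }
            for s in config.sites
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "manifest.json"
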