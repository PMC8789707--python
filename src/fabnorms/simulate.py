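"""Synthetic cohorts with the demographic and score structure of the
normative sample.

The generator emulates a healthy adult normative cohort: ages and years
of education from a truncated bivariate normal (older participants skew
less educated), a fixed female majority, bounded discrete FAB item
scores driven by latent performance with cubic-age / log-education (and,
for the planning and inhibition sub-scales, reciprocal-education /
quadratic-age) effects, and MoCA scores coupled to FAB performance at a
configurable rank correlation.

Latent (continuous) performance scores are retained as ``*_latent``
columns alongside the discretized item scores; parameter-recovery
oracles fit on the latents, because rounding and range-clipping of the
observable scores bias regression estimates by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, DEFAULT_MOCA_DOMAIN_MAX, MOCA_SUB_KEYS
from .errors import ConfigError

#: Centering constants of the transformed predictors (population values
#: of E[age^3], E[ln edu], E[1/edu], E[age^2] in the emulated sample).
AGE_CUBE_CENTER = 269630.547368
AGE_SQUARE_CENTER = 3958.627368
EDU_LOG_CENTER = 2.366383
EDU_RECIPROCAL_CENTER = 0.105356


@dataclass(frozen=True)
class LatentScaleModel:
    """Latent performance model for one two-item sub-scale.

    latent = intercept + beta_age * (T_age(age) - age_center)
                       + beta_edu * (T_edu(education) - edu_center)
                       + shared_loading * g + N(0, noise_sd)

    where ``g`` is a standard-normal general-performance factor shared by
    all sub-scales (it induces the positive sub-scale intercorrelations of
    real data).  The observable sub-scale score is the latent rounded to
    an integer and clipped to 0..6, then split across the two items as
    evenly as possible.
    """

    intercept: float
    beta_age: float
    age_family: str       # "cube" or "square"
    age_center: float
    beta_edu: float
    edu_family: str       # "log" or "reciprocal"
    edu_center: float
    shared_loading: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def _default_scale_models() -> dict[str, LatentScaleModel]:
    # Age/education betas are the negated published adjustment
    # coefficients; intercepts, shared loading and noise are calibrated
    # once so that the generated sample moments match the normative
    # sample (see docs/methods.md).
    return {
        "FAB1": LatentScaleModel(5.430, -1e-6, "cube", AGE_CUBE_CENTER,
                                 +0.607345, "log", EDU_LOG_CENTER, 0.65, 0.942),
        "FAB2": LatentScaleModel(6.515, -2e-6, "cube", AGE_CUBE_CENTER,
                                 -2.527494, "reciprocal", EDU_RECIPROCAL_CENTER, 0.65, 1.965),
        "FAB3": LatentScaleModel(6.055, -1.03e-4, "square", AGE_SQUARE_CENTER,
                                 +0.640471, "log", EDU_LOG_CENTER, 0.65, 1.800),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the emulated normative sample."""

    n: int = 475
    seed: int = 0
    age_mean: float = 61.08
    age_sd: float = 15.1
    age_range: tuple[float, float] = (21.0, 96.0)
    edu_mean: float = 11.67
    edu_sd: float = 4.57
    edu_range: tuple[float, float] = (1.0, 25.0)
    age_edu_corr: float = -0.45
    female_proportion: float = 306 / 475
    scale_models: dict[str, LatentScaleModel] = field(default_factory=_default_scale_models)
    #: target Spearman correlation between FAB total and MoCA total
    moca_coupling: float = 0.49
    moca_mean: float = 24.5
    moca_sd: float = 3.95
    moca_range: tuple[float, float] = (8.0, 30.0)
    moca_domain_max: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MOCA_DOMAIN_MAX))
    #: resample subjects whose scores fall below these healthy-sample
    #: floors (the screening that shaped the normative sample's ranges)
    fab_total_floor: int = 9
    fab1_floor: int = 1
    fab3_floor: int = 1

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        if not (0.0 <= self.female_proportion <= 1.0):
            raise ConfigError("female_proportion must be in [0, 1]")
        if not (-1.0 < self.age_edu_corr < 1.0):
            raise ConfigError("age_edu_corr must be in (-1, 1)")
        if abs(self.moca_coupling) > 1.0:
            raise ConfigError(f"impossible moca_coupling {self.moca_coupling}")
        for name, rng_ in (("age_range", self.age_range), ("edu_range", self.edu_range)):
            if rng_[0] >= rng_[1]:
                raise ConfigError(f"{name} is degenerate: {rng_}")


def default_config(**overrides) -> GeneratorConfig:
    """The default study conditions; keyword overrides replace fields."""
    cfg = GeneratorConfig(**overrides) if overrides else GeneratorConfig()
    cfg.validate()
    return cfg


_FAMILIES = {
    "cube": lambda x: x ** 3,
    "square": lambda x: x ** 2,
    "log": np.log,
    "reciprocal": lambda x: 1.0 / x,
}


def draw_demographics(config: GeneratorConfig, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (age, education, sex) for ``config.n`` subjects.

    Ages and educations come from a truncated bivariate normal, rounded
    to integer years.  Sex is assigned by deterministic count
    (``round(n * female_proportion)`` females) in random order, so the
    default n=475 cohort reproduces the 306 F / 169 M margin exactly.
    """
    n = config.n
    cov = [[1.0, config.age_edu_corr], [config.age_edu_corr, 1.0]]
    ages = np.empty(0)
    edus = np.empty(0)
    while ages.size < n:
        m = max(64, int((n - ages.size) * 2.5))
        z = rng.multivariate_normal([0.0, 0.0], cov, size=m)
        a = config.age_mean + config.age_sd * z[:, 0]
        e = config.edu_mean + config.edu_sd * z[:, 1]
        keep = ((a >= config.age_range[0]) & (a <= config.age_range[1])
                & (e >= config.edu_range[0]) & (e <= config.edu_range[1]))
        ages = np.concatenate([ages, a[keep]])
        edus = np.concatenate([edus, e[keep]])
    ages = np.round(ages[:n]).astype(int)
    edus = np.clip(np.round(edus[:n]), config.edu_range[0], None).astype(int)
    n_female = int(round(n * config.female_proportion))
    sex = np.array(["F"] * n_female + ["M"] * (n - n_female), dtype=object)
    rng.shuffle(sex)
    return ages, edus, sex


def latent_scores(model: LatentScaleModel, ages: np.ndarray, edus: np.ndarray,
                  g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Continuous latent performance for one sub-scale."""
    ta = _FAMILIES[model.age_family](ages.astype(float)) - model.age_center
    te = _FAMILIES[model.edu_family](edus.astype(float)) - model.edu_center
    eps = rng.normal(0.0, model.noise_sd, ages.size) if model.noise_sd > 0 else 0.0
    return (model.intercept + model.beta_age * ta + model.beta_edu * te
            + model.shared_loading * g + eps)


def _split_items(score: int) -> tuple[int, int]:
    # as-even-as-possible split of a 0..6 sub-scale score over two 0..3 items
    hi = math.ceil(score / 2)
    return hi, score - hi


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Generate a cohort; deterministic for a given ``config.seed``."""
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    names = ("FAB1", "FAB2", "FAB3")
    if set(config.scale_models) != set(names):
        raise ConfigError(f"scale_models must define exactly {names}")
    if n == 0:
        cols = {c: [] for c in
                ("id", "sex", "age", "education")}
        df = pd.DataFrame(cols)
        for c in ("fab1", "fab2", "fab3", "fab4", "fab5", "fab6",
                  "moca_total", *[f"moca_{k.lower()}" for k in MOCA_SUB_KEYS]):
            df[c] = pd.Series([], dtype="Int64")
        return Cohort(df, provenance=f"generated:seed={config.seed},n=0")

    ages, edus, sex = draw_demographics(config, rng)
    g = rng.standard_normal(n)
    latents = {s: latent_scores(config.scale_models[s], ages, edus, g, rng)
               for s in names}
    subs = {s: np.clip(np.round(latents[s]), 0, 6).astype(int) for s in names}

    # healthy-sample screening: redraw sub-scale noise for subjects below
    # the observed floors of the normative sample
    def below_floor():
        tot = subs["FAB1"] + subs["FAB2"] + subs["FAB3"]
        return ((tot < config.fab_total_floor)
                | (subs["FAB1"] < config.fab1_floor)
                | (subs["FAB3"] < config.fab3_floor))

    bad = below_floor()
    for _ in range(100):
        if not bad.any():
            break
        idx = np.where(bad)[0]
        for s in names:
            m = config.scale_models[s]
            lat = latent_scores(m, ages[idx], edus[idx], g[idx], rng)
            latents[s][idx] = lat
            subs[s][idx] = np.clip(np.round(lat), 0, 6).astype(int)
        bad = below_floor()

    fab_latent = sum(latents[s] for s in names)
    total = subs["FAB1"] + subs["FAB2"] + subs["FAB3"]

    # MoCA total: mixture of standardized FAB latent and independent noise.
    # The mixing weight maps the target Spearman coupling through the
    # normal rank-correlation identity, inflated by a fixed calibration
    # factor (0.85) for the attenuation from rounding and clipping.
    flz = (fab_latent - fab_latent.mean()) / fab_latent.std()
    w = min(1.0, 2.0 * math.sin(math.pi * config.moca_coupling / 6.0) / 0.85)
    eps = rng.standard_normal(n)
    moca_lat = config.moca_mean + config.moca_sd * (w * flz + math.sqrt(1 - w * w) * eps)
    lo, hi = config.moca_range
    for _ in range(100):
        mask = moca_lat < lo
        if not mask.any():
            break
        eps[mask] = rng.standard_normal(int(mask.sum()))
        moca_lat[mask] = (config.moca_mean
                          + config.moca_sd * (w * flz[mask]
                                              + math.sqrt(1 - w * w) * eps[mask]))
    moca_total = np.clip(np.round(moca_lat), 0, 30).astype(int)

    # sub-domain scores: proportional allocation plus small jitter; the
    # executive sub-domain borrows part of the shared factor so its
    # coupling with FAB is the strongest, as in real data
    moca_sub = {}
    for key in MOCA_SUB_KEYS:
        dm = config.moca_domain_max[key]
        jitter = rng.normal(0.0, 0.4, n)
        if key == "EF":
            jitter = jitter + 0.35 * g
        raw = dm * moca_total / 30.0 + jitter
        moca_sub[key] = np.clip(np.round(raw), 0, dm).astype(int)

    items = np.empty((n, 6), dtype=int)
    for j, s in enumerate(names):
        hi_lo = np.array([_split_items(int(v)) for v in subs[s]])
        items[:, 2 * j] = hi_lo[:, 0]
        items[:, 2 * j + 1] = hi_lo[:, 1]

    width = len(str(n))
    df = pd.DataFrame({
        "id": [f"S{i + 1:0{width}d}" for i in range(n)],
        "sex": sex, "age": ages, "education": edus,
        **{f"fab{k + 1}": items[:, k] for k in range(6)},
        "moca_total": pd.array(moca_total, dtype="Int64"),
        **{f"moca_{k.lower()}": pd.array(moca_sub[k], dtype="Int64")
           for k in MOCA_SUB_KEYS},
        # generator internals (not written by write_cohort)
        **{f"{s.lower()}_latent": latents[s] for s in names},
        "fab_latent": fab_latent,
    })
    del total
    return Cohort(df, provenance=f"generated:seed={config.seed},n={n}")


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
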