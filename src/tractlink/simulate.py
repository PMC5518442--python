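"""Synthetic preterm cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so that
every downstream stage is testable without any real data:

* **Demographics.** Gestational age (GA) at birth is drawn from a scaled
  Beta(4, 2) on ``ga_range`` (median ≈ 30 weeks with a left tail, matching
  a preterm cohort). Postmenstrual age (PMA) at scan is centered on
  ``pma_median`` and jointly distributed with GA so that postnatal age
  (PMA − GA) has the target correlations with PMA and GA
  (``r_postnatal_pma``, ``r_postnatal_ga``); the implied PMA scale and
  PMA–GA correlation are solved in closed form from those two targets.
* **Tract FA.** Each tract's left/right FA pair is
  ``base + beta_pma·(PMA − pma_median) [+ beta_ga·(GA − ga_center)]
  [+ z_loading·z] + noise`` where ``z`` is a standard-normal subject latent
  loading (symmetrically) on the arcuate only, and the left/right noise
  correlation is solved analytically so the *raw* within-pair correlation
  hits ``rho_lr``. Because the developmental (PMA) component is strongly
  shared between hemispheres, hitting a raw correlation as low as 0.58
  requires negatively correlated residual noise; infeasible targets raise
  a configuration error instead of being silently missed.
* **Outcomes.** Language and cognition are affine in a shared outcome
  latent that mixes ``z`` (with weight ``effect``, the population
  correlation between the planted brain latent and the outcome latent)
  and independent variation; language loads ``lang_loading`` and cognition
  ``rho_langcog / lang_loading`` on the shared latent, so their mutual
  correlation equals ``rho_langcog`` while language — the primary outcome
  — tracks the latent most closely. Language additionally carries the
  standardized socioeconomic term ``beta_ses`` plus independent noise.

``effect`` is the single dial for the planted brain-behavior association;
``null_variant`` returns a copy with ``effect = 0`` (confound structure
intact), the global-null used for calibration testing.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import validate_cohort
from .errors import ConfigError

__all__ = ["SyntheticConfig", "generate_cohort", "null_variant"]

_TRACTS = ("arcuate", "cst", "slf")


def _default_fa_base() -> dict[str, float]:
    # neonatal-range median FA levels per tract (free parameters; no
    # per-tract means are printed for the cohort this emulates)
    return {"arcuate": 0.24, "cst": 0.32, "slf": 0.22}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters. Defaults are the emulated study conditions."""

    n: int = 43
    seed: int = 0

    # demographics
    ga_range: tuple[float, float] = (24.0, 33.0)
    ga_beta: tuple[float, float] = (4.0, 2.0)  # shape → median ≈ 30 wk on default range
    pma_range: tuple[float, float] = (39.0, 46.0)
    pma_median: float = 42.0
    r_postnatal_pma: float = 0.79
    r_postnatal_ga: float = -0.90
    p_female: float = 0.42
    ses_mean: float = 17.4293
    ses_sd: float = 8.0772
    wm_mean: float = 170_000.0  # mm³
    wm_sd: float = 15_000.0
    wm_beta_pma: float = 3_000.0  # mm³ per week of PMA

    # tract FA model
    fa_base: Mapping[str, float] = field(default_factory=_default_fa_base)
    beta_pma: float = 0.028  # FA maturation slope per week of PMA (all tracts)
    beta_ga: float = 0.004  # prematurity-dose slope per week of GA (arcuate only)
    z_loading: float = 0.030  # arcuate FA loading of the subject latent z
    noise_sd: float = 0.0223  # per-hemisphere residual FA noise
    rho_lr: float = 0.58  # target raw left-right FA correlation (all pairs)

    # outcomes
    lang_mean: float = 90.0
    lang_sd: float = 16.20
    cog_mean: float = 92.0
    cog_sd: float = 11.85
    rho_langcog: float = 0.79
    lang_loading: float = 0.93  # language loading on the shared outcome latent
    beta_ses: float = -0.28  # standardized SES loading on language (≈ marginal corr)

    # planted brain-behavior association: corr(z, outcome latent)
    effect: float = 0.55

    fa_clip: tuple[float, float] = (0.01, 0.99)

    # ---- derived population quantities -------------------------------------
    @property
    def ga_mean(self) -> float:
        a, b = self.ga_beta
        lo, hi = self.ga_range
        return lo + (hi - lo) * a / (a + b)

    @property
    def ga_sd(self) -> float:
        a, b = self.ga_beta
        lo, hi = self.ga_range
        return (hi - lo) * math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))

    def _pma_joint(self) -> tuple[float, float]:
        """(sigma_pma, rho_pma_ga) solved from the postnatal-age correlation targets.

        With D = PMA − GA, requiring corr(D, PMA) = a and corr(D, GA) = −b
        gives k = σ_PMA/σ_GA = sqrt((1 − b²)/(1 − a²)) and
        ρ = k(1 − a²) − ab.
        """
        a = self.r_postnatal_pma
        b = -self.r_postnatal_ga
        if not (0 < a < 1 and 0 < b < 1):
            raise ConfigError("postnatal-age correlation targets must be in (0,1)/(−1,0)")
        k = math.sqrt((1 - b * b) / (1 - a * a))
        rho = k * (1 - a * a) - a * b
        return k * self.ga_sd, rho

    def _shared_fa_var(self, tract: str) -> float:
        """Population variance of the hemisphere-shared FA component."""
        sigma_pma, rho_pg = self._pma_joint()
        v = (self.beta_pma * sigma_pma) ** 2
        if tract == "arcuate":
            v += (self.beta_ga * self.ga_sd) ** 2
            v += 2 * self.beta_pma * self.beta_ga * rho_pg * sigma_pma * self.ga_sd
            v += self.z_loading**2
        return v

    def _noise_corr(self, tract: str) -> float:
        """L/R residual-noise correlation achieving the raw rho_lr target."""
        shared = self._shared_fa_var(tract)
        total = shared + self.noise_sd**2
        rho_n = (self.rho_lr * total - shared) / self.noise_sd**2
        if not -1.0 <= rho_n <= 1.0:
            raise ConfigError(
                f"rho_lr={self.rho_lr} infeasible for tract '{tract}': would need "
                f"noise correlation {rho_n:.3f}; adjust noise_sd or slopes"
            )
        return rho_n

    # ---- validation ---------------------------------------------------------
    def validate(self) -> "SyntheticConfig":
        if self.n < 1:
            raise ConfigError("n must be ≥ 1")
        if not 0.0 <= self.effect < 1.0:
            raise ConfigError("effect must lie in [0, 1)")
        for name in ("ses_sd", "lang_sd", "cog_sd", "noise_sd", "wm_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("ga_range", "pma_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ConfigError(f"{name} must be a non-degenerate (lo, hi) range")
        if set(self.fa_base) != set(_TRACTS):
            raise ConfigError(f"fa_base must have keys {_TRACTS}")
        if not 0 < self.rho_langcog < 1:
            raise ConfigError("rho_langcog must lie in (0, 1)")
        a = self.lang_loading
        if not 0 < a < 1 or not 0 < self.rho_langcog / a < 1:
            raise ConfigError(
                "lang_loading and rho_langcog/lang_loading must both lie in (0, 1)"
            )
        if a * a + self.beta_ses**2 >= 1.0:
            raise ConfigError("lang_loading and beta_ses jointly exceed unit variance")
        self._pma_joint()
        for tract in _TRACTS:
            self._noise_corr(tract)
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fa_base"] = dict(self.fa_base)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        for key in ("ga_range", "ga_beta", "pma_range", "fa_clip"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()


def null_variant(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of ``config`` with the brain-behavior coupling removed.

    Only ``effect`` is zeroed: with corr(z, outcome latent) = 0 the tracts
    and the outcomes are fully decoupled while every confound relationship
    (PMA maturation, prematurity dose, SES, left/right correlation) is
    retained — the global null used for calibration.
    """
    return dataclasses.replace(config, effect=0.0)


def generate_cohort(
    config: SyntheticConfig, return_latents: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Draw one cohort table; deterministic given ``config.seed``.

    With ``return_latents=True`` also returns the planted per-subject
    latents (ground truth for recovery tests): ``z`` (brain latent) and
    ``y_lat`` (outcome latent, corr(z, y_lat) = effect by construction).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    # demographics
    lo, hi = config.ga_range
    a_sh, b_sh = config.ga_beta
    ga = lo + (hi - lo) * rng.beta(a_sh, b_sh, size=n)
    sigma_pma, rho_pg = config._pma_joint()
    gz = (ga - config.ga_mean) / config.ga_sd
    eps = rng.standard_normal(n)
    pma = config.pma_median + sigma_pma * (rho_pg * gz + math.sqrt(1 - rho_pg**2) * eps)
    pma = np.clip(pma, config.pma_range[0], config.pma_range[1])
    pma = np.maximum(pma, ga + 0.1)  # scans follow birth even under odd configs

    sex = rng.binomial(1, config.p_female, size=n)
    ses = config.ses_mean + config.ses_sd * rng.standard_normal(n)
    wm = (
        config.wm_mean
        + config.wm_beta_pma * (pma - config.pma_median)
        + config.wm_sd * rng.standard_normal(n)
    )

    # subject latents
    z = rng.standard_normal(n)
    eta = rng.standard_normal(n)
    y_lat = config.effect * z + math.sqrt(1 - config.effect**2) * eta

    # tract FA
    cols: dict[str, np.ndarray] = {}
    n_clipped = 0
    for tract in _TRACTS:
        shared = config.fa_base[tract] + config.beta_pma * (pma - config.pma_median)
        if tract == "arcuate":
            shared = shared + config.beta_ga * (ga - config.ga_mean)
            shared = shared + config.z_loading * z
        rho_n = config._noise_corr(tract)
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        noise_l = config.noise_sd * e1
        noise_r = config.noise_sd * (rho_n * e1 + math.sqrt(1 - rho_n**2) * e2)
        for side, noise in (("L", noise_l), ("R", noise_r)):
            fa = shared + noise
            clipped = np.clip(fa, *config.fa_clip)
            n_clipped += int((clipped != fa).sum())
            cols[f"fa_{tract}_{side}"] = clipped
    if n_clipped:
        import logging

        logging.getLogger(__name__).info(
            "generate_cohort: clipped %d FA value(s) into %s", n_clipped, config.fa_clip
        )

    # outcomes: loadings a (language) and rho_langcog/a (cognition) on the
    # shared latent give corr(lang, cog) = rho_langcog; language additionally
    # carries the standardized SES term and its own independent noise
    a = config.lang_loading
    b = config.rho_langcog / a
    s = config.beta_ses
    ses_z = (ses - config.ses_mean) / config.ses_sd
    e_lang = rng.standard_normal(n)
    e_cog = rng.standard_normal(n)
    lang_std = a * y_lat + s * ses_z + math.sqrt(1 - a * a - s * s) * e_lang
    cog_std = b * y_lat + math.sqrt(1 - b * b) * e_cog
    lang = config.lang_mean + config.lang_sd * lang_std
    cog = config.cog_mean + config.cog_sd * cog_std

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "ga_birth": ga,
            "pma_scan": pma,
            "sex": sex,
            "ses": ses,
            "wm_volume": wm,
            **cols,
            "lang": lang,
            "cog": cog,
        }
    )
    table = validate_cohort(table)
    if return_latents:
        return table, {"z": z, "y_lat": y_lat}
    return table


def write_latents(latents: dict[str, np.ndarray], path: str | Path) -> None:
    """Sidecar JSON with the planted per-subject latents."""
    Path(path).write_text(
        json.dumps({k: np.asarray(v).tolist() for k, v in latents.items()}, indent=2)
    )
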