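"""Configuration-driven pipeline driver and report writer.

``run_pipeline`` chains the stages — cohort (read or simulate), confound
residualization, developmental GLM grid, cross-validated link tests for
each regression method and tract set, PLS loading-stability table, partial
correlation and independent-contribution sensitivity analyses, asymmetry
analysis — and renders the results as TSV/JSON tables plus a run log that
records every seed, family definition and permutation scheme used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort as cohort_io, crossval, inference, preprocess, simulate
from .cohort import TRACT_SETS
from .errors import ConfigError

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_pipeline"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a pipeline run depends on."""

    input_path: str | None = None  # None → simulate
    synthetic: simulate.SyntheticConfig = field(
        default_factory=simulate.SyntheticConfig
    )
    methods: tuple[str, ...] = ("ols", "ridge", "pls")
    tracts: tuple[str, ...] = ("arcuate", "cst", "slf")
    include_cognition: bool = False
    b_perms: int = 10_000
    seed: int = 0
    residualize_within_fold: bool = False
    sided: str = "greater"  # link tests; GLM contrasts are two-sided
    ridge_lambda: float = 1.0
    corr_method: str = "pearson"
    out_dir: str = "tractlink_out"

    def validate(self) -> "AnalysisConfig":
        if self.b_perms < 99:
            raise ConfigError("b_perms must be ≥ 99")
        bad = set(self.methods) - {"ols", "ridge", "pls"}
        if bad:
            raise ConfigError(f"unknown method(s): {sorted(bad)}")
        bad = set(self.tracts) - set(TRACT_SETS)
        if bad:
            raise ConfigError(f"unknown tract set(s): {sorted(bad)}")
        if self.sided not in ("greater", "less", "two"):
            raise ConfigError("sided must be greater/less/two")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = simulate.SyntheticConfig.from_dict(d["synthetic"])
        for key in ("methods", "tracts"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        return cls.from_dict(data)


def _child_seeds(seed: int, k: int) -> list[int]:
    """Deterministic per-stage seeds derived from the master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=k)]


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dictionary of in-memory results keyed by stage; the same
    content is written under ``config.out_dir`` as TSV/JSON tables.
    """
    config = config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seeds = dict(
        zip(
            ("glm", "link", "partial", "contrib", "asym"),
            _child_seeds(config.seed, 5),
        )
    )
    B = config.b_perms

    # ---- cohort -----------------------------------------------------------
    if config.input_path is not None:
        logger.info("reading cohort from %s", config.input_path)
        cohort = cohort_io.read_cohort(config.input_path)
    else:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        logger.info("simulating cohort (n=%d, seed=%d)", syn.n, syn.seed)
        cohort = simulate.generate_cohort(syn)
    cohort_io.write_cohort(cohort, out / "cohort.tsv")

    y_cols = ("lang", "cog") if config.include_cognition else ("lang",)
    results: dict = {"cohort": cohort, "y_cols": y_cols}

    # ---- developmental GLM grid ------------------------------------------
    logger.info("developmental GLM grid (B=%d)", B)
    glm_grid = inference.prematurity_glm_grid(cohort, B=B, seed=seeds["glm"])
    rows = []
    for contrast, tests in glm_grid.items():
        for outcome, t in tests.items():
            rows.append(
                {
                    "contrast": contrast,
                    "outcome": outcome,
                    "t": t.t_statistic,
                    "p_uncorrected": t.perm.p_uncorrected,
                    "p_fwe": t.perm.p_fwe,
                }
            )
    glm_table = pd.DataFrame(rows)
    glm_table.to_csv(out / "table_developmental_glm.tsv", sep="\t", index=False)
    results["developmental_glm"] = glm_grid

    # ---- method × tract-set link comparison -------------------------------
    link_tests: dict[str, dict[str, inference.PermutationTest]] = {}
    link_cv: dict[str, dict[str, crossval.CvLinkResult]] = {}
    rows = []
    tract_sets = {t: TRACT_SETS[t] for t in config.tracts}
    for method in config.methods:
        logger.info("link tests, method=%s (B=%d)", method, B)
        fam = inference.tract_link_family(
            cohort,
            y_cols,
            method,
            tract_sets=tract_sets,
            B=B,
            seed=seeds["link"],
            sided=config.sided,
            ridge_lambda=config.ridge_lambda,
            corr_method=config.corr_method,
            residualize_within_fold=config.residualize_within_fold,
        )
        link_tests[method] = fam
        link_cv[method] = {}
        for tract, test in fam.items():
            cv = crossval.loocv_link(
                cohort,
                TRACT_SETS[tract],
                y_cols,
                method,
                residualize_within_fold=config.residualize_within_fold,
                ridge_lambda=config.ridge_lambda,
                corr_method=config.corr_method,
            )
            link_cv[method][tract] = cv
            rows.append(
                {
                    "method": method,
                    "tract_set": tract,
                    "r_cv": test.observed,
                    "p_uncorrected": test.p_uncorrected,
                    "p_fwe": test.p_fwe,
                }
            )
    pd.DataFrame(rows).to_csv(
        out / "table_method_comparison.tsv", sep="\t", index=False
    )
    results["link_tests"] = link_tests
    results["link_cv"] = link_cv

    # ---- PLS loading stability (arcuate) ----------------------------------
    if "pls" in config.methods and "arcuate" in config.tracts:
        cv = link_cv["pls"]["arcuate"]
        rows = []
        for name, mean, sd in zip(
            cv.x_cols, cv.loadings_x_mean, cv.loadings_x_sd
        ):
            rows.append({"space": "X", "variable": name, "mean": mean, "sd": sd})
        for name, mean, sd in zip(
            cv.y_cols, cv.loadings_y_mean, cv.loadings_y_sd
        ):
            rows.append({"space": "Y", "variable": name, "mean": mean, "sd": sd})
        pd.DataFrame(rows).to_csv(
            out / "table_pls_loadings.tsv", sep="\t", index=False
        )
        results["pls_loadings"] = rows
        results["varexp"] = {
            "x": cv.varexp_x_mean,
            "y": cv.varexp_y_mean,
        }

        # ---- partial-correlation sensitivity -----------------------------
        covs = cohort[["ga_birth", "wm_volume", "sex"]].to_numpy(dtype=float)
        partial = inference.partial_corr_perm(
            cv.x_scores,
            cv.y_scores,
            covs,
            B=B,
            seed=seeds["partial"],
            sided=config.sided,
        )
        pd.DataFrame(
            [
                {
                    "r_partial": partial.observed,
                    "p_uncorrected": partial.p_uncorrected,
                    "covariates": "ga_birth,wm_volume,sex",
                }
            ]
        ).to_csv(out / "table_partial_correlation.tsv", sep="\t", index=False)
        results["partial_corr"] = partial

        # ---- independent contributions ------------------------------------
        contrib = inference.independent_contribution_glm(
            cohort, cv.x_scores, B=B, seed=seeds["contrib"]
        )
        pd.DataFrame(
            [
                {
                    "predictor": name,
                    "t": t.t_statistic,
                    "p_uncorrected": t.perm.p_uncorrected,
                    "p_fwe": t.perm.p_fwe,
                }
                for name, t in contrib.items()
            ]
        ).to_csv(out / "table_independent_contributions.tsv", sep="\t", index=False)
        results["independent_contributions"] = contrib

    # ---- asymmetry ---------------------------------------------------------
    ai = inference.asymmetry_index(
        cohort["fa_arcuate_L"].to_numpy(), cohort["fa_arcuate_R"].to_numpy()
    )
    z_val, p_wilcoxon = inference.paired_signed_rank(
        cohort["fa_arcuate_L"].to_numpy(), cohort["fa_arcuate_R"].to_numpy()
    )
    lang = cohort["lang"].to_numpy(dtype=float)
    ses = cohort[["ses"]].to_numpy(dtype=float)
    r = preprocess.fit_residualizer(lang, ses, ("ses",))
    lang_r = preprocess.apply_residualizer(r, lang, ses)
    D = np.column_stack([np.ones(len(cohort)), ai])
    perms = inference.make_permutations(len(cohort), B, seeds["asym"])
    asym_tests = {}
    for label, sided in (("positive", "greater"), ("negative", "less")):
        asym_tests[label] = inference.glm_contrast_perm(
            lang_r,
            D,
            (0.0, 1.0),
            design_cols=("intercept", "asymmetry_index"),
            outcome_name="lang",
            B=B,
            seed=seeds["asym"],
            sided=sided,
            perm_indices=perms,
            family_id="glm:asymmetry",
        )
    asym_payload = {
        "mean_asymmetry_index": float(np.mean(ai)),
        "wilcoxon_z": z_val,
        "wilcoxon_p": p_wilcoxon,
        "glm_positive_p": asym_tests["positive"].perm.p_uncorrected,
        "glm_negative_p": asym_tests["negative"].perm.p_uncorrected,
    }
    (out / "asymmetry.json").write_text(json.dumps(asym_payload, indent=2))
    results["asymmetry"] = asym_payload

    # ---- run log -----------------------------------------------------------
    run_log = {
        "tractlink_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "permutation_scheme": {
            "cv_link": "outcome rows permuted after confound residualization; "
            "FA block fixed; full LOOCV per permutation",
            "glm": "Freedman-Lane (reduced-model residuals permuted)",
            "fwe": "single-step max-statistic over seed-aligned families",
        },
        "families": {
            "link": f"tract sets {list(config.tracts)} within each method",
            "developmental_glm": "six FA outcomes within each contrast",
            "independent_contributions": "four predictors, one outcome",
        },
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    results["run_log"] = run_log
    logger.info("report bundle written to %s", out)
    return results


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write a config as YAML (or JSON if the extension says so)."""
    path = Path(path)
    d = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
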