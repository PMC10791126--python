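"""End-to-end orchestration: simulate, fit, test, and report.

A :class:`RunConfig` (usually read from YAML) selects stages and
parameters; :func:`run_pipeline` executes them in dependency order,
writes every table as TSV into the output directory and records a JSON
manifest with content hashes, the seeds used and package versions, so a
rerun with the same configuration is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from empabayes import (
    __version__,
    bayes_factors,
    censored_model,
    design_analysis,
    reliability,
    synthetic_data,
)

log = logging.getLogger("empabayes.pipeline")


@dataclass
class RunConfig:
    """Pipeline configuration; every number is explicit, nothing hidden.

    ``stages`` may include ``simulate``, ``fit_ratings``, ``bf``,
    ``reliability``, ``power``, ``bfda``.
    """

    out_dir: str = "empabayes_run"
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate", "fit_ratings", "bf", "reliability", "power", "bfda"
    )
    # simulate / fit
    n_control: int = 44
    n_experimental: int = 45
    ratings_per_cell: int = 8
    fixed_effects: Mapping[str, float] | None = None
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    priors: Mapping[str, float] | None = None
    # power grid
    power_d: tuple[float, ...] = (0.3, 0.345, 0.396, 0.445)
    power_N: int = 90
    power_rho: float = 0.5
    power_alpha: float = 0.05
    # bfda grid
    bfda_reps: int = 10_000
    bfda_effect_sizes: tuple[float, ...] = design_analysis.TABLE_EFFECT_SIZES
    bfda_scenarios: Mapping[str, float | None] | None = None
    # BF stage: posterior-density estimation guard and thresholds
    bf_min_draws: int = 4000
    h1_threshold: float = bayes_factors.H1_THRESHOLD
    h0_threshold: float = bayes_factors.H0_THRESHOLD
    cauchy_scale: float = bayes_factors.DEFAULT_CAUCHY_SCALE

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "power_d", "bfda_effect_sizes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {},
    }
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("simulate", "fit_ratings", "bf", "reliability", "power", "bfda"), seeds
        )
    }
    manifest["stage_seeds"] = stage_seed

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path), "sha256": _sha256(path)
        }

    data = None
    draws = None
    current = None
    try:
        current = "simulate"
        if "simulate" in config.stages:
            cfg = synthetic_data.StudyConfig(
                n_control=config.n_control,
                n_experimental=config.n_experimental,
                ratings_per_cell=config.ratings_per_cell,
                fixed_effects=(
                    dict(config.fixed_effects)
                    if config.fixed_effects is not None
                    else synthetic_data._default_empathy_effects()
                ),
                seed=stage_seed["simulate"],
            )
            data = synthetic_data.generate_empathy_ratings(cfg)
            p = out / "ratings.tsv"
            synthetic_data.write_table(data, p)
            record("ratings", p)
            log.info("simulated %d rating rows", len(data))

        current = "fit_ratings"
        if "fit_ratings" in config.stages:
            if data is None:
                data = synthetic_data.read_table(out / "ratings.tsv")
            priors = censored_model.PriorSpec(**(config.priors or {}))
            spec = censored_model.empathy_model_spec(priors)
            draws = censored_model.fit_posterior(
                data, spec,
                n_chains=config.n_chains,
                n_warmup=config.n_warmup,
                n_draws=config.n_draws,
                seed=stage_seed["fit_ratings"],
                check_rhat=config.n_draws >= 500,
            )
            log.info("sampler diagnostics: %s", draws.diagnostics)
            summ = censored_model.summaries_to_frame(
                censored_model.summarize_fixed(draws)
            )
            p = out / "fixed_effects.tsv"
            synthetic_data.write_table(summ, p)
            record("fixed_effects", p)
            p = out / "draws.tsv"
            synthetic_data.write_table(draws.to_frame(), p)
            record("draws", p)

        current = "bf"
        if "bf" in config.stages and draws is not None:
            rows = []
            for term in draws.fixed_terms:
                if term == "intercept":
                    continue
                prior0 = draws.priors.beta_prior_density_at_zero(term)
                res = bayes_factors.savage_dickey_bf(
                    draws.term_draws(term), prior0,
                    min_draws=config.bf_min_draws,
                )
                rows.append({
                    "term": term, "bf10": res.bf10,
                    "category": res.category, "method": res.method,
                })
            res = bayes_factors.sign_restricted_bf(
                draws.term_draws("group:session:intensity"),
                draws.priors.beta_prior_density_at_zero("group:session:intensity"),
                direction="negative",
                min_draws=config.bf_min_draws,
            )
            rows.append({
                "term": "group:session:intensity (one-sided)", "bf10": res.bf10,
                "category": res.category, "method": res.method,
            })
            p = out / "bayes_factors.tsv"
            synthetic_data.write_table(pd.DataFrame(rows), p)
            record("bayes_factors", p)

        current = "reliability"
        if "reliability" in config.stages and draws is not None:
            rel = reliability.behavioral_reliability_posterior(draws)
            p = out / "reliability.tsv"
            synthetic_data.write_table(
                pd.DataFrame([{
                    "measure": "ratings", "rho_mean": rel.rho_mean,
                    "ci_low": rel.ci_low, "ci_high": rel.ci_high,
                }]),
                p,
            )
            record("reliability", p)

        current = "power"
        if "power" in config.stages:
            rows = [
                {
                    "d": d,
                    "N": config.power_N,
                    "rho": config.power_rho,
                    "power": design_analysis.interaction_power(
                        design_analysis.PowerSpec(
                            d=d, N=config.power_N, rho=config.power_rho,
                            alpha=config.power_alpha,
                        )
                    ),
                }
                for d in config.power_d
            ]
            p = out / "power.tsv"
            synthetic_data.write_table(pd.DataFrame(rows), p)
            record("power", p)

        current = "bfda"
        if "bfda" in config.stages:
            grid = design_analysis.bfda_grid(
                n_reps=config.bfda_reps,
                seed=stage_seed["bfda"],
                scenarios=(
                    dict(config.bfda_scenarios)
                    if config.bfda_scenarios is not None
                    else None
                ),
                effect_sizes=config.bfda_effect_sizes,
                n1=config.n_control,
                n2=config.n_experimental,
            )
            p = out / "bfda.tsv"
            synthetic_data.write_table(grid, p)
            record("bfda", p)
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    record_path = out / "manifest.json"
    log.info("wrote manifest %s", record_path)
    return manifest
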