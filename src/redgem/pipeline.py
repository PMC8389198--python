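"""End-to-end workflow: constrain → optimise → explore → compare → validate.

For each cultivation scenario the pipeline applies the measured constraints,
runs two-step FBA, FVA and CHRR sampling; across scenarios it compares flux
distributions (Kruskal–Wallis), assembles the shadow-price matrix, runs PCA
and the |Δ| ranking, and emits SE/MSE validation reports.  All outputs plus
a manifest (seed, package version, config hash) land in one directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io import load_model
from .model import MetabolicModel
from .optimize import (
    Scenario,
    apply_scenario,
    fva,
    read_scenario_csv,
    two_step_fba,
    write_solution_tsv,
)
from .sampling import FluxSample, SamplerConfig, chrr_sample, compare_flux_distributions
from .shadow import ShadowPriceMatrix, shadow_price_pca, top_changing_metabolites
from .validation import read_experimental_csv, validate_scenario

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records which."""


@dataclass
class ScenarioInput:
    """One cultivation state: constraints plus optional measurements."""

    scenario: Scenario | str
    experimental: pd.DataFrame | str | None = None

    def resolve(self) -> tuple[Scenario, pd.DataFrame | None]:
        sc = (
            read_scenario_csv(self.scenario)
            if isinstance(self.scenario, (str, Path))
            else self.scenario
        )
        exp = self.experimental
        if isinstance(exp, (str, Path)):
            exp = read_experimental_csv(exp)
        return sc, exp


@dataclass
class PipelineConfig:
    model: MetabolicModel | str
    scenarios: dict[str, ScenarioInput]
    objective_id: str = ""
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    fva_fraction: float | None = 1.0
    out_dir: str | Path = "redgem_out"
    seed: int = 0
    alpha: float = 0.001
    top_k: int = 70

    def digest(self) -> str:
        payload = {
            "model": str(self.model) if isinstance(self.model, (str, Path))
            else getattr(self.model, "id", "in-memory"),
            "scenarios": sorted(self.scenarios),
            "objective_id": self.objective_id,
            "sampler": [self.sampler.n_points, self.sampler.steps_per_point,
                        self.sampler.warmup_points],
            "fva_fraction": self.fva_fraction,
            "seed": self.seed,
            "alpha": self.alpha,
            "top_k": self.top_k,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the output bundle.

    Outputs written: ``fluxes_<name>.tsv``, ``fva_<name>.tsv``,
    ``samples/<name>.tsv``, ``kw.tsv``, ``shadow_matrix.tsv``,
    ``pca_scores.tsv``/``pca_loadings.tsv``, ``top_metabolites.tsv``,
    ``validation_<name>.tsv`` and ``manifest.json``.  On a stage failure
    the manifest records the stage and error; outputs produced before the
    failure are retained.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "samples").mkdir(exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    logging.getLogger("redgem").addHandler(handler)

    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "config_hash": config.digest(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    bundle: dict = {"manifest": manifest}

    def _fail(stage: str, exc: Exception):
        manifest["stages"][stage] = f"error: {exc}"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logging.getLogger("redgem").removeHandler(handler)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    try:
        model = (
            load_model(config.model)
            if isinstance(config.model, (str, Path))
            else config.model
        )
        model.validate()
        manifest["stages"]["load"] = "ok"
    except Exception as exc:  # noqa: BLE001 - manifest must record any failure
        _fail("load", exc)

    solutions: dict = {}
    samples: dict[str, FluxSample] = {}
    validations: dict = {}
    for i, (name, item) in enumerate(config.scenarios.items()):
        stage = f"scenario:{name}"
        try:
            scenario, experimental = item.resolve()
            constrained = apply_scenario(model, scenario)
            objective = (
                config.objective_id
                or scenario.objective_id
                or constrained.objective_id
            )
            sol = two_step_fba(constrained, objective)
            solutions[name] = sol
            write_solution_tsv(sol, out_dir / f"fluxes_{name}.tsv")

            ranges = fva(constrained, config.fva_fraction, objective_id=objective)
            pd.DataFrame(
                [(fr.reaction_id, fr.minimum, fr.maximum) for fr in ranges],
                columns=["reaction", "min", "max"],
            ).to_csv(out_dir / f"fva_{name}.tsv", sep="\t", index=False)

            cfg_i = SamplerConfig(
                n_points=config.sampler.n_points,
                steps_per_point=config.sampler.steps_per_point,
                seed=(config.seed * 1000 + i) % (2**31 - 1),
                warmup_points=config.sampler.warmup_points,
            )
            sample = chrr_sample(constrained, cfg_i)
            samples[name] = sample
            sample.to_frame().to_csv(
                out_dir / "samples" / f"{name}.tsv", sep="\t", index=False
            )

            if experimental is not None:
                report = validate_scenario(model, scenario, experimental,
                                           objective_id=objective)
                validations[name] = report
                report.to_tsv(out_dir / f"validation_{name}.tsv")
            manifest["stages"][stage] = "ok"
        except Exception as exc:  # noqa: BLE001
            _fail(stage, exc)

    bundle.update(solutions=solutions, samples=samples, validations=validations)

    names = list(config.scenarios)
    if len(names) >= 2:
        try:
            kw = compare_flux_distributions(
                samples[names[0]], samples[names[1]], alpha=config.alpha
            )
            kw.to_csv(out_dir / "kw.tsv", sep="\t", index=False)
            bundle["kruskal_wallis"] = kw
            manifest["stages"]["kruskal_wallis"] = "ok"
        except Exception as exc:  # noqa: BLE001
            _fail("kruskal_wallis", exc)

        try:
            matrix = ShadowPriceMatrix.from_solutions(
                {n: solutions[n] for n in names[:2]}
            )
            matrix.to_tsv(out_dir / "shadow_matrix.tsv")
            pca = shadow_price_pca(matrix)
            pca.scores.rename_axis("metabolite").to_csv(
                out_dir / "pca_scores.tsv", sep="\t"
            )
            pca.loadings.rename_axis("condition").to_csv(
                out_dir / "pca_loadings.tsv", sep="\t"
            )
            top = top_changing_metabolites(matrix, config.top_k)
            top.to_csv(out_dir / "top_metabolites.tsv", sep="\t", index=False)
            bundle.update(shadow_matrix=matrix, pca=pca, top_metabolites=top)
            manifest["stages"]["shadow_analysis"] = "ok"
        except ValueError as exc:
            # zero-variance duals (identical conditions) are a legitimate
            # outcome: record and continue with the |Δ| ranking only
            manifest["stages"]["shadow_analysis"] = f"skipped: {exc}"
            matrix = ShadowPriceMatrix.from_solutions(
                {n: solutions[n] for n in names[:2]}
            )
            bundle["shadow_matrix"] = matrix
            bundle["top_metabolites"] = top_changing_metabolites(
                matrix, config.top_k
            )
        except Exception as exc:  # noqa: BLE001
            _fail("shadow_analysis", exc)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logging.getLogger("redgem").removeHandler(handler)
    return bundle
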