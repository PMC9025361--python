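"""File formats, run configuration and the end-to-end pipeline.

Datasets travel as tidy CSV with header ``batch_id, lactate_pct, atmosphere,
day, pH``.  Traces are written as long-format CSV (chain, iteration,
parameter, value — the stored per-draw deviance included) next to a JSON
run manifest holding the variant, prior specification, sampler
configuration, seed and acceptance rates, which is enough to reload the
trace losslessly.

:func:`run_pipeline` orchestrates the whole workflow from a single
:class:`RunConfig` (YAML-friendly mapping): optionally generate synthetic
data, fit the selected variants, run convergence diagnostics, compare by
DIC, summarise the winner, compute residuals and simulate requested
kinetics bands.  Every stochastic stage derives its stream from the one
global seed, so rerunning a config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import assess_convergence
from .mcmc import MCMCConfig, Trace, run_mcmc
from .model import (
    Atmosphere,
    Condition,
    ModelVariant,
    ParameterState,
    PriorSpec,
    VARIANT_NAMES,
    model_variant,
    reference_estimates,
)
from .selection import compute_dic, goodness_of_fit, select_model, summarize_posterior
from .simulate import simulate_kinetics
from .synth import DATASET_COLUMNS, Dataset, StudyDesign, generate_dataset

logger = logging.getLogger("phkinetics")

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_truth_sidecar",
    "write_trace",
    "read_trace",
    "RunConfig",
    "run_pipeline",
    "DatasetFormatError",
]


class DatasetFormatError(ValueError):
    """Raised for malformed dataset files, listing the offending rows."""


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a tidy pH-monitoring CSV.

    Expects the header ``batch_id, lactate_pct, atmosphere, day, pH``.
    Atmosphere tokens are matched case-insensitively against Air/MAP1/MAP2.
    All invalid rows (unknown atmosphere, negative day or lactate, missing
    or non-numeric pH) are reported together with their file line numbers.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing required columns {missing}")

    problems: list[str] = []

    def lineno(i: int) -> int:
        return i + 2  # header is line 1

    atmospheres: list[str] = []
    for i, tok in enumerate(frame["atmosphere"]):
        try:
            atmospheres.append(Atmosphere.parse(tok).value)
        except ValueError:
            problems.append(f"line {lineno(i)}: unknown atmosphere {tok!r}")
            atmospheres.append(Atmosphere.AIR.value)  # placeholder; error raised below

    for col in ("lactate_pct", "day", "pH"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        for i in frame.index[coerced.isna()]:
            what = "missing" if pd.isna(frame.loc[i, col]) else f"non-numeric {frame.loc[i, col]!r}"
            problems.append(f"line {lineno(i)}: {what} {col}")
        frame[col] = coerced

    for i in frame.index[frame["day"] < 0]:
        problems.append(f"line {lineno(i)}: negative day {frame.loc[i, 'day']}")
    for i in frame.index[frame["lactate_pct"] < 0]:
        problems.append(f"line {lineno(i)}: negative lactate_pct {frame.loc[i, 'lactate_pct']}")

    if problems:
        raise DatasetFormatError(
            f"{path}: {len(problems)} invalid row(s):\n  " + "\n  ".join(problems)
        )
    frame["atmosphere"] = atmospheres
    return Dataset(frame)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.frame.to_csv(path, index=False)


def write_truth_sidecar(dataset: Dataset, path: str | Path) -> None:
    """Write the generator's latent batch pH0 values to a sidecar JSON file.

    Kept separate from the dataset CSV so the fitting pipeline cannot see
    the truth it is later scored against.
    """
    if dataset.truth_pH0 is None:
        raise ValueError("dataset carries no generating truth")
    Path(path).write_text(json.dumps({"pH0_by_batch": dataset.truth_pH0}, indent=2))


# ---------------------------------------------------------------------------
# Trace round trip
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, csv_path: str | Path, manifest_path: str | Path) -> None:
    """Serialise a trace to long CSV plus a JSON manifest."""
    trace.to_dataframe().to_csv(csv_path, index=False)
    pri = trace.variant.priors
    manifest = {
        "phkinetics_version": __version__,
        "variant": {
            "name": trace.variant.name,
            "n_fixed": trace.variant.n_fixed,
            "theta_fixed": trace.variant.theta_fixed,
            "priors": dataclasses.asdict(pri),
        },
        "config": {
            "n_chains": trace.config.n_chains,
            "burn_in": trace.config.burn_in,
            "n_iterations": trace.config.n_iterations,
            "thinning": trace.config.thinning,
            "seed": trace.config.seed,
        },
        "n_obs": trace.n_obs,
        "batch_ids": list(trace.batch_ids),
        "param_names": list(trace.param_names),
        "acceptance": {k: list(v) for k, v in trace.acceptance.items()},
        "proposal_scales": trace.proposal_scales,
        "fixed_values": trace.fixed_values,
        "fixed_pH0": trace.fixed_pH0,
    }
    Path(manifest_path).write_text(json.dumps(manifest, indent=2))


def _priors_from_dict(d: Mapping) -> PriorSpec:
    kwargs = dict(d)
    for key in ("delta_bounds", "lambda_bounds", "n_bounds", "theta_bounds"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return PriorSpec(**kwargs)


def read_trace(csv_path: str | Path, manifest_path: str | Path) -> Trace:
    manifest = json.loads(Path(manifest_path).read_text())
    variant = ModelVariant(
        name=manifest["variant"]["name"],
        n_fixed=manifest["variant"]["n_fixed"],
        theta_fixed=manifest["variant"]["theta_fixed"],
        priors=_priors_from_dict(manifest["variant"]["priors"]),
    )
    config = MCMCConfig(**manifest["config"])
    long = pd.read_csv(csv_path)
    names = manifest["param_names"]
    n_chains = int(long["chain"].max()) + 1
    wide = long.pivot_table(index=["chain", "iteration"], columns="parameter",
                            values="value", sort=False)
    retained = len(wide) // n_chains
    draws = np.empty((n_chains, retained, len(names)))
    deviance = np.empty((n_chains, retained))
    for c in range(n_chains):
        block = wide.loc[c]
        draws[c] = block[names].to_numpy()
        deviance[c] = block["deviance"].to_numpy()
    return Trace(
        draws=draws,
        param_names=tuple(names),
        deviance=deviance,
        variant=variant,
        config=config,
        n_obs=int(manifest["n_obs"]),
        batch_ids=tuple(manifest["batch_ids"]),
        acceptance={k: np.array(v) for k, v in manifest.get("acceptance", {}).items()},
        proposal_scales=manifest.get("proposal_scales", {}),
        fixed_values=manifest.get("fixed_values", {}),
        fixed_pH0=manifest.get("fixed_pH0"),
    )


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """One simulation request: condition, time grid, band mode."""

    lactate: float
    atmosphere: str
    days: tuple[float, float, float] = (0.0, 22.0, 0.5)  # start, stop, step
    new_batch: bool = True
    measurement_noise: bool = False

    @property
    def grid(self) -> np.ndarray:
        start, stop, step = self.days
        return np.arange(start, stop + 1e-9, step)

    @property
    def condition(self) -> Condition:
        return Condition(lactate=self.lactate, atmosphere=Atmosphere.parse(self.atmosphere))


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from a YAML document.

    Either ``dataset`` points at an existing CSV or ``generate`` is true and
    a synthetic dataset is produced under ``design`` from the reference
    truth.  ``seed`` feeds every stochastic stage deterministically.
    """

    outdir: str | Path = "phkinetics_run"
    dataset: str | None = None
    generate: bool = False
    design: StudyDesign = field(default_factory=StudyDesign)
    truth: ParameterState = field(default_factory=reference_estimates)
    variants: tuple[str, ...] = VARIANT_NAMES
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    rhat_threshold: float = 1.1
    geweke_threshold: float = 2.0
    scenarios: tuple[Scenario, ...] = ()
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        kwargs: dict[str, Any] = {}
        for key in ("outdir", "dataset", "generate", "rhat_threshold",
                    "geweke_threshold", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "variants" in raw:
            kwargs["variants"] = tuple(raw["variants"])
        if "design" in raw:
            kwargs["design"] = StudyDesign(**raw["design"])
        if "truth" in raw:
            t = dict(raw["truth"])
            if "lambda" in t:
                t["lam"] = t.pop("lambda")
            kwargs["truth"] = ParameterState(**t)
        if "mcmc" in raw:
            kwargs["mcmc"] = MCMCConfig(**raw["mcmc"])
        if "scenarios" in raw:
            kwargs["scenarios"] = tuple(Scenario(**s) for s in raw["scenarios"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def run_pipeline(config: RunConfig) -> Path:
    """Generate/load data, fit all variants, diagnose, compare, summarise, simulate.

    Writes all artefacts into ``config.outdir`` and returns it.  Any stage
    failure leaves partial outputs plus a ``FAILED`` marker naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "setup"
    master = np.random.default_rng(config.seed)

    def seed32() -> int:
        return int(master.integers(2 ** 31))

    try:
        stage = "data"
        t0 = time.perf_counter()
        if config.generate:
            dataset = generate_dataset(config.design, config.truth, seed=seed32())
            write_dataset(dataset, out / "dataset.csv")
            write_truth_sidecar(dataset, out / "dataset_truth.json")
            logger.info("generated synthetic dataset with %d observations", dataset.n_obs)
        elif config.dataset is not None:
            dataset = read_dataset(config.dataset)
            logger.info("loaded %d observations from %s", dataset.n_obs, config.dataset)
        else:
            raise ValueError("config must set dataset: <path> or generate: true")
        timings[stage] = time.perf_counter() - t0

        traces: dict[str, Trace] = {}
        dics = []
        for name in config.variants:
            stage = f"fit:{name}"
            t0 = time.perf_counter()
            variant = model_variant(name)
            cfg = dataclasses.replace(config.mcmc, seed=seed32())
            trace = run_mcmc(dataset, variant, cfg)
            traces[name] = trace
            write_trace(trace, out / f"trace_{name}.csv", out / f"manifest_{name}.json")
            timings[stage] = time.perf_counter() - t0
            logger.info("fitted %s in %.1fs", name, timings[stage])

            stage = f"diagnose:{name}"
            report = assess_convergence(trace, config.rhat_threshold, config.geweke_threshold)
            report.to_json(out / f"diagnostics_{name}.json")
            if not report.passed:
                logger.warning("convergence flags for %s: rhat=%s geweke=%s",
                               name, report.failed_rhat, report.failed_geweke)

            stage = f"dic:{name}"
            dics.append(compute_dic(trace, dataset))

        stage = "compare"
        dic_table = pd.DataFrame([r.to_dict() for r in dics])
        dic_table.to_csv(out / "dic.csv", index=False)
        winner = select_model(dics)
        (out / "selection.json").write_text(
            json.dumps({"winner": winner,
                        "dic": {r.variant_name: r.dic for r in dics}}, indent=2)
        )
        logger.info("lowest-DIC variant: %s", winner)

        stage = "summarize"
        summary = summarize_posterior(traces[winner])
        summary.to_csv(out / "posterior_summary.csv")
        goodness_of_fit(summary, dataset).to_csv(out / "residuals.csv", index=False)

        stage = "simulate"
        for i, sc in enumerate(config.scenarios):
            band = simulate_kinetics(
                traces[winner], sc.condition, sc.grid,
                new_batch=sc.new_batch, measurement_noise=sc.measurement_noise,
                seed=seed32(),
            )
            band.to_csv(out / f"band_{i}_{sc.lactate}pct_{sc.condition.atmosphere.value}.csv")

        stage = "manifest"
        (out / "manifest.json").write_text(
            json.dumps(
                {
                    "phkinetics_version": __version__,
                    "seed": config.seed,
                    "variants": list(config.variants),
                    "winner": winner,
                    "n_obs": dataset.n_obs,
                    "timings_s": timings,
                },
                indent=2,
            )
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return out
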