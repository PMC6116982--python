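"""Monte Carlo simulation study: generate, fit, score, aggregate.

Runs every requested (model, error family, replicate count) cell over
``n_datasets`` independently seeded synthetic datasets, records the
posterior means of the reported parameters and the prediction mean
squared error of the fitted device-mean function, and aggregates to the
Mean Est / Std Err / Bias / Truth rows of the result tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import simulate as sim
from .models import (
    LMEMSpec,
    MeasurementDataset,
    NaiveModelSpec,
    SMEMNSpec,
    SMEMSpec,
)
from .samplers import ChainConfig, gibbs_fit, rjmcmc_fit
from .bspline import evaluate_spline

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResultTable", "run_study", "pmse", "fit_model"]

MODELS = ("naive", "lmem", "smemn", "smem")
_SPECS = {
    "naive": NaiveModelSpec,
    "lmem": LMEMSpec,
    "smemn": SMEMNSpec,
    "smem": SMEMSpec,
}

#: parameters reported per model, in table column order
_REPORTED = {
    "naive": [
        "sigma_yee", "sigma_yes",
        "gamma_1_ee", "gamma_2_ee", "gamma_3_ee",
        "gamma_1_es", "gamma_2_es", "gamma_3_es",
    ],
    "lmem": [
        "sigma_yee", "sigma_yes", "sigma_wee", "sigma_wes",
        "gamma_1_ee", "gamma_2_ee", "gamma_3_ee",
        "gamma_1_es", "gamma_2_es", "gamma_3_es",
    ],
}
_REPORTED["smemn"] = _REPORTED["lmem"]
_REPORTED["smem"] = _REPORTED["lmem"]


@dataclass(frozen=True)
class StudyConfig:
    """Which cells of the study to run, and at what scale."""

    families: tuple = ("normal",)
    replicates: tuple = (4,)
    models: tuple = ("naive", "lmem", "smemn")
    n_datasets: int = 25
    generator: sim.GeneratorConfig = field(default_factory=sim.default_config)
    chains: ChainConfig = field(
        default_factory=lambda: ChainConfig(
            n_chains=1, n_iterations=4000, burn_in=1000
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.families and self.replicates and self.models):
            raise ValueError("families, replicates and models must be non-empty")
        if self.n_datasets < 2:
            raise ValueError("need at least 2 datasets per cell")
        unknown = set(self.models) - set(MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        bad = set(self.families) - set(sim.ERROR_FAMILIES)
        if bad:
            raise ValueError(f"unknown error families: {sorted(bad)}")


@dataclass
class StudyResultTable:
    """Aggregated parameter table plus per-dataset log-PMSE records."""

    parameters: pd.DataFrame
    pmse: pd.DataFrame
    failures: pd.DataFrame

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.parameters.to_csv(directory / "parameters.csv", index=False)
        self.pmse.to_csv(directory / "pmse.csv", index=False)
        self.failures.to_csv(directory / "failures.csv", index=False)


def cell_seed(root_seed: int, model: str, family: str, replicates: int, index: int):
    """Deterministic per-dataset seed so any cell can be re-run on its own."""
    return np.random.SeedSequence(
        [
            root_seed,
            MODELS.index(model),
            sim.ERROR_FAMILIES.index(family),
            replicates,
            index,
        ]
    )


def fit_model(model: str, dataset: MeasurementDataset, chains: ChainConfig):
    spec = _SPECS[model]()
    if model in ("naive", "lmem"):
        return gibbs_fit(spec, dataset, chains)
    return rjmcmc_fit(spec, dataset, chains)


def _posterior_mean_table(model: str, draws) -> dict[str, float]:
    out = {}
    for attr in ("ee", "es"):
        out[f"sigma_y{attr}"] = float(draws.posterior_mean(f"sigma_y{attr}"))
        if model != "naive":
            out[f"sigma_w{attr}"] = float(draws.posterior_mean(f"sigma_w{attr}"))
        g = draws.posterior_mean(f"gamma_{attr}")
        for d in range(3):
            out[f"gamma_{d + 1}_{attr}"] = float(g[d])
    return out


def pmse(draws, truth_dataset: sim.SimulatedDataset, attribute: str, model: str) -> float:
    """Mean squared error of the posterior-mean device-mean function.

    The latent-variable models expose a mean function of the latent value
    and are evaluated at the simulated subjects' true latents; the naive
    model's regression function takes the gold-standard reading as input,
    so it is evaluated at the subject's average W — the input it would
    receive in use — and its measurement error propagates into the score.
    The reference is the generator's true mean m(x) + gamma' z.
    """
    lat = truth_dataset.latents
    z = truth_dataset.covariates.matrix
    cfg = truth_dataset.config
    x = lat.x_ee if attribute == "ee" else lat.x_es
    m = sim.bias_mee if attribute == "ee" else sim.bias_mes
    gamma_true = np.asarray(
        cfg.gamma_ee if attribute == "ee" else cfg.gamma_es, dtype=float
    )
    true_mean = m(x) + z @ gamma_true

    if model in ("naive", "lmem"):
        b0 = float(draws.posterior_mean(f"beta0_{attribute}"))
        b1 = float(draws.posterior_mean(f"beta1_{attribute}"))
        g = draws.posterior_mean(f"gamma_{attribute}")
        if model == "naive":
            w = truth_dataset.w_ee if attribute == "ee" else truth_dataset.w_es
            x_in = w.mean(axis=1)
        else:
            x_in = x
        pred = b0 + b1 * x_in + z @ g
    else:
        spline_draws = draws.spline_draws(attribute)
        acc = np.zeros_like(x)
        for d in spline_draws:
            xc = np.clip(x, d.knots.lower, d.knots.upper)
            acc += evaluate_spline(xc, d.knots, d.beta) + z @ d.gamma
        pred = acc / len(spline_draws)
    return float(np.mean((pred - true_mean) ** 2))


def run_study(cfg: StudyConfig) -> StudyResultTable:
    """Execute every requested cell; failures are logged and counted."""
    records = []
    pmse_records = []
    failures = []
    for family in cfg.families:
        for j in cfg.replicates:
            datasets = []
            for d_idx in range(cfg.n_datasets):
                seed = cell_seed(cfg.seed, "naive", family, j, d_idx)
                gen = replace(
                    cfg.generator,
                    error_family=family,
                    n_replicates=j,
                    seed=seed.entropy,
                )
                datasets.append(sim.assemble_dataset(gen))
            for model in cfg.models:
                means = []
                for d_idx, simulated in enumerate(datasets):
                    chain_seed = cell_seed(cfg.seed, model, family, j, d_idx)
                    chains = replace(
                        cfg.chains, seed=chain_seed.generate_state(1)[0].item()
                    )
                    try:
                        ds = MeasurementDataset.from_simulated(simulated)
                        draws = fit_model(model, ds, chains)
                        means.append(_posterior_mean_table(model, draws))
                        for attr in ("ee", "es"):
                            pmse_records.append(
                                {
                                    "model": model,
                                    "family": family,
                                    "replicates": j,
                                    "dataset": d_idx,
                                    "attribute": attr,
                                    "pmse": pmse(draws, simulated, attr, model),
                                }
                            )
                    except Exception:
                        logger.exception(
                            "fit failed: model=%s family=%s J=%d dataset=%d",
                            model, family, j, d_idx,
                        )
                        failures.append(
                            {
                                "model": model,
                                "family": family,
                                "replicates": j,
                                "dataset": d_idx,
                            }
                        )
                if not means:
                    continue
                truth = cfg.generator.truth()
                table = pd.DataFrame(means)
                for param in _REPORTED[model]:
                    est = table[param].to_numpy()
                    t = truth.parameter(param)
                    records.append(
                        {
                            "model": model,
                            "family": family,
                            "replicates": j,
                            "parameter": param,
                            "mean_est": est.mean(),
                            "std_err": est.std(ddof=1),
                            "bias": est.mean() - t,
                            "truth": t,
                            "n_datasets": est.size,
                        }
                    )
    return StudyResultTable(
        parameters=pd.DataFrame(records),
        pmse=pd.DataFrame(pmse_records),
        failures=pd.DataFrame(failures, columns=["model", "family", "replicates", "dataset"]),
    )
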