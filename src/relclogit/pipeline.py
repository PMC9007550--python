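"""End-to-end pipeline: simulate → fit/grid → posteriors → three-step →
concordance → report, with a manifest recording seeds, versions, input hashes
and per-stage wall times so any output can be re-derived from the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import RankingDataset, read_choice_data
from .design import generate_design
from .estimation import FitConfig, FitResult, fit, fit_grid
from .params import RELCLParams
from .posterior import (
    class_posteriors,
    cohort_concordance,
    preferences_long,
    regress_factor_scores,
    three_step_membership,
)
from .scheme import AttributeScheme, hiv_testing_scheme
from .simulate import simulate_dataset, study_params

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("relclogit")

ALL_STAGES = ("simulate", "fit", "grid", "posteriors", "threestep",
              "concordance", "report")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``stages`` selects which stages run (in pipeline order).  When
    ``data_path`` is given the simulate stage is skipped and the file is
    read instead; every stochastic stage derives its generator from ``seed``.
    """

    output_dir: str = "relcl_run"
    seed: int = 0
    stages: tuple = ("simulate", "fit", "posteriors", "threestep", "report")
    scheme_path: str | None = None  # default: built-in HIV-testing scheme
    data_path: str | None = None
    participants_path: str | None = None
    n_participants: int | None = None  # default: study scale (740)
    n_tasks: int = 120
    n_blocks: int = 10
    n_alts: int = 3
    generating_params_path: str | None = None  # default: study profile
    n_classes: int = 8
    n_effects: int = 3
    grid_classes: tuple = (1, 10)
    grid_effects: tuple = (0, 3)
    fit_config: FitConfig = field(default_factory=FitConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fc = FitConfig(**raw.pop("fit_config", {}))
        cfg = cls(**{k: v for k, v in raw.items()}, )
        cfg.fit_config = fc
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Every stage logs its wall time; a ``manifest.json`` ties outputs to the
    config, seeds, library versions and input-file hashes.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "versions": _versions(),
        "inputs": {},
        "stage_seconds": {},
        "config": {
            k: v for k, v in asdict(config).items() if k != "fit_config"
        },
        "fit_config": asdict(config.fit_config),
    }

    scheme = (
        AttributeScheme.from_yaml(config.scheme_path)
        if config.scheme_path
        else hiv_testing_scheme()
    )
    if config.scheme_path:
        manifest["inputs"][config.scheme_path] = _sha256(config.scheme_path)
    scheme.to_yaml(out / "scheme.yaml")

    dataset = truth = None
    if config.data_path:
        t0 = time.perf_counter()
        dataset = read_choice_data(config.data_path, scheme, config.participants_path)
        manifest["inputs"][config.data_path] = _sha256(config.data_path)
        if config.participants_path:
            manifest["inputs"][config.participants_path] = _sha256(
                config.participants_path
            )
        manifest["stage_seconds"]["read"] = time.perf_counter() - t0
        log.info("read %d participants", dataset.n_participants)
    elif "simulate" in config.stages:
        t0 = time.perf_counter()
        design = generate_design(
            scheme, config.n_tasks, config.n_blocks, config.n_alts, rng
        )
        design.to_frame(scheme).to_csv(out / "design.csv", index=False)
        gen = (
            RELCLParams.from_json(config.generating_params_path, scheme)
            if config.generating_params_path
            else study_params(scheme)
        )
        dataset, truth = simulate_dataset(
            scheme, design, gen, n=config.n_participants, rng=rng
        )
        dataset.write_csv(out / "choices.csv", out / "participants.csv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)
        manifest["stage_seconds"]["simulate"] = time.perf_counter() - t0
        log.info(
            "simulated %d participants, %d rankings",
            dataset.n_participants, dataset.n_rankings,
        )
    if dataset is None:
        raise ValueError("no data: provide data_path or include the simulate stage")

    result: FitResult | None = None
    if "grid" in config.stages:
        t0 = time.perf_counter()
        gdf = fit_grid(
            dataset, scheme,
            range(config.grid_classes[0], config.grid_classes[1] + 1),
            range(config.grid_effects[0], config.grid_effects[1] + 1),
            config.fit_config,
        )
        gdf.to_csv(out / "grid.csv", index=False)
        best = gdf.loc[gdf["is_best"]].iloc[0]
        config.n_classes = int(best["n_classes"])
        config.n_effects = int(best["n_effects"])
        manifest["stage_seconds"]["grid"] = time.perf_counter() - t0
        log.info("grid best: X=%d D=%d", config.n_classes, config.n_effects)

    if "fit" in config.stages or any(
        s in config.stages for s in ("posteriors", "threestep", "concordance", "report")
    ):
        t0 = time.perf_counter()
        result = fit(dataset, scheme, config.n_classes, config.n_effects,
                     config.fit_config)
        with open(out / "fit.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=1)
        manifest["stage_seconds"]["fit"] = time.perf_counter() - t0
        log.info("fit: loglik=%.2f bic=%.2f", result.loglik, result.bic)

    posteriors = None
    if result and ("posteriors" in config.stages or "threestep" in config.stages
                   or "report" in config.stages):
        t0 = time.perf_counter()
        posteriors = class_posteriors(result, dataset)
        posteriors.to_frame(dataset.participants).to_csv(
            out / "posteriors.csv", index=False
        )
        preferences_long(result, posteriors, dataset.participants).to_csv(
            out / "individual_preferences.csv", index=False
        )
        manifest["stage_seconds"]["posteriors"] = time.perf_counter() - t0

    if result and posteriors is not None and "threestep" in config.stages:
        t0 = time.perf_counter()
        memb = three_step_membership(result, posteriors, dataset)
        memb.membership_frame().to_csv(out / "threestep_membership.csv", index=False)
        fs = regress_factor_scores(posteriors, dataset)
        if fs.factor_coef is not None and fs.factor_coef.size:
            fs.factor_frame().to_csv(out / "threestep_factors.csv", index=False)
        manifest["stage_seconds"]["threestep"] = time.perf_counter() - t0

    if result and "concordance" in config.stages:
        t0 = time.perf_counter()
        groups = dataset.participants["cohort"].unique()
        fits_by_group = {}
        for g in groups:
            idx = np.flatnonzero(dataset.participants["cohort"].to_numpy() == g)
            fits_by_group[g] = fit(
                dataset.subset(idx), scheme, config.n_classes,
                config.n_effects, config.fit_config,
            )
        conc = cohort_concordance(result, fits_by_group, dataset)
        serial = {
            str(k): (
                {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv)
                 for kk, vv in v.items()}
                if isinstance(v, dict) else v
            )
            for k, v in conc.items()
        }
        with open(out / "concordance.json", "w") as fh:
            json.dump(serial, fh, indent=1)
        manifest["stage_seconds"]["concordance"] = time.perf_counter() - t0

    if result and "report" in config.stages:
        _write_report(out, result, dataset, posteriors)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def _write_report(out: Path, result: FitResult, dataset: RankingDataset,
                  posteriors) -> None:
    """Coefficient table in report layout: expanded per-level β per class,
    the loadings column with domain tags, and class sizes overall and by
    cohort."""
    params = result.params
    scheme = params.scheme
    labels = scheme.level_labels()
    be = params.expanded_beta()
    rows = []
    domains = {a.name: a.domain for a in scheme.attributes}
    lam_exp = params.expanded_lam()
    for j, (attr, level) in enumerate(labels):
        row = {"attribute": attr, "level": level}
        for x in range(params.n_classes):
            row[f"class{x + 1}"] = round(float(be[x, j]), 3)
            if result.se_beta_expanded is not None:
                row[f"class{x + 1}_se"] = round(
                    float(result.se_beta_expanded[x, j]), 3
                )
        d = domains[attr]
        row["loading"] = (
            round(float(lam_exp[d - 1, j]), 3) if d <= params.n_effects else np.nan
        )
        row["domain"] = d
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "coefficients.csv", index=False)

    if posteriors is not None:
        shares = {"all": np.bincount(posteriors.modal,
                                     minlength=params.n_classes) / len(posteriors.modal)}
        cohorts = dataset.participants["cohort"].to_numpy()
        for g in np.unique(cohorts):
            sel = cohorts == g
            shares[f"cohort{g}"] = np.bincount(
                posteriors.modal[sel], minlength=params.n_classes
            ) / sel.sum()
        pd.DataFrame(shares, index=[f"class{x + 1}" for x in
                                    range(params.n_classes)]).to_csv(
            out / "class_sizes.csv"
        )


def _versions() -> dict:
    import scipy

    import relclogit

    return {
        "relclogit": relclogit.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
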