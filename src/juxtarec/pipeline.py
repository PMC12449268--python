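"""Configuration-driven pipeline: simulate -> estimate -> compare -> boundaries.

A run is described by a YAML/TOML config with a single global seed; each
stochastic stage receives a seed derived from it via
``numpy.random.SeedSequence``, and the fully resolved config (defaults
materialized, stage seeds recorded) is written into the run directory so
a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io
from .boundary import group_and_correlate, poly_trend
from .meiosis import (
    CrossDesign,
    JuxtapositionModel,
    RecombinationLandscape,
    Scenario,
    ZygosityMap,
    simulate_experiment,
)
from .stats_compare import GroupSample, games_howell, welch_anova, welch_t

logger = logging.getLogger(__name__)

DEFAULT_SIMULATE = {
    "chrom_length": 100_000_000,
    "uniform_rate": 1.5,
    "landscape": None,
    "interval": [45_000_000, 55_000_000],
    "design": "backcross",
    "plants_per_config": 12,
    "progeny_per_plant": 400,
    "resolution_bp": 100_000,
    "model": {"strength": 2.0, "decay_cm": 20.0, "activity_threshold": 0.5,
              "conserve": True},
    "configurations": None,
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            return yaml.safe_load(fh)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    raise ConfigError(f"unsupported config format: {path.suffix}")


def _default_configurations(length: int, interval: list[int]) -> dict[str, list]:
    lo, hi = interval
    third = (hi - lo) // 3
    return {
        "inbred": [[0, length, "HOM"]],
        "hybrid": [[0, length, "HET"]],
        "juxtaposed": [[0, lo, "HOM"], [lo, hi, "HET"], [hi, length, "HOM"]],
        "reverse_juxtaposed": [[0, lo, "HET"], [lo, hi, "HOM"], [hi, length, "HET"]],
        "interrupted_juxtaposed": [
            [0, lo, "HOM"], [lo, lo + third, "HET"],
            [lo + third, hi - third, "HOM"], [hi - third, hi, "HET"],
            [hi, length, "HOM"],
        ],
    }


def resolve_config(config: dict[str, Any]) -> dict[str, Any]:
    """Materialize defaults and derive per-stage seeds from the global seed."""
    resolved = dict(config)
    if "seed" not in resolved:
        raise ConfigError("config must set a global 'seed'")
    resolved.setdefault("stages", ["simulate", "estimate", "compare"])
    sim = {**DEFAULT_SIMULATE, **resolved.get("simulate", {})}
    if sim["configurations"] is None:
        sim["configurations"] = _default_configurations(
            sim["chrom_length"], list(sim["interval"])
        )
    resolved["simulate"] = sim
    ss = np.random.SeedSequence(int(resolved["seed"]))
    stage_seeds = {
        stage: int(child.generate_state(1)[0])
        for stage, child in zip(("simulate",), ss.spawn(1))
    }
    resolved["stage_seeds"] = resolved.get("stage_seeds", stage_seeds)
    return resolved


def build_scenario(sim: dict[str, Any], seed: int) -> Scenario:
    length = int(sim["chrom_length"])
    if sim.get("landscape"):
        wins = [(int(s), int(e), float(r)) for s, e, r in sim["landscape"]]
        base = RecombinationLandscape(length, tuple(wins))
    else:
        base = RecombinationLandscape.uniform(length, float(sim["uniform_rate"]))
    configs = {
        name: ZygosityMap(length, tuple((int(s), int(e), str(st)) for s, e, st in segs))
        for name, segs in sim["configurations"].items()
    }
    model = JuxtapositionModel(**sim["model"])
    lo, hi = sim["interval"]
    design = CrossDesign(sim["design"].replace("seed", "seed_fluorescence")
                         if sim["design"] == "seed" else sim["design"],
                         int(lo), int(hi))
    return Scenario(
        base=base, configurations=configs, model=model, design=design,
        plants_per_config=int(sim["plants_per_config"]),
        progeny_per_plant=int(sim["progeny_per_plant"]),
        seed=seed, resolution_bp=int(sim["resolution_bp"]),
    )


def compare_groups(rf_table: pd.DataFrame, group_col: str = "configuration",
                   value_col: str = "rf") -> pd.DataFrame:
    """Welch ANOVA across groups plus Games–Howell and Welch-t pair rows."""
    groups = [
        GroupSample(str(name), tuple(sub[value_col]))
        for name, sub in rf_table.groupby(group_col, sort=False)
    ]
    rows = []
    anova = welch_anova(groups)
    rows.append({"test": "welch_anova", "pair": "|".join(anova.labels),
                 "statistic": anova.statistic, "df": anova.df, "p": anova.p,
                 "flags": ";".join(anova.flags)})
    for res in games_howell(groups):
        rows.append({"test": "games_howell", "pair": "|".join(res.labels),
                     "statistic": res.statistic, "df": res.df, "p": res.p,
                     "flags": ";".join(res.flags)})
    for a, b in itertools.combinations(groups, 2):
        res = welch_t(a, b)
        rows.append({"test": "welch_t", "pair": "|".join(res.labels),
                     "statistic": res.statistic, "df": res.df, "p": res.p,
                     "flags": ";".join(res.flags)})
    return pd.DataFrame(rows)


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> dict[str, Path]:
    """Execute the configured stages and write all tables under ``outdir``.

    Returns a mapping from output name to written path.  Deterministic
    for a fixed config (all randomness flows from the recorded seeds).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = resolve_config(config)
    cfg_hash = io.config_hash(resolved)
    seed = int(resolved["seed"])

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("juxtarec")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}
    try:
        with open(outdir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(resolved, fh, sort_keys=True)
        outputs["resolved_config"] = outdir / "resolved_config.yaml"

        rf_table: pd.DataFrame | None = None
        stages = resolved["stages"]
        if "simulate" in stages:
            logger.info("stage simulate: seed=%s", resolved["stage_seeds"]["simulate"])
            scenario = build_scenario(resolved["simulate"],
                                      resolved["stage_seeds"]["simulate"])
            rf_table = simulate_experiment(scenario)
            path = outdir / "rf_per_plant.tsv"
            io.write_table(rf_table, path, seed=seed, cfg_hash=cfg_hash)
            outputs["rf_per_plant"] = path
        if "estimate" in stages and "counts_table" in resolved:
            counts = io.read_counts_table(resolved["counts_table"])
            est = io.estimate_counts_table(counts)
            path = outdir / "rf_estimates.tsv"
            io.write_table(est, path, seed=seed, cfg_hash=cfg_hash)
            outputs["rf_estimates"] = path
        if "compare" in stages:
            if rf_table is None:
                source = resolved.get("compare", {}).get("input")
                if source is None:
                    raise ConfigError("compare stage needs simulate output or "
                                      "compare.input")
                rf_table = io.read_table(source)
            comparison = compare_groups(rf_table)
            path = outdir / "comparisons.tsv"
            io.write_table(comparison, path, seed=seed, cfg_hash=cfg_hash)
            outputs["comparisons"] = path
        if "boundaries" in stages:
            bconf = resolved.get("boundaries", {})
            for key in ("segments", "rf", "interval"):
                if key not in bconf:
                    raise ConfigError(f"boundaries stage needs boundaries.{key}")
            inds = io.read_individuals(bconf["segments"], bconf["rf"],
                                       tuple(bconf["interval"]))
            df, corr = group_and_correlate(
                inds, key=bconf.get("key", "distance"),
                bin_width=int(bconf.get("bin_width", 1_000_000)),
            )
            groups = df.attrs["groups"]
            path = outdir / "boundary_groups.tsv"
            io.write_table(groups, path, seed=seed, cfg_hash=cfg_hash)
            outputs["boundary_groups"] = path
            summary = pd.DataFrame([{"rho": corr.rho, "p": corr.p,
                                     "n_groups": corr.n_groups,
                                     "flags": ";".join(corr.flags)}])
            path = outdir / "boundary_correlation.tsv"
            io.write_table(summary, path, seed=seed, cfg_hash=cfg_hash)
            outputs["boundary_correlation"] = path
            fit = poly_trend(inds, degree=int(bconf.get("degree", 3)))
            curve = pd.DataFrame({"x": fit.x, "fitted": fit.fitted,
                                  "ci_low": fit.ci_low, "ci_high": fit.ci_high})
            path = outdir / "boundary_fit.tsv"
            io.write_table(curve.sort_values("x"), path, seed=seed, cfg_hash=cfg_hash)
            outputs["boundary_fit"] = path
    finally:
        root.removeHandler(handler)
        handler.close()
    return outputs
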