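"""Screening pipeline: registry -> design -> simulations -> indices -> analysis.

Stages write tidy CSV artifacts into the run directory and are cached: a
manifest records the configuration hash and a checksum per stage file, so a
re-run with an identical configuration reloads results (and recomputes any
stage whose file is missing or corrupted).  All randomness derives from one
master seed through fixed per-stage child seeds, so a full re-computation is
bit-identical.

Two presets are provided: ``paper`` mirrors the full study geometry
(90 factors, 100 trajectories, 4 sites x 125 years x 3 sowings x 3 N x
2 CO2 — intended for :func:`plan_run` dry-runs and cluster-scale use) and
``desk`` is a reduced screen (20 factors, 20 trajectories, 40 environments,
~17k season simulations) that runs end-to-end on one CPU in minutes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis as an
from . import environments as envs
from . import morris
from .parameters import Registry, count_factors, load_registry, materialize_genotype
from .registry import desk_registry, paper_registry
from .simulator import CropOutputs, CropParameters, run_crop

__all__ = ["RunConfig", "desk_config", "paper_config", "plan_run", "run_pipeline"]

log = logging.getLogger("traitscreen")

REGRESSION_FACTORS = ("tt_end_of_juvenile", "ll_modifier", "y_rue",
                      "potential_grain_filling_rate")


@dataclass(frozen=True)
class RunConfig:
    """Everything a screening run depends on (hashable for stage caching)."""

    registry: str = "desk"  # "paper" | "desk" | path to a registry CSV
    n_levels: int = 6
    r: int = 20
    n_candidates: int | None = None
    seed: int = 1
    sites: tuple[str, ...] = ("Merredin", "Yanco")
    years: int = 5  # synthetic weather years per site
    sowings: tuple[str, ...] = ("tpe",)
    n_tags: tuple[str, ...] = ("low", "tpe")
    co2_levels: tuple[float, ...] = (380.0, 555.0)
    impact_threshold: float = an.IMPACT_THRESHOLD
    et_low: float = 0.2
    et_severe: float = 0.5
    k_clusters: int = 3
    outdir: str = "runs/desk"

    def load_registry(self) -> Registry:
        if self.registry == "paper":
            return paper_registry()
        if self.registry == "desk":
            return desk_registry()
        return load_registry(self.registry)

    def n_environments(self) -> int:
        return (len(self.sites) * self.years * len(self.sowings)
                * len(self.n_tags) * len(self.co2_levels))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def desk_config(seed: int = 1, outdir: str = "runs/desk") -> RunConfig:
    """Reduced screen: 20 factors, r=20, 2 sites x 5 years x 1 x 2 N x 2 CO2."""
    return RunConfig(seed=seed, outdir=outdir)


def paper_config(seed: int = 1, outdir: str = "runs/paper") -> RunConfig:
    """Full study geometry; use with plan_run unless you have a cluster."""
    return RunConfig(
        registry="paper", r=100, n_candidates=500, seed=seed,
        sites=("Emerald", "Narrabri", "Yanco", "Merredin"), years=125,
        sowings=("early", "tpe", "late"), n_tags=("low", "tpe", "high"),
        co2_levels=(380.0, 555.0), outdir=outdir,
    )


def _child_seed(master: int, *key: int) -> int:
    """Deterministic per-stage child seed derived from the master seed."""
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0] % (2**31))


def plan_run(config: RunConfig) -> dict[str, int]:
    """Dry-run manifest: design rows, environments, total planned simulations."""
    g = count_factors(config.load_registry())
    rows = (g + 1) * config.r
    n_env = config.n_environments()
    return {
        "n_factors": g,
        "design_rows": rows,
        "n_environments": n_env,
        "total_simulations": rows * n_env,
    }


# ---------------------------------------------------------------------------
# stage cache

def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Cache:
    def __init__(self, outdir: Path, confhash: str) -> None:
        self.outdir = outdir
        self.path = outdir / "manifest.json"
        self.manifest: dict = {"config": confhash, "stages": {}}
        if self.path.exists():
            try:
                old = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                old = {}
            if old.get("config") == confhash:
                self.manifest = old

    def fresh(self, stage: str, filename: str) -> bool:
        rec = self.manifest["stages"].get(stage)
        f = self.outdir / filename
        if rec is None or not f.exists():
            return False
        if _sha(f) != rec["sha256"]:
            log.warning("stage %s: checksum mismatch on %s, recomputing", stage, filename)
            return False
        return True

    def record(self, stage: str, filename: str) -> None:
        self.manifest["stages"][stage] = {
            "file": filename, "sha256": _sha(self.outdir / filename)}
        self.path.write_text(json.dumps(self.manifest, indent=1))


# ---------------------------------------------------------------------------

_OUTPUT_COLS = list(CropOutputs.OUTPUT_NAMES)


def _simulate_environments(config: RunConfig, registry: Registry,
                           design: morris.MorrisDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every design row and the reference genotype in every environment."""
    factor_ids = registry.factor_names()
    params_by_row = []
    for row in design.rows:
        geno = materialize_genotype(registry, row.tolist())
        params_by_row.append(CropParameters.from_genotype(geno))
    baseline_params = CropParameters.from_genotype(
        materialize_genotype(registry, [0.5] * len(factor_ids)))

    grid = envs.build_environment_grid(
        list(config.sites), list(range(1, config.years + 1)),
        list(config.sowings), list(config.n_tags), list(config.co2_levels))

    # one spare year so a late-sown season can mature past 31 December
    weather_by_site = {
        name: envs.generate_weather(envs.SITES[name], config.years + 1,
                                    seed=_child_seed(config.seed, 2, i))
        for i, name in enumerate(config.sites)
    }
    soil_by_site = {name: envs.SITES[name].soil() for name in config.sites}

    out_rows, base_rows = [], []
    for spec in grid:
        site = envs.SITES[spec.site]
        weather = weather_by_site[spec.site]
        soil = soil_by_site[spec.site]
        man = envs.management_plan(site, spec.sowing_tag, spec.n_tag, spec.co2)

        base = run_crop(baseline_params, weather, soil, man,
                        start_year=spec.year, keep_trajectory=True)
        et = ("ET1" if base.flowering_index in (None, 0) else
              an.drought_type_from_trajectory(
                  base.stress_trajectory, base.flowering_index,
                  an.DroughtThresholds(config.et_low, config.et_severe)))
        base_rows.append({"env_id": spec.env_id, **base.as_dict(),
                          "veg_stress": base.veg_stress,
                          "grainfill_stress": base.grainfill_stress,
                          "env_type": et})

        for ridx, p in enumerate(params_by_row):
            out = run_crop(p, weather, soil, man, start_year=spec.year)
            out_rows.append({"row": ridx, "env_id": spec.env_id, **out.as_dict()})
        log.info("simulated %s", spec.env_id)

    return pd.DataFrame(out_rows), pd.DataFrame(base_rows)


def _compute_indices(design: morris.MorrisDesign, factor_ids: list[str],
                     outputs: pd.DataFrame) -> pd.DataFrame:
    """Raw and environment-standardized mu*/sigma per factor x env x output."""
    std = morris.standardize_by_environment(outputs, _OUTPUT_COLS, "env_id")
    rec = []
    for env_id, sub in outputs.groupby("env_id", sort=True):
        sub = sub.sort_values("row")
        sub_std = std.loc[sub.index]
        for output in _OUTPUT_COLS:
            ee = morris.elementary_effects(design, sub[output].to_numpy(float),
                                           output=output, environment=env_id)
            idx = morris.aggregate_indices(ee)
            ee_s = morris.elementary_effects(design, sub_std[output].to_numpy(float))
            idx_s = morris.aggregate_indices(ee_s, standardized=True)
            for i, fid in enumerate(factor_ids):
                rec.append({"factor": fid, "env_id": env_id, "output": output,
                            "mu_star": idx.mu_star[i], "sigma": idx.sigma[i],
                            "mu_star_std": idx_s.mu_star[i],
                            "sigma_std": idx_s.sigma[i]})
    return pd.DataFrame(rec)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages with caching; returns the result tables.

    Artifacts written to ``config.outdir``: design.csv, environments.csv,
    outputs.csv, baseline.csv, indices.csv, classification.csv, eta2.csv,
    clusters.csv, dendrogram.txt, stress_regression.csv, manifest.json.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = _Cache(outdir, config.config_hash())
    registry = config.load_registry()
    factor_ids = registry.factor_names()

    # --- design ----------------------------------------------------------
    if cache.fresh("design", "design.csv"):
        design = morris.MorrisDesign.from_frame(pd.read_csv(
            outdir / "design.csv", keep_default_na=False))
    else:
        design = morris.build_design(len(factor_ids), config.n_levels, config.r,
                                     config.n_candidates,
                                     seed=_child_seed(config.seed, 1))
        design.to_frame(factor_ids).to_csv(outdir / "design.csv", index=False)
        cache.record("design", "design.csv")

    # --- environments table ---------------------------------------------
    grid = envs.build_environment_grid(
        list(config.sites), list(range(1, config.years + 1)),
        list(config.sowings), list(config.n_tags), list(config.co2_levels))
    env_table = pd.DataFrame([dataclasses.asdict(e) for e in grid])
    env_table.to_csv(outdir / "environments.csv", index=False)
    cache.record("environments", "environments.csv")

    # --- simulations ------------------------------------------------------
    if cache.fresh("outputs", "outputs.csv") and cache.fresh("baseline", "baseline.csv"):
        outputs = pd.read_csv(outdir / "outputs.csv")
        baseline = pd.read_csv(outdir / "baseline.csv")
    else:
        outputs, baseline = _simulate_environments(config, registry, design)
        outputs.to_csv(outdir / "outputs.csv", index=False)
        baseline.to_csv(outdir / "baseline.csv", index=False)
        cache.record("outputs", "outputs.csv")
        cache.record("baseline", "baseline.csv")

    # --- sensitivity indices ---------------------------------------------
    if cache.fresh("indices", "indices.csv"):
        indices = pd.read_csv(outdir / "indices.csv")
    else:
        indices = _compute_indices(design, factor_ids, outputs)
        indices.to_csv(outdir / "indices.csv", index=False)
        cache.record("indices", "indices.csv")

    # --- analysis ----------------------------------------------------------
    yld = indices[indices["output"] == "yield_t_ha"]
    mu_by_env = yld.pivot(index="factor", columns="env_id", values="mu_star")
    mu_by_env = mu_by_env.reindex(factor_ids)
    groups = an.classify_traits(mu_by_env, config.impact_threshold)
    classification = pd.DataFrame({
        "mean_mu_star": mu_by_env.mean(axis=1),
        "max_mu_star": mu_by_env.max(axis=1),
        "group": groups,
    })
    classification.to_csv(outdir / "classification.csv")
    cache.record("classification", "classification.csv")

    impactful = classification.index[classification["group"] == "impactful"].tolist()

    env_meta = env_table.set_index("env_id")
    eta_rows = []
    varying = [c for c in ("site", "sowing_tag", "co2", "n_tag")
               if env_meta[c].nunique() > 1]
    for f in impactful if varying else []:
        y = mu_by_env.loc[f]
        dec = an.eta_squared(y, env_meta.loc[y.index, varying])
        eta_rows.append({"factor": f, **{f"eta2_{k}": v for k, v in dec.eta2.items()},
                         "eta2_residual": dec.residual, "degenerate": dec.degenerate})
    eta2 = pd.DataFrame(eta_rows)
    eta2.to_csv(outdir / "eta2.csv", index=False)
    cache.record("eta2", "eta2.csv")

    clusters = pd.DataFrame()
    if len(impactful) >= 2:
        mat = (indices[indices["factor"].isin(impactful)]
               .groupby(["factor", "output"])["mu_star_std"].mean()
               .unstack("output").reindex(impactful))
        res = an.cluster_impactful(mat, k=min(config.k_clusters, len(mat)))
        clusters = res.labels.to_frame()
        clusters.to_csv(outdir / "clusters.csv")
        (outdir / "dendrogram.txt").write_text(res.to_newick() + "\n")
        cache.record("clusters", "clusters.csv")

    # standardized yield impact vs baseline water stress, per drought type
    reg_rows = []
    base = baseline.set_index("env_id")
    for f in [f for f in REGRESSION_FACTORS if f in set(mu_by_env.index)]:
        data = pd.DataFrame({
            "mu_star_std": yld[yld["factor"] == f].set_index("env_id")["mu_star_std"],
            "stress": base["water_stress_index"],
            "env_type": base["env_type"],
        }).dropna()
        ok = [t for t, sub in data.groupby("env_type")
              if len(sub) >= 3 and np.ptp(sub["stress"].to_numpy()) > 0]
        if not ok:
            continue
        fit = an.stress_regression(data[data["env_type"].isin(ok)])
        fit.insert(0, "factor", f)
        reg_rows.append(fit.reset_index())
    regression = (pd.concat(reg_rows, ignore_index=True)
                  if reg_rows else pd.DataFrame())
    regression.to_csv(outdir / "stress_regression.csv", index=False)
    cache.record("stress_regression", "stress_regression.csv")

    return {
        "design": design.to_frame(factor_ids), "environments": env_table,
        "outputs": outputs, "baseline": baseline, "indices": indices,
        "classification": classification, "eta2": eta2, "clusters": clusters,
        "stress_regression": regression,
    }
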