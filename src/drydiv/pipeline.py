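"""Pipeline orchestration: simulate -> drought -> rings -> neigh -> fit -> report.

Drives the full analysis from a single YAML config, writing every
intermediate artifact as a plain-text table under a run directory, together
with a manifest of content hashes and the resolved config so identical
configs reproduce identical runs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import rings as _rings
from . import synthetic as _syn
from .climate import SoilParams
from .models import (
    ConsecutiveDroughtModel,
    ModelSpec,
    SingleYearDroughtModel,
    compare_models,
    marginal_effects,
)

log = logging.getLogger("drydiv")

__all__ = ["PipelineConfig", "load_config", "validate", "run", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records completed stages."""


@dataclass
class SiteConfig:
    site_id: str
    n_species: int = 4
    hsm_range: tuple[float, float] = (0.8, 1.5)
    richness_levels: tuple[int, ...] = (1, 2, 4)
    spacing_m: float = 1.5
    plot_rows: int = 8
    n_replicates: int = 2
    mortality_rate: float = 0.05
    drought_years: dict[int, str] = field(
        default_factory=lambda: {
            2017: "wet", 2018: "severe", 2019: "moderate", 2020: "moderate", 2021: "wet"
        }
    )


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    sites: list[SiteConfig] = field(default_factory=lambda: [SiteConfig("SIM1")])
    soil: SoilParams = field(default_factory=SoilParams)
    effects: _syn.EffectConfig = field(default_factory=_syn.EffectConfig)
    severe_threshold: float = -1.28
    moderate_threshold: float = -0.5
    rew_stress_threshold: float = 0.4
    models: list[ModelSpec] = field(
        default_factory=lambda: [
            ModelSpec(kind="consecutive", diversity="FD_HSM_norm"),
            ModelSpec(kind="consecutive", diversity="nSR"),
        ]
    )

    def __post_init__(self) -> None:
        if not self.severe_threshold < self.moderate_threshold:
            raise ValueError("thresholds must satisfy severe < moderate")

    def resolved(self) -> dict:
        return {
            "seed": self.seed,
            "sites": [asdict(s) for s in self.sites],
            "soil": asdict(self.soil),
            "effects": {**asdict(self.effects)},
            "thresholds": {
                "severe": self.severe_threshold,
                "moderate": self.moderate_threshold,
                "rew_stress": self.rew_stress_threshold,
            },
            "models": [asdict(m) for m in self.models],
        }


def load_config(path) -> PipelineConfig:
    """Parse the YAML pipeline config (documented keys; all optional)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sites = [
        SiteConfig(
            site_id=s["site_id"],
            n_species=int(s.get("n_species", 4)),
            hsm_range=tuple(s.get("hsm_range", (0.8, 1.5))),
            richness_levels=tuple(s.get("richness_levels", (1, 2, 4))),
            spacing_m=float(s.get("spacing_m", 1.5)),
            plot_rows=int(s.get("plot_rows", 8)),
            n_replicates=int(s.get("n_replicates", 2)),
            mortality_rate=float(s.get("mortality_rate", 0.05)),
            drought_years={int(k): str(v) for k, v in s.get("drought_years", {}).items()}
            or SiteConfig("x").drought_years,
        )
        for s in raw.get("sites", [{"site_id": "SIM1"}])
    ]
    eff_raw = dict(raw.get("effects", {}))
    if "beta_fd" in eff_raw:
        eff_raw["beta_fd"] = {int(k): float(v) for k, v in eff_raw["beta_fd"].items()}
    effects = _syn.EffectConfig(**eff_raw)
    soil = SoilParams(**raw.get("soil", {}))
    th = raw.get("thresholds", {})
    specs = [ModelSpec(**m) for m in raw.get("models", [])] or None
    kwargs = dict(
        seed=int(raw.get("seed", 0)),
        sites=sites,
        soil=soil,
        effects=effects,
        severe_threshold=float(th.get("severe", -1.28)),
        moderate_threshold=float(th.get("moderate", -0.5)),
        rew_stress_threshold=float(th.get("rew_stress", 0.4)),
    )
    if specs is not None:
        kwargs["models"] = specs
    return PipelineConfig(**kwargs)


def validate(config: PipelineConfig) -> list[str]:
    """Schema and cross-reference checks without executing any stage.

    Returns a list of violations (empty when the config is consistent).
    """
    violations: list[str] = []
    seen = set()
    for s in config.sites:
        if s.site_id in seen:
            violations.append(f"duplicate site_id {s.site_id!r}")
        seen.add(s.site_id)
        lo, hi = s.hsm_range
        if not (0 < lo <= hi < 3):
            violations.append(f"{s.site_id}: hsm_range {s.hsm_range} not a valid interval in (0, 3)")
        if not (0 <= s.mortality_rate < 1):
            violations.append(f"{s.site_id}: mortality_rate {s.mortality_rate} outside [0, 1)")
        if max(s.richness_levels) > s.n_species:
            violations.append(
                f"{s.site_id}: richness level {max(s.richness_levels)} exceeds pool of {s.n_species}"
            )
        bad = [v for v in s.drought_years.values() if v not in _syn.SEVERITIES]
        if bad:
            violations.append(f"{s.site_id}: unknown drought severities {bad}")
    for m in config.models:
        if m.kind == "consecutive" and len(config.sites) == 0:
            violations.append(f"model {m.name}: no sites configured")
    return violations


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages and return the manifest.

    Stages run in dependency order per site: synthetic inputs, drought
    indices and calendar, neighborhood covariates, ring simulation and
    response ratios, model fits, and the comparison/marginal-effect report.
    A stage failure halts the run; a partial manifest is still written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.resolved(), "stages": [], "outputs": {}}
    outputs: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        outputs.append(path)
        return path

    def finish_stage(name: str, **counts) -> None:
        manifest["stages"].append({"stage": name, **counts})
        log.info("stage %s done: %s", name, counts)

    try:
        model_tables: dict[str, pd.DataFrame] = {}
        single_year_rows = []
        for i, site in enumerate(config.sites):
            sc = _syn.build_experiment(
                seed=int(np.random.default_rng((config.seed, i)).integers(0, 2**31 - 1)),
                n_species=site.n_species,
                hsm_range=site.hsm_range,
                richness_levels=site.richness_levels,
                mortality_rate=site.mortality_rate,
                site_id=site.site_id,
                drought_spec=site.drought_years,
                soil=config.soil,
                spacing_m=site.spacing_m,
                plot_rows=site.plot_rows,
                n_replicates=site.n_replicates,
            )
            sid = site.site_id
            # --- simulate stage artifacts
            emit(f"{sid}_traits.tsv", lambda p: _write_tsv(sc.traits, p))
            emit(f"{sid}_stem_map.tsv", lambda p: _write_tsv(sc.stem_map, p))
            emit(f"{sid}_climate.tsv", lambda p: sc.climate.to_tsv(p))
            finish_stage(
                f"simulate[{sid}]",
                n_trees=len(sc.stem_map),
                n_focal=int(sc.stem_map["focal"].sum()),
            )
            # --- drought stage
            emit(
                f"{sid}_drought_covariates.tsv",
                lambda p: _write_tsv(sc.drought_covariates.reset_index(), p),
            )
            emit(f"{sid}_calendar.tsv", lambda p: _write_tsv(sc.calendar.to_frame(), p))
            if sc.calendar.empty:
                raise PipelineError(f"{sid}: {sc.calendar.status}")
            finish_stage(f"drought[{sid}]", resp_years=len(sc.calendar.resp_years))
            # --- neighborhood stage
            emit(f"{sid}_covariates.tsv", lambda p: _write_tsv(sc.covariates, p))
            finish_stage(f"neigh[{sid}]", n_focal=len(sc.covariates))
            # --- rings stage: simulate series, write rwl + density, responses
            fd = dict(zip(sc.covariates["tree_id"], sc.covariates["FD_HSM_norm"]))
            series = _syn.simulate_ring_series(
                sc.stem_map,
                sc.traits,
                sc.rew_by_year,
                fd,
                config.effects,
                resp_label_by_year=sc.resp_label_by_year,
                rng=np.random.default_rng((config.seed, i, 1)),
            )
            emit(f"{sid}_rings.rwl", lambda p: _rings.write_rwl(series, p))
            emit(f"{sid}_density.tsv", lambda p: _rings.write_density_table(series, p))
            records = []
            for s in series:
                records.extend(_rings.growth_response(s, sc.calendar, metric="BIOMinc"))
            resp = _rings.response_table(records)
            n_excluded = int(resp["excluded"].sum())
            resp = resp[~resp["excluded"]]
            table = resp.merge(
                sc.covariates[
                    ["tree_id", "site_id", "plot_id", "species_code", "nSR",
                     "FD_HSM_norm", "HSM_TLP", "BA_z", "Hegyi_z"]
                ],
                on="tree_id",
            )
            emit(f"{sid}_responses.tsv", lambda p: _write_tsv(table, p))
            model_tables[sid] = table
            finish_stage(f"rings[{sid}]", n_series=len(series), n_responses=len(table), n_excluded=n_excluded)
            # rows for a cross-site single-year table
            yr1 = table[table["resp_yr"] == 1].copy()
            cov = sc.drought_covariates.loc[sc.calendar.year_of(1)]
            prev = sc.drought_covariates.loc[sc.calendar.year_of(1) - 1]
            for c in ("SPEI12", "SPEI6_AprSep", "REWmin", "DrDays_12m", "DrDays_AprSep"):
                yr1[c] = float(cov[c])
                yr1[f"prev_{c}"] = float(prev[c])
            yr1["age_z"] = 0.0  # equal-aged planting within site
            single_year_rows.append(yr1)

        # --- fit stage
        fits = {}
        single_df = pd.concat(single_year_rows, ignore_index=True) if single_year_rows else None
        for spec in config.models:
            if spec.kind == "consecutive":
                for sid, table in model_tables.items():
                    name = f"{spec.name}_{sid}"
                    fit = ConsecutiveDroughtModel(table, spec).fit()
                    fits[name] = fit
                    emit(
                        f"fit_{name}_coefficients.tsv",
                        lambda p, f=fit: _write_tsv(f.coefficient_table().reset_index(names="term"), p),
                    )
                    emit(
                        f"fit_{name}.json",
                        lambda p, f=fit: p.write_text(
                            json.dumps(
                                {**f.metadata, "aic": f.aic,
                                 "r2_marginal": f.r2()[0], "r2_conditional": f.r2()[1],
                                 "variance_components": f.variance_components},
                                indent=2, sort_keys=True,
                            )
                        ),
                    )
            else:
                if single_df is None or len(config.sites) < 2:
                    log.warning("skipping %s: single-year models need >= 2 sites", spec.name)
                    continue
                name = spec.name
                fit = SingleYearDroughtModel(single_df, spec).fit()
                fits[name] = fit
                emit(
                    f"fit_{name}_coefficients.tsv",
                    lambda p, f=fit: _write_tsv(f.coefficient_table().reset_index(names="term"), p),
                )
        finish_stage("fit", n_models=len(fits))

        # --- report stage
        by_data: dict[str, list] = {}
        for name, f in fits.items():
            key = hashlib.sha256(
                np.sort(f.model.data["log_response"].to_numpy()).tobytes()
            ).hexdigest()[:12]
            by_data.setdefault(key, []).append(f)
        comp_frames = []
        for group in by_data.values():
            if len(group) > 1:
                comp_frames.append(compare_models(group))
        if comp_frames:
            emit("model_comparison.tsv", lambda p: _write_tsv(pd.concat(comp_frames), p))
        for name, f in fits.items():
            grid = {f.model.spec.diversity: [0.0, 0.3, 0.6] if f.model.spec.diversity != "nSR" else [1, 2, 4]}
            if f.model.spec.kind == "consecutive":
                grid["resp_yr"] = sorted(f.model.data["resp_yr"].unique())
            grid["HSM_TLP"] = [0.8, 1.5]
            me = marginal_effects(f, grid)
            emit(f"marginal_{name}.tsv", lambda p, me=me: _write_tsv(me, p))
        finish_stage("report", n_tables=len(fits))
    except Exception as exc:
        manifest["error"] = str(exc)
        for p in outputs:
            manifest["outputs"][p.name] = _sha256(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise PipelineError(f"pipeline halted: {exc}") from exc

    for p in outputs:
        manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
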