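"""Synthetic multi-site tree-diversity experiment generator.

Generates every input the analysis pipeline consumes -- species trait
tables, planted stem maps, site climate series, and per-tree ring series --
from a known ground-truth effect structure, so that drought indexing,
ring processing, neighborhood metrics and the mixed models can all be tested
end to end without field data.

The design emulates a network of planted diversity experiments: a
species-richness gradient realized as replicated square planting grids
(monocultures through mixtures), focal trees picked near plot centers with
intact first-order neighborhoods, and a scripted multiyear drought
(severe year, consecutive moderate years, wet post-drought year).

Ground truth: the log radial biomass increment of tree i in year t is

    log G_it = mu_s + alpha*log(age_it) + gamma_BA*z(BA_i)
               + (theta0 + thetaH*HSM_s) * S_t
               + beta_FD(yr_t) * FD_i
               + u_site + u_plot + u_tree + eps_it

with drought severity S_t = max(0, (0.4 - REWmin_t)/0.4), species hydraulic
safety margin HSM_s, neighborhood functional diversity FD_i (min-max
normalized), and beta_FD a response-year-dependent diversity effect that is
zero before the drought. Ring width is recovered from the simulated biomass
increment through ring density and the basal-area geometry, so the series
round-trip exactly through the ring-processing module.

The growth-generating process is an explicit modelling assumption of this
generator (field studies measure growth; they do not specify its generator);
it encodes the response structure the inference layer assumes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import climate as _climate
from . import neighborhood as _neigh
from . import rings as _rings
from .climate import (
    ClimateSeries,
    SoilParams,
    build_calendar,
    classify_drought_years,
    monthly_to_daily,
    rew_bucket,
    rew_summaries,
    spei,
    water_balance,
)
from .rings import RingSeries

__all__ = [
    "SpeciesTraits",
    "SiteDesign",
    "TreeRecord",
    "EffectConfig",
    "ClimateGenParams",
    "generate_species_pool",
    "generate_site",
    "generate_climate",
    "simulate_ring_series",
    "drought_severity",
    "ExperimentScaffold",
    "build_experiment",
    "simulate_consecutive_responses",
    "truth_consecutive_coefficients",
    "stem_map_frame",
    "traits_frame",
]

SEVERITIES = ("normal", "moderate", "severe", "wet")


@dataclass(frozen=True)
class SpeciesTraits:
    """Species-mean hydraulic and wood traits.

    TLP and P50 are negative water potentials (MPa) with P50 < TLP, so the
    hydraulic safety margin TLP - P50 is positive; wood density in kg m^-3.
    """

    species_code: str
    TLP: float
    P50: float
    wood_density_mean: float
    wood_density_sd: float

    def __post_init__(self) -> None:
        if not (self.P50 < self.TLP < 0):
            raise ValueError(
                f"{self.species_code}: need P50 < TLP < 0, got P50={self.P50}, TLP={self.TLP}"
            )
        if self.wood_density_mean <= 0:
            raise ValueError(f"{self.species_code}: non-positive wood density")

    @property
    def hsm(self) -> float:
        return _neigh.hsm_from_traits(self.TLP, self.P50)


@dataclass
class SiteDesign:
    """Layout of one experimental site.

    ``compositions`` lists the species mixtures planted (tuples of species
    codes); each is replicated ``n_replicates`` times as a square grid plot
    of ``plot_rows`` x ``plot_rows`` planting positions at ``spacing_m``.
    """

    site_id: str
    species_pool: list[SpeciesTraits]
    compositions: list[tuple[str, ...]]
    n_replicates: int = 2
    spacing_m: float = 1.5
    plot_rows: int = 8
    neighborhood_radius_m: float = 1.5
    planting_year: int = 2009

    def __post_init__(self) -> None:
        if self.spacing_m <= 0:
            raise ValueError("spacing must be positive")
        pool_codes = {s.species_code for s in self.species_pool}
        for comp in self.compositions:
            unknown = set(comp) - pool_codes
            if unknown:
                raise ValueError(f"composition {comp} references unknown species {sorted(unknown)}")
        monos = {comp[0] for comp in self.compositions if len(comp) == 1}
        used = set(itertools.chain.from_iterable(self.compositions))
        if not used <= monos | (used - monos):
            raise ValueError("invalid composition set")

    @property
    def richness_levels(self) -> list[int]:
        return sorted({len(c) for c in self.compositions})


def default_compositions(
    pool: list[SpeciesTraits], richness_levels: tuple[int, ...] = (1, 2, 4)
) -> list[tuple[str, ...]]:
    """Monocultures of every species plus systematic mixtures per level.

    Mixtures at level k are contiguous blocks of the (trait-sorted) pool,
    stepped so every species appears in at least one mixture.
    """
    codes = [s.species_code for s in sorted(pool, key=lambda s: s.hsm)]
    n = len(codes)
    comps: list[tuple[str, ...]] = [(c,) for c in codes]
    for k in richness_levels:
        if k <= 1 or k > n:
            continue
        step = 1 if k == 2 else k
        starts = range(0, n, step)
        seen = set()
        for s0 in starts:
            comp = tuple(codes[(s0 + j) % n] for j in range(k))
            key = tuple(sorted(comp))
            if key not in seen:
                seen.add(key)
                comps.append(comp)
    return comps


@dataclass
class TreeRecord:
    """One planted tree in the stem map."""

    tree_id: str
    site_id: str
    plot_id: str
    species_code: str
    x_m: float
    y_m: float
    ba_mm2: float
    alive: bool
    focal: bool
    planting_year: int


def stem_map_frame(trees: list[TreeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tree_id": t.tree_id,
                "site_id": t.site_id,
                "plot_id": t.plot_id,
                "species_code": t.species_code,
                "x_m": t.x_m,
                "y_m": t.y_m,
                "ba_mm2": t.ba_mm2,
                "alive": t.alive,
                "focal": t.focal,
                "planting_year": t.planting_year,
            }
            for t in trees
        ]
    )


def traits_frame(pool: list[SpeciesTraits]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_code": s.species_code,
                "TLP": s.TLP,
                "P50": s.P50,
                "wood_density_mean": s.wood_density_mean,
                "wood_density_sd": s.wood_density_sd,
                "HSM_TLP": s.hsm,
            }
            for s in pool
        ]
    )


def generate_species_pool(
    n_species: int,
    hsm_range: tuple[float, float] = (0.8, 1.5),
    seed: int = 0,
) -> list[SpeciesTraits]:
    """Species pool whose hydraulic safety margins span ``hsm_range``.

    Margins are evenly spaced with the range endpoints assigned (a single
    species sits at the midpoint); TLP and wood density are drawn from
    plausible ranges, and P50 = TLP - HSM. Deterministic given the seed.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    lo, hi = hsm_range
    if not (0 < lo <= hi < 3):
        raise ValueError(f"hsm_range must be a non-inverted interval within (0, 3), got {hsm_range}")
    rng = np.random.default_rng(seed)
    if n_species == 1:
        hsms = np.array([(lo + hi) / 2.0])
    else:
        hsms = np.linspace(lo, hi, n_species)
    pool = []
    for i, h in enumerate(hsms):
        tlp = float(rng.uniform(-2.8, -1.8))
        pool.append(
            SpeciesTraits(
                species_code=f"SP{i + 1:02d}",
                TLP=tlp,
                P50=tlp - float(h),
                wood_density_mean=float(rng.uniform(380.0, 620.0)),
                wood_density_sd=25.0,
            )
        )
    return pool


def generate_site(
    design: SiteDesign, mortality_rate: float = 0.05, seed: int = 0
) -> tuple[list[TreeRecord], pd.DataFrame]:
    """Plant the site and select focal trees.

    Trees are planted on square grids at the design spacing, species assigned
    by balanced random permutation within each plot. Mortality is random
    (drought-linked mortality is out of scope); dead trees stay in the map
    flagged dead. Focal trees are living interior trees (more than one
    planting distance from the plot edge) whose four first-order neighbors
    are all alive, closest to the plot center first, up to 10 per species x
    composition across that composition's replicate plots.

    Returns (tree records, focal-selection report). Compositions whose focal
    quota could not be filled appear in the report (and a warning is raised
    for compositions with no focal trees at all).
    """
    if not (0 <= mortality_rate < 1):
        raise ValueError("mortality_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = design.plot_rows
    trees: list[TreeRecord] = []
    # plot_key -> grid of indices into `trees`
    grids: dict[str, np.ndarray] = {}
    plot_comp: dict[str, tuple[str, ...]] = {}
    counter = 0
    for ci, comp in enumerate(design.compositions):
        for rep in range(design.n_replicates):
            plot_id = f"{design.site_id}-c{ci:02d}r{rep}"
            plot_comp[plot_id] = comp
            slots = n * n
            species_vec = np.array([comp[j % len(comp)] for j in range(slots)])
            rng.shuffle(species_vec)
            grid = np.empty((n, n), dtype=int)
            for row in range(n):
                for col in range(n):
                    sp = species_vec[row * n + col]
                    alive = rng.random() >= mortality_rate
                    ba = float(np.exp(rng.normal(np.log(3000.0), 0.30))) if alive else 0.0
                    trees.append(
                        TreeRecord(
                            tree_id=f"T{counter:05d}",
                            site_id=design.site_id,
                            plot_id=plot_id,
                            species_code=str(sp),
                            x_m=col * design.spacing_m,
                            y_m=row * design.spacing_m,
                            ba_mm2=ba if alive else np.nan,
                            alive=alive,
                            focal=False,
                            planting_year=design.planting_year,
                        )
                    )
                    grid[row, col] = counter
                    counter += 1
            grids[plot_id] = grid

    # focal selection, quota per species x composition shared across replicates
    report_rows = []
    center = (n - 1) / 2.0
    for ci, comp in enumerate(design.compositions):
        plot_ids = [f"{design.site_id}-c{ci:02d}r{rep}" for rep in range(design.n_replicates)]
        for sp in comp:
            candidates = []  # (distance to center, tree index)
            for plot_id in plot_ids:
                grid = grids[plot_id]
                for row in range(1, n - 1):
                    for col in range(1, n - 1):
                        t = trees[grid[row, col]]
                        if t.species_code != sp or not t.alive:
                            continue
                        nbrs_alive = all(
                            trees[grid[r2, c2]].alive
                            for r2, c2 in ((row - 1, col), (row + 1, col), (row, col - 1), (row, col + 1))
                        )
                        if not nbrs_alive:
                            continue
                        d = np.hypot(row - center, col - center)
                        candidates.append((d, grid[row, col]))
            candidates.sort()
            chosen = [idx for _, idx in candidates[:10]]
            for idx in chosen:
                trees[idx].focal = True
            report_rows.append(
                {
                    "composition": "+".join(comp),
                    "species_code": sp,
                    "n_candidates": len(candidates),
                    "n_focal": len(chosen),
                }
            )
            if not chosen:
                warnings.warn(
                    f"{design.site_id}: no focal trees for species {sp} in composition {'+'.join(comp)}",
                    RuntimeWarning,
                    stacklevel=2,
                )
    return trees, pd.DataFrame(report_rows)


# ---------------------------------------------------------------------------
# Climate generation
# ---------------------------------------------------------------------------

@dataclass
class ClimateGenParams:
    """Baseline monthly climate of the synthetic sites.

    Precipitation: gamma-distributed around a mildly seasonal mean (winter
    peak); PET: strongly seasonal (July peak) with small noise. Drought/wet
    years are realized by rescaling that year's precipitation so its annual
    climatic water balance lands at a target anomaly in the SPEI band the
    severity demands (severe < -1.28, moderate in [-1.28, -0.5), wet >= 0.9
    on the standardized scale).
    """

    p_mean_mm: float = 70.0
    p_season_amp_mm: float = 12.0
    p_cv: float = 0.30
    pet_mean_mm: float = 60.0
    pet_season_amp_mm: float = 45.0
    pet_noise_mm: float = 4.0
    severe_band: tuple[float, float] = (-2.4, -1.8)
    moderate_band: tuple[float, float] = (-1.05, -0.72)
    wet_band: tuple[float, float] = (1.0, 1.6)


def generate_climate(
    site_id: str,
    year_span: tuple[int, int] = (1991, 2021),
    drought_spec: dict[int, str] | None = None,
    seed: int = 0,
    params: ClimateGenParams | None = None,
) -> ClimateSeries:
    """Monthly site climate with scripted drought/wet years.

    ``drought_spec`` maps calendar years to a severity in
    {normal, moderate, severe, wet}; unlisted years are normal. A severe
    year is additionally forced below every normal year's annual water
    balance, so a single scripted severe year is the driest of the series by
    construction. Spans shorter than 31 years trigger a warning (the SPEI
    reference period needs 31 years).
    """
    drought_spec = dict(drought_spec or {})
    params = params or ClimateGenParams()
    for y, sev in drought_spec.items():
        if sev not in SEVERITIES:
            raise ValueError(f"severity {sev!r} for year {y}: expected one of {SEVERITIES}")
    y0, y1 = year_span
    n_years = y1 - y0 + 1
    if n_years < 31:
        warnings.warn(
            f"{site_id}: span of {n_years} years is shorter than the 31-year reference period",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    months = np.arange(1, 13)
    p_mu = params.p_mean_mm + params.p_season_amp_mm * np.cos(2 * np.pi * (months - 1) / 12.0)
    pet_mu = np.maximum(
        params.pet_mean_mm + params.pet_season_amp_mm * np.sin(2 * np.pi * (months - 4.0) / 12.0),
        2.0,
    )
    rows = []
    for y in range(y0, y1 + 1):
        shape = 1.0 / params.p_cv**2
        p = rng.gamma(shape, p_mu / shape)
        pet = np.maximum(pet_mu + rng.normal(0.0, params.pet_noise_mm, 12), 0.5)
        for m in months:
            rows.append((y, int(m), float(p[m - 1]), float(pet[m - 1])))
    df = pd.DataFrame(rows, columns=["year", "month", "P_mm", "PET_mm"])

    annual = df.groupby("year").apply(
        lambda g: g["P_mm"].sum() - g["PET_mm"].sum(), include_groups=False
    )
    normal_years = [y for y in annual.index if drought_spec.get(y, "normal") == "normal"]
    mu = float(annual.loc[normal_years].mean())
    sd = float(annual.loc[normal_years].std(ddof=1))
    z_min_normal = float((annual.loc[normal_years].min() - mu) / sd)
    for y, sev in drought_spec.items():
        if sev == "normal":
            continue
        band = {
            "severe": params.severe_band,
            "moderate": params.moderate_band,
            "wet": params.wet_band,
        }[sev]
        z = float(rng.uniform(*band))
        if sev == "severe":
            # force the severe year below every normal year's balance
            z = max(min(z, z_min_normal - 0.2), -3.2)
        target = mu + z * sd
        mask = df["year"] == y
        p_year = float(df.loc[mask, "P_mm"].sum())
        pet_year = float(df.loc[mask, "PET_mm"].sum())
        scale = (target + pet_year) / p_year
        df.loc[mask, "P_mm"] *= max(scale, 0.02)
    return ClimateSeries(site_id, df)


# ---------------------------------------------------------------------------
# Growth simulation
# ---------------------------------------------------------------------------

def drought_severity(rew_min: float, threshold: float = 0.4) -> float:
    """Map minimum growing-season REW to a [0, 1] stress index.

    0 when REW stays at or above the 0.4 stress threshold, rising linearly
    to 1 when REW reaches the wilting point (0) or below.
    """
    return float(min(max((threshold - rew_min) / threshold, 0.0), 1.0))


@dataclass
class EffectConfig:
    """Ground-truth effect sizes for the growth simulator (log scale).

    beta_fd maps response-year labels (1-4) to the diversity effect; the
    pre-drought diversity effect is zero by construction. Variances are the
    site / plot / tree random-intercept and residual components.
    """

    mu_species: dict[str, float] | float = np.log(0.2)
    alpha_age: float = 0.30
    gamma_ba: float = 0.10
    theta0: float = -0.40
    theta_hsm: float = 0.20
    beta_fd: dict[int, float] = field(default_factory=lambda: {1: 0.0, 2: 0.0, 3: -0.3, 4: 0.0})
    sigma2_site: float = 0.01
    sigma2_plot: float = 0.005
    sigma2_tree: float = 0.01
    sigma2_resid: float = 0.0144
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_site", "sigma2_plot", "sigma2_tree", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def mu_of(self, species: str) -> float:
        if isinstance(self.mu_species, dict):
            return self.mu_species[species]
        return float(self.mu_species)

    def null(self) -> "EffectConfig":
        """Copy with every effect and variance component zeroed (pure intercept)."""
        return replace(
            self,
            alpha_age=0.0,
            gamma_ba=0.0,
            theta0=0.0,
            theta_hsm=0.0,
            beta_fd={k: 0.0 for k in self.beta_fd},
            sigma2_site=0.0,
            sigma2_plot=0.0,
            sigma2_tree=0.0,
            sigma2_resid=0.0,
        )


def simulate_ring_series(
    trees: pd.DataFrame,
    traits: pd.DataFrame,
    rew_by_year: dict[int, float],
    fd_by_tree: dict[str, float],
    config: EffectConfig,
    resp_label_by_year: dict[int, int] | None = None,
    years: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> list[RingSeries]:
    """Simulate per-tree annual ring series from the ground-truth model.

    ``trees`` is a stem-map frame (simulation restricted to focal trees);
    ``rew_by_year`` gives the minimum growing-season REW per calendar year
    (missing years are treated as unstressed); ``fd_by_tree`` the normalized
    neighborhood functional diversity; ``resp_label_by_year`` maps calendar
    years to response-year labels 1-4 for the diversity-effect trajectory.

    Biomass increment is generated on the log scale, converted to BAI via a
    per-ring density draw (species mean + noise, floored at 50 kg m^-3), and
    to ring width via the basal-area geometry, so TRW -> BAI -> BIOMinc
    round-trips through the ring module.
    """
    rng = rng or np.random.default_rng(config.seed)
    resp_label_by_year = resp_label_by_year or {}
    trait_idx = traits.set_index("species_code")
    focal = trees[trees["focal"].astype(bool)].copy()

    # z-scored basal area within site x species (the generator's size covariate)
    def _z(g):
        s = g.std(ddof=1)
        if not np.isfinite(s) or s == 0:
            return pd.Series(0.0, index=g.index)
        return (g - g.mean()) / s

    focal["ba_z"] = focal.groupby(["site_id", "species_code"], group_keys=False)["ba_mm2"].apply(_z)

    u_site = {s: rng.normal(0, np.sqrt(config.sigma2_site)) for s in focal["site_id"].unique()}
    u_plot = {p: rng.normal(0, np.sqrt(config.sigma2_plot)) for p in focal["plot_id"].unique()}

    out: list[RingSeries] = []
    for _, t in focal.iterrows():
        plant = int(t["planting_year"])
        y_first = plant + 1 if years is None else years[0]
        y_last = max(rew_by_year) if years is None else years[1]
        if plant >= y_first:
            raise ValueError(f"tree {t['tree_id']}: planting year {plant} >= first ring year {y_first}")
        yrs = np.arange(y_first, y_last + 1)
        u_tree = rng.normal(0, np.sqrt(config.sigma2_tree))
        hsm = float(trait_idx.loc[t["species_code"], "HSM_TLP"])
        dens_mu = float(trait_idx.loc[t["species_code"], "wood_density_mean"])
        dens_sd = float(trait_idx.loc[t["species_code"], "wood_density_sd"])
        fd = float(fd_by_tree.get(t["tree_id"], 0.0))
        logg = np.empty(yrs.size)
        density = np.empty(yrs.size)
        for j, y in enumerate(yrs):
            age = y - plant
            s_t = drought_severity(rew_by_year.get(int(y), 1.0))
            beta = config.beta_fd.get(resp_label_by_year.get(int(y), 0), 0.0)
            eps = rng.normal(0, np.sqrt(config.sigma2_resid))
            logg[j] = (
                config.mu_of(t["species_code"])
                + config.alpha_age * np.log(age)
                + config.gamma_ba * float(t["ba_z"])
                + (config.theta0 + config.theta_hsm * hsm) * s_t
                + beta * fd
                + u_site[t["site_id"]]
                + u_plot[t["plot_id"]]
                + u_tree
                + eps
            )
            d = rng.normal(dens_mu, dens_sd)
            while d < 50.0:
                d = rng.normal(dens_mu, dens_sd)
            density[j] = d
        g = np.exp(logg)
        if not np.all(np.isfinite(g)):
            raise ValueError(f"tree {t['tree_id']}: non-finite simulated growth")
        bai = g / (density * 1e-6)  # kg m^-1 -> mm^2 via kg m^-3 density
        radius = np.sqrt(np.cumsum(bai) / np.pi)
        trw = np.diff(np.concatenate([[0.0], radius]))
        out.append(
            RingSeries(
                tree_id=str(t["tree_id"]),
                years=yrs,
                trw=trw,
                density=density,
                pith_offset=0.0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end in-memory experiment (scaffold + replicated response draws)
# ---------------------------------------------------------------------------

@dataclass
class ExperimentScaffold:
    """Fixed design of one simulated site: everything except the growth noise.

    Holds the stem map, traits, standardized neighborhood covariates, the
    drought calendar with REW covariates, and the year -> stress-index map.
    Replicated growth simulations redraw only the ring series and responses.
    """

    site_id: str
    design: SiteDesign
    pool: list[SpeciesTraits]
    stem_map: pd.DataFrame
    traits: pd.DataFrame
    covariates: pd.DataFrame
    calendar: _climate.DroughtCalendar
    rew_by_year: dict[int, float]
    resp_label_by_year: dict[int, int]
    climate: ClimateSeries
    spei12: _climate.SpeiSeries
    spei6: _climate.SpeiSeries
    drought_covariates: pd.DataFrame


def build_experiment(
    seed: int = 0,
    n_species: int = 6,
    hsm_range: tuple[float, float] = (0.8, 1.5),
    richness_levels: tuple[int, ...] = (1, 2, 3, 6),
    mortality_rate: float = 0.05,
    site_id: str = "SIM1",
    drought_spec: dict[int, str] | None = None,
    soil: SoilParams | None = None,
    spacing_m: float = 1.5,
    plot_rows: int = 8,
    n_replicates: int = 2,
) -> ExperimentScaffold:
    """Build the fixed part of a synthetic single-site experiment.

    Defaults give roughly 300 focal trees on a 1-6 species-richness gradient
    under a 2018 severe / 2019-2020 moderate / 2021 wet drought script, the
    multiyear-drought conditions the consecutive-year models target.
    """
    rng_seed = np.random.default_rng(seed)
    sub = [int(s) for s in rng_seed.integers(0, 2**31 - 1, size=4)]
    # 2017 scripted wet: emulates the study design's requirement that a
    # qualifying normal/wet pre-drought reference year exists at every site
    drought_spec = drought_spec or {
        2017: "wet", 2018: "severe", 2019: "moderate", 2020: "moderate", 2021: "wet"
    }

    pool = generate_species_pool(n_species, hsm_range, seed=sub[0])
    design = SiteDesign(
        site_id=site_id,
        species_pool=pool,
        compositions=default_compositions(pool, richness_levels),
        n_replicates=n_replicates,
        spacing_m=spacing_m,
        plot_rows=plot_rows,
        neighborhood_radius_m=1.5 if spacing_m <= 2.0 else 2.9,
    )
    trees, _ = generate_site(design, mortality_rate=mortality_rate, seed=sub[1])
    stem_map = stem_map_frame(trees)
    traits = traits_frame(pool)

    clim = generate_climate(site_id, (1991, 2021), drought_spec, seed=sub[2])
    D = water_balance(clim)
    spei12 = spei(D, k=12, end_month=12)
    spei6 = spei(D, k=6, end_month=9)
    rew = rew_bucket(monthly_to_daily(clim), soil or SoilParams())
    cov_rows = {}
    for y in clim.years:
        rew_min, dr12, drgs = rew_summaries(rew, int(y))
        cov_rows[int(y)] = {
            "SPEI12": float(spei12.values.get(y, np.nan)),
            "SPEI6_AprSep": float(spei6.values.get(y, np.nan)),
            "REWmin": rew_min,
            "DrDays_12m": dr12,
            "DrDays_AprSep": drgs,
        }
    drought_cov = pd.DataFrame.from_dict(cov_rows, orient="index").rename_axis("year")
    # A single reference year keeps the mapping from the generator's effects
    # to the consecutive-model coefficients exact (the log response ratio is
    # then a plain difference of log growths).
    calendar = build_calendar(
        spei12, drought_cov, focus_span=(2017, 2021), site_id=site_id, max_reference_years=1
    )

    metrics = _neigh.neighborhood_metrics(
        stem_map, traits, {site_id: design.neighborhood_radius_m}
    )
    covariates = _neigh.normalize_and_standardize(metrics)

    rew_by_year = {y: r["REWmin"] for y, r in drought_cov.iterrows()}
    resp_label_by_year = {y: r for r, y in calendar.resp_years.items()}
    return ExperimentScaffold(
        site_id=site_id,
        design=design,
        pool=pool,
        stem_map=stem_map,
        traits=traits,
        covariates=covariates,
        calendar=calendar,
        rew_by_year=rew_by_year,
        resp_label_by_year=resp_label_by_year,
        climate=clim,
        spei12=spei12,
        spei6=spei6,
        drought_covariates=drought_cov,
    )


def simulate_consecutive_responses(
    scaffold: ExperimentScaffold,
    config: EffectConfig,
    seed: int | None = None,
    metric: str = "BIOMinc",
) -> pd.DataFrame:
    """One replicate of the full response dataset for the consecutive model.

    Simulates ring series for every focal tree under ``config``, pushes them
    through the Lloret response computation against the scaffold's drought
    calendar, and joins the standardized neighborhood covariates. Returns a
    long table with one row per tree x response year (log_response, resp_yr,
    FD_HSM_norm, nSR, HSM_TLP, BA_z, Hegyi_z, tree_id).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fd = dict(zip(scaffold.covariates["tree_id"], scaffold.covariates["FD_HSM_norm"]))
    series = simulate_ring_series(
        scaffold.stem_map,
        scaffold.traits,
        scaffold.rew_by_year,
        fd,
        config,
        resp_label_by_year=scaffold.resp_label_by_year,
        rng=rng,
    )
    records = []
    for s in series:
        records.extend(_rings.growth_response(s, scaffold.calendar, metric=metric))
    resp = _rings.response_table(records)
    resp = resp[~resp["excluded"]]
    cov = scaffold.covariates[
        ["tree_id", "site_id", "plot_id", "species_code", "nSR", "FD_HSM_norm", "HSM_TLP", "BA_z", "Hegyi_z"]
    ]
    return resp.merge(cov, on="tree_id", how="inner")


def truth_consecutive_coefficients(
    scaffold: ExperimentScaffold, config: EffectConfig, diversity: str = "FD_HSM_norm"
) -> dict[str, float]:
    """Ground-truth fixed effects implied by ``config`` for the consecutive model.

    With a single pre-drought reference year the log response ratio is
    log G(year_r) - log G(ref), so the year-level intercept absorbs the age
    trend and the mean-trait drought term, the (centered-)HSM-by-year
    coefficients are theta_hsm * (S_r - S_ref), the diversity-by-year
    coefficients are beta_fd(r), and size, competition and the
    diversity-HSM interaction are zero. Keys follow the fitted model's
    term names (HSM centered at the focal-tree sample mean).
    """
    ref_years = scaffold.calendar.reference_years
    plant = int(scaffold.stem_map["planting_year"].iloc[0])
    s_ref = float(np.mean([drought_severity(scaffold.rew_by_year[y]) for y in ref_years]))
    log_age_ref = float(np.mean([np.log(y - plant) for y in ref_years]))
    hsm_mean = float(scaffold.covariates["HSM_TLP"].mean())
    hsm_term = "center(HSM_TLP)"
    truth: dict[str, float] = {"BA_z": 0.0, "Hegyi_z": 0.0, f"{diversity}:{hsm_term}": 0.0}
    for r, y in scaffold.calendar.resp_years.items():
        s_y = drought_severity(scaffold.rew_by_year[y])
        truth[f"C(resp_yr)[{r}]"] = (
            config.alpha_age * (np.log(y - plant) - log_age_ref)
            + (config.theta0 + config.theta_hsm * hsm_mean) * (s_y - s_ref)
        )
        truth[f"C(resp_yr)[{r}]:{hsm_term}"] = config.theta_hsm * (s_y - s_ref)
        truth[f"C(resp_yr)[{r}]:{diversity}"] = config.beta_fd.get(r, 0.0)
    return truth
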