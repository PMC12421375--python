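"""Focal-tree neighborhoods: competition, richness, and trait diversity.

Neighborhoods are all living trees within a fixed radius of a focal tree
(the radius encodes the site's planting density: 2.9 m for wide spacings,
1.5 m for narrow ones). From the stem map and a species trait table this
module computes:

* the hydraulic safety margin HSM_TLP = TLP - P50 of each species, the
  stomatal-closure-to-cavitation buffer used as the drought-tolerance trait;
* the distance-dependent Hegyi competition index
  sum_j (BA_j / BA_i) / d_ij;
* realized neighborhood species richness (nSR), counting the focal species;
* the abundance-weighted functional dispersion of HSM_TLP (FDis): mean
  basal-area-weighted distance of member species' trait values to the
  weighted trait centroid;
* the covariate standardizations used by the growth-response models
  (basal area z-scored within site x species, Hegyi z-scored within site,
  FDis min-max normalized across all sites).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "hsm_from_traits",
    "find_neighbors",
    "hegyi",
    "neighborhood_species_richness",
    "functional_dispersion",
    "neighborhood_metrics",
    "normalize_and_standardize",
]

STEM_MAP_COLUMNS = [
    "tree_id", "site_id", "plot_id", "species_code", "x_m", "y_m",
    "ba_mm2", "alive", "focal",
]


def hsm_from_traits(tlp: float, p50: float) -> float:
    """Hydraulic safety margin HSM_TLP = TLP - P50 (MPa, positive).

    Both water potentials are negative; a species is hydraulically safer the
    earlier its stomata close (TLP) relative to xylem cavitation (P50), so a
    valid margin requires P50 < TLP.
    """
    if p50 >= tlp:
        raise ValueError(f"non-positive hydraulic safety margin: P50={p50} >= TLP={tlp}")
    return tlp - p50


@dataclass
class Neighbor:
    tree_id: str
    species_code: str
    ba_mm2: float
    distance_m: float


def find_neighbors(stem_map: pd.DataFrame, focal_id: str, radius: float) -> list[Neighbor]:
    """All living trees within ``radius`` metres of the focal tree.

    Distances are Euclidean in plot coordinates; the search is restricted to
    the focal tree's plot (plots are spatially independent units).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rows = stem_map[stem_map["tree_id"] == focal_id]
    if rows.empty:
        raise KeyError(f"focal tree {focal_id!r} not in stem map")
    focal = rows.iloc[0]
    plot = stem_map[
        (stem_map["site_id"] == focal["site_id"]) & (stem_map["plot_id"] == focal["plot_id"])
    ]
    dx = plot["x_m"].to_numpy() - float(focal["x_m"])
    dy = plot["y_m"].to_numpy() - float(focal["y_m"])
    dist = np.hypot(dx, dy)
    mask = (dist <= radius) & plot["alive"].to_numpy().astype(bool) & (
        plot["tree_id"].to_numpy() != focal_id
    )
    return [
        Neighbor(str(t), str(sp), float(ba), float(d))
        for t, sp, ba, d in zip(
            plot["tree_id"].to_numpy()[mask],
            plot["species_code"].to_numpy()[mask],
            plot["ba_mm2"].to_numpy()[mask],
            dist[mask],
        )
    ]


def hegyi(focal_ba: float, neighbors: list[tuple[float, float]]) -> float:
    """Distance-dependent Hegyi competition index.

    sum over neighbors j of (BA_j / BA_i) / d_ij, with basal areas in any
    common unit and distances in metres. Zero for an empty neighborhood.
    """
    if focal_ba <= 0:
        raise ValueError("focal basal area must be positive")
    total = 0.0
    for ba_j, d in neighbors:
        if d <= 0:
            raise ValueError("coincident stems: neighbor at zero distance")
        total += (ba_j / focal_ba) / d
    return total


def neighborhood_species_richness(
    focal_species: str, neighbor_species: list[str], include_focal: bool = True
) -> int:
    """Realized species richness of the interacting community.

    Counts distinct species among the living neighbors, including the focal
    tree's own species by default (an empty neighborhood has richness 1).
    """
    species = set(neighbor_species)
    if include_focal:
        species.add(focal_species)
    return len(species)


def functional_dispersion(members: list[tuple[str, float, float]]) -> float:
    """Abundance-weighted functional dispersion (FDis) for a single trait.

    ``members`` are (species, basal_area, trait) tuples for every community
    member (focal + neighbors). Basal areas are pooled by species into
    relative abundances a_k (summing to 1); FDis is the weighted mean
    absolute distance of species trait values to the abundance-weighted
    centroid: FDis = sum_k a_k |t_k - c|, c = sum_k a_k t_k. Zero for a
    single-species community.
    """
    if not members:
        raise ValueError("empty community")
    ba_by_sp: dict[str, float] = {}
    trait_by_sp: dict[str, float] = {}
    for sp, ba, trait in members:
        if ba <= 0:
            raise ValueError(f"non-positive basal area for species {sp!r}")
        if trait is None or not np.isfinite(trait):
            raise ValueError(f"missing trait value for species {sp!r}")
        ba_by_sp[sp] = ba_by_sp.get(sp, 0.0) + ba
        trait_by_sp[sp] = float(trait)
    species = sorted(ba_by_sp)
    a = np.array([ba_by_sp[sp] for sp in species])
    a = a / a.sum()
    t = np.array([trait_by_sp[sp] for sp in species])
    centroid = float(np.dot(a, t))
    return float(np.dot(a, np.abs(t - centroid)))


def neighborhood_metrics(
    stem_map: pd.DataFrame,
    traits: pd.DataFrame,
    radius_by_site: dict[str, float],
    include_focal_in_nsr: bool = True,
) -> pd.DataFrame:
    """Per-focal-tree neighborhood covariates (raw, unstandardized).

    ``traits`` must have columns species_code, TLP, P50 (HSM is derived).
    Returns one row per focal tree: nSR, FD_HSM_raw, Hegyi, n_neighbors,
    focal HSM_TLP, plus identifiers and basal area for standardization.
    Species present in a neighborhood but absent from the trait table raise
    a KeyError naming the species.
    """
    trait_idx = traits.set_index("species_code")
    hsm = {
        sp: hsm_from_traits(float(r["TLP"]), float(r["P50"])) for sp, r in trait_idx.iterrows()
    }
    rows = []
    for _, f in stem_map[stem_map["focal"].astype(bool)].iterrows():
        site = f["site_id"]
        radius = radius_by_site[site] if isinstance(radius_by_site, dict) else float(radius_by_site)
        nbrs = find_neighbors(stem_map, f["tree_id"], radius)
        for n in nbrs:
            if n.species_code not in hsm:
                raise KeyError(f"species {n.species_code!r} missing from trait table")
        if f["species_code"] not in hsm:
            raise KeyError(f"species {f['species_code']!r} missing from trait table")
        members = [(f["species_code"], float(f["ba_mm2"]), hsm[f["species_code"]])] + [
            (n.species_code, n.ba_mm2, hsm[n.species_code]) for n in nbrs
        ]
        rows.append(
            {
                "tree_id": f["tree_id"],
                "site_id": site,
                "plot_id": f["plot_id"],
                "species_code": f["species_code"],
                "ba_mm2": float(f["ba_mm2"]),
                "n_neighbors": len(nbrs),
                "nSR": neighborhood_species_richness(
                    f["species_code"], [n.species_code for n in nbrs], include_focal_in_nsr
                ),
                "FD_HSM_raw": functional_dispersion(members),
                "Hegyi": hegyi(float(f["ba_mm2"]), [(n.ba_mm2, n.distance_m) for n in nbrs]),
                "HSM_TLP": hsm[f["species_code"]],
            }
        )
    return pd.DataFrame(rows)


def _zscore_within(df: pd.DataFrame, value: str, by: list[str], out: str) -> pd.DataFrame:
    def z(g: pd.Series) -> pd.Series:
        if g.size < 2 or g.std(ddof=1) == 0:
            warnings.warn(
                f"group {g.name!r}: zero variance or singleton in {value}; {out} set to 0",
                RuntimeWarning,
                stacklevel=3,
            )
            return pd.Series(0.0, index=g.index)
        return (g - g.mean()) / g.std(ddof=1)

    df = df.copy()
    df[out] = df.groupby(by, group_keys=False)[value].apply(z)
    return df


def normalize_and_standardize(
    metrics: pd.DataFrame, hegyi_group: str = "site"
) -> pd.DataFrame:
    """Standardize covariates for the growth-response models.

    BA_z: basal area z-scored within site x species (relative intraspecific
    tree size); Hegyi_z: Hegyi z-scored within site (relative interspecific
    competition; ``hegyi_group='site_species'`` switches to site x species);
    FD_HSM_norm: FDis min-max normalized across the whole table (0 when all
    values coincide, e.g. an all-monoculture dataset). Groups with zero
    variance are flagged with a warning and set to 0.
    """
    out = _zscore_within(metrics, "ba_mm2", ["site_id", "species_code"], "BA_z")
    hg = ["site_id"] if hegyi_group == "site" else ["site_id", "species_code"]
    out = _zscore_within(out, "Hegyi", hg, "Hegyi_z")
    fd = out["FD_HSM_raw"]
    span = fd.max() - fd.min()
    out["FD_HSM_norm"] = 0.0 if span == 0 else (fd - fd.min()) / span
    return out
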