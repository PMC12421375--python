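"""Tree-ring series: Tucson I/O, BAI, biomass increment, response ratios.

A ring series carries annual tree-ring widths (TRW, mm) and mean ring wood
density (kg m^-3). Basal area increment (BAI, mm^2 yr^-1) is reconstructed
from pith to bark assuming concentric rings, and radial biomass increment
(BIOMinc, kg m^-1 yr^-1) is the product of BAI and ring density. Drought
responses are quantified as the Lloret ratio of growth in a response year to
mean growth over the pre-drought reference year(s); series are used raw and
undetrended (no detrending API is provided).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import DroughtCalendar

__all__ = [
    "RingSeries",
    "ResponseRecord",
    "read_rwl",
    "write_rwl",
    "read_density_table",
    "write_density_table",
    "bai_from_trw",
    "biom_inc",
    "quality_filter",
    "growth_response",
    "RwlFormatError",
]

METRICS = ("TRW", "BAI", "BIOMinc")


class RwlFormatError(ValueError):
    """Malformed Tucson-format ring-width file."""


@dataclass
class RingSeries:
    """Annual ring widths (and optional densities) for one tree.

    years are consecutive calendar years; trw in mm; density in kg m^-3
    (NaN where unknown); pith_offset is the distance (mm) from the pith to
    the innermost measured ring boundary (0 when the core reaches the pith).
    """

    tree_id: str
    years: np.ndarray
    trw: np.ndarray
    density: np.ndarray | None = None
    pith_offset: float = 0.0
    doubtful: bool = False

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.trw = np.asarray(self.trw, dtype=float)
        if self.years.size != self.trw.size:
            raise ValueError("years and trw must have equal length")
        if self.years.size and np.any(np.diff(self.years) != 1):
            raise ValueError("ring years must be consecutive")
        if np.any(self.trw < 0):
            raise ValueError("negative ring width")
        if self.density is not None:
            self.density = np.asarray(self.density, dtype=float)
            if self.density.size != self.trw.size:
                raise ValueError("density must align with trw")

    def __len__(self) -> int:
        return self.years.size

    def bai(self) -> np.ndarray:
        return bai_from_trw(self.trw, self.pith_offset)

    def biominc(self) -> np.ndarray:
        if self.density is None:
            raise ValueError(f"tree {self.tree_id}: no density series")
        return biom_inc(self.bai(), self.density)

    def metric(self, name: str) -> np.ndarray:
        if name == "TRW":
            return self.trw
        if name == "BAI":
            return self.bai()
        if name == "BIOMinc":
            return self.biominc()
        raise ValueError(f"unknown metric {name!r}; expected one of {METRICS}")


@dataclass
class ResponseRecord:
    """Lloret growth response of one tree in one labeled response year."""

    tree_id: str
    resp_yr: int
    year: int
    metric: str
    growth_response: float
    log_response: float
    excluded: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# Tucson (.rwl) reader / writer -- 0.01 mm units, 999 end-of-series marker
# ---------------------------------------------------------------------------

_STOP = 999


def write_rwl(collection: list[RingSeries], path) -> None:
    """Write ring-width series in Tucson decade format at 0.01 mm precision.

    Each line: 8-character series id, 4-character decade-start year, then up
    to ten 6-character integer fields (hundredths of mm); the value 999
    terminates a series.
    """
    with open(path, "w") as fh:
        for s in collection:
            if not len(s):
                continue
            sid = str(s.tree_id)[:8]
            vals = [int(round(v * 100)) for v in s.trw]
            years = list(s.years)
            # append stop marker in the slot after the last ring
            years.append(years[-1] + 1)
            vals.append(_STOP)
            i = 0
            while i < len(vals):
                y = years[i]
                decade_end = (y // 10) * 10 + 10
                ncols = min(decade_end - y, len(vals) - i)
                fields = "".join(f"{v:6d}" for v in vals[i : i + ncols])
                fh.write(f"{sid:<8s}{y:4d}{fields}\n")
                i += ncols


def read_rwl(path) -> list[RingSeries]:
    """Parse a Tucson-format ring-width file into RingSeries (widths in mm).

    Handles the common 0.01 mm dialect with 999 stop marker and the 0.001 mm
    dialect with -9999 stop marker. Malformed decade lines raise with the
    line number; an empty file yields an empty collection with a warning.
    """
    per_tree: dict[str, dict[int, int]] = {}
    stops: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.readlines()
    if not any(ln.strip() for ln in lines):
        warnings.warn(f"{path}: empty ring-width file", RuntimeWarning, stacklevel=2)
        return []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        sid = line[:8].strip()
        try:
            year = int(line[8:12])
        except ValueError as exc:
            raise RwlFormatError(f"{path}:{lineno}: bad decade year field {line[8:12]!r}") from exc
        body = line[12:]
        vals = body.split()
        if not vals:
            raise RwlFormatError(f"{path}:{lineno}: decade line with no values")
        series = per_tree.setdefault(sid, {})
        for j, tok in enumerate(vals):
            try:
                v = int(tok)
            except ValueError as exc:
                raise RwlFormatError(f"{path}:{lineno}: non-integer value {tok!r}") from exc
            y = year + j
            if v in (_STOP, -9999):
                stops[sid] = v
                break
            if y in series:
                raise RwlFormatError(f"{path}:{lineno}: duplicate year {y} for series {sid}")
            series[y] = v
    out = []
    for sid, series in per_tree.items():
        if not series:
            continue
        years = np.array(sorted(series))
        if np.any(np.diff(years) != 1):
            raise RwlFormatError(f"{path}: series {sid} has non-consecutive years")
        scale = 0.001 if stops.get(sid) == -9999 else 0.01
        trw = np.array([series[y] for y in years], dtype=float) * scale
        out.append(RingSeries(tree_id=sid, years=years, trw=trw))
    return out


def write_density_table(collection: list[RingSeries], path) -> None:
    """Write a long table (tree_id, year, density_kg_m3), tab-delimited."""
    rows = []
    for s in collection:
        if s.density is None:
            continue
        for y, d in zip(s.years, s.density):
            rows.append((s.tree_id, int(y), float(d)))
    pd.DataFrame(rows, columns=["tree_id", "year", "density_kg_m3"]).to_csv(
        path, sep="\t", index=False
    )


def read_density_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tree_id": str})


def attach_density(collection: list[RingSeries], density: pd.DataFrame) -> list[RingSeries]:
    """Join a density long table onto ring series by tree and year.

    Ring years without a density record get NaN density (dropped later with
    a warning by biom_inc consumers).
    """
    by_tree = {tid: grp.set_index("year")["density_kg_m3"] for tid, grp in density.groupby("tree_id")}
    for s in collection:
        dens = by_tree.get(s.tree_id)
        if dens is None:
            continue
        s.density = np.array([dens.get(int(y), np.nan) for y in s.years])
    return collection


# ---------------------------------------------------------------------------
# Derived growth metrics
# ---------------------------------------------------------------------------

def bai_from_trw(trw: np.ndarray, pith_offset: float = 0.0) -> np.ndarray:
    """Basal area increment from pith to bark: BAI_t = pi (r_t^2 - r_{t-1}^2).

    r_t = pith_offset + cumulative ring width through year t (mm); the sum
    of BAI over the series telescopes to pi r_final^2 - pi r_0^2 exactly.
    """
    trw = np.asarray(trw, dtype=float)
    if np.any(trw < 0):
        raise ValueError("negative ring width")
    r = pith_offset + np.cumsum(trw)
    r_prev = np.concatenate([[pith_offset], r[:-1]])
    return math.pi * (r**2 - r_prev**2)


def biom_inc(bai: np.ndarray, density: np.ndarray) -> np.ndarray:
    """Radial biomass increment: BAI (mm^2) x 1e-6 x density (kg m^-3).

    Result is kg per metre of stem per year. Years with missing density
    yield NaN (callers drop them with a warning).
    """
    bai = np.asarray(bai, dtype=float)
    density = np.asarray(density, dtype=float)
    if bai.shape != density.shape:
        raise ValueError("BAI and density must have matching years")
    return bai * 1e-6 * density


def quality_filter(
    collection: list[RingSeries],
    threshold: float = 0.40,
    species_site: dict[str, tuple[str, str]] | None = None,
) -> tuple[list[RingSeries], pd.DataFrame]:
    """Drop doubtful series and whole species-by-site groups above threshold.

    Each series carries a ``doubtful`` flag set upstream (crossdating is out
    of scope; flags come from config or fixtures). Doubtful series are always
    removed; when the doubtful proportion of a species-by-site group is
    strictly greater than ``threshold``, the entire group is removed.
    ``species_site`` maps tree_id -> (species, site); trees missing from it
    form their own singleton groups.

    Returns (retained series, report) where the report lists one row per
    group with its doubtful proportion and decision.
    """
    species_site = species_site or {}
    groups: dict[tuple[str, str], list[RingSeries]] = {}
    for s in collection:
        key = species_site.get(s.tree_id, (s.tree_id, "?"))
        groups.setdefault(key, []).append(s)
    kept: list[RingSeries] = []
    rows = []
    for (sp, site), members in groups.items():
        n = len(members)
        n_doubt = sum(m.doubtful for m in members)
        prop = n_doubt / n
        drop_group = prop > threshold
        if not drop_group:
            kept.extend(m for m in members if not m.doubtful)
        rows.append(
            {
                "species": sp,
                "site": site,
                "n_series": n,
                "n_doubtful": n_doubt,
                "prop_doubtful": prop,
                "group_removed": drop_group,
                "n_retained": 0 if drop_group else n - n_doubt,
            }
        )
    report = pd.DataFrame(rows)
    return kept, report


def growth_response(
    series: RingSeries,
    calendar: DroughtCalendar,
    metric: str = "BIOMinc",
) -> list[ResponseRecord]:
    """Lloret relative growth index per response year.

    response(resp_yr i) = growth(year_i) / mean growth(reference years),
    with growth measured as TRW, BAI or BIOMinc; log_response is the natural
    log. Response years with zero growth are flagged and excluded from the
    log scale rather than offset. A zero reference mean is an error: the
    ratio is undefined for that tree.
    """
    g = series.metric(metric)
    by_year = dict(zip((int(y) for y in series.years), g))
    try:
        ref_vals = [by_year[y] for y in calendar.reference_years]
    except KeyError as exc:
        raise ValueError(
            f"tree {series.tree_id}: missing reference year {exc} in ring series"
        ) from exc
    ref_mean = float(np.mean(ref_vals))
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise ValueError(
            f"tree {series.tree_id}: non-positive or missing reference-period mean ({ref_mean})"
        )
    records = []
    for resp, year in sorted(calendar.resp_years.items()):
        if year not in by_year:
            raise ValueError(f"tree {series.tree_id}: ring series lacks response year {year}")
        val = float(by_year[year])
        if not np.isfinite(val):
            records.append(
                ResponseRecord(series.tree_id, resp, year, metric, np.nan, np.nan, True, "missing growth")
            )
            continue
        ratio = val / ref_mean
        if ratio <= 0:
            records.append(
                ResponseRecord(series.tree_id, resp, year, metric, ratio, np.nan, True, "zero growth")
            )
        else:
            records.append(
                ResponseRecord(series.tree_id, resp, year, metric, ratio, math.log(ratio))
            )
    return records


def response_table(records: list[ResponseRecord]) -> pd.DataFrame:
    """Flatten response records to a DataFrame (excluded records flagged)."""
    return pd.DataFrame(
        [
            {
                "tree_id": r.tree_id,
                "resp_yr": r.resp_yr,
                "year": r.year,
                "metric": r.metric,
                "growth_response": r.growth_response,
                "log_response": r.log_response,
                "excluded": r.excluded,
                "reason": r.reason,
            }
            for r in records
        ]
    )
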