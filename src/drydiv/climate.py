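"""Drought indexing from site climate series.

Implements the climate side of the analysis: monthly climatic water balance,
the Standardized Precipitation-Evapotranspiration Index (SPEI) over
configurable windows, a single-bucket soil water balance producing relative
extractable water (REW), drought-duration statistics, and the per-site
calendar of drought response years and pre-drought reference years.

SPEI follows the de-facto standard construction: the k-month aggregate of the
climatic water balance is standardized through a three-parameter log-logistic
distribution fitted to a reference period by unbiased probability-weighted
moments (PWMs), then mapped to standard-normal scores.

The bucket model is a deliberate simplification of full plant-hydraulics
process models: a single soil reservoir with capacity-limited storage,
evapotranspiration throttled linearly below the REW = 0.4 stress threshold,
and overflow discarded as runoff. Every REW value this package produces
comes from this bucket.
"""

from __future__ import annotations

import calendar as _cal
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ClimateSeries",
    "SpeiSeries",
    "SoilParams",
    "RewSeries",
    "DroughtCalendar",
    "water_balance",
    "fit_loglogistic_pwm",
    "loglogistic_cdf",
    "loglogistic_ppf",
    "spei",
    "spei_quantile_threshold",
    "classify_drought_years",
    "monthly_to_daily",
    "rew_bucket",
    "rew_summaries",
    "build_calendar",
    "SEVERE_THRESHOLD",
    "MODERATE_THRESHOLD",
    "REW_STRESS_THRESHOLD",
]

#: SPEI12 threshold below which a year counts as severely dry (strict <).
#: This is the 10% quantile of the standard-normal SPEI scale.
SEVERE_THRESHOLD = -1.28
#: SPEI12 threshold separating moderate drought from normal/wet conditions.
MODERATE_THRESHOLD = -0.5
#: REW below which trees are considered under drought stress.
REW_STRESS_THRESHOLD = 0.4

GROWING_SEASON_MONTHS = (4, 5, 6, 7, 8, 9)  # April-September


class ClimateError(ValueError):
    """Raised for malformed or gappy climate inputs."""


@dataclass
class ClimateSeries:
    """Monthly precipitation and potential evapotranspiration for one site.

    ``data`` columns: year, month, P_mm, PET_mm; rows must form a contiguous
    monthly sequence with non-negative fluxes.
    """

    site_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"year", "month", "P_mm", "PET_mm"}
        missing = required - set(self.data.columns)
        if missing:
            raise ClimateError(f"climate table missing columns: {sorted(missing)}")
        df = self.data.sort_values(["year", "month"]).reset_index(drop=True)
        if (df["P_mm"] < 0).any() or (df["PET_mm"] < 0).any():
            raise ClimateError("precipitation and PET must be non-negative")
        idx = df["year"].to_numpy() * 12 + (df["month"].to_numpy() - 1)
        gaps = np.flatnonzero(np.diff(idx) != 1)
        if gaps.size:
            missing_months = [
                f"{df['year'][g]}-{df['month'][g]:02d} -> {df['year'][g + 1]}-{df['month'][g + 1]:02d}"
                for g in gaps[:10]
            ]
            raise ClimateError(f"non-contiguous monthly records at: {missing_months}")
        object.__setattr__(self, "data", df)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.data["year"].to_numpy())

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, site_id: str | None = None) -> "ClimateSeries":
        df = pd.read_csv(path, sep="\t")
        sid = site_id or (str(df["site_id"].iloc[0]) if "site_id" in df else "site")
        return cls(sid, df[["year", "month", "P_mm", "PET_mm"]])


def water_balance(climate: ClimateSeries) -> pd.Series:
    """Monthly climatic water balance D = P - PET (mm).

    Returns a Series indexed by (year, month).
    """
    df = climate.data
    d = df["P_mm"] - df["PET_mm"]
    d.index = pd.MultiIndex.from_arrays([df["year"], df["month"]], names=["year", "month"])
    return d.rename("D_mm")


# ---------------------------------------------------------------------------
# SPEI: log-logistic standardization via unbiased probability-weighted moments
# ---------------------------------------------------------------------------

def _pwms_unbiased(x: np.ndarray) -> tuple[float, float, float]:
    """Unbiased PWM estimators b0, b1, b2 of E[X F(X)^s], s = 0, 1, 2.

    Standard order-statistic weights on the ascending-sorted sample:
    b_s = n^-1 sum_i x_(i) * prod_{j=1..s} (i - j) / (n - j).
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    i = np.arange(1, n + 1)
    b0 = xs.mean()
    b1 = float(np.sum(xs * (i - 1) / (n - 1)) / n)
    b2 = float(np.sum(xs * (i - 1) * (i - 2) / ((n - 1) * (n - 2))) / n)
    return b0, b1, b2


def fit_loglogistic_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Fit the three-parameter log-logistic family by unbiased PWMs.

    Uses the generalized-logistic parametrization (kappa, alpha, xi), which
    is the log-logistic extended to either skew orientation: for kappa < 0
    it is exactly the classical log-logistic with shape -1/kappa, scale
    -alpha/kappa and location xi + alpha/kappa. Parameters follow Hosking's
    L-moment estimators (kappa = -tau3, alpha = lambda2 sin(kappa pi) /
    (kappa pi), xi = lambda1 - alpha (1/kappa - pi/sin(kappa pi))).

    Returns (kappa, alpha, xi); raises on degenerate samples.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to fit a log-logistic")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    b0, b1, b2 = _pwms_unbiased(x)
    lam1 = b0
    lam2 = 2.0 * b1 - b0
    lam3 = 6.0 * b2 - 6.0 * b1 + b0
    if lam2 <= 0:
        raise ValueError("PWM fit failed: non-positive L-scale")
    kappa = -lam3 / lam2
    if abs(kappa) >= 1.0:
        raise ValueError(f"L-skewness {-kappa} outside the representable range (-1, 1)")
    if abs(kappa) < 1e-8:
        alpha = lam2
        xi = lam1
        kappa = 0.0
    else:
        kp = kappa * math.pi
        alpha = lam2 * math.sin(kp) / kp
        xi = lam1 - alpha * (1.0 / kappa - math.pi / math.sin(kp))
    if alpha <= 0:
        raise ValueError("PWM fit produced non-positive scale")
    return float(kappa), float(alpha), float(xi)


def loglogistic_cdf(x, kappa: float, alpha: float, xi: float) -> np.ndarray:
    """CDF of the fitted (generalized) log-logistic.

    F = 1 / (1 + exp(-y)) with y = -kappa^-1 log(1 - kappa (x - xi)/alpha)
    (plain logistic at kappa = 0). Outside the finite support bound the CDF
    saturates at 0 or 1.
    """
    x = np.asarray(x, dtype=float)
    if kappa == 0.0:
        y = (x - xi) / alpha
    else:
        arg = 1.0 - kappa * (x - xi) / alpha
        y = np.where(arg > 0, -np.log(np.maximum(arg, 1e-300)) / kappa, np.nan)
        # beyond the support bound: upper bound reached for kappa > 0 means F=1,
        # lower bound for kappa < 0 means F=0
        fill = np.inf if kappa > 0 else -np.inf
        y = np.where(np.isnan(y), fill, y)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-y))


def loglogistic_ppf(q, kappa: float, alpha: float, xi: float) -> np.ndarray:
    """Quantile function of the fitted (generalized) log-logistic."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantiles must lie strictly inside (0, 1)")
    if kappa == 0.0:
        return xi + alpha * np.log(q / (1.0 - q))
    return xi + alpha * (1.0 - ((1.0 - q) / q) ** kappa) / kappa


def spei_quantile_threshold(p: float = 0.10) -> float:
    """Standard-normal quantile of the standardized SPEI scale.

    SPEI values are standard-normal by construction, so the p-quantile of the
    SPEI distribution is the normal quantile; at p = 0.10 this is the drought
    threshold -1.28 used to flag abnormally dry years.
    """
    return float(norm.ppf(p))


@dataclass
class SpeiSeries:
    """Annual standardized drought index values for one aggregation window."""

    values: pd.Series  # index: year
    k: int
    end_month: int
    reference_period: tuple[int, int]
    dist_params: tuple[float, float, float] = field(default=(np.nan,) * 3)

    def __getitem__(self, year: int) -> float:
        return float(self.values.loc[year])


def _aggregate(D: pd.Series, k: int, end_month: int) -> pd.Series:
    """k-month sums of the water balance ending at end_month of each year."""
    d = D.sort_index()
    years = d.index.get_level_values("year").to_numpy()
    months = d.index.get_level_values("month").to_numpy()
    mindex = years * 12 + (months - 1)
    vals = d.to_numpy()
    lookup = dict(zip(mindex, vals))
    out = {}
    for y in np.unique(years):
        end = y * 12 + (end_month - 1)
        window = [end - j for j in range(k)]
        if all(m in lookup for m in window):
            out[y] = float(sum(lookup[m] for m in window))
    return pd.Series(out, name=f"A{k}")


def spei(
    D: pd.Series,
    k: int = 12,
    end_month: int = 12,
    reference_period: tuple[int, int] = (1991, 2021),
    clip: float = 3.5,
) -> SpeiSeries:
    """Standardize k-month water-balance aggregates to SPEI scores.

    The aggregate A_y sums D over the k months ending at ``end_month`` of
    year y. A three-parameter log-logistic distribution is fitted to the
    reference-period aggregates by unbiased PWMs; SPEI_y is the standard
    normal quantile of the fitted CDF at A_y, clipped to +/- ``clip``.
    """
    A = _aggregate(D, k, end_month)
    y0, y1 = reference_period
    ref = A[(A.index >= y0) & (A.index <= y1)]
    if ref.size < 25:
        raise ClimateError(
            f"only {ref.size} reference aggregates in {reference_period}; need >= 25"
        )
    kappa, alpha, xi = fit_loglogistic_pwm(ref.to_numpy())
    F = loglogistic_cdf(A.to_numpy(), kappa, alpha, xi)
    extreme = (F <= 0.0) | (F >= 1.0)
    if extreme.any():
        warnings.warn(
            f"{int(extreme.sum())} aggregate(s) outside fitted support; SPEI clipped",
            RuntimeWarning,
            stacklevel=2,
        )
    eps = 1e-12
    z = norm.ppf(np.clip(F, eps, 1.0 - eps))
    z = np.clip(z, -clip, clip)
    return SpeiSeries(
        values=pd.Series(z, index=A.index, name=f"SPEI{k}"),
        k=k,
        end_month=end_month,
        reference_period=reference_period,
        dist_params=(kappa, alpha, xi),
    )


def classify_drought_years(
    spei12: SpeiSeries | pd.Series,
    severe: float = SEVERE_THRESHOLD,
    moderate: float = MODERATE_THRESHOLD,
) -> pd.Series:
    """Label each year severe / moderate / normal_wet from annual SPEI12.

    severe: SPEI12 < severe threshold (strict, so exactly -1.28 is not
    severe); moderate: severe <= SPEI12 < moderate threshold; otherwise
    normal_wet.
    """
    vals = spei12.values if isinstance(spei12, SpeiSeries) else spei12
    labels = pd.Series("normal_wet", index=vals.index, name="severity")
    labels[vals < moderate] = "moderate"
    labels[vals < severe] = "severe"
    return labels


# ---------------------------------------------------------------------------
# Soil water bucket and REW
# ---------------------------------------------------------------------------

@dataclass
class SoilParams:
    """Single-bucket soil parameters.

    capacity_mm: total water held at field capacity (bucket size);
    wilting_frac: fraction of capacity at the wilting point (REW = 0);
    residual_frac: fraction of capacity below which water is unextractable
    (the hard floor; residual <= wilting so REW may go slightly negative,
    mirroring water held below the wilting point).
    """

    capacity_mm: float = 150.0
    wilting_frac: float = 0.15
    residual_frac: float = 0.12

    def __post_init__(self) -> None:
        if self.capacity_mm <= 0:
            raise ValueError("capacity_mm must be positive")
        if not (0 <= self.residual_frac <= self.wilting_frac < 1):
            raise ValueError("need 0 <= residual_frac <= wilting_frac < 1")

    @property
    def w_fc(self) -> float:
        return self.capacity_mm

    @property
    def w_wp(self) -> float:
        return self.wilting_frac * self.capacity_mm

    @property
    def w_res(self) -> float:
        return self.residual_frac * self.capacity_mm

    @property
    def rew_min(self) -> float:
        """Lowest attainable REW: (residual - wilting) / (1 - wilting) <= 0."""
        return (self.residual_frac - self.wilting_frac) / (1.0 - self.wilting_frac)


@dataclass
class RewSeries:
    """Daily relative extractable water with the water-balance ledger.

    ``data`` columns: year, month, day, P_mm, PET_mm, E_mm, runoff_mm, W_mm,
    REW. W_mm is storage at the start of the day; the ledger satisfies
    W(next) - W = P - E - runoff exactly.
    """

    data: pd.DataFrame
    soil: SoilParams


def monthly_to_daily(climate: ClimateSeries) -> pd.DataFrame:
    """Spread monthly P and PET uniformly over the days of each month."""
    rows = []
    for _, r in climate.data.iterrows():
        y, m = int(r["year"]), int(r["month"])
        ndays = _cal.monthrange(y, m)[1]
        for day in range(1, ndays + 1):
            rows.append((y, m, day, r["P_mm"] / ndays, r["PET_mm"] / ndays))
    return pd.DataFrame(rows, columns=["year", "month", "day", "P_mm", "PET_mm"])


def rew_bucket(
    daily: pd.DataFrame,
    soil: SoilParams | None = None,
    initial_fill: float = 1.0,
) -> RewSeries:
    """Step a daily single-bucket water balance and return REW.

    W(d+1) = clamp(W(d) + P(d) - E(d), W_res, W_fc) with
    E(d) = PET(d) * g(REW(d)), g rising linearly from 0 at REW = 0 to 1 at
    REW >= 0.4 (and 0 for REW <= 0); overflow above field capacity leaves as
    runoff; extraction never draws the store below the residual floor.
    """
    soil = soil or SoilParams()
    P = daily["P_mm"].to_numpy(dtype=float)
    PET = daily["PET_mm"].to_numpy(dtype=float)
    n = P.size
    w_fc, w_wp, w_res = soil.w_fc, soil.w_wp, soil.w_res
    span = w_fc - w_wp
    W = np.empty(n)
    E = np.empty(n)
    runoff = np.empty(n)
    rew = np.empty(n)
    w = w_wp + initial_fill * span
    w = min(max(w, w_res), w_fc)
    for d in range(n):
        W[d] = w
        r = (w - w_wp) / span
        rew[d] = r
        g = min(max(r / REW_STRESS_THRESHOLD, 0.0), 1.0)
        e = min(PET[d] * g, w + P[d] - w_res)  # cannot extract below residual
        e = max(e, 0.0)
        w_next = w + P[d] - e
        ro = max(w_next - w_fc, 0.0)
        w_next -= ro
        E[d] = e
        runoff[d] = ro
        w = w_next
    out = daily[["year", "month", "day", "P_mm", "PET_mm"]].copy()
    out["E_mm"] = E
    out["runoff_mm"] = runoff
    out["W_mm"] = W
    out["REW"] = rew
    return RewSeries(out, soil)


def rew_summaries(rew: RewSeries, year: int) -> tuple[float, int, int]:
    """Per-year drought covariates from the daily REW series.

    Returns (REWmin, DrDays_12m, DrDays_AprSep): the minimum over
    April-September of the monthly mean REW, and counts of days with
    REW < 0.4 over the calendar year and over the growing season.
    """
    df = rew.data[rew.data["year"] == year]
    expected = 366 if _cal.isleap(year) else 365
    if len(df) != expected:
        raise ClimateError(f"year {year}: {len(df)} daily records, expected {expected}")
    monthly_mean = df.groupby("month")["REW"].mean()
    rew_min = float(monthly_mean.loc[list(GROWING_SEASON_MONTHS)].min())
    stressed = df["REW"] < REW_STRESS_THRESHOLD
    drdays_12m = int(stressed.sum())
    in_gs = df["month"].isin(GROWING_SEASON_MONTHS)
    drdays_gs = int((stressed & in_gs).sum())
    return rew_min, drdays_12m, drdays_gs


# ---------------------------------------------------------------------------
# Drought calendar
# ---------------------------------------------------------------------------

class NoReferenceYearError(ClimateError):
    """No qualifying pre-drought reference year before the first drought year."""


@dataclass
class DroughtCalendar:
    """Labeled drought response years and pre-drought reference years.

    ``resp_years`` maps Resp_yr label (1..4) to calendar year; empty when the
    focus span contains no severe drought year. ``covariates`` carries the
    per-year drought indices for the response years.
    """

    site_id: str
    reference_years: list[int]
    resp_years: dict[int, int]
    covariates: pd.DataFrame
    status: str = "ok"

    @property
    def empty(self) -> bool:
        return not self.resp_years

    def year_of(self, resp: int) -> int:
        return self.resp_years[resp]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"role": "reference", "resp_yr": 0, "year": y} for y in self.reference_years
        ] + [
            {"role": "response", "resp_yr": r, "year": y}
            for r, y in sorted(self.resp_years.items())
        ]
        return pd.DataFrame(rows)


def build_calendar(
    spei12: SpeiSeries,
    covariates: pd.DataFrame,
    focus_span: tuple[int, int],
    site_id: str = "site",
    max_resp_years: int = 4,
    max_reference_years: int = 2,
) -> DroughtCalendar:
    """Construct the drought calendar from annual SPEI12 and REW covariates.

    Resp_yr 1 is the first severe year (SPEI12 < -1.28) inside the focus
    span; subsequent consecutive drought years (SPEI12 < -0.5) continue the
    event, and the first following non-drought year is retained as the final
    post-drought Resp_yr, up to ``max_resp_years`` labels. Reference years
    are the up-to-two most recent consecutive years immediately preceding
    Resp_yr 1 with SPEI12 >= -0.5.

    ``covariates`` is indexed by year with columns such as SPEI12,
    SPEI6_AprSep, REWmin, DrDays_12m, DrDays_AprSep.
    """
    y0, y1 = focus_span
    vals = spei12.values
    if y0 < vals.index.min() or y1 > vals.index.max():
        raise ClimateError(f"focus span {focus_span} outside SPEI series")
    labels = classify_drought_years(spei12)
    span_years = [y for y in vals.index if y0 <= y <= y1]
    severe_years = [y for y in span_years if labels[y] == "severe"]
    if not severe_years:
        return DroughtCalendar(
            site_id, [], {}, covariates.iloc[0:0],
            status=f"no severe drought year (SPEI12 < {SEVERE_THRESHOLD}) in {focus_span}",
        )
    first = severe_years[0]
    resp_years: dict[int, int] = {1: first}
    y = first + 1
    while len(resp_years) < max_resp_years and y in vals.index:
        if labels[y] in ("severe", "moderate"):
            resp_years[len(resp_years) + 1] = y
            y += 1
        else:
            resp_years[len(resp_years) + 1] = y  # post-drought year, final label
            break

    refs: list[int] = []
    y = first - 1
    while len(refs) < max_reference_years and y in vals.index and labels[y] == "normal_wet":
        refs.append(y)
        y -= 1
    if not refs:
        raise NoReferenceYearError(
            f"no qualifying reference year (SPEI12 >= {MODERATE_THRESHOLD}) before {first}"
        )
    refs = sorted(refs)
    cov = covariates.loc[[yy for yy in resp_years.values() if yy in covariates.index]]
    return DroughtCalendar(site_id, refs, resp_years, cov)
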