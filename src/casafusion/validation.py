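"""Flux-tower evaluation of modelled NPP.

Eddy-covariance towers measure GPP; monthly tower NPP is taken as a fixed
fraction of GPP (0.40-0.50 for temperate ecosystems, default 0.40).  Sites
enter the evaluation only with at least three complete calendar years of
records.  Modelled NPP is extracted at the tower either from the single
containing pixel or as the mean of the 3x3 pixel neighbourhood (an
approximate tower footprint), then regressed against tower NPP pooled,
per site, per season and per land-cover class.

The coefficient of determination reported everywhere is the squared
Pearson correlation, which is invariant to rescaling either series — in
particular to the choice of NPP:GPP ratio within its uncertainty range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: Default NPP:GPP conversion and its admissible range.
DEFAULT_NPP_GPP_RATIO = 0.40
NPP_GPP_RANGE = (0.40, 0.50)

#: Meteorological seasons by month.
DEFAULT_SEASON_MAP = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


@dataclass
class TowerRecord:
    """One flux tower: location, cover class and monthly GPP rows.

    ``rows`` is a DataFrame with columns year, month, gpp (gC m-2 month-1)
    and optionally reco; months must be calendar-ordered.
    """

    site_id: str
    lon: float
    lat: float
    cover_class: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"year", "month", "gpp"}
        if not need.issubset(self.rows.columns):
            raise ValueError(f"tower rows need columns {sorted(need)}")
        if (self.rows["gpp"].dropna() < 0).any():
            raise ValueError(f"site {self.site_id}: negative GPP")
        order = self.rows["year"] * 12 + self.rows["month"]
        if not order.is_monotonic_increasing:
            raise ValueError(f"site {self.site_id}: months not calendar-ordered")


@dataclass
class EvalConfig:
    """Evaluation knobs: NPP:GPP ratio, footprint mode, season grouping."""

    npp_gpp_ratio: float = DEFAULT_NPP_GPP_RATIO
    footprint: str = "point"  # or "mean3x3"
    season_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_SEASON_MAP))

    def __post_init__(self) -> None:
        lo, hi = NPP_GPP_RANGE
        if not lo <= self.npp_gpp_ratio <= hi:
            raise ValueError(f"npp_gpp_ratio must lie in [{lo}, {hi}]")
        if self.footprint not in ("point", "mean3x3"):
            raise ValueError("footprint must be 'point' or 'mean3x3'")


@dataclass
class RegressionResult:
    r2: float | None
    slope: float | None
    intercept: float | None
    n: int
    bias_pct: float | None


@dataclass
class EvalReport:
    """Pooled, per-site, per-season and per-cover regression summaries."""

    pooled: RegressionResult
    per_site: dict[str, RegressionResult]
    per_season: dict[str, RegressionResult]
    per_cover: dict[str, RegressionResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, results in (("pooled", {"all": self.pooled}),
                               ("site", self.per_site),
                               ("season", self.per_season),
                               ("cover", self.per_cover)):
            for name, res in results.items():
                rows.append({"group": group, "name": name, "r2": res.r2,
                             "slope": res.slope, "intercept": res.intercept,
                             "n": res.n, "bias_pct": res.bias_pct})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Site filtering and unit conversion
# ---------------------------------------------------------------------------

def filter_sites(records: list[TowerRecord], min_years: int = 3) -> list[TowerRecord]:
    """Keep sites with >= min_years complete calendar years of GPP.

    A year counts only when all 12 months carry a finite GPP value, so the
    dormant season is always represented.
    """
    kept = []
    for rec in records:
        rows = rec.rows.dropna(subset=["gpp"])
        complete = 0
        for _, grp in rows.groupby("year"):
            if set(grp["month"]) >= set(range(1, 13)):
                complete += 1
        if complete >= min_years:
            kept.append(rec)
    return kept


def npp_from_gpp(gpp, ratio: float = DEFAULT_NPP_GPP_RATIO):
    """Tower NPP as a fixed fraction of GPP."""
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    gpp = np.asarray(gpp, dtype=np.float64)
    if (gpp[np.isfinite(gpp)] < 0).any():
        raise ValueError("GPP must be non-negative")
    out = ratio * gpp
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Footprint extraction
# ---------------------------------------------------------------------------

def extract_footprint(npp, lon: float, lat: float,
                      mode: str = "point") -> pd.Series:
    """Monthly modelled NPP at a tower location.

    ``point`` reads the containing pixel; ``mean3x3`` averages the valid
    cells of the 3x3 window centered on it (truncated at grid edges).
    Returns a Series indexed by (year, month); nodata months are NaN.
    """
    spec = npp.spec
    if not bool(spec.contains(lon, lat)):
        raise ValueError(f"point ({lon}, {lat}) is outside the model grid")
    row, col = (int(x) for x in spec.index_of(lon, lat))
    values = {}
    for key, raster in npp.items():
        vals = raster.masked()
        if mode == "point":
            values[key] = vals[row, col]
        elif mode == "mean3x3":
            window = vals[max(row - 1, 0):row + 2, max(col - 1, 0):col + 2]
            values[key] = (np.nanmean(window)
                           if np.isfinite(window).any() else np.nan)
        else:
            raise ValueError("mode must be 'point' or 'mean3x3'")
    idx = pd.MultiIndex.from_tuples(values.keys(), names=["year", "month"])
    return pd.Series(list(values.values()), index=idx, name="npp_model")


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def regress(modeled, measured) -> RegressionResult:
    """OLS of measured (tower) on modeled NPP with r2 and mean bias.

    r2 is the squared Pearson correlation; bias% = 100 * (mean modeled -
    mean measured) / mean measured.  Zero variance in either series makes
    r2/slope undefined (None), never zero.
    """
    modeled = np.asarray(modeled, dtype=np.float64)
    measured = np.asarray(measured, dtype=np.float64)
    ok = np.isfinite(modeled) & np.isfinite(measured)
    x, y = modeled[ok], measured[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 paired finite values, have {n}")
    mean_meas = y.mean()
    bias = (100.0 * (x.mean() - mean_meas) / mean_meas
            if mean_meas != 0 else None)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RegressionResult(None, None, None, n, bias)
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.rvalue ** 2), float(fit.slope),
                            float(fit.intercept), n, bias)


def _try_regress(modeled, measured) -> RegressionResult:
    try:
        return regress(modeled, measured)
    except ValueError:
        n = int((np.isfinite(np.asarray(modeled, dtype=float))
                 & np.isfinite(np.asarray(measured, dtype=float))).sum())
        return RegressionResult(None, None, None, n, None)


def grouped_reports(pairs: pd.DataFrame,
                    season_map: dict[int, str] | None = None) -> EvalReport:
    """Regressions pooled and grouped by site, season and cover class.

    ``pairs`` needs columns site, cover, year, month, npp_model, npp_tower.
    Groups with fewer than 3 pairs are reported with undefined statistics.
    """
    season_map = season_map or DEFAULT_SEASON_MAP
    need = {"site", "cover", "month", "npp_model", "npp_tower"}
    if not need.issubset(pairs.columns):
        raise ValueError(f"pairs need columns {sorted(need)}")
    pairs = pairs.copy()
    pairs["season"] = pairs["month"].map(season_map)

    pooled = _try_regress(pairs["npp_model"], pairs["npp_tower"])
    per = {}
    for col, dest in (("site", "per_site"), ("season", "per_season"),
                      ("cover", "per_cover")):
        per[dest] = {name: _try_regress(g["npp_model"], g["npp_tower"])
                     for name, g in pairs.groupby(col)}
    return EvalReport(pooled, per["per_site"], per["per_season"], per["per_cover"])


def paired_ratio_ttest(gpp, modeled, ratio_a: float = 0.40,
                       ratio_b: float = 0.50):
    """Paired t-test between tower NPP residuals under two NPP:GPP ratios.

    Compares |modeled - ratio_a*GPP| with |modeled - ratio_b*GPP| pairwise;
    a neutral utility whose interpretation is left to the user.
    """
    gpp = np.asarray(gpp, dtype=np.float64)
    modeled = np.asarray(modeled, dtype=np.float64)
    ok = np.isfinite(gpp) & np.isfinite(modeled)
    a = np.abs(modeled[ok] - ratio_a * gpp[ok])
    b = np.abs(modeled[ok] - ratio_b * gpp[ok])
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Tower CSV round-trip and the full evaluation
# ---------------------------------------------------------------------------

TOWER_CSV_COLUMNS = ["site_id", "lon", "lat", "cover", "year", "month", "gpp", "reco"]


def read_tower_csv(path: str | Path) -> list[TowerRecord]:
    df = pd.read_csv(path)
    missing = set(TOWER_CSV_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"tower CSV missing columns {sorted(missing)}")
    records = []
    for site, grp in df.groupby("site_id", sort=False):
        grp = grp.sort_values(["year", "month"])
        rows = grp[["year", "month", "gpp"]].copy()
        if "reco" in grp.columns:
            rows["reco"] = grp["reco"].to_numpy()
        records.append(TowerRecord(str(site), float(grp["lon"].iloc[0]),
                                   float(grp["lat"].iloc[0]),
                                   str(grp["cover"].iloc[0]),
                                   rows.reset_index(drop=True)))
    return records


def write_tower_csv(records: list[TowerRecord], path: str | Path) -> None:
    frames = []
    for rec in records:
        df = rec.rows.copy()
        df.insert(0, "site_id", rec.site_id)
        df.insert(1, "lon", rec.lon)
        df.insert(2, "lat", rec.lat)
        df.insert(3, "cover", rec.cover_class)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def evaluate(npp, records: list[TowerRecord],
             config: EvalConfig | None = None,
             min_years: int = 3) -> tuple[EvalReport, pd.DataFrame]:
    """Full evaluation: filter sites, convert GPP, extract, regress.

    Returns the grouped report and the paired table it was computed from.
    """
    config = config or EvalConfig()
    rows = []
    for rec in filter_sites(records, min_years):
        series = extract_footprint(npp, rec.lon, rec.lat, config.footprint)
        for _, r in rec.rows.iterrows():
            key = (int(r["year"]), int(r["month"]))
            if key not in series.index or not np.isfinite(r["gpp"]):
                continue
            model = series.loc[key]
            if not np.isfinite(model):
                continue
            rows.append({"site": rec.site_id, "cover": rec.cover_class,
                         "year": key[0], "month": key[1],
                         "npp_model": float(model),
                         "npp_tower": npp_from_gpp(r["gpp"], config.npp_gpp_ratio),
                         "gpp": float(r["gpp"])})
    pairs = pd.DataFrame(rows)
    if pairs.empty:
        raise ValueError("no overlapping tower/model months after filtering")
    return grouped_reports(pairs, config.season_map), pairs
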