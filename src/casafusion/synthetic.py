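"""Seeded synthetic scenes with known ground truth for every pipeline input.

The generators emulate the structure of the real inputs — a fine
categorical land-cover map with contiguous patches, coarse monthly EVI
with per-class seasonal phenology, sinusoidal monthly climate with a
latitude-dependent clear-sky solar cycle, and flux-tower GPP records tied
to a known composite NPP — while returning the exact truth (fractions,
phenology curves, NPP:GPP ratio) alongside, so every stage of the pipeline
can be tested against an oracle without external data.

Every generator is a pure function of its SceneConfig (including the
seed); the same configuration always yields bit-identical products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .casa import ClimateInputs
from .fusion import CoverClassSet, EVI_RANGE, FractionalCover
from .grids import GridSpec, MonthlyStack, Raster, month_range, write_geotiff
from .validation import TowerRecord, write_tower_csv

#: Seasonal EVI phenology per land-cover class: (annual mean, seasonal
#: amplitude, peak month).  Curves stay inside the EVI valid range.
DEFAULT_PHENOLOGY: dict[str, tuple[float, float, int]] = {
    "water": (0.02, 0.02, 7),
    "evergreen forest": (0.45, 0.15, 7),
    "wetlands": (0.40, 0.25, 7),
    "lichen": (0.15, 0.05, 7),
    "mixed forest": (0.42, 0.22, 7),
    "woodlands": (0.35, 0.18, 7),
    "grasslands": (0.30, 0.20, 6),
    "croplands": (0.35, 0.30, 7),
    "deciduous forest": (0.40, 0.30, 7),
    "brushland": (0.25, 0.12, 6),
}

#: Solar constant, MJ m-2 min-1 (FAO-56).
SOLAR_CONSTANT = 0.0820
#: Clear-sky atmospheric transmissivity applied to extraterrestrial radiation.
CLEAR_SKY_TRANSMISSIVITY = 0.75


@dataclass(frozen=True)
class SceneConfig:
    """Everything that defines a synthetic scene (a pure function of this)."""

    seed: int = 0
    coarse_spec: GridSpec = field(
        default_factory=lambda: GridSpec(-111.0, 45.0, 0.004, 40, 40))
    fine_ratio: int = 13          # fine cells per coarse cell side (~0.0003 deg)
    classes: tuple[str, ...] = ("evergreen forest", "grasslands", "wetlands")
    patch_sigma: float = 3.0      # smoothing (coarse cells) of the patch fields
    phenology: dict[str, tuple[float, float, int]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOLOGY))
    evi_noise_sd: float = 0.0
    start_year: int = 2003        # first reporting year
    n_years: int = 3              # reporting years
    spinup_years: int = 2         # climate years generated before reporting
    temp_mean: float = 8.0        # degC, annual mean
    temp_amplitude: float = 12.0  # degC, seasonal half-range (peak July)
    temp_noise_sd: float = 0.0
    precip_mean: float = 60.0     # mm/month, annual mean
    precip_amplitude: float = 30.0  # mm/month seasonal half-range (peak June)
    precip_noise_sd: float = 0.0
    soil_class: str = "clay_5_15"

    def __post_init__(self) -> None:
        if self.fine_ratio < 2:
            raise ValueError("fine_ratio must be >= 2")
        for name in self.classes:
            mean, amp, _ = self.phenology[name]
            lo, hi = EVI_RANGE
            if not lo <= mean - amp and mean + amp <= hi:
                raise ValueError(f"phenology of {name!r} leaves the EVI range")

    @property
    def fine_spec(self) -> GridSpec:
        c = self.coarse_spec
        return GridSpec(c.origin_lon, c.origin_lat, c.cell_size / self.fine_ratio,
                        c.n_rows * self.fine_ratio, c.n_cols * self.fine_ratio)

    @property
    def cover_classes(self) -> CoverClassSet:
        return CoverClassSet(self.classes, tuple(range(1, len(self.classes) + 1)))

    def reporting_keys(self) -> list[tuple[int, int]]:
        return month_range((self.start_year, 1), 12 * self.n_years)

    def climate_keys(self) -> list[tuple[int, int]]:
        return month_range((self.start_year - self.spinup_years, 1),
                           12 * (self.spinup_years + self.n_years))


def class_phenology(cfg: SceneConfig, name: str, month) -> np.ndarray | float:
    """True EVI curve of one class: mean + amp*cos(2*pi*(month - peak)/12)."""
    mean, amp, peak = cfg.phenology[name]
    m = np.asarray(month, dtype=np.float64)
    out = mean + amp * np.cos(2.0 * np.pi * (m - peak) / 12.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def make_landscape(cfg: SceneConfig) -> tuple[Raster, FractionalCover]:
    """Patchy categorical fine raster plus its exact fractional cover.

    Each class gets a Gaussian-smoothed random field on the fine grid; the
    per-cell argmax allocates the class, producing contiguous patches with
    a realistic mix of pure and mixed coarse pixels.  The returned
    fractions are computed by direct counting of fine-cell centers and are
    therefore the oracle for the fusion aggregation.
    """
    rng = np.random.default_rng(cfg.seed)
    fine = cfg.fine_spec
    sigma = cfg.patch_sigma * cfg.fine_ratio
    fields = np.stack([
        ndimage.gaussian_filter(rng.standard_normal(fine.shape), sigma,
                                mode="wrap")
        for _ in cfg.classes
    ])
    codes = np.asarray(cfg.cover_classes.codes)[np.argmax(fields, axis=0)]
    lc = Raster(fine, codes.astype(np.int32), nodata=-1, units="class code")

    # exact fractions by counting fine cells inside each coarse pixel
    r = cfg.fine_ratio
    fractions = {}
    for name, code in zip(cfg.classes, cfg.cover_classes.codes):
        hit = (codes == code).astype(np.float64)
        block = hit.reshape(cfg.coarse_spec.n_rows, r,
                            cfg.coarse_spec.n_cols, r).sum(axis=(1, 3))
        fractions[name] = Raster(cfg.coarse_spec, block / (r * r),
                                 nodata=-9999.0, units="fraction")
    return lc, FractionalCover(cfg.coarse_spec, fractions)


# ---------------------------------------------------------------------------
# EVI
# ---------------------------------------------------------------------------

def make_evi(cfg: SceneConfig, frac: FractionalCover
             ) -> tuple[MonthlyStack, dict[str, dict[int, float]]]:
    """Coarse monthly EVI as the fraction-weighted mix of class phenologies.

    pixel EVI(m) = sum_k fraction_k * curve_k(m) + noise, clipped to the
    EVI valid range.  Returns the stack and the true per-class curves
    (class -> month -> EVI) used to build it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    spec = cfg.coarse_spec
    curves = {name: {m: float(class_phenology(cfg, name, m)) for m in range(1, 13)}
              for name in cfg.classes}
    rasters = {}
    for key in cfg.climate_keys():
        _, month = key
        vals = np.zeros(spec.shape)
        for name in cfg.classes:
            vals += frac[name].values * curves[name][month]
        if cfg.evi_noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.evi_noise_sd, spec.shape)
        rasters[key] = Raster(spec, np.clip(vals, *EVI_RANGE),
                              nodata=-9999.0, units="EVI")
    return MonthlyStack(rasters), curves


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------

def clear_sky_solar_month(lat_deg, year: int, month: int) -> np.ndarray | float:
    """Flat-surface clear-sky monthly solar total, MJ m-2 month-1.

    Sums daily extraterrestrial radiation (FAO-56: solar declination,
    sunset hour angle, inverse relative Earth-Sun distance) over the month
    and applies a constant clear-sky transmissivity.  Always >= 0; peaks
    in June at northern mid-latitudes.
    """
    import calendar as _cal
    lat = np.deg2rad(np.asarray(lat_deg, dtype=np.float64))
    total = np.zeros_like(lat)
    first_doy = sum(_cal.monthrange(year, m)[1] for m in range(1, month)) + 1
    for doy in range(first_doy, first_doy + _cal.monthrange(year, month)[1]):
        dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
        decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
        cos_ws = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
        ws = np.arccos(cos_ws)
        ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
            ws * np.sin(lat) * np.sin(decl)
            + np.cos(lat) * np.cos(decl) * np.sin(ws))
        total = total + np.maximum(ra, 0.0)
    out = CLEAR_SKY_TRANSMISSIVITY * total
    return float(out) if out.ndim == 0 else out


def make_climate(cfg: SceneConfig) -> ClimateInputs:
    """Sinusoidal monthly temperature and precipitation plus clear-sky solar.

    Temperature peaks in July, precipitation in June (both with optional
    seeded noise); solar irradiance is the deterministic clear-sky
    latitude/month surface.  Precipitation is floored at zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    spec = cfg.coarse_spec
    lats = spec.center_lats()[:, None] * np.ones((1, spec.n_cols))
    temp, precip, solar = {}, {}, {}
    for key in cfg.climate_keys():
        year, month = key
        t = cfg.temp_mean + cfg.temp_amplitude * np.cos(
            2.0 * np.pi * (month - 7) / 12.0) * np.ones(spec.shape)
        p = cfg.precip_mean + cfg.precip_amplitude * np.cos(
            2.0 * np.pi * (month - 6) / 12.0) * np.ones(spec.shape)
        if cfg.temp_noise_sd > 0:
            t = t + rng.normal(0.0, cfg.temp_noise_sd, spec.shape)
        if cfg.precip_noise_sd > 0:
            p = p + rng.normal(0.0, cfg.precip_noise_sd, spec.shape)
        temp[key] = Raster(spec, t, nodata=-9999.0, units="degC")
        precip[key] = Raster(spec, np.maximum(p, 0.0), nodata=-9999.0,
                             units="mm month-1")
        solar[key] = Raster(spec, clear_sky_solar_month(lats, year, month),
                            nodata=-9999.0, units="MJ m-2 month-1")
    return ClimateInputs(MonthlyStack(temp), MonthlyStack(precip),
                         MonthlyStack(solar))


# ---------------------------------------------------------------------------
# Towers
# ---------------------------------------------------------------------------

def make_towers(cfg: SceneConfig, composite_npp: MonthlyStack,
                frac: FractionalCover | None = None,
                n_sites: int = 6, true_ratio: float = 0.47,
                noise_sd: float = 0.0) -> list[TowerRecord]:
    """Flux-tower GPP records consistent with a known composite NPP.

    GPP = composite NPP at the tower pixel / true_ratio + noise, floored
    at zero; sites sit at the centers of distinct random valid pixels and
    cover at least three complete years (all reporting months are
    emitted).  The cover label is the locally dominant class when the
    fractional cover is supplied.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    spec = composite_npp.spec
    keys = composite_npp.keys()
    if len(keys) < 36:
        raise ValueError("composite must span >= 3 years for usable towers")

    valid = np.ones(spec.shape, dtype=bool)
    for key in keys:
        valid &= composite_npp[key].valid_mask()
    flat = np.flatnonzero(valid)
    if len(flat) < n_sites:
        raise ValueError("not enough valid pixels to place towers")
    chosen = rng.choice(flat, size=n_sites, replace=False)

    records = []
    for i, idx in enumerate(np.sort(chosen)):
        row, col = divmod(int(idx), spec.n_cols)
        lon, lat = spec.cell_center(row, col)
        cover = "unknown"
        if frac is not None:
            cover = max(frac.classes(), key=lambda c: frac[c].values[row, col])
        rows = []
        for (year, month) in keys:
            npp = composite_npp[(year, month)].values[row, col]
            gpp = npp / true_ratio
            if noise_sd > 0:
                gpp += rng.normal(0.0, noise_sd)
            rows.append({"year": year, "month": month, "gpp": max(gpp, 0.0)})
        records.append(TowerRecord(f"SYN{i:02d}", lon, lat, cover,
                                   pd.DataFrame(rows)))
    return records


# ---------------------------------------------------------------------------
# Whole-scene export
# ---------------------------------------------------------------------------

def write_scene(cfg: SceneConfig, outdir: str | Path) -> dict:
    """Generate and write a complete scene to a directory.

    Products: landcover_fine.tif, soil.tif, monthly {evi,temp,precip,
    solar}_{YYYY}_{MM}.tif, per-class fraction GeoTIFFs, towers are left
    to the pipeline runner (they need the composite NPP).  truth.json
    records the configuration, class codes and phenology curves.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lc, frac = make_landscape(cfg)
    evi, curves = make_evi(cfg, frac)
    climate = make_climate(cfg)

    write_geotiff(lc, outdir / "landcover_fine.tif")
    soil_codes = np.ones(cfg.coarse_spec.shape, dtype=np.int32)
    write_geotiff(Raster(cfg.coarse_spec, soil_codes, nodata=-1,
                         units="soil code"), outdir / "soil.tif")
    for name in cfg.classes:
        safe = name.replace(" ", "_")
        write_geotiff(frac[name], outdir / f"fraction_{safe}.tif")
    for var, stack in (("evi", evi), ("temp", climate.temperature),
                       ("precip", climate.precipitation),
                       ("solar", climate.solar)):
        for (year, month), raster in stack.items():
            write_geotiff(raster, outdir / f"{var}_{year}_{month:02d}.tif")

    truth = {
        "seed": cfg.seed,
        "classes": {name: code for name, code
                    in zip(cfg.classes, cfg.cover_classes.codes)},
        "soil_codes": {"1": cfg.soil_class},
        "phenology": curves,
        "start_year": cfg.start_year,
        "n_years": cfg.n_years,
        "spinup_years": cfg.spinup_years,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
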