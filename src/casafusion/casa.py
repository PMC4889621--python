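"""Light-use-efficiency (CASA) NPP model with a three-layer soil water balance.

Monthly net primary production per pixel is

    NPP = Sr * IVI * e_max * T * W        [gC m-2 month-1]

where Sr is total surface solar irradiance (MJ m-2 month-1), IVI the
(per-land-cover interpolated) vegetation index, e_max a constant maximum
light-use efficiency (0.55 gC per MJ PAR; the irradiance-to-PAR conversion
is absorbed into the constant, so the equation multiplies Sr directly), T a
temperature stress scalar in [0, 1] built around a pixel-wise optimum
temperature, and W a moisture stress scalar in [0.5, 1] from the ratio of
estimated to potential evapotranspiration.

PET follows Priestley-Taylor with the net radiation term taken equal to the
solar irradiance input.  Soil moisture is tracked in three buckets (surface
organic layer, topsoil, subsoil to rooting depth) whose capacities depend
on a clay-content texture class; precipitation recharges the layers
top-down to field capacity, excess drains, and evapotranspiration draws the
stores down.  The balance is spun up over two years of forcing before the
first reporting month so the reported W reflects an equilibrated reservoir.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, MonthlyStack, Raster

#: Maximum light-use efficiency, gC per MJ PAR.
E_MAX_DEFAULT = 0.55

#: Priestley-Taylor coefficient (dimensionless).
PT_ALPHA = 1.26
#: Psychrometric constant, kPa per degC.
PSYCHROMETRIC_GAMMA = 0.066
#: Latent heat of vaporisation, MJ per kg (1 kg water over 1 m2 == 1 mm).
LAMBDA_VAPORIZATION = 2.45

#: Soil texture classes: three-layer water-holding capacities in mm
#: (surface organic, topsoil, subsoil-to-rooting-depth).  Lithosols hold
#: the least water, organic soils the most; the clay classes step linearly
#: between their end members.
DEFAULT_SOIL_CAPACITIES: dict[str, tuple[float, float, float]] = {
    "organic": (40.0, 150.0, 300.0),
    "clay_0_5": (25.0, 100.0, 200.0),
    "clay_5_15": (21.667, 86.667, 173.333),
    "clay_15_30": (18.333, 73.333, 146.667),
    "clay_ge_30": (15.0, 60.0, 120.0),
    "lithosol": (10.0, 40.0, 80.0),
}


@dataclass(frozen=True)
class SoilTexture:
    """A clay-content texture class with its layer capacities.

    ``rooting_multiplier`` scales the subsoil (third-layer) capacity; 1.8
    reproduces the deep-rooted woodland adjustment that makes 80 % more
    soil water available to trees, as a configuration option (default 1.0).
    """

    class_code: str
    layer_capacity: tuple[float, float, float]
    rooting_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.layer_capacity):
            raise ValueError("layer capacities must be non-negative")
        if self.rooting_multiplier < 1.0:
            raise ValueError("rooting_multiplier must be >= 1")

    @property
    def effective_capacity(self) -> np.ndarray:
        """Per-layer storage (mm) after the rooting-depth adjustment."""
        c1, c2, c3 = self.layer_capacity
        return np.array([c1, c2, c3 * self.rooting_multiplier])


def soil_textures_from_yaml(path) -> dict[int, SoilTexture]:
    """Load a raster-code -> texture map from YAML.

    Each entry: ``code: {class: <name>, capacities: [mm, mm, mm],
    rooting_multiplier: x}``; capacities and multiplier are optional and
    default to the built-in table / 1.0.
    """
    import yaml
    mapping = yaml.safe_load(open(path))
    if not isinstance(mapping, dict) or not mapping:
        raise ValueError(f"{path}: expected a non-empty {{code: spec}} mapping")
    out: dict[int, SoilTexture] = {}
    for code, entry in mapping.items():
        name = entry["class"]
        caps = tuple(entry.get("capacities",
                               DEFAULT_SOIL_CAPACITIES.get(name, ())))
        if len(caps) != 3:
            raise ValueError(f"soil class {name!r}: need three layer capacities")
        out[int(code)] = SoilTexture(name, caps,
                                     float(entry.get("rooting_multiplier", 1.0)))
    return out


def soil_texture(class_code: str, rooting_multiplier: float = 1.0) -> SoilTexture:
    """Texture class by name with the default capacity table."""
    try:
        caps = DEFAULT_SOIL_CAPACITIES[class_code]
    except KeyError:
        raise ValueError(
            f"unknown soil texture class {class_code!r}; "
            f"known: {sorted(DEFAULT_SOIL_CAPACITIES)}") from None
    return SoilTexture(class_code, caps, rooting_multiplier)


@dataclass
class SoilMoistureState:
    """Water content (mm) in the three soil layers."""

    layers: np.ndarray  # shape (3,) or (3, ...) for gridded runs

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=np.float64)
        if self.layers.shape[0] != 3:
            raise ValueError("state must have three layers")
        if (self.layers < 0).any():
            raise ValueError("layer contents must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return self.layers.sum(axis=0)

    def copy(self) -> "SoilMoistureState":
        return SoilMoistureState(self.layers.copy())


@dataclass
class CasaParams:
    """Model constants: light-use efficiency, optimum temperature, flooring."""

    e_max: float = E_MAX_DEFAULT
    topt: float | Raster | None = None  # None -> derived from climate
    npp_nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        topt_vals = (self.topt.values if isinstance(self.topt, Raster)
                     else self.topt)
        if topt_vals is not None:
            arr = np.asarray(topt_vals, dtype=np.float64)
            if ((arr < 0) | (arr > 35)).any():
                raise ValueError("topt must lie within [0, 35] degC")


@dataclass
class ClimateInputs:
    """Monthly forcing: temperature (degC), precipitation (mm month-1),
    solar irradiance (MJ m-2 month-1), on one shared grid."""

    temperature: MonthlyStack
    precipitation: MonthlyStack
    solar: MonthlyStack

    def __post_init__(self) -> None:
        spec = self.temperature.spec
        if not (self.precipitation.spec.approx_equal(spec)
                and self.solar.spec.approx_equal(spec)):
            raise ValueError("climate stacks must share one GridSpec")
        if self.temperature.keys() != self.precipitation.keys() or \
                self.temperature.keys() != self.solar.keys():
            raise ValueError("climate stacks must cover identical months")

    @property
    def spec(self) -> GridSpec:
        return self.temperature.spec

    def keys(self) -> list[tuple[int, int]]:
        return self.temperature.keys()


@dataclass
class NPPResult:
    """Per-class and composite monthly NPP plus model diagnostics."""

    per_class: dict[str, MonthlyStack]
    composite: MonthlyStack | None = None
    diagnostics: dict[str, MonthlyStack] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def lst_dn_to_celsius(dn):
    """MODIS land-surface-temperature digital number to degC: dn*0.02 - 273.15."""
    dn = np.asarray(dn, dtype=np.float64)
    if (dn < 0).any():
        raise ValueError("LST digital numbers must be non-negative")
    out = dn * 0.02 - 273.15
    return float(out) if out.ndim == 0 else out


def daily_to_monthly_precip(daily_mean, year: int, month: int):
    """Mean daily precipitation (mm/day) to a leap-aware monthly total."""
    if not 1 <= month <= 12:
        raise ValueError(f"invalid month {month}")
    daily = np.asarray(daily_mean, dtype=np.float64)
    if (daily < 0).any():
        raise ValueError("daily precipitation must be non-negative")
    out = daily * calendar.monthrange(year, month)[1]
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Stress scalars and PET
# ---------------------------------------------------------------------------

def temperature_scalar(t, topt):
    """Temperature stress T = T1 * T2, clipped to [0, 1].

    T1 = 0.8 + 0.02*topt - 0.0005*topt^2 penalises extreme optima;
    T2 = 1.1814 / [(1 + exp(0.2*(topt - 10 - t))) * (1 + exp(0.3*(-topt - 10 + t)))]
    is a double-logistic response peaking near t == topt and collapsing in
    deep cold or heat.
    """
    t = np.asarray(t, dtype=np.float64)
    topt = np.asarray(topt, dtype=np.float64)
    t1 = 0.8 + 0.02 * topt - 0.0005 * topt ** 2
    # exp args clipped to avoid overflow far outside the physical range
    a = np.clip(0.2 * (topt - 10.0 - t), -700, 700)
    b = np.clip(0.3 * (-topt - 10.0 + t), -700, 700)
    t2 = 1.1814 / ((1.0 + np.exp(a)) * (1.0 + np.exp(b)))
    out = np.clip(t1 * t2, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def saturation_slope(t):
    """Slope of the saturation vapour-pressure curve, kPa per degC."""
    t = np.asarray(t, dtype=np.float64)
    return 4098.0 * 0.6108 * np.exp(17.27 * t / (t + 237.3)) / (t + 237.3) ** 2


def priestley_taylor_pet(t, rn):
    """Priestley-Taylor potential evapotranspiration, mm per month.

    PET = alpha * Delta/(Delta + gamma) * Rn/lambda, floored at zero;
    Rn is supplied in MJ m-2 month-1.
    """
    rn = np.asarray(rn, dtype=np.float64)
    if (rn < 0).any():
        raise ValueError("net radiation must be non-negative")
    delta = saturation_slope(t)
    pet = PT_ALPHA * (delta / (delta + PSYCHROMETRIC_GAMMA)) * rn / LAMBDA_VAPORIZATION
    out = np.maximum(pet, 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Water balance
# ---------------------------------------------------------------------------

def water_balance_step(state: SoilMoistureState, precip, pet,
                       soil: SoilTexture | np.ndarray):
    """Advance the three-layer bucket one month.

    When precipitation meets the evaporative demand, EET = PET and the
    surplus recharges the layers top-down to capacity, the remainder
    leaving as drainage.  Otherwise all precipitation evaporates and the
    deficit is drawn from the soil stores top-down, limited by their
    content, so EET = min(PET, precip + extractable soil water).  The
    monthly budget  precip = d(storage) + EET + drainage  closes exactly.

    Returns (new_state, eet, w_scalar, drainage); w = 0.5 + 0.5*EET/PET
    when PET > 0 (else 1.0), hence in [0.5, 1].
    """
    caps = soil.effective_capacity if isinstance(soil, SoilTexture) else np.asarray(soil)
    layers = state.layers.astype(np.float64, copy=True)
    precip = np.asarray(precip, dtype=np.float64)
    pet = np.asarray(pet, dtype=np.float64)
    if (precip < 0).any() or (pet < 0).any():
        raise ValueError("precipitation and PET must be non-negative")

    shape = np.broadcast_shapes(layers.shape[1:], precip.shape, pet.shape)
    precip = np.broadcast_to(precip, shape).copy()
    pet = np.broadcast_to(pet, shape)
    if layers.shape[1:] != shape:
        layers = np.broadcast_to(layers, (3, *shape)).copy()
    if caps.ndim == 1:
        caps = caps.reshape(3, *([1] * len(shape)))
    caps = np.broadcast_to(caps, (3, *shape))

    eet = np.minimum(pet, precip).astype(np.float64)
    surplus = precip - eet          # >= 0 where precip >= pet
    deficit = pet - eet             # >= 0 where pet > precip

    # recharge top-down with the surplus
    for i in range(3):
        room = caps[i] - layers[i]
        add = np.minimum(surplus, np.maximum(room, 0.0))
        layers[i] += add
        surplus = surplus - add
    drainage = surplus

    # draw the unmet demand from the stores top-down
    for i in range(3):
        take = np.minimum(deficit, layers[i])
        layers[i] -= take
        eet = eet + take
        deficit = deficit - take

    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(pet > 0, 0.5 + 0.5 * (eet / np.where(pet > 0, pet, 1.0)), 1.0)
    w = np.clip(w, 0.5, 1.0)

    new_state = SoilMoistureState(layers)
    if np.ndim(w) == 0 or w.shape == ():
        return new_state, float(eet), float(w), float(drainage)
    return new_state, eet, w, drainage


def spin_up(climate: ClimateInputs, soil: SoilTexture | np.ndarray,
            params: CasaParams | None = None) -> SoilMoistureState:
    """Initialise soil moisture by running the first 24 forcing months.

    Layers start at half capacity; the end-state after two years of the
    water balance is returned as the initial state for the first reporting
    year.  Deterministic: no randomness anywhere in the balance.
    """
    keys = climate.keys()
    if len(keys) < 24:
        raise ValueError(f"spin-up needs >= 24 months of climate, have {len(keys)}")
    caps = soil.effective_capacity if isinstance(soil, SoilTexture) else np.asarray(soil)
    shape = climate.spec.shape
    layers = np.broadcast_to(caps.reshape(3, *([1] * len(shape))) / 2.0,
                             (3, *shape)).copy()
    state = SoilMoistureState(layers)
    for key in keys[:24]:
        t = climate.temperature[key].masked()
        p = np.nan_to_num(climate.precipitation[key].masked(), nan=0.0)
        rn = np.nan_to_num(climate.solar[key].masked(), nan=0.0)
        pet = priestley_taylor_pet(np.nan_to_num(t, nan=0.0), rn)
        state, _, _, _ = water_balance_step(state, p, pet, caps)
    return state


# ---------------------------------------------------------------------------
# NPP
# ---------------------------------------------------------------------------

def casa_npp_month(sr, ivi, e_max, t_scalar, w_scalar, npp_nonnegative: bool = True):
    """One month of NPP: Sr * IVI * e_max * T * W (gC m-2 month-1).

    With the non-negativity flag (default), negative vegetation-index
    values (open water, snow) contribute zero rather than negative carbon.
    """
    ivi = np.asarray(ivi, dtype=np.float64)
    if npp_nonnegative:
        ivi = np.maximum(ivi, 0.0)
    out = np.asarray(sr, dtype=np.float64) * ivi * e_max \
        * np.asarray(t_scalar, dtype=np.float64) * np.asarray(w_scalar, dtype=np.float64)
    return float(out) if out.ndim == 0 else out


def derive_topt(climate: ClimateInputs) -> np.ndarray:
    """Default per-pixel optimum temperature.

    Long-term mean temperature of the climatologically warmest month,
    clipped to [0, 35] degC — a latitude/longitude-varying optimum without
    an external map.
    """
    by_month: dict[int, list[np.ndarray]] = {}
    for (_, m), r in climate.temperature.items():
        by_month.setdefault(m, []).append(r.masked())
    clim = np.stack([np.nanmean(np.stack(v), axis=0) for v in by_month.values()])
    with np.errstate(invalid="ignore"):
        warmest = np.nanmax(clim, axis=0)
    return np.clip(np.nan_to_num(warmest, nan=20.0), 0.0, 35.0)


def _split_spinup_reporting(climate: ClimateInputs, reporting_keys):
    """Forcing months used for spin-up, given the reporting span.

    Preferred: the 24 climate months immediately before the first
    reporting month.  Fallback when the climate covers only the reporting
    span: the first reporting year repeated twice.
    """
    keys = climate.keys()
    first = reporting_keys[0]
    if first not in keys:
        raise ValueError(f"climate does not cover reporting month {first}")
    pos = keys.index(first)
    if pos >= 24:
        return keys[pos - 24:pos], False
    if len(keys) - pos < 12:
        raise ValueError("climate span too short: need 24 pre-reporting months "
                         "or at least 12 reporting months to repeat as spin-up")
    return keys[pos:pos + 12] * 2, True


def run_casa_class(ivi_stack: MonthlyStack, climate: ClimateInputs,
                   soil: SoilTexture | Raster, params: CasaParams = CasaParams(),
                   soil_map: dict[int, SoilTexture] | None = None
                   ) -> tuple[MonthlyStack, dict[str, MonthlyStack]]:
    """Run the model for one land-cover class over its IVI stack.

    Per pixel: spin up the soil reservoir, then for each reporting month
    compute the temperature scalar, step the water balance for the moisture
    scalar, and emit NPP.  ``soil`` is either a single texture class or an
    integer-coded raster mapped through ``soil_map``.  Returns the NPP
    stack and diagnostics stacks (t_scalar, w_scalar, pet, eet, drainage).
    """
    spec = climate.spec
    if not ivi_stack.spec.approx_equal(spec):
        raise ValueError("IVI grid is not aligned with the climate grids")

    if isinstance(soil, Raster):
        if soil_map is None:
            raise ValueError("a soil-texture raster requires soil_map (code -> SoilTexture)")
        caps = np.zeros((3, *spec.shape))
        codes = soil.values
        known = np.zeros(spec.shape, dtype=bool)
        for code, tex in soil_map.items():
            hit = codes == code
            caps[:, hit] = tex.effective_capacity[:, None]
            known |= hit
        if not known.all() and soil.valid_mask()[~known].any():
            bad = sorted(set(np.unique(codes[soil.valid_mask() & ~known]).tolist()))
            raise ValueError(f"soil raster contains unmapped texture code(s): {bad}")
    else:
        caps = np.broadcast_to(
            soil.effective_capacity.reshape(3, 1, 1), (3, *spec.shape)).copy()

    reporting = ivi_stack.keys()
    spin_keys, repeated = _split_spinup_reporting(climate, reporting)

    if params.topt is None:
        topt = derive_topt(climate)
    elif isinstance(params.topt, Raster):
        topt = params.topt.masked()
    else:
        topt = np.full(spec.shape, float(params.topt))

    # spin-up from half capacity over the chosen 24 forcing months
    state = SoilMoistureState(caps / 2.0)
    for key in spin_keys:
        t = np.nan_to_num(climate.temperature[key].masked(), nan=0.0)
        p = np.nan_to_num(climate.precipitation[key].masked(), nan=0.0)
        rn = np.nan_to_num(climate.solar[key].masked(), nan=0.0)
        state, _, _, _ = water_balance_step(state, p, priestley_taylor_pet(t, rn), caps)

    nodata = -9999.0
    npp_out: dict[tuple[int, int], Raster] = {}
    diag: dict[str, dict[tuple[int, int], Raster]] = {
        k: {} for k in ("t_scalar", "w_scalar", "pet", "eet", "drainage")}
    for key in reporting:
        t = climate.temperature[key].masked()
        p = np.nan_to_num(climate.precipitation[key].masked(), nan=0.0)
        rn = np.nan_to_num(climate.solar[key].masked(), nan=0.0)
        ivi = ivi_stack[key].masked()

        pet = priestley_taylor_pet(np.nan_to_num(t, nan=0.0), rn)
        state, eet, w, drainage = water_balance_step(state, p, pet, caps)
        ts = temperature_scalar(np.nan_to_num(t, nan=0.0), topt)
        npp = casa_npp_month(rn, ivi, params.e_max, ts, w, params.npp_nonnegative)

        invalid = ~np.isfinite(ivi) | ~np.isfinite(t)
        npp = np.where(invalid, nodata, npp)
        npp_out[key] = Raster(spec, npp, nodata=nodata, units="gC m-2 month-1")
        for name, arr in (("t_scalar", ts), ("w_scalar", w), ("pet", pet),
                          ("eet", eet), ("drainage", drainage)):
            diag[name][key] = Raster(spec, np.asarray(arr, dtype=np.float64),
                                     nodata=nodata, units="")

    diagnostics = {k: MonthlyStack(v) for k, v in diag.items()}
    return MonthlyStack(npp_out), diagnostics
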