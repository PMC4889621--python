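"""Sub-pixel land-cover fusion: fractional cover, pure pixels and per-class IDW.

The fusion chain turns a fine-resolution categorical land-cover raster
(~30 m) and a coarse monthly vegetation-index stack (~500 m) into one
interpolated vegetation index (IVI) surface per land-cover class:

1. aggregate the fine land cover to per-class fractional cover on the
   coarse grid (fine-cell-center containment counting);
2. mark coarse pixels whose dominant class fraction is at least the purity
   threshold (default 0.9) as "pure", convert them to their center points
   and sample the coarse EVI there month by month;
3. interpolate each class's pure-pixel EVI samples over the whole grid by
   inverse-distance weighting, with the IDW power chosen per class by
   leave-one-out cross-validation (minimum RMSPE).

The IVI stack for a class represents the EVI the landscape would show if
every pixel were purely that class; classes with no pure pixels anywhere
are flagged unavailable and excluded downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .grids import GridSpec, MonthlyStack, Raster, full_raster

#: Valid range of the enhanced vegetation index.
EVI_RANGE = (-0.2, 1.0)

#: Land-cover classes named in the source workflow (10 listed; the class
#: set is configuration-driven).
DEFAULT_CLASSES = (
    "water", "evergreen forest", "wetlands", "lichen", "mixed forest",
    "woodlands", "grasslands", "croplands", "deciduous forest", "brushland",
)


@dataclass(frozen=True)
class CoverClassSet:
    """Ordered land-cover classes with their integer raster codes."""

    classes: tuple[str, ...] = DEFAULT_CLASSES
    codes: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.codes is None:
            object.__setattr__(self, "codes", tuple(range(1, len(self.classes) + 1)))
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class names must be unique")
        if len(self.codes) != len(self.classes):
            raise ValueError("one code per class required")
        if len(set(self.codes)) != len(self.codes) or any(c < 0 for c in self.codes):
            raise ValueError("codes must be unique and non-negative")

    def __len__(self) -> int:
        return len(self.classes)

    def code_of(self, name: str) -> int:
        return self.codes[self.classes.index(name)]

    @classmethod
    def from_yaml(cls, path) -> "CoverClassSet":
        """Load a class map from YAML: a flat ``{code: name}`` mapping."""
        import yaml
        mapping = yaml.safe_load(open(path))
        if not isinstance(mapping, dict) or not mapping:
            raise ValueError(f"{path}: expected a non-empty {{code: name}} mapping")
        codes = tuple(int(c) for c in mapping)
        return cls(tuple(str(mapping[c]) for c in mapping), codes)


@dataclass
class FractionalCover:
    """Per-class fraction rasters on the coarse grid (step-1 product)."""

    spec: GridSpec
    fractions: dict[str, Raster]

    def __getitem__(self, name: str) -> Raster:
        return self.fractions[name]

    def classes(self) -> list[str]:
        return list(self.fractions.keys())


@dataclass
class ClassSamples:
    """Pure-pixel center points of one class with their monthly EVI samples.

    ``evi[(year, month)]`` aligns with ``points``; missing samples are NaN.
    """

    class_name: str
    points: np.ndarray  # (n, 2) of (lon, lat)
    evi: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class IDWParams:
    """Inverse-distance-weighting configuration.

    The "variable search radius" of the source workflow is realised as
    k-nearest-neighbour search (default k=12) with no distance cap.
    Distances are planar in degrees on the model grid.
    """

    power: float = 2.0
    candidate_powers: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
    max_neighbors: int = 12

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be positive")
        if not self.candidate_powers:
            raise ValueError("candidate_powers must be non-empty")


# ---------------------------------------------------------------------------
# Step 1: fractional cover
# ---------------------------------------------------------------------------

def aggregate_fractional_cover(fine_lc: Raster, coarse_spec: GridSpec,
                               classes: CoverClassSet) -> FractionalCover:
    """Fraction of each class per coarse pixel, by fine-cell-center counting.

    fraction(k) = #(valid fine cells of class k whose centers fall in the
    coarse pixel) / #(valid fine cells in the pixel).  Coarse pixels with no
    valid fine coverage are nodata in every class raster.
    """
    if fine_lc.spec.cell_size >= coarse_spec.cell_size:
        raise ValueError("fine cell size must be smaller than coarse cell size")

    codes = np.asarray(fine_lc.values)
    valid = fine_lc.valid_mask()
    known = np.isin(codes, classes.codes)
    bad = valid & ~known
    if bad.any():
        offending = sorted(set(np.unique(codes[bad]).tolist()))
        raise ValueError(f"unknown land-cover code(s) in fine raster: {offending}")

    lons = fine_lc.spec.center_lons()
    lats = fine_lc.spec.center_lats()
    rows, cols = coarse_spec.index_of(lons[None, :], lats[:, None])
    inside = (rows >= 0) & (rows < coarse_spec.n_rows) & \
             (cols >= 0) & (cols < coarse_spec.n_cols)
    use = valid & inside

    flat = (rows * coarse_spec.n_cols + cols)[use]
    n_cells = coarse_spec.n_rows * coarse_spec.n_cols
    total = np.bincount(flat, minlength=n_cells).astype(np.float64)

    nodata = -9999.0
    fractions: dict[str, Raster] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name, code in zip(classes.classes, classes.codes):
            count = np.bincount(flat[codes[use] == code], minlength=n_cells)
            frac = np.where(total > 0, count / np.maximum(total, 1), nodata)
            fractions[name] = Raster(coarse_spec, frac.reshape(coarse_spec.shape),
                                     nodata=nodata, units="fraction")
    return FractionalCover(coarse_spec, fractions)


# ---------------------------------------------------------------------------
# Step 2: pure pixels and EVI sampling
# ---------------------------------------------------------------------------

def identify_pure_pixels(frac: FractionalCover,
                         threshold: float = 0.9) -> list[ClassSamples]:
    """Centers of coarse pixels whose class fraction meets the purity threshold.

    The threshold is inclusive: fraction == threshold counts as pure.
    Classes with no pure pixel yield an empty sample set and a warning.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out: list[ClassSamples] = []
    for name in frac.classes():
        r = frac[name]
        pure = r.valid_mask() & (r.values >= threshold)
        rr, cc = np.nonzero(pure)
        lons = frac.spec.origin_lon + (cc + 0.5) * frac.spec.cell_size
        lats = frac.spec.origin_lat - (rr + 0.5) * frac.spec.cell_size
        points = np.column_stack([lons, lats])
        if len(points) == 0:
            warnings.warn(f"class {name!r} has no pure pixels at threshold "
                          f"{threshold}; it will be unavailable downstream")
        out.append(ClassSamples(name, points))
    return out


def sample_evi_at_points(evi: MonthlyStack, samples: ClassSamples) -> ClassSamples:
    """Extract the containing-pixel EVI value per point and month.

    Nodata months become NaN (missing), never zero.  Points must lie inside
    the EVI grid extent.
    """
    pts = samples.points
    if len(pts):
        inside = evi.spec.contains(pts[:, 0], pts[:, 1])
        if not inside.all():
            raise ValueError(
                f"{int((~inside).sum())} point(s) of class {samples.class_name!r} "
                "fall outside the EVI grid extent")
    out = ClassSamples(samples.class_name, pts)
    for key, raster in evi.items():
        if len(pts) == 0:
            out.evi[key] = np.empty(0)
            continue
        rows, cols = evi.spec.index_of(pts[:, 0], pts[:, 1])
        vals = raster.masked()[rows, cols]
        out.evi[key] = vals
    return out


# ---------------------------------------------------------------------------
# Step 3: IDW interpolation with cross-validated power
# ---------------------------------------------------------------------------

def _idw_predict(sample_xy: np.ndarray, sample_z: np.ndarray,
                 query_xy: np.ndarray, power: float,
                 max_neighbors: int | None) -> np.ndarray:
    """Core IDW predictor: weighted mean over the k nearest samples.

    A query coinciding with one or more samples returns the exact sample
    value (the mean over coincident samples), making IDW an exact
    interpolator without a division by zero.
    """
    n = len(sample_xy)
    k = n if max_neighbors is None else min(max_neighbors, n)
    tree = cKDTree(sample_xy)
    dist, idx = tree.query(query_xy, k=k)
    if dist.ndim == 1:  # k == 1
        dist = dist[:, None]
        idx = idx[:, None]

    out = np.empty(len(query_xy))
    exact = dist[:, 0] == 0.0
    if exact.any():
        for i in np.nonzero(exact)[0]:
            hit = dist[i] == 0.0
            out[i] = sample_z[idx[i][hit]].mean()
    rest = ~exact
    if rest.any():
        w = dist[rest] ** (-power)
        out[rest] = (w * sample_z[idx[rest]]).sum(axis=1) / w.sum(axis=1)
    return out


def _valid_month(samples: ClassSamples, key: tuple[int, int]):
    z = samples.evi[key]
    ok = np.isfinite(z)
    return samples.points[ok], z[ok]


def idw_rmspe(samples: ClassSamples, month: tuple[int, int],
              power: float) -> float:
    """Leave-one-out root mean square prediction error for one month.

    Each sample point is predicted by IDW (given power, all other points as
    neighbours); coincident duplicate points predict each other exactly.
    """
    xy, z = _valid_month(samples, month)
    if len(xy) < 2:
        raise ValueError(
            f"class {samples.class_name!r} month {month}: need >= 2 valid "
            f"sample points for cross-validation, have {len(xy)}")
    errs = np.empty(len(xy))
    for i in range(len(xy)):
        mask = np.arange(len(xy)) != i
        pred = _idw_predict(xy[mask], z[mask], xy[i:i + 1], power, None)[0]
        errs[i] = pred - z[i]
    return float(np.sqrt(np.mean(errs ** 2)))


def select_idw_power(samples: ClassSamples, month: tuple[int, int],
                     candidate_powers) -> float:
    """Candidate power with the minimum LOO RMSPE; ties go to the smallest."""
    candidates = sorted(candidate_powers)
    if not candidates:
        raise ValueError("candidate_powers must be non-empty")
    scores = np.array([idw_rmspe(samples, month, p) for p in candidates])
    # scores within 1e-12 of the minimum are ties (weight-sum rounding);
    # the smallest such power wins
    best = scores.min()
    return candidates[int(np.flatnonzero(scores <= best + 1e-12)[0])]


def idw_interpolate(samples: ClassSamples, month: tuple[int, int],
                    target_spec: GridSpec, params: IDWParams) -> Raster:
    """IDW surface of one class/month over the target grid, clipped to EVI range."""
    xy, z = _valid_month(samples, month)
    if len(xy) == 0:
        raise ValueError(
            f"class {samples.class_name!r} month {month}: no valid samples")
    lons = target_spec.center_lons()
    lats = target_spec.center_lats()
    gx, gy = np.meshgrid(lons, lats)
    query = np.column_stack([gx.ravel(), gy.ravel()])
    vals = _idw_predict(xy, z, query, params.power, params.max_neighbors)
    vals = np.clip(vals, *EVI_RANGE)
    return Raster(target_spec, vals.reshape(target_spec.shape),
                  nodata=-9999.0, units="EVI")


def build_ivi(evi: MonthlyStack, frac: FractionalCover, classes: CoverClassSet,
              params: IDWParams = IDWParams(), threshold: float = 0.9,
              select_power: bool = True,
              power_per_month: bool = False) -> tuple[dict[str, MonthlyStack], list[str]]:
    """Compose steps 1-3: per-class interpolated EVI stacks over the full grid.

    Returns (class -> IVI MonthlyStack, list of unavailable classes).  By
    default one IDW power is selected per class by cross-validation on a
    representative month (the month of highest mean sampled EVI, i.e. peak
    greenness); set ``power_per_month`` for a monthly refinement.
    """
    point_sets = {s.class_name: s for s in identify_pure_pixels(frac, threshold)}
    ivi: dict[str, MonthlyStack] = {}
    unavailable: list[str] = []
    for name in classes.classes:
        if name not in point_sets:
            continue
        pts = point_sets[name]
        if pts.n_points == 0:
            unavailable.append(name)
            continue
        samples = sample_evi_at_points(evi, pts)

        class_power = params.power
        if select_power and not power_per_month and pts.n_points >= 2:
            rep = max(samples.evi, key=lambda k: np.nanmean(samples.evi[k])
                      if np.isfinite(samples.evi[k]).any() else -np.inf)
            if np.isfinite(samples.evi[rep]).sum() >= 2:
                class_power = select_idw_power(samples, rep, params.candidate_powers)

        stack: dict[tuple[int, int], Raster] = {}
        for key in evi.keys():
            p = class_power
            if select_power and power_per_month and \
                    np.isfinite(samples.evi[key]).sum() >= 2:
                p = select_idw_power(samples, key, params.candidate_powers)
            month_params = IDWParams(power=p,
                                     candidate_powers=params.candidate_powers,
                                     max_neighbors=params.max_neighbors)
            stack[key] = idw_interpolate(samples, key, frac.spec, month_params)
        ivi[name] = MonthlyStack(stack)
    return ivi, unavailable
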