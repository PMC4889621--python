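"""Steps 4-5: scale per-class NPP by fractional cover and sum per pixel.

Only cover types actually present in a pixel (fraction > 0 and with an
available IVI) influence the composite.  When some classes lack pure
pixels their fraction is missing from the sum; by default the composite is
renormalised by the contributing fraction so the remaining classes are not
biased low, and a coverage-diagnostic raster records that fraction.
"""

from __future__ import annotations

import numpy as np

from .grids import MonthlyStack, Raster
from .fusion import FractionalCover


def weight_by_fraction(npp_class: MonthlyStack, fraction: Raster) -> MonthlyStack:
    """Elementwise product NPP * fraction; nodata where either is nodata."""
    if not npp_class.spec.approx_equal(fraction.spec):
        raise ValueError("NPP stack and fraction raster are not aligned")
    fmask = fraction.valid_mask()
    fvals = fraction.values

    def scale(r: Raster) -> Raster:
        ok = r.valid_mask() & fmask
        out = np.where(ok, r.values * fvals, r.nodata)
        return Raster(r.spec, out, nodata=r.nodata, units=r.units)

    return npp_class.map(scale)


def composite_npp(weighted: dict[str, MonthlyStack],
                  available_classes: list[str] | None = None,
                  frac: FractionalCover | None = None,
                  renormalize: bool = True
                  ) -> tuple[MonthlyStack, Raster | None]:
    """Per-pixel sum of fraction-weighted class NPP.

    ``weighted`` maps class -> fraction-weighted NPP stack (step-4 output).
    Where the total contributing fraction falls short of 1 (some class had
    no pure pixels), the sum is divided by that fraction when
    ``renormalize`` and ``frac`` is given; the contributing-fraction raster
    is returned as a coverage diagnostic (None when no ``frac`` supplied).
    """
    if not weighted:
        raise ValueError("no per-class NPP stacks to composite")
    classes = available_classes if available_classes is not None else list(weighted)
    classes = [c for c in classes if c in weighted]
    if not classes:
        raise ValueError("none of the available classes has a weighted stack")

    first = weighted[classes[0]]
    keys = first.keys()
    spec = first.spec
    for c in classes:
        if weighted[c].keys() != keys or not weighted[c].spec.approx_equal(spec):
            raise ValueError(f"class {c!r} stack is not aligned with the others")

    coverage = None
    if frac is not None:
        cov = np.zeros(spec.shape)
        any_valid = np.zeros(spec.shape, dtype=bool)
        for c in classes:
            f = frac[c]
            ok = f.valid_mask()
            cov[ok] += f.values[ok]
            any_valid |= ok
        cov = np.where(any_valid, cov, -9999.0)
        coverage = Raster(spec, cov, nodata=-9999.0, units="fraction")

    nodata = -9999.0
    out: dict[tuple[int, int], Raster] = {}
    for key in keys:
        total = np.zeros(spec.shape)
        valid = np.zeros(spec.shape, dtype=bool)
        for c in classes:
            r = weighted[c][key]
            ok = r.valid_mask()
            total[ok] += r.values[ok]
            valid |= ok
        if renormalize and coverage is not None:
            cov_ok = coverage.valid_mask() & (coverage.values > 1e-12)
            short = cov_ok & (coverage.values < 1.0 - 1e-6)
            total = np.where(short, total / np.where(short, coverage.values, 1.0), total)
        out[key] = Raster(spec, np.where(valid, total, nodata),
                          nodata=nodata, units="gC m-2 month-1")
    return MonthlyStack(out), coverage


def annual_npp(stack: MonthlyStack, year: int) -> Raster:
    """Simple 12-month sum for one calendar year (utility)."""
    keys = [(year, m) for m in range(1, 13)]
    missing = [k for k in keys if k not in stack]
    if missing:
        raise ValueError(f"year {year} is incomplete in the stack: missing {missing}")
    total = np.zeros(stack.spec.shape)
    valid = np.ones(stack.spec.shape, dtype=bool)
    for k in keys:
        r = stack[k]
        total += np.where(r.valid_mask(), r.values, 0.0)
        valid &= r.valid_mask()
    return Raster(stack.spec, np.where(valid, total, -9999.0),
                  nodata=-9999.0, units="gC m-2 yr-1")
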