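"""End-to-end orchestration: synthetic scene -> fusion -> CASA -> composite -> evaluation.

Thin glue over the library modules, used by the command-line interface and
by reproducibility scripts.  Each step is the public function documented
in its own module; nothing scientific lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import casa, compositing, fusion, synthetic, validation
from .grids import MonthlyStack, Raster


@dataclass
class PipelineResult:
    """Everything the pipeline produced, kept for inspection."""

    landcover: Raster
    frac: fusion.FractionalCover
    evi: MonthlyStack
    ivi: dict[str, MonthlyStack]
    unavailable: list[str]
    climate: casa.ClimateInputs
    npp_per_class: dict[str, MonthlyStack]
    composite: MonthlyStack
    coverage: Raster | None
    diagnostics: dict[str, dict[str, MonthlyStack]] = field(default_factory=dict)


def run_synthetic_pipeline(cfg: synthetic.SceneConfig,
                           idw: fusion.IDWParams | None = None,
                           params: casa.CasaParams | None = None,
                           select_power: bool = False) -> PipelineResult:
    """Run fusion + CASA + compositing on a generated scene.

    ``select_power`` enables the per-class cross-validated IDW power
    search (slower); off, the default power in ``idw`` is used everywhere.
    """
    idw = idw or fusion.IDWParams()
    params = params or casa.CasaParams()

    lc, frac_true = synthetic.make_landscape(cfg)
    evi, _ = synthetic.make_evi(cfg, frac_true)
    climate = synthetic.make_climate(cfg)

    classes = cfg.cover_classes
    frac = fusion.aggregate_fractional_cover(lc, cfg.coarse_spec, classes)
    reporting = cfg.reporting_keys()
    ivi, unavailable = fusion.build_ivi(evi.subset(reporting), frac, classes,
                                        idw, select_power=select_power)

    soil = casa.soil_texture(cfg.soil_class)
    npp_per_class: dict[str, MonthlyStack] = {}
    diagnostics: dict[str, dict[str, MonthlyStack]] = {}
    for name, stack in ivi.items():
        npp, diag = casa.run_casa_class(stack, climate, soil, params)
        npp_per_class[name] = npp
        diagnostics[name] = diag

    weighted = {name: compositing.weight_by_fraction(npp, frac[name])
                for name, npp in npp_per_class.items()}
    composite, coverage = compositing.composite_npp(weighted, frac=frac)

    return PipelineResult(lc, frac, evi, ivi, unavailable, climate,
                          npp_per_class, composite, coverage, diagnostics)


def evaluate_against_towers(result: PipelineResult,
                            records: list[validation.TowerRecord],
                            config: validation.EvalConfig | None = None
                            ) -> tuple[validation.EvalReport, pd.DataFrame]:
    """Run the flux-tower evaluation on a pipeline result."""
    return validation.evaluate(result.composite, records, config)
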