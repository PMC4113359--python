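"""Drought scenario engine: factor grid, warming run, event-depth sweep.

The sensitivity design crosses six levels of the event-depth factor
(1.0 down to 0.5) with six levels of the inter-arrival factor (1.0 up to
1.5) — 36 scenarios including the current-climate baseline — applied to
the growing-season (DJF, SON) rainfall parameters only.  A separate
warming scenario adds the 2100 seasonal temperature offsets while keeping
rainfall at current values.  Summaries report pooled replicate means at
the reporting year and percent change versus the baseline cell.

All cells run under common random numbers (the same replicate seed set),
which makes the response surfaces smooth along the factor axes.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import SimulationConfig, pooled_summary, run_simulation
from .weather import WARMING_2100, ScenarioSpec

__all__ = ["ETA_FACTORS", "LAMBDA_FACTORS", "build_grid", "run_grid",
           "run_warming", "run_eta_sweep"]

ETA_FACTORS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)
LAMBDA_FACTORS = (1.0, 1.1, 1.2, 1.3, 1.4, 1.5)

#: variables summarized per scenario cell
SUMMARY_VARS = ("et_mm", "mean_s", "basal_area_m2_ha", "agb_tc_ha",
                "transpiration_mm", "interception_mm", "pet_mm",
                "pb_realized_gco2_m2")


def build_grid() -> list[ScenarioSpec]:
    """The 36-cell drought factor grid; cell (1.0, 1.0) is the baseline."""
    return [ScenarioSpec(eta_factor=ef, lambda_factor=lf)
            for lf in LAMBDA_FACTORS for ef in ETA_FACTORS]


def _run_cell(config: SimulationConfig, scenario: ScenarioSpec | None,
              replicates: int, report_year: int | None) -> pd.Series:
    cell_cfg = dataclasses.replace(config, scenario=scenario,
                                   replicates=replicates)
    annual = run_simulation(cell_cfg)
    return pooled_summary(annual, report_year)


def run_grid(config: SimulationConfig, replicates: int = 30,
             report_year: int | None = None,
             grid: Sequence[ScenarioSpec] | None = None) -> pd.DataFrame:
    """Run every grid cell; returns a long-format summary table.

    Columns: eta_factor, lambda_factor, variable, baseline_mean,
    scenario_mean, pct_change.  Replicate seeds are shared across cells
    (common random numbers); percent change uses pooled replicate means at
    the reporting year (default: the last simulated year), so the baseline
    cell changes by 0 exactly.
    """
    if grid is None:
        grid = build_grid()
    summaries = {}
    for spec in grid:
        key = (spec.eta_factor, spec.lambda_factor)
        summaries[key] = _run_cell(config, spec, replicates, report_year)
    base_key = (1.0, 1.0)
    if base_key not in summaries:
        summaries[base_key] = _run_cell(config, ScenarioSpec(), replicates,
                                        report_year)
    base = summaries[base_key]
    rows = []
    for (ef, lf), summ in summaries.items():
        for var in SUMMARY_VARS:
            b, v = float(base[var]), float(summ[var])
            pct = (v - b) / b * 100.0 if b != 0 else np.nan
            rows.append((ef, lf, var, b, v, pct))
    return pd.DataFrame(rows, columns=["eta_factor", "lambda_factor",
                                       "variable", "baseline_mean",
                                       "scenario_mean", "pct_change"])


def run_warming(config: SimulationConfig, replicates: int = 30,
                report_year: int | None = None,
                offsets: dict[str, float] | None = None) -> pd.DataFrame:
    """Warming-only scenario (2100 temperature offsets, current rainfall).

    Returns the same long format as :func:`run_grid`, with one scenario
    row set per variable (eta_factor = lambda_factor = 1).
    """
    if offsets is None:
        offsets = dict(WARMING_2100)
    warm = ScenarioSpec(warming_offsets=offsets, affected_seasons=())
    base = _run_cell(config, None, replicates, report_year)
    summ = _run_cell(config, warm, replicates, report_year)
    rows = []
    for var in SUMMARY_VARS:
        b, v = float(base[var]), float(summ[var])
        pct = (v - b) / b * 100.0 if b != 0 else np.nan
        rows.append((1.0, 1.0, var, b, v, pct))
    return pd.DataFrame(rows, columns=["eta_factor", "lambda_factor",
                                       "variable", "baseline_mean",
                                       "scenario_mean", "pct_change"])


def run_eta_sweep(config: SimulationConfig, n_points: int = 6,
                  replicates: int = 5,
                  report_year: int | None = None) -> pd.DataFrame:
    """Monotone sweep of the event-depth factor from 1 toward 0.

    Emits one row per factor with realized gross production, transpiration
    and mean soil moisture at the reporting year (production-vs-moisture
    curves).  Factors below the documented grid are expected here (the
    sweep explores the shutdown limit) — the out-of-grid warning is
    suppressed.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    import warnings

    rows = []
    for f in np.linspace(1.0, 0.0, n_points):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = ScenarioSpec(eta_factor=float(f))
            summ = _run_cell(config, spec, replicates, report_year)
        rows.append((float(f), float(summ["pb_realized_gco2_m2"]),
                     float(summ["transpiration_mm"]), float(summ["mean_s"]),
                     float(summ["et_mm"])))
    return pd.DataFrame(rows, columns=["eta_factor", "pb_realized_gco2_m2",
                                       "transpiration_mm", "mean_s", "et_mm"])
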