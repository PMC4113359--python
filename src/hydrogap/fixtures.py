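"""Synthetic rain-event fixtures for interception verification.

Field studies compare net precipitation (throughfall + stemflow) against
gross rainfall over individual storm events.  This module generates the
model-side analogue: events drawn from the weather generator's seasonal
depth distributions, with expected interception and net precipitation
computed from the canopy equations at a fixed leaf area index.  The
fixture emulates the *shape* of such an event comparison (saturating
interception, net < gross, slope below one); it is synthetic and stands
in for field throughfall data, which it is not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hydrology import CanopyHydroParams, canopy_storage, interception
from .weather import ClimateParams, WeatherGenerator, default_climate

__all__ = ["make_event_fixture"]


def make_event_fixture(n_events: int = 50, lai: float = 5.0,
                       seed: int | np.random.Generator = 0,
                       climate: ClimateParams | None = None,
                       canopy: CanopyHydroParams | None = None,
                       ) -> pd.DataFrame:
    """Generate a synthetic rain-event table with model interception.

    Events come from the event-level rainfall simulator (seasonal
    exponential depths); interception uses the saturating daily canopy
    equation at the given LAI.  Columns: event_id, season, gross_mm,
    lai, interception_mm, net_mm.  Invariant: 0 <= net <= gross.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if canopy is None:
        canopy = CanopyHydroParams()
    gen = WeatherGenerator(climate if climate is not None
                           else default_climate())
    rng = np.random.default_rng(seed)
    events = gen.rain_events(n_events, rng)
    storage = canopy_storage(lai, canopy)
    gross = events["depth_mm"].to_numpy()
    ec = interception(gross, storage, canopy.alpha_h)
    return pd.DataFrame({
        "event_id": np.arange(1, n_events + 1),
        "season": events["season"],
        "gross_mm": gross,
        "lai": lai,
        "interception_mm": ec,
        "net_mm": gross - ec,
    })
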