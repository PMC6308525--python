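"""Nozzle spray modes, flow tables, per-hectare rates and spray decisions.

A boom section carries three fan nozzles of increasing orifice size
(XR11001/11002/11003 class); opening them in combination gives seven
nominal spray modes.  Mode 4 (nozzles 1+2) duplicates mode 3's flow almost
exactly and was dropped from the measured data, leaving six working modes.
Mode 6 is nozzles 2+3 (the published mode list repeats "nozzle 1 open" for
mode 6 — a typo, as only the 2+3 pair is otherwise unused and only it is
consistent with the monotone flow ordering of the tables).

The application rate follows the standard boom-sprayer formula

    R [L/hm^2] = 60000 * Q / (V * W)

with Q the nozzle flow (L/min), V the ground speed (m/s) and W the nozzle
spacing (cm).  The flow tables below are the manufacturer (theoretical)
and flow-meter (measured) values at five line pressures; at V = 2.5 m/s
and W = 100 cm the factor 60000/(V*W) equals 240, so rates in L/hm^2 are
exactly 240 times the flows in L/min.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .weedmap import WeedMap

#: Nozzles opened in each spray mode.
MODE_NOZZLES: dict[int, frozenset[int]] = {
    1: frozenset({1}),
    2: frozenset({2}),
    3: frozenset({3}),
    4: frozenset({1, 2}),  # defined but excluded from decisions
    5: frozenset({1, 3}),
    6: frozenset({2, 3}),
    7: frozenset({1, 2, 3}),
}

#: Line pressures (kPa) at which flows were tabulated.
PRESSURES = (200, 250, 300, 350, 400)

#: Default mapping from weed-intensity level to spray mode (None = off).
DEFAULT_LEVEL_TO_MODE: dict[int, int | None] = {0: None, 1: 1, 2: 2, 3: 3, 4: 5, 5: 7}

_THEORETICAL = {
    #      mode:   1     2     3     4     5     6     7
    200: (0.32, 0.65, 0.96, 0.97, 1.28, 1.61, 1.93),
    250: (0.36, 0.73, 1.08, 1.09, 1.44, 1.81, 2.17),
    300: (0.39, 0.79, 1.18, 1.18, 1.57, 1.97, 2.36),
    350: (0.42, 0.85, 1.28, 1.27, 1.70, 2.13, 2.55),
    400: (0.45, 0.91, 1.36, 1.36, 1.81, 2.27, 2.72),
}

_MEASURED = {
    #      mode:   1     2     3     5     6     7
    200: (0.00, 0.64, 0.92, 1.24, 1.50, 1.93),
    250: (0.36, 0.72, 1.09, 1.43, 1.87, 2.15),
    300: (0.35, 0.83, 1.18, 1.54, 1.99, 2.35),
    350: (0.40, 0.90, 1.27, 1.73, 2.15, 2.55),
    400: (0.44, 0.99, 1.41, 1.81, 2.31, 2.81),
}


@dataclass
class FlowTable:
    """Nozzle flow rates (L/min) indexed by (pressure kPa, mode id)."""

    flows: pd.DataFrame  # index: pressure, columns: mode id
    kind: str = "measured"

    def __post_init__(self):
        if (self.flows.values < 0).any():
            raise ValidationError("flow rates must be non-negative")
        unknown = set(self.flows.columns) - set(MODE_NOZZLES)
        if unknown:
            raise ValidationError(f"unknown spray modes {sorted(unknown)}")

    def flow(self, pressure: int, mode: int) -> float:
        try:
            return float(self.flows.at[pressure, mode])
        except KeyError:
            raise ValidationError(f"no flow entry for pressure {pressure} kPa, mode {mode}")

    @classmethod
    def from_csv(cls, path, kind: str = "measured") -> "FlowTable":
        """Load a long-format CSV with columns pressure, mode, flow."""
        df = pd.read_csv(path)
        wide = df.pivot(index="pressure", columns="mode", values="flow")
        wide.columns = wide.columns.astype(int)
        return cls(wide, kind=kind)

    def to_csv(self, path) -> None:
        long = self.flows.stack().rename("flow").reset_index()
        long.columns = ["pressure", "mode", "flow"]
        long.to_csv(path, index=False)


def theoretical_flows() -> FlowTable:
    """Manufacturer flow rates for all seven modes (L/min)."""
    df = pd.DataFrame(_THEORETICAL, index=range(1, 8)).T
    df.index.name = "pressure"
    return FlowTable(df, kind="theoretical")


def measured_flows() -> FlowTable:
    """Flow-meter readings for the six working modes (L/min).

    Mode 1 at 200 kPa reads 0.00: the flow there was below the meter's
    detection limit.
    """
    df = pd.DataFrame(_MEASURED, index=[1, 2, 3, 5, 6, 7]).T
    df.index.name = "pressure"
    return FlowTable(df, kind="measured")


@dataclass(frozen=True)
class SprayerGeometry:
    """Ground speed V (m/s) and nozzle spacing W (cm) of the sprayer."""

    speed: float = 2.5
    spacing: float = 100.0

    def __post_init__(self):
        if self.speed <= 0 or self.spacing <= 0:
            raise ValidationError("speed and spacing must be positive")


def application_rate(q: float, speed: float = 2.5, spacing: float = 100.0) -> float:
    """Per-hectare application rate R = 60000 * Q / (V * W) in L/hm^2."""
    if speed <= 0 or spacing <= 0:
        raise ValidationError("speed and spacing must be positive")
    if q < 0:
        raise ValidationError("flow rate must be non-negative")
    return 60000.0 * q / (speed * spacing)


def rate_table(flows: FlowTable, geometry: SprayerGeometry = SprayerGeometry()) -> pd.DataFrame:
    """Apply the application-rate formula to every flow-table cell (L/hm^2)."""
    return flows.flows.map(lambda q: application_rate(q, geometry.speed, geometry.spacing))


def flow_error(actual: FlowTable, theoretical: FlowTable) -> pd.DataFrame:
    """Relative flow error in percent: 100 * (actual - theoretical) / theoretical.

    Cells where the theoretical flow is zero are returned as NaN.  The two
    tables must share their pressure rows; error is computed for the modes
    present in the actual table.
    """
    a = actual.flows
    th = theoretical.flows
    if set(a.index) != set(th.index):
        raise ValidationError("pressure levels of the two tables do not match")
    missing = set(a.columns) - set(th.columns)
    if missing:
        raise ValidationError(f"theoretical table lacks modes {sorted(missing)}")
    th = th.loc[a.index, a.columns]
    with np.errstate(divide="ignore", invalid="ignore"):
        err = 100.0 * (a - th) / th
    return err.where(th != 0)


def select_mode(level: int, mapping: dict[int, int | None] | None = None) -> int | None:
    """Spray mode for a weed-intensity level; None means all nozzles closed."""
    mapping = mapping if mapping is not None else DEFAULT_LEVEL_TO_MODE
    if level not in range(6):
        raise ValidationError(f"level must be in 0..5, got {level}")
    mode = mapping.get(level)
    if mode is None:
        return None
    if mode not in MODE_NOZZLES:
        raise ValidationError(f"unknown spray mode {mode}")
    if mode == 4:
        warnings.warn("mode 4 duplicates mode 3 and has no measured flow data", stacklevel=2)
    return mode


@dataclass
class SprayDecision:
    """Actuation message for one inter-row interval."""

    interval: int  # index of the interval in the weed map
    x1: int
    x2: int
    level: int
    mode: int | None
    nozzles: tuple[int, ...]
    pressure: int
    flow: float  # L/min (0 when off)
    rate: float  # L/hm^2 (0 when off)

    @property
    def actuate(self) -> bool:
        return self.mode is not None

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["nozzles"] = list(self.nozzles)
        return json.dumps(d)


class SprayPlanner(BaseEstimator):
    """Turn a weed map into per-interval spray decisions.

    Parameters
    ----------
    pressure : int, default 300
        Line pressure in kPa; must be one of the tabulated pressures.
    level_to_mode : dict or None
        Weed-intensity level -> spray mode; the default opens progressively
        larger nozzle combinations as intensity grows and leaves level 0
        off.
    flow_table : FlowTable or None
        Defaults to the measured flows.
    geometry : SprayerGeometry
        Sprayer speed and nozzle spacing for the rate computation.
    """

    def __init__(
        self,
        pressure: int = 300,
        level_to_mode: dict[int, int | None] | None = None,
        flow_table: FlowTable | None = None,
        geometry: SprayerGeometry = SprayerGeometry(),
    ):
        self.pressure = pressure
        self.level_to_mode = level_to_mode
        self.flow_table = flow_table
        self.geometry = geometry

    def predict(self, weed_map: WeedMap) -> list[SprayDecision]:
        """Deterministic decision list, one entry per inter-row interval."""
        table = self.flow_table if self.flow_table is not None else measured_flows()
        decisions = []
        for i, (iv, level) in enumerate(zip(weed_map.intervals, weed_map.levels)):
            mode = select_mode(level, self.level_to_mode)
            if mode is None:
                q = rate = 0.0
                nozzles: tuple[int, ...] = ()
            else:
                q = table.flow(self.pressure, mode)
                rate = application_rate(q, self.geometry.speed, self.geometry.spacing)
                nozzles = tuple(sorted(MODE_NOZZLES[mode]))
            decisions.append(
                SprayDecision(
                    interval=i,
                    x1=iv.x1,
                    x2=iv.x2,
                    level=level,
                    mode=mode,
                    nozzles=nozzles,
                    pressure=self.pressure,
                    flow=q,
                    rate=rate,
                )
            )
        return decisions
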