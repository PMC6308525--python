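"""End-to-end weed-spray pipeline: segment -> map -> decide.

``WeedSprayPipeline`` chains a threshold segmenter, the inter-row weed
mapper and the spray planner behind a single estimator.  ``predict``
returns the full per-interval decision list; intervals below the
actuation threshold (weed level 0 by default) produce no actuation
messages, mirroring a sprayer that simply keeps its valves shut when no
weeds are found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .segment import make_segmenter
from .spray import FlowTable, SprayDecision, SprayerGeometry, SprayPlanner
from .weedmap import DEFAULT_BREAKPOINTS, WeedMap, WeedMapper


@dataclass
class PipelineResult:
    """Everything one image produces on its way through the pipeline."""

    threshold: int
    fitness: float
    mask: np.ndarray = field(repr=False)
    weed_map: WeedMap = field(repr=False)
    decisions: list[SprayDecision] = field(repr=False)

    @property
    def actuations(self) -> list[SprayDecision]:
        """Decisions that actually open nozzles."""
        return [d for d in self.decisions if d.actuate]


class WeedSprayPipeline(BaseEstimator):
    """Image in, spray decisions out.

    Parameters mirror the three stages: ``method``/``seed``/``segmenter_params``
    configure the threshold search, ``fraction``/``breakpoints`` the weed
    mapper, and ``pressure``/``level_to_mode``/``flow_table``/``geometry``
    the spray planner.  ``min_level`` is the decision threshold: intervals
    below it emit no actuation message regardless of the level->mode map.
    """

    def __init__(
        self,
        method: str = "ipso",
        foreground: str = "above",
        seed: int | None = None,
        segmenter_params: dict | None = None,
        fraction: float = 1.0 / 3.0,
        breakpoints: tuple[float, ...] = DEFAULT_BREAKPOINTS,
        transpose: bool = False,
        pressure: int = 300,
        level_to_mode: dict[int, int | None] | None = None,
        flow_table: FlowTable | None = None,
        geometry: SprayerGeometry = SprayerGeometry(),
        min_level: int = 1,
    ):
        self.method = method
        self.foreground = foreground
        self.seed = seed
        self.segmenter_params = segmenter_params
        self.fraction = fraction
        self.breakpoints = breakpoints
        self.transpose = transpose
        self.pressure = pressure
        self.level_to_mode = level_to_mode
        self.flow_table = flow_table
        self.geometry = geometry
        self.min_level = min_level

    def fit(self, X: np.ndarray, y=None) -> "WeedSprayPipeline":
        """Run all three stages on an image; stage outputs become attributes."""
        params = dict(self.segmenter_params or {})
        params.setdefault("foreground", self.foreground)
        if self.method != "otsu":
            params.setdefault("seed", self.seed)
        segmenter = make_segmenter(self.method, **params)
        mask = segmenter.fit_transform(X)

        mapper = WeedMapper(
            fraction=self.fraction, breakpoints=self.breakpoints, transpose=self.transpose
        )
        weed_map = mapper.transform(mask)

        planner = SprayPlanner(
            pressure=self.pressure,
            level_to_mode=self.level_to_mode,
            flow_table=self.flow_table,
            geometry=self.geometry,
        )
        decisions = planner.predict(weed_map)
        for d in decisions:
            if d.level < self.min_level and d.actuate:
                d.mode, d.nozzles, d.flow, d.rate = None, (), 0.0, 0.0

        self.segmenter_ = segmenter
        self.result_ = PipelineResult(
            threshold=segmenter.threshold_,
            fitness=segmenter.fitness_,
            mask=mask,
            weed_map=weed_map,
            decisions=decisions,
        )
        return self

    def predict(self, X: np.ndarray) -> list[SprayDecision]:
        """Spray decisions for one image."""
        return self.fit(X).result_.decisions


def run_pipeline(image: np.ndarray, **params) -> PipelineResult:
    """One-call wrapper: run :class:`WeedSprayPipeline` and return its result."""
    return WeedSprayPipeline(**params).fit(image).result_
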