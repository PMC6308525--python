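"""Threshold-segmentation estimators and the method-comparison statistics.

The three searchers share a scikit-learn transformer interface: ``fit`` an
image (or a histogram) to estimate ``threshold_``, then ``transform`` an
image into a {0,1} vegetation mask.  ``compare_methods`` implements the
standard benchmark protocol for threshold optimizers: run each method over
a set of images and report, against exhaustive Otsu as reference, the optimization
rate p = n/N*100 (percentage of images with exact threshold agreement) and
the error rate sigma = sqrt(sum((T_i - TU_i)^2) / N).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .io import apply_threshold, compute_histogram
from .swarm import SwarmConfig, ThresholdResult, ipso_segment, otsu_exhaustive, pso_segment


def _as_histogram(X: np.ndarray) -> np.ndarray:
    """Accept either a 2-D image or a 1-D 256-bin histogram."""
    X = np.asarray(X)
    if X.ndim == 1:
        return X.astype(np.float64)
    if X.ndim == 2:
        return compute_histogram(X).astype(np.float64)
    raise ValidationError(f"expected an image or histogram, got shape {X.shape}")


class _BaseThreshold(TransformerMixin, BaseEstimator):
    """Shared fit/transform plumbing for the three threshold searchers."""

    method: str = ""

    def __init__(self, foreground: str = "above"):
        self.foreground = foreground

    def _search(self, hist: np.ndarray) -> ThresholdResult:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X: np.ndarray, y=None) -> "_BaseThreshold":
        """Estimate the threshold from an image or gray-level histogram."""
        result = self._search(_as_histogram(X))
        self.result_ = result
        self.threshold_ = result.threshold
        self.fitness_ = result.fitness
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Binarize an image at the fitted threshold."""
        if not hasattr(self, "threshold_"):
            raise ValidationError("estimator is not fitted; call fit first")
        return apply_threshold(np.asarray(X), self.threshold_, self.foreground)


class OtsuThreshold(_BaseThreshold):
    """Exhaustive Otsu threshold: argmax of between-class variance over all levels."""

    method = "otsu"

    def _search(self, hist: np.ndarray) -> ThresholdResult:
        return otsu_exhaustive(hist)


class PSOThreshold(_BaseThreshold):
    """Standard particle-swarm Otsu search over the full occupied gray range."""

    method = "pso"

    def __init__(
        self,
        foreground: str = "above",
        swarm_size: int = 15,
        max_iter: int = 30,
        c1: float = 2.0,
        c2: float = 2.0,
        w_max: float = 0.8,
        w_min: float = 0.4,
        v_max: float | None = None,
        stall_iter: int | None = 10,
        seed: int | None = None,
    ):
        super().__init__(foreground)
        self.swarm_size = swarm_size
        self.max_iter = max_iter
        self.c1 = c1
        self.c2 = c2
        self.w_max = w_max
        self.w_min = w_min
        self.v_max = v_max
        self.stall_iter = stall_iter
        self.seed = seed

    def _swarm_config(self, **extra) -> SwarmConfig:
        return SwarmConfig(
            swarm_size=self.swarm_size,
            max_iter=self.max_iter,
            c1=self.c1,
            c2=self.c2,
            w_max=self.w_max,
            w_min=self.w_min,
            v_max=self.v_max,
            stall_iter=self.stall_iter,
            seed=self.seed,
            **extra,
        )

    def _search(self, hist: np.ndarray) -> ThresholdResult:
        return pso_segment(hist, self._swarm_config())


class IPSOThreshold(PSOThreshold):
    """Improved PSO: contracted [mu_A, mu_B] range, rescaled swarm, local refinement."""

    method = "ipso"

    def __init__(
        self,
        foreground: str = "above",
        swarm_size: int = 15,
        max_iter: int = 30,
        c1: float = 2.0,
        c2: float = 2.0,
        w_max: float = 0.8,
        w_min: float = 0.4,
        v_max: float | None = None,
        stall_iter: int | None = 10,
        p_refine: int = 2,
        seed: int | None = None,
    ):
        super().__init__(
            foreground, swarm_size, max_iter, c1, c2, w_max, w_min, v_max, stall_iter, seed
        )
        self.p_refine = p_refine

    def _search(self, hist: np.ndarray) -> ThresholdResult:
        return ipso_segment(hist, self._swarm_config(p_refine=self.p_refine))


METHODS = {"otsu": OtsuThreshold, "pso": PSOThreshold, "ipso": IPSOThreshold}


def make_segmenter(method: str, **params) -> _BaseThreshold:
    """Instantiate a threshold estimator by name ('otsu', 'pso' or 'ipso')."""
    try:
        cls = METHODS[method]
    except KeyError:
        raise ValidationError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    if cls is OtsuThreshold:
        params = {k: v for k, v in params.items() if k == "foreground"}
    return cls(**params)


@dataclass
class MethodReport:
    """Benchmark statistics for one method against the exhaustive-Otsu reference."""

    method: str
    n_images: int
    mean_threshold: float
    optimization_number: int  # images with exact threshold agreement
    optimization_rate: float  # p = n/N * 100, percent
    error_rate: float  # sigma = sqrt(mean squared threshold deviation)
    mean_iterations: float
    mean_evaluations: float
    thresholds: list[int]


@dataclass
class EvaluationReport:
    """Per-method benchmark reports plus the reference thresholds."""

    reference_thresholds: list[int]
    methods: dict[str, MethodReport]

    def to_frame(self) -> pd.DataFrame:
        """Benchmark table, one row per method."""
        rows = []
        for rep in self.methods.values():
            d = asdict(rep)
            d.pop("thresholds")
            rows.append(d)
        return pd.DataFrame(rows)


def optimization_stats(thresholds: list[int], reference: list[int]) -> tuple[int, float, float]:
    """(n, p, sigma): exact-agreement count, rate in percent, RMS threshold error."""
    if len(thresholds) != len(reference) or not thresholds:
        raise ValidationError("thresholds and reference must be equal-length, non-empty")
    t = np.asarray(thresholds, dtype=float)
    tu = np.asarray(reference, dtype=float)
    n = int((t == tu).sum())
    p = 100.0 * n / t.size
    sigma = float(np.sqrt(np.mean((t - tu) ** 2)))
    return n, p, sigma


def compare_methods(
    histograms: list[np.ndarray],
    cfg: SwarmConfig | None = None,
    seed: int | None = None,
    methods: tuple[str, ...] = ("otsu", "pso", "ipso"),
) -> EvaluationReport:
    """Run each method on every histogram and score against exhaustive Otsu.

    Each (image, method) run draws its own RNG stream from ``seed`` so
    results per method do not depend on which other methods are run.
    """
    if not histograms:
        raise ValidationError("need at least one histogram")
    cfg = cfg or SwarmConfig()
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    per_image = ss.spawn(len(histograms))

    reference = [otsu_exhaustive(h).threshold for h in histograms]

    reports: dict[str, MethodReport] = {}
    for method in methods:
        results: list[ThresholdResult] = []
        for h, child in zip(histograms, per_image):
            streams = child.spawn(2)  # fixed layout: [pso, ipso]
            if method == "otsu":
                results.append(otsu_exhaustive(h))
            elif method == "pso":
                results.append(pso_segment(h, cfg, np.random.default_rng(streams[0])))
            elif method == "ipso":
                results.append(ipso_segment(h, cfg, np.random.default_rng(streams[1])))
            else:
                raise ValidationError(f"unknown method {method!r}")
        ts = [r.threshold for r in results]
        n, p, sigma = optimization_stats(ts, reference)
        reports[method] = MethodReport(
            method=method,
            n_images=len(histograms),
            mean_threshold=float(np.mean(ts)),
            optimization_number=n,
            optimization_rate=p,
            error_rate=sigma,
            mean_iterations=float(np.mean([r.iterations for r in results])),
            mean_evaluations=float(np.mean([r.evaluations for r in results])),
            thresholds=ts,
        )
    return EvaluationReport(reference_thresholds=reference, methods=reports)


#: Alias kept for symmetry with the operation names used in the docs.
evaluate_methods = compare_methods


def histogram_benchmark(
    n_images: int = 100,
    seed: int | None = None,
    cfg: SwarmConfig | None = None,
    veg_fraction_range: tuple[float, float] = (0.1, 0.3),
    total: int = 100_000,
) -> EvaluationReport:
    """Seeded optimizer benchmark on synthetic bimodal histograms.

    Generates ``n_images`` Gaussian-mixture histograms (soil/vegetation
    means 40/160, sd 12, vegetation fraction uniform in
    ``veg_fraction_range``, ``total`` pixels each) and scores otsu, pso and
    ipso with :func:`compare_methods`.  Fully reproducible from ``seed``.
    """
    from .synthetic import generate_histogram

    ss = np.random.SeedSequence(seed)
    gen_ss, eval_ss = ss.spawn(2)
    hists = []
    for child in gen_ss.spawn(n_images):
        rng = np.random.default_rng(child)
        frac = rng.uniform(*veg_fraction_range)
        hists.append(generate_histogram(veg_fraction=frac, total=total, rng=rng))
    return compare_methods(hists, cfg=cfg, seed=eval_ss)
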