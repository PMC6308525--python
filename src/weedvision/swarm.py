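"""Particle-swarm threshold search: exhaustive Otsu, standard PSO, and IPSO.

The improved variant (IPSO) differs from standard PSO in three ways:

1. the swarm is initialized inside the contracted range [mu_a, mu_b]
   derived from the histogram instead of the full occupied gray range;
2. the swarm size is rescaled to the width of that range,
   G_f = max(5, round(G_s * (mu_b - mu_a) / (L - 1)));
3. after the swarm converges, every integer threshold within a half-width
   ``p_refine`` of the swarm optimum is scanned exhaustively and the best
   one kept.

Both searches stop early once the global best has not improved within a
fixed budget of fitness evaluations (``stall_iter * swarm_size``); because
the IPSO swarm is smaller, it runs more iterations inside the same budget,
which is what lets its local refinement pay off.

Particle positions are continuous; fitness (the Otsu between-class
variance) is evaluated at the rounded integer gray level.  All ties are
broken toward the smallest threshold — in particular the refinement scan
returns the smallest member of an exactly-tied run of thresholds (empty
histogram bins between the classes make whole runs of thresholds exactly
equivalent: they induce identical masks).  Every run is deterministic
given (histogram, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ValidationError
from .otsu import best_threshold, occupied_range, search_bounds, variance_curve


@dataclass
class SwarmConfig:
    """Swarm hyper-parameters.

    Defaults follow the published benchmark protocol: 15 particles, 30
    iterations, learning factors c1 = c2 = 2, inertia weight decaying
    linearly from 0.8 to 0.4.  ``p_refine`` is the half-width (in gray
    levels) of the exhaustive refinement scan around the swarm optimum.
    ``stall_iter`` sets the stagnation patience: the search stops early
    after ``stall_iter * swarm_size`` fitness evaluations without
    improvement of the global best (i.e. ``stall_iter`` iterations of a
    full-size swarm; a contracted swarm gets proportionally more
    iterations from the same budget).
    """

    swarm_size: int = 15
    max_iter: int = 30
    c1: float = 2.0
    c2: float = 2.0
    w_max: float = 0.8
    w_min: float = 0.4
    v_max: float | None = None  # default: half the search-range width
    p_refine: int = 2
    stall_iter: int | None = 10  # None disables the early stop
    seed: int | None = None

    def validate(self) -> None:
        if self.swarm_size < 1:
            raise ValidationError("swarm_size must be >= 1")
        if self.max_iter < 0:
            raise ValidationError("max_iter must be >= 0")
        if not (0 <= self.w_min <= self.w_max):
            raise ValidationError("need 0 <= w_min <= w_max")
        if self.p_refine < 0:
            raise ValidationError("p_refine must be >= 0")


@dataclass
class ThresholdResult:
    """Outcome of a threshold search."""

    threshold: int
    fitness: float
    method: str
    evaluations: int
    iterations: int
    swarm_size_used: int = 0
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=float)


def otsu_exhaustive(counts: np.ndarray) -> ThresholdResult:
    """Exhaustive Otsu: evaluate every gray level, keep the max-variance one."""
    counts = np.asarray(counts, dtype=np.float64)
    occupied_range(counts)  # raises on degenerate input
    sigma2 = variance_curve(counts)
    t = best_threshold(sigma2)
    return ThresholdResult(
        threshold=t,
        fitness=float(sigma2[t]),
        method="otsu",
        evaluations=int(counts.size),
        iterations=1,
    )


def _better(f_new: float, t_new: int, f_old: float, t_old: int) -> bool:
    """Strictly better fitness, or equal fitness at a smaller threshold."""
    return f_new > f_old or (f_new == f_old and t_new < t_old)


def _swarm_search(
    sigma2: np.ndarray,
    lo: float,
    hi: float,
    n_particles: int,
    cfg: SwarmConfig,
    rng: np.random.Generator,
    stall_iter: int | None,
) -> tuple[int, float, int, int]:
    """Run the PSO velocity/position iteration on the variance curve.

    Returns (best integer threshold, its fitness, fitness evaluations,
    iterations executed).
    """
    span = hi - lo
    v_max = cfg.v_max if cfg.v_max is not None else max(span / 2.0, 1.0)

    x = rng.uniform(lo, hi, n_particles)
    v = rng.uniform(-v_max, v_max, n_particles)

    xi = np.rint(x).astype(int)
    f = sigma2[xi]
    evals = n_particles

    pbest_x = x.copy()
    pbest_t = xi.copy()
    pbest_f = f.copy()

    g = _argbest(pbest_f, pbest_t)
    gbest_x, gbest_t, gbest_f = pbest_x[g], int(pbest_t[g]), float(pbest_f[g])

    iters = 0
    stall = 0
    for it in range(cfg.max_iter):
        iters += 1
        if cfg.max_iter > 1:
            w = cfg.w_max - (cfg.w_max - cfg.w_min) * it / (cfg.max_iter - 1)
        else:
            w = cfg.w_max
        r1 = rng.random(n_particles)
        r2 = rng.random(n_particles)
        v = w * v + cfg.c1 * r1 * (pbest_x - x) + cfg.c2 * r2 * (gbest_x - x)
        v = np.clip(v, -v_max, v_max)
        x = np.clip(x + v, lo, hi)

        xi = np.rint(x).astype(int)
        f = sigma2[xi]
        evals += n_particles

        improved = (f > pbest_f) | ((f == pbest_f) & (xi < pbest_t))
        pbest_x[improved] = x[improved]
        pbest_t[improved] = xi[improved]
        pbest_f[improved] = f[improved]

        g = _argbest(pbest_f, pbest_t)
        if _better(float(pbest_f[g]), int(pbest_t[g]), gbest_f, gbest_t):
            gbest_x, gbest_t, gbest_f = pbest_x[g], int(pbest_t[g]), float(pbest_f[g])
            stall = 0
        else:
            stall += 1
            if stall_iter is not None and stall >= stall_iter:
                break
    return gbest_t, gbest_f, evals, iters


def _argbest(f: np.ndarray, t: np.ndarray) -> int:
    """Index of the best (fitness, smallest-threshold) particle."""
    top = f == f.max()
    idx = np.flatnonzero(top)
    return int(idx[np.argmin(t[idx])])


def pso_segment(
    counts: np.ndarray,
    cfg: SwarmConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ThresholdResult:
    """Standard PSO threshold search over the full occupied gray range."""
    cfg = cfg or SwarmConfig()
    cfg.validate()
    rng = _resolve_rng(cfg, rng)
    counts = np.asarray(counts, dtype=np.float64)
    i_min, i_max = occupied_range(counts)
    sigma2 = variance_curve(counts)

    t, fit, evals, iters = _swarm_search(
        sigma2,
        float(i_min),
        float(i_max),
        cfg.swarm_size,
        cfg,
        rng,
        stall_iter=_stall_iters(cfg, cfg.swarm_size),
    )
    return ThresholdResult(
        threshold=t,
        fitness=fit,
        method="pso",
        evaluations=evals,
        iterations=iters,
        swarm_size_used=cfg.swarm_size,
    )


def rescaled_swarm_size(swarm_size: int, mu_a: float, mu_b: float, n_levels: int) -> int:
    """Swarm size proportional to the contracted range width, floor 5."""
    return max(5, int(round(swarm_size * (mu_b - mu_a) / (n_levels - 1))))


def ipso_segment(
    counts: np.ndarray,
    cfg: SwarmConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ThresholdResult:
    """IPSO threshold search: contracted range, rescaled swarm, local refinement."""
    cfg = cfg or SwarmConfig()
    cfg.validate()
    rng = _resolve_rng(cfg, rng)
    counts = np.asarray(counts, dtype=np.float64)
    bounds = search_bounds(counts)
    sigma2 = variance_curve(counts)

    g_f = rescaled_swarm_size(cfg.swarm_size, bounds.mu_a, bounds.mu_b, counts.size)
    t, fit, evals, iters = _swarm_search(
        sigma2, bounds.mu_a, bounds.mu_b, g_f, cfg, rng, stall_iter=_stall_iters(cfg, g_f)
    )

    # local exhaustive refinement of half-width p_refine around the swarm best
    lo = max(bounds.i_min, t - cfg.p_refine)
    hi = min(bounds.i_max, t + cfg.p_refine)
    window = np.arange(lo, hi + 1)
    evals += window.size
    t_ref = int(window[np.argmax(sigma2[window])])
    if _better(float(sigma2[t_ref]), t_ref, fit, t):
        t, fit = t_ref, float(sigma2[t_ref])

    # canonical representative of an exactly-tied plateau: empty bins between
    # the classes leave sigma^2 exactly constant over whole runs of
    # thresholds; all of them induce the same mask, and the smallest one is
    # the package-wide tie-break (it is also what the exhaustive scan picks).
    while t - 1 >= bounds.i_min and sigma2[t - 1] == fit:
        t -= 1
        evals += 1

    return ThresholdResult(
        threshold=t,
        fitness=fit,
        method="ipso",
        evaluations=evals,
        iterations=iters,
        swarm_size_used=g_f,
        diagnostics={"mu_a": bounds.mu_a, "mu_b": bounds.mu_b, "mu_l": bounds.mu_l},
    )


def _stall_iters(cfg: SwarmConfig, n_particles: int) -> int | None:
    """Stagnation patience in iterations for a swarm of ``n_particles``.

    The patience is a fitness-evaluation budget ``stall_iter * swarm_size``
    shared by all methods, so a smaller swarm is allowed proportionally
    more iterations before giving up.
    """
    if cfg.stall_iter is None:
        return None
    budget = cfg.stall_iter * cfg.swarm_size
    return max(1, -(-budget // n_particles))  # ceil division


def _resolve_rng(cfg: SwarmConfig, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(cfg.seed)
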