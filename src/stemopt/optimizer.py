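"""Constrained golden-section search over stem length on the pixel grid.

Candidate lengths live on the raster grid (the stem tip can only move in
whole-pixel steps), so golden-ratio probe points are snapped to the nearest
grid point. Infeasible candidates — shielding constraint g >= threshold —
receive an infinite objective; if the final bracket holds no feasible grid
point the search falls back to an exhaustive scan of the full range. When
the bracket closes below the stop interval every remaining grid point is
evaluated and the feasible one with minimal objective is returned. The
whole pipeline is deterministic: the search itself uses no randomness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fields import FieldResult, StaticSolver
from .loading import LoadCase
from .materials import DEFAULT_MATERIALS, MaterialModel
from .mesh_fe import FEModel, build_mesh
from .metrics import ShieldingMetrics, shielding_metrics
from .phantom import LabeledImage, StemSpec, generate_stem_profile, resect_and_insert

GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class OptimizationProblem:
    """Bounds, grid and constraint of the stem-length search (mm / %)."""

    l_min: float = 68.75
    l_max: float = 117.25
    grid_step: float = 0.05
    stop_interval: float = 0.15
    constraint_threshold: float = 40.0
    objective_mode: str = "sum"

    def __post_init__(self):
        if self.l_min >= self.l_max:
            raise ValueError("l_min must be below l_max")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.stop_interval < self.grid_step:
            raise ValueError("stop_interval must be at least one grid step")

    def grid_points(self, a: float | None = None, b: float | None = None) -> np.ndarray:
        a = self.l_min if a is None else a
        b = self.l_max if b is None else b
        k0 = int(math.ceil((a - self.l_min) / self.grid_step - 1e-9))
        k1 = int(math.floor((b - self.l_min) / self.grid_step + 1e-9))
        return self.l_min + self.grid_step * np.arange(k0, k1 + 1)


def snap_to_grid(l: float, grid_step: float, origin: float,
                 lo: float | None = None, hi: float | None = None,
                 midpoint: float | None = None) -> float:
    """Nearest grid point ``origin + k * grid_step``; ties resolve toward
    ``midpoint``. Out-of-bounds values are clamped with a warning."""
    if lo is not None and l < lo - 1e-12:
        warnings.warn(f"length {l} below lower bound {lo}; clamping", stacklevel=2)
        l = lo
    if hi is not None and l > hi + 1e-12:
        warnings.warn(f"length {l} above upper bound {hi}; clamping", stacklevel=2)
        l = hi
    k = (l - origin) / grid_step
    lo_k, hi_k = math.floor(k + 1e-9), math.ceil(k - 1e-9)
    frac = k - math.floor(k)
    if abs(frac - 0.5) < 1e-9:  # exact tie between neighbours
        cand = (origin + lo_k * grid_step, origin + hi_k * grid_step)
        if midpoint is None:
            return cand[0]
        return min(cand, key=lambda c: abs(c - midpoint))
    return origin + round(k) * grid_step


@dataclass
class CandidateResult:
    """Evaluation of one stem length."""

    length: float
    f: float
    g: float
    feasible: bool
    metrics: ShieldingMetrics

    @property
    def objective(self) -> float:
        return self.f if self.feasible else math.inf


@dataclass
class OptimizationTrace:
    """Full history of a golden-section run."""

    iterations: list = field(default_factory=list)
    evaluated: dict = field(default_factory=dict)  # length -> CandidateResult
    final_length: float | None = None
    fe_evaluations: int = 0
    fallback_scan: bool = False

    def record(self, a, b, x1, x2, f1, f2):
        self.iterations.append({
            "a": a, "b": b, "width": b - a,
            "x1": x1, "x2": x2, "f1": f1, "f2": f2,
        })

    @property
    def interval_widths(self) -> list[float]:
        return [it["width"] for it in self.iterations]

    @property
    def unimodal(self) -> bool:
        """True if the sampled objective is consistent with a unimodal shape.

        Checks for a single descending-then-ascending pattern over the
        finite-objective probes; a False value flags that the returned
        optimum may only be local.
        """
        pts = sorted((l, r.objective) for l, r in self.evaluated.items()
                     if math.isfinite(r.objective))
        vals = [v for _, v in pts]
        if len(vals) < 3:
            return True
        sign_changes = 0
        prev = 0
        for lo, hi in zip(vals, vals[1:]):
            s = int(hi > lo) - int(hi < lo)
            if s != 0 and prev != 0 and s != prev:
                sign_changes += 1
            if s != 0:
                prev = s
        return sign_changes <= 1


class StemLengthEvaluator:
    """Runs insertion -> mesh -> solve for candidate lengths, with caching.

    The intact-femur fields (the shielding reference U0) are solved once.
    Candidate field solutions are cached per length, so metrics under
    different case weightings reuse the same FE solves.
    """

    def __init__(self, image: LabeledImage, cases: list[LoadCase],
                 stem_spec: StemSpec = StemSpec(),
                 materials: MaterialModel = DEFAULT_MATERIALS,
                 objective_mode: str = "sum"):
        self.image = image
        self.cases = cases
        self.stem_spec = stem_spec
        self.materials = materials
        self.objective_mode = objective_mode
        self.pre_model = build_mesh(image, materials)
        solver = StaticSolver(self.pre_model)
        self.pre_results = [solver.solve(c) for c in cases]
        self._cache: dict[float, tuple[FEModel, list[FieldResult]]] = {}
        self.fe_evaluations = 0

    @property
    def weights(self) -> list[float]:
        return [c.weight for c in self.cases]

    def _key(self, length: float) -> float:
        return round(length, 9)

    def fields_at(self, length: float) -> tuple[FEModel, list[FieldResult]]:
        key = self._key(length)
        if key not in self._cache:
            lm = self.image.landmarks
            stem = generate_stem_profile(
                length, self.stem_spec,
                axis_x=lm.get("shaft_axis_x", 32.0),
                top_y=lm.get("stem_top_y", 13.95))
            try:
                implanted = resect_and_insert(self.image, stem)
                model = build_mesh(implanted, self.materials)
                solver = StaticSolver(model)
                results = [solver.solve(c) for c in self.cases]
            except Exception as exc:
                raise RuntimeError(f"evaluation failed at stem length {length} mm") from exc
            self._cache[key] = (model, results)
            self.fe_evaluations += 1
        return self._cache[key]

    def evaluate(self, length: float, weights=None,
                 constraint_threshold: float = 40.0) -> CandidateResult:
        model, results = self.fields_at(length)
        w = self.weights if weights is None else weights
        m = shielding_metrics(self.pre_model, self.pre_results, model, results,
                              w, self.objective_mode)
        return CandidateResult(length, m.f_objective, m.g_percent,
                               m.g_percent < constraint_threshold, m)


def golden_section_optimize(problem: OptimizationProblem, evaluate,
                            trace: OptimizationTrace | None = None):
    """Golden-section minimization of ``evaluate(l).objective`` on the grid.

    ``evaluate`` maps an on-grid length to a :class:`CandidateResult`.
    Returns ``(best_length, best_result, trace)``.
    """
    trace = trace or OptimizationTrace()
    cache: dict[float, CandidateResult] = {}

    def probe(l: float) -> CandidateResult:
        key = round(l, 9)
        if key not in cache:
            cache[key] = evaluate(key)
            trace.evaluated[key] = cache[key]
        return cache[key]

    a, b = problem.l_min, problem.l_max
    snap = lambda l: snap_to_grid(l, problem.grid_step, problem.l_min,
                                  lo=problem.l_min, hi=problem.l_max,
                                  midpoint=(a + b) / 2.0)
    x1 = snap(b - GOLDEN * (b - a))
    x2 = snap(a + GOLDEN * (b - a))
    while b - a > problem.stop_interval + 1e-12 and x1 < x2:
        r1, r2 = probe(x1), probe(x2)
        trace.record(a, b, x1, x2, r1.objective, r2.objective)
        if r1.objective <= r2.objective:
            b = x2
            x2 = x1
            x1 = snap(b - GOLDEN * (b - a))
        else:
            a = x1
            x1 = x2
            x2 = snap(a + GOLDEN * (b - a))
        if x1 >= x2:
            break

    # bracket closed: evaluate every remaining grid point inside it
    finalists = [probe(l) for l in problem.grid_points(a, b)]
    feasible = [r for r in finalists if r.feasible]
    if not feasible:
        trace.fallback_scan = True
        scan = [probe(l) for l in problem.grid_points()]
        feasible = [r for r in scan if r.feasible]
        if not feasible:
            raise RuntimeError("constraint infeasible everywhere on the length grid")
    best = min(feasible, key=lambda r: (r.f, r.length))
    trace.final_length = best.length
    return best.length, best, trace


def optimize_stem_length(image: LabeledImage, cases: list[LoadCase],
                         problem: OptimizationProblem = OptimizationProblem(),
                         stem_spec: StemSpec = StemSpec(),
                         materials: MaterialModel = DEFAULT_MATERIALS,
                         evaluator: StemLengthEvaluator | None = None):
    """End-to-end search; returns (length, CandidateResult, trace, evaluator)."""
    ev = evaluator or StemLengthEvaluator(image, cases, stem_spec, materials,
                                          problem.objective_mode)
    weights = [c.weight for c in cases]

    def evaluate(l: float) -> CandidateResult:
        return ev.evaluate(l, weights, problem.constraint_threshold)

    trace = OptimizationTrace()
    length, best, trace = golden_section_optimize(problem, evaluate, trace)
    trace.fe_evaluations = ev.fe_evaluations
    return length, best, trace, ev
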