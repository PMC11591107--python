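"""Comparison tables: stem-length variants and loading conditions.

Mirrors the validation methodology of the underlying study design: the
shortest, optimized and longest stems are compared under the weighted daily
load set, and the optimization is repeated under each single load case to
show that the optimal length is load-dependent. Percent differences are
reported against the multiple-load optimized stem.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import percent_difference
from .optimizer import (
    CandidateResult,
    OptimizationProblem,
    OptimizationTrace,
    StemLengthEvaluator,
    golden_section_optimize,
)


def compare_stem_lengths(evaluator: StemLengthEvaluator,
                         problem: OptimizationProblem,
                         optimized_length: float) -> pd.DataFrame:
    """Shortest vs optimized vs longest stem under the weighted load set.

    Returns a table with g (%), the weighted maximum cortical stress (MPa)
    and percent differences relative to the optimized row.
    """
    weights = evaluator.weights
    rows = {}
    for name, length in (("shortest", problem.l_min),
                         ("optimized", optimized_length),
                         ("longest", problem.l_max)):
        r = evaluator.evaluate(length, weights, problem.constraint_threshold)
        rows[name] = {
            "length_mm": length,
            "g_percent": r.g,
            "max_stress_MPa": r.metrics.max_stress_weighted,
            "feasible": r.feasible,
        }
    ref = rows["optimized"]
    for name, row in rows.items():
        row["g_vs_optimized_pct"] = percent_difference(row["g_percent"], ref["g_percent"])
        row["stress_vs_optimized_pct"] = percent_difference(
            row["max_stress_MPa"], ref["max_stress_MPa"])
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_loading_conditions(evaluator: StemLengthEvaluator,
                               problem: OptimizationProblem) -> pd.DataFrame:
    """Optimize under each single load case and under the weighted set.

    Single-case runs use a degenerate weight vector (one entry 1); all runs
    share the evaluator's cached FE solves. Returns one row per condition
    with the optimized length, g and weighted maximum cortical stress.
    """
    conditions = {c.name: [1.0 if d is c else 0.0 for d in evaluator.cases]
                  for c in evaluator.cases}
    conditions["multiple"] = list(evaluator.weights)
    rows = {}
    traces = {}
    for name, weights in conditions.items():
        def evaluate(l, _w=weights):
            return evaluator.evaluate(l, _w, problem.constraint_threshold)
        length, best, trace = golden_section_optimize(problem, evaluate,
                                                      OptimizationTrace())
        rows[name] = {
            "optimized_length_mm": length,
            "g_percent": best.g,
            "max_stress_MPa": best.metrics.max_stress_weighted,
        }
        traces[name] = trace
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.attrs["traces"] = traces
    return df


def trace_frame(trace: OptimizationTrace) -> pd.DataFrame:
    """Iteration history of a golden-section run as a table."""
    return pd.DataFrame(trace.iterations)


def candidate_record(result: CandidateResult) -> dict:
    """JSON-ready summary of one evaluated stem length."""
    m = result.metrics
    return {
        "length_mm": result.length,
        "f_objective": result.f,
        "g_percent": result.g,
        "feasible": bool(result.feasible),
        "max_stress_MPa_weighted": m.max_stress_weighted,
        "max_stress_MPa_per_case": m.max_stress_per_case,
        "n_included": m.n_included,
        "n_excluded": m.n_excluded,
    }


def render_field_maps(model, result, path, dpi: int = 150) -> None:
    """Save strain-energy and stress maps of one solved case as an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nr, nc = model.labels_grid.shape
    energy = np.full((nr, nc), np.nan)
    stress = np.full((nr, nc), np.nan)
    r, c = model.elem_pixel.T
    energy[r, c] = result.element_strain_energy
    stress[r, c] = result.nodal_stress.max(axis=1)

    fig, axes = plt.subplots(1, 2, figsize=(9, 6))
    for ax, grid, title in ((axes[0], energy, "strain energy [N mm]"),
                            (axes[1], stress, "corner stress max [MPa]")):
        im = ax.imshow(grid, cmap="viridis")
        ax.set_title(f"{result.case}: {title}")
        ax.axis("off")
        fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
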