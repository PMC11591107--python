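"""Weighted shielding and stress aggregates across load cases.

Two scalar summaries drive the design search:

* the strain-energy change rate in the cancellous bone,
  g = sum_k c_k * (1/n) * sum_{i in S_can} (U0_i(k) - U_i(k)) / U0_i(k),
  expressed in percent — the stress-shielding constraint; and
* the cortical stress objective,
  f = sum_k c_k * sum_{i in S_cor} sum_{n=1..4} sigma_i,n(k)
  (default), with a weighted maximum-stress alternative available since the
  two readings of the formulation differ.

S_can contains cancellous elements present in both the intact and implanted
model at the same pixel; pixels that became stem or were resected drop out,
as do elements whose intact-model energy falls below a numerical floor
(the ratio is unstable there). Summands keep their sign: elements that gain
energy contribute negatively. g is invariant under uniform load scaling;
f scales linearly with load magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import FieldResult
from .materials import LABEL_CANCELLOUS, LABEL_CORTICAL
from .mesh_fe import FEModel

#: intact-model energies below this (N*mm) are excluded from the g average
ENERGY_FLOOR = 1e-12

#: elements at or below this relative density are marrow, not cancellous
#: bone, and are excluded from the shielding set S_can
MARROW_THRESHOLD = 0.02

#: cortical elements closer than this (mm) to the fully constrained base
#: are excluded from the stress set S_cor: the clamped section cut raises
#: an artificial corner singularity there (St-Venant boundary layer)
SUPPORT_MARGIN_MM = 5.0


def cortical_evaluation_set(model: FEModel,
                            support_margin_mm: float = SUPPORT_MARGIN_MM) -> np.ndarray:
    """Boolean mask of cortical elements entering the stress functionals."""
    cortical = model.elem_label == LABEL_CORTICAL
    if not cortical.any():
        raise ValueError("model contains no cortical elements")
    if support_margin_mm > 0:
        y = model.origin[1] + (model.elem_pixel[:, 0] + 0.5) * model.pixel_size
        base_y = y.max()
        trimmed = cortical & (y < base_y - support_margin_mm)
        # shallow meshes (patch tests, unit fixtures) keep the full set
        if trimmed.any():
            cortical = trimmed
    return cortical


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError(f"case weights must sum to 1, got {w.sum()}")
    return w


@dataclass
class ShieldingMetrics:
    """Aggregated metrics for one candidate design."""

    g_percent: float
    f_objective: float
    f_weighted_max: float
    max_stress_per_case: dict[str, float]
    max_stress_weighted: float
    n_included: int
    n_excluded: int


def _shared_cancellous(pre_model: FEModel, post_model: FEModel):
    """Element index pairs (pre, post) of cancellous-bone pixels in both.

    Marrow-density elements are excluded: at mesoscale resolution their
    near-zero intact energy makes the per-element ratio meaningless.
    """
    post_sel = np.nonzero((post_model.elem_label == LABEL_CANCELLOUS)
                          & (post_model.elem_density > MARROW_THRESHOLD))[0]
    pix = post_model.elem_pixel[post_sel]
    if pre_model.elem_id_grid.shape != post_model.elem_id_grid.shape:
        raise ValueError("pre/post models are on different grids")
    pre_ids = pre_model.elem_id_grid[pix[:, 0], pix[:, 1]]
    ok = pre_ids >= 0
    ok &= np.where(ok, pre_model.elem_label[np.maximum(pre_ids, 0)] == LABEL_CANCELLOUS, False)
    if not ok.any():
        raise ValueError("pre/post meshes share no cancellous elements")
    return pre_ids[ok], post_sel[ok]


def strain_energy_change_rate(pre_model: FEModel, pre_results: list[FieldResult],
                              post_model: FEModel, post_results: list[FieldResult],
                              weights, floor: float = ENERGY_FLOOR,
                              absolute: bool = False):
    """Weighted average relative energy drop in shared cancellous bone (%).

    Returns ``(g_percent, n_included, n_excluded)`` where the counts refer to
    element-case pairs entering / excluded from the average.
    """
    w = _check_weights(weights)
    if len(pre_results) != len(post_results) or len(w) != len(pre_results):
        raise ValueError("pre/post results and weights must align per case")
    pre_ids, post_ids = _shared_cancellous(pre_model, post_model)
    g = 0.0
    n_inc = n_exc = 0
    for ck, pre_r, post_r in zip(w, pre_results, post_results):
        u0 = pre_r.element_strain_energy[pre_ids]
        u1 = post_r.element_strain_energy[post_ids]
        ok = u0 >= floor
        n_inc += int(ok.sum())
        n_exc += int((~ok).sum())
        if not ok.any():
            raise ValueError("no cancellous element exceeds the energy floor")
        rate = (u0[ok] - u1[ok]) / u0[ok]
        if absolute:
            rate = np.abs(rate)
        g += ck * float(rate.mean())
    return 100.0 * g, n_inc, n_exc


def stress_objective(post_model: FEModel, post_results: list[FieldResult],
                     weights, mode: str = "sum") -> float:
    """Weighted cortical stress aggregate.

    ``mode='sum'`` (default): weighted sum of every cortical corner stress.
    ``mode='max'``: weighted per-case maximum cortical stress.
    """
    w = _check_weights(weights)
    if len(w) != len(post_results):
        raise ValueError("results and weights must align per case")
    cortical = cortical_evaluation_set(post_model)
    total = 0.0
    for ck, res in zip(w, post_results):
        s = res.nodal_stress[cortical]
        if mode == "sum":
            total += ck * float(s.sum())
        elif mode == "max":
            total += ck * float(s.max())
        else:
            raise ValueError(f"unknown objective mode {mode!r}")
    return total


def shielding_metrics(pre_model: FEModel, pre_results: list[FieldResult],
                      post_model: FEModel, post_results: list[FieldResult],
                      weights, objective_mode: str = "sum") -> ShieldingMetrics:
    """All aggregates for one implanted configuration."""
    g, n_inc, n_exc = strain_energy_change_rate(
        pre_model, pre_results, post_model, post_results, weights)
    f_sum = stress_objective(post_model, post_results, weights, mode="sum")
    f_max = stress_objective(post_model, post_results, weights, mode="max")
    cortical = cortical_evaluation_set(post_model)
    per_case = {r.case: float(r.nodal_stress[cortical].max()) for r in post_results}
    w = _check_weights(weights)
    weighted_max = float(sum(ck * per_case[r.case] for ck, r in zip(w, post_results)))
    f = f_sum if objective_mode == "sum" else f_max
    return ShieldingMetrics(g, f, f_max, per_case, weighted_max, n_inc, n_exc)


def percent_difference(candidate: float, reference: float) -> float:
    """Signed percent difference of ``candidate`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (candidate - reference) / reference


def format_percent(value: float) -> str:
    """Display convention: signed, three significant figures."""
    return f"{value:+.3g}%"
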