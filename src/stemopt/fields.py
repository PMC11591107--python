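"""Static solves and the two bone-response functionals.

For each load case the reduced system is solved directly (sparse LU); from
the displacement field we compute, per element, the strain energy
U_i = 1/2 u_i^T K_i u_i and, per element corner, the stress magnitude
sigma_i,n = sqrt(sigma_x^2 + sigma_y^2) recovered from the element
B-matrix at the corner's local coordinates. Stress is deliberately kept per
element-node — no inter-element averaging and no shear term or von Mises
equivalent in the default magnitude, which mirrors how the shielding and
stress functionals are indexed downstream. A von Mises variant is available
for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import splu

from .loading import LoadCase, ReducedSystem, build_load_vector, select_surface_nodes
from .materials import LABEL_CORTICAL
from .mesh_fe import CORNERS, FEModel, _b_matrix, _unit_stiffness_by_nu, assemble_global, plane_stress_d


@dataclass
class FieldResult:
    """Solution fields of one load case on one model."""

    case: str
    u: np.ndarray                 # (N, 2) nodal displacements, mm
    element_strain_energy: np.ndarray  # (M,) N*mm
    nodal_stress: np.ndarray      # (M, 4) MPa, per element corner
    external_work: float          # f^T u, N*mm


def solve_static(system: ReducedSystem) -> np.ndarray:
    """Solve K u = f on the reduced system; returns the full (2N,) vector.

    Fixed DOFs report zero displacement. The residual is checked against
    1e-8 * ||f||; a singular factorization raises with a diagnostic.
    """
    fnorm = np.linalg.norm(system.f)
    if fnorm == 0.0:
        return np.zeros(system.n_dofs)
    try:
        lu = splu(system.K.tocsc())
        u_red = lu.solve(system.f)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            "singular reduced stiffness: the mesh is likely disconnected or "
            "under-constrained (rigid-body modes remain)") from exc
    resid = np.linalg.norm(system.K @ u_red - system.f)
    if not np.isfinite(resid) or resid > 1e-8 * fnorm:
        raise RuntimeError(
            f"static solve did not converge: residual {resid:.3e} vs "
            f"tolerance {1e-8 * fnorm:.3e} (ill-conditioned system)")
    return system.expand(u_red)


def element_strain_energy(model: FEModel, u: np.ndarray) -> np.ndarray:
    """Per-element strain energy 1/2 u_i^T K_i u_i (N*mm), non-negative."""
    ue = np.asarray(u).ravel()[model.elem_dofs]  # (M, 8)
    stack, idx = _unit_stiffness_by_nu(model)
    energy = np.empty(model.n_elements)
    for g in range(len(stack)):
        sel = idx == g
        q = ue[sel] @ stack[g]
        energy[sel] = 0.5 * model.elem_E[sel] * np.einsum("ij,ij->i", q, ue[sel])
    return np.maximum(energy, 0.0)


def nodal_stress(model: FEModel, u: np.ndarray, measure: str = "xy_magnitude") -> np.ndarray:
    """Stress magnitude at each element corner, shape (M, 4), MPa.

    ``measure='xy_magnitude'`` (default) is sqrt(sx^2 + sy^2) exactly as the
    functional is defined; ``measure='von_mises'`` is the plane-stress von
    Mises equivalent, offered only for sensitivity studies.
    """
    if measure not in ("xy_magnitude", "von_mises"):
        raise ValueError(f"unknown stress measure {measure!r}")
    ue = np.asarray(u).ravel()[model.elem_dofs]  # (M, 8)
    b_corners = [_b_matrix(xi, eta, model.pixel_size) for xi, eta in CORNERS]
    nus, nu_idx = np.unique(model.elem_nu, return_inverse=True)
    out = np.empty((model.n_elements, 4))
    for g, nu in enumerate(nus):
        sel = nu_idx == g
        d_unit = plane_stress_d(1.0, nu)
        E = model.elem_E[sel]
        for c, b in enumerate(b_corners):
            strain = ue[sel] @ b.T              # (m, 3)
            stress = strain @ d_unit.T * E[:, None]
            if measure == "xy_magnitude":
                out[sel, c] = np.hypot(stress[:, 0], stress[:, 1])
            else:
                sx, sy, txy = stress.T
                out[sel, c] = np.sqrt(sx**2 - sx * sy + sy**2 + 3 * txy**2)
    return out


def max_cortical_stress(model: FEModel, stress: np.ndarray) -> float:
    """Highest corner-stress value over cortical elements (MPa)."""
    cortical = model.elem_label == LABEL_CORTICAL
    if not cortical.any():
        raise ValueError("model contains no cortical elements")
    return float(stress[cortical].max())


class StaticSolver:
    """Factorize a model once and solve many load cases against it.

    The base (lowest node row) is fully constrained at construction; each
    :meth:`solve` call builds the case load vector, back-substitutes and
    evaluates both functionals.
    """

    def __init__(self, model: FEModel, stress_measure: str = "xy_magnitude"):
        self.model = model
        self.stress_measure = stress_measure
        self.K = assemble_global(model)
        base = select_surface_nodes(model, "base")
        dofs = np.concatenate([2 * base, 2 * base + 1])
        self.fixed_dofs = np.unique(dofs)
        self.free_dofs = np.setdiff1d(np.arange(model.n_dofs), self.fixed_dofs,
                                      assume_unique=True)
        k_red = self.K.tocsr()[self.free_dofs][:, self.free_dofs]
        self._k_red = k_red
        self._lu = splu(k_red.tocsc())
        self.n_solves = 0

    def solve(self, case: LoadCase) -> FieldResult:
        f = build_load_vector(self.model, case)
        f_red = f[self.free_dofs]
        fnorm = np.linalg.norm(f_red)
        if fnorm == 0.0:
            u = np.zeros(self.model.n_dofs)
        else:
            u_red = self._lu.solve(f_red)
            resid = np.linalg.norm(self._k_red @ u_red - f_red)
            if not np.isfinite(resid) or resid > 1e-8 * fnorm:
                raise RuntimeError(
                    f"static solve for case {case.name!r} did not converge "
                    f"(residual {resid:.3e})")
            u = np.zeros(self.model.n_dofs)
            u[self.free_dofs] = u_red
        self.n_solves += 1
        energy = element_strain_energy(self.model, u)
        stress = nodal_stress(self.model, u, self.stress_measure)
        return FieldResult(case.name, u.reshape(-1, 2), energy, stress, float(f @ u))


def solve_cases(model: FEModel, cases: list[LoadCase],
                stress_measure: str = "xy_magnitude") -> list[FieldResult]:
    """Solve all load cases on one model, reusing a single factorization."""
    solver = StaticSolver(model, stress_measure)
    return [solver.solve(c) for c in cases]
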