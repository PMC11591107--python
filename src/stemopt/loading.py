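"""Daily-activity load cases, surface selection and boundary conditions.

Three activity load cases ship as the preset "daily": one-legged stance,
abduction and adduction, weighted 0.6/0.2/0.2 by assumed daily cycle counts.
Head loads act on the femoral (intact model) or prosthetic (post-insertion
model) head surface; trochanteric loads act on the greater-trochanter arc;
the lowest node row of the model is fully constrained.

Angle convention: degrees from the vertical (shaft) axis, positive toward
the medial side; forces point downward. The trochanteric force direction is
not anatomically fixed here — by default it follows the same convention at
the case angle, and is configurable per case.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse

from .mesh_fe import FEModel


@dataclass(frozen=True)
class LoadCase:
    """One named activity loading (forces in N, angles in degrees)."""

    name: str
    head_force: float
    head_angle: float
    trochanter_force: float
    weight: float
    trochanter_angle: float | None = None  # defaults to head_angle
    #: "up" models the abductor pull (toward the pelvis); "down" a joint-like
    #: compressive load. Only the magnitudes are anatomically fixed.
    trochanter_vertical: str = "up"

    def __post_init__(self):
        if self.head_force < 0 or self.trochanter_force < 0:
            raise ValueError("forces must be non-negative")

    @property
    def trochanter_angle_deg(self) -> float:
        return self.head_angle if self.trochanter_angle is None else self.trochanter_angle


def daily_activity_cases() -> list[LoadCase]:
    """The three daily-activity cases with weights summing to one."""
    return [
        LoadCase("one_legged_stance", 2317.0, 24.0, 703.0, 0.6),
        LoadCase("abduction", 1158.0, -15.0, 351.0, 0.2),
        LoadCase("adduction", 1548.0, 56.0, 468.0, 0.2),
    ]


def single_load_cases(cases: list[LoadCase]) -> dict[str, list[LoadCase]]:
    """Each case alone with weight 1 (degenerate weight vector)."""
    return {c.name: [replace(c, weight=1.0)] for c in cases}


def _adjacency_counts(mask: np.ndarray) -> np.ndarray:
    """Per-corner count (0..4) of adjacent True pixels."""
    nr, nc = mask.shape
    counts = np.zeros((nr + 1, nc + 1), dtype=np.int8)
    counts[:-1, :-1] += mask
    counts[:-1, 1:] += mask
    counts[1:, :-1] += mask
    counts[1:, 1:] += mask
    return counts


def _surface_nodes_of(model: FEModel, region_mask: np.ndarray) -> np.ndarray:
    """Node ids on the free boundary of the given pixel region.

    A node qualifies if it touches at least one region pixel and fewer than
    four meshed pixels (i.e. it lies on the mesh boundary).
    """
    meshed = model.labels_grid > 0
    on_region = _adjacency_counts(region_mask) > 0
    on_boundary = _adjacency_counts(meshed) < 4
    sel = on_region & on_boundary & (model.node_id_grid >= 0)
    return model.node_id_grid[sel]


def select_surface_nodes(model: FEModel, region: str) -> np.ndarray:
    """Node set for a named load/constraint surface.

    Regions: ``base`` (all nodes of the lowest occupied node row),
    ``intact_head`` / ``stem_head`` (superior arc of the respective head),
    ``greater_trochanter`` (lateral arc around the trochanter apex).
    """
    lm = model.landmarks
    if region == "base":
        # clamp the femur's cut surface: lowest-row nodes adjacent to bone.
        # Nodes belonging only to implant pixels stay free — the stem is not
        # part of the femur's section cut and must not anchor to the support.
        occupied = np.nonzero((model.node_id_grid >= 0).any(axis=1))[0]
        row = occupied[-1]
        bone_adj = _adjacency_counts((model.labels_grid == 1) | (model.labels_grid == 2))
        stem_adj = _adjacency_counts(model.labels_grid == 3)
        sel = ((model.node_id_grid[row, :] >= 0) & (bone_adj[row, :] > 0)
               & (stem_adj[row, :] == 0))
        ids = model.node_id_grid[row, :][sel]
        if ids.size == 0:
            raise ValueError("empty node selection for region 'base'")
        return ids

    if region == "intact_head":
        if lm.get("resected"):
            raise ValueError("intact_head surface requested on a resected model")
        center, radius = lm["head_center"], lm["head_radius"]
        mask = model.labels_grid > 0
    elif region == "stem_head":
        if "stem_head_center" not in lm:
            raise ValueError("stem_head surface requested but no stem has been inserted")
        center, radius = lm["stem_head_center"], lm["stem_head_radius"]
        mask = model.labels_grid == 3
    elif region == "greater_trochanter":
        center, radius = lm["gt_apex"], lm["gt_patch_radius"]
        surf = _surface_nodes_of(model, model.labels_grid > 0)
        d = np.linalg.norm(model.nodes[surf] - np.asarray(center), axis=1)
        ids = surf[d <= radius]
        if ids.size == 0:
            raise ValueError("empty node selection for region 'greater_trochanter'")
        return ids
    else:
        raise ValueError(f"unknown surface region {region!r}")

    surf = _surface_nodes_of(model, mask)
    xy = model.nodes[surf]
    d = np.linalg.norm(xy - np.asarray(center), axis=1)
    px = model.pixel_size
    on_arc = (np.abs(d - radius) <= 1.6 * px) & (xy[:, 1] <= center[1])
    ids = surf[on_arc]
    if ids.size == 0:
        raise ValueError(f"empty node selection for region {region!r}")
    return ids


def _direction(angle_deg: float, vertical: str = "down") -> np.ndarray:
    """Unit force direction tilted ``angle_deg`` toward medial (+x).

    ``vertical='down'`` points distally (joint compression); ``'up'`` points
    proximally (muscle pull).
    """
    a = np.radians(angle_deg)
    sign = {"down": 1.0, "up": -1.0}[vertical]
    return np.array([np.sin(a), sign * np.cos(a)])


def build_load_vector(model: FEModel, case: LoadCase) -> np.ndarray:
    """Global force vector (2N,) for one load case.

    Each surface load is split equally over its nodes so the resultant
    magnitude equals the case force exactly. The head load targets the stem
    head on a resected model and the femoral head otherwise; the
    trochanteric load follows the case's vertical convention.
    """
    f = np.zeros(model.n_dofs)
    head_region = "stem_head" if model.landmarks.get("resected") else "intact_head"
    for force, angle, region, vertical in (
        (case.head_force, case.head_angle, head_region, "down"),
        (case.trochanter_force, case.trochanter_angle_deg, "greater_trochanter",
         case.trochanter_vertical),
    ):
        if force == 0.0:
            continue
        ids = select_surface_nodes(model, region)
        share = force / ids.size * _direction(angle, vertical)
        np.add.at(f, 2 * ids, share[0])
        np.add.at(f, 2 * ids + 1, share[1])
    return f


@dataclass
class ReducedSystem:
    """Stiffness/load system with constrained DOFs eliminated."""

    K: sparse.csr_array          # reduced, free DOFs only
    f: np.ndarray                # reduced load
    free_dofs: np.ndarray        # global indices of the free DOFs
    fixed_dofs: np.ndarray
    n_dofs: int                  # size of the unreduced system

    def expand(self, u_red: np.ndarray) -> np.ndarray:
        u = np.zeros(self.n_dofs)
        u[self.free_dofs] = u_red
        return u


def reduce_system(K: sparse.sparray, f: np.ndarray,
                  fixed_dofs: np.ndarray) -> ReducedSystem:
    """Eliminate the given DOFs (homogeneous Dirichlet) from K and f."""
    n = K.shape[0]
    fixed_dofs = np.unique(np.asarray(fixed_dofs, dtype=np.int64))
    if fixed_dofs.size == 0:
        raise ValueError("constraint set is empty")
    if fixed_dofs.size >= n:
        raise ValueError("all DOFs are fixed; nothing to solve")
    free = np.setdiff1d(np.arange(n), fixed_dofs, assume_unique=True)
    K_red = K.tocsr()[free][:, free]
    return ReducedSystem(K_red, np.asarray(f)[free], free, fixed_dofs, n)


def apply_constraints(K: sparse.sparray, f: np.ndarray,
                      fixed_nodes: np.ndarray) -> ReducedSystem:
    """Fully constrain both DOFs of every node in ``fixed_nodes``."""
    fixed_nodes = np.asarray(fixed_nodes, dtype=np.int64)
    if fixed_nodes.size == 0:
        raise ValueError("constraint set is empty")
    dofs = np.concatenate([2 * fixed_nodes, 2 * fixed_nodes + 1])
    return reduce_system(K, f, dofs)


def reaction_forces(K: sparse.sparray, u: np.ndarray, f: np.ndarray,
                    fixed_dofs: np.ndarray) -> np.ndarray:
    """Reactions at the constrained DOFs: (K u - f) restricted to them."""
    return (K @ u - f)[np.asarray(fixed_dofs, dtype=np.int64)]
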