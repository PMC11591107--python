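"""Pixel-based plane-stress finite-element meshing and assembly.

Every non-background pixel of a labelled image becomes one square bilinear
Lagrange quadrilateral; coincident pixel corners share a single node with two
translational degrees of freedom. Element stiffness uses full 2x2 Gauss
integration of the plane-stress B^T D B integrand (for a square element the
result is independent of the side length and linear in E). Node numbering is
row-major over the pixel-corner grid; the DOF order is (ux, uy) per node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .materials import DEFAULT_MATERIALS, MaterialModel, elastic_arrays
from .phantom import LabeledImage

GAUSS_1D = (-1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0))
#: local corner coordinates, matching the CCW node order of each element
CORNERS = ((-1.0, -1.0), (1.0, -1.0), (1.0, 1.0), (-1.0, 1.0))


def _shape_gradients(xi: float, eta: float) -> np.ndarray:
    """dN/d(xi,eta) for the 4 bilinear shape functions, shape (2, 4)."""
    return 0.25 * np.array([
        [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)],
        [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)],
    ])


def _b_matrix(xi: float, eta: float, size: float) -> np.ndarray:
    """Strain-displacement matrix (3x8) of a square element of side ``size``."""
    dn = _shape_gradients(xi, eta) * (2.0 / size)  # physical gradients
    b = np.zeros((3, 8))
    b[0, 0::2] = dn[0]
    b[1, 1::2] = dn[1]
    b[2, 0::2] = dn[1]
    b[2, 1::2] = dn[0]
    return b


def plane_stress_d(E: float, nu: float) -> np.ndarray:
    """Plane-stress constitutive matrix (3x3, MPa)."""
    c = E / (1.0 - nu * nu)
    return c * np.array([
        [1.0, nu, 0.0],
        [nu, 1.0, 0.0],
        [0.0, 0.0, (1.0 - nu) / 2.0],
    ])


def element_stiffness(E: float, nu: float, size: float = 1.0) -> np.ndarray:
    """8x8 plane-stress stiffness of a square bilinear quad (2x2 Gauss)."""
    if E <= 0:
        raise ValueError("E must be positive")
    if not 0.0 < nu < 0.5:
        raise ValueError("nu must lie in (0, 0.5)")
    if size <= 0:
        raise ValueError("size must be positive")
    d = plane_stress_d(E, nu)
    det_j = (size / 2.0) ** 2
    k = np.zeros((8, 8))
    for xi in GAUSS_1D:
        for eta in GAUSS_1D:
            b = _b_matrix(xi, eta, size)
            k += b.T @ d @ b * det_j
    return k


@dataclass
class FEModel:
    """A meshed labelled image: geometry, connectivity and materials."""

    nodes: np.ndarray            # (N, 2) physical mm
    elements: np.ndarray         # (M, 4) CCW node indices
    elem_pixel: np.ndarray       # (M, 2) source (row, col)
    elem_label: np.ndarray       # (M,)
    elem_E: np.ndarray           # (M,) MPa
    elem_nu: np.ndarray          # (M,)
    elem_density: np.ndarray     # (M,) relative density of the source pixel
    pixel_size: float
    node_id_grid: np.ndarray     # (nr+1, nc+1), -1 where unused
    elem_id_grid: np.ndarray     # (nr, nc), -1 where unmeshed
    labels_grid: np.ndarray      # (nr, nc) labels of the meshed image
    landmarks: dict = field(default_factory=dict)
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_dofs(self) -> int:
        return 2 * self.n_nodes

    @property
    def elem_dofs(self) -> np.ndarray:
        """(M, 8) global DOF indices in (ux1, uy1, ..., ux4, uy4) order."""
        dofs = np.empty((self.n_elements, 8), dtype=np.int64)
        dofs[:, 0::2] = 2 * self.elements
        dofs[:, 1::2] = 2 * self.elements + 1
        return dofs


def build_mesh(image: LabeledImage,
               materials: MaterialModel = DEFAULT_MATERIALS) -> FEModel:
    """Convert a labelled image into a plane-stress FE model.

    One square element per pixel with label in {1, 2, 3}; node coordinates
    at pixel corners in mm. If the non-background region is not
    edge-connected, a warning is issued and only the largest component is
    meshed (stray pixels would make the stiffness singular).
    """
    labels = image.labels
    mask = labels > 0
    if not mask.any():
        raise ValueError("image contains no non-background pixels")
    comp, n_comp = ndimage.label(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        warnings.warn(
            f"non-background region has {n_comp} components; keeping the "
            f"largest ({int(sizes[keep - 1])} px)", stacklevel=2)
        mask = comp == keep
        labels = np.where(mask, labels, 0).astype(np.uint8)

    nr, nc = labels.shape
    used = np.zeros((nr + 1, nc + 1), dtype=bool)
    used[:-1, :-1] |= mask
    used[:-1, 1:] |= mask
    used[1:, :-1] |= mask
    used[1:, 1:] |= mask
    node_id = np.full((nr + 1, nc + 1), -1, dtype=np.int64)
    node_id[used] = np.arange(int(used.sum()))

    px = image.pixel_size
    rows, cols = np.nonzero(used)
    nodes = np.column_stack([image.origin[0] + cols * px,
                             image.origin[1] + rows * px]).astype(float)

    er, ec = np.nonzero(mask)
    elements = np.column_stack([
        node_id[er, ec],
        node_id[er, ec + 1],
        node_id[er + 1, ec + 1],
        node_id[er + 1, ec],
    ])
    elem_label = labels[er, ec].astype(np.int64)
    rho = image.density[er, ec]
    E, nu = elastic_arrays(elem_label, rho, materials)

    elem_id_grid = np.full((nr, nc), -1, dtype=np.int64)
    elem_id_grid[er, ec] = np.arange(len(er))

    return FEModel(
        nodes=nodes,
        elements=elements,
        elem_pixel=np.column_stack([er, ec]),
        elem_label=elem_label,
        elem_E=E,
        elem_nu=nu,
        elem_density=rho.astype(float),
        pixel_size=px,
        node_id_grid=node_id,
        elem_id_grid=elem_id_grid,
        labels_grid=labels,
        landmarks=dict(image.landmarks),
        origin=image.origin,
    )


def _unit_stiffness_by_nu(model: FEModel) -> tuple[np.ndarray, np.ndarray]:
    """Stack of E=1 stiffness matrices per distinct Poisson ratio.

    Returns (stack (G, 8, 8), index (M,)) so that element i's stiffness is
    ``elem_E[i] * stack[index[i]]``.
    """
    nus, idx = np.unique(model.elem_nu, return_inverse=True)
    stack = np.stack([element_stiffness(1.0, nu, model.pixel_size) for nu in nus])
    return stack, idx


def assemble_global(model: FEModel) -> sparse.csr_array:
    """Assemble the symmetric global stiffness (CSR, 2N x 2N)."""
    stack, idx = _unit_stiffness_by_nu(model)
    ke = model.elem_E[:, None, None] * stack[idx]
    dofs = model.elem_dofs
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    k = sparse.coo_array((ke.ravel(), (rows, cols)),
                         shape=(model.n_dofs, model.n_dofs)).tocsr()
    # enforce exact symmetry (summation order can differ across the diagonal)
    return ((k + k.T) * 0.5).tocsr()
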