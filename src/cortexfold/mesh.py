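"""Reference meshes: 1-D slender bar and 2-D plane-strain half disc.

The bar discretises the radial column used for calibration (one line of
elements along +x with implied unit cross-section; lateral symmetry
makes the solution one-dimensional).  The half disc is a structured
"butterfly" quadrilateral mesh: a cartesian core block surrounded by
body-fitted rings out to the curved pial surface.  Radial glial fibers
``N`` are stored per element (axial for the bar, radial for the disc).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Mesh", "make_bar_mesh", "make_halfcircle_mesh"]


@dataclass
class Mesh:
    """Reference mesh with named boundary node sets and a fiber field."""

    nodes: np.ndarray          # (n_nodes, dim) referential coordinates [um]
    elements: np.ndarray       # (n_el, nodes_per_el) connectivity
    kind: str                  # "bar1d" | "quad4"
    node_sets: dict = field(default_factory=dict)
    fiber: np.ndarray = None   # (n_el, 3) unit N per element
    R0: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def radial_coordinate(self) -> np.ndarray:
        """Referential radius per node (axial coordinate for the bar)."""
        if self.dim == 1:
            return self.nodes[:, 0].copy()
        return np.linalg.norm(self.nodes, axis=1)


def make_bar_mesh(R0: float, n_elems: int) -> Mesh:
    """Bar of length ``R0`` along +x with ``n_elems`` elements.

    Two-node line elements carrying full 3x3 kinematics; the unit-width
    lateral faces are implicitly roller-supported, so this is the
    one-dimensional reduction of a single row of brick elements with
    symmetry conditions on all long faces.
    """
    if n_elems < 1:
        raise ValueError("n_elems must be >= 1")
    x = np.linspace(0.0, R0, n_elems + 1)
    nodes = x[:, None]
    elements = np.column_stack([np.arange(n_elems), np.arange(1, n_elems + 1)])
    fiber = np.tile([1.0, 0.0, 0.0], (n_elems, 1))
    node_sets = {"fixed": np.array([0]), "free_end": np.array([n_elems])}
    return Mesh(nodes=nodes, elements=elements.astype(int), kind="bar1d",
                node_sets=node_sets, fiber=fiber, R0=float(R0))


def make_halfcircle_mesh(R0: float, target_elems: int = 1147) -> Mesh:
    """Half disc of radius ``R0`` (y >= 0) meshed with quadrilaterals.

    Butterfly layout: a cartesian half-square core of side ``R0/2``
    blended radially onto the semicircular boundary.  The straight cut
    edge (y = 0) is the symmetry edge; the curved edge is traction-free.
    Element count approximates ``target_elems`` (a structured layout
    cannot hit it exactly).
    """
    if target_elems < 16:
        raise ValueError("target_elems must be >= 16")
    # core: 2m x m elements; outer: 4m path segments x nr rings
    m = max(2, int(round(np.sqrt(target_elems / (2.0 + 4.0 * 1.9)))))
    nr = max(2, int(round((target_elems - 2 * m * m) / (4.0 * m))))
    a = 0.5 * R0

    # --- core nodes, (2m+1) x (m+1)
    xs = np.linspace(-a, a, 2 * m + 1)
    ys = np.linspace(0.0, a, m + 1)
    core_id = -np.ones((2 * m + 1, m + 1), dtype=int)
    nodes = []
    for j in range(m + 1):
        for i in range(2 * m + 1):
            core_id[i, j] = len(nodes)
            nodes.append((xs[i], ys[j]))
    elements = []
    for j in range(m):
        for i in range(2 * m):
            elements.append((core_id[i, j], core_id[i + 1, j],
                             core_id[i + 1, j + 1], core_id[i, j + 1]))

    # --- outer boundary path of the core: (a,0) -> (a,a) -> (-a,a) -> (-a,0)
    path = []
    for j in range(m + 1):                       # right edge, upward
        path.append(core_id[2 * m, j])
    for i in range(2 * m - 1, -1, -1):           # top edge, right->left
        path.append(core_id[i, m])
    for j in range(m - 1, -1, -1):               # left edge, downward
        path.append(core_id[0, j])
    npath = len(path)                            # 4m + 1 nodes
    theta = np.linspace(0.0, np.pi, npath)       # angle matching the path

    # --- ring nodes blended between core boundary and the circle
    ring_id = np.zeros((nr + 1, npath), dtype=int)
    ring_id[0, :] = path
    for k in range(1, nr + 1):
        w = k / nr
        for s in range(npath):
            px, py = nodes[path[s]]
            cx, cy = R0 * np.cos(theta[s]), R0 * np.sin(theta[s])
            ring_id[k, s] = len(nodes)
            nodes.append(((1 - w) * px + w * cx, (1 - w) * py + w * cy))
    for k in range(nr):
        for s in range(npath - 1):
            elements.append((ring_id[k, s], ring_id[k + 1, s],
                             ring_id[k + 1, s + 1], ring_id[k, s + 1]))

    nodes = np.asarray(nodes, float)
    elements = np.asarray(elements, int)
    # enforce counter-clockwise orientation
    p = nodes[elements]
    area2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = area2 < 0
    elements[flip] = elements[flip][:, ::-1]

    cent = nodes[elements].mean(axis=1)
    rc = np.linalg.norm(cent, axis=1)
    fiber = np.zeros((len(elements), 3))
    fiber[:, 0] = cent[:, 0] / rc
    fiber[:, 1] = cent[:, 1] / rc

    r_node = np.linalg.norm(nodes, axis=1)
    tol = 1e-8 * R0
    node_sets = {
        "symmetry": np.where(np.abs(nodes[:, 1]) < tol)[0],
        "outer_surface": np.where(np.abs(r_node - R0) < 1e-6 * R0)[0],
        "origin": np.array([int(np.argmin(r_node))]),
    }
    return Mesh(nodes=nodes, elements=elements, kind="quad4",
                node_sets=node_sets, fiber=fiber, R0=float(R0))
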