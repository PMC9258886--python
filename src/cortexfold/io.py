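"""File output: VTK (legacy ASCII) visualization, CSV frames, manifests."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import Mesh
from .simulation import SimulationFrame

__all__ = ["write_vtk", "write_mesh_txt", "read_mesh_txt",
           "write_frame_csv", "write_manifest", "file_checksum"]

_VTK_CELL = {"bar1d": (3, 2), "quad4": (9, 4)}   # (vtk type, nodes/cell)


def write_vtk(path, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None,
              points: np.ndarray | None = None) -> None:
    """Minimal legacy-ASCII VTK unstructured-grid writer.

    ``points`` overrides node positions (e.g. deformed coordinates).
    Scalar fields only; vectors may be passed as (n, 2|3) arrays.
    """
    pts = np.asarray(points if points is not None else mesh.nodes, float)
    if pts.shape[1] < 3:
        pts = np.column_stack([pts, np.zeros((pts.shape[0],
                                              3 - pts.shape[1]))])
    ctype, npc = _VTK_CELL[mesh.kind]
    lines = ["# vtk DataFile Version 3.0", "cortexfold output", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(pts)} double"]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in pts]
    ne = mesh.n_elements
    lines.append(f"CELLS {ne} {ne * (npc + 1)}")
    lines += [f"{npc} " + " ".join(str(int(i)) for i in el)
              for el in mesh.elements]
    lines.append(f"CELL_TYPES {ne}")
    lines += [str(ctype)] * ne

    def emit(data, n, header):
        out = [header]
        for name, arr in (data or {}).items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                out += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
                out += [f"{v:.9g}" for v in arr]
            else:
                vec = np.column_stack(
                    [arr, np.zeros((arr.shape[0], 3 - arr.shape[1]))]) \
                    if arr.shape[1] < 3 else arr
                out.append(f"VECTORS {name} double")
                out += [" ".join(f"{v:.9g}" for v in row) for row in vec]
        return out if len(out) > 1 else []

    lines += emit(point_data, len(pts), f"POINT_DATA {len(pts)}")
    lines += emit(cell_data, ne, f"CELL_DATA {ne}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mesh_txt(path, mesh: Mesh) -> None:
    """Plain-text node/element exchange format."""
    with open(path, "w") as fh:
        fh.write(f"# cortexfold mesh kind={mesh.kind} R0={mesh.R0}\n")
        fh.write(f"nodes {mesh.n_nodes} {mesh.dim}\n")
        for p in mesh.nodes:
            fh.write(" ".join(f"{v:.12g}" for v in np.atleast_1d(p)) + "\n")
        fh.write(f"elements {mesh.n_elements} {mesh.elements.shape[1]}\n")
        for el in mesh.elements:
            fh.write(" ".join(str(int(i)) for i in el) + "\n")
        for name, ids in mesh.node_sets.items():
            fh.write(f"nodeset {name} " +
                     " ".join(str(int(i)) for i in ids) + "\n")


def read_mesh_txt(path) -> Mesh:
    with open(path) as fh:
        header = fh.readline().split()
        kind = next(tok.split("=")[1] for tok in header if
                    tok.startswith("kind="))
        R0 = float(next(tok.split("=")[1] for tok in header if
                        tok.startswith("R0=")))
        tag, n, dim = fh.readline().split()
        nodes = np.array([[float(v) for v in fh.readline().split()]
                          for _ in range(int(n))])
        tag, ne, npc = fh.readline().split()
        elements = np.array([[int(v) for v in fh.readline().split()]
                             for _ in range(int(ne))])
        node_sets = {}
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "nodeset":
                node_sets[parts[1]] = np.array([int(v) for v in parts[2:]])
    fiber = None
    if kind == "bar1d":
        fiber = np.tile([1.0, 0.0, 0.0], (len(elements), 1))
    else:
        cent = nodes[elements].mean(axis=1)
        rc = np.linalg.norm(cent, axis=1, keepdims=True)
        fiber = np.column_stack([cent / rc, np.zeros(len(elements))])
    return Mesh(nodes=nodes, elements=elements, kind=kind,
                node_sets=node_sets, fiber=fiber, R0=R0)


def write_frame_csv(path, frame: SimulationFrame) -> None:
    """Nodal positions and per-cohort spatial densities of one frame."""
    cur = frame.nodes_current
    cols = {"x_um": cur[:, 0]}
    if cur.shape[1] > 1:
        cols["y_um"] = cur[:, 1]
    for i, c in enumerate(frame.c_spatial, start=1):
        cols[f"c{i}_um3"] = c
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(outdir, config: dict, seed: int,
                   t_start: float, files=None) -> Path:
    """One manifest per output directory: config, seed, inventory."""
    from . import __version__

    outdir = Path(outdir)
    inventory = {}
    for f in (files if files is not None else sorted(outdir.iterdir())):
        f = Path(f)
        if f.is_file() and f.name != "manifest.json":
            inventory[f.name] = file_checksum(f)
    manifest = {
        "package": "cortexfold", "version": __version__,
        "config": config, "seed": seed,
        "wall_time_s": round(time.time() - t_start, 3),
        "files": inventory,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
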