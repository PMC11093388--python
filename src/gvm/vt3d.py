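"""Plain-text state serialization ("vt3d dialect") and mesh export.

The state file mirrors the four storage lists of the model -- vertex
positions, edge endpoint lists with head/tail signs, polygon edge lists
with orientation signs, cell polygon lists with outward/inward signs --
in a documented line-oriented plain-text form::

    vt3d 1
    dim 3
    box <Lx> <Ly> <Lz>
    periodic <0|1> <0|1> <0|1>
    vertices <N_v>
    <id> <x> <y> <z>
    edges <N_e>
    <id> <head vertex id> <tail vertex id>
    polygons <N_p>
    <id> <signed edge id> ...      # sign of each id is the edge orientation
    cells <N_c>
    <id> <V0> <signed polygon id> ...
    tensions <N_e>                 # optional block
    <id> <gamma>

This is a dialect compatible in spirit with the ``.vt3d`` files used by
vertex-model tools; the exact upstream grammar is not public, so round
tripping through *this* module is the contract (read of a write is the
identity, bit for bit for positions).
"""

from __future__ import annotations

import numpy as np

from .geometry import SimulationBox, unwrap_polygon
from .graph import GVMGraph

__all__ = ["write_state", "read_state", "export_mesh", "ParseError"]


class ParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def write_state(graph: GVMGraph, positions, box: SimulationBox, path,
                tension: dict[int, float] | None = None) -> None:
    """Serialize a state; float fields use shortest round-trip repr."""
    lines = ["vt3d 1", f"dim {graph.dim}",
             "box " + " ".join(repr(float(x)) for x in box.lengths),
             "periodic " + " ".join(str(int(p)) for p in box.periodic)]
    lines.append(f"vertices {len(graph.vertices)}")
    for v in sorted(graph.vertices):
        x = np.asarray(positions[v], dtype=float)
        lines.append(f"{v} {float(x[0])!r} {float(x[1])!r} {float(x[2])!r}")
    lines.append(f"edges {len(graph.edges)}")
    for e in sorted(graph.edges):
        # open local patches may lack an endpoint; 0 marks "absent"
        vs = graph.edge_vertices(e)
        h = next((v for v, s in vs.items() if s == +1), 0)
        t = next((v for v, s in vs.items() if s == -1), 0)
        lines.append(f"{e} {h} {t}")
    lines.append(f"polygons {len(graph.polygons)}")
    for p in sorted(graph.polygons):
        items = " ".join(f"{sig * e:+d}" for e, sig in
                         sorted(graph.polygon_edges(p).items()))
        lines.append(f"{p} {items}")
    lines.append(f"cells {len(graph.cells)}")
    for c in sorted(graph.cells):
        v0 = float(graph.cells[c].get("v0", 1.0))
        items = " ".join(f"{sig * p:+d}" for p, sig in
                         sorted(graph.cell_polygons(c).items()))
        lines.append(f"{c} {v0!r} {items}")
    if tension is not None:
        lines.append(f"tensions {len(tension)}")
        for e in sorted(tension):
            lines.append(f"{e} {tension[e]!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_state(path):
    """Parse a state file; returns (graph, positions, box[, tension]).

    The tension mapping is returned only if the optional block is present.
    Dangling ids and malformed blocks raise :class:`ParseError` with the
    offending line number; the resulting graph is validated.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    lines = [(i + 1, ln.split("#")[0].strip()) for i, ln in enumerate(raw)]
    lines = [(no, ln) for no, ln in lines if ln]
    it = iter(lines)

    def expect(keyword, nfields=None):
        try:
            no, ln = next(it)
        except StopIteration:
            raise ParseError(len(raw), f"unexpected end of file, expected {keyword}")
        parts = ln.split()
        if parts[0] != keyword:
            raise ParseError(no, f"expected {keyword!r}, found {parts[0]!r}")
        if nfields is not None and len(parts) != nfields + 1:
            raise ParseError(no, f"{keyword} takes {nfields} fields")
        return no, parts[1:]

    _, ver = expect("vt3d", 1)
    if ver[0] != "1":
        raise ParseError(1, f"unsupported version {ver[0]}")
    no, d = expect("dim", 1)
    dim = int(d[0])
    if dim not in (2, 3):
        raise ParseError(no, "dim must be 2 or 3")
    _, bl = expect("box", 3)
    _, per = expect("periodic", 3)
    box = SimulationBox(tuple(float(x) for x in bl),
                        tuple(bool(int(x)) for x in per))
    g = GVMGraph(dim)
    positions: dict[int, np.ndarray] = {}
    open_patch = False

    no, nv = expect("vertices", 1)
    for _ in range(int(nv[0])):
        no, ln = next(it)
        parts = ln.split()
        if len(parts) != 4:
            raise ParseError(no, "vertex line needs: id x y z")
        g.add_node("vertex", int(parts[0]))
        positions[int(parts[0])] = np.array([float(x) for x in parts[1:]])
    no, ne = expect("edges", 1)
    for _ in range(int(ne[0])):
        no, ln = next(it)
        parts = ln.split()
        if len(parts) != 3:
            raise ParseError(no, "edge line needs: id head tail")
        e, h, t = (int(x) for x in parts)
        g.add_node("edge", e)
        for v, s in ((h, +1), (t, -1)):
            if v == 0:  # absent endpoint of an open local patch
                open_patch = True
                continue
            if v not in g.vertices:
                raise ParseError(no, f"edge {e} references missing vertex {v}")
            g.add_relation(("vertex", v), ("edge", e), s)
    no, np_ = expect("polygons", 1)
    for _ in range(int(np_[0])):
        no, ln = next(it)
        parts = ln.split()
        p = int(parts[0])
        g.add_node("polygon", p)
        for item in parts[1:]:
            e = int(item)
            sig, e = (1, e) if e > 0 else (-1, -e)
            if e not in g.edges:
                raise ParseError(no, f"polygon {p} references missing edge {e}")
            g.add_relation(("edge", e), ("polygon", p), sig)
    no, nc = expect("cells", 1)
    if dim == 2 and int(nc[0]) != 0:
        raise ParseError(no, "2D states cannot contain cells")
    for _ in range(int(nc[0])):
        no, ln = next(it)
        parts = ln.split()
        c = int(parts[0])
        g.add_node("cell", c, v0=float(parts[1]))
        for item in parts[2:]:
            p = int(item)
            Sig, p = (1, p) if p > 0 else (-1, -p)
            if p not in g.polygons:
                raise ParseError(no, f"cell {c} references missing polygon {p}")
            g.add_relation(("polygon", p), ("cell", c), Sig)
    tension = None
    rest = list(it)
    if rest:
        no, ln = rest[0]
        parts = ln.split()
        if parts[0] != "tensions":
            raise ParseError(no, f"unexpected block {parts[0]!r}")
        tension = {}
        for no, ln in rest[1:]:
            parts = ln.split()
            if len(parts) != 2:
                raise ParseError(no, "tension line needs: id gamma")
            e = int(parts[0])
            if e not in g.edges:
                raise ParseError(no, f"tension references missing edge {e}")
            tension[e] = float(parts[1])
    # closure and malformedness are fatal; the element-sharing rules are
    # not, because very small periodic crystals violate them benignly
    violations = [v for v in g.validate(boundary_ok=open_patch)
                  if "share" not in v]
    if violations:
        raise ParseError(0, "state violates closure rules: "
                         + "; ".join(violations[:3]))
    if tension is None:
        return g, positions, box
    return g, positions, box, tension


def export_mesh(graph: GVMGraph, positions, box: SimulationBox, path,
                fmt: str = "obj") -> None:
    """Write the interface network as a polygon soup (OBJ or legacy VTK).

    Each polygon is written once with its own unwrapped vertex copies so
    that interfaces crossing the periodic boundary render correctly; faces
    are tagged with the ids of the cells sharing them.  3D states only.
    """
    if graph.dim != 3:
        raise ValueError("mesh export supports 3D states only")
    polys = []
    for p in sorted(graph.polygons):
        _, coords = unwrap_polygon(graph, positions, box, p,
                                   max_span_fraction=1.0)
        cells = sorted(graph.polygon_cells(p))
        polys.append((p, coords, cells))
    if fmt == "obj":
        with open(path, "w") as fh:
            fh.write("# polygon soup export; one group per interface\n")
            offset = 1
            for p, coords, cells in polys:
                fh.write(f"g polygon_{p}_cells_{'_'.join(map(str, cells))}\n")
                for x in coords:
                    fh.write(f"v {x[0]} {x[1]} {x[2]}\n")
                fh.write("f " + " ".join(str(offset + i) for i in range(len(coords)))
                         + "\n")
                offset += len(coords)
    elif fmt == "vtk":
        nverts = sum(len(c) for _, c, _ in polys)
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\ncell interfaces\nASCII\n"
                     "DATASET POLYDATA\n")
            fh.write(f"POINTS {nverts} double\n")
            for _, coords, _ in polys:
                for x in coords:
                    fh.write(f"{x[0]} {x[1]} {x[2]}\n")
            size = sum(len(c) + 1 for _, c, _ in polys)
            fh.write(f"POLYGONS {len(polys)} {size}\n")
            offset = 0
            for _, coords, _ in polys:
                fh.write(str(len(coords)) + " "
                         + " ".join(str(offset + i) for i in range(len(coords)))
                         + "\n")
                offset += len(coords)
            fh.write(f"CELL_DATA {len(polys)}\nSCALARS cell_id int 1\n"
                     "LOOKUP_TABLE default\n")
            for _, _, cells in polys:
                fh.write(f"{cells[0] if cells else -1}\n")
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
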