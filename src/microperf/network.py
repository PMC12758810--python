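"""Vascular network data model and I/O.

A :class:`VascularNetwork` is a planar geometric graph: nodes with 2D
coordinates (micrometres) and vessels with a circular-equivalent lumen
diameter.  Tumour-induced compression is represented per vessel as an
elliptical cross section with a given major/minor aspect ratio; the
cross-sectional *area* of the circular-equivalent lumen is preserved
(compression deforms the lumen rather than removing it).

Networks carry exactly one inlet and one outlet node.  Dead-end branches
(degree-1 nodes other than the terminals) carry no flow in a purely
pressure-driven network and are removed by :func:`prune_dead_ends` before
any haemodynamic computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "Node",
    "Vessel",
    "VascularNetwork",
    "RegionLabels",
    "NetworkError",
    "NetworkFormatError",
    "prune_dead_ends",
    "label_regions",
    "apply_compression",
    "read_network",
    "write_network",
    "write_vtk",
]


class NetworkError(ValueError):
    """Structural problem with a vascular network (invariant violation)."""


class NetworkFormatError(NetworkError):
    """Malformed network file; message carries line/field context."""


@dataclass(frozen=True)
class Node:
    id: int
    x: float
    y: float

    @property
    def xy(self) -> Tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Vessel:
    """A straight vessel segment between two nodes.

    ``diameter`` is the circular-equivalent lumen diameter in micrometres.
    ``length`` defaults to the Euclidean node distance and may only be
    overridden explicitly.  ``aspect_ratio`` is the ellipse major/minor
    axis ratio; it is 1 for uncompressed vessels.
    """

    id: int
    node_a: int
    node_b: int
    diameter: float
    compressed: bool = False
    aspect_ratio: float = 1.0
    length_override: Optional[float] = None

    def __post_init__(self):
        if self.diameter <= 0:
            raise NetworkError(f"vessel {self.id}: diameter must be > 0")
        if self.aspect_ratio < 1.0:
            raise NetworkError(f"vessel {self.id}: aspect_ratio must be >= 1")
        if not self.compressed and self.aspect_ratio != 1.0:
            raise NetworkError(
                f"vessel {self.id}: uncompressed vessel must have aspect_ratio 1"
            )
        if self.node_a == self.node_b:
            raise NetworkError(f"vessel {self.id}: self-loop not allowed")
        if self.length_override is not None and self.length_override <= 0:
            raise NetworkError(f"vessel {self.id}: length must be > 0")

    def ellipse_semi_axes(self, convention: str = "perimeter") -> Tuple[float, float]:
        """Semi-axes (a, b) of the (possibly compressed) lumen ellipse.

        ``convention="perimeter"`` (default) keeps the lumen perimeter of
        the circular-equivalent vessel: the endothelial wall is treated as
        inextensible, so squeezing flattens the cross section and reduces
        its area (Ramanujan perimeter approximation).  ``"area"`` keeps
        the cross-sectional area instead (a*b = (d/2)^2).  Both reduce to
        (d/2, d/2) at aspect ratio 1.
        """
        r = 0.5 * self.diameter
        rho = self.aspect_ratio
        if convention == "area":
            s = math.sqrt(rho)
            return (r * s, r / s)
        if convention == "perimeter":
            # ellipse perimeter ~ pi [3(a+b) - sqrt((3a+b)(a+3b))] = pi d
            denom = 3.0 * (rho + 1.0) - math.sqrt((3.0 * rho + 1.0) * (rho + 3.0))
            b = 2.0 * r / denom
            return (rho * b, b)
        raise ValueError("convention must be 'perimeter' or 'area'")


@dataclass
class VascularNetwork:
    nodes: List[Node]
    vessels: List[Vessel]
    inlet: int
    outlet: int
    domain: Tuple[float, float, float, float]  # (x0, y0, x1, y1), um
    centre: Tuple[float, float]

    def __post_init__(self):
        self._node_index: Dict[int, int] = {}
        self.validate()

    # -- basic accessors -------------------------------------------------
    def node(self, node_id: int) -> Node:
        return self.nodes[self._node_index[node_id]]

    def vessel_length(self, vessel: Vessel) -> float:
        if vessel.length_override is not None:
            return vessel.length_override
        a, b = self.node(vessel.node_a), self.node(vessel.node_b)
        return math.hypot(a.x - b.x, a.y - b.y)

    def lengths(self) -> np.ndarray:
        return np.array([self.vessel_length(v) for v in self.vessels])

    def diameters(self) -> np.ndarray:
        return np.array([v.diameter for v in self.vessels])

    def node_ids(self) -> List[int]:
        return [n.id for n in self.nodes]

    def as_multigraph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, x=n.x, y=n.y)
        for v in self.vessels:
            g.add_edge(v.node_a, v.node_b, key=v.id, vessel=v)
        return g

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(
            nodes=list(self.nodes),
            vessels=list(self.vessels),
            inlet=self.inlet,
            outlet=self.outlet,
            domain=self.domain,
            centre=self.centre,
        )

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate node id(s): {dup}")
        self._node_index = {n.id: i for i, n in enumerate(self.nodes)}
        vids = [v.id for v in self.vessels]
        if len(set(vids)) != len(vids):
            dup = sorted({i for i in vids if vids.count(i) > 1})
            raise NetworkError(f"duplicate vessel id(s): {dup}")
        for v in self.vessels:
            for nid in (v.node_a, v.node_b):
                if nid not in self._node_index:
                    raise NetworkError(f"vessel {v.id}: unknown node {nid}")
        for term, name in ((self.inlet, "inlet"), (self.outlet, "outlet")):
            if term not in self._node_index:
                raise NetworkError(f"{name} node {term} not in network")
        if self.inlet == self.outlet:
            raise NetworkError("inlet and outlet must be distinct nodes")
        x0, y0, x1, y1 = self.domain
        if not (x1 > x0 and y1 > y0):
            raise NetworkError("degenerate domain bounding box")
        eps = 1e-9 * max(x1 - x0, y1 - y0)
        for n in self.nodes:
            if not (x0 - eps <= n.x <= x1 + eps and y0 - eps <= n.y <= y1 + eps):
                raise NetworkError(
                    f"node {n.id} at ({n.x}, {n.y}) lies outside the domain"
                )


@dataclass(frozen=True)
class RegionLabels:
    """Per-vessel core/periphery labels keyed by vessel id."""

    labels: Dict[int, str]
    core_radius: float

    def is_core(self, vessel_id: int) -> bool:
        return self.labels[vessel_id] == "core"

    @property
    def n_core(self) -> int:
        return sum(1 for lab in self.labels.values() if lab == "core")

    @property
    def n_periphery(self) -> int:
        return len(self.labels) - self.n_core


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def prune_dead_ends(network: VascularNetwork) -> VascularNetwork:
    """Iteratively remove dead-end branches.

    Removes vessels incident to degree-1 nodes (other than inlet/outlet)
    until a fixed point is reached, then drops orphaned nodes and any
    component not containing the inlet.  Raises :class:`NetworkError` if
    the inlet becomes disconnected from the outlet.
    """
    g = network.as_multigraph()
    terminals = {network.inlet, network.outlet}
    while True:
        leaves = [n for n in g.nodes if g.degree(n) <= 1 and n not in terminals]
        if not leaves:
            break
        g.remove_nodes_from(leaves)
    if network.inlet not in g or network.outlet not in g:
        raise NetworkError("pruning removed a terminal node: malformed network")
    comp = nx.node_connected_component(g, network.inlet)
    if network.outlet not in comp:
        raise NetworkError("inlet and outlet disconnected after pruning")
    keep_nodes = comp
    kept_vessels = [
        v for v in network.vessels if v.node_a in keep_nodes and v.node_b in keep_nodes
        and g.has_edge(v.node_a, v.node_b, key=v.id)
    ]
    kept_node_objs = [n for n in network.nodes if n.id in keep_nodes]
    return VascularNetwork(
        nodes=kept_node_objs,
        vessels=kept_vessels,
        inlet=network.inlet,
        outlet=network.outlet,
        domain=network.domain,
        centre=network.centre,
    )


def label_regions(network: VascularNetwork, core_radius: float = 1000.0) -> RegionLabels:
    """Label vessels core/periphery.

    A vessel is *core* iff both endpoints lie within ``core_radius`` of the
    network centre (inclusive boundary); all other vessels are periphery.
    """
    if core_radius <= 0:
        raise ValueError("core_radius must be positive")
    cx, cy = network.centre
    labels: Dict[int, str] = {}
    for v in network.vessels:
        a, b = network.node(v.node_a), network.node(v.node_b)
        da = math.hypot(a.x - cx, a.y - cy)
        db = math.hypot(b.x - cx, b.y - cy)
        labels[v.id] = "core" if (da <= core_radius and db <= core_radius) else "periphery"
    return RegionLabels(labels=labels, core_radius=core_radius)


def apply_compression(
    network: VascularNetwork,
    labels: RegionLabels,
    aspect_ratio: float = 4.26,
) -> VascularNetwork:
    """Flag core vessels as compressed with the given aspect ratio.

    ``aspect_ratio=1`` returns a network identical to the uncompressed
    model.  Periphery vessels are never modified.
    """
    if aspect_ratio < 1.0:
        raise ValueError("aspect_ratio must be >= 1")
    missing = [v.id for v in network.vessels if v.id not in labels.labels]
    if missing:
        raise NetworkError(f"labels missing for vessel(s): {missing}")
    new_vessels = []
    for v in network.vessels:
        if labels.is_core(v.id) and aspect_ratio > 1.0:
            new_vessels.append(replace(v, compressed=True, aspect_ratio=aspect_ratio))
        else:
            new_vessels.append(replace(v, compressed=False, aspect_ratio=1.0))
    out = network.copy()
    out.vessels = new_vessels
    out.validate()
    return out


# ---------------------------------------------------------------------------
# file format
# ---------------------------------------------------------------------------
#
# Plain-text, line oriented:
#
#   # comments / blank lines ignored
#   domain x0 y0 x1 y1
#   centre cx cy
#   inlet <node id>
#   outlet <node id>
#   nodes <count>
#   <id> <x> <y>            (count rows)
#   vessels <count>
#   <id> <node_a> <node_b> <diameter_um> <compressed 0/1> <aspect_ratio>
#
# All coordinates and diameters in micrometres.

_HEADER_KEYS = ("domain", "centre", "inlet", "outlet")


def write_network(network: VascularNetwork, path) -> None:
    x0, y0, x1, y1 = network.domain
    cx, cy = network.centre
    lines = [
        "# microperf vascular network (units: micrometre)",
        f"domain {x0!r} {y0!r} {x1!r} {y1!r}",
        f"centre {cx!r} {cy!r}",
        f"inlet {network.inlet}",
        f"outlet {network.outlet}",
        f"nodes {len(network.nodes)}",
    ]
    for n in network.nodes:
        lines.append(f"{n.id} {n.x!r} {n.y!r}")
    lines.append(f"vessels {len(network.vessels)}")
    for v in network.vessels:
        lines.append(
            f"{v.id} {v.node_a} {v.node_b} {v.diameter!r} "
            f"{1 if v.compressed else 0} {v.aspect_ratio!r}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_network(path) -> VascularNetwork:
    with open(path) as fh:
        raw = fh.readlines()
    lines = [
        (i + 1, line.strip()) for i, line in enumerate(raw)
        if line.strip() and not line.strip().startswith("#")
    ]
    header: Dict[str, object] = {}
    pos = 0

    def fail(lineno, msg):
        raise NetworkFormatError(f"{path}:{lineno}: {msg}")

    while pos < len(lines):
        lineno, line = lines[pos]
        key = line.split()[0]
        if key not in _HEADER_KEYS:
            break
        if key in header:
            fail(lineno, f"duplicate header entry '{key}' (exactly one {key} allowed)")
        toks = line.split()[1:]
        try:
            if key == "domain":
                if len(toks) != 4:
                    fail(lineno, "domain needs 4 values: x0 y0 x1 y1")
                header[key] = tuple(float(t) for t in toks)
            elif key == "centre":
                if len(toks) != 2:
                    fail(lineno, "centre needs 2 values: cx cy")
                header[key] = tuple(float(t) for t in toks)
            else:
                if len(toks) != 1:
                    fail(lineno, f"{key} needs a single node id")
                header[key] = int(toks[0])
        except ValueError:
            fail(lineno, f"could not parse {key} entry: '{line}'")
        pos += 1
    for key in _HEADER_KEYS:
        if key not in header:
            raise NetworkFormatError(f"{path}: missing header entry '{key}'")

    def read_block(name, ncols, builder):
        nonlocal pos
        if pos >= len(lines):
            raise NetworkFormatError(f"{path}: missing '{name}' block")
        lineno, line = lines[pos]
        toks = line.split()
        if toks[0] != name or len(toks) != 2:
            fail(lineno, f"expected '{name} <count>', got '{line}'")
        try:
            count = int(toks[1])
        except ValueError:
            fail(lineno, f"bad {name} count: '{toks[1]}'")
        pos += 1
        out = []
        for _ in range(count):
            if pos >= len(lines):
                raise NetworkFormatError(f"{path}: truncated '{name}' block")
            lineno, line = lines[pos]
            toks = line.split()
            if len(toks) != ncols:
                fail(lineno, f"{name} row needs {ncols} fields, got {len(toks)}")
            try:
                out.append(builder(toks))
            except NetworkError as exc:
                fail(lineno, str(exc))
            except ValueError:
                fail(lineno, f"could not parse {name} row: '{line}'")
            pos += 1
        return out

    nodes = read_block(
        "nodes", 3, lambda t: Node(id=int(t[0]), x=float(t[1]), y=float(t[2]))
    )
    vessels = read_block(
        "vessels",
        6,
        lambda t: Vessel(
            id=int(t[0]),
            node_a=int(t[1]),
            node_b=int(t[2]),
            diameter=float(t[3]),
            compressed=bool(int(t[4])),
            aspect_ratio=float(t[5]),
        ),
    )
    try:
        return VascularNetwork(
            nodes=nodes,
            vessels=vessels,
            inlet=header["inlet"],
            outlet=header["outlet"],
            domain=header["domain"],
            centre=header["centre"],
        )
    except NetworkError as exc:
        raise NetworkFormatError(f"{path}: {exc}") from exc


def write_vtk(network: VascularNetwork, path, vessel_scalars: Optional[Dict[str, Sequence[float]]] = None) -> None:
    """Export the network as legacy ASCII VTK polydata (for visualisation)."""
    idx = {n.id: i for i, n in enumerate(network.nodes)}
    lines = [
        "# vtk DataFile Version 3.0",
        "microperf vascular network",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(network.nodes)} float",
    ]
    for n in network.nodes:
        lines.append(f"{n.x} {n.y} 0.0")
    lines.append(f"LINES {len(network.vessels)} {3 * len(network.vessels)}")
    for v in network.vessels:
        lines.append(f"2 {idx[v.node_a]} {idx[v.node_b]}")
    scalars = {"diameter_um": [v.diameter for v in network.vessels],
               "compressed": [float(v.compressed) for v in network.vessels]}
    if vessel_scalars:
        scalars.update({k: list(v) for k, v in vessel_scalars.items()})
    lines.append(f"CELL_DATA {len(network.vessels)}")
    for name, vals in scalars.items():
        if len(vals) != len(network.vessels):
            raise ValueError(f"scalar '{name}' length mismatch")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(str(float(x)) for x in vals)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
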