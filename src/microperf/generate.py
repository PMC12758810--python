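"""Synthetic 2D microvascular network generator.

Produces lattice-based planar networks that are statistically similar to
mesh-grown tumour-adjacent vasculature: a 5000 x 5000 um square domain
with a single inlet (bottom left) and a single outlet (top right), vessel
diameters in 15-110 um, inter-vessel gaps of order 100-1000 um, and
approximately Murray's-law diameter relations at bifurcations.

The construction is a jittered honeycomb (or square) lattice cropped to
the domain, with dedicated single-vessel inlet/outlet trunks attached at
the corners.  Diameters are assigned hierarchically from a
unit-conductance potential flow solved between inlet and outlet:
``d = d_max (Q / Q_max)^(1/m)`` with Murray exponent m, which makes
``d^m`` proportional to flow and therefore conserved exactly at every
junction, up to the ``d_min`` floor applied to the weakest branches.

Randomness: a single integer seed drives all draws, in a documented
stream order (1. node jitter in node order, 2. edge conductance noise in
sorted edge order), so identical configs yield byte-identical networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import networkx as nx
import numpy as np

from .network import Node, NetworkError, VascularNetwork, Vessel, prune_dead_ends

__all__ = [
    "NetworkGenConfig",
    "generate_network",
    "generate_single_vessel_fixture",
    "murray_residuals",
    "intervessel_spacing_sample",
]


@dataclass(frozen=True)
class NetworkGenConfig:
    domain_size: float = 5000.0          # square side, um
    seed: int = 0
    diameter_range: Tuple[float, float] = (15.0, 110.0)   # um
    spacing_range: Tuple[float, float] = (100.0, 1000.0)  # target inter-vessel gap, um
    murray_exponent: float = 3.0
    lattice: str = "hexagonal"           # or "square"
    lattice_pitch: float = 300.0         # lattice edge length, um
    jitter: float = 0.25                 # node jitter as fraction of pitch
    conductance_noise: float = 0.1       # relative noise breaking symmetries

    def __post_init__(self):
        lo, hi = self.diameter_range
        if not (0 < lo < hi):
            raise ValueError("diameter range must be positive and ordered")
        lo, hi = self.spacing_range
        if not (0 < lo < hi):
            raise ValueError("spacing range must be positive and ordered")
        if self.lattice not in ("hexagonal", "square"):
            raise ValueError("lattice must be 'hexagonal' or 'square'")
        if self.lattice_pitch <= 0 or self.murray_exponent <= 0:
            raise ValueError("pitch and Murray exponent must be positive")
        if not (0 <= self.jitter < 0.5):
            raise ValueError("jitter must lie in [0, 0.5)")
        if self.domain_size < 4 * self.lattice_pitch:
            raise ValueError(
                "domain too small to host the requested lattice pitch")


def _lattice_graph(cfg: NetworkGenConfig) -> nx.Graph:
    s = cfg.lattice_pitch
    if cfg.lattice == "hexagonal":
        # unit-edge honeycomb; networkx positions have edge length 1
        m = int(cfg.domain_size / (s * math.sqrt(3))) + 2
        n = int(cfg.domain_size / (s * 1.5)) + 2
        g = nx.hexagonal_lattice_graph(m, n, with_positions=True)
        pos = {k: (p[0] * s, p[1] * s) for k, p in nx.get_node_attributes(g, "pos").items()}
    else:
        m = int(cfg.domain_size / s) + 2
        g = nx.grid_2d_graph(m, m)
        pos = {k: (k[0] * s, k[1] * s) for k in g.nodes}
    nx.set_node_attributes(g, pos, "pos")
    return g


def generate_network(cfg: NetworkGenConfig) -> VascularNetwork:
    """Generate a pruned, single-inlet/single-outlet synthetic network."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.domain_size
    margin = 0.06 * L
    g = _lattice_graph(cfg)

    # stream draw 1: jitter, applied in sorted node order
    nodes_sorted = sorted(g.nodes)
    jit = rng.uniform(-cfg.jitter * cfg.lattice_pitch,
                      cfg.jitter * cfg.lattice_pitch,
                      size=(len(nodes_sorted), 2))
    pos = {}
    for (k, (dx, dy)) in zip(nodes_sorted, jit):
        x, y = g.nodes[k]["pos"]
        pos[k] = (x + dx, y + dy)

    # crop to the interior (leaves room for the corner trunks)
    keep = [k for k in nodes_sorted
            if margin <= pos[k][0] <= L - margin and margin <= pos[k][1] <= L - margin]
    g = g.subgraph(keep).copy()
    if g.number_of_nodes() == 0:
        raise NetworkError("lattice pitch too large for the domain")
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()

    # attach single-vessel inlet/outlet trunks at the corners
    def nearest(point):
        return min(g.nodes, key=lambda k: math.hypot(pos[k][0] - point[0],
                                                     pos[k][1] - point[1]))

    inlet_key, outlet_key = "__inlet__", "__outlet__"
    pos[inlet_key] = (0.02 * L, 0.02 * L)
    pos[outlet_key] = (0.98 * L, 0.98 * L)
    g.add_edge(inlet_key, nearest(pos[inlet_key]))
    g.add_edge(outlet_key, nearest(pos[outlet_key]))

    # remove dead-end chains before assigning flow
    while True:
        leaves = [k for k in g.nodes
                  if g.degree(k) <= 1 and k not in (inlet_key, outlet_key)]
        if not leaves:
            break
        g.remove_nodes_from(leaves)
    if inlet_key not in g or outlet_key not in g or not nx.has_path(g, inlet_key, outlet_key):
        raise NetworkError("generator produced a disconnected network; "
                           "reduce pitch or jitter")

    # stream draw 2: conductance noise, in sorted edge order
    edges = sorted(g.edges, key=str)
    noise = rng.uniform(1.0 - cfg.conductance_noise, 1.0 + cfg.conductance_noise,
                        size=len(edges))

    # unit-conductance potential flow inlet -> outlet
    node_list = sorted(g.nodes, key=str)
    idx = {k: i for i, k in enumerate(node_list)}
    n = len(node_list)
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    lap = sp.lil_matrix((n, n))
    for (u, v), c in zip(edges, noise):
        iu, iv = idx[u], idx[v]
        lap[iu, iu] += c
        lap[iv, iv] += c
        lap[iu, iv] -= c
        lap[iv, iu] -= c
    i_in, i_out = idx[inlet_key], idx[outlet_key]
    free = [i for i in range(n) if i not in (i_in, i_out)]
    a = lap.tocsr()[free][:, free]
    rhs = -lap.tocsr()[free][:, [i_in]].toarray().ravel() * 1.0
    phi = np.zeros(n)
    phi[i_in] = 1.0
    phi[free] = spla.spsolve(a.tocsc(), rhs)
    q = np.array([c * (phi[idx[u]] - phi[idx[v]]) for (u, v), c in zip(edges, noise)])

    # hierarchical diameters: d^m proportional to |Q|, floored at d_min
    d_lo, d_hi = cfg.diameter_range
    qmax = np.abs(q).max()
    diam = d_hi * (np.abs(q) / qmax) ** (1.0 / cfg.murray_exponent)
    diam = np.clip(diam, d_lo, d_hi)

    node_ids = {k: i for i, k in enumerate(node_list)}
    nodes = [Node(id=node_ids[k], x=float(np.clip(pos[k][0], 0, L)),
                  y=float(np.clip(pos[k][1], 0, L))) for k in node_list]
    vessels = [
        Vessel(id=i, node_a=node_ids[u], node_b=node_ids[v], diameter=float(d))
        for i, ((u, v), d) in enumerate(zip(edges, diam))
    ]
    net = VascularNetwork(
        nodes=nodes, vessels=vessels,
        inlet=node_ids[inlet_key], outlet=node_ids[outlet_key],
        domain=(0.0, 0.0, L, L), centre=(0.5 * L, 0.5 * L),
    )
    return prune_dead_ends(net)


def generate_single_vessel_fixture(
    domain_size: float = 1000.0,
    diameter: float = 30.0,
    h_grid: float = 10.0,
):
    """One straight horizontal vessel through the domain centre.

    Returns ``(network, grid)``; used by the analytic validation tests of
    the transport solvers.
    """
    from .transport import TissueGrid

    if diameter >= domain_size:
        raise ValueError("vessel does not fit in the domain")
    L = domain_size
    net = VascularNetwork(
        nodes=[Node(0, 0.0, L / 2), Node(1, L, L / 2)],
        vessels=[Vessel(id=0, node_a=0, node_b=1, diameter=diameter)],
        inlet=0, outlet=1,
        domain=(0.0, 0.0, L, L), centre=(L / 2, L / 2),
    )
    grid = TissueGrid(origin=(0.0, 0.0), h=h_grid,
                      nx=int(round(L / h_grid)), ny=int(round(L / h_grid)))
    return net, grid


def murray_residuals(
    network: VascularNetwork,
    flow: Optional[np.ndarray] = None,
    exponent: float = 3.0,
) -> np.ndarray:
    """Relative Murray's-law residual at every perfused junction.

    For each interior node with at least 3 incident perfused vessels,
    returns ``|sum_in d^m - sum_out d^m| / sum_in d^m`` with in/out taken
    from the flow direction.  If no flow is given, a unit-conductance
    potential flow between inlet and outlet is used.
    """
    from .hemodynamics import BloodModelParams, solve_pressures

    if flow is None:
        params = BloodModelParams(plasma_viscosity=1.0)
        h0 = np.zeros(len(network.vessels))
        _, flow = solve_pressures(network, h0, params)
    absq = np.abs(flow)
    perfused = absq > 1e-12 * absq.mean()
    incident: dict = {}
    for i, v in enumerate(network.vessels):
        if not perfused[i]:
            continue
        signed = flow[i]
        # flow > 0 leaves node_a, enters node_b
        incident.setdefault(v.node_a, []).append((i, -signed))
        incident.setdefault(v.node_b, []).append((i, +signed))
    out = []
    for node_id, inc in incident.items():
        if node_id in (network.inlet, network.outlet) or len(inc) < 3:
            continue
        d_in = sum(network.vessels[i].diameter ** exponent for i, s in inc if s > 0)
        d_out = sum(network.vessels[i].diameter ** exponent for i, s in inc if s < 0)
        if d_in > 0:
            out.append(abs(d_in - d_out) / d_in)
    return np.asarray(out)


def intervessel_spacing_sample(
    network: VascularNetwork,
    n_samples: int = 400,
    seed: int = 0,
    inset: float = 0.1,
) -> np.ndarray:
    """Empirical inter-vessel gap widths sampled at random tissue points.

    For each sample point the gap is the distance to the nearest vessel
    segment plus the distance to the nearest segment that shares no node
    with it (i.e. the width of the avascular corridor the point sits in).
    Points are drawn uniformly from the domain shrunk by ``inset`` on each
    side to avoid the unvascularised rim.
    """
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = network.domain
    w, hgt = x1 - x0, y1 - y0
    pts = np.column_stack([
        rng.uniform(x0 + inset * w, x1 - inset * w, n_samples),
        rng.uniform(y0 + inset * hgt, y1 - inset * hgt, n_samples),
    ])
    a = np.array([network.node(v.node_a).xy for v in network.vessels])
    b = np.array([network.node(v.node_b).xy for v in network.vessels])
    ab = b - a
    ab2 = np.maximum((ab ** 2).sum(axis=1), 1e-300)
    nodesets = [frozenset((v.node_a, v.node_b)) for v in network.vessels]
    gaps = np.empty(n_samples)
    for k, p in enumerate(pts):
        t = np.clip(((p - a) * ab).sum(axis=1) / ab2, 0.0, 1.0)
        proj = a + t[:, None] * ab
        dist = np.hypot(*(p - proj).T)
        i_near = int(np.argmin(dist))
        near_nodes = nodesets[i_near]
        mask = np.array([len(ns & near_nodes) == 0 for ns in nodesets])
        gaps[k] = dist[i_near] + dist[mask].min()
    return gaps
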