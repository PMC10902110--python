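"""Circuit-theory connectivity over a raster resistance surface.

The resistance raster is turned into an electrical network: every cell
is a node, adjacent cells (4- or 8-neighbourhood) are joined by a
resistor whose conductance is

    g = 1 / (mean(r_a, r_b) * d),    d = 1 orthogonal, sqrt(2) diagonal,

i.e. average-resistance coupling with a diagonal distance correction.
Injecting one unit of current between a pair of focal nodes and solving
Kirchhoff's laws (a graph-Laplacian linear system) yields per-cell
current densities — the circuit analogue of expected animal movement
intensity. Averaging the density over all unordered pairs of perimeter
nodes gives the omnidirectional connectivity surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .raster import Raster
from .resistance import NodeSet, ResistanceRaster

__all__ = [
    "RasterGraph",
    "PairSolve",
    "CurrentMap",
    "build_graph",
    "solve_pair",
    "node_current_density",
    "effective_resistance",
    "mean_current_map",
]

_SQRT2 = np.sqrt(2.0)


@dataclass
class RasterGraph:
    """Undirected resistor network on the cells of a raster.

    Edges are stored once per unordered cell pair as parallel arrays of
    flat cell indices and conductances.
    """

    shape: tuple[int, int]
    edge_a: np.ndarray
    edge_b: np.ndarray
    conductance: np.ndarray
    neighbourhood: int
    cell_size: float = 10.0
    xll: float = 0.0
    yll: float = 0.0

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def n_edges(self) -> int:
        return len(self.conductance)

    def laplacian(self) -> sp.csr_matrix:
        """Weighted graph Laplacian L = D - W (symmetric PSD)."""
        n = self.n_cells
        w = sp.coo_matrix(
            (
                np.concatenate([self.conductance, self.conductance]),
                (
                    np.concatenate([self.edge_a, self.edge_b]),
                    np.concatenate([self.edge_b, self.edge_a]),
                ),
            ),
            shape=(n, n),
        ).tocsr()
        deg = np.asarray(w.sum(axis=1)).ravel()
        return sp.diags(deg) - w

    def adjacency(self) -> sp.csr_matrix:
        n = self.n_cells
        return sp.coo_matrix(
            (
                np.ones(2 * self.n_edges),
                (
                    np.concatenate([self.edge_a, self.edge_b]),
                    np.concatenate([self.edge_b, self.edge_a]),
                ),
            ),
            shape=(n, n),
        ).tocsr()

    def incidence_abs(self) -> sp.csr_matrix:
        """|incidence| matrix (cells x edges) with unit entries."""
        e = np.arange(self.n_edges)
        return sp.coo_matrix(
            (
                np.ones(2 * self.n_edges),
                (np.concatenate([self.edge_a, self.edge_b]), np.concatenate([e, e])),
            ),
            shape=(self.n_cells, self.n_edges),
        ).tocsr()


@dataclass
class PairSolve:
    """Node potentials for one unit of current between a source/target pair."""

    source: int
    target: int
    potentials: np.ndarray
    injected: float = 1.0


@dataclass
class CurrentMap:
    """Per-cell mean current density averaged over focal-node pairs."""

    values: np.ndarray  # 2-D, possibly log10-transformed
    n_pairs: int
    log10_applied: bool
    floor: float | None
    cell_size: float = 10.0
    xll: float = 0.0
    yll: float = 0.0

    def to_raster(self) -> Raster:
        return Raster(
            self.values,
            cell_size=self.cell_size,
            xll=self.xll,
            yll=self.yll,
            metadata={
                "n_pairs": self.n_pairs,
                "log10_applied": self.log10_applied,
                "floor": self.floor,
            },
        )


def build_graph(rr: ResistanceRaster | Raster | np.ndarray, neighbourhood: int = 8) -> RasterGraph:
    """Build the resistor network for a resistance raster.

    With ``neighbourhood=8``, diagonal neighbours are connected with an
    extra sqrt(2) distance factor in the resistance.
    """
    if neighbourhood not in (4, 8):
        raise ValueError("neighbourhood must be 4 or 8")
    if isinstance(rr, ResistanceRaster):
        r = rr.values
        cell_size, xll, yll = rr.raster.cell_size, rr.raster.xll, rr.raster.yll
    elif isinstance(rr, Raster):
        r = rr.values
        cell_size, xll, yll = rr.cell_size, rr.xll, rr.yll
    else:
        r = np.asarray(rr, dtype=float)
        cell_size, xll, yll = 1.0, 0.0, 0.0
    if r.size == 0:
        raise ValueError("empty raster")
    if np.any(r <= 0) or not np.all(np.isfinite(r)):
        raise ValueError("resistances must be finite and > 0")
    nrows, ncols = r.shape
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)

    ea, eb, gs = [], [], []

    def _add(a_idx, b_idx, ra, rb, dist):
        ea.append(a_idx.ravel())
        eb.append(b_idx.ravel())
        gs.append(1.0 / (0.5 * (ra.ravel() + rb.ravel()) * dist))

    if ncols > 1:  # horizontal
        _add(idx[:, :-1], idx[:, 1:], r[:, :-1], r[:, 1:], 1.0)
    if nrows > 1:  # vertical
        _add(idx[:-1, :], idx[1:, :], r[:-1, :], r[1:, :], 1.0)
    if neighbourhood == 8 and nrows > 1 and ncols > 1:
        _add(idx[:-1, :-1], idx[1:, 1:], r[:-1, :-1], r[1:, 1:], _SQRT2)  # down-right
        _add(idx[:-1, 1:], idx[1:, :-1], r[:-1, 1:], r[1:, :-1], _SQRT2)  # down-left

    if not ea:
        raise ValueError("raster has a single cell; no edges to build")
    return RasterGraph(
        shape=(nrows, ncols),
        edge_a=np.concatenate(ea),
        edge_b=np.concatenate(eb),
        conductance=np.concatenate(gs),
        neighbourhood=neighbourhood,
        cell_size=cell_size,
        xll=xll,
        yll=yll,
    )


class _GroundedSolver:
    """LU factorisation of the Laplacian with one node grounded.

    Potentials returned are relative to the ground node; current flows
    depend only on potential differences, so any ground choice gives
    the same densities.
    """

    def __init__(self, graph: RasterGraph, ground: int):
        n = graph.n_cells
        L = graph.laplacian().tocsc()
        keep = np.ones(n, dtype=bool)
        keep[ground] = False
        self.keep = keep
        self.ground = ground
        self.n = n
        self._lu = spla.splu(L[keep][:, keep].tocsc())
        self._L = L

    def solve(self, source: int, target: int, injected: float = 1.0) -> np.ndarray:
        e = np.zeros(self.n)
        e[source] += injected
        e[target] -= injected
        v_red = self._lu.solve(e[self.keep])
        v = np.zeros(self.n)
        v[self.keep] = v_red
        return v

    def residual(self, v: np.ndarray, source: int, target: int, injected: float = 1.0) -> float:
        e = np.zeros(self.n)
        e[source] += injected
        e[target] -= injected
        r = self._L @ v - e
        return float(np.linalg.norm(r) / max(np.linalg.norm(e), 1e-300))


def _check_connected(graph: RasterGraph, nodes: np.ndarray) -> None:
    n_comp, labels = csgraph.connected_components(graph.adjacency(), directed=False)
    if n_comp == 1:
        return
    lab = labels[nodes]
    if len(set(lab.tolist())) > 1:
        bad = [(int(nodes[i]), int(nodes[j])) for i, j in combinations(range(len(nodes)), 2) if lab[i] != lab[j]]
        raise ValueError(f"focal nodes are not mutually connected; disconnected pairs: {bad[:5]}")


def solve_pair(graph: RasterGraph, source: int, target: int) -> PairSolve:
    """Solve for node potentials with 1 A injected at source, removed at target.

    The target node is the ground (0 V); the relative residual of the
    full Laplacian system is verified to be <= 1e-8.
    """
    if source == target:
        raise ValueError("source and target must differ")
    _check_connected(graph, np.array([source, target]))
    solver = _GroundedSolver(graph, ground=target)
    v = solver.solve(source, target)
    res = solver.residual(v, source, target)
    if res > 1e-8:
        raise ArithmeticError(f"linear solve residual {res:.2e} exceeds 1e-8")
    return PairSolve(source=source, target=target, potentials=v)


def _density_from_potentials(
    graph: RasterGraph, v: np.ndarray, source: int, target: int, inc: sp.csr_matrix | None = None
) -> np.ndarray:
    """Per-cell current density: half the summed |edge current| at each cell.

    Terminals carry the full injected current by definition.
    """
    edge_current = graph.conductance * (v[graph.edge_a] - v[graph.edge_b])
    if inc is None:
        inc = graph.incidence_abs()
    dens = 0.5 * (inc @ np.abs(edge_current))
    dens[source] = 1.0
    dens[target] = 1.0
    return dens


def node_current_density(graph: RasterGraph, solve: PairSolve) -> np.ndarray:
    """Current density per cell for a single pair solve (flat array)."""
    return _density_from_potentials(graph, solve.potentials, solve.source, solve.target)


def effective_resistance(graph: RasterGraph, a: int, b: int) -> float:
    """Effective (two-point) resistance between cells a and b."""
    ps = solve_pair(graph, a, b)
    return float(ps.potentials[a] - ps.potentials[b])


def mean_current_map(
    graph: RasterGraph,
    nodes: NodeSet,
    log10_floor: float | None = 1e-12,
    pair_mode: str = "all",
    k_nearest: int = 8,
) -> CurrentMap:
    """Average per-cell current density over pairs of focal nodes.

    ``pair_mode='all'`` iterates every unordered pair of the node set
    (50 nodes -> 1225 pairs). ``pair_mode='nearest'`` pairs each node
    only with its ``k_nearest`` nearest node neighbours (by grid
    distance). With ``log10_floor`` set, the mean map is floored there
    and log10-transformed, which is how connectivity maps are usually
    reported (mean densities span orders of magnitude).
    """
    ncols = graph.shape[1]
    flat = nodes.flat_indices(ncols)
    if len(flat) < 2:
        raise ValueError("need at least two focal nodes")
    _check_connected(graph, flat)

    if pair_mode == "all":
        pairs = list(combinations(range(len(flat)), 2))
    elif pair_mode == "nearest":
        pts = np.column_stack([nodes.rows, nodes.cols]).astype(float)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        k = min(k_nearest, len(flat) - 1)
        pair_set = set()
        for i in range(len(flat)):
            for j in np.argsort(d[i])[:k]:
                pair_set.add((min(i, int(j)), max(i, int(j))))
        pairs = sorted(pair_set)
    else:
        raise ValueError("pair_mode must be 'all' or 'nearest'")

    solver = _GroundedSolver(graph, ground=int(flat[0]))
    inc = graph.incidence_abs()
    acc = np.zeros(graph.n_cells)
    for i, j in pairs:
        s, t = int(flat[i]), int(flat[j])
        v = solver.solve(s, t)
        acc += _density_from_potentials(graph, v, s, t, inc=inc)
    mean = acc / len(pairs)

    log10_applied = log10_floor is not None
    if log10_applied:
        vals = np.log10(np.maximum(mean, log10_floor))
    else:
        vals = mean
    return CurrentMap(
        values=vals.reshape(graph.shape),
        n_pairs=len(pairs),
        log10_applied=log10_applied,
        floor=log10_floor,
        cell_size=graph.cell_size,
        xll=graph.xll,
        yll=graph.yll,
    )
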