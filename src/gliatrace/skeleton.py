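"""Per-cell skeleton graphs (soma + traced processes) and SWC round-trip.

A :class:`FilamentGraph` is an undirected tree over nodes with 3D
physical coordinates (µm, ``(z, y, x)``) and radii, with one designated
soma node.  It is the common currency between the synthetic generator,
the tracer and the morphometry module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["FilamentGraph", "write_swc", "read_swc"]


@dataclass
class FilamentGraph:
    """Rooted skeletal representation of one cell.

    ``graph`` nodes carry ``pos`` (ndarray, (z, y, x) µm) and ``radius``
    (µm) attributes; edges are unweighted (lengths derive from node
    positions).  ``soma`` is the root node id.
    """

    graph: nx.Graph
    soma: int
    cell_id: str = ""
    labels: dict = field(default_factory=dict)  # animal_id / group / age ...
    soma_volume_um3: float | None = None
    soma_volume_is_fallback: bool = False

    # -- accessors -----------------------------------------------------
    def pos(self, n) -> np.ndarray:
        return self.graph.nodes[n]["pos"]

    def radius(self, n) -> float:
        return self.graph.nodes[n]["radius"]

    def soma_pos(self) -> np.ndarray:
        return self.pos(self.soma)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def node_positions(self) -> np.ndarray:
        """(n, 3) array of node coordinates in µm, deterministic order."""
        return np.array([self.pos(n) for n in sorted(self.graph.nodes)])

    def leaves(self) -> list[int]:
        return [
            n
            for n in self.graph.nodes
            if self.graph.degree[n] == 1 and n != self.soma
        ]

    def edge_segments(self) -> np.ndarray:
        """(m, 2, 3) array of edge endpoint coordinates, deterministic order."""
        edges = sorted((min(u, v), max(u, v)) for u, v in self.graph.edges)
        if not edges:
            return np.zeros((0, 2, 3))
        return np.array([[self.pos(u), self.pos(v)] for u, v in edges])

    # -- validation / transforms ---------------------------------------
    def validate(self) -> None:
        g = self.graph
        if self.soma not in g:
            raise ValueError("soma node missing from graph")
        if g.number_of_nodes() > 1 and not nx.is_connected(g):
            raise ValueError("graph is not connected")
        if g.number_of_edges() != g.number_of_nodes() - 1:
            raise ValueError("graph is not a tree")

    def copy(self) -> "FilamentGraph":
        return FilamentGraph(
            graph=self.graph.copy(),
            soma=self.soma,
            cell_id=self.cell_id,
            labels=dict(self.labels),
            soma_volume_um3=self.soma_volume_um3,
            soma_volume_is_fallback=self.soma_volume_is_fallback,
        )

    def transformed(self, fn) -> "FilamentGraph":
        """Apply ``fn(pos) -> pos`` to every node coordinate."""
        out = self.copy()
        for n in out.graph.nodes:
            out.graph.nodes[n]["pos"] = np.asarray(fn(self.pos(n)), dtype=float)
        return out

    def resampled(self, max_spacing_um: float) -> "FilamentGraph":
        """Subdivide edges so no edge is longer than *max_spacing_um*.

        Node ids are renumbered; geometry and topology are unchanged up
        to the inserted collinear vertices.
        """
        if max_spacing_um <= 0:
            raise ValueError("max_spacing_um must be positive")
        g = nx.Graph()
        remap = {}
        for n in sorted(self.graph.nodes):
            remap[n] = len(remap)
            g.add_node(remap[n], pos=self.pos(n).copy(), radius=self.radius(n))
        next_id = len(remap)
        for u, v in sorted((min(a, b), max(a, b)) for a, b in self.graph.edges):
            p0, p1 = self.pos(u), self.pos(v)
            r0, r1 = self.radius(u), self.radius(v)
            length = float(np.linalg.norm(p1 - p0))
            n_seg = max(1, int(np.ceil(length / max_spacing_um)))
            prev = remap[u]
            for k in range(1, n_seg):
                t = k / n_seg
                g.add_node(next_id, pos=p0 + t * (p1 - p0), radius=r0 + t * (r1 - r0))
                g.add_edge(prev, next_id)
                prev = next_id
                next_id += 1
            g.add_edge(prev, remap[v])
        return FilamentGraph(
            graph=g,
            soma=remap[self.soma],
            cell_id=self.cell_id,
            labels=dict(self.labels),
            soma_volume_um3=self.soma_volume_um3,
            soma_volume_is_fallback=self.soma_volume_is_fallback,
        )


SWC_SOMA, SWC_PROCESS = 1, 3


def write_swc(fg: FilamentGraph, path) -> None:
    """Write a skeleton as SWC (µm, x y z order; type 1 soma, 3 process)."""
    fg.validate()
    order = list(nx.dfs_preorder_nodes(fg.graph, fg.soma)) if fg.n_nodes() else []
    swc_id = {n: i + 1 for i, n in enumerate(order)}
    parent = {fg.soma: -1}
    for u, v in nx.dfs_edges(fg.graph, fg.soma):
        parent[v] = swc_id[u]
    with open(path, "w") as fh:
        fh.write(f"# gliatrace skeleton cell_id={fg.cell_id}\n")
        fh.write("# id type x y z radius parent (um)\n")
        for n in order:
            z, y, x = fg.pos(n)
            t = SWC_SOMA if n == fg.soma else SWC_PROCESS
            fh.write(
                f"{swc_id[n]} {t} {x:.6f} {y:.6f} {z:.6f} "
                f"{fg.radius(n):.6f} {parent[n]}\n"
            )


def read_swc(path, cell_id: str = "") -> FilamentGraph:
    g = nx.Graph()
    soma = None
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, typ, x, y, z, r, par = line.split()
            n = int(sid) - 1
            g.add_node(n, pos=np.array([float(z), float(y), float(x)]), radius=float(r))
            if int(typ) == SWC_SOMA and soma is None:
                soma = n
            if int(par) != -1:
                edges.append((int(par) - 1, n))
    g.add_edges_from(edges)
    if soma is None:
        raise ValueError(f"{path}: no soma (type-1) node in SWC file")
    return FilamentGraph(graph=g, soma=soma, cell_id=cell_id)
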