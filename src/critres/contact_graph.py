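"""Residue contact graphs.

Two residues are in contact when the minimal distance between their atoms
(under the chosen atom mode) is at most a cutoff, 5 Angstrom by default.
The graph is undirected and unweighted; node indices are the chain's
0-based residue indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ChainStructure

log = logging.getLogger(__name__)

ATOM_MODES = ("heavy", "CA", "CB")


@dataclass
class ResidueContactGraph:
    n_nodes: int
    edges: set[tuple[int, int]]
    cutoff: float = 5.0
    atom_mode: str = "heavy"
    _adj: dict[int, set[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        norm = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-edge on node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) out of range")
            norm.add((min(i, j), max(i, j)))
        self.edges = norm
        self._adj = {i: set() for i in range(self.n_nodes)}
        for i, j in self.edges:
            self._adj[i].add(j)
            self._adj[j].add(i)

    def neighbors(self, i: int) -> set[int]:
        if not (0 <= i < self.n_nodes):
            raise IndexError(f"node {i} out of range [0, {self.n_nodes})")
        return set(self._adj[i])

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=int)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1
        return a

    # --- plain-text interchange -------------------------------------------
    def to_edge_tsv(self) -> str:
        lines = [f"{i}\t{j}" for i, j in sorted(self.edges)]
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_edge_tsv(cls, text: str, n_nodes: int, cutoff: float = 5.0,
                      atom_mode: str = "heavy") -> "ResidueContactGraph":
        edges = set()
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            i, j = (int(v) for v in line.split("\t"))
            edges.add((i, j))
        return cls(n_nodes=n_nodes, edges=edges, cutoff=cutoff, atom_mode=atom_mode)

    def to_matrix_csv(self) -> str:
        return "\n".join(
            ",".join(str(v) for v in row) for row in self.adjacency_matrix()
        ) + "\n"


def _mode_coords(s: ChainStructure, atom_mode: str):
    """Per-residue coordinate sets for the contact definition."""
    coords, owner = [], []
    for res in s.residues:
        if atom_mode == "heavy":
            pts = [(a.x, a.y, a.z) for a in res.atoms]
        else:
            at = res.atom(atom_mode)
            if at is None and atom_mode == "CB":
                at = res.atom("CA")
                if at is not None:
                    log.debug("residue %d lacks CB; using CA", res.seq_index)
            if at is None:
                at = res.atoms[0]
                log.warning(
                    "residue %d lacks %s atom; falling back to %s",
                    res.seq_index, atom_mode, at.name,
                )
            pts = [(at.x, at.y, at.z)]
        coords.extend(pts)
        owner.extend([res.seq_index] * len(pts))
    return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)


def build_contact_graph(
    s: ChainStructure,
    cutoff: float = 5.0,
    atom_mode: str = "heavy",
    min_seq_sep: int = 1,
) -> ResidueContactGraph:
    """Build the undirected residue contact graph of one chain.

    An edge (i, j) is present iff the minimal inter-residue atom distance
    under *atom_mode* is <= *cutoff* and ``|i - j| >= min_seq_sep``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if atom_mode not in ATOM_MODES:
        raise ValueError(f"atom_mode must be one of {ATOM_MODES}")
    if len(s) < 1:
        raise ValueError("structure has no residues")

    coords, owner = _mode_coords(s, atom_mode)
    tree = cKDTree(coords)
    edges = set()
    for a, b in tree.query_pairs(cutoff):
        i, j = int(owner[a]), int(owner[b])
        if i != j and abs(i - j) >= min_seq_sep:
            edges.add((min(i, j), max(i, j)))
    return ResidueContactGraph(
        n_nodes=len(s), edges=edges, cutoff=cutoff, atom_mode=atom_mode
    )
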