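import numpy as np
import pytest

from critres.contact_graph import ResidueContactGraph


def graph_from_edges(n, edges, **kw):
    return ResidueContactGraph(n_nodes=n, edges=set(edges), **kw)


def random_graph(n, p, seed):
    """Erdos-Renyi graph as a ResidueContactGraph."""
    rng = np.random.default_rng(seed)
    edges = {
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    }
    return graph_from_edges(n, edges)


@pytest.fixture
def path4():
    return graph_from_edges(4, {(0, 1), (1, 2), (2, 3)})


@pytest.fixture
def k4():
    return graph_from_edges(4, {(i, j) for i in range(4) for j in range(i + 1, 4)})


# Hand-written PDB fixture: 3 ALA in chain A, one GLY in chain B, one
# water, one hydrogen, and an altloc pair on residue 2's CA (A occ 0.60
# at x=10, B occ 0.40 at x=99).
TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  H   ALA A   1       1.500   1.000   0.000  1.00  0.00           H
ATOM      4  N   ALA A   2       9.000   0.000   0.000  1.00  0.00           N
ATOM      5  CA AALA A   2      10.000   0.000   0.000  0.60  0.00           C
ATOM      6  CA BALA A   2      99.000   0.000   0.000  0.40  0.00           C
ATOM      7  N   ALA A   3      18.000   0.000   0.000  1.00  0.00           N
ATOM      8  CA  ALA A   3      19.000   0.000   0.000  1.00  0.00           C
ATOM      9  CA  GLY B   1       0.000   5.000   0.000  1.00  0.00           C
HETATM   10  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture
def toy_pdb_path(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p
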