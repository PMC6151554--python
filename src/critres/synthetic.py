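"""Synthetic fixtures with planted, machine-readable ground truth.

Each generator is a pure function of its seed and emits alongside its
output the quantities downstream modules should reproduce, so every
pipeline stage is testable without external downloads:

- toy chain structures with analytically known contact graphs;
- alignments with known per-column substitution frequencies;
- mutagenesis tables engineered to hit target criticality indices;
- feature tables with class-conditional mean shifts planted in a known
  subset of descriptors (defaults: ~20% critical instances, shift 1.5
  within-class SDs per informative descriptor — strong enough that the
  planted set separates the classes, weak enough that no single
  descriptor does).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aa_factors import AMINO_ACIDS
from .criticality import SubstitutionRanking, ci_from_ranks
from .features import FeatureTable
from .structure_io import Atom, ChainStructure, Residue, write_pdb

GEOMETRIES = ("lattice", "spiral", "coil")


def make_structure(
    n_residues: int,
    geometry: str = "spiral",
    spacing: float = 3.8,
    seed: int = 0,
) -> tuple[str, ChainStructure]:
    """A CA-only toy chain and its PDB text.

    ``lattice``: collinear residues *spacing* apart (contact graph at a
    5 A cutoff is the path graph).  ``spiral``: helix-like winding with
    near-sequence contacts.  ``coil``: self-avoiding random walk.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if geometry not in GEOMETRIES:
        raise ValueError(f"geometry must be one of {GEOMETRIES}")
    rng = np.random.default_rng(seed)

    coords = []
    if geometry == "lattice":
        coords = [(i * spacing, 0.0, 0.0) for i in range(n_residues)]
    elif geometry == "spiral":
        radius, twist, rise = 2.3, math.radians(100.0), 1.5
        coords = [
            (radius * math.cos(i * twist), radius * math.sin(i * twist), i * rise)
            for i in range(n_residues)
        ]
    else:  # coil
        pts = [np.zeros(3)]
        while len(pts) < n_residues:
            for _ in range(1000):
                v = rng.normal(size=3)
                cand = pts[-1] + spacing * v / np.linalg.norm(v)
                if all(np.linalg.norm(cand - p) >= spacing * 0.95 for p in pts[:-1]):
                    pts.append(cand)
                    break
            else:
                raise RuntimeError("random coil could not be extended")
        coords = [tuple(float(c) for c in p) for p in pts]

    residues = []
    for i, (x, y, z) in enumerate(coords):
        aa = AMINO_ACIDS[int(rng.integers(0, 20))]
        residues.append(
            Residue(
                chain_id="A", seq_index=i, pdb_resseq=i + 1, icode=" ",
                aa=aa, atoms=[Atom("CA", round(x, 3), round(y, 3), round(z, 3), "C")],
            )
        )
    chain = ChainStructure(pdb_id="SYN", chain_id="A", residues=residues)
    return write_pdb(chain), chain


def make_msa(
    reference: str,
    n_rows: int = 20,
    substitution_prob: float = 0.3,
    seed: int = 0,
) -> tuple[str, np.ndarray]:
    """FASTA alignment of homologs mutated i.i.d. from *reference*.

    Returns the alignment text and the realized per-column substitution
    frequency S (ground truth for the conservation module).
    """
    if n_rows < 2:
        raise ValueError("need at least 2 rows (reference + 1 homolog)")
    rng = np.random.default_rng(seed)
    ncol = len(reference)
    rows = [list(reference)]
    differing = np.zeros(ncol, dtype=int)
    for _ in range(n_rows - 1):
        row = []
        for c, ref in enumerate(reference):
            if rng.random() < substitution_prob:
                alt = ref
                while alt == ref:
                    alt = AMINO_ACIDS[int(rng.integers(0, 20))]
                row.append(alt)
                differing[c] += 1
            else:
                row.append(ref)
        rows.append(row)
    s_true = differing / (n_rows - 1)
    fasta = []
    for i, row in enumerate(rows):
        name = "reference" if i == 0 else f"homolog_{i}"
        fasta.append(f">{name}\n{''.join(row)}")
    return "\n".join(fasta) + "\n", s_true


def make_mutagenesis(
    ranking: SubstitutionRanking,
    targets: dict[int, float],
    seed: int = 0,
    tolerance: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mutagenesis records engineered so each position's CI hits its target.

    For every position the generator picks a wild-type residue and a set
    of 1-3 mutant-phenotype substitutions whose criticality index lies
    within *tolerance* of the requested target, and reports the exact
    expected CI it computed.
    """
    rng = np.random.default_rng(seed)
    by_wt = {
        wt: sorted(
            ((r, t) for (f, t), r in ranking.rank_of.items() if f == wt)
        )
        for wt in AMINO_ACIDS
    }
    records, expected = [], []
    for pos, target in targets.items():
        if not 0.0 < target <= 1.0:
            raise ValueError(f"target CI for position {pos} must lie in (0, 1]")
        best = None  # (err, wt, [(rank, mut), ...], ci)
        wts = list(AMINO_ACIDS)
        rng.shuffle(wts)
        for wt in wts:
            options = by_wt[wt]
            for m in (1, 2, 3):
                for combo in itertools.combinations(options, m):
                    ci = ci_from_ranks([r for r, _ in combo])
                    err = abs(ci - target)
                    if best is None or err < best[0]:
                        best = (err, wt, list(combo), ci)
                if best[0] == 0.0:
                    break
            if best[0] == 0.0:
                break
        err, wt, combo, ci = best
        if err > tolerance:
            raise RuntimeError(
                f"no rank multiset within {tolerance} of target {target}"
            )
        for rank, mut in combo:
            records.append(
                {"position": pos, "wt": wt, "mut": mut, "phenotype": "mutant"}
            )
        expected.append({"position": pos, "m": len(combo), "expected_ci": ci})
    return pd.DataFrame(records), pd.DataFrame(expected)


@dataclass
class FeatureTableTruth:
    informative: list[str]
    noise: list[str]
    twins: dict[str, str]


def make_feature_table(
    n_instances: int = 300,
    n_informative: int = 5,
    n_noise: int = 95,
    class_balance: float = 0.2,
    effect_size: float = 1.5,
    n_twins: int = 0,
    n_constant: int = 0,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTableTruth]:
    """Feature table with a planted informative subset.

    Informative descriptors are N(0,1) shifted by *effect_size* for the
    critical class; noise descriptors are class-independent N(0,1).
    Optional monotone-transformed twins of the first informative columns
    (for the redundancy filter) and constant columns (for the useless
    filter) can be planted; twins and constants are appended after the
    columns they duplicate.
    """
    if n_instances < 20:
        raise ValueError("need at least 20 instances")
    if n_twins > n_informative:
        raise ValueError("cannot plant more twins than informative descriptors")
    rng = np.random.default_rng(seed)
    n_pos = max(1, round(n_instances * class_balance))
    y = np.array(["critical"] * n_pos + ["non-critical"] * (n_instances - n_pos))
    rng.shuffle(y)
    is_pos = (y == "critical").astype(float)

    cols = {}
    inf_names = [f"inf_{i}" for i in range(n_informative)]
    noise_names = [f"noise_{i}" for i in range(n_noise)]
    for name in inf_names:
        cols[name] = rng.normal(size=n_instances) + effect_size * is_pos
    for name in noise_names:
        cols[name] = rng.normal(size=n_instances)
    twins = {}
    for i in range(n_twins):
        src = inf_names[i]
        name = f"twin_of_{src}"
        cols[name] = np.exp(cols[src] / 2.0)  # strictly monotone transform
        twins[name] = src
    for i in range(n_constant):
        cols[f"const_{i}"] = np.full(n_instances, float(i))

    X = pd.DataFrame(cols)
    ids = pd.DataFrame(
        {"protein": ["SYN"] * n_instances, "residue": np.arange(n_instances)}
    )
    table = FeatureTable(X, pd.Series(y, name="class"), ids, "nominal")
    return table, FeatureTableTruth(inf_names, noise_names, twins)
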