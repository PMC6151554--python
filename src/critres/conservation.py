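"""Correlated-mutation index from a multiple sequence alignment.

For every column aligned to a chain residue, S is the normalized
substitution frequency: the fraction of non-gap homolog rows whose residue
differs from the reference row.  The correlated-mutation index of residue
j is then the sum of S over j's structural contacts:

    CM_j = sum_{i in contacts(j)} S_i

so 0 <= CM_j <= degree(j).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

from .contact_graph import ResidueContactGraph

log = logging.getLogger(__name__)

GAP_CHARS = {"-", ".", "~"}


@dataclass
class AlignmentColumnStats:
    column_index: int
    n_sequences: int
    n_non_gap: int
    n_differing: int
    S: float


def read_msa(path, fmt: str | None = None):
    """Read a FASTA or Stockholm alignment (format inferred from suffix)."""
    path = str(path)
    if fmt is None:
        fmt = "stockholm" if path.endswith((".sto", ".stk", ".stockholm")) else "fasta"
    return AlignIO.read(path, fmt)


def find_reference_row(msa, chain_sequence: str | None = None,
                       reference_id: str | None = None,
                       max_mismatch: float = 0.05) -> int:
    """Locate the alignment row representing the structure's chain.

    Either by record identifier, or by the row whose ungapped sequence best
    matches the chain sequence.  A mismatch fraction above *max_mismatch*
    aborts: a silently misaligned reference would corrupt every CM value.
    """
    if reference_id is not None:
        for i, rec in enumerate(msa):
            if rec.id == reference_id:
                return i
        raise KeyError(f"reference id {reference_id!r} not in alignment")
    if chain_sequence is None:
        raise ValueError("need chain_sequence or reference_id")

    best_row, best_frac = None, 1.0
    for i, rec in enumerate(msa):
        ungapped = "".join(c for c in str(rec.seq).upper() if c not in GAP_CHARS)
        if len(ungapped) != len(chain_sequence):
            continue
        mism = sum(a != b for a, b in zip(ungapped, chain_sequence))
        frac = mism / len(chain_sequence)
        if frac < best_frac:
            best_row, best_frac = i, frac
    if best_row is None or best_frac > max_mismatch:
        raise ValueError(
            "no alignment row matches the chain sequence within "
            f"{max_mismatch:.0%} mismatches (best {best_frac:.0%})"
        )
    return best_row


def column_substitution_frequency(msa, reference_row: int, column: int) -> float:
    """Fraction of non-gap homologs differing from the reference at *column*."""
    ref = str(msa[reference_row].seq)[column].upper()
    if ref in GAP_CHARS:
        raise ValueError(f"unaligned reference position: column {column} is a gap")
    non_gap = differing = 0
    for row, rec in enumerate(msa):
        if row == reference_row:
            continue
        c = str(rec.seq)[column].upper()
        if c in GAP_CHARS:
            continue
        non_gap += 1
        if c != ref:
            differing += 1
    if non_gap == 0:
        log.warning("column %d has no non-gap homolog rows; S = 0", column)
        return 0.0
    return differing / non_gap


def substitution_profile(msa, reference_row: int) -> list[AlignmentColumnStats]:
    """Per-residue column statistics for the reference's non-gap columns.

    The k-th entry corresponds to the reference's k-th ungapped position,
    i.e. to chain residue seq_index k.
    """
    out = []
    refseq = str(msa[reference_row].seq).upper()
    n_rows = len(msa)
    for col, ref in enumerate(refseq):
        if ref in GAP_CHARS:
            continue
        non_gap = differing = 0
        for row, rec in enumerate(msa):
            if row == reference_row:
                continue
            c = str(rec.seq)[col].upper()
            if c in GAP_CHARS:
                continue
            non_gap += 1
            if c != ref:
                differing += 1
        s = differing / non_gap if non_gap else 0.0
        out.append(
            AlignmentColumnStats(
                column_index=col, n_sequences=n_rows,
                n_non_gap=non_gap, n_differing=differing, S=s,
            )
        )
    return out


def correlated_mutation_index(
    g: ResidueContactGraph, s_values
) -> np.ndarray:
    """CM_j = sum of S over j's contacting residues.

    *s_values* is indexed by residue seq_index; NaN entries mark residues
    without an aligned column and contribute 0 (logged).
    """
    s = np.asarray(s_values, dtype=float)
    if len(s) != g.n_nodes:
        raise ValueError(
            f"S vector length {len(s)} does not match graph size {g.n_nodes}"
        )
    if np.isnan(s).any():
        log.warning("%d residues unaligned; they contribute S=0", int(np.isnan(s).sum()))
        s = np.nan_to_num(s, nan=0.0)
    cm = np.zeros(g.n_nodes)
    for j in range(g.n_nodes):
        cm[j] = sum(s[i] for i in g.neighbors(j))
    return cm


def conservation_table(msa, reference_row: int, g: ResidueContactGraph) -> pd.DataFrame:
    """Per-residue S and CM as a DataFrame keyed by seq_index."""
    stats = substitution_profile(msa, reference_row)
    if len(stats) != g.n_nodes:
        raise ValueError(
            f"alignment covers {len(stats)} residues, graph has {g.n_nodes}"
        )
    s = np.array([st.S for st in stats])
    cm = correlated_mutation_index(g, s)
    return pd.DataFrame({"seq_index": np.arange(g.n_nodes), "S": s, "CM": cm})
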