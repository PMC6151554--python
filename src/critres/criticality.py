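"""Criticality index from site-directed mutagenesis data.

Every one of the 380 ordered amino-acid substitutions (400 ordered pairs
minus the 20 identities) is scored by the Euclidean distance between the
two residues' five physicochemical factor vectors and ranked ascending, so
rank 380 is the most dissimilar substitution.

For a position with m reported mutations, all with mutant phenotype,

    CI = sum(R_i) / sum of the m largest rank values,

which lies in (0, 1] and equals 1 exactly when the m reported mutations
are the m most dissimilar substitutions possible.  When a position has
both wild-type-phenotype and mutant-phenotype reports,

    CI = 1/2 * [(1 - sum(RW_i)/D_w) + sum(RM_i)/D_m]

with D_w, D_m the corresponding top-m_w / top-m_m rank sums: dissimilar
tolerated mutations argue against criticality, dissimilar deleterious
ones for it.  A position with only wild-type-phenotype reports is scored
by the tolerance term alone, 1 - sum(RW_i)/D_w.

Residues are labeled critical when CI > 0.5 (strictly).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aa_factors import AMINO_ACIDS, ATCHLEY_FACTORS, validate_factor_table

log = logging.getLogger(__name__)

N_SUBSTITUTIONS = 380
PHENOTYPES = ("wild-type", "mutant")
CI_THRESHOLD = 0.5


@dataclass
class SubstitutionRanking:
    """All 380 ordered substitutions with distances and ranks 1..380."""

    entries: list[tuple[str, str, float, int]]  # (from_aa, to_aa, distance, rank)

    def __post_init__(self):
        if len(self.entries) != N_SUBSTITUTIONS:
            raise ValueError(f"expected {N_SUBSTITUTIONS} substitutions")
        self.rank_of = {(f, t): r for f, t, _, r in self.entries}
        self.distance_of = {(f, t): d for f, t, d, _ in self.entries}

    def rank(self, from_aa: str, to_aa: str) -> int:
        key = (from_aa.upper(), to_aa.upper())
        if key not in self.rank_of:
            raise KeyError(f"unknown substitution {key[0]}->{key[1]}")
        return self.rank_of[key]

    def ranks_from(self, from_aa: str) -> list[int]:
        return sorted(r for (f, _), r in self.rank_of.items() if f == from_aa)


def build_substitution_ranking(factors: dict | None = None) -> SubstitutionRanking:
    """Rank all ordered substitutions by 5-factor Euclidean distance.

    Ties are broken lexicographically by (from_aa, to_aa); ranks are then
    assigned 1..380 without gaps, rank 380 = most dissimilar.
    """
    factors = ATCHLEY_FACTORS if factors is None else factors
    validate_factor_table(factors)
    scored = []
    for f, t in itertools.permutations(AMINO_ACIDS, 2):
        d = math.dist(factors[f], factors[t])
        scored.append((d, f, t))
    scored.sort(key=lambda x: (x[0], x[1], x[2]))
    entries = [(f, t, d, rank) for rank, (d, f, t) in enumerate(scored, start=1)]
    return SubstitutionRanking(entries)


def top_rank_sum(m: int, strict_paper: bool = False) -> int:
    """Denominator of the criticality index for m reported mutations.

    Default: sum of the m largest ranks, 381-m .. 380.  ``strict_paper``
    uses the literal bounds 380-m .. 380 (m+1 terms), under which CI = 1
    is unattainable.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    lo = N_SUBSTITUTIONS - m if strict_paper else N_SUBSTITUTIONS - m + 1
    return sum(range(lo, N_SUBSTITUTIONS + 1))


# --- mutagenesis tables -----------------------------------------------------

_PHENOTYPE_ALIASES = {
    "wild-type": "wild-type", "wild_type": "wild-type", "wildtype": "wild-type",
    "wt": "wild-type", "mutant": "mutant", "mut": "mutant",
}

MUTAGENESIS_COLUMNS = ["position", "wt", "mut", "phenotype"]


def validate_mutagenesis(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate a mutagenesis table.

    Enforces the binary phenotype vocabulary, drops exact duplicates, and
    splits conflicting duplicate reports of the same substitution into one
    wild-type and one mutant record (routing the position to the mixed
    formula).
    """
    missing = [c for c in MUTAGENESIS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutagenesis table missing columns {missing}")
    df = df.loc[:, MUTAGENESIS_COLUMNS].copy()
    df["wt"] = df["wt"].str.upper().str.strip()
    df["mut"] = df["mut"].str.upper().str.strip()
    pheno = df["phenotype"].str.lower().str.strip().map(_PHENOTYPE_ALIASES)
    if pheno.isna().any():
        bad = sorted(df.loc[pheno.isna(), "phenotype"].unique())
        raise ValueError(
            f"unsupported phenotype values {bad}; expected {list(PHENOTYPES)}"
        )
    df["phenotype"] = pheno
    for col in ("wt", "mut"):
        bad = sorted(set(df[col]) - set(AMINO_ACIDS))
        if bad:
            raise ValueError(f"invalid amino-acid codes in {col!r}: {bad}")
    if (df["wt"] == df["mut"]).any():
        raise ValueError("records with wt == mut are not mutations")
    df = df.drop_duplicates()
    wt_per_pos = df.groupby("position")["wt"].nunique()
    if (wt_per_pos > 1).any():
        bad = wt_per_pos[wt_per_pos > 1].index.tolist()
        raise ValueError(f"conflicting wild-type residues at positions {bad}")
    return df.reset_index(drop=True)


def read_mutagenesis(path) -> pd.DataFrame:
    """Read a CSV/TSV mutagenesis table with header position,wt,mut,phenotype."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"position": int})
    return validate_mutagenesis(df)


# --- the index --------------------------------------------------------------

def _position_ranks(ranking: SubstitutionRanking, df: pd.DataFrame, position):
    recs = df[df["position"] == position]
    if recs.empty:
        raise KeyError(f"no mutagenesis data for position {position}")
    rw = [ranking.rank(r.wt, r.mut) for r in recs.itertuples() if r.phenotype == "wild-type"]
    rm = [ranking.rank(r.wt, r.mut) for r in recs.itertuples() if r.phenotype == "mutant"]
    return rw, rm


def criticality_index(
    ranking: SubstitutionRanking,
    muts: pd.DataFrame,
    position,
    strict_paper: bool = False,
) -> float:
    """CI for one position, dispatching on the phenotypes reported there."""
    rw, rm = _position_ranks(ranking, muts, position)
    if rw and rm:
        return 0.5 * (
            (1.0 - sum(rw) / top_rank_sum(len(rw), strict_paper))
            + sum(rm) / top_rank_sum(len(rm), strict_paper)
        )
    if rm:
        return sum(rm) / top_rank_sum(len(rm), strict_paper)
    # only tolerated substitutions reported
    return 1.0 - sum(rw) / top_rank_sum(len(rw), strict_paper)


def ci_from_ranks(ranks, strict_paper: bool = False) -> float:
    """CI of a set of mutant-phenotype ranks (no table needed)."""
    ranks = list(ranks)
    return sum(ranks) / top_rank_sum(len(ranks), strict_paper)


def ci_mixed_from_ranks(ranks_wt, ranks_mut, strict_paper: bool = False) -> float:
    """Mixed-phenotype CI from explicit rank sets."""
    ranks_wt, ranks_mut = list(ranks_wt), list(ranks_mut)
    return 0.5 * (
        (1.0 - sum(ranks_wt) / top_rank_sum(len(ranks_wt), strict_paper))
        + sum(ranks_mut) / top_rank_sum(len(ranks_mut), strict_paper)
    )


def binarize(ci_values) -> np.ndarray:
    """Critical iff CI > 0.5 (CI = 0.5 exactly is non-critical)."""
    ci = np.asarray(ci_values, dtype=float)
    if ((ci < 0) | (ci > 1)).any():
        raise ValueError("CI values must lie in [0, 1]")
    return np.where(ci > CI_THRESHOLD, "critical", "non-critical")


def annotate_criticality(
    ranking: SubstitutionRanking,
    muts: pd.DataFrame,
    strict_paper: bool = False,
) -> pd.DataFrame:
    """Per-position m, CI and binary label for every covered position."""
    muts = validate_mutagenesis(muts)
    rows = []
    for pos in sorted(muts["position"].unique()):
        ci = criticality_index(ranking, muts, pos, strict_paper)
        m = int((muts["position"] == pos).sum())
        rows.append({"position": pos, "m": m, "ci": ci})
    out = pd.DataFrame(rows)
    out["label"] = binarize(out["ci"].clip(lower=0.0))
    return out
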