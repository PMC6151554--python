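"""PDB chain ingestion.

Reads one chain of a PDB file into an ordered list of residues with
heavy-atom coordinates.  Only the 20 standard amino acids (plus a small
table of modified residues mapped to their parent, e.g. MSE -> M) are
kept; hydrogens, waters and other heteroatoms are dropped.  Alternate
locations are resolved to the highest-occupancy conformer.

Residues carry two numbering schemes: ``seq_index`` (0-based, contiguous,
used by every downstream graph computation) and the original PDB
``pdb_resseq``/insertion code, preserved for reporting.
"""

from __future__ import annotations

import gzip
import json
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

from Bio.PDB import PDBParser

log = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Modified residues mapped to the parent amino acid (selenomethionine etc.).
NONSTANDARD_PARENT = {
    "MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y",
    "CSO": "C", "HYP": "P", "PCA": "E",
}


class Atom(NamedTuple):
    name: str
    x: float
    y: float
    z: float
    element: str


@dataclass
class Residue:
    chain_id: str
    seq_index: int
    pdb_resseq: int
    icode: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def pdb_label(self) -> str:
        return f"{self.pdb_resseq}{self.icode.strip()}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self):
        import numpy as np

        return np.array([(a.x, a.y, a.z) for a in self.atoms], dtype=float)


@dataclass
class ChainStructure:
    pdb_id: str
    chain_id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def to_json(self) -> str:
        return json.dumps(
            {
                "pdb_id": self.pdb_id,
                "chain_id": self.chain_id,
                "residues": [
                    {
                        "seq_index": r.seq_index,
                        "pdb_resseq": r.pdb_resseq,
                        "icode": r.icode,
                        "aa": r.aa,
                        "atoms": [list(a) for a in r.atoms],
                    }
                    for r in self.residues
                ],
            }
        )


def _best_altloc(atom):
    """Highest-occupancy conformer of a (possibly disordered) Biopython atom."""
    if not atom.is_disordered():
        return atom
    children = sorted(
        atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def read_chain(path, chain_id: str = "A", model: int = 0) -> ChainStructure:
    """Read one chain of a PDB file (optionally gzip-compressed).

    Parameters
    ----------
    path : str or Path
        PDB file; ``.gz`` suffix is transparently decompressed.
    chain_id : str
        Chain identifier to extract.
    model : int
        Index (0-based) into the file's models; crystal structures have one.

    Returns
    -------
    ChainStructure
        Standard amino-acid residues only, hydrogens excluded, altlocs
        resolved to the highest-occupancy conformer.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    parser = PDBParser(QUIET=True)
    with opener(path, "rt") as fh:
        structure = parser.get_structure("pdb", fh)

    models = list(structure)
    if model >= len(models):
        raise ValueError(f"model {model} not present ({len(models)} model(s) in file)")
    mdl = models[model]

    chains = {c.id: c for c in mdl}
    if chain_id not in chains:
        raise KeyError(
            f"chain {chain_id!r} not found; available: {sorted(chains)}"
        )

    residues: list[Residue] = []
    for res in chains[chain_id]:
        hetflag, resseq, icode = res.id
        resname = res.get_resname().strip()
        if resname in THREE_TO_ONE:
            aa = THREE_TO_ONE[resname]
        elif resname in NONSTANDARD_PARENT:
            aa = NONSTANDARD_PARENT[resname]
            log.warning("mapping modified residue %s %s to %s", resname, resseq, aa)
        else:
            if hetflag.strip() and resname != "HOH":
                log.debug("skipping heteroatom group %s %s", resname, resseq)
            continue

        atoms: list[Atom] = []
        for at in res:
            best = _best_altloc(at)
            element = (best.element or "").strip().upper()
            if element in ("H", "D"):
                continue
            x, y, z = (float(v) for v in best.get_coord())
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ValueError(
                    f"non-finite coordinate in residue {resname} {resseq}"
                )
            atoms.append(Atom(best.get_name().strip(), x, y, z, element))
        if not atoms:
            continue
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_index=len(residues),
                pdb_resseq=int(resseq),
                icode=icode,
                aa=aa,
                atoms=atoms,
            )
        )

    if not residues:
        raise ValueError(f"empty chain: no standard residues in chain {chain_id!r}")
    return ChainStructure(pdb_id="", chain_id=chain_id, residues=residues)


def write_pdb(chain: ChainStructure) -> str:
    """Serialize a ChainStructure back to PDB ATOM records."""
    lines = []
    serial = 1
    for res in chain.residues:
        resname = ONE_TO_THREE.get(res.aa, "UNK")
        for a in res.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {res.chain_id}"
                f"{res.pdb_resseq:4d}{res.icode:1s}   "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
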