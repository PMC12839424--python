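"""Single-chain Cα-trace structure models.

Every perturbation metric downstream is defined on Cα atoms, so structures
are reduced at parse time to an ordered Cα trace: one residue record per
residue that has an alpha carbon, renumbered sequentially from 1 (author
numbering, including insertion codes, is kept as metadata).  Side-chain and
backbone atoms other than Cα are parsed and dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "StructureModel",
    "ChainNotFoundError",
    "EmptyModelError",
    "read_structure",
    "write_structure",
    "sequence_of",
]

log = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"


class ChainNotFoundError(KeyError):
    """Requested chain absent from the file."""


class EmptyModelError(ValueError):
    """No Cα atoms found, or fewer than two residues."""


@dataclass(frozen=True)
class Residue:
    """One residue of a Cα trace: sequential index, one-letter code, Cα in Å."""

    index: int
    aa: str
    ca: tuple[float, float, float]
    author_num: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.ca)):
            raise ValueError(f"non-finite Cα coordinate for residue {self.index}")


@dataclass(frozen=True)
class StructureModel:
    """Ordered Cα-bearing residues of one chain."""

    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise EmptyModelError("a structure model needs at least 2 residues")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_array(self) -> np.ndarray:
        """(n, 3) float array of Cα coordinates in residue order."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def by_index(self) -> dict[int, Residue]:
        return {r.index: r for r in self.residues}


def _pick_ca(res: gemmi.Residue) -> gemmi.Atom | None:
    """Resolve altlocs: highest occupancy, then first seen."""
    cas = [a for a in res if a.name == "CA" and a.element.name != "Ca"]
    if not cas:
        return None
    return max(cas, key=lambda a: a.occ)  # max is stable: first wins ties


def read_structure(path: str, chain: str | None = None) -> StructureModel:
    """Read a Cα trace for one chain from a PDB (or mmCIF) file.

    ``chain`` may be omitted only for single-chain files; multi-chain files
    require an explicit chain id.  Residues lacking a Cα are skipped with a
    logged warning.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        if len(names) != 1:
            raise ChainNotFoundError(
                f"{path} has chains {names}; specify one explicitly"
            )
        chain = names[0]
    if chain not in names:
        raise ChainNotFoundError(f"chain {chain!r} not in {path} (has {names})")
    residues: list[Residue] = []
    for res in model[chain]:
        ca = _pick_ca(res)
        if ca is None:
            if res.het_flag == "A":
                log.warning(
                    "%s chain %s residue %s%s lacks a CA atom; skipped",
                    path, chain, res.seqid.num, res.seqid.icode.strip(),
                )
            continue
        residues.append(
            Residue(
                index=len(residues) + 1,
                aa=THREE_TO_ONE.get(res.name, "X"),
                ca=(ca.pos.x, ca.pos.y, ca.pos.z),
                author_num=f"{res.seqid.num}{res.seqid.icode.strip()}",
            )
        )
    if not residues:
        raise EmptyModelError(f"{path} chain {chain}: no Cα atoms")
    return StructureModel(chain_id=chain, residues=tuple(residues))


def write_structure(model: StructureModel, path: str) -> None:
    """Write the Cα trace as fixed-column PDB ATOM records.

    Occupancy 1.00, B-factor 0.00.  Coordinates beyond the 8.3 PDB field
    (|x| > 9999.999) cannot be represented and raise a ValueError.
    """
    for r in model.residues:
        if any(abs(c) > 9999.999 for c in r.ca):
            raise ValueError(
                f"residue {r.index} coordinate out of PDB field range: {r.ca}"
            )
    st = gemmi.Structure()
    st.name = "catrace"
    gm = gemmi.Model("1")
    ch = gemmi.Chain(model.chain_id)
    for r in model.residues:
        res = gemmi.Residue()
        res.name = ONE_TO_THREE.get(r.aa, "UNK")
        res.seqid = gemmi.SeqId(r.index, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*r.ca)
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
        ch.add_residue(res)
    gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def sequence_of(model: StructureModel) -> str:
    """One-letter amino-acid string in residue order."""
    return "".join(r.aa for r in model.residues)
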