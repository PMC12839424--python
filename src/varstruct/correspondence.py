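"""Residue correspondence between wild-type and mutant chains.

Superposition and neighbor-distance metrics need to know which mutant residue
"is" which wild-type residue once substitutions and in-frame indels have
shifted the numbering.  The exact route derives the map from the known
variant effects; a sequence-alignment fallback (global Needleman–Wunsch with
affine gaps, BLOSUM62) covers the case where no variant list is available.
Frameshifted proteins have no residue-wise correspondence and are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .variant_effects import ProteinEffect

__all__ = [
    "CorrespondenceMap",
    "UnsupportedCorrespondenceError",
    "map_from_effects",
    "map_by_alignment",
]


class UnsupportedCorrespondenceError(ValueError):
    """Raised for frameshifts: downstream residues are not comparable."""


@dataclass(frozen=True)
class CorrespondenceMap:
    """Paired WT↔mutant residue indices plus unmatched residues.

    ``pairs`` is strictly increasing in both coordinates (no crossings);
    ``wt_only`` are residues deleted in the mutant, ``mut_only`` residues
    inserted in it.
    """

    pairs: tuple[tuple[int, int], ...]
    wt_only: tuple[int, ...] = ()
    mut_only: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for (w1, m1), (w2, m2) in zip(self.pairs, self.pairs[1:]):
            if w2 <= w1 or m2 <= m1:
                raise ValueError("correspondence pairs must not cross")
        wt_seen = [w for w, _ in self.pairs] + list(self.wt_only)
        mut_seen = [m for _, m in self.pairs] + list(self.mut_only)
        if len(set(wt_seen)) != len(wt_seen) or len(set(mut_seen)) != len(mut_seen):
            raise ValueError("residue index used twice in correspondence")

    @property
    def wt_to_mut(self) -> dict[int, int]:
        return {w: m for w, m in self.pairs}

    @property
    def mut_to_wt(self) -> dict[int, int]:
        return {m: w for w, m in self.pairs}

    @classmethod
    def identity(cls, n: int) -> "CorrespondenceMap":
        return cls(pairs=tuple((i, i) for i in range(1, n + 1)))


def map_from_effects(
    effects: Sequence[ProteinEffect], wt_len: int, mut_len: int
) -> CorrespondenceMap:
    """Build the WT↔mutant map from classified variant effects.

    Substitutions pair i↔i; an in-frame insertion of k residues after WT
    residue r contributes k ``mut_only`` indices and shifts every downstream
    pair by +k; deletions are symmetric.  Frameshifts are rejected.
    """
    deleted: set[int] = set()
    ins_after: dict[int, int] = {}
    for e in effects:
        if e.effect_class == "frameshift":
            raise UnsupportedCorrespondenceError(
                f"frameshift effect {e.notation or e.residue_index} has no "
                "residue-wise correspondence"
            )
        if e.effect_class not in ("inframe_insertion", "inframe_deletion"):
            continue  # substitution-level effects keep i↔i
        n_wt, n_mut = len(e.wt_aa), len(e.mut_aa)
        matched = min(n_wt, n_mut)  # delins: overlap stays paired i↔shifted i
        if n_mut > n_wt:
            anchor = e.residue_index - 1 + matched
            ins_after[anchor] = ins_after.get(anchor, 0) + (n_mut - n_wt)
        else:
            deleted.update(
                range(e.residue_index + matched, e.residue_index + n_wt)
            )
    pairs: list[tuple[int, int]] = []
    wt_only: list[int] = []
    mut_only: list[int] = []
    m = 0
    for k in range(ins_after.get(0, 0)):
        m += 1
        mut_only.append(m)
    for w in range(1, wt_len + 1):
        if w in deleted:
            wt_only.append(w)
        else:
            m += 1
            pairs.append((w, m))
        for _ in range(ins_after.get(w, 0)):
            m += 1
            mut_only.append(m)
    if m != mut_len:
        raise ValueError(
            f"effects imply mutant length {m}, model has {mut_len}"
        )
    return CorrespondenceMap(tuple(pairs), tuple(wt_only), tuple(mut_only))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def map_by_alignment(wt_seq: str, mut_seq: str) -> CorrespondenceMap:
    """Pair residues by global sequence alignment (BLOSUM62, gap 10/1).

    Aligned non-gap columns become pairs; gapped positions go to ``wt_only``
    / ``mut_only``.  The first optimal traceback is used, which is
    deterministic for a fixed scoring scheme.
    """
    if not wt_seq or not mut_seq:
        raise ValueError("sequences must be non-empty")
    aln = _make_aligner().align(wt_seq, mut_seq)[0]
    pairs: list[tuple[int, int]] = []
    for (ws, we), (ms, _) in zip(*aln.aligned):
        pairs.extend((int(ws) + 1 + k, int(ms) + 1 + k) for k in range(we - ws))
    paired_wt = {w for w, _ in pairs}
    paired_mut = {m for _, m in pairs}
    return CorrespondenceMap(
        tuple(pairs),
        tuple(i for i in range(1, len(wt_seq) + 1) if i not in paired_wt),
        tuple(i for i in range(1, len(mut_seq) + 1) if i not in paired_mut),
    )
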