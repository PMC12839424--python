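"""Protein-level consequences of coding-sequence variants.

Variants are expressed in 1-based CDS nucleotide coordinates on the coding
strand.  A single-nucleotide substitution at position ``pos`` falls in codon
``ceil(pos/3)``; insertions are anchored *after* a position, so an insertion
after a multiple of 3 sits cleanly on a codon boundary.  Each variant is
classified independently against the wild-type frame (missense, synonymous,
stop gain/loss, in-frame indel, frameshift) and rendered in the conventional
WT-first compact notation, e.g. ``Q114E`` or ``H194_S195insY``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CodingSequence",
    "Variant",
    "ProteinEffect",
    "STANDARD_CODE",
    "ReferenceMismatchError",
    "VariantConflictError",
    "codon_index",
    "apply_variants",
    "translate",
    "classify_effects",
    "to_notation",
]


class ReferenceMismatchError(ValueError):
    """Variant ref allele does not match the CDS at its position."""


class VariantConflictError(ValueError):
    """Two variants touch overlapping CDS intervals."""


# Standard genetic code (translation table 1), typed out so that translation
# does not depend on any external lookup; '*' marks the three stop codons.
STANDARD_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """A coding sequence: DNA over {A,C,G,T}, positions counted 1-based."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 3:
            raise ValueError(f"CDS {self.id!r} shorter than one codon")
        bad = set(self.seq) - _DNA
        if bad:
            raise ValueError(
                f"CDS {self.id!r} contains non-ACGT characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Variant:
    """One CDS-coordinate edit.

    ``kind`` is one of SNP / INS / DEL.  ``pos`` is 1-based; for insertions it
    is the position *after which* ``alt`` is inserted.  ``ref`` is empty for
    insertions, ``alt`` empty for deletions.
    """

    kind: str
    pos: int
    ref: str = ""
    alt: str = ""
    id: str = ""

    def __post_init__(self) -> None:
        if self.kind == "SNP":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(f"malformed SNP {self!r}")
        elif self.kind == "INS":
            if self.ref or not self.alt:
                raise ValueError(f"malformed INS {self!r}")
        elif self.kind == "DEL":
            if self.alt or not self.ref:
                raise ValueError(f"malformed DEL {self!r}")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.pos}")

    @property
    def net_length(self) -> int:
        return len(self.alt) - len(self.ref)

    def interval(self) -> tuple[float, float]:
        """CDS interval touched; insertions occupy the inter-base point."""
        if self.kind == "INS":
            return (self.pos + 0.5, self.pos + 0.5)
        return (float(self.pos), float(self.pos + len(self.ref) - 1))


@dataclass(frozen=True)
class ProteinEffect:
    """Classified protein-level consequence of one variant.

    ``wt_aa`` / ``mut_aa`` hold one-letter residues, or peptides (possibly
    empty) for in-frame indels.  ``anchors`` carries the flanking WT residues
    of a pure insertion, needed for ``X_YinsZ`` notation.
    """

    effect_class: str
    residue_index: int
    wt_aa: str
    mut_aa: str
    variant_id: str = ""
    anchors: tuple[tuple[str, int], tuple[str, int]] | None = None
    notation: str = field(default="", compare=False)


def codon_index(pos: int) -> int:
    """Map a 1-based CDS nucleotide position to its 1-based codon index.

    Codon ``c`` spans nucleotides ``3c-2 .. 3c``, so this is ``ceil(pos/3)``:
    position 34 lies in codon 12, position 764 in codon 255.
    """
    if pos < 1:
        raise ValueError(f"CDS position must be >= 1, got {pos}")
    return math.ceil(pos / 3)


def _check_ref(cds: CodingSequence, v: Variant) -> None:
    if v.kind == "INS":
        if v.pos > len(cds):
            raise ReferenceMismatchError(
                f"insertion anchor {v.pos} beyond CDS {cds.id!r} length {len(cds)}"
            )
        return
    end = v.pos + len(v.ref) - 1
    if end > len(cds):
        raise ReferenceMismatchError(
            f"variant at {v.pos} extends past CDS {cds.id!r} end ({len(cds)})"
        )
    found = cds.seq[v.pos - 1 : end]
    if found != v.ref:
        raise ReferenceMismatchError(
            f"ref mismatch at CDS position {v.pos}: expected {v.ref!r}, "
            f"sequence has {found!r}"
        )


def apply_variants(cds: CodingSequence, variants: Sequence[Variant]) -> CodingSequence:
    """Apply non-overlapping CDS edits and return the edited sequence.

    Edits are applied in descending position order so upstream coordinates are
    unaffected by downstream length changes.
    """
    ivs = []
    for v in variants:
        _check_ref(cds, v)
        ivs.append((v.interval(), v))
    ivs.sort(key=lambda t: t[0])
    for ((s1, e1), a), ((s2, e2), b) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise VariantConflictError(
                f"overlapping variants at positions {a.pos} and {b.pos}"
            )
    seq = cds.seq
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        if v.kind == "SNP":
            seq = seq[: v.pos - 1] + v.alt + seq[v.pos :]
        elif v.kind == "DEL":
            seq = seq[: v.pos - 1] + seq[v.pos - 1 + len(v.ref) :]
        else:  # INS after pos
            seq = seq[: v.pos] + v.alt + seq[v.pos :]
    return CodingSequence(id=cds.id, seq=seq)


def translate(
    seq: str | CodingSequence,
    code: dict[str, str] = STANDARD_CODE,
    *,
    stop_at_terminator: bool = True,
) -> str:
    """Translate successive codons from position 1.

    By default translation stops at (and excludes) the first stop codon; with
    ``stop_at_terminator=False`` stops are kept as ``'*'`` (used internally to
    diff WT against mutant frames).  A trailing partial codon is ignored.
    """
    s = seq.seq if isinstance(seq, CodingSequence) else seq
    out: list[str] = []
    for i in range(0, len(s) - len(s) % 3, 3):
        aa = code[s[i : i + 3]]
        if aa == "*" and stop_at_terminator:
            break
        out.append(aa)
    return "".join(out)


def _diff_region(wt: str, mut: str) -> tuple[int, str, str]:
    """Locate the changed region between two translations.

    Returns (0-based start of the region after the longest common prefix,
    replaced WT peptide, replacement mutant peptide).  Anchoring at the
    longest common prefix makes placement deterministic for repeats.
    """
    p = 0
    while p < min(len(wt), len(mut)) and wt[p] == mut[p]:
        p += 1
    s = 0
    while (
        s < min(len(wt), len(mut)) - p
        and wt[len(wt) - 1 - s] == mut[len(mut) - 1 - s]
    ):
        s += 1
    return p, wt[p : len(wt) - s], mut[p : len(mut) - s]


def _classify_snp(cds: CodingSequence, v: Variant, code: dict[str, str]) -> ProteinEffect:
    c = codon_index(v.pos)
    wt_codon = cds.seq[3 * c - 3 : 3 * c]
    off = (v.pos - 1) % 3
    mut_codon = wt_codon[:off] + v.alt + wt_codon[off + 1 :]
    wt_aa, mut_aa = code[wt_codon], code[mut_codon]
    if wt_aa == mut_aa:
        cls = "synonymous"
    elif mut_aa == "*":
        cls = "stop_gained"
    elif wt_aa == "*":
        cls = "stop_lost"
    else:
        cls = "missense"
    return ProteinEffect(cls, c, wt_aa, mut_aa, variant_id=v.id)


def _classify_indel(cds: CodingSequence, v: Variant, code: dict[str, str]) -> ProteinEffect:
    wt_prot = translate(cds, code, stop_at_terminator=False)
    if v.net_length % 3 != 0:
        first = codon_index(v.pos + 1 if v.kind == "INS" else v.pos)
        first = min(first, len(wt_prot))
        return ProteinEffect(
            "frameshift", first, wt_prot[first - 1], "", variant_id=v.id
        )
    mut_prot = translate(apply_variants(cds, [v]), code, stop_at_terminator=False)
    p, wt_pep, mut_pep = _diff_region(wt_prot, mut_prot)
    if "*" in mut_pep and "*" not in wt_pep:
        return ProteinEffect(
            "stop_gained", p + 1, wt_pep, mut_pep, variant_id=v.id
        )
    cls = "inframe_insertion" if v.kind == "INS" else "inframe_deletion"
    anchors = None
    if cls == "inframe_insertion" and not wt_pep and 1 <= p < len(wt_prot):
        anchors = ((wt_prot[p - 1], p), (wt_prot[p], p + 1))
    return ProteinEffect(
        cls, p + 1, wt_pep, mut_pep, variant_id=v.id, anchors=anchors
    )


def classify_effects(
    cds: CodingSequence,
    variants: Iterable[Variant],
    code: dict[str, str] = STANDARD_CODE,
) -> list[ProteinEffect]:
    """Classify each variant independently against the wild-type frame.

    Returns one :class:`ProteinEffect` per input variant, in input order, with
    compact notation filled in.  For a combined haplotype translation apply
    all variants with :func:`apply_variants` and translate the result.
    """
    effects: list[ProteinEffect] = []
    for v in variants:
        _check_ref(cds, v)
        eff = (
            _classify_snp(cds, v, code)
            if v.kind == "SNP"
            else _classify_indel(cds, v, code)
        )
        effects.append(
            ProteinEffect(
                eff.effect_class,
                eff.residue_index,
                eff.wt_aa,
                eff.mut_aa,
                variant_id=eff.variant_id,
                anchors=eff.anchors,
                notation=to_notation(eff),
            )
        )
    return effects


def to_notation(effect: ProteinEffect) -> str:
    """Render the conventional WT-first compact notation.

    Missense ``A12S``; pure in-frame insertion ``H194_S195insY``; deletion
    ``K10del`` / ``K10_L12del``; frameshift ``G5fs``.
    """
    e, i = effect, effect.residue_index
    if e.effect_class in ("synonymous", "missense", "stop_gained", "stop_lost"):
        return f"{e.wt_aa}{i}{e.mut_aa}"
    if e.effect_class == "frameshift":
        return f"{e.wt_aa}{i}fs"
    if e.effect_class == "inframe_insertion" and not e.wt_aa:
        if e.anchors is not None:
            (la, li), (ra, ri) = e.anchors
            return f"{la}{li}_{ra}{ri}ins{e.mut_aa}"
        return f"{i}ins{e.mut_aa}"
    if e.effect_class == "inframe_deletion" and not e.mut_aa:
        if len(e.wt_aa) == 1:
            return f"{e.wt_aa}{i}del"
        return f"{e.wt_aa[0]}{i}_{e.wt_aa[-1]}{i + len(e.wt_aa) - 1}del"
    # indel that also substitutes flanking residues: delins form
    return f"{i}delins{e.mut_aa or '-'}"
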