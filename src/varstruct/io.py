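"""File formats: FASTA, variant TSV, effects TSV, minimal VCF, BED.

The variant TSV has columns ``id  kind  pos  ref  alt`` (header required,
``-`` for an empty ref/alt).  The VCF reader deliberately covers only the
CHROM/POS/ID/REF/ALT columns of plain or gzipped files — genotypes and INFO
semantics belong to callers, not to this summary pipeline.  BED input is
0-based half-open and converted to 1-based internally.
"""

from __future__ import annotations

import gzip
import logging
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .landscape import GenomicVariant
from .variant_effects import CodingSequence, ProteinEffect, Variant

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_variant_tsv",
    "write_variant_tsv",
    "write_effects_tsv",
    "write_correspondence_tsv",
    "read_vcf_minimal",
    "read_bed",
]

log = logging.getLogger(__name__)


def read_fasta(path: str) -> list[CodingSequence]:
    """Read CDS records; sequences are uppercased and alphabet-checked."""
    return [
        CodingSequence(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[CodingSequence], path: str) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def read_variant_tsv(path: str) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["id", "kind", "pos", "ref", "alt"]
    if list(df.columns[:5]) != required:
        raise ValueError(f"variant TSV must have header {required}")
    out = []
    for row in df.itertuples(index=False):
        ref = "" if row.ref in ("-", "", None) or pd.isna(row.ref) else row.ref
        alt = "" if row.alt in ("-", "", None) or pd.isna(row.alt) else row.alt
        out.append(Variant(kind=row.kind, pos=int(row.pos), ref=ref, alt=alt, id=row.id))
    return out


def write_variant_tsv(variants: Sequence[Variant], path: str) -> None:
    pd.DataFrame(
        [
            {"id": v.id, "kind": v.kind, "pos": v.pos,
             "ref": v.ref or "-", "alt": v.alt or "-"}
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


def write_effects_tsv(effects: Sequence[ProteinEffect], path: str) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": e.variant_id,
                "effect_class": e.effect_class,
                "residue_index": e.residue_index,
                "wt_aa": e.wt_aa or "-",
                "mut_aa": e.mut_aa or "-",
                "notation": e.notation,
            }
            for e in effects
        ],
        columns=["variant_id", "effect_class", "residue_index",
                 "wt_aa", "mut_aa", "notation"],
    ).to_csv(path, sep="\t", index=False)


def write_correspondence_tsv(cmap, path: str) -> None:
    rows = [{"wt_index": w, "mut_index": m} for w, m in cmap.pairs]
    rows += [{"wt_index": w, "mut_index": "-"} for w in cmap.wt_only]
    rows += [{"wt_index": "-", "mut_index": m} for m in cmap.mut_only]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf_minimal(path: str) -> list[GenomicVariant]:
    """Read CHROM/POS/REF/ALT from a plain or gzipped VCF-like table.

    Multi-allelic ALT fields are split into one record per allele; malformed
    lines are skipped with a logged count.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    out: list[GenomicVariant] = []
    skipped = 0
    with opener(str(path), "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                skipped += 1
                continue
            chrom, pos, _, ref, alts = fields[:5]
            try:
                for alt in alts.split(","):
                    if alt in (".", ""):
                        continue
                    out.append(GenomicVariant(chrom=chrom, pos=int(pos),
                                              ref=ref, alt=alt))
            except ValueError:
                skipped += 1
    if skipped:
        log.warning("%s: skipped %d malformed line(s)", path, skipped)
    return out


def read_bed(path: str) -> dict[str, list[int]]:
    """BED intervals → 1-based start positions per chromosome."""
    out: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            chrom, start = line.split("\t")[:2]
            out.setdefault(chrom, []).append(int(start) + 1)
    return out
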