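"""Deterministic synthetic fixtures with analytic oracles.

Two generators make every pipeline stage testable without any download:

* an ideal α-helix Cα trace (radius 2.3 Å, rise 1.5 Å/residue, twist
  100°/residue — the canonical helix parameters, giving the realistic
  ~3.8 Å consecutive-Cα spacing and non-trivial 8 Å neighborhoods), plus a
  controlled perturbation that rigidly displaces a chosen segment and
  optionally adds seeded Gaussian jitter;
* coding-sequence fixtures whose codons are consistent with a set of known
  variant calls at fixed positions.

``apply_perturbation`` also measures, by direct brute-force distance
computation on the pre/post coordinate arrays (sharing no code with the
metric modules), the expected local RMSD, ΔD and rejection-survivor set —
the independent oracle the pipeline is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Residue, StructureModel
from .variant_effects import CodingSequence, Variant

__all__ = [
    "PerturbationPlan",
    "ExpectedMetrics",
    "make_helix",
    "apply_perturbation",
    "cds_for_printed_effects",
]

HELIX_RADIUS = 2.3  # Å
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue


@dataclass(frozen=True)
class PerturbationPlan:
    """Rigid displacement of one residue segment, with optional jitter.

    ``segment`` is an inclusive 1-based index range; ``displacement`` a
    translation vector in Å applied to every Cα in the segment;
    ``jitter_sigma`` the per-coordinate Gaussian noise added to the segment.
    """

    segment: tuple[int, int]
    displacement: tuple[float, float, float]
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.segment
        if lo < 1 or hi < lo:
            raise ValueError(f"bad segment {self.segment}")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass(frozen=True)
class ExpectedMetrics:
    """Oracle values measured directly on pre/post coordinates.

    ``local_rmsd`` maps site index → expected window RMSD assuming the
    superposition is fitted on residues outside the displaced segment (for
    which the optimal transform is the identity when jitter leaves them
    untouched).  ``delta_d`` maps (site, neighbor) → expected signed distance
    change; ``neighbors`` the brute-force 8 Å neighbor scan on the original
    coordinates; ``retained`` the residues moved by at most the rejection
    cutoff.
    """

    local_rmsd: dict[int, float]
    delta_d: dict[tuple[int, int], float]
    neighbors: dict[int, tuple[int, ...]]
    retained: tuple[int, ...]


def make_helix(n: int, seed: int = 0, sequence: str | None = None) -> StructureModel:
    """Ideal α-helix Cα trace of ``n`` residues (poly-Ala by default).

    Deterministic for a given (n, seed); the helix itself does not depend on
    the seed, which is accepted for interface uniformity with the perturbed
    generators.
    """
    if n < 4:
        raise ValueError(f"helix needs at least 4 residues, got {n}")
    if sequence is not None and len(sequence) != n:
        raise ValueError("sequence length must equal n")
    theta = np.deg2rad(HELIX_TWIST) * np.arange(n)
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta),
         HELIX_RISE * np.arange(n)]
    )
    residues = tuple(
        Residue(
            index=i + 1,
            aa=sequence[i] if sequence else "A",
            ca=(float(coords[i, 0]), float(coords[i, 1]), float(coords[i, 2])),
        )
        for i in range(n)
    )
    return StructureModel(chain_id="A", residues=residues)


def apply_perturbation(
    model: StructureModel,
    plan: PerturbationPlan,
    sites: tuple[int, ...] = (),
    flank: int = 5,
    neighbor_cutoff: float = 8.0,
    reject_cutoff: float = 2.0,
) -> tuple[StructureModel, ExpectedMetrics]:
    """Displace a segment and return the mutant plus its analytic oracle.

    ``sites`` are WT residue indices (site = same index in the mutant: the
    perturbation changes no residue identities) for which expected local
    RMSD, neighbors and ΔD are measured brute-force on the raw coordinates.
    """
    lo, hi = plan.segment
    n = len(model)
    if hi > n:
        raise ValueError(f"segment {plan.segment} outside model of length {n}")
    pre = model.ca_array()
    post = pre.copy()
    rng = np.random.default_rng(plan.seed)
    seg = slice(lo - 1, hi)
    post[seg] += np.asarray(plan.displacement, dtype=float)
    if plan.jitter_sigma > 0:
        post[seg] += rng.normal(0.0, plan.jitter_sigma, size=post[seg].shape)
    mutant = StructureModel(
        chain_id=model.chain_id,
        residues=tuple(
            Residue(index=r.index, aa=r.aa,
                    ca=(float(post[i, 0]), float(post[i, 1]), float(post[i, 2])),
                    author_num=r.author_num)
            for i, r in enumerate(model.residues)
        ),
    )

    # --- oracle: plain loops over raw coordinates, no pipeline code ---
    exp_local: dict[int, float] = {}
    exp_dd: dict[tuple[int, int], float] = {}
    exp_neigh: dict[int, tuple[int, ...]] = {}
    for s in sites:
        w_lo, w_hi = max(1, s - flank), min(n, s + flank)
        sq = 0.0
        for i in range(w_lo, w_hi + 1):
            dx = post[i - 1] - pre[i - 1]
            sq += float(dx @ dx)
        exp_local[s] = float(np.sqrt(sq / (w_hi - w_lo + 1)))
        neigh = []
        for j in range(1, n + 1):
            if j == s:
                continue
            if float(np.linalg.norm(pre[s - 1] - pre[j - 1])) <= neighbor_cutoff:
                neigh.append(j)
        exp_neigh[s] = tuple(neigh)
        for j in neigh:
            d0 = float(np.linalg.norm(pre[s - 1] - pre[j - 1]))
            d1 = float(np.linalg.norm(post[s - 1] - post[j - 1]))
            exp_dd[(s, j)] = d1 - d0
    retained = tuple(
        i + 1
        for i in range(n)
        if float(np.linalg.norm(post[i] - pre[i])) <= reject_cutoff
    )
    return mutant, ExpectedMetrics(
        local_rmsd=exp_local, delta_d=exp_dd, neighbors=exp_neigh, retained=retained
    )


# CDS fixtures consistent with a fixed set of variant calls.  Filler codons
# are a constant GCT (Ala) so fixtures are identical across platforms and
# the translation is stop-free by construction.
_FIXTURE_SPECS = {
    "015992": {
        "n_codons": 255,
        "codons": {1: "ATG", 12: "GCT", 114: "CAA", 255: "GGA"},
        "variants": [
            Variant("SNP", 34, "G", "T", id="snp_34_G_T"),
            Variant("SNP", 340, "C", "G", id="snp_340_C_G"),
            Variant("SNP", 764, "G", "A", id="snp_764_G_A"),
        ],
    },
    "040854": {
        "n_codons": 223,
        "codons": {1: "ATG", 187: "AAT", 194: "CAT", 195: "TCT", 223: "ATT"},
        "variants": [
            Variant("SNP", 560, "A", "G", id="snp_560_A_G"),
            Variant("INS", 579, "", "ATG", id="ins_579_580_ATG"),
            Variant("SNP", 667, "A", "G", id="snp_667_A_G"),
        ],
    },
}


def cds_for_printed_effects(gene_tag: str) -> tuple[CodingSequence, list[Variant]]:
    """Synthetic CDS + variants realizing a fixed set of published-style calls.

    ``"015992"`` — 255 codons with codon 12 = GCT (Ala), 114 = CAA (Gln),
    255 = GGA (Gly) and three SNPs (G34T, C340G, G764A) giving the missense
    calls at residues 12, 114 and 255.  ``"040854"`` — 223 codons with codon
    187 = AAT (Asn) and 223 = ATT (Ile), two SNPs (A560G, A667G) and an
    in-frame ATG insertion between CDS positions 579/580 (the codon-193/194
    boundary), i.e. one inserted residue after codon 193.

    The full-length genes are not published; these are synthetic stand-ins
    whose codons at the variant positions are forced by the printed base
    changes.
    """
    if gene_tag not in _FIXTURE_SPECS:
        raise ValueError(
            f"unknown gene tag {gene_tag!r}; choose from {sorted(_FIXTURE_SPECS)}"
        )
    spec = _FIXTURE_SPECS[gene_tag]
    codons = ["GCT"] * spec["n_codons"]
    for idx, codon in spec["codons"].items():
        codons[idx - 1] = codon
    cds = CodingSequence(id=f"gene-{gene_tag}", seq="".join(codons))
    return cds, list(spec["variants"])
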