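# Methods

## Scope and model

`varstruct` analyses the structural consequences of coding-sequence variants
in three coupled stages: (1) protein-level classification of CDS-coordinate
SNPs and small InDels; (2) rigid-body comparison of a wild-type and a mutant
single-chain Cα-trace model; (3) per-mutation-site perturbation statistics.
Structure prediction itself is out of scope — WT/mutant models (e.g.
AlphaFold output) are inputs.  All structural metrics are defined on Cα
atoms only: the mutation-site reference is the site's Cα, the neighbor end
of each distance is the neighbor's Cα, and side-chain atoms are parsed and
dropped.

### Variant effects

CDS coordinates are 1-based on the coding strand; codon *c* spans
nucleotides 3c−2…3c, so a nucleotide position maps to codon ⌈pos/3⌉.
Translation uses the standard genetic code (table 1) and truncates at the
first stop codon.  Each variant is classified **independently against the
wild-type frame** — this matches how variant calls are conventionally
reported per-SNP; a cumulative "haplotype" translation is available by
applying all variants and re-translating.  SNPs are classified by comparing
the WT and mutant codon translations (synonymous / missense / stop gain /
stop loss).  In-frame indels are classified by diffing the full WT and
mutant translations at the longest common prefix/suffix, which handles
insertions at and away from codon boundaries uniformly and places ambiguous
repeats deterministically (leftmost anchor after the common prefix).  Any
indel with net length not divisible by 3 is a frameshift.  Notation is
WT-first (`A12S` = WT Ala 12 → mutant Ser); pure insertions use the
`H194_S195insY` anchor form.

### Correspondence

Metrics require knowing which mutant residue corresponds to each WT residue
once indels shift the numbering.  The default, exact route derives the map
from the classified effects: substitutions pair i↔i, an insertion of k
residues after WT residue r contributes k mutant-only indices and shifts
downstream pairs by +k, deletions symmetrically.  When no variant list is
available, a global Needleman–Wunsch alignment of the two amino-acid
sequences (BLOSUM62, gap open 10, gap extend 1 — standard defaults; any
fixed choice works because realistic WT/mutant pairs are nearly identical)
provides the same map; the two routes are tested to coincide on random
substitution+indel cases with unambiguous gap placement.  Frameshifted
proteins are rejected: downstream of the shift there is no meaningful
residue-wise pairing.

### Superposition and global RMSD

The rigid transform minimizing Σ‖R·q + t − p‖² over paired Cα atoms is the
closed-form Kabsch solution (SVD of the cross-covariance; the smallest
singular vector is sign-corrected so det R = +1, excluding reflections).
Global RMSD = √(mean squared residual).  The default is the transparent
all-pair fit (cycles = 0).  An optional refinement emulates iterative
aligners: each cycle re-evaluates **all** pairs against the current
transform, retains those within `reject_cutoff` (default 2.0 Å), and
refits, stopping at a fixed point or after `cycles` rounds.  Re-evaluating
all pairs (rather than only previously retained ones) lets residues that
were unfairly penalized by an outlier-skewed first fit re-enter; when the
cutoff would reject nearly everything under such a skewed fit, the
best-fitting half is retained for that round so refinement can recover.
Both `rmsd_all` (all pairs, final transform) and `rmsd_retained` (surviving
pairs) are always reported, so either convention of an external aligner's
"RMSD" is recoverable.

### Per-site metrics

* **Local window**: residues [i−flank, i+flank] around the site, clipped to
  the chain; default flank = 5 (five upstream and five downstream
  residues).  For insertion sites the window is centred on the mutant
  inserted residue and mapped to WT through the correspondence.
* **Local RMSD**: RMSD over the paired window Cα atoms *under the global
  transform* — deliberately no local re-fit.  A locally re-fit 11-residue
  window could never show tens-of-Å values; only a global-frame measurement
  preserves the magnitude of a displaced segment's excursion, which is the
  quantity of interest.
* **Neighborhood**: all residues whose Cα lies within `neighbor_cutoff`
  (default 8.0 Å) of the site Cα, excluding the site.  The neighborhood is
  determined in the wild-type structure (the pre-mutation reference) for
  substitution sites.  Sequence-adjacent residues (i±1, i±2) are not
  excluded; their ΔD ≈ 0 under backbone rigidity and serves as an internal
  sanity check.
* **ΔD = D_MUT − D_WT** per neighbor, signed, with D the site↔neighbor
  Cα–Cα distance in each structure (mutant counterparts located through the
  correspondence).  ΔD involves only internal distances and is therefore
  exactly invariant under rigid motion of either model, and antisymmetric
  under swapping WT and mutant.  Flagging uses |ΔD| ≥ `flag_threshold`
  (default 3.0 Å).
* **Insertion sites**: the inserted residue exists only in the mutant, so
  D_MUT is measured from its Cα while D_WT is measured from the Cα of the
  WT residue immediately preceding the insertion point.  This is an
  explicit convention (echoed in the output metadata); alternatives (e.g.
  midpoint of the flanking residues) would change individual values by at
  most one backbone spacing.

### Variant landscape

SNPs are binned into the six strand-collapsed substitution types by
complementing purine-reference records onto the pyrimidine-context label
(G→A ≡ C:G>T:A); totals are conserved and non-SNP/ambiguous records are
counted separately.  InDel lengths are signed (+ = insertion); windowed
densities use non-overlapping tiling windows (default 1 Mb — window size is
a parameter since published density tracks rarely state theirs) with the
last window truncated at the chromosome end.  Association between two
tracks reports Spearman's rho (Pearson on mid-ranks, ties averaged),
Pearson's r, and the OLS slope/intercept/R² (= squared Pearson r of the
fit).  The VCF reader is a deliberate minimal subset (CHROM/POS/ID/REF/ALT,
multi-allelic records split); genotype and INFO semantics belong to variant
callers, not to this summary stage.

## Synthetic data and what the tests show

The generator produces ideal α-helix Cα traces (radius 2.3 Å, rise
1.5 Å/residue, twist 100°/residue — giving the realistic ~3.83 Å
consecutive-Cα spacing and non-trivial 8 Å neighborhoods) and perturbs them
by rigidly translating a chosen residue segment, optionally with seeded
Gaussian jitter.  The expected local RMSD, neighbor sets, ΔD values and
rejection-survivor sets are computed by direct brute-force distance
measurement on the pre/post coordinate arrays, sharing no code with the
metric modules; the central test suite asserts pipeline/oracle agreement to
1e−6.  CDS fixtures use fixed GCT (Ala) filler codons — not random — so
they are byte-identical across platforms and stop-free by construction,
with the codons at variant positions forced by the intended base changes.

Passing these suites shows the *method* is implemented correctly: the
machinery recovers known displacements exactly and respects the metrics'
invariances.  It does not certify behaviour on real predicted structures,
whose deviations are not rigid-segment translations, whose models carry
prediction error, and whose published per-protein RMSD/ΔD magnitudes depend
entirely on those specific models.  Rigid displacement of one segment is the
designed regime because it admits an analytic oracle; correlated backbone
rearrangements are deliberately not emulated.

A documented inconsistency is reproduced faithfully: the `"040854"` fixture
encodes its printed nucleotides (an ATG insertion at the codon-193/194
boundary), whose in-frame product is a Met inserted after residue 193 — no
codon arrangement makes an ATG insertion there encode a Tyr between
residues 194/195, so the expected call is asserted only at that level.
Similarly, the position-12 substitution is reported with explicit direction
(WT Ala → mutant Ser, `A12S`), which is what the codon arithmetic
(GCx→TCx under a G→T change) supports.

## Numerical choices

* Rotation orthonormality enforced to 1e−8; determinant +1 required.
* Near-collinear point sets (second singular value < 1e−8 of the largest)
  are fit but logged as ill-conditioned.
* ΔD equals d_mut − d_wt to 1e−9 by construction; antisymmetry holds to
  machine precision.
* TSV/JSON outputs print Å at 3 decimals (the precision of typical
  published structural tables) and echo the full configuration plus tool
  version, making repeat runs byte-identical.
* PDB round-trips preserve coordinates to the format's 3-decimal field.
* Altloc Cα records are resolved by highest occupancy, first-seen on ties;
  residues lacking a Cα are skipped with a logged warning.

## Problem sizes

Test and reproduction runs use 60-residue helices, 100 random 8-point
superposition instances against a multi-start BFGS rotation minimization,
50 random correspondence cases, and a 600-SNP synthetic landscape over 50
density windows — sizes at which the brute-force oracles are exact and the
full suite runs in seconds while exercising every code path.

## Known limitations

* Cα-only: no side-chain or all-atom distance options.
* Single chain per analysis; oligomeric interfaces are out of scope.
* No ΔΔG/stability prediction, contact-map analytics or flexible
  superposition; TM-score is not computed.
* Frameshift variants terminate structural comparison by design.
* The alignment fallback can mis-place gaps between tandem repeats; the
  effect-derived map is exact and preferred whenever variants are known.
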