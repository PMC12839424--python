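"""Mutation-site conformational perturbation metrics.

Three per-site statistics quantify how far a mutant model departs from the
wild type around each mutation:

* **local RMSD** — RMSD over the paired Cα atoms of a window of ``flank``
  residues on each side of the site, measured under the *global*
  superposition (no local re-fit, so a displaced segment shows its full
  excursion rather than being re-centred away);
* **Cα neighborhood** — residues whose Cα lies within ``neighbor_cutoff``
  (default 8 Å) of the mutation-site Cα;
* **ΔD = D_MUT − D_WT** — the signed change of the site↔neighbor Cα–Cα
  distance.  ΔD compares internal distances, so it is exactly invariant
  under any rigid motion of either structure.  Records with
  abs(ΔD) ≥ ``flag_threshold`` (default 3 Å) are flagged as pronounced.

Substitution sites live at a paired WT residue.  An inserted residue exists
only in the mutant: its site Cα is the mutant inserted residue, D_MUT is
measured there, and D_WT from the Cα of the WT residue immediately
preceding the insertion point (an explicit convention, echoed in output
metadata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .correspondence import CorrespondenceMap
from .structure import StructureModel
from .superposition import SuperpositionResult, superpose

__all__ = [
    "MetricConfig",
    "SiteSpec",
    "LocalRMSDResult",
    "DeltaDRecord",
    "PerturbationReport",
    "EmptyWindowError",
    "local_window",
    "local_rmsd",
    "find_neighbors",
    "compute_delta_d",
    "perturbation_report",
]

log = logging.getLogger(__name__)


class EmptyWindowError(ValueError):
    """No paired residues fall inside the local window."""


@dataclass(frozen=True)
class MetricConfig:
    """Tunables: flank residues per side, neighbor cutoff (Å), flag level (Å)."""

    flank: int = 5
    neighbor_cutoff: float = 8.0
    flag_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.flank < 0 or self.neighbor_cutoff <= 0 or self.flag_threshold <= 0:
            raise ValueError(f"invalid metric configuration {self}")


@dataclass(frozen=True)
class SiteSpec:
    """One mutation site: a paired WT residue, or a mutant-only insertion."""

    kind: str  # "substitution" | "insertion"
    wt_index: int | None = None
    mut_index: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind == "substitution" and self.wt_index is None:
            raise ValueError("substitution site needs wt_index")
        if self.kind == "insertion" and self.mut_index is None:
            raise ValueError("insertion site needs mut_index")
        if self.kind not in ("substitution", "insertion"):
            raise ValueError(f"unknown site kind {self.kind!r}")


@dataclass(frozen=True)
class LocalRMSDResult:
    site: SiteSpec
    window_wt: tuple[int, ...]  # WT residue indices of the window
    n_pairs: int
    value: float  # Å


@dataclass(frozen=True)
class DeltaDRecord:
    site: SiteSpec
    neighbor_wt_index: int
    d_wt: float
    d_mut: float
    delta_d: float  # mutant minus wild type, signed
    flagged: bool


@dataclass(frozen=True)
class PerturbationReport:
    superposition: SuperpositionResult
    local: tuple[LocalRMSDResult, ...]
    delta_d: tuple[DeltaDRecord, ...]
    failures: tuple[tuple[str, str], ...] = ()  # (site label, message)


def _site_indices(
    site: SiteSpec, cmap: CorrespondenceMap
) -> tuple[int | None, int]:
    """Resolve (wt_index for D_WT, mut_index for D_MUT) for a site."""
    if site.kind == "substitution":
        w = site.wt_index
        m = cmap.wt_to_mut.get(w)
        if m is None:
            raise ValueError(f"substitution site {w} is not paired in the map")
        return w, m
    m = site.mut_index
    if m not in set(cmap.mut_only):
        raise ValueError(f"insertion site {m} is not a mutant-only residue")
    # WT anchor: paired partner of the closest preceding paired mutant residue
    prev = [mm for _, mm in cmap.pairs if mm < m]
    if not prev:
        raise ValueError(f"insertion site {m} has no preceding paired residue")
    return cmap.mut_to_wt[max(prev)], m


def local_window(
    model: StructureModel,
    site: SiteSpec,
    flank: int,
    cmap: CorrespondenceMap | None = None,
) -> tuple[int, ...]:
    """WT residue indices of the ±flank window around a site.

    For a substitution at WT residue i this is [i−flank, i+flank] clipped to
    the chain.  For an insertion the window is centred on the mutant inserted
    residue and mapped back to WT through the correspondence (the inserted
    residue itself has no WT member).
    """
    n = len(model)
    if site.kind == "substitution":
        i = site.wt_index
        return tuple(range(max(1, i - flank), min(n, i + flank) + 1))
    if cmap is None:
        raise ValueError("insertion windows require the correspondence map")
    m = site.mut_index
    lo, hi = m - flank, m + flank
    return tuple(
        sorted(w for w, mm in cmap.pairs if lo <= mm <= hi)
    )


def local_rmsd(
    wt: StructureModel,
    mut: StructureModel,
    cmap: CorrespondenceMap,
    sup: SuperpositionResult,
    site: SiteSpec,
    cfg: MetricConfig = MetricConfig(),
) -> LocalRMSDResult:
    """Window RMSD under the global superposition transform (no re-fit)."""
    window = local_window(wt, site, cfg.flank, cmap)
    wt_ca, mut_ca = wt.by_index(), mut.by_index()
    w2m = cmap.wt_to_mut
    paired = [w for w in window if w in w2m]
    if not paired:
        raise EmptyWindowError(f"site {site.label or site}: no paired window residues")
    P = np.array([wt_ca[w].ca for w in paired])
    Q = np.array([mut_ca[w2m[w]].ca for w in paired])
    value = float(np.sqrt(np.mean(np.sum((sup.transform.apply(Q) - P) ** 2, axis=1))))
    return LocalRMSDResult(site=site, window_wt=window, n_pairs=len(paired), value=value)


def find_neighbors(
    wt: StructureModel,
    site: SiteSpec,
    cfg: MetricConfig = MetricConfig(),
    mut: StructureModel | None = None,
    cmap: CorrespondenceMap | None = None,
) -> tuple[int, ...]:
    """Residues whose Cα lies within the cutoff of the mutation-site Cα.

    Substitution sites scan the wild-type structure (the pre-mutation
    reference).  Insertion sites scan the mutant around the inserted residue
    and map hits back to WT indices; unmatched mutant hits are dropped with
    a warning.  The site itself is excluded; indices are sorted.
    """
    if site.kind == "substitution":
        ca = wt.by_index()
        center = np.array(ca[site.wt_index].ca)
        out = [
            r.index
            for r in wt.residues
            if r.index != site.wt_index
            and np.linalg.norm(np.array(r.ca) - center) <= cfg.neighbor_cutoff
        ]
    else:
        if mut is None or cmap is None:
            raise ValueError("insertion sites need the mutant model and map")
        ca = mut.by_index()
        center = np.array(ca[site.mut_index].ca)
        m2w = cmap.mut_to_wt
        out = []
        for r in mut.residues:
            if r.index == site.mut_index:
                continue
            if np.linalg.norm(np.array(r.ca) - center) > cfg.neighbor_cutoff:
                continue
            if r.index not in m2w:
                log.warning(
                    "neighbor %d of insertion site %d has no WT counterpart; dropped",
                    r.index, site.mut_index,
                )
                continue
            out.append(m2w[r.index])
    if not out:
        log.warning("site %s: empty neighbor set at %.1f Å",
                    site.label or site, cfg.neighbor_cutoff)
    return tuple(sorted(out))


def compute_delta_d(
    wt: StructureModel,
    mut: StructureModel,
    cmap: CorrespondenceMap,
    site: SiteSpec,
    neighbors: tuple[int, ...],
    cfg: MetricConfig = MetricConfig(),
) -> list[DeltaDRecord]:
    """Signed site↔neighbor Cα distance changes, mutant minus wild type.

    Internal distances only — no superposition enters, so the result is
    invariant under rigid motion of either model.  Neighbors with no mutant
    counterpart are skipped with a warning.
    """
    wt_site, mut_site = _site_indices(site, cmap)
    wt_ca, mut_ca = wt.by_index(), mut.by_index()
    p_site = np.array(wt_ca[wt_site].ca)
    q_site = np.array(mut_ca[mut_site].ca)
    w2m = cmap.wt_to_mut
    records: list[DeltaDRecord] = []
    for j in neighbors:
        if j == wt_site:
            continue
        jm = w2m.get(j)
        if jm is None:
            log.warning("neighbor %d unmatched in mutant; record skipped", j)
            continue
        d_wt = float(np.linalg.norm(p_site - np.array(wt_ca[j].ca)))
        d_mut = float(np.linalg.norm(q_site - np.array(mut_ca[jm].ca)))
        delta = d_mut - d_wt
        records.append(
            DeltaDRecord(
                site=site,
                neighbor_wt_index=j,
                d_wt=d_wt,
                d_mut=d_mut,
                delta_d=delta,
                flagged=abs(delta) >= cfg.flag_threshold,
            )
        )
    return records


def perturbation_report(
    wt: StructureModel,
    mut: StructureModel,
    cmap: CorrespondenceMap,
    sites: list[SiteSpec],
    cfg: MetricConfig = MetricConfig(),
    cycles: int = 0,
    reject_cutoff: float = 2.0,
) -> PerturbationReport:
    """Assemble the full per-site report on top of one global superposition.

    Sites are processed in index order; a failure at one site is recorded
    and does not abort the others.
    """
    sup = superpose(wt, mut, cmap, cycles=cycles, reject_cutoff=reject_cutoff)
    order = sorted(
        sites, key=lambda s: (s.wt_index if s.kind == "substitution" else s.mut_index)
    )
    local: list[LocalRMSDResult] = []
    deltas: list[DeltaDRecord] = []
    failures: list[tuple[str, str]] = []
    for site in order:
        try:
            lr = local_rmsd(wt, mut, cmap, sup, site, cfg)
            neigh = find_neighbors(wt, site, cfg, mut=mut, cmap=cmap)
            dd = compute_delta_d(wt, mut, cmap, site, neigh, cfg)
        except (ValueError, KeyError) as exc:
            failures.append((site.label or str(site), str(exc)))
            continue
        local.append(lr)
        deltas.extend(dd)
    return PerturbationReport(
        superposition=sup,
        local=tuple(local),
        delta_d=tuple(deltas),
        failures=tuple(failures),
    )
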