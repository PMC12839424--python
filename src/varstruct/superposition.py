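"""Least-squares rigid superposition of paired Cα atoms (Kabsch) and RMSD.

The closed-form Kabsch solution minimizes Σ‖R·q + t − p‖² over proper
rotations R (reflections excluded by sign-correcting the smallest singular
vector) and translations t.  ``superpose`` adds optional outlier-rejection
refinement cycles — refit after dropping pairs whose deviation exceeds a
cutoff — emulating the iterative behaviour of common structure aligners;
with zero cycles it is the plain all-pair fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .correspondence import CorrespondenceMap
from .structure import StructureModel

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "InsufficientPairsError",
    "RejectionCollapseError",
    "kabsch_fit",
    "superpose",
]

log = logging.getLogger(__name__)


class InsufficientPairsError(ValueError):
    """Fewer than 3 atom pairs: rotation underdetermined."""


class RejectionCollapseError(RuntimeError):
    """Outlier rejection left too few pairs to fit."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (rotation matrix R, translation t, Å)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid motions")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd_all: float  # over all input pairs, final transform
    rmsd_retained: float  # over pairs surviving rejection
    retained: tuple[int, ...]  # indices into the input pair list
    cycles_run: int


def kabsch_fit(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid transform mapping points Q onto points P, and its RMSD.

    P and Q are (n, 3) arrays of paired coordinates, n ≥ 3.  Near-collinear
    point sets are fit anyway but logged as ill-conditioned.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"need matching (n,3) arrays, got {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise InsufficientPairsError(f"{len(P)} pairs; at least 3 required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8 * max(S[0], 1.0):
        log.warning("kabsch_fit: near-collinear points, rotation ill-conditioned")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = pc - R @ qc
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(Q) - P) ** 2, axis=1))))
    return transform, rmsd


def superpose(
    wt: StructureModel,
    mut: StructureModel,
    cmap: CorrespondenceMap,
    cycles: int = 0,
    reject_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Superpose mutant onto wild type over the paired Cα atoms.

    Cycle 0 fits all pairs; each further cycle drops pairs whose post-fit
    deviation exceeds ``reject_cutoff`` (Å) and refits, stopping early when
    nothing is dropped.  ``rmsd_retained`` is measured over surviving pairs,
    ``rmsd_all`` over all input pairs, both under the final transform.
    """
    wt_ca = wt.by_index()
    mut_ca = mut.by_index()
    P = np.array([wt_ca[w].ca for w, _ in cmap.pairs])
    Q = np.array([mut_ca[m].ca for _, m in cmap.pairs])
    if len(P) < 3:
        raise InsufficientPairsError("correspondence has fewer than 3 pairs")
    keep = np.arange(len(P))
    transform, rmsd = kabsch_fit(P, Q)
    cycles_run = 0
    for _ in range(cycles):
        # re-evaluate every pair against the current transform, so pairs
        # unfairly penalized by an outlier-skewed earlier fit can re-enter
        dev = np.linalg.norm(transform.apply(Q) - P, axis=1)
        survivors = np.flatnonzero(dev <= reject_cutoff)
        if len(survivors) < 3:
            # cutoff rejects (nearly) everything under a skewed fit: retain
            # the best-fitting half so refinement can recover
            half = max(3, len(P) // 2)
            survivors = np.sort(np.argsort(dev, kind="stable")[:half])
            if len(survivors) < 3:
                raise RejectionCollapseError(
                    f"rejection at {reject_cutoff} Å left {len(survivors)} pairs"
                )
        if np.array_equal(survivors, keep):
            break
        keep = survivors
        transform, rmsd = kabsch_fit(P[keep], Q[keep])
        cycles_run += 1
    rmsd_all = float(np.sqrt(np.mean(np.sum((transform.apply(Q) - P) ** 2, axis=1))))
    return SuperpositionResult(
        transform=transform,
        rmsd_all=rmsd_all,
        rmsd_retained=rmsd,
        retained=tuple(int(i) for i in keep),
        cycles_run=cycles_run,
    )
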