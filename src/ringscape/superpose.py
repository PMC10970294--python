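"""Rigid-body superposition of conformers and monomers.

Least-squares (Kabsch) fitting with optional atom masks, batch alignment of
whole ensembles, canonicalization of the six-fold ring register, and the
hexamer→monomer split used for the monomer-level analysis.  The default
alignment frame excludes the mobile N-domains: hexamers and monomers are
fitted on their D1+D2 core so that domain motion is measured, not absorbed
into the pose.  Only proper rotations are considered — protein structures
are chiral.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble_io import ConformerEnsemble
from .toy_complex import HexamerTemplate, rotation_about_axis

__all__ = [
    "RigidTransform",
    "AtomMask",
    "kabsch",
    "align_ensemble",
    "canonicalize_register",
    "split_monomers",
    "regroup_monomers",
    "core_mask",
]

CORE_DOMAINS = ("D1", "D2")


class SuperpositionError(ValueError):
    """Degenerate or invalid superposition problem."""


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ x·Rᵀ + t with R proper orthogonal."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = self.rotation
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise SuperpositionError("rotation must be proper (det = +1)")
        if np.abs(r.T @ r - np.eye(3)).max() > 1e-9:
            raise SuperpositionError("rotation must be orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def angle_deg(self) -> float:
        """Rotation angle of the transform, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass(frozen=True)
class AtomMask:
    """A named selection of atom indices used as the fitting frame."""

    indices: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise SuperpositionError("mask indices must be unique")
        object.__setattr__(self, "indices", idx)

    @classmethod
    def from_bool(cls, mask: np.ndarray, description: str = "") -> "AtomMask":
        return cls(indices=np.flatnonzero(np.asarray(mask, dtype=bool)), description=description)

    def __len__(self) -> int:
        return len(self.indices)


def core_mask(
    topology: HexamerTemplate | ConformerEnsemble,
    monomers: Sequence[int] | None = None,
) -> AtomMask:
    """D1+D2 mask — the standard rigid frame that excludes the N-domains."""
    if isinstance(topology, HexamerTemplate):
        mask = topology.atom_mask(domains=CORE_DOMAINS, monomers=monomers)
    else:
        mask = topology.domain_mask(*CORE_DOMAINS)
        if monomers is not None:
            mask &= np.isin(topology.monomer_index, list(monomers))
    return AtomMask.from_bool(mask, description="D1+D2 only")


def _resolve_mask(mask: AtomMask | np.ndarray | None, n_atoms: int) -> np.ndarray:
    if mask is None:
        return np.arange(n_atoms)
    if isinstance(mask, AtomMask):
        idx = mask.indices
    else:
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
    if len(idx) and (idx.min() < 0 or idx.max() >= n_atoms):
        raise SuperpositionError("mask indices out of range")
    return idx


def _check_degenerate(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise SuperpositionError(
            "masked selection is collinear or degenerate; rotation is underdetermined"
        )


def _kabsch_batch(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotations/translations for (N, M, 3) onto (M, 3) or (N, M, 3)."""
    mob_com = mobile.mean(axis=1, keepdims=True)
    tgt = target if target.ndim == 3 else target[None, :, :]
    tgt_com = tgt.mean(axis=1, keepdims=True)
    mob_c = mobile - mob_com
    tgt_c = tgt - tgt_com
    # cross-covariance C_n = Σ_a t_na m_naᵀ; R = U diag(1,1,det) Vᵀ
    if tgt_c.shape[0] == 1:
        cov = np.einsum("ai,naj->nij", tgt_c[0], mob_c)
    else:
        cov = np.einsum("nai,naj->nij", tgt_c, mob_c)
    u, _, vt = np.linalg.svd(cov)
    det = np.linalg.det(u @ vt)
    u = u.copy()
    u[:, :, 2] *= det[:, None]
    rot = u @ vt
    trans = tgt_com[:, 0, :] - np.einsum("nij,nj->ni", rot, mob_com[:, 0, :])
    return rot, trans


def kabsch(
    mobile: np.ndarray,
    target: np.ndarray,
    mask: AtomMask | np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``target``.

    Returns the least-squares transform over the masked atoms and the
    post-fit RMSD over those atoms.  Raises for masks with fewer than three
    atoms or collinear selections, where the rotation is underdetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise SuperpositionError("mobile and target must share topology")
    idx = _resolve_mask(mask, mobile.shape[0])
    if len(idx) < 3:
        raise SuperpositionError(f"mask has {len(idx)} atoms; need at least 3")
    mob, tgt = mobile[idx], target[idx]
    _check_degenerate(tgt)
    _check_degenerate(mob)
    rot, trans = _kabsch_batch(mob[None, :, :], tgt)
    transform = RigidTransform(rotation=rot[0], translation=trans[0])
    fitted = transform.apply(mob)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - tgt) ** 2, axis=1))))
    return transform, rmsd


def align_ensemble(
    ensemble: ConformerEnsemble,
    reference: np.ndarray,
    mask: AtomMask | np.ndarray | None = None,
) -> ConformerEnsemble:
    """Superpose every conformer onto ``reference`` using the masked frame.

    The returned ensemble carries an ``alignment`` report (particle_id,
    rmsd over masked atoms).  Idempotent: re-aligning an aligned ensemble
    changes coordinates only at float round-off.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != ensemble.coords.shape[1:]:
        raise SuperpositionError("reference does not share the ensemble topology")
    idx = _resolve_mask(mask, ensemble.n_atoms)
    if len(idx) < 3:
        raise SuperpositionError(f"mask has {len(idx)} atoms; need at least 3")
    _check_degenerate(reference[idx])
    rot, trans = _kabsch_batch(ensemble.coords[:, idx, :], reference[idx])
    aligned = (
        np.einsum("nai,nji->naj", ensemble.coords, rot) + trans[:, None, :]
    )
    fitted = aligned[:, idx, :]
    rmsd = np.sqrt(np.mean(np.sum((fitted - reference[idx]) ** 2, axis=2), axis=1))
    report = pd.DataFrame({"particle_id": ensemble.particle_ids, "rmsd": rmsd})
    return replace(ensemble, coords=aligned, alignment=report)


def _roll_register(coords: np.ndarray, k: int, n_monomers: int = 6) -> np.ndarray:
    """Cyclic relabeling: slot j receives the atoms of monomer (j+k) mod 6."""
    blocks = coords.reshape(n_monomers, -1, 3)
    return np.roll(blocks, -k, axis=0).reshape(-1, 3)


def canonicalize_register(
    structure: np.ndarray,
    reference: np.ndarray,
    mask: AtomMask | np.ndarray | None = None,
    n_monomers: int = 6,
) -> tuple[np.ndarray, int, float]:
    """Resolve the six-fold ring register of a hexamer against a reference.

    Tries all six cyclic relabelings (each re-fitted rigidly, so the
    compensating k·60° rotation is found by the superposition itself) and
    returns the relabeled, superposed coordinates with the register k that
    minimizes masked RMSD.  Ties break toward the smallest k.
    """
    structure = np.asarray(structure, dtype=float)
    best: tuple[float, int, np.ndarray] | None = None
    for k in range(n_monomers):
        candidate = _roll_register(structure, k, n_monomers)
        transform, rmsd = kabsch(candidate, reference, mask)
        if best is None or rmsd < best[0] - 1e-12:
            best = (rmsd, k, transform.apply(candidate))
    assert best is not None
    rmsd, k, coords = best
    return coords, k, rmsd


def split_monomers(
    ensemble: ConformerEnsemble,
) -> tuple[ConformerEnsemble, pd.DataFrame]:
    """Split each hexamer into its six monomer records.

    Output order is particle-major (particle p, monomers 0..5 at rows
    6p..6p+5); the returned table maps each monomer record to its parent
    particle and ring slot, so :func:`regroup_monomers` inverts the split
    exactly.
    """
    n, m = len(ensemble), ensemble.n_monomers
    per = ensemble.atoms_per_monomer
    coords = ensemble.coords.reshape(n * m, per, 3)
    table = pd.DataFrame(
        {
            "monomer_record_id": np.arange(n * m),
            "parent_particle_id": np.repeat(ensemble.particle_ids, m),
            "monomer_index": np.tile(np.arange(m), n),
        }
    )
    mono = ConformerEnsemble(
        coords=coords,
        particle_ids=np.arange(n * m),
        domain_labels=ensemble.domain_labels[:per],
        n_monomers=1,
    )
    return mono, table


def regroup_monomers(
    monomers: ConformerEnsemble, table: pd.DataFrame
) -> ConformerEnsemble:
    """Inverse of :func:`split_monomers` (bookkeeping check, not refinement)."""
    order = table.sort_values(["parent_particle_id", "monomer_index"], kind="stable")
    idx = monomers.index_of(order["monomer_record_id"].to_numpy())
    parents = order["parent_particle_id"].to_numpy()
    unique_parents = pd.unique(parents)
    m = int(order["monomer_index"].max()) + 1
    per = monomers.n_atoms
    coords = monomers.coords[idx].reshape(len(unique_parents), m * per, 3)
    return ConformerEnsemble(
        coords=coords,
        particle_ids=unique_parents,
        domain_labels=np.tile(monomers.domain_labels, m),
        n_monomers=m,
    )
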