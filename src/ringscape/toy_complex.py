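"""Procedural Cα stand-in for a C6 double-ring AAA+ hexamer.

The model mimics the architecture of p97: six identical protomers, each with
two core domains (D1, D2) that stack into two coaxial rings, and a peripheral
N-terminal domain attached at the N–D1 junction by a hinge.  The N-domain sits
~75° above the plane of the D1 ring in the "up" conformation and can swing
about the hinge; the two core rings can be pulled apart into a split-washer
geometry.  All coordinates are in ångström, the symmetry axis is z by
construction, and monomer k is monomer 0 rotated by k·60° about z.

The module also provides an anisotropic-network (pairwise harmonic, distance
cutoff) normal-mode analysis of any Cα point cloud, used to characterise the
low-frequency motions of the toy complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csgraph, csr_matrix
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "DOMAIN_LABELS",
    "MonomerTemplate",
    "HexamerTemplate",
    "NormalModeSet",
    "build_template",
    "swing_n_domain",
    "apply_ring_split",
    "enm_hessian",
    "enm_modes",
    "rotation_about_axis",
    "load_template_from_pdb",
]

DOMAIN_LABELS = ("N", "D1", "D2")

# Default toy geometry (Å).  The numbers echo the scale of the real hexamer:
# ~40 Å ring radius, ~25 Å axial separation of the two core rings, N-domain
# lever arm of ~25 Å producing the large peripheral excursions.
RING_RADIUS = 40.0
D1_D2_SPACING = 25.0
N_LEVER_ARM = 25.0
CORE_BLOB_RADIUS = 18.0
N_BLOB_RADIUS = 16.0
UP_OFFSET_DEG = 75.0
# Cutoff scaled to the toy lattice: blob atoms sit ~8-10 Å apart (coarser
# than residue-level Cα), so the interaction cutoff is ~1.5x that spacing,
# the same ratio residue-level networks use with their 12 Å convention.
ENM_CUTOFF = 16.0


class GeometryError(ValueError):
    """Invalid geometric parameters or degenerate geometry."""


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def _fibonacci_ball(n: int, radius: float) -> np.ndarray:
    """Deterministic, roughly uniform point cloud filling a ball.

    Golden-angle spiral directions with cube-root radial spacing; gives a
    reproducible blob with near-constant local density, standing in for the
    Cα cloud of a globular domain.
    """
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    # radial shells biased slightly outward so surfaces of adjacent blobs touch
    r = radius * ((i + 0.5) / n) ** (1.0 / 3.0)
    theta = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    azimuth = 2.0 * np.pi * i / phi
    sin_t = np.sin(theta)
    pts = np.column_stack(
        [r * sin_t * np.cos(azimuth), r * sin_t * np.sin(azimuth), r * np.cos(theta)]
    )
    return pts - pts.mean(axis=0)


@dataclass(frozen=True)
class MonomerTemplate:
    """One protomer: Cα coordinates, per-atom domain labels, hinge definition.

    ``hinge_point``/``hinge_axis`` define the rotation axis of the N-domain;
    ``up_offset_deg`` records how far the stored N-domain orientation is
    rotated above the coplanar (in-D1-plane) reference.
    """

    coords: np.ndarray
    labels: np.ndarray
    hinge_point: np.ndarray
    hinge_axis: np.ndarray
    up_offset_deg: float = UP_OFFSET_DEG

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.hinge_axis) - 1.0) > 1e-9:
            raise GeometryError("hinge_axis must have unit norm")
        for lab in DOMAIN_LABELS:
            if int(np.sum(self.labels == lab)) < 3:
                raise GeometryError(f"domain {lab!r} needs at least 3 atoms")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def domain_mask(self, *domains: str) -> np.ndarray:
        bad = set(domains) - set(DOMAIN_LABELS)
        if bad:
            raise GeometryError(f"unknown domain labels: {sorted(bad)}")
        return np.isin(self.labels, list(domains))

    def n_center_of_mass(self, coords: np.ndarray | None = None) -> np.ndarray:
        c = self.coords if coords is None else np.asarray(coords, dtype=float)
        return c[self.domain_mask("N")].mean(axis=0)


@dataclass(frozen=True)
class HexamerTemplate:
    """Six protomers in counter-clockwise ring order about the z axis."""

    monomers: tuple[MonomerTemplate, ...]
    symmetry_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    ring_radius: float = RING_RADIUS

    def __post_init__(self) -> None:
        if len(self.monomers) != 6:
            raise GeometryError("a hexamer template needs exactly 6 monomers")

    @property
    def atoms_per_monomer(self) -> int:
        return self.monomers[0].n_atoms

    @property
    def n_atoms(self) -> int:
        return 6 * self.atoms_per_monomer

    @property
    def coords(self) -> np.ndarray:
        return np.concatenate([m.coords for m in self.monomers], axis=0)

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([m.labels for m in self.monomers])

    @property
    def monomer_index(self) -> np.ndarray:
        return np.repeat(np.arange(6), self.atoms_per_monomer)

    def atom_mask(
        self, domains: Sequence[str] = DOMAIN_LABELS, monomers: Sequence[int] | None = None
    ) -> np.ndarray:
        """Boolean mask over all hexamer atoms, by domain and/or monomer."""
        mask = np.isin(self.labels, list(domains))
        if monomers is not None:
            mask &= np.isin(self.monomer_index, list(monomers))
        return mask

    def c6_deviation(self) -> float:
        """Max atom-wise deviation of monomer k from rotated monomer 0 (Å)."""
        dev = 0.0
        ref = self.monomers[0].coords
        for k in range(1, 6):
            rot = rotation_about_axis(self.symmetry_axis, 60.0 * k)
            dev = max(dev, float(np.abs(ref @ rot.T - self.monomers[k].coords).max()))
        return dev

    def write_pdb(self, path: str | Path, b_factor: np.ndarray | None = None) -> None:
        from . import ensemble_io

        ensemble_io.write_template_pdb(self, path, b_factor=b_factor)

    def write_label_sidecar(self, path: str | Path) -> None:
        from . import ensemble_io

        ensemble_io.write_label_sidecar(self, path)


def _build_monomer(
    atoms_per_domain: int,
    ring_radius: float,
    up_offset_deg: float,
    core_spacing: float,
    lever_arm: float,
) -> MonomerTemplate:
    radial = np.array([1.0, 0.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    # hinge axis tangential to the ring so a positive swing lifts the
    # N-domain along +z, away from the D2 ring below
    hinge_axis = np.cross(radial, z)
    hinge_axis /= np.linalg.norm(hinge_axis)

    d1_center = ring_radius * radial
    d2_center = d1_center - core_spacing * z
    hinge_point = d1_center + (CORE_BLOB_RADIUS - 2.0) * radial
    n_center_coplanar = hinge_point + lever_arm * radial

    blob_core = _fibonacci_ball(atoms_per_domain, CORE_BLOB_RADIUS)
    blob_n = _fibonacci_ball(atoms_per_domain, N_BLOB_RADIUS)

    n_coords = blob_n + n_center_coplanar
    if up_offset_deg != 0.0:
        rot = rotation_about_axis(hinge_axis, up_offset_deg)
        n_coords = (n_coords - hinge_point) @ rot.T + hinge_point

    coords = np.concatenate([n_coords, blob_core + d1_center, blob_core + d2_center])
    labels = np.repeat(np.array(DOMAIN_LABELS), atoms_per_domain)
    return MonomerTemplate(
        coords=coords,
        labels=labels,
        hinge_point=hinge_point,
        hinge_axis=hinge_axis,
        up_offset_deg=float(up_offset_deg),
    )


def build_template(
    atoms_per_domain: int = 30,
    ring_radius: float = RING_RADIUS,
    up_offset_deg: float = UP_OFFSET_DEG,
    core_spacing: float = D1_D2_SPACING,
    lever_arm: float = N_LEVER_ARM,
) -> HexamerTemplate:
    """Build the C6-symmetric toy hexamer.

    Each protomer is three atom blobs: D1 and D2 (two stacked rings of six
    blobs each) and a peripheral N blob attached at the N–D1 junction, raised
    ``up_offset_deg`` above the coplanar orientation.  Monomers 1..5 are exact
    60° rotations of monomer 0 about z, so the C6 invariant holds to float
    round-off.
    """
    if atoms_per_domain < 3:
        raise GeometryError("atoms_per_domain must be >= 3")
    if ring_radius <= 0 or core_spacing <= 0 or lever_arm <= 0:
        raise GeometryError("geometry lengths must be positive")

    m0 = _build_monomer(atoms_per_domain, ring_radius, up_offset_deg, core_spacing, lever_arm)
    monomers = [m0]
    for k in range(1, 6):
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 60.0 * k)
        monomers.append(
            MonomerTemplate(
                coords=m0.coords @ rot.T,
                labels=m0.labels,
                hinge_point=rot @ m0.hinge_point,
                hinge_axis=rot @ m0.hinge_axis,
                up_offset_deg=m0.up_offset_deg,
            )
        )
    return HexamerTemplate(monomers=tuple(monomers), ring_radius=float(ring_radius))


def swing_n_domain(
    template: HexamerTemplate,
    monomer_index: int,
    angle_deg: float,
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Rotate one monomer's N-domain rigidly about its hinge.

    Positive angles move the N-domain away from the D2 ring (upward).  Only
    the N-labelled atoms of that monomer move; the operation is an isometry
    of the N-domain point cloud.  Pass ``coords`` to compose swings.
    """
    if not 0 <= monomer_index <= 5:
        raise IndexError(f"monomer_index {monomer_index} out of range 0..5")
    if abs(angle_deg) > 180.0:
        raise GeometryError("|angle_deg| must be <= 180")
    out = template.coords.copy() if coords is None else np.array(coords, dtype=float)
    if angle_deg == 0.0:
        return out
    mono = template.monomers[monomer_index]
    mask = template.atom_mask(domains=("N",), monomers=[monomer_index])
    rot = rotation_about_axis(mono.hinge_axis, angle_deg)
    out[mask] = (out[mask] - mono.hinge_point) @ rot.T + mono.hinge_point
    return out


def apply_ring_split(
    template: HexamerTemplate,
    rise_per_monomer: float,
    seam_gap_deg: float = 0.0,
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Deform the hexamer into a split-washer (open-ring) geometry.

    Monomer m is translated by m·rise along the symmetry axis and rotated
    about it by −m·seam_gap/6, accumulating an axial stagger and an angular
    gap at the seam between monomers 5 and 0 — the open conformation seen for
    substrate-engaged AAA+ rings.
    """
    if rise_per_monomer < 0:
        raise GeometryError("rise_per_monomer must be >= 0")
    out = template.coords.copy() if coords is None else np.array(coords, dtype=float)
    if rise_per_monomer == 0.0 and seam_gap_deg == 0.0:
        return out
    axis = np.asarray(template.symmetry_axis, dtype=float)
    for m in range(6):
        mask = template.monomer_index == m
        if seam_gap_deg != 0.0 and m > 0:
            rot = rotation_about_axis(axis, -seam_gap_deg * m / 6.0)
            out[mask] = out[mask] @ rot.T
        out[mask] = out[mask] + (m * rise_per_monomer) * axis
    return out


# ---------------------------------------------------------------------------
# Elastic-network normal modes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalModeSet:
    """Result of an elastic-network normal-mode analysis.

    ``eigenvalues`` is the full ascending spectrum of the network Hessian
    (units of spring_constant); ``modes`` holds the requested lowest-frequency
    non-rigid-body displacement vectors, one orthonormal column per mode over
    the 3N Cartesian coordinates.  A connected network has exactly six
    eigenvalues at zero (rigid-body translations and rotations).
    """

    eigenvalues: np.ndarray
    modes: np.ndarray
    cutoff: float
    spring_constant: float
    n_zero: int

    @property
    def mode_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero : self.n_zero + self.modes.shape[1]]


class DisconnectedNetworkError(ValueError):
    """Contact network falls apart at the given cutoff."""

    def __init__(self, components: list[np.ndarray]):
        self.components = components
        sizes = [len(c) for c in components]
        super().__init__(
            f"elastic network is disconnected: {len(components)} components "
            f"with sizes {sizes}"
        )


def _contact_pairs(coords: np.ndarray, cutoff: float) -> np.ndarray:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs


def enm_hessian(
    coords: np.ndarray, cutoff: float = ENM_CUTOFF, spring_constant: float = 1.0
) -> np.ndarray:
    """Dense 3N×3N Hessian of the pairwise-harmonic (cutoff) network.

    Energy model: E = k/2 Σ_contacts (|r_ij| − |r_ij⁰|)²; the Hessian at the
    reference geometry has off-diagonal blocks −k·d̂d̂ᵀ per contact.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 atoms for normal modes")
    pairs = _contact_pairs(coords, cutoff)
    hess = np.zeros((3 * n, 3 * n))
    d = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    for (i, j), dv in zip(pairs, d):
        block = spring_constant * np.outer(dv, dv)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        hess[si, sj] -= block
        hess[sj, si] -= block
        hess[si, si] += block
        hess[sj, sj] += block
    return hess


def _check_connected(coords: np.ndarray, cutoff: float) -> None:
    n = coords.shape[0]
    pairs = _contact_pairs(coords, cutoff)
    data = np.ones(len(pairs))
    adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [np.flatnonzero(labels == c) for c in range(n_comp)]
        raise DisconnectedNetworkError(comps)


def enm_modes(
    coords: np.ndarray,
    cutoff: float = ENM_CUTOFF,
    n_modes: int = 5,
    spring_constant: float = 1.0,
    zero_tol: float = 1e-8,
) -> NormalModeSet:
    """Lowest-frequency non-rigid-body modes of the elastic network.

    Diagonalises the symmetric positive-semidefinite network Hessian and
    discards the null space (six rigid-body modes for a connected network,
    identified as eigenvalues below ``zero_tol`` × the largest eigenvalue).
    The default of five modes matches common practice for normal-mode-guided
    flexible fitting.
    """
    coords = np.asarray(coords, dtype=float)
    _check_connected(coords, cutoff)
    hess = enm_hessian(coords, cutoff, spring_constant)
    eigvals, eigvecs = np.linalg.eigh(hess)
    tol = zero_tol * max(eigvals.max(), 1.0)
    n_zero = int(np.sum(np.abs(eigvals) < tol))
    available = eigvals.size - n_zero
    if n_modes > available:
        raise GeometryError(
            f"requested {n_modes} modes but only {available} non-rigid modes exist"
        )
    modes = eigvecs[:, n_zero : n_zero + n_modes]
    return NormalModeSet(
        eigenvalues=eigvals,
        modes=modes,
        cutoff=float(cutoff),
        spring_constant=float(spring_constant),
        n_zero=n_zero,
    )


def load_template_from_pdb(
    pdb_path: str | Path,
    label_table: str | Path,
    hinge_point: np.ndarray,
    hinge_axis: np.ndarray,
    up_offset_deg: float,
) -> HexamerTemplate:
    """Load a real Cα hexamer as a template (caller supplies domain labels).

    The label table is a TSV with columns chain, res_id, label (N/D1/D2).
    Published entries for the real complex disagree about which deposited
    model corresponds to the up-conformation, so no default reference
    orientation is assumed here: the caller must state the hinge geometry and
    up-offset explicitly for the model they load.
    """
    from . import ensemble_io

    return ensemble_io.read_template_pdb(
        pdb_path, label_table, hinge_point, hinge_axis, up_offset_deg
    )
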