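"""Monomer hinge angles, equal-count discretization, and ring-state algebra.

The monomer landscape is discretized into K regions of equal particle count
(tertiles by default, annotated "−20°/0°/+20°"); each monomer's region label
is mapped back onto its slot in the parent hexamer, giving an ordered
six-tuple of states per particle.  Because the ring has no distinguishable
starting subunit, tuples are identified up to cyclic rotation (C6 — the ring
is chiral, so reflections are excluded): the canonical form of a tuple is
its lexicographically smallest rotation, and with three states per monomer
the 3⁶ = 729 ordered tuples collapse to 130 necklace classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble_io import ConformerEnsemble
from .toy_complex import MonomerTemplate

__all__ = [
    "DEFAULT_REGION_NAMES",
    "hinge_angle",
    "measure_hinge_angles",
    "discretize_equal_count",
    "canonical_rotation",
    "map_to_hexamers",
    "enumerate_states",
    "necklace_count",
    "state_histogram",
    "adjacency_stats",
    "max_cyclic_run",
]

DEFAULT_REGION_NAMES = ("-20deg", "0deg", "+20deg")


# ---------------------------------------------------------------------------
# Hinge angles
# ---------------------------------------------------------------------------


def _signed_angle_about_axis(
    v_ref: np.ndarray, v: np.ndarray, axis: np.ndarray
) -> np.ndarray:
    """Signed angle (deg) from v_ref to v, measured about ``axis``.

    Both vectors are projected onto the plane perpendicular to the axis;
    positive angles follow the right-hand rule about the axis.
    """
    v = np.atleast_2d(v)
    u_ref = v_ref - np.dot(v_ref, axis) * axis
    u = v - np.outer(v @ axis, axis)
    norm = np.linalg.norm(u, axis=1)
    if np.any(norm < 1e-9) or np.linalg.norm(u_ref) < 1e-9:
        raise ValueError("N-domain centroid coincides with the hinge axis")
    sin_term = np.cross(np.broadcast_to(u_ref, u.shape), u) @ axis
    cos_term = u @ u_ref
    return np.degrees(np.arctan2(sin_term, cos_term))


def _reference_direction(template: MonomerTemplate, reference: str) -> np.ndarray:
    v_up = template.n_center_of_mass() - template.hinge_point
    if reference == "up":
        return v_up
    if reference == "coplanar":
        from .toy_complex import rotation_about_axis

        rot = rotation_about_axis(template.hinge_axis, -template.up_offset_deg)
        return rot @ v_up
    raise ValueError(f"reference must be 'up' or 'coplanar', not {reference!r}")


def hinge_angle(
    monomer_coords: np.ndarray,
    template: MonomerTemplate,
    reference: str = "up",
) -> float:
    """Signed swing angle of one core-aligned monomer, in degrees.

    Measured from the hinge point to the N-domain centre of mass, about the
    hinge axis.  ``reference='up'`` zeroes the angle at the template's stored
    up-orientation (positive = further upward, away from the D2 ring);
    ``reference='coplanar'`` measures from the in-plane orientation instead,
    so the template itself reads as its up-offset (~75°).
    """
    v = template.n_center_of_mass(np.asarray(monomer_coords, dtype=float))
    return float(
        _signed_angle_about_axis(
            _reference_direction(template, reference),
            v - template.hinge_point,
            template.hinge_axis,
        )[0]
    )


def measure_hinge_angles(
    monomers: ConformerEnsemble,
    template: MonomerTemplate,
    reference: str = "up",
    align: bool = True,
) -> np.ndarray:
    """Hinge angles for a whole monomer ensemble (vectorized).

    Core-aligns every monomer onto the template with the D1+D2 mask first
    (unless ``align=False`` and the caller already did), then measures the
    signed angle of each N centre of mass about the hinge.
    """
    from .superpose import AtomMask, align_ensemble

    ens = monomers
    if align:
        mask = AtomMask.from_bool(
            np.isin(monomers.domain_labels, ["D1", "D2"]), "D1+D2 only"
        )
        ens = align_ensemble(monomers, template.coords, mask)
    n_mask = monomers.domain_labels == "N"
    coms = ens.coords[:, n_mask, :].mean(axis=1)
    return _signed_angle_about_axis(
        _reference_direction(template, reference),
        coms - template.hinge_point,
        template.hinge_axis,
    )


# ---------------------------------------------------------------------------
# Equal-count discretization
# ---------------------------------------------------------------------------


def discretize_equal_count(
    values: np.ndarray, k: int = 3, region_names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split a scalar axis into K contiguous regions of equal particle count.

    Values are ranked (stable sort, so ties break by input order) and cut
    into K contiguous blocks whose sizes differ by at most one particle —
    earlier regions absorb the remainder.  Returns integer labels in input
    order and the K−1 boundary values (midpoints between the flanking
    sorted values).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; equal-count split is meaningless")
    order = np.argsort(values, kind="stable")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    stops = np.cumsum(sizes)
    labels = np.empty(n, dtype=int)
    labels[order] = np.repeat(np.arange(k), sizes)
    sorted_vals = values[order]
    boundaries = 0.5 * (sorted_vals[stops[:-1] - 1] + sorted_vals[stops[:-1]])
    return labels, boundaries


# ---------------------------------------------------------------------------
# Necklace canonicalization and state statistics
# ---------------------------------------------------------------------------


def canonical_rotation(labels: Sequence[int]) -> tuple[int, ...]:
    """Lexicographically smallest cyclic rotation of a label tuple."""
    t = tuple(int(x) for x in labels)
    return min(t[i:] + t[:i] for i in range(len(t)))


@dataclass(frozen=True)
class HexamerState:
    """One particle's ordered six-tuple of monomer states."""

    particle_id: int
    labels: tuple[int, ...]

    @property
    def canonical(self) -> tuple[int, ...]:
        return canonical_rotation(self.labels)


def map_to_hexamers(
    monomer_labels: np.ndarray,
    particle_table: pd.DataFrame,
    ring_size: int = 6,
) -> list[HexamerState]:
    """Assemble per-monomer labels into per-particle ring states.

    ``particle_table`` is the split table (monomer_record_id,
    parent_particle_id, monomer_index) with one row per monomer label, in
    the same order as ``monomer_labels``.  Raises if any hexamer is missing
    a slot.
    """
    table = particle_table.copy()
    table["state"] = np.asarray(monomer_labels)
    states = []
    for pid, group in table.groupby("parent_particle_id", sort=True):
        slots = group.sort_values("monomer_index")
        idx = slots["monomer_index"].to_numpy()
        if len(slots) != ring_size or not np.array_equal(idx, np.arange(ring_size)):
            raise ValueError(
                f"particle {pid}: expected monomer slots 0..{ring_size - 1}, "
                f"got {idx.tolist()}"
            )
        states.append(
            HexamerState(particle_id=int(pid), labels=tuple(slots["state"].tolist()))
        )
    return states


def necklace_count(k: int, ring_size: int = 6) -> int:
    """Closed-form count of K-ary necklaces: (1/n)·Σ_{d|n} φ(d)·K^{n/d}."""
    from math import gcd

    def phi(m: int) -> int:
        return sum(1 for i in range(1, m + 1) if gcd(i, m) == 1)

    divisors = [d for d in range(1, ring_size + 1) if ring_size % d == 0]
    return sum(phi(d) * k ** (ring_size // d) for d in divisors) // ring_size


def enumerate_states(k: int, ring_size: int = 6) -> int:
    """Distinct ring states by exhaustive canonicalization of all K^n tuples.

    Cross-checked against :func:`necklace_count` (Burnside's lemma); with
    K=3 states on a six-ring both give 130.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seen = {canonical_rotation(t) for t in product(range(k), repeat=ring_size)}
    count = len(seen)
    assert count == necklace_count(k, ring_size)
    return count


def state_histogram(states: Sequence[HexamerState]) -> pd.DataFrame:
    """Counts per canonical state, descending; Σcounts = number of particles."""
    counts = Counter(s.canonical for s in states)
    frame = pd.DataFrame(
        {
            "state": ["".join(map(str, s)) for s in counts],
            "count": list(counts.values()),
        }
    )
    return (
        frame.sort_values(["count", "state"], ascending=[False, True])
        .reset_index(drop=True)
    )


def max_cyclic_run(labels: Sequence[int]) -> int:
    """Longest run of equal labels on the cycle (with wraparound)."""
    t = list(labels)
    n = len(t)
    if len(set(t)) == 1:
        return n
    doubled = t + t
    best = run = 1
    for i in range(1, len(doubled)):
        run = run + 1 if doubled[i] == doubled[i - 1] else 1
        best = max(best, min(run, n))
    return best


def adjacency_stats(states: Sequence[HexamerState]) -> pd.DataFrame:
    """Per-particle ring-adjacency summary.

    Columns: particle_id, canonical state string, max equal-label run
    (cyclic), number of distinct labels, and whether at least five of the
    six N-domains share a state — the coordination statistic of interest
    for ring complexes.
    """
    rows = []
    for s in states:
        run = max_cyclic_run(s.labels)
        rows.append(
            {
                "particle_id": s.particle_id,
                "state": "".join(map(str, s.canonical)),
                "max_run": run,
                "n_distinct": len(set(s.labels)),
                "ge5_equal": run >= 5,
            }
        )
    return pd.DataFrame(rows)
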