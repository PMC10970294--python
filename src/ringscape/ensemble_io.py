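"""Containers and I/O for conformer ensembles.

A :class:`ConformerEnsemble` is N particle structures sharing one Cα
topology — the unit that flows through alignment, embedding and averaging.
On disk an ensemble is a multi-model PDB (MODEL/ENDMDL records, one chain
per monomer, Cα only) plus a particle-table TSV; a compressed ``.npz``
coordinate store is available for large runs where a text PDB would be
impractically slow.  Coordinates round-trip bitwise through the PDB path at
the format's three-decimal precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .toy_complex import DOMAIN_LABELS, HexamerTemplate, MonomerTemplate

__all__ = [
    "ConformerEnsemble",
    "EnsembleFormatError",
    "write_ensemble",
    "read_ensemble",
    "write_coordinate_store",
    "read_coordinate_store",
    "write_template_pdb",
    "write_label_sidecar",
    "read_template_pdb",
    "expand_particle_table",
]

CHAIN_IDS = "ABCDEF"


class EnsembleFormatError(ValueError):
    """Malformed ensemble file or inconsistent topology."""


@dataclass
class ConformerEnsemble:
    """N conformers over a shared Cα topology.

    coords
        (N, A, 3) array in Å, one row of atoms per particle.
    particle_ids
        length-N integer identifiers; order defines ensemble order.
    domain_labels
        (A,) per-atom domain labels (N/D1/D2) of the shared topology.
    n_monomers
        6 for hexamer ensembles, 1 for split monomer ensembles.
    alignment
        optional per-conformer superposition report (particle_id, rmsd, ...),
        attached by :func:`ringscape.superpose.align_ensemble`.
    """

    coords: np.ndarray
    particle_ids: np.ndarray
    domain_labels: np.ndarray
    n_monomers: int = 6
    alignment: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleFormatError("coords must have shape (N, A, 3)")
        self.particle_ids = np.asarray(self.particle_ids)
        if self.particle_ids.shape[0] != self.coords.shape[0]:
            raise EnsembleFormatError("particle_ids length must equal conformer count")
        if len(np.unique(self.particle_ids)) != len(self.particle_ids):
            raise EnsembleFormatError("particle_ids must be unique")
        self.domain_labels = np.asarray(self.domain_labels)
        if self.domain_labels.shape[0] != self.coords.shape[1]:
            raise EnsembleFormatError("domain_labels length must equal atom count")
        if self.coords.shape[1] % self.n_monomers:
            raise EnsembleFormatError("atom count not divisible by n_monomers")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def atoms_per_monomer(self) -> int:
        return self.n_atoms // self.n_monomers

    @property
    def monomer_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_monomers), self.atoms_per_monomer)

    def domain_mask(self, *domains: str) -> np.ndarray:
        return np.isin(self.domain_labels, list(domains))

    def index_of(self, particle_ids: Sequence[int]) -> np.ndarray:
        """Positions of the given particle ids in ensemble order."""
        order = {pid: i for i, pid in enumerate(self.particle_ids.tolist())}
        try:
            return np.array([order[p] for p in particle_ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"particle id {err.args[0]} not in ensemble") from None

    def subset(self, particle_ids: Sequence[int]) -> "ConformerEnsemble":
        idx = self.index_of(particle_ids)
        return replace(
            self,
            coords=self.coords[idx],
            particle_ids=self.particle_ids[idx],
            alignment=None,
        )

    def particle_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"particle_id": self.particle_ids, "source_model": np.arange(len(self))}
        )


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------


def _atom_array_stack(ensemble: ConformerEnsemble):
    import biotite.structure as struc

    n, a = len(ensemble), ensemble.n_atoms
    stack = struc.AtomArrayStack(n, a)
    per = ensemble.atoms_per_monomer
    stack.chain_id = np.array(
        [CHAIN_IDS[m] for m in ensemble.monomer_index], dtype="U4"
    )
    # residue numbering restarts per chain, 1-based (PDB convention)
    stack.res_id = np.tile(np.arange(1, per + 1), ensemble.n_monomers)
    stack.res_name = np.full(a, "ALA", dtype="U5")
    stack.atom_name = np.full(a, "CA", dtype="U6")
    stack.element = np.full(a, "C", dtype="U2")
    stack.hetero = np.zeros(a, dtype=bool)
    stack.set_annotation("b_factor", np.zeros(a))
    stack.coord = np.asarray(ensemble.coords, dtype=np.float32)
    return stack


def write_ensemble(
    ensemble: ConformerEnsemble,
    pdb_path: str | Path,
    table_path: str | Path | None = None,
    extra_columns: pd.DataFrame | None = None,
) -> tuple[Path, Path]:
    """Write a multi-model PDB plus particle-table TSV; returns both paths."""
    import biotite.structure.io.pdb as pdb_io

    if len(ensemble) == 0:
        raise EnsembleFormatError("cannot write an empty ensemble")
    pdb_path = Path(pdb_path)
    table_path = (
        Path(table_path)
        if table_path is not None
        else pdb_path.with_name(pdb_path.stem + "_particles.tsv")
    )
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(_atom_array_stack(ensemble))
    pdb_file.write(str(pdb_path))
    if len(ensemble) == 1:
        # keep MODEL/ENDMDL records even for a one-conformer ensemble so the
        # file stays a multi-model container
        body = pdb_path.read_text()
        if "MODEL" not in body:
            pdb_path.write_text(f"MODEL        1\n{body.rstrip()}\nENDMDL\nEND\n")

    table = ensemble.particle_table()
    if extra_columns is not None:
        table = pd.concat([table, extra_columns.reset_index(drop=True)], axis=1)
    table.to_csv(table_path, sep="\t", index=False)
    return pdb_path, table_path


def _validate_models(pdb_file, expected_monomers: int) -> None:
    """Per-model chain/atom validation used to produce descriptive errors."""
    import biotite.structure.io.pdb as pdb_io

    expected_chains = set(CHAIN_IDS[:expected_monomers])
    n_models = pdb_file.get_model_count()
    counts = []
    for model in range(1, n_models + 1):
        arr = pdb_io.get_structure(pdb_file, model=model)
        chains = set(np.unique(arr.chain_id).tolist())
        missing = expected_chains - chains
        if missing:
            raise EnsembleFormatError(
                f"model {model}: missing chain(s) {sorted(missing)}"
            )
        non_ca = np.unique(arr.atom_name[arr.atom_name != "CA"]).tolist()
        if non_ca:
            raise EnsembleFormatError(
                f"model {model}: non-Cα atoms present: {non_ca}"
            )
        counts.append(arr.array_length())
    if len(set(counts)) > 1:
        raise EnsembleFormatError(
            f"inconsistent atom counts across models: {sorted(set(counts))}"
        )


def read_ensemble(
    pdb_path: str | Path,
    table_path: str | Path | None = None,
    domain_labels: np.ndarray | None = None,
    n_monomers: int = 6,
) -> ConformerEnsemble:
    """Read a multi-model PDB (chains A→0 … F→5) back into an ensemble.

    ``domain_labels`` may be supplied from a label sidecar; otherwise atoms
    are labelled by equal thirds per chain in template order (N, D1, D2),
    which matches everything this package writes.
    """
    import biotite.structure.io.pdb as pdb_io

    pdb_path = Path(pdb_path)
    pdb_file = pdb_io.PDBFile.read(str(pdb_path))
    _validate_models(pdb_file, n_monomers)
    stack = pdb_io.get_structure(pdb_file)
    order = np.lexsort(
        (stack.res_id, np.vectorize(CHAIN_IDS.index)(stack.chain_id))
    )
    coords = np.asarray(stack.coord, dtype=float)[:, order, :]

    n, a = coords.shape[0], coords.shape[1]
    per = a // n_monomers
    if a % n_monomers:
        raise EnsembleFormatError(
            f"atom count {a} is not divisible by {n_monomers} monomers"
        )
    if domain_labels is None:
        if per % 3:
            raise EnsembleFormatError(
                "cannot infer domain labels: atoms per monomer not divisible by 3"
            )
        domain_labels = np.tile(np.repeat(np.array(DOMAIN_LABELS), per // 3), n_monomers)

    if table_path is None:
        guess = pdb_path.with_name(pdb_path.stem + "_particles.tsv")
        table_path = guess if guess.exists() else None
    if table_path is not None:
        table = pd.read_csv(table_path, sep="\t")
        if len(table) != n:
            raise EnsembleFormatError(
                f"particle table has {len(table)} rows but PDB has {n} models"
            )
        particle_ids = table["particle_id"].to_numpy()
    else:
        particle_ids = np.arange(n)

    return ConformerEnsemble(
        coords=coords,
        particle_ids=particle_ids,
        domain_labels=domain_labels,
        n_monomers=n_monomers,
    )


# ---------------------------------------------------------------------------
# Compressed coordinate store (fast path for large ensembles)
# ---------------------------------------------------------------------------


def write_coordinate_store(ensemble: ConformerEnsemble, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        coords=ensemble.coords,
        particle_ids=ensemble.particle_ids,
        domain_labels=ensemble.domain_labels,
        n_monomers=np.array([ensemble.n_monomers]),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_coordinate_store(path: str | Path) -> ConformerEnsemble:
    with np.load(path, allow_pickle=False) as data:
        return ConformerEnsemble(
            coords=data["coords"],
            particle_ids=data["particle_ids"],
            domain_labels=data["domain_labels"],
            n_monomers=int(data["n_monomers"][0]),
        )


# ---------------------------------------------------------------------------
# Template I/O
# ---------------------------------------------------------------------------


def write_template_pdb(
    template: HexamerTemplate, path: str | Path, b_factor: np.ndarray | None = None
) -> Path:
    """Write the template as a single-model PDB (chains A–F, Cα only).

    ``b_factor`` (e.g. an RMSF profile) fills the B-factor column; zero
    otherwise.
    """
    import biotite.structure.io.pdb as pdb_io

    ens = ConformerEnsemble(
        coords=template.coords[None, :, :],
        particle_ids=np.array([0]),
        domain_labels=template.labels,
        n_monomers=6,
    )
    stack = _atom_array_stack(ens)
    arr = stack[0]
    if b_factor is not None:
        arr.b_factor = np.asarray(b_factor, dtype=float)
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))
    return Path(path)


def write_label_sidecar(template: HexamerTemplate, path: str | Path) -> Path:
    per = template.atoms_per_monomer
    table = pd.DataFrame(
        {
            "chain": [CHAIN_IDS[m] for m in template.monomer_index],
            "res_id": np.tile(np.arange(1, per + 1), 6),
            "label": template.labels,
        }
    )
    table.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_template_pdb(
    pdb_path: str | Path,
    label_table: str | Path,
    hinge_point: np.ndarray,
    hinge_axis: np.ndarray,
    up_offset_deg: float,
) -> HexamerTemplate:
    """Load a Cα hexamer PDB plus a label sidecar as a template.

    See :func:`ringscape.toy_complex.load_template_from_pdb` for caveats about
    reference-orientation conventions; the hinge geometry is taken verbatim
    from the caller for monomer 0 and rotated by k·60° for the others.
    """
    labels = pd.read_csv(label_table, sep="\t")["label"].to_numpy()
    ens = read_ensemble(pdb_path, domain_labels=labels, n_monomers=6)
    if labels.shape[0] != ens.n_atoms:
        raise EnsembleFormatError("label table length does not match PDB atom count")
    per = ens.atoms_per_monomer
    from .toy_complex import rotation_about_axis

    hinge_point = np.asarray(hinge_point, dtype=float)
    hinge_axis = np.asarray(hinge_axis, dtype=float)
    hinge_axis = hinge_axis / np.linalg.norm(hinge_axis)
    monomers = []
    for k in range(6):
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 60.0 * k)
        monomers.append(
            MonomerTemplate(
                coords=ens.coords[0, k * per : (k + 1) * per],
                labels=labels[k * per : (k + 1) * per],
                hinge_point=rot @ hinge_point,
                hinge_axis=rot @ hinge_axis,
                up_offset_deg=float(up_offset_deg),
            )
        )
    return HexamerTemplate(monomers=tuple(monomers))


# ---------------------------------------------------------------------------
# Particle-table bookkeeping
# ---------------------------------------------------------------------------


def expand_particle_table(table: pd.DataFrame, ring_size: int = 6) -> pd.DataFrame:
    """Symmetry-expand a particle table: one row per (particle, ring slot).

    Metadata twin of image-domain symmetry expansion: each particle record is
    replicated once per symmetry-related orientation (6× for C6) so a single
    asymmetric unit can be analysed.  No coordinates are touched.
    """
    n = len(table)
    out = table.loc[table.index.repeat(ring_size)].reset_index(drop=True)
    out["monomer_index"] = np.tile(np.arange(ring_size), n)
    out["monomer_record_id"] = np.arange(len(out))
    return out
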