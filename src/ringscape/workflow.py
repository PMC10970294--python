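"""End-to-end orchestration: simulate → align → landscape → states → report.

A :class:`RunConfig` fully determines a run (template geometry, ensemble
spec, alignment and embedding options, discretization K); every stage writes
its tables under one run directory together with a manifest recording the
config hash, seed and library versions, so any output can be reproduced from
the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble_io import (
    ConformerEnsemble,
    read_coordinate_store,
    read_ensemble,
    write_coordinate_store,
    write_ensemble,
)
from .ensemble_sim import EnsembleSpec, GroundTruth, sample_ensemble
from .landscape import (
    cluster_average,
    embed,
    free_energy_surface,
    rmsf,
    select_region,
    two_cluster_partition,
)
from .ring_states import (
    DEFAULT_REGION_NAMES,
    adjacency_stats,
    discretize_equal_count,
    enumerate_states,
    map_to_hexamers,
    measure_hinge_angles,
    state_histogram,
)
from .superpose import align_ensemble, canonicalize_register, core_mask, split_monomers
from .toy_complex import HexamerTemplate, build_template

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_states", "write_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of a complete analysis run."""

    ensemble: EnsembleSpec = field(default_factory=lambda: EnsembleSpec(n_particles=2000))
    atoms_per_domain: int = 30
    ring_radius: float = 40.0
    up_offset_deg: float = 75.0
    alignment_mask: str = "core"  # "core" (D1+D2) or "all"
    canonicalize_register: bool = False
    embed_method: str = "pca"
    embed_dimensions: int = 10
    embed_seed: int = 0
    n_bins: int = 60
    k_regions: int = 3
    states_axis: str = "component1"  # or "angle"
    store: str = "pdb"  # "pdb" or "npz"

    def template(self) -> HexamerTemplate:
        return build_template(
            atoms_per_domain=self.atoms_per_domain,
            ring_radius=self.ring_radius,
            up_offset_deg=self.up_offset_deg,
        )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return Path(path)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        spec = data.pop("ensemble", {})
        return cls(ensemble=EnsembleSpec(**spec), **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(config: RunConfig, outdir: Path, stage: str) -> Path:
    import scipy
    import sklearn

    manifest = {
        "stage": stage,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.ensemble.seed,
        "versions": {
            "ringscape": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_simulate(
    config: RunConfig, outdir: str | Path
) -> tuple[ConformerEnsemble, GroundTruth]:
    """Generate the synthetic ensemble and write it with its ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    template = config.template()
    ensemble, truth = sample_ensemble(config.ensemble, template)
    if len(ensemble) > 0:
        if config.store == "npz":
            write_coordinate_store(ensemble, outdir / "ensemble.npz")
        else:
            write_ensemble(ensemble, outdir / "ensemble.pdb")
    truth.to_tsv(outdir / "ground_truth.tsv")
    config.to_yaml(outdir / "config.yaml")
    _write_manifest(config, outdir, "simulate")
    logger.info("simulated %d particles into %s", len(ensemble), outdir)
    return ensemble, truth


def load_run_ensemble(config: RunConfig, outdir: str | Path) -> ConformerEnsemble:
    outdir = Path(outdir)
    if (outdir / "ensemble.npz").exists():
        return read_coordinate_store(outdir / "ensemble.npz")
    return read_ensemble(outdir / "ensemble.pdb")


def _hexamer_alignment(
    config: RunConfig, ensemble: ConformerEnsemble, template: HexamerTemplate
) -> ConformerEnsemble:
    mask = None if config.alignment_mask == "all" else core_mask(template)
    aligned = align_ensemble(ensemble, template.coords, mask)
    if config.canonicalize_register:
        coords = aligned.coords.copy()
        registers = np.empty(len(aligned), dtype=int)
        for i in range(len(aligned)):
            coords[i], registers[i], _ = canonicalize_register(
                aligned.coords[i], template.coords, mask
            )
        aligned = dataclasses.replace(aligned, coords=coords)
        aligned.alignment["register"] = registers
    return aligned


def run_analyze(
    config: RunConfig,
    ensemble: ConformerEnsemble,
    outdir: str | Path,
    make_figure: bool = True,
) -> dict[str, Any]:
    """Hexamer-level landscape, free-energy surface and two-cluster report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    template = config.template()
    aligned = _hexamer_alignment(config, ensemble, template)
    embedding = embed(
        aligned, config.embed_method, config.embed_dimensions, config.embed_seed
    )
    surface = free_energy_surface(embedding, n_bins=config.n_bins)
    partition = two_cluster_partition(embedding, seed=config.embed_seed)

    clusters: list[dict[str, Any]] = []
    cluster_ids = (
        [partition["major_ids"], partition["minor_ids"]]
        if partition["n_clusters"] == 2
        else [embedding.particle_ids]
    )
    rmsf_frames = []
    for label, ids in enumerate(cluster_ids):
        selection = select_region(embedding, particle_ids=ids, label=f"cluster{label}")
        avg = cluster_average(aligned, selection)
        profile = rmsf(aligned, selection, avg)
        n_mask = aligned.domain_mask("N")
        clusters.append(
            {
                "label": label,
                "n_particles": int(len(ids)),
                "fraction": float(len(ids) / len(embedding)),
                "rmsf_n_domain_mean": float(profile[n_mask].mean()),
                "rmsf_core_mean": float(profile[~n_mask].mean()),
            }
        )
        rmsf_frames.append(
            pd.DataFrame(
                {"cluster": label, "atom": np.arange(profile.size), "rmsf": profile}
            )
        )

    embedding.to_frame().to_csv(outdir / "embedding.tsv", sep="\t", index=False)
    surface.to_frame().to_csv(outdir / "surface.tsv", sep="\t", index=False)
    pd.concat(rmsf_frames).to_csv(outdir / "rmsf.tsv", sep="\t", index=False)
    report = {
        "n_particles": int(len(embedding)),
        "n_clusters": int(partition["n_clusters"]),
        "minor_fraction": partition["minor_fraction"],
        "separation": partition["separation"],
        "clusters": clusters,
    }
    (outdir / "clusters.json").write_text(json.dumps(report, indent=2))
    _write_manifest(config, outdir, "analyze")
    if make_figure:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ax = surface.plot()
        ax.figure.savefig(outdir / "surface.png", dpi=150)
        plt.close(ax.figure)
    return report


def run_states(
    config: RunConfig, ensemble: ConformerEnsemble, outdir: str | Path
) -> dict[str, Any]:
    """Monomer landscape → equal-count labels → hexamer states → histogram."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    template = config.template()
    monomer_template = template.monomers[0]

    monomers, table = split_monomers(ensemble)
    mono_mask = core_mask(monomers)
    aligned = align_ensemble(monomers, monomer_template.coords, mono_mask)
    angles = measure_hinge_angles(aligned, monomer_template, align=False)

    if config.states_axis == "angle":
        axis_values = angles
    else:
        embedding = embed(
            aligned, config.embed_method, config.embed_dimensions, config.embed_seed
        )
        comp1 = embedding.points[:, 0]
        # orient component 1 with the physical swing so region order is
        # downward → upward (the embedding's sign is arbitrary)
        if np.corrcoef(comp1, angles)[0, 1] < 0:
            comp1 = -comp1
        axis_values = comp1
        embedding.to_frame().to_csv(
            outdir / "monomer_embedding.tsv", sep="\t", index=False
        )

    labels, boundaries = discretize_equal_count(axis_values, config.k_regions)
    states = map_to_hexamers(labels, table)
    histogram = state_histogram(states)
    adjacency = adjacency_stats(states)

    label_frame = table.copy()
    label_frame["angle_deg"] = angles
    label_frame["axis_value"] = axis_values
    label_frame["region"] = labels
    if config.k_regions == len(DEFAULT_REGION_NAMES):
        label_frame["region_name"] = np.asarray(DEFAULT_REGION_NAMES)[labels]
    label_frame.to_csv(outdir / "monomer_labels.tsv", sep="\t", index=False)
    histogram.to_csv(outdir / "state_histogram.tsv", sep="\t", index=False)
    adjacency.to_csv(outdir / "states.tsv", sep="\t", index=False)

    summary = {
        "n_monomers": int(len(monomers)),
        "n_hexamers": int(len(states)),
        "k_regions": int(config.k_regions),
        "region_sizes": np.bincount(labels, minlength=config.k_regions).tolist(),
        "boundaries": [float(b) for b in boundaries],
        "angle_range_deg": float(np.ptp(angles)),
        "observed_states": int(len(histogram)),
        "theoretical_states": int(enumerate_states(config.k_regions)),
        "fraction_ge5_equal": float(adjacency["ge5_equal"].mean()),
    }
    (outdir / "states_summary.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(config, outdir, "states")
    return summary


def write_report(outdir: str | Path) -> Path:
    """Aggregate the run directory's JSON/TSV outputs into one markdown file."""
    outdir = Path(outdir)
    lines = ["# ringscape run report", ""]
    for name in ("manifest_simulate", "manifest_analyze", "manifest_states"):
        path = outdir / f"{name}.json"
        if path.exists():
            manifest = json.loads(path.read_text())
            lines += [
                f"- {manifest['stage']}: config {manifest['config_sha256']}, "
                f"seed {manifest['seed']}, ringscape {manifest['versions']['ringscape']}"
            ]
    clusters = outdir / "clusters.json"
    if clusters.exists():
        report = json.loads(clusters.read_text())
        lines += [
            "",
            "## Hexamer landscape",
            f"- particles: {report['n_particles']}",
            f"- clusters declared: {report['n_clusters']} "
            f"(separation {report['separation']:.2f})",
            f"- minor-cluster fraction: {100 * report['minor_fraction']:.2f}%",
        ]
        for c in report["clusters"]:
            lines.append(
                f"- cluster {c['label']}: {c['n_particles']} particles, "
                f"RMSF N-domain {c['rmsf_n_domain_mean']:.2f} Å vs core "
                f"{c['rmsf_core_mean']:.2f} Å"
            )
    summary = outdir / "states_summary.json"
    if summary.exists():
        s = json.loads(summary.read_text())
        lines += [
            "",
            "## Monomer states",
            f"- monomers: {s['n_monomers']} from {s['n_hexamers']} hexamers",
            f"- equal-count regions: {s['region_sizes']} "
            f"(boundaries {[round(b, 2) for b in s['boundaries']]})",
            f"- hinge-angle range: {s['angle_range_deg']:.1f} deg",
            f"- ring states observed/possible: {s['observed_states']}"
            f"/{s['theoretical_states']}",
            f"- hexamers with >=5 equal N-domain states: "
            f"{100 * s['fraction_ge5_equal']:.1f}%",
        ]
    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
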