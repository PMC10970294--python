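"""Embedding, free-energy surface, region selection, averages and RMSF."""

import numpy as np
import pytest
from scipy.stats import binom, spearmanr

from ringscape import EnsembleSpec, build_template, embed, free_energy_surface, rmsf
from ringscape.ensemble_io import ConformerEnsemble
from ringscape.ensemble_sim import sample_ensemble
from ringscape.landscape import (
    Embedding,
    cluster_average,
    select_region,
    suggest_density_peaks,
    two_cluster_partition,
)
from ringscape.superpose import align_ensemble, core_mask
from ringscape.toy_complex import swing_n_domain


def _manual_embedding(points):
    points = np.asarray(points, dtype=float)
    return Embedding(
        points=points,
        method="pca",
        particle_ids=np.arange(points.shape[0]),
    )


class TestEmbed:
    def test_identical_conformers_coincide(self, small_template):
        coords = np.repeat(small_template.coords[None], 20, axis=0)
        ensemble = ConformerEnsemble(
            coords=coords,
            particle_ids=np.arange(20),
            domain_labels=small_template.labels,
        )
        aligned = align_ensemble(ensemble, small_template.coords)
        embedding = embed(aligned, "pca", n_dimensions=2)
        spread = np.abs(embedding.points - embedding.points[0]).max()
        assert spread < 1e-9

    def test_single_hinge_sweep_maps_to_first_component(self, default_template):
        angles = np.linspace(-30.0, 30.0, 500)
        coords = np.stack(
            [swing_n_domain(default_template, 0, a) for a in angles]
        )
        ensemble = ConformerEnsemble(
            coords=coords,
            particle_ids=np.arange(500),
            domain_labels=default_template.labels,
        )
        aligned = align_ensemble(
            ensemble, default_template.coords, core_mask(default_template)
        )
        embedding = embed(aligned, "pca", n_dimensions=2)
        rho = spearmanr(embedding.points[:, 0], angles).statistic
        assert abs(rho) >= 0.99

    def test_split_subpopulation_recovered_from_embedding(self, pipeline_run):
        embedding = embed(pipeline_run["aligned"], "pca", n_dimensions=10, seed=0)
        partition = two_cluster_partition(embedding)
        planted = pipeline_run["truth"].is_split
        predicted = partition["labels"].astype(bool)
        agreement = max((predicted == planted).mean(), (~predicted == planted).mean())
        assert partition["n_clusters"] == 2
        assert agreement >= 0.99

    def test_minor_fraction_within_binomial_interval(self, pipeline_run):
        embedding = embed(pipeline_run["aligned"], "pca", n_dimensions=10, seed=0)
        partition = two_cluster_partition(embedding)
        n = len(embedding)
        lo = binom.ppf(0.005, n, 0.02) / n
        hi = binom.ppf(0.995, n, 0.02) / n
        assert lo <= partition["minor_fraction"] <= hi

    def test_unaligned_ensemble_warns(self, small_template):
        spec = EnsembleSpec(n_particles=30, seed=0)
        ensemble, _ = sample_ensemble(spec, small_template)
        with pytest.warns(UserWarning, match="alignment"):
            embed(ensemble, "pca", n_dimensions=2)

    def test_too_few_conformers_raise(self, small_template):
        spec = EnsembleSpec(n_particles=5, seed=0)
        ensemble, _ = sample_ensemble(spec, small_template)
        with pytest.raises(ValueError, match="n_dimensions"):
            embed(ensemble, "pca", n_dimensions=10)

    def test_pca_invariant_to_conformer_order(self, small_template, rng):
        spec = EnsembleSpec(n_particles=60, seed=21)
        ensemble, _ = sample_ensemble(spec, small_template)
        aligned = align_ensemble(ensemble, small_template.coords)
        base = embed(aligned, "pca", n_dimensions=3)
        perm = rng.permutation(60)
        shuffled = ConformerEnsemble(
            coords=aligned.coords[perm],
            particle_ids=aligned.particle_ids[perm],
            domain_labels=aligned.domain_labels,
            alignment=aligned.alignment,
        )
        other = embed(shuffled, "pca", n_dimensions=3)
        for c in range(3):
            col, ref = other.points[:, c], base.points[perm, c]
            assert np.allclose(col, ref, atol=1e-8) or np.allclose(
                col, -ref, atol=1e-8
            )

    def test_umap_is_deterministic_at_fixed_seed(self, small_template):
        spec = EnsembleSpec(n_particles=150, seed=2)
        ensemble, _ = sample_ensemble(spec, small_template)
        aligned = align_ensemble(ensemble, small_template.coords)
        a = embed(aligned, "umap", n_dimensions=2, seed=7)
        b = embed(aligned, "umap", n_dimensions=2, seed=7)
        assert np.array_equal(a.points, b.points)


class TestFreeEnergySurface:
    def test_single_occupied_bin_is_the_zero_of_energy(self):
        embedding = _manual_embedding(np.zeros((50, 2)))
        surface = free_energy_surface(embedding, n_bins=5)
        assert surface.occupied.sum() == 1
        assert np.nanmin(surface.dg_kt) == 0.0

    def test_half_populated_bin_costs_ln2(self):
        points = np.concatenate(
            [np.tile([0.5, 0.5], (100, 1)), np.tile([9.5, 9.5], (50, 1))]
        )
        embedding = _manual_embedding(points)
        surface = free_energy_surface(embedding, n_bins=2)
        dg = surface.dg_kt[surface.occupied]
        assert sorted(np.round(dg, 4)) == [0.0, pytest.approx(np.log(2.0), abs=1e-4)]

    def test_conservation_and_zero_minimum(self, pipeline_run):
        embedding = embed(pipeline_run["aligned"], "pca", n_dimensions=4, seed=0)
        surface = free_energy_surface(embedding, n_bins=40)
        assert surface.counts.sum() == len(embedding)
        assert np.nanmin(surface.dg_kt) == 0.0
        assert np.isnan(surface.dg_kt[~surface.occupied]).all()

    def test_density_peak_suggestion_finds_the_mode(self):
        rng = np.random.default_rng(0)
        points = np.concatenate([rng.normal(0, 0.5, (900, 2)), rng.normal(6, 0.5, (100, 2))])
        surface = free_energy_surface(_manual_embedding(points), n_bins=30)
        peaks = suggest_density_peaks(surface, min_count=5)
        assert np.hypot(peaks.iloc[0]["x_center"], peaks.iloc[0]["y_center"]) < 1.0


class TestRegions:
    def test_whole_space_selects_everything(self):
        embedding = _manual_embedding(np.random.default_rng(0).normal(size=(40, 2)))
        sel = select_region(embedding, bounds={0: (-10, 10), 1: (-10, 10)})
        assert len(sel) == 40

    def test_point_sized_bounds_select_one(self):
        pts = np.arange(20, dtype=float).reshape(10, 2)
        embedding = _manual_embedding(pts)
        sel = select_region(embedding, bounds={0: (3.9, 4.1), 1: (4.9, 5.1)})
        assert sel.particle_ids.tolist() == [2]

    def test_empty_selection_echoes_bounds(self):
        embedding = _manual_embedding(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="bounds"):
            select_region(embedding, bounds={0: (100.0, 101.0)})

    def test_rectangle_over_coherent_split_cluster_has_high_recall(
        self, default_template
    ):
        # register fixed: the split subpopulation is a coherent cluster and
        # an axis-aligned box in the landscape should capture it
        spec = EnsembleSpec(n_particles=1500, randomize_register=False, seed=6)
        ensemble, truth = sample_ensemble(spec, default_template)
        aligned = align_ensemble(
            ensemble, default_template.coords, core_mask(default_template)
        )
        embedding = embed(aligned, "pca", n_dimensions=10, seed=0)
        planted = truth.table.loc[truth.is_split, "particle_id"].to_numpy()
        idx = embedding.particle_ids.searchsorted(planted)
        box = {
            axis: (
                embedding.points[idx, axis].min() - 1.0,
                embedding.points[idx, axis].max() + 1.0,
            )
            for axis in range(2)
        }
        sel = select_region(embedding, bounds=box)
        recall = np.isin(planted, sel.particle_ids).mean()
        assert recall >= 0.95

    def test_union_and_intersection_compose(self):
        embedding = _manual_embedding(np.arange(10, dtype=float).reshape(5, 2))
        a = select_region(embedding, particle_ids=[0, 1, 2], label="a")
        b = select_region(embedding, particle_ids=[2, 3], label="b")
        assert a.union(b).particle_ids.tolist() == [0, 1, 2, 3]
        assert a.intersection(b).particle_ids.tolist() == [2]


class TestAveragesAndRmsf:
    def _noise_ensemble(self, small_template, n, sigma, seed=0):
        rng = np.random.default_rng(seed)
        base = small_template.monomers[0].coords
        coords = base[None] + rng.normal(0, sigma, (n, *base.shape))
        return ConformerEnsemble(
            coords=coords,
            particle_ids=np.arange(n),
            domain_labels=small_template.monomers[0].labels,
            n_monomers=1,
        )

    def test_average_of_one_is_itself(self, pipeline_run):
        ens = pipeline_run["aligned"]
        sel = select_region(
            embed(ens, "pca", 2, 0), particle_ids=[ens.particle_ids[3]]
        )
        avg = cluster_average(ens, sel)
        assert np.array_equal(avg, ens.coords[3])

    def test_average_of_two_is_the_midpoint(self, small_template):
        ens = self._noise_ensemble(small_template, 2, 1.0)
        sel = select_region(_manual_embedding(np.zeros((2, 2))), particle_ids=[0, 1])
        avg = cluster_average(ens, sel)
        assert np.allclose(avg, ens.coords.mean(axis=0))

    def test_average_matches_brute_force_accumulation(self, small_template):
        ens = self._noise_ensemble(small_template, 100, 2.0, seed=3)
        sel = select_region(
            _manual_embedding(np.zeros((100, 2))), particle_ids=list(range(100))
        )
        avg = cluster_average(ens, sel)
        brute = np.zeros_like(avg)
        for i in range(100):
            brute += ens.coords[i]
        brute /= 100
        assert np.allclose(avg, brute, atol=1e-10)

    def test_identical_copies_have_zero_rmsf(self, small_template):
        ens = self._noise_ensemble(small_template, 10, 0.0)
        sel = select_region(
            _manual_embedding(np.zeros((10, 2))), particle_ids=list(range(10))
        )
        assert rmsf(ens, sel).max() < 1e-12

    def test_rmsf_of_isotropic_noise_is_sigma_root3(self, small_template):
        ens = self._noise_ensemble(small_template, 10_000, 1.0, seed=11)
        sel = select_region(
            _manual_embedding(np.zeros((10_000, 2))),
            particle_ids=list(range(10_000)),
        )
        profile = rmsf(ens, sel, reference=small_template.monomers[0].coords)
        assert profile.mean() == pytest.approx(np.sqrt(3.0), rel=0.02)

    def test_n_domain_fluctuates_more_than_core(self, pipeline_run):
        # lever-arm construction: swing variability concentrates in the
        # N-domains while the D1/D2 rings stay rigid
        ens = pipeline_run["aligned"]
        truth = pipeline_run["truth"]
        main_ids = truth.table.loc[~truth.is_split, "particle_id"].to_numpy()
        sel = select_region(
            embed(ens, "pca", 2, 0), particle_ids=main_ids, label="main"
        )
        profile = rmsf(ens, sel)
        n_mask = ens.domain_mask("N")
        assert profile[n_mask].min() > profile[~n_mask].max()
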