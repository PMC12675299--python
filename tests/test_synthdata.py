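"""Synthetic-data generator tests: geometry, states, counts, intensities, I/O."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plaquemap import simulate_dataset, write_dataset, read_dataset
from plaquemap.synthdata import (
    ConfigurationError,
    SimulationConfig,
    generate_plaques,
    _stage_rngs,
)


def _cfg(**kw):
    base = dict(seed=0, n_cells=500, n_genes=100, n_plaques=8, region=(0, 0, 500, 500))
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"region": (0, 0, 0, 100)},
            {"frac_states": (0.5, 0.5, 0.5)},
            {"nb_dispersion": 0.0},
            {"proximity_enrichment": 0.5},
            {"n_genes": 10},
            {"plaque_radius_range": (20.0, 10.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            _cfg(**kw)

    def test_config_hash_changes_iff_config_changes(self):
        a, b, c = _cfg(), _cfg(), _cfg(n_plaques=9)
        assert a.config_hash() == b.config_hash()
        assert a.config_hash() != c.config_hash()


class TestGeneratePlaques:
    def test_zero_plaques_vacuous(self):
        cfg = _cfg(n_plaques=0)
        assert generate_plaques(cfg, _stage_rngs(0)["plaques"]) == []

    def test_vertices_within_radius_of_centre_and_inside_region(self):
        cfg = _cfg(n_plaques=5, plaque_radius_range=(10.0, 20.0))
        plaques = generate_plaques(cfg, _stage_rngs(1)["plaques"])
        assert [p.plaque_id for p in plaques] == [1, 2, 3, 4, 5]
        xmin, ymin, xmax, ymax = cfg.region
        for p in plaques:
            centre = p.perimeter.mean(axis=0)
            radii = np.hypot(*(p.perimeter - centre).T)
            assert (radii <= 20.0 + 20.0).all()  # vertex within range of the sampled centre
            assert (p.perimeter[:, 0] >= xmin).all() and (p.perimeter[:, 0] <= xmax).all()
            assert (p.perimeter[:, 1] >= ymin).all() and (p.perimeter[:, 1] <= ymax).all()
            assert p.area_um2 > 0

    def test_same_seed_identical_vertices(self):
        cfg = _cfg(n_plaques=6)
        a = generate_plaques(cfg, _stage_rngs(3)["plaques"])
        b = generate_plaques(cfg, _stage_rngs(3)["plaques"])
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.perimeter, pb.perimeter)


class TestAssignStates:
    def test_all_homeostatic_when_frac_is_one(self):
        ds = simulate_dataset(_cfg(frac_states=(1.0, 0.0, 0.0), dropout_cells={}))
        assert (ds.truth.cell_state == "homeostatic").all()

    def test_null_enrichment_states_independent_of_proximity(self):
        """With enrichment 1, state and proximity are independent (pooled chi-square)."""
        table = np.zeros((2, 3))
        for seed in range(10):
            ds = simulate_dataset(_cfg(seed=seed, n_cells=800, proximity_enrichment=1.0, dropout_cells={}))
            df = pd.DataFrame({"near": ds.truth.true_proximity_label == "plaque_associated",
                               "state": ds.truth.cell_state})
            ct = pd.crosstab(df["near"], df["state"]).reindex(
                index=[False, True], columns=["homeostatic", "DAM", "lymphoid_DAM"], fill_value=0
            )
            table += ct.to_numpy()
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_enrichment_raises_lymphoid_fraction_near_plaques(self):
        ds = simulate_dataset(_cfg(seed=4, n_cells=2000, proximity_enrichment=10.0, dropout_cells={}))
        near = ds.truth.true_proximity_label == "plaque_associated"
        lymph = ds.truth.cell_state == "lymphoid_DAM"
        assert lymph[near].mean() > lymph[~near].mean()

    def test_marginal_state_fractions_converge(self):
        """Empirical fractions approach frac_states within 3 binomial SE."""
        frac = (0.65, 0.25, 0.10)
        ds = simulate_dataset(_cfg(seed=8, n_cells=4000, frac_states=frac,
                                   proximity_enrichment=1.0, dropout_cells={}))
        obs = ds.truth.cell_state.value_counts(normalize=True)
        for state, f in zip(("homeostatic", "DAM", "lymphoid_DAM"), frac):
            se = np.sqrt(f * (1 - f) / 4000)
            assert abs(obs.get(state, 0.0) - f) <= 3 * se


class TestGenerateCounts:
    def test_null_effects_pooled_mean_near_baseline(self):
        """With no effects, per-gene pooled means sit within 3 SE of the NB baseline."""
        cfg = _cfg(seed=5, n_cells=2000, effect_log2fc=(0, 0, 0), gene_baseline_sigma=0.0,
                   sample_depth=(1.0, 1.0), dropout_cells={})
        ds = simulate_dataset(cfg)
        X = ds.counts.values.to_numpy()
        mu = cfg.nb_mean_baseline
        var = mu + mu**2 / cfg.nb_dispersion
        se = np.sqrt(var / X.shape[0])
        frac_outside = (np.abs(X.mean(axis=0) - mu) > 3 * se).mean()
        assert frac_outside < 0.05

    def test_program_effect_multiplies_group_mean_by_four(self):
        cfg = _cfg(seed=6, n_cells=3000, frac_states=(0.5, 0.5, 0.0), proximity_enrichment=1.0,
                   effect_log2fc=(0.0, 2.0, 0.0), sample_depth=(1.0, 1.0), dropout_cells={})
        ds = simulate_dataset(cfg)
        g = ds.truth.program_genes["DAM"][0]
        dam = ds.truth.cell_state == "DAM"
        col = ds.counts.values[g]
        ratio = col[dam.to_numpy()].mean() / col[(~dam).to_numpy()].mean()
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_large_dispersion_approaches_poisson_variance(self):
        cfg = _cfg(seed=7, n_cells=4000, nb_dispersion=1e6, effect_log2fc=(0, 0, 0),
                   gene_baseline_sigma=0.0, sample_depth=(1.0, 1.0), dropout_cells={})
        ds = simulate_dataset(cfg)
        X = ds.counts.values.to_numpy()
        ratios = X.var(axis=0) / X.mean(axis=0)  # Poisson limit: 1
        assert np.median(ratios) == pytest.approx(1.0, abs=0.1)

    def test_sample_depth_scales_totals(self):
        ds = simulate_dataset(_cfg(seed=9, n_cells=2000, dropout_cells={}))
        totals = ds.counts.total_counts()
        by_sample = totals.groupby(ds.cells.set_index("cell_id")["sample_id"]).mean()
        assert by_sample["sample_2"] / by_sample["sample_1"] == pytest.approx(1.3, rel=0.05)


class TestGenerateIntensities:
    def test_component_follows_state_mapping(self, small_dataset):
        comp = small_dataset.truth.intensity_component
        state = small_dataset.truth.cell_state
        assert (comp[state == "lymphoid_DAM"] == 0).all()
        assert (comp[state == "homeostatic"] == 1).all()
        assert (comp[state == "DAM"] == 2).all()

    def test_adjacent_component_mean_ratio(self):
        """Sampled component means honour the configured lognormal ratio."""
        mixture = ((np.log(100.0), 0.05, 0.5), (np.log(125.0), 0.05, 0.3), (np.log(156.25), 0.05, 0.2))
        cfg = _cfg(seed=10, n_cells=5000, frac_states=(0.3, 0.2, 0.5),
                   intensity_mixture=mixture, dropout_cells={})
        ds = simulate_dataset(cfg)
        comp = ds.truth.intensity_component
        vals = ds.intensities.set_index("nucleus_id")["mean_intensity"]
        m_low = vals[comp[comp == 0].index].mean()
        m_med = vals[comp[comp == 1].index].mean()
        assert m_med / m_low == pytest.approx(1.25, rel=0.02)

    def test_same_seed_identical_intensities(self):
        a = simulate_dataset(_cfg(seed=11))
        b = simulate_dataset(_cfg(seed=11))
        pd.testing.assert_frame_equal(a.intensities, b.intensities)


class TestDeterminismAndIO:
    def test_identical_config_and_seed_byte_identical_on_disk(self, tmp_path):
        ds1 = simulate_dataset(_cfg(seed=21))
        ds2 = simulate_dataset(_cfg(seed=21))
        m1 = write_dataset(ds1, tmp_path / "a")
        m2 = write_dataset(ds2, tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_round_trip_reproduces_dataset(self, tmp_path):
        ds = simulate_dataset(_cfg(seed=22))
        write_dataset(ds, tmp_path / "d")
        back = read_dataset(tmp_path / "d")
        pd.testing.assert_frame_equal(ds.counts.values, back.counts.values, check_dtype=False)
        pd.testing.assert_frame_equal(ds.cells, back.cells)
        pd.testing.assert_frame_equal(ds.intensities, back.intensities)
        pd.testing.assert_series_equal(ds.truth.cell_state, back.truth.cell_state, check_names=False)
        pd.testing.assert_series_equal(ds.truth.gene_baseline, back.truth.gene_baseline, check_names=False)
        for a, b in zip(ds.plaques, back.plaques):
            np.testing.assert_array_equal(a.perimeter, b.perimeter)
        np.testing.assert_array_equal(ds.region_polygon.vertices, back.region_polygon.vertices)
        # and writing the round-tripped dataset reproduces the same bytes
        m1 = write_dataset(ds, tmp_path / "e")
        m2 = write_dataset(back, tmp_path / "f")
        assert m1["files"] == m2["files"]

    def test_mtx_nonzero_count_matches_matrix(self, tmp_path):
        ds = simulate_dataset(_cfg(seed=23))
        write_dataset(ds, tmp_path / "d")
        header_free = [
            ln for ln in (tmp_path / "d" / "counts.mtx").read_text().splitlines() if not ln.startswith("%")
        ]
        n_rows, n_cols, nnz = map(int, header_free[0].split())
        assert (n_rows, n_cols) == (ds.counts.n_cells, ds.counts.n_genes)
        assert nnz == int((ds.counts.values.to_numpy() != 0).sum())

    def test_manifest_hash_tracks_config(self, tmp_path):
        m1 = write_dataset(simulate_dataset(_cfg(seed=24)), tmp_path / "a")
        m2 = write_dataset(simulate_dataset(_cfg(seed=24, n_plaques=9)), tmp_path / "b")
        assert m1["config_sha256"] != m2["config_sha256"]

    def test_centroids_inside_region_and_counts_aligned(self, small_dataset):
        ds = small_dataset
        xmin, ymin, xmax, ymax = ds.config.region
        assert ds.cells["x_um"].between(xmin, xmax).all()
        assert ds.cells["y_um"].between(ymin, ymax).all()
        assert list(ds.counts.cell_ids) == list(ds.cells["cell_id"])
        assert (ds.counts.values.to_numpy() >= 0).all()

    def test_program_gene_sets_disjoint(self, small_dataset):
        sets = [set(g) for g in small_dataset.truth.program_genes.values()]
        assert sets[0] & sets[1] == set() and sets[0] & sets[2] == set() and sets[1] & sets[2] == set()
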