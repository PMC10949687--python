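"""Synthetic generators: determinism, exact perturbation counts, fidelity."""

import numpy as np
import pytest

from nichespan import (
    Band,
    Disc,
    DomainSpec,
    SimulationConfig,
    inject_dropout,
    inject_label_noise,
    simulate_expression,
    simulate_multislice,
    simulate_slice,
)
from nichespan.embedding import estimate_grid_unit
from nichespan.scenarios import banded_slices, tls_multislice


def simple_config(seed=0, **kw):
    return SimulationConfig(
        cell_types=("A", "B"),
        domains=(
            DomainSpec("top", np.array([0.8, 0.2]), Band(0, 50, 0, 20), 100),
            DomainSpec("bottom", np.array([0.1, 0.9]), Band(0, 50, 40, 60), 100),
        ),
        seed=seed,
        **kw,
    )


class TestSimulateSlice:
    def test_same_seed_bitwise_identical(self):
        s1, t1 = simulate_slice(simple_config(seed=5))
        s2, t2 = simulate_slice(simple_config(seed=5))
        np.testing.assert_array_equal(s1.coords, s2.coords)
        np.testing.assert_array_equal(s1.annotation.values, s2.annotation.values)
        np.testing.assert_array_equal(t1, t2)

    def test_different_seed_differs(self):
        s1, _ = simulate_slice(simple_config(seed=5))
        s2, _ = simulate_slice(simple_config(seed=6))
        assert not np.array_equal(s1.coords, s2.coords)

    def test_coords_within_regions_and_truth_matches(self):
        s, truth = simulate_slice(simple_config(seed=1))
        top = truth == "top"
        assert np.all(s.coords[top, 1] <= 20) and np.all(s.coords[~top, 1] >= 40)

    def test_type_frequencies_converge_to_composition(self):
        cfg = SimulationConfig(
            cell_types=("A", "B", "C"),
            domains=(
                DomainSpec("d", np.array([0.5, 0.3, 0.2]), Band(0, 100, 0, 100), 500),
            ),
            seed=9,
        )
        s, _ = simulate_slice(cfg)
        freq = s.annotation.values.mean(axis=0)
        se = np.sqrt(np.array([0.5, 0.3, 0.2]) * np.array([0.5, 0.7, 0.8]) / 500)
        assert np.all(np.abs(freq - [0.5, 0.3, 0.2]) < 3 * se)

    def test_overlapping_regions_error(self):
        cfg = SimulationConfig(
            cell_types=("A", "B"),
            domains=(
                DomainSpec("x", np.array([1.0, 0]), Band(0, 10, 0, 10), 10),
                DomainSpec("y", np.array([0, 1.0]), Disc(5, 5, 3), 10),
            ),
            seed=0,
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_slice(cfg)

    def test_spot_mode_grid_unit_equals_spacing(self):
        cfg = SimulationConfig(
            cell_types=("A", "B"),
            domains=(
                DomainSpec("d", np.array([0.5, 0.5]), Band(0, 40, 0, 40), 2000),
            ),
            seed=3,
            resolution="spot",
            grid_spacing=2.0,
        )
        s, truth = simulate_slice(cfg)
        assert s.resolution == "spot"
        assert estimate_grid_unit(s.coords) == pytest.approx(2.0)
        assert len(truth) == s.n_obs

    def test_spot_mode_dirichlet_jitter_stays_simplex(self):
        cfg = SimulationConfig(
            cell_types=("A", "B", "C"),
            domains=(
                DomainSpec("d", np.array([0.5, 0.3, 0.2]), Band(0, 40, 0, 40), 2000),
            ),
            seed=3,
            resolution="spot",
            grid_spacing=2.0,
            dirichlet_concentration=100.0,
        )
        s, _ = simulate_slice(cfg)
        np.testing.assert_allclose(s.annotation.values.sum(axis=1), 1.0, atol=1e-9)


class TestSimulateMultislice:
    def test_rare_domain_presence_subset(self):
        mset, truths = simulate_multislice(tls_multislice(seed=8))
        present = [int("tls" in truths[sid]) for sid in mset.slice_ids]
        assert present == [1, 1, 1, 1, 0]

    def test_identical_configs_give_similar_compositions(self):
        mset, _ = simulate_multislice(banded_slices(2, seed=5, n_slices=3))
        comps = np.array([s.annotation.values.mean(axis=0) for s in mset])
        assert np.abs(comps - comps.mean(axis=0)).max() < 0.1

    def test_rare_domain_without_slices_errors(self):
        with pytest.raises(ValueError, match="rare_domain_in"):
            SimulationConfig(
                cell_types=("A", "B"),
                domains=(DomainSpec("d", np.array([1.0, 0]), Band(0, 1, 0, 1), 5),),
                seed=0,
                rare_domain=DomainSpec("r", np.array([0, 1.0]), Disc(9, 9, 1), 5),
            )

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        raw = {
            "cell_types": ["A", "B"],
            "seed": 4,
            "n_slices": 2,
            "domains": [
                {
                    "name": "top",
                    "composition": {"A": 0.8, "B": 0.2},
                    "region": {"kind": "band", "x_min": 0, "x_max": 50,
                               "y_min": 0, "y_max": 20},
                    "n_obs": 30,
                },
                {
                    "name": "focus",
                    "composition": [0.1, 0.9],
                    "region": {"kind": "disc", "cx": 25, "cy": 60, "radius": 5},
                    "n_obs": 20,
                },
            ],
        }
        path = tmp_path / "sim.yaml"
        path.write_text(yaml.safe_dump(raw))
        config = SimulationConfig.from_yaml(path)
        mset, truths = simulate_multislice(config)
        assert len(mset) == 2 and mset.n_obs == 100


class TestPipelineNoiseResponse:
    def test_recovery_degrades_as_label_noise_rises(self):
        """Clean detection is near-perfect and mean ARI is non-increasing
        across label-noise rates 0 -> 0.1 -> 0.3 -> 0.5."""
        from nichespan import ari, detect_domains

        means = []
        for noise in (0.0, 0.1, 0.3, 0.5):
            aris = []
            for s in range(5):
                mset, truths = simulate_multislice(
                    banded_slices(2, seed=s, label_noise_rate=noise)
                )
                a, _, _ = detect_domains(mset, n_domains=2, k=30)
                aris.append(ari(a.labels, truths["slice_1"]))
            means.append(np.mean(aris))
        assert means[0] >= 0.95
        assert all(means[i + 1] <= means[i] + 1e-9 for i in range(3))


class TestLabelNoise:
    def test_rate_zero_is_identity(self):
        s, _ = simulate_slice(simple_config(seed=2))
        out = inject_label_noise(s, 0.0, seed=1)
        np.testing.assert_array_equal(out.annotation.values, s.annotation.values)

    def test_rate_one_changes_every_label(self):
        s, _ = simulate_slice(simple_config(seed=2))
        out = inject_label_noise(s, 1.0, seed=1)
        assert np.all(out.annotation.labels() != s.annotation.labels())

    def test_exact_count_changed(self):
        cfg = SimulationConfig(
            cell_types=("A", "B", "C"),
            domains=(
                DomainSpec("d", np.array([0.5, 0.3, 0.2]), Band(0, 100, 0, 100), 1000),
            ),
            seed=7,
        )
        s, _ = simulate_slice(cfg)
        out = inject_label_noise(s, 0.1, seed=3)
        changed = int(np.sum(out.annotation.labels() != s.annotation.labels()))
        assert changed == 100

    def test_spot_mode_rejected(self):
        cfg = simple_config(seed=2)
        cfg = SimulationConfig(
            cell_types=cfg.cell_types, domains=cfg.domains, seed=2,
            resolution="spot", grid_spacing=5.0,
        )
        s, _ = simulate_slice(cfg)
        with pytest.raises(ValueError, match="single-cell"):
            inject_label_noise(s, 0.1, seed=0)


class TestDropout:
    def test_rate_zero_and_one(self, rng):
        m = rng.poisson(2.0, size=(20, 30)).astype(float)
        np.testing.assert_array_equal(inject_dropout(m, 0.0, seed=1), m)
        out = inject_dropout(m, 1.0, seed=1)
        assert np.all(out == 0)

    def test_exact_nonzero_count_zeroed(self, rng):
        m = np.zeros(2000)
        m[rng.choice(2000, size=1000, replace=False)] = 1.0
        m = m.reshape(40, 50)
        out = inject_dropout(m, 0.3, seed=5)
        assert int((m != 0).sum() - (out != 0).sum()) == 300
        # only nonzero entries were touched
        assert np.all(m[out != 0] != 0)

    def test_deterministic_under_seed(self, rng):
        m = rng.poisson(1.0, size=(30, 30)).astype(float)
        np.testing.assert_array_equal(
            inject_dropout(m, 0.5, seed=9), inject_dropout(m, 0.5, seed=9)
        )

    def test_all_zero_matrix_warns_identity(self):
        with pytest.warns(UserWarning, match="no nonzero"):
            out = inject_dropout(np.zeros((3, 3)), 0.5, seed=0)
        assert np.all(out == 0)

    def test_expression_utility_feeds_dropout(self):
        s, _ = simulate_slice(simple_config(seed=2))
        expr = simulate_expression(s, seed=1)
        assert expr.shape[0] == s.n_obs
        nnz = int((expr != 0).sum())
        out = inject_dropout(expr, 0.5, seed=2)
        assert int((out != 0).sum()) == nnz - int(round(0.5 * nnz))
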