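"""Differential-expression engine, spline smoothing, and kinetic modules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import trichodyn as td
from trichodyn.synthgen import kinetic_curve

from conftest import bh_definitional, wilcoxon_enum_p


class TestDeTest:
    def test_identical_groups_give_p_one_and_zero_lfc(self):
        a = [0.5, 1.0, 1.5, 0.2]
        p, lfc = td.de_test(a, list(a))
        assert p == pytest.approx(1.0)
        assert lfc == pytest.approx(0.0)

    def test_extreme_separation_exact_enumeration_value(self):
        # A occupies the top four ranks of eight: p = 2 / C(8, 4) = 2/70
        p, _ = td.de_test([1.2, 0.8, 1.5, 2.0], [0.1, 0.0, 0.3, 0.2])
        assert p == pytest.approx(2 / 70)

    def test_lfc_matches_stated_formula(self):
        a = np.full(6, np.log(2.0))
        b = np.zeros(5)
        _, lfc = td.de_test(a, b)
        assert lfc == pytest.approx(np.log(2.0))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            td.de_test([], [1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_exact_path_equals_enumeration_oracle(self, data):
        n_a = data.draw(st.integers(1, 7))
        n_b = data.draw(st.integers(1, 7))
        vals = data.draw(st.lists(
            st.floats(-10, 10, allow_nan=False),
            min_size=n_a + n_b, max_size=n_a + n_b, unique=True,
        ))
        a, b = vals[:n_a], vals[n_a:]
        p, _ = td.de_test(a, b)
        assert p == pytest.approx(wilcoxon_enum_p(a, b), abs=1e-12)


class TestBhAdjust:
    @pytest.mark.parametrize("p_in, expected", [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.04, 0.03], [0.015, 0.04, 0.04]),
    ])
    def test_hand_computed_examples(self, p_in, expected):
        np.testing.assert_allclose(td.bh_adjust(p_in), expected, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            td.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            td.bh_adjust([-0.1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_properties_and_definitional_oracle(self, p):
        q = td.bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        np.testing.assert_allclose(q, bh_definitional(p), atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(td.bh_adjust(p)[perm],
                                   td.bh_adjust(p[perm]), atol=1e-12)


@pytest.fixture(scope="module")
def one_type_sim():
    cfg = td.SimConfig(
        n_genes=500, n_cell_types=1, cells_per_condition=50,
        genes_per_module={1: 20, 2: 20, 3: 20, 4: 20},
        markers_per_type=0, seed=21,
    )
    matrix, meta, truth = td.simulate_dataset(cfg)
    return matrix, meta, truth, td.normalize_log(matrix)


class TestFindTimeDegs:
    def test_constant_gene_excluded_and_thresholds_strict(self):
        rng = np.random.default_rng(4)
        n_cells = 120
        meta = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "group": "treated", "cell_type": "CT1",
            "day": np.repeat([0, 3, 9, 15], n_cells // 4),
        })
        lognorm = np.vstack([
            np.full(n_cells, 0.7),                      # constant
            rng.normal(1.0, 0.05, n_cells),             # no day effect
        ])
        genes, records, _ = td.find_time_degs(
            lognorm, meta, ["const", "flat"], cell_type="CT1", group="treated")
        assert genes == []

    def test_threshold_boundary_excludes_lfc_at_exactly_quarter(self):
        # significant rank separation but |avg_logFC| below/at 0.25 -> out
        n = 60
        meta = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(2 * n)],
            "group": "treated", "cell_type": "CT1",
            "day": np.repeat([0, 15], n),
        })
        # degenerate point masses: avg_logFC = hi - ln 2 = 0.20 exactly
        lo = np.full(n, np.log(2.0))
        expr = np.concatenate([np.full(n, np.log(2.0) + 0.20), lo])[None, :]
        genes, records, _ = td.find_time_degs(
            lognorm=expr, meta=meta, gene_names=["small_shift"],
            cell_type="CT1", group="treated", days=[0, 15])
        assert abs(records["avg_logFC"].iloc[0]) < 0.25
        assert records["p_val_adj"].iloc[0] < 0.05
        assert genes == []

    def test_planted_module4_gene_detected(self, one_type_sim):
        matrix, meta, truth, lognorm = one_type_sim
        genes, records, _ = td.find_time_degs(
            lognorm, meta, matrix.gene_names, cell_type="CT1", group="treated")
        mod4 = [g for g, m in truth.gene_module.items() if m == 4]
        found = set(genes) & set(mod4)
        assert len(found) >= 0.9 * len(mod4)
        d0_d15 = records[(records.dayA == 0) & (records.dayB == 15)]
        hits = d0_d15[(d0_d15.avg_logFC.abs() > 0.25)
                      & (d0_d15.p_val_adj < 0.05)]
        assert len(set(hits.gene) & set(mod4)) >= 0.9 * len(mod4)

    def test_too_few_timepoints_rejected(self):
        meta = pd.DataFrame({
            "cell_id": ["a", "b", "c", "d"], "group": "treated",
            "cell_type": "CT1", "day": [0, 0, 0, 3],
        })
        with pytest.raises(ValueError, match="2 time points"):
            td.find_time_degs(np.ones((2, 4)), meta, ["g1", "g2"],
                              cell_type="CT1", group="treated")


class TestSmoothTimeCurves:
    def _meta_time(self, n_per_day=10, days=(0, 3, 9, 15)):
        return np.repeat(days, n_per_day).astype(float)

    def test_constant_gene_fits_constant(self):
        t = self._meta_time()
        expr = np.full((1, t.size), 2.5)
        curves = td.smooth_time_curves(expr, t, ["g"], ["g"])
        np.testing.assert_allclose(curves.values[0], 2.5, atol=1e-8)
        assert curves.constant_genes == ["g"]
        assert np.all(curves.standardized[0] == 0)

    def test_affine_trend_reproduced_exactly(self):
        t = self._meta_time()
        expr = (0.3 + 0.11 * t)[None, :]
        curves = td.smooth_time_curves(expr, t, ["g"], ["g"])
        np.testing.assert_allclose(curves.values[0], 0.3 + 0.11 * curves.grid,
                                   atol=1e-6)

    def test_bell_gene_peaks_strictly_interior(self):
        t = self._meta_time(n_per_day=25)
        expr = kinetic_curve(2, t, "treated", 4.0)[None, :]
        curves = td.smooth_time_curves(expr, t, ["g"], ["g"])
        peak = curves.grid[np.argmax(curves.values[0])]
        assert 0 < peak < 15

    def test_standardized_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(5)
        t = self._meta_time()
        expr = rng.normal(size=(20, t.size))
        curves = td.smooth_time_curves(expr, t, [f"g{i}" for i in range(20)],
                                       [f"g{i}" for i in range(20)])
        np.testing.assert_allclose(curves.standardized.mean(axis=1), 0,
                                   atol=1e-8)
        np.testing.assert_allclose(curves.standardized.std(axis=1), 1,
                                   atol=1e-6)

    def test_df_not_below_distinct_days_rejected(self):
        t = np.array([0.0, 3.0, 9.0] * 5)
        with pytest.raises(ValueError, match="df"):
            td.smooth_time_curves(np.ones((1, 15)), t, ["g"], ["g"], df=3)


def _template_curves(n_per_module, noise_sd, seed, grid=None):
    """Standardized template curves with optional Gaussian noise."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(0, 15, 100) if grid is None else grid
    rows, labels = [], []
    for m in (1, 2, 3, 4):
        base = kinetic_curve(m, grid, "treated", 4.0)
        base = (base - base.mean()) / base.std()
        for _ in range(n_per_module):
            rows.append(base + rng.normal(0, noise_sd, size=grid.size))
            labels.append(m)
    values = np.array(rows)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    curves = td.SmoothedCurves(
        genes=[f"g{i}" for i in range(len(rows))], grid=grid,
        values=values, standardized=(values - mean) / sd,
    )
    return curves, np.array(labels)


class TestClusterKineticModules:
    def test_k_one_puts_all_genes_in_one_module(self):
        curves, _ = _template_curves(3, 0.0, 0)
        asg = td.cluster_kinetic_modules(curves, k=1)
        assert set(asg.module_of) == {1}

    def test_noiseless_planted_shapes_recovered_exactly(self):
        curves, labels = _template_curves(10, 0.0, 1)
        asg = td.cluster_kinetic_modules(curves, k=4)
        assert adjusted_rand_score(labels, asg.module_of) == 1.0

    def test_noisy_recovery_mean_ari(self):
        aris = []
        for seed in range(5):
            curves, labels = _template_curves(10, 0.3, seed)
            asg = td.cluster_kinetic_modules(curves, k=4)
            aris.append(adjusted_rand_score(labels, asg.module_of))
        assert np.mean(aris) >= 0.8

    def test_gene_order_invariance_up_to_relabeling(self):
        curves, _ = _template_curves(8, 0.2, 3)
        rng = np.random.default_rng(6)
        perm = rng.permutation(len(curves.genes))
        shuffled = td.SmoothedCurves(
            genes=[curves.genes[i] for i in perm], grid=curves.grid,
            values=curves.values[perm], standardized=curves.standardized[perm],
        )
        a1 = td.cluster_kinetic_modules(curves, k=4)
        a2 = td.cluster_kinetic_modules(shuffled, k=4)
        l1 = {g: m for g, m in zip(a1.genes, a1.module_of)}
        l2 = {g: m for g, m in zip(a2.genes, a2.module_of)}
        common = list(l1)
        assert adjusted_rand_score([l1[g] for g in common],
                                   [l2[g] for g in common]) == 1.0

    def test_k_larger_than_genes_rejected(self):
        curves, _ = _template_curves(1, 0.0, 0)
        with pytest.raises(ValueError):
            td.cluster_kinetic_modules(curves, k=5)


class TestLabelModuleShapes:
    def test_canonical_shapes_mapped_bijectively(self):
        curves, labels = _template_curves(10, 0.0, 2)
        asg = td.label_module_shapes(td.cluster_kinetic_modules(curves, k=4))
        assert asg.shape_of_module == {
            1: "decreasing", 2: "bell", 3: "valley", 4: "increasing"}
        # after renumbering, module ids equal the planted template ids
        assert all(m == lab for m, lab in zip(asg.module_of, labels))

    def test_monotone_curves_get_expected_labels(self):
        grid = np.linspace(0, 15, 100)
        rows = {
            "increasing": grid.copy(),
            "valley": -np.exp(-((grid - 7.5) ** 2) / 8.0),
            "decreasing": -grid,
            "bell": np.exp(-((grid - 7.5) ** 2) / 8.0),
        }
        values = np.array([rows[s] for s in rows])
        sd = values.std(axis=1, keepdims=True)
        curves = td.SmoothedCurves(
            genes=list(rows), grid=grid, values=values,
            standardized=(values - values.mean(axis=1, keepdims=True)) / sd,
        )
        asg = td.label_module_shapes(td.cluster_kinetic_modules(curves, k=4))
        got = {g: asg.shape_of_module[int(m)]
               for g, m in zip(asg.genes, asg.module_of)}
        assert got == {s: s for s in rows}

    def test_nonfinite_curve_rejected(self):
        curves, _ = _template_curves(2, 0.0, 0)
        asg = td.cluster_kinetic_modules(curves, k=4)
        asg.mean_curves[1][0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            td.label_module_shapes(asg)


class TestSharedTdegGenes:
    def _random_assignments(self, seed, n_genes=200, n_types=10):
        rng = np.random.default_rng(seed)
        out = {}
        genes = [f"g{i}" for i in range(n_genes)]
        for t in range(n_types):
            chosen = rng.choice(n_genes, size=rng.integers(20, 80),
                                replace=False)
            out[f"T{t}"] = td.ModuleAssignment(
                cell_type=f"T{t}", group="treated",
                genes=[genes[i] for i in chosen],
                module_of=rng.integers(1, 5, size=chosen.size),
                grid=np.linspace(0, 15, 5), mean_curves={},
            )
        return out

    @pytest.mark.parametrize("module_id,min_ct", [(4, 5), (1, 4), (2, 3)])
    def test_matches_nested_loop_oracle(self, module_id, min_ct):
        assignments = self._random_assignments(seed=module_id * 7)
        got = td.shared_tdeg_genes(assignments, module_id, min_ct)
        counts = {}
        for asg in assignments.values():
            for g, m in zip(asg.genes, asg.module_of):
                if m == module_id:
                    counts[g] = counts.get(g, 0) + 1
        expected = sorted(
            [(g, c) for g, c in counts.items() if c >= min_ct],
            key=lambda t: (-t[1], t[0]),
        )
        assert list(map(tuple, got.itertuples(index=False))) == expected

    def test_inclusive_threshold_boundary(self):
        assignments = {
            f"T{t}": td.ModuleAssignment(
                cell_type=f"T{t}", group="treated", genes=["shared", "rare"],
                module_of=np.array([4, 4 if t < 4 else 1]),
                grid=np.linspace(0, 15, 5), mean_curves={},
            )
            for t in range(5)
        }
        got = td.shared_tdeg_genes(assignments, 4, 5)
        assert got.gene.tolist() == ["shared"]
        assert got.n_cell_types.tolist() == [5]

    def test_unknown_module_rejected(self):
        with pytest.raises(ValueError):
            td.shared_tdeg_genes({}, 7, 1)


def test_pipeline_conservation_every_tdeg_in_exactly_one_module():
    cfg = td.SimConfig(
        n_genes=400, n_cell_types=1, cells_per_condition=30,
        genes_per_module={1: 15, 2: 15, 3: 15, 4: 15},
        markers_per_type=0, seed=31,
    )
    matrix, meta, _ = td.simulate_dataset(cfg)
    lognorm = td.normalize_log(matrix)
    genes, _, _ = td.find_time_degs(lognorm, meta, matrix.gene_names,
                                    cell_type="CT1", group="treated")
    idx = np.flatnonzero((meta.group == "treated").to_numpy())
    curves = td.smooth_time_curves(lognorm[:, idx],
                                   meta.day.to_numpy()[idx], genes,
                                   matrix.gene_names)
    asg = td.cluster_kinetic_modules(curves, k=4)
    assert sorted(asg.genes) == sorted(genes)
    assert set(asg.module_of) <= {1, 2, 3, 4}
    assert len(asg.genes) == len(set(asg.genes))
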