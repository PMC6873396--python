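import numpy as np
import pytest

from tacitus import integrate
from tacitus.types import ExpressionMatrix, SampleMetadata, TacitusError

from conftest import make_matrix, make_metadata


def _mat(probes, samples, values, scale="log2_intensity"):
    return ExpressionMatrix(probes, samples, np.asarray(values, dtype=float), scale=scale)


def _meta(ids, attrs=()):
    return SampleMetadata(list(ids), list(attrs), {s: {} for s in ids})


# ---------------------------------------------------------------------------
# merging


class TestMergeMetadata:
    def test_attribute_union_in_first_seen_order(self):
        m1 = SampleMetadata(["s1"], ["a", "b"], {"s1": {"a": "1", "b": "2"}})
        m2 = SampleMetadata(["s2"], ["b", "c"], {"s2": {"b": "3", "c": "4"}})
        merged = integrate.merge_metadata([m1, m2])
        assert merged.attributes == ["a", "b", "c", "batch"]
        assert merged.value("s2", "a") == ""
        assert merged.value("s1", "batch") == "0"
        assert merged.value("s2", "batch") == "1"

    def test_duplicate_sample_id_gets_suffix(self):
        m1 = _meta(["GSM1"])
        m2 = _meta(["GSM1"])
        merged = integrate.merge_metadata([m1, m2])
        assert merged.sample_ids == ["GSM1", "GSM1_1"]

    def test_single_input_gets_zero_batch(self):
        m1 = SampleMetadata(["s1", "s2"], ["a"], {"s1": {"a": "x"}, "s2": {"a": "y"}})
        merged = integrate.merge_metadata([m1])
        assert merged.sample_ids == ["s1", "s2"]
        assert merged.attributes == ["a", "batch"]
        assert all(merged.value(s, "batch") == "0" for s in merged.sample_ids)

    def test_empty_list_errors(self):
        with pytest.raises(TacitusError):
            integrate.merge_metadata([])


class TestMergeMatrices:
    def test_row_intersection_ordered_as_first_input(self):
        a = _mat(["g1", "g2", "g3"], ["s1"], [[1], [2], [3]])
        b = _mat(["g2", "g3", "g4"], ["s2"], [[5], [6], [7]])
        merged, batches = integrate.merge_matrices([a, b])
        assert merged.probe_ids == ["g2", "g3"]
        np.testing.assert_array_equal(merged.values, [[2, 5], [3, 6]])
        assert batches == {"s1": 0, "s2": 1}

    def test_identical_row_sets_concatenate_unchanged(self, rng):
        a = make_matrix(5, 3, rng)
        b = make_matrix(5, 2, rng, sample_prefix="T")
        merged, _ = integrate.merge_matrices([a, b])
        assert merged.probe_ids == a.probe_ids
        np.testing.assert_array_equal(merged.values,
                                      np.concatenate([a.values, b.values], axis=1))

    def test_disjoint_rows_error_reports_counts(self):
        a = _mat(["g1"], ["s1"], [[1]])
        b = _mat(["g2"], ["s2"], [[2]])
        with pytest.raises(TacitusError, match="1 ids"):
            integrate.merge_matrices([a, b])

    def test_duplicate_sample_ids_renamed_consistently(self):
        a = _mat(["g1"], ["X"], [[1]])
        b = _mat(["g1"], ["X"], [[2]])
        merged, batches = integrate.merge_matrices([a, b])
        assert merged.sample_ids == ["X", "X_1"]
        assert batches == {"X": 0, "X_1": 1}


# ---------------------------------------------------------------------------
# mean-centering (sims)


class TestMeanCenter:
    def test_single_row_centered(self):
        a = _mat(["g"], ["s1", "s2", "s3"], [[2, 4, 6]])
        b = _mat(["g"], ["t1", "t2", "t3"], [[0, 0, 0]])
        out = integrate.mean_center_integration([a, b])
        np.testing.assert_allclose(out.matrix.values[0, :3], [-2, 0, 2])

    def test_two_dataset_hand_example(self):
        a = _mat(["g"], ["a1", "a2"], [[1, 3]])
        b = _mat(["g"], ["b1", "b2"], [[10, 14]])
        out = integrate.mean_center_integration([a, b])
        np.testing.assert_allclose(out.matrix.values, [[-1, 1, -2, 2]])

    def test_idempotent(self, rng):
        a = make_matrix(6, 4, rng)
        b = make_matrix(6, 3, rng, sample_prefix="T")
        once = integrate.mean_center_integration([a, b])
        a2 = a.subset_samples(a.sample_ids)
        a2.values[:] = once.matrix.values[:, :4]
        b2 = b.subset_samples(b.sample_ids)
        b2.values[:] = once.matrix.values[:, 4:]
        twice = integrate.mean_center_integration([a2, b2])
        np.testing.assert_allclose(twice.matrix.values, once.matrix.values, atol=1e-12)

    def test_per_dataset_gene_means_zero(self, rng):
        a = make_matrix(20, 5, rng)
        b = make_matrix(20, 7, rng, sample_prefix="T")
        out = integrate.mean_center_integration([a, b])
        assert np.abs(out.matrix.values[:, :5].mean(axis=1)).max() < 1e-9
        assert np.abs(out.matrix.values[:, 5:].mean(axis=1)).max() < 1e-9


# ---------------------------------------------------------------------------
# gene standardization


class TestGeneStandardize:
    def test_two_sample_row(self):
        a = _mat(["g"], ["a1", "a2"], [[1, 3]])
        b = _mat(["g"], ["b1", "b2"], [[5, 6]])
        out = integrate.gene_standardize_integration([a, b])
        np.testing.assert_allclose(out.matrix.values[0, :2],
                                   [-0.70710678, 0.70710678], atol=1e-8)

    def test_constant_row_becomes_zero(self):
        a = _mat(["g"], ["a1", "a2", "a3"], [[5, 5, 5]])
        b = _mat(["g"], ["b1", "b2"], [[1, 2]])
        out = integrate.gene_standardize_integration([a, b])
        np.testing.assert_array_equal(out.matrix.values[0, :3], [0, 0, 0])

    def test_idempotent(self, rng):
        a = make_matrix(8, 5, rng)
        b = make_matrix(8, 4, rng, sample_prefix="T")
        once = integrate.gene_standardize_integration([a, b])
        a2 = ExpressionMatrix(a.probe_ids, a.sample_ids, once.matrix.values[:, :5],
                              scale="standardized")
        b2 = ExpressionMatrix(b.probe_ids, b.sample_ids, once.matrix.values[:, 5:],
                              scale="standardized")
        twice = integrate.gene_standardize_integration([a2, b2])
        np.testing.assert_allclose(twice.matrix.values, once.matrix.values, atol=1e-9)

    def test_mean_zero_sd_one(self, rng):
        a = make_matrix(30, 6, rng)
        b = make_matrix(30, 5, rng, sample_prefix="T")
        out = integrate.gene_standardize_integration([a, b])
        for block in (out.matrix.values[:, :6], out.matrix.values[:, 6:]):
            assert np.abs(block.mean(axis=1)).max() < 1e-9
            assert np.abs(block.std(axis=1, ddof=1) - 1).max() < 1e-9

    def test_single_sample_dataset_errors(self, rng):
        a = make_matrix(4, 1, rng)
        b = make_matrix(4, 3, rng, sample_prefix="T")
        with pytest.raises(TacitusError, match=">=2 samples"):
            integrate.gene_standardize_integration([a, b])

    def test_scale_tag(self, rng):
        out = integrate.gene_standardize_integration(
            [make_matrix(5, 3, rng), make_matrix(5, 3, rng, sample_prefix="T")])
        assert out.matrix.scale == "standardized"


# ---------------------------------------------------------------------------
# ComBat


def _shifted_batches(rng, n_genes=2000, n_per_batch=20, shift=1.0):
    """Two batches with heterogeneous per-gene sds; batch 2 shifted."""
    sd = rng.lognormal(mean=-1.0, sigma=0.8, size=n_genes)
    base = rng.normal(7, 1.5, n_genes)
    b1 = base[:, None] + rng.normal(0, 1, (n_genes, n_per_batch)) * sd[:, None]
    b2 = base[:, None] + shift + rng.normal(0, 1, (n_genes, n_per_batch)) * sd[:, None]
    values = np.concatenate([b1, b2], axis=1)
    batches = np.array([0] * n_per_batch + [1] * n_per_batch)
    return values, batches


class TestCombat:
    def test_no_batch_effect_fixed_point(self, rng):
        """Duplicated batches have equal means and (MLE) variances per gene,
        so the adjustment is the identity."""
        block = rng.normal(0, 1, (50, 10))
        values = np.concatenate([block, block], axis=1)
        batches = np.array([0] * 10 + [1] * 10)
        adjusted = integrate.combat_adjust(values, batches)
        np.testing.assert_allclose(adjusted, values, atol=1e-8)

    def test_shift_removed(self, rng):
        values, batches = _shifted_batches(rng)
        adjusted = integrate.combat_adjust(values, batches)
        before = np.abs(values[:, :20].mean(1) - values[:, 20:].mean(1)).mean()
        after = np.abs(adjusted[:, :20].mean(1) - adjusted[:, 20:].mean(1)).mean()
        assert after < 0.05
        assert before / after > 20

    def test_variance_ratio_balanced(self, rng):
        values, batches = _shifted_batches(rng)
        adjusted = integrate.combat_adjust(values, batches)
        v1 = adjusted[:, :20].var(axis=1, ddof=1)
        v2 = adjusted[:, 20:].var(axis=1, ddof=1)
        assert 0.9 < np.mean(v1 / v2) < 1.1

    def test_large_sample_limit_matches_unshrunken_oracle(self, rng):
        """With 500 samples per batch the EB adjustment approaches the direct
        per-gene location/scale adjustment: the typical gene agrees within 1%
        (shrinkage only stays visible for the few genes with near-zero
        batch variance, where any relative measure blows up)."""
        n_genes, n = 300, 500
        sd = rng.lognormal(-0.3, 0.5, n_genes)
        base = rng.normal(7, 1.5, n_genes)
        gamma = rng.normal(0.0, 1.0, n_genes)  # heterogeneous batch effects
        delta = rng.lognormal(0.0, 0.6, n_genes)
        b1 = base[:, None] + rng.normal(0, 1, (n_genes, n)) * sd[:, None]
        b2 = (base[:, None] + gamma[:, None]
              + rng.normal(0, 1, (n_genes, n)) * (sd * delta)[:, None])
        values = np.concatenate([b1, b2], axis=1)
        batches = np.array([0] * n + [1] * n)
        adjusted = integrate.combat_adjust(values, batches)

        # direct oracle: standardize, remove per-batch gene mean/sd (MLE), restore
        bm = np.stack([values[:, :n].mean(1), values[:, n:].mean(1)], axis=1)
        grand = bm.mean(axis=1)
        resid = values.copy()
        resid[:, :n] -= bm[:, [0]]
        resid[:, n:] -= bm[:, [1]]
        pooled_sd = np.sqrt((resid**2).sum(1) / (2 * n))
        z = (values - grand[:, None]) / pooled_sd[:, None]
        oracle = np.empty_like(z)
        for j, cols in enumerate((slice(0, n), slice(n, 2 * n))):
            zb = z[:, cols]
            g = zb.mean(1)
            d = ((zb - g[:, None]) ** 2).mean(1)
            oracle[:, cols] = (zb - g[:, None]) / np.sqrt(d)[:, None]
        oracle = oracle * pooled_sd[:, None] + grand[:, None]
        rel = (np.abs(adjusted - oracle)
               / (np.abs(oracle - grand[:, None]) + 1.0)).mean(axis=1)
        assert np.median(rel) < 0.01
        assert np.quantile(rel, 0.9) < 0.05

    def test_single_sample_batch_errors(self, rng):
        values = rng.normal(0, 1, (10, 3))
        with pytest.raises(TacitusError, match=">=2"):
            integrate.combat_adjust(values, np.array([0, 0, 1]))

    def test_deterministic(self, rng):
        values, batches = _shifted_batches(rng, n_genes=100)
        a1 = integrate.combat_adjust(values, batches)
        a2 = integrate.combat_adjust(values, batches)
        np.testing.assert_array_equal(a1, a2)


# ---------------------------------------------------------------------------
# XPN


class TestXPN:
    def _pair(self, rng, n_genes=200, n=10, shift=0.0):
        vals = rng.normal(7, 1.5, (n_genes, 1)) + rng.normal(0, 0.8, (n_genes, n))
        a = _mat([f"g{i}" for i in range(n_genes)],
                 [f"a{j}" for j in range(n)], vals)
        b = _mat([f"g{i}" for i in range(n_genes)],
                 [f"b{j}" for j in range(n)], vals + shift)
        return a, b

    def test_identical_inputs_fixed_point(self, rng):
        a, b = self._pair(rng)
        out = integrate.xpn_integration(a, b, n_repeats=3, seed=7)
        expected = np.concatenate([a.values, b.values], axis=1)
        np.testing.assert_allclose(out.matrix.values, expected, atol=1e-8)

    def test_seed_determinism(self, rng):
        a, b = self._pair(rng, shift=1.0)
        r1 = integrate.xpn_integration(a, b, n_repeats=3, seed=11)
        r2 = integrate.xpn_integration(a, b, n_repeats=3, seed=11)
        np.testing.assert_array_equal(r1.matrix.values, r2.matrix.values)

    def test_different_seeds_stable_gene_means(self, rng):
        a, b = self._pair(rng, shift=1.0)
        r1 = integrate.xpn_integration(a, b, n_repeats=5, seed=1)
        r2 = integrate.xpn_integration(a, b, n_repeats=5, seed=2)
        assert not np.array_equal(r1.matrix.values, r2.matrix.values)
        diff = np.abs(r1.matrix.values.mean(1) - r2.matrix.values.mean(1))
        assert diff.max() < 0.05

    def test_constant_shift_removed(self, rng):
        a, b = self._pair(rng, shift=2.0)
        out = integrate.xpn_integration(a, b, n_repeats=5, seed=3)
        n = a.n_samples
        before = np.abs(a.values.mean(1) - b.values.mean(1)).mean()
        after = np.abs(out.matrix.values[:, :n].mean(1)
                       - out.matrix.values[:, n:].mean(1)).mean()
        assert after < 0.1 * before

    def test_small_input_clamps_clusters_with_warning(self, rng, caplog):
        a, b = self._pair(rng, n_genes=10, n=4)
        with caplog.at_level("WARNING"):
            out = integrate.xpn_integration(a, b, n_gene_clusters=25,
                                            n_sample_clusters=5, n_repeats=2, seed=0)
        assert out.matrix.n_probes == 10
        assert any("clamp" in rec.getMessage() for rec in caplog.records)

    def test_too_few_samples_errors(self, rng):
        a = make_matrix(5, 1, rng)
        b = make_matrix(5, 4, rng, sample_prefix="T")
        with pytest.raises(TacitusError, match=">=2 samples"):
            integrate.xpn_integration(a, b)


# ---------------------------------------------------------------------------
# dispatch


class TestIntegrate:
    def _selections(self, rng, n_each=(4, 3)):
        sels = []
        for i, n in enumerate(n_each):
            m = make_matrix(12, n, rng, sample_prefix=f"B{i}S")
            sels.append((m, make_metadata(m.sample_ids, rng)))
        return sels

    def test_none_keeps_values_bit_identical(self, rng):
        sels = self._selections(rng)
        out = integrate.integrate(sels, method="none")
        expected = np.concatenate([m.values for m, _ in sels], axis=1)
        np.testing.assert_array_equal(out.matrix.values, expected)
        assert out.method == "none"

    def test_sims_equals_mean_center(self, rng):
        sels = self._selections(rng)
        via_dispatch = integrate.integrate(sels, method="sims")
        direct = integrate.mean_center_integration([m for m, _ in sels],
                                                   [md for _, md in sels])
        np.testing.assert_array_equal(via_dispatch.matrix.values, direct.matrix.values)

    def test_metadata_row_count_is_sum_of_inputs(self, rng):
        sels = self._selections(rng)
        out = integrate.integrate(sels, method="none")
        assert out.metadata.n_samples == sum(m.n_samples for m, _ in sels)

    def test_batch_labels_cover_all_samples(self, rng):
        sels = self._selections(rng)
        out = integrate.integrate(sels, method="genestd")
        assert set(out.batch_labels) == set(out.matrix.sample_ids)
        assert sorted(set(out.batch_labels.values())) == [0, 1]

    def test_xpn_wrong_arity_errors(self, rng):
        sels = self._selections(rng, n_each=(4, 4, 4))
        with pytest.raises(TacitusError, match="pairwise"):
            integrate.integrate(sels, method="xpn")

    def test_counts_are_log_cpm_transformed(self, rng):
        sels = []
        for i in range(2):
            m = make_matrix(10, 4, rng, sample_prefix=f"B{i}S", scale="linear_count")
            m.values[:] = np.abs(m.values) * 10
            sels.append((m, make_metadata(m.sample_ids, rng)))
        out = integrate.integrate(sels, method="sims")
        assert out.matrix.scale == "log2_cpm"

    def test_none_single_selection_allowed(self, rng):
        sels = self._selections(rng, n_each=(4,))
        out = integrate.integrate(sels, method="none")
        assert out.matrix.n_samples == 4

    def test_unknown_method_errors(self, rng):
        with pytest.raises(TacitusError, match="method"):
            integrate.integrate(self._selections(rng), method="magic")

    def test_combat_dispatch_runs(self, rng):
        sels = self._selections(rng, n_each=(6, 6))
        out = integrate.integrate(sels, method="combat")
        assert out.method == "combat"
        assert out.matrix.n_samples == 12

    def test_write_integrated_round_trip(self, rng, tmp_path):
        from tacitus import io_formats
        out = integrate.integrate(self._selections(rng), method="none")
        mpath, dpath = integrate.write_integrated(out, tmp_path / "out")
        got = io_formats.read_table(mpath)
        assert got.sample_ids == out.matrix.sample_ids
        np.testing.assert_array_equal(got.values, out.matrix.values)


def test_log2_cpm_only_transforms_counts(rng):
    m = make_matrix(5, 3, rng)
    assert integrate.log2_cpm(m) is m
    counts = make_matrix(5, 3, rng, scale="linear_count")
    counts.values[:] = np.round(np.abs(counts.values) * 10)
    cpm = integrate.log2_cpm(counts)
    assert cpm.scale == "log2_cpm"
    lib = counts.values.sum(axis=0)
    expected = np.log2((counts.values + 0.5) / (lib + 1.0) * 1e6)
    np.testing.assert_allclose(cpm.values, expected)
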