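import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import RBFInterpolator
from scipy.linalg import orthogonal_procrustes

from morphdrift.morphio import ShapeDataset, SpecimenRecord
from morphdrift.superimpose import (
    centroid_size,
    estimate_missing_tps,
    gpa_align,
    impute_dataset,
    merge_views,
    opa_fit,
    reflect_relabel,
    symmetric_decomposition,
)
from morphdrift.synthgen import SyntheticShapeConfig, make_template, simulate_shapes
from morphdrift.templates import cranium_template

from conftest import random_configuration, random_rotation


class TestCentroidSize:
    def test_closed_form_square(self):
        config = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        assert centroid_size(config) == pytest.approx(np.sqrt(8))

    def test_translation_invariance(self):
        config = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        assert centroid_size(config + np.array([5.0, 5.0, 5.0])) == pytest.approx(
            centroid_size(config)
        )

    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_homogeneity(self, seed, factor):
        config = random_configuration(np.random.default_rng(seed))
        assert centroid_size(config * factor) == pytest.approx(
            factor * centroid_size(config), rel=1e-9
        )

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            centroid_size(np.full((4, 3), np.nan))


class TestOpaFit:
    def test_rotation_recovered_exactly(self):
        rng = np.random.default_rng(0)
        config = random_configuration(rng)
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        target = config @ Rz.T + np.array([3.0, -2.0, 7.0])
        fit = opa_fit(config, target)
        assert fit.residual == pytest.approx(0.0, abs=1e-18)

    def test_reflection_toggle(self):
        rng = np.random.default_rng(1)
        config = random_configuration(rng)
        mirror = config * np.array([-1.0, 1.0, 1.0])
        assert opa_fit(config, mirror, allow_reflection=False).residual > 1e-3
        assert opa_fit(config, mirror, allow_reflection=True).residual == pytest.approx(
            0.0, abs=1e-18
        )
        R = opa_fit(config, config @ random_rotation(rng).T, allow_reflection=False).rotation
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_beats_monte_carlo_rotations(self):
        """Residual is the minimum: no random rotation out of 10,000 does better."""
        rng = np.random.default_rng(2)
        moving = random_configuration(rng)
        target = random_configuration(rng)
        fit = opa_fit(moving, target)
        A = moving - moving.mean(axis=0)
        B = target - target.mean(axis=0)
        best = np.inf
        for _ in range(10_000):
            R = random_rotation(rng)
            best = min(best, float(((A @ R - B) ** 2).sum()))
        assert fit.residual <= best + 1e-9

    def test_degenerate_raises(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            opa_fit(line, line)


def brute_force_gpa(configs, scale=True, n_iter=200):
    """Independent GPA oracle: pairwise OPA (scipy orthogonal_procrustes) to a
    fixed reference, iterated with explicit centering/scaling."""
    shapes = [c - c.mean(axis=0) for c in configs]
    if scale:
        shapes = [s / np.sqrt((s**2).sum()) for s in shapes]
    shapes = np.stack(shapes)
    ref = shapes[0]
    for _ in range(n_iter):
        for i in range(len(shapes)):
            R, _ = orthogonal_procrustes(shapes[i], ref)
            shapes[i] = shapes[i] @ R
        new_ref = shapes.mean(axis=0)
        if scale:
            new_ref = new_ref / np.sqrt((new_ref**2).sum())
        ref = new_ref
    return shapes, float(((shapes - shapes.mean(axis=0)) ** 2).sum())


class TestGpaAlign:
    def test_two_copies_align_identically(self):
        rng = np.random.default_rng(3)
        config = random_configuration(rng)
        other = config @ random_rotation(rng).T + rng.uniform(-5, 5, 3)
        aligned = gpa_align(np.stack([config, other]), scale=True)
        np.testing.assert_allclose(aligned.shapes[0], aligned.shapes[1], atol=1e-9)
        np.testing.assert_allclose(aligned.consensus, aligned.shapes[0], atol=1e-9)

    def test_unit_centroid_size_when_scaled(self):
        rng = np.random.default_rng(4)
        configs = np.stack([random_configuration(rng) for _ in range(8)])
        aligned = gpa_align(configs, scale=True)
        for shape in aligned.shapes:
            assert centroid_size(shape) == pytest.approx(1.0, abs=1e-9)
        # original sizes kept separately
        for config, cs in zip(configs, aligned.centroid_sizes):
            assert cs == pytest.approx(centroid_size(config))

    def test_residual_log_non_increasing(self):
        rng = np.random.default_rng(5)
        template, base = make_template(2, 3, seed=9)
        ds = simulate_shapes(
            SyntheticShapeConfig(
                template=template,
                base_shape=base,
                n_per_group={("1890s", "F"): 5, ("2010s", "M"): 5},
                individual_sd=0.5,
                seed=6,
            )
        )
        aligned = gpa_align(ds)
        log = np.array(aligned.iterations)
        assert (np.diff(log) <= 1e-12).all()

    def test_consensus_is_mean_of_shapes(self):
        rng = np.random.default_rng(6)
        configs = np.stack([random_configuration(rng) for _ in range(6)])
        aligned = gpa_align(configs)
        np.testing.assert_allclose(aligned.consensus, aligned.shapes.mean(axis=0), atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        configs = np.stack([random_configuration(rng) for _ in range(6)])
        moved = np.stack(
            [c @ random_rotation(rng).T + rng.uniform(-9, 9, 3) for c in configs]
        )
        a1 = gpa_align(configs)
        a2 = gpa_align(moved)
        np.testing.assert_allclose(a1.shapes, a2.shapes, atol=1e-8)
        # "exact" up to float rounding of the rotated inputs (last-ulp level)
        np.testing.assert_allclose(a1.centroid_sizes, a2.centroid_sizes, rtol=1e-12)

    @pytest.mark.parametrize("n,p", [(3, 4), (5, 6), (4, 5)])
    def test_brute_force_oracle_agreement(self, n, p):
        rng = np.random.default_rng(100 + n)
        base = random_configuration(rng, p=p)
        configs = np.stack([base + rng.normal(0, 0.5, (p, 3)) for _ in range(n)])
        aligned = gpa_align(configs, scale=True)
        total = float(((aligned.shapes - aligned.consensus) ** 2).sum())
        _, oracle_total = brute_force_gpa(configs, scale=True)
        assert total == pytest.approx(oracle_total, abs=1e-8)


class TestReflectRelabel:
    def test_involution(self, small_template):
        template, base = small_template
        rng = np.random.default_rng(7)
        config = base + rng.normal(0, 0.3, base.shape)
        twice = reflect_relabel(reflect_relabel(config, template), template)
        np.testing.assert_array_equal(twice, config)

    def test_symmetric_config_rigid_equivalent(self, small_template):
        template, base = small_template
        reflected = reflect_relabel(base, template)
        assert opa_fit(reflected, base).residual == pytest.approx(0.0, abs=1e-16)

    def test_midline_rows_keep_index(self, small_template):
        template, base = small_template
        out = reflect_relabel(base, template)
        for name in template.midline:
            i = template.index(name)
            np.testing.assert_allclose(out[i], base[i] * np.array([-1.0, 1.0, 1.0]))


class TestSymmetricDecomposition:
    def make_dataset(self, template, base, sd, seed, symmetric=False):
        rng = np.random.default_rng(seed)
        specimens = []
        for i in range(6):
            noise = rng.normal(0, sd, base.shape)
            if symmetric:
                cfg = base.copy()
                sym_noise = noise.copy()
                for left, right in template.paired:
                    li, ri = template.index(left), template.index(right)
                    sym_noise[ri] = sym_noise[li] * np.array([-1.0, 1.0, 1.0])
                for name in template.midline:
                    sym_noise[template.index(name), 0] = 0.0
                cfg = cfg + sym_noise
            else:
                cfg = base + noise
            specimens.append(SpecimenRecord(f"s{i}", cfg, period="1890s", sex="F", year=1890))
        return ShapeDataset(template, specimens)

    def test_symmetric_dataset_zero_asymmetry(self, small_template):
        template, base = small_template
        ds = self.make_dataset(template, base, 0.3, 8, symmetric=True)
        _, asym = symmetric_decomposition(ds)
        assert np.abs(asym.shapes).max() < 1e-8

    def test_reconstruction_identity(self, small_template):
        template, base = small_template
        ds = self.make_dataset(template, base, 0.3, 9)
        sym, asym = symmetric_decomposition(ds)
        doubled = gpa_align(
            np.concatenate(
                [ds.coords_array(), np.stack([reflect_relabel(c, template) for c in ds.coords_array()])]
            )
        )
        originals = doubled.shapes[: len(ds)]
        np.testing.assert_allclose(sym.shapes + asym.shapes, originals, atol=1e-10)

    def test_variance_partition(self, small_template):
        """Summed squared deviations split exactly between components."""
        template, base = small_template
        ds = self.make_dataset(template, base, 0.3, 10)
        sym, asym = symmetric_decomposition(ds)
        doubled = gpa_align(
            np.concatenate(
                [ds.coords_array(), np.stack([reflect_relabel(c, template) for c in ds.coords_array()])]
            )
        )
        total = float(((doubled.shapes - doubled.consensus) ** 2).sum())
        sym_part = 2 * float(((sym.shapes - doubled.consensus) ** 2).sum())
        asym_part = 2 * float((asym.shapes**2).sum())
        assert total == pytest.approx(sym_part + asym_part, rel=1e-8)

    def test_relabel_equivariance(self, small_template):
        """Swapping left/right labels leaves the symmetric component unchanged
        up to a rigid transformation (possibly including reflection)."""
        template, base = small_template
        ds = self.make_dataset(template, base, 0.3, 12)
        sym1, _ = symmetric_decomposition(ds)
        swapped = type(template)(
            landmark_names=template.landmark_names,
            dim=template.dim,
            paired=[(r, l) for l, r in template.paired],
            midline=template.midline,
            views=template.views,
            distance_defs=template.distance_defs,
        )
        ds2 = ShapeDataset(swapped, ds.specimens)
        sym2, _ = symmetric_decomposition(ds2)
        for a, b in zip(sym1.shapes, sym2.shapes):
            assert opa_fit(a, b, allow_reflection=True).residual < 1e-10

    def test_template_without_pairs_rejected(self):
        template, base = make_template(0, 4, seed=3)
        ds = ShapeDataset(
            template, [SpecimenRecord(f"s{i}", base + i * 0.01) for i in range(3)]
        )
        with pytest.raises(Exception):
            symmetric_decomposition(ds)


class TestTpsImputation:
    def test_identity_recovery(self, cranium_like_template):
        template, base = cranium_like_template
        rec = SpecimenRecord("s1", base.copy())
        rec.coords[5] = np.nan
        rec.missing_mask[5] = True
        out = estimate_missing_tps(rec, base)
        np.testing.assert_allclose(out.coords[5], base[5], atol=1e-8)
        assert not out.missing_mask.any()
        assert out.imputed_mask[5] and out.imputed_mask.sum() == 1

    @pytest.mark.parametrize("masked", [0, 7, 20, 42])
    def test_affine_exact(self, cranium_like_template, masked):
        template, base = cranium_like_template
        rng = np.random.default_rng(13)
        A = np.eye(3) + rng.normal(0, 0.1, (3, 3))
        b = rng.uniform(-4, 4, 3)
        warped = base @ A.T + b
        rec = SpecimenRecord("s1", warped.copy())
        rec.coords[masked] = np.nan
        rec.missing_mask[masked] = True
        out = estimate_missing_tps(rec, base)
        np.testing.assert_allclose(out.coords[masked], warped[masked], atol=1e-8)

    def test_observed_untouched(self, cranium_like_template):
        template, base = cranium_like_template
        rng = np.random.default_rng(14)
        coords = base + rng.normal(0, 0.5, base.shape)
        rec = SpecimenRecord("s1", coords.copy())
        rec.coords[3] = np.nan
        rec.missing_mask[3] = True
        out = estimate_missing_tps(rec, base)
        keep = np.ones(len(base), dtype=bool)
        keep[3] = False
        np.testing.assert_array_equal(out.coords[keep], coords[keep])

    def test_nonlinear_warp_vs_rbf_oracle(self, cranium_like_template):
        """Smooth nonlinear warp, one masked landmark: recovery within 5% of
        the mean interlandmark distance, cross-checked against an independent
        radial-basis interpolator."""
        template, base = cranium_like_template
        rng = np.random.default_rng(15)
        warped = base + 0.02 * np.sin(base[:, [1, 2, 0]] / 4.0) * 10
        p = base.shape[0]
        from scipy.spatial.distance import pdist

        mean_dist = pdist(base).mean()
        for masked in rng.choice(p, size=5, replace=False):
            rec = SpecimenRecord("s1", warped.copy())
            rec.coords[masked] = np.nan
            rec.missing_mask[masked] = True
            out = estimate_missing_tps(rec, base)
            err = np.linalg.norm(out.coords[masked] - warped[masked])
            assert err < 0.05 * mean_dist
            keep = np.arange(p) != masked
            oracle = RBFInterpolator(base[keep], warped[keep], kernel="linear")
            oracle_pred = oracle(base[masked][None, :])[0]
            oracle_err = np.linalg.norm(oracle_pred - warped[masked])
            assert err <= oracle_err + 0.01 * mean_dist

    def test_too_few_observed_raises(self, small_template):
        template, base = small_template
        rec = SpecimenRecord("s1", base.copy())
        rec.coords[3:] = np.nan
        rec.missing_mask[3:] = True
        with pytest.raises(ValueError):
            estimate_missing_tps(rec, base)

    def test_impute_dataset_end_to_end(self, small_dataset):
        ds = small_dataset
        ds.specimens[0].coords[2] = np.nan
        ds.specimens[0].missing_mask[2] = True
        out = impute_dataset(ds)
        assert all(s.is_complete for s in out.specimens)
        assert out.specimens[0].imputed_mask[2]


class TestMergeViews:
    def make_views(self, template, truth, rng):
        """Split one ground-truth configuration into dorsal/ventral records,
        the ventral one rigidly displaced."""
        p = template.n_landmarks
        dorsal = np.full((p, 3), np.nan)
        ventral = np.full((p, 3), np.nan)
        d_mask = np.ones(p, dtype=bool)
        v_mask = np.ones(p, dtype=bool)
        R = random_rotation(rng)
        t = rng.uniform(-8, 8, 3)
        for j, name in enumerate(template.landmark_names):
            view = template.views[name]
            if view in ("dorsal", "common"):
                dorsal[j] = truth[j]
                d_mask[j] = False
            if view in ("ventral", "common"):
                ventral[j] = truth[j] @ R.T + t
                v_mask[j] = False
        return (
            SpecimenRecord("s1", dorsal, missing_mask=d_mask),
            SpecimenRecord("s1", ventral, missing_mask=v_mask),
        )

    def test_exact_rigid_merge(self):
        template, base = cranium_template()
        rng = np.random.default_rng(16)
        truth = base + rng.normal(0, 0.3, base.shape)
        dorsal, ventral = self.make_views(template, truth, rng)
        merged = merge_views(dorsal, ventral, template)
        assert not merged.missing_mask.any()
        np.testing.assert_allclose(merged.coords, truth, atol=1e-9)

    def test_cranium_view_counts(self):
        template, _ = cranium_template()
        n_dorsal = len(template.view_landmarks("dorsal"))
        n_ventral = len(template.view_landmarks("ventral"))
        n_common = sum(1 for v in template.views.values() if v == "common")
        assert (n_dorsal, n_ventral, n_common) == (18, 30, 5)
        assert n_dorsal + n_ventral - n_common == template.n_landmarks == 43

    def test_identity_common_landmarks_unchanged(self):
        template, base = cranium_template()
        rng = np.random.default_rng(17)
        truth = base + rng.normal(0, 0.2, base.shape)
        p = template.n_landmarks
        dorsal = np.full((p, 3), np.nan)
        ventral = np.full((p, 3), np.nan)
        d_mask = np.ones(p, bool)
        v_mask = np.ones(p, bool)
        for j, name in enumerate(template.landmark_names):
            view = template.views[name]
            if view in ("dorsal", "common"):
                dorsal[j], d_mask[j] = truth[j], False
            if view in ("ventral", "common"):
                ventral[j], v_mask[j] = truth[j], False
        merged = merge_views(
            SpecimenRecord("s1", dorsal, missing_mask=d_mask),
            SpecimenRecord("s1", ventral, missing_mask=v_mask),
            template,
        )
        common_idx = [template.index(n) for n, v in template.views.items() if v == "common"]
        np.testing.assert_allclose(merged.coords[common_idx], truth[common_idx], atol=1e-9)

    def test_too_few_common_raises(self):
        template, base = cranium_template()
        rng = np.random.default_rng(18)
        dorsal, ventral = self.make_views(template, base, rng)
        for n, v in template.views.items():
            if v == "common":
                ventral.missing_mask[template.index(n)] = True
        with pytest.raises(ValueError, match="common"):
            merge_views(dorsal, ventral, template)

    def test_residual_threshold(self):
        template, base = cranium_template()
        rng = np.random.default_rng(19)
        truth = base + rng.normal(0, 0.2, base.shape)
        dorsal, ventral = self.make_views(template, truth, rng)
        # blunder: corrupt one common landmark in the ventral view
        name = next(n for n, v in template.views.items() if v == "common")
        ventral.coords[template.index(name)] += 25.0
        with pytest.raises(ValueError, match="residual"):
            merge_views(dorsal, ventral, template, max_fit_residual=1.0)
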