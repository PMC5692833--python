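import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import basisbrain as bb
from basisbrain.basis import BisquareLevelSpec, RADIUS_SPACING_RATIO
from basisbrain.errors import DimensionError, EmptyBasisError, ParameterError


class TestBisquareValue:
    @pytest.mark.parametrize(
        "dist_frac,expected",
        [(0.0, 1.0), (1.0, 0.0), (0.5, 0.5625)],
    )
    def test_radial_profile(self, dist_frac, expected):
        r = 6.0
        x = np.array([dist_frac * r, 0.0, 0.0])
        assert bb.bisquare_value(x, np.zeros(3), r) == pytest.approx(expected)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ParameterError):
            bb.bisquare_value(np.zeros(3), np.zeros(3), 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        d=st.floats(0, 30, allow_nan=False),
        r=st.floats(0.1, 20, allow_nan=False),
    )
    def test_values_bounded_and_continuous_at_boundary(self, d, r):
        v = bb.bisquare_value(np.array([d, 0, 0]), np.zeros(3), r)
        assert 0.0 <= v <= 1.0
        just_in = bb.bisquare_value(np.array([r * (1 - 1e-9), 0, 0]), np.zeros(3), r)
        assert just_in < 1e-6


def brute_force_center_count(mask, spec):
    """Independent oracle: enumerate lattice centres with >=1 strictly
    supported mask voxel."""
    coords = mask.world_coords()
    kept = 0
    for c in spec.candidate_centers(mask):
        d = np.sqrt(((coords - c) ** 2).sum(axis=1))
        if np.any(d < spec.r_mm):
            kept += 1
    return kept


class TestTileBisquare:
    @pytest.mark.parametrize("spacing", [4.0, 6.0, 9.0])
    def test_column_count_matches_brute_force(self, toy_mask, spacing):
        spec = BisquareLevelSpec(spacing_mm=spacing, level=0)
        basis = bb.tile_bisquare(toy_mask, [spec])
        assert basis.M == brute_force_center_count(toy_mask, spec)

    def test_default_levels_use_stated_radii(self):
        specs = bb.default_bisquare_specs()
        assert [s.r_mm for s in specs] == [6.0, 12.0, 18.0]
        for s in specs:
            assert s.r_mm == pytest.approx(RADIUS_SPACING_RATIO * s.spacing_mm)

    def test_support_fits_in_ball(self, toy_mask):
        spec = BisquareLevelSpec(spacing_mm=6.0, level=0)
        basis = bb.tile_bisquare(toy_mask, [spec])
        coords = toy_mask.world_coords()
        centers = spec.candidate_centers(toy_mask)
        # every nonzero voxel of every column lies within r of some centre
        for m in range(basis.M):
            support = coords[basis.matrix[:, m] > 0]
            d = np.sqrt(((support[:, None, :] - centers[None]) ** 2).sum(-1))
            assert np.all(d.min(axis=1) <= spec.r_mm)

    def test_multi_level_counts_add(self, toy_mask):
        specs = [
            BisquareLevelSpec(spacing_mm=4.0, level=0),
            BisquareLevelSpec(spacing_mm=8.0, level=1),
        ]
        combined = bb.tile_bisquare(toy_mask, specs)
        singles = [bb.tile_bisquare(toy_mask, [s]).M for s in specs]
        assert combined.M == sum(singles)
        assert np.array_equal(np.unique(combined.level_of), [0, 1])

    def test_no_overlap_raises(self, toy_mask):
        spec = BisquareLevelSpec(spacing_mm=4.0, level=0)
        spec.centers = np.array([[1e4, 1e4, 1e4]])
        with pytest.raises(EmptyBasisError):
            bb.tile_bisquare(toy_mask, [spec])


class TestAtlasBasis:
    def _prob_maps(self, mask, k, seed=0):
        rng = np.random.default_rng(seed)
        return [
            bb.unmask(rng.uniform(0, 1, mask.V), mask) for _ in range(k)
        ]

    @pytest.mark.parametrize("k", [4, 7])
    def test_one_column_per_map(self, toy_mask, k):
        basis = bb.atlas_to_basis(self._prob_maps(toy_mask, k), toy_mask)
        assert basis.M == k
        assert basis.provenance == "atlas"

    def test_zero_map_dropped_with_warning(self, toy_mask):
        maps = self._prob_maps(toy_mask, 3)
        maps.append(bb.unmask(np.zeros(toy_mask.V), toy_mask))
        with pytest.warns(UserWarning, match="zero inside the mask"):
            basis = bb.atlas_to_basis(maps, toy_mask)
        assert basis.M == 3
        with pytest.raises(EmptyBasisError):
            bb.atlas_to_basis(maps, toy_mask, strict=True)

    def test_negative_values_rejected(self, toy_mask):
        vol = bb.unmask(-np.ones(toy_mask.V), toy_mask)
        with pytest.raises(ParameterError):
            bb.atlas_to_basis([vol], toy_mask)


def _orthonormal_columns(n, k, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    return Q[:, :k]


class TestCorrelationSummary:
    def test_orthogonal_columns_mean_zero(self):
        Q = _orthonormal_columns(50, 3)
        mean, _ = bb.correlation_summary(bb.BasisSet(Q, list("abc")))
        assert mean == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_column_mean_one(self):
        col = np.random.default_rng(1).standard_normal(30)
        basis = bb.BasisSet(np.stack([col, col], axis=1), ["a", "b"])
        mean, sd = bb.correlation_summary(basis)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_constructed_pairwise_correlations(self):
        # columns with pairwise correlations {0.5, -0.5, 0} -> mean |rho| = 1/3
        Q = _orthonormal_columns(60, 3, seed=2)
        a = Q[:, 0]
        b = 0.5 * Q[:, 0] + np.sqrt(0.75) * Q[:, 1]
        x = 0.25 / np.sqrt(0.75)
        c = -0.5 * Q[:, 0] + x * Q[:, 1] + np.sqrt(1 - 0.25 - x**2) * Q[:, 2]
        mean, _ = bb.correlation_summary(
            bb.BasisSet(np.stack([a, b, c], axis=1), list("abc"))
        )
        assert mean == pytest.approx(1.0 / 3.0, abs=1e-10)

    def test_invariance_to_scaling_and_order(self, small_basis):
        ref = bb.correlation_summary(small_basis)
        scaled = bb.BasisSet(
            small_basis.matrix * np.arange(1, small_basis.M + 1),
            list(small_basis.names),
        )
        perm = np.random.default_rng(3).permutation(small_basis.M)
        shuffled = small_basis.select(perm)
        assert bb.correlation_summary(scaled) == pytest.approx(ref)
        assert bb.correlation_summary(shuffled) == pytest.approx(ref)

    def test_single_column_rejected(self, toy_mask):
        basis = bb.random_smooth_basis(toy_mask, 1, seed=0)
        with pytest.raises(DimensionError):
            bb.correlation_summary(basis)


class TestEigenspectrum:
    def test_orthonormal_columns_flat(self):
        Q = _orthonormal_columns(80, 4)
        spec = bb.eigenspectrum(bb.BasisSet(Q, list("abcd")))
        assert np.allclose(spec, 0.25, atol=1e-10)

    def test_rank_one_spectrum(self):
        col = np.random.default_rng(4).standard_normal(40)
        basis = bb.BasisSet(np.stack([col, 2 * col, -col], axis=1), list("abc"))
        spec = bb.eigenspectrum(basis)
        assert spec[0] == pytest.approx(1.0)
        assert np.allclose(spec[1:], 0.0, atol=1e-12)

    def test_normalization_contract(self, small_basis):
        spec = bb.eigenspectrum(small_basis)
        assert spec.sum() == pytest.approx(1.0)
        assert np.all(np.diff(spec) <= 1e-12)
        assert np.all(spec >= -1e-15)


class TestSmoothBasis:
    def test_fwhm_zero_identity(self, toy_mask, small_basis):
        out = bb.smooth_basis(small_basis, toy_mask, 0.0)
        assert np.array_equal(out.matrix, small_basis.matrix)

    def test_impulse_spreads_without_sign_flip(self, toy_mask):
        col = np.zeros(toy_mask.V)
        col[toy_mask.V // 2] = 1.0
        basis = bb.BasisSet(col[:, None], ["imp"])
        out = bb.smooth_basis(basis, toy_mask, 6.0)
        assert (out.matrix[:, 0] >= 0).all()
        assert (out.matrix[:, 0] > 0).sum() > 1

    def test_smoothing_increases_adjacent_impulse_correlation(self, toy_mask):
        # two impulses at neighbouring voxels: uncorrelated before smoothing,
        # strongly correlated after their kernels overlap
        ijk = toy_mask.voxel_ijk()
        i0 = 0
        neigh = np.flatnonzero((np.abs(ijk - ijk[i0]).sum(axis=1) == 1))
        i1 = int(neigh[0])
        cols = np.zeros((toy_mask.V, 2))
        cols[i0, 0] = 1.0
        cols[i1, 1] = 1.0
        basis = bb.BasisSet(cols, ["a", "b"])
        before, _ = bb.correlation_summary(basis)
        after, _ = bb.correlation_summary(bb.smooth_basis(basis, toy_mask, 8.0))
        assert after > before


def test_basis_round_trip(tmp_path, toy_mask, small_basis):
    from basisbrain.basis import load_basis, save_basis

    save_basis(small_basis, toy_mask, tmp_path / "basis.nii.gz")
    loaded = load_basis(tmp_path / "basis.nii.gz", toy_mask)
    assert np.allclose(loaded.matrix, small_basis.matrix)
    assert loaded.names == small_basis.names
    assert loaded.provenance == small_basis.provenance
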