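import numpy as np
import pytest

from dualniche.geodata import EnvStack, GridGeometry, RasterGrid, PSEUDO_ABSENCE
from dualniche.pseudoabs import (environmental_profile_mask, kmeans_eligibility,
                                 sample_pseudo_absences)
from dualniche.spatialcv import make_blocks

from conftest import presence_points


def split_stack(n=20):
    """Landscape whose left half has env value 0 and right half value 10."""
    geo = GridGeometry(n, n, 0.0, float(n), 1.0)
    vals = np.zeros((n, n))
    vals[:, n // 2:] = 10.0
    noise = np.random.default_rng(0).normal(0, 0.01, (n, n))
    return EnvStack({"env": RasterGrid(vals + noise, geo)}), geo


class TestEnvironmentalProfile:
    def test_envelope_logic_on_split_landscape(self):
        # exact two-valued landscape: presences all at value 0
        geo = GridGeometry(20, 20, 0.0, 20.0, 1.0)
        vals = np.zeros((20, 20))
        vals[:, 10:] = 10.0
        stack = EnvStack({"env": RasterGrid(vals, geo)})
        pres = presence_points(geo, [1, 2, 3, 4, 5], [1, 2, 3, 4, 5])  # left half
        mask = environmental_profile_mask(stack, pres, envelope_quantiles=(0.0, 1.0))
        elig = mask.eligible
        assert elig[:, 10:].all()          # value-10 half eligible
        assert not elig[:, :10].any()      # value-0 half inside the envelope

    def test_presence_cells_never_eligible(self, small_landscape, small_presences):
        _, stack, _ = small_landscape
        mask = environmental_profile_mask(stack, small_presences)
        rows, cols = small_presences.cell_indices(stack.geometry)
        assert not mask.eligible[rows, cols].any()

    def test_matches_brute_force_envelope_oracle(self, small_landscape, small_presences):
        _, stack, _ = small_landscape
        mask = environmental_profile_mask(stack, small_presences,
                                          envelope_quantiles=(0.05, 0.95))
        rows, cols = small_presences.cell_indices(stack.geometry)
        names = stack.continuous_names()
        bounds = {}
        for n in names:
            pv = stack[n].values[rows, cols]
            bounds[n] = np.quantile(pv, [0.05, 0.95])
        occupied = set(zip(rows.tolist(), cols.tolist()))
        geo = stack.geometry
        for r in range(geo.n_rows):
            for c in range(geo.n_cols):
                inside_all = all(bounds[n][0] <= stack[n].values[r, c] <= bounds[n][1]
                                 for n in names)
                expected = (not inside_all) and (r, c) not in occupied
                assert mask.eligible[r, c] == expected

    def test_envelope_covering_everything_raises(self):
        geo = GridGeometry(6, 6, 0.0, 6.0, 1.0)
        vals = np.random.default_rng(1).normal(size=(6, 6))
        stack = EnvStack({"e": RasterGrid(vals, geo)})
        # presences on every cell: envelope spans the full range
        rr, cc = np.meshgrid(range(6), range(6), indexing="ij")
        pres = presence_points(geo, rr.ravel(), cc.ravel())
        with pytest.raises(ValueError):
            environmental_profile_mask(stack, pres, envelope_quantiles=(0.0, 1.0))


class TestKMeansEligibility:
    def test_separable_blobs_flag_presence_free_blob(self):
        stack, geo = split_stack()
        pres = presence_points(geo, [1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        mask = kmeans_eligibility(stack, pres, k=2, runs=5,
                                  presence_poor_quantile=0.5, seed=0)
        assert mask.eligible[:, 10:].all()
        assert not mask.eligible[:, :10].any()

    def test_single_run_majority_reduces_to_that_run(self):
        stack, geo = split_stack()
        pres = presence_points(geo, [1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        m1 = kmeans_eligibility(stack, pres, k=2, runs=1,
                                presence_poor_quantile=0.5, seed=3)
        m2 = kmeans_eligibility(stack, pres, k=2, runs=1,
                                presence_poor_quantile=0.5, seed=3)
        assert np.array_equal(m1.eligible, m2.eligible)

    def test_replayed_seeded_clustering_matches(self, small_landscape, small_presences):
        """Independent replay of the seeded run sequence reproduces the mask."""
        from sklearn.cluster import KMeans
        _, stack, _ = small_landscape
        pres = small_presences
        k, runs, q, seed = 4, 3, 0.25, 17
        mask = kmeans_eligibility(stack, pres, k=k, runs=runs,
                                  presence_poor_quantile=q, seed=seed)
        # replay: same standardization, same derived seeds, same vote rule
        names = stack.continuous_names()
        valid = ~stack.combined_nodata()
        cols = []
        for n in names:
            v = stack[n].values[valid].astype(float)
            cols.append((v - v.mean()) / v.std())
        X = np.column_stack(cols)
        rows_p, cols_p = pres.cell_indices(stack.geometry)
        flat_index = np.full(stack.geometry.shape, -1, int)
        flat_index[valid] = np.arange(X.shape[0])
        pres_pos = flat_index[rows_p, cols_p]
        rng = np.random.default_rng(seed)
        votes = np.zeros(X.shape[0], int)
        for _ in range(runs):
            km = KMeans(n_clusters=k, n_init=1,
                        random_state=int(rng.integers(2**31 - 1))).fit(X)
            sizes = np.bincount(km.labels_, minlength=k)
            pc = np.bincount(km.labels_[pres_pos], minlength=k)
            density = pc / np.maximum(sizes, 1)
            flagged = density <= np.quantile(density, q)
            votes += flagged[km.labels_]
        expected = np.zeros(stack.geometry.shape, bool)
        expected[valid] = votes > runs / 2
        expected[rows_p, cols_p] = False
        assert np.array_equal(mask.eligible, expected)

    def test_k_larger_than_cells_rejected(self):
        stack, geo = split_stack(4)
        pres = presence_points(geo, [0, 1, 2, 3, 0], [0, 1, 2, 3, 1])
        with pytest.raises(ValueError):
            kmeans_eligibility(stack, pres, k=100)


class TestSamplePseudoAbsences:
    def _mask_from(self, eligible, geo):
        from dualniche.pseudoabs import EligibilityMask
        return EligibilityMask(RasterGrid(eligible.astype(np.int32), geo,
                                          is_categorical=True))

    def test_exhaustive_intersection_returned(self):
        geo = GridGeometry(5, 5, 0.0, 5.0, 1.0)
        elig = np.zeros((5, 5), bool)
        elig[0, :3] = True
        pts = sample_pseudo_absences([self._mask_from(elig, geo)], 3, seed=1)
        rows, cols = pts.cell_indices(geo)
        assert sorted(zip(rows, cols)) == [(0, 0), (0, 1), (0, 2)]
        assert all(l == PSEUDO_ABSENCE for l in pts.label)

    def test_per_block_counts_respected(self):
        geo = GridGeometry(10, 10, 0.0, 10.0, 1.0)
        blocks = make_blocks(geo, 5)  # 4 blocks of 25 cells
        elig = np.ones((10, 10), bool)
        pts = sample_pseudo_absences([self._mask_from(elig, geo)], {0: 3, 3: 7},
                                     seed=2, block_ids=blocks)
        rows, cols = pts.cell_indices(geo)
        got = np.bincount(blocks.values[rows, cols], minlength=4)
        assert list(got) == [3, 0, 0, 7]

    def test_samples_avoid_presence_cells(self, small_landscape, small_presences):
        _, stack, _ = small_landscape
        mask = environmental_profile_mask(stack, small_presences)
        pts = sample_pseudo_absences([mask], 50, seed=9)
        pr, pc = small_presences.cell_indices(stack.geometry)
        presence_cells = set(zip(pr.tolist(), pc.tolist()))
        ar, ac = pts.cell_indices(stack.geometry)
        assert not (set(zip(ar.tolist(), ac.tolist())) & presence_cells)

    def test_insufficient_eligibility_reports_available(self):
        geo = GridGeometry(4, 4, 0.0, 4.0, 1.0)
        elig = np.zeros((4, 4), bool)
        elig[0, 0] = True
        with pytest.raises(ValueError, match="have 1"):
            sample_pseudo_absences([self._mask_from(elig, geo)], 5, seed=0)

    def test_dual_filter_at_least_as_restrictive(self, small_landscape,
                                                 small_presences):
        _, stack, _ = small_landscape
        prof = environmental_profile_mask(stack, small_presences)
        km = kmeans_eligibility(stack, small_presences, k=4, runs=3, seed=1)
        dual = prof.eligible & km.eligible
        assert dual.sum() <= min(prof.n_eligible, km.n_eligible)
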