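"""PPMs: the participation formula, clustering, network projection, tests."""

import numpy as np
import pytest
from scipy import stats

import brainpolarity as bp
from brainpolarity import participation as part
from brainpolarity.polarity import IALMatrix


def _ial(levels):
    return IALMatrix(np.asarray(levels, dtype=np.int8), "gaussian_threshold", (0, 0))


class TestComputePPM:
    def test_combined_count_formula(self):
        # 4 High TRs (voxel0 at +1 in 3) then 6 Low TRs (voxel0 at -1 in 3)
        labels = np.array([0] * 4 + [1] * 6)
        v0 = [1, 1, 1, 0] + [-1, -1, -1, 0, 0, 1]
        v1 = [0, -1, 0, 0] + [1, 1, 0, 0, 0, 0]   # never matches
        ppm = bp.compute_ppm(_ial([v0, v1]), labels)
        assert ppm.values[0] == pytest.approx(0.6)
        assert ppm.values[1] == 0.0
        assert ppm.n_polarized_trs == 10

    def test_perfect_participation_is_one(self):
        labels = np.array([0, 0, 1, 1, 2])
        v = [[1, 1, -1, -1, 0]]
        assert bp.compute_ppm(_ial(v), labels).values[0] == 1.0

    def test_values_stay_in_unit_interval(self, rng):
        levels = rng.integers(-1, 2, size=(50, 80)).astype(np.int8)
        labels = rng.integers(0, 3, size=80)
        ppm = bp.compute_ppm(_ial(levels), labels)
        assert ppm.values.min() >= 0 and ppm.values.max() <= 1

    def test_invariant_to_relabeling_neutral_trs(self, rng):
        levels = rng.integers(-1, 2, size=(30, 60)).astype(np.int8)
        labels = rng.integers(0, 3, size=60)
        a = bp.compute_ppm(_ial(levels), labels)
        relabeled = labels.copy()
        relabeled[labels == 2] = 7   # any non-polarized tag
        b = bp.compute_ppm(_ial(levels), relabeled)
        np.testing.assert_array_equal(a.values, b.values)

    def test_no_polarized_trs_flagged_invalid(self):
        ppm = bp.compute_ppm(_ial([[1, 0, -1]]), np.array([2, 2, 2]))
        assert not ppm.is_valid

    def test_per_state_denominator_variant_can_exceed_one(self):
        labels = np.array([0, 1])
        v = [[1, -1]]
        ppm = bp.compute_ppm(_ial(v), labels, per_state_denominator=True)
        assert ppm.values[0] == pytest.approx(2.0)

    def test_planted_field_recovered_from_generator(self, cohort, coded_cohort,
                                                    dpr_model):
        """High-gain subjects' PPMs correlate > 0.8 with the true field."""
        subjects, _ = cohort
        ials, _, _ = coded_cohort
        for subj, ial, lab in list(zip(subjects, ials, dpr_model.labels))[:3]:  # HC
            ppm = bp.compute_ppm(ial, lab)
            assert ppm.is_valid
            r = np.corrcoef(ppm.values, subj.true_participation_map)[0, 1]
            assert r > 0.8


class TestClusterPPMs:
    def _maps(self, rng, n_per=10, V=200):
        t1 = rng.uniform(0.6, 0.9, size=V)
        t2 = rng.uniform(0.1, 0.4, size=V)
        maps, truth = [], []
        for i in range(2 * n_per):
            t = t1 if i % 2 == 0 else t2
            maps.append(part.ParticipationMap(
                values=np.clip(t + rng.normal(0, 0.03, V), 0, 1),
                n_polarized_trs=10, subject_id=f"s{i}"))
            truth.append(i % 2)
        return maps, np.array(truth)

    def test_separated_templates_fully_recovered(self, rng):
        maps, truth = self._maps(rng)
        model = bp.cluster_ppms(maps, k=2, seed=0, replicates=5)
        labels = np.array([l[0] for l in model.labels])
        # cluster 0 is the higher-participation template by construction
        assert (labels == truth).all()
        assert model.centroids[0].mean() > model.centroids[1].mean()

    def test_k1_centroid_is_mean_map(self, rng):
        maps, _ = self._maps(rng, n_per=5)
        model = bp.cluster_ppms(maps, k=1, seed=0, replicates=2)
        np.testing.assert_allclose(
            model.centroids[0], np.mean([m.values for m in maps], axis=0),
            atol=1e-9)

    def test_fewer_valid_maps_than_k_rejected(self):
        bad = part.ParticipationMap(np.zeros(5), n_polarized_trs=0)
        with pytest.raises(ValueError, match="valid maps"):
            bp.cluster_ppms([bad, bad], k=2)

    def test_seeded_determinism(self, rng):
        maps, _ = self._maps(rng)
        a = bp.cluster_ppms(maps, k=2, seed=3, replicates=5)
        b = bp.cluster_ppms(maps, k=2, seed=3, replicates=5)
        np.testing.assert_array_equal(
            [l[0] for l in a.labels], [l[0] for l in b.labels])


class TestNetworkParticipation:
    def test_ordering_by_construction(self, rng):
        V = 300
        values = np.linspace(0, 1, V)
        ppm = part.ParticipationMap(values, n_polarized_trs=5)
        top_net = np.zeros(V); top_net[-30:] = 1.0
        bottom_net = np.zeros(V); bottom_net[:30] = 1.0
        out = bp.network_participation(ppm, np.vstack([top_net, bottom_net]))
        assert out[0] > 0 > out[1]

    def test_constant_ppm_rejected(self):
        ppm = part.ParticipationMap(np.full(50, 0.5), n_polarized_trs=5)
        with pytest.raises(ValueError, match="constant"):
            bp.network_participation(ppm, np.eye(50)[:2])

    def test_threshold_retains_gaussian_tail_fraction(self, rng):
        """z >= 1.25 keeps ~10.6% of a Gaussian-valued map's voxels."""
        V = 200_000
        net = rng.normal(size=V)
        ppm = part.ParticipationMap(rng.uniform(0, 1, V), n_polarized_trs=5)
        netz = (net - net.mean()) / net.std()
        frac = (netz >= 1.25).mean()
        expected = stats.norm.sf(1.25)
        assert frac == pytest.approx(expected, abs=0.005)
        # and the module actually uses that voxel set
        out = bp.network_participation(ppm, net[None, :])
        assert np.isfinite(out[0])

    def test_empty_network_flagged_nan(self, rng):
        V = 100
        ppm = part.ParticipationMap(rng.uniform(0, 1, V), n_polarized_trs=5)
        flat = np.zeros(V)  # constant map: no supra-threshold voxels
        out = bp.network_participation(ppm, flat[None, :])
        assert np.isnan(out[0])


class TestGroupDifference:
    def _null_maps(self, rng, n=20, V=150):
        return [part.ParticipationMap(rng.uniform(0.3, 0.7, V), 5, f"s{i}")
                for i in range(n)]

    def test_null_data_has_few_fdr_survivors(self):
        survivors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            maps = self._null_maps(rng)
            groups = ["HC"] * 10 + ["SZ"] * 10
            res = part.voxelwise_group_difference(maps, groups, contrast="group")
            survivors.append(res["fdr_mask"].sum())
        assert np.mean(survivors) < 1.0

    def test_planted_region_dominates_survivors(self, rng):
        maps = self._null_maps(rng, n=24, V=150)
        for m in maps[12:]:
            m.values[:25] += 0.4   # shifted region in the second group
        groups = ["HC"] * 12 + ["SZ"] * 12
        res = part.voxelwise_group_difference(maps, groups, contrast="group")
        hits = np.flatnonzero(res["fdr_mask"])
        assert hits.size > 0
        assert (hits < 25).mean() > 0.9

    def test_difference_from_population_mean_contrast(self, rng):
        maps = self._null_maps(rng, n=15, V=80)
        for m in maps:
            m.values[:10] = np.clip(m.values[:10] + 0.3, 0, 1)
        res = part.voxelwise_group_difference(maps, contrast="mean")
        assert res["t"][:10].mean() > res["t"][10:].mean()

    def test_constant_maps_rejected(self):
        maps = [part.ParticipationMap(np.full(30, 0.4), 5, f"s{i}")
                for i in range(6)]
        with pytest.raises(ValueError, match="constant"):
            part.voxelwise_group_difference(maps, ["HC"] * 3 + ["SZ"] * 3)
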