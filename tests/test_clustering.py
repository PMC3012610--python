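"""Expression-wave clustering: z-scores, K-means, CAST, modality calls."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cypwaves.clustering import (
    ProfileMatrix,
    affinity_matrix,
    affinity_search,
    cast_clusters,
    classify_modality,
    kmeans_clusters,
    maternal_seed_profile,
    timepoint_means,
    z_normalize,
)
from cypwaves.preprocess import average_duplicates
from cypwaves.simulate import ArchetypeSpec, ArrayDesign, generate_timecourse

TIMEPOINTS = [3.0, 6.0, 12.0, 24.0, 36.0, 48.0]


def _profiles(rows, columns=TIMEPOINTS):
    return ProfileMatrix(
        data=pd.DataFrame(rows, columns=columns, index=[f"g{i}" for i in range(len(rows))])
    )


def recovery_profiles(mix, noise, seed, n=400):
    table, truth = generate_timecourse(
        design=ArrayDesign(n_probes=n),
        archetype_mix=mix,
        noise=noise,
        distortion="identity",
        seed=seed,
    )
    prof = z_normalize(timepoint_means(average_duplicates(table).values))
    truth_ids = truth.probes.set_index("probe_id").loc[prof.data.index, "cluster_id"]
    return prof, truth_ids


class TestZNormalize:
    def test_arithmetic(self):
        z = z_normalize(_profiles([[1.0, 2.0, 3.0]], columns=[3.0, 6.0, 12.0]))
        assert np.allclose(z.data.to_numpy()[0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_row_flagged_zero(self):
        z = z_normalize(_profiles([[5.0] * 6]))
        assert np.allclose(z.data.to_numpy(), 0.0)
        assert bool(z.degenerate.iloc[0])

    def test_rows_standardized(self, rng):
        z = z_normalize(_profiles(rng.normal(8, 2, size=(40, 6))))
        assert np.allclose(z.data.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.data.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_idempotent_on_nondegenerate_rows(self, rng):
        z1 = z_normalize(_profiles(rng.normal(0, 1, size=(20, 6))))
        z2 = z_normalize(z1)
        assert np.allclose(z1.data.to_numpy(), z2.data.to_numpy(), atol=1e-12)


class TestKmeans:
    def test_three_separated_archetypes_fully_recovered(self):
        mix = {
            ArchetypeSpec("maternal_decay"): 0.34,
            ArchetypeSpec("unimodal_wave", center=24.0): 0.33,
            ArchetypeSpec("bimodal"): 0.33,
        }
        prof, truth_ids = recovery_profiles(mix, (0.0, 0.0), seed=1, n=120)
        result = kmeans_clusters(prof, k=3, seed=0)
        assert adjusted_rand_score(truth_ids, result.assignment) == 1.0

    def test_k_one_single_cluster(self, rng):
        prof = _profiles(rng.normal(size=(10, 6)))
        result = kmeans_clusters(prof, k=1, seed=0)
        assert result.n_clusters == 1

    def test_duplicate_rows_share_cluster(self, rng):
        rows = rng.normal(size=(8, 6))
        rows[7] = rows[0]
        prof = _profiles(rows)
        result = kmeans_clusters(prof, k=3, seed=0)
        assert result.assignment.iloc[0] == result.assignment.iloc[7]

    def test_k_exceeding_rows_errors(self, rng):
        with pytest.raises(ValueError):
            kmeans_clusters(_profiles(rng.normal(size=(3, 6))), k=5, seed=0)

    def test_deterministic(self, rng):
        prof = _profiles(rng.normal(size=(50, 6)))
        a = kmeans_clusters(prof, k=4, seed=0).assignment
        b = kmeans_clusters(prof, k=4, seed=0).assignment
        assert a.equals(b)


def oracle_cast(profiles, threshold):
    """Independent naive implementation of the greedy affinity rule."""
    data = profiles.data.to_numpy(dtype=float)
    n = len(data)

    def corr(a, b):
        xa, xb = data[a] - data[a].mean(), data[b] - data[b].mean()
        den = np.sqrt((xa**2).sum() * (xb**2).sum())
        return (xa @ xb) / den if den > 0 else np.nan

    aff = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                r = corr(i, j)
                aff[i, j] = 0.5 if np.isnan(r) else (r + 1) / 2

    labels = [-1] * n
    cid = 0
    unassigned = list(range(n))
    while unassigned:
        best, best_conn = unassigned[0], -1.0
        for g in unassigned:
            conn = sum(aff[g, h] for h in unassigned if h != g)
            if conn > best_conn:
                best, best_conn = g, conn
        cluster = [best]
        pool = [g for g in unassigned if g != best]
        while True:
            moved = False
            while True:
                cands = [(np.mean([aff[g, m] for m in cluster]), g) for g in pool]
                cands = [(a, g) for a, g in cands if a >= threshold]
                if not cands:
                    break
                a_best = max(a for a, _ in cands)
                g_best = min(g for a, g in cands if a == a_best)
                pool.remove(g_best)
                cluster.append(g_best)
                moved = True
            while len(cluster) > 1:
                means = [
                    (np.mean([aff[g, m] if g != m else 1.0 for m in cluster]), g)
                    for g in cluster
                ]
                lows = [(a, g) for a, g in means if a < threshold]
                if not lows:
                    break
                a_min = min(a for a, _ in lows)
                g_out = min(g for a, g in lows if a == a_min)
                cluster.remove(g_out)
                pool.append(g_out)
                pool.sort()
                moved = True
            if not moved:
                break
        for g in cluster:
            labels[g] = cid
        unassigned = [g for g in unassigned if labels[g] == -1]
        cid += 1
    return labels


class TestCast:
    def test_identical_profiles_single_cluster(self):
        prof = _profiles([[1.0, 2, 3, 2, 1, 0]] * 5)
        result = cast_clusters(prof)
        assert result.n_clusters == 1

    def test_anticorrelated_groups_split(self):
        up = [0.0, 1, 2, 3, 4, 5]
        down = [5.0, 4, 3, 2, 1, 0]
        prof = _profiles([up, up, down, down])
        result = cast_clusters(prof, affinity_threshold=0.7)
        assert result.n_clusters == 2
        assert result.assignment.iloc[0] == result.assignment.iloc[1]
        assert result.assignment.iloc[2] == result.assignment.iloc[3]

    def test_matches_exhaustive_oracle_on_small_instances(self, rng):
        for trial in range(6):
            n = int(rng.integers(4, 13))
            prof = _profiles(rng.normal(size=(n, 6)))
            got = cast_clusters(prof, affinity_threshold=0.7).assignment.to_numpy()
            expected = np.asarray(oracle_cast(prof, 0.7))
            assert adjusted_rand_score(got, expected) == 1.0

    def test_termination_invariant_mean_affinity(self):
        mix = {
            ArchetypeSpec("maternal_decay"): 0.25,
            ArchetypeSpec("unimodal_wave", center=24.0): 0.25,
            ArchetypeSpec("unimodal_wave", center=36.0): 0.25,
            ArchetypeSpec("bimodal"): 0.25,
        }
        prof, _ = recovery_profiles(mix, (0.25, 0.10), seed=5, n=200)
        result = cast_clusters(prof, affinity_threshold=0.7)
        aff = affinity_matrix(prof)
        idx = {g: i for i, g in enumerate(prof.data.index)}
        for cid in result.assignment.unique():
            members = [idx[g] for g in result.members(cid)]
            block = aff[np.ix_(members, members)]
            np.fill_diagonal(block, 1.0)
            assert (block.mean(axis=1) >= 0.7 - 1e-12).all()

    def test_partition(self, rng):
        prof = _profiles(rng.normal(size=(30, 6)))
        result = cast_clusters(prof)
        assert (result.assignment >= 0).all()
        assert len(result.assignment) == 30


class TestRecovery:
    def test_both_methods_recover_planted_archetypes(self, four_archetype_mix):
        for noise, floor_ari in [((0.0, 0.0), 0.95), ((0.25, 0.10), 0.7)]:
            prof, truth_ids = recovery_profiles(four_archetype_mix, noise, seed=11)
            km = kmeans_clusters(prof, k=4, seed=0)
            ca = cast_clusters(prof, affinity_threshold=0.7)
            assert adjusted_rand_score(truth_ids, km.assignment) >= floor_ari
            assert adjusted_rand_score(truth_ids, ca.assignment) >= floor_ari


class TestAffinitySearch:
    def test_planted_maternal_recovered_exactly(self):
        mix = {
            ArchetypeSpec("maternal_decay"): 0.3,
            ArchetypeSpec("unimodal_wave", center=24.0): 0.4,
            ArchetypeSpec("bimodal"): 0.3,
        }
        table, truth = generate_timecourse(
            design=ArrayDesign(n_probes=200), archetype_mix=mix,
            noise=(0.0, 0.0), distortion="identity", seed=2,
        )
        prof = z_normalize(timepoint_means(average_duplicates(table).values))
        hits = set(affinity_search(prof))
        assert hits == set(truth.probes_of_kind("maternal_decay"))

    def test_gene_matches_its_own_profile(self, rng):
        prof = _profiles(rng.normal(size=(5, 6)))
        hits = affinity_search(prof, seed_profile=prof.data.iloc[2].to_numpy())
        assert "g2" in hits

    def test_flat_gene_excluded(self):
        prof = _profiles([[1.0] * 6])
        assert affinity_search(prof) == []

    def test_seed_length_validated(self):
        with pytest.raises(ValueError):
            affinity_search(_profiles([[1.0] * 6]), seed_profile=[1, 2, 3])

    def test_default_seed_is_strictly_decreasing(self):
        seed = maternal_seed_profile(TIMEPOINTS)
        assert (np.diff(seed) < 0).all()


class TestModality:
    def test_elevated_at_both_ends_is_bimodal(self):
        call = classify_modality([2.0, -1, -1, -1, -1, 1.5], TIMEPOINTS)
        assert call.kind == "bimodal"

    def test_monotone_decreasing_is_peak_at_start(self):
        call = classify_modality([1.5, 0.9, 0.2, -0.5, -0.9, -1.2], TIMEPOINTS)
        assert call.kind == "peak_at_start"

    def test_constant_is_flat(self):
        assert classify_modality([0.0] * 6, TIMEPOINTS).kind == "flat"

    def test_unimodal_reports_peak_time(self):
        call = classify_modality([-1.0, -0.5, 0.3, 1.8, 0.2, -0.8], TIMEPOINTS)
        assert call.kind == "unimodal"
        assert call.peak_time == 24.0
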