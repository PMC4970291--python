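"""OTU clustering and alpha diversity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from mockamp import (
    DistanceMatrix,
    OTUTable,
    alpha_diversity,
    cluster_otus,
    estimated_total_otus,
    mock_reference_set,
    pairwise_distances,
)

from .oracles import average_linkage_partition


def dm_from(matrix) -> DistanceMatrix:
    m = np.asarray(matrix, dtype=float)
    return DistanceMatrix(ids=[f"s{i}" for i in range(len(m))], data=m)


def otu_table(counts: dict) -> OTUTable:
    df = pd.DataFrame(counts).T
    df.columns = [f"S{i+1}" for i in range(df.shape[1])]
    return OTUTable(members={k: [k] for k in df.index}, counts=df.astype(int), cutoff=0.03)


class TestPairwiseDistances:
    def test_identical_pair_zero(self):
        dm = pairwise_distances({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert dm.data[0, 1] == 0.0

    def test_divergent_copy_pair_near_nominal(self, mock_refs):
        pair = {n: mock_refs.sequences[n] for n in mock_refs.names
                if n.startswith("Haemophilus")}
        dm = pairwise_distances(pair)
        assert dm.data[0, 1] == pytest.approx(0.06, abs=0.01)

    def test_symmetry_and_shape(self, mock_refs):
        seqs = {n: mock_refs.sequences[n] for n in mock_refs.names[:6]}
        dm = pairwise_distances(seqs)
        assert dm.data.shape == (6, 6)
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)

    def test_distance_cap_only_affects_far_pairs(self, mock_refs):
        seqs = {n: mock_refs.sequences[n] for n in mock_refs.names[:8]}
        exact = pairwise_distances(seqs)
        capped = pairwise_distances(seqs, max_distance=0.1)
        near = exact.data <= 0.1
        assert np.allclose(exact.data[near], capped.data[near])
        assert np.all(capped.data[~near] >= 0.1)


class TestClusterOTUs:
    def test_all_far_apart_one_otu_each(self):
        dm = dm_from([[0, 0.5, 0.6], [0.5, 0, 0.7], [0.6, 0.7, 0]])
        otus = cluster_otus(dm, 0.03)
        assert otus.n_otus == 3

    def test_close_pair_merges(self):
        dm = dm_from([[0, 0.02], [0.02, 0]])
        assert cluster_otus(dm, 0.03).n_otus == 1

    def test_mock_references_form_twenty_bacterial_otus(self, mock_refs):
        """19 bacterial genomes with one ~6%-divergent intragenomic copy
        pair yield 20 bacterial OTUs at the 0.03 cutoff."""
        bact = {n: s for n, s in mock_refs.sequences.items()
                if mock_refs.is_bacterial[n]}
        dm = pairwise_distances(bact)
        otus = cluster_otus(dm, 0.03)
        assert otus.n_otus == 20

    def test_read_conservation(self, mock_refs):
        seqs = {n: mock_refs.sequences[n] for n in mock_refs.names[:5]}
        dm = pairwise_distances(seqs)
        counts = pd.DataFrame(
            {"S1": [5, 1, 2, 0, 1], "S2": [0, 3, 1, 1, 1]}, index=dm.ids
        )
        otus = cluster_otus(dm, 0.03, counts=counts)
        assert otus.total_reads() == counts.to_numpy().sum()

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=2, max_value=8), st.integers(0, 10_000))
    def test_matches_naive_average_linkage_oracle(self, n, seed):
        """Partitions match a from-scratch average-distance oracle on
        random instances of up to 8 sequences."""
        rng = np.random.default_rng(seed)
        D = np.round(rng.random((n, n)) * 0.2, 3)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        cutoff = 0.08
        otus = cluster_otus(dm_from(D), cutoff)
        got = {
            frozenset(int(m[1:]) for m in members)
            for members in otus.members.values()
        }
        assert got == average_linkage_partition(D, cutoff)

    def test_matches_scipy_upgma_cut(self):
        """Cross-check against scipy's average-linkage dendrogram cut."""
        rng = np.random.default_rng(99)
        n = 40
        D = rng.random((n, n)) * 0.3
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        cutoff = 0.12
        otus = cluster_otus(dm_from(D), cutoff)
        Z = linkage(squareform(D, checks=False), method="average")
        labels = fcluster(Z, t=cutoff, criterion="distance")
        scipy_parts = {}
        for i, lab in enumerate(labels):
            scipy_parts.setdefault(lab, set()).add(i)
        got = {
            frozenset(int(m[1:]) for m in members)
            for members in otus.members.values()
        }
        assert got == {frozenset(v) for v in scipy_parts.values()}

    def test_invalid_cutoff_rejected(self):
        dm = dm_from([[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError):
            cluster_otus(dm, 0.0)


class TestAlphaDiversity:
    def test_single_otu_degenerate(self):
        rep = alpha_diversity(otu_table({"o1": [10]}))
        assert rep.per_sample.loc["S1", "observed_otus"] == 1
        assert rep.per_sample.loc["S1", "shannon"] == 0.0
        # every read identical: unbiased inverse Simpson is exactly 1
        assert rep.per_sample.loc["S1", "inverse_simpson"] == pytest.approx(1.0)

    def test_two_even_otus_closed_forms(self):
        rep = alpha_diversity(otu_table({"a": [50], "b": [50]}))
        assert rep.per_sample.loc["S1", "shannon"] == pytest.approx(np.log(2))
        # unbiased form: 1 / (2 * 50*49 / (100*99)) = 99/49
        assert rep.per_sample.loc["S1", "inverse_simpson"] == pytest.approx(99 / 49)

    def test_chao_no_singletons_equals_observed(self):
        rep = alpha_diversity(otu_table({"a": [5], "b": [3], "c": [2]}))
        assert rep.per_sample.loc["S1", "chao"] == rep.per_sample.loc["S1", "observed_otus"]

    def test_chao_closed_form_with_rare_otus(self):
        # S_obs=4, n1=2, n2=1: chao = 4 + 2*1/(2*2) = 4.5
        rep = alpha_diversity(otu_table({"a": [5], "b": [1], "c": [1], "d": [2]}))
        assert rep.per_sample.loc["S1", "chao"] == pytest.approx(4.5)

    def test_chao_at_least_observed_and_invariants(self, noisy_table, mock_refs):
        counts, id_to_seq = noisy_table.indexed()
        dm = pairwise_distances(id_to_seq, max_distance=0.1)
        otus = cluster_otus(dm, 0.03, counts=counts)
        rep = alpha_diversity(otus)
        for s in rep.per_sample.index:
            row = rep.per_sample.loc[s]
            assert row["chao"] >= row["observed_otus"]
            assert row["shannon"] >= 0
            assert np.isnan(row["inverse_simpson"]) or row["inverse_simpson"] >= 1

    def test_zero_read_sample_rejected(self):
        with pytest.raises(ValueError, match="zero reads"):
            alpha_diversity(otu_table({"a": [3, 0], "b": [1, 0]}))

    def test_sem_across_samples(self):
        rep = alpha_diversity(otu_table({"a": [10, 20], "b": [10, 0]}))
        obs = rep.per_sample["observed_otus"]
        assert rep.sem("observed_otus") == pytest.approx(obs.std(ddof=1) / np.sqrt(2))


class TestEstimatedTotal:
    def test_no_rare_otus_estimate_equals_observed(self):
        est = estimated_total_otus(otu_table({"a": [5], "b": [4]}))
        assert est.estimate == 2.0

    def test_many_singletons_inflate_estimate(self):
        counts = {f"o{i}": [1] for i in range(30)}
        counts["big"] = [100]
        est = estimated_total_otus(otu_table(counts))
        assert est.estimate > 5 * 31

    def test_true_richness_recovered_with_deep_sampling(self, flat_refs):
        """Deeply sampled noise-free community: Chao converges on the true
        template count."""
        from mockamp import SimConfig, dereplicate, simulate_run

        cfg = SimConfig(n_samples=2, depth=3000, sub_rate=0.0, ins_rate=0.0,
                        del_rate=0.0, chimera_prob=0.0, noise_prob=0.0, seed=41)
        run = simulate_run(flat_refs, cfg)
        table = dereplicate(run.sequences_by_sample())
        counts, id_to_seq = table.indexed()
        dm = pairwise_distances(id_to_seq, max_distance=0.1)
        otus = cluster_otus(dm, 0.03, counts=counts)
        est = estimated_total_otus(otus)
        # 21 mutually >3%-divergent templates (19 bacteria + the divergent
        # copy pair + the archaeal control), all deeply sampled
        assert est.estimate == pytest.approx(21, abs=1)
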