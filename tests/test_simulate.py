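"""Reference generation and ground-truthed read simulation."""

import numpy as np
import pytest

from mockamp import (
    SimConfig,
    dereplicate,
    generate_references,
    mock_reference_set,
    pairwise_identity,
    simulate_run,
)
from mockamp.align import align_pair


class TestGenerateReferences:
    def test_constrained_pair_hits_target_identity(self):
        refs = generate_references(
            20, length=250, divergence_spec={(0, 1): 0.94}, seed=3
        )
        names = refs.names
        ident = pairwise_identity(refs.sequences[names[0]], refs.sequences[names[1]])
        assert 93.0 <= ident <= 95.0

    def test_identity_one_gives_identical_strings(self):
        refs = generate_references(2, length=100, divergence_spec={(0, 1): 1.0}, seed=0)
        a, b = refs.sequences.values()
        assert a == b

    def test_low_identity_targets_realized(self):
        refs = generate_references(
            3, length=200, divergence_spec={(0, 1): 0.80}, seed=1
        )
        seqs = list(refs.sequences.values())
        assert pairwise_identity(seqs[0], seqs[1]) <= 81.0

    def test_unconstrained_pairs_well_below_otu_cutoff(self):
        refs = generate_references(6, length=200, seed=2)
        seqs = list(refs.sequences.values())
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert pairwise_identity(seqs[i], seqs[j]) < 97.0

    def test_contradictory_spec_rejected(self):
        with pytest.raises(ValueError):
            generate_references(
                3, divergence_spec={(0, 1): 0.9, (1, 2): 0.9}, seed=0
            )
        with pytest.raises(ValueError):
            generate_references(2, divergence_spec={(0, 1): 1.5}, seed=0)


class TestMockReferenceSet:
    def test_twenty_members_one_divergent_pair(self, mock_refs):
        # 19 bacteria + 1 archaeon; one genus contributes two ~94% copies
        assert len(mock_refs) == 21
        pair = [n for n in mock_refs.names if n.startswith("Haemophilus")]
        assert len(pair) == 2
        ident = pairwise_identity(
            mock_refs.sequences[pair[0]], mock_refs.sequences[pair[1]]
        )
        assert 93.0 <= ident <= 95.0

    def test_member_weights_are_balanced(self, mock_refs):
        # 16S-balanced design: every member's templates sum to equal weight
        by_genus = {}
        for n in mock_refs.names:
            by_genus.setdefault(mock_refs.taxa[n], 0.0)
            by_genus[mock_refs.taxa[n]] += mock_refs.template_weights[n]
        assert all(w == pytest.approx(1.0) for w in by_genus.values())

    def test_archaeal_control_flagged(self, mock_refs):
        nonbact = [n for n in mock_refs.names if not mock_refs.is_bacterial[n]]
        assert len(nonbact) == 1
        assert mock_refs.taxa[nonbact[0]] == "Methanobrevibacter"


class TestSimulateRun:
    def test_seed_determinism(self, flat_refs):
        cfg = SimConfig(n_samples=2, depth=50, seed=9)
        a = simulate_run(flat_refs, cfg)
        b = simulate_run(flat_refs, cfg)
        assert a.reads == b.reads
        assert a.truth.equals(b.truth)

    def test_each_sample_has_exactly_depth_reads(self, noisy_run):
        for sample, pairs in noisy_run.reads.items():
            assert len(pairs) == noisy_run.config.depth

    def test_read_ids_unique_and_covered_by_truth(self, noisy_run):
        ids = [rid for pairs in noisy_run.reads.values() for rid, _ in pairs]
        assert len(ids) == len(set(ids))
        assert set(ids) == set(noisy_run.truth["read_id"])

    def test_noise_free_reads_are_exact_template_copies(self, noisefree_run, flat_refs):
        templates = set(flat_refs.sequences.values())
        for pairs in noisefree_run.reads.values():
            for _, seq in pairs:
                assert seq in templates
        table = dereplicate(noisefree_run.sequences_by_sample())
        drawn = set(noisefree_run.truth["source"])
        assert table.n_unique == len(drawn)

    def test_truth_table_error_counts_recoverable_by_alignment(self, mock_refs):
        """For sparse substitution-only reads the injected error count
        equals the edit distance to the source template.  (At dense error
        loads gapped realignments can undercut the substitution count, so
        equality is asserted in the sparse regime only.)"""
        cfg = SimConfig(
            n_samples=1, depth=150, sub_rate=0.005, ins_rate=0.0, del_rate=0.0,
            chimera_prob=0.0, noise_prob=0.0, bad_read_prob=0.0, seed=13,
        )
        run = simulate_run(mock_refs, cfg)
        seqs = dict(run.reads["S01"])
        for row in run.truth.itertuples():
            aln = align_pair(seqs[row.read_id], mock_refs.sequences[row.source])
            assert aln.edit_distance == row.n_sub

    def test_truth_table_indel_counts_bound_alignment_distance(self, mock_refs):
        cfg = SimConfig(
            n_samples=1, depth=100, sub_rate=0.002, ins_rate=0.002, del_rate=0.002,
            chimera_prob=0.0, noise_prob=0.0, seed=14,
        )
        run = simulate_run(mock_refs, cfg)
        seqs = dict(run.reads["S01"])
        exact = 0
        for row in run.truth.itertuples():
            aln = align_pair(seqs[row.read_id], mock_refs.sequences[row.source])
            injected = row.n_sub + row.n_ins + row.n_del
            assert aln.edit_distance <= injected
            exact += aln.edit_distance == injected
        # adjacent edits can collapse, but almost never at these rates
        assert exact >= 0.95 * len(run.truth)

    def test_chimeras_join_two_templates_at_breakpoint(self, mock_refs):
        cfg = SimConfig(
            n_samples=1, depth=200, sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
            chimera_prob=1.0, noise_prob=0.0, seed=15,
        )
        run = simulate_run(mock_refs, cfg)
        seqs = dict(run.reads["S01"])
        chimeric = run.truth[run.truth["is_chimera"]]
        assert len(chimeric) == 200
        for row in chimeric.itertuples():
            a = mock_refs.sequences[row.source]
            b = mock_refs.sequences[row.source2]
            assert seqs[row.read_id] == a[: row.breakpoint] + b[row.breakpoint :]
            assert 0 < row.breakpoint < min(len(a), len(b))

    def test_low_efficiency_template_underdetected(self, flat_refs):
        """A template amplifying at 1% efficiency is read far below its
        nominal abundance share."""
        refs = mock_reference_set(seed=11, low_efficiency={"Salmonella": 0.01})
        cfg = SimConfig(n_samples=2, depth=2000, sub_rate=0.0, chimera_prob=0.0,
                        ins_rate=0.0, del_rate=0.0, noise_prob=0.0, seed=16)
        run = simulate_run(refs, cfg)
        frac = (run.truth["source"] == "Salmonella_1").mean()
        nominal = 1.0 / 20.0
        assert frac < nominal / 5.0

    def test_template_draws_follow_weights(self, flat_refs):
        """Observed template frequencies match the weight distribution
        within multinomial 3-sigma."""
        cfg = SimConfig(n_samples=3, depth=2000, sub_rate=0.0, ins_rate=0.0,
                        del_rate=0.0, chimera_prob=0.0, noise_prob=0.0, seed=17)
        run = simulate_run(flat_refs, cfg)
        n = len(run.truth)
        p = flat_refs.sampling_probabilities()
        counts = run.truth["source"].value_counts()
        for name, pi in zip(flat_refs.names, p):
            obs = counts.get(name, 0)
            sigma = np.sqrt(n * pi * (1 - pi))
            assert abs(obs - n * pi) < 3.5 * sigma
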