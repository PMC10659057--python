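"""Dominant homologs, collinear backbone, and precedence-ordered labeling."""

import itertools

import numpy as np
import pytest

from asmcompare import (
    Label,
    SimulationConfig,
    apply_filters,
    backbone,
    catalog_from_sequences,
    classify_blocks,
    dominant_strand,
    dominant_target,
    simulate,
)
from asmcompare.classifier import UndefinedHomologError

from .conftest import make_block


def two_chromosome_catalogs():
    query = catalog_from_sequences(
        {"q_chr1": "A" * 200_000, "q_chr2": "A" * 200_000, "q_scrap": "A" * 5_000},
        chromosomes=["q_chr1", "q_chr2"],
    )
    ref = catalog_from_sequences(
        {"t_chr1": "A" * 200_000, "t_chr2": "A" * 200_000, "t_scrap": "A" * 5_000},
        chromosomes=["t_chr1", "t_chr2"],
    )
    return query, ref


class TestDominantTarget:
    def test_argmax_by_supporting_bp(self):
        blocks = [
            make_block(query_name="q_chr1", query_end=8_000, target_name="t_chr1"),
            make_block(query_name="q_chr1", query_end=1_000, target_name="t_chr2"),
        ]
        assert dominant_target(blocks, "q_chr1") == ("t_chr1", 8_000)

    def test_single_block_is_its_own_target(self):
        blocks = [make_block(query_name="q_chr1", target_name="t_chr9")]
        assert dominant_target(blocks, "q_chr1")[0] == "t_chr9"

    def test_tie_broken_lexicographically(self):
        blocks = [
            make_block(query_name="q", query_end=5_000, target_name="t_b"),
            make_block(query_name="q", query_end=5_000, target_name="t_a"),
        ]
        assert dominant_target(blocks, "q")[0] == "t_a"

    def test_no_blocks_signals_undefined_homolog(self):
        with pytest.raises(UndefinedHomologError):
            dominant_target([], "q_chr1")

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            blocks = []
            for _ in range(int(rng.integers(1, 30))):
                span = int(rng.integers(100, 10_000))
                blocks.append(
                    make_block(
                        query_name="q",
                        query_end=span,
                        target_name=f"t{int(rng.integers(0, 4))}",
                    )
                )
            sums = {}
            for b in blocks:
                sums[b.target_name] = sums.get(b.target_name, 0) + b.query_span
            expected = max(sorted(sums), key=lambda t: sums[t])
            assert dominant_target(blocks, "q") == (expected, sums[expected])


class TestDominantStrand:
    def test_majority_bp_wins(self):
        blocks = [
            make_block(query_end=10_000, strand="+"),
            make_block(query_end=2_000, strand="-"),
        ]
        assert dominant_strand(blocks, "t1") == "+"

    def test_exact_tie_is_forward(self):
        blocks = [
            make_block(query_end=5_000, strand="-"),
            make_block(query_end=5_000, strand="+"),
        ]
        assert dominant_strand(blocks, "t1") == "+"

    def test_matches_per_strand_summation_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            blocks = [
                make_block(
                    query_end=int(rng.integers(100, 10_000)),
                    strand="+" if rng.random() < 0.5 else "-",
                )
                for _ in range(int(rng.integers(1, 25)))
            ]
            fwd = sum(b.query_span for b in blocks if b.strand == "+")
            rev = sum(b.query_span for b in blocks if b.strand == "-")
            assert dominant_strand(blocks, "t1") == ("+" if fwd >= rev else "-")


def brute_force_backbone_weight(blocks, dominant="+"):
    """Max total weight over all strictly increasing subsets (n <= 15)."""
    sign = 1 if dominant == "+" else -1
    order = sorted(range(len(blocks)),
                   key=lambda i: (blocks[i].query_name, sign * blocks[i].query_start))
    starts = [blocks[i].target_start for i in order]
    weights = [blocks[i].query_span for i in order]
    best = 0
    for r in range(1, len(blocks) + 1):
        for combo in itertools.combinations(range(len(blocks)), r):
            if all(starts[a] < starts[b] for a, b in zip(combo, combo[1:])):
                best = max(best, sum(weights[i] for i in combo))
    return best


class TestBackbone:
    def _chain(self, positions_and_spans):
        blocks = []
        qpos = 0
        for tstart, span in positions_and_spans:
            blocks.append(
                make_block(
                    query_start=qpos, query_end=qpos + span,
                    target_start=tstart, target_end=tstart + span,
                    block_len=span,
                )
            )
            qpos += span
        return blocks

    def test_collinear_blocks_all_in_backbone(self):
        blocks = self._chain([(0, 1_000), (2_000, 1_000), (4_000, 1_000)])
        assert backbone(blocks) == {0, 1, 2}

    def test_small_displaced_block_excluded(self):
        spans = [(i * 12_000, 10_000) for i in range(5)]
        blocks = self._chain(spans)
        # a 2 kbp block whose target position jumps backwards, placed last
        # in query order
        stray = make_block(
            query_start=60_000, query_end=62_000,
            target_start=5_000, target_end=7_000, block_len=2_000,
        )
        members = backbone(blocks + [stray])
        assert members == {0, 1, 2, 3, 4}

    def test_reverse_dominant_reverses_query_order(self):
        # target positions decrease along the query: collinear for a
        # reverse-dominant target
        blocks = self._chain([(40_000, 1_000), (20_000, 1_000), (0, 1_000)])
        assert backbone(blocks, dominant="-") == {0, 1, 2}
        assert len(backbone(blocks, dominant="+")) == 1

    def test_weight_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            n = int(rng.integers(1, 13))
            blocks = []
            qpos = 0
            for _ in range(n):
                span = int(rng.integers(100, 5_000))
                tstart = int(rng.integers(0, 100_000))
                blocks.append(
                    make_block(
                        query_start=qpos, query_end=qpos + span,
                        target_start=tstart, target_end=tstart + span,
                        block_len=span,
                    )
                )
                qpos += span + int(rng.integers(0, 1_000))
            members = backbone(blocks)
            weight = sum(blocks[i].query_span for i in members)
            assert weight == brute_force_backbone_weight(blocks)


class TestClassifyBlocks:
    def test_translocation_takes_precedence_over_inversion(self):
        query, ref = two_chromosome_catalogs()
        blocks = [
            make_block(query_name="q_chr1", query_start=0, query_end=100_000,
                       query_seq_len=200_000, target_name="t_chr1",
                       target_start=0, target_end=100_000),
            # non-dominant target AND opposite strand
            make_block(query_name="q_chr1", query_start=100_000, query_end=110_000,
                       query_seq_len=200_000, strand="-", target_name="t_chr2",
                       target_start=0, target_end=10_000),
        ]
        labeled, _ = classify_blocks(blocks, query, ref)
        assert labeled[1].label is Label.TRANSLOCATION

    def test_debris_takes_precedence_over_everything(self):
        query, ref = two_chromosome_catalogs()
        block = make_block(query_name="q_scrap", query_seq_len=5_000,
                           query_start=0, query_end=5_000, strand="-",
                           target_name="t_chr2", target_start=0, target_end=5_000)
        labeled, _ = classify_blocks([block], query, ref)
        assert labeled[0].label is Label.DEBRIS

    def test_debris_side_switch(self):
        query, ref = two_chromosome_catalogs()
        block = make_block(query_name="q_chr1", query_seq_len=200_000,
                           query_start=0, query_end=5_000,
                           target_name="t_scrap", target_start=0, target_end=5_000)
        labeled_q, _ = classify_blocks([block], query, ref, debris_side="query")
        labeled_r, _ = classify_blocks([block], query, ref, debris_side="reference")
        assert labeled_q[0].label is not Label.DEBRIS
        assert labeled_r[0].label is Label.DEBRIS

    def test_debris_to_debris_collinear_is_congruent(self):
        query, ref = two_chromosome_catalogs()
        block = make_block(query_name="q_scrap", query_seq_len=5_000,
                           query_start=0, query_end=5_000,
                           target_name="t_scrap", target_start=0, target_end=5_000)
        labeled, _ = classify_blocks([block], query, ref)
        assert labeled[0].label is Label.CONGRUENT

    def test_missing_sequence_names_the_offender(self):
        query, ref = two_chromosome_catalogs()
        block = make_block(query_name="mystery", query_seq_len=100_000)
        with pytest.raises(KeyError, match="mystery"):
            classify_blocks([block], query, ref)

    def test_no_reverse_blocks_means_no_inversions(self, default_sim):
        outcome = apply_filters(default_sim.blocks)
        forward_only = [b for b in outcome.retained if b.strand == "+"]
        labeled, _ = classify_blocks(
            forward_only, default_sim.query_catalog, default_sim.ref_catalog
        )
        assert all(lb.label is not Label.INVERSION for lb in labeled)

    def test_label_multiset_invariant_to_input_order(self, small_sim):
        outcome = apply_filters(small_sim.blocks)
        labeled, _ = classify_blocks(
            outcome.retained, small_sim.query_catalog, small_sim.ref_catalog
        )
        baseline = sorted((id(lb.block), lb.label.value) for lb in labeled)
        shuffled = list(outcome.retained)
        np.random.default_rng(1).shuffle(shuffled)
        labeled2, _ = classify_blocks(
            shuffled, small_sim.query_catalog, small_sim.ref_catalog
        )
        assert sorted((id(lb.block), lb.label.value) for lb in labeled2) == baseline


class TestSimulatorTruth:
    def test_single_inversion_recovered_exactly(self):
        cfg = SimulationConfig(
            seed=5, chromosome_lengths=(500_000, 500_000), x_index=1,
            n_inversions=1, n_translocations=0, n_relocations=0, n_debris=0,
            min_event_size=20_000, max_event_size=20_000,
            inversion_size_mode=20_000, inversion_sigma=1e-9,
            repeat_densities=(10.0, 20.0),
        )
        sim = simulate(cfg, with_noise=False)
        outcome = apply_filters(sim.blocks)
        labeled, _ = classify_blocks(outcome.retained, sim.query_catalog, sim.ref_catalog)
        inv = [lb for lb in labeled if lb.label is Label.INVERSION]
        assert len(inv) == 1
        assert inv[0].block.query_span == sim.events.events[0].length
        assert all(
            lb.label in (Label.CONGRUENT, Label.INVERSION) for lb in labeled
        )

    def test_identity_comparison_is_all_congruent(self):
        cfg = SimulationConfig(
            seed=6, chromosome_lengths=(400_000, 400_000), x_index=1,
            n_inversions=0, n_translocations=0, n_relocations=0, n_debris=0,
            repeat_densities=(10.0, 20.0), insert_gaps=False,
        )
        sim = simulate(cfg, with_noise=False)
        outcome = apply_filters(sim.blocks)
        labeled, _ = classify_blocks(outcome.retained, sim.query_catalog, sim.ref_catalog)
        assert all(lb.label is Label.CONGRUENT for lb in labeled)
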