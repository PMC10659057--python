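import numpy as np
import pytest
from hypothesis import settings

from asmcompare import AlignmentBlock, SimulationConfig, simulate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_block(
    query_name="q1",
    query_seq_len=100_000,
    query_start=0,
    query_end=10_000,
    strand="+",
    target_name="t1",
    target_seq_len=200_000,
    target_start=0,
    target_end=10_000,
    residue_matches=None,
    block_len=None,
    mapq=60,
):
    """An AlignmentBlock with sane defaults for single-field tweaks."""
    if block_len is None:
        block_len = query_end - query_start
    if residue_matches is None:
        residue_matches = block_len
    return AlignmentBlock(
        query_name=query_name,
        query_seq_len=query_seq_len,
        query_start=query_start,
        query_end=query_end,
        strand=strand,
        target_name=target_name,
        target_seq_len=target_seq_len,
        target_start=target_start,
        target_end=target_end,
        residue_matches=residue_matches,
        block_len=block_len,
        mapq=mapq,
    )


def random_blocks(rng: np.random.Generator, n: int, n_queries: int = 5, n_targets: int = 5):
    """Random valid blocks spanning the filter thresholds on every axis."""
    blocks = []
    for _ in range(n):
        qlen = int(rng.integers(500, 2_000_000))
        span = int(rng.integers(100, min(qlen, 50_000)))
        qstart = int(rng.integers(0, qlen - span + 1))
        tlen = 2_000_000
        tspan = span
        tstart = int(rng.integers(0, tlen - tspan + 1))
        block_len = int(rng.integers(span, span + 2_000))
        matches = int(rng.integers(int(0.5 * block_len), block_len + 1))
        blocks.append(
            AlignmentBlock(
                query_name=f"q{int(rng.integers(0, n_queries))}",
                query_seq_len=qlen,
                query_start=qstart,
                query_end=qstart + span,
                strand="+" if rng.random() < 0.5 else "-",
                target_name=f"t{int(rng.integers(0, n_targets))}",
                target_seq_len=tlen,
                target_start=tstart,
                target_end=tstart + tspan,
                residue_matches=matches,
                block_len=block_len,
                mapq=int(rng.integers(0, 61)),
            )
        )
    return blocks


@pytest.fixture(scope="session")
def small_sim():
    """A compact seeded assembly pair, noise-free, shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        chromosome_lengths=(600_000,) * 3,
        x_index=2,
        n_inversions=3,
        n_translocations=2,
        n_relocations=2,
        n_debris=2,
        max_event_size=60_000,
        repeat_densities=(20.0, 25.0, 50.0),
    )
    return simulate(cfg, with_noise=False)


@pytest.fixture(scope="session")
def default_sim():
    """The default 10 Mbp study conditions with fragmentation noise."""
    return simulate(SimulationConfig(seed=7))
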