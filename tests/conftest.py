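"""Shared fixtures and independent alignment oracles.

The Smith-Waterman oracle wraps Bio.Align.PairwiseAligner (gapped, local)
and is deliberately independent of the package's seed-and-extend engine:
tests compare the two routes, never one library call against itself.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from virocat.config import PipelineConfig
from virocat.io import Contig

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


def random_seq(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return rng.choice(BASES, size=length).tobytes().decode()


def plant_region(target: str, donor: str, start: int, length: int,
                 n_mismatch: int, seed: int) -> str:
    """Copy ``donor[start:start+length]`` into the same position of
    ``target`` with ``n_mismatch`` substitutions."""
    rng = np.random.default_rng(seed)
    block = np.frombuffer(donor[start:start + length].encode(),
                          dtype=np.uint8).copy()
    for pos in rng.choice(length, size=n_mismatch, replace=False):
        block[pos] = rng.choice(BASES[BASES != block[pos]])
    return target[:start] + block.tobytes().decode() + target[start + length:]


def sw_oracle_region(query: str, subject: str, min_identity: float = 95.0,
                     min_len: int = 100):
    """Best gapped local alignment (Smith-Waterman scoring) as a query
    region, or None when nothing passes the identity/length thresholds.

    Scoring matches the engine's match/mismatch economy (+1/-2) with
    affine gaps so that a gapped optimum can only beat the ungapped one.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(mode="local", match_score=1,
                                    mismatch_score=-2, open_gap_score=-5,
                                    extend_gap_score=-2)
    alignments = aligner.align(query, subject)
    try:
        aln = alignments[0]
    except IndexError:
        return None
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    if aligned_cols == 0:
        return None
    identity = 100.0 * counts.identities / aligned_cols
    q_blocks = aln.aligned[0]
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    if identity >= min_identity and (q_end - q_start) >= min_len:
        return q_start, q_end
    return None


@pytest.fixture(scope="session")
def small_workspace(tmp_path_factory) -> Path:
    """A compact synthetic workspace shared by pipeline-level tests."""
    from virocat.simulate import simulate_workspace

    root = tmp_path_factory.mktemp("ws") / "small"
    simulate_workspace(root, n_genomes=40, n_samples=3, seed=11)
    return root
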