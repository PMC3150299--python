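import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from estpoly.alnio import Pileup
from estpoly.simulate import SimulationConfig, generate_reference_set, simulate_est_reads


@pytest.fixture
def rng():
    return np.random.default_rng(20110718)


def random_sourced_pileup(rng, n_columns: int, max_depth: int = 40) -> Pileup:
    """A single-contig two-source pileup with a mix of diffuse and
    near-fixed columns, exercising the calling thresholds' boundaries."""
    pile = Pileup({"c": n_columns}, ["A", "B"])
    for src in ("A", "B"):
        counts = pile.counts("c", src)
        for pos in range(n_columns):
            depth = int(rng.integers(0, max_depth + 1))
            if depth == 0:
                continue
            style = rng.random()
            if style < 0.4:          # nearly fixed for one base
                probs = np.full(4, 0.03)
                probs[rng.integers(4)] = 0.91
            elif style < 0.7:        # two-base mixture
                probs = np.zeros(4)
                i, j = rng.choice(4, size=2, replace=False)
                f = rng.uniform(0.5, 1.0)
                probs[i], probs[j] = f, 1 - f
            else:                    # diffuse
                probs = rng.dirichlet(np.ones(4))
            counts[pos, :4] = rng.multinomial(depth, probs / probs.sum())
    return pile


@pytest.fixture(scope="session")
def clean_simulation():
    """Error-free, het-free two-source simulation used by several
    recovery tests: 20 contigs of ~1 kb at 20x per source."""
    cfg = SimulationConfig(n_contigs=20, fixed_divergence=2e-3,
                           het_rate=0.0, error_rate=0.0,
                           read_depth=20.0, seed=11)
    refset = generate_reference_set(cfg)
    reads, placements = simulate_est_reads(refset, cfg)
    return cfg, refset, reads, placements
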