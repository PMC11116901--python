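"""Shared fixtures: small genomes for unit tests, desk-scale for recovery
suites.  Everything is generated programmatically with fixed seeds."""

from __future__ import annotations

import numpy as np
import pytest

from translokit import generate_wt_genome, reciprocal_junction_pair, simulate_mutant


@pytest.fixture(scope="session")
def small_wt():
    """3 chromosomes x 30 kb: fast enough for per-test derivations."""
    return generate_wt_genome(3, [30_000] * 3, 0.35, seed=11, name="WT")


@pytest.fixture(scope="session")
def desk_wt():
    """The desk-scale karyotype: 11 chromosomes x 200 kb."""
    return generate_wt_genome(11, [200_000] * 11, 0.35, seed=7, name="WT-a")


@pytest.fixture(scope="session")
def mta_small(small_wt):
    """An MT-a-like reciprocal event on the small genome: 3 bp deletions on
    each junction, TTTAT micro-homology on the first."""
    pair = reciprocal_junction_pair(
        ("Chr1", 18_000), ("Chr2", 12_000), deletions=(3, 3), motifs=("TTTAT", "")
    )
    wt, mt, truth = simulate_mutant(small_wt, [pair], "MTa")
    return wt, mt, truth


def random_exchange(rng: np.random.Generator, lengths: dict[str, int],
                    chroms=None, max_deletion: int = 25):
    """A random reciprocal exchange with proximal-flank deletions 0..25 bp."""
    names = list(lengths) if chroms is None else list(chroms)
    ca, cb = rng.choice(names, size=2, replace=False)
    pa = int(rng.integers(lengths[ca] // 4, 3 * lengths[ca] // 4))
    pb = int(rng.integers(lengths[cb] // 4, 3 * lengths[cb] // 4))
    d1, d2 = (int(x) for x in rng.integers(0, max_deletion + 1, size=2))
    return reciprocal_junction_pair((ca, pa), (cb, pb), deletions=(d1, d2))
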