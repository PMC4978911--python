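import numpy as np
import pytest

from driftbarrier import (
    read_newick,
    read_species_table,
    simulate_ma_experiment,
    simulate_reference,
    simulate_site_counts,
)


@pytest.fixture(scope="session")
def species_records():
    return read_species_table()


@pytest.fixture(scope="session")
def species_tree():
    return read_newick()


@pytest.fixture(scope="session")
def small_experiment():
    """A small MA experiment with counts: 5 lines x 50 kb, planted mutations."""
    ref = simulate_reference(50_000, 0.5, seed=11)
    exp = simulate_ma_experiment(
        ref, n_lines=5, T=1000, u_bs=2e-7, u_id=1e-7, seed=12
    )
    counts = {
        line.line_id: simulate_site_counts(
            line, ref, mean_coverage=100, error_rate=1e-3, seed=100 + i
        )
        for i, line in enumerate(exp.lines)
    }
    return ref, exp, counts


def random_bifurcating_newick(rng: np.random.Generator, n_taxa: int) -> str:
    """Random rooted bifurcating newick with branch lengths in [0.5, 2]."""
    nodes = [f"T{i}" for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b1, b2 = rng.uniform(0.5, 2.0, size=2)
        merged = f"({nodes[i]}:{b1:.6f},{nodes[j]}:{b2:.6f})"
        nodes[i] = merged
        del nodes[j]
    return nodes[0] + ";"
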