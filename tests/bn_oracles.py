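"""Independent oracles for structure-learning tests: a toy discrete-DAG
sampler and an exhaustive-search Markov blanket finder."""

import itertools

import numpy as np
import pandas as pd

from ckdtraj.bayesnet import DiscreteDataset, g2_ci_test


def sample_chain(n, rng, flip=0.1):
    """X -> Y -> Z binary chain with strong links (noise = flip)."""
    x = rng.integers(0, 2, n)
    y = np.where(rng.random(n) < flip, 1 - x, x)
    z = np.where(rng.random(n) < flip, 1 - y, y)
    return DiscreteDataset.from_frame(
        pd.DataFrame({"X": x, "Y": y, "Z": z}))


def sample_collider(n, rng):
    """X -> Z <- Y, noisy-OR style: X, Y marginally independent, each
    marginally associated with Z, and dependent given Z."""
    x = rng.integers(0, 2, n)
    y = rng.integers(0, 2, n)
    p = np.select([x + y == 2, x + y == 1], [0.9, 0.6], default=0.1)
    z = (rng.random(n) < p).astype(int)
    return DiscreteDataset.from_frame(
        pd.DataFrame({"X": x, "Y": y, "Z": z}))


FIVE_NODE_ARCS = [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D"), ("D", "E")]
FIVE_NODE_SKELETON = {frozenset(a) for a in FIVE_NODE_ARCS}


def sample_five_node(n, rng, flip=0.15):
    """Known 5-node DAG A->B, A->C, B->D, C->D, D->E with strong effects
    (noisy-OR collider at D so every link is marginally visible)."""
    a = rng.integers(0, 2, n)
    b = np.where(rng.random(n) < flip, 1 - a, a)
    c = np.where(rng.random(n) < flip, 1 - a, a)
    pd_ = np.select([b + c == 2, b + c == 1], [0.9, 0.65], default=0.1)
    d = (rng.random(n) < pd_).astype(int)
    e = np.where(rng.random(n) < flip, 1 - d, d)
    return DiscreteDataset.from_frame(
        pd.DataFrame({"A": a, "B": b, "C": c, "D": d, "E": e}))


def five_node_true_blankets():
    return {
        "A": {"B", "C"},
        "B": {"A", "C", "D"},
        "C": {"A", "B", "D"},
        "D": {"B", "C", "E"},
        "E": {"D"},
    }


def brute_force_blanket(target, data, alpha=0.05):
    """Smallest variable set S (by size, then lexicographic) such that
    every variable outside S u {target} is independent of the target given
    S.  Exhaustive enumeration; independent of the IAMB code path."""
    others = sorted(v for v in data.names if v != target)
    for size in range(len(others) + 1):
        for s in itertools.combinations(others, size):
            rest = [v for v in others if v not in s]
            if all(g2_ci_test(v, target, list(s), data).p_value >= alpha
                   for v in rest):
                return set(s)
    return set(others)
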