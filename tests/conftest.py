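"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from regcycle.containers import TranscriptionalNetwork
from regcycle.simulate import SimulationConfig, simulate_cohort


def make_truth_network(truth, universe) -> TranscriptionalNetwork:
    """Planted regulons as a network object (unit MI weights)."""
    rows = [(tf, t, m, 1.0) for tf, reg in truth.regulons.items()
            for t, m in reg.items()]
    edges = pd.DataFrame(rows, columns=["tf", "target", "mode", "weight"])
    return TranscriptionalNetwork(universe=list(universe), edges=edges,
                                  tfs=list(truth.tf_programs), parameters={})


def brute_force_es(signature: pd.Series, gene_set, exponent: float = 0.0) -> float:
    """Independent O(N) running-sum recomputation of the enrichment score."""
    members = set(gene_set)
    order = sorted(signature.index, key=lambda g: (-signature[g], g))
    hits = [g in members for g in order]
    n, k = len(order), sum(hits)
    weights = [abs(signature[g]) ** exponent if h else 0.0
               for g, h in zip(order, hits)]
    total = sum(weights)
    if total == 0:  # degenerate weighting: uniform fallback
        weights = [1.0 if h else 0.0 for h in hits]
        total = float(k)
    p_hit = p_miss = 0.0
    max_dev = -np.inf
    min_dev = np.inf
    for w, h in zip(weights, hits):
        if h:
            p_hit += w / total
        else:
            p_miss += 1.0 / (n - k)
        dev = p_hit - p_miss
        max_dev = max(max_dev, dev)
        min_dev = min(min_dev, dev)
    # signed maximum deviation; magnitude ties resolve positive
    return max_dev if max_dev + min_dev >= -1e-9 else min_dev


def brute_force_dpi(edges: dict, tolerance: float) -> dict:
    """Exhaustive all-triples DPI oracle."""
    norm = {tuple(sorted(k)): float(v) for k, v in edges.items()}
    nodes = sorted({n for pair in norm for n in pair})
    removed = set()
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            b = nodes[j]
            for c in nodes[j + 1:]:
                trio = [(a, b), (a, c), (b, c)]
                if not all(p in norm for p in trio):
                    continue
                ws = sorted(trio, key=lambda p: norm[p])
                if norm[ws[0]] < (1.0 - tolerance) * norm[ws[1]]:
                    removed.add(ws[0])
    return {pair: w for pair, w in norm.items() if pair not in removed}


@pytest.fixture(scope="session")
def strong_cohort():
    """Default-strength cohort: 20 latent-linked TFs, 300 samples."""
    return simulate_cohort(SimulationConfig(n_samples=300, seed=42))


@pytest.fixture(scope="session")
def dual_cohort():
    """Cohort with 3 co-activating and 3 antagonistic planted TF pairs."""
    cfg = SimulationConfig(n_samples=300, n_coactivating_pairs=3,
                           n_antagonistic_pairs=3, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture
def small_expression():
    rng = np.random.default_rng(3)
    genes = [f"G{i:02d}" for i in range(20)]
    samples = [f"S{i}" for i in range(12)]
    return pd.DataFrame(rng.standard_normal((20, 12)), index=genes,
                        columns=samples)
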