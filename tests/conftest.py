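"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from skbio import TreeNode

from soilredox.community import OtuTable


def random_tree(otu_ids, rng, mean_branch=0.5) -> TreeNode:
    """Random bifurcating tree for test fixtures (independent of the
    simulator's tree builder in usage, same construction idea)."""
    nodes = [TreeNode(name=o, length=float(rng.exponential(mean_branch)))
             for o in otu_ids]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(
            TreeNode(length=float(rng.exponential(mean_branch)), children=[a, b])
        )
    return TreeNode(children=nodes)


def brute_force_gunifrac(table: OtuTable, tree: TreeNode, alpha: float,
                         i: int, j: int) -> float:
    """Branch-by-branch oracle: explicit leaf-set sums with python floats."""
    prop = table.counts / table.counts.sum(axis=0, keepdims=True)
    otu_index = {o: k for k, o in enumerate(table.otu_ids)}
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            continue
        leaves = [t.name for t in node.tips()] or [node.name]
        pa = sum(prop[otu_index[l], i] for l in leaves if l in otu_index)
        pb = sum(prop[otu_index[l], j] for l in leaves if l in otu_index)
        tot = pa + pb
        if tot <= 0:
            continue
        w = node.length * tot**alpha
        num += w * abs(pa - pb) / tot
        den += w
    return num / den if den > 0 else 0.0


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_table():
    """5 OTUs x 4 samples with taxonomy, hand-sized for exact checks."""
    counts = np.array(
        [
            [25, 0, 10, 1],
            [25, 0, 20, 1],
            [25, 100, 30, 2],
            [25, 0, 40, 5],
            [0, 0, 0, 0],
        ]
    )
    taxonomy = {
        "O1": "Bacteria;Firmicutes;Clostridia;Clostridiales;FamA;GenA",
        "O2": "Bacteria;Firmicutes;Clostridia;Clostridiales;FamA;GenB",
        "O3": "Bacteria;Proteobacteria;Delta;Desulfobacterales;FamB;GenC",
        "O4": "Bacteria;Proteobacteria;Delta;Desulfobacterales;FamC;GenD",
        "O5": "Bacteria;Bacteroidetes",
    }
    return OtuTable(
        otu_ids=["O1", "O2", "O3", "O4", "O5"],
        sample_ids=["S1", "S2", "S3", "S4"],
        counts=counts,
        taxonomy=taxonomy,
    )
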