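import numpy as np
import pandas as pd
import pytest

from lnpscreen.lipids import default_core_registry, default_tail_registry, enumerate_library
from lnpscreen.simulate import BarcodeWhitelist, BiodistributionModel, ReadLayout, design_whitelist


@pytest.fixture(scope="session")
def default_library():
    return enumerate_library(default_core_registry(), default_tail_registry())


@pytest.fixture(scope="session")
def whitelist96():
    return design_whitelist(96, barcode_len=8, min_dist=3, seed=7)


@pytest.fixture
def tiny_whitelist():
    """Four hand-picked barcodes at pairwise distance >= 3."""
    entries = pd.DataFrame(
        {
            "barcode_id": ["bc001", "bc002", "bc003", "naked"],
            "sequence": ["AAAAAAAA", "CCCAAAAA", "AAAAACCC", "GGGGGGGG"],
            "lnp_name": ["LNP1", "LNP2", "LNP3", "naked_control"],
        }
    )
    return BarcodeWhitelist(entries=entries, min_pairwise_hamming=3)


@pytest.fixture
def layout():
    return ReadLayout()


def brute_force_directional(umi_counts: dict) -> int:
    """Independent reference for directional UMI collapse.

    Edges and components are derived purely from the definition: all-pairs
    Hamming distances, the 2c-1 rule, and reachability from roots taken in
    (count desc, lexicographic) order.
    """
    umis = list(umi_counts)
    edges = {
        (u, v)
        for u in umis
        for v in umis
        if u != v
        and sum(a != b for a, b in zip(u, v)) == 1
        and umi_counts[u] >= 2 * umi_counts[v] - 1
    }
    visited: set = set()
    components = 0
    for root in sorted(umis, key=lambda u: (-umi_counts[u], u)):
        if root in visited:
            continue
        components += 1
        frontier = [root]
        while frontier:
            u = frontier.pop()
            if u in visited:
                continue
            visited.add(u)
            frontier.extend(v for (s, v) in edges if s == u and v not in visited)
    return components


def exact_rank_sum_p(x, y) -> float:
    """Exact two-sided rank-sum p by full enumeration over C(n+m, n) splits."""
    from itertools import combinations

    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in x)
    n = len(x)
    stats = [sum(c) for c in combinations(range(1, len(pooled) + 1), n)]
    total = len(stats)
    lo = sum(s <= observed for s in stats) / total
    hi = sum(s >= observed for s in stats) / total
    return min(1.0, 2 * min(lo, hi))
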