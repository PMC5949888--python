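"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (dynamic
programming, exhaustive enumeration) kept separate from the package code
they check.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from tadscreen import simulate as sim


# ---------------------------------------------------------------------------
# oracles


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook DP edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def all_optimal_identities(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Identities of every optimal global alignment under the given scores.

    Returns the set of matches/columns fractions achievable by co-optimal
    alignments (exhaustive backtrack; for short sequences only).
    """

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == 0 and j == 0:
            return 0
        cands = []
        if i > 0 and j > 0:
            cands.append(best(i - 1, j - 1) + (match if a[i - 1] == b[j - 1] else mismatch))
        if i > 0:
            cands.append(best(i - 1, j) + gap)
        if j > 0:
            cands.append(best(i, j - 1) + gap)
        return max(cands)

    @lru_cache(maxsize=None)
    def paths(i, j):
        # set of (matches, columns) over optimal alignments of prefixes
        if i == 0 and j == 0:
            return frozenset({(0, 0)})
        out = set()
        target = best(i, j)
        if i > 0 and j > 0:
            step = match if a[i - 1] == b[j - 1] else mismatch
            if best(i - 1, j - 1) + step == target:
                inc = 1 if a[i - 1] == b[j - 1] else 0
                out.update((m + inc, c + 1) for m, c in paths(i - 1, j - 1))
        if i > 0 and best(i - 1, j) + gap == target:
            out.update((m, c + 1) for m, c in paths(i - 1, j))
        if j > 0 and best(i, j - 1) + gap == target:
            out.update((m, c + 1) for m, c in paths(i, j - 1))
        return frozenset(out)

    return {m / c for m, c in paths(len(a), len(b))}


def exact_mannwhitney_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    observed = u_stat(x, y)
    mu = n1 * len(y) / 2
    count = 0
    total = 0
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in idx if i not in combo]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


def count_minimotif_pairs(peptide, group1, group2, min_gap, max_gap, symmetric):
    """Exhaustive position-pair scan for degenerate mini-motif counting.

    Counts start positions at which some residue of group1 (or, when
    symmetric, either group) begins a motif whose partner lies min_gap to
    max_gap residues further along (the overlapping-start contract).
    """
    starts = set()
    pairs = [(group1, group2)]
    if symmetric and set(group1) != set(group2):
        pairs.append((group2, group1))
    for g1, g2 in pairs:
        for i, aa in enumerate(peptide):
            if aa not in g1:
                continue
            for gap in range(min_gap, max_gap + 1):
                j = i + 1 + gap
                if j < len(peptide) and peptide[j] in g2:
                    starts.add(i)
                    break
    return len(starts)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def default_rule():
    return sim.GroundTruthRule()


@pytest.fixture(scope="session")
def small_library(default_rule):
    """300 labeled random inserts (fixed seed; contains a few functional)."""
    return sim.label_library(sim.generate_random_inserts(300, seed=17), default_rule)


@pytest.fixture(scope="session")
def small_counts(small_library):
    design = sim.ScreenDesign(depth=20_000, seed=12)
    return sim.simulate_screen(small_library, design)


@pytest.fixture(scope="session")
def wt_tads():
    """Two small WT TAD peptides for design-library tests."""
    return [("tadA", "DDLFEYWFDE"), ("tadB", "MEDFDWSLFD")]
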