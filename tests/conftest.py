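"""Shared fixtures and independent oracles for the test suite.

The parsimony oracles here deliberately avoid the package's tree machinery:
topologies are nested tuples, enumeration is by recursive edge insertion,
and scoring is Sankoff dynamic programming (not Fitch), so agreement with
the package is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from mycopop.alignment_io import GAP, AlignedLocus, expand_char

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# tuple-tree oracle machinery


def all_tuple_topologies(names: list[str]):
    """All unrooted binary topologies as nested tuples with a 3-way root."""
    if len(names) < 4:
        yield tuple(names)
        return

    def insert_everywhere(tree, leaf):
        # replace any subtree S (a child slot anywhere) by (S, leaf)
        for i, sub in enumerate(tree):
            yield tree[:i] + ((sub, leaf),) + tree[i + 1 :]
            if isinstance(sub, tuple):
                for new_sub in insert_everywhere(sub, leaf):
                    yield tree[:i] + (new_sub,) + tree[i + 1 :]

    trees = [tuple(names[:3])]
    for leaf in names[3:]:
        trees = [t2 for t in trees for t2 in insert_everywhere(t, leaf)]
    yield from trees


def sankoff_length(tree, columns: dict[str, str]) -> int:
    """Minimum substitutions over the tuple tree, by Sankoff DP per column.

    ``columns`` maps taxon -> one-character state; IUPAC codes expand to
    their base sets and gaps count as missing (any state allowed).
    """
    total = 0
    n_chars = len(next(iter(columns.values())))
    for k in range(n_chars):
        states = "ACGT"

        def cost(node) -> dict[str, int]:
            if isinstance(node, str):
                c = columns[node][k]
                allowed = set(states) if c == GAP else expand_char(c)
                return {s: (0 if s in allowed else 10**6) for s in states}
            child_costs = [cost(ch) for ch in node]
            return {
                s: sum(
                    min(cc[t] + (0 if t == s else 1) for t in states)
                    for cc in child_costs
                )
                for s in states
            }

        # treat the tuple as a root with len(tree) children
        root_costs = [cost(ch) for ch in tree]
        best = min(
            sum(min(cc[t] + (0 if t == s else 1) for t in states) for cc in root_costs)
            for s in states
        )
        total += best
    return total


def oracle_best_length(locus: AlignedLocus) -> int:
    """Exhaustive minimum parsimony length over every topology."""
    cols = dict(zip(locus.strain_ids, locus.rows))
    return min(
        sankoff_length(t, cols) for t in all_tuple_topologies(list(locus.strain_ids))
    )


# ---------------------------------------------------------------------------
# random alignments for fuzzing


def random_alignment(rng: np.random.Generator, n_taxa: int, n_chars: int) -> AlignedLocus:
    """Random alignment including occasional ambiguity codes and gaps."""
    alphabet = list("ACGT") + ["R", "Y", "-"]
    probs = [0.2, 0.2, 0.2, 0.2, 0.07, 0.07, 0.06]
    rows = [
        "".join(rng.choice(alphabet, p=probs) for _ in range(n_chars))
        for _ in range(n_taxa)
    ]
    return AlignedLocus("fuzz", [f"t{i}" for i in range(n_taxa)], rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
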