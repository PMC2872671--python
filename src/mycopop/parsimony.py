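"""Maximum-parsimony engine.

Fitch small-parsimony scoring, stepwise-addition + NNI heuristic search,
consistency/retention indices, nonparametric bootstrap, the incongruence-
length-difference (partition homogeneity) test, and monophyly-constrained
search for genealogical-concordance arguments.

Characters are alignment columns encoded as 4-bit state masks over
{A, C, G, T}.  Heterozygous IUPAC codes become the union of their two
bases; gap characters are treated as missing data (all four bits set) —
indel information is carried by the genotyping and divergence modules, not
by tree length.

Trees are unrooted with all internal nodes of degree 3.  Topologies are
identified by their set of non-trivial bipartitions; ties between equally
parsimonious trees are broken by a lexicographic encoding of that set, so
every search is reproducible given its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import GAP, AlignedLocus, expand_char
from .errors import TreeError

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
MISSING = 0b1111


def _char_mask(c: str) -> int:
    if c == GAP:
        return MISSING  # gaps scored as missing data
    mask = 0
    for b in expand_char(c):
        mask |= _BASE_BIT[b]
    return mask


def encode_characters(
    locus: AlignedLocus, variable_only: bool = False
) -> tuple[list[str], np.ndarray]:
    """Encode alignment columns as state masks.

    Returns (taxa, masks) with masks of shape (n_chars, n_taxa), dtype
    uint8.  With ``variable_only`` set, columns whose non-missing masks
    cannot all agree on a single base are kept and the rest dropped.
    """
    taxa = list(locus.strain_ids)
    cols = []
    for j in range(locus.n_sites):
        cols.append([_char_mask(c) for c in locus.column(j)])
    masks = np.array(cols, dtype=np.uint8)
    if masks.size == 0:
        masks = masks.reshape(0, len(taxa))
    if variable_only:
        keep = [i for i in range(masks.shape[0]) if _min_steps_row(masks[i]) > 0]
        masks = masks[keep]
    return taxa, masks


# ---------------------------------------------------------------------------
# unrooted trees


class UnrootedTree:
    """Unrooted tree; leaves have degree 1, internal nodes degree 3.

    Node ids are ints assigned in construction order, which together with
    canonical edge ordering keeps the whole search deterministic.
    """

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.leaf_name: dict[int, str] = {}
        self.name_leaf: dict[str, int] = {}
        self._next = 0

    # -- construction ------------------------------------------------------

    def _new_node(self, name: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        if name is not None:
            self.leaf_name[nid] = name
            self.name_leaf[name] = nid
        return nid

    def _connect(self, a: int, b: int) -> None:
        self.adj[a].add(b)
        self.adj[b].add(a)

    def _disconnect(self, a: int, b: int) -> None:
        self.adj[a].discard(b)
        self.adj[b].discard(a)

    @classmethod
    def initial(cls, names: Sequence[str]) -> "UnrootedTree":
        """Star over the first three taxa (the unique 3-leaf topology)."""
        if len(names) < 3:
            raise TreeError("need at least 3 taxa to build a tree")
        t = cls()
        hub = t._new_node()
        for nm in names[:3]:
            t._connect(hub, t._new_node(nm))
        return t

    def insert_leaf(self, name: str, edge: tuple[int, int]) -> tuple[int, int]:
        """Attach a new leaf on ``edge``; returns (new internal, new leaf)."""
        u, v = edge
        self._disconnect(u, v)
        mid = self._new_node()
        leaf = self._new_node(name)
        self._connect(u, mid)
        self._connect(mid, v)
        self._connect(mid, leaf)
        return mid, leaf

    def remove_leaf(self, leaf: int) -> None:
        """Undo ``insert_leaf`` (leaf's internal neighbor is unspliced)."""
        (mid,) = self.adj[leaf]
        self._disconnect(leaf, mid)
        a, b = self.adj[mid]
        self._disconnect(mid, a)
        self._disconnect(mid, b)
        self._connect(a, b)
        del self.adj[mid], self.adj[leaf]
        name = self.leaf_name.pop(leaf)
        del self.name_leaf[name]

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree()
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t.leaf_name = dict(self.leaf_name)
        t.name_leaf = dict(self.name_leaf)
        t._next = self._next
        return t

    # -- structure queries -------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return sorted(self.name_leaf)

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for a in sorted(self.adj):
            for b in self.adj[a]:
                if a < b:
                    out.append((a, b))
        return out

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (a, b)
            for a, b in self.edges()
            if a not in self.leaf_name and b not in self.leaf_name
        ]

    def _side_leaves(self, start: int, blocked: int) -> frozenset[str]:
        """Leaf names reachable from ``start`` without crossing ``blocked``."""
        seen = {blocked, start}
        stack = [start]
        names = []
        while stack:
            n = stack.pop()
            if n in self.leaf_name:
                names.append(self.leaf_name[n])
            for m in self.adj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return frozenset(names)

    def splits(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Bipartitions as the side not containing the smallest taxon name."""
        ref = min(self.name_leaf)
        out: set[frozenset[str]] = set()
        edge_list = self.edges() if include_trivial else self.internal_edges()
        for a, b in edge_list:
            side = self._side_leaves(a, b)
            if ref in side:
                side = self._side_leaves(b, a)
            out.add(side)
        return out

    def canonical_key(self) -> tuple:
        """Lexicographic encoding of the topology for tie-breaking."""
        return tuple(sorted(tuple(sorted(s)) for s in self.splits()))

    def is_compatible(self, groups: Sequence[frozenset[str]]) -> bool:
        """True if every group (restricted to present taxa) is monophyletic."""
        present = set(self.name_leaf)
        sides = self.splits(include_trivial=True)
        all_taxa = frozenset(present)
        for g in groups:
            gp = frozenset(g & present)
            if len(gp) <= 1 or len(all_taxa - gp) <= 1:
                continue
            if gp not in sides and (all_taxa - gp) not in sides:
                return False
        return True

    # -- traversal ---------------------------------------------------------

    def rooted_postorder(self) -> tuple[int, list[tuple[int, int, int]]]:
        """Root on the edge above the lexicographically first leaf.

        Returns (root_leaf, postorder) where postorder lists internal nodes
        as (node, child_a, child_b); the final entry is the first leaf's
        neighbor, whose set combines with the root leaf's own states.
        """
        root_leaf = self.name_leaf[min(self.name_leaf)]
        (top,) = self.adj[root_leaf]
        order: list[tuple[int, int, int]] = []
        # iterative postorder
        stack: list[tuple[int, int, bool]] = [(top, root_leaf, False)]
        while stack:
            node, parent, expanded = stack.pop()
            if node in self.leaf_name:
                continue
            children = sorted(self.adj[node] - {parent})
            if expanded:
                order.append((node, children[0], children[1]))
            else:
                stack.append((node, parent, True))
                for c in children:
                    stack.append((c, node, False))
        return root_leaf, order

    # -- newick ------------------------------------------------------------

    def newick(self, support: dict[frozenset[str], float] | None = None) -> str:
        """Newick string; optional bootstrap supports as internal labels."""
        root_leaf = self.name_leaf[min(self.name_leaf)]
        (top,) = self.adj[root_leaf]
        ref = min(self.name_leaf)

        def sub(node: int, parent: int) -> str:
            if node in self.leaf_name:
                return self.leaf_name[node]
            parts = [sub(c, node) for c in sorted(self.adj[node] - {parent})]
            label = ""
            if support is not None:
                side = self._side_leaves(node, parent)
                if ref in side:
                    side = frozenset(self.name_leaf.values()) - side
                if side in support:
                    label = f"{support[side]:.0f}"
            return "(" + ",".join(parts) + ")" + label

        return f"({self.leaf_name[root_leaf]},{sub(top, root_leaf)});"


def tree_from_groups(outer: Sequence) -> UnrootedTree:
    """Build a tree from a nested-tuple topology, e.g. (("a","b"),("c","d")).

    Intended for tests and small fixed topologies.
    """

    t = UnrootedTree()

    def build(spec) -> int:
        if isinstance(spec, str):
            return t._new_node(spec)
        if len(spec) != 2:
            raise TreeError("nested topology must be binary")
        node = t._new_node()
        for child in spec:
            t._connect(node, build(child))
        return node

    if len(outer) == 3:
        hub = t._new_node()
        for part in outer:
            t._connect(hub, build(part))
    elif len(outer) == 2:
        a = build(outer[0])
        b = build(outer[1])
        # splice the two root nodes together into an unrooted tree:
        # connect a and b directly; both must end up degree 3 or be leaves.
        t._connect(a, b)
    else:
        raise TreeError("top level must have 2 or 3 parts")
    # suppress degree-2 nodes created at the join
    for node in [n for n in list(t.adj) if n not in t.leaf_name and len(t.adj[n]) == 2]:
        x, y = t.adj[node]
        t._disconnect(node, x)
        t._disconnect(node, y)
        t._connect(x, y)
        del t.adj[node]
    return t


def read_newick(text: str) -> UnrootedTree:
    """Parse a newick string (leaf labels only) into an UnrootedTree."""
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick")

    t = UnrootedTree()

    def build(nd) -> int:
        if nd.is_leaf():
            return t._new_node(nd.taxon.label.replace(" ", "_"))
        node = t._new_node()
        for ch in nd.child_nodes():
            t._connect(node, build(ch))
        return node

    build(dt.seed_node)
    # suppress degree-2 nodes (rooted input -> unrooted)
    changed = True
    while changed:
        changed = False
        for node in list(t.adj):
            if node not in t.leaf_name and len(t.adj[node]) == 2:
                x, y = t.adj[node]
                t._disconnect(node, x)
                t._disconnect(node, y)
                t._connect(x, y)
                del t.adj[node]
                changed = True
    return t


# ---------------------------------------------------------------------------
# Fitch scoring


def _fitch_steps(tree: UnrootedTree, masks: np.ndarray, taxa_index: dict[str, int]) -> np.ndarray:
    """Per-character parsimony steps of ``tree`` (vectorized over characters)."""
    n_chars = masks.shape[0]
    if n_chars == 0:
        return np.zeros(0, dtype=np.int64)
    root_leaf, order = tree.rooted_postorder()
    steps = np.zeros(n_chars, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}

    def leaf_states(node: int) -> np.ndarray:
        return masks[:, taxa_index[tree.leaf_name[node]]]

    for node, ca, cb in order:
        a = sets.pop(ca) if ca in sets else leaf_states(ca)
        b = sets.pop(cb) if cb in sets else leaf_states(cb)
        inter = a & b
        empty = inter == 0
        steps += empty
        sets[node] = np.where(empty, a | b, inter)
    if order:
        top_set = sets[order[-1][0]]
    else:  # 3-taxon star handled by rooted_postorder producing one entry; safety
        top_set = leaf_states(next(iter(tree.adj[root_leaf])))
    steps += (top_set & leaf_states(root_leaf)) == 0
    return steps


def _min_steps_row(row: np.ndarray) -> int:
    """Minimum steps of one character over *any* tree.

    Equals (size of the smallest state set hitting every non-missing leaf
    mask) - 1; for unambiguous data this is (#distinct states - 1).
    """
    leaf_masks = [int(m) for m in row if int(m) != MISSING]
    if not leaf_masks:
        return 0
    union = 0
    for m in leaf_masks:
        union |= m
    bits = [b for b in (1, 2, 4, 8) if union & b]
    for size in range(1, len(bits) + 1):
        for combo in itertools.combinations(bits, size):
            s = 0
            for b in combo:
                s |= b
            if all(m & s for m in leaf_masks):
                return size - 1
    return len(bits) - 1  # unreachable


def _max_steps_row(row: np.ndarray) -> int:
    """Steps of one character on the completely unresolved (star) tree.

    n_eff minus the count of the best-supported single state; an upper
    bound on the steps of any binary resolution.
    """
    leaf_masks = [int(m) for m in row if int(m) != MISSING]
    if not leaf_masks:
        return 0
    best = max(sum(1 for m in leaf_masks if m & b) for b in (1, 2, 4, 8))
    return len(leaf_masks) - best


@dataclass
class ParsimonyScore:
    """Tree length with per-character step decomposition and CI/RI.

    ``ci``/``ri`` are computed over all variable characters (parsimony-
    uninformative autapomorphies included); ``ci_informative`` excludes
    characters whose step count is the same on every topology (g_i = m_i).
    The RI is unaffected by that choice, so only CI is reported both ways.
    Both indices are ``nan`` when their denominators vanish (e.g. a tree of
    length 0).
    """

    length: int
    steps: np.ndarray = field(repr=False)
    minima: np.ndarray = field(repr=False)
    maxima: np.ndarray = field(repr=False)

    @property
    def ci(self) -> float:
        s = int(self.steps.sum())
        return float(self.minima.sum()) / s if s else float("nan")

    @property
    def ci_informative(self) -> float:
        inf = self.maxima > self.minima
        s = int(self.steps[inf].sum())
        return float(self.minima[inf].sum()) / s if s else float("nan")

    @property
    def ri(self) -> float:
        g, s, m = self.maxima.sum(), self.steps.sum(), self.minima.sum()
        denom = float(g - m)
        return float(g - s) / denom if denom else float("nan")


def fitch_length(tree: UnrootedTree, locus: AlignedLocus) -> ParsimonyScore:
    """Score ``tree`` against the locus alignment.

    Tree leaves must match the alignment's strain set exactly.
    """
    taxa, masks = encode_characters(locus)
    if set(tree.name_leaf) != set(taxa):
        raise TreeError(
            f"tree leaves do not match alignment strains for locus {locus.locus_name!r}"
        )
    return score_masks(tree, masks, taxa)


def score_masks(tree: UnrootedTree, masks: np.ndarray, taxa: Sequence[str]) -> ParsimonyScore:
    taxa_index = {t: i for i, t in enumerate(taxa)}
    steps = _fitch_steps(tree, masks, taxa_index)
    minima = np.array([_min_steps_row(masks[i]) for i in range(masks.shape[0])], dtype=np.int64)
    maxima = np.array([_max_steps_row(masks[i]) for i in range(masks.shape[0])], dtype=np.int64)
    return ParsimonyScore(int(steps.sum()), steps, minima, maxima)


def _tree_length(tree: UnrootedTree, masks: np.ndarray, taxa_index: dict[str, int]) -> int:
    return int(_fitch_steps(tree, masks, taxa_index).sum())


# ---------------------------------------------------------------------------
# heuristic search


def _stepwise_addition(
    order: Sequence[str],
    masks: np.ndarray,
    taxa_index: dict[str, int],
    constraint: Sequence[frozenset[str]] | None,
) -> UnrootedTree:
    tree = UnrootedTree.initial(order)
    if constraint and not tree.is_compatible(constraint):
        # try the other two 3-taxon seeds by reordering; a 3-star is the
        # only 3-leaf topology, so incompatibility here cannot be fixed by
        # topology — but with <=3 present taxa every group restriction has
        # <=1 members outside, so this cannot actually trigger.
        raise TreeError("constraint incompatible with 3-taxon seed")
    for name in order[3:]:
        best_len: int | None = None
        best_edge: tuple[int, int] | None = None
        for edge in tree.edges():
            tree.insert_leaf(name, edge)
            ok = constraint is None or tree.is_compatible(constraint)
            if ok:
                ln = _tree_length(tree, masks, taxa_index)
                if best_len is None or ln < best_len:
                    best_len, best_edge = ln, edge
            tree.remove_leaf(tree.name_leaf[name])
        if best_edge is None:
            raise TreeError(f"no constraint-compatible insertion point for {name!r}")
        tree.insert_leaf(name, best_edge)
    return tree


def _nni_neighbors(tree: UnrootedTree) -> Iterable[UnrootedTree]:
    """The two NNI rearrangements around every internal edge."""
    for u, v in tree.internal_edges():
        u_sub = sorted(tree.adj[u] - {v})
        v_sub = sorted(tree.adj[v] - {u})
        b = u_sub[1]
        for c in v_sub:
            t = tree.copy()
            t._disconnect(u, b)
            t._disconnect(v, c)
            t._connect(u, c)
            t._connect(v, b)
            yield t


def _nni_hillclimb(
    tree: UnrootedTree,
    masks: np.ndarray,
    taxa_index: dict[str, int],
    constraint: Sequence[frozenset[str]] | None,
) -> tuple[UnrootedTree, int]:
    current = tree
    cur_len = _tree_length(current, masks, taxa_index)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(current):
            if constraint is not None and not cand.is_compatible(constraint):
                continue
            ln = _tree_length(cand, masks, taxa_index)
            if ln < cur_len:
                current, cur_len = cand, ln
                improved = True
                break
    return current, cur_len


@dataclass
class SearchResult:
    trees: list[UnrootedTree]
    length: int

    @property
    def best(self) -> UnrootedTree:
        return self.trees[0]


#: exact enumeration below this taxon count (10395 topologies at 8 taxa)
EXACT_SEARCH_BELOW = 8


def search_masks(
    masks: np.ndarray,
    taxa: Sequence[str],
    n_random_addition: int = 10,
    seed: int = 0,
    constraint: Sequence[frozenset[str]] | None = None,
    exact_below: int = EXACT_SEARCH_BELOW,
) -> SearchResult:
    """MP search on encoded characters.

    Below ``exact_below`` taxa every unrooted topology is enumerated, so
    the result is the exact optimum; beyond that, random-addition stepwise
    starting trees followed by NNI hill-climbing (which can in principle
    stop at a local optimum).  Returns all distinct minimal-length
    topologies found, sorted by their canonical bipartition encoding.
    Deterministic given ``seed``.
    """
    if len(taxa) < 4:
        raise TreeError(f"need >= 4 taxa to search, got {len(taxa)}")
    if len(taxa) < exact_below:
        return exhaustive_search_masks(masks, taxa, constraint=constraint)
    # a character whose masks all share a state costs 0 on every topology,
    # so searching only the rest changes no tree length
    keep = [i for i in range(masks.shape[0]) if _min_steps_row(masks[i]) > 0]
    if len(keep) < masks.shape[0]:
        masks = masks[keep]
    taxa_index = {t: i for i, t in enumerate(taxa)}
    rng = np.random.default_rng(seed)
    best_len: int | None = None
    found: dict[tuple, UnrootedTree] = {}
    taxa_arr = np.array(sorted(taxa))
    for _ in range(max(1, n_random_addition)):
        order = list(taxa_arr[rng.permutation(len(taxa_arr))])
        tree = _stepwise_addition(order, masks, taxa_index, constraint)
        tree, ln = _nni_hillclimb(tree, masks, taxa_index, constraint)
        if best_len is None or ln < best_len:
            best_len = ln
            found = {tree.canonical_key(): tree}
        elif ln == best_len:
            found.setdefault(tree.canonical_key(), tree)
    trees = [found[k] for k in sorted(found)]
    return SearchResult(trees, int(best_len))


def mp_search(
    locus: AlignedLocus,
    n_random_addition: int = 10,
    seed: int = 0,
    constraint: Sequence[frozenset[str]] | None = None,
    exact_below: int = EXACT_SEARCH_BELOW,
) -> SearchResult:
    """Maximum-parsimony search over a locus alignment (see search_masks)."""
    taxa, masks = encode_characters(locus)
    return search_masks(masks, taxa, n_random_addition, seed, constraint, exact_below)


def exhaustive_search_masks(
    masks: np.ndarray,
    taxa: Sequence[str],
    constraint: Sequence[frozenset[str]] | None = None,
) -> SearchResult:
    """Exact MP search by enumerating every unrooted topology.

    Feasible to ~8 taxa (10395 topologies); used for small datasets and as
    the exact branch of :func:`search_masks`.
    """
    taxa_sorted = sorted(taxa)
    if len(taxa_sorted) < 4:
        raise TreeError("need >= 4 taxa")
    taxa_index = {t: i for i, t in enumerate(taxa)}
    best_len: int | None = None
    found: dict[tuple, UnrootedTree] = {}
    for tree in _all_topologies(taxa_sorted):
        if constraint is not None and not tree.is_compatible(constraint):
            continue
        ln = _tree_length(tree, masks, taxa_index)
        if best_len is None or ln < best_len:
            best_len = ln
            found = {tree.canonical_key(): tree}
        elif ln == best_len:
            found.setdefault(tree.canonical_key(), tree)
    if best_len is None:
        raise TreeError("no topology satisfies the constraint")
    trees = [found[k] for k in sorted(found)]
    return SearchResult(trees, int(best_len))


def _all_topologies(names: Sequence[str]) -> Iterable[UnrootedTree]:
    """Generate all unrooted binary topologies by sequential edge insertion."""

    def recurse(tree: UnrootedTree, remaining: list[str]):
        if not remaining:
            yield tree.copy()
            return
        name = remaining[0]
        for edge in list(tree.edges()):
            tree.insert_leaf(name, edge)
            yield from recurse(tree, remaining[1:])
            tree.remove_leaf(tree.name_leaf[name])

    yield from recurse(UnrootedTree.initial(list(names)), list(names[3:]))


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    tree: UnrootedTree
    support: dict[frozenset[str], float]  # internal splits of ``tree`` -> %
    n_reps: int
    n_variable_sites: int

    def newick(self) -> str:
        return self.tree.newick(support=self.support)


def bootstrap_support(
    locus: AlignedLocus,
    n_reps: int = 100,
    seed: int = 0,
    n_random_addition: int = 3,
) -> BootstrapResult:
    """Column-resampling bootstrap support on the best MP tree.

    Supports are percentages of replicates whose (first, canonically
    ordered) best tree contains each bipartition of the original best tree.
    Resampling is indexed by column, so supports do not depend on strain
    input order beyond the seed protocol.  With no variable sites the tree
    is arbitrary and no supports are reported.
    """
    if n_reps < 1:
        raise TreeError("n_reps must be >= 1")
    taxa, masks = encode_characters(locus)
    rng = np.random.default_rng(seed)
    base = search_masks(masks, taxa, n_random_addition, seed=int(rng.integers(2**31)))
    base_tree = base.trees[0]
    n_var = sum(1 for i in range(masks.shape[0]) if _min_steps_row(masks[i]) > 0)
    if n_var == 0:
        return BootstrapResult(base_tree, {}, n_reps, 0)
    target = base_tree.splits()
    counts = {s: 0 for s in target}
    n_chars = masks.shape[0]
    for _ in range(n_reps):
        idx = rng.integers(0, n_chars, size=n_chars)
        rep = search_masks(masks[idx], taxa, n_random_addition, seed=int(rng.integers(2**31)))
        rep_splits = rep.trees[0].splits()
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return BootstrapResult(base_tree, support, n_reps, n_var)


# ---------------------------------------------------------------------------
# incongruence length difference (partition homogeneity) test


@dataclass
class ILDResult:
    observed: int
    null: list[int]
    p_value: float
    n_reps: int
    seed: int


def ild_test(
    loci: Sequence[AlignedLocus],
    n_reps: int = 99,
    seed: int = 0,
    n_random_addition: int = 3,
) -> ILDResult:
    """Partition homogeneity test over two or more loci.

    The statistic is the sum over loci of the best MP length of that locus'
    variable characters.  The null redistributes the pooled characters into
    random blocks of the original sizes; the p-value is the fraction of
    arrangements (observed included) whose summed length is <= the
    observed sum.  Congruent partitions leave the sum unchanged under
    repartitioning (p near 1); conflicting partitions make random blocks
    internally homoplastic, so the observed sum sits in the low tail and p
    is small.
    """
    if len(loci) < 2:
        raise TreeError("ild_test needs at least 2 loci")
    taxa0 = set(loci[0].strain_ids)
    for lc in loci[1:]:
        if set(lc.strain_ids) != taxa0:
            raise TreeError(
                f"loci {loci[0].locus_name!r} and {lc.locus_name!r} have different strain sets"
            )
    taxa = sorted(taxa0)
    blocks = []
    for lc in loci:
        t, m = encode_characters(lc, variable_only=True)
        reorder = [t.index(name) for name in taxa]
        blocks.append(m[:, reorder])
    sizes = [b.shape[0] for b in blocks]
    if any(s == 0 for s in sizes):
        raise TreeError("every locus must contribute at least one variable character")
    pooled = np.concatenate(blocks, axis=0)
    rng = np.random.default_rng(seed)

    def stat(parts: list[np.ndarray]) -> int:
        total = 0
        for p in parts:
            total += search_masks(p, taxa, n_random_addition, seed=int(rng.integers(2**31))).length
        return total

    observed = stat(blocks)
    null: list[int] = []
    for _ in range(n_reps):
        perm = rng.permutation(pooled.shape[0])
        parts = []
        at = 0
        for s in sizes:
            parts.append(pooled[perm[at : at + s]])
            at += s
        null.append(stat(parts))
    p = (1 + sum(x <= observed for x in null)) / (n_reps + 1)
    return ILDResult(observed, null, p, n_reps, seed)


# ---------------------------------------------------------------------------
# monophyly-constrained search


@dataclass
class ConstraintResult:
    constrained_length: int
    unconstrained_length: int
    p_value: float | None
    n_permutations: int

    @property
    def delta(self) -> int:
        return self.constrained_length - self.unconstrained_length


def constrained_search(
    locus: AlignedLocus,
    constraint: Sequence[Iterable[str]],
    seed: int = 0,
    n_random_addition: int = 10,
    n_permutations: int = 0,
) -> ConstraintResult:
    """Compare constrained and unconstrained MP tree lengths.

    ``constraint`` is a set of disjoint strain groups each forced to be
    monophyletic.  Delta = constrained - unconstrained length is >= 0 by
    construction (the constrained optimum is also a candidate for the
    unconstrained search).  With ``n_permutations`` > 0, a permutation
    null is built by shuffling each character's states among taxa
    independently and recomputing delta; the tail probability is the
    fraction of arrangements (observed included) with delta >= observed.
    """
    groups = [frozenset(g) for g in constraint]
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            if g1 & g2:
                raise TreeError(f"constraint groups overlap: {sorted(g1 & g2)}")
    taxa, masks = encode_characters(locus)
    rng = np.random.default_rng(seed)

    def delta_for(m: np.ndarray) -> tuple[int, int]:
        un = search_masks(m, taxa, n_random_addition, seed=int(rng.integers(2**31)))
        con = search_masks(
            m, taxa, n_random_addition, seed=int(rng.integers(2**31)), constraint=groups
        )
        return con.length, min(un.length, con.length)

    con_len, un_len = delta_for(masks)
    observed = con_len - un_len
    if n_permutations <= 0:
        return ConstraintResult(con_len, un_len, None, 0)
    null = []
    for _ in range(n_permutations):
        perm_masks = masks.copy()
        for i in range(perm_masks.shape[0]):
            perm_masks[i] = perm_masks[i][rng.permutation(perm_masks.shape[1])]
        c, u = delta_for(perm_masks)
        null.append(c - u)
    p = (1 + sum(d >= observed for d in null)) / (n_permutations + 1)
    return ConstraintResult(con_len, un_len, p, n_permutations)


# ---------------------------------------------------------------------------
# reports


def write_newick(tree_or_result, path: str | Path) -> None:
    text = tree_or_result.newick() if hasattr(tree_or_result, "newick") else str(tree_or_result)
    with open(path, "w") as fh:
        fh.write(text.rstrip() + "\n")


def write_character_steps(score: ParsimonyScore, path: str | Path) -> None:
    """TSV of per-character steps with their min/max bounds (1-based index)."""
    with open(path, "w") as fh:
        fh.write("character\tsteps\tmin_steps\tmax_steps\n")
        for i, (s, m, g) in enumerate(zip(score.steps, score.minima, score.maxima), start=1):
            fh.write(f"{i}\t{int(s)}\t{int(m)}\t{int(g)}\n")
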