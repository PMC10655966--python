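"""Ranked-genealogy matrix encoding.

A contemporaneously sampled binary genealogy with ``n`` leaves is encoded by
three stacked ``(n-1) x (n-1)`` lower-triangular channels:

* ``F`` -- the topology channel: ``F[i, j]`` (1-based ``i >= j``) counts the
  branches whose lifespan covers the full window between coalescent times
  ``t_{n-1-i}`` and ``t_{n-j}`` (with ``t_0 = 0`` the sampling time and
  ``t_{n-1}`` the TMRCA).
* ``W`` -- the coalescent-interval channel: ``W[i, j] = t_{n-j} - t_{n-1-i}``,
  in generations.
* ``R`` -- the derived-subtree channel: the same counts as ``F`` restricted to
  branches carrying the derived allele at the focal site (the mutation branch
  and every branch inside the derived clade).

Row/column index 1 is the most ancient interval, so the top-left cell of
``F`` always equals 2 and the diagonal satisfies ``F[k, k] = k + 1``. The
``(F, W)`` pair is a bijective encoding of the ranked tree shape plus its
coalescent times, which :func:`decode_F` verifies constructively for small
``n`` by exhaustive search over ranked shapes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Genealogy",
    "EncodedGenealogy",
    "GenealogyError",
    "EncodingError",
    "encode_genealogy",
    "branch_span_count",
    "decode_F",
    "enumerate_ranked_shapes",
    "extract_focal_genealogy",
    "nearest_segregating_site",
    "genealogy_from_tskit",
    "genealogy_from_newick",
    "random_genealogy",
]


class GenealogyError(ValueError):
    """Structurally invalid genealogy (non-binary, non-ultrametric, ...)."""


class EncodingError(ValueError):
    """Invalid encoding request or matrix (e.g. derived leaves not a clade)."""


@dataclass(frozen=True)
class Genealogy:
    """A ranked, contemporaneously sampled binary coalescent tree.

    Nodes ``0 .. n-1`` are leaves (time 0); nodes ``n .. 2n-2`` are internal.
    ``parent[u]`` gives the parent of node ``u`` (``-1`` for the root).
    ``derived_leaves`` is the (optional) set of leaves carrying the derived
    allele at the focal site; it must form a clade whose stem branch is the
    mutation branch.
    """

    n: int
    node_times: np.ndarray  # shape (2n-1,), generations
    parent: np.ndarray  # shape (2n-1,), int, -1 for root
    derived_leaves: frozenset[int] | None = None
    mutation_node: int | None = field(default=None)

    def __post_init__(self) -> None:
        n = self.n
        if n < 2:
            raise GenealogyError(f"need at least 2 leaves, got n={n}")
        times = np.asarray(self.node_times, dtype=float)
        parent = np.asarray(self.parent, dtype=int)
        if times.shape != (2 * n - 1,) or parent.shape != (2 * n - 1,):
            raise GenealogyError(
                f"expected {2 * n - 1} nodes for n={n} "
                f"(binary tree: n-1 internal nodes)"
            )
        object.__setattr__(self, "node_times", times)
        object.__setattr__(self, "parent", parent)
        if np.any(times[:n] != 0.0):
            raise GenealogyError("all leaves must be sampled at time 0")
        if np.any(times[n:] <= 0.0):
            raise GenealogyError("internal node times must be strictly positive")
        nchild = np.zeros(2 * n - 1, dtype=int)
        roots = 0
        for u in range(2 * n - 1):
            p = parent[u]
            if p == -1:
                roots += 1
            else:
                if not (n <= p < 2 * n - 1):
                    raise GenealogyError(f"parent of node {u} is not internal: {p}")
                if times[p] <= times[u]:
                    raise GenealogyError(
                        f"parent {p} (t={times[p]}) not older than child {u} "
                        f"(t={times[u]})"
                    )
                nchild[p] += 1
        if roots != 1:
            raise GenealogyError(f"expected a single root, found {roots}")
        if np.any(nchild[n:] != 2):
            bad = [int(u) for u in range(n, 2 * n - 1) if nchild[u] != 2]
            raise GenealogyError(f"non-binary internal nodes: {bad}")
        if len(np.unique(times[n:])) != n - 1:
            raise GenealogyError(
                "coalescent times must be strictly increasing; resolve ties "
                "with resolve_ties() before encoding"
            )
        if self.derived_leaves is not None:
            d = frozenset(int(v) for v in self.derived_leaves)
            if not d or not d < frozenset(range(n)):
                raise GenealogyError(
                    "derived_leaves must be a proper, non-empty subset of leaves"
                )
            object.__setattr__(self, "derived_leaves", d)

    # -- basic structure ---------------------------------------------------

    @property
    def root(self) -> int:
        return int(np.argmax(self.parent == -1))

    @property
    def tmrca(self) -> float:
        return float(self.node_times[self.root])

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {u: [] for u in range(self.n, 2 * self.n - 1)}
        for u in range(2 * self.n - 1):
            p = self.parent[u]
            if p != -1:
                ch[int(p)].append(u)
        return ch

    def branches(self) -> list[tuple[int, float, float]]:
        """All branches as (child_node, child_time, parent_time) triples."""
        out = []
        for u in range(2 * self.n - 1):
            p = self.parent[u]
            if p != -1:
                out.append((u, float(self.node_times[u]), float(self.node_times[p])))
        return out

    def leaf_sets(self) -> dict[int, frozenset[int]]:
        """Descendant-leaf set of every node."""
        sets: dict[int, frozenset[int]] = {u: frozenset([u]) for u in range(self.n)}
        for u in self._internal_by_time():
            cs = [v for v in range(2 * self.n - 1) if self.parent[v] == u]
            sets[u] = frozenset().union(*(sets[c] for c in cs))
        return sets

    def _internal_by_time(self) -> list[int]:
        order = sorted(range(self.n, 2 * self.n - 1), key=lambda u: self.node_times[u])
        return order

    def coalescent_times(self) -> np.ndarray:
        """The n-1 internal node times, strictly increasing."""
        return np.sort(self.node_times[self.n :])

    def mrca(self, leaves: Iterable[int]) -> int:
        leaves = list(leaves)
        sets = self.leaf_sets()
        target = frozenset(leaves)
        best, best_size = self.root, self.n + 1
        for u, s in sets.items():
            if target <= s and len(s) < best_size:
                best, best_size = u, len(s)
        return best

    def derived_branch_children(self) -> frozenset[int]:
        """Child nodes of derived-carrying branches.

        A branch carries the derived allele iff every leaf below it is
        derived; since ``derived_leaves`` forms a clade, this is the
        mutation (stem) branch plus every branch inside the clade.
        """
        if self.derived_leaves is None:
            raise EncodingError("genealogy has no derived_leaves set")
        sets = self.leaf_sets()
        mut = self.mutation_node
        if mut is None:
            mut = self.mrca(self.derived_leaves)
        if sets[mut] != self.derived_leaves:
            offending = sorted(sets[mut] ^ self.derived_leaves)
            raise EncodingError(
                f"derived_leaves is not a clade: minimal clade containing it "
                f"disagrees at leaves {offending}"
            )
        carriers = frozenset(
            u for u, s in sets.items() if s <= self.derived_leaves and self.parent[u] != -1
        )
        return carriers

    def resolve_ties(self, eps_rel: float = 1e-9) -> "Genealogy":
        """Break simultaneous coalescent times by adding k*eps in node order.

        ``eps`` is ``eps_rel`` times the TMRCA. Needed for discrete-generation
        ingested trees; a no-op when times are already distinct.
        """
        times = self.node_times.copy()
        internal = sorted(range(self.n, 2 * self.n - 1), key=lambda u: (times[u], u))
        eps = eps_rel * float(times.max())
        last = 0.0
        for k, u in enumerate(internal):
            if times[u] <= last:
                times[u] = last + eps
            last = times[u]
        # keep parent strictly older than child
        for u in internal:
            p = self.parent[u]
            if p != -1 and times[p] <= times[u]:
                times[p] = times[u] + eps
        return replace(self, node_times=times)


@dataclass(frozen=True)
class EncodedGenealogy:
    """The stacked F/W/R lower-triangular channels of one genealogy."""

    F: np.ndarray  # (n-1, n-1) int
    W: np.ndarray  # (n-1, n-1) float, generations
    R: np.ndarray  # (n-1, n-1) int

    @property
    def n(self) -> int:
        return self.F.shape[0] + 1

    def stacked(self) -> np.ndarray:
        """A (n-1, n-1, 3) tensor, channel order (F, W, R)."""
        return np.stack([self.F.astype(float), self.W, self.R.astype(float)], axis=-1)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def encode_genealogy(g: Genealogy, require_derived: bool = True) -> EncodedGenealogy:
    """Encode a genealogy into its F/W/R channels.

    For 1-based ``i >= j``: ``W[i, j] = t_{n-j} - t_{n-1-i}``; ``F[i, j]``
    counts branches whose closed lifespan contains ``[t_{n-1-i}, t_{n-j}]``;
    ``R`` is the same count over derived-carrying branches. Branches born or
    dying exactly at a window endpoint count as covering it.

    With ``require_derived=False`` and no derived set on ``g``, ``R`` is all
    zeros (used when only the ranked shape matters, e.g. decoding tests).
    """
    n = g.n
    t = np.concatenate([[0.0], g.coalescent_times()])  # t[0..n-1]
    # rank of each node's time among the boundaries t[0..n-1]
    rank = np.empty(2 * n - 1, dtype=int)
    rank[: n] = 0
    order = np.argsort(g.node_times[n:], kind="stable")
    for r, idx in enumerate(order, start=1):
        rank[n + idx] = r

    def count_matrix(children: Sequence[int]) -> np.ndarray:
        # M[a, b] = number of branches with child rank a, parent rank b
        M = np.zeros((n, n), dtype=np.int64)
        for u in children:
            M[rank[u], rank[g.parent[u]]] += 1
        # C[a, b] = # branches with child rank <= a and parent rank >= b
        C = np.cumsum(np.cumsum(M[:, ::-1], axis=0), axis=1)[:, ::-1]
        # F[i, j] (1-based) = C[n-1-i, n-j]; build via index arrays
        i = np.arange(1, n)
        j = np.arange(1, n)
        out = C[np.ix_(n - 1 - i, n - j)]
        return np.tril(out)

    all_children = [u for u in range(2 * n - 1) if g.parent[u] != -1]
    F = count_matrix(all_children)

    i = np.arange(1, n)[:, None]
    j = np.arange(1, n)[None, :]
    W = np.tril(t[n - j] - t[n - 1 - i])

    if g.derived_leaves is None:
        if require_derived:
            raise EncodingError(
                "genealogy has no derived_leaves; pass require_derived=False "
                "to encode without the R channel"
            )
        R = np.zeros_like(F)
    else:
        R = count_matrix(sorted(g.derived_branch_children()))
    return EncodedGenealogy(F=F, W=W, R=R)


def branch_span_count(
    g: Genealogy, t_recent: float, t_ancient: float, derived_only: bool = False
) -> int:
    """Count branches whose closed lifespan covers ``[t_recent, t_ancient]``.

    The brute-force oracle primitive behind :func:`encode_genealogy`: it
    enumerates every branch's ``[child_time, parent_time]`` span directly.
    """
    if not (0.0 <= t_recent <= t_ancient <= g.tmrca):
        raise ValueError(
            f"window [{t_recent}, {t_ancient}] outside [0, TMRCA={g.tmrca}]"
        )
    if derived_only:
        allowed = g.derived_branch_children()
    count = 0
    for u, t_child, t_parent in g.branches():
        if derived_only and u not in allowed:
            continue
        if t_child <= t_recent and t_parent >= t_ancient:
            count += 1
    return count


# ---------------------------------------------------------------------------
# ranked tree shapes and decoding
# ---------------------------------------------------------------------------


def _canonical(shape) -> tuple:
    """Canonical hashable form of a ranked-shape tree (nested tuples).

    Leaves are ``(0,)``; an internal node of rank ``k >= 1`` (rank 1 = the
    youngest coalescence) is ``(k, left, right)`` with children sorted.
    """
    if shape == "L" or shape == (0,):
        return (0,)
    rank, left, right = shape
    lc, rc = _canonical(left), _canonical(right)
    if rc < lc:
        lc, rc = rc, lc
    return (rank, lc, rc)


def enumerate_ranked_shapes(n: int) -> list[tuple]:
    """All distinct ranked tree shapes on ``n`` leaves (canonical forms).

    Enumerates every labeled coalescent history (merge one pair per step,
    oldest rank = n-1) and deduplicates by canonical form. Exhaustive and
    exact; intended for small n (the count is 1, 1, 2, 5, 16, 61 for
    n = 2..7).
    """
    shapes: set[tuple] = set()

    def rec(blocks: tuple, next_rank: int) -> None:
        if len(blocks) == 1:
            shapes.add(_canonical(blocks[0]))
            return
        for a, b in itertools.combinations(range(len(blocks)), 2):
            merged = (next_rank, blocks[a], blocks[b])
            rest = tuple(
                blk for k, blk in enumerate(blocks) if k not in (a, b)
            ) + (merged,)
            rec(rest, next_rank + 1)

    rec(tuple("L" for _ in range(n)), 1)
    return sorted(shapes)


def genealogy_from_shape(shape: tuple, times: Sequence[float] | None = None) -> Genealogy:
    """Instantiate a concrete genealogy from a canonical ranked shape.

    Internal node of rank k gets time ``times[k-1]`` (default k).
    """

    def count_leaves(s) -> int:
        return 1 if s == (0,) else count_leaves(s[1]) + count_leaves(s[2])

    n = count_leaves(shape)
    if times is None:
        times = list(range(1, n))
    node_times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=int)
    next_leaf = [0]
    next_internal = [n]

    def build(s) -> int:
        if s == (0,):
            u = next_leaf[0]
            next_leaf[0] += 1
            return u
        rank, left, right = s
        lu, ru = build(left), build(right)
        u = next_internal[0]
        next_internal[0] += 1
        node_times[u] = times[rank - 1]
        parent[lu] = u
        parent[ru] = u
        return u

    build(shape)
    return Genealogy(n=n, node_times=node_times, parent=parent)


def ranked_shape_of(g: Genealogy) -> tuple:
    """The canonical ranked shape of a genealogy (rank 1 = youngest merge)."""
    ranks = {u: r for r, u in enumerate(g._internal_by_time(), start=1)}
    children = g.children()

    def rec(u: int):
        if u < g.n:
            return "L"
        c1, c2 = children[u]
        return (ranks[u], rec(c1), rec(c2))

    return _canonical(rec(g.root))


def decode_F(F: np.ndarray) -> tuple:
    """Recover the unique ranked tree shape encoded by ``F``.

    Exhaustive search over all ranked shapes of ``n`` leaves (test-scale,
    ``n - 1 <= 6``). Raises :class:`EncodingError` if no shape matches and a
    bijectivity-violation error if more than one does (which must never
    happen for a valid encoding).
    """
    F = np.asarray(F)
    m = F.shape[0]
    n = m + 1
    if m > 6:
        raise ValueError("decode_F is exhaustive-search based; requires n-1 <= 6")
    if F.shape != (m, m) or np.any(np.triu(F, 1) != 0):
        raise EncodingError("F must be square and lower-triangular")
    if np.any(np.diag(F) != np.arange(2, n + 1)):
        raise EncodingError(
            f"invalid diagonal {np.diag(F)}; expected {np.arange(2, n + 1)}"
        )
    matches = []
    for shape in enumerate_ranked_shapes(n):
        g = genealogy_from_shape(shape)
        enc = encode_genealogy(g, require_derived=False)
        if np.array_equal(enc.F, F):
            matches.append(shape)
    if not matches:
        raise EncodingError("no ranked tree shape reproduces this F matrix")
    if len(matches) > 1:
        raise EncodingError(
            f"bijectivity violation: {len(matches)} ranked shapes share this F"
        )
    return matches[0]


# ---------------------------------------------------------------------------
# bridges from tree sequences and newick
# ---------------------------------------------------------------------------


def genealogy_from_tskit(
    tree, derived_leaves: Iterable[int] | None = None
) -> Genealogy:
    """Convert a tskit ``Tree`` (binary, contemporaneous samples) to a Genealogy.

    Sample nodes are renumbered 0..n-1 in tskit sample order; simultaneous
    coalescent times (if any) are resolved by :meth:`Genealogy.resolve_ties`.
    """
    ts = tree.tree_sequence
    samples = list(ts.samples())
    n = len(samples)
    if any(ts.node(s).time != 0 for s in samples):
        raise GenealogyError("samples are not contemporaneous (time 0)")
    node_map = {s: i for i, s in enumerate(samples)}
    internal = [u for u in tree.nodes() if u not in node_map]
    internal.sort(key=lambda u: (tree.time(u), u))
    if len(internal) != n - 1:
        raise GenealogyError(
            f"tree is not strictly binary: {len(internal)} internal nodes "
            f"for {n} samples"
        )
    for k, u in enumerate(internal):
        node_map[u] = n + k
    node_times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=int)
    for u in tree.nodes():
        node_times[node_map[u]] = tree.time(u)
        p = tree.parent(u)
        if p != -1:
            parent[node_map[u]] = node_map[p]
    d = None
    if derived_leaves is not None:
        d = frozenset(node_map[s] for s in derived_leaves)
    if len(np.unique(node_times[n:])) != n - 1:
        # discrete-generation trees can tie; break ties before validation
        tmp = Genealogy.__new__(Genealogy)
        object.__setattr__(tmp, "n", n)
        object.__setattr__(tmp, "node_times", node_times)
        object.__setattr__(tmp, "parent", parent)
        object.__setattr__(tmp, "derived_leaves", d)
        object.__setattr__(tmp, "mutation_node", None)
        return tmp.resolve_ties()
    return Genealogy(n=n, node_times=node_times, parent=parent, derived_leaves=d)


def nearest_segregating_site(ts, position: float):
    """The biallelic segregating site nearest ``position`` (or None)."""
    best = None
    best_dist = np.inf
    for var in ts.variants():
        k = int(var.genotypes.sum())
        if len(var.alleles) != 2 or k == 0 or k == len(var.genotypes):
            continue
        d = abs(var.site.position - position)
        if d < best_dist:
            best, best_dist = var.site, d
    return best


def extract_focal_genealogy(
    ts, focal_position: float, focal_site_required: bool = True
) -> Genealogy:
    """The marginal genealogy at ``focal_position`` of a tree sequence.

    ``derived_leaves`` is taken from the variant at the focal site when one
    exists (half-open interval convention for tree lookup; exact position
    match for the site). A site whose derived allele is carried by zero or
    all samples is rejected.
    """
    if not (0 <= focal_position < ts.sequence_length):
        raise ValueError(
            f"position {focal_position} outside [0, {ts.sequence_length})"
        )
    tree = ts.at(focal_position)
    derived = None
    site = None
    for s in ts.sites():
        if s.position == focal_position:
            site = s
            break
    if site is not None:
        var = next(v for v in ts.variants(left=site.position) if v.site.id == site.id)
        if len(var.alleles) != 2:
            raise ValueError(f"focal site at {focal_position} is not biallelic")
        carriers = [s for s, gt in zip(ts.samples(), var.genotypes) if gt == 1]
        if len(carriers) == 0 or len(carriers) == ts.num_samples:
            raise ValueError(
                f"focal site at {focal_position} has derived count "
                f"{len(carriers)}; need a proper subset of samples"
            )
        derived = carriers
    elif focal_site_required:
        raise ValueError(f"no site at focal position {focal_position}")
    return genealogy_from_tskit(tree, derived_leaves=derived)


def genealogy_from_newick(newick: str) -> Genealogy:
    """Read a single ultrametric binary tree from a newick string.

    Branch lengths are in generations; node times are reconstructed from
    leaf depth (leaves at 0).
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf for lf in tree.leaf_node_iter()]
    n = len(leaves)
    depths = tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(lf.root_distance for lf in leaves)
    nodes = list(tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    if len(internal) != n - 1:
        raise GenealogyError("newick tree is not strictly binary")
    idx = {}
    for i, lf in enumerate(leaves):
        idx[id(lf)] = i
        if abs(height - lf.root_distance) > 1e-6 * max(height, 1.0):
            raise GenealogyError("newick tree is not ultrametric")
    internal.sort(key=lambda nd: nd.root_distance, reverse=True)
    for k, nd in enumerate(internal):
        idx[id(nd)] = n + k
    node_times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=int)
    for nd in nodes:
        u = idx[id(nd)]
        node_times[u] = 0.0 if nd.is_leaf() else height - nd.root_distance
        if nd.parent_node is not None:
            parent[u] = idx[id(nd.parent_node)]
    tmp = Genealogy.__new__(Genealogy)
    object.__setattr__(tmp, "n", n)
    object.__setattr__(tmp, "node_times", node_times)
    object.__setattr__(tmp, "parent", parent)
    object.__setattr__(tmp, "derived_leaves", None)
    object.__setattr__(tmp, "mutation_node", None)
    if len(np.unique(node_times[n:])) != n - 1:
        return tmp.resolve_ties()
    return Genealogy(n=n, node_times=node_times, parent=parent)


def random_genealogy(
    n: int, rng: np.random.Generator, with_derived: bool = True
) -> Genealogy:
    """A random coalescent genealogy (standard Kingman waiting times).

    Used throughout the test-suite as a cheap source of valid inputs.
    """
    node_times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=int)
    lineages = list(range(n))
    t = 0.0
    for step in range(n - 1):
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        u = n + step
        node_times[u] = t
        a, b = rng.choice(len(lineages), size=2, replace=False)
        ua, ub = lineages[int(a)], lineages[int(b)]
        parent[ua] = u
        parent[ub] = u
        lineages = [x for x in lineages if x not in (ua, ub)] + [u]
    g = Genealogy(n=n, node_times=node_times, parent=parent)
    if with_derived:
        sets = g.leaf_sets()
        candidates = [
            u for u, s in sets.items() if 0 < len(s) < n and g.parent[u] != -1
        ]
        u = candidates[int(rng.integers(len(candidates)))]
        g = replace(g, derived_leaves=sets[u], mutation_node=u)
    return g
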