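"""Genealogy-inference-error surrogate.

Inferred ancestral recombination graphs deviate from the truth in two
characteristic ways: noisy branch lengths and local topology errors. This
module emulates both directly on a true genealogy, producing target-domain
trees that differ from the source domain the way ARG-inference output does,
without running an external inference tool:

* every branch length is multiplied by an independent lognormal(0, sigma_bl)
  factor, and the tree is re-ultrametrized by leaf-depth renormalization
  (each internal node's new time is its mean distance to its descendant
  leaves, with a monotonicity repair so parents stay older than children);
* each internal edge is independently subjected to a nearest-neighbour
  interchange (NNI) with probability p_nni.

With ``sigma_bl = 0`` and ``p_nni = 0`` the output is the input, exactly.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .genealogy import Genealogy

__all__ = ["apply_inference_error"]


def _reultrametrize(g: Genealogy, lengths: dict[int, float]) -> np.ndarray:
    """New node times from perturbed branch lengths (leaf-depth renormalized)."""
    n = g.n
    children = g.children()
    order = g._internal_by_time()  # children before parents
    # distance-to-leaves averages, bottom-up
    new_t = np.zeros(2 * n - 1)
    leaf_count = np.ones(2 * n - 1)
    for u in order:
        cs = children[u]
        k = sum(leaf_count[c] for c in cs)
        tot = sum((new_t[c] + lengths[c]) * leaf_count[c] for c in cs)
        leaf_count[u] = k
        new_t[u] = tot / k
    # monotonicity repair: a parent averaging over an unbalanced pair of
    # subtrees can land below its deeper child
    eps = 1e-9 * max(new_t.max(), 1.0)
    for u in order:
        mx = max(new_t[c] for c in children[u])
        if new_t[u] <= mx:
            new_t[u] = mx + eps
    return new_t


def apply_inference_error(
    g: Genealogy, sigma_bl: float, p_nni: float, seed: int | None = None
) -> Genealogy:
    """Perturb a genealogy the way ARG inference error does.

    See module docstring. ``derived_leaves`` membership is re-derived after
    topology moves as the minimal clade containing the original derived
    leaves (if that clade becomes the whole tree, the root child holding the
    majority of derived leaves is used instead).
    """
    if sigma_bl < 0:
        raise ValueError("sigma_bl must be non-negative")
    if not (0 <= p_nni <= 1):
        raise ValueError("p_nni must be in [0, 1]")
    if sigma_bl == 0 and p_nni == 0:
        return g
    rng = np.random.default_rng(seed)
    n = g.n
    parent = g.parent.copy()
    times = g.node_times.copy()

    if sigma_bl > 0:
        lengths = {}
        for u, t_child, t_parent in g.branches():
            lengths[u] = (t_parent - t_child) * float(
                np.exp(rng.normal(0.0, sigma_bl))
            )
        times = _reultrametrize(g, lengths)
        times[:n] = 0.0

    if p_nni > 0:
        children: dict[int, list[int]] = {u: [] for u in range(n, 2 * n - 1)}
        for u in range(2 * n - 1):
            if parent[u] != -1:
                children[int(parent[u])].append(u)
        root = int(np.argmax(parent == -1))
        internal_edges = [
            v for v in range(n, 2 * n - 1) if v != root and parent[v] != -1
        ]
        for v in internal_edges:
            if rng.random() >= p_nni:
                continue
            u = int(parent[v])
            sib = next(c for c in children[u] if c != v)
            c = children[v][int(rng.integers(2))]
            # swap c (child of v) with sib (child of u)
            children[v].remove(c)
            children[u].remove(sib)
            children[v].append(sib)
            children[u].append(c)
            parent[c] = u
            parent[sib] = v
            mx = max(times[w] for w in children[v])
            if times[v] <= mx:
                times[v] = float(rng.uniform(mx, times[u])) if times[u] > mx else (
                    mx + 1e-9 * times[u]
                )

    tmp = Genealogy.__new__(Genealogy)
    object.__setattr__(tmp, "n", n)
    object.__setattr__(tmp, "node_times", times)
    object.__setattr__(tmp, "parent", parent)
    object.__setattr__(tmp, "derived_leaves", None)
    object.__setattr__(tmp, "mutation_node", None)
    out = tmp.resolve_ties()

    if g.derived_leaves is not None:
        m = out.mrca(g.derived_leaves)
        sets = out.leaf_sets()
        if m == out.root:
            ch = [u for u in range(2 * n - 1) if out.parent[u] == m]
            m = max(ch, key=lambda u: len(sets[u] & g.derived_leaves))
        if out.parent[m] == -1 or len(sets[m]) >= n:
            return out
        out = replace(out, derived_leaves=sets[m], mutation_node=int(m))
    return out
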