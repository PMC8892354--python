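"""Neighbor-joining phylogeny of broad zinc-finger domains with bootstrap.

The broad transcription factor is alternatively spliced into isoforms whose
C2H2 zinc-finger domains fall into conserved clades (ZF1-ZF6 across
insects; ZFa-ZFg within Odonata). Given an amino-acid alignment of domain
sequences, this module computes p-distances with pairwise gap deletion,
builds a neighbor-joining tree (negative branch lengths clamped to zero),
estimates bipartition support by column-bootstrap, and assigns query
domains to the clade of the reference group they nest within.

The alignment itself is an input; no aligner is implemented here.
"""

from __future__ import annotations

import io
from collections.abc import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = [
    "read_alignment",
    "pdistance",
    "nj_tree",
    "tree_bipartitions",
    "bootstrap_support",
    "assign_clade",
    "write_newick",
]

GAP_CHARS = frozenset("-.")


def read_alignment(path) -> dict[str, str]:
    """Aligned FASTA -> ordered {id: sequence}; enforces equal lengths."""
    from Bio import SeqIO

    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not aln:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal lengths")
    return aln


def _as_array(aln: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    ids = list(aln)
    lengths = {len(aln[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal lengths")
    arr = np.array([list(aln[i]) for i in ids], dtype="U1")
    return ids, arr


def pdistance(aln: Mapping[str, str]) -> pd.DataFrame:
    """Proportion of differing sites over pairwise non-gap columns."""
    ids, arr = _as_array(aln)
    nongap = ~np.isin(arr, list(GAP_CHARS))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = nongap[i] & nongap[j]
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            diff = int((arr[i, comparable] != arr[j, comparable]).sum())
            d[i, j] = d[j, i] = diff / m
    return pd.DataFrame(d, index=ids, columns=ids)


def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    if dist.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    mat = dist.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("non-finite distances")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    mat = 0.5 * (mat + mat.T)  # exact symmetry for the solver
    dm = _SkbioDM(mat, ids=[str(i) for i in dist.index])
    return _skbio_nj(dm, neg_as_zero=True)


def tree_bipartitions(tree: TreeNode, positive_only: bool = False) -> set[frozenset]:
    """Non-trivial bipartitions as leaf-name sets not containing the anchor.

    Each internal edge splits the leaves in two; the side not containing the
    lexicographically smallest leaf represents the bipartition, so supports
    can be compared across replicate trees regardless of rooting. With
    ``positive_only`` a zero-length internal edge counts as unresolved (used
    by the bootstrap so signal-free alignments yield no supported splits).
    """
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    all_leaves = frozenset(leaves)
    parts = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        if positive_only and (node.length is None or node.length <= 0):
            continue
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            parts.add(side)
    return parts


def bootstrap_support(
    aln: Mapping[str, str],
    reps: int = 1000,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Column-bootstrap bipartition support (%) for the NJ tree.

    Resamples alignment columns with replacement, rebuilds the NJ tree per
    replicate, and reports the frequency of each bipartition of the
    full-alignment tree. Values below 50% follow the figure convention of
    being reported but flagged as weak by callers.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ids, arr = _as_array(aln)
    if arr.shape[1] < 1:
        raise ValueError("alignment length must be >= 1")
    base_parts = tree_bipartitions(nj_tree(pdistance(aln)), positive_only=True)
    counts = {part: 0 for part in base_parts}
    rng = np.random.default_rng(seed)
    ncol = arr.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = {i: "".join(arr[k, cols]) for k, i in enumerate(ids)}
        try:
            parts = tree_bipartitions(nj_tree(pdistance(resampled)), positive_only=True)
        except ValueError:  # a pair may lose all comparable columns
            continue
        for part in base_parts:
            if part in parts:
                counts[part] += 1
    return {part: 100.0 * c / reps for part, c in counts.items()}


def assign_clade(
    tree: TreeNode,
    references: Mapping[str, str],
) -> tuple[dict[str, str | None], list[str]]:
    """Assign unlabeled query leaves to reference clades.

    ``references`` maps reference leaf name -> clade label. For each clade,
    the smallest bipartition side containing all its references and no
    reference of another clade is found; queries inside that side take the
    clade label. A clade with no such side is unresolvable (its queries stay
    unassigned). Returns (query -> label or None, unresolvable clades).
    """
    leaves = sorted(t.name for t in tree.tips())
    queries = [leaf for leaf in leaves if leaf not in references]
    by_clade: dict[str, set] = {}
    for leaf, clade in references.items():
        by_clade.setdefault(clade, set()).add(leaf)
    all_leaves = frozenset(leaves)
    sides = set()
    for part in tree_bipartitions(tree):
        sides.add(part)
        sides.add(all_leaves - part)
    # leaf edges give singleton sides; include them so a lone reference works
    for leaf in leaves:
        sides.add(frozenset({leaf}))
        sides.add(all_leaves - frozenset({leaf}))
    assignment: dict[str, str | None] = {q: None for q in queries}
    unresolvable = []
    for clade, refs in sorted(by_clade.items()):
        other_refs = set(references) - refs
        candidates = [
            s for s in sides if refs <= s and not (s & other_refs) and len(s) < len(leaves)
        ]
        if not candidates:
            unresolvable.append(clade)
            continue
        smallest = min(candidates, key=len)
        for q in queries:
            if q in smallest:
                assignment[q] = clade
    return assignment, unresolvable


def random_additive_distances(
    n_leaves: int,
    rng: np.random.Generator,
    min_branch: float = 0.05,
    max_branch: float = 1.0,
) -> tuple[pd.DataFrame, set[frozenset]]:
    """Random unrooted binary tree -> (additive leaf distances, bipartitions).

    Grows the tree by attaching each new leaf to a uniformly chosen edge
    with strictly positive branch lengths, then returns exact path-length
    distances and the true non-trivial bipartitions (anchor-normalized as in
    :func:`tree_bipartitions`). NJ is consistent on such matrices, which
    makes the generating topology an oracle.
    """
    if n_leaves < 4:
        raise ValueError("need >= 4 leaves for a non-trivial topology")
    labels = [f"L{i}" for i in range(n_leaves)]
    adj: dict[str, dict[str, float]] = {}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def blen():
        return float(rng.uniform(min_branch, max_branch))

    connect(labels[0], "I0", blen())
    connect(labels[1], "I0", blen())
    connect(labels[2], "I0", blen())
    n_internal = 1
    for leaf in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid = f"I{n_internal}"
        n_internal += 1
        split = float(rng.uniform(0.25, 0.75)) * w
        connect(u, mid, split)
        connect(v, mid, w - split)
        connect(leaf, mid, blen())

    def leaf_distances(start):
        dist, stack = {start: 0.0}, [start]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        return dist

    mat = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        d = leaf_distances(a)
        for j, b in enumerate(labels):
            mat[i, j] = d[b]
    np.fill_diagonal(mat, 0.0)

    anchor = min(labels)
    all_leaves = frozenset(labels)
    parts = set()
    for u in adj:
        for v in adj[u]:
            if u < v and u.startswith("I") and v.startswith("I"):
                side = set()
                stack = [(v, u)]
                while stack:
                    node, parent = stack.pop()
                    for nbr in adj[node]:
                        if nbr == parent:
                            continue
                        if nbr.startswith("I"):
                            stack.append((nbr, node))
                        else:
                            side.add(nbr)
                side = frozenset(side)
                if anchor in side:
                    side = all_leaves - side
                if 2 <= len(side) <= n_leaves - 2:
                    parts.add(side)
    return pd.DataFrame(mat, index=labels, columns=labels), parts


def write_newick(
    tree: TreeNode,
    support: Mapping[frozenset, float] | None = None,
    path=None,
) -> str:
    """Newick string with bootstrap supports as internal-node labels."""
    tree = tree.copy()
    if support is not None:
        leaves = sorted(t.name for t in tree.tips())
        anchor, all_leaves = leaves[0], frozenset(leaves)
        for node in tree.traverse(include_self=False):
            if node.is_tip():
                continue
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = all_leaves - side
            if side in support:
                node.name = str(int(round(support[side])))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
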