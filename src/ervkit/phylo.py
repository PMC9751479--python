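"""p-distance matrices, neighbor-joining trees, bootstrap support.

Distances are pairwise-deletion p-distances over shared reference
columns (optionally CpG-masked).  Tree inference is the Saitou-Nei
neighbor-joining agglomeration with deterministic lowest-index
tie-breaking; negative branch-length estimates are clamped to zero with
a warning.  Bootstrap resamples reference-projected columns, so every
replicate shares one coordinate space.  Trees are scikit-bio TreeNode
objects and serialize to Newick with supports as internal-node labels.
"""

from __future__ import annotations

import warnings

import numpy as np
import skbio
from skbio import DistanceMatrix

from ._rng import substream
from ._seq import seq_to_array
from .align import ReferenceProjection
from .dating import _cpg_mask, p_distance
from .reference import ReferenceModel


def distance_matrix_from_alignment(seqs: dict[str, str],
                                   mask_cpg: bool = False) -> DistanceMatrix:
    """Pairwise p-distance matrix over a set of aligned sequences."""
    labels = list(seqs)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d, _ = p_distance(seqs[labels[i]], seqs[labels[j]],
                                  mask_cpg=mask_cpg)
            except ValueError as exc:
                raise ValueError(
                    f"no shared columns between {labels[i]!r} and "
                    f"{labels[j]!r}") from exc
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=labels)


def distance_matrix(projections: list[ReferenceProjection],
                    model: ReferenceModel, region: str = "full",
                    mask_cpg: bool = True) -> DistanceMatrix:
    """Distance matrix over projected loci, restricted to one region."""
    if region == "full":
        span = (0, len(model.provirus_seq))
    else:
        span = model.provirus_span(region)
    seqs = {p.locus_id or f"locus{i}": p.column_string(span)
            for i, p in enumerate(projections)}
    return distance_matrix_from_alignment(seqs, mask_cpg=mask_cpg)


def nj_tree(dm: DistanceMatrix) -> skbio.TreeNode:
    """Neighbor-joining tree (Saitou-Nei) from a distance matrix.

    Deterministic: Q-matrix ties are broken toward the lowest index
    pair.  On an additive matrix the generating topology and branch
    lengths are recovered exactly.  The tree is unrooted, represented
    with a trifurcating root.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    nodes = [skbio.TreeNode(name=lb) for lb in labels]
    clamped = False

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))          # row-major => lowest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = skbio.TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[x] for x in keep] + [parent]

    # resolve the final three nodes around an unrooted center
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    if min(la, lb, lc) < 0:
        clamped = True
    root = skbio.TreeNode()
    for node, ln in ((a, la), (b, lb), (c, lc)):
        node.length = float(max(ln, 0.0))
        root.append(node)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to zero",
                      stacklevel=2)
        root.clamped = True
    return root


def _canonical_splits(tree: skbio.TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions, each named by its smaller labeled side."""
    tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips - side) < 2:
            continue
        other = tips - side
        splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def _pair_distances(codes: np.ndarray, usable: np.ndarray,
                    cols: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    D = np.zeros((n, n))
    sub = codes[:, cols]
    ok = usable[:, cols]
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            sites = int(both.sum())
            if sites == 0:
                d = 0.75
            else:
                d = float(((sub[i] != sub[j]) & both).sum()) / sites
            D[i, j] = D[j, i] = d
    return D


def bootstrap_support(seqs: dict[str, str], n_reps: int = 500,
                      seed: int = 0, mask_cpg: bool = True
                      ) -> skbio.TreeNode:
    """NJ tree with bootstrap supports over resampled alignment columns.

    Supports (percent of replicates containing each split) are attached
    to internal nodes as ``.support`` and as the node name, so Newick
    output carries them as internal labels.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = list(seqs)
    base = nj_tree(distance_matrix_from_alignment(seqs, mask_cpg=mask_cpg))

    L = len(next(iter(seqs.values())))
    codes = np.stack([seq_to_array(seqs[lb]) for lb in labels])
    usable = codes < 4
    if mask_cpg:
        for i, lb in enumerate(labels):
            usable[i] &= ~_cpg_mask(seqs[lb])

    rng = substream(seed, "bootstrap")
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        D = _pair_distances(codes, usable, cols)
        rep = nj_tree(DistanceMatrix(D, ids=labels))
        for split in _canonical_splits(rep):
            counts[split] = counts.get(split, 0) + 1

    tips = frozenset(labels)
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips - side) < 2:
            continue
        key = min(side, tips - side, key=lambda s: (len(s), sorted(s)))
        pct = 100.0 * counts.get(key, 0) / n_reps
        node.support = pct
        node.name = f"{pct:.0f}"
    return base
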