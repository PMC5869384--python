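"""Family trees and the clade-evidence retention rule.

Per-family phylogenies are built by neighbor-joining on log-identity
distances, midpoint rooted, annotated at the leaves with expression and
proteome evidence, and then pruned by a patristic-radius rule: a candidate
toxin is kept only if some leaf within a distance ``d_max`` of it carries
direct evidence (proteomic detection or passing the comparative-expression
filter). This formalizes, as a monotone and testable rule, the practice of
retaining variably expressed isoforms that fall in clades with venom
evidence while discarding evidence-free (likely non-toxin) clades.
"""

from __future__ import annotations

import io
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .sequence import pairwise_identity

MAX_DISTANCE = 5.0


def distance_matrix(
    seqs: Mapping[str, str],
    max_distance: float = MAX_DISTANCE,
) -> DistanceMatrix:
    """Pairwise distances d(a,b) = -ln(identity(a,b)), clamped to ``max_distance``.

    Identity is global-alignment identity over the shorter sequence; zero
    identity is clamped to the maximum with a warning.
    """
    ids = sorted(seqs)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(seqs[ids[i]], seqs[ids[j]])
            if ident <= 0:
                warnings.warn(f"zero identity between {ids[i]} and {ids[j]}; "
                              f"distance clamped to {max_distance}")
                dist = max_distance
            else:
                dist = min(-np.log(ident), max_distance)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining (Saitou-Nei Q criterion) with deterministic tie-breaks.

    Ties in Q are resolved by joining the pair whose (lexicographically
    smallest leaf label in each subtree) pair sorts first. Negative branch
    lengths are clamped to 0 with the deficit moved onto the sibling edge.
    Returns an unrooted tree (trifurcating root node) for n >= 3; for n = 2,
    a root with the two leaves at d/2 each.
    """
    d = np.array(dm.data, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    nodes = [TreeNode(name=i) for i in dm.ids]
    keys = [str(i) for i in dm.ids]  # smallest leaf label per subtree
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        half = d[0, 1] / 2
        for nd in nodes:
            nd.length = half
        return TreeNode(children=nodes)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        d = d2

    # terminal 3-star with closed-form branch lengths
    (a, b, c) = (0, 1, 2)
    la = max(0.0, (d[a, b] + d[a, c] - d[b, c]) / 2)
    lb = max(0.0, (d[a, b] + d[b, c] - d[a, c]) / 2)
    lc = max(0.0, (d[a, c] + d[b, c] - d[a, b]) / 2)
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
    return TreeNode(children=nodes)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The two maximally distant leaves become equidistant from the root;
    all patristic distances are preserved.
    """
    n_tips = tree.count(tips=True)
    if n_tips < 2:
        raise ValueError("need at least 2 leaves")
    if n_tips == 2:
        # already a root of degree 2: just balance the two edges
        out = tree.copy()
        a, b = out.children
        half = ((a.length or 0) + (b.length or 0)) / 2
        a.length = b.length = half
        return out
    return tree.root_at_midpoint(reset=True)


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    return tree.tip_tip_distances()


def clade_evidence_filter(
    tree: TreeNode,
    evidence_ids: set[str],
    d_max: float | str = "median",
) -> set[str]:
    """Retain leaves within patristic distance ``d_max`` of an evidence leaf.

    Evidence leaves (proteomically detected, or passing the comparative
    expression filter) are always retained. ``d_max='median'`` uses the
    median of all pairwise patristic distances in the tree, so the radius
    adapts to each family's depth. A tree with no evidence leaves yields an
    empty retained set, with a warning.
    """
    tips = [t.name for t in tree.tips()]
    evid = [t for t in tips if t in evidence_ids]
    if not evid:
        warnings.warn("no evidence leaves in tree: retaining nothing")
        return set()
    dm = tree.tip_tip_distances()
    arr = np.array(dm.data)
    if d_max == "median":
        d_max_val = float(np.median(arr[np.triu_indices(len(tips), k=1)]))
    else:
        d_max_val = float(d_max)
    idx = {name: i for i, name in enumerate(dm.ids)}
    evid_idx = [idx[e] for e in evid]
    retained = set(evid)
    for name in tips:
        if name in retained:
            continue
        if arr[idx[name], evid_idx].min() <= d_max_val:
            retained.add(name)
    return retained


def annotate_and_export(
    tree: TreeNode,
    records: pd.DataFrame,
    proteome_ids: set[str],
    retained_ids: set[str],
    newick_path,
    annotation_path,
    id_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Write the tree (newick) and a leaf annotation TSV side by side.

    ``records`` is an expression table keyed by transcript id; ``id_map``
    translates leaf (CDS) ids to transcript ids when they differ. Every leaf
    must resolve to an expression record; missing leaves raise with the full
    list of offenders.
    """
    id_map = id_map or {}
    fpkm_vg = dict(zip(records["id"], records["fpkm_vg"]))
    fpkm_mu = dict(zip(records["id"], records["fpkm_muscle"]))
    leaves = [t.name for t in tree.tips()]
    missing = [l for l in leaves if id_map.get(l, l) not in fpkm_vg]
    if missing:
        raise KeyError(f"leaves without expression records: {missing}")
    rows = []
    for leaf in sorted(leaves):
        rid = id_map.get(leaf, leaf)
        rows.append((leaf, fpkm_vg[rid], fpkm_mu[rid],
                     rid in proteome_ids, leaf in retained_ids))
    df = pd.DataFrame(rows, columns=["id", "fpkm_vg", "fpkm_muscle", "detected", "retained"])
    tree.write(str(newick_path), format="newick")
    df.to_csv(annotation_path, sep="\t", index=False)
    return df


def load_annotated(newick_path, annotation_path) -> tuple[TreeNode, pd.DataFrame]:
    tree = TreeNode.read(str(newick_path), format="newick")
    df = pd.read_csv(annotation_path, sep="\t")
    return tree, df
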