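"""Desk-scale tree inference: distances, neighbor joining, bootstrap,
majority-rule consensus, and Fitch parsimony scoring of a fixed topology.

Conventions, stated because several are genuinely open choices:

* Distances use column-wise pairwise deletion (a column contributes to a
  pair only when both residues are non-gap).
* Jukes-Cantor and Kimura two-parameter corrections signal saturation
  (log-domain violations) per pair instead of storing infinities.
* Neighbor joining breaks Q-matrix ties by the smallest (i, j) index pair;
  negative branch-length estimates are clamped to zero with the deficit
  moved to the sister edge, preserving their sum.
* Majority-rule consensus keeps bipartitions with frequency strictly above
  the cutoff (>= 0.5), so retained splits are pairwise compatible.
* Fitch scoring treats gaps as missing data (the full state set).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .records import GAP, Msa
from .tree import PhyloTree, TreeNode

P_MODEL, JC_MODEL, K2P_MODEL = "p", "JC", "K2P"
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    model: str = P_MODEL
    saturated: set[frozenset] = field(default_factory=set)  # pairs past correction

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


def distance_matrix(msa: Msa, model: str = P_MODEL) -> DistanceMatrix:
    """Pairwise distances under p, JC or K2P with pairwise deletion.

    JC: -(3/4) ln(1 - 4p/3). K2P: -(1/2) ln((1-2P-Q) sqrt(1-2Q)) with P, Q
    the transition and transversion proportions. Saturated pairs get NaN and
    are recorded in ``saturated``.
    """
    n = len(msa.ids)
    d = np.zeros((n, n))
    saturated: set[frozenset] = set()
    seqs = [r.residues for r in msa.records]
    for i in range(n):
        for j in range(i + 1, n):
            valid = ts = tv = 0
            for x, y in zip(seqs[i], seqs[j]):
                if x == GAP or y == GAP:
                    continue
                valid += 1
                if x != y:
                    if frozenset((x, y)) in _TRANSITION_PAIRS:
                        ts += 1
                    else:
                        tv += 1
            if valid == 0:
                raise ValueError(f"no shared columns for {msa.ids[i]}/{msa.ids[j]}")
            p = (ts + tv) / valid
            if model == P_MODEL:
                val = p
            elif model == JC_MODEL:
                if p >= 0.75:
                    val = math.nan
                else:
                    val = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            elif model == K2P_MODEL:
                P, Q = ts / valid, tv / valid
                if 1.0 - 2.0 * P - Q <= 0.0 or 1.0 - 2.0 * Q <= 0.0:
                    val = math.nan
                else:
                    val = -0.5 * math.log((1.0 - 2.0 * P - Q) * math.sqrt(1.0 - 2.0 * Q))
            else:
                raise ValueError(f"unknown model {model!r}")
            if math.isnan(val):
                saturated.add(frozenset((msa.ids[i], msa.ids[j])))
            d[i, j] = d[j, i] = val
    return DistanceMatrix(ids=list(msa.ids), d=d, model=model, saturated=saturated)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    """Clamp a negative branch estimate to 0, moving the deficit to the
    sister edge so the pair's sum is preserved."""
    if vi < 0:
        vj += vi
        vi = 0.0
    if vj < 0:
        vi += vj
        vj = 0.0
    return max(vi, 0.0), max(vj, 0.0)


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration; unrooted output with a trifurcating root."""
    if D.saturated:
        raise ValueError(f"saturated pairs present: {sorted(map(sorted, D.saturated))}")
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = D.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in D.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (i, j) index pair on ties
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or Q[a, b] < Q[best] - 1e-12:
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        vi = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        vj = dij - vi
        vi, vj = _clamp_pair(vi, vj)
        parent = TreeNode()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # new distances to the remaining taxa
        d = np.pad(d, ((0, 1), (0, 1)))
        k_new = d.shape[0] - 1
        for c in active:
            if c in (i, j):
                continue
            d[k_new, c] = d[c, k_new] = max(0.5 * (d[i, c] + d[j, c] - dij), 0.0)
        nodes.append(parent)
        active = [c for c in active if c not in (i, j)] + [k_new]

    # final join: trifurcating root via the three-point formulas
    i, j, k = active
    root = TreeNode()
    a = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    b = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    c = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, a), (j, b), (k, c)):
        nodes[idx].length = max(length, 0.0)
        root.add_child(nodes[idx])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    trees: list[PhyloTree]  # replicate NJ trees (successful replicates)
    tree: PhyloTree  # NJ tree on the original alignment, support-annotated
    n_skipped: int  # replicates dropped because a pair saturated


def bootstrap_support(
    msa: Msa,
    n_reps: int,
    seed: int,
    model: str = P_MODEL,
) -> BootstrapResult:
    """Column-resampling bootstrap of the NJ tree.

    Each replicate resamples alignment columns with replacement (same
    width), rebuilds the NJ tree, and an internal edge's support is the
    fraction of successful replicates containing its bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    base = neighbor_joining(distance_matrix(msa, model))
    replicates: list[PhyloTree] = []
    n_skipped = 0
    from .records import SeqRecord  # local to avoid cycle at import time

    for _ in range(n_reps):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        resampled = Msa(
            [
                SeqRecord(id=r.id, residues="".join(r.residues[c] for c in cols))
                for r in msa.records
            ]
        )
        dm = distance_matrix(resampled, model)
        if dm.saturated:
            n_skipped += 1
            continue
        replicates.append(neighbor_joining(dm))
    if not replicates:
        raise ValueError("every bootstrap replicate was saturated")

    counts = Counter()
    for t in replicates:
        counts.update(t.bipartitions())
    denom = len(replicates)
    all_leaves = frozenset(base.leaf_names)
    anchor = min(all_leaves)
    for node in base.root.traverse_postorder():
        if node is base.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            node.support = counts.get(side, 0) / denom
    return BootstrapResult(trees=replicates, tree=base, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Majority-rule consensus
# ---------------------------------------------------------------------------

def majority_rule_consensus(trees: list[PhyloTree], cutoff: float = 0.5) -> PhyloTree:
    """Tree of the bipartitions present in strictly more than ``cutoff`` of
    the input trees (cutoff >= 0.5 makes them pairwise compatible), with
    frequencies as support values. Branch lengths are not assigned."""
    if cutoff < 0.5:
        raise ValueError("cutoff must be >= 0.5")
    if not trees:
        raise ValueError("no trees given")
    leafsets = {frozenset(t.leaf_names) for t in trees}
    if len(leafsets) > 1:
        raise ValueError("trees have inconsistent leaf sets")
    (all_leaves,) = leafsets
    anchor = min(all_leaves)

    counts = Counter()
    for t in trees:
        counts.update(t.bipartitions())
    keep = {
        split: cnt / len(trees)
        for split, cnt in counts.items()
        if cnt / len(trees) > cutoff
    }

    # splits are canonicalized away from the anchor leaf, so the kept family
    # is laminar: build the rooted tree by nesting smaller clusters first
    root = TreeNode()
    cluster_nodes: dict[frozenset, TreeNode] = {}
    for leaf in sorted(all_leaves):
        node = TreeNode(name=leaf)
        cluster_nodes[frozenset([leaf])] = node
    for split in sorted(keep, key=len):
        node = TreeNode(support=keep[split])
        children = []
        covered: set[str] = set()
        # maximal existing clusters inside this split
        for cl in sorted(cluster_nodes, key=len, reverse=True):
            if cl <= split and not (cl & covered):
                children.append(cluster_nodes[cl])
                covered |= cl
        for child in children:
            node.add_child(child)
            cluster_nodes.pop(frozenset(child.leaf_names()))
        cluster_nodes[split] = node
    for cl in sorted(cluster_nodes, key=lambda c: min(c)):
        root.add_child(cluster_nodes[cl])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Fitch parsimony score
# ---------------------------------------------------------------------------

def fitch_score(tree: PhyloTree, msa: Msa) -> int:
    """Minimum mutation count of the alignment on the fixed topology, summed
    over columns; characters are unordered states, gaps are missing data."""
    leaf_names = set(tree.leaf_names)
    if leaf_names != set(msa.ids):
        raise ValueError(
            f"leaf/id mismatch: tree has {sorted(leaf_names)}, msa has {sorted(msa.ids)}"
        )
    post = [n for n in tree.root.traverse_postorder()]
    total = 0
    for col in range(msa.n_cols):
        states = {rec.id: rec.residues[col] for rec in msa.records}
        observed = {s for s in states.values() if s != GAP}
        if len(observed) <= 1:
            continue
        full = frozenset(observed)
        sets: dict[int, frozenset] = {}
        changes = 0
        for node in post:
            if node.is_leaf:
                s = states[node.name]
                sets[id(node)] = frozenset([s]) if s != GAP else full
            else:
                # Hartigan's upward pass: keep the states present in the
                # largest number of child sets; exact for multifurcations
                # (reduces to Fitch intersection/union on binary nodes)
                count = Counter()
                for child in node.children:
                    count.update(sets[id(child)])
                top = max(count.values())
                sets[id(node)] = frozenset(s for s, c in count.items() if c == top)
                changes += len(node.children) - top
        total += changes
    return total
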