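"""Hierarchical clustering, Neighbor-Joining phylogenetics, nucleotide
distances, bootstrap supports, and Newick I/O.

``ward_cluster`` is an explicit agglomerative implementation of the ward.D2
criterion: the Lance–Williams update is applied to *squared* dissimilarities
and merge heights are the (unsquared) distances at merge, matching R's
``hclust(method="ward.D2")``.  ``nj_tree`` is the Saitou–Nei Neighbor-Joining
algorithm, which reconstructs additive distance matrices exactly.  Nucleotide
distances support the p-distance and the Jukes–Cantor (JC69) correction with
pairwise deletion of gapped/ambiguous columns.  Trees are scikit-bio
``TreeNode`` objects, so standard Newick serialization applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .alignment import DistanceMatrix, Msa
from .errors import NewickParseError

VALID_BASES = set("ACGT")
_VALID_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode_rows(rows: list[str]) -> np.ndarray:
    """Alignment rows as a (n_rows, n_cols) uint8 array of ASCII codes."""
    return np.frombuffer("".join(r.upper() for r in rows).encode(),
                         dtype=np.uint8).reshape(len(rows), -1)


@dataclass
class Dendrogram:
    """Agglomerative merge history: (cluster_a, cluster_b, height, new_size).

    Cluster indices follow the scipy convention: leaves are 0..n-1, the i-th
    merge creates cluster n+i.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")
        heights = [h for _, _, h, _ in self.merges]
        if any(h < 0 for h in heights):
            raise ValueError("negative merge height")
        if any(b < a for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights are not non-decreasing")

    def to_linkage(self) -> np.ndarray:
        """scipy-style linkage matrix (for plotting/interop)."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def merge_order(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, _, _ in self.merges]


@dataclass(frozen=True)
class NucDistanceModel:
    model: str = "jc69"  # or "p_distance"
    deletion: str = "pairwise"  # or "complete"

    def __post_init__(self) -> None:
        if self.model not in ("jc69", "p_distance"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.deletion not in ("pairwise", "complete"):
            raise ValueError(f"unknown deletion mode {self.deletion!r}")


def ward_cluster(D: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with the ward.D2 criterion.

    Lance–Williams on squared dissimilarities:
    ``d(k, i∪j)^2 = [(n_i+n_k) d(k,i)^2 + (n_j+n_k) d(k,j)^2 - n_k d(i,j)^2]
    / (n_i+n_j+n_k)``.  Merge height is the distance at merge.  Ties are
    broken by the lexicographically smallest pair of cluster representative
    labels, so the merge sequence is deterministic.
    """
    n = len(D.labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    d2 = {}  # squared distances between active clusters
    active = {}  # cluster index -> (size, representative label)
    for i in range(n):
        active[i] = (1, D.labels[i])
        for j in range(i + 1, n):
            d2[(i, j)] = float(D.values[i, j]) ** 2
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), v in d2.items():
            li, lj = active[i][1], active[j][1]
            key = (v, min(li, lj), max(li, lj))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij2 = d2[(i, j)]
        ni, li = active[i]
        nj, lj = active[j]
        new_size = ni + nj
        merges.append((i, j, math.sqrt(dij2), new_size))
        new_d2 = {}
        for k, (nk, lk) in active.items():
            if k in (i, j):
                continue
            dki2 = d2[(min(i, k), max(i, k))]
            dkj2 = d2[(min(j, k), max(j, k))]
            new_d2[k] = ((ni + nk) * dki2 + (nj + nk) * dkj2 - nk * dij2) / (
                ni + nj + nk
            )
        del active[i], active[j]
        d2 = {
            (a, b): v
            for (a, b), v in d2.items()
            if a not in (i, j) and b not in (i, j)
        }
        for k, v in new_d2.items():
            d2[(min(k, next_id), max(k, next_id))] = v
        active[next_id] = (new_size, min(li, lj))
        next_id += 1
    return Dendrogram(merges=merges, leaf_labels=list(D.labels))


def cut_dendrogram(dend: Dendrogram, k: int) -> dict[str, int]:
    """Cut into ``k`` clusters by removing the ``k - 1`` highest merges.

    Returns leaf label -> cluster id, with cluster ids numbered by first leaf
    appearance order.
    """
    n = len(dend.leaf_labels)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (a, b, _, _) in enumerate(dend.merges[: n - k]):
        new = n + idx
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, int] = {}
    assignment = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        assignment[dend.leaf_labels[leaf]] = roots[r]
    return assignment


def nuc_distance(aln: Msa, model: NucDistanceModel | None = None):
    """Pairwise nucleotide distances from an alignment.

    Pairwise deletion drops, per sequence pair, every column where either row
    has a gap or an ambiguous base; complete deletion drops such columns for
    all pairs.  p = mismatches / valid columns; JC69 applies
    ``d = -(3/4) ln(1 - (4/3) p)`` and requires p < 0.75 — saturated pairs
    are flagged and their entries set to NaN.

    Returns ``(DistanceMatrix, flags)`` where flags is a dict
    ``(id_a, id_b) -> message`` for saturated pairs.
    """
    model = model or NucDistanceModel()
    ids = aln.ids
    arr = _encode_rows(aln.rows)
    return _distances_from_array(arr, list(ids), model)


def _distances_from_array(arr: np.ndarray, ids: list[str],
                          model: NucDistanceModel):
    if model.deletion == "complete":
        good = np.ones(arr.shape[1], dtype=bool)
        for row in arr:
            good &= np.isin(row, _VALID_CODES)
        arr = arr[:, good]
    n = len(ids)
    valid_mask = np.isin(arr, _VALID_CODES)
    D = np.zeros((n, n))
    flags: dict[tuple[str, str], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            both = valid_mask[i] & valid_mask[j]
            valid = int(both.sum())
            if valid == 0:
                flags[(ids[i], ids[j])] = "no comparable sites"
                D[i, j] = D[j, i] = np.nan
                continue
            mism = int((arr[i][both] != arr[j][both]).sum())
            p = mism / valid
            if model.model == "p_distance":
                d = p
            else:
                if p >= 0.75:
                    flags[(ids[i], ids[j])] = f"saturated (p={p:.3f} >= 0.75)"
                    D[i, j] = D[j, i] = np.nan
                    continue
                d = -0.75 * math.log(1 - 4 * p / 3)
            D[i, j] = D[j, i] = d
    if np.isnan(D).any():
        # DistanceMatrix forbids NaN; callers must handle flagged pairs.
        return _RawDistances(labels=list(ids), values=D), flags
    return DistanceMatrix(labels=list(ids), values=D), flags


@dataclass
class _RawDistances:
    """Distance container used only when entries are flagged (NaN present)."""

    labels: list[str]
    values: np.ndarray


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Saitou–Nei Neighbor-Joining tree from a distance matrix.

    Iteratively joins the pair minimizing
    ``Q(i,j) = (r - 2) d(i,j) - R_i - R_j`` with ``R_i = Σ_k d(i,k)``;
    branch lengths follow the standard NJ formulas.  Ties break on the
    lexicographically smallest label pair.  Negative branch-length estimates
    are clamped to zero for output, with the raw estimate kept on the node
    (``raw_length``).  The result is an unrooted binary tree (trifurcating
    root) of scikit-bio ``TreeNode`` nodes.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    nodes = {lab: TreeNode(name=lab) for lab in D.labels}
    dist = {}
    for i, a in enumerate(D.labels):
        for j in range(i + 1, n):
            b = D.labels[j]
            dist[frozenset((a, b))] = float(D.values[i, j])
    labels = sorted(D.labels)

    def d(a, b):
        return dist[frozenset((a, b))]

    counter = 0
    while len(labels) > 3:
        r = len(labels)
        R = {a: sum(d(a, b) for b in labels if b != a) for a in labels}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = labels[i], labels[j]
                q = (r - 2) * d(a, b) - R[a] - R[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * d(a, b) + (R[a] - R[b]) / (2 * (r - 2))
        lb = d(a, b) - la
        new_name = f"_nj{counter}"
        counter += 1
        parent = TreeNode(name=None)
        for child, raw in ((nodes[a], la), (nodes[b], lb)):
            child.length = max(0.0, raw)
            child.raw_length = raw
            parent.append(child)
        nodes[new_name] = parent
        for c in labels:
            if c in (a, b):
                continue
            dist[frozenset((new_name, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        labels = sorted([l for l in labels if l not in (a, b)] + [new_name])
    # Final three-way join via the three-point formulas.
    a, b, c = labels
    root = TreeNode(name=None)
    lengths = {
        a: 0.5 * (d(a, b) + d(a, c) - d(b, c)),
        b: 0.5 * (d(a, b) + d(b, c) - d(a, c)),
        c: 0.5 * (d(a, c) + d(b, c) - d(a, b)),
    }
    for lab in (a, b, c):
        child = nodes[lab]
        child.length = max(0.0, lengths[lab])
        child.raw_length = lengths[lab]
        root.append(child)
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each normalized to the
    side not containing the alphabetically first leaf."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    all_set = frozenset(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def path_length(tree: TreeNode, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    return tree.find(a).distance(tree.find(b))


def bootstrap_supports(
    aln: Msa,
    model: NucDistanceModel | None = None,
    replicates: int = 1000,
    seed: int | None = None,
    unit: str = "codon",
) -> TreeNode:
    """NJ tree with bootstrap supports on internal edges.

    Alignment units (single columns or codon triples) are resampled with
    replacement per replicate; the NJ tree is rebuilt from each resample and
    the support of each internal edge of the full-data tree is the percentage
    of replicates whose tree contains the same bipartition.  Supports are
    stored as internal node names (and ``bootstrap_support`` attributes).  Replicates
    whose resampled distances are saturated/undefined are counted as not
    containing any bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if unit not in ("column", "codon"):
        raise ValueError(f"unknown resampling unit {unit!r}")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    model = model or NucDistanceModel()
    D, flags = nuc_distance(aln, model)
    if flags:
        raise ValueError(f"distance undefined for pairs: {sorted(flags)}")
    tree = nj_tree(D)
    cols = aln.column_count
    step = 3 if unit == "codon" else 1
    if step == 3 and cols % 3:
        raise ValueError("codon resampling requires column count divisible by 3")
    n_units = cols // step
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in tree_bipartitions(tree)}
    arr = _encode_rows(aln.rows)
    unit_cols = arr.reshape(arr.shape[0], n_units, step)
    for _ in range(replicates):
        idx = rng.integers(0, n_units, size=n_units)
        rep_arr = unit_cols[:, idx, :].reshape(arr.shape[0], -1)
        Dr, fl = _distances_from_array(rep_arr, list(aln.ids), model)
        if fl:
            continue
        rep_bps = tree_bipartitions(nj_tree(Dr))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    all_set = frozenset(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_set - side
        if side in counts:
            support = 100.0 * counts[side] / replicates
            node.bootstrap_support = support
            node.name = f"{support:g}"
    return tree


def dendrogram_to_tree(dend: Dendrogram) -> TreeNode:
    """Rooted ultrametric tree from a merge history (leaf depth = height/2)."""
    n = len(dend.leaf_labels)
    nodes = [TreeNode(name=lab) for lab in dend.leaf_labels]
    height = [0.0] * n
    for a, b, h, _ in dend.merges:
        parent = TreeNode(name=None)
        for child_idx in (a, b):
            child = nodes[child_idx]
            child.length = h / 2 - height[child_idx]
            parent.append(child)
        nodes.append(parent)
        height.append(h / 2)
    return nodes[-1]


def write_newick(tree, path) -> None:
    """Serialize a tree (or dendrogram) to a Newick file."""
    if isinstance(tree, Dendrogram):
        tree = dendrogram_to_tree(tree)
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    """Parse a Newick file; malformed input raises NewickParseError."""
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as err:
        raise NewickParseError(f"{path}: {err}") from err
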