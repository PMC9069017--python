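"""Reference-anchored alignment, NJ phylogeny, and clade composition checks.

The tree-building route is deliberately simple and fully deterministic:
every sequence (already trimmed to the polymerase domain) is pairwise
aligned to the reference domain and projected onto reference columns,
giving a fixed-width anchored alignment keyed to *E. coli* numbering;
p-distances over shared columns feed a neighbor-joining tree, rooted on
the reference sequence. Bootstrap support comes from a plain column
resampling. Group composition on the rooted tree (monophyly, intruder
counts) is assessed per 762 class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import AlignmentParams, pairwise_align
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AnchoredMSA",
    "TreeNode",
    "PhyloTree",
    "MonophylyReport",
    "GroupReport",
    "build_anchored_msa",
    "p_distance_matrix",
    "nj_tree",
    "root_on",
    "bootstrap_support",
    "assess_group_monophyly",
    "annotate_tree",
]


# ---------------------------------------------------------------------------
# Anchored MSA


@dataclass(frozen=True)
class AnchoredMSA:
    """Fixed-width alignment in reference column space.

    Every row has exactly as many columns as the reference domain;
    insertions relative to the reference are discarded so that column *k*
    is always reference position *k*. The reference itself is row 0 and is
    gap-free.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    reference_id: str

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("anchored MSA rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)


def build_anchored_msa(
    records: Sequence[ProteinRecord],
    reference: ProteinRecord,
    params: AlignmentParams | None = None,
) -> AnchoredMSA:
    """Project pairwise alignments of each record onto reference columns.

    Records contributing zero aligned columns are excluded with a warning.
    """
    params = params or AlignmentParams()
    ids = [reference.id]
    rows = [reference.residues]
    width = len(reference)
    for rec in records:
        if rec.id == reference.id:
            continue
        aln = pairwise_align(reference, rec, params)
        row = ["-"] * width
        n_aligned = 0
        for pa, pb in aln.column_map:
            if pa is not None and pb is not None:
                row[pa - 1] = rec.residues[pb - 1]
                n_aligned += 1
        if n_aligned == 0:
            warnings.warn(f"record {rec.id!r}: no columns aligned to reference; excluded")
            continue
        ids.append(rec.id)
        rows.append("".join(row))
    return AnchoredMSA(ids=tuple(ids), rows=tuple(rows), reference_id=reference.id)


# ---------------------------------------------------------------------------
# Distances


def p_distance_matrix(
    msa: AnchoredMSA, min_shared_columns: int = 100
) -> tuple[tuple[str, ...], np.ndarray]:
    """Pairwise p-distances: mismatches over shared non-gap columns.

    Pairs sharing fewer than ``min_shared_columns`` columns are an error —
    a p-distance from a handful of columns is noise.
    """
    n = len(msa)
    if n < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    arr = np.array([list(r) for r in msa.rows])
    residue = arr != "-"
    d = np.zeros((n, n))
    for i in range(n):
        shared = residue[i] & residue[i + 1 :]
        n_shared = shared.sum(axis=1)
        mism = ((arr[i] != arr[i + 1 :]) & shared).sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            if n_shared[k] < min_shared_columns:
                raise ValueError(
                    f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share only "
                    f"{n_shared[k]} columns (< {min_shared_columns})"
                )
            d[i, j] = d[j, i] = mism[k] / n_shared[k]
    return msa.ids, d


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    """A node of a phylogenetic tree; ``support`` lives on the edge above."""

    name: str | None = None
    branch_length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    """A (possibly rooted) binary tree over sequence ids."""

    root: TreeNode
    rooted: bool = False

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    # -- Newick -------------------------------------------------------------

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})"
                if with_support and node.support is not None:
                    label += f"{node.support:g}"
            if node.branch_length is not None:
                label += f":{node.branch_length:.6g}"
            return label

        return fmt(self.root) + ";"

    # -- Bipartitions ---------------------------------------------------------

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Unrooted bipartitions induced by internal edges (non-trivial only)."""
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset[frozenset[str]]] = set()
        for node in self.root.walk():
            if node is self.root:
                continue
            side = frozenset(leaf.name for leaf in node.leaves())
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset((side, other)))
        return out


def _edge_list(tree: PhyloTree) -> tuple[dict[int, str | None], list[tuple[int, int, float, float | None]]]:
    """Flatten a tree into node names and undirected weighted edges."""
    names: dict[int, str | None] = {}
    edges: list[tuple[int, int, float, float | None]] = []
    counter = [0]

    def visit(node: TreeNode) -> int:
        nid = counter[0]
        counter[0] += 1
        names[nid] = node.name
        for child in node.children:
            cid = visit(child)
            edges.append((nid, cid, child.branch_length or 0.0, child.support))
        return nid

    visit(tree.root)
    return names, edges


def nj_tree(ids: Sequence[str], matrix: np.ndarray) -> PhyloTree:
    """Neighbor joining (Saitou–Nei) on a symmetric distance matrix.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of subtree-minimum leaf ids, making the topology deterministic.
    Negative branch lengths are clamped to zero and the deficit logged.
    NJ is exact on additive matrices: the true topology and branch lengths
    are recovered whenever the four-point condition holds.
    """
    d = np.asarray(matrix, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ValueError("matrix shape does not match ids")
    if np.isnan(d).any():
        raise ValueError("NaN in distance matrix")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if len(set(ids)) != n:
        raise ValueError("duplicate taxon ids")

    def clamp(x: float, where: str) -> float:
        if x < 0:
            logger.debug("clamped negative branch length %.4g at %s", x, where)
            return 0.0
        return x

    nodes: list[TreeNode] = [TreeNode(name=i, branch_length=None) for i in ids]
    labels: list[str] = list(ids)  # minimum leaf id of each active subtree
    active = list(range(n))
    dist = d.copy()

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for a, b in np.argwhere(q <= qmin + 1e-12):
            if a >= b:
                continue
            pair = tuple(sorted((labels[active[a]], labels[active[b]])))
            if best is None or pair < best:
                best, bi, bj = pair, int(a), int(b)
        i, j = active[bi], active[bj]
        dij = dist[i, j]
        li = clamp(0.5 * dij + (r[bi] - r[bj]) / (2 * (m - 2)), f"join({labels[i]},{labels[j]})")
        lj = clamp(dij - li, f"join({labels[i]},{labels[j]})")
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        new_node = TreeNode(children=[nodes[i], nodes[j]])
        new_idx = dist.shape[0]
        newrow = 0.5 * (dist[i, :] + dist[j, :] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[new_idx, : new_idx] = newrow
        dist[: new_idx, new_idx] = newrow
        nodes.append(new_node)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # Three-point closed form for the final trifurcation.
    a, b, c = active
    la = clamp(0.5 * (dist[a, b] + dist[a, c] - dist[b, c]), "final")
    lb = clamp(0.5 * (dist[a, b] + dist[b, c] - dist[a, c]), "final")
    lc = clamp(0.5 * (dist[a, c] + dist[b, c] - dist[a, b]), "final")
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].branch_length = ln
    order = sorted((a, b, c), key=lambda k: labels[k])
    root = TreeNode(children=[nodes[k] for k in order])
    return PhyloTree(root=root, rooted=False)


def root_on(tree: PhyloTree, leaf_id: str) -> PhyloTree:
    """Root the tree at the midpoint of a leaf's pendant edge.

    The unrooted bipartition set is unchanged; only the direction of edges
    is. Typically used with the reference sequence as outgroup.
    """
    names, edges = _edge_list(tree)
    leaf_nodes = [nid for nid, nm in names.items() if nm == leaf_id]
    if not leaf_nodes:
        raise ValueError(f"leaf {leaf_id!r} not in tree")
    leaf = leaf_nodes[0]
    adj: dict[int, list[tuple[int, float, float | None]]] = {nid: [] for nid in names}
    for u, v, ln, sup in edges:
        adj[u].append((v, ln, sup))
        adj[v].append((u, ln, sup))
    if len(adj[leaf]) != 1:
        raise ValueError(f"{leaf_id!r} is not a leaf")
    parent, pend_len, pend_sup = adj[leaf][0]

    def build(node: int, come_from: int) -> TreeNode:
        kids = [
            (v, ln, sup) for v, ln, sup in adj[node] if v != come_from
        ]
        tn = TreeNode(name=names[node])
        for v, ln, sup in sorted(kids, key=lambda t: t[0]):
            child = build(v, node)
            child.branch_length = ln
            child.support = sup
            tn.children.append(child)
        return tn

    leaf_side = TreeNode(name=leaf_id, branch_length=pend_len / 2)
    rest = build(parent, leaf)
    rest.branch_length = pend_len / 2
    rest.support = pend_sup
    root = TreeNode(children=[leaf_side, rest])
    return PhyloTree(root=root, rooted=True)


def bootstrap_support(
    msa: AnchoredMSA,
    n_replicates: int = 100,
    seed: int | None = None,
    min_shared_columns: int = 100,
) -> PhyloTree:
    """NJ tree with column-bootstrap support on internal edges.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of an internal edge is the fraction of replicate trees
    containing the same (unrooted) bipartition.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    ids, d = p_distance_matrix(msa, min_shared_columns=min_shared_columns)
    tree = nj_tree(ids, d)
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    width = msa.n_columns
    arr = np.array([list(r) for r in msa.rows])
    for _ in range(n_replicates):
        cols = rng.integers(0, width, size=width)
        rep_rows = tuple("".join(row) for row in arr[:, cols])
        rep = AnchoredMSA(ids=msa.ids, rows=rep_rows, reference_id=msa.reference_id)
        try:
            rep_ids, rep_d = p_distance_matrix(rep, min_shared_columns=1)
        except ValueError:
            continue
        rep_bps = nj_tree(rep_ids, rep_d).bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_leaves = frozenset(tree.leaf_names())
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(leaf.name for leaf in node.leaves())
        bp = frozenset((side, all_leaves - side))
        if bp in counts:
            node.support = counts[bp] / n_replicates
    return tree


# ---------------------------------------------------------------------------
# Monophyly


@dataclass(frozen=True)
class GroupReport:
    group: str
    n_members: int
    clade_size: int
    intruders: tuple[str, ...]
    verdict: str  # "monophyletic" | "non-monophyletic"
    n_intruder_subclades: int
    flagged_small: bool = False


@dataclass(frozen=True)
class MonophylyReport:
    groups: Mapping[str, GroupReport]

    def all_monophyletic(self) -> bool:
        return all(g.verdict == "monophyletic" for g in self.groups.values())


def _mrca(root: TreeNode, targets: set[str]) -> TreeNode:
    """Deepest node whose leaf set contains all targets."""
    node = root
    while True:
        for child in node.children:
            leaf_set = {l.name for l in child.leaves()}
            if targets <= leaf_set:
                node = child
                break
        else:
            return node


def assess_group_monophyly(
    tree: PhyloTree, leaf_classes: Mapping[str, str]
) -> MonophylyReport:
    """Per-class clade composition on a rooted tree.

    For each class: the MRCA clade of its leaves, the intruder leaves
    (clade members of other classes), a monophyly verdict, and the minimal
    number of complete subclades covering the intruders (the count of
    maximal all-intruder subtrees under the MRCA). Classes with fewer than
    two leaves are monophyletic by convention and flagged.
    """
    if not tree.rooted:
        raise ValueError("monophyly assessment requires a rooted tree")
    leaf_names = tree.leaf_names()
    missing = [l for l in leaf_names if l not in leaf_classes]
    if missing:
        raise ValueError(f"unmapped leaves: {missing[:5]}")
    groups: dict[str, GroupReport] = {}
    for group in sorted(set(leaf_classes[l] for l in leaf_names)):
        members = {l for l in leaf_names if leaf_classes[l] == group}
        if len(members) < 2:
            groups[group] = GroupReport(
                group=group,
                n_members=len(members),
                clade_size=len(members),
                intruders=(),
                verdict="monophyletic",
                n_intruder_subclades=0,
                flagged_small=True,
            )
            continue
        mrca = _mrca(tree.root, members)
        clade = {l.name for l in mrca.leaves()}
        intruders = clade - members

        def count_maximal_intruder_subtrees(node: TreeNode) -> int:
            leafset = {l.name for l in node.leaves()}
            if leafset <= intruders:
                return 1
            return sum(count_maximal_intruder_subtrees(c) for c in node.children)

        n_sub = count_maximal_intruder_subtrees(mrca) if intruders else 0
        groups[group] = GroupReport(
            group=group,
            n_members=len(members),
            clade_size=len(clade),
            intruders=tuple(sorted(intruders)),
            verdict="monophyletic" if not intruders else "non-monophyletic",
            n_intruder_subclades=n_sub,
        )
    return MonophylyReport(groups=groups)


# ---------------------------------------------------------------------------
# Annotation output


def annotate_tree(
    tree: PhyloTree,
    leaf_classes: Mapping[str, str],
    leaf_sources: Mapping[str, str] | None = None,
    newick_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> tuple[str, str]:
    """Emit Newick (supports as internal labels) and a leaf-annotation TSV.

    Returns (newick string, TSV string); writes them when paths are given.
    Raises if any leaf lacks a class annotation.
    """
    missing = [l for l in tree.leaf_names() if l not in leaf_classes]
    if missing:
        raise ValueError(f"unmapped leaves: {missing[:5]}")
    newick = tree.to_newick(with_support=True)
    lines = ["leaf_id\tclass762\tsource"]
    for leaf in tree.leaf_names():
        src = (leaf_sources or {}).get(leaf, "")
        lines.append(f"{leaf}\t{leaf_classes[leaf]}\t{src}")
    tsv = "\n".join(lines) + "\n"
    if newick_path is not None:
        Path(newick_path).write_text(newick + "\n")
    if tsv_path is not None:
        Path(tsv_path).write_text(tsv)
    return newick, tsv
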