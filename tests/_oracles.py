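"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the package's own algorithms: alignment scores
come from exhaustive memoized recursion over alignment states, local
scores from enumeration of all substring pairs, clustering from a direct
re-statement of the greedy rule, and monophyly metrics from enumeration
of all clades of a tree.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def global_score_oracle(a: str, b: str, gap_open: float = -11.0,
                        gap_extend: float = -1.0) -> float:
    """Optimal global affine-gap score by exhaustive state recursion.

    State: position (i, j) consumed so far and which move produced the
    previous column (match, gap-in-b, gap-in-a); a gap column scores
    ``gap_open`` when it opens a gap and ``gap_extend`` when it extends one.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, _B62[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):  # a-residue against gap in b
            cost = gap_extend if prev == "GB" else gap_open
            best = max(best, cost + rec(i + 1, j, "GB"))
        if j < len(b):  # b-residue against gap in a
            cost = gap_extend if prev == "GA" else gap_open
            best = max(best, cost + rec(i, j + 1, "GA"))
        return best

    return rec(0, 0, "M")


def local_score_oracle(a: str, b: str, gap_open: float = -11.0,
                       gap_extend: float = -1.0) -> float:
    """Optimal local score: best global score over all substring pairs
    (an optimal local alignment never starts or ends with a gap, and
    terminal gaps only lower a global score), floored at 0."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = global_score_oracle(a[i1:i2], b[j1:j2], gap_open, gap_extend)
                    best = max(best, s)
    return best


def greedy_cluster_oracle(records, aligner) -> list[tuple[str, tuple[str, ...]]]:
    """Direct restatement of the greedy rule: records in (length desc, id
    asc) order; each joins the first representative (creation order) it
    matches under ``aligner(rep, rec) -> bool``, else founds a cluster."""
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    clusters: list[tuple] = []  # (rep record, [member ids])
    for rec in ordered:
        for rep, members in clusters:
            if aligner(rep, rec):
                members.append(rec.id)
                break
        else:
            clusters.append((rec, [rec.id]))
    return [(rep.id, tuple(members)) for rep, members in clusters]


def all_clades(node) -> list[frozenset[str]]:
    """Leaf sets of every node (including leaves) of a rooted tree."""
    out = [frozenset(l.name for l in node.leaves())]
    for c in node.children:
        out.extend(all_clades(c))
    return out


def monophyly_oracle(tree, leaf_classes: dict[str, str], group: str):
    """(verdict, intruders, minimal subclade cover) from clade enumeration.

    The MRCA clade is the smallest clade containing the group; the cover
    count is the number of inclusion-maximal all-intruder clades.
    """
    members = frozenset(l for l, c in leaf_classes.items() if c == group)
    clades = all_clades(tree.root)
    containing = [c for c in clades if members <= c]
    mrca_clade = min(containing, key=len)
    intruders = mrca_clade - members
    monophyletic = intruders == frozenset()
    pure = [c for c in clades if c and c <= intruders and c <= mrca_clade]
    maximal = [c for c in pure if not any(c < d for d in pure)]
    return (
        "monophyletic" if monophyletic else "non-monophyletic",
        intruders,
        len(maximal),
    )
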