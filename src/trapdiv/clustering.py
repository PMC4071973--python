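"""UPGMA dendrograms, threshold cuts, Newick export, cophenetic diagnostics.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the two closest clusters; the distance from a merged cluster ``A u B`` to any
other cluster ``X`` is the unweighted average over all cross leaf pairs,
maintained incrementally as ``(n_A d_AX + n_B d_BX) / (n_A + n_B)``. Merge
heights are therefore non-decreasing and the tree is ultrametric.

Ties are broken deterministically: among all pairs at the minimum distance,
the pair whose clusters contain the smallest original leaf indices (compared
lexicographically) is merged first.

Cluster cuts are specified on the *similarity* scale, as is conventional for
band-sharing studies: cutting at similarity ``s`` keeps every merge whose
height is strictly below ``1 - s``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from trapdiv.errors import ValidationError
from trapdiv.similarity import DistanceMatrix


@dataclass
class Dendrogram:
    """Rooted ultrametric tree produced by :func:`upgma`.

    Nodes are integer ids: ``0 .. n-1`` are the leaves in ``leaves`` order;
    merge ``k`` (0-based) creates internal node ``n + k``. ``merges`` holds
    ``(left_id, right_id, height)`` with heights on the distance scale,
    non-decreasing in merge order.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValidationError(
                f"{n} leaves require {n - 1} merges, got {len(self.merges)}"
            )
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def node_members(self) -> dict[int, frozenset[int]]:
        """Leaf-index set of every node (leaves and internal)."""
        n = self.n_leaves
        members: dict[int, frozenset[int]] = {
            i: frozenset([i]) for i in range(n)
        }
        for k, (a, b, _) in enumerate(self.merges):
            members[n + k] = members[a] | members[b]
        return members

    def cophenetic_matrix(self) -> np.ndarray:
        """n x n matrix of merge heights at which leaf pairs first join."""
        n = self.n_leaves
        members = self.node_members()
        coph = np.zeros((n, n))
        for k, (a, b, h) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    coph[i, j] = coph[j, i] = h
        return coph

    def to_linkage(self) -> np.ndarray:
        """Merges in scipy ``linkage`` array layout (for plotting/interop)."""
        members = self.node_members()
        n = self.n_leaves
        return np.array(
            [
                [a, b, h, len(members[n + k])]
                for k, (a, b, h) in enumerate(self.merges)
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of the strains obtained by cutting a dendrogram."""

    threshold_similarity: float
    labels: dict[str, int]
    k: int

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for strain, cid in self.labels.items():
            out.setdefault(cid, []).append(strain)
        return out

    def write_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["strain", "cluster", "threshold_similarity"])
            for strain, cid in self.labels.items():
                w.writerow([strain, cid, f"{self.threshold_similarity:g}"])


def _check_distance(d: DistanceMatrix) -> np.ndarray:
    vals = np.asarray(d.values, dtype=float)
    if vals.shape[0] != vals.shape[1] or not np.allclose(vals, vals.T):
        raise ValidationError("distance matrix must be square and symmetric")
    if (vals < -1e-12).any():
        raise ValidationError("distances must be non-negative")
    return vals


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Build the UPGMA dendrogram of a distance matrix (n >= 2)."""
    vals = _check_distance(d)
    n = d.n
    if n < 2:
        raise ValidationError("need >= 2 strains to cluster")

    # active clusters ordered by smallest contained leaf index; that order is
    # preserved across merges, so "first pair at the minimum" is exactly the
    # lexicographic tie rule
    node_id = list(range(n))
    size = [1] * n
    cur = vals.astype(float).copy()
    merges: list[tuple[int, int, float]] = []
    active = list(range(n))  # indices into node_id/size rows of cur

    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                dist = cur[active[ai], active[bi]]
                if best is None or dist < best[0]:
                    best = (dist, ai, bi)
        dist, ai, bi = best
        ra, rb = active[ai], active[bi]
        merges.append((node_id[ra], node_id[rb], float(dist)))
        # proportional (unweighted over leaves) average to every other cluster
        for other in active:
            if other in (ra, rb):
                continue
            newd = (
                size[ra] * cur[ra, other] + size[rb] * cur[rb, other]
            ) / (size[ra] + size[rb])
            cur[ra, other] = cur[other, ra] = newd
        node_id[ra] = n + step
        size[ra] += size[rb]
        del active[bi]

    return Dendrogram(list(d.strain_ids), merges)


_PLAIN_LABEL = re.compile(r"^[^\s()\[\]:;,']+$")


def _newick_label(label: str) -> str:
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(t: Dendrogram) -> str:
    """Serialize a dendrogram as an ultrametric Newick string.

    Node depths are half the merge heights, so every root-to-leaf path has
    length ``root_height / 2`` and cophenetic distances are recovered as
    twice the path depth of the connecting node.
    """
    n = t.n_leaves
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h) in enumerate(t.merges):
        heights[n + k] = h
        children[n + k] = (a, b)

    def render(node: int, parent_height: float) -> str:
        blen = (parent_height - heights[node]) / 2.0
        if node < n:
            return f"{_newick_label(t.leaves[node])}:{blen:.10g}"
        a, b = children[node]
        inner = f"({render(a, heights[node])},{render(b, heights[node])})"
        return f"{inner}:{blen:.10g}"

    root = n + len(t.merges) - 1 if t.merges else 0
    if not t.merges:  # single leaf, not reachable through upgma (n >= 2)
        return f"{_newick_label(t.leaves[0])};"
    a, b = children[root]
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"


def _assignment_from_merges(
    t: Dendrogram, applied: Sequence[tuple[int, int, float]], s: float
) -> ClusterAssignment:
    n = t.n_leaves
    parent = list(range(n + len(t.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, _) in enumerate(applied):
        node = n + k
        parent[find(a)] = node
        parent[find(b)] = node

    labels: dict[str, int] = {}
    root_to_cid: dict[int, int] = {}
    for i, strain in enumerate(t.leaves):
        r = find(i)
        if r not in root_to_cid:
            root_to_cid[r] = len(root_to_cid) + 1
        labels[strain] = root_to_cid[r]
    return ClusterAssignment(
        threshold_similarity=s, labels=labels, k=len(root_to_cid)
    )


def cut_at_similarity(t: Dendrogram, s: float) -> ClusterAssignment:
    """Cut the tree at similarity ``s``: keep merges with height < ``1 - s``.

    ``s = 1`` yields all singletons; ``s = 0`` yields one cluster (every
    merge is kept, including any at distance exactly 1). Cluster ids are
    assigned 1..k in order of first strain appearance.
    """
    if not 0.0 <= s <= 1.0:
        raise ValidationError(f"similarity threshold {s} outside [0, 1]")
    if s == 0.0:
        applied = t.merges
    else:
        cutoff = 1.0 - s
        applied = [m for m in t.merges if m[2] < cutoff]
        # merges are height-sorted, so `applied` is a prefix and the union
        # below never references an unbuilt internal node
        applied = t.merges[: len(applied)]
    return _assignment_from_merges(t, applied, s)


def cut_into_k(t: Dendrogram, k: int) -> ClusterAssignment:
    """Partition into exactly ``k`` clusters by undoing the last merges.

    The recorded threshold is the similarity complement of the first merge
    left unapplied (the height at which the partition would coarsen).
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    applied = t.merges[: n - k]
    if k == 1:
        s = 0.0
    else:
        s = 1.0 - t.merges[n - k][2]
    return _assignment_from_merges(t, applied, s)


def cophenetic_correlation(t: Dendrogram, d: DistanceMatrix) -> float:
    """Pearson correlation between input and cophenetic pairwise distances.

    The standard goodness-of-fit diagnostic for a UPGMA tree; 1.0 means the
    input was already ultrametric. Undefined (error) for n < 3.
    """
    if t.leaves != list(d.strain_ids):
        raise ValidationError("dendrogram and distance matrix leaf sets differ")
    n = t.n_leaves
    if n < 3:
        raise ValidationError("cophenetic correlation needs >= 3 leaves")
    coph = t.cophenetic_matrix()
    iu = np.triu_indices(n, k=1)
    x = np.asarray(d.values)[iu]
    y = coph[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError(
            "cophenetic correlation undefined for constant distances"
        )
    return float(np.corrcoef(x, y)[0, 1])
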