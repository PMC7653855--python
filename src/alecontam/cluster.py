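"""Complete-linkage (farthest-neighbour) clustering of binary genotypes.

Genotypes are 0/1 presence/absence vectors; the pairwise metric is the
plain Euclidean distance, so two isolates differing in k mutations are
sqrt(k) apart.  The agglomeration is written out directly rather than
delegated so that ties are broken deterministically: when two candidate
merges have equal height, the pair containing the lowest original row
index is merged first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .catalog import CatalogError, GenotypeMatrix

__all__ = ["Dendrogram", "cluster_genotypes", "complete_linkage"]


@dataclass
class Dendrogram:
    """Agglomeration result in scipy linkage convention.

    ``merges`` has one entry per merge: (cluster_a, cluster_b, height, size)
    where clusters 0..n-1 are the original leaves and each merge creates
    cluster n+i.  Heights are Euclidean-distance units and, for complete
    linkage, non-decreasing.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order obtained by expanding the merge tree."""
        n = self.n_leaves
        children: dict[int, tuple[int, int]] = {
            n + i: (a, b) for i, (a, b, _, _) in enumerate(self.merges)
        }

        def expand(node: int) -> list[int]:
            if node < n:
                return [node]
            a, b = children[node]
            return expand(a) + expand(b)

        return expand(n + len(self.merges) - 1) if self.merges else [0]


def complete_linkage(vectors: list[list[float]]) -> list[tuple[int, int, float, int]]:
    """Naive O(n^3) complete-linkage agglomeration with index tie-breaking.

    Suitable for the tens of isolates typical of an ALE resequencing panel.
    """
    n = len(vectors)
    dist = [
        [
            math.sqrt(sum((a - b) ** 2 for a, b in zip(vectors[i], vectors[j])))
            for j in range(n)
        ]
        for i in range(n)
    ]
    # active clusters: id -> (member leaf indices, min original index)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(members) > 1:
        best: tuple[float, int, int, int, int] | None = None
        ids = sorted(members)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                h = max(dist[x][y] for x in members[a] for y in members[b])
                lowest = min(min(members[a]), min(members[b]))
                key = (h, lowest, min(members[a] + members[b], default=0), a, b)
                if best is None or key < best:
                    best = key
        h, _, _, a, b = best
        merges.append((a, b, h, len(members[a]) + len(members[b])))
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    return merges


def cluster_genotypes(matrix: GenotypeMatrix) -> Dendrogram:
    """Cluster isolates of a genotype matrix (Euclidean, complete linkage)."""
    if matrix.n_isolates < 2:
        raise CatalogError("clustering requires at least two isolates")
    labels = [f"{iso.culture}-{iso.timepoint}" for iso in matrix.isolates]
    merges = complete_linkage([[float(v) for v in row] for row in matrix.calls])
    return Dendrogram(merges=merges, leaf_labels=labels)
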