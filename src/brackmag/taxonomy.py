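"""Bin-level taxonomy from contig-level probabilistic classifications.

Each contig of a bin may carry one or more ranked-lineage classifications
with a mass probability.  To turn these into a single bin-level call, each
classification's probability is weighted by the contig's length in bases;
a lineage node's support is the weighted mass of all classifications passing
through it divided by the total classified mass.  The reported lineage is the
last common ancestor of all nodes reaching the support threshold (default
30 %): starting from the root, the walk descends while exactly one child
qualifies and stops when zero or several children do.

Support is inclusive at the threshold (a node at exactly the threshold
qualifies).  Unclassified contigs are excluded from the denominator by
default; ``include_unclassified=True`` divides by the total length of all
contigs instead, making supports absolute rather than relative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = ["WeightedAssignment", "weighted_lca"]


@dataclass(frozen=True)
class WeightedAssignment:
    """Bin-level lineage with per-node weighted support fractions."""

    bin_id: str
    lineage: str  # semicolon-joined ranked path, possibly truncated
    support_per_node: dict[str, float]

    @property
    def depth(self) -> int:
        return 0 if not self.lineage else len(self.lineage.split(";"))


def _as_path(lineage: str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(lineage, str):
        return tuple(p.strip() for p in lineage.split(";") if p.strip())
    return tuple(lineage)


def weighted_lca(
    classifications: Iterable[tuple[str, str | Sequence[str], float]],
    contig_lengths: Mapping[str, int],
    min_support: float = 0.30,
    bin_id: str = "bin",
    include_unclassified: bool = False,
) -> WeightedAssignment:
    """Aggregate (contig_id, lineage, probability) rows into a bin-level call.

    Multiple classifications per contig are allowed and contribute
    independently; probabilities need not sum to one.
    """
    rows = list(classifications)
    if not rows:
        raise ValueError("no classifications supplied")
    node_weight: dict[tuple[str, ...], float] = {}
    children: dict[tuple[str, ...], set[tuple[str, ...]]] = {(): set()}
    classified_mass = 0.0
    for contig_id, lineage, prob in rows:
        if contig_id not in contig_lengths:
            raise KeyError(f"no length for classified contig {contig_id!r}")
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"probability out of [0,1] for contig {contig_id!r}")
        path = _as_path(lineage)
        w = prob * contig_lengths[contig_id]
        classified_mass += w
        for depth in range(1, len(path) + 1):
            node = path[:depth]
            node_weight[node] = node_weight.get(node, 0.0) + w
            children.setdefault(node, set())
            children.setdefault(node[:-1], set()).add(node)
    if include_unclassified:
        total = float(sum(contig_lengths.values()))
    else:
        total = classified_mass
    if total <= 0:
        raise ValueError("zero total classification weight")
    support = {node: w / total for node, w in node_weight.items()}
    # walk down: descend while exactly one child reaches the threshold
    node: tuple[str, ...] = ()
    while True:
        qualifying = [c for c in sorted(children.get(node, ())) if support[c] >= min_support - 1e-12]
        if len(qualifying) != 1:
            break
        node = qualifying[0]
    return WeightedAssignment(
        bin_id=bin_id,
        lineage=";".join(node),
        support_per_node={";".join(n): s for n, s in sorted(support.items())},
    )
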