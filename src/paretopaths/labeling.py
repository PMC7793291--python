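"""Multi-criteria label-correcting search for the complete efficient path set.

This is a Martins-style label-correcting algorithm over the three additive,
monotone objective attributes.  Each node carries a set of labels; a label is
a 5-tuple of the three accumulated objective values plus two backtracking
references (predecessor node, predecessor label id).  Nodes whose label set
changed are queued for reconsideration (FIFO), and labels dominated by a
newly found one are dropped as soon as they appear.  On termination every
surviving label at a destination encodes one efficient path from the origin,
supported or unsupported; paths are reconstructed by walking the predecessor
references.

Because the objective attributes are all >= 0 and additive, subpath
optimality holds (every prefix of an efficient path is efficient to its
intermediate node), which is what makes the dynamic program exact.

Zero-cost cycles — wetland-internal arcs cost (0, 0, 0) — would relabel
forever if labels with equal objective vectors accumulated, so by default an
incoming label whose vector equals an existing one at the node is discarded
(first found wins).  ``keep_equal_vectors=True`` retains equal-vector
alternatives as distinct labels (distinct arc sequences for one frontier
point); in that mode a cycle check on the predecessor chain guarantees
termination instead.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .model import LandscapeNetwork, ObjectiveVector, ParetoSet, Path
from .pareto import dominates

__all__ = ["Label", "label_all", "merge_labels"]


@dataclass(frozen=True)
class Label:
    """Non-dominated cost tuple of one origin-to-node path.

    ``g`` holds the three accumulated objective values; ``pred_node`` and
    ``pred_label`` reference the predecessor node and the label there that
    this one extends (both ``None`` for the origin's initial label);
    ``own_id`` is unique within the node.
    """

    g: Tuple[float, float, float]
    pred_node: Optional[str]
    pred_label: Optional[int]
    own_id: int


def merge_labels(
    existing: List[Label],
    candidate_g: Tuple[float, float, float],
    keep_equal_vectors: bool = False,
) -> Tuple[List[Label], bool]:
    """Dominance-filter a candidate vector into a node's label set.

    Returns ``(surviving labels, accept)`` where ``accept`` says the
    candidate should be inserted.  Dominated existing labels are dropped.
    The caller attaches backtracking references and ids on insertion.
    """
    for lab in existing:
        if lab.g == candidate_g and not keep_equal_vectors:
            return existing, False
        if dominates(lab.g, candidate_g):
            return existing, False
    survivors = [lab for lab in existing if not dominates(candidate_g, lab.g)]
    return survivors, True


def _walk_predecessors(
    archive: Dict[str, Dict[int, Label]], node: str, label_id: int
):
    """Yield (node, label) pairs from a label back to the origin.

    Walks the archive of every label ever created: a predecessor label may
    have been pruned from its node's live set after being extended, but the
    chain recorded at extension time is still the path that produced the
    label being walked.
    """
    while node is not None:
        lab = archive[node][label_id]
        yield node, lab
        node, label_id = lab.pred_node, lab.pred_label


def label_all(
    network: LandscapeNetwork,
    origin: str,
    destinations: Optional[Iterable[str]] = None,
    keep_equal_vectors: bool = False,
) -> Dict[str, ParetoSet]:
    """All efficient paths (supported and unsupported) from one origin.

    Runs the label-correcting search to fixpoint, then reconstructs the
    non-dominated path set for each requested destination (default: every
    other node) by backtracking.  Unreachable destinations yield empty sets.
    """
    if origin not in network.nodes:
        raise KeyError(f"unknown origin {origin!r}")

    labels: Dict[str, Dict[int, Label]] = {n: {} for n in network.nodes}
    archive: Dict[str, Dict[int, Label]] = {n: {} for n in network.nodes}
    next_id: Dict[str, int] = {n: 0 for n in network.nodes}
    init = Label((0.0, 0.0, 0.0), None, None, 0)
    labels[origin][0] = init
    archive[origin][0] = init
    next_id[origin] = 1

    queue = deque([origin])
    queued = {origin}

    while queue:
        i = queue.popleft()
        queued.discard(i)
        for arc in network.out_arcs(i):
            j = arc.to_id
            obj = arc.objectives
            step = (obj.f1, obj.f2, obj.f3)
            changed = False
            for lab in list(labels[i].values()):
                cand_g = (lab.g[0] + step[0], lab.g[1] + step[1], lab.g[2] + step[2])
                if keep_equal_vectors:
                    # reject duplicate extensions and cyclic walks
                    if any(
                        e.pred_node == i and e.pred_label == lab.own_id and e.g == cand_g
                        for e in labels[j].values()
                    ):
                        continue
                    if any(n == j for n, _ in _walk_predecessors(archive, i, lab.own_id)):
                        continue
                current = list(labels[j].values())
                survivors, accept = merge_labels(current, cand_g, keep_equal_vectors)
                if not accept:
                    continue
                if len(survivors) != len(current):
                    changed = True
                labels[j] = {s.own_id: s for s in survivors}
                new = Label(cand_g, i, lab.own_id, next_id[j])
                next_id[j] += 1
                labels[j][new.own_id] = new
                archive[j][new.own_id] = new
                changed = True
            if changed and j not in queued:
                queue.append(j)
                queued.add(j)

    if destinations is None:
        destinations = [n for n in network.nodes if n != origin]

    out: Dict[str, ParetoSet] = {}
    for d in destinations:
        paths: List[Path] = []
        for lab in sorted(labels[d].values(), key=lambda l: (l.g, l.own_id)):
            chain = list(_walk_predecessors(archive, d, lab.own_id))
            chain.reverse()  # origin ... destination
            arcs = [
                (chain[k][0], chain[k + 1][0]) for k in range(len(chain) - 1)
            ]
            paths.append(
                Path(
                    origin=origin,
                    destination=d,
                    arcs=arcs,
                    objectives=ObjectiveVector(*lab.g),
                )
            )
        out[d] = ParetoSet(origin=origin, destination=d, paths=paths)
    return out
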