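"""Dollo parsimony mapping of protein-family origins onto a rooted tree.

Each family is gained exactly once — at the most recent common ancestor of
the taxa possessing it — and explained absences are attributed to the
smallest number of losses: the roots of the maximal subtrees under the
gain node that contain no present leaf.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

from .csp import CSPCall
from .hits import AnnotatedHitTable
from .tree import PhyloTree, TreeError, TreeNode


class DolloError(ValueError):
    pass


@dataclass
class PresenceMatrix:
    families: list[str]
    taxa: list[str]                  # column order
    data: dict[str, frozenset[str]]  # family -> present taxon set

    def row(self, family: str) -> frozenset[str]:
        return self.data[family]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("family\t" + "\t".join(self.taxa) + "\n")
            for fam in self.families:
                present = self.data[fam]
                fh.write(fam + "\t" +
                         "\t".join("1" if t in present else "0" for t in self.taxa)
                         + "\n")

    @classmethod
    def from_tsv(cls, path: str) -> "PresenceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            taxa = header[1:]
            families, data = [], {}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                fam = parts[0]
                families.append(fam)
                data[fam] = frozenset(
                    t for t, v in zip(taxa, parts[1:]) if v == "1")
        return cls(families, taxa, data)


@dataclass(frozen=True)
class GainLossAnnotation:
    family: str
    gain_node: TreeNode
    loss_branches: tuple[TreeNode, ...]

    @property
    def n_losses(self) -> int:
        return len(self.loss_branches)


def build_presence_matrix(source, taxa: set[str],
                          e_presence: float = 1e-6,
                          query_taxa: dict[str, str] | None = None,
                          queries: list[str] | None = None) -> PresenceMatrix:
    """Presence/absence matrix over ``taxa`` from CSP calls or annotated hits.

    ``source`` is either a list of :class:`~cladesig.csp.CSPCall` (presence
    sets are taken from the decisions) or an
    :class:`~cladesig.hits.AnnotatedHitTable` (a taxon is present when it
    has a hit at E <= ``e_presence``; the query's own taxon, supplied via
    ``query_taxa``, is always present).  ``queries`` restricts the hit-table
    route to designated query ids (e.g. one representative per family).
    All-zero rows are dropped with a warning on stderr.
    """
    cols = sorted(taxa)
    families: list[str] = []
    data: dict[str, frozenset[str]] = {}
    if isinstance(source, AnnotatedHitTable):
        for qid in (sorted(queries) if queries is not None else source.queries()):
            present = {ah.taxon_id for ah in source.hits_for(qid)
                       if ah.evalue <= e_presence and ah.taxon_id in taxa}
            qt = (query_taxa or {}).get(qid)
            if qt in taxa:
                present.add(qt)
            if present:
                families.append(qid)
                data[qid] = frozenset(present)
            else:
                print(f"warning: dropping all-absent row {qid}", file=sys.stderr)
    else:
        for call in source:
            if not isinstance(call, CSPCall):
                raise DolloError(f"unsupported presence source entry {call!r}")
            present = set(call.decision.presence_taxa) & taxa
            bad = set(call.decision.presence_taxa) - taxa
            if bad:
                raise DolloError(
                    f"presence taxa of {call.query_id} not in tree leaf set: {sorted(bad)}")
            if present:
                families.append(call.query_id)
                data[call.query_id] = frozenset(present)
            else:
                print(f"warning: dropping all-absent row {call.query_id}",
                      file=sys.stderr)
    return PresenceMatrix(families, cols, data)


def infer_gain_loss(family: str, present: frozenset[str] | set[str],
                    tree: PhyloTree) -> GainLossAnnotation:
    """Single-gain / minimal-loss placement of one presence row."""
    if not tree.rooted:
        raise TreeError("Dollo inference requires a rooted tree")
    if not present:
        raise DolloError(f"family {family}: all-absent row")
    present = frozenset(present)
    unknown = present - tree.leaf_names()
    if unknown:
        raise DolloError(f"family {family}: taxa not in tree: {sorted(unknown)}")
    gain = tree.mrca(present)

    losses: list[TreeNode] = []

    def walk(node: TreeNode) -> bool:
        """Return True if the subtree contains a present leaf; collect
        maximal absent subtrees as losses."""
        if node.is_leaf:
            return node.name in present
        child_has = [walk(c) for c in node.children]
        if not any(child_has):
            return False
        for c, has in zip(node.children, child_has):
            if not has:
                losses.append(c)
        return True

    walk(gain)
    return GainLossAnnotation(family, gain, tuple(losses))


def annotate_matrix(matrix: PresenceMatrix,
                    tree: PhyloTree) -> list[GainLossAnnotation]:
    return [infer_gain_loss(fam, matrix.row(fam), tree)
            for fam in matrix.families]


def summarize_gains(annotations: list[GainLossAnnotation],
                    tree: PhyloTree) -> dict[TreeNode, int]:
    """Per-node gain counts; nodes without gains map to 0."""
    counts: dict[TreeNode, int] = {n: 0 for n in tree.nodes()}
    for ann in annotations:
        if ann.gain_node not in counts:
            raise DolloError(
                f"gain node of {ann.family} is not a node of the given tree")
        counts[ann.gain_node] += 1
    return counts


def _node_label(node: TreeNode, tree: PhyloTree) -> str:
    if node.name:
        return node.name
    return "MRCA(" + ",".join(sorted(node.leaf_names())[:3]) + \
        (",..." if len(node.leaf_names()) > 3 else "") + ")"


def write_annotations_tsv(annotations: list[GainLossAnnotation],
                          tree: PhyloTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#family\tgain_node\tn_losses\tloss_branches\n")
        for ann in annotations:
            losses = ",".join(sorted(_node_label(n, tree) for n in ann.loss_branches))
            fh.write(f"{ann.family}\t{_node_label(ann.gain_node, tree)}\t"
                     f"{ann.n_losses}\t{losses or '.'}\n")


def write_gain_summary_tsv(counts: dict[TreeNode, int], tree: PhyloTree,
                           path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#node\tn_gains\n")
        for node, n in sorted(counts.items(),
                              key=lambda kv: _node_label(kv[0], tree)):
            if n:
                fh.write(f"{_node_label(node, tree)}\t{n}\n")
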