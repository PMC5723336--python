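"""Readers/writers for the formats the pipeline touches.

All downstream modules operate on the in-memory types defined here:
:class:`SeqRecord` for sequences, :class:`NumberedTree` for reference
phylogenies with stable integer edge ids, and :class:`PlacementDocument`
for jplace (v3) placement results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import skbio
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SeqRecord",
    "NumberedTree",
    "PlacementDocument",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "filter_by_mean_quality",
    "read_newick_numbered",
    "parse_newick_numbered",
    "write_newick",
    "write_placements",
    "read_placements",
]


@dataclass
class SeqRecord:
    """A named sequence, optionally with per-residue Phred qualities."""

    id: str
    seq: str
    qual: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path) -> list[SeqRecord]:
    """Read FASTA records, stripping whitespace inside sequences.

    Order is preserved, case is preserved, duplicate ids raise.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"empty sequence for record {header!r}")
        if header in seen:
            raise ValueError(f"duplicate id {header}")
        seen.add(header)
        records.append(SeqRecord(header, seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise ValueError("FASTA header with empty id")
                chunks = []
            elif line.strip():
                if header is None:
                    raise ValueError("sequence data before first '>' header")
                chunks.append("".join(line.split()))
        flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> list[SeqRecord]:
    """Read FASTQ (Phred+33). Duplicate ids raise."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            rid = title.split()[0]
            if rid in seen:
                raise ValueError(f"duplicate id {rid}")
            seen.add(rid)
            records.append(SeqRecord(rid, seq, [ord(c) - 33 for c in qual]))
    return records


def filter_by_mean_quality(
    records: Iterable[SeqRecord], min_mean_q: float
) -> list[SeqRecord]:
    """Optional coarse quality gate: keep records whose mean Phred quality
    reaches ``min_mean_q`` (records without qualities always pass).
    Fine-grained quality trimming is expected upstream."""
    out = []
    for rec in records:
        if rec.qual is None or sum(rec.qual) / len(rec.qual) >= min_mean_q:
            out.append(rec)
    return out


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else [40] * len(rec.seq)
            qstr = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qstr}\n")


class NumberedTree:
    """A rooted tree whose non-root nodes carry stable integer edge ids.

    Nodes are stored in postorder (children visited in input order, root
    last); the edge above node ``i`` has edge id ``i``, so edge ids run
    0..E-1 and are a pure function of the Newick string.
    """

    def __init__(
        self,
        parent: np.ndarray,
        lengths: np.ndarray,
        names: list[Optional[str]],
        children: list[list[int]],
    ):
        self.parent = parent
        self.lengths = lengths
        self.names = names
        self.children = children
        self.n_nodes = len(names)
        self.root = self.n_nodes - 1
        self.n_edges = self.n_nodes - 1
        self._leaf_index = {
            names[i]: i for i in range(self.n_nodes) if not children[i]
        }
        if len(self._leaf_index) != sum(1 for c in children if not c):
            raise ValueError("leaf names are not unique")
        if np.any(lengths[: self.n_edges] < 0):
            raise ValueError("negative branch length")

    # -- queries ---------------------------------------------------------
    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in range(self.n_nodes) if not self.children[i]]

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def leaf_id(self, name: str) -> int:
        return self._leaf_index[name]

    def pendant_edge(self, leaf_name: str) -> int:
        """Edge id of the terminal branch leading to a named leaf."""
        return self._leaf_index[leaf_name]

    def postorder(self) -> range:
        return range(self.n_nodes)

    def subtree_leaves(self, node: int) -> set[str]:
        out: set[str] = set()
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.add(self.names[v])
            else:
                stack.extend(self.children[v])
        return out

    def subtree_edges(self, node: int) -> set[int]:
        """Edge ids strictly inside the subtree rooted at ``node``
        (excluding the stem edge above ``node``)."""
        out: set[int] = set()
        stack = list(self.children[node])
        while stack:
            v = stack.pop()
            out.add(v)
            stack.extend(self.children[v])
        return out

    def mrca(self, leaf_names: Sequence[str]) -> int:
        ids = [self._leaf_index[n] for n in leaf_names]
        if not ids:
            raise ValueError("mrca of empty set")
        paths = []
        for i in ids:
            path = set()
            v = i
            while v != -1:
                path.add(v)
                v = int(self.parent[v])
            paths.append(path)
        common = set.intersection(*paths)
        # ancestors have larger postorder ids than descendants, so the
        # deepest common ancestor is the smallest id in the intersection
        return min(common)

    def adjacent_edges(self, edge: int) -> set[int]:
        """Edges sharing an endpoint with ``edge`` (including itself)."""
        out = {edge}
        v = edge  # edge id == child node id of that edge
        out.update(self.children[v])
        p = int(self.parent[v])
        if p != -1:
            out.update(self.children[p])
            if p != self.root:
                out.add(p)
        return out

    # -- serialization ---------------------------------------------------
    def newick(self, edge_annotations: bool = False) -> str:
        def fmt_len(x: float) -> str:
            return repr(float(x))  # shortest lossless decimal

        def render(v: int) -> str:
            if self.is_leaf(v):
                s = self.names[v]
            else:
                s = "(" + ",".join(render(c) for c in self.children[v]) + ")"
                if self.names[v]:
                    s += self.names[v]
            if v != self.root:
                s += ":" + fmt_len(self.lengths[v])
                if edge_annotations:
                    s += "{%d}" % v
            return s

        return render(self.root) + ";"


def parse_newick_numbered(
    newick: str, default_length: Optional[float] = None
) -> NumberedTree:
    """Parse a Newick string and assign deterministic postorder edge ids."""
    sk = skbio.TreeNode.read([newick], convert_underscores=False)
    nodes = list(sk.postorder(include_self=True))
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    lengths = np.zeros(n, dtype=np.float64)
    names: list[Optional[str]] = [None] * n
    children: list[list[int]] = [[] for _ in range(n)]
    for i, nd in enumerate(nodes):
        names[i] = nd.name
        if nd.parent is not None:
            parent[i] = index[id(nd.parent)]
            if nd.length is None:
                if default_length is None:
                    raise ValueError(
                        f"missing branch length above node {nd.name or '(internal)'}"
                    )
                lengths[i] = default_length
            else:
                lengths[i] = nd.length
        children[i] = [index[id(c)] for c in nd.children]
    for i in range(n - 1):
        if names[i] is None and not children[i]:
            raise ValueError("unnamed leaf in tree")
    return NumberedTree(parent, lengths, names, children)


def read_newick_numbered(path, default_length: Optional[float] = None) -> NumberedTree:
    with open(path) as fh:
        text = fh.read().strip()
    return parse_newick_numbered(text, default_length=default_length)


def write_newick(tree: NumberedTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


PLACEMENT_FIELDS = ["edge_num", "likelihood", "like_weight_ratio", "pendant_length"]


@dataclass
class PlacementDocument:
    """In-memory jplace (version 3) document."""

    tree: NumberedTree
    # query id -> list of (edge_id, log_likelihood, lwr, pendant_length)
    placements: dict[str, list[tuple[int, float, float, float]]] = field(
        default_factory=dict
    )
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for qid, rows in self.placements.items():
            if not rows:
                continue
            lwr_sum = 0.0
            for edge, _ll, lwr, _pl in rows:
                if not 0 <= edge < self.tree.n_edges:
                    raise ValueError(
                        f"query {qid!r} references edge {edge} absent from tree"
                    )
                lwr_sum += lwr
            if abs(lwr_sum - 1.0) > 1e-6:
                raise ValueError(
                    f"query {qid!r}: likelihood weight ratios sum to {lwr_sum}"
                )


def write_placements(doc: PlacementDocument, path) -> None:
    """Serialize to jplace v3 JSON with ``{edge_id}`` tree annotations."""
    doc.validate()
    payload = {
        "version": 3,
        "tree": doc.tree.newick(edge_annotations=True),
        "fields": PLACEMENT_FIELDS,
        "placements": [
            {
                "p": [
                    [int(e), float(ll), float(lwr), float(pl)]
                    for e, ll, lwr, pl in rows
                ],
                "n": [qid],
            }
            for qid, rows in doc.placements.items()
        ],
        "metadata": doc.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def _strip_edge_annotations(tree_str: str) -> tuple[str, bool]:
    import re

    stripped = re.sub(r"\{\d+\}", "", tree_str)
    return stripped, stripped != tree_str


def read_placements(path) -> PlacementDocument:
    with open(path) as fh:
        payload = json.load(fh)
    tree_str, _had = _strip_edge_annotations(payload["tree"])
    tree = parse_newick_numbered(tree_str)
    fields = payload["fields"]
    order = [fields.index(f) for f in PLACEMENT_FIELDS]
    placements: dict[str, list[tuple[int, float, float, float]]] = {}
    for entry in payload["placements"]:
        names = entry.get("n") or [nm for nm, _ in entry.get("nm", [])]
        rows = [
            (int(p[order[0]]), float(p[order[1]]), float(p[order[2]]), float(p[order[3]]))
            for p in entry["p"]
        ]
        for nm in names:
            placements[nm] = rows
    doc = PlacementDocument(tree=tree, placements=placements,
                            metadata=payload.get("metadata", {}))
    doc.validate()
    return doc
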