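"""Per-gene reference packages: aligned references, numbered tree, clade
labels, outgroup definition, and substitution-model settings.

A reference package on disk is a directory holding ``refs.fasta`` (aligned,
amino-acid), ``tree.nwk``, ``clades.tsv`` (leaf<TAB>label), ``outgroup.txt``
(one leaf per line) and ``model.yaml``.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .formats import (
    NumberedTree,
    SeqRecord,
    read_fasta,
    read_newick_numbered,
    write_fasta,
    write_newick,
)

GAP_CHARS = set("-.")

OUTGROUP_LABEL = "outgroup"
UNASSIGNED_LABEL = "unassigned_ingroup"


@dataclass
class ModelSpec:
    """Substitution-model settings for a reference package.

    The gamma shape alpha and category count k control among-site rate
    heterogeneity; frequencies are either the matrix-supplied values
    ("model") or empirical counts from the reference alignment
    ("empirical").
    """

    matrix: str = "LG"
    frequencies: str = "model"
    alpha: float = 1.0
    k: int = 4

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be > 0")
        if self.k < 1:
            raise ValueError("category count k must be >= 1")
        if self.frequencies not in ("model", "empirical"):
            raise ValueError("frequencies must be 'model' or 'empirical'")


def dedup_identical(
    seqs: list[SeqRecord],
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Collapse records with exactly identical sequences.

    The first occurrence (input order) is the representative; the returned
    map sends every id, including representatives, to its representative.
    """
    unique: list[SeqRecord] = []
    by_seq: dict[str, str] = {}
    dedup_map: dict[str, str] = {}
    for rec in seqs:
        rep = by_seq.get(rec.seq)
        if rep is None:
            by_seq[rec.seq] = rec.id
            unique.append(rec)
            dedup_map[rec.id] = rec.id
        else:
            dedup_map[rec.id] = rep
    return unique, dedup_map


def ungapped_length(seq: str) -> int:
    return sum(1 for c in seq if c not in GAP_CHARS)


@dataclass
class ReferencePackage:
    gene_name: str
    alignment: list[SeqRecord]  # deduplicated, aligned (equal column count)
    tree: NumberedTree
    clade_map: dict[str, set[str]]
    outgroup: set[str]
    model_spec: ModelSpec
    dedup_map: dict[str, str] = field(default_factory=dict)
    ref_length_aa: float = 0.0

    @property
    def n_columns(self) -> int:
        return len(self.alignment[0].seq)

    @property
    def ingroup_ids(self) -> list[str]:
        return [r.id for r in self.alignment if r.id not in self.outgroup]

    def row(self, ref_id: str) -> str:
        for r in self.alignment:
            if r.id == ref_id:
                return r.seq
        raise KeyError(ref_id)

    def ungapped_references(self) -> list[SeqRecord]:
        """References with gap columns removed, for translated search."""
        return [
            SeqRecord(r.id, "".join(c for c in r.seq if c not in GAP_CHARS))
            for r in self.alignment
        ]


def build_refpkg(
    gene_name: str,
    alignment: list[SeqRecord],
    tree: NumberedTree,
    clade_map: dict[str, set[str]],
    outgroup: set[str],
    model_spec: ModelSpec | None = None,
) -> ReferencePackage:
    """Assemble and cross-validate a reference package.

    De-duplicates identical amino-acid rows, checks that the tree leaf set
    equals the deduplicated row ids, that clades and the outgroup are
    disjoint and monophyletic, and computes ``ref_length_aa`` as the median
    ungapped amino-acid length over ingroup rows.
    """
    if model_spec is None:
        model_spec = ModelSpec()
    ncol = {len(r.seq) for r in alignment}
    if len(ncol) != 1:
        raise ValueError(f"alignment rows have unequal lengths: {sorted(ncol)}")

    unique, dedup_map = dedup_identical(alignment)
    leaf_set = set(tree.leaf_names)
    row_set = {r.id for r in unique}
    missing_in_tree = sorted(row_set - leaf_set)
    missing_in_aln = sorted(leaf_set - row_set)
    if missing_in_tree or missing_in_aln:
        raise ValueError(
            "unmatched reference(s): "
            + ", ".join(missing_in_tree + missing_in_aln)
        )

    # remap clade/outgroup members through the dedup map
    outgroup = {dedup_map.get(x, x) for x in outgroup}
    clade_map = {
        label: {dedup_map.get(x, x) for x in leaves}
        for label, leaves in clade_map.items()
    }

    seen: dict[str, str] = {}
    for label, leaves in clade_map.items():
        if not leaves:
            raise ValueError(f"clade {label!r} is empty")
        for leaf in leaves:
            if leaf not in leaf_set:
                raise ValueError(f"clade {label!r} names unknown leaf {leaf!r}")
            if leaf in seen:
                raise ValueError(
                    f"clades must be disjoint: {leaf!r} in both "
                    f"{seen[leaf]!r} and {label!r}"
                )
            if leaf in outgroup:
                raise ValueError(
                    f"clade {label!r} overlaps the outgroup at leaf {leaf!r}"
                )
            seen[leaf] = label

    for label, leaves in list(clade_map.items()) + [(OUTGROUP_LABEL, outgroup)]:
        if not leaves:
            continue
        node = tree.mrca(sorted(leaves))
        spanned = tree.subtree_leaves(node)
        intruders = sorted(spanned - leaves)
        if intruders:
            raise ValueError(
                f"clade {label!r} not monophyletic; intruding leaves: "
                + ", ".join(intruders)
            )

    ingroup_rows = [r for r in unique if r.id not in outgroup]
    if len(ingroup_rows) < 2:
        raise ValueError("alignment must contain at least 2 ingroup rows")
    ref_length = statistics.median(ungapped_length(r.seq) for r in ingroup_rows)
    if ref_length <= 0:
        raise ValueError("ingroup references have no residues")

    return ReferencePackage(
        gene_name=gene_name,
        alignment=unique,
        tree=tree,
        clade_map={k: set(v) for k, v in clade_map.items()},
        outgroup=set(outgroup),
        model_spec=model_spec,
        dedup_map=dedup_map,
        ref_length_aa=float(ref_length),
    )


@dataclass
class CladeEdgeIndex:
    """Maps every tree edge to exactly one label: a named clade, the
    outgroup, or ``unassigned_ingroup``."""

    edge_label: dict[int, str]

    def label_of(self, edge: int) -> str:
        try:
            return self.edge_label[edge]
        except KeyError:
            raise KeyError(f"edge {edge} not in index") from None

    def edges_for(self, label: str) -> set[int]:
        return {e for e, lab in self.edge_label.items() if lab == label}

    @property
    def labels(self) -> set[str]:
        return set(self.edge_label.values())


def clade_edges(refpkg: ReferencePackage, include_stem: bool = True) -> CladeEdgeIndex:
    """Assign edge ids to clades: edges inside each clade's MRCA subtree
    plus (by default) the MRCA stem edge; likewise for the outgroup; all
    remaining edges are ``unassigned_ingroup``."""
    tree = refpkg.tree
    edge_label: dict[int, str] = {}
    groups = list(refpkg.clade_map.items())
    if refpkg.outgroup:
        groups.append((OUTGROUP_LABEL, refpkg.outgroup))
    for label, leaves in groups:
        node = tree.mrca(sorted(leaves))
        edges = tree.subtree_edges(node)
        if include_stem and node != tree.root:
            edges.add(node)  # stem edge id == node id
        for e in edges:
            prev = edge_label.get(e)
            if prev is not None and prev != label:
                raise ValueError(
                    f"clades must be disjoint: edge {e} claimed by "
                    f"{prev!r} and {label!r}"
                )
            edge_label[e] = label
    for e in range(tree.n_edges):
        edge_label.setdefault(e, UNASSIGNED_LABEL)
    return CladeEdgeIndex(edge_label)


# -- on-disk layout -------------------------------------------------------

def save_refpkg(refpkg: ReferencePackage, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(refpkg.alignment, outdir / "refs.fasta")
    write_newick(refpkg.tree, outdir / "tree.nwk")
    with open(outdir / "clades.tsv", "w") as fh:
        for label in sorted(refpkg.clade_map):
            for leaf in sorted(refpkg.clade_map[label]):
                fh.write(f"{leaf}\t{label}\n")
    with open(outdir / "outgroup.txt", "w") as fh:
        for leaf in sorted(refpkg.outgroup):
            fh.write(leaf + "\n")
    spec = refpkg.model_spec
    with open(outdir / "model.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "gene": refpkg.gene_name,
                "matrix": spec.matrix,
                "frequencies": spec.frequencies,
                "alpha": spec.alpha,
                "k": spec.k,
            },
            fh,
        )
    return outdir


def load_refpkg(path) -> ReferencePackage:
    path = Path(path)
    alignment = read_fasta(path / "refs.fasta")
    tree = read_newick_numbered(path / "tree.nwk")
    clade_map: dict[str, set[str]] = {}
    clades_file = path / "clades.tsv"
    if clades_file.exists():
        with open(clades_file) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                leaf, label = line.split("\t")
                clade_map.setdefault(label, set()).add(leaf)
    outgroup: set[str] = set()
    og_file = path / "outgroup.txt"
    if og_file.exists():
        outgroup = {line.strip() for line in open(og_file) if line.strip()}
    with open(path / "model.yaml") as fh:
        meta = yaml.safe_load(fh)
    spec = ModelSpec(
        matrix=meta.get("matrix", "LG"),
        frequencies=meta.get("frequencies", "model"),
        alpha=float(meta.get("alpha", 1.0)),
        k=int(meta.get("k", 4)),
    )
    return build_refpkg(
        meta.get("gene", path.name), alignment, tree, clade_map, outgroup, spec
    )
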