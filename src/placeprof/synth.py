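"""Synthetic reference packages, communities, and read sets with ground truth.

The generator embodies the statistical structure the quantification assumes:
every genome carries the single-copy gene rpoB, marker genes sit in a
configurable subset of genomes at configurable copy number, gene phylotypes
derive from distinct reference-tree clades, and an optional contaminant
fraction of a gene's reads originates from its outgroup. Read pairs carry
substitution errors at a stated rate; every pair is recorded in a truth
table.

Reference sequences are simulated along the reference tree under the same
substitution model used for placement; genome-resident gene copies are the
source leaf evolved a little further (so reads are near, not identical to,
a reference). Synthetic marker genes and rpoB share the same amino-acid
length so that fragment-position edge effects cancel exactly in the
percent-of-community ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .formats import SeqRecord, parse_newick_numbered, write_fastq
from .matrices import AA_ORDER
from .place import SubstitutionModel, build_model
from .quantify import SampleMeta
from .recruit import reverse_complement, translate
from .refpkg import (
    GAP_CHARS,
    ModelSpec,
    OUTGROUP_LABEL,
    ReferencePackage,
    UNASSIGNED_LABEL,
    build_refpkg,
    save_refpkg,
)

SCENARIOS = (
    "basic",
    "multicopy",
    "outgroup_stress",
    "particle_vs_free",
    "depth_profile",
)

RPOB = "rpoB"

_DNA = "ACGT"


# -- sequence simulation ----------------------------------------------------

def simulate_alignment_on_tree(
    tree, model: SubstitutionModel, root_length_aa: int, seed
) -> dict[str, str]:
    """Evolve an amino-acid alignment along a tree.

    The root is drawn from the stationary distribution; each site gets one
    gamma category for the whole tree; residues evolve independently along
    each branch. Identical seeds give identical leaves.
    """
    rng = np.random.default_rng(seed)
    S = root_length_aa
    cats = rng.integers(0, model.k, size=S)
    root_states = rng.choice(20, size=S, p=model.pi)
    states = {tree.root: root_states}
    out: dict[str, str] = {}
    # preorder: parents before children (reverse postorder)
    for v in reversed(range(tree.n_nodes)):
        if v == tree.root:
            pass
        else:
            parent_states = states[int(tree.parent[v])]
            t = float(tree.lengths[v])
            child = np.empty(S, dtype=np.int64)
            for c in range(model.k):
                mask = cats == c
                if not mask.any():
                    continue
                P = model.transition(t, float(model.rates[c]))
                # normalize rows defensively (clip can shave mass)
                P = P / P.sum(axis=1, keepdims=True)
                ps = parent_states[mask]
                u = rng.random(ps.shape[0])
                cum = np.cumsum(P[ps], axis=1)
                child[mask] = (u[:, None] > cum).sum(axis=1)
            states[v] = child
        if tree.is_leaf(v):
            out[tree.names[v]] = "".join(AA_ORDER[a] for a in states[v])
    return out


def evolve_sequence(
    aa: str, model: SubstitutionModel, t: float, rng: np.random.Generator
) -> str:
    """Evolve one amino-acid sequence for branch length ``t``."""
    S = len(aa)
    cats = rng.integers(0, model.k, size=S)
    from .matrices import AA_INDEX

    states = np.array([AA_INDEX[c] for c in aa])
    out = states.copy()
    for c in range(model.k):
        mask = cats == c
        if not mask.any():
            continue
        P = model.transition(t, float(model.rates[c]))
        P = P / P.sum(axis=1, keepdims=True)
        u = rng.random(int(mask.sum()))
        cum = np.cumsum(P[states[mask]], axis=1)
        out[mask] = (u[:, None] > cum).sum(axis=1)
    return "".join(AA_ORDER[a] for a in out)


def _codon_usage() -> dict[str, list[str]]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[11]
    usage: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        usage.setdefault(aa, []).append(codon)
    return usage


_USAGE = _codon_usage()


def reverse_translate(
    aa_seq: str,
    codon_usage: Optional[dict[str, list[str]]] = None,
    seed=None,
) -> str:
    """Back-translate, sampling uniformly among synonymous codons (or from
    a supplied usage table). translate(result) round-trips to the input."""
    rng = np.random.default_rng(seed)
    usage = codon_usage or _USAGE
    out = []
    for c in aa_seq.upper():
        codons = usage.get(c)
        if not codons:
            raise ValueError(f"no codon for residue {c!r}")
        out.append(codons[int(rng.integers(len(codons)))])
    return "".join(out)


# -- community specification -------------------------------------------------

@dataclass
class GeneContent:
    gene: str
    source_leaf: str
    copies: int = 1


@dataclass
class GenomeSpec:
    genome_id: str
    abundance: float
    genes: list[GeneContent]


@dataclass
class CommunitySpec:
    """A synthetic community: genomes x gene content x copy number x
    abundance. Every genome must carry rpoB at exactly one copy."""

    genomes: list[GenomeSpec]
    outgroup_contaminant: dict[str, float] = field(default_factory=dict)
    background_fraction: float = 0.0

    def validate(self) -> None:
        total = sum(g.abundance for g in self.genomes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")
        for g in self.genomes:
            rpob = [gc for gc in g.genes if gc.gene == RPOB]
            if len(rpob) != 1 or rpob[0].copies != 1:
                raise ValueError(
                    f"genome {g.genome_id!r} must carry {RPOB} at exactly 1 copy"
                )
            for gc in g.genes:
                if gc.copies < 1 or int(gc.copies) != gc.copies:
                    raise ValueError("copies must be integers >= 1")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background fraction must be in [0, 1)")


@dataclass
class ReadSimParams:
    read_length: int = 150
    insert_mean: float = 260.0
    insert_sd: float = 25.0
    error_rate: float = 0.002
    n_pairs: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 36:
            raise ValueError("read length must be >= 36")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error rate must be in [0, 0.05]")


def _ungapped(seq: str) -> str:
    return "".join(c for c in seq if c not in GAP_CHARS)


def realize_gene_sequences(
    spec: CommunitySpec,
    refpkgs: dict[str, ReferencePackage],
    divergence: float = 0.03,
    seed=0,
) -> dict[tuple[str, str], str]:
    """DNA coding sequence for every (genome, gene): the source leaf's
    amino-acid sequence evolved by ``divergence`` substitutions/site and
    reverse-translated. Outgroup-contaminant sources are keyed
    ('__outgroup__', gene leaf)."""
    rng = np.random.default_rng(seed)
    models = {g: build_model(rp.model_spec, rp.alignment) for g, rp in refpkgs.items()}
    out: dict[tuple[str, str], str] = {}
    for genome in spec.genomes:
        for gc in genome.genes:
            rp = refpkgs[gc.gene]
            aa = _ungapped(rp.row(gc.source_leaf))
            aa2 = evolve_sequence(aa, models[gc.gene], divergence, rng)
            out[(genome.genome_id, gc.gene)] = reverse_translate(
                aa2, seed=rng.integers(2**31 - 1)
            )
    for gene, frac in spec.outgroup_contaminant.items():
        if frac <= 0:
            continue
        rp = refpkgs[gene]
        for leaf in sorted(rp.outgroup):
            aa = _ungapped(rp.row(leaf))
            aa2 = evolve_sequence(aa, models[gene], divergence, rng)
            out[("__outgroup__" + leaf, gene)] = reverse_translate(
                aa2, seed=rng.integers(2**31 - 1)
            )
    return out


def _clade_of(refpkg: ReferencePackage, leaf: str) -> str:
    if leaf in refpkg.outgroup:
        return OUTGROUP_LABEL
    for label, leaves in refpkg.clade_map.items():
        if leaf in leaves:
            return label
    return UNASSIGNED_LABEL


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in _DNA if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def generate_metagenome_reads(
    spec: CommunitySpec,
    refpkgs: dict[str, ReferencePackage],
    params: ReadSimParams,
    sample_id: str = "S1",
    gene_sequences: Optional[dict[tuple[str, str], str]] = None,
    divergence: float = 0.03,
) -> tuple[list[SeqRecord], list[SeqRecord], pd.DataFrame]:
    """Simulate paired reads plus a per-pair truth table.

    Fragments are drawn from gene copies with probability proportional to
    abundance x copies x gene length (background and outgroup-contaminant
    mass added on top), starts uniform among positions where the insert
    fits, substitution errors applied at ``params.error_rate``.
    """
    spec.validate()
    for genome in spec.genomes:
        for gc in genome.genes:
            if gc.gene not in refpkgs:
                raise ValueError(f"no reference package for gene {gc.gene!r}")
            if gc.source_leaf not in set(refpkgs[gc.gene].tree.leaf_names):
                raise ValueError(
                    f"source leaf {gc.source_leaf!r} missing from "
                    f"{gc.gene} reference package"
                )
    rng = np.random.default_rng(params.seed)
    if gene_sequences is None:
        gene_sequences = realize_gene_sequences(
            spec, refpkgs, divergence=divergence, seed=params.seed
        )

    units = []  # (weight, genome, gene, source_leaf, clade, dna)
    gene_weight: dict[str, float] = {}
    for genome in spec.genomes:
        for gc in genome.genes:
            dna = gene_sequences[(genome.genome_id, gc.gene)]
            w = genome.abundance * gc.copies * len(dna)
            units.append(
                (
                    w,
                    genome.genome_id,
                    gc.gene,
                    gc.source_leaf,
                    _clade_of(refpkgs[gc.gene], gc.source_leaf),
                    dna,
                )
            )
            gene_weight[gc.gene] = gene_weight.get(gc.gene, 0.0) + w
    for gene, frac in spec.outgroup_contaminant.items():
        if frac <= 0:
            continue
        og_leaves = sorted(refpkgs[gene].outgroup)
        extra = gene_weight.get(gene, 0.0) * frac / (1.0 - frac)
        for leaf in og_leaves:
            dna = gene_sequences[("__outgroup__" + leaf, gene)]
            units.append(
                (extra / len(og_leaves), "contaminant", gene, leaf,
                 OUTGROUP_LABEL, dna)
            )
    total_w = sum(u[0] for u in units)
    if spec.background_fraction > 0:
        bg_w = total_w * spec.background_fraction / (1 - spec.background_fraction)
        units.append((bg_w, "background", "background", "", "", None))

    weights = np.array([u[0] for u in units])
    weights = weights / weights.sum()
    qual_char = max(2, min(40, int(round(-10 * np.log10(max(params.error_rate, 1e-4))))))

    r1_out: list[SeqRecord] = []
    r2_out: list[SeqRecord] = []
    truth_rows = []
    choices = rng.choice(len(units), size=params.n_pairs, p=weights)
    inserts = rng.normal(params.insert_mean, params.insert_sd, size=params.n_pairs)
    for i in range(params.n_pairs):
        u = units[choices[i]]
        _w, genome, gene, leaf, clade, dna = u
        insert = int(round(inserts[i]))
        insert = max(params.read_length, insert)
        if dna is None:
            frag = "".join(_DNA[b] for b in rng.integers(0, 4, size=insert))
        else:
            insert = min(insert, len(dna))
            start = int(rng.integers(0, len(dna) - insert + 1))
            frag = dna[start : start + insert]
        r1 = _add_errors(frag[: params.read_length], params.error_rate, rng)
        r2 = _add_errors(
            reverse_complement(frag)[: params.read_length], params.error_rate, rng
        )
        rid = f"{sample_id}.{i:06d}"
        qual = [qual_char] * len(r1)
        r1_out.append(SeqRecord(rid, r1, list(qual)))
        r2_out.append(SeqRecord(rid, r2, [qual_char] * len(r2)))
        truth_rows.append(
            {
                "read_id": rid,
                "genome": genome,
                "gene": gene,
                "source_leaf": leaf,
                "clade": clade,
                "is_outgroup": clade == OUTGROUP_LABEL,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return r1_out, r2_out, truth


# -- synthetic reference packages --------------------------------------------

def synth_refpkg(
    gene: str,
    seed,
    clade_names: tuple[str, str] = ("OTU_I", "OTU_II"),
    leaves_per_clade: int = 3,
    n_outgroup: int = 3,
    length_aa: int = 300,
    model_spec: Optional[ModelSpec] = None,
) -> ReferencePackage:
    """Build a small two-clade-plus-outgroup reference package with
    sequences simulated under the placement model."""
    rng = np.random.default_rng(seed)
    if model_spec is None:
        model_spec = ModelSpec()

    def clade(names, leaf_lo=0.08, leaf_hi=0.15, stem=0.25):
        parts = ",".join(
            f"{n}:{rng.uniform(leaf_lo, leaf_hi):.4f}" for n in names
        )
        return f"({parts}):{stem:.4f}"

    cladeA = [f"{gene}_{clade_names[0]}_{i}" for i in range(leaves_per_clade)]
    cladeB = [f"{gene}_{clade_names[1]}_{i}" for i in range(leaves_per_clade)]
    og = [f"{gene}_og_{i}" for i in range(n_outgroup)]
    newick = f"(({clade(cladeA)},{clade(cladeB)}):0.15,{clade(og, stem=0.5)});"
    tree = parse_newick_numbered(newick)
    model = build_model(model_spec)
    leaves = simulate_alignment_on_tree(
        tree, model, length_aa, seed=rng.integers(2**31 - 1)
    )
    alignment = [SeqRecord(n, leaves[n]) for n in tree.leaf_names]
    return build_refpkg(
        gene,
        alignment,
        tree,
        {clade_names[0]: set(cladeA), clade_names[1]: set(cladeB)},
        set(og),
        model_spec,
    )


@dataclass
class Scenario:
    name: str
    refpkgs: dict[str, ReferencePackage]
    samples: list[tuple[SampleMeta, CommunitySpec]]
    params: ReadSimParams
    copy_numbers: dict[tuple[str, str], float] = field(default_factory=dict)
    truth_percent: dict[str, float] = field(default_factory=dict)
    gene_sequences: dict[tuple[str, str], str] = field(default_factory=dict)


def _genomes(
    n: int,
    gene: str,
    carriers: dict[int, tuple[str, int]],  # genome idx -> (source leaf, copies)
    rpob_leaves: list[str],
    abundances: Optional[list[float]] = None,
) -> list[GenomeSpec]:
    if abundances is None:
        abundances = [1.0 / n] * n
    genomes = []
    for i in range(n):
        genes = [GeneContent(RPOB, rpob_leaves[i % len(rpob_leaves)], 1)]
        if i in carriers:
            leaf, copies = carriers[i]
            genes.append(GeneContent(gene, leaf, copies))
        genomes.append(GenomeSpec(f"g{i:02d}", abundances[i], genes))
    return genomes


def make_benchmark_scenario(
    name: str,
    seed: int = 42,
    n_pairs: Optional[int] = None,
    error_rate: Optional[float] = None,
    carrier_fraction: Optional[float] = None,
) -> Scenario:
    """Fully seeded benchmark fixtures tying the generator to the pipeline.

    ``carrier_fraction`` (basic scenario only) overrides the fraction of
    genomes carrying the marker gene; it must produce an integer carrier
    count out of 20 genomes.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(8) % (2**31 - 1)
    rpob = synth_refpkg(RPOB, seeds[0], clade_names=("cladeA", "cladeB"),
                        leaves_per_clade=5)
    rpob_leaves = sorted(rpob.ingroup_ids)
    params = ReadSimParams(seed=int(seeds[1]))
    if n_pairs is not None:
        params = replace(params, n_pairs=n_pairs)
    if error_rate is not None:
        params = replace(params, error_rate=error_rate)

    if name == "basic":
        gene = "nirK"
        rp = synth_refpkg(gene, seeds[2])
        n, frac = 20, carrier_fraction if carrier_fraction is not None else 0.2
        n_carriers = frac * n
        if abs(n_carriers - round(n_carriers)) > 1e-9:
            raise ValueError("carrier_fraction must give whole genomes out of 20")
        n_carriers = int(round(n_carriers))
        ingroup = sorted(rp.ingroup_ids)
        carriers = {i: (ingroup[i % len(ingroup)], 1) for i in range(n_carriers)}
        spec = CommunitySpec(
            _genomes(n, gene, carriers, rpob_leaves), background_fraction=0.15
        )
        meta = SampleMeta("S1", "st136", 100.0)
        return Scenario(
            name, {RPOB: rpob, gene: rp}, [(meta, spec)], params,
            truth_percent={gene: 100.0 * n_carriers / n},
        )

    if name == "multicopy":
        gene = "narG"
        rp = synth_refpkg(gene, seeds[2], clade_names=("SAR11", "OTU_I"))
        sar11 = sorted(rp.clade_map["SAR11"])
        n = 10
        carriers = {i: (sar11[i % len(sar11)], 2) for i in range(5)}
        spec = CommunitySpec(
            _genomes(n, gene, carriers, rpob_leaves), background_fraction=0.1
        )
        meta = SampleMeta("S1", "st136", 160.0)
        return Scenario(
            name, {RPOB: rpob, gene: rp}, [(meta, spec)], params,
            copy_numbers={(gene, "SAR11"): 2.0},
            truth_percent={gene: 50.0},  # corrected; uncorrected is 100%
        )

    if name == "outgroup_stress":
        gene = "narG"
        rp = synth_refpkg(gene, seeds[2], clade_names=("SAR11", "OTU_I"))
        ingroup = sorted(rp.ingroup_ids)
        n = 10
        carriers = {i: (ingroup[i % len(ingroup)], 1) for i in range(5)}
        spec = CommunitySpec(
            _genomes(n, gene, carriers, rpob_leaves),
            outgroup_contaminant={gene: 0.10},
            background_fraction=0.1,
        )
        meta = SampleMeta("S1", "st136", 160.0)
        return Scenario(
            name, {RPOB: rpob, gene: rp}, [(meta, spec)], params,
            truth_percent={gene: 50.0},
        )

    if name == "particle_vs_free":
        gene = "nosZ"
        rp = synth_refpkg(gene, seeds[2])
        cI = sorted(rp.clade_map["OTU_I"])
        cII = sorted(rp.clade_map["OTU_II"])
        n = 10
        carriers = {0: (cI[0], 1), 1: (cI[1], 1), 2: (cII[0], 1), 3: (cII[1], 1)}
        # particle sample: clade-II carrier genomes 5x more abundant
        base = [1.0] * n
        particle = list(base)
        particle[2] = particle[3] = 5.0
        free_ab = [x / sum(base) for x in base]
        part_ab = [x / sum(particle) for x in particle]
        spec_free = CommunitySpec(
            _genomes(n, gene, carriers, rpob_leaves, free_ab),
            background_fraction=0.1,
        )
        spec_part = CommunitySpec(
            _genomes(n, gene, carriers, rpob_leaves, part_ab),
            background_fraction=0.1,
        )
        samples = [
            (SampleMeta("P120", "BB2", 120.0, "particle_gt30um"), spec_part),
            (SampleMeta("F120", "BB2", 120.0, "lt30um"), spec_free),
        ]
        return Scenario(name, {RPOB: rpob, gene: rp}, samples, params)

    # depth_profile
    gene = "nirK"
    rp = synth_refpkg(gene, seeds[2])
    cI = sorted(rp.clade_map["OTU_I"])
    cII = sorted(rp.clade_map["OTU_II"])
    depths = [60.0, 80.0, 100.0, 150.0, 200.0, 300.0]
    samples = []
    n = 10
    for d_i, depth in enumerate(depths):
        shallow = max(0.0, 1.0 - d_i / 3.0)  # clade I peaks shallow
        deep = max(0.0, d_i / 5.0)           # clade II peaks deep
        base = [1.0] * n
        base[0] = 1.0 + 4.0 * shallow
        base[1] = 1.0 + 4.0 * deep
        ab = [x / sum(base) for x in base]
        carriers = {0: (cI[0], 1), 1: (cII[0], 1)}
        spec = CommunitySpec(
            _genomes(n, gene, carriers, rpob_leaves, ab),
            background_fraction=0.1,
        )
        samples.append((SampleMeta(f"D{int(depth)}", "st136", depth), spec))
    return Scenario(name, {RPOB: rpob, gene: rp}, samples, params)


def write_scenario(scenario: Scenario, outdir) -> Path:
    """Materialize a scenario: refpkg dirs, per-sample FASTQ pairs, truth
    tables, sample manifest, and a spec.yaml describing the community."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gene, rp in scenario.refpkgs.items():
        save_refpkg(rp, outdir / "refpkgs" / gene)
    manifest = []
    shared = realize_gene_sequences(
        _merged_spec(scenario), scenario.refpkgs, seed=scenario.params.seed
    )
    for i, (meta, spec) in enumerate(scenario.samples):
        params = replace(scenario.params, seed=int(scenario.params.seed + i))
        r1, r2, truth = generate_metagenome_reads(
            spec, scenario.refpkgs, params, sample_id=meta.sample_id,
            gene_sequences={k: v for k, v in shared.items()
                            if k in _spec_keys(spec, scenario.refpkgs)},
        )
        write_fastq(r1, outdir / f"{meta.sample_id}_R1.fastq")
        write_fastq(r2, outdir / f"{meta.sample_id}_R2.fastq")
        truth.to_csv(outdir / f"{meta.sample_id}_truth.tsv", sep="\t", index=False)
        manifest.append(
            {
                "sample_id": meta.sample_id,
                "r1": f"{meta.sample_id}_R1.fastq",
                "r2": f"{meta.sample_id}_R2.fastq",
                "station": meta.station,
                "depth": meta.depth,
                "fraction": meta.fraction,
            }
        )
    pd.DataFrame(manifest).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    with open(outdir / "spec.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "scenario": scenario.name,
                "seed": int(scenario.params.seed),
                "n_pairs": int(scenario.params.n_pairs),
                "error_rate": float(scenario.params.error_rate),
                "read_length": int(scenario.params.read_length),
                "genes": sorted(scenario.refpkgs),
                "truth_percent": scenario.truth_percent,
            },
            fh,
        )
    return outdir


def _merged_spec(scenario: Scenario) -> CommunitySpec:
    """Union community over samples (genomes keyed by id) so gene
    sequences are shared across samples."""
    seen: dict[str, GenomeSpec] = {}
    contaminant: dict[str, float] = {}
    for _meta, spec in scenario.samples:
        for g in spec.genomes:
            seen.setdefault(g.genome_id, g)
        contaminant.update(spec.outgroup_contaminant)
    genomes = list(seen.values())
    total = sum(g.abundance for g in genomes)
    genomes = [replace(g, abundance=g.abundance / total) for g in genomes]
    return CommunitySpec(genomes, outgroup_contaminant=contaminant)


def _spec_keys(
    spec: CommunitySpec, refpkgs: dict[str, ReferencePackage]
) -> set[tuple[str, str]]:
    keys = {
        (g.genome_id, gc.gene) for g in spec.genomes for gc in g.genes
    }
    for gene, frac in spec.outgroup_contaminant.items():
        if frac > 0:
            for leaf in refpkgs[gene].outgroup:
                keys.add(("__outgroup__" + leaf, gene))
    return keys
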