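"""End-to-end orchestration: recruit -> align -> place -> quantify over many
samples and genes, with provenance logging and per-sample crash isolation.

Gate counts (reads recruited, pairs combined, outgroup-discarded, placed)
are logged per gene x sample; they are the primary debugging surface for
the recruitment and filtering thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .formats import PlacementDocument, read_fastq, write_fasta, write_placements
from .formats import SeqRecord
from .place import (
    AlignedQuery,
    PlacementEngine,
    align_read_to_profile,
    build_model,
    combine_pair_in_alignment,
)
from .quantify import (
    SampleMeta,
    clade_depth_profile,
    enrichment_table,
    gene_abundances,
    tally_clades,
    abundance_frame,
)
from .recruit import RecruitedRead, ScoringScheme, recruit_and_trim
from .refpkg import ReferencePackage, clade_edges, load_refpkg

logger = logging.getLogger("placeprof")

RPOB = "rpoB"


@dataclass
class SampleInput:
    sample_id: str
    r1: str
    r2: Optional[str] = None
    station: str = ""
    depth: float = 1.0
    fraction: str = "whole_water"

    def meta(self) -> SampleMeta:
        return SampleMeta(self.sample_id, self.station, self.depth, self.fraction)


@dataclass
class RunConfig:
    refpkg_paths: dict[str, str]
    samples: list[SampleInput]
    out_dir: str = "placeprof_out"
    e_recruit: float = 1e-5
    min_aa: int = 33
    gap_open: float = 11.0
    gap_ext: float = 1.0
    phase2_frac: float = 0.1
    pseudo_count: float = 0.1
    normalization: str = "reads"  # or "residues": summed aligned columns
    copy_numbers: dict = field(default_factory=dict)  # (gene, clade) -> copies
    seed: int = 0

    def __post_init__(self) -> None:
        if RPOB not in self.refpkg_paths:
            raise ValueError(f"a {RPOB} reference package is required")
        if not (0 < self.e_recruit <= 1.0):
            raise ValueError("e_recruit must be in (0, 1]")
        if self.min_aa < 1:
            raise ValueError("min_aa must be >= 1")
        if self.normalization not in ("reads", "residues"):
            raise ValueError("normalization must be 'reads' or 'residues'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleInput(**s) for s in raw.pop("samples")]
        copy_numbers = {}
        cn = raw.pop("copy_numbers", None)
        if isinstance(cn, str):
            df = pd.read_csv(cn, sep="\t")
            for _, row in df.iterrows():
                copy_numbers[(row["gene"], row["clade"])] = float(
                    row["copies_per_genome"]
                )
        elif isinstance(cn, dict):
            for key, v in cn.items():
                gene, clade = key.split(":", 1)
                copy_numbers[(gene, clade)] = float(v)
        refpkgs = raw.pop("refpkgs")
        return cls(refpkg_paths=refpkgs, samples=samples,
                   copy_numbers=copy_numbers, **raw)

    def to_yaml(self, path) -> None:
        payload = {
            "refpkgs": dict(self.refpkg_paths),
            "samples": [vars(s) for s in self.samples],
            "out_dir": self.out_dir,
            "e_recruit": self.e_recruit,
            "min_aa": self.min_aa,
            "gap_open": self.gap_open,
            "gap_ext": self.gap_ext,
            "phase2_frac": self.phase2_frac,
            "pseudo_count": self.pseudo_count,
            "normalization": self.normalization,
            "copy_numbers": {
                f"{g}:{c}": v for (g, c), v in self.copy_numbers.items()
            },
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


def _recruited_table(rows: list[RecruitedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "mate": r.mate,
                "frame": r.frame,
                "score": r.score,
                "evalue": r.evalue,
                "best_ref": r.best_ref,
                "dna_start": r.dna_span[0],
                "dna_end": r.dna_span[1],
            }
            for r in rows
        ],
        columns=[
            "read_id", "mate", "frame", "score", "evalue",
            "best_ref", "dna_start", "dna_end",
        ],
    )


def build_queries(
    recruited_by_mate: dict[str, list[RecruitedRead]],
    refpkg: ReferencePackage,
    gap_open: float = 11.0,
    gap_ext: float = 1.0,
) -> list[AlignedQuery]:
    """Align recruited mates to the reference columns and combine pairs
    sharing a read id into one query (singletons pass through)."""
    aligned: dict[str, dict[str, AlignedQuery]] = {}
    for mate, rows in recruited_by_mate.items():
        for rr in rows:
            q = align_read_to_profile(rr, refpkg, gap_open, gap_ext)
            aligned.setdefault(rr.read_id, {})[mate] = q
    queries: list[AlignedQuery] = []
    for rid in sorted(aligned):
        mates = aligned[rid]
        if len(mates) == 2:
            q1, q2 = mates["1"], mates["2"]
            queries.append(combine_pair_in_alignment(q1, q2))
        else:
            queries.append(next(iter(mates.values())))
    return queries


def process_sample_gene(
    gene: str,
    refpkg: ReferencePackage,
    engine: PlacementEngine,
    reads1: list[SeqRecord],
    reads2: list[SeqRecord],
    config: RunConfig,
    out_prefix: Optional[Path] = None,
) -> tuple[dict[str, int], int, int]:
    """Recruit, align, and place one sample against one gene.

    Returns (clade tallies of kept placements, n discarded as outgroup,
    n recruited reads). Side effects: recruited.tsv/.fasta and
    placements.jplace when ``out_prefix`` is given.
    """
    scheme = ScoringScheme(gap_open=config.gap_open, gap_ext=config.gap_ext)
    rec1 = recruit_and_trim(
        reads1, refpkg, scheme, config.e_recruit, config.min_aa, mate="1"
    )
    rec2 = recruit_and_trim(
        reads2, refpkg, scheme, config.e_recruit, config.min_aa, mate="2"
    )
    n_recruited = len(rec1) + len(rec2)
    queries = build_queries(
        {"1": rec1, "2": rec2}, refpkg, config.gap_open, config.gap_ext
    )
    placements = []
    weights: Optional[dict[str, float]] = (
        {} if config.normalization == "residues" else None
    )
    for q in queries:
        if q.n_covered < config.min_aa:
            continue
        placements.append(engine.place(q))
        if weights is not None:
            weights[q.query_id] = float(q.n_covered)
    if out_prefix is not None:
        table = _recruited_table(rec1 + rec2)
        table.to_csv(out_prefix.with_suffix(".recruited.tsv"), sep="\t", index=False)
        if rec1 or rec2:
            write_fasta(
                [SeqRecord(f"{r.read_id}/{r.mate}", r.aa_seq) for r in rec1 + rec2],
                out_prefix.with_suffix(".recruited.fasta"),
            )
        doc = PlacementDocument(
            refpkg.tree,
            {p.query_id: p.rows for p in placements},
            metadata={"gene": gene, "invocation": "placeprof"},
        )
        write_placements(doc, out_prefix.with_suffix(".jplace"))
    index = clade_edges(refpkg)
    tallies, n_discarded = tally_clades(placements, index, weights)
    logger.info(
        "%s: recruited=%d combined_queries=%d outgroup_discarded=%d placed=%d",
        gene, n_recruited, len(queries), n_discarded, sum(tallies.values()),
    )
    return dict(tallies), n_discarded, n_recruited


def run_pipeline(config: RunConfig) -> Path:
    """Run recruit -> place -> quantify for every sample x gene.

    Per-sample failures are isolated (logged, the run continues); outputs:
    per gene x sample recruited/jplace artifacts, abundance.tsv,
    depth_profile.tsv, enrichment.tsv, and run_log.yaml.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refpkgs = {g: load_refpkg(p) for g, p in config.refpkg_paths.items()}
    engines = {
        g: PlacementEngine(
            rp,
            build_model(rp.model_spec, rp.alignment),
            phase2_frac=config.phase2_frac,
            min_aa=config.min_aa,
        )
        for g, rp in refpkgs.items()
    }
    genes = sorted(g for g in refpkgs if g != RPOB)
    all_abundances = []
    failures: dict[str, str] = {}
    metas = []
    gate_log: list[dict] = []
    for sample in config.samples:
        metas.append(sample.meta())
        try:
            reads1 = read_fastq(sample.r1)
            reads2 = read_fastq(sample.r2) if sample.r2 else []
            sdir = out / sample.sample_id
            sdir.mkdir(exist_ok=True)
            rpob_tallies, rpob_disc, _n = process_sample_gene(
                RPOB, refpkgs[RPOB], engines[RPOB], reads1, reads2, config,
                out_prefix=sdir / RPOB,
            )
            rpob_count = sum(rpob_tallies.values())
            gate_log.append(
                {"sample": sample.sample_id, "gene": RPOB,
                 "placed": rpob_count, "outgroup_discarded": rpob_disc}
            )
            if rpob_count == 0:
                logger.warning(
                    "sample %s: no rpoB reads placed; percents undefined",
                    sample.sample_id,
                )
            for gene in genes:
                rp = refpkgs[gene]
                tallies, disc, nrec = process_sample_gene(
                    gene, rp, engines[gene], reads1, reads2, config,
                    out_prefix=sdir / gene,
                )
                gate_log.append(
                    {"sample": sample.sample_id, "gene": gene,
                     "recruited": nrec, "placed": sum(tallies.values()),
                     "outgroup_discarded": disc}
                )
                copy_map = {
                    clade: v
                    for (g, clade), v in config.copy_numbers.items()
                    if g == gene
                }
                all_abundances.extend(
                    gene_abundances(
                        sample.sample_id,
                        gene,
                        tallies,
                        rp.ref_length_aa,
                        rpob_count,
                        refpkgs[RPOB].ref_length_aa,
                        copy_numbers=copy_map,
                        clade_labels=sorted(rp.clade_map),
                    )
                )
        except Exception as exc:  # crash isolation per sample
            logger.error("sample %s failed: %s", sample.sample_id, exc)
            failures[sample.sample_id] = str(exc)

    df = abundance_frame(all_abundances)
    df = df.sort_values(["sample_id", "gene", "clade"], kind="mergesort")
    df.to_csv(out / "abundance.tsv", sep="\t", index=False, na_rep="NA",
              float_format="%.10g")
    profile = clade_depth_profile(all_abundances, metas)
    profile.to_csv(out / "depth_profile.tsv", sep="\t", index=False,
                   na_rep="NA", float_format="%.10g")
    enrich = enrichment_table(profile, config.pseudo_count) if not profile.empty \
        else pd.DataFrame()
    enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False, na_rep="NA",
                  float_format="%.10g")
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "placeprof_version": __version__,
                "seed": config.seed,
                "thresholds": {
                    "e_recruit": config.e_recruit,
                    "min_aa": config.min_aa,
                    "gap_open": config.gap_open,
                    "gap_ext": config.gap_ext,
                    "phase2_frac": config.phase2_frac,
                    "pseudo_count": config.pseudo_count,
                    "normalization": config.normalization,
                },
                "gates": gate_log,
                "failures": failures,
            },
            fh,
        )
    return out
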