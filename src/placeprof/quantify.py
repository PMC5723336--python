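"""From placements to % of the prokaryotic community.

The headline statistic normalizes a gene's length-normalized placed-read
count to that of the universal single-copy gene rpoB:

    % community = 100 * (gene reads / gene length) / (rpoB reads / rpoB length)

Placements whose best edge falls among a tree's outgroup edges are not
counted (critical for closely related genes, e.g. narG with its nxrA
outgroup). Clade-level tallies drive per-depth phylotype profiles, and
known per-genome copy numbers (e.g. two narG types in SAR11, two nxrB in
Nitrospina) divide the estimate before totals are re-summed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .place import Placement
from .refpkg import OUTGROUP_LABEL, CladeEdgeIndex

FRACTIONS = ("whole_water", "particle_gt30um", "lt30um")

TOTAL_LABEL = "total"


@dataclass
class SampleMeta:
    sample_id: str
    station: str
    depth: float
    fraction: str = "whole_water"

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.fraction not in FRACTIONS:
            raise ValueError(
                f"fraction {self.fraction!r} not in {FRACTIONS}"
            )


@dataclass
class GeneAbundance:
    sample_id: str
    gene_name: str
    clade: str  # clade label, "unassigned_ingroup", or "total"
    placed_read_count: int
    ref_length_aa: float
    rpob_read_count: int
    rpob_length_aa: float
    percent_community: float  # NaN when rpoB count is 0 (undefined)
    copy_number_applied: float = 1.0


def filter_outgroup_placements(
    placements: Iterable[Placement], index: CladeEdgeIndex
) -> tuple[list[tuple[Placement, str]], list[Placement]]:
    """Split placements into (kept with clade label, discarded-as-outgroup).

    A placement is discarded iff its best edge lies in the outgroup edge
    set; kept placements carry the clade label of their best edge
    (``unassigned_ingroup`` when unlabeled).
    """
    kept: list[tuple[Placement, str]] = []
    discarded: list[Placement] = []
    for pl in placements:
        label = index.label_of(pl.best_edge)
        if label == OUTGROUP_LABEL:
            discarded.append(pl)
        else:
            kept.append((pl, label))
    return kept, discarded


def percent_community(
    gene_count: int, gene_len: float, rpob_count: int, rpob_len: float
) -> float:
    """The normalization equation; NaN (undefined) when no rpoB reads."""
    if gene_len <= 0 or rpob_len <= 0:
        raise ValueError("reference lengths must be > 0")
    if gene_count < 0 or rpob_count < 0:
        raise ValueError("read counts must be >= 0")
    if rpob_count == 0:
        return math.nan
    return 100.0 * (gene_count / gene_len) / (rpob_count / rpob_len)


def copy_number_correct(percent: float, copies_per_genome: float) -> float:
    """Divide a percent-community estimate by per-genome gene copies."""
    if copies_per_genome < 1:
        raise ValueError("copies_per_genome must be >= 1")
    return percent / copies_per_genome


def fraction_enrichment(
    percent_particle: float, percent_freeliving: float, pseudo: float = 0.1
) -> float:
    """log2((particle + pseudo) / (free-living + pseudo)); positive values
    mean particle-enriched. The pseudo-count keeps zero-vs-zero at 0."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0")
    if percent_particle < 0 or percent_freeliving < 0:
        raise ValueError("percents must be >= 0")
    return math.log2((percent_particle + pseudo) / (percent_freeliving + pseudo))


def tally_clades(
    placements: Iterable[Placement],
    index: CladeEdgeIndex,
    weights: Optional[dict[str, float]] = None,
) -> tuple[Counter, int]:
    """Tally kept placements per clade label; returns (tallies, n_discarded).

    By default each placed query counts once (a combined mate pair is one
    read). ``weights`` switches to an alternative accounting, e.g. summed
    aligned residue columns per query, keyed by query id.
    """
    kept, discarded = filter_outgroup_placements(placements, index)
    tallies: Counter = Counter()
    for pl, label in kept:
        tallies[label] += 1 if weights is None else weights[pl.query_id]
    return tallies, len(discarded)


def gene_abundances(
    sample_id: str,
    gene_name: str,
    clade_counts: dict[str, int],
    ref_length_aa: float,
    rpob_count: int,
    rpob_length_aa: float,
    copy_numbers: Optional[dict[str, float]] = None,
    clade_labels: Optional[Iterable[str]] = None,
) -> list[GeneAbundance]:
    """Build per-clade and total abundance rows for one gene in one sample.

    ``copy_numbers`` maps clade label -> copies per genome; correction is
    applied per clade before the total is re-summed. ``clade_labels`` fixes
    the set of emitted clades (dense output: absent clades get 0 rows).
    """
    copy_numbers = copy_numbers or {}
    labels = set(clade_counts) | set(clade_labels or [])
    labels.discard(TOTAL_LABEL)
    rows: list[GeneAbundance] = []
    total_corrected = 0.0
    total_count = 0
    for label in sorted(labels):
        count = int(clade_counts.get(label, 0))
        copies = float(copy_numbers.get(label, 1.0))
        pct = percent_community(count, ref_length_aa, rpob_count, rpob_length_aa)
        pct_corr = copy_number_correct(pct, copies) if not math.isnan(pct) else pct
        rows.append(
            GeneAbundance(
                sample_id, gene_name, label, count, ref_length_aa,
                rpob_count, rpob_length_aa, pct_corr, copies,
            )
        )
        total_count += count
        if not math.isnan(pct_corr):
            total_corrected += pct_corr
    total_pct = (
        math.nan if rpob_count == 0 else total_corrected
    )
    rows.append(
        GeneAbundance(
            sample_id, gene_name, TOTAL_LABEL, total_count, ref_length_aa,
            rpob_count, rpob_length_aa, total_pct, 1.0,
        )
    )
    return rows


def abundance_frame(abundances: Iterable[GeneAbundance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "gene": a.gene_name,
                "clade": a.clade,
                "placed_read_count": a.placed_read_count,
                "ref_length_aa": a.ref_length_aa,
                "rpob_read_count": a.rpob_read_count,
                "rpob_length_aa": a.rpob_length_aa,
                "percent_community": a.percent_community,
                "copy_number_applied": a.copy_number_applied,
            }
            for a in abundances
        ]
    )


def clade_depth_profile(
    abundances: Iterable[GeneAbundance],
    meta: Union[dict[str, SampleMeta], list[SampleMeta]],
) -> pd.DataFrame:
    """Long-format depth profile: one row per (sample, gene, clade),
    ordered by depth, dense in clades (missing combinations emit 0)."""
    if isinstance(meta, list):
        meta = {m.sample_id: m for m in meta}
    rows = list(abundances)
    seen: set[tuple[str, str, str]] = set()
    for a in rows:
        key = (a.sample_id, a.gene_name, a.clade)
        if key in seen:
            raise ValueError(f"duplicate abundance row for {key}")
        seen.add(key)
    df = abundance_frame(rows)
    if df.empty:
        return df
    clades_per_gene = {
        g: sorted(set(sub["clade"])) for g, sub in df.groupby("gene")
    }
    samples = sorted(set(df["sample_id"]))
    dense = []
    existing = {(r.sample_id, r.gene_name, r.clade) for r in rows}
    for g, clades in clades_per_gene.items():
        for s in samples:
            for c in clades:
                if (s, g, c) not in existing:
                    dense.append(
                        {
                            "sample_id": s,
                            "gene": g,
                            "clade": c,
                            "placed_read_count": 0,
                            "ref_length_aa": np.nan,
                            "rpob_read_count": 0,
                            "rpob_length_aa": np.nan,
                            "percent_community": 0.0,
                            "copy_number_applied": 1.0,
                        }
                    )
    if dense:
        df = pd.concat([df, pd.DataFrame(dense)], ignore_index=True)
    df["depth"] = df["sample_id"].map(
        lambda s: meta[s].depth if s in meta else np.nan
    )
    df["fraction"] = df["sample_id"].map(
        lambda s: meta[s].fraction if s in meta else ""
    )
    df = df.sort_values(
        ["gene", "depth", "sample_id", "clade"], kind="mergesort"
    ).reset_index(drop=True)
    return df


def enrichment_table(
    profile: pd.DataFrame, pseudo: float = 0.1
) -> pd.DataFrame:
    """Particle (>30 um) vs free-living (<30 um) comparison at matched
    depths: per (gene, clade, depth) log2 enrichment ratio."""
    part = profile[profile["fraction"] == "particle_gt30um"]
    free = profile[profile["fraction"] == "lt30um"]
    merged = part.merge(
        free,
        on=["gene", "clade", "depth"],
        suffixes=("_particle", "_freeliving"),
    )
    out = merged[["gene", "clade", "depth"]].copy()
    out["percent_particle"] = merged["percent_community_particle"]
    out["percent_freeliving"] = merged["percent_community_freeliving"]
    out["log2_enrichment"] = [
        fraction_enrichment(p, f, pseudo)
        for p, f in zip(out["percent_particle"], out["percent_freeliving"])
    ]
    return out.sort_values(["gene", "depth", "clade"], kind="mergesort").reset_index(
        drop=True
    )
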