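"""Simplified phylogenetic footprinting.

A binding site is called conserved for a focal gene when the motif also
matches the upstream region of orthologous genes in enough related genomes.
Ortholog upstream sequences are an input table (orthology itself is not
computed here); no phylogenetic weighting is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome import MarkovBackground
from .motifs import PSSM
from .regulon import Regulon
from .scanning import ScoreDistribution, scan_sequence, score_distribution

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_MIN_GENOMES = 3   # including the focal genome


@dataclass
class OrthologSet:
    """Upstream sequences of one focal gene and its orthologs (same 400/40 windows)."""

    focal_gene: str
    focal_genome: str
    upstream: dict[str, str]  # genome_id -> upstream sequence

    def __post_init__(self) -> None:
        if self.focal_genome not in self.upstream:
            raise ValueError(f"focal genome {self.focal_genome!r} missing from set")
        if any(not s for s in self.upstream.values()):
            raise ValueError("upstream sequences must be non-empty")


@dataclass
class ConservationCall:
    focal_gene: str
    genomes_with_site: list[str]
    n_genomes_tested: int
    conserved: bool


def footprint_scan(pssm: PSSM, ortholog_set: OrthologSet,
                   background: MarkovBackground,
                   p_threshold: float = DEFAULT_P_THRESHOLD,
                   min_genomes: int = DEFAULT_MIN_GENOMES,
                   dist: ScoreDistribution | None = None) -> ConservationCall:
    """Scan each ortholog's upstream region; conserved requires a site in the
    focal genome plus at least ``min_genomes - 1`` other genomes."""
    if len(ortholog_set.upstream) < 2:
        raise ValueError("need at least 2 genomes for a conservation test")
    if dist is None:
        dist = score_distribution(pssm, background)
    with_site = []
    for genome_id, seq in ortholog_set.upstream.items():
        hits = scan_sequence(pssm, seq, background, p_threshold, dist=dist)
        if hits:
            with_site.append(genome_id)
    focal_hit = ortholog_set.focal_genome in with_site
    conserved = focal_hit and len(with_site) >= min_genomes
    return ConservationCall(focal_gene=ortholog_set.focal_gene,
                            genomes_with_site=sorted(with_site),
                            n_genomes_tested=len(ortholog_set.upstream),
                            conserved=conserved)


def conserved_regulon(regulon: Regulon, ortholog_sets: list[OrthologSet],
                      pssm: PSSM, background: MarkovBackground,
                      p_threshold: float = DEFAULT_P_THRESHOLD,
                      min_genomes: int = DEFAULT_MIN_GENOMES) -> Regulon:
    """Add the 'conserved' evidence flag to edges whose target genes pass
    :func:`footprint_scan`; targets without ortholog data are left unflagged."""
    sets_by_gene = {s.focal_gene: s for s in ortholog_sets}
    dist = score_distribution(pssm, background)
    for edge in regulon.edges:
        for gene in edge.target_genes:
            oset = sets_by_gene.get(gene)
            if oset is None:
                continue
            call = footprint_scan(pssm, oset, background, p_threshold=p_threshold,
                                  min_genomes=min_genomes, dist=dist)
            if call.conserved:
                edge.evidence.flags.add("conserved")
                break
    return regulon


def read_ortholog_sets(path: str | Path, focal_genome: str) -> list[OrthologSet]:
    """Read ortholog upstream sequences from a 3-column TSV
    (focal_gene, genome_id, upstream_sequence)."""
    df = pd.read_csv(path, sep="\t",
                     names=["focal_gene", "genome_id", "upstream_sequence"],
                     header=None, comment="#")
    sets = []
    for gene, grp in df.groupby("focal_gene", sort=True):
        upstream = dict(zip(grp["genome_id"], grp["upstream_sequence"]))
        sets.append(OrthologSet(focal_gene=str(gene), focal_genome=focal_genome,
                                upstream=upstream))
    return sets


def write_ortholog_sets(sets: list[OrthologSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            for genome_id, seq in s.upstream.items():
                fh.write(f"{s.focal_gene}\t{genome_id}\t{seq}\n")
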