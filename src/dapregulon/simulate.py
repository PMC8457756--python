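"""Synthetic genomes, annotations, planted binding sites and fragment libraries.

The generator emulates the study design the pipeline targets: a Markov
genome with operon structure, a transcription factor whose binding words
(sampled from a high-information PSSM) are planted into regulatory windows,
and an in-vitro selection experiment producing ~200 bp fragments — a TF
sample whose fragments concentrate over planted sites at a chosen fold
enrichment, and a uniform negative control.  Everything is deterministic
given (seed, parameters); the manifest is the ground-truth oracle for
recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import decode, encode, revcomp
from .genome import (Gene, Genome, MarkovBackground, NoncodingRegion, Operon,
                     extract_noncoding_regions, infer_operons)
from .motifs import PSSM

logger = logging.getLogger(__name__)

MIN_FRAGMENT_LEN = 50


@dataclass
class PlantedSite:
    tf: str
    position: int
    strand: str
    word: str
    operon: str
    overlaps_other: bool = False


@dataclass
class SyntheticTruth:
    """Ground truth and full parameter manifest of one synthetic dataset."""

    seed: int
    genome_length: int
    background_order: int
    gc_content: float
    n_operons: int
    genes_per_operon: int
    gene_length: int
    intergenic_length: int
    intra_operon_gap: int
    motif_consensus: str
    motif_concentration: float
    planted_sites: list[PlantedSite] = field(default_factory=list)
    planted_regulon: list[tuple[str, str]] = field(default_factory=list)
    n_fragments: int = 0
    frag_len_mean: float = 200.0
    frag_len_sd: float = 30.0
    enrichment_fold: float = 10.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_regulon"] = [list(t) for t in self.planted_regulon]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        required = {f.name for f in dataclasses.fields(cls)
                    if f.default is dataclasses.MISSING
                    and f.default_factory is dataclasses.MISSING}  # type: ignore[misc]
        missing = required - set(d)
        if missing:
            raise ValueError(f"manifest missing required fields: {sorted(missing)}")
        d = dict(d)
        d["planted_sites"] = [PlantedSite(**s) for s in d.get("planted_sites", [])]
        d["planted_regulon"] = [tuple(t) for t in d.get("planted_regulon", [])]
        return cls(**d)


def default_background(order: int = 2, gc: float = 0.39,
                       repeat_boost: float = 1.15) -> MarkovBackground:
    """A deterministic order-m background emulating an AT-rich bacterial genome.

    Base composition is set by ``gc``; for m > 0 a mild boost of same-base
    repetition adds the short-range autocorrelation real genomes show.
    """
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    n_ctx = 4 ** order
    probs = np.tile(base, (n_ctx, 1))
    if order > 0:
        for c in range(n_ctx):
            last = c % 4
            probs[c, last] *= repeat_boost
            probs[c] /= probs[c].sum()
    return MarkovBackground(order, probs, base)


def generate_genome(length: int, background: MarkovBackground, seed: int,
                    genome_id: str = "synthetic") -> Genome:
    """Sample a genome from the Markov chain; reproducible given the seed."""
    if length <= 0:
        raise ValueError("length must be > 0")
    rng = np.random.default_rng(seed)
    return Genome(id=genome_id, sequence=background.sample(length, rng))


def plant_annotation(genome: Genome, n_operons: int, genes_per_operon: int = 2,
                     intergenic_length: int = 300, gene_length: int = 900,
                     intra_operon_gap: int = 20,
                     strand_period: int = 4) -> tuple[list[Gene], list[Operon]]:
    """Lay out alternating-strand operon blocks with fixed intergenic stretches.

    Strands alternate every ``strand_period`` operons, so most heads face a
    same-strand neighbor (a private window) while every '-' to '+' block
    boundary yields a divergently transcribed pair whose heads share one
    intergenic stretch.
    """
    block = genes_per_operon * gene_length + (genes_per_operon - 1) * intra_operon_gap
    needed = n_operons * block + (n_operons + 1) * intergenic_length
    if needed > genome.length:
        raise ValueError(f"layout needs {needed} bp but genome has {genome.length}")
    genes: list[Gene] = []
    pos = intergenic_length
    for i in range(n_operons):
        strand = "+" if (i // strand_period) % 2 == 0 else "-"
        for j in range(genes_per_operon):
            start = pos + j * (gene_length + intra_operon_gap)
            genes.append(Gene(locus_tag=f"syn_{i:04d}_{j}", start=start,
                              end=start + gene_length, strand=strand,
                              product=f"synthetic protein {i}.{j}"))
        pos += block + intergenic_length
    operons = infer_operons(genes, max_gap=max(intra_operon_gap + 1, 150))
    assert len(operons) == n_operons
    return genes, operons


def consensus_pssm(consensus: str, nsites: int = 50,
                   concentration: float = 0.95, name: str = "planted") -> PSSM:
    """High-information PSSM around a consensus word (the planting motif)."""
    codes = encode(consensus)
    counts = np.full((len(consensus), 4), nsites * (1 - concentration) / 3)
    counts[np.arange(len(consensus)), codes] = nsites * concentration
    return PSSM(counts, name=name)


def sample_site_word(pssm: PSSM, rng: np.random.Generator) -> str:
    """Draw one site word from the PSSM's column frequency distributions."""
    f = pssm.frequencies()
    out = [int(rng.choice(4, p=f[i] / f[i].sum())) for i in range(pssm.width)]
    return decode(np.array(out))


def plant_sites(genome: Genome, regions: list[NoncodingRegion], pssm: PSSM,
                tf_to_targets: dict[str, list[str]], seed: int,
                edge_margin: int = 60,
                allow_shared: bool = False) -> tuple[Genome, list[PlantedSite]]:
    """Write motif words into the regulatory windows of the requested targets.

    Each (tf, operon) pair gets one word sampled from the PSSM, placed at a
    random offset and strand inside the target's window, at least
    ``edge_margin`` bp from the window edges so the fragment pileup apex
    stays inside the window.  Unless ``allow_shared``, positions falling in
    the shared stretch of divergent windows are resampled so each site maps
    to exactly one operon.  Overlap between two planted sites is permitted
    but flagged.
    """
    rng = np.random.default_rng(seed)
    seq = np.array(list(genome.sequence))
    w = pssm.width
    by_operon: dict[str, NoncodingRegion] = {}
    for r in regions:
        for op in r.downstream_operons:
            by_operon.setdefault(op, r)
    planted: list[PlantedSite] = []
    occupied: list[tuple[int, int]] = []
    for tf, targets in sorted(tf_to_targets.items()):
        for operon in targets:
            region = by_operon.get(operon)
            if region is None:
                raise ValueError(f"no regulatory window for operon {operon!r}")
            lo = region.start + edge_margin
            hi = region.end - edge_margin - w
            if hi <= lo:
                raise ValueError(f"window of operon {operon!r} too narrow for planting")
            position = None
            for _ in range(200):
                cand = int(rng.integers(lo, hi + 1))
                if not allow_shared:
                    containing = [r for r in regions
                                  if r.start <= cand and cand + w <= r.end]
                    owners = {op for r in containing for op in r.downstream_operons}
                    if owners != {operon}:
                        continue
                position = cand
                break
            if position is None:
                raise ValueError(f"could not place a site for operon {operon!r}")
            word = sample_site_word(pssm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = word if strand == "+" else revcomp(word)
            overlaps = any(position < b and position + w > a for a, b in occupied)
            seq[position:position + w] = list(inserted)
            occupied.append((position, position + w))
            planted.append(PlantedSite(tf=tf, position=position, strand=strand,
                                       word=word, operon=operon,
                                       overlaps_other=overlaps))
    return Genome(id=genome.id, sequence="".join(seq)), planted


def uniquely_plantable_operons(regions: list[NoncodingRegion], width: int,
                               edge_margin: int = 60) -> list[str]:
    """Operons whose window offers positions not shared with another operon."""
    out = []
    for r in regions:
        lo, hi = r.start + edge_margin, r.end - edge_margin - width
        if hi < lo:
            continue
        # subtract placements that would also fall inside another operon's window
        free = [(lo, hi)]
        for q in regions:
            if q is r or set(q.downstream_operons) == set(r.downstream_operons):
                continue
            a, b = q.start, q.end - width
            free = [seg for pair in free
                    for seg in _interval_minus(pair, (a, b))]
            if not free:
                break
        if free:
            for op in r.downstream_operons:
                if op not in out:
                    out.append(op)
    return out


def _interval_minus(seg: tuple[int, int], cut: tuple[int, int]):
    """Closed-interval difference seg \\ cut (may yield 0-2 intervals)."""
    lo, hi = seg
    a, b = cut
    if b < lo or a > hi:
        return [seg]
    parts = []
    if a > lo:
        parts.append((lo, a - 1))
    if b < hi:
        parts.append((b + 1, hi))
    return parts


def simulate_fragments(genome: Genome, planted: list[PlantedSite],
                       sample: str, n_fragments: int,
                       frag_len_mean: float = 200.0, frag_len_sd: float = 30.0,
                       enrichment_fold: float = 10.0, seed: int = 0) -> pd.DataFrame:
    """Simulate one fragment library as a sorted BED-style DataFrame.

    ``sample='control'`` places fragments uniformly.  A TF sample reserves
    enough fragments per planted site of that TF to raise expected coverage
    over the site to ``enrichment_fold`` times background, placing each
    reserved fragment so it covers the site center; the remainder is uniform.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    rng = np.random.default_rng(seed)
    G = genome.length
    sites = [] if sample == "control" else [s for s in planted if s.tf == sample]
    bg_cov = n_fragments * frag_len_mean / G
    n_extra_per_site = int(round((enrichment_fold - 1.0) * bg_cov)) if sites else 0
    n_extra = n_extra_per_site * len(sites)
    if n_extra >= n_fragments:
        raise ValueError("enrichment demands more fragments than the library holds")
    lengths = rng.normal(frag_len_mean, frag_len_sd, size=n_fragments)
    lengths = np.maximum(np.rint(lengths), MIN_FRAGMENT_LEN).astype(np.int64)
    starts = np.empty(n_fragments, dtype=np.int64)
    n_bg = n_fragments - n_extra
    starts[:n_bg] = rng.integers(0, np.maximum(G - lengths[:n_bg], 1))
    idx = n_bg
    for s in sites:
        center = s.position + len(s.word) // 2
        for _ in range(n_extra_per_site):
            L = lengths[idx]
            lo = max(0, center - L + 1)
            hi = min(G - L, center)
            starts[idx] = rng.integers(lo, max(hi, lo) + 1)
            idx += 1
    ends = np.minimum(starts + lengths, G)
    df = pd.DataFrame({"chrom": genome.id, "start": starts, "end": ends})
    return df.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)


def write_fragments_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_manifest(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2) + "\n")


def read_manifest(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------------------
# One-call dataset assembly
# ----------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic dataset.

    The defaults describe the desk-scale test genome: 500 kb, 200 operons,
    an AT-rich order-2 background, one TF with 20 planted 14-bp sites,
    ~200 +/- 30 bp fragments at 30x background coverage and 10-fold
    enrichment over planted sites.
    """

    seed: int = 0
    genome_length: int = 500_000
    background_order: int = 2
    gc_content: float = 0.39
    n_operons: int = 200
    genes_per_operon: int = 2
    gene_length: int = 900
    intergenic_length: int = 300
    intra_operon_gap: int = 20
    tf_name: str = "synTF"
    motif_consensus: str = "TGACCATTGGTCAT"
    motif_concentration: float = 0.95
    motif_nsites: int = 50
    n_planted_sites: int = 20
    background_coverage: float = 30.0
    frag_len_mean: float = 200.0
    frag_len_sd: float = 30.0
    enrichment_fold: float = 10.0


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: Genome
    genes: list[Gene]
    operons: list[Operon]
    regions: list[NoncodingRegion]
    pssm: PSSM
    truth: SyntheticTruth
    tf_fragments: pd.DataFrame
    control_fragments: pd.DataFrame


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic study: genome, annotation, planted sites,
    and TF + control fragment libraries, with the truth manifest."""
    cfg = config or SimulationConfig()
    background = default_background(cfg.background_order, cfg.gc_content)
    genome = generate_genome(cfg.genome_length, background, cfg.seed)
    genes, operons = plant_annotation(genome, cfg.n_operons, cfg.genes_per_operon,
                                      cfg.intergenic_length, cfg.gene_length,
                                      cfg.intra_operon_gap)
    regions = extract_noncoding_regions(genome, operons)
    pssm = consensus_pssm(cfg.motif_consensus, nsites=cfg.motif_nsites,
                          concentration=cfg.motif_concentration)
    rng = np.random.default_rng(cfg.seed + 1)
    candidate_ops = uniquely_plantable_operons(regions, pssm.width)
    chosen = [str(o) for o in rng.choice(candidate_ops, size=cfg.n_planted_sites,
                                         replace=False)]
    genome, planted = plant_sites(genome, regions, pssm,
                                  {cfg.tf_name: chosen}, seed=cfg.seed + 2)
    n_fragments = int(round(cfg.background_coverage * cfg.genome_length
                            / cfg.frag_len_mean))
    tf_df = simulate_fragments(genome, planted, cfg.tf_name, n_fragments,
                               cfg.frag_len_mean, cfg.frag_len_sd,
                               cfg.enrichment_fold, seed=cfg.seed + 3)
    ctrl_df = simulate_fragments(genome, planted, "control", n_fragments,
                                 cfg.frag_len_mean, cfg.frag_len_sd,
                                 cfg.enrichment_fold, seed=cfg.seed + 4)
    truth = SyntheticTruth(
        seed=cfg.seed, genome_length=cfg.genome_length,
        background_order=cfg.background_order, gc_content=cfg.gc_content,
        n_operons=cfg.n_operons, genes_per_operon=cfg.genes_per_operon,
        gene_length=cfg.gene_length, intergenic_length=cfg.intergenic_length,
        intra_operon_gap=cfg.intra_operon_gap,
        motif_consensus=cfg.motif_consensus,
        motif_concentration=cfg.motif_concentration,
        planted_sites=planted,
        planted_regulon=sorted({(s.tf, s.operon) for s in planted}),
        n_fragments=n_fragments, frag_len_mean=cfg.frag_len_mean,
        frag_len_sd=cfg.frag_len_sd, enrichment_fold=cfg.enrichment_fold)
    return SyntheticDataset(config=cfg, genome=genome, genes=genes,
                            operons=operons, regions=regions, pssm=pssm,
                            truth=truth, tf_fragments=tf_df,
                            control_fragments=ctrl_df)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA, GFF3, per-sample BED and the JSON manifest."""
    from .genome import write_annotation, write_genome

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "annotation.gff3",
        "tf_fragments": outdir / f"{dataset.config.tf_name}.bed",
        "control_fragments": outdir / "control.bed",
        "manifest": outdir / "manifest.json",
    }
    write_genome(dataset.genome, paths["genome"])
    write_annotation(dataset.genes, dataset.genome, paths["annotation"])
    write_fragments_bed(dataset.tf_fragments, paths["tf_fragments"])
    write_fragments_bed(dataset.control_fragments, paths["control_fragments"])
    write_manifest(dataset.truth, paths["manifest"])
    return paths
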