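"""Genome, annotation, operon and background models for regulon reconstruction.

This module holds the coordinate layer of the pipeline: the genome sequence,
gene annotations, an intergenic-distance operon caller, the extraction of
candidate regulatory ("non-coding") windows upstream of operon heads, and the
Markov background model of genomic composition used for motif discovery and
site scanning.

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the parsing boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import BASES, N_CODE, clean_sequence, decode, encode

logger = logging.getLogger(__name__)

#: default maximum intergenic gap (bp) for merging same-strand genes into an operon
DEFAULT_OPERON_GAP = 150
#: regulatory window: up to this many bases upstream of a gene start ...
UPSTREAM_EXTENT = 400
#: ... through this many bases into the coding sequence
CDS_OVERHANG = 40


@dataclass
class Genome:
    """A single DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("genome sequence restricted to A,C,G,T,N")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def codes(self) -> np.ndarray:
        return encode(self.sequence)


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene; start/end are 0-based half-open genomic coordinates."""

    locus_tag: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.locus_tag}: invalid interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.locus_tag}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Operon:
    """A co-transcribed run of same-strand genes, ordered by transcription direction.

    ``id`` is the locus tag of the first gene in transcription order (the
    leftmost gene on '+', the rightmost on '-').
    """

    id: str
    genes: list[Gene]
    strand: str

    @property
    def head(self) -> Gene:
        return self.genes[0]

    @property
    def span(self) -> tuple[int, int]:
        return (min(g.start for g in self.genes), max(g.end for g in self.genes))

    @property
    def locus_tags(self) -> list[str]:
        return [g.locus_tag for g in self.genes]


@dataclass
class NoncodingRegion:
    """Candidate regulatory window upstream of an operon head.

    Spans up to :data:`UPSTREAM_EXTENT` bp upstream of the head gene start
    through :data:`CDS_OVERHANG` bp into its coding sequence, truncated so it
    never reaches into a neighboring gene's CDS.  For divergently transcribed
    operon pairs the two windows may overlap; a feature falling in the shared
    stretch is assigned to both downstream operons (see
    :func:`dapregulon.regulon.assign_targets`).
    """

    start: int
    end: int
    strand: str
    downstream_operons: tuple[str, ...]
    upstream_extent: int
    cds_overhang: int

    def __contains__(self, position: int) -> bool:
        return self.start <= position < self.end


class MarkovBackground:
    """Order-``m`` Markov model of genomic base composition.

    ``probs[c, x]`` is the conditional probability of base ``x`` (A,C,G,T)
    given the length-``m`` preceding context with base-4 code ``c``.
    Estimated from (m+1)-mer counts on both strands with a pseudocount, which
    makes the model reverse-complement symmetric.
    """

    def __init__(self, order: int, probs: np.ndarray, base_freqs: np.ndarray,
                 pseudocount: float = 1.0):
        if order < 0:
            raise ValueError("order must be >= 0")
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (4 ** order, 4):
            raise ValueError(f"probs must have shape ({4 ** order}, 4)")
        sums = probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("conditional probabilities must sum to 1 per context")
        if np.any(probs <= 0):
            raise ValueError("all conditional probabilities must be > 0")
        self.order = order
        self.probs = probs
        self.base_freqs = np.asarray(base_freqs, dtype=float)
        self.base_freqs = self.base_freqs / self.base_freqs.sum()
        self.pseudocount = pseudocount
        self.log2_probs = np.log2(probs)
        self.log2_base = np.log2(self.base_freqs)

    # -- construction -----------------------------------------------------

    @classmethod
    def uniform(cls, order: int = 0) -> "MarkovBackground":
        return cls(order, np.full((4 ** order, 4), 0.25), np.full(4, 0.25))

    @classmethod
    def fit(cls, sequence: str, order: int, pseudocount: float = 1.0) -> "MarkovBackground":
        """Estimate conditional probabilities from (order+1)-mer counts on both strands."""
        if order < 0:
            raise ValueError("order must be >= 0")
        counts = np.full((4 ** order, 4), pseudocount, dtype=float)
        base_counts = np.full(4, pseudocount, dtype=float)
        from ._seq import revcomp

        for strand_seq in (sequence, revcomp(sequence)):
            codes = encode(strand_seq)
            valid = codes != N_CODE
            np.add.at(base_counts, codes[valid], 1.0)
            if order == 0:
                np.add.at(counts[0], codes[valid], 1.0)
                continue
            if len(codes) < order + 1:
                continue
            # context index via base-4 positional encoding
            powers = 4 ** np.arange(order - 1, -1, -1)
            windows = np.lib.stride_tricks.sliding_window_view(codes, order + 1)
            ok = (windows != N_CODE).all(axis=1)
            ctx = windows[ok, :order] @ powers
            nxt = windows[ok, order]
            np.add.at(counts, (ctx, nxt), 1.0)
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(order, probs, base_counts, pseudocount=pseudocount)

    # -- evaluation -------------------------------------------------------

    def position_log2(self, codes: np.ndarray) -> np.ndarray:
        """Per-position log2 probability of each base given its preceding context.

        The first ``order`` positions, and positions whose context contains N,
        fall back to the marginal base composition.  Positions that are N
        themselves get NaN (windows containing N are skipped by scanners).
        """
        codes = np.asarray(codes)
        L = len(codes)
        out = np.empty(L, dtype=float)
        is_n = codes == N_CODE
        safe = np.where(is_n, 0, codes)
        out[:] = self.log2_base[safe]
        if self.order > 0 and L > self.order:
            m = self.order
            powers = 4 ** np.arange(m - 1, -1, -1)
            windows = np.lib.stride_tricks.sliding_window_view(codes, m + 1)
            ok = (windows != N_CODE).all(axis=1)
            # N-containing windows are masked out below; clip keeps indexing valid
            ctx = windows[:, :m].clip(0, 3) @ powers
            vals = self.log2_probs[ctx, windows[:, m].clip(0, 3)]
            idx = np.arange(m, L)
            out[idx[ok]] = vals[ok]
        out[is_n] = np.nan
        return out

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """Draw a sequence of the given length from the Markov chain."""
        if length <= 0:
            raise ValueError("length must be > 0")
        m = self.order
        out = np.empty(length, dtype=np.int8)
        # seed the first m bases from the marginal composition
        for i in range(min(m, length)):
            out[i] = rng.choice(4, p=self.base_freqs)
        if m == 0:
            out[:] = rng.choice(4, size=length, p=self.base_freqs) if length else out
        else:
            powers = 4 ** np.arange(m - 1, -1, -1)
            cum = np.cumsum(self.probs, axis=1)
            u = rng.random(length)
            for i in range(m, length):
                ctx = int(out[i - m:i] @ powers)
                out[i] = np.searchsorted(cum[ctx], u[i], side="right")
        return decode(out.clip(0, 3))


# ----------------------------------------------------------------------
# I/O and derivation operations
# ----------------------------------------------------------------------


def read_genome(path: str | Path) -> Genome:
    """Load the first record of a FASTA file as a :class:`Genome`.

    Lowercase is normalized to uppercase; any character outside ACGTN is
    mapped to N with a warning.  Multiple records trigger a warning and the
    first is used.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        logger.warning("%s contains %d records; using the first (%s)",
                       path, len(records), records[0].id)
    rec = records[0]
    seq, n_replaced = clean_sequence(str(rec.seq))
    if n_replaced:
        logger.warning("%d non-ACGTN characters in %s mapped to N", n_replaced, rec.id)
    return Genome(id=rec.id, sequence=seq)


def write_genome(genome: Genome, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(path), "fasta")


def read_annotation(path: str | Path, genome: Genome) -> list[Gene]:
    """Parse CDS (or, failing that, gene) features from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Features must carry a ``locus_tag`` attribute; duplicates or features
    outside the genome are input errors.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    features = list(db.features_of_type("CDS"))
    if not features:
        features = list(db.features_of_type("gene"))
    genes: list[Gene] = []
    seen: set[str] = set()
    for feat in features:
        tags = feat.attributes.get("locus_tag")
        if not tags:
            continue
        tag = tags[0]
        if tag in seen:
            raise ValueError(f"duplicate locus_tag {tag!r} in {path}")
        seen.add(tag)
        start, end = feat.start - 1, feat.end
        if start < 0 or end > genome.length:
            raise ValueError(
                f"feature {tag!r} [{feat.start},{feat.end}] exceeds genome bounds "
                f"(length {genome.length})")
        product = (feat.attributes.get("product") or [""])[0]
        genes.append(Gene(tag, start, end, feat.strand, product))
    genes.sort(key=lambda g: (g.start, g.end))
    return genes


def write_annotation(genes: Sequence[Gene], genome: Genome, path: str | Path) -> None:
    """Write genes as GFF3 CDS features (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for g in sorted(genes, key=lambda g: g.start):
            attrs = f"ID=cds-{g.locus_tag};locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(f"{genome.id}\tdapregulon\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t0\t{attrs}\n")


def infer_operons(genes: Sequence[Gene], max_gap: int = DEFAULT_OPERON_GAP) -> list[Operon]:
    """Merge consecutive same-strand genes with intergenic gap <= max_gap.

    Genes must be sorted by start.  Every gene ends up in exactly one operon;
    a strand switch or a gap larger than ``max_gap`` starts a new operon.
    """
    operons: list[Operon] = []
    block: list[Gene] = []

    def _close(block: list[Gene]) -> None:
        if not block:
            return
        strand = block[0].strand
        ordered = block if strand == "+" else block[::-1]
        operons.append(Operon(id=ordered[0].locus_tag, genes=ordered, strand=strand))

    for g in genes:
        if block and (g.strand != block[-1].strand or g.start - block[-1].end > max_gap):
            _close(block)
            block = []
        block.append(g)
    _close(block)
    return operons


def extract_noncoding_regions(
    genome: Genome,
    operons: Sequence[Operon],
    upstream: int = UPSTREAM_EXTENT,
    cds_overhang: int = CDS_OVERHANG,
    include_internal: bool = False,
) -> list[NoncodingRegion]:
    """One regulatory window per operon head gene (or per gene if requested).

    The window spans ``min(upstream, distance to the nearest neighboring gene
    boundary)`` bases upstream of the head gene's translational start through
    ``cds_overhang`` bases into its CDS, strand-aware.  Windows never extend
    into a neighboring CDS.
    """
    all_genes = [g for op in operons for g in op.genes]
    starts = np.array(sorted(g.start for g in all_genes))
    ends = np.array(sorted(g.end for g in all_genes))
    # prefix max of end over genes sorted by start, for upstream-boundary lookup
    by_start = sorted(all_genes, key=lambda g: g.start)
    prefix_max_end = np.maximum.accumulate([g.end for g in by_start]) if all_genes else np.array([])
    start_arr = np.array([g.start for g in by_start])
    by_end = sorted(all_genes, key=lambda g: g.end)
    suffix_min_start = (np.minimum.accumulate([g.start for g in by_end][::-1])[::-1]
                        if all_genes else np.array([]))
    end_arr = np.array([g.end for g in by_end])

    def upstream_bound_plus(tss: int) -> int:
        # max over genes with start < tss of min(end, tss); 0 if none
        i = np.searchsorted(start_arr, tss, side="left")
        if i == 0:
            return 0
        return int(min(tss, prefix_max_end[i - 1]))

    def upstream_bound_minus(tss: int) -> int:
        # min over genes with end > tss of max(start, tss); genome length if none
        i = np.searchsorted(end_arr, tss, side="right")
        if i == len(end_arr):
            return genome.length
        return int(max(tss, suffix_min_start[i]))

    regions: list[NoncodingRegion] = []
    for op in operons:
        heads = op.genes if include_internal else [op.head]
        for head in heads:
            ov = min(cds_overhang, head.length)
            if ov < cds_overhang:
                logger.warning("gene %s shorter than %d bp; CDS overhang truncated to %d",
                               head.locus_tag, cds_overhang, ov)
            if op.strand == "+":
                tss = head.start
                bound = upstream_bound_plus(tss)
                start = max(tss - upstream, bound)
                end = tss + ov
                extent = tss - start
            else:
                tss = head.end
                bound = upstream_bound_minus(tss)
                end = min(tss + upstream, bound)
                start = tss - ov
                extent = end - tss
            if end <= start:
                continue
            regions.append(NoncodingRegion(start=start, end=end, strand=op.strand,
                                           downstream_operons=(op.id,),
                                           upstream_extent=extent, cds_overhang=ov))
    regions.sort(key=lambda r: (r.start, r.end))
    return regions


def fit_markov_background(genome: Genome, order: int,
                          pseudocount: float = 1.0) -> MarkovBackground:
    """Fit an order-``m`` Markov background from both strands of the genome."""
    if order < 0:
        raise ValueError("order must be >= 0")
    if order > 5:
        raise ValueError("order > 5 not supported")
    if genome.length <= 4 ** (order + 1):
        logger.warning("genome length %d is small for order %d; estimates will be noisy",
                       genome.length, order)
    return MarkovBackground.fit(genome.sequence, order, pseudocount=pseudocount)


def regions_to_bed(regions: Iterable[NoncodingRegion], genome: Genome,
                   path: str | Path) -> None:
    """Write regulatory windows as BED6 (name = comma-joined downstream operon ids)."""
    with open(path, "w") as fh:
        for r in regions:
            name = ",".join(r.downstream_operons)
            fh.write(f"{genome.id}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")
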