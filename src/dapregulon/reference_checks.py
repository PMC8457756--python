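"""Worked-example checks against a locally available reference genome.

These checks verify printed sequence facts on the *C. thermocellum* DSM 1313
chromosome (RefSeq NC_017304) when a local FASTA copy is supplied: the
TetR-bound perfect palindrome occurs exactly once; the two-word BlaI motif
has four instances upstream of its own operon; and the antitoxin operator
consensus has exactly two exact non-coding instances.  The genome itself is
not bundled (it is several megabases); callers pass a path to it.
"""

from __future__ import annotations

from pathlib import Path

from .genome import (Genome, extract_noncoding_regions, infer_operons,
                     read_annotation, read_genome)
from .scanning import scan_degenerate_word

TETR_PALINDROME = "TGACCACGTGGTCA"
BLAI_WORDS = ("ATAGTCC", "ATAGTCT")
ANTITOXIN_CONSENSUS = "TACATCNNNNNNGATGTA"


def count_palindrome(genome: Genome, word: str = TETR_PALINDROME) -> int:
    """Duplex occurrences of a self-reverse-complementary word in the genome."""
    return len(scan_degenerate_word(word, genome.sequence, max_mismatch=0))


def count_words_upstream(genome: Genome, regions, operon_id: str,
                         words=BLAI_WORDS) -> int:
    """Total occurrences of the given words (both strands) in the regulatory
    window(s) of one operon."""
    total = 0
    for region in regions:
        if operon_id not in region.downstream_operons:
            continue
        seq = genome.sequence[region.start:region.end]
        for word in words:
            total += len(scan_degenerate_word(word, seq, max_mismatch=0))
    return total


def noncoding_consensus_hits(genome: Genome, regions,
                             pattern: str = ANTITOXIN_CONSENSUS) -> list:
    """Exact matches of a degenerate consensus inside regulatory windows,
    deduplicated across overlapping windows."""
    seen = {}
    for region in regions:
        seq = genome.sequence[region.start:region.end]
        for site in scan_degenerate_word(pattern, seq, max_mismatch=0,
                                         genome_offset=region.start):
            site.operons = tuple(region.downstream_operons)
            prev = seen.get((site.location, site.strand))
            if prev is None:
                seen[(site.location, site.strand)] = site
            else:
                prev.operons = tuple(sorted(set(prev.operons) | set(site.operons)))
    return sorted(seen.values(), key=lambda s: s.location)


def run_reference_checks(fasta_path: str | Path,
                         gff_path: str | Path | None = None) -> dict:
    """Run all reference checks; the annotation-dependent ones need the GFF3."""
    genome = read_genome(fasta_path)
    out = {"palindrome_occurrences": count_palindrome(genome)}
    if gff_path is not None:
        genes = read_annotation(gff_path, genome)
        operons = infer_operons(genes)
        regions = extract_noncoding_regions(genome, operons)
        out["blai_word_instances_upstream_1845"] = count_words_upstream(
            genome, regions, operon_id="Clo1313_1845")
        hits = noncoding_consensus_hits(genome, regions)
        out["antitoxin_consensus_noncoding_hits"] = len(hits)
        out["antitoxin_hit_operons"] = sorted(
            {op for h in hits for op in h.operons})
    return out
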