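"""Regulon assembly: combine peaks and scanned sites into TF -> operon edges.

The evidence rules mirror regulon-reconstruction practice for in-vitro
binding screens: a peak only counts when its apex lies in a candidate
regulatory (non-coding) window AND its sequence contains a significant motif
match; genome-scan sites contribute independently; a scan site that falls
inside a retained peak window is attributed to the peak-derived evidence
column rather than double-counted.  Targets are whole operons, expanded to
every member gene, with divergent shared windows yielding two targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome, NoncodingRegion, Operon
from .peaks import Peak, PeakSequence
from .scanning import BindingSite, scan_degenerate_word

logger = logging.getLogger(__name__)

EVIDENCE_FLAGS = ("peak", "peak_site", "genome_site", "degenerate_site", "conserved")

#: degenerate recognition word used by the word-rule fallback (self-reverse-complementary)
GLYR2_PATTERN = "GTAANNTTAC"


@dataclass
class Evidence:
    """Evidence flags plus the supporting peak ids and site records for one edge."""

    flags: set[str] = field(default_factory=set)
    peak_ids: list[str] = field(default_factory=list)
    sites: list[BindingSite] = field(default_factory=list)

    def validate(self) -> None:
        if not self.flags:
            raise ValueError("every edge must carry at least one evidence flag")
        if "peak_site" in self.flags and "peak" not in self.flags:
            raise ValueError("peak_site evidence implies peak evidence")
        unknown = self.flags - set(EVIDENCE_FLAGS)
        if unknown:
            raise ValueError(f"unknown evidence flags: {unknown}")


@dataclass
class RegulonEdge:
    tf: str
    target_operon: str
    target_genes: list[str]
    evidence: Evidence
    site_offsets: list[int] = field(default_factory=list)  # relative to operon start


@dataclass
class Regulon:
    tf: str
    edges: list[RegulonEdge]
    autoregulatory: bool = False

    @property
    def target_operons(self) -> list[str]:
        return [e.target_operon for e in self.edges]


def filter_peaks(peaks: list[Peak], sites_in_peaks: dict[str, list[BindingSite]],
                 regions: list[NoncodingRegion]) -> list[Peak]:
    """Retain peaks whose apex is in a non-coding window and whose peak window
    contains at least one qualifying motif match."""
    retained = []
    for p in peaks:
        in_region = any(p.apex in r for r in regions)
        has_site = bool(sites_in_peaks.get(p.name))
        if in_region and has_site:
            retained.append(p)
    return retained


def assign_targets(position: int, regions: list[NoncodingRegion]) -> list[str]:
    """Downstream operon ids of every regulatory window containing a position.

    A position in the shared stretch of a divergent pair lies in both windows
    and therefore yields both operons.  Outside every window, an empty list.
    """
    targets: list[str] = []
    for r in regions:
        if position in r:
            for op in r.downstream_operons:
                if op not in targets:
                    targets.append(op)
    if not targets:
        logger.warning("position %d falls in no regulatory window", position)
    return targets


def _operon_start(op: Operon) -> int:
    """Transcription start coordinate of the operon (head gene 5' end)."""
    return op.head.start if op.strand == "+" else op.head.end


def assemble_regulon(
    tf: str,
    retained_peaks: list[Peak],
    sites_in_peaks: dict[str, list[BindingSite]],
    genome_sites: list[BindingSite],
    degenerate_sites: list[BindingSite],
    operons: list[Operon],
    regions: list[NoncodingRegion],
    peak_windows: dict[str, tuple[int, int]] | None = None,
    tf_operon: str | None = None,
) -> Regulon:
    """One edge per target operon with the union of evidence.

    ``peak_windows`` maps retained peak names to the genomic extent of their
    scanned sequence window; a genome-scan site inside a retained window is
    counted as peak-derived evidence (not double-counted).  ``tf_operon`` is
    the id of the TF's own operon, used to set the autoregulation flag.
    """
    op_by_id = {op.id: op for op in operons}
    edges: dict[str, RegulonEdge] = {}

    def edge_for(operon_id: str) -> RegulonEdge:
        if operon_id not in edges:
            op = op_by_id[operon_id]
            edges[operon_id] = RegulonEdge(tf=tf, target_operon=operon_id,
                                           target_genes=op.locus_tags,
                                           evidence=Evidence())
        return edges[operon_id]

    peak_windows = peak_windows or {}

    for peak in retained_peaks:
        targets = assign_targets(peak.apex, regions)
        for t in targets:
            e = edge_for(t)
            e.evidence.flags |= {"peak", "peak_site"}
            e.evidence.peak_ids.append(peak.name)
            for site in sites_in_peaks.get(peak.name, []):
                e.evidence.sites.append(site)
                op = op_by_id[t]
                e.site_offsets.append(site.location - _operon_start(op))

    def _inside_retained_peak(site: BindingSite) -> bool:
        for name, (lo, hi) in peak_windows.items():
            if lo <= site.location < hi:
                return True
        return False

    for site in genome_sites:
        if _inside_retained_peak(site):
            continue  # already attributed to the peak-derived evidence column
        targets = site.operons or tuple(assign_targets(site.location, regions))
        for t in targets:
            e = edge_for(t)
            e.evidence.flags.add("genome_site")
            e.evidence.sites.append(site)
            e.site_offsets.append(site.location - _operon_start(op_by_id[t]))

    for site in degenerate_sites:
        targets = site.operons or tuple(assign_targets(site.location, regions))
        for t in targets:
            e = edge_for(t)
            e.evidence.flags.add("degenerate_site")
            e.evidence.sites.append(site)
            e.site_offsets.append(site.location - _operon_start(op_by_id[t]))

    for e in edges.values():
        e.evidence.validate()
    edge_list = [edges[k] for k in sorted(edges)]
    auto = tf_operon is not None and tf_operon in edges
    return Regulon(tf=tf, edges=edge_list, autoregulatory=auto)


def evidence_counts(regulon: Regulon) -> dict[str, int]:
    """Site accounting per evidence source, counting each site once.

    Peak-derived and scan-only sites are disjoint: a scan site inside a
    retained peak was already folded into the peak-derived column during
    assembly.
    """
    by_peak = 0
    by_scan = 0
    by_word = 0
    for e in regulon.edges:
        for s in e.evidence.sites:
            if s.source == "peak_scan":
                by_peak += 1
            elif s.source == "genome_scan":
                by_scan += 1
            elif s.source == "degenerate_word":
                by_word += 1
    return {"by_dapseq": by_peak, "by_motif_scanning": by_scan,
            "by_degenerate_word": by_word,
            "total": by_peak + by_scan + by_word}


def glyr2_rule(genome: Genome, regions: list[NoncodingRegion],
               retained_peaks: list[Peak],
               pattern: str = GLYR2_PATTERN,
               peak_window_width: int = 500) -> list[BindingSite]:
    """Word-rule site search for a TF whose PSSM fails to capture known targets.

    Exact instances of the (self-reverse-complementary) pattern anywhere in a
    non-coding window are included; one-mismatch instances are included only
    when they fall inside a retained peak window that intersects a non-coding
    window.  The union is deduplicated by position.
    """
    found: dict[tuple[int, str], BindingSite] = {}
    for region in regions:
        seq = genome.sequence[region.start:region.end]
        for site in scan_degenerate_word(pattern, seq, max_mismatch=0,
                                         genome_offset=region.start):
            site.operons = tuple(region.downstream_operons)
            site.region_id = ",".join(region.downstream_operons)
            key = (site.location, site.strand)
            if key in found:
                found[key].operons = tuple(sorted(set(found[key].operons) | set(site.operons)))
            else:
                found[key] = site

    half = peak_window_width // 2
    for peak in retained_peaks:
        lo = max(0, peak.apex - half)
        hi = min(genome.length, peak.apex + peak_window_width - half)
        intersecting = [r for r in regions if r.start < hi and lo < r.end]
        if not intersecting:
            continue
        seq = genome.sequence[lo:hi]
        for site in scan_degenerate_word(pattern, seq, max_mismatch=1,
                                         genome_offset=lo):
            containing = [r for r in regions if site.location in r]
            if not containing:
                continue
            ops = tuple(sorted({o for r in containing for o in r.downstream_operons}))
            key = (site.location, site.strand)
            if key not in found:
                site.operons = ops
                found[key] = site
    return sorted(found.values(), key=lambda s: (s.location, s.strand))


@dataclass
class ArchitectureReport:
    """Binding-site geometry within one regulatory window."""

    count: int
    spacings: list[int]
    strand_pattern: str
    paired_clusters: int = 0
    dimer_of_dimers: bool = False


def site_architecture(sites: list[BindingSite],
                      spacing_tolerance: int = 3) -> ArchitectureReport:
    """Count, inter-site spacings, and strand pattern of co-located sites.

    Flags the 'two pairs of inverted repeats' geometry: four or more sites
    whose spacing vector alternates short-long-short with the two short
    spacings equal within ``spacing_tolerance`` bp.
    """
    if not sites:
        return ArchitectureReport(0, [], "")
    ordered = sorted(sites, key=lambda s: s.location)
    spacings = [b.location - a.location for a, b in zip(ordered, ordered[1:])]
    strands = "".join(s.strand for s in ordered)
    paired = 0
    i = 0
    while i < len(spacings):
        # a pair = two adjacent sites closer to each other than to their neighbors
        left_gap = spacings[i - 1] if i > 0 else np.inf
        right_gap = spacings[i + 1] if i + 1 < len(spacings) else np.inf
        if spacings[i] < min(left_gap, right_gap):
            paired += 1
            i += 2
        else:
            i += 1
    dimer = False
    if len(ordered) >= 4:
        for j in range(len(spacings) - 2):
            s1, gap, s2 = spacings[j], spacings[j + 1], spacings[j + 2]
            if abs(s1 - s2) <= spacing_tolerance and gap > max(s1, s2):
                dimer = True
                break
    return ArchitectureReport(count=len(ordered), spacings=spacings,
                              strand_pattern=strands, paired_clusters=paired,
                              dimer_of_dimers=dimer)


def regulon_to_table(regulon: Regulon) -> pd.DataFrame:
    """Deterministic TSV-ready table of a regulon (one row per edge)."""
    rows = []
    for e in regulon.edges:
        rows.append({
            "tf": e.tf,
            "operon": e.target_operon,
            "genes": ",".join(e.target_genes),
            "evidence": ",".join(sorted(e.evidence.flags)),
            "peaks": ",".join(sorted(set(e.evidence.peak_ids))),
            "site_offsets": ",".join(str(o) for o in sorted(e.site_offsets)),
            "site_p_values": ",".join(
                f"{s.p_value:.3g}" if s.p_value is not None else "NA"
                for s in e.evidence.sites),
        })
    return pd.DataFrame(rows)
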