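"""End-to-end regulon reconstruction from fragment libraries.

Chains the pipeline stages: coverage -> peak calling -> apex windows ->
near-duplicate purge -> motif discovery -> peak/genome scanning -> evidence
filtering -> regulon assembly.  Used both on real fragment BED input and on
synthetic datasets with planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome import (Genome, MarkovBackground, NoncodingRegion, Operon,
                     fit_markov_background)
from .motifs import PSSM, discover_motif
from .peaks import (CoverageTrack, Peak, PeakSequence, call_peaks,
                    coverage_from_fragments, peak_sequences, purge_similar)
from .regulon import Regulon, assemble_regulon, filter_peaks
from .scanning import (BindingSite, ScanThresholds, scan_regions,
                       scan_sequence, score_distribution)
from .simulate import SimulationConfig, SyntheticDataset, simulate_dataset


@dataclass
class ReconstructionResult:
    """All intermediates of one TF's regulon reconstruction."""

    tf: str
    peaks: list[Peak]
    peak_seqs: list[PeakSequence]
    pssm: PSSM
    sites_in_peaks: dict[str, list[BindingSite]]
    retained_peaks: list[Peak]
    genome_sites: list[BindingSite]
    regulon: Regulon
    background: MarkovBackground
    peak_windows: dict[str, tuple[int, int]] = field(default_factory=dict)


def reconstruct_regulon(
    genome: Genome,
    operons: list[Operon],
    regions: list[NoncodingRegion],
    tf_track: CoverageTrack,
    control_track: CoverageTrack,
    tf_name: str,
    thresholds: ScanThresholds | None = None,
    background: MarkovBackground | None = None,
    background_order: int = 2,
    peak_window_width: int = 500,
    discovery_seed: int = 0,
    compute_evalue: bool = False,
    tf_operon: str | None = None,
) -> ReconstructionResult:
    """Run the full reconstruction for one TF sample against its control."""
    thresholds = thresholds or ScanThresholds()
    if background is None:
        background = fit_markov_background(genome, background_order)
    peaks = call_peaks(tf_track, control_track)
    if not peaks:
        raise ValueError(f"no peaks called for {tf_name}; cannot learn a motif")
    pseqs = peak_sequences(peaks, genome, width=peak_window_width)
    kept = purge_similar([p.sequence for p in pseqs])
    pssm = discover_motif(kept, background, seed=discovery_seed,
                          compute_evalue=compute_evalue)
    pssm.name = tf_name

    dist = score_distribution(pssm, background)
    sites_in_peaks = {
        p.name: scan_sequence(pssm, ps.sequence, background, thresholds.p_peak,
                              dist=dist, source="peak_scan", region_id=p.name,
                              genome_offset=ps.start)
        for p, ps in zip(peaks, pseqs)
    }
    retained = filter_peaks(peaks, sites_in_peaks, regions)
    half = peak_window_width // 2
    peak_windows = {p.name: (max(0, p.apex - half),
                             min(genome.length, p.apex + peak_window_width - half))
                    for p in retained}
    genome_sites = scan_regions(pssm, regions, genome, background, thresholds,
                                tf=tf_name if thresholds.overrides else None)
    regulon = assemble_regulon(tf_name, retained, sites_in_peaks, genome_sites,
                               [], operons, regions, peak_windows=peak_windows,
                               tf_operon=tf_operon)
    return ReconstructionResult(tf=tf_name, peaks=peaks, peak_seqs=pseqs,
                                pssm=pssm, sites_in_peaks=sites_in_peaks,
                                retained_peaks=retained,
                                genome_sites=genome_sites, regulon=regulon,
                                background=background,
                                peak_windows=peak_windows)


def run_synthetic_study(
    config: SimulationConfig | None = None,
    **reconstruct_kwargs,
) -> tuple[SyntheticDataset, ReconstructionResult]:
    """Simulate a planted study and reconstruct the TF's regulon from it."""
    dataset = simulate_dataset(config)
    tf_track = coverage_from_fragments(dataset.tf_fragments, dataset.genome,
                                       sample_id=dataset.config.tf_name)
    control_track = coverage_from_fragments(dataset.control_fragments,
                                            dataset.genome, sample_id="control")
    result = reconstruct_regulon(dataset.genome, dataset.operons,
                                 dataset.regions, tf_track, control_track,
                                 tf_name=dataset.config.tf_name,
                                 **reconstruct_kwargs)
    return dataset, result
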