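"""DAP-seq fragment coverage and enrichment peak calling.

Coverage is built per base from fragment intervals (BED).  Peaks are runs of
bases whose smoothed, library-size-scaled fold enrichment over the negative
control passes a threshold; each run is tested with a Poisson upper-tail
test of the TF fragment count in the run against a conservative local
expectation from the control, and Benjamini-Hochberg correction across runs
gives the Q-value.  Duplicate fragments are retained by default, matching
the screening convention this pipeline models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .genome import Genome

logger = logging.getLogger(__name__)

DEFAULT_MIN_FOLD = 1.0      # enrichment threshold relative to scaled control
DEFAULT_SMOOTHING = 50      # bp moving average for depth smoothing
DEFAULT_MERGE_GAP = 100     # bp between candidate runs merged into one peak
DEFAULT_FDR = 0.05
PSEUDO_DEPTH = 1.0          # alpha added to depths/counts
CONTROL_WINDOW = 1000       # bp window for the control local rate


@dataclass
class CoverageTrack:
    """Per-base fragment coverage for one sample.

    ``depth[i]`` counts fragments overlapping base i; ``starts[i]`` counts
    fragments starting at i (used for count-level peak testing).
    """

    sample_id: str
    depth: np.ndarray
    starts: np.ndarray
    n_fragments: int

    @property
    def length(self) -> int:
        return len(self.depth)


@dataclass
class Peak:
    """An enriched interval with its apex, fold change and BH Q-value."""

    start: int
    end: int
    apex: int
    fold_change: float
    q_value: float
    p_value: float
    sample_id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.apex < self.end):
            raise ValueError("apex must lie inside the peak interval")


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a fragment BED file (chrom, start, end[, ...])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return df


def coverage_from_fragments(path: str | Path | pd.DataFrame, genome: Genome,
                            deduplicate: bool = False,
                            sample_id: str | None = None) -> CoverageTrack:
    """Per-base depth from fragment intervals.

    Duplicates are retained unless ``deduplicate`` is set (retaining them is
    the default operating convention).  Intervals outside the genome are an
    input error; an empty file yields an all-zero track with a warning.
    """
    if isinstance(path, pd.DataFrame):
        df = path
        sample_id = sample_id or "fragments"
    else:
        df = read_fragments(path)
        sample_id = sample_id or Path(path).stem
    if len(df) == 0:
        logger.warning("sample %s has zero fragments", sample_id)
        z = np.zeros(genome.length, dtype=np.int64)
        return CoverageTrack(sample_id, z, z.copy(), 0)
    if deduplicate:
        df = df.drop_duplicates(subset=["start", "end"])
    starts = df["start"].to_numpy(dtype=np.int64)
    ends = df["end"].to_numpy(dtype=np.int64)
    if (starts < 0).any() or (ends > genome.length).any() or (starts >= ends).any():
        bad = df[(starts < 0) | (ends > genome.length) | (starts >= ends)].iloc[0]
        raise ValueError(f"fragment [{bad.start},{bad.end}) out of bounds for "
                         f"genome of length {genome.length}")
    diff = np.zeros(genome.length + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    depth = np.cumsum(diff[:-1])
    start_track = np.zeros(genome.length, dtype=np.int64)
    np.add.at(start_track, starts, 1)
    return CoverageTrack(sample_id, depth, start_track, len(df))


def call_peaks(tf: CoverageTrack, control: CoverageTrack,
               min_fold: float = DEFAULT_MIN_FOLD,
               smoothing_window: int = DEFAULT_SMOOTHING,
               merge_gap: int = DEFAULT_MERGE_GAP,
               fdr: float = DEFAULT_FDR,
               alpha: float = PSEUDO_DEPTH,
               control_window: int = CONTROL_WINDOW) -> list[Peak]:
    """Call enrichment peaks of the TF track over the scaled control.

    fold(i) = (smoothed tf depth + alpha) / (s * smoothed control depth + alpha)
    with library-size scale s = tf.n_fragments / control.n_fragments.
    Candidate bases with fold >= min_fold are merged into runs (gap <=
    merge_gap).  Each run's TF fragment count X is compared to the control
    count C by the exact conditional test of two Poisson rates: given
    X + C fragments, X ~ Binomial with success probability
    n_tf / (n_tf + n_ctrl) under the null.  Unlike a fixed-lambda Poisson
    test this accounts for the control's own sampling noise, so two
    independent same-rate libraries stay null.  C takes the larger of the
    in-run control count and the windowed local rate (conservative; peak
    calling on identical tracks can never reach significance).  Runs passing
    Benjamini-Hochberg at ``fdr`` are returned sorted by fold change,
    descending.
    """
    if min_fold < 0:
        raise ValueError("min_fold must be >= 0")
    if control.n_fragments == 0:
        raise ValueError("control track has zero fragments")
    if tf.length != control.length:
        raise ValueError("tracks must cover the same genome")
    s = tf.n_fragments / control.n_fragments
    sm_tf = uniform_filter1d(tf.depth.astype(float), smoothing_window, mode="nearest")
    sm_ctrl = uniform_filter1d(control.depth.astype(float), smoothing_window,
                               mode="nearest")
    fold = (sm_tf + alpha) / (s * sm_ctrl + alpha)

    candidate = fold >= min_fold
    if not candidate.any():
        return []
    # runs of candidate bases, merged across gaps <= merge_gap
    padded = np.concatenate([[0], candidate.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs: list[list[int]] = []
    for a, b in zip(starts, ends):
        if runs and a - runs[-1][1] <= merge_gap:
            runs[-1][1] = b
        else:
            runs.append([a, b])

    ctrl_rate = uniform_filter1d(control.starts.astype(float), control_window,
                                 mode="nearest")
    cum_tf = np.concatenate([[0], np.cumsum(tf.starts)])
    cum_ctrl = np.concatenate([[0], np.cumsum(control.starts)])
    cum_rate = np.concatenate([[0], np.cumsum(ctrl_rate)])

    pi = tf.n_fragments / (tf.n_fragments + control.n_fragments)
    peaks: list[Peak] = []
    pvals: list[float] = []
    for a, b in runs:
        x = int(cum_tf[b] - cum_tf[a])
        ctrl_count = cum_ctrl[b] - cum_ctrl[a]
        rate_count = cum_rate[b] - cum_rate[a]
        c_eff = max(ctrl_count, rate_count) + alpha
        total = int(round(x + c_eff))
        p = float(binom.sf(x - 1, total, pi))
        apex = a + int(np.argmax(fold[a:b]))
        peaks.append(Peak(start=a, end=b, apex=apex, fold_change=float(fold[apex]),
                          q_value=1.0, p_value=p, sample_id=tf.sample_id))
        pvals.append(p)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    kept = []
    for peak, q in zip(peaks, qvals):
        peak.q_value = float(q)
        if q <= fdr:
            kept.append(peak)
    kept.sort(key=lambda p: -p.fold_change)
    for i, p in enumerate(kept, start=1):
        p.name = f"{p.sample_id}_peak_{i}"
    return kept


@dataclass
class PeakSequence:
    """A width-window of genome sequence centered on a peak apex."""

    peak_id: str
    sequence: str
    start: int
    apex_offset: int
    fold_change: float = 0.0


def peak_sequences(peaks: list[Peak], genome: Genome,
                   width: int = 500) -> list[PeakSequence]:
    """Width-windows centered on each peak apex, clipped at genome ends."""
    if width <= 0:
        raise ValueError("width must be > 0")
    half = width // 2
    out = []
    for p in peaks:
        lo = max(0, p.apex - half)
        hi = min(genome.length, p.apex + width - half)
        out.append(PeakSequence(peak_id=p.name or f"peak@{p.apex}",
                                sequence=genome.sequence[lo:hi], start=lo,
                                apex_offset=p.apex - lo, fold_change=p.fold_change))
    return out


def purge_similar(sequences: list[str], max_identity: float = 0.8,
                  min_overlap: int = 100) -> list[str]:
    """Greedy near-duplicate removal, in input order.

    A sequence is dropped when its best ungapped alignment against any
    retained sequence (either strand, any offset) reaches ``max_identity``
    over a window of at least ``min_overlap`` bases.  This removes repeated
    peaks and transposon-scale repeats while keeping motif-scale similarity.
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    from ._seq import encode, revcomp

    retained: list[str] = []
    retained_codes: list[tuple[np.ndarray, np.ndarray]] = []
    for seq in sequences:
        a = encode(seq)
        drop = False
        for b_f, b_r in retained_codes:
            if _max_window_identity(a, b_f, min_overlap) > max_identity or \
               _max_window_identity(a, b_r, min_overlap) > max_identity:
                drop = True
                break
        if not drop:
            retained.append(seq)
            retained_codes.append((a, encode(revcomp(seq))))
    return retained


def _max_window_identity(a: np.ndarray, b: np.ndarray, min_overlap: int) -> float:
    """Best identity over any diagonal window of >= min_overlap bases."""
    la, lb = len(a), len(b)
    win = min(min_overlap, la, lb)
    best = 0.0
    for shift in range(-(lb - win), la - win + 1):
        lo_a = max(0, shift)
        hi_a = min(la, shift + lb)
        seg_a = a[lo_a:hi_a]
        seg_b = b[lo_a - shift:hi_a - shift]
        m = (seg_a == seg_b).astype(float)
        n = len(m)
        if n < win:
            continue
        # identity over the full overlap and over every exact-length window
        best = max(best, float(m.mean()))
        if n > win:
            c = np.concatenate([[0.0], np.cumsum(m)])
            wins = (c[win:] - c[:-win]) / win
            best = max(best, float(wins.max()))
        if best >= 1.0:
            break
    return best


def coverage_to_bedgraph(track: CoverageTrack, genome: Genome, path: str | Path) -> None:
    """Write a coverage track as bedGraph (runs of equal depth)."""
    depth = track.depth
    change = np.flatnonzero(np.diff(depth)) + 1
    bounds = np.concatenate([[0], change, [len(depth)]])
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={track.sample_id}\n")
        for a, b in zip(bounds[:-1], bounds[1:]):
            fh.write(f"{genome.id}\t{a}\t{b}\t{int(depth[a])}\n")


def peaks_to_bed(peaks: list[Peak], genome: Genome, path: str | Path) -> None:
    """Write peaks as BED6 plus a q_value column."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{genome.id}\t{p.start}\t{p.end}\t{p.name}\t"
                     f"{p.fold_change:.4f}\t.\t{p.q_value:.6g}\n")


def peaks_to_table(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame([{
        "start": p.start, "end": p.end, "apex": p.apex,
        "fold_change": p.fold_change, "p_value": p.p_value,
        "q_value": p.q_value, "sample_id": p.sample_id, "name": p.name,
    } for p in peaks])
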