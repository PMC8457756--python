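"""PSSM scanning with exact match p-values under a Markov background.

A word's score is the log2 likelihood ratio of the motif column frequencies
over the background.  The match p-value is the probability that a random
background word scores at least as high, computed exactly by dynamic
programming over the column score distribution (for narrow motifs the DP
support is enumerated exactly; for wide motifs column scores are discretized
on an epsilon-bit grid).  Scanning covers both strands; windows containing N
are skipped.

For backgrounds of order m > 0 the score denominator uses the sequence
context at each scanned position, while p-values are computed under the
order-0 marginal composition — a documented, conservative approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import N_CODE, encode, revcomp
from .genome import Genome, MarkovBackground, NoncodingRegion
from .motifs import PSSM

logger = logging.getLogger(__name__)

#: DP discretization step in bits for wide motifs
EPSILON_BITS = 1e-4
#: widths up to this are handled by the exact (ungridded) DP
MAX_EXACT_WIDTH = 9


@dataclass
class BindingSite:
    """A located motif match.

    ``location`` is the 0-based start of the match on the forward strand of
    the coordinate system it was found in (genomic after region lifting).
    ``source`` is one of peak_scan | genome_scan | degenerate_word.
    """

    location: int
    strand: str
    width: int
    score: float
    p_value: float | None
    matched_word: str
    source: str
    region_id: str = ""
    operons: tuple[str, ...] = ()

    @property
    def end(self) -> int:
        return self.location + self.width


@dataclass
class ScanThresholds:
    """Scan p-value thresholds with optional per-TF overrides.

    Defaults follow the two-tier convention: a permissive threshold for peak
    sequences (1e-4) and a stricter genome-wide threshold (1e-5), with
    per-PSSM overrides (e.g. a 2e-4 cutoff for a two-word motif whose top
    score has exact p between 1e-4 and 2e-4).
    """

    p_peak: float = 1e-4
    p_genome: float = 1e-5
    overrides: dict[str, float] = field(default_factory=dict)
    probe_negative_max_p: float = 1e-3

    def __post_init__(self) -> None:
        for v in (self.p_peak, self.p_genome, self.probe_negative_max_p,
                  *self.overrides.values()):
            if not (0 < v < 1):
                raise ValueError("all thresholds must lie in (0,1)")

    def genome_threshold(self, tf: str | None) -> float:
        if tf is None:
            return self.p_genome
        if tf in self.overrides:
            return self.overrides[tf]
        if self.overrides:
            logger.warning("no threshold override for TF %r; using default %g",
                           tf, self.p_genome)
        return self.p_genome

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScanThresholds":
        import yaml

        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(p_peak=cfg.get("p_peak", 1e-4),
                   p_genome=cfg.get("p_genome", 1e-5),
                   overrides=dict(cfg.get("overrides", {})),
                   probe_negative_max_p=cfg.get("probe_negative_max_p", 1e-3))


class ScoreDistribution:
    """Exact null distribution of PSSM word scores under an order-0 background.

    Holds the sorted support and upper-tail (survival) probabilities;
    ``pvalue(s)`` returns P(score >= s) with a small tolerance so that a word
    score computed by summing the same column scores maps onto its own atom.
    """

    def __init__(self, scores: np.ndarray, survival: np.ndarray, scale: float = 1.0):
        self.scores = scores        # ascending, finite support (in bits)
        self.survival = survival    # P(S >= scores[i]) including -inf mass below
        self.scale = scale

    def pvalue(self, score: float) -> float:
        return float(self.pvalues(np.array([score]))[0])

    def pvalues(self, scores: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.scores, np.asarray(scores) - 1e-9, side="left")
        idx = np.minimum(idx, len(self.scores) - 1)
        out = self.survival[idx]
        # a query above the maximum attainable score has zero tail mass;
        # report the top atom's mass to keep p in (0,1]
        return out

    @property
    def min_score(self) -> float:
        return float(self.scores[0])

    @property
    def max_score(self) -> float:
        return float(self.scores[-1])


def score_distribution(pssm: PSSM, background: MarkovBackground,
                       epsilon: float = EPSILON_BITS,
                       max_exact_width: int = MAX_EXACT_WIDTH) -> ScoreDistribution:
    """Null score distribution of the PSSM under the background's order-0 marginal."""
    lom = pssm.log_odds(background)
    b0 = background.base_freqs
    w = pssm.width
    if w <= max_exact_width:
        dist: dict[float, float] = {0.0: 1.0}
        for i in range(w):
            new: dict[float, float] = {}
            col = lom[i]
            for s, p in dist.items():
                for x in range(4):
                    ns = s + col[x]
                    new[ns] = new.get(ns, 0.0) + p * b0[x]
            dist = new
        neg_mass = dist.pop(float("-inf"), 0.0)
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores])
        survival = np.cumsum(probs[::-1])[::-1]
        return ScoreDistribution(scores, survival)
    # grid DP: integer column scores at epsilon resolution
    finite = np.isfinite(lom)
    iq = np.where(finite, np.rint(lom / epsilon), 0).astype(np.int64)
    mins = np.where(finite, iq, np.iinfo(np.int64).max).min(axis=1)
    maxs = np.where(finite, iq, np.iinfo(np.int64).min).max(axis=1)
    total_min, total_max = int(mins.sum()), int(maxs.sum())
    probs = np.zeros(total_max - total_min + 1)
    offset = 0  # running minimum of partial sums
    cur = np.array([1.0])
    for i in range(w):
        lo, hi = int(mins[i]), int(maxs[i])
        new = np.zeros(len(cur) + hi - lo)
        for x in range(4):
            if not finite[i, x]:
                continue  # zero-frequency cell: its words score -inf
            shift = int(iq[i, x]) - lo
            new[shift:shift + len(cur)] += b0[x] * cur
        cur = new
        offset += lo
    probs[:len(cur)] = cur
    survival = np.cumsum(probs[::-1])[::-1]
    scores = (np.arange(total_min, total_max + 1)) * epsilon
    keep = probs > 0
    # keep full grid for robust searchsorted but drop leading/trailing zeros
    nz = np.nonzero(keep)[0]
    lo, hi = nz[0], nz[-1]
    return ScoreDistribution(scores[lo:hi + 1], survival[lo:hi + 1], scale=epsilon)


def score_word(pssm: PSSM, word: str, background: MarkovBackground,
               context: str = "") -> float:
    """Log2 likelihood-ratio score of one word (bits).

    For order-m backgrounds the denominator conditions on the preceding
    context; ``context`` supplies up to m bases preceding the word (the
    marginal composition is used where context is unavailable).  Words
    containing N score NaN.
    """
    if len(word) != pssm.width:
        raise ValueError(f"word length {len(word)} != PSSM width {pssm.width}")
    codes = encode(word)
    if (codes == N_CODE).any():
        return float("nan")
    f = pssm.frequencies(background)
    with np.errstate(divide="ignore"):
        num = np.log2(f[np.arange(pssm.width), codes]).sum()
    full = encode(context[-background.order:] + word) if background.order else codes
    logbg = background.position_log2(full)[-pssm.width:]
    return float(num - logbg.sum())


def score_pvalue(pssm: PSSM, background: MarkovBackground, score: float,
                 dist: ScoreDistribution | None = None) -> float:
    """Exact probability that a random background word scores >= ``score``."""
    if dist is None:
        dist = score_distribution(pssm, background)
    return dist.pvalue(score)


# ----------------------------------------------------------------------
# Scanning
# ----------------------------------------------------------------------


def _window_scores(codes: np.ndarray, pssm: PSSM,
                   background: MarkovBackground) -> np.ndarray:
    """Score of every window start on this strand; NaN where the window has N."""
    w = pssm.width
    L = len(codes)
    if L < w:
        return np.empty(0)
    f = pssm.frequencies(background)
    with np.errstate(divide="ignore"):
        log_f = np.log2(f)
    pos_bg = background.position_log2(codes)
    safe = codes.clip(0, 3)
    num = np.zeros(L - w + 1)
    for k in range(w):
        num += log_f[k, safe[k:L - w + 1 + k]]
    csum = np.concatenate([[0.0], np.cumsum(np.nan_to_num(pos_bg, nan=0.0))])
    den = csum[w:] - csum[:-w]
    has_n = np.convolve((codes == N_CODE).astype(float), np.ones(w), mode="valid") > 0
    out = num - den
    out[has_n] = np.nan
    return out


def scan_sequence(pssm: PSSM, sequence: str, background: MarkovBackground,
                  threshold_p: float, dist: ScoreDistribution | None = None,
                  source: str = "peak_scan", region_id: str = "",
                  genome_offset: int = 0) -> list[BindingSite]:
    """All positions x strands with match p < threshold_p.

    Overlapping sites are retained.  Sites are sorted by position, '+' before
    '-'.  ``genome_offset`` shifts reported locations into a parent
    coordinate system.
    """
    w = pssm.width
    if len(sequence) < w:
        return []
    if dist is None:
        dist = score_distribution(pssm, background)
    sites: list[BindingSite] = []
    codes_f = encode(sequence)
    codes_r = encode(revcomp(sequence))
    L = len(sequence)
    for strand, codes in (("+", codes_f), ("-", codes_r)):
        scores = _window_scores(codes, pssm, background)
        valid = np.isfinite(scores)
        pvals = np.full(len(scores), np.inf)
        pvals[valid] = dist.pvalues(scores[valid])
        for j in np.nonzero(pvals < threshold_p)[0]:
            start = int(j) if strand == "+" else L - int(j) - w
            word = sequence[start:start + w]
            if strand == "-":
                word = revcomp(word)
            sites.append(BindingSite(
                location=start + genome_offset, strand=strand, width=w,
                score=float(scores[j]), p_value=float(pvals[j]),
                matched_word=word, source=source, region_id=region_id))
    sites.sort(key=lambda s: (s.location, s.strand))
    return sites


def scan_regions(pssm: PSSM, regions: list[NoncodingRegion], genome: Genome,
                 background: MarkovBackground, thresholds: ScanThresholds,
                 tf: str | None = None) -> list[BindingSite]:
    """Scan every regulatory window at the genome-wide threshold (or TF override).

    Site locations are lifted to genomic coordinates.  A site falling in the
    shared stretch of two divergent windows is reported once, carrying both
    downstream operon ids.
    """
    threshold = thresholds.genome_threshold(tf)
    dist = score_distribution(pssm, background)
    merged: dict[tuple[int, str], BindingSite] = {}
    for region in regions:
        rid = ",".join(region.downstream_operons)
        seq = genome.sequence[region.start:region.end]
        for site in scan_sequence(pssm, seq, background, threshold, dist=dist,
                                  source="genome_scan", region_id=rid,
                                  genome_offset=region.start):
            key = (site.location, site.strand)
            if key in merged:
                prev = merged[key]
                prev.operons = tuple(sorted(set(prev.operons) | set(region.downstream_operons)))
                prev.region_id = ",".join(sorted({prev.region_id, rid}))
            else:
                site.operons = tuple(region.downstream_operons)
                merged[key] = site
    return sorted(merged.values(), key=lambda s: (s.location, s.strand))


def scan_degenerate_word(pattern: str, sequence: str, max_mismatch: int = 0,
                         genome_offset: int = 0) -> list[BindingSite]:
    """Find a degenerate word (IUPAC n = any base) with up to ``max_mismatch``
    mismatches at the non-n positions, on both strands.

    Self-reverse-complementary patterns match the same duplex windows on both
    strands, so each duplex occurrence is reported once (strand '+').
    p_value is unset for this evidence source.
    """
    pat = pattern.upper()
    if set(pat) - set("ACGTN"):
        raise ValueError("pattern must be over A,C,G,T,n")
    informative = [i for i, c in enumerate(pat) if c != "N"]
    if max_mismatch >= len(informative):
        raise ValueError("max_mismatch must be below the number of non-n positions")
    w = len(pat)
    if len(sequence) < w:
        return []
    self_rc = revcomp(pat) == pat
    codes = encode(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    pat_codes = encode(pat)

    def matches(pat_codes: np.ndarray) -> np.ndarray:
        idx = np.array([i for i, c in enumerate(pat_codes) if c != N_CODE])
        sub = windows[:, idx]
        # N in the sequence never matches a concrete pattern base
        mism = (sub != pat_codes[idx]).sum(axis=1)
        return np.nonzero(mism <= max_mismatch)[0]

    sites: list[BindingSite] = []
    for j in matches(pat_codes):
        sites.append(BindingSite(int(j) + genome_offset, "+", w, float("nan"), None,
                                 sequence[j:j + w], "degenerate_word"))
    if not self_rc:
        rc_codes = encode(revcomp(pat))
        for j in matches(rc_codes):
            sites.append(BindingSite(int(j) + genome_offset, "-", w, float("nan"), None,
                                     revcomp(sequence[j:j + w]), "degenerate_word"))
    sites.sort(key=lambda s: (s.location, s.strand))
    return sites


def calibrate_threshold_null(pssm: PSSM, regions: list[NoncodingRegion],
                             genome: Genome, background: MarkovBackground,
                             n_shuffles: int = 10, seed: int = 0,
                             thresholds: tuple[float, ...] = (1e-4, 1e-5, 1e-6),
                             mode: str = "motif") -> dict[float, dict]:
    """Empirical null site counts for threshold selection.

    ``mode='motif'`` permutes the PSSM columns (preserving per-column
    composition but destroying positional structure) before rescanning the
    regions; ``mode='sequence'`` instead shuffles each region's sequence.
    Returns per-threshold mean and 95th-percentile null counts.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if n_shuffles < 10:
        logger.warning("n_shuffles=%d is low for quantile estimates", n_shuffles)
    rng = np.random.default_rng(seed)
    counts: dict[float, list[int]] = {t: [] for t in thresholds}
    scan_ths = ScanThresholds(p_genome=min(thresholds))
    for _ in range(n_shuffles):
        if mode == "motif":
            perm = rng.permutation(pssm.width)
            null_pssm = PSSM(pssm.counts[perm], pseudocount=pssm.pseudocount)
            sites = scan_regions(null_pssm, regions, genome, background, scan_ths)
        elif mode == "sequence":
            dist = score_distribution(pssm, background)
            sites = []
            for region in regions:
                seq = list(genome.sequence[region.start:region.end])
                rng.shuffle(seq)
                sites.extend(scan_sequence(pssm, "".join(seq), background,
                                           min(thresholds), dist=dist))
        else:
            raise ValueError("mode must be 'motif' or 'sequence'")
        for t in thresholds:
            counts[t].append(sum(1 for s in sites if (s.p_value or 1.0) < t))
    return {t: {"mean": float(np.mean(v)), "q95": float(np.quantile(v, 0.95)),
                "counts": v} for t, v in counts.items()}


# ----------------------------------------------------------------------
# EMSA probe design
# ----------------------------------------------------------------------


def design_probes(pssm: PSSM, peak_sequences: list, background: MarkovBackground,
                  flank: int = 10,
                  thresholds: ScanThresholds | None = None) -> tuple[str, str]:
    """Positive and negative EMSA probes from peak sequences.

    The positive probe is the lowest-p-value site plus ``flank`` bases of its
    source-peak context on each side (ties: highest-fold peak, then leftmost
    site).  The negative probe is a same-length peak-context window with no
    motif match at p <= probe_negative_max_p.
    """
    thresholds = thresholds or ScanThresholds()
    dist = score_distribution(pssm, background)
    best = None  # (p, -fold, location, seq, site)
    entries = []
    for ps in peak_sequences:
        seq = ps.sequence if hasattr(ps, "sequence") else ps[1]
        fold = getattr(ps, "fold_change", 0.0)
        entries.append((seq, fold))
        for site in scan_sequence(pssm, seq, background, thresholds.p_peak, dist=dist):
            key = (site.p_value, -fold, site.location)
            if best is None or key < best[0]:
                best = (key, seq, site)
    if best is None:
        raise ValueError("no binding site found in the peak sequences")
    _, seq, site = best
    lo = max(0, site.location - flank)
    hi = min(len(seq), site.end + flank)
    positive = seq[lo:hi]

    probe_len = len(positive)
    for seq, _ in entries:
        hits = scan_sequence(pssm, seq, background, thresholds.probe_negative_max_p,
                             dist=dist)
        blocked = np.zeros(len(seq), dtype=bool)
        for h in hits:
            blocked[h.location:h.end] = True
        for start in range(0, len(seq) - probe_len + 1):
            window = seq[start:start + probe_len]
            if "N" in window or blocked[start:start + probe_len].any():
                continue
            return positive, window
    raise ValueError("no negative probe window without a motif match was found")


def sites_to_bed(sites: list[BindingSite], genome: Genome, path: str | Path) -> None:
    """Write sites as BED6; score column is -log10 p capped at 999."""
    with open(path, "w") as fh:
        for s in sites:
            if s.p_value is None or not np.isfinite(s.p_value) or s.p_value <= 0:
                score = 999
            else:
                score = min(999, int(round(-np.log10(s.p_value))))
            name = s.matched_word
            fh.write(f"{genome.id}\t{s.location}\t{s.end}\t{name}\t{score}\t{s.strand}\n")


def sites_to_table(sites: list[BindingSite]):
    """Sites as a pandas DataFrame with all fields."""
    import pandas as pd

    return pd.DataFrame([{
        "location": s.location, "end": s.end, "strand": s.strand,
        "width": s.width, "score": s.score, "p_value": s.p_value,
        "matched_word": s.matched_word, "source": s.source,
        "region_id": s.region_id, "operons": ",".join(s.operons),
    } for s in sites])
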