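"""Motif discovery from peak apex sequences.

The motif object is a position-specific scoring matrix (PSSM) held as a
count matrix.  Discovery runs a ZOOPS (zero-or-one occurrence per sequence)
expectation-maximization against a Markov background, over both strands,
from multiple word-seeded starts and over a sweep of candidate widths.  The
enrichment E-value is estimated by a shuffle-calibrated normal approximation
to the null log-likelihood-ratio objective.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm, pearsonr

from ._seq import BASES, N_CODE, decode, encode, revcomp
from .genome import MarkovBackground

logger = logging.getLogger(__name__)

DEFAULT_WIDTH_RANGE = (6, 24)
MIN_WIDTH, MAX_WIDTH = 3, 60


class PSSM:
    """Position-specific scoring matrix backed by a count matrix.

    ``counts`` is (width, 4) with columns in A,C,G,T order; each column sums
    to ``nsites``.  Column frequencies are regularized by a pseudocount
    distributed according to the background base composition:

        f_i(x) = (counts[i, x] + pseudocount * b0(x)) / (nsites + pseudocount)

    The default pseudocount is 0.1 * nsites.
    """

    def __init__(self, counts: np.ndarray, pseudocount: float | None = None,
                 e_value: float = float("nan"), name: str = "motif"):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be (width, 4)")
        if not (MIN_WIDTH <= counts.shape[0] <= MAX_WIDTH):
            raise ValueError(f"width must be in [{MIN_WIDTH},{MAX_WIDTH}]")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        col_sums = counts.sum(axis=1)
        if not np.allclose(col_sums, col_sums[0], atol=1e-6):
            raise ValueError("every column must sum to the same site count")
        self.counts = counts
        self.nsites = float(col_sums[0])
        self.pseudocount = 0.1 * self.nsites if pseudocount is None else float(pseudocount)
        self.e_value = e_value
        self.name = name

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_sites(cls, sites: list[str], **kw) -> "PSSM":
        """Build a PSSM from equal-weight aligned site words."""
        if not sites:
            raise ValueError("need at least one site")
        w = len(sites[0])
        if any(len(s) != w for s in sites):
            raise ValueError("sites must share one length")
        counts = np.zeros((w, 4))
        for s in sites:
            codes = encode(s)
            if (codes == N_CODE).any():
                raise ValueError(f"site {s!r} contains non-ACGT characters")
            counts[np.arange(w), codes] += 1.0
        return cls(counts, **kw)

    def frequencies(self, background: MarkovBackground | None = None) -> np.ndarray:
        b0 = background.base_freqs if background is not None else np.full(4, 0.25)
        return (self.counts + self.pseudocount * b0) / (self.nsites + self.pseudocount)

    def log_odds(self, background: MarkovBackground) -> np.ndarray:
        """Per-column log2(f/b0) against the background's marginal composition.

        Zero-probability cells (possible only at pseudocount 0) map to -inf.
        """
        f = self.frequencies(background)
        with np.errstate(divide="ignore"):
            return np.log2(f) - background.log2_base[None, :]

    def consensus(self, background: MarkovBackground | None = None) -> str:
        return decode(np.argmax(self.frequencies(background), axis=1))

    def information_content(self, background: MarkovBackground | None = None) -> np.ndarray:
        """Per-column relative entropy (bits) vs the background composition."""
        f = self.frequencies(background)
        b0 = background.base_freqs if background is not None else np.full(4, 0.25)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * (np.log2(f) - np.log2(b0)), 0.0)
        return terms.sum(axis=1)

    def reverse_complement(self) -> "PSSM":
        return PSSM(self.counts[::-1, ::-1].copy(), pseudocount=self.pseudocount,
                    e_value=self.e_value, name=self.name)


@dataclass
class DyadAnnotation:
    """Symmetry annotation of a motif consensus (inverted/direct repeat arms)."""

    kind: str                      # inverted | direct | none
    arm_length: int = 0
    arm_positions: tuple[int, int] = (0, 0)
    arm_identity: float = 0.0


# ----------------------------------------------------------------------
# ZOOPS EM
# ----------------------------------------------------------------------


def _prepare(sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pad encoded sequences into one matrix (pad = N) and return lengths."""
    codes = [encode(s) for s in sequences]
    L = max(len(c) for c in codes)
    mat = np.full((len(codes), L), N_CODE, dtype=np.int8)
    for i, c in enumerate(codes):
        mat[i, :len(c)] = c
    return mat, np.array([len(c) for c in codes])


def _window_logbg(mat: np.ndarray, background: MarkovBackground, w: int) -> np.ndarray:
    """log2 background probability of every length-w window; NaN where invalid."""
    n, L = mat.shape
    per_pos = np.empty((n, L))
    for i in range(n):
        per_pos[i] = background.position_log2(mat[i])
    if L < w:
        return np.empty((n, 0))
    sw = np.lib.stride_tricks.sliding_window_view(per_pos, w, axis=1)
    return sw.sum(axis=2)


class _EMState:
    """Vectorized ZOOPS EM over both strands for one width."""

    def __init__(self, sequences: list[str], background: MarkovBackground, w: int):
        self.w = w
        self.bg = background
        self.mat, self.lengths = _prepare(sequences)
        self.rc_mat, _ = _prepare([revcomp(s) for s in sequences])
        # windows: (n, P, w) base codes for forward and reverse-complement reads
        self.fwd = np.lib.stride_tricks.sliding_window_view(self.mat, w, axis=1)
        self.rev = np.lib.stride_tricks.sliding_window_view(self.rc_mat, w, axis=1)
        self.valid_fwd = (self.fwd != N_CODE).all(axis=2)
        self.valid_rev = (self.rev != N_CODE).all(axis=2)
        self.logbg_fwd = np.nan_to_num(_window_logbg(self.mat, background, w), nan=0.0)
        self.logbg_rev = np.nan_to_num(_window_logbg(self.rc_mat, background, w), nan=0.0)
        self.n_pos = np.maximum(self.lengths - w + 1, 0)

    def _window_logf(self, log_f: np.ndarray, windows: np.ndarray) -> np.ndarray:
        # sum_k log f_k(base at offset k); fancy-index per offset to bound memory
        n, P, w = windows.shape
        out = np.zeros((n, P))
        safe = windows.clip(0, 3)
        for k in range(w):
            out += log_f[k, safe[:, :, k]]
        return out

    def estep(self, freqs: np.ndarray, gamma: float):
        """Posterior site probabilities and the ZOOPS log-likelihood-ratio."""
        log_f = np.log2(freqs)
        llr_f = self._window_logf(log_f, self.fwd) - self.logbg_fwd
        llr_r = self._window_logf(log_f, self.rev) - self.logbg_rev
        lr_f = np.where(self.valid_fwd, np.exp2(llr_f), 0.0)
        lr_r = np.where(self.valid_rev, np.exp2(llr_r), 0.0)
        n_slots = np.maximum(2 * self.n_pos, 1)
        prior_site = gamma / n_slots
        mix = (1.0 - gamma) + prior_site * (lr_f.sum(axis=1) + lr_r.sum(axis=1))
        z_f = prior_site[:, None] * lr_f / mix[:, None]
        z_r = prior_site[:, None] * lr_r / mix[:, None]
        objective = float(np.sum(np.log2(np.maximum(mix, 1e-300))))
        return z_f, z_r, objective

    def mstep(self, z_f: np.ndarray, z_r: np.ndarray) -> tuple[np.ndarray, float, float]:
        w = self.w
        counts = np.zeros((w, 4))
        for k in range(w):
            base_f = self.fwd[:, :, k].clip(0, 3)
            base_r = self.rev[:, :, k].clip(0, 3)
            np.add.at(counts[k], base_f.ravel(), z_f.ravel())
            np.add.at(counts[k], base_r.ravel(), z_r.ravel())
        nsites = float(z_f.sum() + z_r.sum())
        gamma = min(max(nsites / len(self.lengths), 1e-6), 1 - 1e-6)
        return counts, nsites, gamma


def _seed_words(sequences: list[str], w: int, n_seeds: int,
                rng: np.random.Generator, central_halfwidth: int = 30) -> list[str]:
    """Candidate starting words.

    Peak windows are apex-centered and binding sites concentrate at the apex,
    so words overlapping the central window of each sequence are the prime
    candidates; repeated w-mers anywhere come next, then random draws fill up.
    All candidates are screened by a short EM run before full optimization.
    """
    from collections import Counter

    seeds: list[str] = []
    seen: set[str] = set()

    def add(word: str) -> None:
        if "N" not in word and word not in seen:
            seen.add(word)
            seeds.append(word)

    for s in sequences:
        if len(s) < w:
            continue
        center = len(s) // 2
        lo = max(0, center - central_halfwidth - w)
        hi = min(len(s) - w, center + central_halfwidth)
        for i in range(lo, hi + 1):
            add(s[i:i + w])

    counter: Counter[str] = Counter()
    for s in sequences:
        for i in range(len(s) - w + 1):
            word = s[i:i + w]
            if "N" not in word:
                counter[min(word, revcomp(word))] += 1
    for word, c in counter.most_common():
        if c < 2:
            break
        add(word)

    pool = [s for s in sequences if len(s) >= w]
    tries = 0
    while len(seeds) < n_seeds and pool and tries < 10 * n_seeds:
        s = pool[rng.integers(len(pool))]
        i = int(rng.integers(len(s) - w + 1))
        add(s[i:i + w])
        tries += 1
    return seeds


def _prescreen_seeds(state: "_EMState", seeds: list[str], keep: int) -> list[str]:
    """Rank candidate seed words by total best-window similarity.

    For each seed, the per-sequence maximum Hamming similarity to any window
    (either strand) is summed over sequences; the top ``keep`` seeds move on
    to the EM screen.  Vectorized, so hundreds of candidates stay cheap.
    """
    if len(seeds) <= keep:
        return seeds
    seed_codes = np.stack([encode(s) for s in seeds])          # (S, w)
    scores = np.zeros(len(seeds))
    for windows, valid in ((state.fwd, state.valid_fwd), (state.rev, state.valid_rev)):
        if windows.shape[1] == 0:
            continue
        # (S, n, P) match counts, accumulated column by column
        sim = np.zeros((len(seeds), windows.shape[0], windows.shape[1]), dtype=np.int16)
        for k in range(state.w):
            sim += windows[None, :, :, k] == seed_codes[:, None, None, k]
        sim = np.where(valid[None, :, :], sim, -1)
        scores += sim.max(axis=2).sum(axis=1)
    order = np.argsort(-scores, kind="stable")[:keep]
    return [seeds[i] for i in order]


def _seed_freqs(word: str, major: float = 0.7) -> np.ndarray:
    codes = encode(word)
    f = np.full((len(word), 4), (1 - major) / 3)
    f[np.arange(len(word)), codes] = major
    return f


def _run_em(state: _EMState, init_freqs: np.ndarray, background: MarkovBackground,
            max_iter: int = 200, tol: float = 1e-6,
            pseudocount_frac: float = 0.1) -> tuple[np.ndarray, float, float]:
    """Run EM to convergence; returns (counts, nsites, objective)."""
    freqs = init_freqs
    gamma = 0.5
    prev = -np.inf
    counts = None
    nsites = 0.0
    for _ in range(max_iter):
        z_f, z_r, objective = state.estep(freqs, gamma)
        counts, nsites, gamma = state.mstep(z_f, z_r)
        pc = pseudocount_frac * max(nsites, 1e-9)
        freqs = (counts + pc * background.base_freqs) / (nsites + pc)
        if prev > -np.inf and abs(objective - prev) <= tol * max(abs(prev), 1.0):
            prev = objective
            break
        prev = objective
    return counts, nsites, prev


def discover_motif(
    sequences: list[str],
    background: MarkovBackground,
    width_range: tuple[int, int] = DEFAULT_WIDTH_RANGE,
    n_starts: int = 20,
    seed: int = 0,
    width_step: int = 2,
    compute_evalue: bool = True,
    evalue_shuffles: int = 100,
    trim_edges: bool = True,
) -> PSSM:
    """Learn the best-enriched motif from peak-apex sequences by ZOOPS EM.

    For each candidate width, ``n_starts`` word-seeded initializations are
    screened by one EM sweep, the best few run to convergence, and widths are
    compared through a shuffle-calibrated z-score of the final objective.
    """
    lo, hi = width_range
    if not (MIN_WIDTH <= lo <= hi <= MAX_WIDTH):
        raise ValueError(f"width_range must lie within [{MIN_WIDTH},{MAX_WIDTH}]")
    if len(sequences) < 5:
        raise ValueError("need at least 5 sequences for motif discovery")
    usable_max = max(len(s) for s in sequences)
    widths = [w for w in range(lo, hi + 1, width_step) if w <= usable_max]
    if not widths:
        raise ValueError("all sequences shorter than the minimum motif width")
    rng = np.random.default_rng(seed)

    n_unique = len(set(sequences))
    if n_unique < max(3, len(sequences) // 10):
        logger.warning("low site diversity: %d unique sequences of %d",
                       n_unique, len(sequences))

    best = None  # (zscore, objective, counts, nsites, width)
    for w in widths:
        state = _EMState(sequences, background, w)
        seeds = _seed_words(sequences, w, n_starts, rng)
        seeds = _prescreen_seeds(state, seeds, keep=n_starts)
        screened = []
        for word in seeds:
            counts, nsites, obj = _run_em(state, _seed_freqs(word), background,
                                          max_iter=1)
            screened.append((obj, counts, nsites))
        screened.sort(key=lambda t: -t[0])
        best_w = None
        for obj0, counts0, nsites0 in screened[:max(5, n_starts // 4)]:
            pc = 0.1 * max(nsites0, 1e-9)
            init = (counts0 + pc * background.base_freqs) / (nsites0 + pc)
            counts, nsites, obj = _run_em(state, init, background)
            if best_w is None or obj > best_w[0]:
                best_w = (obj, counts, nsites)
        if best_w is None:
            continue
        obj, counts, nsites = best_w
        null_mu, _ = _null_objective_stats(
            sequences, background, w, rng, n_shuffles=4, n_starts=max(2, n_starts // 5))
        # widths compete on the objective's excess over its shuffle-null mean;
        # the null mean grows with width, so raw objectives are not comparable
        margin = obj - null_mu
        if best is None or margin > best[0]:
            best = (margin, obj, counts, nsites, w)

    z, obj, counts, nsites, w = best
    counts = np.maximum(counts, 0.0)
    col = counts.sum(axis=1)
    # EM soft counts can drift per column at machine precision; renormalize
    counts = counts * (nsites / np.maximum(col, 1e-300))[:, None]
    pssm = PSSM(counts, name="discovered")
    if trim_edges:
        pssm = trim_low_information(pssm, background)
    if compute_evalue:
        pssm.e_value = motif_evalue(pssm, sequences, background,
                                    n_shuffles=evalue_shuffles, seed=seed + 1,
                                    n_widths_tried=len(widths),
                                    objective=obj if pssm.width == w else None)
    return pssm


def trim_low_information(pssm: PSSM, background: MarkovBackground | None = None,
                         min_ic: float = 0.3) -> PSSM:
    """Trim uninformative edge columns (relative entropy < ``min_ic`` bits).

    EM over a width sweep can pad a motif with near-background flanking
    columns; trimming from the edges recovers the informative core without
    touching interior low-information positions (e.g. free spacer columns of
    a gapped dyad).  Never trims below the minimum motif width.
    """
    ic = pssm.information_content(background)
    lo, hi = 0, pssm.width
    while hi - lo > MIN_WIDTH and ic[lo] < min_ic:
        lo += 1
    while hi - lo > MIN_WIDTH and ic[hi - 1] < min_ic:
        hi -= 1
    if (lo, hi) == (0, pssm.width):
        return pssm
    return PSSM(pssm.counts[lo:hi].copy(), pseudocount=pssm.pseudocount,
                e_value=pssm.e_value, name=pssm.name)


def _shuffle_each(sequences: list[str], rng: np.random.Generator) -> list[str]:
    out = []
    for s in sequences:
        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        rng.shuffle(arr)
        out.append(arr.tobytes().decode())
    return out


def _null_objective_stats(sequences, background, w, rng, n_shuffles: int,
                          n_starts: int) -> tuple[float, float]:
    objs = []
    for _ in range(n_shuffles):
        shuf = _shuffle_each(sequences, rng)
        state = _EMState(shuf, background, w)
        seeds = _seed_words(shuf, w, n_starts, rng)
        seeds = _prescreen_seeds(state, seeds, keep=n_starts)
        best = -np.inf
        for word in seeds:
            _, _, obj = _run_em(state, _seed_freqs(word), background, max_iter=20)
            best = max(best, obj)
        objs.append(best)
    mu = float(np.mean(objs))
    sd = float(np.std(objs, ddof=1)) if len(objs) > 1 else 1.0
    return mu, max(sd, 1e-6)


def motif_evalue(pssm: PSSM, sequences: list[str], background: MarkovBackground,
                 n_shuffles: int = 100, seed: int = 0,
                 n_widths_tried: int = 1, objective: float | None = None) -> float:
    """Enrichment E-value of a fitted motif.

    The null distribution of the ZOOPS objective for this width is estimated
    by refitting on composition-preserving shuffles of the input sequences;
    a normal approximation gives the tail probability p of the observed
    objective, and E = p * n_widths_tried.  Smaller E means more enriched.
    """
    rng = np.random.default_rng(seed)
    w = pssm.width
    if objective is None:
        state = _EMState(sequences, background, w)
        freqs = pssm.frequencies(background)
        _, _, objective = state.estep(freqs, 0.5)
    mu, sd = _null_objective_stats(sequences, background, w, rng,
                                   n_shuffles=n_shuffles, n_starts=2)
    p = float(norm.sf((objective - mu) / sd))
    return max(p * n_widths_tried, 0.0)


# ----------------------------------------------------------------------
# Symmetry and comparison
# ----------------------------------------------------------------------


def detect_dyad(pssm: PSSM, min_arm: int = 4, min_identity: float = 0.8) -> DyadAnnotation:
    """Best inverted- or direct-repeat arm pair in the motif consensus.

    Ties are broken toward inverted repeats, then longer arms, then leftmost
    positions; identity below ``min_identity`` reports kind 'none'.
    """
    cons = pssm.consensus()
    w = len(cons)
    if w < 2 * min_arm:
        raise ValueError("pssm width must be >= 2*min_arm")
    best: tuple | None = None
    for arm in range(w // 2, min_arm - 1, -1):
        for o1 in range(0, w - 2 * arm + 1):
            a = cons[o1:o1 + arm]
            for o2 in range(o1 + arm, w - arm + 1):
                b = cons[o2:o2 + arm]
                ident_inv = sum(x == y for x, y in zip(a, revcomp(b))) / arm
                ident_dir = sum(x == y for x, y in zip(a, b)) / arm
                for kind, ident in (("inverted", ident_inv), ("direct", ident_dir)):
                    key = (round(ident, 9), 1 if kind == "inverted" else 0, arm, -o1, -o2)
                    if best is None or key > best[0]:
                        best = (key, DyadAnnotation(kind, arm, (o1, o2), ident))
    if best is None or best[1].arm_identity < min_identity:
        return DyadAnnotation("none")
    return best[1]


def compare_motifs(a: PSSM, b: PSSM, min_overlap: int = 4) -> dict:
    """Best alignment of two motifs by mean per-column Pearson correlation.

    Slides ``b`` (forward and reverse-complement) across ``a`` over all
    offsets with at least ``min_overlap`` overlapping columns.  The reported
    ``correlation`` is the mean column correlation scaled by the fraction of
    the shorter motif covered by the overlap, so a chance 4-column agreement
    cannot outrank a full-length alignment; the unscaled mean is returned as
    ``mean_column_correlation``.
    """
    fa = a.frequencies()
    shorter = min(a.width, b.width)
    best = {"correlation": -np.inf, "mean_column_correlation": -np.inf,
            "offset": 0, "orientation": "forward", "overlap": 0}
    for orientation in ("forward", "reverse"):
        fb = b.frequencies() if orientation == "forward" else b.reverse_complement().frequencies()
        for offset in range(-(fb.shape[0] - min_overlap), fa.shape[0] - min_overlap + 1):
            lo_a, hi_a = max(0, offset), min(fa.shape[0], offset + fb.shape[0])
            if hi_a - lo_a < min_overlap:
                continue
            cols_a = fa[lo_a:hi_a]
            cols_b = fb[lo_a - offset:hi_a - offset]
            rs = []
            for ca, cb in zip(cols_a, cols_b):
                if np.std(ca) < 1e-12 or np.std(cb) < 1e-12:
                    rs.append(1.0 if np.allclose(ca, cb) else 0.0)
                else:
                    rs.append(pearsonr(ca, cb).statistic)
            mean_r = float(np.mean(rs))
            r = mean_r * (hi_a - lo_a) / shorter
            if r > best["correlation"]:
                best = {"correlation": r, "mean_column_correlation": mean_r,
                        "offset": offset, "orientation": orientation,
                        "overlap": hi_a - lo_a}
    return best


# ----------------------------------------------------------------------
# MEME minimal motif format
# ----------------------------------------------------------------------


def write_meme(pssm: PSSM, path: str | Path,
               background: MarkovBackground | None = None) -> None:
    """Write a PSSM in MEME minimal motif format (frequencies to 6 decimals)."""
    b0 = background.base_freqs if background is not None else np.full(4, 0.25)
    f = pssm.frequencies(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {b0[i]:.6f}" for i, b in enumerate(BASES)) + "\n\n")
        fh.write(f"MOTIF {pssm.name}\n")
        ev = pssm.e_value if math.isfinite(pssm.e_value) else 0.0
        fh.write(f"letter-probability matrix: alength= 4 w= {pssm.width} "
                 f"nsites= {int(round(pssm.nsites))} E= {ev:.6g}\n")
        for row in f:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_meme(path: str | Path) -> PSSM:
    """Read the first motif from a MEME minimal-format file.

    Frequencies are converted back to counts via the recorded nsites; the
    round trip preserves frequencies to 1e-6 (pseudocount set to 0 so the
    stored frequencies are reproduced exactly).
    """
    lines = Path(path).read_text().splitlines()
    name = None
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[1].strip().replace(" ", "")
            if alpha not in ("ACGT", ""):
                raise ValueError(f"line {i + 1}: unsupported alphabet {alpha!r}")
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else "motif"
            i += 1
            break
        i += 1
    if name is None:
        raise ValueError("no MOTIF record found")
    while i < len(lines) and not lines[i].startswith("letter-probability matrix"):
        i += 1
    if i == len(lines):
        raise ValueError(f"line {i}: missing letter-probability matrix header")
    header = lines[i]
    m = re.search(r"w=\s*(\d+)", header)
    if not m:
        raise ValueError(f"line {i + 1}: matrix header missing w=")
    w = int(m.group(1))
    m = re.search(r"nsites=\s*(\d+)", header)
    nsites = int(m.group(1)) if m else 20
    m = re.search(r"E=\s*(\S+)", header)
    e_value = float(m.group(1)) if m else float("nan")
    rows = []
    for j in range(i + 1, i + 1 + w):
        if j >= len(lines):
            raise ValueError(f"line {j + 1}: truncated matrix (expected {w} rows)")
        vals = lines[j].split()
        if len(vals) != 4:
            raise ValueError(f"line {j + 1}: expected 4 frequencies, got {len(vals)}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise ValueError(f"line {j + 1}: {exc}") from exc
    freqs = np.array(rows)
    # 6-decimal rows may sum to 0.999999x; renormalize so counts stay exact
    freqs = freqs / freqs.sum(axis=1, keepdims=True)
    return PSSM(freqs * nsites, pseudocount=0.0, e_value=e_value, name=name)
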