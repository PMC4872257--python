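"""De novo motif discovery on one promoter subset.

Three engines play the roles of the classic seed-and-extend, exhaustive
and EM-based discovery tools, each with its own significance gate:

``seed_qvalue``
    exhaustive word enumeration with a sequence-hit binomial tail against
    the Markov background and Benjamini-Hochberg control; motifs with
    q <= 0.05 are significant.
``ranked_topk``
    the same enumeration, but significance is rank-based: the top five
    candidates by p-value are reported.
``em_refine``
    EM refinement of PWMs seeded from the strongest candidate words; a
    motif is significant when its e-value-like score (seed p-value times
    the number of candidates tested) is <= 0.001.

All engines search both strands; a word and its reverse complement are
collapsed to one canonical entry (the lexicographically smaller of the
pair).  The minimum motif width is 6 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _seq
from ._seq import ALPHABET
from .genome_io import BackgroundModel, UpstreamRegion
from .motifs import (Motif, information_content, pwm_from_instances,
                     reverse_complement_word)

logger = logging.getLogger(__name__)

MIN_WIDTH = 6

ENGINES = ("seed_qvalue", "ranked_topk", "em_refine")


@dataclass(frozen=True)
class EngineConfig:
    """One engine's search parameters and significance gate."""

    engine: str = "seed_qvalue"
    width_range: tuple[int, int] = (6, 8)
    max_mismatches: int = 0
    q_max: float = 0.05        # seed_qvalue gate
    score_max: float = 0.001   # em_refine gate (e-value-like)
    top_k: int = 5             # ranked_topk gate
    both_strands: bool = True
    pseudocount: float = 0.1
    em_seeds: int = 20
    em_max_iter: int = 20
    em_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine {self.engine!r}; "
                             f"choose from {ENGINES}")
        w_min, w_max = self.width_range
        if w_min < MIN_WIDTH:
            raise ValueError(f"minimum motif width is {MIN_WIDTH} bp")
        if w_max < w_min:
            raise ValueError("width_range must be (w_min, w_max) with "
                             "w_max >= w_min")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not (self.q_max > 0 and self.score_max > 0 and self.top_k > 0):
            raise ValueError("significance thresholds must be positive")


@dataclass
class CandidateWord:
    """A canonical word with its subset occurrence counts and significance.

    ``seq_hits`` is the number of subset sequences containing at least one
    match (either strand, within ``max_mismatches``); ``total_hits`` counts
    matching start offsets, a palindromic word's forward and reverse match
    at one offset counted once.
    """

    word: str
    width: int
    seq_hits: int
    total_hits: int
    p: float = float("nan")
    q: float = float("nan")


def enumerate_words(subset: Sequence[UpstreamRegion], width: int,
                    max_mismatches: int = 0, both_strands: bool = True
                    ) -> list[CandidateWord]:
    """Count every candidate word of ``width`` occurring in the subset.

    With ``max_mismatches > 0``, candidates are all words whose Hamming
    neighbourhood intersects the subset, and a window counts as a hit of
    every candidate within ``max_mismatches`` of it (either strand).
    Returned sorted by word.
    """
    if not subset:
        raise ValueError("empty subset")
    if any(width > r.length for r in subset):
        raise ValueError(f"width {width} exceeds a region length")
    totals: dict[int, int] = {}
    seqhits: dict[int, int] = {}
    for region in subset:
        packed, valid = _seq.window_codes(_seq.encode(region.sequence), width)
        codes = packed[valid]
        if codes.size == 0:
            continue
        if max_mismatches == 0:
            keys = _seq.canonical_codes(codes, width) if both_strands \
                else codes
            vals, cnts = np.unique(keys, return_counts=True)
            for v, c in zip(vals.tolist(), cnts.tolist()):
                totals[v] = totals.get(v, 0) + c
                seqhits[v] = seqhits.get(v, 0)
            for v in vals.tolist():
                seqhits[v] += 1
        else:
            seen_here: set[int] = set()
            vals, cnts = np.unique(codes, return_counts=True)
            for code, cnt in zip(vals.tolist(), cnts.tolist()):
                for cand in _window_candidates(code, width, max_mismatches,
                                               both_strands):
                    totals[cand] = totals.get(cand, 0) + cnt
                    if cand not in seen_here:
                        seen_here.add(cand)
                        seqhits[cand] = seqhits.get(cand, 0) + 1
    return [CandidateWord(_seq.decode_word(code, width), width,
                          seqhits[code], totals[code])
            for code in sorted(totals)]


def _window_candidates(code: int, k: int, mm: int,
                       both_strands: bool) -> set[int]:
    """Canonical candidate words matched by one window within mm."""
    neigh = _hamming_ball(code, k, mm)
    if both_strands:
        neigh |= _hamming_ball(int(_seq.revcomp_codes(
            np.array([code]), k)[0]), k, mm)
        return {int(_seq.canonical_codes(np.array([u]), k)[0])
                for u in neigh}
    return neigh


def _hamming_ball(code: int, k: int, mm: int) -> set[int]:
    ball = {code}
    frontier = {code}
    for _ in range(mm):
        nxt = set()
        for c in frontier:
            for pos in range(k):
                shift = 2 * pos
                base = (c >> shift) & 3
                for b in range(4):
                    if b != base:
                        nxt.add((c & ~(3 << shift)) | (b << shift))
        ball |= nxt
        frontier = nxt
    return ball


def _dense_freq(background: BackgroundModel, k: int) -> np.ndarray:
    """Order-k frequency table as a dense array over all 4^k codes,
    cached on the background object."""
    cache = background.__dict__.setdefault("_dense_cache", {})
    if k not in cache:
        arr = np.zeros(4 ** k)
        for word, f in background.frequencies[k].items():
            arr[int(_seq.window_codes(_seq.encode(word), k)[0][0])] = f
        cache[k] = arr
    return cache[k]


def _word_probs_codes(background: BackgroundModel, codes: np.ndarray,
                      w: int) -> np.ndarray:
    """Vectorized word probabilities for packed codes of width ``w``
    (empirical table up to K, order-(K-1) Markov factorization above)."""
    K = background.max_order
    if w <= K:
        return _dense_freq(background, w)[codes]
    if K == 1:
        f1 = _dense_freq(background, 1)
        p = np.ones(len(codes))
        for i in range(w):
            p *= f1[(codes >> (2 * (w - 1 - i))) & 3]
        return p
    fK = _dense_freq(background, K)
    fK1 = _dense_freq(background, K - 1)
    maskK = 4 ** K - 1
    p = fK[(codes >> (2 * (w - K))) & maskK]
    for i in range(1, w - K + 1):
        km = (codes >> (2 * (w - K - i))) & maskK
        denom = fK1[km >> 2]
        ok = denom > 0
        p = np.where(ok, p * fK[km] / np.where(ok, denom, 1.0), 0.0)
    return p


def _window_match_probs(background: BackgroundModel, codes: np.ndarray,
                        w: int, both_strands: bool) -> np.ndarray:
    """Probability a single background window matches each word (either
    strand; a palindrome counted once)."""
    p = _word_probs_codes(background, codes, w)
    if both_strands:
        rc = _seq.revcomp_codes(codes, w)
        prc = _word_probs_codes(background, rc, w)
        p = np.where(rc == codes, p, p + prc)
    return np.minimum(p, 1.0)


def _window_match_probability(background: BackgroundModel, word: str,
                              both_strands: bool) -> float:
    """Scalar wrapper over :func:`_window_match_probs`."""
    codes, valid = _seq.window_codes(_seq.encode(word), len(word))
    if not valid.all():
        raise ValueError(f"word {word!r} is not plain A/C/G/T")
    return float(_window_match_probs(background, codes[:1], len(word),
                                     both_strands)[0])


def word_significance(candidate: CandidateWord, background: BackgroundModel,
                      subset_size: int, region_length: int,
                      both_strands: bool = True) -> float:
    """Binomial-tail p-value for a candidate's sequence hits.

    Under the background, one window matches the word with probability
    ``p_w`` (both strands summed), so a region of length L contains >= 1
    match with probability ``p1 = 1 - (1 - p_w)^(L - w + 1)`` (window
    independence approximation).  The p-value is the binomial upper tail
    ``P(X >= seq_hits | n = subset_size, p1)``.
    """
    if candidate.seq_hits == 0:
        return 1.0
    p_w = _window_match_probability(background, candidate.word, both_strands)
    n_windows = region_length - candidate.width + 1
    p1 = 1.0 - (1.0 - p_w) ** n_windows
    if p1 == 0.0:
        logger.warning("word %s has zero background probability but %d "
                       "sequence hits", candidate.word, candidate.seq_hits)
        return 0.0
    p = float(stats.binom.sf(candidate.seq_hits - 1, subset_size, p1))
    return min(max(p, 0.0), 1.0)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up Benjamini-Hochberg q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def _count_width(encoded: list[np.ndarray], width: int, both_strands: bool
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Array counting for one width at zero mismatches: returns sorted
    candidate codes with their seq_hits and total_hits."""
    chunks, seq_ids = [], []
    for si, codes in enumerate(encoded):
        packed, valid = _seq.window_codes(codes, width)
        kept = packed[valid]
        if kept.size == 0:
            continue
        if both_strands:
            kept = _seq.canonical_codes(kept, width)
        chunks.append(kept)
        seq_ids.append(np.full(kept.size, si, dtype=np.int64))
    if not chunks:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    codes = np.concatenate(chunks)
    seqs = np.concatenate(seq_ids)
    words, totals = np.unique(codes, return_counts=True)
    n_seq = len(encoded)
    pair_words = np.unique(codes * n_seq + seqs) // n_seq
    sh_words, seq_hits = np.unique(pair_words, return_counts=True)
    assert np.array_equal(words, sh_words)
    return words, seq_hits, totals


def _score_candidates_arrays(subset: Sequence[UpstreamRegion],
                             background: BackgroundModel,
                             config: EngineConfig) -> dict[str, np.ndarray]:
    """Enumerate all widths and attach vectorized p- and q-values.

    Returns parallel arrays (codes, widths, seq_hits, total_hits, p, q)
    over every candidate pooled across the width range; q-values are
    corrected within this subset run.
    """
    w_min, w_max = config.width_range
    mean_length = float(np.mean([r.length for r in subset]))
    if config.max_mismatches == 0:
        encoded = [_seq.encode(r.sequence) for r in subset]
        cols = {"codes": [], "widths": [], "seq_hits": [], "total_hits": [],
                "p": []}
        for width in range(w_min, w_max + 1):
            if any(width > r.length for r in subset):
                raise ValueError(f"width {width} exceeds a region length")
            words, seq_hits, totals = _count_width(encoded, width,
                                                   config.both_strands)
            if words.size == 0:
                continue
            p_w = _window_match_probs(background, words, width,
                                      config.both_strands)
            n_windows = mean_length - width + 1
            p1 = 1.0 - (1.0 - p_w) ** n_windows
            p = np.where(p1 > 0,
                         stats.binom.sf(seq_hits - 1, len(subset),
                                        np.clip(p1, 0.0, 1.0)),
                         0.0)
            cols["codes"].append(words)
            cols["widths"].append(np.full(words.size, width))
            cols["seq_hits"].append(seq_hits)
            cols["total_hits"].append(totals)
            cols["p"].append(np.clip(p, 0.0, 1.0))
        if not cols["codes"]:
            return {k: np.empty(0) for k in
                    ("codes", "widths", "seq_hits", "total_hits", "p", "q")}
        out = {k: np.concatenate(v) for k, v in cols.items()}
    else:
        candidates: list[CandidateWord] = []
        for width in range(w_min, w_max + 1):
            candidates.extend(enumerate_words(subset, width,
                                              config.max_mismatches,
                                              config.both_strands))
        for c in candidates:
            c.p = word_significance(c, background, len(subset),
                                    int(round(mean_length)),
                                    config.both_strands)
        out = {
            "codes": np.array([int(_seq.window_codes(
                _seq.encode(c.word), c.width)[0][0]) for c in candidates],
                dtype=np.int64),
            "widths": np.array([c.width for c in candidates]),
            "seq_hits": np.array([c.seq_hits for c in candidates]),
            "total_hits": np.array([c.total_hits for c in candidates]),
            "p": np.array([c.p for c in candidates]),
        }
    out["q"] = np.array(benjamini_hochberg(out["p"])) \
        if out["p"].size else np.empty(0)
    return out


def _score_candidates(subset: Sequence[UpstreamRegion],
                      background: BackgroundModel, config: EngineConfig
                      ) -> list[CandidateWord]:
    """Candidate words over all widths with p- and q-values attached."""
    arrays = _score_candidates_arrays(subset, background, config)
    return [CandidateWord(_seq.decode_word(int(code), int(w)), int(w),
                          int(sh), int(th), float(p), float(q))
            for code, w, sh, th, p, q in zip(
                arrays["codes"], arrays["widths"], arrays["seq_hits"],
                arrays["total_hits"], arrays["p"], arrays["q"])]


def collect_instances(subset: Sequence[UpstreamRegion], word: str,
                      max_mismatches: int = 0, both_strands: bool = True
                      ) -> list[str]:
    """Motif-oriented instance words for all subset matches of ``word``."""
    k = len(word)
    target = _seq.encode(word)
    if (target >= 4).any():
        raise ValueError(f"word {word!r} is not plain A/C/G/T")
    instances: list[str] = []
    rc_word = reverse_complement_word(word)
    for region in subset:
        packed, valid = _seq.window_codes(_seq.encode(region.sequence), k)
        seq = region.sequence
        for i in np.nonzero(valid)[0].tolist():
            window = seq[i:i + k]
            d_fwd = sum(a != b for a, b in zip(window, word))
            d_rev = sum(a != b for a, b in zip(window, rc_word)) \
                if both_strands else k + 1
            if min(d_fwd, d_rev) > max_mismatches:
                continue
            instances.append(window if d_fwd <= d_rev
                             else reverse_complement_word(window))
    return instances


def discover_motifs(subset: Sequence[UpstreamRegion],
                    background: BackgroundModel,
                    config: EngineConfig) -> list[Motif]:
    """Run one engine on one subset and return its significant motifs."""
    arrays = _score_candidates_arrays(subset, background, config)
    n = arrays["p"].size
    if n == 0:
        return []
    # p ascending, then width (= point-mass information content)
    # descending, then lexicographic word (code ascending)
    order = np.lexsort((arrays["codes"], -arrays["widths"], arrays["p"]))

    def materialize(i: int) -> CandidateWord:
        return CandidateWord(
            _seq.decode_word(int(arrays["codes"][i]),
                             int(arrays["widths"][i])),
            int(arrays["widths"][i]), int(arrays["seq_hits"][i]),
            int(arrays["total_hits"][i]), float(arrays["p"][i]),
            float(arrays["q"][i]))

    if config.engine == "seed_qvalue":
        selected = [materialize(i) for i in order
                    if arrays["q"][i] <= config.q_max]
        return [_motif_from_candidate(subset, c, config, score=c.q)
                for c in selected]

    if config.engine == "ranked_topk":
        return [_motif_from_candidate(subset, materialize(i), config,
                                      score=float(rank))
                for rank, i in enumerate(order[:config.top_k], start=1)]

    # em_refine
    motifs = []
    seen_consensus: set[str] = set()
    for i in order[:config.em_seeds]:
        c = materialize(int(i))
        evalue = c.p * n
        if evalue > config.score_max:
            continue
        seed = _motif_from_candidate(subset, c, config, score=evalue)
        refined = em_refine_pwm(seed, subset, background,
                                max_iter=config.em_max_iter,
                                tol=config.em_tol,
                                pseudocount=config.pseudocount)
        refined = refined.with_meta(source="em_refine", score=evalue)
        if refined.consensus not in seen_consensus:
            seen_consensus.add(refined.consensus)
            motifs.append(refined)
    return motifs


def _motif_from_candidate(subset, c: CandidateWord, config: EngineConfig,
                          score: float) -> Motif:
    words = collect_instances(subset, c.word, config.max_mismatches,
                              config.both_strands)
    if not words:  # cannot happen for enumerated candidates with hits
        words = [c.word]
    return pwm_from_instances(words, config.pseudocount,
                              source=config.engine, score=score)


def em_refine_pwm(seed: Motif, subset: Sequence[UpstreamRegion],
                  background: BackgroundModel, max_iter: int = 20,
                  tol: float = 1e-4, pseudocount: float = 0.1) -> Motif:
    """Refine a PWM by EM over the subset.

    Each sequence is assumed to contain one instance at an unknown
    position and strand (posterior proportional to the PWM/background
    likelihood ratio); the M-step re-estimates columns from the expected
    letter counts.  Stops after ``max_iter`` iterations or when the mean
    per-sequence log likelihood-ratio improves by less than ``tol``.
    """
    w = seed.width
    bg = np.array([max(background.frequencies[1].get(b, 0.0), 1e-9)
                   for b in ALPHABET])
    bg = bg / bg.sum()
    windows_per_seq = []
    for region in subset:
        packed, valid = _seq.window_codes(_seq.encode(region.sequence), w)
        if not valid.any():
            continue
        idx = np.lib.stride_tricks.sliding_window_view(
            _seq.encode(region.sequence), w)[valid].astype(np.int64)
        rc = 3 - idx[:, ::-1]
        windows_per_seq.append(np.vstack([idx, rc]))
    if not windows_per_seq:
        return seed

    theta = seed.matrix.copy()
    prev_obj = -np.inf
    cols = np.arange(w)
    for _ in range(max_iter):
        log_ratio = np.log(np.maximum(theta, 1e-12) / bg[None, :])
        counts = np.zeros((w, 4))
        obj = 0.0
        for wins in windows_per_seq:
            scores = log_ratio[cols, wins].sum(axis=1)
            z = np.exp(scores - scores.max())
            z /= z.sum()
            obj += float(np.log(np.exp(scores).sum() / len(scores)))
            for b in range(4):
                counts[:, b] += (z[:, None] * (wins == b)).sum(axis=0)
        theta = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
        obj /= len(windows_per_seq)
        if abs(obj - prev_obj) < tol:
            break
        prev_obj = obj
    return Motif(theta, source=seed.source, score=seed.score,
                 provenance=seed.provenance)


def write_candidate_table(candidates: Sequence[CandidateWord], handle) -> None:
    handle.write("word\twidth\tseq_hits\ttotal_hits\tp\tq\n")
    for c in candidates:
        handle.write(f"{c.word}\t{c.width}\t{c.seq_hits}\t{c.total_hits}\t"
                     f"{c.p:.6g}\t{c.q:.6g}\n")
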