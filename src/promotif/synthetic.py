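"""Synthetic inputs with known ground truth.

Every pipeline stage can be exercised at desk scale with data from this
module: promoter sequences drawn from a background word model, motif
instances planted at controlled prevalence, grids of per-condition
differential-expression tables with designated consistently-responsive
genes, and motif databases containing single-substitution variants of true
motifs among random decoys.

All generators are deterministic given their seed and return ground truth
sufficient to score the downstream stage without re-deriving it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seq import ALPHABET
from .genome_io import BackgroundModel, UpstreamRegion
from .de_consensus import DERecord
from .motifs import (DatabaseMotif, Motif, pwm_from_instances,
                     reverse_complement_word)
from .map_annotate import MotifInstance


def uniform_background(max_order: int = 1) -> BackgroundModel:
    """A flat background: every k-word equally frequent, k = 1..max_order."""
    frequencies = {}
    totals = {}
    for k in range(1, max_order + 1):
        words = ["".join(w) for w in _product_words(k)]
        frequencies[k] = {w: 1.0 / len(words) for w in words}
        totals[k] = len(words)
    return BackgroundModel(frequencies, totals, n_regions=0)


def _product_words(k: int) -> list[str]:
    words = [""]
    for _ in range(k):
        words = [w + b for w in words for b in ALPHABET]
    return words


def sample_background_sequences(model: BackgroundModel, n: int, length: int,
                                seed: int,
                                gene_ids: Sequence[str] | None = None
                                ) -> list[UpstreamRegion]:
    """Sample ``n`` sequences of ``length`` bp from the background model as
    an order-(K-1) Markov chain; deterministic given ``seed``."""
    if n <= 0 or length <= 0:
        raise ValueError("n and length must be positive")
    K = model.max_order
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"synth{i:05d}" for i in range(n)]
    elif len(gene_ids) != n:
        raise ValueError("gene_ids must have length n")

    base_probs = np.array([model.frequencies[1].get(b, 0.0)
                           for b in ALPHABET])
    base_probs = base_probs / base_probs.sum()

    regions = []
    if K == 1:
        draws = rng.choice(4, size=(n, length), p=base_probs)
        for i in range(n):
            seq = "".join(ALPHABET[b] for b in draws[i])
            regions.append(UpstreamRegion(gene_ids[i], "synthetic", "+",
                                          0, length, seq))
        return regions

    # order-(K-1) chain: initial (K-1)-mer from its marginal, then
    # conditional next-base probabilities from the order-K table
    prefixes = list(model.frequencies[K - 1])
    prefix_probs = np.array([model.frequencies[K - 1][p] for p in prefixes])
    prefix_probs = prefix_probs / prefix_probs.sum()
    cond: dict[str, np.ndarray] = {}
    for word, f in model.frequencies[K].items():
        pre = word[:-1]
        vec = cond.setdefault(pre, np.zeros(4))
        vec[ALPHABET.index(word[-1])] += f
    for pre, vec in cond.items():
        cond[pre] = vec / vec.sum()

    for i in range(n):
        chars = list(prefixes[rng.choice(len(prefixes), p=prefix_probs)])
        while len(chars) < length:
            pre = "".join(chars[-(K - 1):])
            vec = cond.get(pre)
            if vec is None:  # unseen prefix: fall back to base marginal
                vec = base_probs
            chars.append(ALPHABET[rng.choice(4, p=vec)])
        regions.append(UpstreamRegion(gene_ids[i], "synthetic", "+",
                                      0, length, "".join(chars[:length])))
    return regions


@dataclass(frozen=True)
class PlantedMotifSpec:
    """How motif instances are planted into background promoters.

    ``prevalence`` is the fraction of sequences receiving at least one
    instance; each selected sequence receives ``instances_per_sequence``
    words sampled column-wise from the motif, written over the background
    at non-overlapping uniform offsets (sequence length unchanged).  With
    probability ``strand_probability`` an instance goes on the reverse
    strand, i.e. the reverse complement of the sampled word is written.
    """

    motif: Motif
    prevalence: float = 0.3
    instances_per_sequence: int = 1
    strand_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.instances_per_sequence < 1:
            raise ValueError("instances_per_sequence must be >= 1")
        if not 0.0 <= self.strand_probability <= 1.0:
            raise ValueError("strand_probability must be in [0, 1]")


def motif_from_consensus(consensus: str, certainty: float = 1.0) -> Motif:
    """Point-mass (or near point-mass) PWM from a plain A/C/G/T word."""
    mat = np.full((len(consensus), 4), (1 - certainty) / 3)
    for j, c in enumerate(consensus.upper()):
        mat[j, ALPHABET.index(c)] = certainty
    return Motif(mat, source="planted")


def plant_motifs(regions: Sequence[UpstreamRegion], spec: PlantedMotifSpec
                 ) -> tuple[list[UpstreamRegion], list[MotifInstance]]:
    """Plant motif instances into a subset of regions.

    Returns modified copies of all regions (order preserved) and the
    ground-truth instance list.  ``matched_word`` in the ground truth is
    the motif-strand word; for a minus-strand instance its reverse
    complement appears in the region sequence.
    """
    width = spec.motif.width
    if any(width > r.length for r in regions):
        raise ValueError("motif wider than a region")
    rng = np.random.default_rng(spec.seed)
    n_planted = math.ceil(spec.prevalence * len(regions))
    chosen = set(rng.choice(len(regions), size=n_planted,
                            replace=False).tolist()) if n_planted else set()

    out_regions: list[UpstreamRegion] = []
    truth: list[MotifInstance] = []
    for i, region in enumerate(regions):
        if i not in chosen:
            out_regions.append(region)
            continue
        seq = list(region.sequence)
        occupied: list[tuple[int, int]] = []
        for _ in range(spec.instances_per_sequence):
            offset = _free_offset(rng, region.length, width, occupied)
            occupied.append((offset, offset + width))
            word = _sample_word(rng, spec.motif)
            minus = rng.random() < spec.strand_probability
            written = reverse_complement_word(word) if minus else word
            seq[offset:offset + width] = written
            truth.append(MotifInstance(
                motif_id=spec.motif.consensus, gene_id=region.gene_id,
                offset=offset - region.length,
                strand="-" if minus else "+",
                matched_word=word, score=float("nan")))
        out_regions.append(UpstreamRegion(
            region.gene_id, region.contig_id, region.strand,
            region.start, region.end, "".join(seq)))
    return out_regions, truth


def _free_offset(rng: np.random.Generator, length: int, width: int,
                 occupied: list[tuple[int, int]]) -> int:
    candidates = [o for o in range(length - width + 1)
                  if all(o + width <= s or o >= e for s, e in occupied)]
    if not candidates:
        raise ValueError("requested instances cannot fit without overlap")
    return int(candidates[rng.integers(len(candidates))])


def _sample_word(rng: np.random.Generator, motif: Motif) -> str:
    return "".join(ALPHABET[rng.choice(4, p=col)] for col in motif.matrix)


@dataclass(frozen=True)
class DESimulationSpec:
    """Design of a simulated cultivar x timepoint differential-expression
    grid with designated ground-truth response classes.

    ``consistent_up`` / ``consistent_down`` genes are significant with the
    stated sign in every grid cell; ``timepoint_specific`` genes are
    significant only at their designated timepoint (in all cultivars);
    every other gene is non-significant everywhere.
    """

    cultivars: tuple[str, ...] = ("cv1", "cv2", "cv3")
    timepoints: tuple[str, ...] = ("t1", "t2")
    n_genes: int = 200
    consistent_up: tuple[str, ...] = ()
    consistent_down: tuple[str, ...] = ()
    timepoint_specific: Mapping[str, tuple[str, str]] = field(
        default_factory=dict)  # gene -> (direction "up"/"down", timepoint)
    alpha: float = 0.05
    effect_size: float = 2.0
    effect_sd: float = 0.5
    null_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        up, down = set(self.consistent_up), set(self.consistent_down)
        tp = set(self.timepoint_specific)
        if up & down or up & tp or down & tp:
            raise ValueError("designated gene lists must be disjoint")
        n_designated = len(up) + len(down) + len(tp)
        if n_designated > self.n_genes:
            raise ValueError("n_genes smaller than the designated lists")
        for g, (direction, t) in self.timepoint_specific.items():
            if direction not in ("up", "down"):
                raise ValueError(f"gene {g!r}: direction must be up/down")
            if t not in self.timepoints:
                raise ValueError(f"gene {g!r}: unknown timepoint {t!r}")

    def gene_universe(self) -> list[str]:
        designated = (list(self.consistent_up) + list(self.consistent_down)
                      + list(self.timepoint_specific))
        fillers = [f"gene{i:05d}" for i in range(self.n_genes)]
        fillers = [g for g in fillers if g not in set(designated)]
        return sorted(designated + fillers[:self.n_genes - len(designated)])


def simulate_de_tables(spec: DESimulationSpec
                       ) -> dict[tuple[str, str], list[DERecord]]:
    """One DE table per (cultivar, timepoint) cell, honouring the spec's
    designated response classes; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_universe()
    up, down = set(spec.consistent_up), set(spec.consistent_down)
    tables: dict[tuple[str, str], list[DERecord]] = {}
    for cultivar in spec.cultivars:
        for timepoint in spec.timepoints:
            records = []
            for g in genes:
                direction = None
                if g in up:
                    direction = "up"
                elif g in down:
                    direction = "down"
                elif g in spec.timepoint_specific:
                    d, t = spec.timepoint_specific[g]
                    if t == timepoint:
                        direction = d
                if direction is None:
                    lfc = float(rng.normal(0.0, spec.null_sd))
                    q = float(rng.uniform(spec.alpha * 1.05, 1.0))
                    p = q * float(rng.uniform(0.3, 1.0))
                    records.append(DERecord(g, lfc, p, q, False))
                else:
                    mag = spec.effect_size + abs(
                        float(rng.normal(0.0, spec.effect_sd)))
                    lfc = mag if direction == "up" else -mag
                    q = float(rng.uniform(1e-8, spec.alpha * 0.9))
                    p = q * float(rng.uniform(0.05, 1.0))
                    records.append(DERecord(g, lfc, p, q, True))
            tables[(cultivar, timepoint)] = records
    return tables


def make_database_fixture(true_motifs: Sequence[Motif], n_decoys: int,
                          mutation_rate: float = 1.0, seed: int = 0
                          ) -> tuple[list[DatabaseMotif], dict[str, str]]:
    """A motif database containing one variant of each true motif's
    consensus plus random decoys.

    With probability ``mutation_rate`` each variant carries a single random
    substitution (one position changed to a different base); otherwise it
    is the consensus verbatim.  Returns the database and a ground-truth
    map from true consensus to its database id.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    entries: list[DatabaseMotif] = []
    truth: dict[str, str] = {}
    for i, m in enumerate(true_motifs):
        consensus = m.consensus.upper()
        variant = consensus
        if rng.random() < mutation_rate:
            pos = int(rng.integers(len(consensus)))
            base = consensus[pos]
            choices = [b for b in ALPHABET if b != base] \
                if base in ALPHABET else list(ALPHABET)
            variant = (consensus[:pos]
                       + choices[rng.integers(len(choices))]
                       + consensus[pos + 1:])
        db_id = f"TRUE{i:03d}"
        entries.append(DatabaseMotif(db_id, variant, ("planted-variant",)))
        truth[m.consensus] = db_id
    widths = [m.width for m in true_motifs] or [6]
    for j in range(n_decoys):
        w = int(widths[rng.integers(len(widths))])
        word = "".join(ALPHABET[b] for b in rng.integers(0, 4, size=w))
        entries.append(DatabaseMotif(f"DECOY{j:03d}", word, ("decoy",)))
    return entries, truth
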