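"""Motif mapping and database annotation.

Maps motifs (typically cluster averages) back onto upstream flanking
regions on both strands by log-odds scanning against the background,
tallies instances per motif and gene, lays instances out TSS-relative
(TSS at the right end, offset 0), and ranks flat-file database consensi
(PLACE/JASPAR-consensus style) by IUPAC-compatible mismatch count against
a discovered motif.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seq
from ._seq import ALPHABET
from .genome_io import BackgroundModel, UpstreamRegion
from .motifs import (DatabaseMotif, Motif, iupac_compatible,
                     iupac_reverse_complement, reverse_complement_word)


@dataclass(frozen=True)
class MotifInstance:
    """One mapped occurrence of a motif in a region.

    ``offset`` is TSS-relative with the TSS at the right end of the
    region: an instance starting ``offset`` bases before the TSS has
    ``offset + width <= 0``.  ``matched_word`` is read on the motif's
    strand (for a minus-strand instance, the reverse complement of the
    region slice).
    """

    motif_id: str
    gene_id: str
    offset: int
    strand: str
    matched_word: str
    score: float

    def __post_init__(self) -> None:
        if self.offset + len(self.matched_word) > 0:
            raise ValueError(
                f"instance of {self.motif_id!r} in {self.gene_id!r}: "
                f"offset {self.offset} + width extends past the TSS")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class MatchResult:
    """One database hit for a query motif, ranked by mismatches."""

    query_motif_id: str
    database_id: str
    mismatches: int
    best_offset: int
    orientation: str
    rank: int


def scan_regions(motif: Motif, regions: Sequence[UpstreamRegion],
                 background: BackgroundModel, score_fraction: float = 0.85,
                 motif_id: str | None = None) -> list[MotifInstance]:
    """Scan regions on both strands by log-odds against the order-0
    background; positions scoring at least ``score_fraction`` of the
    motif's maximum achievable score are reported.  Windows containing N
    are skipped; a (gene, offset, strand) locus is never reported twice.
    """
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    w = motif.width
    bg = np.array([max(background.frequencies[1].get(b, 0.0), 1e-9)
                   for b in ALPHABET])
    bg = bg / bg.sum()
    lods = np.log2(np.maximum(motif.matrix, 1e-12) / bg[None, :])
    max_score = float(lods.max(axis=1).sum())
    threshold = score_fraction * max_score
    cols = np.arange(w)

    instances: list[MotifInstance] = []
    name = motif_id if motif_id is not None else (motif.provenance
                                                  or motif.consensus)
    for region in regions:
        if w > region.length:
            continue
        codes = _seq.encode(region.sequence)
        idx = np.lib.stride_tricks.sliding_window_view(codes, w)
        valid = (idx < 4).all(axis=1)
        if not valid.any():
            continue
        safe = np.where(idx < 4, idx, 0)
        fwd = lods[cols, safe].sum(axis=1)
        rc_lods = lods[::-1, [3, 2, 1, 0]]
        rev = rc_lods[cols, safe].sum(axis=1)
        for strand, scores in (("+", fwd), ("-", rev)):
            hits = np.nonzero(valid & (scores >= threshold - 1e-12))[0]
            for i in hits.tolist():
                word = region.sequence[i:i + w]
                if strand == "-":
                    word = reverse_complement_word(word)
                instances.append(MotifInstance(
                    name, region.gene_id, i - region.length, strand,
                    word, float(scores[i])))
    return instances


@dataclass
class TallyResult:
    """Motif x gene instance counts with totals and duplicate-layout
    groups (genes whose per-motif instance layouts are identical)."""

    table: pd.DataFrame
    totals: pd.Series
    identical_layout_groups: list[tuple[str, ...]]


def tally_instances(instances: Sequence[MotifInstance],
                    motif_ids: Sequence[str],
                    gene_ids: Sequence[str]) -> TallyResult:
    """Complete motif x gene count table (zero cells included), per-motif
    totals, and groups of genes with identical instance layouts."""
    motif_ids = list(motif_ids)
    gene_ids = list(gene_ids)
    known_m, known_g = set(motif_ids), set(gene_ids)
    table = pd.DataFrame(0, index=motif_ids, columns=gene_ids, dtype=int)
    layouts: dict[str, list] = {g: [] for g in gene_ids}
    for inst in instances:
        if inst.motif_id not in known_m:
            raise ValueError(f"instance references unknown motif "
                             f"{inst.motif_id!r}")
        if inst.gene_id not in known_g:
            raise ValueError(f"instance references unknown gene "
                             f"{inst.gene_id!r}")
        table.at[inst.motif_id, inst.gene_id] += 1
        layouts[inst.gene_id].append((inst.motif_id, inst.offset,
                                      inst.strand))
    totals = table.sum(axis=1)
    by_layout: dict[tuple, list[str]] = {}
    for g, lay in layouts.items():
        if lay:
            by_layout.setdefault(tuple(sorted(lay)), []).append(g)
    groups = [tuple(sorted(gs)) for gs in by_layout.values() if len(gs) > 1]
    return TallyResult(table, totals, sorted(groups))


def match_database(query: Motif, database: Sequence[DatabaseMotif],
                   top_n: int = 5, min_overlap: int = 4,
                   query_id: str | None = None) -> list[MatchResult]:
    """Rank database consensi against the query motif's consensus.

    Every ungapped offset with overlap >= ``min_overlap`` and both query
    orientations are searched; the mismatch count of an alignment is the
    number of overlapping positions whose IUPAC codes share no base
    ('.' matches anything).  Results are sorted by mismatches then
    database id; the top ``top_n`` are returned with ranks from 1.
    """
    if not database:
        raise ValueError("empty motif database")
    qid = query_id if query_id is not None else (query.provenance
                                                 or query.consensus)
    results = []
    for entry in database:
        best = None  # (mismatches, -overlap, offset, orientation)
        for orient, qcons in (("+", query.consensus),
                              ("-", iupac_reverse_complement(
                                  query.consensus))):
            lq, ld = len(qcons), len(entry.consensus)
            if min(lq, ld) < min_overlap:
                continue
            for off in range(-(lq - min_overlap), ld - min_overlap + 1):
                lo, hi = max(0, off), min(ld, off + lq)
                mm = sum(
                    not iupac_compatible(qcons[i - off], entry.consensus[i])
                    for i in range(lo, hi))
                cand = (mm, -(hi - lo), off, orient)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            results.append((best[0], entry.id, best[2], best[3]))
    results.sort(key=lambda r: (r[0], r[1]))
    return [MatchResult(qid, db_id, mm, off, orient, rank)
            for rank, (mm, db_id, off, orient)
            in enumerate(results[:top_n], start=1)]


def consensus_alignment_distance(a: str, b: str,
                                 count_overhang: bool = True) -> int:
    """Alignment-based Hamming distance between two IUPAC consensi.

    Minimum over all ungapped offsets and both orientations of the
    mismatch count in the overlap plus (when ``count_overhang``) the
    number of positions of either string left outside the overlap.  For
    equal-length strings at full overlap this is the plain Hamming
    distance.
    """
    best = None
    for bc in (b, iupac_reverse_complement(b)):
        la, lb = len(a), len(bc)
        for off in range(-lb + 1, la):
            lo, hi = max(0, off), min(la, off + lb)
            if hi <= lo:
                continue
            overlap = hi - lo
            mm = sum(not iupac_compatible(a[i], bc[i - off])
                     for i in range(lo, hi))
            if count_overhang:
                mm += (la - overlap) + (lb - overlap)
            if best is None or mm < best:
                best = mm
    if best is None:
        raise ValueError("empty consensus")
    return best


# ---------------------------------------------------------------------------
# layout export (TSS-anchored instance map)

def write_instances_bed(instances: Sequence[MotifInstance],
                        regions: Sequence[UpstreamRegion], handle) -> None:
    """BED-like export: region-relative 0-based half-open coordinates with
    strand and matched word columns."""
    lengths = {r.gene_id: r.length for r in regions}
    for inst in sorted(instances, key=lambda x: (x.gene_id, x.offset,
                                                 x.strand, x.motif_id)):
        L = lengths[inst.gene_id]
        start = inst.offset + L
        end = start + len(inst.matched_word)
        handle.write(f"{inst.gene_id}\t{start}\t{end}\t{inst.motif_id}\t"
                     f"{inst.score:.6g}\t{inst.strand}\t"
                     f"{inst.matched_word}\n")


def read_instances_bed(handle,
                       regions: Sequence[UpstreamRegion]
                       ) -> list[MotifInstance]:
    lengths = {r.gene_id: r.length for r in regions}
    out = []
    for line in handle:
        if not line.strip():
            continue
        gene, start, end, motif_id, score, strand, word = \
            line.rstrip("\n").split("\t")
        out.append(MotifInstance(motif_id, gene,
                                 int(start) - lengths[gene], strand, word,
                                 float(score)))
    return out


def export_map(instances: Sequence[MotifInstance],
               regions: Sequence[UpstreamRegion],
               bed_path: str, layout_path: str) -> dict:
    """Write the BED-like instance file and a per-gene JSON layout (every
    gene present, instances sorted by TSS-relative offset); returns the
    layout mapping."""
    layout: dict[str, list] = {r.gene_id: [] for r in regions}
    for inst in instances:
        if inst.gene_id not in layout:
            raise ValueError(f"instance references unknown gene "
                             f"{inst.gene_id!r}")
        layout[inst.gene_id].append({
            "motif": inst.motif_id, "offset": inst.offset,
            "strand": inst.strand, "word": inst.matched_word,
            "score": inst.score})
    for gene in layout:
        layout[gene].sort(key=lambda d: (d["offset"], d["strand"],
                                         d["motif"]))
    with open(bed_path, "w") as fh:
        write_instances_bed(instances, regions, fh)
    with open(layout_path, "w") as fh:
        json.dump(layout, fh, indent=2)
    return layout


def plot_instance_map(instances: Sequence[MotifInstance],
                      regions: Sequence[UpstreamRegion], ax=None):
    """Draw the TSS-anchored instance map: one horizontal track per gene,
    TSS at x = 0 on the right, one coloured rectangle per instance."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.3 * max(len(regions), 4)))
    motif_ids = sorted({i.motif_id for i in instances})
    cmap = plt.get_cmap("tab10")
    colors = {m: cmap(i % 10) for i, m in enumerate(motif_ids)}
    genes = [r.gene_id for r in regions]
    for y, region in enumerate(regions):
        ax.hlines(y, -region.length, 0, color="0.8", lw=1)
    for inst in instances:
        y = genes.index(inst.gene_id)
        ax.add_patch(Rectangle((inst.offset, y - 0.3),
                               len(inst.matched_word), 0.6,
                               color=colors[inst.motif_id]))
    ax.set_yticks(range(len(genes)), genes, fontsize=7)
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_xlim(-max(r.length for r in regions) - 10, 10)
    ax.set_ylim(-1, len(genes))
    handles = [Rectangle((0, 0), 1, 1, color=colors[m]) for m in motif_ids]
    if handles:
        ax.legend(handles, motif_ids, fontsize=6, loc="upper left")
    return ax
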