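"""Genome input, upstream flanking-region extraction and background model.

Reads a genome (FASTA) and gene annotation (GFF3), extracts the 1000 bp
flanking region immediately 5' of each gene's transcription start site on
the gene's own strand, and builds genome-wide word-frequency tables (orders
1..K) over all upstream regions.  The background model is what discovery
statistics and synthetic promoter generation are judged against.

Coordinates are 0-based half-open internally; GFF3's 1-based closed
convention is converted once, on read.
"""

from __future__ import annotations

import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from . import _seq

logger = logging.getLogger(__name__)

DEFAULT_FLANK_LENGTH = 1000
MIN_KEPT_LENGTH = 50


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's location: contig, strand and 0-based TSS coordinate."""

    gene_id: str
    contig_id: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative TSS")


@dataclass(frozen=True)
class UpstreamRegion:
    """A gene's 5' flanking sequence with genomic provenance.

    ``sequence`` reads 5'->3' on the gene's strand; its last base abuts the
    TSS (the base at the TSS itself is never included).  For minus-strand
    genes the sequence is the reverse complement of the genomic slice
    ``[start, end)``.
    """

    gene_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"region {self.gene_id!r}: interval length "
                f"{self.end - self.start} != sequence length "
                f"{len(self.sequence)}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BackgroundModel:
    """Word-frequency tables over upstream regions, per word length 1..K.

    ``frequencies[k]`` maps each observed k-word (no N) to its frequency
    among all valid k-windows; frequencies for each k sum to 1.  Words of
    length > K are assigned probabilities by an order-(K-1) Markov
    factorization.
    """

    frequencies: dict[int, dict[str, float]]
    totals: dict[int, int]
    n_regions: int

    @property
    def max_order(self) -> int:
        return max(self.frequencies)

    def frequency(self, word: str) -> float:
        """Frequency of a word of length <= K (0 if unobserved)."""
        k = len(word)
        if k not in self.frequencies:
            raise ValueError(f"background has no order-{k} table")
        return self.frequencies[k].get(word.upper(), 0.0)

    def word_probability(self, word: str) -> float:
        """Probability of a word under the model.

        Words up to length K use the empirical table directly; longer
        words use the order-(K-1) Markov chain built from the K and K-1
        tables.
        """
        word = word.upper()
        w, K = len(word), self.max_order
        if w <= K:
            return self.frequency(word)
        if K < 2:
            p = 1.0
            for c in word:
                p *= self.frequency(c)
            return p
        p = self.frequency(word[:K])
        for i in range(1, w - K + 1):
            denom = self.frequency(word[i:i + K - 1])
            if denom == 0.0:
                return 0.0
            p *= self.frequency(word[i:i + K]) / denom
        return p


def load_reference(genome_source, annotation_source
                   ) -> tuple[dict[str, str], list[GeneAnnotation]]:
    """Read genome FASTA and GFF3 gene features.

    Returns uppercased contig sequences keyed by id and one
    :class:`GeneAnnotation` per ``gene`` feature.  GFF3 coordinates are
    1-based closed; the TSS is ``start - 1`` for plus-strand genes and
    ``end - 1`` for minus-strand genes (0-based).
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(genome_source, "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig id {record.id!r} in FASTA")
        contigs[record.id] = str(record.seq).upper()

    annotations: list[GeneAnnotation] = []
    seen: set[str] = set()
    for gene_id, contig_id, strand, start, end in _parse_gff3_genes(
            annotation_source):
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r} in annotation")
        seen.add(gene_id)
        if contig_id not in contigs:
            raise ValueError(
                f"gene {gene_id!r} references contig {contig_id!r} "
                f"absent from the genome FASTA")
        if strand not in ("+", "-"):
            raise ValueError(
                f"gene {gene_id!r} has no usable strand ({strand!r})")
        tss = start - 1 if strand == "+" else end - 1
        L = len(contigs[contig_id])
        if not 0 <= tss < L:
            raise ValueError(
                f"gene {gene_id!r}: TSS {tss} outside contig "
                f"{contig_id!r} of length {L}")
        annotations.append(GeneAnnotation(gene_id, contig_id, strand, tss))
    return contigs, annotations


def _parse_gff3_genes(source) -> Iterable[tuple[str, str, str, int, int]]:
    """Yield (gene_id, contig, strand, start, end) for GFF3 gene features.

    Uses gffutils when the source is a file path; falls back to direct
    column parsing for in-memory streams.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        import gffutils
        db = gffutils.create_db(str(source), dbfn=":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
        for feat in db.features_of_type("gene"):
            yield feat.id, feat.seqid, feat.strand, feat.start, feat.end
        return
    text = source.read() if hasattr(source, "read") else str(source)
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9 or cols[2] != "gene":
            continue
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        gene_id = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
        if gene_id is None:
            raise ValueError(f"gene feature without ID attribute: {line!r}")
        yield gene_id, cols[0], cols[6], int(cols[3]), int(cols[4])


def extract_upstream(contigs: Mapping[str, str],
                     annotations: Sequence[GeneAnnotation],
                     flank_length: int = DEFAULT_FLANK_LENGTH,
                     min_length: int = MIN_KEPT_LENGTH
                     ) -> list[UpstreamRegion]:
    """Extract the ``flank_length`` bp upstream of each gene's TSS.

    Plus strand: genomic ``[max(0, tss - flank), tss)``.  Minus strand:
    ``[tss + 1, min(L, tss + 1 + flank))``, reverse complemented.  Regions
    truncated by a contig edge are kept at their true shorter length when
    at least ``min_length`` bp remain; shorter ones are dropped with a
    warning.
    """
    if flank_length < 1:
        raise ValueError("flank_length must be >= 1")
    regions: list[UpstreamRegion] = []
    for ann in annotations:
        contig = contigs[ann.contig_id]
        L = len(contig)
        if ann.strand == "+":
            start, end = max(0, ann.tss - flank_length), ann.tss
            seq = contig[start:end]
        else:
            start = ann.tss + 1
            end = min(L, ann.tss + 1 + flank_length)
            seq = str(Seq(contig[start:end]).reverse_complement())
        if end - start == 0:
            logger.warning("gene %s: upstream region has zero length "
                           "(TSS at contig edge); omitted", ann.gene_id)
            continue
        if end - start < min_length:
            logger.warning("gene %s: upstream region truncated to %d bp "
                           "(< %d); omitted", ann.gene_id, end - start,
                           min_length)
            continue
        if end - start < flank_length:
            logger.info("gene %s: upstream region truncated to %d bp at "
                        "contig edge", ann.gene_id, end - start)
        regions.append(UpstreamRegion(ann.gene_id, ann.contig_id,
                                      ann.strand, start, end, seq))
    return regions


def build_background(regions: Sequence[UpstreamRegion],
                     max_order: int = 4) -> BackgroundModel:
    """Count every k-window (k = 1..max_order, single strand, windows with
    N excluded) pooled over all regions and normalize to frequencies."""
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if not regions:
        raise ValueError("build_background requires at least one region")
    encoded = [_seq.encode(r.sequence) for r in regions]
    frequencies: dict[int, dict[str, float]] = {}
    totals: dict[int, int] = {}
    for k in range(1, max_order + 1):
        counter: Counter[int] = Counter()
        total = 0
        for codes in encoded:
            packed, valid = _seq.window_codes(codes, k)
            if packed.size == 0:
                continue
            kept = packed[valid]
            total += int(kept.size)
            vals, cnts = np.unique(kept, return_counts=True)
            for v, c in zip(vals.tolist(), cnts.tolist()):
                counter[v] += c
        if total == 0:
            raise ValueError(
                f"no valid window of length {k}: all regions too short "
                f"or all windows contain N")
        frequencies[k] = {_seq.decode_word(code, k): cnt / total
                          for code, cnt in sorted(counter.items())}
        totals[k] = total
    return BackgroundModel(frequencies, totals, len(regions))


# ---------------------------------------------------------------------------
# serialization

def write_regions_fasta(regions: Iterable[UpstreamRegion], handle) -> None:
    """Regions as FASTA with ``gene|contig|strand|start-end`` headers."""
    for r in regions:
        handle.write(f">{r.gene_id}|{r.contig_id}|{r.strand}|"
                     f"{r.start}-{r.end}\n{r.sequence}\n")


def read_regions_fasta(source) -> list[UpstreamRegion]:
    regions = []
    for record in SeqIO.parse(source, "fasta"):
        gene_id, contig, strand, interval = record.id.split("|")
        start, end = (int(x) for x in interval.split("-"))
        regions.append(UpstreamRegion(gene_id, contig, strand, start, end,
                                      str(record.seq).upper()))
    return regions


def write_background(model: BackgroundModel, base_path: str) -> None:
    """Serialize as one two-column table per order plus a JSON sidecar."""
    for k, freqs in model.frequencies.items():
        with open(f"{base_path}.k{k}.tsv", "w") as fh:
            for word, f in freqs.items():
                fh.write(f"{word}\t{f:.12g}\n")
    with open(f"{base_path}.json", "w") as fh:
        json.dump({"totals": model.totals, "n_regions": model.n_regions,
                   "max_order": model.max_order}, fh, indent=2)


def read_background(base_path: str) -> BackgroundModel:
    with open(f"{base_path}.json") as fh:
        meta = json.load(fh)
    frequencies = {}
    for k in range(1, meta["max_order"] + 1):
        with open(f"{base_path}.k{k}.tsv") as fh:
            frequencies[k] = {w: float(f) for w, f in
                              (line.split("\t") for line in fh
                               if line.strip())}
    return BackgroundModel(frequencies,
                           {int(k): v for k, v in meta["totals"].items()},
                           meta["n_regions"])
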