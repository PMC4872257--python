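"""Position weight matrix model and algebra.

A :class:`Motif` is a width x 4 column-stochastic matrix over (A, C, G, T)
together with an IUPAC consensus string, the engine that produced it and an
engine-native significance score.  The module provides the operations the
rest of the pipeline composes: PWM construction from instance words, IUPAC
consensus rendering, reverse complementation, information content, and an
offset/orientation-searching inter-motif distance used for redundancy
clustering.

Consensus notation uses three tiers: an uppercase base where one nucleotide
dominates a column, a lowercase two-base IUPAC code where two nucleotides
jointly dominate (e.g. ``r`` = A/G), and ``.`` for uninformative columns —
the style used to print degenerate plant promoter motifs such as
``A.ATrGAC``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

#: IUPAC code -> set of bases it stands for ('.' behaves like N)
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"}, ".": {"A", "C", "G", "T"},
}

#: two-base set -> lowercase IUPAC code used in the consensus middle tier
_PAIR_CODES = {
    frozenset("AG"): "r", frozenset("CT"): "y", frozenset("CG"): "s",
    frozenset("AT"): "w", frozenset("GT"): "k", frozenset("AC"): "m",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", ".": ".",
}


def iupac_complement(code: str) -> str:
    """Complement of a single IUPAC code, preserving case."""
    upper = code.upper()
    if upper not in _IUPAC_COMPLEMENT:
        raise ValueError(f"not an IUPAC code: {code!r}")
    comp = _IUPAC_COMPLEMENT[upper]
    return comp.lower() if code.islower() else comp


def iupac_reverse_complement(consensus: str) -> str:
    """Reverse complement of an IUPAC consensus string."""
    return "".join(iupac_complement(c) for c in reversed(consensus))


def iupac_compatible(a: str, b: str) -> bool:
    """True when two IUPAC codes share at least one concrete base."""
    try:
        return bool(IUPAC_SETS[a.upper()] & IUPAC_SETS[b.upper()])
    except KeyError as exc:
        raise ValueError(f"not an IUPAC code: {exc.args[0]!r}") from None


def reverse_complement_word(word: str) -> str:
    """Reverse complement of a plain A/C/G/T word (N allowed)."""
    table = str.maketrans("ACGTN", "TGCAN")
    return word.translate(table)[::-1]


@dataclass(frozen=True)
class Motif:
    """A column-stochastic position weight matrix with provenance.

    Parameters
    ----------
    matrix
        ``(width, 4)`` array; each row is a probability distribution over
        (A, C, G, T).
    consensus
        IUPAC consensus string of length ``width`` (derived if omitted).
    source
        Label of the discovery engine (or ``"planted"``, ``"average"`` ...).
    score
        Engine-native significance: a q-value, an e-value-like score, or a
        rank, depending on ``source``.
    provenance
        Free-form origin tag, e.g. ``"subset=17"`` or ``"cluster=3"``.
    """

    matrix: np.ndarray
    consensus: str = ""
    source: str = ""
    score: float = float("nan")
    provenance: str = ""

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError("motif matrix must have shape (width, 4)")
        if mat.shape[0] < 1:
            raise ValueError("motif must have width >= 1")
        if (mat < -1e-12).any():
            raise ValueError("motif matrix entries must be non-negative")
        sums = mat.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every motif column must sum to 1")
        object.__setattr__(self, "matrix", mat)
        if not self.consensus:
            object.__setattr__(self, "consensus", consensus_string(self))
        if len(self.consensus) != mat.shape[0]:
            raise ValueError("consensus length must equal motif width")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def with_meta(self, **kwargs) -> "Motif":
        """Copy with updated metadata fields."""
        return replace(self, **kwargs)

    def __eq__(self, other) -> bool:  # matrix-aware equality
        if not isinstance(other, Motif):
            return NotImplemented
        return (self.matrix.shape == other.matrix.shape
                and np.allclose(self.matrix, other.matrix, atol=1e-12)
                and self.consensus == other.consensus)

    def __hash__(self) -> int:
        return hash((self.consensus, self.width, self.source, self.provenance))

    def __repr__(self) -> str:
        return (f"Motif({self.consensus!r}, width={self.width}, "
                f"source={self.source!r}, score={self.score:g})")


@dataclass(frozen=True)
class DatabaseMotif:
    """One entry of a flat-file motif database: id, IUPAC consensus, keywords."""

    id: str
    consensus: str
    keywords: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"database motif {self.id!r} has empty consensus")
        for c in self.consensus:
            if c.upper() not in IUPAC_SETS:
                raise ValueError(
                    f"database motif {self.id!r}: invalid IUPAC code {c!r}")
        object.__setattr__(self, "keywords", tuple(self.keywords))


def pwm_from_instances(words: Sequence[str], pseudocount: float = 0.1,
                       **meta) -> Motif:
    """Build a PWM from equal-length instance words.

    Column probability for base *b* is ``(count_b + pseudocount) /
    (n + 4 * pseudocount)``.
    """
    if not words:
        raise ValueError("pwm_from_instances requires at least one word")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    width = len(words[0])
    if any(len(w) != width for w in words):
        raise ValueError("instance words must all have the same length")
    counts = np.zeros((width, 4), dtype=float)
    for w in words:
        for j, c in enumerate(w.upper()):
            try:
                counts[j, BASE_INDEX[c]] += 1
            except KeyError:
                raise ValueError(f"word {w!r} contains non-ACGT base {c!r}")
    matrix = (counts + pseudocount) / (len(words) + 4 * pseudocount)
    return Motif(matrix, **meta)


def consensus_string(motif: Motif, strong: float = 0.7,
                     pair: float = 0.8) -> str:
    """Render a three-tier IUPAC consensus.

    Per column: if the top base's probability is >= ``strong`` it is printed
    uppercase; otherwise if the top two bases jointly reach ``pair`` their
    two-base IUPAC code is printed lowercase; otherwise ``.``.
    """
    out = []
    for col in motif.matrix:
        order = np.argsort(col)[::-1]
        if col[order[0]] >= strong:
            out.append(ALPHABET[order[0]])
        elif col[order[0]] + col[order[1]] >= pair:
            pair_set = frozenset(ALPHABET[i] for i in order[:2])
            out.append(_PAIR_CODES[pair_set])
        else:
            out.append(".")
    return "".join(out)


def reverse_complement(motif: Motif) -> Motif:
    """Reverse complement: columns reversed, bases complemented."""
    mat = motif.matrix[::-1, COMPLEMENT_INDEX]
    return Motif(np.ascontiguousarray(mat), source=motif.source,
                 score=motif.score, provenance=motif.provenance)


def information_content(motif: Motif) -> float:
    """Total information content in bits: sum over columns of
    ``2 + sum_b p_b log2 p_b`` with ``0 log 0 := 0``."""
    p = motif.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return float((2.0 + plogp.sum(axis=1)).sum())


def _alignment_offsets(wa: int, wb: int, min_overlap: int) -> range:
    """Offsets of b relative to a with >= min_overlap overlapping columns."""
    return range(-(wb - min_overlap), wa - min_overlap + 1)


def best_alignment(a: Motif, b: Motif, min_overlap: int = 4
                   ) -> tuple[float, int, str]:
    """Best ungapped alignment of ``b`` onto ``a``.

    Searches every offset with at least ``min_overlap`` overlapping columns
    and both orientations of ``b``; the cost of an alignment is the mean
    Euclidean distance between overlapping column distributions.

    Returns
    -------
    (distance, offset, orientation)
        ``offset`` is the position of b's first column in a's coordinates
        (for orientation ``"-"``, of the reverse complement's first column);
        ``orientation`` is ``"+"`` or ``"-"``.
    """
    if a.width < min_overlap or b.width < min_overlap:
        raise ValueError(
            f"motif widths ({a.width}, {b.width}) below min_overlap "
            f"{min_overlap}: no valid alignment")
    best: tuple | None = None  # (d, -overlap, |off|, orient!=+, off, orient)
    for orient, bm in (("+", b.matrix),
                       ("-", b.matrix[::-1, COMPLEMENT_INDEX])):
        for off in _alignment_offsets(a.width, b.width, min_overlap):
            lo_a, hi_a = max(0, off), min(a.width, off + b.width)
            cols_a = a.matrix[lo_a:hi_a]
            cols_b = bm[lo_a - off:hi_a - off]
            d = float(np.mean(np.linalg.norm(cols_a - cols_b, axis=1)))
            # ties resolved toward longer overlaps, then "+" orientation
            key = (round(d, 12), -(hi_a - lo_a), abs(off),
                   orient != "+", off, orient)
            if best is None or key < best:
                best = key
    assert best is not None
    return best[0], best[4], best[5]


def motif_distance(a: Motif, b: Motif, min_overlap: int = 4) -> float:
    """Distance between two motifs: minimum over all ungapped offsets (with
    >= ``min_overlap`` overlapping columns) and both orientations of ``b`` of
    the mean per-column Euclidean distance.  Symmetric and zero iff some
    alignment matches all overlapping columns exactly."""
    return best_alignment(a, b, min_overlap)[0]


def motif_distance_pearson(a: Motif, b: Motif, min_overlap: int = 4) -> float:
    """Alternative metric: one minus the best mean per-column Pearson
    correlation over the same alignment search.  Provided for sensitivity
    analyses; the Euclidean form is the default everywhere."""
    if a.width < min_overlap or b.width < min_overlap:
        raise ValueError("motif widths below min_overlap")
    best = np.inf
    for bm in (b.matrix, b.matrix[::-1, COMPLEMENT_INDEX]):
        for off in _alignment_offsets(a.width, b.width, min_overlap):
            lo_a, hi_a = max(0, off), min(a.width, off + b.width)
            cols_a = a.matrix[lo_a:hi_a]
            cols_b = bm[lo_a - off:hi_a - off]
            ca = cols_a - cols_a.mean(axis=1, keepdims=True)
            cb = cols_b - cols_b.mean(axis=1, keepdims=True)
            denom = (np.linalg.norm(ca, axis=1) * np.linalg.norm(cb, axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, (ca * cb).sum(axis=1) / denom, 0.0)
            best = min(best, float(1.0 - r.mean()))
    return best


# ---------------------------------------------------------------------------
# serialization

def write_meme(motifs: Iterable[Motif], handle,
               background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> None:
    """Write motifs in MEME minimal motif format."""
    handle.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    handle.write("Background letter frequencies\n")
    handle.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*background))
    for i, m in enumerate(motifs, start=1):
        name = m.consensus or f"motif_{i}"
        handle.write(f"MOTIF {name} {m.provenance or i}\n")
        handle.write(
            f"letter-probability matrix: alength= 4 w= {m.width} "
            f"nsites= 20 E= {0.0 if np.isnan(m.score) else m.score:g}\n")
        for row in m.matrix:
            handle.write(" {:8.6f} {:8.6f} {:8.6f} {:8.6f}\n".format(*row))
        handle.write("\n")


def read_meme(handle) -> list[Motif]:
    """Read motifs from MEME minimal motif format."""
    motifs: list[Motif] = []
    lines = handle.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else ""
            prov = parts[2] if len(parts) > 2 else ""
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability"):
                i += 1
            header = lines[i].strip()
            width = int(header.split("w=")[1].split()[0])
            score = float(header.split("E=")[1].split()[0]) \
                if "E=" in header else float("nan")
            rows = []
            for j in range(width):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            mat = np.array(rows)
            mat = mat / mat.sum(axis=1, keepdims=True)
            motifs.append(Motif(mat, consensus=name if set(name.upper())
                                <= set(IUPAC_SETS) and len(name) == width
                                else "", provenance=prov, score=score))
            i += 1 + width
        else:
            i += 1
    return motifs


def load_motif_database(handle) -> list[DatabaseMotif]:
    """Read a flat-file motif database: tab-delimited ``id<TAB>consensus
    [<TAB>keyword;keyword...]`` with ``#`` comments."""
    entries = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"database line {lineno}: expected at least "
                             f"id<TAB>consensus, got {line!r}")
        keywords = tuple(k for k in parts[2].split(";")) if len(parts) > 2 \
            else ()
        entries.append(DatabaseMotif(parts[0], parts[1], keywords))
    return entries


def write_motif_database(entries: Iterable[DatabaseMotif], handle) -> None:
    for e in entries:
        handle.write(f"{e.id}\t{e.consensus}\t{';'.join(e.keywords)}\n")
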