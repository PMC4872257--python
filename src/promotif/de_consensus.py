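"""Cross-condition differential-expression consensus.

Consumes per-condition DE tables (CuffDiff-style gene_exp.diff output) for
a grid of cultivars x time points and intersects them into single lists of
genes consistently over- or under-expressed in every cell, plus a tally of
genes responsive in all cultivars at exactly one time point.  Also provides
the housekeeping geometric-mean normalization and Spearman rank-correlation
computations used to validate expression measurements across platforms.

Differential expression itself is consumed, never recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

#: default column mapping for CuffDiff gene_exp.diff-style tables
CUFFDIFF_COLUMNS = {"gene_id": "gene_id", "log2fc": "log2(fold_change)",
                    "p": "p_value", "q": "q_value",
                    "significant": "significant"}


@dataclass(frozen=True)
class DERecord:
    """One gene's DE result in one (cultivar, timepoint) analysis."""

    gene_id: str
    log2fc: float
    p: float
    q: float
    significant: bool

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative q-value")


@dataclass(frozen=True)
class ConsensusResult:
    """Genes responsive in every grid cell, plus per-timepoint-only counts.

    ``timepoint_only[t] = (n_over, n_under)`` counts genes significant in
    all cultivars at time point ``t`` only (the single-timepoint response
    class that is reported but excluded from the consensus lists).
    """

    over_expressed: tuple[str, ...]
    under_expressed: tuple[str, ...]
    timepoint_only: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.over_expressed) & set(self.under_expressed):
            raise ValueError("over/under lists must be disjoint")

    @property
    def all_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.over_expressed + self.under_expressed))


def load_de_tables(sources: Mapping[tuple[str, str], object],
                   columns: Mapping[str, str] | None = None
                   ) -> dict[tuple[str, str], list[DERecord]]:
    """Parse one tab-delimited DE table per (cultivar, timepoint) cell.

    ``columns`` maps the canonical field names (gene_id, log2fc, p, q,
    significant) to the table's column headers; defaults to CuffDiff's
    gene_exp.diff names.  The ``significant`` column holds ``yes``/``no``.
    """
    cols = dict(CUFFDIFF_COLUMNS)
    if columns:
        cols.update(columns)
    tables: dict[tuple[str, str], list[DERecord]] = {}
    for cell, source in sources.items():
        try:
            df = pd.read_csv(source, sep="\t")
        except pd.errors.EmptyDataError:
            logger.warning("DE table for %s is empty", cell)
            tables[cell] = []
            continue
        missing = [v for v in cols.values() if v not in df.columns]
        if missing:
            raise ValueError(f"DE table {cell}: missing columns {missing}")
        records = []
        seen: set[str] = set()
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            r = dict(zip(df.columns, row))
            gene = str(r[cols["gene_id"]])
            if gene in seen:
                raise ValueError(
                    f"DE table {cell}: duplicate gene {gene!r}")
            seen.add(gene)
            try:
                rec = DERecord(
                    gene, float(r[cols["log2fc"]]), float(r[cols["p"]]),
                    float(r[cols["q"]]),
                    str(r[cols["significant"]]).strip().lower()
                    in ("yes", "true", "1"))
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"DE table {cell}, line {lineno}: malformed row "
                    f"({exc})") from None
            records.append(rec)
        tables[cell] = records
    return tables


def _is_significant(rec: DERecord, alpha: float) -> bool:
    # the loader's flag takes precedence; the q threshold always applies
    return rec.significant and rec.q <= alpha


def consensus_gene_lists(tables: Mapping[tuple[str, str], Sequence[DERecord]],
                         alpha: float = DEFAULT_ALPHA,
                         require_direction: bool = True) -> ConsensusResult:
    """Intersect the grid into consistent over/under-expressed gene lists.

    A gene is over-expressed iff it is significant (flag and q <= alpha)
    with positive log2 fold change in *every* grid cell; under-expressed
    likewise with negative sign.  With ``require_direction=False`` the sign
    consistency requirement is dropped and direction is taken from the
    first cell.  Genes significant in all cultivars at exactly one time
    point are tallied per direction in ``timepoint_only``.  Genes absent
    from a table are treated as non-significant there.
    """
    if not tables:
        raise ValueError("empty DE table grid")
    cells = sorted(tables)
    cultivars = sorted({c for c, _ in cells})
    timepoints = sorted({t for _, t in cells})
    if {(c, t) for c in cultivars for t in timepoints} != set(cells):
        missing = [(c, t) for c in cultivars for t in timepoints
                   if (c, t) not in tables]
        raise ValueError(f"incomplete grid: missing cells {missing}")

    index: dict[tuple[str, str], dict[str, DERecord]] = {
        cell: {r.gene_id: r for r in tables[cell]} for cell in cells}
    universe = sorted({g for cell in cells for g in index[cell]})

    def cell_call(gene: str, cell: tuple[str, str]) -> int:
        """+1 significant up, -1 significant down, 0 otherwise."""
        rec = index[cell].get(gene)
        if rec is None or not _is_significant(rec, alpha):
            return 0
        if rec.log2fc > 0:
            return 1
        if rec.log2fc < 0:
            return -1
        return 0

    over, under = [], []
    tp_only = {t: [0, 0] for t in timepoints}
    for gene in universe:
        calls = {cell: cell_call(gene, cell) for cell in cells}
        if require_direction:
            consistent_up = all(calls[c] == 1 for c in cells)
            consistent_down = all(calls[c] == -1 for c in cells)
        else:
            all_sig = all(calls[c] != 0 for c in cells)
            first = calls[cells[0]]
            consistent_up = all_sig and first == 1
            consistent_down = all_sig and first == -1
        if consistent_up:
            over.append(gene)
            continue
        if consistent_down:
            under.append(gene)
            continue
        # timepoint-specific: consistent within exactly one timepoint
        per_tp = {}
        for t in timepoints:
            tp_calls = [calls[(c, t)] for c in cultivars]
            if all(v == 1 for v in tp_calls):
                per_tp[t] = 1
            elif all(v == -1 for v in tp_calls):
                per_tp[t] = -1
        if len(per_tp) == 1:
            (t, direction), = per_tp.items()
            tp_only[t][0 if direction == 1 else 1] += 1
    return ConsensusResult(tuple(over), tuple(under),
                           {t: (n[0], n[1]) for t, n in tp_only.items()})


def normalize_by_housekeeping(counts: pd.DataFrame,
                              housekeeping_ids: Sequence[str]
                              ) -> pd.DataFrame:
    """Rescale a gene x sample count matrix so the housekeeping genes'
    geometric mean is equal across samples.

    Per-sample factor = (mean over samples of the housekeeping geometric
    means) / (this sample's housekeeping geometric mean); every count is
    multiplied by its sample's factor.
    """
    if not housekeeping_ids:
        raise ValueError("at least one housekeeping gene required")
    missing = [g for g in housekeeping_ids if g not in counts.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    hk = counts.loc[list(housekeeping_ids)]
    bad = hk <= 0
    if bad.to_numpy().any():
        gene, sample = next((g, s) for g in hk.index for s in hk.columns
                            if hk.at[g, s] <= 0)
        raise ValueError(
            f"housekeeping gene {gene!r} has non-positive count in sample "
            f"{sample!r}")
    gmeans = pd.Series(stats.gmean(hk.to_numpy(), axis=0),
                       index=counts.columns)
    factors = gmeans.mean() / gmeans
    return counts.mul(factors, axis=1)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# serialization

def write_consensus(result: ConsensusResult, over_path: str, under_path: str,
                    summary_path: str) -> None:
    """Two one-column gene lists plus a JSON summary with the
    per-timepoint-only counts."""
    import json
    with open(over_path, "w") as fh:
        fh.write("\n".join(result.over_expressed) + "\n")
    with open(under_path, "w") as fh:
        fh.write("\n".join(result.under_expressed) + "\n")
    with open(summary_path, "w") as fh:
        json.dump({"n_over": len(result.over_expressed),
                   "n_under": len(result.under_expressed),
                   "timepoint_only": {t: {"over": n[0], "under": n[1]}
                                      for t, n in
                                      result.timepoint_only.items()}},
                  fh, indent=2)


def write_de_table(records: Sequence[DERecord], handle) -> None:
    """Write records in the CuffDiff-style format the loader reads."""
    cols = CUFFDIFF_COLUMNS
    handle.write("\t".join([cols["gene_id"], cols["log2fc"], cols["p"],
                            cols["q"], cols["significant"]]) + "\n")
    for r in records:
        handle.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.p:.6g}\t{r.q:.6g}\t"
                     f"{'yes' if r.significant else 'no'}\n")
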