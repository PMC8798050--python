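"""Alignment-quality filters applied before phylogenetic analysis.

Three screens for violations of the stationarity/reversibility/homogeneity
(SRH) assumptions of standard substitution models:

* **RCFV** — relative composition frequency variation: the mean over taxa of
  the summed absolute deviations of per-taxon state frequencies from the
  across-taxa mean frequency.  Compositional heterogeneity within a
  partition is considered high when RCFV >= 0.1.
* **Bowker's maximum symmetry test** — chi-square test of symmetry of the
  4x4 pairwise substitution count matrix for a sequence pair; rejection
  (p < 0.05) flags SRH violation / saturation.
* **Completeness** ``Ca`` — fraction of matrix cells that are unambiguous
  nucleotides.

``filter_partitions`` applies the exclusion rule: drop a partition when its
RCFV >= cutoff or its minimum pairwise Bowker p-value < alpha.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .distances import _encode
from .errors import MotuinvError
from .io import DNA_STATES, Alignment, PartitionScheme

logger = logging.getLogger(__name__)

RCFV_CUTOFF = 0.1
SYMMETRY_ALPHA = 0.05


def _state_counts(aln: Alignment) -> np.ndarray:
    """(n_taxa, 4) counts of A,C,G,T per row; other symbols ignored."""
    mat = aln.to_char_matrix()
    return np.stack([(mat == s).sum(axis=1) for s in DNA_STATES], axis=1)


def rcfv(aln: Alignment) -> float:
    """Relative composition frequency variation of one partition.

    Frequencies are computed over resolved (A/C/G/T) sites only; taxa with no
    resolved sites are excluded with a warning.  With per-taxon frequencies
    f_ts and across-taxa means m_s,

        RCFV = sum_t sum_s |f_ts - m_s| / n_taxa.
    """
    counts = _state_counts(aln)
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise MotuinvError("no taxon has any resolved site")
    if not keep.all():
        dropped = [aln.ids[i] for i in np.flatnonzero(~keep)]
        logger.warning("rcfv: excluding taxa with no resolved sites: %s", dropped)
    freqs = counts[keep] / totals[keep, None]
    if freqs.shape[0] < 2:
        raise MotuinvError("RCFV needs at least 2 taxa with resolved sites")
    mean = freqs.mean(axis=0)
    return float(np.abs(freqs - mean).sum() / freqs.shape[0])


@dataclass(frozen=True)
class BowkerResult:
    statistic: float
    df: int
    p_value: float
    degenerate: bool = False


def bowker_test(a: str, b: str) -> BowkerResult:
    """Bowker's test of symmetry on the pairwise substitution count matrix.

    Sites where either symbol is not A/C/G/T are excluded.  With n_ij the
    count of (a=i, b=j) site pairs,

        S = sum_{i<j, n_ij + n_ji > 0} (n_ij - n_ji)^2 / (n_ij + n_ji)

    and df counts the included (i, j) pairs.  If no off-diagonal pair has
    any counts (e.g. identical sequences), the result is degenerate with
    p = 1.
    """
    if len(a) != len(b):
        raise MotuinvError("Bowker test requires equal-length sequences")
    codes = _encode([a, b])
    both = (codes[0] != 255) & (codes[1] != 255)
    pairs = codes[0][both].astype(np.int64) * 4 + codes[1][both]
    n = np.bincount(pairs, minlength=16).reshape(4, 4)
    s = 0.0
    df = 0
    for i, j in itertools.combinations(range(4), 2):
        tot = n[i, j] + n[j, i]
        if tot > 0:
            s += (n[i, j] - n[j, i]) ** 2 / tot
            df += 1
    if df == 0:
        return BowkerResult(0.0, 0, 1.0, degenerate=True)
    return BowkerResult(float(s), df, float(chi2.sf(s, df)))


def pairwise_symmetry(aln: Alignment) -> pd.DataFrame:
    """Bowker results for all taxon pairs of one partition (long format)."""
    rows = []
    for (ra, rb) in itertools.combinations(aln.records, 2):
        res = bowker_test(ra.seq, rb.seq)
        rows.append(
            {
                "taxon_a": ra.id,
                "taxon_b": rb.id,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["taxon_a", "taxon_b", "statistic", "df", "p_value", "degenerate"],
    )


def completeness_score(aln: Alignment) -> float:
    """Overall completeness Ca: fraction of cells that are A/C/G/T."""
    mat = aln.to_char_matrix()
    resolved = np.isin(mat, list(DNA_STATES))
    return float(resolved.mean())


def completeness_by_taxon(aln: Alignment) -> pd.Series:
    mat = aln.to_char_matrix()
    resolved = np.isin(mat, list(DNA_STATES))
    return pd.Series(resolved.mean(axis=1), index=aln.ids, name="Cr")


@dataclass
class QCReport:
    """Per-partition QC metrics plus keep/drop decisions."""

    table: pd.DataFrame
    pairwise: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["keep"]])

    @property
    def dropped(self) -> list[str]:
        return list(self.table.index[~self.table["keep"]])


def partition_qc(
    aln: Alignment,
    scheme: PartitionScheme,
    rcfv_cutoff: float = RCFV_CUTOFF,
    symmetry_alpha: float = SYMMETRY_ALPHA,
) -> QCReport:
    """Compute RCFV, pairwise symmetry and completeness for each partition
    and apply the exclusion rule (see :func:`filter_partitions`)."""
    rows = []
    pairwise: dict[str, pd.DataFrame] = {}
    unusable: list[str] = []
    for name, sl in scheme.slices().items():
        part = aln.columns(sl.start, sl.stop)
        try:
            rcfv_value = rcfv(part)
        except MotuinvError:
            # fewer than 2 taxa carry any data in this partition
            unusable.append(name)
            rcfv_value = float("nan")
        pw = pairwise_symmetry(part)
        pairwise[name] = pw
        non_degenerate = pw.loc[~pw["degenerate"], "p_value"]
        min_p = float(non_degenerate.min()) if len(non_degenerate) else 1.0
        frac_failing = (
            float((pw["p_value"] < symmetry_alpha).mean()) if len(pw) else 0.0
        )
        rows.append(
            {
                "partition": name,
                "rcfv": rcfv_value,
                "min_bowker_p": min_p,
                "frac_pairs_failing": frac_failing,
                "ca": completeness_score(part),
            }
        )
    table = pd.DataFrame(rows).set_index("partition")
    report = QCReport(table, pairwise)
    filter_partitions(report, rcfv_cutoff, symmetry_alpha)
    for name in unusable:
        table.loc[name, "keep"] = False
        table.loc[name, "reason"] = "insufficient_data"
    return report


def filter_partitions(
    report: QCReport,
    rcfv_cutoff: float = RCFV_CUTOFF,
    symmetry_alpha: float = SYMMETRY_ALPHA,
) -> tuple[list[str], list[str]]:
    """Apply the exclusion rule and record decisions in the report table.

    A partition is dropped when RCFV >= ``rcfv_cutoff`` or the minimum
    pairwise Bowker p-value < ``symmetry_alpha``; the reason is recorded.
    Returns (kept, dropped) partition name lists.
    """
    t = report.table
    reasons = []
    for _, row in t.iterrows():
        r = []
        if row["rcfv"] >= rcfv_cutoff:
            r.append("RCFV")
        if row["min_bowker_p"] < symmetry_alpha:
            r.append("symmetry")
        reasons.append(",".join(r))
    t["keep"] = [not r for r in reasons]
    t["reason"] = reasons
    return report.kept, report.dropped
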