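"""Regional diversity, endemism and turnover accounting.

Turns an mOTU partition plus voucher metadata into the headline tables of a
DNA-based inventory: per-region mOTU counts at each delimitation threshold
against formally described species counts (with analyzed/described ratios),
endemic mOTU tallies, and cross-landmass turnover classified by the sea
barrier separating each landmass pair (deep sea > 200 m, inundated shelf
< 100 m, or contiguous land).

Counting rules
--------------
* An mOTU contributes to every region where at least one member occurs, so
  regional rows can share mOTUs; the TOTAL row counts each mOTU once and a
  separate TOTAL_BY_OCCURRENCE row gives the column sums.
* Ratios are rounded half-up to 2 decimals and an undefined ratio (zero
  described species) renders as an em dash.
* A multi-landmass mOTU is counted once per barrier class found among the
  landmass pairs it spans; single-landmass mOTUs are excluded from turnover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import MotuinvError
from .io import BARRIER_CLASSES, BarrierMap, VoucherMetadata
from .motu import MotuPartition

logger = logging.getLogger(__name__)

UNDEFINED_RATIO = "—"  # em dash

TOTAL_ROW = "TOTAL"
OCCURRENCE_ROW = "TOTAL_BY_OCCURRENCE"


def described_ratio(analyzed: int, described: int) -> float | None:
    """analyzed/described rounded half-up to 2 decimals; None if undefined."""
    if described < 0 or analyzed < 0:
        raise MotuinvError("counts must be non-negative")
    if described == 0:
        return None
    q = (Decimal(analyzed) / Decimal(described)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def _occurrences(
    partition: MotuPartition,
    metadata: Iterable[VoucherMetadata],
    unit: str,
) -> dict[int, set[str]]:
    """mOTU id -> set of units (regions or landmasses) of occurrence."""
    meta = {m.terminal_id: m for m in metadata}
    occ: dict[int, set[str]] = {}
    missing = 0
    for term, cid in partition.assignment.items():
        m = meta.get(term)
        if m is None or not getattr(m, unit):
            missing += 1
            continue
        occ.setdefault(cid, set()).add(getattr(m, unit))
    if missing:
        logger.warning(
            "%d terminals without %s metadata excluded from accounting",
            missing, unit,
        )
    return occ


def aggregate_regions(
    partitions: Mapping[str, MotuPartition],
    metadata: Iterable[VoucherMetadata],
    described: Mapping[str, int],
) -> pd.DataFrame:
    """Per-region described-species and mOTU counts with ratios.

    ``partitions`` maps a threshold label (e.g. ``"2%"``) to a partition;
    ``described`` maps region to its formally described species count.
    Returns a table with one row per region plus TOTAL (unique mOTUs) and
    TOTAL_BY_OCCURRENCE (column sums) rows.
    """
    metadata = list(metadata)
    labels = list(partitions)
    regions = list(described)
    occ_by_label = {
        lab: _occurrences(partitions[lab], metadata, "region")
        for lab in labels
    }
    for lab, occ in occ_by_label.items():
        extra = {r for units in occ.values() for r in units} - set(regions)
        if extra:
            regions.extend(sorted(extra))
    rows = []
    for region in regions:
        row = {"region": region, "described": int(described.get(region, 0))}
        for lab in labels:
            count = sum(
                1 for units in occ_by_label[lab].values() if region in units
            )
            row[f"motus_{lab}"] = count
            ratio = described_ratio(count, row["described"])
            row[f"ratio_{lab}"] = ratio
        rows.append(row)
    total = {"region": TOTAL_ROW, "described": sum(
        int(described[r]) for r in described
    )}
    occurrence = {"region": OCCURRENCE_ROW, "described": total["described"]}
    for lab in labels:
        total[f"motus_{lab}"] = len(occ_by_label[lab])
        total[f"ratio_{lab}"] = described_ratio(
            total[f"motus_{lab}"], total["described"]
        )
        occurrence[f"motus_{lab}"] = sum(r[f"motus_{lab}"] for r in rows)
        occurrence[f"ratio_{lab}"] = described_ratio(
            occurrence[f"motus_{lab}"], occurrence["described"]
        )
    rows.extend([total, occurrence])
    return pd.DataFrame(rows).set_index("region")


def endemism_table(
    partition: MotuPartition,
    metadata: Iterable[VoucherMetadata],
    level: str = "landmass",
) -> tuple[pd.DataFrame, float]:
    """Per-unit endemic mOTU counts and the global endemic proportion.

    An mOTU is endemic when all its occurrences fall in a single unit
    (``level`` is ``"region"`` or ``"landmass"``).
    """
    if level not in ("region", "landmass"):
        raise MotuinvError("level must be 'region' or 'landmass'")
    occ = _occurrences(partition, list(metadata), level)
    if not occ:
        return (
            pd.DataFrame(columns=["motus", "endemics", "endemic_prop"]),
            float("nan"),
        )
    units = sorted({u for s in occ.values() for u in s})
    rows = []
    for unit in units:
        present = [cid for cid, s in occ.items() if unit in s]
        endemics = [cid for cid in present if occ[cid] == {unit}]
        rows.append(
            {
                "unit": unit,
                "motus": len(present),
                "endemics": len(endemics),
                "endemic_prop": len(endemics) / len(present),
            }
        )
    global_prop = sum(1 for s in occ.values() if len(s) == 1) / len(occ)
    return pd.DataFrame(rows).set_index("unit"), global_prop


@dataclass
class TurnoverTable:
    """Counts of mOTUs spanning landmass pairs, by barrier class."""

    per_motu: pd.DataFrame
    counts: dict[str, int]

    @property
    def n_multi_landmass(self) -> int:
        return len(self.per_motu)


def turnover(
    partition: MotuPartition,
    metadata: Iterable[VoucherMetadata],
    barriers: BarrierMap,
) -> TurnoverTable:
    """Classify every multi-landmass mOTU by the barriers it spans.

    For each mOTU occupying >= 2 landmasses, every spanned landmass pair is
    classified with the barrier map; the mOTU increments the count of each
    barrier class it spans at least once.  Counts are invariant to terminal
    order and to duplicate occurrences.
    """
    occ = _occurrences(partition, list(metadata), "landmass")
    rows = []
    counts = {cls: 0 for cls in BARRIER_CLASSES}
    for cid in sorted(occ):
        landmasses = occ[cid]
        if len(landmasses) < 2:
            continue
        classes = set()
        pair_list = []
        lm = sorted(landmasses)
        for i, a in enumerate(lm):
            for b in lm[i + 1:]:
                cls = barriers.classify(a, b)
                classes.add(cls)
                pair_list.append(f"{a}|{b}:{cls}")
        for cls in classes:
            counts[cls] += 1
        rows.append(
            {
                "motu": cid,
                "landmasses": ",".join(lm),
                "barrier_classes": ",".join(sorted(classes)),
                "pairs": ";".join(pair_list),
            }
        )
    per_motu = pd.DataFrame(
        rows, columns=["motu", "landmasses", "barrier_classes", "pairs"]
    )
    return TurnoverTable(per_motu, counts)


def render_report(
    tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
) -> list[Path]:
    """Write each table as TSV with deterministic column order.

    Ratios are already rounded; undefined ratios render as an em dash.
    Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = outdir / f"{name}.tsv"
        df = tables[name].copy()
        for col in df.columns:
            if str(col).startswith("ratio_"):
                df[col] = [
                    UNDEFINED_RATIO if v is None or pd.isna(v) else f"{v:.2f}"
                    for v in df[col]
                ]
        df.to_csv(path, sep="\t")
        written.append(path)
    return written
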