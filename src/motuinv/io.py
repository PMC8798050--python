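"""Readers/writers for the formats the pipeline touches.

Sequences travel as :class:`Alignment` (equal-length rows over the IUPAC DNA
alphabet plus ``-``/``?``/``N``), trees as :class:`dendropy.Tree`, voucher
metadata as :class:`VoucherMetadata` rows, and sea barriers between landmasses
as a :class:`BarrierMap`.  Fragment supermatrices are assembled by
:func:`concatenate_fragments`, which records fragment coordinates in a
:class:`PartitionScheme` (1-based inclusive in files, 0-based half-open via
:meth:`PartitionScheme.slices`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DuplicateIdError, MotuinvError, RaggedAlignmentError

logger = logging.getLogger(__name__)

#: Unambiguous nucleotide states; everything else is treated as missing
#: by the distance and QC machinery.
DNA_STATES = "ACGT"

#: Characters accepted in an aligned row.
ALPHABET = set("ACGTRYSWKMBDHVN-?")

#: Missing-fragment fill character, distinct from the alignment gap '-';
#: both are missing downstream.
FILL_CHAR = "?"

BARRIER_CLASSES = ("deep_sea", "shelf", "contiguous")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned terminal: a voucher specimen's sequence row."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise MotuinvError(f"empty sequence for id {self.id!r}")

    @property
    def ungapped_length(self) -> int:
        """Number of residues that are not '-' or '?'."""
        return sum(1 for c in self.seq if c not in "-?")


class Alignment:
    """An ordered, equal-length collection of aligned DNA sequences."""

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: list[SequenceRecord] = list(records)
        if not self.records:
            raise MotuinvError("alignment must contain at least one sequence")
        length = len(self.records[0].seq)
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate terminal id {rec.id!r}")
            seen.add(rec.id)
            if len(rec.seq) != length:
                raise RaggedAlignmentError(
                    f"ragged alignment: {rec.id!r} has length {len(rec.seq)}, "
                    f"expected {length}"
                )
        self.length = length

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, terminal_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == terminal_id:
                return rec
        raise KeyError(terminal_id)

    def __contains__(self, terminal_id: str) -> bool:
        return any(rec.id == terminal_id for rec in self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and self.records == other.records

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def to_char_matrix(self) -> np.ndarray:
        """Rows as a (n_taxa, n_columns) array of single characters."""
        return np.array([list(rec.seq) for rec in self.records], dtype="<U1")

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Row subset in the given order; unknown ids raise ``KeyError``."""
        index = {rec.id: rec for rec in self.records}
        return Alignment([index[i] for i in ids])

    def columns(self, start: int, stop: int) -> "Alignment":
        """Column slice [start, stop) as a new alignment."""
        return Alignment(
            [SequenceRecord(rec.id, rec.seq[start:stop]) for rec in self.records]
        )


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file, preserving record order and upper-casing.

    Raises on ragged rows (naming the offending id), duplicate ids, and
    characters outside the IUPAC + gap/missing alphabet.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise MotuinvError(
                f"{path.name}: sequence {rec.id!r} contains invalid characters "
                f"{sorted(bad)}"
            )
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise MotuinvError(f"{path.name}: no FASTA records found")
    return Alignment(records)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(rec.seq), id=rec.id, description="") for rec in aln),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Voucher metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = (
    "terminal_id",
    "subtribe",
    "subregion",
    "region",
    "landmass",
    "fragments",
)


@dataclass(frozen=True)
class VoucherMetadata:
    """Geographic and taxonomic context for one sequenced voucher."""

    terminal_id: str
    subtribe: str
    subregion: str
    region: str
    landmass: str
    fragments_present: frozenset[str] = field(default_factory=frozenset)


def read_metadata(
    path: str | Path,
    regions: Sequence[str] | None = None,
    landmasses: Sequence[str] | None = None,
    alignment: Alignment | None = None,
) -> list[VoucherMetadata]:
    """Read a voucher table (TSV with a header).

    ``regions``/``landmasses`` are controlled vocabularies; labels outside
    them are an error.  Terminals absent from ``alignment`` (when given) are
    retained with a warning — vouchers routinely outnumber usable sequences.
    """
    path = Path(path)
    rows: list[VoucherMetadata] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in METADATA_COLUMNS if c not in header]
        if missing:
            raise MotuinvError(f"{path.name}: missing metadata columns {missing}")
        idx = {c: header.index(c) for c in METADATA_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            get = lambda c: fields[idx[c]].strip() if idx[c] < len(fields) else ""
            region = get("region")
            landmass = get("landmass")
            if regions is not None and region not in regions:
                raise MotuinvError(
                    f"{path.name}:{lineno}: unknown region {region!r} "
                    f"(declared: {sorted(regions)})"
                )
            if landmasses is not None and landmass not in landmasses:
                raise MotuinvError(
                    f"{path.name}:{lineno}: unknown landmass {landmass!r}"
                )
            frag_field = get("fragments")
            fragments = frozenset(f for f in frag_field.split(",") if f)
            rows.append(
                VoucherMetadata(
                    terminal_id=get("terminal_id"),
                    subtribe=get("subtribe"),
                    subregion=get("subregion"),
                    region=region,
                    landmass=landmass,
                    fragments_present=fragments,
                )
            )
    if alignment is not None:
        absent = [r.terminal_id for r in rows if r.terminal_id not in alignment]
        if absent:
            logger.warning(
                "%d metadata terminals absent from alignment (retained), e.g. %s",
                len(absent),
                absent[:3],
            )
    return rows


def write_metadata(rows: Iterable[VoucherMetadata], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(METADATA_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.terminal_id,
                        r.subtribe,
                        r.subregion,
                        r.region,
                        r.landmass,
                        ",".join(sorted(r.fragments_present)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sea barriers between landmasses
# ---------------------------------------------------------------------------


class BarrierMap:
    """Symmetric map from unordered landmass pairs to a barrier class.

    Classes: ``deep_sea`` (sea deeper than 200 m between the landmasses),
    ``shelf`` (inundated shelf shallower than 100 m), ``contiguous``.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], str] | None = None):
        self._map: dict[frozenset, str] = {}
        for (a, b), cls in (pairs or {}).items():
            self.set(a, b, cls)

    def set(self, a: str, b: str, barrier_class: str) -> None:
        if barrier_class not in BARRIER_CLASSES:
            raise MotuinvError(
                f"unknown barrier class {barrier_class!r}; "
                f"expected one of {BARRIER_CLASSES}"
            )
        if a == b:
            raise MotuinvError("a landmass cannot have a barrier to itself")
        self._map[frozenset((a, b))] = barrier_class

    def classify(self, a: str, b: str) -> str:
        key = frozenset((a, b))
        if key not in self._map:
            raise MotuinvError(f"landmass pair ({a!r}, {b!r}) is not classified")
        return self._map[key]

    def pairs(self) -> dict[tuple[str, str], str]:
        return {tuple(sorted(k)): v for k, v in self._map.items()}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "BarrierMap":
        """Build from ``{"A|B": "shelf", ...}`` (YAML-friendly)."""
        bm = cls()
        for key, val in mapping.items():
            a, _, b = key.partition("|")
            if not b:
                raise MotuinvError(f"barrier key {key!r} must look like 'A|B'")
            bm.set(a.strip(), b.strip(), val)
        return bm

    def to_dict(self) -> dict[str, str]:
        return {f"{a}|{b}": v for (a, b), v in sorted(self.pairs().items())}


# ---------------------------------------------------------------------------
# Partition scheme / concatenation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered fragment coordinates: (name, start, end), 1-based inclusive."""

    ranges: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        expected_start = 1
        for name, start, end in self.ranges:
            if start != expected_start or end < start:
                raise MotuinvError(
                    f"partition {name!r} range {start}-{end} is not contiguous "
                    f"(expected start {expected_start})"
                )
            expected_start = end + 1

    @property
    def length(self) -> int:
        return self.ranges[-1][2] if self.ranges else 0

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.ranges]

    def slices(self) -> dict[str, slice]:
        """0-based half-open column slices, keyed by fragment name."""
        return {name: slice(s - 1, e) for name, s, e in self.ranges}

    def to_raxml(self) -> str:
        return "".join(f"DNA, {n} = {s}-{e}\n" for n, s, e in self.ranges)

    @classmethod
    def from_raxml(cls, text: str) -> "PartitionScheme":
        ranges = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            m = re.fullmatch(r"\w+,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)", line)
            if not m:
                raise MotuinvError(f"cannot parse partition line {line!r}")
            ranges.append((m.group(1), int(m.group(2)), int(m.group(3))))
        return cls(tuple(ranges))


def concatenate_fragments(
    fragments: Sequence[tuple[str, Alignment]],
    taxon_union: Sequence[str] | None = None,
) -> tuple[Alignment, PartitionScheme]:
    """Concatenate named fragment alignments into a supermatrix.

    Every taxon in the union gets a row; a taxon absent from a fragment is
    filled with '?' across that fragment's columns.  Default taxon order is
    first appearance across fragments.
    """
    if not fragments:
        raise MotuinvError("no fragments to concatenate")
    if taxon_union is None:
        taxon_union = []
        seen: set[str] = set()
        for _, aln in fragments:
            for rec in aln:
                if rec.id not in seen:
                    seen.add(rec.id)
                    taxon_union.append(rec.id)
    ranges = []
    start = 1
    parts: dict[str, list[str]] = {t: [] for t in taxon_union}
    for name, aln in fragments:
        index = {rec.id: rec.seq for rec in aln}
        for taxon in taxon_union:
            parts[taxon].append(index.get(taxon, FILL_CHAR * aln.length))
        ranges.append((name, start, start + aln.length - 1))
        start += aln.length
    out = Alignment(
        [SequenceRecord(t, "".join(parts[t])) for t in taxon_union]
    )
    return out, PartitionScheme(tuple(ranges))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a newick tree (file path or newick string); multifurcations kept."""
    text = source if isinstance(source, str) and source.lstrip().startswith("(") else None
    try:
        if text is not None:
            tree = dendropy.Tree.get(data=text, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=str(source), schema="newick",
                                     preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise MotuinvError(f"newick parse error: {exc}") from exc
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path, precision: int = 10) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        real_value_format_specifier=f".{precision}f",
        suppress_rooting=True,
    )


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True).strip()
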