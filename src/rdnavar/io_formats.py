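"""Readers and writers for the pipeline's plain-text tables.

Single home for coordinate conventions: every file uses 1-based inclusive
positions (matching BEDTools ``-d`` per-base output), all result tables are
TSV with a header line, and lines starting with ``#`` are ignored.

Formats handled here:

* BEDTools ``-d`` style per-base depth tables (3 columns, no header),
* per-site nucleotide allele-count tables (TSV with header),
* classic samtools pileup text (adapter feeding the allele-count schema),
* sample metadata (lineage, treatment, line, generation),
* generic result tables (round-trip stable TSV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed set of treatment labels used in the mutation-accumulation design.
TREATMENTS = ("control", "Ni80", "Cu40", "Ni80Cu40")

ALLELE_COUNT_COLUMNS = [
    "sample_id", "region", "position", "ref_base", "nA", "nC", "nG", "nT", "total",
]

METADATA_COLUMNS = ["sample_id", "lineage", "treatment", "line_number", "generation"]

_NUCS = "ACGT"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class LineRecord:
    """Metadata for one sequenced sample of a mutation-accumulation line."""

    sample_id: str
    lineage: str
    treatment: str
    line_number: int
    generation: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise FormatError(
                f"unknown treatment {self.treatment!r} for sample {self.sample_id!r}; "
                f"expected one of {TREATMENTS}"
            )
        if self.generation < 0:
            raise FormatError(f"negative generation for sample {self.sample_id!r}")


@dataclass
class DepthProfile:
    """Per-base read depth over one reference region for one sample.

    ``depth[i]`` is the depth at 1-based position ``i + 1``; positions are
    contiguous from 1 to ``L``. ``n_gap_filled`` counts positions absent from
    the source file that were filled with depth 0.
    """

    region: str
    sample_id: str
    depth: np.ndarray
    n_gap_filled: int = 0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise FormatError(f"depth profile for {self.region!r} must be non-empty 1-D")
        if (self.depth < 0).any():
            raise FormatError(f"negative depth in profile for {self.region!r}")

    @property
    def L(self) -> int:
        return int(self.depth.size)


def read_depth_table(path: str | Path, sample_id: str | None = None) -> list[DepthProfile]:
    """Parse a BEDTools ``-d`` style per-base depth table.

    Each data line is ``reference<TAB>position<TAB>depth`` with 1-based
    positions, strictly increasing within a reference. Positions missing
    within ``1..max(position)`` are filled with depth 0 and counted in
    ``n_gap_filled``. Returns one :class:`DepthProfile` per reference.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    per_ref: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            ref, pos_s, depth_s = parts
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer position or depth"
                ) from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1")
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth")
            rows = per_ref.setdefault(ref, [])
            if rows and pos <= rows[-1][0]:
                raise FormatError(
                    f"{path}:{lineno}: positions not strictly increasing for {ref!r}"
                )
            rows.append((pos, depth))
    if not per_ref:
        logger.warning("empty depth table: %s", path)
        return []
    profiles = []
    for ref, rows in per_ref.items():
        L = rows[-1][0]
        depth = np.zeros(L, dtype=np.int64)
        for pos, d in rows:
            depth[pos - 1] = d
        n_filled = L - len(rows)
        if n_filled:
            logger.info("%s/%s: gap-filled %d missing positions", path.name, ref, n_filled)
        profiles.append(DepthProfile(region=ref, sample_id=sample_id, depth=depth,
                                     n_gap_filled=n_filled))
    logger.info("%s: %d profiles", path, len(profiles))
    return profiles


def write_depth_table(profiles: Iterable[DepthProfile], path: str | Path) -> None:
    """Write profiles in BEDTools ``-d`` layout (all positions, no header)."""
    with open(path, "w") as fh:
        for prof in profiles:
            for pos, d in enumerate(prof.depth, start=1):
                fh.write(f"{prof.region}\t{pos}\t{d}\n")


def _validate_allele_counts(df: pd.DataFrame, source: str) -> pd.DataFrame:
    for base in df["ref_base"]:
        if base not in _NUCS:
            raise FormatError(f"{source}: ref_base {base!r} outside ACGT")
    counts = df[["nA", "nC", "nG", "nT"]].to_numpy()
    if (counts < 0).any():
        raise FormatError(f"{source}: negative allele count")
    df = df.copy()
    df["total"] = counts.sum(axis=1)
    return df[ALLELE_COUNT_COLUMNS]


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-site nucleotide count table.

    Columns: sample_id, region, position, ref_base, nA, nC, nG, nT. The
    reader stores counts verbatim — threshold filtering happens downstream
    in the variants stage, never here. Returns rows with a recomputed
    ``total`` column.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample_id": str, "region": str})
    missing = [c for c in ALLELE_COUNT_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if not df.empty and not np.issubdtype(df["position"].dtype, np.integer):
        raise FormatError(f"{path}: non-integer position")
    for c in ["nA", "nC", "nG", "nT"]:
        if not df.empty and not np.issubdtype(df[c].dtype, np.integer):
            raise FormatError(f"{path}: non-integer count in column {c}")
    logger.info("%s: %d allele-count rows", path, len(df))
    return _validate_allele_counts(df, str(path))


def allele_counts_from_records(records: Sequence[dict]) -> pd.DataFrame:
    """Build a validated allele-count frame from in-memory records."""
    df = pd.DataFrame.from_records(records, columns=ALLELE_COUNT_COLUMNS[:-1])
    return _validate_allele_counts(df, "<records>")


def _decode_pileup_bases(bases: str, quals: str, ref: str,
                         min_base_quality: int, where: str) -> dict[str, int]:
    """Decode one pileup base string into strand-collapsed ACGT counts.

    Handles ``^X`` mapping anchors, ``$`` read ends, ``+n``/``-n`` indel
    runs, ``*`` deletions and ``>``/``<`` reference skips. Bases whose
    phred quality (offset 33) is below ``min_base_quality`` are dropped.
    """
    counts = dict.fromkeys(_NUCS, 0)
    qi = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret plus mapping-quality char carry no base
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num)  # skip inserted/deleted sequence
            continue
        # every remaining symbol consumes one quality char
        if qi >= len(quals):
            raise FormatError(f"{where}: base/quality string length mismatch")
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if c in "*><":
            continue
        if q < min_base_quality:
            continue
        if c in ".,":
            counts[ref] += 1
        elif c.upper() in _NUCS:
            counts[c.upper()] += 1
        # N/n and anything else: ignored
    if qi != len(quals):
        raise FormatError(f"{where}: base/quality string length mismatch")
    return counts


def parse_pileup(path: str | Path, min_base_quality: int = 13,
                 sample_id: str | None = None) -> pd.DataFrame:
    """Adapter: decode classic samtools pileup text into allele-count rows.

    Expects ``chrom  pos  ref  depth  bases  quals`` per line. Counts are
    strand-collapsed (upper/lowercase pooled). Output follows the
    :func:`read_allele_counts` schema.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 pileup fields")
            chrom, pos_s, ref, depth_s, bases, quals = parts[:6]
            ref = ref.upper()
            if ref not in _NUCS:
                raise FormatError(f"{path}:{lineno}: ref base {ref!r} outside ACGT")
            counts = _decode_pileup_bases(bases, quals, ref, min_base_quality,
                                          f"{path}:{lineno} (pos {pos_s})")
            if sum(counts.values()) > int(depth_s):
                raise FormatError(
                    f"{path}:{lineno}: decoded bases exceed declared depth"
                )
            records.append({
                "sample_id": sample_id, "region": chrom, "position": int(pos_s),
                "ref_base": ref, "nA": counts["A"], "nC": counts["C"],
                "nG": counts["G"], "nT": counts["T"],
            })
    logger.info("%s: %d pileup rows decoded", path, len(records))
    return allele_counts_from_records(records)


def read_metadata(path: str | Path) -> list[LineRecord]:
    """Read sample metadata; unknown treatment strings raise FormatError."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "lineage": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = [
        LineRecord(sample_id=row.sample_id, lineage=row.lineage,
                   treatment=row.treatment, line_number=int(row.line_number),
                   generation=int(row.generation))
        for row in df.itertuples()
    ]
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample_id")
    return records


def metadata_frame(records: Iterable[LineRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.lineage, r.treatment, r.line_number, r.generation)
         for r in records],
        columns=METADATA_COLUMNS,
    )


def write_metadata(records: Iterable[LineRecord], path: str | Path) -> None:
    write_table(metadata_frame(records), path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with header and fixed numeric formatting.

    The formatting (%.10g for floats) is pinned so that write→read→write
    round-trips are byte-identical, which the pipeline manifest relies on.
    """
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
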