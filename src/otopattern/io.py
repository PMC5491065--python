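"""Readers and writers for every on-disk artifact of the pipeline.

Four artifact families are handled here:

* per-array feature tables (Agilent-FE-like TSV: probe name, control-type
  flag, processed signal), one file per scanned array;
* sample sheets assigning each array to a biological group (ES / OS / CSE)
  and, optionally, to a technical-duplicate pair;
* probes x samples expression matrices with scale (linear / log2) and
  processing-stage provenance;
* probe annotation tables (probe -> gene symbol -> GO ids) and a minimal
  GEO series-matrix dialect for reanalysing deposited data.

All text I/O is UTF-8, tab-delimited, "." decimal separator.  Matrix
round-trips (``read_matrix(write_matrix(m))``) are value-identical because
floats are rendered with shortest-round-trip ``repr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, StageError, ValidationError

logger = logging.getLogger(__name__)

GROUPS = ("ES", "OS", "CSE")

#: processing stages, in the only order transitions may occur
STAGES = ("raw", "background_corrected", "normalized", "filtered")
SCALES = ("linear", "log2")

#: default Agilent-Feature-Extraction-like column names for feature tables
DEFAULT_FEATURE_COLUMNS = ("ProbeName", "ControlType", "gProcessedSignal")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureScan:
    """One array's raw probe intensities with control-type flags.

    ``control_types`` uses the Agilent convention: -1 = negative control,
    0 = regular probe, +1 = positive control.  Row order of the source file
    is preserved.
    """

    array_id: str
    probe_ids: np.ndarray          # dtype=object, unique within a scan
    control_types: np.ndarray      # int, values in {-1, 0, +1}
    signals: np.ndarray            # float, linear scale, >= 0

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.control_types = np.asarray(self.control_types, dtype=int)
        self.signals = np.asarray(self.signals, dtype=float)
        n = len(self.probe_ids)
        if len(self.control_types) != n or len(self.signals) != n:
            raise ValidationError("feature scan arrays have unequal lengths")
        bad = np.flatnonzero(self.signals < 0)
        if bad.size:
            raise ValidationError(
                f"array {self.array_id!r}: negative signal at row {bad[0]}"
            )
        if not np.isin(self.control_types, (-1, 0, 1)).all():
            raise ValidationError(
                f"array {self.array_id!r}: control_type outside {{-1,0,+1}}"
            )
        if len(set(self.probe_ids)) != n:
            raise ValidationError(
                f"array {self.array_id!r}: duplicate probe ids"
            )

    def __len__(self) -> int:
        return len(self.probe_ids)

    @property
    def n_negative_controls(self) -> int:
        return int((self.control_types == -1).sum())


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    group: str
    duplicate_pair_id: str = ""


@dataclass
class SampleSheet:
    """Assignment of arrays to groups and technical-duplicate pairs."""

    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample id(s): {dup}")
        for e in self.entries:
            if e.group not in GROUPS:
                raise ValidationError(
                    f"sample {e.sample_id!r}: unknown group {e.group!r} "
                    f"(expected one of {GROUPS})"
                )
        pairs: dict[str, list[str]] = {}
        for e in self.entries:
            if e.duplicate_pair_id:
                pairs.setdefault(e.duplicate_pair_id, []).append(e.sample_id)
        for pid, members in pairs.items():
            if len(members) != 2:
                raise ValidationError(
                    f"duplicate pair {pid!r} names {len(members)} samples, "
                    "expected exactly 2"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def groups(self) -> list[str]:
        return [e.group for e in self.entries]

    def samples_in_group(self, group: str) -> list[str]:
        return [e.sample_id for e in self.entries if e.group == group]

    @property
    def duplicate_pairs(self) -> dict[str, tuple[str, str]]:
        pairs: dict[str, list[str]] = {}
        for e in self.entries:
            if e.duplicate_pair_id:
                pairs.setdefault(e.duplicate_pair_id, []).append(e.sample_id)
        return {k: (v[0], v[1]) for k, v in pairs.items()}

    def require_all_groups(self) -> None:
        present = set(self.groups)
        missing = [g for g in GROUPS if g not in present]
        if missing:
            raise ValidationError(f"group(s) missing from sample sheet: {missing}")


@dataclass
class ExpressionMatrix:
    """Probes x samples value grid with scale and stage provenance.

    Stage transitions must follow ``raw -> background_corrected ->
    normalized -> filtered``; :meth:`with_values` enforces this.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "linear"
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-D")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value grid {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def require(self, stage: str | None = None, scale: str | None = None) -> None:
        if stage is not None and self.stage != stage:
            raise StageError(f"expected stage {stage!r}, got {self.stage!r}")
        if scale is not None and self.scale != scale:
            raise StageError(f"expected scale {scale!r}, got {self.scale!r}")

    def with_values(
        self,
        values: np.ndarray,
        *,
        stage: str | None = None,
        scale: str | None = None,
        probe_ids: list[str] | None = None,
    ) -> "ExpressionMatrix":
        """Derived matrix; enforces forward-only stage transitions."""
        new_stage = stage or self.stage
        if STAGES.index(new_stage) < STAGES.index(self.stage):
            raise StageError(
                f"illegal stage transition {self.stage!r} -> {new_stage!r}"
            )
        return ExpressionMatrix(
            probe_ids=list(probe_ids if probe_ids is not None else self.probe_ids),
            sample_ids=list(self.sample_ids),
            values=values,
            scale=scale or self.scale,
            stage=new_stage,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.probe_ids, columns=self.sample_ids
        )


@dataclass
class AnnotationTable:
    """Probe -> gene symbol -> GO accession mapping."""

    frame: pd.DataFrame = field(repr=False)  # columns: probe_id, gene_symbol, go_ids

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_symbol", "go_ids"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(
                f"annotation needs columns {sorted(required)}"
            )
        if self.frame["probe_id"].duplicated().any():
            dup = self.frame.loc[self.frame["probe_id"].duplicated(), "probe_id"]
            raise ValidationError(f"duplicate probe id(s) in annotation: {list(dup[:5])}")
        self.frame = self.frame.reset_index(drop=True)
        self.frame["go_ids"] = self.frame["go_ids"].apply(
            lambda g: frozenset(g) if not isinstance(g, str)
            else frozenset(x for x in g.split(";") if x)
        )

    def gene_of(self) -> dict[str, str]:
        return dict(zip(self.frame["probe_id"], self.frame["gene_symbol"]))

    def probes_of_gene(self, gene: str) -> list[str]:
        m = self.frame["gene_symbol"] == gene
        return list(self.frame.loc[m, "probe_id"])

    def genes_with_go(self, go_id: str) -> set[str]:
        has = self.frame["go_ids"].apply(lambda s: go_id in s)
        return set(self.frame.loc[has, "gene_symbol"])


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def read_feature_table(
    path: str | Path,
    columns: Sequence[str] = DEFAULT_FEATURE_COLUMNS,
    array_id: str | None = None,
) -> FeatureScan:
    """Read one array's tab-delimited feature table.

    ``columns`` names the (probe id, control type, signal) columns in that
    order; the default matches Agilent Feature Extraction exports.  Row
    order is preserved and control types are validated to {-1, 0, +1}.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={columns[0]: str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    probe_col, ctrl_col, sig_col = columns
    signals = pd.to_numeric(df[sig_col], errors="coerce")
    if signals.isna().any():
        row = int(signals.isna().idxmax())
        raise FormatError(f"{path}: non-numeric signal at row {row}")
    neg = signals < 0
    if neg.any():
        row = int(neg.idxmax())
        raise ValidationError(f"{path}: negative signal at row {row}")
    return FeatureScan(
        array_id=array_id or path.stem,
        probe_ids=df[probe_col].to_numpy(dtype=object),
        control_types=df[ctrl_col].to_numpy(dtype=int),
        signals=signals.to_numpy(dtype=float),
    )


def write_feature_table(
    scan: FeatureScan,
    path: str | Path,
    columns: Sequence[str] = DEFAULT_FEATURE_COLUMNS,
) -> None:
    df = pd.DataFrame(
        {
            columns[0]: scan.probe_ids,
            columns[1]: scan.control_types,
            columns[2]: scan.signals,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(
    path: str | Path,
    group_aliases: Mapping[str, str] | None = None,
) -> SampleSheet:
    """Read a CSV or TSV sample sheet (delimiter sniffed from the header).

    Columns: ``sample_id``, ``group`` and optional ``duplicate_pair_id``.
    Group labels outside {ES, OS, CSE} are rejected unless ``group_aliases``
    maps them onto canonical labels.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if "duplicate_pair_id" not in df.columns:
        df["duplicate_pair_id"] = ""
    aliases = dict(group_aliases or {})
    entries = [
        SampleEntry(
            sample_id=r.sample_id,
            group=aliases.get(r.group, r.group),
            duplicate_pair_id=r.duplicate_pair_id,
        )
        for r in df.itertuples()
    ]
    return SampleSheet(entries)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": sheet.sample_ids,
            "group": sheet.groups,
            "duplicate_pair_id": [e.duplicate_pair_id for e in sheet.entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrix assembly and (de)serialization
# ---------------------------------------------------------------------------

def assemble_matrix(
    scans: Iterable[FeatureScan], sheet: SampleSheet
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Column-bind per-array scans into a raw linear expression matrix.

    Every sheet sample must have exactly one scan and all scans must share
    an identical probe-id set (row order taken from the first scan).
    Returns the matrix plus the shared control-type vector, needed later by
    the negative-control filter.
    """
    by_id = {}
    for s in scans:
        if s.array_id in by_id:
            raise ValidationError(f"two scans share array id {s.array_id!r}")
        by_id[s.array_id] = s
    missing = [sid for sid in sheet.sample_ids if sid not in by_id]
    if missing:
        raise ValidationError(f"no scan for sample(s): {missing[:10]}")

    first = by_id[sheet.sample_ids[0]]
    ref_ids = first.probe_ids
    ref_set = set(ref_ids)
    columns = []
    for sid in sheet.sample_ids:
        scan = by_id[sid]
        if len(scan) != len(ref_ids) or set(scan.probe_ids) != ref_set:
            diff = sorted(set(scan.probe_ids) ^ ref_set)[:10]
            raise ValidationError(
                f"probe-set mismatch between {first.array_id!r} and "
                f"{scan.array_id!r}; symmetric difference starts {diff}"
            )
        if not np.array_equal(scan.probe_ids, ref_ids):
            order = pd.Index(scan.probe_ids).get_indexer(ref_ids)
            columns.append(scan.signals[order])
            if not np.array_equal(scan.control_types[order], first.control_types):
                raise ValidationError("control-type flags differ across scans")
        else:
            columns.append(scan.signals)
            if not np.array_equal(scan.control_types, first.control_types):
                raise ValidationError("control-type flags differ across scans")
    matrix = ExpressionMatrix(
        probe_ids=list(ref_ids),
        sample_ids=list(sheet.sample_ids),
        values=np.column_stack(columns),
        scale="linear",
        stage="raw",
    )
    return matrix, first.control_types.copy()


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """TSV with probe ids in the first column and a two-line provenance
    header (``# scale=... stage=...``) so round trips preserve metadata."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# scale={matrix.scale} stage={matrix.stage}\n")
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for pid, row in zip(matrix.probe_ids, matrix.values):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        meta = {}
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            header = fh.readline().rstrip("\n")
        else:
            header = first
        cols = header.split("\t")
        if not cols or cols[0] != "probe_id":
            raise FormatError(f"{path}: expected 'probe_id' as first header column")
        sample_ids = cols[1:]
        probe_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=3):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} fields, "
                    f"expected {len(cols)}"
                )
            probe_ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    values = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, len(sample_ids)))
    )
    return ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        values=values,
        scale=meta.get("scale", "linear"),
        stage=meta.get("stage", "raw"),
    )


# ---------------------------------------------------------------------------
# GEO series-matrix dialect
# ---------------------------------------------------------------------------

def read_series_matrix(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    """Parse a GEO series-matrix TSV (``!``-prefixed metadata, data table
    between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``).

    Series matrices hold post-processing values, so the result carries
    stage ``normalized``; the scale cannot be inferred from the file and is
    supplied by the caller (default log2, the common deposit convention).
    """
    path = Path(path)
    in_table = False
    saw_end = False
    header: list[str] | None = None
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            low = line.strip().lower()
            if low == "!series_matrix_table_begin":
                in_table = True
                continue
            if low == "!series_matrix_table_end":
                saw_end = True
                break
            if not in_table:
                continue
            parts = [p.strip().strip('"') for p in line.split("\t")]
            if header is None:
                header = parts
                continue
            if not parts or parts == [""]:
                continue
            probe_ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if header is None or not saw_end:
        raise FormatError(
            f"{path}: missing series_matrix table_begin/table_end markers"
        )
    sample_ids = header[1:]
    values = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, len(sample_ids)))
    )
    return ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        values=values,
        scale=scale,
        stage="normalized",
    )


def write_series_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the minimal series-matrix dialect understood by
    :func:`read_series_matrix` (used for fixtures and round-trip tests)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!Series_title\t\"otopattern export\"\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write(
            '"ID_REF"\t' + "\t".join(f'"{s}"' for s in matrix.sample_ids) + "\n"
        )
        for pid, row in zip(matrix.probe_ids, matrix.values):
            fh.write(f'"{pid}"\t' + "\t".join(repr(float(v)) for v in row) + "\n")
        fh.write("!series_matrix_table_end\n")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> AnnotationTable:
    """TSV with columns probe_id, gene_symbol, go_ids (semicolon-separated
    GO accessions; empty allowed)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("probe_id", "gene_symbol"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if "go_ids" not in df.columns:
        df["go_ids"] = ""
    return AnnotationTable(df[["probe_id", "gene_symbol", "go_ids"]].copy())


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    df = table.frame.copy()
    df["go_ids"] = df["go_ids"].apply(lambda s: ";".join(sorted(s)))
    df.to_csv(path, sep="\t", index=False)
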