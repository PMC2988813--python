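"""Readers and writers for the tabular formats the pipeline touches.

Microarray feature tables arrive either as plain TSV (one header line) or as
GenePix-style ``.gpr`` exports, where an ATF preamble precedes the column
header line.  Spot-level records are parsed into :class:`ArrayScan` /
:class:`SpotRecord`, duplicate spots are averaged per feature, and control
features and bad spots (negative GenePix flags) are removed before any
statistics run.

All on-disk formats are UTF-8 tab-delimited text.  Missing measurements are
represented as missing (NaN), never as zero.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rbpscreen")


class FormatError(ValueError):
    """A mandatory column is missing or the file cannot be interpreted."""


class EmptyInputError(ValueError):
    """The file contains no data rows."""


@dataclass
class SpotRecord:
    """One spot on one array.

    ``net_signal`` is the background-subtracted median intensity per channel
    (arbitrary fluorescence units; may be negative after subtraction).
    ``flag`` follows the GenePix convention: negative values mark bad spots.
    """

    feature_id: str
    spot_index: int
    net_signal: Dict[str, float]
    flag: int = 0
    signal_over_background: Optional[Dict[str, float]] = None
    regression_correlation: Optional[float] = None


@dataclass
class ArrayScan:
    """All spot records of a single array scan."""

    array_id: str
    features: List[SpotRecord]
    channel_names: List[str]


@dataclass
class ParseReport:
    """Bookkeeping for one parsed file."""

    path: str
    n_rows: int
    n_parsed: int
    skipped_rows: List[int] = field(default_factory=list)  # 0-based data-row indices


@dataclass
class ColumnMap:
    """Mapping from logical fields to column names in an array table.

    ``channels`` maps channel name -> signal column.  If empty, every column
    other than the named ones is treated as a signal channel.  Optional
    per-channel S/B columns use the pattern ``sob_<channel>``.
    """

    feature_id: str = "feature_id"
    spot_index: Optional[str] = "spot"
    flag: Optional[str] = "flag"
    channels: Dict[str, str] = field(default_factory=dict)
    regression_correlation: Optional[str] = None


def _locate_header(lines: Sequence[str], feature_col: str) -> int:
    """Index of the column-header line in a GPR-style file.

    GenePix exports start with an ATF preamble of ``"key=value"`` records;
    the first tab-separated line containing the feature-ID column name is
    taken as the header.
    """
    for i, line in enumerate(lines):
        fields = [f.strip().strip('"') for f in line.rstrip("\n").split("\t")]
        if feature_col in fields:
            return i
    raise FormatError(f"missing mandatory column {feature_col!r}")


def read_array_table(
    path: str | Path,
    format: str = "plain-tsv",
    column_map: Optional[ColumnMap] = None,
    assume_flag: Optional[int] = None,
    array_id: Optional[str] = None,
) -> tuple[ArrayScan, ParseReport]:
    """Parse one array scan from a tab-delimited file.

    Parameters
    ----------
    format:
        ``"plain-tsv"`` (single header line) or ``"gpr-like"`` (GenePix ATF
        preamble skipped by locating the column-header line).
    assume_flag:
        Used for every spot when the flag column is absent; without it a
        missing flag column is a :class:`FormatError`.

    Rows whose numeric fields cannot be parsed are skipped and recorded in
    the returned :class:`ParseReport`.
    """
    if format not in ("plain-tsv", "gpr-like"):
        raise ValueError(f"unknown format {format!r}")
    cmap = column_map or ColumnMap()
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise EmptyInputError(f"{path}: empty file")
    start = _locate_header(lines, cmap.feature_id) if format == "gpr-like" else 0
    header = [f.strip().strip('"') for f in lines[start].split("\t")]
    if cmap.feature_id not in header:
        raise FormatError(f"missing mandatory column {cmap.feature_id!r}")
    has_flag = cmap.flag is not None and cmap.flag in header
    if not has_flag and assume_flag is None:
        raise FormatError(f"missing mandatory column {cmap.flag!r}")

    if cmap.channels:
        channels = dict(cmap.channels)
        for ch, col in channels.items():
            if col not in header:
                raise FormatError(f"missing mandatory column {col!r} (channel {ch})")
    else:
        reserved = {cmap.feature_id, cmap.spot_index, cmap.flag,
                    cmap.regression_correlation}
        channels = {c: c for c in header
                    if c not in reserved and not c.startswith("sob_")}
    if not channels:
        raise FormatError("no signal channel columns found")
    sob_cols = {ch: f"sob_{ch}" for ch in channels if f"sob_{ch}" in header}

    idx = {c: i for i, c in enumerate(header)}
    records: List[SpotRecord] = []
    skipped: List[int] = []
    data_lines = [ln for ln in lines[start + 1:] if ln.strip()]
    if not data_lines:
        raise EmptyInputError(f"{path}: no data rows")
    spot_counter: Dict[str, int] = {}
    for row_i, line in enumerate(data_lines):
        fields = [f.strip().strip('"') for f in line.split("\t")]
        try:
            fid = fields[idx[cmap.feature_id]]
            net = {ch: float(fields[idx[col]]) for ch, col in channels.items()}
            flag = int(float(fields[idx[cmap.flag]])) if has_flag else int(assume_flag)
            if cmap.spot_index and cmap.spot_index in idx:
                spot = int(float(fields[idx[cmap.spot_index]]))
            else:
                spot_counter[fid] = spot_counter.get(fid, 0) + 1
                spot = spot_counter[fid]
            sob = None
            if sob_cols:
                sob = {ch: float(fields[idx[col]]) for ch, col in sob_cols.items()}
            regcorr = None
            if cmap.regression_correlation and cmap.regression_correlation in idx:
                regcorr = float(fields[idx[cmap.regression_correlation]])
        except (ValueError, IndexError):
            skipped.append(row_i)
            continue
        records.append(SpotRecord(fid, spot, net, flag, sob, regcorr))

    report = ParseReport(str(path), len(data_lines), len(records), skipped)
    logger.info("read %s: %d rows, %d parsed, %d skipped",
                path, report.n_rows, report.n_parsed, len(skipped))
    scan = ArrayScan(array_id or path.stem, records, sorted(channels))
    return scan, report


def filter_features(
    rows: Iterable[SpotRecord],
    drop_controls: Sequence[str] = (),
    min_flag: Optional[int] = 0,
) -> List[SpotRecord]:
    """Remove control features and bad spots.

    Features whose ID matches any ``drop_controls`` glob pattern are removed
    (non-yeast controls such as GST); spots with ``flag < min_flag`` are
    removed before duplicate averaging.  Idempotent.
    """
    rows = list(rows)
    kept: List[SpotRecord] = []
    n_ctrl = n_flag = 0
    for r in rows:
        if any(fnmatch.fnmatch(r.feature_id, pat) for pat in drop_controls):
            n_ctrl += 1
            continue
        if min_flag is not None and r.flag < min_flag:
            n_flag += 1
            continue
        kept.append(r)
    logger.info("filter_features: %d rows in, %d control rows removed, "
                "%d flagged spots removed (min_flag=%s), %d kept",
                len(rows), n_ctrl, n_flag, min_flag, len(kept))
    return kept


def average_duplicate_spots(
    scan: ArrayScan, min_flag: Optional[int] = 0,
) -> tuple[pd.DataFrame, List[str]]:
    """Average duplicate spots per feature and channel.

    Returns a feature x channel DataFrame of arithmetic means over retained
    (unflagged) spots, plus the list of features whose spots were all
    removed — absence is data, not an error.
    """
    rows = [r for r in scan.features
            if min_flag is None or r.flag >= min_flag]
    all_ids = list(dict.fromkeys(r.feature_id for r in scan.features))
    sums: Dict[str, np.ndarray] = {}
    counts: Dict[str, int] = {}
    chans = scan.channel_names
    for r in rows:
        v = np.array([r.net_signal[c] for c in chans], dtype=float)
        if r.feature_id in sums:
            sums[r.feature_id] += v
            counts[r.feature_id] += 1
        else:
            sums[r.feature_id] = v.copy()
            counts[r.feature_id] = 1
    kept_ids = [f for f in all_ids if f in sums]
    absent = [f for f in all_ids if f not in sums]
    data = np.array([sums[f] / counts[f] for f in kept_ids]) if kept_ids \
        else np.empty((0, len(chans)))
    table = pd.DataFrame(data, index=pd.Index(kept_ids, name="feature_id"),
                         columns=chans)
    if absent:
        logger.info("average_duplicate_spots(%s): %d features lost all spots",
                    scan.array_id, len(absent))
    return table, absent


def build_feature_table(
    scans: Sequence[ArrayScan], channel: str, min_flag: Optional[int] = 0,
) -> pd.DataFrame:
    """Assemble a feature x array matrix of duplicate-averaged net signals.

    Features absent from an array (all spots flagged) are NaN there.
    """
    cols = {}
    for scan in scans:
        table, _ = average_duplicate_spots(scan, min_flag=min_flag)
        cols[scan.array_id] = table[channel]
    df = pd.DataFrame(cols)
    df.index.name = "feature_id"
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV with full float precision (round-trip exact)."""
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (first column = index)."""
    return pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a gene→term annotation TSV.

    Required columns: gene_id, namespace, term_id, term_name.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "namespace", "term_id", "term_name"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    return df


def read_gene_set(path: str | Path) -> set[str]:
    """Read a one-ID-per-line gene set file (blank lines and '#' ignored)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.split("\t")[0])
    return out
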