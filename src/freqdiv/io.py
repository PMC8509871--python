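"""Readers and writers for allele-frequency time-series files.

Two dialects are supported:

* PoPoolation2 ``sync`` files (chrom, pos, ref, then one ``A:T:C:G:N:del``
  count sextuple per sequenced sample), the de-facto interchange format for
  pool-seq evolve-and-resequence data;
* a plain tab-separated table with ``chrom``, ``pos`` and ``freq_<label>``
  (optionally ``depth_<label>``) columns, which round-trips losslessly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .table import FrequencyTable

logger = logging.getLogger(__name__)

__all__ = ["read_sync", "read_freq_table", "write_freq_table", "SyncParseError"]

_NUCS = ("A", "T", "C", "G")
# alphabetical order used to pick the focal allele among the two segregating
_ALPHA = ("A", "C", "G", "T")


class SyncParseError(ValueError):
    """Raised for a malformed sync line, with its line number."""


def _parse_sextuple(field: str, line_no: int) -> np.ndarray:
    parts = field.split(":")
    if len(parts) != 6:
        raise SyncParseError(
            f"line {line_no}: expected A:T:C:G:N:del sextuple, got {field!r}"
        )
    try:
        return np.array([int(x) for x in parts], dtype=np.int64)
    except ValueError:
        raise SyncParseError(
            f"line {line_no}: non-integer count in {field!r}"
        ) from None


def read_sync(path, timepoint_columns=None, t_labels=None) -> FrequencyTable:
    """Read a PoPoolation2 sync file into a :class:`FrequencyTable`.

    Parameters
    ----------
    path : str or path-like
        Sync file. Columns: chrom, pos, ref base, then per-sample count
        sextuples ``A:T:C:G:N:del``.
    timepoint_columns : sequence of int, optional
        0-based indices into the sample columns (i.e. after the three fixed
        columns), in temporal order. Default: all sample columns in file
        order.
    t_labels : sequence of str, optional
        Labels for the selected timepoints; default ``t0, t1, ...``.

    Returns
    -------
    FrequencyTable
        Biallelic loci only. A locus is biallelic when exactly two of the
        four nucleotides have a nonzero count pooled across the selected
        timepoints; N and deletion counts are ignored. The focal allele is
        the alphabetically first of the two; its frequency is computed
        against the two-allele total, and depth is that total. Zero
        two-allele depth at a timepoint gives a missing (NaN) frequency.
    """
    chroms, poss, freqs, depths = [], [], [], []
    n_dropped = 0
    n_lines = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise SyncParseError(
                    f"line {line_no}: expected chrom, pos, ref and >=1 sample column"
                )
            n_lines += 1
            sample_fields = fields[3:]
            if timepoint_columns is None:
                cols = range(len(sample_fields))
            else:
                cols = list(timepoint_columns)
            counts = []
            for c in cols:
                try:
                    f = sample_fields[c]
                except IndexError:
                    raise SyncParseError(
                        f"line {line_no}: sample column {c} out of range "
                        f"({len(sample_fields)} sample columns present)"
                    ) from None
                counts.append(_parse_sextuple(f, line_no))
            counts = np.stack(counts)  # (timepoints, 6)
            if counts.shape[0] < 2:
                raise ValueError(
                    "need at least two timepoint columns to build a table"
                )
            pooled = counts[:, :4].sum(axis=0)
            seg = np.flatnonzero(pooled > 0)
            if seg.size != 2:
                n_dropped += 1
                continue
            # focal allele: alphabetically first of the two segregating
            names = [_NUCS[i] for i in seg]
            focal_name = min(names, key=_ALPHA.index)
            i_focal = seg[names.index(focal_name)]
            two = counts[:, seg].sum(axis=1).astype(np.float64)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(two > 0, counts[:, i_focal] / two, np.nan)
            chroms.append(fields[0])
            poss.append(int(fields[1]))
            freqs.append(f)
            depths.append(two)
    k = len(timepoint_columns) if timepoint_columns is not None else (
        len(freqs[0]) if freqs else 2
    )
    if t_labels is None:
        t_labels = tuple(f"t{i}" for i in range(k))
    if not chroms:
        logger.warning("no biallelic loci read from %s (%d lines dropped)",
                       path, n_dropped)
        table = FrequencyTable(
            chrom=np.empty(0, dtype=object),
            pos=np.empty(0, dtype=np.int64),
            freq=np.empty((0, k)),
            t_labels=t_labels,
            depth=np.empty((0, k)),
        )
        table.n_dropped = n_dropped
        return table
    table = FrequencyTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        freq=np.stack(freqs),
        t_labels=t_labels,
        depth=np.stack(depths),
    )
    table.n_dropped = n_dropped
    logger.info(
        "read %d biallelic loci from %s (%d of %d lines dropped by the "
        "biallelic filter)", table.n_loci, path, n_dropped, n_lines,
    )
    return table


def read_freq_table(path) -> FrequencyTable:
    """Read a tab-separated frequency table written by :func:`write_freq_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    return FrequencyTable.from_dataframe(df)


def write_freq_table(table: FrequencyTable, path) -> None:
    """Write a table as TSV at full float precision (round-trip exact)."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False)
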