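"""Core container for allele-frequency time series.

A :class:`FrequencyTable` holds, for every SNP, its genomic coordinate and
the focal-allele frequency at each of an ordered set of timepoints, plus
optional read depths. It is the universal input to the variance scan, the
block bootstrap and the simulators' output format.

Conventions
-----------
* positions are 1-based and strictly increasing within a chromosome;
* frequencies lie in [0, 1]; NaN marks a missing measurement (e.g. zero
  read depth at that timepoint);
* at least two timepoints are required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["FrequencyTable"]


@dataclass
class FrequencyTable:
    chrom: np.ndarray
    pos: np.ndarray
    freq: np.ndarray
    t_labels: tuple
    depth: np.ndarray | None = None
    validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.freq = np.atleast_2d(np.asarray(self.freq, dtype=np.float64))
        self.t_labels = tuple(str(t) for t in self.t_labels)
        if self.depth is not None:
            self.depth = np.atleast_2d(np.asarray(self.depth, dtype=np.float64))
        if self.validate:
            self._check()

    def _check(self):
        n = self.chrom.shape[0]
        if self.pos.shape[0] != n or self.freq.shape[0] != n:
            raise ValueError("chrom, pos and freq must have one row per locus")
        if len(self.t_labels) < 2:
            raise ValueError("a FrequencyTable needs at least two timepoints")
        if self.freq.shape[1] != len(self.t_labels):
            raise ValueError(
                f"freq has {self.freq.shape[1]} columns but "
                f"{len(self.t_labels)} timepoint labels were given"
            )
        if self.depth is not None and self.depth.shape != self.freq.shape:
            raise ValueError("depth must have the same shape as freq")
        with np.errstate(invalid="ignore"):
            bad = (self.freq < 0) | (self.freq > 1)
        if bad.any():
            i = int(np.argwhere(bad)[0, 0])
            raise ValueError(
                f"frequency outside [0, 1] at locus {self.chrom[i]}:{self.pos[i]}"
            )
        # positions strictly increasing within each chromosome block
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c!r}"
                )

    # -- basic introspection -------------------------------------------------

    @property
    def n_loci(self) -> int:
        return int(self.chrom.shape[0])

    @property
    def n_timepoints(self) -> int:
        return len(self.t_labels)

    def __len__(self) -> int:
        return self.n_loci

    def label_index(self, label: str) -> int:
        try:
            return self.t_labels.index(str(label))
        except ValueError:
            raise KeyError(
                f"timepoint {label!r} not among {self.t_labels}"
            ) from None

    def freq_at(self, label: str) -> np.ndarray:
        """Focal-allele frequencies at one timepoint (view)."""
        return self.freq[:, self.label_index(label)]

    # -- derived tables ------------------------------------------------------

    def take(self, idx, validate: bool = False) -> "FrequencyTable":
        """Row subset (or row resample) of the table.

        Resampled tables may repeat loci, so validation is off by default.
        """
        idx = np.asarray(idx)
        return FrequencyTable(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            freq=self.freq[idx],
            t_labels=self.t_labels,
            depth=None if self.depth is None else self.depth[idx],
            validate=validate,
        )

    def drop_missing(self) -> "FrequencyTable":
        """Remove loci with a missing (NaN) frequency at any timepoint."""
        keep = ~np.isnan(self.freq).any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d loci with missing frequencies", n_drop)
        return self.take(np.flatnonzero(keep), validate=False)

    def sorted(self) -> "FrequencyTable":
        """Loci ordered by (chromosome, position)."""
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.take(order, validate=False)

    # -- pandas interop ------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        data = {"chrom": self.chrom, "pos": self.pos}
        for k, lab in enumerate(self.t_labels):
            data[f"freq_{lab}"] = self.freq[:, k]
        if self.depth is not None:
            for k, lab in enumerate(self.t_labels):
                data[f"depth_{lab}"] = self.depth[:, k]
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, validate: bool = True) -> "FrequencyTable":
        for col in ("chrom", "pos"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        freq_cols = [c for c in df.columns if c.startswith("freq_")]
        if len(freq_cols) < 2:
            raise ValueError("need at least two freq_<label> columns")
        labels = [c[len("freq_"):] for c in freq_cols]
        depth_cols = [f"depth_{lab}" for lab in labels]
        has_depth = all(c in df.columns for c in depth_cols)
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            freq=df[freq_cols].to_numpy(dtype=np.float64),
            t_labels=tuple(labels),
            depth=df[depth_cols].to_numpy(np.float64) if has_depth else None,
            validate=validate,
        )

    def equals(self, other: "FrequencyTable") -> bool:
        if self.t_labels != other.t_labels or self.n_loci != other.n_loci:
            return False
        same_depth = (self.depth is None) == (other.depth is None)
        if not same_depth:
            return False
        ok = (
            (self.chrom == other.chrom).all()
            and (self.pos == other.pos).all()
            and np.array_equal(self.freq, other.freq, equal_nan=True)
        )
        if ok and self.depth is not None:
            ok = np.array_equal(self.depth, other.depth, equal_nan=True)
        return bool(ok)
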