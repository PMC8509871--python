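"""Block bootstrap over genomic windows.

Nearby SNPs are correlated through linkage, so locus-level resampling
understates uncertainty. Instead each chromosome is tiled with fixed-size
windows (1 Mb by default) and whole windows are resampled with
replacement; any scan statistic is then recomputed per replicate and its
percentile interval reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .table import FrequencyTable

logger = logging.getLogger(__name__)

__all__ = ["GenomicBlock", "BootstrapResult", "make_blocks", "block_bootstrap"]

DEFAULT_BLOCK_SIZE = 1_000_000


@dataclass(frozen=True)
class GenomicBlock:
    chrom: str
    start: int  # half-open [start, end) in bp
    end: int
    loci: np.ndarray  # row indices into the source table

    def __len__(self):
        return int(self.loci.size)


@dataclass
class BootstrapResult:
    point: float
    ci_lo: float | None
    ci_hi: float | None
    B: int
    alpha: float
    seed: int | None
    n_dropped: int = 0
    replicates: np.ndarray | None = None


def make_blocks(table: FrequencyTable, block_size: int = DEFAULT_BLOCK_SIZE):
    """Tile each chromosome with half-open [k*size, (k+1)*size) windows.

    Every locus falls in exactly one window; windows containing no loci are
    dropped. Returns a list of :class:`GenomicBlock`.
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    blocks = []
    for c in dict.fromkeys(table.chrom):  # preserve order
        rows = np.flatnonzero(table.chrom == c)
        win = table.pos[rows] // block_size
        for w in np.unique(win):
            loci = rows[win == w]
            blocks.append(
                GenomicBlock(
                    chrom=str(c),
                    start=int(w * block_size),
                    end=int((w + 1) * block_size),
                    loci=loci,
                )
            )
    logger.info("tiled %d loci into %d non-empty blocks of %d bp",
                table.n_loci, len(blocks), block_size)
    return blocks


def _resample_table(table, blocks, draw):
    """Concatenate drawn blocks into a new table.

    Each drawn block becomes its own pseudo-chromosome so that repeated
    blocks do not violate the position-ordering convention.
    """
    idx = np.concatenate([blocks[b].loci for b in draw])
    out = table.take(idx, validate=False)
    chrom = np.concatenate(
        [np.repeat(f"b{j}", blocks[b].loci.size) for j, b in enumerate(draw)]
    ).astype(object)
    out.chrom = chrom
    return out


def block_bootstrap(
    stat,
    table: FrequencyTable,
    blocks=None,
    B: int = 1000,
    alpha: float = 0.05,
    seed=None,
    keep_replicates: bool = False,
) -> BootstrapResult:
    """Percentile block-bootstrap interval for ``stat(table)``.

    Each replicate draws ``len(blocks)`` blocks with replacement,
    concatenates their loci and re-evaluates ``stat`` (so binning and
    variance are recomputed per replicate). The CI spans the alpha/2 and
    1-alpha/2 empirical percentiles over the B replicate values.
    Deterministic given ``seed``: one root seed spawns one stream per
    replicate. Replicates on which ``stat`` is undefined (raises or returns
    NaN) are dropped and counted; a warning is emitted if more than 20% are
    dropped.
    """
    if blocks is None:
        blocks = make_blocks(table)
    if not blocks:
        raise ValueError("no blocks to resample")
    point = float(stat(table))
    if B < 1:
        return BootstrapResult(point, None, None, 0, alpha, seed)
    root = np.random.SeedSequence(seed)
    streams = root.spawn(B)
    nb = len(blocks)
    values = np.empty(B)
    dropped = 0
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        draw = rng.integers(0, nb, size=nb)
        sub = _resample_table(table, blocks, draw)
        try:
            v = float(stat(sub))
        except Exception:
            v = np.nan
        values[b] = v
        if np.isnan(v):
            dropped += 1
    good = values[~np.isnan(values)]
    if good.size == 0:
        raise ValueError("statistic undefined on every bootstrap replicate")
    if dropped > 0.2 * B:
        logger.warning("%d of %d bootstrap replicates dropped", dropped, B)
    lo, hi = np.percentile(good, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        point=point,
        ci_lo=float(lo),
        ci_hi=float(hi),
        B=B,
        alpha=alpha,
        seed=seed,
        n_dropped=dropped,
        replicates=values if keep_replicates else None,
    )
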