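"""Observed-data containers: genomic windows, count matrices, offsets, I/O.

Counts are tabulated over fixed-width, non-overlapping genomic windows
(BED convention: 0-based, half-open).  A :class:`CountDataset` bundles the
N x M count matrix (N samples, M windows) with the sample-to-condition map,
the window coordinates and an optional matrix of normalization offsets on
the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicWindows",
    "CountDataset",
    "make_windows",
    "tabulate_counts",
    "library_size_offsets",
    "read_counts_table",
    "write_counts_table",
]


@dataclass(frozen=True)
class GenomicWindows:
    """Sorted, non-overlapping, constant-width genomic intervals.

    Coordinates follow the BED convention (0-based, half-open).
    """

    chrom: np.ndarray  # str per window
    start: np.ndarray  # int, inclusive
    end: np.ndarray  # int, exclusive

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=object)
        start = np.asarray(self.start, dtype=np.int64)
        end = np.asarray(self.end, dtype=np.int64)
        if not (chrom.shape == start.shape == end.shape) or chrom.ndim != 1:
            raise ValueError("chrom, start, end must be 1-D arrays of equal length")
        if len(start) == 0:
            raise ValueError("empty window set")
        widths = end - start
        if not np.all(widths == widths[0]) or widths[0] <= 0:
            raise ValueError("all windows must share one positive width")
        # sorted by (chromosome, start) and non-overlapping within chromosome
        for c in pd.unique(chrom):
            s = start[chrom == c]
            if np.any(np.diff(s) < widths[0]):
                raise ValueError(f"windows on {c} overlap or are unsorted")
        # chromosome blocks must be contiguous in the array
        seen: list = []
        for c in chrom:
            if not seen or seen[-1] != c:
                if c in seen:
                    raise ValueError("windows are not grouped by chromosome")
                seen.append(c)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    def __len__(self) -> int:
        return len(self.start)

    @property
    def width(self) -> int:
        return int(self.end[0] - self.start[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})

    def adjacency(self) -> np.ndarray:
        """Boolean vector a[j] = window j+1 directly follows window j.

        True requires the same chromosome and end[j] == start[j+1]; peaks are
        never merged across chromosome boundaries or grid gaps.
        """
        same = self.chrom[:-1] == self.chrom[1:]
        touch = self.end[:-1] == self.start[1:]
        return np.asarray(same & touch, dtype=bool)


def make_windows(chrom_sizes: Mapping[str, int], width: int = 500) -> GenomicWindows:
    """Tile each chromosome with non-overlapping `width`-bp windows from 0.

    A trailing partial window is dropped so that every window has the same
    width.  500 bp is a common choice for broad histone marks; 250 bp suits
    short marks.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    chroms, starts = [], []
    for name, size in chrom_sizes.items():
        n = int(size) // width
        if n == 0:
            continue
        chroms.extend([name] * n)
        starts.extend(range(0, n * width, width))
    if not chroms:
        raise ValueError("no chromosome can hold a full window")
    start = np.asarray(starts, dtype=np.int64)
    return GenomicWindows(np.asarray(chroms, dtype=object), start, start + width)


@dataclass
class CountDataset:
    """Window read counts for N samples over M windows, with condition map.

    Attributes
    ----------
    counts
        (N, M) non-negative integer matrix; row order matches `sample_names`.
    condition_of_sample
        (N,) integer array mapping each sample to a condition index in
        ``0..G-1``.
    windows
        The M genomic windows the columns refer to.
    offsets
        (N, M) real matrix of log-scale normalization offsets (default zero).
    """

    counts: np.ndarray
    condition_of_sample: np.ndarray
    windows: GenomicWindows
    offsets: np.ndarray | None = None
    sample_names: Sequence[str] | None = None
    condition_labels: Sequence[str] | None = None
    dropped_reads: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D (samples x windows) matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValueError("counts must be finite integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        cond = np.asarray(self.condition_of_sample, dtype=np.int64)
        if cond.shape != (counts.shape[0],):
            raise ValueError("condition_of_sample length must equal the number of samples")
        g = self.n_conditions_from(cond)
        if not np.array_equal(np.unique(cond), np.arange(g)):
            raise ValueError("conditions must be labelled 0..G-1 with >=1 sample each")
        if counts.shape[1] != len(self.windows):
            raise ValueError("count columns must match the number of windows")
        if self.offsets is None:
            offsets = np.zeros(counts.shape, dtype=np.float64)
        else:
            offsets = np.asarray(self.offsets, dtype=np.float64)
            if offsets.shape != counts.shape:
                raise ValueError("offsets must have the same shape as counts")
            if not np.all(np.isfinite(offsets)):
                raise ValueError("offsets must be finite")
        if self.sample_names is None:
            names = [f"sample{i}" for i in range(counts.shape[0])]
        else:
            names = list(self.sample_names)
            if len(names) != counts.shape[0]:
                raise ValueError("sample_names length mismatch")
        if self.condition_labels is None:
            labels = [f"cond{h}" for h in range(g)]
        else:
            labels = list(self.condition_labels)
            if len(labels) != g:
                raise ValueError("condition_labels length mismatch")
        self.counts = counts
        self.condition_of_sample = cond
        self.offsets = offsets
        self.sample_names = names
        self.condition_labels = labels

    @staticmethod
    def n_conditions_from(cond: np.ndarray) -> int:
        return int(cond.max()) + 1 if len(cond) else 0

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_windows(self) -> int:
        return self.counts.shape[1]

    @property
    def n_conditions(self) -> int:
        return self.n_conditions_from(self.condition_of_sample)

    @property
    def n_per_condition(self) -> np.ndarray:
        return np.bincount(self.condition_of_sample, minlength=self.n_conditions)


def _assignment_position(start: int, end: int) -> int:
    # fragment assignment position: interval midpoint (strand-symmetric)
    return (int(start) + int(end)) // 2


def tabulate_counts(
    reads: Iterable[tuple[str, int, int]],
    windows: GenomicWindows,
    sample_name: str = "sample0",
) -> np.ndarray:
    """Count reads per window for one sample.

    Each read is a ``(chrom, start, end)`` interval (0-based, half-open); it
    contributes 1 to the single window containing its midpoint.  Reads whose
    midpoint falls outside every window, or on a chromosome absent from the
    window set, are dropped (the dropped total is logged).

    Returns the per-window integer count row; combine rows from several
    samples into a :class:`CountDataset`.
    """
    width = windows.width
    # per-chromosome lookup: start offset of the chromosome block + grid origin
    blocks: dict[str, tuple[int, np.ndarray]] = {}
    chrom_arr = windows.chrom
    for c in pd.unique(chrom_arr):
        mask = chrom_arr == c
        blocks[c] = (int(np.flatnonzero(mask)[0]), windows.start[mask])
    counts = np.zeros(len(windows), dtype=np.int64)
    dropped = 0
    for chrom, start, end in reads:
        block = blocks.get(chrom)
        if block is None:
            dropped += 1
            continue
        offset, starts = block
        pos = _assignment_position(start, end)
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        if k < 0 or pos >= starts[k] + width:
            dropped += 1
            continue
        counts[offset + k] += 1
    if dropped:
        logger.info("tabulate_counts(%s): dropped %d reads outside windows", sample_name, dropped)
    return counts


def tabulate_bam(path: str | Path, windows: GenomicWindows) -> np.ndarray:
    """Count aligned reads from a SAM/BAM file over `windows` (needs pysam)."""
    import pysam

    def _iter():
        with pysam.AlignmentFile(str(path)) as bam:
            for rec in bam:
                if rec.is_unmapped or rec.reference_name is None:
                    continue
                yield rec.reference_name, rec.reference_start, rec.reference_end

    return tabulate_counts(_iter(), windows, sample_name=str(path))


def library_size_offsets(dataset: CountDataset) -> np.ndarray:
    """Per-sample sequencing-depth offsets, constant across windows.

    ``u_hij = log(d_hi / g)`` where ``d_hi`` is the sample's total count and
    ``g`` the geometric mean of the totals; the offsets sum to zero across
    samples.
    """
    totals = dataset.counts.sum(axis=1).astype(np.float64)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total count: {[dataset.sample_names[i] for i in zero]}"
        )
    log_totals = np.log(totals)
    u = log_totals - log_totals.mean()
    return np.repeat(u[:, None], dataset.n_windows, axis=1)


# ---------------------------------------------------------------------------
# plain-text I/O
#
# counts table: TSV with columns chrom, start, end, then one column per
# sample; sample map: TSV with columns sample, condition.


def write_counts_table(dataset: CountDataset, path: str | Path, sample_map: str | Path | None = None) -> None:
    path = Path(path)
    df = dataset.windows.to_frame()
    for i, name in enumerate(dataset.sample_names):
        df[name] = dataset.counts[i]
    df.to_csv(path, sep="\t", index=False)
    map_path = Path(sample_map) if sample_map else path.with_suffix(path.suffix + ".samples")
    pd.DataFrame(
        {
            "sample": dataset.sample_names,
            "condition": [dataset.condition_labels[h] for h in dataset.condition_of_sample],
        }
    ).to_csv(map_path, sep="\t", index=False)


def read_counts_table(path: str | Path, sample_map: str | Path | None = None) -> CountDataset:
    """Read a counts table plus its sample->condition sidecar.

    Conditions are ordered by first appearance in the sample map; a header
    that does not match the map, ragged rows or non-integer counts are
    rejected.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty counts table")
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: first columns must be {required}")
    if len(df) == 0:
        raise ValueError(f"{path}: counts table has no rows")
    map_path = Path(sample_map) if sample_map else path.with_suffix(path.suffix + ".samples")
    smap = pd.read_csv(map_path, sep="\t")
    names = list(smap["sample"].astype(str))
    if list(df.columns[3:]) != names:
        raise ValueError(f"{path}: sample columns {list(df.columns[3:])} do not match map {names}")
    labels = list(pd.unique(smap["condition"].astype(str)))
    cond = np.array([labels.index(c) for c in smap["condition"].astype(str)], dtype=np.int64)
    count_block = df[names]
    for name in names:
        col = pd.to_numeric(count_block[name], errors="coerce")
        bad = col.isna() | (col != np.floor(col))
        if bad.any():
            raise ValueError(f"{path}: non-integer count in column {name}, row {int(np.flatnonzero(bad)[0])}")
    windows = GenomicWindows(
        df["chrom"].to_numpy(dtype=object),
        df["start"].to_numpy(dtype=np.int64),
        df["end"].to_numpy(dtype=np.int64),
    )
    return CountDataset(
        counts=count_block.to_numpy(dtype=np.int64).T,
        condition_of_sample=cond,
        windows=windows,
        sample_names=names,
        condition_labels=labels,
    )
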