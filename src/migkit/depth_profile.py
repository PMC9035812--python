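"""Mapped-base-count statistics from per-base depth tables.

The central quantity is the number of genomic positions whose coverage depth
meets a stability threshold (DP >= 10 by default), optionally normalized to
0.5 Gb of raw read data.  Per-variant DP distributions are summarized as
quantile tables.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import IO, Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

QUANTILES = (0.0, 0.05, 0.25, 0.50, 0.75, 0.95, 1.0)


@dataclass
class PerBaseDepth:
    """Dense per-position depths for one sample.

    ``depths[chrom][i]`` is the depth at 1-based position ``i + 1``;
    positions absent from sparse input are depth 0.
    """

    sample: str
    depths: Dict[str, np.ndarray]
    raw_read_gb: Optional[float] = None

    def __post_init__(self) -> None:
        for chrom, arr in self.depths.items():
            arr = np.asarray(arr, dtype=np.int64)
            if (arr < 0).any():
                raise ValueError(f"negative depth on {chrom}")
            self.depths[chrom] = arr

    @property
    def genome_length(self) -> int:
        return sum(len(a) for a in self.depths.values())

    def total_mapped_bases(self) -> int:
        """Sum of depths over all positions (read-bases mapped)."""
        return int(sum(int(a.sum()) for a in self.depths.values()))


@dataclass
class DepthSummary:
    sample: str
    mapped_base_count: Dict[int, int] = field(default_factory=dict)
    dp_per_half_gb: Optional[float] = None
    variant_dp_quantiles: Optional[List[float]] = None


def read_depth_table(
    source: str | IO[str],
    sample: str = "sample",
    chrom_lengths: Optional[Mapping[str, int]] = None,
    raw_read_gb: Optional[float] = None,
) -> PerBaseDepth:
    """Parse a 3-column TSV (chrom, 1-based pos, depth) into dense arrays.

    Sparse rows are densified with zeros.  ``chrom_lengths`` declares the full
    extent of each chromosome; without it, the largest observed position per
    chromosome is used.  Malformed rows raise with their line number.
    """
    close = False
    if isinstance(source, str):
        handle: IO[str] = open(source)
        close = True
    else:
        handle = source
    per_chrom: Dict[str, List[tuple]] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                pos = int(parts[1])
                depth = int(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric field") from exc
            if pos < 1:
                raise ValueError(f"line {lineno}: position must be >= 1")
            if depth < 0:
                raise ValueError(f"line {lineno}: negative depth")
            per_chrom.setdefault(chrom, []).append((pos, depth))
    finally:
        if close:
            handle.close()

    depths: Dict[str, np.ndarray] = {}
    names = set(per_chrom)
    if chrom_lengths is not None:
        names |= set(chrom_lengths)
    for chrom in names:
        rows = per_chrom.get(chrom, [])
        max_pos = max((p for p, _ in rows), default=0)
        length = max_pos
        if chrom_lengths is not None and chrom in chrom_lengths:
            length = max(chrom_lengths[chrom], max_pos)
        arr = np.zeros(length, dtype=np.int64)
        for pos, depth in rows:
            arr[pos - 1] = depth
        depths[chrom] = arr
    return PerBaseDepth(sample=sample, depths=depths, raw_read_gb=raw_read_gb)


def write_depth_table(pbd: PerBaseDepth, target: str | IO[str], sparse: bool = True) -> None:
    """Write (chrom, 1-based pos, depth) rows; ``sparse`` skips zero depths."""
    close = False
    if isinstance(target, str):
        handle: IO[str] = open(target, "w")
        close = True
    else:
        handle = target
    try:
        for chrom in sorted(pbd.depths):
            arr = pbd.depths[chrom]
            idx = np.flatnonzero(arr) if sparse else np.arange(len(arr))
            for i in idx:
                handle.write(f"{chrom}\t{i + 1}\t{arr[i]}\n")
    finally:
        if close:
            handle.close()


def depth_table_string(pbd: PerBaseDepth, sparse: bool = True) -> str:
    buf = _io.StringIO()
    write_depth_table(pbd, buf, sparse=sparse)
    return buf.getvalue()


def mapped_base_count(pbd: PerBaseDepth, min_dp: int = 10, strict: bool = False) -> int:
    """Number of positions with depth >= ``min_dp`` (``strict``: > min_dp)."""
    if min_dp < 1:
        raise ValueError("min_dp must be >= 1")
    total = 0
    for arr in pbd.depths.values():
        total += int((arr > min_dp).sum() if strict else (arr >= min_dp).sum())
    return total


def depth_histogram(pbd: PerBaseDepth) -> Dict[int, int]:
    """Exact-depth counts; values sum to the genome length."""
    counts: Dict[int, int] = {}
    for arr in pbd.depths.values():
        vals, n = np.unique(arr, return_counts=True)
        for v, c in zip(vals, n):
            counts[int(v)] = counts.get(int(v), 0) + int(c)
    return counts


def normalize_per_half_gb(value: float, raw_read_gb: float) -> float:
    """Scale a count to a 0.5 Gb raw-data equivalent: value / Gb * 0.5."""
    if raw_read_gb <= 0:
        raise ValueError("raw_read_gb must be positive")
    return value / raw_read_gb * 0.5


def variant_dp_summary(
    dp: np.ndarray,
    sample_groups: Optional[Mapping[str, str]] = None,
    samples: Optional[Sequence[str]] = None,
    quantiles: Sequence[float] = QUANTILES,
) -> pd.DataFrame:
    """Quantiles of per-variant mean DP.

    ``dp`` is a (sites x samples) array; the per-variant statistic is the mean
    DP across samples (optionally within groups).  Returns one row per group
    with columns min/q05/q25/q50/q75/q95/max; empty input gives an empty frame.
    """
    dp = np.asarray(dp, dtype=float)
    cols = ["min", "q05", "q25", "q50", "q75", "q95", "max"]
    if dp.size == 0:
        return pd.DataFrame(columns=["group", "n_variants", *cols])
    if dp.ndim == 1:
        dp = dp[:, None]
    group_to_idx: Dict[str, List[int]] = {}
    if sample_groups is not None and samples is not None:
        for i, s in enumerate(samples):
            group_to_idx.setdefault(sample_groups.get(s, "all"), []).append(i)
    else:
        group_to_idx["all"] = list(range(dp.shape[1]))
    rows = []
    for group, idx in sorted(group_to_idx.items()):
        means = dp[:, idx].mean(axis=1)
        qs = np.quantile(means, quantiles)
        rows.append({"group": group, "n_variants": len(means),
                     **dict(zip(cols, qs.tolist()))})
    return pd.DataFrame(rows)


def summarize_sample(
    pbd: PerBaseDepth,
    thresholds: Sequence[int] = (5, 10),
    strict: bool = False,
) -> DepthSummary:
    """Mapped-base counts at several thresholds plus 0.5-Gb normalization of
    the DP>=10 (or first-threshold) count when raw_read_gb is known."""
    summary = DepthSummary(sample=pbd.sample)
    for t in thresholds:
        summary.mapped_base_count[t] = mapped_base_count(pbd, t, strict=strict)
    if pbd.raw_read_gb:
        key = 10 if 10 in summary.mapped_base_count else thresholds[0]
        summary.dp_per_half_gb = normalize_per_half_gb(
            summary.mapped_base_count[key], pbd.raw_read_gb
        )
    return summary
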