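"""Virtual-F1 heterozygous-call accuracy curves.

Two homozygous parents' marker-level read counts are subsampled (without
replacement) and merged into an artificial heterozygote; every marker that
differs between the parents is truth-het.  A minimal allele-depth caller then
produces error and missing rates over a grid of minimum-depth thresholds,
with an exact analytic oracle for validation: at a truth-het marker with
total depth d (error-free), the probability of a homozygous call is 2^(1-d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

HOM_A = "hom_A"
HOM_B = "hom_B"
HET = "het"
MISSING = "missing"


@dataclass
class VirtualF1:
    """Merged parental allele depths at truth-het markers."""

    replicate: int
    reads_per_parent: int
    ad_a: np.ndarray  # depth supporting parent A's allele, per marker
    ad_b: np.ndarray

    def __post_init__(self) -> None:
        self.ad_a = np.asarray(self.ad_a, dtype=np.int64)
        self.ad_b = np.asarray(self.ad_b, dtype=np.int64)
        if self.ad_a.shape != self.ad_b.shape:
            raise ValueError("allele-depth arrays must align")
        if (self.ad_a < 0).any() or (self.ad_b < 0).any():
            raise ValueError("negative depths")

    @property
    def total_dp(self) -> np.ndarray:
        return self.ad_a + self.ad_b

    @property
    def n_markers(self) -> int:
        return len(self.ad_a)


def subsample_counts(
    depths: np.ndarray, n_reads: int, total_reads: int, seed: int = 0
) -> np.ndarray:
    """Hypergeometric thinning of marker-level read counts.

    Draws ``n_reads`` of ``total_reads`` reads without replacement; reads not
    mapped to any marker (total_reads - sum(depths)) form an extra stratum.
    Each marker's expected depth scales by n_reads / total_reads.
    """
    depths = np.asarray(depths, dtype=np.int64)
    mapped = int(depths.sum())
    if total_reads < mapped:
        raise ValueError("total_reads smaller than mapped read count")
    if n_reads > total_reads:
        raise ValueError("cannot subsample more reads than available")
    if n_reads == total_reads:
        return depths.copy()
    if n_reads == 0:
        return np.zeros_like(depths)
    rng = np.random.default_rng(seed)
    colors = np.concatenate([depths, [total_reads - mapped]])
    drawn = rng.multivariate_hypergeometric(colors, n_reads, method="marginals")
    return drawn[:-1]


def make_virtual_f1(
    parent_a_depths: Mapping[str, int] | np.ndarray,
    parent_b_depths: Mapping[str, int] | np.ndarray,
    replicate: int = 0,
    reads_per_parent: int = 0,
    base_error_rate: float = 0.0,
    seed: int = 0,
) -> VirtualF1:
    """Merge per-marker parental depths into a virtual heterozygote.

    With ``base_error_rate`` > 0, each read independently shows the wrong
    allele with that probability, giving the error curves a non-zero floor.
    """
    if isinstance(parent_a_depths, Mapping):
        keys = list(parent_a_depths)
        if set(keys) != set(parent_b_depths):
            raise ValueError("parents must share one marker universe")
        a = np.array([parent_a_depths[k] for k in keys], dtype=np.int64)
        b = np.array([parent_b_depths[k] for k in keys], dtype=np.int64)
    else:
        a = np.asarray(parent_a_depths, dtype=np.int64)
        b = np.asarray(parent_b_depths, dtype=np.int64)
        if a.shape != b.shape:
            raise ValueError("parents must share one marker universe")
    if base_error_rate > 0:
        rng = np.random.default_rng(seed)
        a_to_b = rng.binomial(a, base_error_rate)
        b_to_a = rng.binomial(b, base_error_rate)
        a = a - a_to_b + b_to_a
        b = b - b_to_a + a_to_b
    return VirtualF1(replicate=replicate, reads_per_parent=reads_per_parent,
                     ad_a=a, ad_b=b)


def call_genotype(ad: Tuple[int, int], min_dp: int) -> str:
    """Minimal AD caller: missing below min_dp, het if both alleles seen,
    else hom of the observed allele."""
    a, b = ad
    if a < 0 or b < 0:
        raise ValueError("negative allele depths")
    if a + b < min_dp:
        return MISSING
    if a > 0 and b > 0:
        return HET
    return HOM_A if a > 0 else HOM_B


def _rates_one(f1: VirtualF1, min_dp: int) -> Tuple[float, float, int, int]:
    """(error_rate, missing_rate, n_called, n_markers) at one threshold.

    All markers are truth-het; an error is a homozygous call among the
    non-missing calls."""
    total = f1.total_dp
    n = f1.n_markers
    missing = total < min_dp
    called = ~missing
    hom = called & ((f1.ad_a == 0) | (f1.ad_b == 0))
    n_called = int(called.sum())
    error = float(hom.sum() / n_called) if n_called else float("nan")
    return error, float(missing.sum() / n), n_called, n


def error_missing_curves(
    replicates: Sequence[VirtualF1],
    min_dp_grid: Iterable[int] = range(1, 21),
) -> pd.DataFrame:
    """Long-format error/missing rates per (reads, min_dp, replicate), plus
    replicate-averaged rows tagged replicate = -1."""
    if not replicates:
        raise ValueError("need >= 1 virtual F1 replicate")
    rows: List[Dict[str, object]] = []
    grid = list(min_dp_grid)
    for min_dp in grid:
        per_rep = []
        for f1 in replicates:
            err, miss, n_called, n = _rates_one(f1, min_dp)
            rows.append(dict(
                reads_per_f1=2 * f1.reads_per_parent, min_dp=min_dp,
                replicate=f1.replicate, error_rate=err, missing_rate=miss,
                n_called=n_called, n_markers=n,
            ))
            per_rep.append((err, miss, n_called, n))
        errs = [e for e, _, nc, _ in per_rep if nc > 0]
        rows.append(dict(
            reads_per_f1=2 * replicates[0].reads_per_parent, min_dp=min_dp,
            replicate=-1,
            error_rate=float(np.mean(errs)) if errs else float("nan"),
            missing_rate=float(np.mean([m for _, m, _, _ in per_rep])),
            n_called=sum(nc for _, _, nc, _ in per_rep),
            n_markers=sum(n for _, _, _, n in per_rep),
        ))
    return pd.DataFrame(rows)


def analytic_het_error(
    depth_distribution: Mapping[int, float], min_dp: int
) -> Tuple[float, float]:
    """Exact (error, missing) expectations for an error-free truth-het marker
    whose total depth is drawn from ``depth_distribution``.

    missing = P(d < min_dp); error = E[2^(1-d) | d >= min_dp] (a depth-d draw
    is called hom when all reads show one allele: 2 * (1/2)^d).
    """
    probs = np.array(list(depth_distribution.values()), dtype=float)
    depths = np.array(list(depth_distribution.keys()), dtype=int)
    if probs.min() < 0 or not np.isclose(probs.sum(), 1.0, atol=1e-8):
        raise ValueError("depth distribution must sum to 1")
    below = depths < min_dp
    missing = float(probs[below].sum())
    p_called = float(probs[~below].sum())
    if p_called == 0:
        raise ValueError("no support at or above min_dp: error undefined")
    hom_given_d = np.power(2.0, 1.0 - depths[~below].astype(float))
    # depth 0 cannot occur among called markers unless min_dp == 0
    hom_given_d = np.where(depths[~below] == 0, 1.0, hom_given_d)
    error = float((probs[~below] * hom_given_d).sum() / p_called)
    return error, missing
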