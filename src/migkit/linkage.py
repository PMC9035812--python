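"""Two-point linkage statistics and a single-marker QTL scan.

Recombination fractions come from an EM fit over the 9-class joint genotype
table (F2) or from the observed recombinant fraction with the selfing-RIL
correction r = R / (2 - 2R).  Distances use Kosambi's mapping function
d = 25 ln((1+2r)/(1-2r)) cM.  The QTL scan is a per-marker least-squares
regression on additively coded genotypes, LOD = (n/2) log10(RSS0/RSS1), with
a permutation-based genome-wide threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_qc import MISSING

# ---------------------------------------------------------------------------
# two-point recombination


def _f2_em(table: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> float:
    """Maximum-likelihood r for an F2 9-class joint genotype table via EM.

    ``table[g1, g2]`` counts individuals with g alt-allele dosages (0/1/2) at
    the two markers.  Gametes carry 0 or 1 recombination events; the
    double-het class mixes 0- and 2-recombinant gamete pairs.
    """
    n = table.sum()
    if n == 0:
        raise ValueError("no jointly genotyped individuals")
    # genotype class -> list of (gamete pair probability weight, recombinants)
    # gametes: (a1, a2, rec) with prob (1-r)/2 for parental, r/2 for recomb.
    gametes = [(0, 0, 0), (1, 1, 0), (0, 1, 1), (1, 0, 1)]
    r = 0.25
    for _ in range(max_iter):
        exp_rec = 0.0
        for g1 in range(3):
            for g2 in range(3):
                c = table[g1, g2]
                if c == 0:
                    continue
                num = 0.0
                den = 0.0
                for a1, a2, rec1 in gametes:
                    for b1, b2, rec2 in gametes:
                        if a1 + b1 != g1 or a2 + b2 != g2:
                            continue
                        p1 = r / 2 if rec1 else (1 - r) / 2
                        p2 = r / 2 if rec2 else (1 - r) / 2
                        p = p1 * p2
                        den += p
                        num += p * (rec1 + rec2)
                exp_rec += c * num / den
        r_new = exp_rec / (2.0 * n)
        r_new = min(max(r_new, 1e-12), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return float(r)


def recombination_fraction(
    g1: np.ndarray, g2: np.ndarray, population: str = "F2"
) -> float:
    """Estimate the recombination fraction between two markers.

    ``g1``/``g2`` are genotype codes 0/1/2 (missing = -1) for each
    individual.  F2 uses the EM MLE over the 9-class table; RIL uses the
    observed recombinant fraction among hom/hom pairs mapped back through
    r = R / (2 - 2R).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    both = (g1 != MISSING) & (g2 != MISSING)
    if population == "RIL":
        both &= (g1 != 1) & (g2 != 1)
    if both.sum() < 10:
        raise ValueError("need >= 10 jointly genotyped individuals")
    a, b = g1[both], g2[both]
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("monomorphic marker: recombination fraction undefined")
    if population == "F2":
        table = np.zeros((3, 3), dtype=np.int64)
        np.add.at(table, (a, b), 1)
        return _f2_em(table)
    if population == "RIL":
        R = float((a != b).mean())
        if R >= 0.5:
            return 0.5
        return R / (2.0 - 2.0 * R)
    raise ValueError("population must be 'F2' or 'RIL'")


def kosambi_cM(r: float) -> float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM for r in [0, 0.5)."""
    if r < 0:
        raise ValueError("recombination fraction must be >= 0")
    if r >= 0.5:
        raise ValueError("r >= 0.5 maps to infinite distance")
    return 25.0 * float(np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r)))


def haldane_cM(r: float) -> float:
    """Haldane map distance d = -50 ln(1-2r) cM (no interference)."""
    if not 0 <= r < 0.5:
        raise ValueError("r must be in [0, 0.5)")
    return -50.0 * float(np.log(1.0 - 2.0 * r))


# ---------------------------------------------------------------------------
# maps


@dataclass
class OrderedMap:
    """Ordered markers per linkage group with physical and genetic positions."""

    groups: Dict[str, pd.DataFrame]  # columns: marker, pos_bp, cM (cumulative)

    def __post_init__(self) -> None:
        for name, df in self.groups.items():
            if not (np.diff(df["cM"].to_numpy()) >= -1e-9).all():
                raise ValueError(f"cM positions must be non-decreasing in {name}")

    @property
    def n_markers(self) -> int:
        return sum(len(df) for df in self.groups.values())

    @property
    def total_cM(self) -> float:
        return float(sum(df["cM"].iloc[-1] for df in self.groups.values() if len(df)))

    @classmethod
    def evenly_spaced(cls, total_cM: float, n_markers: int,
                      group: str = "LG1") -> "OrderedMap":
        cm = np.linspace(0.0, total_cM, n_markers)
        df = pd.DataFrame({
            "marker": [f"m{i + 1}" for i in range(n_markers)],
            "pos_bp": (cm * 1e6).astype(int),
            "cM": cm,
        })
        return cls(groups={group: df})


def map_summary(ordered_map: OrderedMap) -> Tuple[float, int, float]:
    """(total length cM, marker count, average spacing = length / markers)."""
    if ordered_map.n_markers < 2:
        raise ValueError("need >= 2 markers")
    total = ordered_map.total_cM
    n = ordered_map.n_markers
    return total, n, total / n


def map_from_genotypes(
    geno: np.ndarray,
    chrom: Sequence[str],
    pos: Sequence[int],
    population: str = "F2",
) -> OrderedMap:
    """Chain adjacent-marker Kosambi distances along the physical order."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    groups: Dict[str, pd.DataFrame] = {}
    for c in dict.fromkeys(chrom.tolist()):
        idx = np.flatnonzero(chrom == c)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        cm = [0.0]
        for i, j in zip(idx, idx[1:]):
            r = recombination_fraction(geno[i], geno[j], population)
            cm.append(cm[-1] + kosambi_cM(min(r, 0.499999)))
        groups[c] = pd.DataFrame({
            "marker": [f"{c}_{pos[i]}" for i in idx],
            "pos_bp": pos[idx],
            "cM": cm,
        })
    return OrderedMap(groups=groups)


def segregation_distortion(
    geno: np.ndarray, expected_ratio: Sequence[float]
) -> pd.DataFrame:
    """Pearson chi-square per marker against the expected genotype ratio.

    ``geno`` is (markers x individuals) coded 0/1/2 (missing -1).  A 2-class
    ratio (e.g. 1:1 for RILs) tests the hom classes only.
    """
    geno = np.atleast_2d(np.asarray(geno))
    ratio = np.asarray(expected_ratio, dtype=float)
    ratio = ratio / ratio.sum()
    classes = [0, 1, 2] if len(ratio) == 3 else [0, 2]
    rows = []
    for i in range(geno.shape[0]):
        row = geno[i]
        counts = np.array([(row == c).sum() for c in classes], dtype=float)
        n = counts.sum()
        if n == 0:
            rows.append(dict(marker=i, n=0, chi2=np.nan, p=np.nan))
            continue
        chi2, p = stats.chisquare(counts, f_exp=ratio * n)
        rows.append(dict(marker=i, n=int(n), chi2=float(chi2), p=float(p)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# single-marker QTL scan


@dataclass
class LODProfile:
    table: pd.DataFrame  # columns: marker, lod, effect, r2, n
    threshold: Optional[float] = None
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def peak_index(self) -> int:
        return int(self.table["lod"].idxmax())


def _additive_coding(geno: np.ndarray) -> np.ndarray:
    """Code 0/1/2 as -1/0/+1 with NaN for missing."""
    x = geno.astype(float)
    x[geno == MISSING] = np.nan
    return x - 1.0


def _masked_lod(X: np.ndarray, Y: np.ndarray) -> Tuple[np.ndarray, ...]:
    """Vectorized per-marker simple regression of each column of Y on each
    column of X, honouring NaN in X.

    X: (n x m) additively coded genotypes (NaN = missing).
    Y: (n x p) phenotype columns (no NaN).
    Returns (lod, slope, r2, n_obs) where lod/slope/r2 are (m x p) and
    n_obs is (m,).
    """
    W = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X)
    n_j = W.sum(axis=0)  # (m,)
    sx = X0.sum(axis=0)
    sxx = (X0 * X0).sum(axis=0)
    sy = W.T @ Y  # (m, p)
    syy = W.T @ (Y * Y)
    sxy = X0.T @ Y
    with np.errstate(invalid="ignore", divide="ignore"):
        nj = n_j[:, None]
        cov = sxy - sx[:, None] * sy / nj
        varx = (sxx - sx * sx / n_j)[:, None]
        vary = syy - sy * sy / nj
        r2 = np.where((varx > 0) & (vary > 0), cov**2 / (varx * vary), 0.0)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        lod = -(nj / 2.0) * np.log10(1.0 - r2)
        slope = np.where(varx > 0, cov / varx, 0.0)
    return lod, slope, r2, n_j


def lod_scan(
    geno: np.ndarray,
    phenotype: np.ndarray,
    marker_names: Optional[Sequence[str]] = None,
) -> LODProfile:
    """Single-marker additive scan.

    geno: (markers x individuals) codes 0/1/2/-1.  Monomorphic markers get
    LOD 0 and are flagged in the table.  The additive effect is the
    regression slope under -1/0/+1 coding (half the hom-class mean
    difference); R2 = 1 - RSS1/RSS0.
    """
    geno = np.atleast_2d(np.asarray(geno))
    y = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 20:
        raise ValueError("need phenotype for >= 20 individuals")
    X = _additive_coding(geno[:, ok].T)
    lod, slope, r2, n_obs = _masked_lod(X, y[ok][:, None])
    mono = np.array([
        len(np.unique(col[~np.isnan(col)])) < 2 for col in X.T
    ])
    lod = lod[:, 0].copy()
    lod[mono] = 0.0
    names = (list(marker_names) if marker_names is not None
             else [f"m{i}" for i in range(geno.shape[0])])
    table = pd.DataFrame({
        "marker": names,
        "lod": lod,
        "effect": slope[:, 0],
        "r2": r2[:, 0],
        "n": n_obs.astype(int),
        "monomorphic": mono,
    })
    return LODProfile(table=table)


def max_lod(geno: np.ndarray, phenotypes: np.ndarray) -> np.ndarray:
    """Maximum LOD over markers for each phenotype column (batched)."""
    X = _additive_coding(np.atleast_2d(np.asarray(geno)).T)
    Y = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    lod, _, _, _ = _masked_lod(X, Y)
    return lod.max(axis=0)


def permutation_threshold(
    geno: np.ndarray,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold from the permutation null.

    The phenotype is permuted across individuals ``n_perm`` times; the
    threshold is the k-th order statistic of the per-permutation maximum LOD
    with k = ceil((1-alpha)(n_perm+1)), so the exceedance probability of an
    exchangeable observation is ~alpha.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    y = np.sort(np.asarray(phenotype, dtype=float))  # canonical base: the
    # threshold depends on the phenotype only through its multiset of values
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
    maxima = np.sort(max_lod(geno, perms))
    k = int(np.ceil((1.0 - alpha) * (n_perm + 1)))
    k = min(max(k, 1), n_perm)
    return float(maxima[k - 1])


def qtl_scan(
    geno: np.ndarray,
    phenotype: np.ndarray,
    marker_names: Optional[Sequence[str]] = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> LODProfile:
    """LOD profile plus permutation threshold and its provenance."""
    profile = lod_scan(geno, phenotype, marker_names)
    profile.threshold = permutation_threshold(geno, phenotype, n_perm, alpha, seed)
    profile.provenance = {"n_perm": n_perm, "alpha": alpha, "seed": seed}
    return profile
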