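"""Genotype-matrix quality control.

Implements the filter stack applied to joint-genotyped VCF matrices: per-cell
depth masking, site-level genotype-rate/quality/heterozygosity filters,
individual-level missingness filters, parental-replicate consistency marker
extraction, and heterozygote-to-missing conversion for inbred designs.

Genotype codes: 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype calls with per-cell DP and allele depths.

    Sites are sorted by (chrom, pos).  ``ad`` has shape (sites, samples, 2)
    holding ref/alt supporting read counts; sum(AD) <= DP always.
    """

    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int, 1-based
    ref: np.ndarray  # (n_sites,) str
    alt: np.ndarray  # (n_sites,) str
    qual: np.ndarray  # (n_sites,) float
    samples: List[str]
    gt: np.ndarray  # (n_sites, n_samples) int8
    dp: np.ndarray  # (n_sites, n_samples) int32
    ad: np.ndarray  # (n_sites, n_samples, 2) int32

    def __post_init__(self) -> None:
        n, s = self.gt.shape
        if not (len(self.chrom) == len(self.pos) == len(self.ref) == len(self.alt) == n):
            raise ValueError("site annotation length mismatch")
        if len(self.samples) != s:
            raise ValueError("sample count mismatch")
        if (self.ad.sum(axis=2) > self.dp).any():
            raise ValueError("sum(AD) exceeds DP")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            for name in ("chrom", "pos", "ref", "alt", "qual"):
                setattr(self, name, getattr(self, name)[order])
            self.gt = self.gt[order]
            self.dp = self.dp[order]
            self.ad = self.ad[order]

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def site_keys(self) -> List[Tuple[str, int]]:
        return list(zip(self.chrom.tolist(), self.pos.tolist()))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom.copy(), pos=self.pos.copy(), ref=self.ref.copy(),
            alt=self.alt.copy(), qual=self.qual.copy(), samples=list(self.samples),
            gt=self.gt.copy(), dp=self.dp.copy(), ad=self.ad.copy(),
        )

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom[idx], pos=self.pos[idx], ref=self.ref[idx],
            alt=self.alt[idx], qual=self.qual[idx], samples=list(self.samples),
            gt=self.gt[idx], dp=self.dp[idx], ad=self.ad[idx],
        )

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            chrom=self.chrom.copy(), pos=self.pos.copy(), ref=self.ref.copy(),
            alt=self.alt.copy(), qual=self.qual.copy(),
            samples=[self.samples[i] for i in idx],
            gt=self.gt[:, idx], dp=self.dp[:, idx], ad=self.ad[:, idx],
        )

    def is_indel(self) -> np.ndarray:
        reflen = np.char.str_len(self.ref.astype(str))
        altlen = np.char.str_len(self.alt.astype(str))
        return (reflen != 1) | (altlen != 1)


@dataclass
class MarkerSet:
    """Accepted site keys plus a record of which filters they passed."""

    keys: List[Tuple[str, int]]
    provenance: Dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.keys)

    def mask_for(self, m: GenotypeMatrix) -> np.ndarray:
        wanted = set(self.keys)
        return np.fromiter(
            (k in wanted for k in m.site_keys()), dtype=bool, count=m.n_sites
        )


def mask_low_depth(m: GenotypeMatrix, min_dp: int, strict: bool = False) -> GenotypeMatrix:
    """Set genotype cells to missing where DP < min_dp (strict: DP <= min_dp)."""
    if min_dp < 1:
        raise ValueError("min_dp must be >= 1")
    out = m.copy()
    low = out.dp <= min_dp if strict else out.dp < min_dp
    out.gt[low] = MISSING
    return out


def filter_sites(
    m: GenotypeMatrix,
    min_genotype_rate: float = 0.0,
    remove_any_het: bool = False,
    min_site_quality: float = 0.0,
    biallelic_only: bool = True,
    rate_comparator: str = ">",
) -> MarkerSet:
    """Site filter: genotype rate (fraction of non-missing calls) above the
    threshold (strict ``>`` by default; ``>=`` reproduces a max-missing-1
    style boundary), site quality >= min, optionally zero het cells.
    """
    if not 0.0 <= min_genotype_rate <= 1.0:
        raise ValueError("min_genotype_rate must be in [0, 1]")
    if rate_comparator not in (">", ">="):
        raise ValueError("rate_comparator must be '>' or '>='")
    called = m.gt != MISSING
    rate = called.mean(axis=1) if m.n_samples else np.zeros(m.n_sites)
    if rate_comparator == ">":
        keep = rate > min_genotype_rate
    else:
        keep = rate >= min_genotype_rate
    keep &= m.qual >= min_site_quality
    if remove_any_het:
        keep &= ~(m.gt == HET).any(axis=1)
    if biallelic_only:
        multi = np.fromiter(("," in a for a in m.alt.astype(str)), dtype=bool,
                            count=m.n_sites)
        keep &= ~multi
    keys = [k for k, ok in zip(m.site_keys(), keep) if ok]
    return MarkerSet(
        keys=keys,
        provenance={
            "min_genotype_rate": min_genotype_rate,
            "rate_comparator": rate_comparator,
            "remove_any_het": remove_any_het,
            "min_site_quality": min_site_quality,
            "biallelic_only": biallelic_only,
            "n_in": m.n_sites,
            "n_out": len(keys),
        },
    )


def filter_individuals(m: GenotypeMatrix, max_missing_fraction: float) -> GenotypeMatrix:
    """Drop samples whose per-sample missing fraction exceeds the bound."""
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    if m.n_sites == 0:
        return m.copy()
    missing_frac = (m.gt == MISSING).mean(axis=0)
    keep = [i for i in range(m.n_samples) if missing_frac[i] <= max_missing_fraction]
    if not keep:
        raise ValueError("all individuals removed by missingness filter")
    return m.take_samples(keep)


def het_to_missing(m: GenotypeMatrix) -> GenotypeMatrix:
    """Convert every heterozygous call to missing (idempotent)."""
    out = m.copy()
    out.gt[out.gt == HET] = MISSING
    return out


def parental_marker_set(
    replicates_a: GenotypeMatrix,
    replicates_b: GenotypeMatrix,
    mode: str = "strict",
) -> MarkerSet:
    """Markers consistent across parental replicates and polymorphic between
    parents.

    strict:  every replicate non-missing and identical within each parent.
    lenient: replicates identical within the non-missing data (at least one
             non-missing call per parent).
    Both modes additionally require the two parental genotypes to differ.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    if replicates_a.n_samples < 2 or replicates_b.n_samples < 2:
        raise ValueError("need >= 2 replicates per parent")
    keys_a = replicates_a.site_keys()
    if keys_a != replicates_b.site_keys():
        raise ValueError("replicate matrices must share the same sites")

    def consensus(gt_row: np.ndarray) -> Optional[int]:
        called = gt_row[gt_row != MISSING]
        if mode == "strict":
            if len(called) != len(gt_row):
                return None
        elif len(called) == 0:
            return None
        first = called[0]
        if (called != first).any():
            return None
        return int(first)

    keys = []
    for i, key in enumerate(keys_a):
        ga = consensus(replicates_a.gt[i])
        gb = consensus(replicates_b.gt[i])
        if ga is None or gb is None or ga == gb:
            continue
        keys.append(key)
    return MarkerSet(keys=keys, provenance={"mode": mode, "n_in": len(keys_a),
                                            "n_out": len(keys)})


def apply_marker_set(m: GenotypeMatrix, markers: MarkerSet) -> GenotypeMatrix:
    return m.take_sites(markers.mask_for(m))


#: Preset filter stacks keyed by population type.
PRESETS = {
    # diversity panel: mask DP<5, site quality >= 30, fully genotyped, no hets
    "panel": dict(mask_min_dp=5, mask_strict=False, min_site_quality=30.0,
                  min_genotype_rate=1.0, rate_comparator=">=",
                  remove_any_het=True, het_to_missing=False,
                  max_missing_fraction=None),
    # F2: mask DP<10, drop individuals missing >5%, keep sites with rate >0.97
    "f2": dict(mask_min_dp=10, mask_strict=False, min_site_quality=0.0,
               min_genotype_rate=0.97, rate_comparator=">",
               remove_any_het=False, het_to_missing=False,
               max_missing_fraction=0.05),
    # RIL: mask DP<=5, hets to missing, individuals >10%, sites rate >0.95
    "ril": dict(mask_min_dp=5, mask_strict=True, min_site_quality=0.0,
                min_genotype_rate=0.95, rate_comparator=">",
                remove_any_het=False, het_to_missing=True,
                max_missing_fraction=0.10),
}


def qc_preset(m: GenotypeMatrix, population: str) -> Tuple[GenotypeMatrix, MarkerSet]:
    """Apply the preset filter stack for ``population`` in
    {'panel', 'f2', 'ril'}; returns the filtered matrix and its MarkerSet."""
    if population not in PRESETS:
        raise ValueError(f"unknown population preset: {population!r}")
    p = PRESETS[population]
    out = mask_low_depth(m, p["mask_min_dp"], strict=p["mask_strict"])
    if p["het_to_missing"]:
        out = het_to_missing(out)
    if p["max_missing_fraction"] is not None:
        out = filter_individuals(out, p["max_missing_fraction"])
    markers = filter_sites(
        out,
        min_genotype_rate=p["min_genotype_rate"],
        remove_any_het=p["remove_any_het"],
        min_site_quality=p["min_site_quality"],
        rate_comparator=p["rate_comparator"],
    )
    markers.provenance["population"] = population
    return apply_marker_set(out, markers), markers
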