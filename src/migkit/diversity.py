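"""All-pairs nucleotide diversity and linear marker-count extrapolation.

For each unordered sample pair, diversity is the number of SNP differences
divided by the number of bases jointly covered at DP >= 5 in both samples.
The extrapolation assumes the number of polymorphisms between two parents is
proportional to their diversity, so a target marker count translates into a
minimum required diversity via a reference map.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .depth_profile import PerBaseDepth
from .genotype_qc import HOM_ALT, HOM_REF, GenotypeMatrix


@dataclass
class PairDiversity:
    sample_a: str
    sample_b: str
    snp_count: int
    common_bases: int
    pi: Optional[float]  # None when common_bases == 0 (undefined, flagged)
    relation: Optional[str] = None  # same-group | different-group

    @property
    def pair(self) -> Tuple[str, str]:
        return tuple(sorted((self.sample_a, self.sample_b)))


def pairwise_diversity(
    m: GenotypeMatrix,
    depths: Mapping[str, PerBaseDepth],
    min_dp: int = 5,
    snps_only: bool = True,
    min_site_quality: float = 0.0,
) -> List[PairDiversity]:
    """Diversity for all C(n, 2) sample pairs.

    The numerator counts sites where both samples are called homozygous with
    different alleles, each with genotype DP >= min_dp (indels excluded when
    ``snps_only``); the denominator counts genome positions with per-base
    depth >= min_dp in both samples.  Pairs with no common bases get pi=None.
    """
    missing = [s for s in m.samples if s not in depths]
    if missing:
        raise ValueError(f"no depth table for samples: {missing}")
    masks = {
        s: {c: arr >= min_dp for c, arr in depths[s].depths.items()}
        for s in m.samples
    }
    hom = (m.gt == HOM_REF) | (m.gt == HOM_ALT)
    usable_site = m.qual >= min_site_quality
    if snps_only:
        usable_site &= ~m.is_indel()
    deep = m.dp >= min_dp
    out: List[PairDiversity] = []
    for ia, ib in itertools.combinations(range(m.n_samples), 2):
        sa, sb = m.samples[ia], m.samples[ib]
        common = 0
        for c, mask_a in masks[sa].items():
            mask_b = masks[sb].get(c)
            if mask_b is not None:
                common += int((mask_a & mask_b).sum())
        diff = (
            usable_site
            & hom[:, ia] & hom[:, ib]
            & deep[:, ia] & deep[:, ib]
            & (m.gt[:, ia] != m.gt[:, ib])
        )
        snps = int(diff.sum())
        pi = snps / common if common > 0 else None
        out.append(PairDiversity(sample_a=sa, sample_b=sb,
                                 snp_count=snps, common_bases=common, pi=pi))
    return out


def predict_min_diversity(
    target_markers: int, ref_markers: int, ref_pi: float
) -> float:
    """Minimum parental diversity expected to yield ``target_markers`` map
    markers, scaling linearly from a reference map: target/ref * ref_pi."""
    if min(target_markers, ref_markers) <= 0 or ref_pi <= 0:
        raise ValueError("all inputs must be > 0")
    return target_markers / ref_markers * ref_pi


def predict_marker_count(pi: float, ref_markers: int, ref_pi: float) -> float:
    """Expected marker count at diversity ``pi``: pi / ref_pi * ref_markers."""
    if ref_pi <= 0:
        raise ValueError("ref_pi must be > 0")
    return pi / ref_pi * ref_markers


def summarize_by_group(
    pairs: Sequence[PairDiversity],
    labels: Mapping[str, str],
    threshold: float,
) -> Dict[str, Dict[str, object]]:
    """Fraction of pairs with pi above ``threshold``, stratified into
    same-group vs different-group pairs.  A stratum with zero pairs reports
    fraction None."""
    unlabelled = {
        s for p in pairs for s in (p.sample_a, p.sample_b) if s not in labels
    }
    if unlabelled:
        raise ValueError(f"unlabelled samples: {sorted(unlabelled)}")
    strata: Dict[str, List[PairDiversity]] = {"same-group": [], "different-group": []}
    for p in pairs:
        rel = ("same-group" if labels[p.sample_a] == labels[p.sample_b]
               else "different-group")
        p.relation = rel
        strata[rel].append(p)
    out: Dict[str, Dict[str, object]] = {}
    for rel, members in strata.items():
        defined = [p for p in members if p.pi is not None]
        above = sum(1 for p in defined if p.pi > threshold)
        out[rel] = {
            "n_pairs": len(members),
            "n_defined": len(defined),
            "n_above": above,
            "fraction_above": above / len(defined) if defined else None,
        }
    return out
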