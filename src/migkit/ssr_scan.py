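"""Microsatellite (SSR) scanning restricted to short di-/tri-nucleotide motifs.

The scanner reports maximal, non-overlapping perfect tandem runs, resolved
greedily left to right (longer run wins ties at the same start).  Motifs are
canonicalized under cyclic rotation and, optionally, reverse complement, so
that e.g. GT, TG, AC and CA all collapse into a single class.  The four motif
classes targeted by the first-PCR primers (ACT, TTG, GTG, GT) are reported
under those representative spellings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Printed representatives for the targeted classes, keyed by canonical form.
TARGET_MOTIFS = ("ACT", "TTG", "GTG", "GT")

DEFAULT_MIN_REPEATS: Dict[int, int] = {2: 7, 3: 5}


def _rotations(motif: str) -> List[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def canonical_motif(motif: str, strand_collapse: bool = True) -> str:
    """Canonical form: lexicographic minimum over rotations (and the reverse
    complement's rotations when ``strand_collapse``)."""
    forms = _rotations(motif)
    if strand_collapse:
        forms += _rotations(reverse_complement(motif))
    return min(forms)


def _representative_table(strand_collapse: bool) -> Dict[str, str]:
    table: Dict[str, str] = {}
    for rep in TARGET_MOTIFS:
        table[canonical_motif(rep, strand_collapse)] = rep
    return table


def motif_class(motif: str, strand_collapse: bool = True) -> str:
    """Class label for a motif: the targeted representative when the motif
    belongs to a targeted class, otherwise the canonical form itself."""
    canon = canonical_motif(motif, strand_collapse)
    return _representative_table(strand_collapse).get(canon, canon)


def _has_smaller_period(motif: str) -> bool:
    k = len(motif)
    for p in range(1, k):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return True
    return False


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat: 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    motif_class: str
    repeat_count: int
    motif: str = ""
    strand_collapsed: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start != self.repeat_count * len(
            self.motif or self.motif_class
        ):
            raise ValueError("interval length inconsistent with repeat count")

    @property
    def motif_length(self) -> int:
        return len(self.motif or self.motif_class)


def _acgt_segments(seq: str) -> Iterable[Tuple[int, str]]:
    """Yield (offset, subsequence) chunks free of non-ACGT characters."""
    start = None
    for i, c in enumerate(seq):
        if c in "ACGT":
            if start is None:
                start = i
        else:
            if start is not None:
                yield start, seq[start:i]
                start = None
    if start is not None:
        yield start, seq[start:]


def find_tandem_runs(
    seq: str, k: int, min_repeats: int
) -> List[Tuple[int, int, str]]:
    """Maximal left-anchored tandem runs of unit length ``k`` with at least
    ``min_repeats`` copies.  Returns (start, end, motif) with end - start a
    multiple of ``k``.  Units that are themselves periodic (homopolymers for
    k=2,3) are excluded; non-ACGT characters break runs.
    """
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    out: List[Tuple[int, int, str]] = []
    for offset, chunk in _acgt_segments(seq):
        n = len(chunk)
        if n < k * min_repeats:
            continue
        a = np.frombuffer(chunk.encode("ascii"), dtype=np.uint8)
        match = a[k:] == a[:-k]
        # boundaries of maximal True stretches in `match`
        padded = np.concatenate(([False], match, [False]))
        diffs = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diffs == 1)
        ends = np.flatnonzero(diffs == -1)  # exclusive, in `match` coordinates
        for s, e in zip(starts, ends):
            span = (e - s) + k  # tandem array length in bases
            rc = span // k
            if rc < min_repeats:
                continue
            motif = chunk[s : s + k]
            if _has_smaller_period(motif):
                continue
            out.append((offset + s, offset + s + rc * k, motif))
    return out


def resolve_overlaps(
    candidates: Sequence[Tuple[int, int, str]]
) -> List[Tuple[int, int, str]]:
    """Greedy left-to-right: sort by (start, -length, unit length) and accept
    each run that does not overlap an already accepted one."""
    ordered = sorted(candidates, key=lambda c: (c[0], c[0] - c[1], len(c[2])))
    accepted: List[Tuple[int, int, str]] = []
    last_end = -1
    for c in ordered:
        if c[0] >= last_end:
            accepted.append(c)
            last_end = c[1]
    return accepted


def scan_ssrs(
    sequences: Mapping[str, str],
    min_repeats: Mapping[int, int] | None = None,
    strand_collapse: bool = True,
) -> List[SSRLocus]:
    """Scan FASTA-style sequences for SSR loci of di- and tri-nucleotide motifs.

    Parameters
    ----------
    sequences
        Mapping chromosome name -> nucleotide string (case-insensitive).
    min_repeats
        Mapping motif length -> minimum repeat count (default di>=7, tri>=5).
    strand_collapse
        Collapse reverse-complement motifs into one class.

    Returns
    -------
    Loci sorted by (chromosome, start); intervals never overlap.
    """
    if not sequences:
        raise ValueError("empty FASTA: no sequences to scan")
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    if any(v < 2 for v in min_repeats.values()):
        raise ValueError("minimum repeat counts must be >= 2")
    loci: List[SSRLocus] = []
    for chrom in sorted(sequences):
        seq = sequences[chrom].upper()
        candidates: List[Tuple[int, int, str]] = []
        for k, mr in min_repeats.items():
            candidates.extend(find_tandem_runs(seq, k, mr))
        for start, end, motif in resolve_overlaps(candidates):
            loci.append(
                SSRLocus(
                    chrom=chrom,
                    start=start,
                    end=end,
                    motif_class=motif_class(motif, strand_collapse),
                    repeat_count=(end - start) // len(motif),
                    motif=motif,
                    strand_collapsed=strand_collapse,
                )
            )
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


def count_targeted_ssrs(
    loci: Iterable[SSRLocus],
    targets: Sequence[str] = TARGET_MOTIFS,
    strand_collapse: bool = True,
) -> Tuple[Dict[str, int], int]:
    """Per-class counts over the targeted motif classes, plus their total."""
    wanted = {motif_class(t, strand_collapse): 0 for t in targets}
    for locus in loci:
        if locus.motif_class in wanted:
            wanted[locus.motif_class] += 1
    return wanted, sum(wanted.values())


def correlate_metrics(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)
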