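"""Synthetic-data generation with known truth tables.

Everything the analysis stages consume can be generated here: genomes seeded
with SSR loci of the four targeted motif classes, panels of inbred accessions
diverged at a requested pairwise nucleotide diversity, F2 / RIL crosses with
interference-free meiosis, additive phenotypes, and MIG-seq style coverage
with strong per-locus overdispersion (lognormal locus weights + Poisson
sampling) and depth-dependent missingness.

Every operation takes an explicit seed; derived randomness is a deterministic
function of (seed, sample index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .depth_profile import PerBaseDepth
from .genotype_qc import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from .ssr_scan import SSRLocus, find_tandem_runs, motif_class

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_MOTIF_WEIGHTS = {"ACT": 1.0, "TTG": 1.0, "GTG": 1.0, "GT": 1.0}

Variant = Tuple[str, int, str, str]  # chrom, 1-based pos, ref, alt


@dataclass
class GenomeTruth:
    sequences: Dict[str, str]
    ssr_loci: List[SSRLocus]

    @property
    def length_bp(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


@dataclass
class PanelTruth:
    variants: Dict[str, List[Variant]]
    target_pi: float

    @property
    def accessions(self) -> List[str]:
        return list(self.variants)


@dataclass
class CrossTruth:
    """Progeny genotypes coded 0/1/2 = AA/AB/BB (A = first parent's allele)."""

    design: str  # "F2" or "RIL"
    generation: int
    genotypes: np.ndarray  # (n_markers, n_progeny) int8
    marker_chrom: np.ndarray
    marker_pos: np.ndarray  # 1-based
    marker_ref: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    cM_per_Mb: float
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_progeny(self) -> int:
        return self.genotypes.shape[1]

    @property
    def progeny(self) -> List[str]:
        return [f"{self.design}_{i + 1:03d}" for i in range(self.n_progeny)]

    def marker_index(self, chrom: str, pos: int) -> int:
        hits = np.flatnonzero((self.marker_chrom == chrom) & (self.marker_pos == pos))
        if len(hits) == 0:
            raise KeyError(f"unknown marker {chrom}:{pos}")
        return int(hits[0])


@dataclass
class CoverageModel:
    mean_depth: float = 20.0
    overdispersion: float = 1.0  # log-scale sd of per-locus amplification weight
    insert_range: Tuple[int, int] = (350, 800)
    read_length: int = 150
    base_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.mean_depth, self.overdispersion, self.base_error_rate) < 0:
            raise ValueError("coverage parameters must be >= 0")
        if self.insert_range[0] > self.insert_range[1]:
            raise ValueError("insert_range min must be <= max")


def _sanitize_background(seq: np.ndarray, rng: np.random.Generator,
                         min_repeats: Mapping[int, int]) -> None:
    """Break any background tandem run reaching the scanner thresholds so the
    placed loci are the only ones a default scan finds (in place)."""
    for _ in range(20):
        text = seq.tobytes().decode("ascii")
        runs = []
        for k, mr in min_repeats.items():
            runs.extend(find_tandem_runs(text, k, mr))
        if not runs:
            return
        for start, end, mot in runs:
            mid = (start + end) // 2
            old = seq[mid]
            choices = BASES[BASES != old]
            seq[mid] = rng.choice(choices)
    raise RuntimeError("failed to sanitize background sequence")


def simulate_genome(
    length_bp: int,
    n_chromosomes: int = 1,
    ssr_density: float = 50.0,
    motif_weights: Optional[Mapping[str, float]] = None,
    repeat_range: Tuple[int, int] = (7, 15),
    seed: int = 0,
    min_repeats: Optional[Mapping[int, int]] = None,
) -> GenomeTruth:
    """Random genome with SSR loci placed uniformly without overlap.

    ``ssr_density`` is loci per Mb; the realized count is Poisson.  Background
    sequence is i.i.d. uniform ACGT, scrubbed of incidental runs that would
    reach the default scanner thresholds, and locus flanks are fixed so each
    placed run is maximal.
    """
    if length_bp < 10_000:
        raise ValueError("length_bp must be >= 10,000")
    if ssr_density < 0:
        raise ValueError("ssr_density must be >= 0")
    weights = dict(motif_weights or DEFAULT_MOTIF_WEIGHTS)
    if sum(weights.values()) <= 0:
        raise ValueError("motif weights must sum > 0")
    if min_repeats is None:
        min_repeats = {2: 7, 3: 5}
    rng = np.random.default_rng(seed)

    base_len = length_bp // n_chromosomes
    lengths = [base_len] * n_chromosomes
    lengths[-1] += length_bp - base_len * n_chromosomes
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]

    motifs = list(weights)
    probs = np.array([weights[m] for m in motifs], dtype=float)
    probs /= probs.sum()

    n_loci = rng.poisson(ssr_density * length_bp / 1e6)
    chrom_probs = np.array(lengths, dtype=float) / length_bp

    sequences: Dict[str, np.ndarray] = {}
    for name, L in zip(names, lengths):
        arr = BASES[rng.integers(0, 4, size=L)]
        _sanitize_background(arr, rng, min_repeats)
        sequences[name] = arr

    placed: Dict[str, List[Tuple[int, int]]] = {name: [] for name in names}
    loci: List[SSRLocus] = []
    attempts = 0
    max_attempts = 200 * max(n_loci, 1)
    placed_count = 0
    while placed_count < n_loci:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "cannot place SSR loci: density too high for genome length"
            )
        motif = motifs[rng.choice(len(motifs), p=probs)]
        rc = int(rng.integers(repeat_range[0], repeat_range[1] + 1))
        span = rc * len(motif)
        ci = rng.choice(n_chromosomes, p=chrom_probs)
        name, L = names[ci], lengths[ci]
        if L < span + 8:
            continue
        start = int(rng.integers(4, L - span - 4))
        # 4 bp margin prevents merging with neighbours
        if any(start - 4 < e and s < start + span + 4 for s, e in placed[name]):
            continue
        seq = sequences[name]
        unit = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
        seq[start : start + span] = np.tile(unit, rc)
        # flanks must not extend the tandem array
        left_bad, right_bad = unit[-1], unit[0]
        if seq[start - 1] == left_bad:
            seq[start - 1] = rng.choice(BASES[BASES != left_bad])
        if seq[start + span] == right_bad:
            seq[start + span] = rng.choice(BASES[BASES != right_bad])
        placed[name].append((start, start + span))
        loci.append(
            SSRLocus(chrom=name, start=start, end=start + span,
                     motif_class=motif_class(motif), repeat_count=rc, motif=motif)
        )
        placed_count += 1

    loci.sort(key=lambda l: (l.chrom, l.start))
    return GenomeTruth(
        sequences={n: s.tobytes().decode("ascii") for n, s in sequences.items()},
        ssr_loci=loci,
    )


def simulate_panel(
    genome: GenomeTruth, n_accessions: int, pi: float, seed: int = 0
) -> PanelTruth:
    """Inbred accessions diverged by independent infinite-sites mutations.

    Each lineage receives Poisson(pi/2 * L) mutations at uniform positions, so
    the expected pairwise difference density is ``pi``.
    """
    if not 0.0 <= pi <= 0.05:
        raise ValueError("pi must be in [0, 0.05]")
    if n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    L = genome.length_bp
    chroms = list(genome.sequences)
    lengths = np.array([len(genome.sequences[c]) for c in chroms])
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    variants: Dict[str, List[Variant]] = {}
    for i in range(n_accessions):
        rng = np.random.default_rng((seed, i))
        n_mut = rng.poisson(pi / 2.0 * L)
        n_mut = min(n_mut, L)
        flat = rng.choice(L, size=n_mut, replace=False)
        acc_variants: List[Variant] = []
        for f in np.sort(flat):
            ci = int(np.searchsorted(offsets, f, side="right") - 1)
            pos0 = int(f - offsets[ci])
            ref = genome.sequences[chroms[ci]][pos0]
            alt_choices = [b for b in "ACGT" if b != ref]
            alt = alt_choices[int(rng.integers(3))]
            acc_variants.append((chroms[ci], pos0 + 1, ref, alt))
        variants[f"acc{i + 1:03d}"] = acc_variants
    return PanelTruth(variants=variants, target_pi=pi)


def _alleles_at(variants: Sequence[Variant]) -> Dict[Tuple[str, int], Tuple[str, str]]:
    return {(c, p): (r, a) for c, p, r, a in variants}


def _gametes(haplo_pair: Tuple[np.ndarray, np.ndarray], marker_pos: np.ndarray,
             morgans: float, rng: np.random.Generator) -> np.ndarray:
    """One meiotic product for a single chromosome: Poisson crossovers, no
    interference; returns the allele carried at each marker."""
    h0, h1 = haplo_pair
    n_xo = rng.poisson(morgans)
    phase0 = int(rng.integers(2))
    if n_xo == 0:
        return (h0 if phase0 == 0 else h1).copy()
    L = marker_pos[-1] if len(marker_pos) else 1
    xo = np.sort(rng.uniform(0, max(L, 1), size=n_xo))
    phase = (phase0 + np.searchsorted(xo, marker_pos)) % 2
    return np.where(phase == 0, h0, h1)


def simulate_cross(
    parent_a: Sequence[Variant],
    parent_b: Sequence[Variant],
    design: str = "F2",
    n_progeny: int = 100,
    cM_per_Mb: float = 2.0,
    seed: int = 0,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    generation: int = 6,
) -> CrossTruth:
    """Cross two inbred parents: F2 (two F1 gametes) or RIL by single-seed
    descent selfing to ``generation`` (F1 is generation 1)."""
    if design not in ("F2", "RIL"):
        raise ValueError("design must be 'F2' or 'RIL'")
    alle_a = _alleles_at(parent_a)
    alle_b = _alleles_at(parent_b)
    keys = sorted(set(alle_a) | set(alle_b))
    markers: List[Tuple[str, int, str, str, str]] = []  # chrom,pos,ref,aA,aB
    for key in keys:
        ref_a, a = alle_a.get(key, (None, None))
        ref_b, b = alle_b.get(key, (None, None))
        ref = ref_a or ref_b
        allele_a_base = a if a is not None else ref
        allele_b_base = b if b is not None else ref
        if allele_a_base == allele_b_base:
            continue
        if allele_a_base != ref and allele_b_base != ref:
            continue  # tri-allelic collision: skipped to stay biallelic
        markers.append((key[0], key[1], ref, allele_a_base, allele_b_base))
    if not markers:
        raise ValueError("no segregating markers: parents are identical")

    chrom_of = np.array([m[0] for m in markers], dtype=object)
    pos_of = np.array([m[1] for m in markers], dtype=np.int64)
    by_chrom: Dict[str, np.ndarray] = {
        c: np.flatnonzero(chrom_of == c) for c in dict.fromkeys(chrom_of.tolist())
    }
    lengths = dict(chrom_lengths or {})
    for c, idx in by_chrom.items():
        lengths.setdefault(c, int(pos_of[idx].max()))

    n_markers = len(markers)
    geno = np.empty((n_markers, n_progeny), dtype=np.int8)
    for j in range(n_progeny):
        rng = np.random.default_rng((seed, j))
        for c, idx in by_chrom.items():
            mpos = pos_of[idx].astype(float)
            morgans = cM_per_Mb * lengths[c] / 1e6 / 100.0
            h0 = np.zeros(len(idx), dtype=np.int8)
            h1 = np.ones(len(idx), dtype=np.int8)
            if design == "F2":
                g1 = _gametes((h0, h1), mpos, morgans, rng)
                g2 = _gametes((h0, h1), mpos, morgans, rng)
            else:
                ha, hb = h0, h1
                for _ in range(generation - 1):
                    ha2 = _gametes((ha, hb), mpos, morgans, rng)
                    hb2 = _gametes((ha, hb), mpos, morgans, rng)
                    ha, hb = ha2, hb2
                g1, g2 = ha, hb
            geno[idx, j] = g1 + g2

    return CrossTruth(
        design=design,
        generation=2 if design == "F2" else generation,
        genotypes=geno,
        marker_chrom=chrom_of,
        marker_pos=pos_of,
        marker_ref=np.array([m[2] for m in markers], dtype=object),
        allele_a=np.array([m[3] for m in markers], dtype=object),
        allele_b=np.array([m[4] for m in markers], dtype=object),
        cM_per_Mb=cM_per_Mb,
        chrom_lengths=lengths,
    )


def _amplicons(
    genome: GenomeTruth, model: CoverageModel, rng: np.random.Generator
) -> List[Tuple[str, int, int]]:
    """Candidate ISSR amplicons, one nucleated at each SSR locus.

    When two SSR loci sit within the insert window the amplicon spans them;
    otherwise the insert size is drawn uniformly from the model's range and
    the amplicon extends downstream of the anchoring locus (clipped at the
    chromosome end).  This keeps one amplifiable locus per SSR without
    requiring unrealistically dense SSR placement."""
    out: List[Tuple[str, int, int]] = []
    loci = sorted(genome.ssr_loci, key=lambda l: (l.chrom, l.start))
    lengths = genome.chrom_lengths
    for i, a in enumerate(loci):
        nxt = loci[i + 1] if i + 1 < len(loci) else None
        if (nxt is not None and nxt.chrom == a.chrom
                and model.insert_range[0] <= nxt.end - a.start <= model.insert_range[1]):
            out.append((a.chrom, a.start, nxt.end))
            continue
        insert = int(rng.integers(model.insert_range[0], model.insert_range[1] + 1))
        end = min(a.start + insert, lengths[a.chrom])
        out.append((a.chrom, a.start, end))
    return out


def _covered_slices(start: int, end: int, read_length: int) -> List[Tuple[int, int]]:
    span = end - start
    if span <= 2 * read_length:
        return [(start, end)]
    return [(start, start + read_length), (end - read_length, end)]


def _truth_sites_and_genotypes(
    samples: Union[PanelTruth, CrossTruth]
) -> Tuple[List[Tuple[str, int, str, str]], List[str], np.ndarray]:
    """Site list (chrom,pos,ref,alt), sample names, truth genotype codes."""
    if isinstance(samples, PanelTruth):
        names = samples.accessions
        allele_maps = [_alleles_at(samples.variants[n]) for n in names]
        site_alts: Dict[Tuple[str, int], Tuple[str, str]] = {}
        conflicted = set()
        for amap in allele_maps:
            for key, (ref, alt) in amap.items():
                if key in site_alts and site_alts[key][1] != alt:
                    conflicted.add(key)
                site_alts.setdefault(key, (ref, alt))
        for key in conflicted:  # multi-allelic collisions are dropped
            site_alts.pop(key, None)
        keys = sorted(site_alts)
        sites = [(c, p, site_alts[(c, p)][0], site_alts[(c, p)][1]) for c, p in keys]
        gt = np.full((len(sites), len(names)), HOM_REF, dtype=np.int8)
        for j, amap in enumerate(allele_maps):
            for i, (c, p, _, _) in enumerate(sites):
                if (c, p) in amap:
                    gt[i, j] = HOM_ALT
        return sites, names, gt
    if isinstance(samples, CrossTruth):
        names = samples.progeny
        sites = []
        gt = np.empty((samples.n_markers, samples.n_progeny), dtype=np.int8)
        for i in range(samples.n_markers):
            ref = samples.marker_ref[i]
            a, b = samples.allele_a[i], samples.allele_b[i]
            alt = a if a != ref else b
            sites.append((samples.marker_chrom[i], int(samples.marker_pos[i]), ref, alt))
            code_a = HOM_REF if a == ref else HOM_ALT
            code_b = HOM_REF if b == ref else HOM_ALT
            row = samples.genotypes[i]
            gt[i] = np.where(row == 0, code_a, np.where(row == 2, code_b, HET))
        return sites, names, gt
    raise TypeError("samples must be PanelTruth or CrossTruth")


def simulate_migseq_depths(
    genome: GenomeTruth,
    samples: Union[PanelTruth, CrossTruth],
    model: CoverageModel,
    n_read_pairs: int,
    seed: int = 0,
) -> Tuple[Dict[str, PerBaseDepth], GenotypeMatrix]:
    """MIG-seq style coverage: per-amplicon lognormal weights shared across
    samples, Poisson read counts per (sample, amplicon), read pairs covering
    ``read_length`` bases from each amplicon end.

    Returns per-sample dense depth tables and a GenotypeMatrix whose DP/AD
    reflect the simulated coverage (cells with zero depth are missing).
    """
    if n_read_pairs <= 0:
        raise ValueError("n_read_pairs must be > 0")
    rng = np.random.default_rng(seed)
    amps = _amplicons(genome, model, rng)
    if not amps:
        raise ValueError("no amplifiable loci: genome carries no SSR loci")
    logw = rng.normal(0.0, model.overdispersion, size=len(amps))
    weights = np.exp(logw)
    weights /= weights.sum()

    sites, names, truth_gt = _truth_sites_and_genotypes(samples)
    chrom_lengths = genome.chrom_lengths

    depth_tables: Dict[str, PerBaseDepth] = {}
    n_sites = len(sites)
    dp = np.zeros((n_sites, len(names)), dtype=np.int32)
    site_index: Dict[Tuple[str, int], int] = {
        (c, p): i for i, (c, p, _, _) in enumerate(sites)
    }

    for j, name in enumerate(names):
        srng = np.random.default_rng((seed, 1, j))
        arrays = {c: np.zeros(L, dtype=np.int64) for c, L in chrom_lengths.items()}
        counts = srng.poisson(n_read_pairs * weights)
        for (chrom, a_start, a_end), c in zip(amps, counts):
            if c == 0:
                continue
            for s, e in _covered_slices(a_start, a_end, model.read_length):
                arrays[chrom][s:e] += c
        depth_tables[name] = PerBaseDepth(sample=name, depths=arrays)
        for (c, p), i in site_index.items():
            dp[i, j] = arrays[c][p - 1]

    gt = np.where(dp > 0, truth_gt, MISSING).astype(np.int8)
    ad = np.zeros((n_sites, len(names), 2), dtype=np.int32)
    erng = np.random.default_rng((seed, 2))
    for i in range(n_sites):
        for j in range(len(names)):
            d = int(dp[i, j])
            if d == 0:
                continue
            g = truth_gt[i, j]
            if g == HET:
                a_ref = int(erng.binomial(d, 0.5))
            elif g == HOM_REF:
                a_ref = d
            else:
                a_ref = 0
            if model.base_error_rate > 0:
                flips_to_alt = int(erng.binomial(a_ref, model.base_error_rate))
                flips_to_ref = int(erng.binomial(d - a_ref, model.base_error_rate))
                a_ref = a_ref - flips_to_alt + flips_to_ref
            ad[i, j] = (a_ref, d - a_ref)

    matrix = GenotypeMatrix(
        chrom=np.array([s[0] for s in sites], dtype=object),
        pos=np.array([s[1] for s in sites], dtype=np.int64),
        ref=np.array([s[2] for s in sites], dtype=object),
        alt=np.array([s[3] for s in sites], dtype=object),
        qual=np.full(n_sites, 60.0),
        samples=names,
        gt=gt,
        dp=dp,
        ad=ad,
    )
    return depth_tables, matrix


def simulate_phenotype(
    cross: CrossTruth,
    qtl_spec: Sequence[Tuple[Tuple[str, int], float]],
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline: float = 100.0,
) -> np.ndarray:
    """Additive phenotype: baseline + sum of effect * coded genotype + noise.

    Genotypes are coded -1/0/+1 for AA/AB/BB, so a positive effect means the
    second parent's allele raises the phenotype by ``effect`` per allele copy
    relative to the midpoint (hom classes differ by 2 * effect).
    """
    rng = np.random.default_rng(seed)
    y = np.full(cross.n_progeny, baseline, dtype=float)
    for (chrom, pos), effect in qtl_spec:
        idx = cross.marker_index(chrom, pos)  # raises KeyError if unknown
        coded = cross.genotypes[idx].astype(float) - 1.0
        y += effect * coded
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=cross.n_progeny)
    return y
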