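import itertools
import re

import numpy as np
import pytest

from migkit import simulate as sim
from migkit.ssr_scan import motif_class


@pytest.fixture(scope="session")
def small_genome():
    return sim.simulate_genome(100_000, n_chromosomes=2, ssr_density=150,
                               seed=11)


@pytest.fixture(scope="session")
def panel(small_genome):
    return sim.simulate_panel(small_genome, n_accessions=4, pi=0.0025, seed=12)


@pytest.fixture(scope="session")
def coverage(small_genome, panel):
    model = sim.CoverageModel(overdispersion=1.0)
    return sim.simulate_migseq_depths(small_genome, panel, model,
                                      n_read_pairs=40_000, seed=13)


@pytest.fixture(scope="session")
def ril_cross(panel, small_genome):
    names = panel.accessions
    return sim.simulate_cross(
        panel.variants[names[0]], panel.variants[names[1]],
        design="RIL", n_progeny=80, cM_per_Mb=3.0, seed=14,
        chrom_lengths=small_genome.chrom_lengths, generation=6,
    )


def _all_motifs(k):
    """Non-degenerate k-mers (no period smaller than k)."""
    out = []
    for combo in itertools.product("ACGT", repeat=k):
        motif = "".join(combo)
        if any(motif == motif[:p] * (k // p) for p in range(1, k) if k % p == 0):
            continue
        out.append(motif)
    return out


def regex_ssr_oracle(seq, min_repeats=None, strand_collapse=True):
    """Brute-force SSR finder: per-motif regex matches, restricted to
    left-maximal tandem arrays, then the documented greedy left-to-right
    resolution (longer run wins ties, shorter unit breaks exact ties).

    Returns a set of (start, end, class) tuples.
    """
    if min_repeats is None:
        min_repeats = {2: 7, 3: 5}
    seq = seq.upper()
    candidates = []
    for k, mr in min_repeats.items():
        for motif in _all_motifs(k):
            for m in re.finditer(f"(?:{motif}){{{mr},}}", seq):
                s = m.start()
                # skip phase-shifted sub-runs: array must be left-maximal
                if s >= 1 and seq[s - 1] == seq[s - 1 + k] and seq[s - 1] in "ACGT":
                    continue
                candidates.append((s, m.end(), motif))
    accepted = []
    last_end = -1
    for s, e, motif in sorted(candidates, key=lambda c: (c[0], c[0] - c[1],
                                                         len(c[2]))):
        if s >= last_end:
            accepted.append((s, e, motif_class(motif, strand_collapse)))
            last_end = e
    return set(accepted)


def random_repeat_rich_sequence(rng, length, n_implants=20):
    """Uniform random sequence with implanted tandem repeats of random
    di/tri motifs (some below, some above the scanner thresholds)."""
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length))
    for _ in range(n_implants):
        k = int(rng.integers(2, 4))
        motif = "".join(rng.choice(bases, size=k))
        reps = int(rng.integers(3, 15))
        start = int(rng.integers(0, length - reps * k))
        seq[start : start + reps * k] = list(motif * reps)
    return "".join(seq)
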