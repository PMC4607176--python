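"""Overlapping motif counting and composition-matched Monte-Carlo enrichment.

The enrichment test mirrors a simple and transparent protocol: count every
(overlapping) occurrence of a short motif in a region, simulate iid random
sequences of the same length and G+C fraction, count the motif in each, and
compare observed vs null counts with an exact Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .seq import NucleotideSequence, composition, reverse_complement

MOTIF = "TATAATATA"  # the default 9-mer; not its own reverse complement


@dataclass(frozen=True)
class MotifHit:
    position: int  # 1-based start on the forward sequence
    strand: str
    text: str


@dataclass(frozen=True)
class NullModelConfig:
    length: int
    gc_fraction: float
    n_samples: int = 25
    seed: int = 0
    motif: str = MOTIF

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0 <= self.gc_fraction <= 1):
            raise ValueError("gc_fraction must be in [0,1]")
        if self.length < len(self.motif):
            raise ValueError("length must be >= motif length")


@dataclass
class EnrichmentResult:
    observed_count: int
    null_counts: List[int]
    null_mean: float
    fold_enrichment: float  # math.inf when null_mean == 0 and observed > 0
    p_value: Optional[float]  # None when the test is undefined (all ties)
    test: str = "wilcoxon-signed-rank-exact"
    region_id: str = ""
    region_length: int = 0
    at_fraction: float = float("nan")
    n_samples: int = 0
    seed: int = 0


def _expand_hamming1(motif: str) -> List[str]:
    out = {motif}
    for i, c in enumerate(motif):
        for b in "ACGT":
            if b != c:
                out.add(motif[:i] + b + motif[i + 1:])
    return sorted(out)


def count_motif(seq, motif: str = MOTIF, strand_mode: str = "forward",
                hamming1: bool = False) -> Tuple[int, List[MotifHit]]:
    """Count all overlapping motif occurrences.

    Every start position is tested, so occurrences may overlap. With
    ``strand_mode="both"`` the reverse complement of the motif is also
    scanned on the given strand (identical spans deduplicated). N in the
    sequence never matches. ``hamming1`` additionally accepts motif variants
    one substitution away.
    """
    if not motif or set(motif) - set("ACGT"):
        raise ValueError("motif must be non-empty over A/C/G/T")
    if strand_mode not in ("forward", "both"):
        raise ValueError("strand_mode must be 'forward' or 'both'")
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq
    motifs = _expand_hamming1(motif) if hamming1 else [motif]
    k = len(motif)
    hits = {}
    for m, strand in [(m, "+") for m in motifs]:
        start = 0
        while True:
            i = s.find(m, start)
            if i < 0:
                break
            hits[(i + 1, i + k)] = MotifHit(i + 1, "+", m)
            start = i + 1
    if strand_mode == "both":
        rc_motifs = [reverse_complement(m) for m in motifs]
        for m in rc_motifs:
            start = 0
            while True:
                i = s.find(m, start)
                if i < 0:
                    break
                hits.setdefault((i + 1, i + k), MotifHit(i + 1, "-", m))
                start = i + 1
    ordered = [hits[k_] for k_ in sorted(hits)]
    return len(ordered), ordered


def generate_random_sequence(length: int, gc_fraction: float,
                             seed: int) -> NucleotideSequence:
    """IID random DNA with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 <= gc_fraction <= 1):
        raise ValueError("gc_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length,
                       p=[p_at, p_gc, p_gc, p_at])
    return NucleotideSequence(f"random_L{length}_gc{gc_fraction:g}_s{seed}",
                              "".join(bases))


def expected_motif_count(length: int, gc_fraction: float,
                         motif: str = MOTIF) -> float:
    """Analytic expected overlapping count under the iid model.

    (L - |m| + 1) * prod over motif positions of the per-base probability.
    """
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over A/C/G/T")
    k = len(motif)
    if length < k:
        return 0.0
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    p = 1.0
    for c in motif:
        p *= p_at if c in "AT" else p_gc
    return (length - k + 1) * p


def sample_null_counts(config: NullModelConfig) -> List[int]:
    """Motif counts in ``n_samples`` composition-matched random sequences."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_samples)
    out = []
    for s in seeds:
        seq = generate_random_sequence(config.length, config.gc_fraction, int(s))
        out.append(count_motif(seq, config.motif, "forward")[0])
    return out


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float,
                         alternative: str) -> float:
    """Exact signed-rank p by DP over the distribution of W+.

    Ranks may be midranks (half-integers); everything is doubled to work on
    an integer lattice. Equivalent to enumerating all 2^n sign vectors.
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    # counts[w] = number of sign vectors with doubled W+ == w
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    n = len(r2)
    denom = 1 << n
    w2 = int(round(w_plus * 2))
    p_ge = int(np.sum(counts[w2:])) / denom
    p_le = int(np.sum(counts[:w2 + 1])) / denom
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def wilcoxon_signed_rank(observed: float, null_counts: List[float],
                         alternative: str = "two-sided",
                         exact_max_n: int = 25) -> Optional[float]:
    """Wilcoxon signed-rank p for observed vs each null count.

    Zero differences are dropped before ranking; ties get midranks. The p is
    exact (full signed-rank distribution) for n <= ``exact_max_n`` and a
    normal approximation with continuity and tie corrections above that.
    Returns None (undefined) when every difference is zero.
    """
    diffs = np.asarray([observed - x for x in null_counts], dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        return None
    if n < 5:
        # exact p still computable, but warn-level minimum pairs not met;
        # we compute anyway (smallest attainable two-sided p is 2/2^n)
        pass
    absd = np.abs(diffs)
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_plus = float(np.sum(ranks[diffs > 0]))
    if n <= exact_max_n:
        return _signed_rank_exact_p(ranks, w_plus, alternative)
    # normal approximation with continuity correction and tie correction
    mean = n * (n + 1) / 4.0
    tie_term = 0.0
    _, tie_counts = np.unique(sorted_abs, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    from scipy.stats import norm
    z_num = w_plus - mean
    cc = 0.5 * np.sign(z_num) if z_num != 0 else 0.0
    z = (z_num - cc) / math.sqrt(var)
    if alternative == "greater":
        return float(norm.sf(z))
    if alternative == "less":
        return float(norm.cdf(z))
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def enrichment_test(region_seq: NucleotideSequence, motif: str = MOTIF,
                    n_samples: int = 25, seed: int = 0,
                    alternative: str = "two-sided") -> EnrichmentResult:
    """Monte-Carlo motif enrichment against a composition-matched iid null.

    The null model uses the region's own length and measured G+C fraction
    (rounded to 0.1%), so the test self-adapts to the region analysed.
    """
    if region_seq.length < len(motif):
        raise ValueError("region shorter than motif")
    comp = composition(region_seq)
    gc = round(comp.gc_fraction, 3)
    observed, _ = count_motif(region_seq, motif, "forward")
    cfg = NullModelConfig(length=region_seq.length, gc_fraction=gc,
                          n_samples=n_samples, seed=seed, motif=motif)
    nulls = sample_null_counts(cfg)
    null_mean = float(np.mean(nulls))
    if null_mean == 0:
        fold = math.inf if observed > 0 else 0.0
    else:
        fold = observed / null_mean
    p = wilcoxon_signed_rank(observed, nulls, alternative=alternative)
    return EnrichmentResult(
        observed_count=observed, null_counts=nulls, null_mean=null_mean,
        fold_enrichment=fold, p_value=p, region_id=region_seq.id,
        region_length=region_seq.length, at_fraction=comp.at_fraction,
        n_samples=n_samples, seed=seed)


def copy_number_ratio(count_a: int, count_b: int) -> Optional[float]:
    """Cross-species copy-number ratio, reported to 1 decimal; None if b == 0."""
    if count_b == 0:
        return None
    return round(count_a / count_b, 1)
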