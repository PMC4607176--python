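"""Inverted-repeat (PATRR-like) stem-loop detection and structural features.

A hairpin is modelled as a two-arm inverted repeat: a local alignment of the
sequence against its own reverse complement. Aligned complementary columns
become base pairs; mismatch and gap columns become internal loops or bulges.
This captures the long A:T-paired stems that palindromic A+T-rich repeats
(PATRRs) form, without running a full minimum-free-energy folder; branched
"mini stem loops" protruding from the main stem are represented as internal
loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .enrichment import count_motif, MOTIF
from .seq import GenomicRegion, NucleotideSequence, reverse_complement
from .thermo import DEFAULT_PARAMS, ThermoParams

_PAIRED = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass
class StemLoop:
    """A two-arm hairpin on one sequence; coordinates 1-based inclusive.

    ``pairs`` lists (left_pos, right_pos) base pairs ordered from the apex
    outward; every pair is complementary and the list is strictly nested.
    ``internal_loops`` holds (left_span_nt, right_span_nt) between
    consecutive pairs, also ordered from the apex outward.
    """

    left_arm: GenomicRegion
    right_arm: GenomicRegion
    apex_loop: Optional[GenomicRegion]
    pairs: List[Tuple[int, int]]
    internal_loops: List[Tuple[int, int]]
    score: float

    def validate(self) -> None:
        prev = None
        for l, r in self.pairs:  # apex outward: l decreasing, r increasing
            if l >= r:
                raise ValueError(f"pair ({l},{r}) not left-of-right")
            if prev is not None:
                pl, pr = prev
                if not (l < pl and r > pr):
                    raise ValueError("pairs not strictly nested")
            prev = (l, r)


@dataclass
class StemFeatures:
    n_bp: int
    n_gc_pairs: int
    gc_per_bp: float
    apex_loop_len: int
    at_frac_upper_third: float
    gc_frac_lower_two_thirds: float
    largest_internal_loop_nt: int
    delta_g: float
    motif_near_apex_5p: bool
    motif_near_apex_3p: bool
    param_set: str = DEFAULT_PARAMS.name


def _self_aligner(match: float, mismatch: float,
                  gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    alphabet = "ACGTNX"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a in "ACGT" and b in "ACGT":
                mat[a, b] = match if a == b else mismatch
            elif "X" in (a, b):
                mat[a, b] = -100.0  # masked positions from earlier hits
            else:
                mat[a, b] = mismatch  # N never pairs
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    # EMBOSS-style gap of length L costs open + L*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _pairs_from_alignment(aln, s: str, n: int, min_loop: int
                          ) -> List[Tuple[int, int]]:
    """Convert a local self-vs-revcomp alignment into nested 1-based pairs."""
    pairs = []
    for (qs, qe), (ts, te) in zip(aln.aligned[0], aln.aligned[1]):
        for off in range(qe - qs):
            i = int(qs) + off       # 0-based in s
            j = int(ts) + off       # 0-based in revcomp(s)
            jo = n - 1 - j          # 0-based original coordinate
            lo, hi = (i, jo) if i < jo else (jo, i)
            if hi - lo - 1 < min_loop:
                continue
            if (s[lo], s[hi]) not in _PAIRED:
                continue
            pairs.append((lo + 1, hi + 1))
    # order from apex outward (innermost first), enforce strict nesting
    pairs.sort(key=lambda p: (-p[0], p[1]))
    nested = []
    for l, r in pairs:
        if nested and not (l < nested[-1][0] and r > nested[-1][1]):
            continue
        nested.append((l, r))
    return nested


def _trim_pairs(pairs: List[Tuple[int, int]], match: float, mismatch: float,
                gap_open: float, gap_extend: float) -> List[Tuple[int, int]]:
    """Truncate the pair chain (apex outward) at its maximum cumulative score.

    Interruptions between consecutive pairs are charged as aligned mismatch
    columns when symmetric and as a gap (open + extend per column) plus
    mismatches otherwise, matching the aligner's own scoring.
    """
    if not pairs:
        return pairs
    best_score, best_idx = match, 0
    score = match
    for idx, ((l1, r1), (l2, r2)) in enumerate(zip(pairs, pairs[1:]), 1):
        left_span = l1 - l2 - 1
        right_span = r2 - r1 - 1
        if left_span or right_span:
            sym = min(left_span, right_span)
            asym = abs(left_span - right_span)
            score += mismatch * sym
            if asym:
                score -= gap_open + gap_extend * asym
        score += match
        if score > best_score:
            best_score, best_idx = score, idx
    return pairs[:best_idx + 1]


def find_stem_loops(seq: Union[str, NucleotideSequence],
                    min_stem_bp: int = 10, min_loop: int = 3,
                    max_loop: int = 1000,
                    match: float = 5.0, mismatch: float = -6.0,
                    gap_open: float = 15.0, gap_extend: float = 5.0,
                    max_results: int = 5) -> List[StemLoop]:
    """Detect PATRR-like stem loops as local self/reverse-complement alignments.

    Hits are found greedily: the best-scoring inverted repeat is extracted,
    its arms masked, and the search repeated up to ``max_results`` times.
    Hits whose apex loop falls outside [min_loop, max_loop] or whose stem has
    fewer than ``min_stem_bp`` pairs are discarded. Results are sorted by
    score (ties: leftmost, then longest stem).

    The default penalties are deliberately stiffer than generic DNA-vs-DNA
    alignment scoring: an A+T-biased sequence pairs with its own reverse
    complement at ~25-50% per position by chance, and permissive gap
    extension would let the alignment percolate indefinitely through
    unrelated flanks. After alignment each arm is trimmed back to the
    outward position of maximum cumulative score under the same scoring,
    which cuts residual chance extension.
    """
    if min_stem_bp < 5:
        raise ValueError("min_stem_bp must be >= 5")
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    seq_id = seq.id if isinstance(seq, NucleotideSequence) else "seq"
    s = seq.residues if isinstance(seq, NucleotideSequence) else str(seq).upper()
    n = len(s)
    if n < 2 * min_stem_bp + min_loop:
        return []
    aligner = _self_aligner(match, mismatch, gap_open, gap_extend)
    work = list(s)
    results: List[StemLoop] = []
    min_score = min_stem_bp * match
    for _ in range(max_results):
        cur = "".join(work)
        rc = reverse_complement(cur)
        score = aligner.score(cur, rc)
        if score < min_score:
            break
        aln = next(iter(aligner.align(cur, rc)))
        pairs = _pairs_from_alignment(aln, cur, n, min_loop)
        pairs = _trim_pairs(pairs, match, mismatch, gap_open, gap_extend)
        if not pairs:
            break
        stem = _build_stemloop(seq_id, pairs, float(score))
        # mask both arms (and apex) so the next pass finds a different stem
        for pos in range(stem.left_arm.start - 1, stem.right_arm.end):
            work[pos] = "X"
        if stem.apex_loop is None or not (
                min_loop <= stem.apex_loop.length() <= max_loop):
            continue
        if len(stem.pairs) < min_stem_bp:
            continue
        stem.validate()
        results.append(stem)
    results.sort(key=lambda st: (-st.score, st.left_arm.start,
                                 -len(st.pairs)))
    return results


def _build_stemloop(seq_id: str, pairs: List[Tuple[int, int]],
                    score: float) -> StemLoop:
    inner_l, inner_r = pairs[0]
    outer_l, outer_r = pairs[-1]
    apex = None
    if inner_r - inner_l - 1 > 0:
        apex = GenomicRegion(seq_id, inner_l + 1, inner_r - 1)
    loops = []
    for (l1, r1), (l2, r2) in zip(pairs, pairs[1:]):
        left_span = l1 - l2 - 1
        right_span = r2 - r1 - 1
        if left_span or right_span:
            loops.append((left_span, right_span))
    return StemLoop(
        left_arm=GenomicRegion(seq_id, outer_l, inner_l),
        right_arm=GenomicRegion(seq_id, inner_r, outer_r),
        apex_loop=apex,
        pairs=pairs,
        internal_loops=loops,
        score=score,
    )


def delta_g(stem: StemLoop, seq: Union[str, NucleotideSequence],
            params: ThermoParams = DEFAULT_PARAMS) -> float:
    """Nearest-neighbor free energy of a stem loop (kcal/mol, 37 °C).

    Sums stack energies over consecutive pairs with no intervening unpaired
    bases, adds the hairpin penalty for the apex loop (if any) and an
    internal-loop or bulge penalty for every interruption.
    """
    if len(stem.pairs) < 2:
        raise ValueError("delta_g needs a stem of >= 2 pairs")
    s = seq.residues if isinstance(seq, NucleotideSequence) else str(seq).upper()
    total = 0.0
    for (l1, r1), (l2, r2) in zip(stem.pairs, stem.pairs[1:]):
        if l2 == l1 - 1 and r2 == r1 + 1:
            # contiguous stack; top-strand dimer read 5'->3' is s[l2-1], s[l1-1]
            total += params.stack_dg(s[l2 - 1] + s[l1 - 1])
    if stem.apex_loop is not None:
        total += params.hairpin_penalty(stem.apex_loop.length())
    for left_span, right_span in stem.internal_loops:
        if left_span and right_span:
            total += params.internal_penalty(left_span + right_span)
        else:
            total += params.bulge_penalty(left_span + right_span)
    return total


def stem_features(stem: StemLoop, seq: Union[str, NucleotideSequence],
                  motif: str = MOTIF, apex_window: int = 50,
                  params: ThermoParams = DEFAULT_PARAMS) -> StemFeatures:
    """Compute the structural features used to rate translocation propensity.

    Strata are defined on the pair list ordered from the apex: the upper
    third is the first ceil(n_bp/3) pairs, the lower two-thirds the rest.
    The motif flags report whether the motif occurs within ``apex_window``
    nt of the apex loop on the 5' and 3' arms respectively.
    """
    n_bp = len(stem.pairs)
    if n_bp == 0:
        raise ValueError("empty stem")
    s = seq.residues if isinstance(seq, NucleotideSequence) else str(seq).upper()
    gc_flags = [s[l - 1] in "GC" for l, _ in stem.pairs]
    n_gc = sum(gc_flags)
    n_upper = math.ceil(n_bp / 3)
    upper = gc_flags[:n_upper]
    lower = gc_flags[n_upper:]
    at_upper = 1.0 - (sum(upper) / len(upper)) if upper else 0.0
    gc_lower = (sum(lower) / len(lower)) if lower else 0.0
    largest_loop = max((max(l, r) for l, r in stem.internal_loops), default=0)
    if stem.apex_loop is not None:
        apex_start, apex_end = stem.apex_loop.start, stem.apex_loop.end
        apex_len = stem.apex_loop.length()
    else:
        apex_start = stem.pairs[0][0] + 1
        apex_end = stem.pairs[0][1] - 1
        apex_len = 0
    win5 = s[max(stem.left_arm.start, apex_start - apex_window) - 1:
             apex_start - 1]
    win3 = s[apex_end:min(stem.right_arm.end, apex_end + apex_window)]
    near5 = count_motif(win5, motif, "forward")[0] > 0 if len(win5) >= len(motif) else False
    near3 = count_motif(win3, motif, "forward")[0] > 0 if len(win3) >= len(motif) else False
    dg = delta_g(stem, s, params) if n_bp >= 2 else 0.0
    return StemFeatures(
        n_bp=n_bp, n_gc_pairs=n_gc, gc_per_bp=n_gc / n_bp,
        apex_loop_len=apex_len, at_frac_upper_third=at_upper,
        gc_frac_lower_two_thirds=gc_lower,
        largest_internal_loop_nt=largest_loop, delta_g=dg,
        motif_near_apex_5p=near5, motif_near_apex_3p=near3,
        param_set=params.name)


def dot_bracket(stem: StemLoop, start: Optional[int] = None,
                end: Optional[int] = None) -> str:
    """Dot-bracket string over the stem span (dots for loops/bulges)."""
    start = stem.left_arm.start if start is None else start
    end = stem.right_arm.end if end is None else end
    chars = ["." for _ in range(start, end + 1)]
    for l, r in stem.pairs:
        chars[l - start] = "("
        chars[r - start] = ")"
    return "".join(chars)
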