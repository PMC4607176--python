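"""Pairwise alignment, seed-and-extend homology mapping, motif gain/loss.

``global_align`` is an affine-gap Needleman–Wunsch with free end gaps and
EMBOSS-Needle-like scoring (match +5, mismatch −4, gap open 10, extend 0.5).
``local_map`` is a lightweight BLAST-style mapper: exact k-mer seeding,
diagonal clustering, and gapped extension of each cluster window, on both
strands. ``classify_motif_fate`` projects motif occurrences of two aligned
sequences onto alignment columns and calls each occurrence conserved,
species-specific by substitution, or species-specific by indel.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

from Bio import Align

from .enrichment import count_motif
from .seq import GenomicRegion, NucleotideSequence, reverse_complement


@dataclass
class Alignment:
    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    aligned_length: int
    gap_columns: int


@dataclass
class HomologyHit:
    query_region: GenomicRegion
    target_region: GenomicRegion
    strand: str
    identity_pct: float
    score: float


@dataclass
class MotifFateRecord:
    species_a_position: Optional[int]
    species_b_position: Optional[int]
    category: str  # conserved | a_only | b_only
    cause: Optional[str]  # substitution | insertion | deletion | complex


def _residues(x: Union[str, NucleotideSequence]) -> Tuple[str, str]:
    if isinstance(x, NucleotideSequence):
        return x.id, x.residues
    return "seq", str(x).upper()


def _needle_aligner(match: float, mismatch: float, gap_open: float,
                    gap_extend: float, end_gaps_free: bool
                    ) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if end_gaps_free:
        try:
            aligner.open_end_gap_score = 0.0
            aligner.extend_end_gap_score = 0.0
        except AttributeError:  # Biopython < 1.88 naming
            aligner.end_open_gap_score = 0.0
            aligner.end_extend_gap_score = 0.0
    return aligner


def global_align(a: Union[str, NucleotideSequence],
                 b: Union[str, NucleotideSequence],
                 match: float = 5.0, mismatch: float = -4.0,
                 gap_open: float = 10.0, gap_extend: float = 0.5,
                 end_gaps_free: bool = True,
                 max_length: int = 100_000) -> Alignment:
    """Global affine-gap alignment; a gap of length L costs open + L*extend."""
    id_a, sa = _residues(a)
    id_b, sb = _residues(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    if max(len(sa), len(sb)) > max_length:
        raise ValueError(f"sequence longer than max_length={max_length}")
    aligner = _needle_aligner(match, mismatch, gap_open, gap_extend,
                              end_gaps_free)
    aln = next(iter(aligner.align(sa, sb)))
    sA, sB = str(aln[0]), str(aln[1])
    ident = sum(1 for x, y in zip(sA, sB) if x == y and x != "-")
    gaps = sum(1 for x, y in zip(sA, sB) if x == "-" or y == "-")
    out = Alignment(seq_a_id=id_a, seq_b_id=id_b, aligned_a=sA, aligned_b=sB,
                    score=float(aln.score), identity_pct=0.0,
                    aligned_length=len(sA), gap_columns=gaps)
    out.identity_pct = percent_identity(out, mode="exclude_end_gaps")
    return out


def percent_identity(aln: Alignment,
                     mode: str = "exclude_end_gaps") -> float:
    """Identity percentage over the chosen denominator, to 1 decimal."""
    sA, sB = aln.aligned_a, aln.aligned_b
    if not sA:
        raise ValueError("zero-length alignment")
    lo, hi = 0, len(sA)
    if mode == "exclude_end_gaps":
        while lo < hi and (sA[lo] == "-" or sB[lo] == "-"):
            lo += 1
        while hi > lo and (sA[hi - 1] == "-" or sB[hi - 1] == "-"):
            hi -= 1
        if hi == lo:
            return 0.0  # fully staggered: no aligned residues at all
    elif mode != "all_columns":
        raise ValueError("mode must be 'all_columns' or 'exclude_end_gaps'")
    ident = sum(1 for x, y in zip(sA[lo:hi], sB[lo:hi])
                if x == y and x != "-")
    return round(100.0 * ident / (hi - lo), 1)


def _cluster_seeds(seeds: List[Tuple[int, int]], diag_band: int = 20,
                   max_gap: int = 400) -> List[Tuple[int, int, int, int]]:
    """Group (qpos, tpos) seeds into clusters; return (q0, q1, t0, t1)."""
    by_diag = sorted(seeds, key=lambda s: (s[1] - s[0], s[0]))
    clusters = []
    cur = []
    for q, t in by_diag:
        d = t - q
        if cur and (d - (cur[-1][1] - cur[-1][0]) > diag_band
                    or q - cur[-1][0] > max_gap):
            clusters.append(cur)
            cur = []
        cur.append((q, t))
    if cur:
        clusters.append(cur)
    out = []
    for cl in clusters:
        qs = [q for q, _ in cl]
        ts = [t for _, t in cl]
        out.append((min(qs), max(qs), min(ts), max(ts)))
    return out


def local_map(query: Union[str, NucleotideSequence],
              target: Union[str, NucleotideSequence],
              k: int = 12, min_identity_pct: float = 90.0,
              min_span: int = 100, both_strands: bool = True,
              pad: int = 60) -> List[HomologyHit]:
    """Map a query onto a target by k-mer seeding and gapped extension.

    Each diagonal cluster of exact k-mer seeds is extended by aligning the
    query against a padded target window (free end gaps); hits shorter than
    ``min_span`` on the target or below ``min_identity_pct`` are dropped,
    and overlapping target hits keep only the best score. Minus-strand hits
    report target coordinates on the plus strand with strand "−".
    """
    qid, q = _residues(query)
    tid, t = _residues(target)
    if len(q) < k:
        raise ValueError("query shorter than seed size k")
    index = defaultdict(list)
    for i in range(len(t) - k + 1):
        index[t[i:i + k]].append(i)
    hits: List[HomologyHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        qs = q if strand == "+" else reverse_complement(q)
        seeds = []
        for i in range(len(qs) - k + 1):
            for tpos in index.get(qs[i:i + k], ()):
                seeds.append((i, tpos))
        if not seeds:
            continue
        for q0, q1, t0, t1 in _cluster_seeds(seeds):
            w0 = max(0, t0 - (q0 + pad))
            w1 = min(len(t), t1 + k + (len(qs) - q1) + pad)
            window = t[w0:w1]
            aln = global_align(qs, window)
            hit = _hit_from_alignment(aln, qid, tid, strand, len(qs),
                                      w0)
            if hit is None:
                continue
            if hit.target_region.length() < min_span:
                continue
            if hit.identity_pct < min_identity_pct:
                continue
            hits.append(hit)
    return _merge_hits(hits)


def _hit_from_alignment(aln: Alignment, qid: str, tid: str, strand: str,
                        qlen: int, t_offset: int) -> Optional[HomologyHit]:
    sA, sB = aln.aligned_a, aln.aligned_b  # A = query, B = target window
    lo, hi = 0, len(sA)
    while lo < hi and (sA[lo] == "-" or sB[lo] == "-"):
        lo += 1
    while hi > lo and (sA[hi - 1] == "-" or sB[hi - 1] == "-"):
        hi -= 1
    if hi <= lo:
        return None
    q_start = sum(1 for c in sA[:lo] if c != "-")       # 0-based
    q_end = q_start + sum(1 for c in sA[lo:hi] if c != "-")  # exclusive
    t_start = sum(1 for c in sB[:lo] if c != "-")
    t_end = t_start + sum(1 for c in sB[lo:hi] if c != "-")
    if q_end <= q_start or t_end <= t_start:
        return None
    if strand == "-":
        q_start, q_end = qlen - q_end, qlen - q_start
    qreg = GenomicRegion(qid, q_start + 1, q_end, "+")
    treg = GenomicRegion(tid, t_offset + t_start + 1, t_offset + t_end, "+")
    return HomologyHit(query_region=qreg, target_region=treg, strand=strand,
                       identity_pct=percent_identity(aln),
                       score=aln.score)


def _merge_hits(hits: List[HomologyHit]) -> List[HomologyHit]:
    hits = sorted(hits, key=lambda h: -h.score)
    kept: List[HomologyHit] = []
    for h in hits:
        overlap = False
        for kh in kept:
            if (h.target_region.start <= kh.target_region.end
                    and kh.target_region.start <= h.target_region.end):
                overlap = True
                break
        if not overlap:
            kept.append(h)
    kept.sort(key=lambda h: (-h.score, h.target_region.start))
    return kept


def classify_motif_fate(aln: Alignment, motif: str) -> List[MotifFateRecord]:
    """Call each motif occurrence conserved, a-only or b-only with a cause.

    Occurrences are located in each ungapped sequence, projected to
    alignment columns; occurrences with identical column spans in both
    sequences are conserved. For the rest, the cause reflects the aligned
    span in the motif-less partner: pure mismatches give ``substitution``,
    extra partner bases across the span give ``insertion``, missing partner
    bases give ``deletion``, and a mixture gives ``complex``.
    """
    sA, sB = aln.aligned_a, aln.aligned_b
    a = sA.replace("-", "")
    b = sB.replace("-", "")
    col_a, col_b = [], []
    for col, (x, y) in enumerate(zip(sA, sB)):
        if x != "-":
            col_a.append(col)
        if y != "-":
            col_b.append(col)
    k = len(motif)
    occ_a = [h.position - 1 for h in count_motif(a, motif, "forward")[1]]
    occ_b = [h.position - 1 for h in count_motif(b, motif, "forward")[1]]
    span_a = {(col_a[p], col_a[p + k - 1]): p for p in occ_a}
    span_b = {(col_b[p], col_b[p + k - 1]): p for p in occ_b}
    records = []
    for span, p in sorted(span_a.items()):
        if span in span_b:
            records.append(MotifFateRecord(p + 1, span_b[span] + 1,
                                           "conserved", None))
        else:
            records.append(MotifFateRecord(
                p + 1, None, "a_only", _cause(sA, sB, span)))
    for span, p in sorted(span_b.items()):
        if span not in span_a:
            records.append(MotifFateRecord(
                None, p + 1, "b_only", _cause(sB, sA, span)))
    return records


def _cause(own: str, partner: str, span: Tuple[int, int]) -> str:
    lo, hi = span
    own_gap = any(own[c] == "-" for c in range(lo, hi + 1))
    partner_gap = any(partner[c] == "-" for c in range(lo, hi + 1))
    if own_gap and partner_gap:
        return "complex"
    if own_gap:
        return "insertion"
    if partner_gap:
        return "deletion"
    return "substitution"
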