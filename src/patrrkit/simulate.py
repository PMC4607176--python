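"""Synthetic loci with known truth.

Generators for the three kinds of fixture the analysis needs:

* A+T-rich "variable regions" with a known number of planted motif copies
  on an iid background (the scale mirrors the ~1 kb, 93–94% A+T segments
  the analysis targets).
* PATRR-like palindromes: a stratified stem (A:T-rich apex-proximal third,
  G:C-bearing lower two-thirds), small apex loop, optional motif copies
  adjacent to the apex on both arms, and optional asymmetric internal loops.
* A full two-species locus pair: a mosaic of breakpoint-flank-like inserts
  and variable regions in the 5' half plus a conserved 3' half, with the
  comparator derived by per-region-class mutation (low substitution rate in
  the conserved half, high substitution + indel rates in variable regions,
  some inserts wholly deleted).

Every generator is deterministic under a fixed seed and returns a
machine-readable truth structure (JSON-serializable; 1-based inclusive
coordinates).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .enrichment import MOTIF
from .seq import GenomicRegion, NucleotideSequence, reverse_complement

_BASES = np.array(list("ACGT"))


def _rng_background(rng: np.random.Generator, length: int,
                    gc: float) -> list:
    p_gc, p_at = gc / 2.0, (1.0 - gc) / 2.0
    return list(rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at]))


def _stratified_arm(rng: np.random.Generator, stem_bp: int,
                    at_frac_upper: float, gc_frac_lower: float) -> List[str]:
    """Left arm, written outer -> apex; last ceil(n/3) bases are apex-proximal."""
    n_upper = math.ceil(stem_bp / 3)
    n_lower = stem_bp - n_upper
    arm = []
    for _ in range(n_lower):
        if rng.random() < gc_frac_lower:
            arm.append(rng.choice(["G", "C"]))
        else:
            arm.append(rng.choice(["A", "T"]))
    for _ in range(n_upper):
        if rng.random() < at_frac_upper:
            arm.append(rng.choice(["A", "T"]))
        else:
            arm.append(rng.choice(["G", "C"]))
    return arm


def make_variable_region(length: int, gc_fraction: float, motif: str = MOTIF,
                         n_planted: int = 0, seed: int = 0,
                         allow_overlap: bool = False
                         ) -> Tuple[NucleotideSequence, Dict]:
    """IID background with motif copies planted at random positions.

    Planted positions are non-overlapping by default; the truth lists the
    exact planted (position, strand) pairs. The final motif count may exceed
    ``n_planted`` because the background can contain chance copies.
    """
    k = len(motif)
    if n_planted * k > length / 2:
        raise ValueError("cannot pack that many motif copies into the region")
    rng = np.random.default_rng(seed)
    bases = _rng_background(rng, length, gc_fraction)
    positions: List[int] = []  # 0-based starts
    max_start = length - k
    attempts = 0
    while len(positions) < n_planted:
        attempts += 1
        if attempts > 1000 * max(1, n_planted):
            raise RuntimeError("motif packing did not converge")
        p = int(rng.integers(0, max_start + 1))
        if not allow_overlap and any(abs(p - q) < k for q in positions):
            continue
        positions.append(p)
    for p in sorted(positions):
        bases[p:p + k] = list(motif)
    seq = NucleotideSequence(f"vr_L{length}_gc{gc_fraction:g}_s{seed}",
                             "".join(bases))
    truth = {"planted_motifs": [(p + 1, "+") for p in sorted(positions)],
             "motif": motif, "length": length, "gc_fraction": gc_fraction,
             "seed": seed}
    return seq, truth


@dataclass
class InternalLoopSpec:
    """Unpaired insertion ``offset_from_apex`` pairs below the apex.

    ``left_nt`` / ``right_nt`` extra bases on the 5' and 3' arms (either may
    be zero for a bulge)."""
    offset_from_apex: int
    left_nt: int
    right_nt: int


def make_patrr(stem_bp: int, apex_len: int,
               at_frac_upper: float = 0.95, gc_frac_lower: float = 0.40,
               internal_loops: Sequence[InternalLoopSpec] = (),
               flank_len: int = 500, seed: int = 0,
               plant_motif: bool = True, motif: str = MOTIF,
               flank_gc: float = 0.5) -> Tuple[NucleotideSequence, Dict]:
    """Plant a two-arm palindrome with a stratified stem in random flanks.

    When ``plant_motif`` is set, the apex-proximal ends of both arms carry
    the motif in the linear (5'->3') reading, mirroring the motif-near-apex
    arrangement of natural PATRRs. Apex-loop and insertion bases are drawn
    from {A, C} so they cannot pair with each other.
    """
    if stem_bp < 10:
        raise ValueError("stem_bp must be >= 10")
    if apex_len < 3:
        raise ValueError("apex_len must be >= 3")
    rng = np.random.default_rng(seed)
    arm = _stratified_arm(rng, stem_bp, at_frac_upper, gc_frac_lower)
    if plant_motif:
        k = len(motif)
        if stem_bp < 2 * k + 2:
            raise ValueError("stem too short to carry apex-proximal motifs")
        # linear reading of the right arm is revcomp(left arm), so putting
        # motif + revcomp(motif) at the arm's apex end puts the motif next
        # to the apex on both arms
        tail = list(motif) + list(reverse_complement(motif))
        arm[-len(tail):] = tail
    loop = [rng.choice(["A", "C"]) for _ in range(apex_len)]
    left = list(arm)
    right = list(reverse_complement("".join(arm)))
    # apply internal loops: insert unpaired bases at mirrored stem offsets
    for spec in sorted(internal_loops, key=lambda s: s.offset_from_apex):
        if not (0 < spec.offset_from_apex < stem_bp):
            raise ValueError("internal loop offset outside the stem")
    left_ins: Dict[int, int] = {}
    right_ins: Dict[int, int] = {}
    for spec in internal_loops:
        left_ins[spec.offset_from_apex] = spec.left_nt
        right_ins[spec.offset_from_apex] = spec.right_nt
    def _insert(arm_seq: List[str], ins: Dict[int, int], from_apex_at_end: bool) -> List[str]:
        out = []
        n = len(arm_seq)
        for i, c in enumerate(arm_seq):
            # pairs from apex: for the left arm (outer->apex) base i is
            # n-i pairs from apex; insert after the base `offset` pairs in
            if from_apex_at_end:
                off = n - i
                if off in ins and ins[off]:
                    out.extend(rng.choice(["A", "C"]) for _ in range(ins[off]))
            out.append(c)
            if not from_apex_at_end:
                off = i + 1
                if off in ins and ins[off]:
                    out.extend(rng.choice(["A", "C"]) for _ in range(ins[off]))
        return out
    left_full = _insert(left, left_ins, from_apex_at_end=True)
    right_full = _insert(right, right_ins, from_apex_at_end=False)
    flank5 = _rng_background(rng, flank_len, flank_gc)
    flank3 = _rng_background(rng, flank_len, flank_gc)
    parts = flank5 + left_full + loop + right_full + flank3
    seq = NucleotideSequence(f"patrr_stem{stem_bp}_apex{apex_len}_s{seed}",
                             "".join(parts))
    l0 = flank_len + 1
    l1 = flank_len + len(left_full)
    a0, a1 = l1 + 1, l1 + apex_len
    r0, r1 = a1 + 1, a1 + len(right_full)
    truth = {
        "left_arm": (l0, l1), "apex_loop": (a0, a1), "right_arm": (r0, r1),
        "stem_bp": stem_bp, "apex_len": apex_len,
        "internal_loops": [dataclasses.asdict(s) for s in internal_loops],
        "at_frac_upper": at_frac_upper, "gc_frac_lower": gc_frac_lower,
        "motif_near_apex": bool(plant_motif), "seed": seed,
    }
    return seq, truth


def mutate_sequence(residues: str, sub_rate: float, indel_rate: float,
                    rng: np.random.Generator, indel_mean_len: float = 4.0
                    ) -> str:
    """Per-base substitution (always to a different base) and geometric-length
    indels (insertion or deletion with equal probability)."""
    out = []
    i = 0
    n = len(residues)
    while i < n:
        c = residues[i]
        if indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.geometric(1.0 / indel_mean_len))
            if rng.random() < 0.5:  # insertion before this base
                out.extend(rng.choice(_BASES, size=length))
                out.append(c)
                i += 1
            else:  # deletion of `length` bases
                i += length
            continue
        if sub_rate > 0 and rng.random() < sub_rate and c in "ACGT":
            alts = [b for b in "ACGT" if b != c]
            out.append(alts[int(rng.integers(0, 3))])
        else:
            out.append(c)
        i += 1
    return "".join(out)


@dataclass
class LocusConfig:
    """Layout and divergence settings for the two-species synthetic locus.

    The default layout is a 10,000 nt unit: three breakpoint-flank-like
    inserts alternating with three A+T-rich variable regions in the 5' half
    (motif copy numbers 38 / 20 / 26 at ~1 kb scale, ~94% A+T), a 120 bp
    planted palindrome inside the third variable region, and a conserved 3'
    tail. The comparator diverges at 3% substitutions (no indels) in the
    conserved tail, heavily (15% substitutions + indels) in variable
    regions, and two of the three inserts are deleted outright.
    """

    total_length: int = 10_000
    insert_len: int = 800
    exon_len: int = 212
    intron_len: int = 133
    vr_specs: Tuple[Tuple[int, float, int], ...] = (
        (1054, 0.06, 38), (732, 0.06, 20), (1100, 0.07, 26))
    vr_stem_bp: int = 120
    vr_stem_apex: int = 4
    conserved_gc: float = 0.45
    conserved_sub_rate: float = 0.03
    vr_sub_rate: float = 0.15
    vr_indel_rate: float = 0.02
    insert_sub_rate: float = 0.02
    deleted_inserts: Tuple[int, ...] = (1, 2)  # indices of inserts absent in b
    motif: str = MOTIF
    seed: int = 0


@dataclass
class SyntheticLocusTruth:
    planted_motifs: List[Tuple[int, str]]
    planted_stems: List[Dict]
    planted_inserts: List[Dict]
    variable_regions: List[GenomicRegion]
    conserved_region: GenomicRegion
    divergence: Dict
    insert_library: Dict[str, str]
    seed: int

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, GenomicRegion):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=enc, indent=1)


def make_locus(config: LocusConfig = LocusConfig()
               ) -> Tuple[NucleotideSequence, NucleotideSequence,
                          SyntheticLocusTruth]:
    """Build the two-species locus pair with full truth tracking."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    # one fixed insert source per seed, with exon/intron-like submotifs
    insert_src = "".join(_rng_background(rng, cfg.insert_len, 0.45))
    exon_off, intron_off = 100, 450
    insert_lib = {
        "bp_flank": insert_src,
        "exon": insert_src[exon_off:exon_off + cfg.exon_len],
        "intron": insert_src[intron_off:intron_off + cfg.intron_len],
    }
    segments = []  # (kind, residues, meta)
    planted_motifs: List[Tuple[int, str]] = []
    planted_stems: List[Dict] = []
    planted_inserts: List[Dict] = []
    variable_regions: List[GenomicRegion] = []
    pos = 0  # 0-based running offset in locus_a

    def add(kind, residues, meta=None):
        nonlocal pos
        segments.append((kind, residues, meta or {}))
        start = pos + 1
        pos += len(residues)
        return start, pos

    for i, (vr_len, vr_gc, n_copies) in enumerate(cfg.vr_specs):
        s, e = add("insert", insert_src, {"index": i})
        planted_inserts.append({
            "source": "bp_flank", "start": s, "end": e, "strand": "+",
            "deleted_in_b": i in cfg.deleted_inserts,
            "mutation_rate": 0.0 if i in cfg.deleted_inserts
            else cfg.insert_sub_rate})
        if i == len(cfg.vr_specs) - 1 and cfg.vr_stem_bp:
            # last VR carries a planted palindrome between two motif halves
            stem_total = 2 * cfg.vr_stem_bp + cfg.vr_stem_apex
            part_len = (vr_len - stem_total) // 2
            n_half = n_copies // 2
            sub_seed = int(rng.integers(0, 2**31 - 1))
            p1, t1 = make_variable_region(part_len, vr_gc, cfg.motif,
                                          n_half, sub_seed)
            pal_seed = int(rng.integers(0, 2**31 - 1))
            pal, pal_truth = make_patrr(
                cfg.vr_stem_bp, cfg.vr_stem_apex, 0.95, 0.40,
                flank_len=0, seed=pal_seed, plant_motif=False)
            sub_seed2 = int(rng.integers(0, 2**31 - 1))
            rest = vr_len - part_len - stem_total
            p2, t2 = make_variable_region(rest, vr_gc, cfg.motif,
                                          n_copies - n_half, sub_seed2)
            s1, _ = add("vr", p1.residues, {"index": i})
            ps, pe = add("vr_stem", pal.residues)
            s2, e2 = add("vr", p2.residues, {"index": i})
            variable_regions.append(
                GenomicRegion("locus_a", s1, e2))
            planted_motifs += [(s1 - 1 + p, st) for p, st in t1["planted_motifs"]]
            planted_motifs += [(s2 - 1 + p, st) for p, st in t2["planted_motifs"]]
            off = ps - 1
            planted_stems.append({
                "left_arm": (off + pal_truth["left_arm"][0],
                             off + pal_truth["left_arm"][1]),
                "right_arm": (off + pal_truth["right_arm"][0],
                              off + pal_truth["right_arm"][1]),
                "apex_loop": (off + pal_truth["apex_loop"][0],
                              off + pal_truth["apex_loop"][1]),
                "stem_bp": cfg.vr_stem_bp, "apex_len": cfg.vr_stem_apex})
        else:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            vr, vt = make_variable_region(vr_len, vr_gc, cfg.motif,
                                          n_copies, sub_seed)
            s, e = add("vr", vr.residues, {"index": i})
            variable_regions.append(GenomicRegion("locus_a", s, e))
            planted_motifs += [(s - 1 + p, st) for p, st in vt["planted_motifs"]]
    cons_len = cfg.total_length - pos
    if cons_len <= 0:
        raise ValueError("layout exceeds total_length")
    cons = "".join(_rng_background(rng, cons_len, cfg.conserved_gc))
    cs, ce = add("conserved", cons)
    conserved_region = GenomicRegion("locus_a", cs, ce)

    locus_a = NucleotideSequence(
        "locus_a", "".join(res for _, res, _ in segments))

    # derive locus_b per segment class
    b_parts = []
    for kind, residues, meta in segments:
        if kind == "insert" and meta.get("index") in cfg.deleted_inserts:
            continue
        if kind == "insert":
            b_parts.append(mutate_sequence(residues, cfg.insert_sub_rate,
                                           0.0, rng))
        elif kind in ("vr", "vr_stem"):
            b_parts.append(mutate_sequence(residues, cfg.vr_sub_rate,
                                           cfg.vr_indel_rate, rng))
        else:
            b_parts.append(mutate_sequence(residues, cfg.conserved_sub_rate,
                                           0.0, rng))
    locus_b = NucleotideSequence("locus_b", "".join(b_parts))

    truth = SyntheticLocusTruth(
        planted_motifs=sorted(planted_motifs),
        planted_stems=planted_stems,
        planted_inserts=planted_inserts,
        variable_regions=variable_regions,
        conserved_region=conserved_region,
        divergence={
            "conserved_sub_rate": cfg.conserved_sub_rate,
            "vr_sub_rate": cfg.vr_sub_rate,
            "vr_indel_rate": cfg.vr_indel_rate,
            "insert_sub_rate": cfg.insert_sub_rate,
        },
        insert_library=insert_lib,
        seed=cfg.seed)
    return locus_a, locus_b, truth
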