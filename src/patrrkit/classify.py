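"""Rule-based translocation-propensity rating for PATRR-like stem loops.

High-frequency translocation PATRRs share a recognisable structural
signature: a near-perfect stem of roughly 200 bp or more, a small apex loop,
a strongly A:T-paired upper third of the stem, a moderate G:C content in the
lower two-thirds, and no large interruptions. The classifier encodes those
criteria as transparent boolean rules over :class:`StemFeatures`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

from .stemloop import StemFeatures


@dataclass(frozen=True)
class PatrrThresholds:
    """Tunable cutoffs for the five structural criteria.

    ``apex_max`` is inclusive (<= 5 nt): the canonical high-frequency
    exemplar itself carries a 5-base apex loop. The "moderate" G:C window
    and the internal-loop cutoff are deliberately generous; the underlying
    qualitative descriptions carry no exact bounds.
    """

    stem_min: int = 200
    apex_max: int = 5
    at_min: float = 0.90
    gc_lo: float = 0.25
    gc_hi: float = 0.55
    loop_max: int = 10


@dataclass
class PatrrVerdict:
    long_stem: bool
    small_apex: bool
    at_rich_upper: bool
    gc_moderate_lower: bool
    no_large_interruptions: bool
    motif_near_apex: bool
    propensity_class: str  # high | low | none
    criteria_met: int

    def to_dict(self) -> dict:
        return asdict(self)


def classify_patrr(features: Optional[StemFeatures],
                   thresholds: PatrrThresholds = PatrrThresholds()
                   ) -> PatrrVerdict:
    """Rate a stem loop's translocation propensity.

    ``high`` requires all five structural flags; the motif-near-apex flag is
    reported but not required (the motif is absent from some translocating
    PATRRs). ``none`` is returned when no stem was provided.
    """
    if features is None:
        return PatrrVerdict(False, False, False, False, False, False,
                            "none", 0)
    t = thresholds
    long_stem = features.n_bp >= t.stem_min
    small_apex = features.apex_loop_len <= t.apex_max
    at_rich = features.at_frac_upper_third >= t.at_min
    gc_mod = t.gc_lo <= features.gc_frac_lower_two_thirds <= t.gc_hi
    no_big_loops = features.largest_internal_loop_nt <= t.loop_max
    motif = features.motif_near_apex_5p or features.motif_near_apex_3p
    flags = [long_stem, small_apex, at_rich, gc_mod, no_big_loops]
    cls = "high" if all(flags) else "low"
    return PatrrVerdict(
        long_stem=long_stem, small_apex=small_apex, at_rich_upper=at_rich,
        gc_moderate_lower=gc_mod, no_large_interruptions=no_big_loops,
        motif_near_apex=motif, propensity_class=cls,
        criteria_met=sum(flags))
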