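"""IDscore computation, three-way classification and RdRp-core trimming.

The IDscore of a hit is its bit score divided by the amino-acid length of
the sequence-to-profile alignment.  An ORF whose best IDscore is below
0.25 is *unclassified*; if the second-best significant profile scores
within 20% of the best the ORF is *ambiguous*; otherwise it is
*classified* to the best profile.  Both thresholds sit in
:class:`PipelineConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .orfs import Orf
from .profilehmm import Hit

CLASSIFIED = "classified"
AMBIGUOUS = "ambiguous"
UNCLASSIFIED = "unclassified"


@dataclass
class PipelineConfig:
    """The pipeline's tunable constants with their default values."""

    unclassified_threshold: float = 0.25
    ambiguity_margin: float = 0.20
    p_threshold: float = 1e-6
    min_orf_nt: int = 60
    tables: tuple[int, ...] = (1, 4, 6)
    cluster_thresholds: tuple[float, ...] = (0.50, 0.70, 0.90, 1.00)
    core_len_cutoff_aa: int = 400
    calibration_decoys: int = 5000
    calibration_decoy_len: int = 350

    def __post_init__(self) -> None:
        if self.unclassified_threshold <= 0:
            raise ValueError("unclassified_threshold must be positive")
        if not (0 < self.ambiguity_margin < 1):
            raise ValueError("ambiguity_margin must be in (0, 1)")


@dataclass
class ClassificationRecord:
    orf_ref: str
    status: str
    best_profile: str
    best_idscore: float
    second_profile: Optional[str] = None
    second_idscore: Optional[float] = None
    all_significant: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class CoreSequence:
    """The profile-matched slice of an ORF: the approximate RdRp core."""

    orf_ref: str
    profile_name: str
    aa_seq: str
    seq_from: int  # 1-based inclusive on the parent ORF
    seq_to: int


def idscore(hit: Hit) -> float:
    """Bit score per aligned amino acid; may be negative."""
    if hit.aln_len_aa < 1:
        raise ValueError("alignment length must be >= 1")
    return hit.bit_score / hit.aln_len_aa


def _within_margin(best: float, second: float, margin: float) -> bool:
    """True when the runner-up is strictly less than ``margin`` below the
    best score.  A gap of exactly ``margin`` (up to floating-point noise)
    counts as outside, so the boundary case classifies."""
    cutoff = best * (1.0 - margin)
    if math.isclose(second, cutoff, rel_tol=1e-9, abs_tol=1e-12):
        return False
    return second > cutoff


def sort_orf(hits: Sequence[Hit], config: Optional[PipelineConfig] = None) -> ClassificationRecord:
    """Sort one ORF's significant hits into classified/ambiguous/unclassified.

    Rules, applied in order to IDscores ranked descending (ties broken by
    descending bit score, then profile name):

    * best IDscore < 0.25 -> unclassified;
    * a second profile scores less than 20% below the best -> ambiguous;
    * otherwise classified to the best profile (a difference of exactly
      20%, or a best of exactly 0.25, classifies).
    """
    if not hits:
        raise ValueError("sort_orf requires at least one significant hit")
    config = config or PipelineConfig()
    orf_refs = {h.orf_ref for h in hits}
    if len(orf_refs) > 1:
        raise ValueError(f"hits span multiple ORFs: {sorted(orf_refs)}")

    ranked = sorted(hits, key=lambda h: (-idscore(h), -h.bit_score, h.profile_name))
    scored = [(h.profile_name, idscore(h)) for h in ranked]
    best_profile, best = scored[0]
    second_profile, second = (None, None)
    if len(scored) > 1:
        second_profile, second = scored[1]

    if best < config.unclassified_threshold:
        status = UNCLASSIFIED
    elif second is not None and _within_margin(best, second, config.ambiguity_margin):
        status = AMBIGUOUS
    else:
        status = CLASSIFIED
    return ClassificationRecord(
        orf_ref=hits[0].orf_ref,
        status=status,
        best_profile=best_profile,
        best_idscore=best,
        second_profile=second_profile,
        second_idscore=second,
        all_significant=scored,
    )


def trim_to_core(orf: Orf, best_hit: Hit) -> CoreSequence:
    """Slice the ORF to the span matched by its best profile."""
    if best_hit.orf_ref and best_hit.orf_ref != orf.id:
        raise ValueError(f"hit {best_hit.orf_ref!r} does not belong to ORF {orf.id!r}")
    if not (1 <= best_hit.seq_from <= best_hit.seq_to <= len(orf.aa_seq)):
        raise ValueError(
            f"hit span {best_hit.seq_from}..{best_hit.seq_to} outside "
            f"ORF of length {len(orf.aa_seq)}"
        )
    return CoreSequence(
        orf_ref=orf.id,
        profile_name=best_hit.profile_name,
        aa_seq=orf.aa_seq[best_hit.seq_from - 1 : best_hit.seq_to],
        seq_from=best_hit.seq_from,
        seq_to=best_hit.seq_to,
    )
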