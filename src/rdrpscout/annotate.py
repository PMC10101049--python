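"""Motif-C analysis, profile co-occurrence and host assignment.

Motif C is the most conserved RdRp motif, centred on a catalytic triplet
(canonically GDD; the observed variants include SDD, GDN, IDD, ADN and
ADD).  Its position in a trimmed core is read off the profile column
annotated as the motif anchor via the stored Viterbi match map; a
pattern-based fallback covers profiles without an anchor.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import CLASSIFIED, ClassificationRecord, CoreSequence
from .profilehmm import Hit

MOTIF_FIRST = set("GSAINH")
MOTIF_THIRD = set("DNEQ")
FLANK = 5  # residues kept on each side of the triplet


@dataclass
class MotifC:
    core_ref: str
    position: int  # 1-based index of the triplet start within the core
    triplet: str
    window: str  # 13 aa: 5 flanking + 3 + 5, '-'-padded at core edges


@dataclass
class HostAssignment:
    contig_id: str
    category: str
    lineage: str


@dataclass
class CooccurrenceMatrix:
    profiles: list[str]
    counts: np.ndarray  # square, rows = best profile, cols = second best
    normalized: np.ndarray  # counts row-divided by row maximum

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.normalized if normalized else self.counts
        return pd.DataFrame(data, index=self.profiles, columns=self.profiles)


def _window(core: str, pos0: int) -> str:
    left = core[max(0, pos0 - FLANK) : pos0]
    right = core[pos0 + 3 : pos0 + 3 + FLANK]
    return "-" * (FLANK - len(left)) + left + core[pos0 : pos0 + 3] + right + "-" * (
        FLANK - len(right)
    )


def locate_motif_c(
    core: CoreSequence,
    family_anchor: Optional[int] = None,
    hit: Optional[Hit] = None,
) -> Optional[MotifC]:
    """Locate motif C in a trimmed core.

    With ``family_anchor`` (a 1-based profile column) and the core's
    ``hit`` carrying its Viterbi match map, the triplet is read at the
    core position aligned to that column.  Otherwise the fallback scans
    for an X-D-X pattern (first residue in GSAINH, third in DNEQ) and
    prefers the occurrence closest to 70% of the core length.  Returns
    ``None`` when no candidate exists.
    """
    seq = core.aa_seq
    if len(seq) < 3:
        return None

    if family_anchor is not None and hit is not None and hit.match_map is not None:
        seq_pos, prof_col = hit.match_map
        idx = np.nonzero(prof_col == family_anchor)[0]
        if idx.size:
            # hit coordinates are on the parent ORF; the core starts at seq_from
            pos0 = int(seq_pos[idx[0]]) - core.seq_from
            if 0 <= pos0 <= len(seq) - 3:
                return MotifC(
                    core_ref=core.orf_ref,
                    position=pos0 + 1,
                    triplet=seq[pos0 : pos0 + 3],
                    window=_window(seq, pos0),
                )

    target = 0.70 * len(seq)
    best_pos: Optional[int] = None
    for pos0 in range(len(seq) - 2):
        if seq[pos0] in MOTIF_FIRST and seq[pos0 + 1] == "D" and seq[pos0 + 2] in MOTIF_THIRD:
            if best_pos is None or abs(pos0 + 1 - target) < abs(best_pos + 1 - target):
                best_pos = pos0
    if best_pos is None:
        return None
    return MotifC(
        core_ref=core.orf_ref,
        position=best_pos + 1,
        triplet=seq[best_pos : best_pos + 3],
        window=_window(seq, best_pos),
    )


def triplet_census(motifs: Sequence[MotifC]) -> tuple[pd.Series, pd.DataFrame]:
    """Census of central triplets plus positional residue counts.

    Returns ``(triplet counts sorted by descending frequency, 13-column
    residue count table)``; '-' padding is excluded from the positional
    counts.  The total census count equals the number of motifs.
    """
    trip_counts = Counter(m.triplet for m in motifs)
    census = pd.Series(dict(trip_counts), dtype=int).sort_values(
        ascending=False, kind="stable"
    )
    census = census.reindex(sorted(census.index, key=lambda t: (-census[t], t)))

    pos_counts: list[Counter] = [Counter() for _ in range(2 * FLANK + 3)]
    for m in motifs:
        for i, ch in enumerate(m.window):
            if ch != "-":
                pos_counts[i][ch] += 1
    residues = sorted(set().union(*[set(c) for c in pos_counts]) if motifs else set())
    table = pd.DataFrame(
        {i + 1: {r: pos_counts[i].get(r, 0) for r in residues} for i in range(len(pos_counts))}
    )
    return census, table


def cooccurrence_matrix(records: Iterable[ClassificationRecord]) -> CooccurrenceMatrix:
    """Best-profile x second-best-profile counts over classified records.

    Only classified records with at least two significant hits contribute;
    each record increments ``counts[best][second]`` once.  ``normalized``
    divides each row by its maximum (zero rows stay zero), so the argmax
    of every nonzero row is exactly 1.0.
    """
    pairs = [
        (r.best_profile, r.second_profile)
        for r in records
        if r.status == CLASSIFIED and r.second_profile is not None
    ]
    profiles = sorted({p for pair in pairs for p in pair})
    index = {p: i for i, p in enumerate(profiles)}
    n = len(profiles)
    counts = np.zeros((n, n), dtype=int)
    for best, second in pairs:
        counts[index[best], index[second]] += 1
    normalized = np.zeros_like(counts, dtype=float)
    if n:
        row_max = counts.max(axis=1)
        nz = row_max > 0
        normalized[nz] = counts[nz] / row_max[nz, None]
    return CooccurrenceMatrix(profiles=profiles, counts=counts, normalized=normalized)


HOST_CATEGORIES = (
    "metagenomic",
    "fungi",
    "plants",
    "arthropods",
    "vertebrates",
    "invertebrates",
    "protists",
)


def assign_host(contig_id: str, lineage: Optional[str]) -> HostAssignment:
    """Assign a host category from a semicolon-delimited taxonomy lineage.

    Keyword rules, applied in order on exact semicolon-delimited tokens
    (case-sensitive): no "Eukaryota" -> metagenomic; "Fungi" -> fungi;
    "Viridiplantae" -> plants; "Arthropoda" -> arthropods; "Vertebrata" ->
    vertebrates; "Metazoa" without either -> invertebrates; remaining
    Eukaryota -> protists.  Total and deterministic: the seven categories
    partition all inputs.
    """
    lineage = lineage or ""
    tokens = {t.strip() for t in lineage.split(";")}
    if "Eukaryota" not in tokens:
        category = "metagenomic"
    elif "Fungi" in tokens:
        category = "fungi"
    elif "Viridiplantae" in tokens:
        category = "plants"
    elif "Arthropoda" in tokens:
        category = "arthropods"
    elif "Vertebrata" in tokens:
        category = "vertebrates"
    elif "Metazoa" in tokens:
        category = "invertebrates"
    else:
        category = "protists"
    return HostAssignment(contig_id=contig_id, category=category, lineage=lineage)


def host_summary(rows: Iterable[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise classified RdRps by host category.

    ``rows`` are dicts with keys ``family`` (best profile), ``core_seq``,
    ``category`` (host category; missing/None counts as "unknown"),
    ``dataset_id`` and ``species``.  Duplicate 100% identical cores within
    a family group are counted once.  Returns two tables: per-category
    (RdRp, dataset and species counts plus mean RdRps per species) and
    per-(family x category) RdRp/species counts.
    """
    seen: set[tuple[str, str]] = set()
    kept = []
    for row in rows:
        key = (row["family"], row["core_seq"])
        if key in seen:
            continue
        seen.add(key)
        kept.append(
            {
                "family": row["family"],
                "category": row.get("category") or "unknown",
                "dataset_id": row.get("dataset_id") or "unknown",
                "species": row.get("species") or "unknown",
            }
        )
    if not kept:
        empty_cat = pd.DataFrame(
            columns=["rdrp_count", "dataset_count", "species_count", "mean_rdrps_per_species"]
        )
        empty_fam = pd.DataFrame(columns=["rdrp_count", "species_count"])
        return empty_cat, empty_fam

    df = pd.DataFrame(kept)
    per_cat = df.groupby("category").agg(
        rdrp_count=("family", "size"),
        dataset_count=("dataset_id", "nunique"),
        species_count=("species", "nunique"),
    )
    per_cat["mean_rdrps_per_species"] = per_cat["rdrp_count"] / per_cat["species_count"]
    per_fam = df.groupby(["family", "category"]).agg(
        rdrp_count=("species", "size"), species_count=("species", "nunique")
    )
    return per_cat.sort_index(), per_fam.sort_index()
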