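"""GU/AG intron detection in mononegavirus-like genomes.

Some negative-sense RNA viruses express their polymerase (L) protein from
spliced mRNAs: the L ORF is interrupted by short AU-rich spliceosomal
introns with canonical GU/AG boundaries, and only after their removal does
the coding region fuse into one long ORF.  This module enumerates GT..AG
excision hypotheses (DNA alphabet internally; reports may render GU/AG),
scores their splice-junction context against a fixed plant-like consensus
PWM, measures AU content, and searches for the intron subset whose
excision maximises the longest resulting ORF.  It also scans for the
mononegavirus transcription stop-start motif.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .seqio import Contig

# ---------------------------------------------------------------------------
# Splice-junction position weight matrix
#
# A minimal donor/acceptor consensus modelled on the plant (Arabidopsis-like)
# splice sites: donor context AG|GTAAGT (two exonic positions, six intronic)
# and acceptor context TTTTGCAG|G (eight intronic, one exonic).  Consensus
# bases carry probability 0.7 (0.97 at the invariant GT/AG dinucleotides),
# the rest is spread uniformly; the background is uniform 0.25, so each
# consensus position contributes log2(0.7/0.25) ~ 1.49 bits.

_BASES = "ACGT"


def _pwm_rows(consensus: str, strict: str) -> np.ndarray:
    rows = np.empty((len(consensus), 4))
    for i, (ch, s) in enumerate(zip(consensus, strict)):
        major = 0.97 if s == "!" else 0.7
        rows[i] = (1.0 - major) / 3.0
        rows[i, _BASES.index(ch)] = major
    return np.log2(rows / 0.25)


DONOR_CONSENSUS = "AGGTAAGT"  # positions -2..-1 exon, 0..5 intron
DONOR_PWM = _pwm_rows(DONOR_CONSENSUS, "..!!....")
ACCEPTOR_CONSENSUS = "TTTTGCAGG"  # positions -8..-1 intron, last exon
ACCEPTOR_PWM = _pwm_rows(ACCEPTOR_CONSENSUS, "......!!.")

#: Score of a perfect-consensus junction (donor + acceptor), in bits.
MAX_JUNCTION_SCORE = float(DONOR_PWM.max(axis=1).sum() + ACCEPTOR_PWM.max(axis=1).sum())

#: Default minimum junction score for an excision hypothesis to enter
#: subset selection.  Perfect consensus scores ~27.1 bits; random GT..AG
#: pairs essentially never reach 24 (11+ of 13 non-fixed positions would
#: have to match consensus by chance).
DEFAULT_MIN_JUNCTION_SCORE = 24.0

#: Default minimum AU-fraction excess of a selectable intron over the
#: whole-contig AU fraction.  Spliceosomal introns in these genomes are
#: markedly AU-rich (roughly 0.68 against a 0.56 genome background); a
#: 0.10 excess keeps genuine introns while rejecting excisions that span
#: ordinary coding or intergenic sequence.
DEFAULT_MIN_AU_EXCESS = 0.10

DEFAULT_BEAM_WIDTH = 50
EXHAUSTIVE_LIMIT = 15


@dataclass
class IntronCandidate:
    contig_id: str
    donor: int  # 0-based position of the G of GT
    acceptor: int  # 0-based position just after AG (excision = seq[donor:acceptor])
    length: int
    au_fraction: float
    junction_score: float
    fused_orf_gain: Optional[int] = None  # aa gain of the longest ORF on excision

    def overlaps(self, other: "IntronCandidate") -> bool:
        return self.donor < other.acceptor and other.donor < self.acceptor


@dataclass
class MotifOccurrence:
    contig_id: str
    position: int  # 1-based end coordinate of the match
    mismatches: int
    matched_text: str


@dataclass
class SplicingResult:
    introns: list[IntronCandidate]
    spliced_seq: str
    longest_orf_aa: int
    unspliced_orf_aa: int = 0
    candidates_considered: int = 0
    exhaustive: bool = True


# --- fast longest-ORF scan --------------------------------------------------

_NT_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i

# table-1 stop codons as base-4 codon values (A=0 C=1 G=2 T=3)
_STOPS_T1 = {
    16 * 3 + 4 * 0 + 0,  # TAA
    16 * 3 + 4 * 0 + 2,  # TAG
    16 * 3 + 4 * 2 + 0,  # TGA
}

_RC = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def _longest_run(codons: np.ndarray) -> int:
    """Longest stop-free run of codons (codons with N never count as stops)."""
    vals = np.where(
        (codons < 4).all(axis=1), 16 * codons[:, 0] + 4 * codons[:, 1] + codons[:, 2], -1
    )
    is_stop = np.isin(vals, list(_STOPS_T1))
    stops = np.flatnonzero(is_stop)
    n = len(vals)
    if stops.size == 0:
        return n
    gaps = np.diff(np.concatenate(([-1], stops, [n]))) - 1
    return int(gaps.max())


def longest_orf_aa(seq: str) -> int:
    """Length (aa) of the longest between-stop ORF under code table 1,
    over both strands and all three frames, complete codons only."""
    codes = _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    best = 0
    for strand_codes in (codes, _RC[codes[::-1]]):
        for frame in range(3):
            usable = (len(strand_codes) - frame) // 3
            if usable <= 0:
                continue
            codons = strand_codes[frame : frame + 3 * usable].reshape(-1, 3)
            best = max(best, _longest_run(codons))
    return best


def _splice_out(seq: str, introns: Sequence[IntronCandidate]) -> str:
    pieces = []
    pos = 0
    for c in sorted(introns, key=lambda c: c.donor):
        pieces.append(seq[pos : c.donor])
        pos = c.acceptor
    pieces.append(seq[pos:])
    return "".join(pieces)


def _junction_scores(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position donor/acceptor PWM scores.

    donor[d] scores window seq[d-2:d+6] for a donor at d; acceptor[a]
    scores seq[a-9:a] plus the first exon base seq[a] for an acceptor
    ending at a.  Out-of-range or N positions score 0 (background).
    """
    codes = _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    n = len(codes)
    donor = np.zeros(n)
    acceptor = np.zeros(n + 1)
    for off in range(8):  # donor window offset -2..5 relative to d
        rel = off - 2
        idx = np.arange(n) + rel
        ok = (idx >= 0) & (idx < n)
        vals = np.where(ok, codes[np.clip(idx, 0, n - 1)], 4)
        contrib = np.where(vals < 4, DONOR_PWM[off][np.clip(vals, 0, 3)], 0.0)
        donor += contrib
    for off in range(9):  # acceptor window offset -8..0 relative to a
        rel = off - 8
        idx = np.arange(n + 1) + rel
        ok = (idx >= 0) & (idx < n)
        vals = np.where(ok, codes[np.clip(idx, 0, n - 1)], 4)
        contrib = np.where(vals < 4, ACCEPTOR_PWM[off][np.clip(vals, 0, 3)], 0.0)
        acceptor += contrib
    return donor, acceptor


def find_intron_candidates(
    contig: Contig,
    min_len: int = 40,
    max_len: int = 2000,
    with_orf_gain: bool = True,
) -> list[IntronCandidate]:
    """Enumerate every GT..AG excision hypothesis within the length window.

    Each candidate is annotated with its AU fraction, junction PWM score
    and (if ``with_orf_gain``) the change in longest-ORF length caused by
    its excision.  Candidates are returned sorted by (donor, acceptor).
    """
    if min_len < 4:
        raise ValueError("min_len must be >= 4")
    seq = contig.seq
    n = len(seq)
    codes = _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    is_au = (codes == 0) | (codes == 3)
    au_prefix = np.concatenate(([0], np.cumsum(is_au)))

    donors = np.array(
        [i for i in range(n - 1) if seq[i] == "G" and seq[i + 1] == "T"], dtype=int
    )
    acceptors = np.array(
        [i for i in range(2, n + 1) if seq[i - 2] == "A" and seq[i - 1] == "G"], dtype=int
    )
    if donors.size == 0 or acceptors.size == 0:
        return []
    donor_sc, acceptor_sc = _junction_scores(seq)

    base_orf = longest_orf_aa(seq) if with_orf_gain else None
    out: list[IntronCandidate] = []
    for d in donors:
        lo = np.searchsorted(acceptors, d + min_len)
        hi = np.searchsorted(acceptors, d + max_len, side="right")
        for a in acceptors[lo:hi]:
            length = int(a - d)
            cand = IntronCandidate(
                contig_id=contig.id,
                donor=int(d),
                acceptor=int(a),
                length=length,
                au_fraction=float((au_prefix[a] - au_prefix[d]) / length),
                junction_score=float(donor_sc[d] + acceptor_sc[a]),
            )
            if with_orf_gain:
                cand.fused_orf_gain = longest_orf_aa(_splice_out(seq, [cand])) - base_orf
            out.append(cand)
    return out


def resolve_splicing(
    contig: Contig,
    max_introns: int = 4,
    min_len: int = 40,
    max_len: int = 2000,
    min_junction_score: float = DEFAULT_MIN_JUNCTION_SCORE,
    min_au_excess: float = DEFAULT_MIN_AU_EXCESS,
    beam_width: int = DEFAULT_BEAM_WIDTH,
    method: str = "auto",
) -> SplicingResult:
    """Choose the intron subset whose excision maximises the longest ORF.

    Candidates below ``min_junction_score``, or whose AU fraction does
    not exceed the contig's by ``min_au_excess``, are never selected
    (they are still reported by :func:`find_intron_candidates`).
    Subsets of
    non-overlapping candidates up to ``max_introns`` are searched
    exhaustively when at most 15 candidates survive the score filter,
    otherwise by beam search over candidates in genome order (beam width
    50).  Ties are broken towards fewer introns, then higher summed
    junction score, then genome order, so an intron-free genome returns
    the empty subset.  ``method`` forces ``"exhaustive"`` or ``"beam"``
    instead of the automatic choice.
    """
    if max_introns < 0:
        raise ValueError("max_introns must be >= 0")
    if method not in ("auto", "exhaustive", "beam"):
        raise ValueError("method must be 'auto', 'exhaustive' or 'beam'")
    seq = contig.seq
    base_orf = longest_orf_aa(seq)
    contig_au = sum(1 for b in seq if b in "AT") / max(1, len(seq))
    candidates = [
        c
        for c in find_intron_candidates(contig, min_len, max_len, with_orf_gain=False)
        if c.junction_score >= min_junction_score
        and c.au_fraction >= contig_au + min_au_excess
    ]
    candidates.sort(key=lambda c: (c.donor, c.acceptor))

    def evaluate(subset: tuple[IntronCandidate, ...]):
        orf = longest_orf_aa(_splice_out(seq, list(subset))) if subset else base_orf
        score = sum(c.junction_score for c in subset)
        order = tuple((c.donor, c.acceptor) for c in subset)
        return (orf, -len(subset), score, tuple(-x for pair in order for x in pair))

    if method == "auto":
        exhaustive = len(candidates) <= EXHAUSTIVE_LIMIT
    else:
        exhaustive = method == "exhaustive"
    best_subset: tuple[IntronCandidate, ...] = ()
    best_key = evaluate(())

    if max_introns > 0 and candidates:
        if exhaustive:
            for r in range(1, min(max_introns, len(candidates)) + 1):
                for combo in itertools.combinations(candidates, r):
                    if any(
                        combo[i].overlaps(combo[j])
                        for i in range(r)
                        for j in range(i + 1, r)
                    ):
                        continue
                    key = evaluate(combo)
                    if key > best_key:
                        best_key, best_subset = key, combo
        else:
            # beam over candidates in genome order; states are subsets
            beam: list[tuple[tuple, tuple[IntronCandidate, ...]]] = [(best_key, ())]
            for cand in candidates:
                extended = []
                for key, subset in beam:
                    if len(subset) < max_introns and all(
                        not cand.overlaps(c) for c in subset
                    ):
                        new_subset = subset + (cand,)
                        extended.append((evaluate(new_subset), new_subset))
                beam.extend(extended)
                beam.sort(key=lambda t: t[0], reverse=True)
                beam = beam[:beam_width]
            best_key, best_subset = max(beam, key=lambda t: t[0])

    chosen = sorted(best_subset, key=lambda c: c.donor)
    spliced = _splice_out(seq, chosen)
    return SplicingResult(
        introns=chosen,
        spliced_seq=spliced,
        longest_orf_aa=best_key[0],
        unspliced_orf_aa=base_orf,
        candidates_considered=len(candidates),
        exhaustive=exhaustive,
    )


# --- transcription stop-start motif ----------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "U": "T",
    "W": "AT", "S": "CG", "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_STOP_START_CONSENSUS = "ACT(T/A)TAAAAAAGTGAAA(G/A)(G/A)C"


def parse_consensus(consensus: str) -> list[frozenset[str]]:
    """Parse a degenerate consensus into per-position allowed base sets.

    Accepts both the explicit ``(X/Y)`` notation and IUPAC one-letter
    codes; U is treated as T.
    """
    positions: list[frozenset[str]] = []
    i = 0
    s = consensus.upper()
    while i < len(s):
        ch = s[i]
        if ch == "(":
            j = s.find(")", i)
            if j < 0:
                raise ValueError(f"unclosed '(' at position {i + 1} in consensus")
            alts = s[i + 1 : j].split("/")
            bases = set()
            for alt in alts:
                if len(alt) != 1 or alt not in _IUPAC:
                    raise ValueError(f"bad alternative {alt!r} in consensus")
                bases.update(_IUPAC[alt])
            positions.append(frozenset(bases))
            i = j + 1
        elif ch in _IUPAC:
            positions.append(frozenset(_IUPAC[ch]))
            i += 1
        else:
            raise ValueError(f"illegal consensus character {ch!r} at position {i + 1}")
    if not positions:
        raise ValueError("empty consensus")
    return positions


def scan_stop_start(
    contig: Contig,
    consensus: str = DEFAULT_STOP_START_CONSENSUS,
    max_mismatch: int = 1,
) -> list[MotifOccurrence]:
    """Sliding-window scan for the transcription stop-start motif.

    Degenerate positions match any listed base at zero cost; other
    mismatches are counted.  Occurrences with at most ``max_mismatch``
    mismatches are reported by 1-based end position, ascending.
    """
    pattern = parse_consensus(consensus)
    m = len(pattern)
    seq = contig.seq
    out = []
    for start in range(len(seq) - m + 1):
        window = seq[start : start + m]
        mism = sum(1 for ch, allowed in zip(window, pattern) if ch not in allowed)
        if mism <= max_mismatch:
            out.append(
                MotifOccurrence(
                    contig_id=contig.id,
                    position=start + m,
                    mismatches=mism,
                    matched_text=window,
                )
            )
    return out
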