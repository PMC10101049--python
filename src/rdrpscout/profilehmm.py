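"""Build, calibrate and search protein profile HMMs.

A profile is built per virus family from a seed alignment of RdRp cores:
alignment columns with less than 50% gaps become match states, emission
probabilities are residue counts regularised with background-proportional
pseudocounts, and insert emissions are tied to the background.  Single-row
seeds are supported (the one observed sequence plus the pseudocount mass).

Searching is local Viterbi in log-odds space against an i.i.d. background
null over the aligned span, with significance from a Gumbel (type-I
extreme value) distribution fitted by maximum likelihood to Viterbi scores
of random background decoys.  E-values are p-values scaled by the number
of ORFs scanned in the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import gumbel_r

from . import _dp
from .orfs import Orf
from .seqio import SeedAlignment

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
X_CODE = 20

# Robinson & Robinson (1991) amino-acid background frequencies, the
# standard table used for protein null models; order follows AA_ORDER.
ROBINSON_BG = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
ROBINSON_BG = ROBINSON_BG / ROBINSON_BG.sum()

_TRANS_KEYS = ("mm", "mi", "md", "im", "ii", "dm", "dd")

# Dirichlet-style prior pseudo-counts for transition distributions.
_PRIOR_M = np.array([1.8, 0.1, 0.1])  # M -> M, I, D
_PRIOR_I = np.array([0.3, 0.1])  # I -> M, I
_PRIOR_D = np.array([0.3, 0.1])  # D -> M, D

# pseudocount mass added per match column, distributed as the background
EMISSION_PSEUDOCOUNT = 1.0


def encode_aa(seq: str) -> np.ndarray:
    """Map an amino-acid string to integer codes (X and any non-standard
    residue to the neutral code 20)."""
    return np.array([_AA_INDEX.get(ch, X_CODE) for ch in seq], dtype=np.int64)


@dataclass
class ProfileHMM:
    """A family-level protein profile with optional Gumbel calibration."""

    name: str
    M: int
    match_em: np.ndarray  # (M, 20) probabilities
    ins_em: np.ndarray  # (20,) probabilities, background-tied
    trans: dict[str, np.ndarray]  # each (M,); entries for the last state unused
    bg: np.ndarray  # (20,)
    gumbel_mu: Optional[float] = None
    gumbel_lambda: Optional[float] = None
    crop: Optional[tuple[int, int]] = None
    motif_anchor_col: Optional[int] = None  # 1-based profile column of motif C

    def __post_init__(self) -> None:
        self.match_em = np.asarray(self.match_em, dtype=float)
        self.ins_em = np.asarray(self.ins_em, dtype=float)
        self.bg = np.asarray(self.bg, dtype=float)
        self.trans = {k: np.asarray(v, dtype=float) for k, v in self.trans.items()}
        self.validate()

    def validate(self) -> None:
        if self.M < 1:
            raise ValueError("profile must have at least one match state")
        if self.match_em.shape != (self.M, 20):
            raise ValueError("match_em must be (M, 20)")
        if not np.allclose(self.match_em.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not np.allclose(self.ins_em.sum(), 1.0, atol=1e-9):
            raise ValueError("insert emissions must sum to 1")
        if not np.allclose(self.bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if np.any(self.match_em <= 0) or np.any(self.bg <= 0):
            raise ValueError("probabilities must be strictly positive")
        for keys in (("mm", "mi", "md"), ("im", "ii"), ("dm", "dd")):
            total = sum(self.trans[k] for k in keys)
            if not np.allclose(total, 1.0, atol=1e-9):
                raise ValueError(f"transition group {keys} must sum to 1")
            for k in keys:
                if np.any(self.trans[k] <= 0):
                    raise ValueError("transition probabilities must be strictly positive")
        if self.gumbel_lambda is not None and self.gumbel_lambda <= 0:
            raise ValueError("gumbel_lambda must be positive")

    @property
    def calibrated(self) -> bool:
        return self.gumbel_mu is not None and self.gumbel_lambda is not None

    # cached kernel arguments -------------------------------------------------
    def _dp_args(self):
        cached = getattr(self, "_dp_cache", None)
        if cached is None:
            lo = np.zeros((self.M, 21))
            lo[:, :20] = np.log2(self.match_em / self.bg[None, :])
            lo[:, X_CODE] = 0.0  # unknown residue is score-neutral
            logs = tuple(np.log2(self.trans[k]) for k in _TRANS_KEYS)
            entry = -float(np.log2(self.M))
            cached = (lo, *logs, entry)
            object.__setattr__(self, "_dp_cache", cached)
        return cached

    def p_value(self, bit_score: float) -> float:
        """Gumbel tail probability P(S >= bit_score) under the null."""
        if not self.calibrated:
            raise ValueError(f"profile {self.name!r} is not calibrated")
        z = self.gumbel_lambda * (bit_score - self.gumbel_mu)
        p = -np.expm1(-np.exp(-z))
        return float(min(max(p, 5e-324), 1.0))


@dataclass
class Hit:
    """Best local alignment of one ORF against one profile."""

    orf_ref: str
    profile_name: str
    bit_score: float
    seq_from: int  # 1-based inclusive on the ORF
    seq_to: int
    prof_from: int  # 1-based inclusive profile columns
    prof_to: int
    p_value: Optional[float] = None
    e_value: Optional[float] = None
    # parallel 1-based arrays: residue position / profile column of each
    # match state on the Viterbi path (used for motif anchoring)
    match_map: Optional[tuple[np.ndarray, np.ndarray]] = field(default=None, repr=False)

    @property
    def aln_len_aa(self) -> int:
        return self.seq_to - self.seq_from + 1


def _match_columns(rows: Sequence[str]) -> list[int]:
    n_rows = len(rows)
    cols = []
    for c in range(len(rows[0])):
        gaps = sum(1 for r in rows if r[c] == "-")
        if gaps / n_rows < 0.5:
            cols.append(c)
    return cols


def build_profile(
    seed: SeedAlignment,
    crop: Optional[tuple[int, int]] = None,
    motif_anchor_seed_col: Optional[int] = None,
) -> ProfileHMM:
    """Construct a profile from a seed alignment.

    ``crop`` is an optional 0-based half-open column range of the seed to
    retain (the RdRp-core window).  ``motif_anchor_seed_col`` is an
    optional 0-based seed column marking the first residue of motif C; it
    is converted to the corresponding profile match column and stored as
    metadata.

    Columns with less than 50% gaps become match states.  The background
    is the seed's own residue frequencies blended 1:1 with the Robinson &
    Robinson table; match emissions are column counts plus one unit of
    background-proportional pseudocount mass.
    """
    rows = [aligned for _, aligned in seed.rows]
    n_cols_full = len(rows[0])
    if crop is not None:
        start, end = crop
        if not (0 <= start < end <= n_cols_full):
            raise ValueError(f"crop {crop} outside alignment columns [0, {n_cols_full})")
        rows = [r[start:end] for r in rows]
    else:
        start = 0

    cols = _match_columns(rows)
    if not cols:
        raise ValueError(f"seed {seed.name!r}: no match columns after cropping")
    M = len(cols)
    match_col_set = set(cols)

    # background: seed residue frequencies blended with the standard table
    counts_bg = np.zeros(20)
    for r in rows:
        for ch in r:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts_bg[idx] += 1
    if counts_bg.sum() > 0:
        seed_freq = counts_bg / counts_bg.sum()
    else:
        seed_freq = ROBINSON_BG
    bg = 0.5 * seed_freq + 0.5 * ROBINSON_BG
    bg = bg / bg.sum()

    # match emissions
    match_em = np.zeros((M, 20))
    for k, c in enumerate(cols):
        counts = np.zeros(20)
        for r in rows:
            idx = _AA_INDEX.get(r[c])
            if idx is not None:
                counts[idx] += 1
        match_em[k] = (counts + EMISSION_PSEUDOCOUNT * bg) / (
            counts.sum() + EMISSION_PSEUDOCOUNT
        )

    # transition counts along each row over the match-column skeleton
    cm = np.zeros((M, 3))  # M -> M, I, D
    ci = np.zeros((M, 2))  # I -> M, I
    cd = np.zeros((M, 2))  # D -> M, D
    for r in rows:
        states = ["M" if r[c] != "-" else "D" for c in cols]
        n_ins = []  # insert residues between match column k and k+1
        for k in range(M - 1):
            lo, hi = cols[k], cols[k + 1]
            n_ins.append(
                sum(1 for c in range(lo + 1, hi) if c not in match_col_set and r[c] != "-")
            )
        for k in range(M - 1):
            here, nxt = states[k], states[k + 1]
            ins = n_ins[k]
            if here == "M":
                if ins > 0:
                    cm[k, 1] += 1  # M->I
                    ci[k, 1] += ins - 1  # I->I
                    if nxt == "M":
                        ci[k, 0] += 1
                    else:
                        # I->D is not modelled; attribute re-entry to I->M
                        ci[k, 0] += 1
                else:
                    cm[k, 0 if nxt == "M" else 2] += 1
            else:  # delete at k; inserts adjacent to deletes are not modelled
                cd[k, 0 if nxt == "M" else 1] += 1

    trans = {key: np.zeros(M) for key in _TRANS_KEYS}
    for k in range(M):
        m = cm[k] + _PRIOR_M
        trans["mm"][k], trans["mi"][k], trans["md"][k] = m / m.sum()
        i = ci[k] + _PRIOR_I
        trans["im"][k], trans["ii"][k] = i / i.sum()
        d = cd[k] + _PRIOR_D
        trans["dm"][k], trans["dd"][k] = d / d.sum()

    anchor = None
    if motif_anchor_seed_col is not None:
        local = motif_anchor_seed_col - start
        anchor = sum(1 for c in cols if c <= local)
        anchor = max(anchor, 1)

    return ProfileHMM(
        name=seed.name,
        M=M,
        match_em=match_em,
        ins_em=bg.copy(),
        trans=trans,
        bg=bg,
        crop=crop,
        motif_anchor_col=anchor,
    )


def sample_decoys(bg: np.ndarray, n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """Integer-coded random protein decoys drawn i.i.d. from ``bg``."""
    return rng.choice(20, size=(n, length), p=bg).astype(np.int64)


def calibrate_profile(
    profile: ProfileHMM, n_decoys: int = 10_000, decoy_len: int = 350, seed: int = 0
) -> ProfileHMM:
    """Fit a Gumbel law to Viterbi decoy scores and store it on the profile.

    Decoys are drawn i.i.d. from the profile background; the location and
    scale of the score distribution are estimated by maximum likelihood.
    Deterministic given ``seed``.
    """
    if n_decoys < 200:
        raise ValueError("n_decoys must be >= 200 for a stable Gumbel fit")
    rng = np.random.default_rng(seed)
    decoys = sample_decoys(profile.bg, n_decoys, decoy_len, rng)
    scores = _dp.viterbi_batch(*_batch_args(profile, decoys))
    mu, beta = gumbel_r.fit(scores)
    if not np.isfinite(beta) or beta <= 0:
        raise ValueError(
            f"degenerate Gumbel fit for {profile.name!r} (scale {beta}); use more decoys"
        )
    out = replace(profile, gumbel_mu=float(mu), gumbel_lambda=float(1.0 / beta))
    return out


def _batch_args(profile: ProfileHMM, seqs: np.ndarray):
    lo, tmm, tmi, tmd, tim, tii, tdm, tdd, entry = profile._dp_args()
    return lo, tmm, tmi, tmd, tim, tii, tdm, tdd, seqs, entry


def _seq_args(profile: ProfileHMM, codes: np.ndarray):
    lo, tmm, tmi, tmd, tim, tii, tdm, tdd, entry = profile._dp_args()
    return lo, tmm, tmi, tmd, tim, tii, tdm, tdd, codes, entry


def viterbi_bits(profile: ProfileHMM, aa_seq: str) -> float:
    """Viterbi bit score only (no coordinates)."""
    if not aa_seq:
        raise ValueError("empty sequence")
    return float(_dp.viterbi_score(*_seq_args(profile, encode_aa(aa_seq))))


def forward_bits(profile: ProfileHMM, aa_seq: str) -> float:
    """Forward bit score: log2 summed odds over all local paths (>= Viterbi)."""
    if not aa_seq:
        raise ValueError("empty sequence")
    return float(_dp.forward_score(*_seq_args(profile, encode_aa(aa_seq))))


def score_sequence(
    profile: ProfileHMM,
    aa_seq: str,
    orf_ref: str = "",
    with_pvalue: bool = False,
    database_size: Optional[int] = None,
) -> Hit:
    """Score one amino-acid sequence and return the best local alignment.

    ``with_pvalue`` requires a calibrated profile; ``database_size`` adds
    an E-value (p-value times database size).
    """
    if not aa_seq:
        raise ValueError("empty sequence")
    bits, sfrom, sto, pfrom, pto, mi, mk = _dp.viterbi_align(
        *_seq_args(profile, encode_aa(aa_seq))
    )
    hit = Hit(
        orf_ref=orf_ref,
        profile_name=profile.name,
        bit_score=float(bits),
        seq_from=int(sfrom),
        seq_to=int(sto),
        prof_from=int(pfrom),
        prof_to=int(pto),
        match_map=(mi, mk),
    )
    if with_pvalue:
        hit.p_value = profile.p_value(hit.bit_score)
        if database_size is not None:
            hit.e_value = hit.p_value * database_size
    return hit


def search(
    profiles: Iterable[ProfileHMM],
    orfs: Sequence[Orf],
    p_threshold: float = 1e-6,
    database_size: Optional[int] = None,
) -> list[Hit]:
    """Scan ORFs against calibrated profiles, retaining one best hit per
    (ORF, profile) pair with p-value <= ``p_threshold``.

    ``database_size`` defaults to the number of ORFs supplied and must not
    be smaller than it; E-values are p-values times this size, so the
    p-value cut is equivalent to an E-value cut of
    ``p_threshold * database_size``.  Hits come back grouped by ORF in
    input order, descending bit score within an ORF.
    """
    profiles = list(profiles)
    if database_size is None:
        database_size = len(orfs)
    if database_size < len(orfs):
        raise ValueError(
            f"database_size {database_size} is smaller than the {len(orfs)} ORFs supplied"
        )
    for prof in profiles:
        if not prof.calibrated:
            raise ValueError(f"profile {prof.name!r} is not calibrated")

    hits: list[Hit] = []
    for orf in orfs:
        codes = encode_aa(orf.aa_seq)
        orf_hits = []
        for prof in profiles:
            bits = float(_dp.viterbi_score(*_seq_args(prof, codes)))
            p = prof.p_value(bits)
            if p <= p_threshold:
                hit = score_sequence(prof, orf.aa_seq, orf_ref=orf.id)
                hit.p_value = prof.p_value(hit.bit_score)
                hit.e_value = hit.p_value * database_size
                orf_hits.append(hit)
        orf_hits.sort(key=lambda h: (-h.bit_score, h.profile_name))
        hits.extend(orf_hits)
    return hits
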