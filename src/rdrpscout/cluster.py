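"""Pairwise identity, greedy representative clustering and alignment diversity.

Identity between two unaligned protein sequences follows the parameter-free
definition used throughout the package: a global alignment with match 1,
mismatch 0 and free gaps (equivalently, the longest common subsequence),
divided by the shorter sequence length.  This implements the definition
directly rather than a word-filtered heuristic, so clustering is exact and
deterministic at the cost of quadratic pairwise alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SeedAlignment

_ALIGN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    n = len(_ALIGN_ALPHABET)
    # identity matrix; X (and *) never count as an identity
    mat = np.eye(n)
    for ch in ("X", "*"):
        i = _ALIGN_ALPHABET.index(ch)
        mat[i, i] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.Array(
        alphabet=_ALIGN_ALPHABET, dims=2, data=mat
    )
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def lcs_identity_count(a: str, b: str) -> int:
    """Number of identical residues in the best free-gap global alignment
    of ``a`` and ``b`` (the longest common subsequence; X matches nothing)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return int(_aligner().score(a, b))


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity: identical aligned residues over the shorter
    sequence length.  Always in [0, 1]."""
    return lcs_identity_count(a, b) / min(len(a), len(b))


@dataclass
class Cluster:
    representative: str
    members: list[str]
    threshold: float


def greedy_cluster(seqs: list[tuple[str, str]], threshold: float) -> list[Cluster]:
    """Greedy incremental clustering at a fixed identity threshold.

    Sequences are taken longest first (ties by id, ascending); each joins
    the first existing cluster whose representative it matches at
    ``>= threshold`` identity, else founds a new cluster.  Representatives
    are therefore always a longest member.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    ids = [sid for sid, _ in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    by_id = dict(seqs)
    order = sorted(ids, key=lambda sid: (-len(by_id[sid]), sid))
    clusters: list[Cluster] = []
    for sid in order:
        seq = by_id[sid]
        for cl in clusters:
            if pairwise_identity(seq, by_id[cl.representative]) >= threshold:
                cl.members.append(sid)
                break
        else:
            clusters.append(Cluster(representative=sid, members=[sid], threshold=threshold))
    return clusters


def cluster_increase(
    base: list[tuple[str, str]],
    added: list[tuple[str, str]],
    threshold: float,
    min_len_aa: int = 1,
) -> float:
    """Percentage increase in cluster count when ``added`` sequences join
    ``base``, after filtering both sets to length >= ``min_len_aa``."""
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    base_f = [(i, s) for i, s in base if len(s) >= min_len_aa]
    added_f = [(i, s) for i, s in added if len(s) >= min_len_aa]
    n_base = len(greedy_cluster(base_f, threshold)) if base_f else 0
    if n_base == 0:
        raise ValueError("base set has no clusters after length filtering")
    n_union = len(greedy_cluster(base_f + added_f, threshold))
    return 100.0 * (n_union - n_base) / n_base


def alignment_diversity(seed: SeedAlignment) -> tuple[float | None, np.ndarray]:
    """Diversity of a seed alignment.

    Returns ``(mean pairwise identity, per-column Shannon entropies in
    nats)``.  Pairwise identity between two rows counts identical residues
    over columns not gapped in both; entropy uses residue frequencies only
    (gaps excluded) and skips all-gap columns.  Mean identity is ``None``
    for single-row alignments.
    """
    from scipy.stats import entropy as scipy_entropy

    rows = [aligned for _, aligned in seed.rows]
    n = len(rows)

    mean_ident: float | None = None
    if n >= 2:
        idents = []
        for i in range(n):
            for j in range(i + 1, n):
                a, b = rows[i], rows[j]
                pairs = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
                if not pairs:
                    continue
                same = sum(1 for x, y in pairs if x == y and x != "-" and x != "X")
                idents.append(same / len(pairs))
        mean_ident = float(np.mean(idents)) if idents else None

    entropies = []
    for col in range(seed.n_cols):
        residues = [r[col] for r in rows if r[col] != "-"]
        if not residues:
            continue
        _, counts = np.unique(residues, return_counts=True)
        entropies.append(float(scipy_entropy(counts)))
    return mean_ident, np.array(entropies)
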