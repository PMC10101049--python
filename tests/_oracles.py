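"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and greedy
implementations: path scores are found by exhaustive enumeration over the
state graph, clusterings by a literal transcription of the ordered rule
over a full pairwise matrix.
"""

from __future__ import annotations

import numpy as np

from rdrpscout.profilehmm import ProfileHMM, encode_aa

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_profile(rng: np.random.Generator, M: int, name: str = "rand") -> ProfileHMM:
    """A structurally valid profile with Dirichlet-random parameters."""
    match_em = rng.dirichlet(np.full(20, 0.7), size=M)
    bg = rng.dirichlet(np.full(20, 5.0))
    trans = {}
    m = rng.dirichlet([8.0, 1.0, 1.0], size=M)
    i = rng.dirichlet([3.0, 1.0], size=M)
    d = rng.dirichlet([3.0, 1.0], size=M)
    trans["mm"], trans["mi"], trans["md"] = m[:, 0], m[:, 1], m[:, 2]
    trans["im"], trans["ii"] = i[:, 0], i[:, 1]
    trans["dm"], trans["dd"] = d[:, 0], d[:, 1]
    return ProfileHMM(
        name=name, M=M, match_em=match_em, ins_em=bg.copy(), trans=trans, bg=bg
    )


def enumerate_local_path_scores(profile: ProfileHMM, aa_seq: str) -> list[float]:
    """Log2 odds ratio of every complete local path (entry at any match
    state/residue, exit after any match state).  Exponential; only for
    tiny profiles and sequences."""
    M = profile.M
    codes = encode_aa(aa_seq)
    L = len(codes)
    lo = np.zeros((M, 21))
    lo[:, :20] = np.log2(profile.match_em / profile.bg[None, :])
    t = {k: np.log2(v) for k, v in profile.trans.items()}
    entry = -np.log2(M)
    scores: list[float] = []

    def step(state: str, k: int, i: int, score: float) -> None:
        # `i` residues consumed so far; current state already scored
        if state == "M":
            scores.append(score)  # free exit after any match
            if i < L:
                if k + 1 < M:
                    step("M", k + 1, i + 1, score + t["mm"][k] + lo[k + 1, codes[i]])
                step("I", k, i + 1, score + t["mi"][k])
            if k + 1 < M:
                step("D", k + 1, i, score + t["md"][k])
        elif state == "I":
            if i < L:
                step("I", k, i + 1, score + t["ii"][k])
                if k + 1 < M:
                    step("M", k + 1, i + 1, score + t["im"][k] + lo[k + 1, codes[i]])
        else:  # D
            if k + 1 < M:
                step("D", k + 1, i, score + t["dd"][k])
                if i < L:
                    step("M", k + 1, i + 1, score + t["dm"][k] + lo[k + 1, codes[i]])

    for i0 in range(L):
        for k0 in range(M):
            step("M", k0, i0 + 1, entry + lo[k0, codes[i0]])
    return scores


def brute_force_greedy_clusters(
    seqs: list[tuple[str, str]], threshold: float, identity_fn
) -> list[tuple[str, list[str]]]:
    """Literal transcription of the ordered greedy rule over a full
    pairwise identity matrix."""
    by_id = dict(seqs)
    order = sorted(by_id, key=lambda sid: (-len(by_id[sid]), sid))
    clusters: list[tuple[str, list[str]]] = []
    for sid in order:
        placed = False
        for rep, members in clusters:
            if identity_fn(by_id[sid], by_id[rep]) >= threshold:
                members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append((sid, [sid]))
    return clusters


def lcs_dp(a: str, b: str) -> int:
    """Textbook LCS dynamic program; X never matches."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1] and a[i - 1] not in "X*":
                dp[i, j] = dp[i - 1, j - 1] + 1
            else:
                dp[i, j] = max(dp[i - 1, j], dp[i, j - 1])
    return int(dp[n, m])
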