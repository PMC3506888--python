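"""Independent oracles used by the test suite.

The path enumerator below recursively visits every local single-hit state
path through a profile (entry at any match state and sequence position,
exit from any match state) and accumulates its odds ratio directly from
the model's linear-space parameters. It shares no code with the dynamic
programs it checks.
"""

from __future__ import annotations

import numpy as np

from transposcan.profile import BACKGROUND_FREQS, ProfileHMM


def random_profile(M: int, rng, name: str = "T/ORF1") -> ProfileHMM:
    """A fully random (Dirichlet) profile for property tests."""
    em = rng.dirichlet(np.ones(20), size=M)
    m = rng.dirichlet(np.ones(3), size=M)
    i = rng.dirichlet(np.ones(2), size=M)
    d = rng.dirichlet(np.ones(2), size=M)
    trans = {
        "MM": m[:, 0], "MI": m[:, 1], "MD": m[:, 2],
        "IM": i[:, 0], "II": i[:, 1],
        "DM": d[:, 0], "DD": d[:, 1],
    }
    return ProfileHMM(
        name=name,
        match_emissions=em,
        insert_emissions=BACKGROUND_FREQS.copy(),
        transitions=trans,
        null_freqs=BACKGROUND_FREQS.copy(),
    )


def enumerate_path_odds(profile: ProfileHMM, idx) -> list:
    """Odds ratio of every admissible local path (exhaustive; tiny inputs only)."""
    M = profile.M
    L = len(idx)
    em = profile.match_emissions
    null = profile.null_freqs
    t = profile.transitions
    entry = 1.0 / M
    exit_p = 1.0 / M

    def ratio_em(k, i):
        a = idx[i]
        return 1.0 if a == 20 else em[k - 1, a] / null[a]

    ratios: list = []

    def rec(state, k, i, acc):
        if state == "M":
            ratios.append(acc * exit_p)
        if state in ("M", "D"):
            row = t["MM"] if state == "M" else t["DM"]
            tm = row[k - 1]
            td = (t["MD"] if state == "M" else t["DD"])[k - 1]
            if k < M:
                if i + 1 < L:
                    rec("M", k + 1, i + 1, acc * tm * ratio_em(k + 1, i + 1))
                rec("D", k + 1, i, acc * td)
            if state == "M" and i + 1 < L:
                rec("I", k, i + 1, acc * t["MI"][k - 1])
        else:  # insert; emits at background, odds contribution 1
            if i + 1 < L:
                rec("I", k, i + 1, acc * t["II"][k - 1])
                if k < M:
                    rec("M", k + 1, i + 1, acc * t["IM"][k - 1] * ratio_em(k + 1, i + 1))

    for i0 in range(L):
        for k0 in range(1, M + 1):
            rec("M", k0, i0, entry * ratio_em(k0, i0))
    return ratios


def roc_counts_bruteforce(pos, neg, threshold):
    """Confusion counts at one threshold by a double loop (call iff e <= t)."""
    tp = sum(1 for e in pos if e <= threshold)
    fp = sum(1 for e in neg if e <= threshold)
    return tp, fp, len(neg) - fp, len(pos) - tp
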