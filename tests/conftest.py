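"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive behavior from first principles
(recursive grammar membership, nucleotide marking, exhaustive enumeration)
so that the fast implementations are checked against a second, structurally
different route.
"""

from __future__ import annotations

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# RGG grammar oracle
# ---------------------------------------------------------------------------

def grammar_member(s: str) -> bool:
    """True iff the *entire* string is one RGG motif.

    Recursive definition: a repeat unit (RG or RGG) followed by one or more
    (linker of 0-4 residues, unit) blocks consuming the whole string;
    linkers may be any residue except the unknown 'X' or a stop '*'.
    """
    n = len(s)
    memo: dict[tuple[int, int], bool] = {}

    def units_at(j: int) -> list[int]:
        out = []
        if j + 2 <= n and s[j] == "R" and s[j + 1] == "G":
            out.append(2)
            if j + 3 <= n and s[j + 2] == "G":
                out.append(3)
        return out

    def consume(i: int, n_units: int) -> bool:
        """Can s[i:] be consumed as (linker unit)* ending exactly at n?"""
        if i == n:
            return n_units >= 2
        key = (i, min(n_units, 2))
        if key in memo:
            return memo[key]
        ok = False
        for lk in range(5):
            j = i + lk
            if j > n or any(ch in "X*" for ch in s[i:j]):
                break
            for u in units_at(j):
                if consume(j + u, n_units + 1):
                    ok = True
                    break
            if ok:
                break
        memo[key] = ok
        return ok

    return any(consume(u, 1) for u in units_at(0))


def oracle_motif_spans(s: str) -> list[tuple[int, int]]:
    """Leftmost-longest non-overlapping motif spans by exhaustive search."""
    spans = []
    p = 0
    n = len(s)
    while p < n:
        best = None
        for e in range(n, p + 3, -1):  # longest first; min motif length is 4
            if grammar_member(s[p:e]):
                best = (p, e)
                break
        if best:
            spans.append(best)
            p = best[1]
        else:
            p += 1
    return spans


# ---------------------------------------------------------------------------
# overlap-run oracle
# ---------------------------------------------------------------------------

def oracle_consecutive_overlap(
    motif_iv: tuple[int, int], intervals, cutoff: int
) -> tuple[bool, int, int]:
    """(encoded, union overlap nt, longest run) by nucleotide marking."""
    lo, hi = motif_iv
    marked = np.zeros(hi - lo, dtype=bool)
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            marked[s2 - lo : e2 - lo] = True
    best = run = 0
    for m in marked:
        run = run + 1 if m else 0
        best = max(best, run)
    return best >= cutoff, int(marked.sum()), best


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_bundle():
    """A small noiseless association-mode synthetic bundle."""
    from rg4rgg.simulate import SimConfig, generate

    cfg = SimConfig(
        n_transcripts=20,
        cds_len_mean=120,
        cds_len_sd=30,
        motif_rate=1.5,
        g_bias=0.5,
        rg4_mode="association",
        planted_rg4_rate=0.7,
        sensitivity=1.0,
        false_call_rate_per_kb=0.0,
        jitter_sd=0.0,
        seed=11,
    )
    return generate(cfg)
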