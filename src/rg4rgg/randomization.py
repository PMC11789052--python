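"""Genetic-code randomization experiments and empirical p-values.

Three null models probe whether the rG4/RGG coding overlap is a property of
the *structure* of the genetic code rather than of sequence content alone:

``codon_shuffle``
    The 61 sense codons are randomly reassigned (degeneracy preserved) and
    every CDS is re-translated while the rG4 regions stay fixed; RGG motifs
    are detected anew in each alternative proteome.
``arg_gly_assignment``
    Arginine and glycine are assigned to the native codon boxes of two
    distinct amino acids (379 alternatives beside the native assignment);
    only R/G placement matters for the motif grammar.
``recoding``
    Each CDS is synonymously rewritten under a codon permutation (protein
    and motifs fixed, UTR flanks fixed) and rG4s are re-*predicted* on the
    recoded sequence.

In every scheme the statistic is the fraction of RGG motifs partly encoded
by rG4s, and the empirical p-value is the fraction of randomized codes
achieving a greater-or-equal fraction than the native code (the native draw
is not counted in the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .genetic_code import (
    ALL_CODONS,
    Transcript,
    codon_indices,
    enumerate_arg_gly_assignments,
    shuffle_codons,
    standard_table,
)
from .intervals import merge_intervals, overlap_length
from .overlap_stats import DEFAULT_CUTOFF
from .rg4_detect import RG4Region, g4hunter_regions, qgrs_scan
from .rgg_motifs import find_rgg_motifs

__all__ = [
    "RandomizationResult",
    "empirical_pvalue",
    "translation_experiment",
    "recoding_experiment",
    "pvalue_length_sweep",
    "SCHEMES",
]

SCHEMES = ("codon_shuffle", "arg_gly_assignment", "recoding")


@dataclass(frozen=True)
class RandomizationResult:
    """Outcome of one randomization experiment."""

    scheme: str
    native_fraction: float
    null_fractions: tuple[float, ...]
    p_value: float
    n: int
    seed: int | None
    annotations: tuple[dict, ...] = field(default=(), compare=False)
    extras: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.null_fractions) != self.n:
            raise ValueError("null_fractions length must equal n")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def empirical_pvalue(native: float, null: Sequence[float]) -> float:
    """Fraction of null draws with a statistic >= the native one."""
    null = list(null)
    if not null:
        raise ValueError("null distribution is empty")
    return sum(1 for x in null if x >= native) / len(null)


# ---------------------------------------------------------------------------
# fast translation machinery
# ---------------------------------------------------------------------------

class _TxCache:
    """Per-transcript precomputation shared by all randomized codes."""

    __slots__ = ("tx_id", "idx", "flank5", "rg4", "cds_len")

    def __init__(self, tx: Transcript, regions: Sequence[RG4Region]):
        self.tx_id = tx.id
        idx = codon_indices(tx.cds)
        # a trailing stop codon is a fixed point of every scheme; drop it so
        # translations never carry a trailing '*'
        std = standard_table().byte_array()
        if len(idx) and std[idx[-1]] == ord("*"):
            idx = idx[:-1]
        self.idx = idx
        self.flank5 = len(tx.utr5_flank)
        self.cds_len = 3 * len(idx)
        self.rg4 = merge_intervals([r.interval for r in regions]) if regions else []


def _build_caches(
    transcripts: Sequence[Transcript],
    rg4_regions: Mapping[str, Sequence[RG4Region]] | Sequence[RG4Region],
) -> list[_TxCache]:
    if not isinstance(rg4_regions, Mapping):
        by_tx: dict[str, list[RG4Region]] = {}
        for r in rg4_regions:
            by_tx.setdefault(r.transcript_id, []).append(r)
        rg4_regions = by_tx
    return [_TxCache(tx, rg4_regions.get(tx.id, [])) for tx in transcripts]


def _motif_outcomes(
    caches: Sequence[_TxCache], table_bytes: np.ndarray, cutoff: int
) -> tuple[np.ndarray, np.ndarray]:
    """(motif lengths, encoded flags) over all transcripts under one code."""
    lengths: list[int] = []
    encoded: list[bool] = []
    for c in caches:
        protein = table_bytes[c.idx].tobytes().decode("ascii")
        for m in find_rgg_motifs(protein):
            lengths.append(m.length)
            iv = (c.flank5 + 3 * m.start, c.flank5 + 3 * m.end)
            encoded.append(
                any(overlap_length(iv, r) >= cutoff for r in c.rg4)
            )
    return np.asarray(lengths, dtype=int), np.asarray(encoded, dtype=bool)


def _fraction(lengths: np.ndarray, encoded: np.ndarray, min_len: int) -> tuple[float, int]:
    keep = lengths >= min_len
    n = int(keep.sum())
    if n == 0:
        return 0.0, 0
    return float(encoded[keep].sum() / n), n


def _null_tables(scheme: str, n: int, seed: int | None):
    """Yield (table byte array, annotation) per randomized code."""
    if scheme == "codon_shuffle":
        ss = np.random.SeedSequence(seed)
        for child in ss.spawn(n):  # per-code substreams: order-independent
            perm = shuffle_codons(np.random.Generator(np.random.PCG64(child)))
            yield perm.induced_table().byte_array(), {}
    elif scheme == "arg_gly_assignment":
        for a in enumerate_arg_gly_assignments():
            if a.native:
                continue
            yield a.table.byte_array(), {
                "arg_source": a.arg_source,
                "gly_source": a.gly_source,
                "gly_native": a.gly_native,
            }
    else:
        raise ValueError(f"unknown translation scheme {scheme!r}")


def translation_experiment(
    transcripts: Sequence[Transcript],
    rg4_regions: Mapping[str, Sequence[RG4Region]] | Sequence[RG4Region],
    scheme: str = "codon_shuffle",
    n: int = 10_000,
    seed: int | None = 0,
    cutoff: int = DEFAULT_CUTOFF,
    min_motif_len: int = 0,
) -> RandomizationResult:
    """Alternative-translation null: rG4s fixed, proteome re-translated.

    For every randomized code the CDS set is translated, RGG motifs are
    detected in the alternative proteome with the identical grammar, and
    the fraction partly encoded by the *fixed* rG4 regions is recorded.
    For ``arg_gly_assignment`` the null size is forced to the 379
    alternative assignments and each draw is annotated with its Arg/Gly
    sources and the ``gly_native`` flag.  A code yielding zero motifs
    records fraction 0 (annotated ``no_motifs``).
    """
    caches = _build_caches(transcripts, rg4_regions)
    native_len, native_enc = _motif_outcomes(
        caches, standard_table().byte_array(), cutoff
    )
    native_frac, native_n = _fraction(native_len, native_enc, min_motif_len)
    if scheme == "arg_gly_assignment":
        n = sum(1 for a in enumerate_arg_gly_assignments() if not a.native)
    nulls: list[float] = []
    annotations: list[dict] = []
    for tbl, note in _null_tables(scheme, n, seed):
        lens, enc = _motif_outcomes(caches, tbl, cutoff)
        frac, nm = _fraction(lens, enc, min_motif_len)
        if nm == 0:
            note = dict(note, no_motifs=True)
        nulls.append(frac)
        annotations.append(note)
    return RandomizationResult(
        scheme=scheme,
        native_fraction=native_frac,
        null_fractions=tuple(nulls),
        p_value=empirical_pvalue(native_frac, nulls),
        n=n,
        seed=seed,
        annotations=tuple(annotations),
        extras={"native_n_motifs": native_n},
    )


# ---------------------------------------------------------------------------
# recoding experiment
# ---------------------------------------------------------------------------

_PREDICTORS: dict[str, Callable[..., list[RG4Region]]] = {
    "g4hunter": g4hunter_regions,
    "qgrs": qgrs_scan,
}


def _resolve_predictor(predictor) -> Callable[[str], list[RG4Region]]:
    if callable(predictor):
        return predictor
    try:
        return _PREDICTORS[predictor]
    except KeyError:
        raise ValueError(
            f"unknown predictor {predictor!r}; expected one of {sorted(_PREDICTORS)}"
        ) from None


def _recoding_stats(
    transcripts: Sequence[Transcript],
    seqs: Sequence[str],
    motif_ivs: Sequence[list[tuple[int, int]]],
    predict: Callable[[str], list[RG4Region]],
    cutoff: int,
) -> tuple[float, float, int]:
    """(fraction of motifs encoded, fraction of rG4s coding, rG4 count)."""
    n_motifs = n_encoded = n_rg4 = n_rg4_coding = 0
    for tx, seq, ivs in zip(transcripts, seqs, motif_ivs):
        pred = predict(seq)
        regions = merge_intervals([r.interval for r in pred]) if pred else []
        n_rg4 += len(regions)
        for iv in ivs:
            n_motifs += 1
            if any(overlap_length(iv, r) >= cutoff for r in regions):
                n_encoded += 1
        for r in regions:
            if any(overlap_length(iv, r) >= cutoff for iv in ivs):
                n_rg4_coding += 1
    frac_motifs = n_encoded / n_motifs if n_motifs else 0.0
    frac_rg4 = n_rg4_coding / n_rg4 if n_rg4 else 0.0
    return frac_motifs, frac_rg4, n_rg4


def recoding_experiment(
    transcripts: Sequence[Transcript],
    predictor: str | Callable[[str], list[RG4Region]] = "g4hunter",
    n: int = 1000,
    seed: int | None = 0,
    cutoff: int = DEFAULT_CUTOFF,
) -> RandomizationResult:
    """Synonymous-recoding null: proteins and motifs fixed, mRNA rewritten.

    For every codon permutation, each CDS is recoded (sigma^-1 applied codon
    by codon; UTR flanks fixed), rG4s are re-predicted on the recoded
    transcript, and the fraction of the fixed native motifs partly encoded
    is recorded.  ``extras`` additionally carries, for the native sequence
    and every null draw, the reverse statistic — the fraction of predicted
    rG4s that code for an RGG motif — and the total rG4 count per code.
    """
    predict = _resolve_predictor(predictor)
    motif_ivs: list[list[tuple[int, int]]] = []
    idx_arrays: list[np.ndarray] = []
    for tx in transcripts:
        flank5 = len(tx.utr5_flank)
        motif_ivs.append(
            [
                (flank5 + 3 * m.start, flank5 + 3 * m.end)
                for m in find_rgg_motifs(tx.protein)
            ]
        )
        idx_arrays.append(codon_indices(tx.cds))
    native_seqs = [tx.seq for tx in transcripts]
    native_frac, native_rev, native_count = _recoding_stats(
        transcripts, native_seqs, motif_ivs, predict, cutoff
    )
    codon_strs = np.array([c for c in ALL_CODONS] + ["NNN"])
    nulls, revs, counts = [], [], []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n):
        perm = shuffle_codons(np.random.Generator(np.random.PCG64(child)))
        lut = perm.index_array()
        seqs = []
        for tx, idx in zip(transcripts, idx_arrays):
            body = "".join(codon_strs[lut[idx]])
            # codons containing N were passed through as NNN; restore originals
            if "NNN" in body:
                body = "".join(
                    tx.cds[3 * i : 3 * i + 3] if idx[i] == 64 else codon_strs[lut[idx[i]]]
                    for i in range(len(idx))
                )
            seqs.append(tx.utr5_flank + body + tx.utr3_flank)
        frac, rev, count = _recoding_stats(transcripts, seqs, motif_ivs, predict, cutoff)
        nulls.append(frac)
        revs.append(rev)
        counts.append(count)
    return RandomizationResult(
        scheme="recoding",
        native_fraction=native_frac,
        null_fractions=tuple(nulls),
        p_value=empirical_pvalue(native_frac, nulls),
        n=n,
        seed=seed,
        extras={
            "native_rg4_coding_fraction": native_rev,
            "native_rg4_count": native_count,
            "null_rg4_coding_fractions": tuple(revs),
            "null_rg4_counts": tuple(counts),
        },
    )


def pvalue_length_sweep(
    transcripts: Sequence[Transcript],
    rg4_regions: Mapping[str, Sequence[RG4Region]] | Sequence[RG4Region],
    cutoffs: Sequence[int],
    scheme: str = "codon_shuffle",
    n: int = 1000,
    seed: int | None = 0,
    overlap_cutoff: int = DEFAULT_CUTOFF,
):
    """p-value as a function of the motif-length cutoff.

    The null translations are drawn once (same seed as the unrestricted
    experiment, so the L=0 row reproduces it exactly) and re-thresholded at
    every motif-length cutoff.  Rows where a code produced zero qualifying
    motifs are counted with fraction 0; an empty *native* motif class flags
    the row undefined, and ``all_null_below`` marks rows where no
    randomized code reached the native fraction (p = 0).
    """
    import pandas as pd

    caches = _build_caches(transcripts, rg4_regions)
    native_len, native_enc = _motif_outcomes(
        caches, standard_table().byte_array(), overlap_cutoff
    )
    if scheme == "arg_gly_assignment":
        n = sum(1 for a in enumerate_arg_gly_assignments() if not a.native)
    draws = [
        _motif_outcomes(caches, tbl, overlap_cutoff)
        for tbl, _ in _null_tables(scheme, n, seed)
    ]
    rows = []
    for L in cutoffs:
        native_frac, native_n = _fraction(native_len, native_enc, L)
        nulls = [_fraction(lens, enc, L)[0] for lens, enc in draws]
        defined = native_n > 0
        p = empirical_pvalue(native_frac, nulls) if defined else float("nan")
        rows.append(
            {
                "min_length": L,
                "n_native_motifs": native_n,
                "native_fraction": native_frac if defined else float("nan"),
                "p_value": p,
                "defined": defined,
                "all_null_below": defined and p == 0.0,
            }
        )
    return pd.DataFrame(rows)
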