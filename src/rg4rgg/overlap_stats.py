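"""Overlap between RGG-motif coding sequences and rG4 regions.

The central decision rule: an RGG motif is *partly encoded* by an rG4 if its
coding sequence shares at least ``cutoff`` (default 6) *consecutive*
nucleotides with an rG4 region.  Consecutive means within one merged region
(abutting calls from the same source merge first, so adjacency counts as
consecutive).  Motif coding intervals are compared in transcript space,
i.e. shifted by the 5' flank length; experimental regions extending beyond
the CDS still count where they intersect the motif interval.

The rest of the module computes the descriptive statistics built on that
rule: per-dataset overlap summaries, the motif-length sweep, nucleobase
composition of motif coding sequences and rG4 regions, nucleotide-level
agreement between datasets, the amino acids/tripeptides encoded by rG4s,
and windowed guanine-density vs. residue-preference profile correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import Transcript, standard_table
from .intervals import (
    clip_intervals,
    containment,
    jaccard,
    merge_intervals,
    overlap_length,
    total_length,
)
from .rg4_detect import RG4Region
from .rgg_motifs import RGGMotif, motif_cds_interval

__all__ = [
    "OverlapRecord",
    "classify_motif",
    "overlap_summary",
    "length_sweep",
    "composition",
    "dataset_agreement",
    "rg4_encoded_peptides",
    "profile_correlation",
]

DEFAULT_CUTOFF = 6  # minimum consecutive overlapping nucleotides


@dataclass(frozen=True)
class OverlapRecord:
    """Verdict for one motif against one rG4 dataset."""

    motif: RGGMotif
    source: str
    encoded: bool
    overlap_nt: int
    coverage: float
    max_single_overlap: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage outside [0, 1]")
        if self.overlap_nt > 3 * self.motif.length:
            raise ValueError("overlap exceeds motif coding length")


def motif_tx_interval(m: RGGMotif, flank5: int = 0) -> tuple[int, int]:
    """Motif coding interval shifted into transcript space by the 5' flank."""
    s, e = motif_cds_interval(m)
    return s + flank5, e + flank5


def classify_motif(
    m: RGGMotif,
    regions: Sequence[RG4Region] | Sequence[tuple[int, int]],
    cutoff: int = DEFAULT_CUTOFF,
    flank5: int = 0,
    source: str | None = None,
) -> OverlapRecord:
    """Decide whether one motif is partly encoded by the given rG4 set.

    ``encoded`` is true iff some single merged region overlaps the motif
    coding interval by at least ``cutoff`` consecutive nucleotides.
    ``overlap_nt`` and ``coverage`` are union statistics over all regions.
    """
    ivs = [r.interval if isinstance(r, RG4Region) else tuple(r) for r in regions]
    if source is None:
        srcs = {r.source for r in regions if isinstance(r, RG4Region)}
        source = srcs.pop() if len(srcs) == 1 else ""
    motif_iv = motif_tx_interval(m, flank5)
    merged = merge_intervals(ivs) if ivs else []
    max_single = max((overlap_length(motif_iv, iv) for iv in merged), default=0)
    union_nt = total_length(clip_intervals(merged, motif_iv))
    cds_len = 3 * m.length
    return OverlapRecord(
        motif=m,
        source=source,
        encoded=max_single >= cutoff,
        overlap_nt=union_nt,
        coverage=union_nt / cds_len,
        max_single_overlap=max_single,
    )


def overlap_summary(records: Sequence[OverlapRecord]) -> dict:
    """Encoded-motif summary: counts, percentage and mean +- SD statistics.

    Means and SDs of overlap nucleotides and motif coverage are taken over
    encoded motifs only (absent when none is encoded).
    """
    n = len(records)
    enc = [r for r in records if r.encoded]
    out: dict[str, object] = {
        "n_motifs": n,
        "n_encoded": len(enc),
        "pct_encoded": 100.0 * len(enc) / n if n else float("nan"),
    }
    if enc:
        ov = np.array([r.overlap_nt for r in enc], dtype=float)
        cov = np.array([r.coverage for r in enc], dtype=float)
        out.update(
            mean_overlap_nt=float(ov.mean()),
            sd_overlap_nt=float(ov.std(ddof=1)) if len(enc) > 1 else 0.0,
            mean_coverage=float(cov.mean()),
            sd_coverage=float(cov.std(ddof=1)) if len(enc) > 1 else 0.0,
        )
    else:
        out.update(
            mean_overlap_nt=None, sd_overlap_nt=None,
            mean_coverage=None, sd_coverage=None,
        )
    return out


def length_sweep(
    records: Sequence[OverlapRecord], cutoffs: Sequence[int]
) -> pd.DataFrame:
    """Percentage of motifs encoded among motifs of length >= L, per L."""
    rows = []
    for L in cutoffs:
        sub = [r for r in records if r.motif.length >= L]
        enc = sum(r.encoded for r in sub)
        rows.append(
            {
                "min_length": L,
                "n_motifs": len(sub),
                "n_encoded": enc,
                "pct_encoded": 100.0 * enc / len(sub) if sub else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _base_fractions(seq: str) -> dict[str, float]:
    n = len(seq)
    # transcript-space sequences are stored in the DNA alphabet; report U
    return {
        "A": seq.count("A") / n,
        "C": seq.count("C") / n,
        "G": seq.count("G") / n,
        "U": seq.count("T") / n,
    }


def composition(
    intervals_by_tx: Mapping[str, Sequence[tuple[int, int]]],
    transcripts: Mapping[str, Transcript],
    per_gene: bool = True,
) -> pd.DataFrame:
    """Nucleobase content of interval sets (transcript-space coordinates).

    ``per_gene=True``: fractions computed per transcript, reported as mean
    and SD across transcripts (the convention for motif coding sequences).
    ``per_gene=False``: fractions pooled over all interval nucleotides
    (the convention for rG4 region sets).  Rows sum to 1 within the mean
    columns.
    """
    per_tx: list[dict[str, float]] = []
    pooled = []
    for tx_id, ivs in intervals_by_tx.items():
        if not ivs:
            continue
        seq = transcripts[tx_id].seq
        chunks = "".join(seq[s:e] for s, e in merge_intervals(ivs))
        if not chunks:
            continue
        pooled.append(chunks)
        per_tx.append(_base_fractions(chunks))
    if not pooled:
        raise ValueError("no interval nucleotides to summarize")
    if per_gene:
        df = pd.DataFrame(per_tx)
        out = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1).fillna(0.0)})
    else:
        fr = _base_fractions("".join(pooled))
        out = pd.DataFrame({"mean": pd.Series(fr), "sd": 0.0})
    out.index.name = "base"
    return out


def dataset_agreement(
    region_sets: Mapping[str, Sequence[RG4Region]],
    restrict_to: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Pairwise nucleotide-level agreement between rG4 datasets.

    Emits the symmetric Jaccard index plus both asymmetric containment
    fractions for every ordered pair of sources.  ``restrict_to`` (e.g. the
    RGG-motif coding intervals per transcript) limits every dataset to
    those nucleotides first.
    """
    by_src: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for src, regions in region_sets.items():
        d: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            d.setdefault(r.transcript_id, []).append(r.interval)
        if restrict_to is not None:
            d = {
                tx: clip_ivs
                for tx, ivs in d.items()
                if (clip_ivs := _restrict(ivs, restrict_to.get(tx, [])))
            }
        by_src[src] = d
    rows = []
    labels = list(region_sets)
    for a in labels:
        for b in labels:
            if a >= b:
                continue
            txs = set(by_src[a]) | set(by_src[b])
            flat_a = [
                (off + s, off + e)
                for off, tx in _tx_offsets(txs, by_src)
                for s, e in by_src[a].get(tx, [])
            ]
            flat_b = [
                (off + s, off + e)
                for off, tx in _tx_offsets(txs, by_src)
                for s, e in by_src[b].get(tx, [])
            ]
            rows.append(
                {
                    "source_a": a,
                    "source_b": b,
                    "jaccard": jaccard(flat_a, flat_b),
                    "frac_a_in_b": containment(flat_a, flat_b),
                    "frac_b_in_a": containment(flat_b, flat_a),
                }
            )
    return pd.DataFrame(rows)


def _restrict(
    ivs: Sequence[tuple[int, int]], mask: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    if not mask:
        return []
    out = []
    for m in merge_intervals(mask):
        out.extend(clip_intervals(ivs, m))
    return merge_intervals(out) if out else []


def _tx_offsets(txs, by_src):
    """Disjoint coordinate offsets so per-transcript intervals never collide."""
    offsets = []
    off = 0
    for tx in sorted(txs):
        offsets.append((off, tx))
        hi = max(
            (e for d in by_src.values() for _, e in d.get(tx, [])),
            default=0,
        )
        off += hi + 1
    return offsets


def rg4_encoded_peptides(
    regions: Sequence[RG4Region],
    transcripts: Mapping[str, Transcript],
) -> tuple[pd.Series, pd.Series]:
    """Amino-acid and overlapping-tripeptide tallies of rG4-encoded peptides.

    For each region, the codons lying *fully inside* the region (reading
    frame taken from the CDS) are translated; partial codons at region
    boundaries are trimmed.  Regions covering fewer than one full in-frame
    codon contribute nothing; tripeptides are counted with overlap within
    each region's contiguous peptide.
    """
    aa_counts: dict[str, int] = {}
    tri_counts: dict[str, int] = {}
    table = standard_table()
    for r in regions:
        tx = transcripts[r.transcript_id]
        cds_s, cds_e = tx.cds_span
        s = max(r.start, cds_s) - cds_s
        e = min(r.end, cds_e) - cds_s
        if e <= s:
            continue
        first = -(-s // 3)  # ceil: first codon fully inside
        last = e // 3  # exclusive
        if last <= first:
            continue
        frag = tx.cds[3 * first : 3 * last]
        pep = "".join(
            table.mapping.get(frag[i : i + 3], "X") for i in range(0, len(frag), 3)
        )
        for aa in pep:
            if aa not in ("*", "X"):
                aa_counts[aa] = aa_counts.get(aa, 0) + 1
        for i in range(len(pep) - 2):
            tri = pep[i : i + 3]
            if "*" not in tri and "X" not in tri:
                tri_counts[tri] = tri_counts.get(tri, 0) + 1
    return (
        pd.Series(aa_counts, dtype=int).sort_index(),
        pd.Series(tri_counts, dtype=int).sort_index(),
    )


def profile_correlation(
    cds: str,
    protein: str,
    scale: Mapping[str, float],
    window: int = 21,
) -> dict:
    """Correlate per-residue CDS guanine density with a residue preference.

    The guanine-density profile at residue i is the fraction of G among the
    nucleotides of the codons in a ``window``-residue window centred on i
    (clipped at the termini); the preference profile is the window mean of
    the supplied per-residue scale.  Returns the two profiles and their
    Pearson r (None when either profile is constant).

    With an affinity-like scale where lower values mean stronger guanine
    preference, matching profiles yield *negative* r.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    missing = set(protein) - set(scale) - {"*", "X"}
    if missing:
        raise ValueError(f"scale is missing residues: {sorted(missing)}")
    n = len(protein)
    if len(cds) < 3 * n:
        raise ValueError("CDS shorter than 3x protein length")
    g_per_codon = np.array(
        [cds[3 * i : 3 * i + 3].upper().replace("U", "T").count("G") for i in range(n)],
        dtype=float,
    )
    pref = np.array([scale.get(aa, np.nan) for aa in protein], dtype=float)
    half = window // 2
    dens_prof = np.empty(n)
    pref_prof = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        dens_prof[i] = g_per_codon[lo:hi].mean() / 3.0
        pref_prof[i] = np.nanmean(pref[lo:hi])
    valid = ~np.isnan(pref_prof)
    r = None
    if valid.sum() >= 3 and np.std(dens_prof[valid]) > 0 and np.std(pref_prof[valid]) > 0:
        r = float(stats.pearsonr(dens_prof[valid], pref_prof[valid])[0])
    return {
        "g_density": dens_prof,
        "preference": pref_prof,
        "pearson_r": r,
        "n": int(valid.sum()),
    }
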