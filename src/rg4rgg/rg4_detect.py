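"""rG4 region assignment: native predictors, experimental-call ingestion,
RT-stop expansion, and multi-sample consensus.

Every route produces :class:`RG4Region` records in transcript coordinates
(0-based, half-open, with UTR flanks included in the coordinate system).
Regions from a single (transcript, source) pair are non-overlapping after
merging.

Two predictors are implemented natively:

* a G4Hunter-style run-length scorer — every G in a maximal G-run of length
  ``k`` scores ``min(k, 4)`` and every C scores the negative of the same
  rule; windows whose mean reaches a threshold (default 1.2) are merged and
  trimmed to start and end on a G;
* a QGRS-style scanner — enumerates four G-tracts of at least ``min_tract``
  consecutive guanines separated by three loops, within a maximum total
  length, scores candidates by a G-score that rewards more tetrads, shorter
  loops and more even loops, and resolves overlaps greedily by score.

Experimental calls arrive as BED intervals, RT-stop positions are expanded
to the 60 nucleotides upstream of each stop, and per-sample call sets are
reduced to nucleotide-level consensus (positions supported by at least
``min_samples`` samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .intervals import merge_intervals

__all__ = [
    "RG4Region",
    "g4hunter_profile",
    "g4hunter_regions",
    "qgrs_gscore",
    "qgrs_scan",
    "rtstop_to_regions",
    "consensus_regions",
    "ingest_bed",
    "write_bed",
    "merge_regions",
]

RT_STOP_UPSTREAM = 60  # nt upstream of an RT stop taken as the rG4 region


@dataclass(frozen=True)
class RG4Region:
    """One non-overlapping rG4 interval in transcript coordinates."""

    transcript_id: str
    start: int
    end: int
    source: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError(f"negative coordinate {self.start}")

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    def __len__(self) -> int:
        return self.end - self.start


def merge_regions(regions: Iterable[RG4Region]) -> list[RG4Region]:
    """Merge overlapping/abutting regions per (transcript, source).

    The merged region keeps the maximum score of its members (None if all
    are unscored).
    """
    by_key: dict[tuple[str, str], list[RG4Region]] = {}
    for r in regions:
        by_key.setdefault((r.transcript_id, r.source), []).append(r)
    out: list[RG4Region] = []
    for (tx, src), group in sorted(by_key.items()):
        group.sort(key=lambda r: (r.start, r.end))
        cur = group[0]
        cur_s, cur_e, cur_score = cur.start, cur.end, cur.score
        for r in group[1:]:
            if r.start <= cur_e:
                cur_e = max(cur_e, r.end)
                if r.score is not None:
                    cur_score = r.score if cur_score is None else max(cur_score, r.score)
            else:
                out.append(RG4Region(tx, cur_s, cur_e, src, cur_score))
                cur_s, cur_e, cur_score = r.start, r.end, r.score
        out.append(RG4Region(tx, cur_s, cur_e, src, cur_score))
    return out


# ---------------------------------------------------------------------------
# G4Hunter-style predictor
# ---------------------------------------------------------------------------

def g4hunter_profile(seq: str) -> np.ndarray:
    """Per-base run-length score: +min(k,4) in G-runs, -min(k,4) in C-runs."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    prof = np.zeros(n, dtype=float)
    i = 0
    while i < n:
        ch = seq[i]
        j = i
        while j < n and seq[j] == ch:
            j += 1
        if ch == "G":
            prof[i:j] = min(j - i, 4)
        elif ch == "C":
            prof[i:j] = -min(j - i, 4)
        i = j
    return prof


def g4hunter_regions(
    seq: str,
    window: int = 25,
    threshold: float = 1.2,
    transcript_id: str = "",
    source: str = "g4hunter",
) -> list[RG4Region]:
    """Windows with mean score >= threshold, merged and trimmed to G bounds.

    Only the positive (G-side) strand is scored: rG4s fold on the given mRNA
    strand.  A sequence shorter than the window is treated as one window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = seq.upper().replace("U", "T")
    prof = g4hunter_profile(seq)
    n = len(seq)
    if n == 0:
        return []
    w = min(window, n)
    csum = np.concatenate([[0.0], np.cumsum(prof)])
    means = (csum[w:] - csum[:-w]) / w
    hits = np.nonzero(means >= threshold)[0]
    if hits.size == 0:
        return []
    spans = merge_intervals([(int(i), int(i) + w) for i in hits])
    out = []
    for s, e in spans:
        # refine: region must begin and end on a guanine
        while s < e and seq[s] != "G":
            s += 1
        while e > s and seq[e - 1] != "G":
            e -= 1
        if e <= s:
            continue
        win_in = hits[(hits < e) & (hits + w > s)]  # windows overlapping region
        score = float(means[win_in].max()) if win_in.size else float(means.max())
        out.append(RG4Region(transcript_id, s, e, source, score))
    return out


# ---------------------------------------------------------------------------
# QGRS-style predictor
# ---------------------------------------------------------------------------

def qgrs_gscore(tracts: int, loops: Sequence[int]) -> float:
    """G-score of a four-tract candidate.

    Monotone in the three properties that define quadruplex-forming
    potential: more stacked tetrads score higher (dominant term), shorter
    loops score higher, and for a fixed total loop length, evenly sized
    loops score at least as high as uneven ones.
    """
    if len(loops) != 3:
        raise ValueError("a quadruplex candidate has exactly 3 loops")
    mean_loop = sum(loops) / 3
    unevenness = sum(abs(l - mean_loop) for l in loops) / 3
    return 13.0 * tracts - mean_loop - unevenness


def _g_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _qgrs_candidates(
    seq: str, max_len: int, min_tract: int
) -> list[tuple[float, int, int, int]]:
    """All (score, start, end, tracts) candidates G_x N G_x N G_x N G_x.

    Tracts have equal length x >= min_tract; loops are >= 0 with at most one
    zero-length loop; total length <= max_len.
    """
    seq = seq.upper().replace("U", "T")
    runs = _g_runs(seq)
    cands: list[tuple[float, int, int, int]] = []
    max_x = max_len // 4
    for x in range(min_tract, max_x + 1):
        # all start positions of >= x consecutive G's
        starts = [p for (a, b) in runs for p in range(a, b - x + 1)]
        m = len(starts)
        for i1 in range(m):
            s1 = starts[i1]
            lim = s1 + max_len  # candidate must end by here
            for i2 in range(i1 + 1, m):
                s2 = starts[i2]
                if s2 < s1 + x:
                    continue
                if s2 + 3 * x > lim:
                    break
                l1 = s2 - (s1 + x)
                for i3 in range(i2 + 1, m):
                    s3 = starts[i3]
                    if s3 < s2 + x:
                        continue
                    if s3 + 2 * x > lim:
                        break
                    l2 = s3 - (s2 + x)
                    if l1 == 0 and l2 == 0:
                        continue
                    for i4 in range(i3 + 1, m):
                        s4 = starts[i4]
                        if s4 < s3 + x:
                            continue
                        if s4 + x > lim:
                            break
                        l3 = s4 - (s3 + x)
                        zeros = (l1 == 0) + (l2 == 0) + (l3 == 0)
                        if zeros > 1:
                            continue
                        score = qgrs_gscore(x, (l1, l2, l3))
                        cands.append((score, s1, s4 + x, x))
    return cands


def qgrs_scan(
    seq: str,
    max_len: int = 30,
    min_tract: int = 2,
    threshold: float = 19.0,
    transcript_id: str = "",
    source: str = "qgrs",
) -> list[RG4Region]:
    """Non-overlapping QGRS candidates with G-score >= threshold.

    Overlaps are resolved greedily by descending score; ties go to the
    leftmost, then the shortest candidate.
    """
    if max_len < 4 * min_tract:
        raise ValueError("max_len must allow four tracts of min_tract G's")
    cands = [c for c in _qgrs_candidates(seq, max_len, min_tract) if c[0] >= threshold]
    cands.sort(key=lambda c: (-c[0], c[1], c[2] - c[1]))
    chosen: list[tuple[float, int, int]] = []
    for score, s, e, _x in cands:
        if all(e <= cs or s >= ce for _, cs, ce in chosen):
            chosen.append((score, s, e))
    chosen.sort(key=lambda c: c[1])
    return [RG4Region(transcript_id, s, e, source, score) for score, s, e in chosen]


# ---------------------------------------------------------------------------
# Experimental routes
# ---------------------------------------------------------------------------

def rtstop_to_regions(
    stops: Iterable[int],
    seq_len: int,
    transcript_id: str = "",
    source: str = "rtstop",
    upstream: int = RT_STOP_UPSTREAM,
) -> list[RG4Region]:
    """Expand RT-stop positions to upstream windows and merge.

    Each stop at position p yields [max(0, p - upstream), p): the stalled
    reverse transcriptase sits just 3' of the structure, so the region
    upstream of the stop is taken as the rG4 region (stop position itself
    excluded).  Out-of-bounds stops are skipped with a warning.
    """
    ivs = []
    for p in stops:
        p = int(p)
        if p <= 0 or p > seq_len:
            warnings.warn(
                f"{transcript_id}: RT stop {p} outside transcript (len {seq_len}); skipped",
                stacklevel=2,
            )
            continue
        ivs.append((max(0, p - upstream), p))
    if not ivs:
        return []
    return [
        RG4Region(transcript_id, s, e, source) for s, e in merge_intervals(ivs)
    ]


def consensus_regions(
    per_sample: Sequence[Sequence[RG4Region]],
    min_samples: int = 2,
    transcript_id: str | None = None,
    source: str = "consensus",
) -> list[RG4Region]:
    """Nucleotide-level consensus across samples of one transcript.

    Keeps maximal runs of positions supported by at least ``min_samples``
    of the given per-sample region lists.
    """
    if len(per_sample) < min_samples:
        raise ValueError("need at least min_samples sample lists")
    ivs = [r.interval for regions in per_sample for r in regions]
    if transcript_id is None:
        tx_ids = {r.transcript_id for regions in per_sample for r in regions}
        if len(tx_ids) > 1:
            raise ValueError("regions from multiple transcripts; pass transcript_id")
        transcript_id = tx_ids.pop() if tx_ids else ""
    if not ivs:
        return []
    hi = max(e for _, e in ivs)
    depth = np.zeros(hi + 1, dtype=np.int32)
    for regions in per_sample:
        # count each sample at most once per position
        for s, e in merge_intervals([r.interval for r in regions]) if regions else []:
            depth[s] += 1
            depth[e] -= 1
    cov = np.cumsum(depth)[:-1] >= min_samples
    out = []
    diff = np.diff(np.concatenate([[0], cov.view(np.int8), [0]]))
    for s, e in zip(np.nonzero(diff == 1)[0], np.nonzero(diff == -1)[0]):
        out.append(RG4Region(transcript_id, int(s), int(e), source))
    return out


def ingest_bed(path, source_label: str) -> list[RG4Region]:
    """Read BED3+ interval calls (transcript space, 0-based half-open).

    Lines are validated (malformed lines and end <= start raise with the
    offending line number); intervals are merged per transcript and labeled
    with ``source_label``.  Column 5, if present and numeric, is kept as the
    score.
    """
    raw: list[RG4Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            tx = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate {start}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
            score = None
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            raw.append(RG4Region(tx, start, end, source_label, score))
    return merge_regions(raw)


def write_bed(regions: Iterable[RG4Region], path) -> None:
    """Write regions as BED (name column = source, score column if present)."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.transcript_id, r.start)):
            score = "." if r.score is None else f"{r.score:g}"
            fh.write(f"{r.transcript_id}\t{r.start}\t{r.end}\t{r.source}\t{score}\n")
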