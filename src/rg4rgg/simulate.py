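"""Synthetic transcriptomes with known rG4/RGG ground truth.

The generator emulates the data the pipeline consumes in the real analysis:
protein-coding transcripts with UTR flanks, planted RGG motifs whose
synonymous codon choices carry a tunable guanine bias, planted
quadruplex-forming G-tracts, noisy experimental-style interval calls and
RT-stop positions derived from the planted truth, and per-sample expression
tables — all deterministic given the seed, so every pipeline stage can be
tested without downloads.

Two placement modes control the planted association:

``association``
    planted rG4 intervals lie inside motif coding spans (the coding
    relationship exists by construction; with ``g_bias`` near 1 the motif
    codons are the guanine-richest synonyms, so native predictors find the
    tracts too);
``null``
    planted tracts are placed in motif-free spans only; any overlap with
    motifs then comes from the false-call noise, which is placed uniformly
    and independently of the motifs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    AMINO_ACIDS,
    SENSE_CODONS,
    Transcript,
    standard_table,
    translate,
)
from .intervals import merge_intervals, overlap_length
from .rg4_detect import RG4Region

__all__ = ["SimConfig", "TruthMotif", "TruthManifest", "SimResult", "generate", "expression_table"]

# residues used for linkers and motif-buffer zones: never R or G, so planted
# motifs are re-detected at exactly their planted coordinates
_NEUTRAL = "ASTPLFYNQDEHIKV"

#: sample layout mirroring the two experimental designs the filters expect
CPM_SAMPLES = ("Li_1", "Li_2", "K_1", "K_2", "KPDS_1", "KPDS_2")
TPM_SAMPLES = ("HEK_K", "HEK_Na", "HeLa_K", "HeLa_Na")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic transcriptome."""

    n_transcripts: int = 100
    cds_len_mean: float = 300.0  # codons
    cds_len_sd: float = 100.0
    cds_len_min: int = 60
    motif_rate: float = 1.0  # mean planted motifs per transcript (Poisson)
    motif_len_median: int = 7  # geometric tail above the grammar minimum 4
    motif_len_max: int = 52
    g_bias: float = 0.0  # P(motif codon = guanine-richest synonym)
    rg4_mode: str = "association"  # or "null"
    planted_rg4_rate: float = 0.8  # association: P(motif carries a planted rG4)
    null_rg4_per_transcript: float = 1.0  # null mode: mean planted tracts
    rg4_tetrads: int = 3
    rg4_loop_max: int = 4
    background: str = "uniform_aa"  # or "uniform_codon" (iid sense codons)
    sensitivity: float = 0.9  # P(planted rG4 reported by a mock dataset)
    false_call_rate_per_kb: float = 0.1
    jitter_sd: float = 0.0  # boundary jitter, nt
    n_datasets: int = 2
    flank_len: int = 50
    expression_fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "g_bias",
            "planted_rg4_rate",
            "sensitivity",
            "expression_fail_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.motif_len_median < 4:
            raise ValueError("motif length support starts at the grammar minimum 4")
        if self.rg4_mode not in ("association", "null"):
            raise ValueError(f"unknown rg4_mode {self.rg4_mode!r}")
        if self.background not in ("uniform_aa", "uniform_codon"):
            raise ValueError(f"unknown background {self.background!r}")
        if self.cds_len_min < 20:
            raise ValueError("cds_len_min too small to host motifs with buffers")


@dataclass(frozen=True)
class TruthMotif:
    """One planted motif: protein coordinates, sequence, and expectation."""

    transcript_id: str
    aa_start: int
    aa_end: int
    protein_seq: str
    rg4_interval: tuple[int, int] | None  # transcript space
    expected_encoded: bool


@dataclass
class TruthManifest:
    motifs: list[TruthMotif]
    planted_rg4: dict[str, list[tuple[int, int]]]  # tx id -> transcript-space
    expression_failed: dict[str, list[str]]  # filter name -> gene ids

    def to_json(self, path) -> None:
        payload = {
            "motifs": [asdict(m) for m in self.motifs],
            "planted_rg4": self.planted_rg4,
            "expression_failed": self.expression_failed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SimResult:
    config: SimConfig
    transcripts: list[Transcript]
    truth: TruthManifest
    datasets: dict[str, list[RG4Region]]  # mock experimental interval calls
    rtstops: dict[str, list[int]]  # tx id -> stop positions
    expression_cpm: pd.DataFrame
    expression_tpm: pd.DataFrame


_CODONS_BY_AA = {aa: standard_table().codons_for(aa) for aa in AMINO_ACIDS}
#: guanine-richest synonyms per amino acid (all ties kept: CGG and AGG for R)
_MAX_G_BY_AA = {
    aa: tuple(c for c in cods if c.count("G") == max(x.count("G") for x in cods))
    for aa, cods in _CODONS_BY_AA.items()
}
_AA_OF_SENSE = tuple(standard_table().mapping[c] for c in SENSE_CODONS)


def _sample_codon(aa: str, rng: np.random.Generator, g_biased: bool) -> str:
    codons = _MAX_G_BY_AA[aa] if g_biased else _CODONS_BY_AA[aa]
    return codons[rng.integers(len(codons))]


def _motif_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    # geometric above the minimum 4 with the configured median; mimics the
    # observed abundance of short motifs
    p = 1.0 - 0.5 ** (1.0 / max(cfg.motif_len_median - 4 + 1, 1))
    L = 4 + rng.geometric(p) - 1
    return int(min(L, cfg.motif_len_max))


def _motif_protein(L: int, rng: np.random.Generator) -> str:
    """Random protein string of exactly L residues matching the motif grammar."""
    while True:
        parts = ["RGG" if (L > 5 and rng.random() < 0.5) else "RG"]
        used = len(parts[0])
        n_units = 1
        while used < L:
            rem = L - used
            choices = []
            for unit in ("RG", "RGG"):
                for lk in range(0, 5):
                    tail = rem - lk - len(unit)
                    if tail == 0 or tail >= 2:
                        if lk + len(unit) <= rem:
                            choices.append((lk, unit))
            if not choices:
                break
            lk, unit = choices[rng.integers(len(choices))]
            linker = "".join(
                _NEUTRAL[rng.integers(len(_NEUTRAL))] for _ in range(lk)
            )
            parts.append(linker + unit)
            used += lk + len(unit)
            n_units += 1
        if used == L and n_units >= 2:
            return "".join(parts)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _g_tract(cfg: SimConfig, rng: np.random.Generator) -> str:
    t = cfg.rg4_tetrads
    loops = [int(rng.integers(1, cfg.rg4_loop_max + 1)) for _ in range(3)]
    seq = "G" * t
    for lk in loops:
        seq += "".join("ACT"[i] for i in rng.integers(3, size=lk)) + "G" * t
    return seq


def generate(config: SimConfig) -> SimResult:
    """Build one synthetic transcriptome bundle (deterministic given seed)."""
    rng = np.random.default_rng(config.seed)
    transcripts: list[Transcript] = []
    truth_motifs: list[TruthMotif] = []
    planted_rg4: dict[str, list[tuple[int, int]]] = {}
    buffer = 6  # non-R/G residues around each planted motif

    for k in range(config.n_transcripts):
        tx_id = f"tx{k:04d}"
        n_codons = int(
            max(
                config.cds_len_min,
                round(rng.normal(config.cds_len_mean, config.cds_len_sd)),
            )
        )
        # background: either a uniform residue alphabet with uniform
        # synonymous codons, or iid uniform sense codons (the latter makes
        # the sequence law invariant under any relabeling of the code)
        if config.background == "uniform_codon":
            bg_idx = rng.integers(len(SENSE_CODONS), size=n_codons)
            bg_codons: list[str | None] = [SENSE_CODONS[i] for i in bg_idx]
            protein = [_AA_OF_SENSE[i] for i in bg_idx]
        else:
            bg_codons = [None] * n_codons
            protein = list(
                AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=n_codons)
            )
        # plant motifs in non-overlapping slots with buffer zones
        n_motifs = int(rng.poisson(config.motif_rate))
        placed: list[tuple[int, int, str]] = []
        for _ in range(n_motifs):
            L = _motif_length(config, rng)
            if L + 2 * buffer >= n_codons:
                continue
            for _attempt in range(30):
                s = int(rng.integers(buffer, n_codons - L - buffer))
                if all(
                    s + L + buffer <= ps or s >= pe + buffer
                    for ps, pe, _ in placed
                ):
                    placed.append((s, s + L, _motif_protein(L, rng)))
                    break
        placed.sort()
        g_biased_res: set[int] = set()
        touched: set[int] = set()
        for s, e, mot in placed:
            protein[s:e] = list(mot)
            touched.update(range(max(0, s - buffer), min(n_codons, e + buffer)))
            for i in range(max(0, s - buffer), s):
                protein[i] = _NEUTRAL[rng.integers(len(_NEUTRAL))]
            for i in range(e, min(n_codons, e + buffer)):
                protein[i] = _NEUTRAL[rng.integers(len(_NEUTRAL))]
            for i in range(s, e):
                if rng.random() < config.g_bias:
                    g_biased_res.add(i)
        cds = "".join(
            bg_codons[i]
            if bg_codons[i] is not None and i not in touched
            else _sample_codon(aa, rng, i in g_biased_res)
            for i, aa in enumerate(protein)
        ) + ("TAA", "TAG", "TGA")[rng.integers(3)]
        flank5 = _random_nt(config.flank_len, rng)
        flank3 = _random_nt(config.flank_len, rng)
        tx = Transcript(id=tx_id, cds=cds, utr5_flank=flank5, utr3_flank=flank3)
        transcripts.append(tx)

        # plant rG4 intervals (transcript space)
        tx_rg4: list[tuple[int, int]] = []
        f5 = len(flank5)
        if config.rg4_mode == "association":
            for s, e, mot in placed:
                rg4_iv = None
                if rng.random() < config.planted_rg4_rate:
                    span = (f5 + 3 * s, f5 + 3 * e)
                    span_len = span[1] - span[0]
                    cov = rng.uniform(0.6, 1.0)
                    ln = max(6, int(round(cov * span_len)))
                    off = int(rng.integers(0, span_len - ln + 1))
                    rg4_iv = (span[0] + off, span[0] + off + ln)
                    tx_rg4.append(rg4_iv)
                truth_motifs.append(
                    TruthMotif(
                        tx_id, s, e, mot, rg4_iv, expected_encoded=rg4_iv is not None
                    )
                )
        else:  # null mode: tracts only in motif-free spans
            for s, e, mot in placed:
                truth_motifs.append(
                    TruthMotif(tx_id, s, e, mot, None, expected_encoded=False)
                )
            n_tracts = int(rng.poisson(config.null_rg4_per_transcript))
            motif_nt = [
                (f5 + 3 * s - buffer, f5 + 3 * e + buffer) for s, e, _ in placed
            ]
            tract = _g_tract(config, rng)
            total = len(tx.seq)
            for _ in range(n_tracts):
                for _attempt in range(30):
                    s0 = int(rng.integers(0, total - len(tract)))
                    iv = (s0, s0 + len(tract))
                    if all(overlap_length(iv, miv) == 0 for miv in motif_nt):
                        tx_rg4.append(iv)
                        break
        if tx_rg4:
            planted_rg4[tx_id] = merge_intervals(tx_rg4)

    # mock experimental datasets: independent noise per dataset
    datasets: dict[str, list[RG4Region]] = {}
    rtstops: dict[str, list[int]] = {}
    for d in range(config.n_datasets):
        label = f"mock{d + 1}"
        calls: list[RG4Region] = []
        for tx in transcripts:
            total = len(tx.seq)
            for s, e in planted_rg4.get(tx.id, []):
                if rng.random() >= config.sensitivity:
                    continue
                if config.jitter_sd > 0:
                    s = int(round(s + rng.normal(0, config.jitter_sd)))
                    e = int(round(e + rng.normal(0, config.jitter_sd)))
                s, e = max(0, s), min(total, e)
                if e - s >= 1:
                    calls.append(RG4Region(tx.id, s, e, label))
            n_false = rng.poisson(config.false_call_rate_per_kb * total / 1000.0)
            for _ in range(int(n_false)):
                ln = int(rng.integers(15, 41))
                s0 = int(rng.integers(0, max(1, total - ln)))
                calls.append(RG4Region(tx.id, s0, s0 + ln, label))
        from .rg4_detect import merge_regions

        datasets[label] = merge_regions(calls)
        if d == 0:
            # RT-stop mock: the polymerase stalls at the 3' end of each call
            for r in datasets[label]:
                rtstops.setdefault(r.transcript_id, []).append(r.end)

    cpm, tpm, failed = _expression_frames(config, [t.id for t in transcripts], rng)
    truth = TruthManifest(
        motifs=truth_motifs, planted_rg4=planted_rg4, expression_failed=failed
    )
    return SimResult(
        config=config,
        transcripts=transcripts,
        truth=truth,
        datasets=datasets,
        rtstops=rtstops,
        expression_cpm=cpm,
        expression_tpm=tpm,
    )


def _expression_frames(
    config: SimConfig, genes: Sequence[str], rng: np.random.Generator
):
    n = len(genes)
    fail = rng.random(n) < config.expression_fail_fraction
    cpm = pd.DataFrame(
        rng.lognormal(mean=2.0, sigma=1.0, size=(n, len(CPM_SAMPLES))),
        index=genes,
        columns=list(CPM_SAMPLES),
    )
    tpm = pd.DataFrame(
        rng.lognormal(mean=1.5, sigma=1.0, size=(n, len(TPM_SAMPLES))),
        index=genes,
        columns=list(TPM_SAMPLES),
    )
    cpm[fail] = 0.0
    tpm[fail] = 0.0
    failed = {
        "cpm": [g for g, f in zip(genes, fail) if f],
        "tpm": [g for g, f in zip(genes, fail) if f],
    }
    cpm.index.name = "gene"
    tpm.index.name = "gene"
    return cpm, tpm, failed


def expression_table(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Stand-alone expression tables (CPM and TPM) plus failure truth."""
    rng = np.random.default_rng(config.seed + 7)
    genes = [f"tx{k:04d}" for k in range(config.n_transcripts)]
    return _expression_frames(config, genes, rng)


def write_bundle(result: SimResult, outdir) -> dict[str, Path]:
    """Serialize a bundle in the dialects the pipeline consumes.

    FASTA for transcript and protein sequences, a CDS-coordinate annotation
    TSV, BED per mock dataset, RT-stop TSV, expression TSVs, and the truth
    manifest as JSON.  Returns the path of each artifact.
    """
    from .io import write_fasta
    from .rg4_detect import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["transcripts"] = outdir / "transcripts.fasta"
    write_fasta(
        ((tx.id, tx.seq) for tx in result.transcripts), paths["transcripts"]
    )
    paths["proteins"] = outdir / "proteins.fasta"
    write_fasta(((tx.id, tx.protein) for tx in result.transcripts), paths["proteins"])
    paths["annotation"] = outdir / "cds_coords.tsv"
    with open(paths["annotation"], "w") as fh:
        fh.write("transcript_id\tcds_start\tcds_end\n")
        for tx in result.transcripts:
            s, e = tx.cds_span
            fh.write(f"{tx.id}\t{s}\t{e}\n")
    for label, regions in result.datasets.items():
        paths[label] = outdir / f"{label}.bed"
        write_bed(regions, paths[label])
    paths["rtstops"] = outdir / "rtstops.tsv"
    with open(paths["rtstops"], "w") as fh:
        fh.write("transcript_id\tposition\n")
        for tx_id in sorted(result.rtstops):
            for p in result.rtstops[tx_id]:
                fh.write(f"{tx_id}\t{p}\n")
    paths["cpm"] = outdir / "expression_cpm.tsv"
    result.expression_cpm.to_csv(paths["cpm"], sep="\t")
    paths["tpm"] = outdir / "expression_tpm.tsv"
    result.expression_tpm.to_csv(paths["tpm"], sep="\t")
    paths["truth"] = outdir / "truth.json"
    result.truth.to_json(paths["truth"])
    return paths
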