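"""End-to-end orchestration: expression filters, dataset assembly, reports.

A run is described by a :class:`RunConfig` (usually loaded from YAML):
transcript inputs, a list of rG4 dataset descriptors (each ``predicted``,
``bed`` or ``rtstop``), the overlap cutoff, predictor thresholds, optional
expression filters and an optional randomization block.  :func:`run` executes
the whole analysis and writes per-dataset TSV report tables plus a JSON log
with seeds and versions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .genetic_code import Transcript
from .intervals import overlap_length
from .io import read_expression, read_rtstops, read_transcripts
from .overlap_stats import (
    OverlapRecord,
    classify_motif,
    composition,
    dataset_agreement,
    length_sweep,
    motif_tx_interval,
    overlap_summary,
)
from .rg4_detect import (
    RG4Region,
    g4hunter_regions,
    ingest_bed,
    merge_regions,
    qgrs_scan,
    rtstop_to_regions,
)
from .rgg_motifs import RGGMotif, find_rgg_motifs, motif_features
from .randomization import recoding_experiment, translation_experiment

log = logging.getLogger("rg4rgg")

__all__ = [
    "DatasetSpec",
    "RunConfig",
    "filter_cpm",
    "filter_tpm",
    "annotate_intervals",
    "detect_all_motifs",
    "assemble_dataset",
    "run",
]

#: default condition groups for the CPM filter (sample-name prefixes)
CPM_GROUPS = {"Li": ("Li",), "K": ("K_",), "KPDS": ("KPDS",)}

#: default cell-line layout for the TPM filter: line -> (K+ column, Na+ column)
TPM_CELL_LINES = {"HEK": ("HEK_K", "HEK_Na"), "HeLa": ("HeLa_K", "HeLa_Na")}


# ---------------------------------------------------------------------------
# expression filters
# ---------------------------------------------------------------------------

def _group_columns(columns: Sequence[str], prefixes: Sequence[str]) -> list[str]:
    return [c for c in columns if any(c.startswith(p) for p in prefixes)]


def filter_cpm(
    table: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    condition_groups: Mapping[str, Sequence[str]] | None = None,
    grouped: bool = True,
) -> set[str]:
    """Genes expressed in the stalling assay's libraries.

    A gene is kept iff at least ``min_samples`` samples reach ``min_cpm``
    and — under the default grouped reading — the qualifying samples cover
    the less-stabilizing (Li+) condition and at least one of the
    stabilizing conditions (K+ or K+ + PDS).  ``grouped=False`` relaxes the
    rule to the plain any-two-samples reading.
    """
    groups = condition_groups or CPM_GROUPS
    ok = table >= min_cpm
    enough = ok.sum(axis=1) >= min_samples
    if not grouped:
        return set(table.index[enough])
    li_cols = _group_columns(table.columns, groups.get("Li", ()))
    k_cols = _group_columns(table.columns, groups.get("K", ())) + _group_columns(
        table.columns, groups.get("KPDS", ())
    )
    has_li = ok[li_cols].any(axis=1) if li_cols else False
    has_k = ok[k_cols].any(axis=1) if k_cols else False
    return set(table.index[enough & has_li & has_k])


def filter_tpm(
    table: pd.DataFrame,
    min_tpm: float = 0.5,
    cell_lines: Mapping[str, tuple[str, str]] | None = None,
) -> set[str]:
    """Genes expressed in the RT-stop profiling assay.

    Kept iff some cell line shows TPM >= ``min_tpm`` in *both* its
    stabilizing (K+) and less-stabilizing (Na+) sample (inclusive bound).
    """
    lines = cell_lines or TPM_CELL_LINES
    keep = pd.Series(False, index=table.index)
    for k_col, na_col in lines.values():
        if k_col in table.columns and na_col in table.columns:
            keep |= (table[k_col] >= min_tpm) & (table[na_col] >= min_tpm)
    return set(table.index[keep])


def annotate_intervals(
    records: Sequence[OverlapRecord],
    annotation: Sequence[RG4Region] | Sequence[tuple[str, int, int]],
    flank5_by_tx: Mapping[str, int] | None = None,
) -> list[bool]:
    """Flag motifs whose coding interval intersects any annotation interval.

    Intervals are half-open, so touching without overlap does not flag; a
    single shared nucleotide does.  Returns one boolean per record, in
    order (e.g. eCLIP autogenous-binding cross-referencing).
    """
    by_tx: dict[str, list[tuple[int, int]]] = {}
    for a in annotation:
        if isinstance(a, RG4Region):
            by_tx.setdefault(a.transcript_id, []).append(a.interval)
        else:
            tx, s, e = a
            by_tx.setdefault(tx, []).append((int(s), int(e)))
    flags = []
    for rec in records:
        tx_id = rec.motif.protein_id
        f5 = (flank5_by_tx or {}).get(tx_id, 0)
        iv = motif_tx_interval(rec.motif, f5)
        flags.append(
            any(overlap_length(iv, other) >= 1 for other in by_tx.get(tx_id, []))
        )
    return flags


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class DatasetSpec:
    """One rG4 dataset: label + how to obtain its regions."""

    label: str
    kind: str  # predicted | bed | rtstop
    path: str | None = None  # bed / rtstop input
    predictor: str = "g4hunter"  # for kind == predicted
    params: dict = field(default_factory=dict)
    expression_filter: str | None = None  # cpm | tpm | None


@dataclass
class RunConfig:
    transcripts_fasta: str = ""
    annotation_tsv: str = ""
    datasets: list[DatasetSpec] = field(default_factory=list)
    overlap_cutoff: int = 6
    flank_len: int = 50
    g4hunter_threshold: float = 1.2
    g4hunter_window: int = 25
    qgrs_threshold: float = 19.0
    qgrs_max_len: int = 30
    length_cutoffs: tuple[int, ...] = (0, 4, 7, 10, 15, 20, 30)
    expression_cpm_tsv: str | None = None
    expression_tpm_tsv: str | None = None
    randomization: dict | None = None  # {scheme, n, seed, predictor}
    outdir: str = "rg4rgg_out"

    def __post_init__(self) -> None:
        labels = [d.label for d in self.datasets]
        if len(labels) != len(set(labels)):
            raise ValueError("dataset labels must be unique")
        for thr in (
            self.overlap_cutoff,
            self.g4hunter_threshold,
            self.g4hunter_window,
            self.qgrs_threshold,
            self.qgrs_max_len,
        ):
            if thr <= 0:
                raise ValueError("all thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw["datasets"] = [DatasetSpec(**d) for d in raw.get("datasets", [])]
        return cls(**raw)


# ---------------------------------------------------------------------------
# assembly + run
# ---------------------------------------------------------------------------

def detect_all_motifs(transcripts: Sequence[Transcript]) -> dict[str, list[RGGMotif]]:
    """RGG motifs per transcript (protein_id = transcript id)."""
    return {tx.id: find_rgg_motifs(tx.protein, protein_id=tx.id) for tx in transcripts}


def assemble_dataset(
    spec: DatasetSpec, transcripts: Sequence[Transcript], cfg: RunConfig
) -> list[RG4Region]:
    """Materialize one dataset's rG4 regions in transcript space."""
    if spec.kind == "predicted":
        out: list[RG4Region] = []
        for tx in transcripts:
            if spec.predictor == "g4hunter":
                out.extend(
                    g4hunter_regions(
                        tx.seq,
                        window=spec.params.get("window", cfg.g4hunter_window),
                        threshold=spec.params.get("threshold", cfg.g4hunter_threshold),
                        transcript_id=tx.id,
                        source=spec.label,
                    )
                )
            elif spec.predictor == "qgrs":
                out.extend(
                    qgrs_scan(
                        tx.seq,
                        max_len=spec.params.get("max_len", cfg.qgrs_max_len),
                        threshold=spec.params.get("threshold", cfg.qgrs_threshold),
                        transcript_id=tx.id,
                        source=spec.label,
                    )
                )
            else:
                raise ValueError(f"unknown predictor {spec.predictor!r}")
        return merge_regions(out)
    if spec.kind == "bed":
        if not spec.path:
            raise ValueError(f"dataset {spec.label}: 'path' required for kind=bed")
        return ingest_bed(spec.path, spec.label)
    if spec.kind == "rtstop":
        if not spec.path:
            raise ValueError(f"dataset {spec.label}: 'path' required for kind=rtstop")
        stops = read_rtstops(spec.path)
        lens = {tx.id: len(tx.seq) for tx in transcripts}
        out = []
        for tx_id, positions in stops.items():
            if tx_id not in lens:
                log.warning("RT stops for unknown transcript %s skipped", tx_id)
                continue
            out.extend(
                rtstop_to_regions(
                    positions, lens[tx_id], transcript_id=tx_id, source=spec.label
                )
            )
        return out
    raise ValueError(f"unknown dataset kind {spec.kind!r}")


def run(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Per dataset: per-motif overlap verdicts, summary, length sweep and
    composition tables; across datasets: the motif x dataset membership
    matrix and pairwise agreement; optionally the randomization experiment.
    Returns the report as a dict of DataFrames/records (also written to
    ``config.outdir``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts = read_transcripts(
        config.transcripts_fasta, config.annotation_tsv, max_flank=config.flank_len
    )
    if not transcripts:
        raise ValueError("no transcripts loaded")
    tx_by_id = {tx.id: tx for tx in transcripts}
    motifs = detect_all_motifs(transcripts)

    retained: dict[str, set[str]] = {}
    if config.expression_cpm_tsv:
        retained["cpm"] = filter_cpm(read_expression(config.expression_cpm_tsv))
    if config.expression_tpm_tsv:
        retained["tpm"] = filter_tpm(read_expression(config.expression_tpm_tsv))

    report: dict[str, object] = {}
    per_motif_rows = []
    membership: dict[tuple[str, int], dict[str, bool]] = {}
    region_sets: dict[str, list[RG4Region]] = {}
    summaries = []
    for spec in config.datasets:
        regions = assemble_dataset(spec, transcripts, config)
        region_sets[spec.label] = regions
        by_tx: dict[str, list[RG4Region]] = {}
        for r in regions:
            by_tx.setdefault(r.transcript_id, []).append(r)
        keep = retained.get(spec.expression_filter) if spec.expression_filter else None
        records = []
        for tx in transcripts:
            if keep is not None and tx.id not in keep:
                continue
            for m in motifs[tx.id]:
                rec = classify_motif(
                    m,
                    by_tx.get(tx.id, []),
                    cutoff=config.overlap_cutoff,
                    flank5=len(tx.utr5_flank),
                    source=spec.label,
                )
                records.append(rec)
                feats = motif_features(m)
                per_motif_rows.append(
                    {
                        "dataset": spec.label,
                        "transcript_id": tx.id,
                        "start": m.start,
                        "end": m.end,
                        "sequence": m.sequence,
                        "length": m.length,
                        "n_rg": feats["n_rg"],
                        "n_rgg": feats["n_rgg"],
                        "mean_linker": feats["mean_linker"],
                        "encoded": rec.encoded,
                        "overlap_nt": rec.overlap_nt,
                        "coverage": rec.coverage,
                        "max_single_overlap": rec.max_single_overlap,
                    }
                )
                membership.setdefault((tx.id, m.start), {})[spec.label] = rec.encoded
        summary = overlap_summary(records)
        summary["dataset"] = spec.label
        summary["n_regions"] = len(regions)
        summaries.append(summary)
        sweep = length_sweep(records, config.length_cutoffs)
        sweep.insert(0, "dataset", spec.label)
        sweep.to_csv(outdir / f"length_sweep_{spec.label}.tsv", sep="\t", index=False)
        report[f"length_sweep_{spec.label}"] = sweep

    per_motif = pd.DataFrame(per_motif_rows)
    per_motif.to_csv(outdir / "per_motif.tsv", sep="\t", index=False)
    report["per_motif"] = per_motif
    summary_df = pd.DataFrame(summaries)
    summary_df.to_csv(outdir / "dataset_summary.tsv", sep="\t", index=False)
    report["summary"] = summary_df

    # motif x dataset membership matrix
    if membership:
        memb_df = (
            pd.DataFrame.from_dict(membership, orient="index")
            .fillna(False)
            .rename_axis(["transcript_id", "motif_start"])
            .reset_index()
        )
        memb_df.to_csv(outdir / "motif_dataset_membership.tsv", sep="\t", index=False)
        report["membership"] = memb_df

    # composition of motif coding sequences (per gene) and rG4 sets (pooled)
    motif_ivs = {
        tx.id: [motif_tx_interval(m, len(tx.utr5_flank)) for m in motifs[tx.id]]
        for tx in transcripts
        if motifs[tx.id]
    }
    if motif_ivs:
        comp = composition(motif_ivs, tx_by_id, per_gene=True)
        comp.to_csv(outdir / "composition_motifs.tsv", sep="\t")
        report["composition_motifs"] = comp
    for label, regions in region_sets.items():
        ivs: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            ivs.setdefault(r.transcript_id, []).append(r.interval)
        if ivs:
            comp = composition(ivs, tx_by_id, per_gene=False)
            comp.to_csv(outdir / f"composition_{label}.tsv", sep="\t")
            report[f"composition_{label}"] = comp

    if len(region_sets) >= 2:
        agree = dataset_agreement(region_sets)
        agree_rgg = dataset_agreement(region_sets, restrict_to=motif_ivs or None)
        agree["restricted_to_motifs"] = False
        agree_rgg["restricted_to_motifs"] = True
        agreement = pd.concat([agree, agree_rgg], ignore_index=True)
        agreement.to_csv(outdir / "dataset_agreement.tsv", sep="\t", index=False)
        report["agreement"] = agreement

    if config.randomization:
        rnd = dict(config.randomization)
        scheme = rnd.get("scheme", "codon_shuffle")
        target = rnd.get("dataset", config.datasets[0].label if config.datasets else None)
        if scheme == "recoding":
            result = recoding_experiment(
                transcripts,
                predictor=rnd.get("predictor", "g4hunter"),
                n=int(rnd.get("n", 1000)),
                seed=int(rnd.get("seed", 0)),
                cutoff=config.overlap_cutoff,
            )
        else:
            result = translation_experiment(
                transcripts,
                region_sets.get(target, []),
                scheme=scheme,
                n=int(rnd.get("n", 1000)),
                seed=int(rnd.get("seed", 0)),
                cutoff=config.overlap_cutoff,
            )
        payload = {
            "scheme": result.scheme,
            "dataset": target,
            "native_fraction": result.native_fraction,
            "p_value": result.p_value,
            "n": result.n,
            "seed": result.seed,
            "null_fractions": list(result.null_fractions),
        }
        (outdir / "randomization.json").write_text(json.dumps(payload, indent=1))
        report["randomization"] = payload

    log_payload = {
        "version": __version__,
        "n_transcripts": len(transcripts),
        "n_motifs": int(sum(len(v) for v in motifs.values())),
        "datasets": {k: len(v) for k, v in region_sets.items()},
        "overlap_cutoff": config.overlap_cutoff,
        "seeds": (config.randomization or {}).get("seed"),
        "retained": {k: len(v) for k, v in retained.items()},
    }
    (outdir / "run_log.json").write_text(json.dumps(log_payload, indent=1))
    report["log"] = log_payload
    log.info("run complete: %s", log_payload)
    return report
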