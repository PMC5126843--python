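"""End-to-end orchestration of the mu-protein discovery stages.

The pipeline mirrors how a comparative small-ORF screen is actually run:
scan transcribed intergenic regions of strain A for candidate ORFs, evaluate
each candidate's coding potential against its homolog in the comparison
strain, keep the significant candidates, flag reciprocal-best-hit orthologs
(comparison strain plus any configured reference proteomes), attach
expression specificity (UEF) from a condition x TU count matrix, compute
physicochemical features and promoter-motif geometry, and write a catalogue,
a feature report and a run manifest.  All randomness derives from the single
configured seed; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as _io
from .coding import CodonAlignment, align_pair, coding_pvalue, filter_significant
from .coords import GenomeRecord
from .discovery import (
    find_candidate_orfs,
    merge_with_annotation,
    transcribed_intergenic_regions,
)
from .expression import condition_max_census, uef_table
from .features import feature_table, translate
from .orthology import ProteinRecord, cross_reference_flags, pairs_as_table, reciprocal_best_hits, search_best_hits
from .promoters import MotifModel, scan_promoter

logger = logging.getLogger("smorfkit")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run; round-trips through YAML."""

    genome_a: str = ""
    tu_table_a: str = ""
    annotation_a: str = ""
    genome_b: Optional[str] = None
    tu_table_b: Optional[str] = None
    annotation_b: Optional[str] = None
    counts: Optional[str] = None
    reference_proteomes: dict = field(default_factory=dict)
    out_dir: str = "smorf_out"
    seed: int = 0
    alpha: float = 0.05
    e_max: float = 1e-2
    max_len_aa: int = 80
    min_len_aa: int = 15
    max_len_diff: float = 0.2
    start_codons: list = field(default_factory=lambda: ["ATG"])
    pseudocount: float = 1.0
    n_permutations: int = 1000
    stop_penalty: float = 10.0
    frameshift_penalty: float = 8.0
    strain_b_label: str = "strainB"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if self.e_max <= 0:
            raise ConfigError("e_max must be positive")
        if not 0 < self.min_len_aa <= self.max_len_aa:
            raise ConfigError("need 0 < min_len_aa <= max_len_aa")
        if not 0 <= self.max_len_diff < 1:
            raise ConfigError("max_len_diff must be in [0, 1)")
        if self.n_permutations < 19:
            raise ConfigError("n_permutations must be >= 19")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    catalogue: pd.DataFrame
    features: pd.DataFrame
    uef: Optional[pd.DataFrame]
    census: Optional[pd.Series]
    orthologs: pd.DataFrame
    promoter_hits: pd.DataFrame
    summary: dict
    manifest: dict
    out_dir: Path


def _require(path: Optional[str], label: str, optional: bool = False) -> Optional[Path]:
    if path is None or path == "":
        if optional:
            return None
        raise FileNotFoundError(f"required input {label!r} not configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{label}: no such file {p}")
    return p


def _candidate_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 1_000_003 + 7919 * index + 1) % (2**31))


def _discover(genome_path, tu_path, ann_path, config) -> pd.DataFrame:
    genomes = {g.replicon_id: g for g in _io.read_genome_fasta(genome_path)}
    tus = _io.read_tu_table(tu_path)
    annotation = _io.read_gff3_cds(ann_path)
    regions = transcribed_intergenic_regions(tus, annotation) if tus else []
    candidates = find_candidate_orfs(
        genomes,
        regions,
        min_len_aa=config.min_len_aa,
        max_len_aa=config.max_len_aa,
        start_codons=tuple(config.start_codons),
    )
    return merge_with_annotation(candidates, annotation), genomes, tus


def _as_proteins(catalogue: pd.DataFrame, source_set: str) -> list[ProteinRecord]:
    out = []
    for _, row in catalogue.iterrows():
        peptide = translate(row["nt_sequence"]).peptide
        out.append(ProteinRecord(id=row["candidate_id"], sequence=peptide, source_set=source_set))
    return out


def run_discovery(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the catalogue, reports and manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}
    stage = "inputs"
    try:
        genome_a = _require(config.genome_a, "genome_a")
        tu_a = _require(config.tu_table_a, "tu_table_a")
        ann_a = _require(config.annotation_a, "annotation_a")
        genome_b = _require(config.genome_b, "genome_b", optional=True)
        tu_b = _require(config.tu_table_b, "tu_table_b", optional=True)
        ann_b = _require(config.annotation_b, "annotation_b", optional=True)
        counts_path = _require(config.counts, "counts", optional=True)
        ref_paths = {
            name: _require(p, f"reference_proteomes[{name}]")
            for name, p in config.reference_proteomes.items()
        }

        stage = "discovery_a"
        cat_a, genomes_a, tus_a = _discover(genome_a, tu_a, ann_a, config)
        stage_counts["candidates_a"] = len(cat_a)
        logger.info("discovery_a: %d candidate ORFs", len(cat_a))
        if cat_a.empty:
            logger.warning("empty candidate set (empty TU table?); writing empty outputs")

        cat_b = pd.DataFrame()
        if genome_b is not None and tu_b is not None and ann_b is not None:
            stage = "discovery_b"
            cat_b, _, _ = _discover(genome_b, tu_b, ann_b, config)
            stage_counts["candidates_b"] = len(cat_b)
            logger.info("discovery_b: %d candidate ORFs", len(cat_b))

        proteins_a = _as_proteins(cat_a, "A") if len(cat_a) else []
        proteins_b = _as_proteins(cat_b, "B") if len(cat_b) else []
        nt_b = dict(zip(cat_b["candidate_id"], cat_b["nt_sequence"])) if len(cat_b) else {}

        stage = "coding_potential"
        assessments = []
        if proteins_a and proteins_b:
            hits = search_best_hits(proteins_a, proteins_b, e_max=config.e_max)
        else:
            hits = {}
        for k, (_, row) in enumerate(cat_a.iterrows()):
            cid = row["candidate_id"]
            hit = hits.get(cid)
            if hit is None:
                assessments.append(
                    {"candidate_id": cid, "score": np.nan, "p_value": np.nan,
                     "n_rows": 0, "n_codons": 0, "partner": None, "reason": "no_homolog"}
                )
                continue
            ref_nt = row["nt_sequence"][:-3]  # strip the stop codon
            partner_nt = nt_b[hit.target_id][:-3]
            aligned = align_pair(ref_nt, partner_nt)
            aln = CodonAlignment(rows=aligned, ids=(cid, hit.target_id))
            assessment = coding_pvalue(
                aln,
                n_permutations=config.n_permutations,
                seed=_candidate_seed(config.seed, k),
                stop_penalty=config.stop_penalty,
                frameshift_penalty=config.frameshift_penalty,
            )
            assessments.append(
                {"candidate_id": cid, "score": assessment.score, "p_value": assessment.p_value,
                 "n_rows": aln.n_rows, "n_codons": aln.n_codons, "partner": hit.target_id,
                 "reason": ""}
            )
        assess_df = pd.DataFrame(
            assessments,
            columns=["candidate_id", "score", "p_value", "n_rows", "n_codons", "partner", "reason"],
        )
        stage_counts["scored"] = int(assess_df["p_value"].notna().sum())

        stage = "significance_filter"
        scored = assess_df[assess_df["p_value"].notna()]
        retained = filter_significant(scored, alpha=config.alpha)
        retained_ids = set(retained["candidate_id"])
        stage_counts["significant"] = len(retained)
        logger.info("coding filter: %d of %d scored candidates at alpha=%.3g",
                    len(retained), len(scored), config.alpha)

        catalogue = cat_a.merge(assess_df.drop(columns=["reason"]), on="candidate_id", how="left")
        catalogue["retained"] = catalogue["candidate_id"].isin(retained_ids)
        catalogue = catalogue.merge(
            retained[["candidate_id", "borderline"]], on="candidate_id", how="left"
        )
        catalogue["borderline"] = catalogue["borderline"].eq(True)

        stage = "orthology"
        pairs = []
        if proteins_a and proteins_b:
            pairs = reciprocal_best_hits(
                proteins_a, proteins_b,
                e_max=config.e_max, max_len_diff=config.max_len_diff, max_len=config.max_len_aa,
            )
        ortho_df = pairs_as_table(pairs)
        partner_of = dict(zip(ortho_df["id_a"], ortho_df["id_b"])) if len(ortho_df) else {}
        flag_cols = {}
        if proteins_b:
            flag_cols[config.strain_b_label] = [
                "Y" if cid in partner_of else "N" for cid in catalogue["candidate_id"]
            ]
        for name, path in ref_paths.items():
            refs = _io.read_protein_fasta(path, source_set=name)
            flags = cross_reference_flags(
                proteins_a, {name: refs},
                e_max=config.e_max, max_len_diff=config.max_len_diff, max_len=config.max_len_aa,
            ) if proteins_a else pd.DataFrame(columns=[name])
            flag_cols[name] = [
                flags.loc[cid, name] if cid in flags.index else "N"
                for cid in catalogue["candidate_id"]
            ]
        for name, col in flag_cols.items():
            catalogue[f"flag_{name}"] = col
        stage_counts["ortholog_pairs"] = len(ortho_df)

        stage = "expression"
        uef_df, census = None, None
        if counts_path is not None:
            matrix = _io.read_counts(counts_path)
            uef_df = uef_table(matrix, pseudocount=config.pseudocount)
            census = condition_max_census(matrix)
            catalogue = catalogue.merge(
                uef_df.rename(columns={"tu_id": "parent_tu"})[["parent_tu", "uef", "max_condition"]],
                on="parent_tu", how="left",
            )

        stage = "protein_features"
        kept = catalogue[catalogue["retained"]]
        features = feature_table(
            [(row["candidate_id"], translate(row["nt_sequence"]).peptide) for _, row in kept.iterrows()]
        )

        stage = "promoter_motifs"
        tss_of = {tu.tu_id: (tu.replicon_id, tu.tss_position, tu.strand) for tu in tus_a}
        promoter_rows = []
        for _, row in kept.iterrows():
            info = tss_of.get(row["parent_tu"])
            if info is None:
                continue
            replicon, tss, strand = info
            hits_m = scan_promoter(genomes_a[replicon], tss, strand, MotifModel())
            for h in hits_m:
                promoter_rows.append(
                    {"candidate_id": row["candidate_id"], "parent_tu": row["parent_tu"],
                     "site": h.matched_sequence, "center_offset": h.center_offset,
                     "floor_offset": h.floor_offset, "classification": h.classification}
                )
        promoter_df = pd.DataFrame(
            promoter_rows,
            columns=["candidate_id", "parent_tu", "site", "center_offset", "floor_offset", "classification"],
        )
        stage_counts["promoter_hits"] = len(promoter_df)

        stage = "reports"
        summary = report_summary(catalogue)
        manifest = {
            "smorfkit_version": __version__,
            "seed": config.seed,
            "thresholds": {
                "alpha": config.alpha, "e_max": config.e_max,
                "max_len_aa": config.max_len_aa, "min_len_aa": config.min_len_aa,
                "max_len_diff": config.max_len_diff,
                "start_codons": list(config.start_codons),
                "pseudocount": config.pseudocount,
                "n_permutations": config.n_permutations,
                "stop_penalty": config.stop_penalty,
                "frameshift_penalty": config.frameshift_penalty,
            },
            "inputs": {
                "genome_a": str(config.genome_a), "tu_table_a": str(config.tu_table_a),
                "annotation_a": str(config.annotation_a),
                "genome_b": str(config.genome_b), "tu_table_b": str(config.tu_table_b),
                "annotation_b": str(config.annotation_b),
                "counts": str(config.counts),
                "reference_proteomes": {k: str(v) for k, v in config.reference_proteomes.items()},
            },
            "stage_counts": stage_counts,
        }
        _write_outputs(out_dir, catalogue, features, uef_df, census, ortho_df, promoter_df, summary, manifest)
        return PipelineResult(
            catalogue=catalogue, features=features, uef=uef_df, census=census,
            orthologs=ortho_df, promoter_hits=promoter_df,
            summary=summary, manifest=manifest, out_dir=out_dir,
        )
    except Exception:
        logger.exception("pipeline failed in stage %r (partial outputs in %s)", stage, out_dir)
        raise


def _write_outputs(out_dir, catalogue, features, uef_df, census, ortho_df, promoter_df, summary, manifest):
    catalogue.to_csv(out_dir / "catalogue.tsv", sep="\t", index=False, float_format="%.6g")
    features.to_csv(out_dir / "features.tsv", sep="\t", index=False, float_format="%.6g")
    ortho_df.to_csv(out_dir / "orthologs.tsv", sep="\t", index=False, float_format="%.6g")
    promoter_df.to_csv(out_dir / "promoter_hits.tsv", sep="\t", index=False, float_format="%.6g")
    if uef_df is not None:
        uef_df.to_csv(out_dir / "uef.tsv", sep="\t", index=False, float_format="%.6g")
    if census is not None:
        census.to_csv(out_dir / "census.tsv", sep="\t")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_summary(catalogue: pd.DataFrame) -> dict:
    """Headline counts of a catalogue: totals, the <=50 aa class, per-flag
    ortholog counts, and the annotated vs novel split."""
    if catalogue.empty:
        return {
            "n_candidates": 0, "n_le50_aa": 0, "n_retained": 0,
            "n_annotated": 0, "novel_fraction": 0.0, "flags": {},
        }
    flags = {}
    for col in catalogue.columns:
        if col.startswith("flag_"):
            flags[col[len("flag_"):]] = int((catalogue[col] == "Y").sum())
    n = len(catalogue)
    n_annot = int(catalogue["locus_tag"].notna().sum())
    return {
        "n_candidates": n,
        "n_le50_aa": int((catalogue["length_aa"] <= 50).sum()),
        "n_retained": int(catalogue["retained"].sum()) if "retained" in catalogue else n,
        "n_annotated": n_annot,
        "novel_fraction": round(1.0 - n_annot / n, 4),
        "flags": flags,
    }
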