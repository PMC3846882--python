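"""End-to-end orchestration: filters -> scoring -> NSAF -> REF -> candidates.

A :class:`PipelineConfig` collects every path and numeric cutoff in one
place (loadable from a flat YAML file); :func:`run_pipeline` executes the
stages, writes all report TSVs plus a run manifest, and aborts with the
stage name on any error. :func:`make_fixtures` materialises a complete
synthetic demo dataset readable by the same pipeline.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

import apmsref
from apmsref import digest, enrichment, io, scoring, simulate

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Paths, thresholds and simulation settings for one pipeline run."""

    # paths (fixture mode fills these in under outdir)
    fasta: str | None = None
    counts: str | None = None
    design: str | None = None
    reference: str | None = None
    peptides: str | None = None
    outdir: str = "apmsref_out"

    # thresholds
    probability_threshold: float = scoring.DEFAULT_PROBABILITY_THRESHOLD
    min_spectra: int = scoring.DEFAULT_MIN_SPECTRA
    min_peptide_length: int = 7
    ref_member_threshold: float = enrichment.DEFAULT_MEMBER_THRESHOLD
    ref_report_threshold: float = enrichment.DEFAULT_REPORT_THRESHOLD

    # scoring / enrichment options
    pseudocount: float = scoring.DEFAULT_PSEUDOCOUNT
    require_replicate_presence: bool = False
    profile_mode: str = "replicate_mean"

    # simulation (fixture mode)
    seed: int = 0
    sim: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.probability_threshold <= 1):
            raise io.ValidationError("probability threshold must lie in (0, 1]")
        if self.min_spectra < 0 or self.min_peptide_length < 1:
            raise io.ValidationError("spectra/peptide-length thresholds out of range")
        if self.ref_report_threshold < 0 or self.ref_member_threshold < 0:
            raise io.ValidationError("REF thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise io.ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> simulate.SimConfig:
        sim = dict(self.sim)
        sim.setdefault("seed", self.seed)
        if "baits" in sim:
            sim["baits"] = tuple(sim["baits"])
        if "complex_enrichment_range" in sim:
            sim["complex_enrichment_range"] = tuple(sim["complex_enrichment_range"])
        return simulate.SimConfig(**sim)

    def snapshot(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def make_fixtures(config: PipelineConfig) -> PipelineConfig:
    """Write a synthetic demo dataset and return a config pointing at it.

    Emits FASTA, count matrix, design, reference-set and peptide tables
    under ``outdir/fixtures``; deterministic under the seed.
    """
    simcfg = config.sim_config()
    records, truth = simulate.generate_protein_db(simcfg)
    matrix, design = simulate.simulate_apms_counts(records, truth, simcfg)
    peptides = simulate.generate_peptide_evidence(records, truth, matrix, simcfg)

    fixdir = Path(config.outdir) / "fixtures"
    fixdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(records, fixdir / "proteins.fasta")
    io.write_count_matrix(matrix, fixdir / "counts.tsv")
    io.write_design(design, fixdir / "design.tsv")
    io.write_reference_set(
        io.ReferenceSet(tuple(truth.reference_ids)), fixdir / "reference.tsv"
    )
    io.write_peptide_table(peptides, fixdir / "peptides.tsv", matrix.run_ids)
    truth.labels.rename("label").to_csv(fixdir / "truth_labels.tsv", sep="\t")
    logger.info("fixtures written to %s", fixdir)

    return dataclasses.replace(
        config,
        fasta=str(fixdir / "proteins.fasta"),
        counts=str(fixdir / "counts.tsv"),
        design=str(fixdir / "design.tsv"),
        reference=str(fixdir / "reference.tsv"),
        peptides=str(fixdir / "peptides.tsv"),
    )


def _require(config: PipelineConfig, *names: str) -> None:
    for name in names:
        if getattr(config, name) is None:
            raise io.ValidationError(
                f"pipeline requires the {name!r} path; set it in the config"
            )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages and write reports under ``config.outdir``.

    Returns a bundle with the in-memory results and per-stage row counts.
    Reruns with an identical config and inputs produce byte-identical
    outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}
    bundle: dict[str, Any] = {"stage_counts": stage_counts}

    def stage(name: str):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return deco

    @stage("load")
    def _load():
        _require(config, "fasta", "counts", "design")
        bundle["records"] = io.read_fasta(config.fasta)
        bundle["design"] = io.read_design(config.design)
        bundle["matrix"] = io.read_count_matrix(config.counts, bundle["design"])
        bundle["matrix"].validate_against_db(bundle["records"])
        bundle["peptides"] = (
            io.read_peptide_table(config.peptides) if config.peptides else None
        )
        stage_counts["proteins_in_db"] = len(bundle["records"])
        stage_counts["runs"] = len(bundle["matrix"].run_ids)
        stage_counts["proteins_identified"] = len(bundle["matrix"].protein_ids)
        return None

    @stage("identification_filters")
    def _filter():
        bundle["filtered"] = io.apply_identification_filters(
            bundle["matrix"],
            bundle["design"],
            bundle["peptides"],
            min_peptide_length=config.min_peptide_length,
            min_bait_total=config.min_spectra,
            require_replicate_presence=config.require_replicate_presence,
        )
        stage_counts["proteins_after_filters"] = len(bundle["filtered"].protein_ids)

    @stage("interaction_scoring")
    def _score():
        scores = scoring.score_all(
            bundle["filtered"],
            bundle["design"],
            pseudocount=config.pseudocount,
            threshold=config.probability_threshold,
        )
        interactome = scoring.filter_interactome(
            scores, min_spectra=config.min_spectra
        )
        scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        interactome.to_csv(outdir / "interactome.tsv", sep="\t", index=False)
        bundle["scores"] = scores
        bundle["interactome"] = interactome
        stage_counts["scored_pairs"] = len(scores)
        stage_counts["qualified_pairs"] = len(interactome)

    @stage("enrichment")
    def _enrich():
        _require(config, "reference")
        reference = io.read_reference_set(config.reference)
        reference.validate_against_db(bundle["records"])
        lengths = io.protein_lengths(bundle["records"])
        tables = enrichment.bait_ref_tables(
            bundle["filtered"],
            bundle["design"],
            lengths,
            reference,
            profile_mode=config.profile_mode,
        )
        wide = None
        for bait, table in tables.items():
            part = table.rename(
                columns={"quotient": f"quotient_{bait}", "ref": f"ref_{bait}"}
            )
            part[f"ref_{bait}"] = part[f"ref_{bait}"].round(2)
            part = part.drop(columns=["in_reference_set"])
            wide = part if wide is None else wide.join(part, how="outer")
        wide["in_reference_set"] = [p in reference for p in wide.index]
        wide.sort_index().to_csv(outdir / "enrichment.tsv", sep="\t")
        candidates = enrichment.nominate_candidates(
            tables,
            member_threshold=config.ref_member_threshold,
            report_threshold=config.ref_report_threshold,
        )
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        bundle["ref_tables"] = tables
        bundle["candidates"] = candidates
        stage_counts["enrichment_proteins"] = len(wide)
        stage_counts["candidates_reported"] = len(candidates)

    @stage("isoforms")
    def _isoforms():
        if bundle["peptides"] is None:
            stage_counts["isoform_peptides"] = 0
            return
        params = digest.DigestParams(min_length=config.min_peptide_length)
        evidence = [
            p for p in bundle["peptides"]
            if len(p.peptide_sequence) >= config.min_peptide_length
        ]
        table = digest.isoform_evidence_table(evidence, bundle["records"], None, params)
        table.to_csv(outdir / "isoform_evidence.tsv", sep="\t", index=False)
        classifications = {
            row["peptide_sequence"]: digest.Classification(
                row["classification"], frozenset(row["protein_ids"].split(";"))
            )
            for _, row in table.iterrows()
        }
        unique, other = digest.tally_isoform_counts(evidence, classifications)
        tally = pd.DataFrame(
            sorted(unique.items()), columns=["protein_id", "unique_spectra"]
        )
        tally.to_csv(outdir / "isoform_tallies.tsv", sep="\t", index=False)
        bundle["isoform_evidence"] = table
        bundle["isoform_tallies"] = (unique, other)
        stage_counts["isoform_peptides"] = len(table)

    @stage("manifest")
    def _manifest():
        manifest = {
            "package": "apmsref",
            "version": apmsref.__version__,
            "seed": config.seed,
            "config": config.snapshot(),
            "stage_counts": stage_counts,
        }
        with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        bundle["manifest"] = manifest

    logger.info("pipeline finished: %s", stage_counts)
    return bundle
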