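"""End-to-end orchestration: registry -> digest -> quantify -> enrichment
-> peptide pairs -> paralog status calls -> report.

`run_all` is a pure function of its configuration and input files: two runs
with identical inputs produce byte-identical output tables. All thresholds
and modes live in :class:`PipelineConfig`; every intermediate table is
written to the output directory alongside a JSON summary and a log with
versions, the configuration hash and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import (
    call_status,
    rna_protein_concordance,
    summary_report,
    write_calls,
)
from .digestion import DigestParams, build_peptide_index
from .enrichment import call_enriched, cluster_rows, compare, write_comparisons
from .peptide_pairs import (
    estimate_pair_ratio,
    find_discriminating_pairs,
    write_estimates,
    write_matches,
)
from .quantify import (
    SampleDesign,
    aggregate,
    filter_psms,
    normalize_total,
    read_psm_table,
    row_zscores,
    scale,
)
from .registry import distinguishable_pairs, load_bundled_registry, load_registry

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage that raised it."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and modes for a full analysis run."""

    psm_table: str
    design_table: str
    output_dir: str
    registry_fasta: str | None = None  # None -> bundled fixture
    registry_annotation: str | None = None
    rna_table: str | None = None
    reference_tissue: str = "head"
    rna_tissues: tuple[str, str] | None = None  # (a, b) for concordance
    digest: DigestParams = field(default_factory=DigestParams)
    max_qvalue: float = 0.05
    scale_mode: str = "pooled"  # or "replicate_mean"
    fc_threshold: float = 1.5
    fc_scale: str = "linear"  # or "log2"
    p_threshold: float = 0.05
    min_subs: int = 1
    max_subs: int = 2
    switch_threshold: float = 1.0
    equal_band: float = 0.5
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "complete"
    complex: str = "m80S"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        digest = DigestParams(**raw.pop("digest", {}))
        if "rna_tissues" in raw and raw["rna_tissues"] is not None:
            raw["rna_tissues"] = tuple(raw["rna_tissues"])
        return cls(digest=digest, **raw)

    def validate(self) -> None:
        for name in ("psm_table", "design_table"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise PipelineError(f"[config] missing {name} file: {path}")
        for name in ("registry_fasta", "registry_annotation", "rna_table"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise PipelineError(f"[config] missing {name} file: {path}")
        if not (0 <= self.max_qvalue <= 1 and 0 < self.p_threshold <= 1):
            raise PipelineError("[config] thresholds out of range")
        if self.switch_threshold <= 0 or self.equal_band < 0:
            raise PipelineError("[config] status thresholds out of range")

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in vars(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute the whole chain and write all outputs; returns the report."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("registry")
        if config.registry_fasta is not None:
            if config.registry_annotation is None:
                raise PipelineError("registry_fasta given without annotation")
            registry = load_registry(config.registry_fasta, config.registry_annotation)
        else:
            registry = load_bundled_registry()

        name = stage("digest")
        index = build_peptide_index(registry, config.digest)
        index.write_tsv(outdir / "peptide_index.tsv")

        name = stage("quantify")
        design = SampleDesign.read(config.design_table)
        psms = read_psm_table(config.psm_table)
        filtered = filter_psms(
            psms, max_qvalue=config.max_qvalue, require_unique=True, index=index
        )
        raw = aggregate(filtered, registry, design)
        normalized = normalize_total(raw)
        scaled = scale(normalized, config.scale_mode, design)
        for m, fname in ((raw, "abundance_raw.tsv"),
                         (normalized, "abundance_normalized.tsv"),
                         (scaled, "abundance_scaled.tsv")):
            m.write(outdir / fname)

        name = stage("enrichment")
        tissues = [
            t for t in dict.fromkeys(design.table["tissue"]) if t != "pool"
        ]
        comparisons = []
        pairs_of_interest = [
            (t, config.reference_tissue)
            for t in tissues
            if t != config.reference_tissue
        ]
        if "testis" in tissues and "ovary" in tissues:
            pairs_of_interest.append(("testis", "ovary"))
        for tissue_a, tissue_b in pairs_of_interest:
            res = compare(
                scaled,
                {"tissue": tissue_a, "complex": config.complex},
                {"tissue": tissue_b, "complex": config.complex},
                design,
            )
            comparisons.extend(
                call_enriched(
                    res,
                    fc_threshold=config.fc_threshold,
                    p_threshold=config.p_threshold,
                    scale=config.fc_scale,
                )
            )
        write_comparisons(comparisons, outdir / "comparisons.tsv")

        name = stage("clustering")
        zmat = row_zscores(scaled)
        zmat.write(outdir / "abundance_zscore.tsv")
        dendro = None
        complete = zmat.values.dropna(axis=0)
        if len(complete) >= 2:
            dendro = cluster_rows(
                zmat, metric=config.cluster_metric, method=config.cluster_linkage
            )
            (outdir / "dendrogram.newick").write_text(
                dendro.to_newick(), encoding="utf-8"
            )

        name = stage("pairs")
        matches_all, estimates = [], []
        replicates = sorted(set(design.table["replicate"]))
        for group in distinguishable_pairs(registry):
            matches = find_discriminating_pairs(
                registry,
                group.group_id,
                config.digest,
                min_subs=config.min_subs,
                max_subs=config.max_subs,
                index=index,
            )
            matches_all.extend(matches)
            if not matches:
                continue
            for tissue in tissues:
                for rep in replicates:
                    estimates.append(
                        estimate_pair_ratio(
                            matches,
                            filtered,
                            design,
                            tissue,
                            complex=config.complex,
                            replicate=rep,
                        )
                    )
        write_matches(matches_all, outdir / "pair_matches.tsv")
        write_estimates(estimates, outdir / "pair_estimates.tsv")

        name = stage("classify")
        calls = call_status(
            registry,
            comparisons,
            estimates,
            switch_threshold=config.switch_threshold,
            equal_band=config.equal_band,
        )
        write_calls(calls, outdir / "paralog_calls.tsv")

        concordance = None
        if config.rna_table is not None and config.rna_tissues is not None:
            name = stage("concordance")
            rna = pd.read_csv(config.rna_table, sep="\t", index_col="gene_symbol")
            ta, tb = config.rna_tissues
            subset = [
                c for c in comparisons
                if c.group_a.startswith(f"{ta}:") and c.group_b.startswith(f"{tb}:")
            ]
            symbols = {
                acc: registry.gene_symbol(acc) for acc in registry.proteins
            }
            records = rna_protein_concordance(
                rna, subset, ta, tb, gene_symbols=symbols
            )
            concordance = [vars(r) for r in records]
            pd.DataFrame(concordance).to_csv(
                outdir / "rna_protein_concordance.tsv", sep="\t", index=False
            )

        name = stage("report")
        report = summary_report(calls, registry)
        report.update(
            {
                "version": __version__,
                "config_hash": config.content_hash(),
                "seed": config.seed,
                "n_psms_input": int(len(psms)),
                "n_psms_used": int(len(filtered)),
                "n_proteins_quantified": int(len(raw.values)),
                "comparisons": [
                    f"{a} vs {b}" for a, b in pairs_of_interest
                ],
            }
        )
        if concordance is not None:
            report["n_concordance_records"] = len(concordance)
        (outdir / "summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
        )
        (outdir / "run.log").write_text(
            f"ribopara {__version__}\nconfig_hash {config.content_hash()}\n"
            f"seed {config.seed}\n",
            encoding="utf-8",
        )
        return report
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(f"[{name}] {exc}") from exc
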