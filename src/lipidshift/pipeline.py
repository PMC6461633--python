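"""End-to-end analysis pipeline binding all stages.

Stage order: isotope interference correction -> ISTD quantification ->
QC filter cascade -> paired differential statistics per group ->
saturation-class aggregation -> multivariate views.  A JSON run manifest
(config echo, package version, species counts at each stage) makes the
run reproducible: identical inputs and manifest settings yield identical
output files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .diffstats import differential_table, log2fc_matrix
from .io import write_json, write_matrix
from .multivariate import ClusterResult, PCAResult, cluster_heatmap, pca_abundance, pca_log2fc
from .qc_filter import FilterConfig, QCReport, apply_qc, finalize_dataset
from .quantify import Quantification, correct_s1p_interference, quantify_table
from .saturation import DEFAULT_CLASSES, SaturationSummary, saturation_analysis

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.05
    fdr_scope: str = "group"                  # "group" | "class"
    saturation_classes: Tuple[str, ...] = DEFAULT_CLASSES
    ward_variant: str = "D2"                  # "D" | "D2"
    isotope_interferer: str = "S1P d18:1"
    isotope_target: str = "S1P d18:0"
    isotope_fraction: Optional[float] = None  # None -> binomial default
    drop_subjects: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PipelineResult:
    quantification: Quantification
    qc_report: QCReport
    final_species: list
    matrices_by_group: Dict[str, pd.DataFrame]
    combined_matrix: pd.DataFrame
    differential: Dict[str, pd.DataFrame]
    saturation: Dict[str, Dict[str, SaturationSummary]]
    log2fc: pd.DataFrame
    pca_conc: PCAResult
    pca_fc: PCAResult
    clusters: Dict[str, ClusterResult]
    manifest: dict


def _stage(name: str):
    """Decorating stage errors with the stage name keeps failures locatable."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(
    areas: pd.DataFrame,
    metadata: pd.DataFrame,
    istd_map: pd.DataFrame,
    config: RunConfig | None = None,
    outdir: Optional[Path] = None,
) -> PipelineResult:
    """Execute the full pipeline; optionally write all result files to ``outdir``."""
    config = config or RunConfig()
    groups = list(pd.unique(metadata["group"].dropna()))

    with _stage("isotope_correction"):
        corrected = correct_s1p_interference(
            areas,
            interferer=config.isotope_interferer,
            target=config.isotope_target,
            fraction=config.isotope_fraction,
        )
    with _stage("quantify"):
        quant = quantify_table(corrected, istd_map)
    with _stage("qc_filter"):
        report = apply_qc(corrected, quant, metadata, config.filter)
        final_species, per_group, combined = finalize_dataset(report, quant, metadata)

    differential: Dict[str, pd.DataFrame] = {}
    saturation: Dict[str, Dict[str, SaturationSummary]] = {}
    fc_rows = []
    with _stage("diffstats"):
        for g in groups:
            differential[g] = differential_table(
                per_group[g],
                metadata,
                g,
                alpha=config.alpha,
                fdr_scope=config.fdr_scope,
                drop_subjects=config.drop_subjects,
            )
            fc_rows.append(
                log2fc_matrix(combined, metadata, g, config.drop_subjects)
            )
        log2fc = pd.concat(fc_rows)
    with _stage("saturation"):
        for g in groups:
            saturation[g] = saturation_analysis(
                per_group[g],
                metadata,
                g,
                classes=config.saturation_classes,
                drop_subjects=config.drop_subjects,
            )
    with _stage("multivariate"):
        pca_conc = pca_abundance(combined)
        pca_fc = pca_log2fc(log2fc)
        clusters = {}
        for g in groups:
            g_samples = metadata.loc[
                (metadata["group"] == g) & (metadata["role"] == "study"), "sample_id"
            ]
            clusters[g] = cluster_heatmap(
                combined.reindex(g_samples), ward_variant=config.ward_variant
            )

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "groups": groups,
        "n_samples": int(metadata.shape[0]),
        "species_counts": {
            "catalog": int(quant.concentration.shape[1]),
            "reporting": {g: len(report.reporting_species[g]) for g in groups},
            "final": len(final_species),
        },
        "qc_summary": report.summary(),
    }

    result = PipelineResult(
        quantification=quant,
        qc_report=report,
        final_species=final_species,
        matrices_by_group=per_group,
        combined_matrix=combined,
        differential=differential,
        saturation=saturation,
        log2fc=log2fc,
        pca_conc=pca_conc,
        pca_fc=pca_fc,
        clusters=clusters,
        manifest=manifest,
    )
    if outdir is not None:
        write_results(result, Path(outdir))
    return result


def write_results(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    quant = result.quantification
    write_matrix(quant.normalized, quant.panels, outdir / "normalized_areas.tsv")
    write_matrix(quant.concentration, quant.panels, outdir / "concentrations.tsv")
    result.qc_report.to_tsv(outdir / "qc_report.tsv")
    result.qc_report.to_json(outdir / "qc_summary.json")
    for g, table in result.differential.items():
        table.to_csv(outdir / f"differential_{g}.tsv", sep="\t")
    sat_json = {}
    for g, by_class in result.saturation.items():
        for cls, summ in by_class.items():
            summ.totals.to_csv(outdir / f"saturation_{g}_{cls}.tsv", sep="\t", index=False)
            sat_json.setdefault(g, {})[cls] = summ.p_values()
    write_json(sat_json, outdir / "saturation_pvalues.json")
    result.pca_conc.scores.to_csv(outdir / "pca_conc_scores.tsv", sep="\t")
    result.pca_conc.loadings.to_csv(outdir / "pca_conc_loadings.tsv", sep="\t")
    result.pca_fc.scores.to_csv(outdir / "pca_fc_scores.tsv", sep="\t")
    result.pca_fc.loadings.to_csv(outdir / "pca_fc_loadings.tsv", sep="\t")
    write_json(
        {
            "pca_conc_variance_pct": result.pca_conc.variance_explained,
            "pca_fc_variance_pct": result.pca_fc.variance_explained,
        },
        outdir / "pca_variance.json",
    )
    for g, cl in result.clusters.items():
        (outdir / f"cluster_{g}_species.nwk").write_text(cl.species_newick + "\n")
        (outdir / f"cluster_{g}_samples.nwk").write_text(cl.sample_newick + "\n")
        cl.z_matrix.to_csv(outdir / f"cluster_{g}_zmatrix.tsv", sep="\t")
    write_json(result.manifest, outdir / "manifest.json")
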