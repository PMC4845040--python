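"""End-to-end orchestration: config validation, staged execution, reports.

``run_all`` executes the four analysis stages (miRNA, RNA-seq DE, exact
rank correlations, peak/promoter overlap) on either generated or on-disk
inputs and writes the report tables — a differential table, significant
correlations split into positive/negative panels, a promoter-hit distance
table, top induced/reduced gene lists — plus a machine-readable run log
with every parameter that produced them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    TransporterCatalogue,
    default_catalogue,
    load_catalogue,
    load_refgene,
    promoter_windows,
)
from .chipseq import load_peaks, unique_peaks, intersect_promoters, distance_report
from .correlation import correlation_matrix, select_significant
from .mirna import CtMatrix, MirnaDifferential, preprocess
from .rnaseq import CountMatrix, TransporterDE
from .simulate import TruthManifest, generate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run.

    Input paths may be omitted when running from a synthetic manifest.
    All stage thresholds default to the study's analysis settings.
    """

    counts: str | None = None
    count_samples: str | None = None
    ct: str | None = None
    ct_samples: str | None = None
    treated_peaks: str | None = None
    control_peaks: str | None = None
    annotation: str | None = None
    catalogue: str | None = None
    manifest: str | None = None
    seed: int = 0
    flank: int = 2000
    ct_cutoff: float = 35.0
    min_detected: int = 4
    min_reads: float = 10.0
    alpha: float = 0.05
    q_threshold: float = 0.05
    mirna_orientation: str = "abundance"
    distance_mode: str = "stranded"
    test_mode: str = "paired"
    top_n: int = 15

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def validate(self) -> None:
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if not 0 <= self.alpha <= 1 or not 0 <= self.q_threshold <= 1:
            raise ValueError("alpha and q_threshold must lie in [0, 1]")
        if self.mirna_orientation not in ("abundance", "ct"):
            raise ValueError("mirna_orientation must be 'abundance' or 'ct'")
        if self.distance_mode not in ("stranded", "genomic"):
            raise ValueError("distance_mode must be 'stranded' or 'genomic'")
        if self.test_mode not in ("paired", "pooled"):
            raise ValueError("test_mode must be 'paired' or 'pooled'")
        has_files = self.counts is not None and self.ct is not None
        if not has_files and self.manifest is None:
            raise ValueError("provide either input files or a synthetic manifest")


def _load_inputs(config: RunConfig) -> dict:
    if config.manifest is not None and config.counts is None:
        manifest = TruthManifest.from_yaml(config.manifest)
        return generate(manifest)
    bundle: dict = {}
    bundle["counts"] = CountMatrix.from_tsv(config.counts, config.count_samples)
    bundle["ct"] = CtMatrix.from_csv(config.ct, config.ct_samples)
    bundle["transcripts"] = (
        load_refgene(config.annotation) if config.annotation else []
    )
    bundle["treated_peaks"] = (
        load_peaks(config.treated_peaks, "rifampin") if config.treated_peaks else []
    )
    bundle["control_peaks"] = (
        load_peaks(config.control_peaks, "vehicle") if config.control_peaks else []
    )
    return bundle


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle to ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalogue: TransporterCatalogue = (
        load_catalogue(config.catalogue) if config.catalogue else default_catalogue()
    )

    try:
        bundle = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("load_inputs", exc) from exc

    results: dict = {}

    # --- RNA-seq differential expression over the catalogue -------------
    try:
        model = TransporterDE(
            bundle["counts"], catalogue, min_reads=config.min_reads
        )
        de = model.fit(test_mode=config.test_mode)
        de_tab = de.de_table()
        de_tab.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
        results["de"] = de
    except Exception as exc:  # noqa: BLE001
        raise StageError("rnaseq_de", exc) from exc

    # --- miRNA preprocessing + differential ------------------------------
    try:
        norm = preprocess(
            bundle["ct"], min_samples=config.min_detected, ct_cutoff=config.ct_cutoff
        )
        mirna_res = MirnaDifferential(
            norm, orientation=config.mirna_orientation
        ).fit()
        mirna_res.frame.to_csv(outdir / "mirna_table.tsv", sep="\t")
        results["mirna"] = mirna_res
    except Exception as exc:  # noqa: BLE001
        raise StageError("mirna", exc) from exc

    # --- correlations ----------------------------------------------------
    try:
        sig_genes = de.frame.index[de.frame["q"] < config.q_threshold]
        gene_vecs = de.effect_vectors(sig_genes)
        mirna_vecs = mirna_res.effect_vectors()
        tt = correlation_matrix(gene_vecs) if len(gene_vecs) > 1 else pd.DataFrame(
            columns=["id_a", "id_b", "rho", "p_exact", "n", "ties"]
        )
        tm = (
            correlation_matrix(gene_vecs, mirna_vecs)
            if len(gene_vecs) and len(mirna_vecs)
            else pd.DataFrame(columns=["id_a", "id_b", "rho", "p_exact", "n", "ties"])
        )
        sig_tt = select_significant(tt, alpha=config.alpha)
        sig_tm = select_significant(tm, alpha=config.alpha)
        sig_tt.to_csv(outdir / "correlations_transporter.tsv", sep="\t", index=False)
        sig_tm.to_csv(outdir / "correlations_mirna.tsv", sep="\t", index=False)
        results["correlations_transporter"] = sig_tt
        results["correlations_mirna"] = sig_tm
    except Exception as exc:  # noqa: BLE001
        raise StageError("correlation", exc) from exc

    # --- peak/promoter overlap -------------------------------------------
    try:
        transcripts = bundle.get("transcripts") or []
        if transcripts and bundle.get("treated_peaks"):
            windows = promoter_windows(transcripts, flank=config.flank)
            uniq = unique_peaks(bundle["treated_peaks"], bundle.get("control_peaks") or [])
            hits = intersect_promoters(uniq, windows, distance_mode=config.distance_mode)
            per_gene, per_isoform = distance_report(hits)
        else:
            per_gene = per_isoform = pd.DataFrame()
        per_gene.to_csv(outdir / "promoter_hits.tsv", sep="\t", index=False)
        per_isoform.to_csv(outdir / "promoter_hits_isoforms.tsv", sep="\t", index=False)
        results["promoter_hits"] = per_gene
    except Exception as exc:  # noqa: BLE001
        raise StageError("chipseq", exc) from exc

    # --- top induced/reduced lists ----------------------------------------
    sig = de_tab[de_tab["significant"]]
    top_induced = sig[sig["fold_change"] > 0].nlargest(config.top_n, "fold_change")
    top_reduced = sig[sig["fold_change"] < 0].nsmallest(config.top_n, "fold_change")
    top_induced.to_csv(outdir / "top_induced.tsv", sep="\t", index=False)
    top_reduced.to_csv(outdir / "top_reduced.tsv", sep="\t", index=False)
    results["top_induced"] = top_induced
    results["top_reduced"] = top_reduced

    log = {
        "xenoduct_version": __version__,
        "parameters": asdict(config),
        "n_genes_tested": int(de.frame["q"].notna().sum()),
        "n_de_significant": int(sig.shape[0]),
        "n_mirnas_retained": int(len(mirna_res.frame)),
        "n_promoter_hit_genes": int(len(results["promoter_hits"])),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    results["run_log"] = log
    return results
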