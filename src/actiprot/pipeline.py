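"""End-to-end orchestration: simulate -> process -> quantify -> covariates
-> fit -> summarize, with a JSON manifest for bit-reproducibility."""

from __future__ import annotations

import json
import logging
import time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .annotate import summarize_categories
from .config import PipelineConfig
from .covariates import build_covariates
from .models import fit_all
from .psm import apply_purity_correction, filter_psm_table
from .quantify import quantify
from .simulate import simulate_cohort

logger = logging.getLogger(__name__)


def category_vocabulary() -> pd.DataFrame:
    """The editable category vocabulary shipped with the package."""
    with resources.files("actiprot.data").joinpath("categories.tsv").open("rb") as fh:
        return pd.read_csv(fh, sep="\t")


def random_annotation(
    accessions: list[str], seed: int, frac_annotated: float = 0.6
) -> pd.DataFrame:
    """Assign random vocabulary categories to synthetic accessions."""
    rng = np.random.default_rng(seed)
    vocab = [c for c in category_vocabulary()["category"] if c != "other"]
    rows = []
    for acc in accessions:
        cats: list[str] = []
        if rng.random() < frac_annotated:
            k = 1 + int(rng.random() < 0.2)  # a few proteins carry two labels
            cats = list(rng.choice(vocab, size=k, replace=False))
        rows.append({"accession": acc, "categories": ";".join(cats)})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order and return the manifest dict.

    Stage outputs are pure functions of (inputs, config, seed); the
    manifest records the seed, row counts and SHA-256 of every table so
    two runs can be compared byte for byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "actiprot_version": __version__,
        "seed": config.seed,
        "stages": [],
        "files": {},
        "counts": {},
    }

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"].append(name)
        return time.perf_counter()

    def done(name: str, t0: float, **files: Path) -> None:
        for key, path in files.items():
            manifest["files"][f"{name}.{key}"] = io.sha256_file(path)
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    # --- simulate / load --------------------------------------------------
    t0 = stage("simulate")
    if config.psm_path and config.samples_path:
        psm = io.read_psm_table(config.psm_path)
        samples = io.read_samples_table(config.samples_path)
        truth = None
    else:
        config.cohort.seed = config.seed
        psm, samples, truth = simulate_cohort(config.cohort)
        io.write_tsv(psm, out / "psm.tsv")
        io.write_tsv(samples, out / "samples.tsv")
        io.write_tsv(truth.protein_effects, out / "truth.tsv")
        for w in truth.report.get("warnings", []):
            logger.warning("generator: %s", w)
        done("simulate", t0, psm=out / "psm.tsv", samples=out / "samples.tsv",
             truth=out / "truth.tsv")
    manifest["counts"]["psm_records"] = len(psm)
    manifest["counts"]["samples"] = len(samples)

    # --- process ----------------------------------------------------------
    t0 = stage("process")
    purity = (
        io.read_purity_matrix(config.purity_path)
        if config.purity_path
        else config.cohort.purity_matrix
    )
    corrected = apply_purity_correction(psm, purity)
    filtered, report = filter_psm_table(corrected, samples, config.filters)
    io.write_tsv(filtered, out / "psm.filtered.tsv")
    io.write_tsv(report.to_frame(), out / "filter_report.tsv")
    manifest["counts"]["psm_retained"] = len(filtered)
    manifest["counts"]["proteins_retained"] = report.n_proteins_out
    done("process", t0, filtered=out / "psm.filtered.tsv",
         report=out / "filter_report.tsv")

    # --- quantify ---------------------------------------------------------
    t0 = stage("quantify")
    matrix = quantify(filtered, samples)
    io.write_tsv(matrix.values_df, out / "protein_matrix.tsv", index=True)
    io.write_tsv(matrix.provenance, out / "provenance.tsv")
    manifest["counts"]["proteins_quantified"] = len(matrix.values_df)
    done("quantify", t0, matrix=out / "protein_matrix.tsv",
         provenance=out / "provenance.tsv")

    # --- covariates -------------------------------------------------------
    t0 = stage("covariates")
    covariates = build_covariates(samples, matrix)
    io.write_tsv(covariates.reset_index(), out / "covariates.tsv")
    done("covariates", t0, covariates=out / "covariates.tsv")

    # --- fit --------------------------------------------------------------
    t0 = stage("fit")
    results, meta = fit_all(matrix, covariates, config.model, alpha=config.alpha)
    io.write_tsv(results, out / "results.tsv")
    meta_path = out / "model_meta.json"
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump({**meta, "seed": config.seed}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["counts"]["significant"] = int(
        (results["direction"] != "ns").sum()
    )
    done("fit", t0, results=out / "results.tsv", meta=meta_path)

    # --- summarize --------------------------------------------------------
    t0 = stage("summarize")
    if config.annotation_path:
        from .annotate import load_annotation

        annotation = load_annotation(config.annotation_path)
    else:
        annotation = random_annotation(list(results["accession"]), config.seed)
        io.write_tsv(annotation, out / "annotation.tsv")
    summary = summarize_categories(results, annotation)
    io.write_tsv(summary, out / "category_summary.tsv")
    done("summarize", t0, summary=out / "category_summary.tsv")

    io.write_manifest(out / "manifest.json", manifest)
    return manifest
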