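"""Annotation-category summaries of the differential results.

Joins per-protein results to a curated accession -> category table and
counts, per category, how many quantified proteins were significantly
associated with activity and in which direction.  Multi-label proteins
count toward each of their categories; unannotated proteins fall into
``other``.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

OTHER_CATEGORY = "other"


def load_annotation(path: str) -> pd.DataFrame:
    """Read an annotation TSV (accession, ';'-separated categories)."""
    ann = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"accession", "categories"}.issubset(ann.columns):
        raise ValueError("annotation table needs 'accession' and 'categories' columns")
    if ann["accession"].duplicated().any():
        dup = ann.loc[ann["accession"].duplicated(), "accession"].iloc[0]
        raise ValueError(f"duplicate accession in annotation table: {dup!r}")
    return ann


def summarize_categories(
    results: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    multi_label: bool = True,
) -> pd.DataFrame:
    """Per-category counts of quantified / significant / up / down proteins.

    ``results`` is a ``fit_all`` table (accession, beta, p_value,
    direction).  ``annotation`` maps accession to ';'-separated category
    labels; proteins without labels are counted under ``other``.  With
    ``multi_label=False`` only each protein's first listed category is
    used.  Annotation accessions absent from the results are reported in
    the log, never fatal.
    """
    labels: dict[str, list[str]] = {}
    if annotation is not None and len(annotation):
        for _, row in annotation.iterrows():
            cats = [c.strip() for c in str(row["categories"]).split(";") if c.strip()]
            labels[row["accession"]] = cats if multi_label else cats[:1]
        unmatched = set(labels) - set(results["accession"])
        if unmatched:
            logger.warning(
                "%d annotated accession(s) absent from results, e.g. %s",
                len(unmatched),
                sorted(unmatched)[:3],
            )

    rows = []
    for _, res in results.iterrows():
        cats = labels.get(res["accession"]) or [OTHER_CATEGORY]
        for cat in cats:
            rows.append(
                {
                    "category": cat,
                    "significant": res["direction"] in ("up", "down"),
                    "up": res["direction"] == "up",
                    "down": res["direction"] == "down",
                }
            )
    long = pd.DataFrame(rows)
    summary = (
        long.groupby("category")
        .agg(
            n_quantified=("category", "size"),
            n_significant=("significant", "sum"),
            n_up=("up", "sum"),
            n_down=("down", "sum"),
        )
        .reset_index()
    )
    summary["fraction_up_of_significant"] = (
        summary["n_up"] / summary["n_significant"].where(summary["n_significant"] > 0)
    )
    return summary.sort_values("category").reset_index(drop=True)
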