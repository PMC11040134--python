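"""Joint occupancy-vs-protein classification (the "dichotomy").

Joins per-gene ribosome-occupancy verdicts with per-protein abundance
verdicts and collapses each (occupancy, protein) verdict pair into a
category label. The two headline categories contrast translation load with
protein output:

* ``category-1`` — occupancy up while protein is down or unchanged:
  ribosomes pile onto the transcript without a matching gain in protein
  (stalling / unproductive translation signature).
* ``category-2`` — occupancy unchanged while protein is down or up:
  protein-level change without a translation-load change (turnover or
  import effects).

All other verdict combinations receive systematic combinatorial labels, so
the category map is a total function over the verdict grid.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptRecord

logger = logging.getLogger(__name__)

OCC_VERDICTS = ("up", "unchanged", "down", "untested")
PROT_VERDICTS = ("up", "unchanged", "down", "untested", "not_detected")
COMPARISONS = ("het", "homo")


def join_omics(
    occupancy_verdicts: pd.DataFrame,
    protein_verdicts: pd.DataFrame,
    id_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Full outer join of occupancy and protein verdicts on gene symbol.

    ``id_map`` translates transcript gene ids to protein ids (identity by
    default). Genes absent from the proteomics table get protein verdict
    ``not_detected``; proteins absent from the occupancy table get occupancy
    verdict ``untested``. One row per (gene, comparison).
    """
    id_map = dict(id_map or {})
    occ_ids = [id_map.get(g, g) for g in occupancy_verdicts.index]
    if len(set(occ_ids)) != len(occ_ids):
        dupes = sorted({g for g in occ_ids if occ_ids.count(g) > 1})
        raise ValueError(f"duplicate symbols after id mapping: {dupes}")

    occ = occupancy_verdicts.copy()
    occ.index = occ_ids
    all_ids = sorted(set(occ.index) | set(protein_verdicts.index))

    rows = []
    for gene in all_ids:
        for comp in COMPARISONS:
            if gene in occ.index and f"verdict_{comp}" in occ.columns:
                ov = occ.loc[gene, f"verdict_{comp}"]
            else:
                ov = "untested"
            if gene in protein_verdicts.index:
                pv = protein_verdicts.loc[gene, f"verdict_{comp}"]
            else:
                pv = "not_detected"
            rows.append((gene, f"{comp}_vs_control", ov, pv))
    joined = pd.DataFrame(rows, columns=["gene_id", "comparison",
                                         "occupancy_verdict", "protein_verdict"])
    n_both = len(set(occ.index) & set(protein_verdicts.index))
    logger.info("join: %d occupancy genes, %d proteins, %d shared",
                len(occ.index), len(protein_verdicts.index), n_both)
    return joined


def dichotomy_category(occupancy_verdict: str, protein_verdict: str) -> str:
    """Collapse one verdict pair to its category label (total function)."""
    if occupancy_verdict not in OCC_VERDICTS:
        raise ValueError(f"unknown occupancy verdict {occupancy_verdict!r}")
    if protein_verdict not in PROT_VERDICTS:
        raise ValueError(f"unknown protein verdict {protein_verdict!r}")
    if occupancy_verdict == "untested":
        return "occupancy-untested"
    if protein_verdict == "not_detected":
        return "protein-not-detected"
    if protein_verdict == "untested":
        return "protein-untested"
    if occupancy_verdict == "up" and protein_verdict in ("down", "unchanged"):
        return "category-1"
    if occupancy_verdict == "unchanged" and protein_verdict in ("down", "up"):
        return "category-2"
    if occupancy_verdict == protein_verdict:
        return f"concordant-{occupancy_verdict}" if occupancy_verdict != "unchanged" \
            else "unchanged"
    return f"occupancy-{occupancy_verdict}-protein-{protein_verdict}"


def classify_dichotomy(joined: pd.DataFrame) -> pd.DataFrame:
    """Assign the category label to every (gene, comparison) row."""
    out = joined.copy()
    out["category"] = [dichotomy_category(o, p) for o, p in
                       zip(out["occupancy_verdict"], out["protein_verdict"])]
    return out


def stratify_report(
    records: pd.DataFrame,
    annotation: Sequence[TranscriptRecord],
) -> tuple[pd.DataFrame, str]:
    """Per-stratum verdict/category counts plus a human-readable summary.

    Strata are the annotation gene classes (mt-OXPHOS, nu-OXPHOS,
    mito-associated, other); genes absent from the annotation are grouped
    under ``unannotated``. Counts across cells sum to the record count.
    """
    gene_class = {r.gene_id: r.gene_class for r in annotation if not r.is_contaminant}
    rec = records.copy()
    rec["stratum"] = [gene_class.get(g, "unannotated") for g in rec["gene_id"]]

    table = (rec.groupby(["stratum", "comparison", "occupancy_verdict", "category"])
             .size().rename("n").reset_index())

    lines = ["Dichotomy summary (counts of gene x comparison records)", ""]
    for stratum, sub in rec.groupby("stratum"):
        lines.append(f"[{stratum}] {len(sub)} records")
        for comp, csub in sub.groupby("comparison"):
            occ = csub["occupancy_verdict"].value_counts().to_dict()
            cat = csub["category"].value_counts().to_dict()
            lines.append(f"  {comp}: occupancy {occ}")
            lines.append(f"  {comp}: categories {cat}")
        lines.append("")
    return table, "\n".join(lines)
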