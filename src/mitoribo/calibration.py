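"""Simulation studies: effect recovery, error-rate calibration, end-to-end
category assignment.

These studies drive the whole pipeline (generator -> statistics ->
classification) on replicated synthetic experiments with known ground truth
and summarize how well planted effects are recovered and how calibrated the
null error rates are. They are ordinary package functionality — usable for
power analysis when planning designs of this shape — and double as the
package's empirical self-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import AnnotationConfig, build_default_annotation
from .integrate import classify_dichotomy, join_omics
from .occupancy import classify_occupancy_change, compute_occupancy, occupancy_stats
from .align import CountMatrix
from .pipeline import detected_proteins
from .proteomics import (
    classify_protein_change,
    normalize_channels,
    protein_statistics,
    rollup_proteins,
)
from .simulate import (
    RiboseqParams,
    TmtParams,
    TruthTable,
    paired_design,
    simulate_counts,
    simulate_tmt_experiment,
)


def _occupancy_from_counts(rpf: pd.DataFrame, mrna: pd.DataFrame,
                           design) -> pd.DataFrame:
    rpf_cm = CountMatrix(rpf, rpf.sum(axis=0).astype(float), "RPF")
    mrna_cm = CountMatrix(mrna, mrna.sum(axis=0).astype(float), "mRNA")
    return compute_occupancy(rpf_cm, mrna_cm, design, mode="raw")


def occupancy_recovery_study(
    n_sims: int = 50,
    n_planted: int = 20,
    fold_change: float = 3.0,
    n_replicates: int = 3,
    params: RiboseqParams | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Recovery of a planted het occupancy fold change on mt-OXPHOS genes.

    Each simulation plants ``fold_change`` on ``n_planted`` mitochondrially
    encoded genes (het only), runs the count model at the default depth, and
    tests with ANOVA + Dunnett. Reports the geometric-mean estimated fold
    change over planted genes and the fraction detected at ``alpha``.
    """
    params = params or RiboseqParams()
    cfg = AnnotationConfig(n_mt_oxphos=n_planted)
    design = paired_design(n_replicates)
    root = np.random.default_rng(seed)

    log_fcs, detected, total = [], 0, 0
    for _ in range(n_sims):
        rng = np.random.default_rng(root.integers(2**31))
        records = build_default_annotation(cfg, rng)
        genes = [r.gene_id for r in records if not r.is_contaminant]
        planted = [r.gene_id for r in records if r.gene_class == "mt-OXPHOS"]
        truth = TruthTable.null(genes).set_occupancy_fc(planted, het=fold_change)
        rpf, mrna, _ = simulate_counts(records, design, truth, params, rng)
        occ = _occupancy_from_counts(rpf, mrna, design)
        stats = occupancy_stats(occ)
        sub = stats.loc[planted]
        tested = sub["status"] == "tested"
        est = sub.loc[tested, "mean_het"] / sub.loc[tested, "mean_control"]
        log_fcs.extend(np.log(est[est > 0]))
        detected += int(((sub["dunnett_p_het"] < alpha)
                         & (sub["direction_het"] == "up")).sum())
        total += len(planted)
    return {
        "geomean_fc": float(np.exp(np.mean(log_fcs))),
        "power": detected / total,
        "n_gene_tests": total,
    }


def dunnett_null_calibration(
    n_sims: int = 50,
    n_genes: int = 500,
    n_replicates: int = 3,
    params: RiboseqParams | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Family-wise error of the per-gene Dunnett procedure under the null.

    Simulates expression with no planted effects and counts genes where any
    Dunnett-adjusted contrast p falls below ``alpha``. Under exact
    calibration the rate equals the nominal family-wise level.
    """
    params = params or RiboseqParams()
    cfg = AnnotationConfig(n_mt_oxphos=13, n_nu_oxphos=0, n_mito_associated=0,
                           n_other=max(n_genes - 13, 0))
    design = paired_design(n_replicates)
    root = np.random.default_rng(seed)

    false_pos, tested = 0, 0
    for _ in range(n_sims):
        rng = np.random.default_rng(root.integers(2**31))
        records = build_default_annotation(cfg, rng)
        genes = [r.gene_id for r in records if not r.is_contaminant]
        truth = TruthTable.null(genes)
        rpf, mrna, _ = simulate_counts(records, design, truth, params, rng)
        occ = _occupancy_from_counts(rpf, mrna, design)
        stats = occupancy_stats(occ)
        ok = stats["status"] == "tested"
        any_sig = ((stats.loc[ok, "dunnett_p_het"] < alpha)
                   | (stats.loc[ok, "dunnett_p_homo"] < alpha))
        false_pos += int(any_sig.sum())
        tested += int(ok.sum())
    rate = false_pos / tested
    return {
        "familywise_rate": rate,
        "nominal": alpha,
        "binomial_sd": float(np.sqrt(alpha * (1 - alpha) / tested)),
        "n_gene_tests": tested,
    }


def tmt_fdr_calibration(
    n_sims: int = 50,
    n_proteins: int = 2000,
    params: TmtParams | None = None,
    fdr_alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Realized false-discovery proportion of the ANOVA + BH gate on null
    TMT experiments (no planted shifts; every discovery is false)."""
    params = params or TmtParams(peptides_per_protein=(1, 3))
    root = np.random.default_rng(seed)
    ids = [f"P{i:04d}" for i in range(n_proteins)]
    truth = TruthTable.null(ids)

    fdps = []
    n_discoveries = 0
    for _ in range(n_sims):
        rng = np.random.default_rng(root.integers(2**31))
        pep, plex, _ = simulate_tmt_experiment(ids, truth, params=params, seed=rng)
        rolled = rollup_proteins(normalize_channels(pep))
        stats = protein_statistics(rolled, plex, fdr_alpha=fdr_alpha)
        disc = int((stats["bh_q"] < fdr_alpha).sum())
        n_discoveries += disc
        fdps.append(1.0 if disc > 0 else 0.0)  # all discoveries are false
    return {
        "mean_fdp": float(np.mean(fdps)),
        "total_discoveries": n_discoveries,
        "n_protein_tests": n_sims * n_proteins,
    }


def dichotomy_recovery_study(
    n_sims: int = 50,
    n_category1: int = 8,
    n_category2: int = 8,
    n_replicates: int = 3,
    ribo_params: RiboseqParams | None = None,
    tmt_params: TmtParams | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """End-to-end recovery of planted dichotomy categories.

    Category-1 genes get occupancy FC 3 with protein log2 shift -1 (ribosome
    load up, protein down); category-2 genes keep occupancy flat with
    protein shifts of +/-1. Both effects are planted in het and homo, and
    recovery is scored per comparison over both planted sets.
    """
    ribo_params = ribo_params or RiboseqParams()
    tmt_params = tmt_params or TmtParams()
    cfg = AnnotationConfig()
    design = paired_design(n_replicates)
    root = np.random.default_rng(seed)

    correct, total = 0, 0
    for _ in range(n_sims):
        rng = np.random.default_rng(root.integers(2**31))
        records = build_default_annotation(cfg, rng)
        genes = [r.gene_id for r in records if not r.is_contaminant]
        mt = [r.gene_id for r in records if r.gene_class == "mt-OXPHOS"]
        assoc = [r.gene_id for r in records if r.gene_class == "mito-associated"]
        cat1 = mt[:n_category1]
        cat2 = assoc[:n_category2]
        truth = (TruthTable.null(genes)
                 .set_occupancy_fc(cat1, het=3.0, homo=3.0)
                 .set_protein_shift(cat1, het=-1.0, homo=-1.0)
                 .set_protein_shift(cat2[: len(cat2) // 2], het=-1.0, homo=-1.0)
                 .set_protein_shift(cat2[len(cat2) // 2:], het=1.0, homo=1.0))

        rpf, mrna, _ = simulate_counts(records, design, truth, ribo_params, rng)
        occ = _occupancy_from_counts(rpf, mrna, design)
        overd = classify_occupancy_change(occupancy_stats(occ))

        proteins = detected_proteins(records, undetected=())
        pep, plex, _ = simulate_tmt_experiment(proteins, truth,
                                               params=tmt_params, seed=rng)
        rolled = rollup_proteins(normalize_channels(pep))
        pverd = classify_protein_change(protein_statistics(rolled, plex))

        dich = classify_dichotomy(join_omics(overd, pverd))
        by_gene = dich.set_index(["gene_id", "comparison"])["category"]
        for comp in ("het_vs_control", "homo_vs_control"):
            for g in cat1:
                correct += int(by_gene.get((g, comp)) == "category-1")
            for g in cat2:
                correct += int(by_gene.get((g, comp)) == "category-2")
            total += len(cat1) + len(cat2)
    return {"recovery": correct / total, "n_planted_records": total}
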