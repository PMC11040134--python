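"""TMT isobaric proteomics: impurity correction, normalization, rollup, stats.

The quantification cascade mirrors standard practice for reporter-ion TMT
data: (1) invert the label isotope-impurity mixing per peptide, (2) log2
transform and median-sweep normalize channels (the fixed-effects median
solution of the ANOVA-style normalization model), (3) roll peptides up to
proteins by the mean, (4) per-protein one-way ANOVA across genotypes with
Benjamini-Hochberg FDR control, gated pairwise t-tests (het vs control,
homo vs control), and (5) mitochondrial annotation against a supplied
MitoCarta-style gene list.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .simulate import UNUSED
from .stats import bh_adjust, oneway_anova

logger = logging.getLogger(__name__)

META_COLS = ("peptide_id", "protein_id")


def _channel_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def correct_isotope_impurities(
    table: pd.DataFrame,
    impurity: pd.DataFrame,
) -> pd.DataFrame:
    """Undo reporter-channel crosstalk: solve observed = M^T . true per peptide.

    ``impurity`` rows give the observed channel composition of each label.
    Missing values propagate as missing (treated as zero during the solve);
    negative solutions are clamped to zero via nonnegative least squares.
    A numerically singular matrix without a nonnegative solution leaves the
    row uncorrected with a warning.
    """
    channels = _channel_columns(table)
    m = impurity.loc[channels, channels].to_numpy(dtype=float)
    obs = table[channels].to_numpy(dtype=float)
    missing = np.isnan(obs)
    filled = np.where(missing, 0.0, obs)

    mt = m.T
    try:
        solved = np.linalg.solve(mt, filled.T).T
    except np.linalg.LinAlgError:
        solved = None

    out = np.empty_like(filled)
    for i in range(filled.shape[0]):
        if missing[i].all():
            out[i] = filled[i]
            continue
        row = solved[i] if solved is not None else None
        if row is None or np.any(row < -1e-9 * max(filled[i].max(), 1.0)):
            try:
                row, _ = nnls(mt, filled[i])
            except RuntimeError:
                logger.warning("impurity correction failed for row %d; passing through", i)
                row = filled[i]
        out[i] = np.clip(row, 0.0, None)

    corrected = table.copy()
    corrected[channels] = np.where(missing, np.nan, out)
    return corrected


def normalize_channels(table: pd.DataFrame, min_values: int = 10) -> pd.DataFrame:
    """Log2 transform and equalize per-channel medians (median sweep).

    Each occupied channel's peptide-level median is subtracted and the grand
    median added back, so all channels end with equal medians while the
    overall intensity scale is preserved. Zeros are treated as missing.
    Channels with fewer than ``min_values`` observations are only shifted by
    the grand median (warning logged).
    """
    channels = _channel_columns(table)
    vals = table[channels].to_numpy(dtype=float)
    vals = np.where(vals > 0, vals, np.nan)
    log2 = np.log2(vals)

    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(log2, axis=0)
    n_obs = np.sum(~np.isnan(log2), axis=0)
    grand = np.nanmedian(log2)
    for j, ch in enumerate(channels):
        if n_obs[j] < min_values:
            # empty columns are unused channels; only sparse ones are notable
            log = logger.debug if n_obs[j] == 0 else logger.warning
            log("channel %s has %d values; normalized by grand median only",
                ch, n_obs[j])
            med[j] = grand
    normalized = log2 - med + grand

    out = table.copy()
    out[channels] = normalized
    return out


def rollup_proteins(table: pd.DataFrame, shared_peptides: str = "drop") -> pd.DataFrame:
    """Protein x channel matrix: mean of each protein's peptide log2 values.

    Peptides assigned to multiple proteins (same peptide_id under several
    protein_ids) are dropped by default or kept with their first listed
    protein (``shared_peptides="assign_first"``). Missing values are ignored
    in the mean; proteins keep a row as long as they have >= 1 peptide.
    """
    if shared_peptides not in ("drop", "assign_first"):
        raise ValueError(f"unknown shared_peptides policy {shared_peptides!r}")
    channels = _channel_columns(table)
    tab = table
    dup = table.groupby("peptide_id")["protein_id"].nunique()
    shared = set(dup[dup > 1].index)
    if shared:
        if shared_peptides == "drop":
            tab = table[~table["peptide_id"].isin(shared)]
        else:
            tab = table.drop_duplicates(subset="peptide_id", keep="first")
    grouped = tab.groupby("protein_id")[channels].mean()
    grouped["n_peptides"] = tab.groupby("protein_id").size()
    return grouped


def protein_statistics(
    proteins: pd.DataFrame,
    plex: pd.DataFrame,
    fdr_alpha: float = 0.05,
    t_alpha: float = 0.05,
    ttest: str = "welch",
) -> pd.DataFrame:
    """Per-protein ANOVA + BH FDR + gated pairwise t-tests.

    One-way ANOVA across the genotypes, BH step-up over all testable
    proteins, then het-vs-control and homo-vs-control two-sample t-tests
    (Welch by default, pooled with ``ttest="student"``). ``passes_gate_*``
    requires bh_q < fdr_alpha AND the comparison's t-test p < t_alpha — the
    gated cascade; log2 fold changes (mutant mean - control mean) are
    reported for every protein regardless of the gate.
    """
    plex = plex[plex["genotype"] != UNUSED]
    genotypes = ["control", "het", "homo"]
    chans = {g: list(plex.loc[plex["genotype"] == g, "channel"]) for g in genotypes}
    for g, cols in chans.items():
        if not cols:
            raise ValueError(f"plex design has no channels for genotype {g}")
    if ttest not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {ttest!r}")

    groups = [proteins[chans[g]].to_numpy(dtype=float) for g in genotypes]
    anova = oneway_anova(groups)

    out = pd.DataFrame(index=proteins.index)
    out["n_peptides"] = proteins.get("n_peptides", pd.Series(1, index=proteins.index))
    for gi, g in enumerate(genotypes):
        out[f"mean_log2_{g}"] = anova["means"][:, gi]
    out["log2fc_het"] = out["mean_log2_het"] - out["mean_log2_control"]
    out["log2fc_homo"] = out["mean_log2_homo"] - out["mean_log2_control"]
    anova_p = np.where(anova["testable"], anova["p"], np.nan)
    out["anova_p"] = anova_p
    out["bh_q"] = bh_adjust(anova_p)
    out["testable"] = anova["testable"] & ~anova["degenerate"]

    for comp, gi in (("het", 1), ("homo", 2)):
        pvals = _pairwise_t_pvalues(groups[gi], groups[0], ttest)
        out[f"ttest_p_{comp}"] = pvals
        out[f"passes_gate_{comp}"] = ((out["bh_q"] < fdr_alpha)
                                      & (pvals < t_alpha)).fillna(False)
    return out


def _pairwise_t_pvalues(a: np.ndarray, b: np.ndarray, ttest: str) -> np.ndarray:
    """Row-wise two-sample t-test p-values, NaN-aware and vectorized.

    Matches scipy.stats.ttest_ind (equal_var per ``ttest``) on each row;
    rows with fewer than two observations in either group give NaN.
    """
    from scipy import stats as sps

    import warnings

    def moments(x):
        n = np.sum(~np.isnan(x), axis=1).astype(float)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(x, axis=1)
            v = np.nanvar(x, axis=1, ddof=1)
        return n, m, v

    na, ma, va = moments(np.asarray(a, dtype=float))
    nb, mb, vb = moments(np.asarray(b, dtype=float))
    valid = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        if ttest == "welch":
            sa, sb = va / na, vb / nb
            t = (ma - mb) / np.sqrt(sa + sb)
            df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
            df = na + nb - 2
        p = 2.0 * sps.t.sf(np.abs(t), df)
    return np.where(valid, p, np.nan)


def annotate_mito(records: pd.DataFrame, mito_genes: Iterable[str]) -> pd.DataFrame:
    """Flag proteins on a MitoCarta-style list (case-insensitive symbol match)."""
    mito = {g.strip().lower() for g in mito_genes if str(g).strip()}
    if not mito:
        logger.warning("empty mitochondrial gene list; all mito_flag False")
    out = records.copy()
    out["mito_flag"] = [str(p).lower() in mito for p in out.index]
    return out


def classify_protein_change(stats: pd.DataFrame) -> pd.DataFrame:
    """Verdict per comparison from the gated cascade: up/down when the gate
    passes with the fold-change sign, unchanged when testable but gated out,
    untested otherwise."""
    out = pd.DataFrame(index=stats.index)
    for comp in ("het", "homo"):
        verdict = np.full(len(stats), "untested", dtype=object)
        testable = stats["testable"].to_numpy(dtype=bool)
        verdict[testable] = "unchanged"
        passed = (stats[f"passes_gate_{comp}"].to_numpy(dtype=bool)) & testable
        fc = stats[f"log2fc_{comp}"].to_numpy(dtype=float)
        verdict[passed & (fc > 0)] = "up"
        verdict[passed & (fc < 0)] = "down"
        out[f"verdict_{comp}"] = verdict
    return out


def dotplot_table(stats: pd.DataFrame, p_cap: float = 10.0) -> pd.DataFrame:
    """Plot-ready long table: one row per (protein, comparison) with the
    log2 fold change and the -log10 t-test p (capped for p == 0)."""
    rows = []
    for comp in ("het", "homo"):
        p = stats[f"ttest_p_{comp}"].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            neglog = np.where(p > 0, -np.log10(p), p_cap)
        neglog = np.where(np.isnan(p), np.nan, np.minimum(neglog, p_cap))
        rows.append(pd.DataFrame({
            "protein_id": stats.index,
            "comparison": f"{comp}_vs_control",
            "log2fc": stats[f"log2fc_{comp}"].to_numpy(),
            "neg_log10_p": neglog,
        }))
    return pd.concat(rows, ignore_index=True)


def render_dotplot(table: pd.DataFrame, path: str) -> None:
    """Dot plot in the style of a multi-omics comparison figure: dot size
    proportional to -log10 p, color encoding log2 fold change."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    proteins = sorted(table["protein_id"].unique())
    comps = sorted(table["comparison"].unique())
    fig, ax = plt.subplots(figsize=(max(4, len(proteins) * 0.3), 2 + len(comps)))
    ypos = {c: i for i, c in enumerate(comps)}
    xpos = {p: i for i, p in enumerate(proteins)}
    sub = table.dropna(subset=["neg_log10_p"])
    sc = ax.scatter([xpos[p] for p in sub["protein_id"]],
                    [ypos[c] for c in sub["comparison"]],
                    s=20 + 40 * sub["neg_log10_p"], c=sub["log2fc"],
                    cmap="coolwarm", vmin=-2, vmax=2, edgecolor="k", linewidth=0.3)
    ax.set_xticks(range(len(proteins)))
    ax.set_xticklabels(proteins, rotation=90, fontsize=6)
    ax.set_yticks(range(len(comps)))
    ax.set_yticklabels(comps)
    fig.colorbar(sc, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
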