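"""Ribosome occupancy (RPF/mRNA) and its genotype statistics.

Occupancy — often called translation efficiency — is the per-gene ratio of
ribosome-protected-fragment abundance to mRNA abundance. High occupancy with
unchanged or reduced protein output is the signature of slow or stalled
ribosomes. Genotype effects are assessed per gene by one-way ANOVA followed
by Dunnett's many-to-one comparisons of each mutant genotype (het, homo)
against the shared control; with only two genotypes present the analysis
falls back to a Student t test.

Also provides the coverage polarity score: the coverage-weighted mean of a
linear position map over the CDS (-1 at the 5' end, +1 at the 3' end), a
signed one-number summary of where footprints accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import CountMatrix, CoverageProfile
from .simulate import GENOTYPES, SampleDesign, DesignError
from .stats import dunnett_pvalues, many_to_one_t, oneway_anova, student_ttest

COMPARISONS = ("het", "homo")
VERDICTS = ("up", "unchanged", "down", "untested")


def compute_occupancy(
    rpf: CountMatrix,
    mrna: CountMatrix,
    design: Sequence[SampleDesign],
    mode: str = "raw",
) -> pd.DataFrame:
    """Per-gene, per-replicate occupancy table.

    Columns are (genotype, replicate) pairs; each cell is RPF/mRNA for that
    replicate pair of samples, computed from raw counts (``mode="raw"``) or
    from counts-per-million (``mode="cpm"``). Entries where the mRNA count
    is zero are NaN (undefined, not infinite); RPF 0 over mRNA > 0 is 0.0.
    """
    if mode not in ("raw", "cpm"):
        raise ValueError(f"unknown occupancy mode {mode!r}")
    if list(rpf.counts.index) != list(mrna.counts.index):
        raise ValueError("RPF and mRNA matrices must share gene order")

    by_key = {(d.genotype, d.replicate, d.assay): d.sample_id for d in design}
    pairs = sorted({(d.genotype, d.replicate) for d in design})
    for g, r in pairs:
        if (g, r, "RPF") not in by_key or (g, r, "mRNA") not in by_key:
            raise DesignError(f"unpaired replicate: {g} rep {r}")

    rpf_vals = rpf.cpm() if mode == "cpm" else rpf.counts
    mrna_vals = mrna.cpm() if mode == "cpm" else mrna.counts

    out = {}
    for g, r in pairs:
        num = rpf_vals[by_key[(g, r, "RPF")]].to_numpy(dtype=float)
        den = mrna_vals[by_key[(g, r, "mRNA")]].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            occ = np.where(den > 0, num / den, np.nan)
        out[(g, r)] = occ
    table = pd.DataFrame(out, index=rpf.counts.index)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["genotype", "replicate"])
    return table


def genotype_summary(occupancy: pd.DataFrame, how: str = "mean_of_ratios") -> pd.DataFrame:
    """Genotype-level occupancy summaries.

    ``mean_of_ratios`` averages per-replicate ratios; ``ratio_of_means``
    would be computed upstream from replicate-mean abundances — here it is
    approximated by the median for robustness reporting. Both are exposed
    because figure-style summaries can be computed either way.
    """
    if how == "mean_of_ratios":
        return occupancy.T.groupby(level="genotype").mean().T
    if how == "median_of_ratios":
        return occupancy.T.groupby(level="genotype").median().T
    raise ValueError(f"unknown summary {how!r}")


def occupancy_stats(
    occupancy: pd.DataFrame,
    alpha: float = 0.05,
    dunnett_method: str = "mvt",
    mc_seed: int = 0,
) -> pd.DataFrame:
    """Per-gene ANOVA + Dunnett many-to-one statistics across genotypes.

    Genes with any undefined (NaN) replicate are reported ``untested``
    (mirroring the treatment of transcripts with missing replicates rather
    than imputing); genes whose within-group variance is exactly zero are
    flagged ``degenerate`` with NaN p-values. Two-genotype tables fall back
    to a pooled-variance Student t test per contrast.
    """
    genotypes = [g for g in GENOTYPES if g in occupancy.columns.get_level_values(0)]
    if len(genotypes) < 2 or "control" not in genotypes:
        raise DesignError("need a control plus at least one mutant genotype")
    groups = [occupancy[g].to_numpy(dtype=float) for g in genotypes]
    n_reps = {g: occupancy[g].shape[1] for g in genotypes}
    if min(n_reps.values()) < 2:
        raise DesignError("need >= 2 replicates per genotype for statistics")

    genes = occupancy.index
    complete = ~np.any([np.isnan(g).any(axis=1) for g in groups], axis=0)

    out = pd.DataFrame(index=genes)
    for g in genotypes:
        out[f"mean_{g}"] = np.nanmean(groups[genotypes.index(g)], axis=1)
        out[f"n_{g}"] = np.sum(~np.isnan(groups[genotypes.index(g)]), axis=1)
    out["anova_p"] = np.nan
    for comp in COMPARISONS:
        out[f"dunnett_p_{comp}"] = np.nan
        out[f"direction_{comp}"] = "untested"
    out["status"] = np.where(complete, "tested", "untested")

    if not complete.any():
        return out

    sub = [g[complete] for g in groups]
    mutants = [g for g in genotypes if g != "control"]
    if len(genotypes) == 2:
        # two-group fallback: Student's t, reported in both p columns
        t_p = np.array([student_ttest(a, b) for a, b in
                        zip(sub[genotypes.index(mutants[0])],
                            sub[genotypes.index("control")])])
        out.loc[complete, "anova_p"] = t_p[:, 1]
        out.loc[complete, f"dunnett_p_{mutants[0]}"] = t_p[:, 1]
        diffs = (out.loc[complete, f"mean_{mutants[0]}"]
                 - out.loc[complete, "mean_control"]).to_numpy()
        out.loc[complete, f"direction_{mutants[0]}"] = np.where(diffs > 0, "up", "down")
        degenerate = np.isnan(t_p[:, 1])
        out.loc[out.index[complete][degenerate], "status"] = "degenerate"
        return out

    order = ["control"] + mutants
    anova = oneway_anova([sub[genotypes.index(g)] for g in order])
    t = many_to_one_t(anova, control_index=0)
    df = float(np.unique(anova["df_within"])[0])
    ns = anova["ns"]
    p_adj = np.full_like(t, np.nan)
    ok = anova["testable"] & ~anova["degenerate"]
    if ok.any():
        p_adj[ok] = dunnett_pvalues(t[ok], df=df, ns_treat=ns[0, 1:],
                                    n_control=ns[0, 0], method=dunnett_method,
                                    mc_seed=mc_seed)

    idx = out.index[complete]
    out.loc[idx, "anova_p"] = anova["p"]
    for j, comp in enumerate(mutants):
        out.loc[idx, f"dunnett_p_{comp}"] = p_adj[:, j]
        diffs = anova["means"][:, j + 1] - anova["means"][:, 0]
        out.loc[idx, f"direction_{comp}"] = np.where(diffs > 0, "up", "down")
    out.loc[idx[anova["degenerate"]], "status"] = "degenerate"
    out.loc[out["status"] == "degenerate",
            [f"dunnett_p_{c}" for c in mutants] + ["anova_p"]] = np.nan
    return out


def classify_occupancy_change(stats: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-comparison verdicts: up/down when the Dunnett-adjusted p clears
    ``alpha`` with the matching sign of the mean difference; unchanged when
    tested but not significant; untested propagates."""
    out = pd.DataFrame(index=stats.index)
    for comp in COMPARISONS:
        pcol, dcol = f"dunnett_p_{comp}", f"direction_{comp}"
        if pcol not in stats.columns:
            continue
        verdict = np.full(len(stats), "untested", dtype=object)
        tested = (stats["status"] == "tested") & stats[pcol].notna()
        sig = tested & (stats[pcol] < alpha)
        verdict[tested.to_numpy()] = "unchanged"
        verdict[(sig & (stats[dcol] == "up")).to_numpy()] = "up"
        verdict[(sig & (stats[dcol] == "down")).to_numpy()] = "down"
        out[f"verdict_{comp}"] = verdict
    return out


@dataclass
class SkewScore:
    """Signed 5'/3' coverage concentration for one transcript in one sample."""

    transcript_id: str
    sample_id: str
    polarity: float
    total_footprints: float


def polarity_score(profile: CoverageProfile) -> SkewScore:
    """Coverage-weighted mean of the linear position map w_i = 2i/(L-1) - 1.

    Uniform coverage scores ~0; all mass at the last CDS position scores +1,
    at the first position -1. Undefined (raises) for empty profiles.
    """
    c = np.asarray(profile.counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError(f"{profile.transcript_id}: empty coverage profile")
    length = len(c)
    if length == 1:
        w = np.zeros(1)
    else:
        w = 2.0 * np.arange(length) / (length - 1) - 1.0
    return SkewScore(profile.transcript_id, profile.sample_id,
                     float((c * w).sum() / total), float(total))


def polarity_table(profiles: Mapping[tuple[str, str], CoverageProfile]) -> pd.DataFrame:
    rows = []
    for (tid, sample), profile in sorted(profiles.items()):
        if profile.total > 0:
            s = polarity_score(profile)
            rows.append((tid, sample, s.polarity, s.total_footprints))
    return pd.DataFrame(rows, columns=["transcript_id", "sample_id",
                                       "polarity", "total_footprints"])
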