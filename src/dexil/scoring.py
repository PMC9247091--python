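"""Dexamethasone-reversal scoring and gene-signature Z-scores.

The resistance score asks, per gene induced or repressed by IL-17A: how much
of that effect persists when dexamethasone is present?  It is the ratio of
the combination-vs-control effect to the IL-17A-vs-control effect on the
log2 scale, clamped to [0, 1] and expressed as a percentage - 100% fully
dexamethasone-resistant, 0% fully sensitive.  Signature scores summarize a
gene set per sample as the mean of gene-wise standardized log2 expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import CountMatrix


def compute_reversal_scores(
    de_il17: pd.DataFrame,
    de_combo: pd.DataFrame,
    fc_threshold: float = 1.5,
    cutoff: float = 50.0,
    padj_filter: float | None = None,
) -> pd.DataFrame:
    """Score each IL-17A-responsive gene for dexamethasone resistance.

    Eligibility requires |log2FC(IL-17A vs ctrl)| >= log2(fc_threshold)
    (optionally also padj < padj_filter).  For eligible genes the raw ratio
    r = log2FC(combo) / log2FC(IL-17A) is clamped to [0, 1] and scaled to a
    0-100% resistance score: overshoot past baseline (r < 0) scores 0
    (fully reversed), amplification (r > 1) scores 100 (fully resistant).
    class = "sensitive" iff score < cutoff (inhibition >= 100-cutoff %).
    """
    a = de_il17.set_index("gene_id")
    b = de_combo.set_index("gene_id")
    if not a.index.sort_values().equals(b.index.sort_values()):
        offenders = a.index.symmetric_difference(b.index).tolist()
        raise ValueError(f"gene universes differ between contrasts: {offenders[:20]}")
    b = b.reindex(a.index)

    d_il17 = a["log2fc"].to_numpy()
    d_combo = b["log2fc"].to_numpy()
    eligible = np.abs(d_il17) >= np.log2(fc_threshold)
    if padj_filter is not None:
        eligible &= a["padj"].to_numpy() < padj_filter

    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(eligible, d_combo / d_il17, np.nan)
    score = 100.0 * np.clip(r, 0.0, 1.0)
    cls = np.where(
        eligible, np.where(score < cutoff, "sensitive", "resistant"), "ineligible"
    )
    return pd.DataFrame(
        {
            "gene_id": a.index,
            "delta_il17": d_il17,
            "delta_combo": d_combo,
            "eligible": eligible,
            "resistance_score": score,
            "class": cls,
        }
    ).reset_index(drop=True)


def _round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


@dataclass
class ClassificationSummary:
    n_eligible: int
    n_sensitive: int
    n_resistant: int
    pct_sensitive: float | None
    pct_resistant: float | None


def summarize_classification(table: pd.DataFrame) -> ClassificationSummary:
    """Counts and percentages of dexamethasone-sensitive vs -resistant genes.

    Percentages are rounded half-away-from-zero to two decimals and then
    reconciled by largest remainder on the last digit so they always sum to
    exactly 100.00.  An empty eligible set yields None percentages.
    """
    cls = table["class"]
    n_sens = int((cls == "sensitive").sum())
    n_res = int((cls == "resistant").sum())
    n_elig = n_sens + n_res
    if int(table["eligible"].sum()) != n_elig:
        raise ValueError("eligible flags inconsistent with class labels")
    if n_elig == 0:
        return ClassificationSummary(0, 0, 0, None, None)
    raw = np.array([100.0 * n_sens / n_elig, 100.0 * n_res / n_elig])
    centi = np.floor(raw * 100).astype(int)
    remainder = raw * 100 - centi
    short = 10000 - centi.sum()
    for i in np.argsort(-remainder)[:short]:
        centi[i] += 1
    return ClassificationSummary(
        n_eligible=n_elig,
        n_sensitive=n_sens,
        n_resistant=n_res,
        pct_sensitive=float(centi[0]) / 100.0,
        pct_resistant=float(centi[1]) / 100.0,
    )


def zscore_matrix(
    matrix: CountMatrix,
    size_factors: pd.Series,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-wise z-scores of log2 normalized expression across samples.

    y = log2(count/s + pseudocount); z = (y - mean_g) / sd_g with ddof=1.
    Genes constant across samples (sd = 0) cannot be standardized and are
    excluded with a warning.  Returns (z matrix, per-gene parameter table
    with mean, sd and an excluded flag).
    """
    if matrix.counts.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    y = np.log2(
        matrix.counts.to_numpy(float) / size_factors.to_numpy()[None, :] + pseudocount
    )
    mu = y.mean(axis=1)
    sd = y.std(axis=1, ddof=1)
    scored = sd > 0
    if (~scored).any():
        warnings.warn(
            f"{int((~scored).sum())} constant gene(s) excluded from z-scoring"
        )
    z = (y[scored] - mu[scored, None]) / sd[scored, None]
    zdf = pd.DataFrame(z, index=matrix.gene_ids[scored], columns=matrix.sample_ids)
    params = pd.DataFrame(
        {"mean": mu, "sd": sd, "excluded": ~scored}, index=matrix.gene_ids
    )
    return zdf, params


def signature_score(
    z: pd.DataFrame,
    gene_set: list[str],
    samples: pd.DataFrame,
    reference_group: str = "ctrl",
) -> dict:
    """Per-sample signature score (mean z over the set) with group summaries.

    Samples are grouped by condition (ctrl/il17/dex/combo from the two flags).
    Reports each group's mean score, its difference from the reference group,
    and its ratio to the reference (NaN when the reference mean is within
    1e-6 of zero, where a ratio is meaningless).
    """
    present = [g for g in gene_set if g in z.index]
    if not present:
        raise ValueError(f"no signature gene present in z matrix: {list(gene_set)}")
    scores = z.loc[present].mean(axis=0)
    cond = np.select(
        [
            (samples["il17"] == 0) & (samples["dex"] == 0),
            (samples["il17"] == 1) & (samples["dex"] == 0),
            (samples["il17"] == 0) & (samples["dex"] == 1),
        ],
        ["ctrl", "il17", "dex"],
        default="combo",
    )
    per_sample = pd.DataFrame(
        {"score": scores, "group": pd.Series(cond, index=samples.index)}
    )
    group_means = per_sample.groupby("group")["score"].mean()
    ref = group_means.get(reference_group)
    if ref is None:
        raise ValueError(f"reference group {reference_group!r} has no samples")
    diffs = group_means - ref
    ratios = group_means / ref if abs(ref) >= 1e-6 else group_means * np.nan
    return {
        "genes_used": present,
        "per_sample": per_sample,
        "group_means": group_means,
        "difference_vs_reference": diffs,
        "ratio_vs_reference": ratios,
        "reference_group": reference_group,
    }


def top_genes(de: pd.DataFrame, n: int = 10) -> list[str]:
    """The n most regulated genes: padj ascending, then |log2FC| descending,
    then gene id as the final deterministic tiebreak."""
    if de.empty:
        raise ValueError("empty differential-expression table")
    if n > len(de):
        warnings.warn(f"requested {n} genes but only {len(de)} available")
    ranked = de.assign(_abs=lambda d: d["log2fc"].abs()).sort_values(
        ["padj", "_abs", "gene_id"], ascending=[True, False, True], kind="mergesort"
    )
    return ranked["gene_id"].head(n).tolist()
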