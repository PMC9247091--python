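"""Barrier-phenotype association and small assay conversions.

Folds the continuous FITC-dextran permeability readout into the per-gene
NB-GLM as a standardized covariate alongside donor blocks, so genes whose
expression tracks epithelial leakiness get a Wald test on the phenotype
coefficient.  Also houses the fluorescence standard curve and the
comparative-Ct (ddCt) relative-quantification helper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from . import decore
from .simdata import CountMatrix


@dataclass
class StandardCurve:
    """Linear concentration = slope * fluorescence + intercept."""

    slope: float
    intercept: float
    r_squared: float
    f_min: float
    f_max: float


def fit_standard_curve(
    fluorescence: np.ndarray, concentration: np.ndarray
) -> StandardCurve:
    """OLS fit of concentration on fluorescence from calibration standards."""
    f = np.asarray(fluorescence, float)
    c = np.asarray(concentration, float)
    if len(f) < 2 or len(np.unique(f)) < 2:
        raise ValueError("need >= 2 standards with distinct fluorescence values")
    res = scipy.stats.linregress(f, c)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        f_min=float(f.min()),
        f_max=float(f.max()),
    )


def fluorescence_to_concentration(
    curve: StandardCurve, fluorescence: np.ndarray
) -> pd.DataFrame:
    """Convert readings to concentrations with clamping/extrapolation flags.

    Predictions below zero are clamped to 0 (a concentration cannot be
    negative) and flagged; inputs outside the calibrated fluorescence range
    are flagged as extrapolated.
    """
    f = np.asarray(fluorescence, float)
    pred = curve.slope * f + curve.intercept
    clamped = pred < 0
    out_of_range = (f < curve.f_min) | (f > curve.f_max)
    return pd.DataFrame(
        {
            "fluorescence": f,
            "concentration": np.where(clamped, 0.0, pred),
            "clamped": clamped,
            "extrapolated": out_of_range,
        }
    )


def associate_phenotype(
    matrix: CountMatrix,
    phenotype: pd.Series | np.ndarray | None = None,
    pairing: bool = True,
    de_il17: pd.DataFrame | None = None,
    padj_threshold: float = 0.05,
    method: str = "nbglm",
) -> pd.DataFrame:
    """Per-gene association of expression with the permeability phenotype.

    The phenotype (default: the ``permeability`` sample annotation) is
    standardized and enters the NB-GLM as the only non-block covariate, so
    ``beta_pheno`` is the log2 expression change per phenotype standard
    deviation.  Wald p on that coefficient, BH across genes, direction from
    the coefficient sign (up = higher expression with leakier barrier).
    When an IL-17A contrast table is supplied, each significant gene is
    cross-annotated with its IL-17A direction.  ``method="spearman"`` gives
    a rank-correlation fallback for comparison.
    """
    samples = matrix.samples.copy()
    if phenotype is not None:
        samples["permeability"] = np.asarray(phenotype, float)
    pheno = samples["permeability"].to_numpy(float)
    if np.isnan(pheno).any():
        raise ValueError("phenotype missing for some samples")
    if np.ptp(pheno) == 0:
        raise ValueError("phenotype is constant; covariate degenerate")

    if method == "spearman":
        norm = matrix.counts.to_numpy(float) / decore.estimate_size_factors(
            matrix
        ).to_numpy()
        rho = np.empty(matrix.counts.shape[0])
        pv = np.empty_like(rho)
        for g in range(len(rho)):
            rho[g], pv[g] = scipy.stats.spearmanr(norm[g], pheno)
        out = pd.DataFrame(
            {
                "gene_id": matrix.gene_ids,
                "beta_pheno": rho,
                "se": np.nan,
                "pvalue": pv,
            }
        )
    elif method == "nbglm":
        mat = CountMatrix(counts=matrix.counts, samples=samples)
        design = decore.DesignSpec(
            il17=False, dex=False, interaction=False, pairing=pairing,
            covariate="permeability",
        )
        fit = decore.fit_glm_matrix(mat, design)
        c = np.zeros(len(fit.columns))
        c[fit.columns.index("permeability")] = 1.0
        tbl = decore.wald_contrast(fit, c)
        out = tbl.rename(columns={"log2fc": "beta_pheno"})[
            ["gene_id", "beta_pheno", "se", "pvalue", "converged"]
        ]
    else:
        raise KeyError(f"unknown method {method!r}")

    out["padj"] = decore.bh_adjust(out["pvalue"].to_numpy())
    out["direction"] = np.where(out["beta_pheno"] >= 0, "up", "down")
    out["significant"] = out["padj"] < padj_threshold
    if de_il17 is not None:
        il17 = de_il17.set_index("gene_id")
        sig = il17["padj"] < padj_threshold
        il17_dir = pd.Series(
            np.where(sig, np.where(il17["log2fc"] > 0, "up", "down"), "ns"),
            index=il17.index,
        )
        out["il17_direction"] = (
            out["gene_id"].map(il17_dir).fillna("absent").to_numpy()
        )
    return out.reset_index(drop=True)


def ddct_relative_expression(
    cts: pd.DataFrame,
    target: str,
    reference_genes: list[str],
    control_samples: list[str],
) -> pd.DataFrame:
    """Comparative-Ct relative quantification against reference genes.

    Per sample: reference Ct = arithmetic mean of the reference-gene Cts
    (geometric mean on the expression scale); dCt = Ct_target - Ct_ref;
    ddCt = dCt - mean dCt over control samples; RQ = 2^(-ddCt).

    ``cts`` is long format with columns sample_id, gene, ct.
    """
    bad = cts[(cts["ct"] <= 0) | (cts["ct"] >= 45)]
    if len(bad):
        raise ValueError(f"Ct values out of range (0, 45): {bad.to_dict('records')}")
    wide = cts.pivot_table(index="sample_id", columns="gene", values="ct")
    for ref in reference_genes:
        if ref not in wide.columns or wide[ref].isna().any():
            missing = (
                wide.index.tolist()
                if ref not in wide.columns
                else wide.index[wide[ref].isna()].tolist()
            )
            raise ValueError(f"reference gene {ref!r} missing for samples {missing}")
    if target not in wide.columns or wide[target].isna().any():
        raise ValueError(f"target gene {target!r} missing for some samples")
    ref_ct = wide[reference_genes].mean(axis=1)
    dct = wide[target] - ref_ct
    ctrl = [s for s in control_samples if s in dct.index]
    if not ctrl:
        raise ValueError("no control samples present in the Ct table")
    ddct = dct - dct.loc[ctrl].mean()
    rq = 2.0 ** (-ddct)
    return pd.DataFrame(
        {"sample_id": wide.index, "dct": dct, "ddct": ddct, "rq": rq}
    ).reset_index(drop=True)
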