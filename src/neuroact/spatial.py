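"""Spot-level analyses for spatial transcriptomics.

A Visium-style spot mixes signal from many cells, so regional differences in
activity score confound neuronal responsiveness with neuronal abundance.
This module estimates per-spot cell-class composition by regressing spot
expression on three class-averaged signatures (GABAergic, glutamatergic,
non-neuronal), sums the neuronal classes into a density proxy, tests
per-region group effects on activity with a donor random intercept, and
residualizes the log effect sizes on regional density to obtain
density-corrected regional effects.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "deconvolve_classes",
    "neuron_density",
    "region_effects",
    "density_correct",
]


def deconvolve_classes(spot_expr: np.ndarray, signatures: pd.DataFrame,
                       gene_ids=None, n_top_var: int = 500) -> pd.DataFrame:
    """Per-spot class abundances from least squares on class signatures.

    `spot_expr` is genes x spots; `signatures` a genes x 3 table of
    class-averaged profiles (columns GABAergic, glutamatergic, non-neuronal in
    any naming). Only the `n_top_var` genes most variable across class
    profiles are used. Raw coefficients are min-max scaled to [0, 1] per
    class across spots, then renormalized to sum to one within each spot.
    """
    x = np.asarray(spot_expr, dtype=float)
    if gene_ids is not None:
        common = [g for g in signatures.index if g in set(gene_ids)]
        pos = {g: i for i, g in enumerate(gene_ids)}
        x = x[[pos[g] for g in common], :]
        sig = signatures.loc[common]
    else:
        if x.shape[0] != len(signatures):
            raise ValueError("expression rows do not match signature genes")
        sig = signatures
    var = sig.to_numpy().var(axis=1)
    top = np.argsort(var)[::-1][: min(n_top_var, len(var))]
    S = sig.to_numpy()[top]
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValueError("collinear class signatures")
    coef, *_ = np.linalg.lstsq(S, x[top, :], rcond=None)  # 3 x spots
    coef = coef.T  # spots x 3
    lo = coef.min(axis=0)
    rng_ = coef.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0
    scaled = (coef - lo) / rng_
    totals = scaled.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return pd.DataFrame(scaled / totals, columns=signatures.columns)


def neuron_density(abundances: pd.DataFrame, gaba_col=None, glut_col=None,
                   regions=None):
    """Per-spot neuron density = GABAergic + glutamatergic abundance; with
    region labels, also the per-region mean density.

    Returns (density Series, region_means Series or None).
    """
    cols = list(abundances.columns)
    gaba_col = gaba_col or cols[0]
    glut_col = glut_col or cols[1]
    density = abundances[gaba_col] + abundances[glut_col]
    density.name = "neuron_density"
    if regions is None:
        return density, None
    region_means = density.groupby(np.asarray(regions)).mean()
    region_means.name = "mean_neuron_density"
    return density, region_means


def region_effects(scores, spots: pd.DataFrame, group_col: str = "group",
                   donor_col: str = "donor", region_col: str = "region",
                   baseline: str | None = None) -> pd.DataFrame:
    """Per-region group effect on activity with a donor random intercept.

    Fits activity ~ group + (1 | donor) separately per region, reporting the
    coefficient of the non-baseline group, its standard error, a normal-
    approximation p-value, and Benjamini-Hochberg FDR across regions.
    """
    df = spots.copy()
    df["activity"] = np.asarray(scores, dtype=float)
    levels = sorted(df[group_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    baseline = baseline or levels[0]
    other = [g for g in levels if g != baseline][0]
    df["_g"] = (df[group_col].astype(str) == other).astype(float)
    for g in levels:
        n_donors = df.loc[df[group_col].astype(str) == g, donor_col].nunique()
        if n_donors < 2:
            raise ValueError(f"group {g!r} has fewer than 2 donors")
    regions = sorted(df[region_col].astype(str).unique())
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    rows = []
    for region in regions:
        sub = df[df[region_col].astype(str) == region]
        if np.allclose(sub["activity"].var(), 0):
            rows.append((region, 0.0, np.nan, 1.0, len(sub)))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(
                "activity ~ _g", sub, groups=sub[donor_col]
            ).fit(reml=True)
        beta = float(fit.params["_g"])
        se = float(fit.bse["_g"])
        from scipy.stats import norm

        p = float(2 * norm.sf(abs(beta / se))) if se > 0 else 1.0
        rows.append((region, beta, se, p, len(sub)))
    out = pd.DataFrame(
        rows, columns=["region", "beta", "se", "p", "n_spots"]
    ).set_index("region")
    out["p_adjusted"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    return out


def density_correct(effects: pd.DataFrame, region_density: pd.Series,
                    beta_col: str = "beta") -> pd.DataFrame:
    """Residualize ln(beta) on regional mean neuron density.

    Regions with non-positive coefficients cannot enter the log fit and are
    excluded (reported via the `included` column). Returns the input effects
    with columns log_beta, density, residual, and fit attributes
    (slope/intercept) in `DataFrame.attrs`.
    """
    df = effects.copy()
    df["density"] = region_density.reindex(df.index)
    pos = df[beta_col] > 0
    if (~pos).any():
        warnings.warn(
            f"{int((~pos).sum())} regions with beta <= 0 excluded from the log fit"
        )
    if pos.sum() < 3:
        raise ValueError("need >= 3 regions with positive coefficients")
    sub = df[pos]
    logb = np.log(sub[beta_col].to_numpy())
    d = sub["density"].to_numpy()
    if np.allclose(d.var(), 0):
        slope, intercept = 0.0, float(logb.mean())
    else:
        slope, intercept = np.polyfit(d, logb, 1)
    df["log_beta"] = np.where(pos, np.log(df[beta_col].where(pos)), np.nan)
    df["residual"] = df["log_beta"] - (intercept + slope * df["density"])
    df["included"] = pos
    df.attrs["slope"] = float(slope)
    df.attrs["intercept"] = float(intercept)
    return df
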