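"""Haplotype-specific methylation-expression association and variance decomposition.

The scan regresses the 5-mCpG rate of an MDS, measured on each haplotype of
each individual, on the fraction of mRNA fragments of a nearby isoform that
originate from that same haplotype, with the usual covariates. Variance
decompositions report how much expression variance is explained by
genotype, by methylation, and by each after residualizing on the other —
the quantities behind the claim that sequence variation drives most of the
methylation-expression correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .asmqtl import _ols_effects, _prepare_covariates, inverse_normal_transform


@dataclass
class ExpressionScanResult:
    associations: pd.DataFrame
    n_tests: int
    alpha: float
    skipped: pd.DataFrame


def haplotype_expression_scan(
    mds_rates: pd.DataFrame,
    mds_positions: pd.DataFrame,
    expression: pd.DataFrame,
    covariates: pd.DataFrame,
    window: int = 100_000,
    min_mds_reads: int = 6,
    min_obs: int = 100,
    alpha_total: float = 0.05,
) -> ExpressionScanResult:
    """Associate MDS methylation with haplotype expression fractions.

    ``mds_rates``: long table (mds_id, sample, haplotype, rate, n_calls);
    ``mds_positions``: (mds_id, chrom, start, end); ``expression``:
    (sample, isoform_id, tss_chrom, tss_pos, total_fragments,
    paternal_fragments). Pairs are tested when the isoform TSS lies within
    ``window`` bp of the MDS edges. Haplotype rates based on fewer than
    ``min_mds_reads`` calls are dropped, as are pairs with <= ``min_obs``
    informative observations. Bonferroni over tests performed.
    """
    if not set(expression["sample"]) & set(mds_rates["sample"]):
        raise ValueError("expression and methylation sample sets do not overlap")

    expr = expression[expression["total_fragments"] > 0].copy()
    expr["paternal_fraction"] = expr["paternal_fragments"] / expr["total_fragments"]

    rates = mds_rates[mds_rates["n_calls"] >= min_mds_reads].dropna(subset=["rate"])
    pos = mds_positions.set_index("mds_id")

    fits = []
    skipped = []
    for mds_id, grp in rates.groupby("mds_id", observed=True, sort=True):
        if mds_id not in pos.index:
            skipped.append((mds_id, None, "no_position"))
            continue
        chrom = pos.loc[mds_id, "chrom"]
        lo = int(pos.loc[mds_id, "start"]) - window
        hi = int(pos.loc[mds_id, "end"]) + window
        isoforms = expr[
            (expr["tss_chrom"] == chrom) & (expr["tss_pos"] >= lo) & (expr["tss_pos"] <= hi)
        ]
        for isoform_id, egrp in isoforms.groupby("isoform_id", observed=True, sort=True):
            merged = grp.merge(egrp[["sample", "paternal_fraction"]], on="sample")
            # predictor: fraction of expression from the observation's haplotype
            merged["hap_fraction"] = np.where(
                merged["haplotype"] == "P",
                merged["paternal_fraction"],
                1.0 - merged["paternal_fraction"],
            )
            obs = merged.set_index(["sample", "haplotype"]).join(covariates, how="inner")
            frac = obs["hap_fraction"].to_numpy()
            if len(obs) <= min_obs:
                skipped.append((mds_id, isoform_id, f"n_obs={len(obs)}<={min_obs}"))
                continue
            y = inverse_normal_transform(obs["rate"].to_numpy())
            covar = _prepare_covariates(obs[covariates.columns])
            beta, se, p = _ols_effects(y, frac[:, None], covar)
            fits.append((mds_id, isoform_id, len(obs), beta[0], se[0], p[0]))

    assoc = pd.DataFrame(
        fits, columns=["mds_id", "isoform_id", "n_obs", "beta", "se", "p"]
    )
    n_tests = len(assoc)
    threshold = alpha_total / n_tests if n_tests else np.nan
    assoc["significant"] = assoc["p"] < threshold
    return ExpressionScanResult(
        associations=assoc,
        n_tests=n_tests,
        alpha=threshold,
        skipped=pd.DataFrame(skipped, columns=["mds_id", "isoform_id", "reason"]),
    )


@dataclass
class VarianceDecomposition:
    r2_e_g: float
    r2_e_m: float
    r2_e_m_given_g: float
    r2_e_g_given_m: float
    r2_m_g: float
    r2_m_e: float
    r2_m_e_given_g: float
    r2_m_g_given_e: float


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def _residual(x: np.ndarray, on: np.ndarray) -> np.ndarray:
    on_c = on - on.mean()
    denom = on_c @ on_c
    if denom == 0:
        return x - x.mean()
    b = (on_c @ (x - x.mean())) / denom
    return x - x.mean() - b * on_c


def variance_decomposition(G, M, E) -> VarianceDecomposition:
    """Plain and conditional r-squared among genotype, methylation, expression.

    Conditional terms residualize the *predictor* on the conditioning
    variable first (e.g. r2_e_m_given_g correlates E with the residuals of
    M on G). A predictor with zero residual variance contributes 0 with a
    warning rather than NaN.
    """
    G, M, E = (np.asarray(v, dtype=float) for v in (G, M, E))
    if len(G) < 10:
        raise ValueError("need at least 10 observations")
    for name, v in (("G", G), ("M", M), ("E", E)):
        if np.std(v) == 0:
            raise ValueError(f"zero-variance input {name}")
    import warnings

    def cond_r2(target, predictor, conditioning):
        resid = _residual(predictor, conditioning)
        if np.std(resid) < 1e-12:
            warnings.warn("conditioned predictor has no residual variance; r2 set to 0")
            return 0.0
        return _r2(target, resid)

    return VarianceDecomposition(
        r2_e_g=_r2(E, G),
        r2_e_m=_r2(E, M),
        r2_e_m_given_g=cond_r2(E, M, G),
        r2_e_g_given_m=cond_r2(E, G, M),
        r2_m_g=_r2(M, G),
        r2_m_e=_r2(M, E),
        r2_m_e_given_g=cond_r2(M, E, G),
        r2_m_g_given_e=cond_r2(M, G, E),
    )


def binned_proportion_report(
    mds_table: pd.DataFrame,
    n_bins: int = 5,
    thin_window: int = 100_000,
) -> tuple[pd.DataFrame, float, float]:
    """Proportion of MDSs with an ASM-QTL by rate-variance bin and link status.

    ``mds_table`` columns: mds_id, chrom, start, rate_variance, has_asmqtl,
    has_expression_link. One MDS is kept per ``thin_window`` bp segment of
    the genome (the first by position). MDSs are then binned into
    rate-variance quantile bins of near-equal size; within each bin the
    proportion with an ASM-QTL is reported separately for expression-linked
    and unlinked MDSs with Wilson 95% CIs. Returns (report, chi2, p) where
    the chi-square compares ASM-QTL proportions between linked and unlinked
    MDSs overall (1 df, no continuity correction).
    """
    df = mds_table.copy()
    df["segment"] = df["start"] // thin_window
    df = (
        df.sort_values(["chrom", "start"])
        .groupby(["chrom", "segment"], observed=True)
        .head(1)
        .reset_index(drop=True)
    )
    n_distinct = df["rate_variance"].nunique()
    if n_distinct < n_bins:
        import warnings

        warnings.warn(f"only {n_distinct} distinct variance values; using fewer bins")
        n_bins = max(n_distinct, 1)
    # rank-based quantile bins so bin sizes differ by at most 1
    order = df["rate_variance"].rank(method="first") - 1
    df["bin"] = (order * n_bins // len(df)).astype(int)

    rows = []
    for b, grp in df.groupby("bin"):
        for linked in (True, False):
            sub = grp[grp["has_expression_link"] == linked]
            n = len(sub)
            x = int(sub["has_asmqtl"].sum())
            if n == 0:
                rows.append((b, linked, 0, 0, np.nan, np.nan, np.nan))
                continue
            lo, hi = proportion_confint(x, n, alpha=0.05, method="wilson")
            rows.append((b, linked, n, x, x / n, lo, hi))
    report = pd.DataFrame(
        rows, columns=["bin", "expression_linked", "n", "n_asmqtl",
                       "proportion", "ci_low", "ci_high"]
    )

    linked = df[df["has_expression_link"]]
    unlinked = df[~df["has_expression_link"]]
    tab = np.array(
        [
            [linked["has_asmqtl"].sum(), len(linked) - linked["has_asmqtl"].sum()],
            [unlinked["has_asmqtl"].sum(), len(unlinked) - unlinked["has_asmqtl"].sum()],
        ],
        dtype=float,
    )
    if tab.min() < 0 or len(linked) == 0 or len(unlinked) == 0 or tab.sum(axis=0).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        chi2, p = float(chi2), float(p)
    return report, chi2, p
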