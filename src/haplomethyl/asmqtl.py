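"""Cis association mapping of sequence variants to haplotype 5-mCpG rates.

The scan regresses inverse-normal-transformed per-haplotype methylation
rates of each target (MDS or CpG unit) on the allele carried by that
haplotype at every variant within 100 kb of the target, adjusting for
covariates (age, sex, parental haplotype, leave-one-chromosome-out PCs).
Each haplotype of an individual contributes one observation. Significance
is Bonferroni-corrected over the tests actually performed; the most
significant passing variant per target is the primary ASM-QTL, and a
secondary scan conditions on carriers of the primary variant's major
allele. A second phase refits passing associations with cell-composition
covariates on the subset where they are measured and keeps those that
survive a Benjamini-Hochberg FDR of 0.5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AssociationResult:
    target_id: str
    variant_id: str
    n_obs: int
    beta: float
    se: float
    p: float
    rank: str = "primary"  # primary | secondary | none
    phase2_pass: bool | None = None


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform: z_i = Phi^-1((r_i - 0.5)/n).

    Ties receive average ranks; missing (NaN) values stay missing and do
    not consume ranks. All-identical input maps to all zeros.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    ranks = stats.rankdata(x[mask], method="average")
    out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def _ols_effects(y: np.ndarray, X: np.ndarray, covar: np.ndarray):
    """Per-column effect of X on y adjusting for covariates, via FWL.

    ``covar`` must include an intercept column. Residualizes y and every
    column of X against the covariates once, then computes slope, SE and
    two-sided p per column with the exact OLS degrees of freedom
    n - n_covar - 1. Returns (beta, se, p) arrays.
    """
    n, k = covar.shape
    Q, _ = np.linalg.qr(covar)
    y_r = y - Q @ (Q.T @ y)
    X_r = X - Q @ (Q.T @ X)
    sxx = np.einsum("ij,ij->j", X_r, X_r)
    sxy = X_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    rss = (y_r @ y_r) - beta * sxy
    df = n - k - 1
    if df <= 0:
        raise ValueError("not enough observations for the design")
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0) / df / np.where(sxx > 0, sxx, np.nan))
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def _prepare_covariates(covar: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([np.ones(len(covar)), covar.to_numpy(dtype=float)])
    # drop collinear columns so the QR-based projection stays exact
    keep = [0]
    for j in range(1, X.shape[1]):
        sub = X[:, keep + [j]]
        if np.linalg.matrix_rank(sub) > len(keep):
            keep.append(j)
    return X[:, keep]


@dataclass
class ScanResult:
    associations: pd.DataFrame   # all tests performed
    primaries: pd.DataFrame      # one row per target with a significant hit
    n_tests: int
    alpha: float                 # Bonferroni threshold used
    skipped: pd.DataFrame        # targets skipped with reasons


def cis_scan(
    target_rates: pd.DataFrame,
    target_positions: pd.DataFrame,
    genotypes: "HaplotypeGenotypes",
    covariates: pd.DataFrame,
    window: int = 100_000,
    min_obs: int = 100,
    alpha_total: float = 0.05,
) -> ScanResult:
    """Cis scan of all targets against variants within ``window`` bp.

    ``target_rates``: long table (target_id, sample, haplotype, rate);
    ``target_positions``: (target_id, chrom, start, end);
    ``genotypes``: haplotype-level allele matrix (see
    :class:`HaplotypeGenotypes`); ``covariates``: indexed by
    (sample, haplotype) with numeric columns. Rates are INT-transformed per
    target before fitting. The Bonferroni threshold is
    ``alpha_total / n_tests`` with n_tests the number of regressions
    actually performed across all targets.
    """
    pos = target_positions.set_index("target_id")
    rows = []
    skipped = []
    per_target: dict[str, tuple] = {}

    for target_id, grp in target_rates.groupby("target_id", observed=True, sort=True):
        grp = grp.dropna(subset=["rate"])
        if target_id not in pos.index:
            skipped.append((target_id, "no_position"))
            continue
        chrom = pos.loc[target_id, "chrom"]
        lo = int(pos.loc[target_id, "start"]) - window
        hi = int(pos.loc[target_id, "end"]) + window
        variant_ids = genotypes.variants_in(chrom, lo, hi)
        if len(variant_ids) == 0:
            skipped.append((target_id, "no_variants"))
            continue
        obs = grp.set_index(["sample", "haplotype"])
        obs = obs.join(covariates, how="inner")
        if len(obs) < min_obs:
            skipped.append((target_id, f"n_obs={len(obs)}<{min_obs}"))
            continue
        y = inverse_normal_transform(obs["rate"].to_numpy())
        covar = _prepare_covariates(obs[covariates.columns])
        G = genotypes.allele_matrix(variant_ids, obs.index)
        beta, se, p = _ols_effects(y, G, covar)
        per_target[target_id] = (variant_ids, beta, se, p, len(obs), chrom, lo, hi)

    n_tests = sum(len(v[0]) for v in per_target.values())
    threshold = alpha_total / n_tests if n_tests else np.nan
    primaries = []
    for target_id, (variant_ids, beta, se, p, n_obs, chrom, lo, hi) in per_target.items():
        for vid, b, s, pv in zip(variant_ids, beta, se, p):
            rows.append((target_id, vid, n_obs, b, s, pv))
        sig = np.flatnonzero(p < threshold)
        if sig.size:
            # tie-break equal minimum p: nearest to target midpoint, then id
            mid = (pos.loc[target_id, "start"] + pos.loc[target_id, "end"]) / 2
            pmin = p[sig].min()
            cand = [i for i in sig if p[i] == pmin]
            cand.sort(key=lambda i: (abs(genotypes.position(variant_ids[i]) - mid),
                                     variant_ids[i]))
            i = cand[0]
            primaries.append((target_id, variant_ids[i], n_obs, beta[i], se[i], p[i]))

    assoc = pd.DataFrame(rows, columns=["target_id", "variant_id", "n_obs", "beta", "se", "p"])
    prim = pd.DataFrame(
        primaries, columns=["target_id", "variant_id", "n_obs", "beta", "se", "p"]
    )
    return ScanResult(
        associations=assoc,
        primaries=prim,
        n_tests=n_tests,
        alpha=threshold,
        skipped=pd.DataFrame(skipped, columns=["target_id", "reason"]),
    )


def secondary_scan(
    target_id: str,
    primary_variant: str,
    target_rates: pd.DataFrame,
    target_positions: pd.DataFrame,
    genotypes: "HaplotypeGenotypes",
    covariates: pd.DataFrame,
    window: int = 100_000,
    min_obs: int = 100,
    alpha: float | None = None,
) -> AssociationResult | None:
    """Search for a secondary ASM-QTL among major-allele carriers.

    Observations are restricted to haplotypes carrying the major allele of
    the primary variant (allele 0 on an exact 50/50 tie), then the same
    model is fitted; the most significant variant below ``alpha`` (the
    phase-1 Bonferroni threshold) is the secondary. Returns None when the
    restriction leaves fewer than ``min_obs`` rows or nothing passes.
    """
    grp = target_rates[target_rates["target_id"] == target_id].dropna(subset=["rate"])
    obs = grp.set_index(["sample", "haplotype"]).join(covariates, how="inner")
    g_prim = genotypes.allele_matrix([primary_variant], obs.index)[:, 0]
    major = 0 if np.mean(g_prim) <= 0.5 else 1
    obs = obs[g_prim == major]
    if len(obs) < min_obs:
        return None
    pos = target_positions.set_index("target_id")
    chrom = pos.loc[target_id, "chrom"]
    lo = int(pos.loc[target_id, "start"]) - window
    hi = int(pos.loc[target_id, "end"]) + window
    variant_ids = [v for v in genotypes.variants_in(chrom, lo, hi) if v != primary_variant]
    if not variant_ids:
        return None
    y = inverse_normal_transform(obs["rate"].to_numpy())
    covar = _prepare_covariates(obs[covariates.columns])
    G = genotypes.allele_matrix(variant_ids, obs.index)
    beta, se, p = _ols_effects(y, G, covar)
    if alpha is None:
        alpha = 0.05 / len(variant_ids)
    order = np.argsort(p, kind="stable")
    best = order[0]
    if not np.isfinite(p[best]) or p[best] >= alpha:
        return None
    return AssociationResult(
        target_id, variant_ids[best], len(obs),
        float(beta[best]), float(se[best]), float(p[best]), rank="secondary",
    )


def phase2_filter(
    results: pd.DataFrame,
    target_rates: pd.DataFrame,
    genotypes: "HaplotypeGenotypes",
    covariates: pd.DataFrame,
    cell_counts: pd.DataFrame,
    fdr: float = 0.005,
) -> pd.DataFrame:
    """Refit phase-1 hits with cell-composition covariates on the measured subset.

    ``cell_counts`` is indexed by sample with numeric cell-count columns;
    only samples present there are used. Benjamini-Hochberg is applied at
    ``fdr`` across the refitted p-values; the returned copy of ``results``
    gains ``p_phase2`` and ``phase2_pass`` columns.
    """
    out = results.copy()
    if len(cell_counts) == 0:
        out["p_phase2"] = np.nan
        out["phase2_pass"] = False
        return out
    p2 = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        grp = target_rates[target_rates["target_id"] == row.target_id].dropna(subset=["rate"])
        obs = grp.set_index(["sample", "haplotype"]).join(covariates, how="inner")
        samples = obs.index.get_level_values("sample")
        obs = obs[samples.isin(cell_counts.index)]
        if len(obs) < 3:
            continue
        cells = cell_counts.loc[obs.index.get_level_values("sample")]
        cells.index = obs.index
        design = pd.concat([obs[covariates.columns], cells.add_prefix("cell_")], axis=1)
        covar = _prepare_covariates(design)
        y = inverse_normal_transform(obs["rate"].to_numpy())
        G = genotypes.allele_matrix([row.variant_id], obs.index)
        _, _, p = _ols_effects(y, G, covar)
        p2[i] = p[0]
    out["p_phase2"] = p2
    tested = ~np.isnan(p2)
    passed = np.zeros(len(out), dtype=bool)
    if tested.any():
        from statsmodels.stats.multitest import multipletests
        rej, *_ = multipletests(p2[tested], alpha=fdr, method="fdr_bh")
        passed[np.flatnonzero(tested)] = rej
    out["phase2_pass"] = passed
    return out


def effect_consistency(
    beta_ox, se_ox, beta_nano, se_nano, n_ox, alpha: float = 0.05
):
    """Cross-cohort effect-size consistency.

    t = (beta_ox - beta_nano) / sqrt(se_ox^2 + se_nano^2), with a two-sided
    p from the t distribution with n_ox - 1 degrees of freedom. Returns a
    DataFrame of per-pair (t, p) plus the fraction of nominally
    nonsignificant differences (p > alpha), the study's consistency summary.
    """
    beta_ox = np.atleast_1d(np.asarray(beta_ox, dtype=float))
    beta_nano = np.atleast_1d(np.asarray(beta_nano, dtype=float))
    se_ox = np.atleast_1d(np.asarray(se_ox, dtype=float))
    se_nano = np.atleast_1d(np.asarray(se_nano, dtype=float))
    if np.any(se_ox <= 0) or np.any(se_nano <= 0):
        raise ValueError("standard errors must be positive")
    t = (beta_ox - beta_nano) / np.sqrt(se_ox**2 + se_nano**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=int(n_ox) - 1)
    table = pd.DataFrame({"t": t, "p": p})
    return table, float(np.mean(p > alpha))


class HaplotypeGenotypes:
    """Phased haplotype-level allele matrix.

    ``alleles``: (n_variants, n_samples, 2) int8 array, last axis ordered
    (paternal, maternal); ``variants``: DataFrame with variant_id, chrom,
    pos (0-based), maf; ``samples``: list of sample ids.
    """

    def __init__(self, alleles: np.ndarray, variants: pd.DataFrame, samples: list):
        self.alleles = np.asarray(alleles, dtype=np.int8)
        self.variants = variants.reset_index(drop=True)
        self.samples = list(samples)
        self._vidx = {v: i for i, v in enumerate(self.variants["variant_id"])}
        self._sidx = {s: i for i, s in enumerate(self.samples)}
        self._hidx = {"P": 0, "M": 1}

    def variants_in(self, chrom: str, lo: int, hi: int) -> list:
        v = self.variants
        mask = (v["chrom"] == chrom) & (v["pos"] >= lo) & (v["pos"] <= hi)
        return list(v.loc[mask, "variant_id"])

    def position(self, variant_id: str) -> int:
        return int(self.variants.loc[self._vidx[variant_id], "pos"])

    def maf(self, variant_id: str) -> float:
        return float(self.variants.loc[self._vidx[variant_id], "maf"])

    def allele_matrix(self, variant_ids, obs_index) -> np.ndarray:
        """(n_obs, n_variants) alleles for a (sample, haplotype) MultiIndex."""
        vi = np.array([self._vidx[v] for v in variant_ids])
        si = np.array([self._sidx[s] for s in obs_index.get_level_values("sample")])
        hi = np.array([self._hidx[h] for h in obs_index.get_level_values("haplotype")])
        return self.alleles[np.ix_(vi,)][:, si, hi].T.astype(float)

    def haplotype_vector(self, variant_id: str) -> np.ndarray:
        """Flat haplotype allele vector (paternal block then maternal)."""
        a = self.alleles[self._vidx[variant_id]]
        return np.concatenate([a[:, 0], a[:, 1]]).astype(float)
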