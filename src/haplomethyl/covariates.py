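"""Regression covariates: leave-one-chromosome-out PCs and add-one selection.

Principal components of the unit-rate matrix are computed once per autosome
using only units on the *other* autosomes, so that the PC covariates for a
target can never absorb the cis signal being tested. Candidate technical
covariates are screened with an "add one" procedure: rank by median
association P on a training subset of units, then accept covariates one at
a time while the richer model is significantly better for most test units.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._util import spawn_rng


@dataclass
class PcSet:
    chromosome: str
    scores: pd.DataFrame        # samples x pc1..pck, zero-mean columns
    explained_variance: np.ndarray


def _impute_center(X: np.ndarray) -> np.ndarray:
    """Mean-impute missing entries per column, then center columns."""
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    return X - X.mean(axis=0)


def loco_pca(
    rate_matrix: pd.DataFrame,
    unit_chroms: pd.Series,
    k: int = 5,
    subsample_fraction: float = 1.0,
    seed: int = 0,
) -> dict[str, PcSet]:
    """Leave-one-chromosome-out PCA of the unit-rate matrix.

    ``rate_matrix``: observations (samples or haplotypes) x units;
    ``unit_chroms``: chromosome label per unit (aligned to columns). For
    each chromosome c, units on c are excluded, an optional random subset
    of the remaining units is taken, missing rates are mean-imputed, and
    the first ``k`` left-singular-vector scores per observation are
    returned with zero-mean columns.
    """
    chroms = pd.unique(unit_chroms)
    if len(chroms) < 2:
        raise ValueError("LOCO PCA needs at least 2 chromosomes")
    if rate_matrix.shape[0] < k + 1:
        raise ValueError("need more observations than components")
    unit_chroms = np.asarray(unit_chroms)
    out = {}
    for focal in chroms:
        cols = np.flatnonzero(unit_chroms != focal)
        if subsample_fraction < 1.0:
            rng = spawn_rng(seed, abs(hash(str(focal))) % (2**31))
            take = max(k + 1, int(round(len(cols) * subsample_fraction)))
            cols = np.sort(rng.choice(cols, size=min(take, len(cols)), replace=False))
        X = _impute_center(rate_matrix.iloc[:, cols].to_numpy(dtype=float))
        rank = np.linalg.matrix_rank(X)
        k_eff = min(k, rank)
        if k_eff < k:
            warnings.warn(
                f"rank {rank} < requested {k} components for chromosome {focal}"
            )
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        scores = U[:, :k_eff] * s[:k_eff]
        scores = scores - scores.mean(axis=0)
        out[focal] = PcSet(
            chromosome=str(focal),
            scores=pd.DataFrame(
                scores,
                index=rate_matrix.index,
                columns=[f"pc{i + 1}" for i in range(k_eff)],
            ),
            explained_variance=(s[:k_eff] ** 2) / max(X.shape[0] - 1, 1),
        )
    return out


def _f_test_nested(y, X_small, X_big):
    """F test of the larger OLS model against the nested smaller one."""
    beta_s, res_s, *_ = np.linalg.lstsq(X_small, y, rcond=None)
    beta_b, res_b, *_ = np.linalg.lstsq(X_big, y, rcond=None)
    rss_s = float(np.sum((y - X_small @ beta_s) ** 2))
    rss_b = float(np.sum((y - X_big @ beta_b) ** 2))
    df1 = X_big.shape[1] - X_small.shape[1]
    df2 = len(y) - X_big.shape[1]
    if df2 <= 0 or rss_b <= 0:
        return 1.0
    f = max(rss_s - rss_b, 0.0) / df1 / (rss_b / df2)
    return float(stats.f.sf(f, df1, df2))


def add_one_selection(
    candidates: pd.DataFrame,
    train_rates: pd.DataFrame,
    test_rates: pd.DataFrame,
    alpha: float = 0.05,
    majority: float = 0.5,
) -> list[str]:
    """Add-one covariate selection against per-unit methylation rates.

    ``candidates``: observations x candidate covariates; ``train_rates`` /
    ``test_rates``: observations x units (disjoint unit subsets). Candidates
    are ranked by their median univariate association P over training
    units; then, walking down the ranking, the model with n+1 covariates is
    compared to the n-covariate model by a nested F test on every test
    unit, and the candidate is accepted iff it improves the fit at
    ``alpha`` for more than ``majority`` of test units. Stops at the first
    rejection, so the result is a prefix of the ranking.
    """
    names = list(candidates.columns)
    if not names:
        return []
    C = candidates.to_numpy(dtype=float)
    ones = np.ones((len(candidates), 1))

    median_p = {}
    for j, name in enumerate(names):
        X = np.column_stack([ones, C[:, j]])
        ps = []
        for u in range(train_rates.shape[1]):
            y = train_rates.iloc[:, u].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            ps.append(_f_test_nested(y[ok], ones[ok], X[ok]))
        median_p[name] = float(np.median(ps))
    ranking = sorted(names, key=lambda nm: (median_p[nm], nm))

    accepted: list[str] = []
    current = ones
    for name in ranking:
        j = names.index(name)
        bigger = np.column_stack([current, C[:, j]])
        wins = 0
        for u in range(test_rates.shape[1]):
            y = test_rates.iloc[:, u].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if _f_test_nested(y[ok], current[ok], bigger[ok]) < alpha:
                wins += 1
        if wins / test_rates.shape[1] > majority:
            accepted.append(name)
            current = bigger
        else:
            break
    return accepted


def build_covariate_frame(
    phenotypes: pd.DataFrame,
    pc_sets: dict[str, PcSet] | None = None,
    chromosome: str | None = None,
) -> pd.DataFrame:
    """Assemble the per-observation covariate frame for one focal chromosome.

    ``phenotypes`` is indexed by sample with columns such as age and sex;
    rows are duplicated per haplotype with a binary ``parental_haplotype``
    column (0 = paternal, 1 = maternal). PC scores for the focal chromosome
    are joined per sample when provided.
    """
    rows = []
    for hap, flag in (("P", 0), ("M", 1)):
        block = phenotypes.copy()
        block["parental_haplotype"] = flag
        block["haplotype"] = hap
        rows.append(block)
    frame = pd.concat(rows)
    frame = frame.set_index("haplotype", append=True)
    frame.index.names = ["sample", "haplotype"]
    if pc_sets is not None and chromosome is not None:
        scores = pc_sets[chromosome].scores
        frame = frame.join(scores, on="sample")
    return frame
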