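"""Annotation enrichment of ASM-QTLs.

Two machines:

* LD-matched resampling: observed ASM-QTLs are thinned to >1 Mb spacing,
  and each resample draws the same number of variants from a pool near MDS
  midpoints, matched on LD-proxy count and subject to the same spacing; a
  signal (variant plus proxies) counts as overlapping an annotation if any
  of its members is annotated. The empirical tail probability and fold
  enrichment fall out of the resample distribution, with a binomial tail as
  fallback when no resample reaches the observed count.

* Frequency-binned GWA enrichment likelihood: the probability that the
  causal variant of a GWA signal belongs to annotation c is modeled as
  E_c q_{c,f} / sum_k E_k q_{k,f} within allele-frequency bin f, so that
  MAF-skewed annotations are not spuriously enriched. Enrichments E_c >= 0
  are estimated by maximum likelihood with the largest annotation fixed at
  E = 1 as the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._util import spawn_rng

#: Default proxy-count matching strata (upper edges, inclusive).
DEFAULT_PROXY_STRATA = (1, 5, 20, 100)


def thin_by_distance(variants: pd.DataFrame, min_dist: int = 1_000_000) -> pd.DataFrame:
    """Greedy thinning to >= ``min_dist`` spacing within each chromosome.

    ``variants``: columns variant_id, chrom, pos, p. Repeatedly takes the
    most significant remaining variant whose distance to every selected
    variant on the same chromosome is at least ``min_dist``; ties broken by
    smaller p then lexicographic id.
    """
    df = variants.sort_values(["p", "variant_id"], kind="stable")
    selected_pos: dict[str, list[int]] = {}
    keep = []
    for row in df.itertuples():
        taken = selected_pos.setdefault(row.chrom, [])
        if all(abs(row.pos - q) >= min_dist for q in taken):
            taken.append(row.pos)
            keep.append(row.Index)
    return variants.loc[keep].sort_values(["chrom", "pos"])


def ld_proxies(
    genotypes: "HaplotypeGenotypes",
    lead_variant: str,
    candidate_variants: list | None = None,
    r2_min: float = 0.80,
) -> list:
    """Variants in high LD (r^2 > ``r2_min``, strict) with a lead variant.

    r^2 is the squared Pearson correlation between 0/1 haplotype allele
    vectors, so allele flips do not matter. Monomorphic candidates are
    excluded; the lead itself is included by convention.
    """
    lead = genotypes.haplotype_vector(lead_variant)
    if np.std(lead) == 0:
        return [lead_variant]
    if candidate_variants is None:
        candidate_variants = list(genotypes.variants["variant_id"])
    proxies = [lead_variant]
    for vid in candidate_variants:
        if vid == lead_variant:
            continue
        v = genotypes.haplotype_vector(vid)
        if np.std(v) == 0:
            continue
        r2 = np.corrcoef(lead, v)[0, 1] ** 2
        if r2 > r2_min:
            proxies.append(vid)
    return proxies


@dataclass
class SamplingEnrichment:
    x: int              # observed overlapping signals
    n: int              # observed (thinned) ASM-QTL count
    n_resamples: int
    z: np.ndarray       # per-resample overlap counts
    p_background: float  # sum(z) / (n * N)
    p_observed: float    # x / n
    fold: float
    p_value: float
    p_value_method: str  # empirical | binomial


def _proxy_stratum(count: int, strata=DEFAULT_PROXY_STRATA) -> int:
    for i, edge in enumerate(strata):
        if count <= edge:
            return i
    return len(strata)


def matched_sampling_enrichment(
    observed: pd.DataFrame,
    pool: pd.DataFrame,
    n_resamples: int = 50_000,
    min_dist: int = 1_000_000,
    proxy_strata=DEFAULT_PROXY_STRATA,
    seed: int = 0,
) -> SamplingEnrichment:
    """LD-matched resampling enrichment of observed ASM-QTLs in an annotation.

    ``observed``: thinned ASM-QTLs with columns variant_id, chrom, pos,
    n_proxies, annotated (bool: the variant or any proxy is annotated).
    ``pool``: candidate variants (near MDS midpoints) with variant_id,
    chrom, pos, n_proxies, annotated. Each resample draws, for every
    observed ASM-QTL, one pool variant from the same proxy-count stratum
    while keeping drawn variants >= ``min_dist`` apart; when a stratum
    cannot supply a compatible variant it is widened to the neighboring
    strata (documented fallback).
    """
    n = len(observed)
    x = int(observed["annotated"].sum())
    rng = spawn_rng(seed, 11)

    pool = pool.reset_index(drop=True)
    pool_stratum = pool["n_proxies"].map(lambda c: _proxy_stratum(c, proxy_strata)).to_numpy()
    obs_stratum = observed["n_proxies"].map(lambda c: _proxy_stratum(c, proxy_strata)).to_numpy()
    pool_chrom = pool["chrom"].to_numpy()
    pool_pos = pool["pos"].to_numpy()
    pool_annot = pool["annotated"].to_numpy(dtype=bool)
    by_stratum = {s: np.flatnonzero(pool_stratum == s) for s in np.unique(pool_stratum)}
    max_stratum = max(_proxy_stratum(10**9, proxy_strata), int(pool_stratum.max(initial=0)))

    def candidates_for(s: int) -> np.ndarray:
        if s in by_stratum:
            return by_stratum[s]
        # widen: nearest available strata
        for width in range(1, max_stratum + 2):
            ids = [by_stratum[t] for t in (s - width, s + width) if t in by_stratum]
            if ids:
                return np.concatenate(ids)
        return np.arange(len(pool))

    z = np.zeros(n_resamples, dtype=np.int64)
    for it in range(n_resamples):
        chosen_pos: dict = {}
        overlap = 0
        for s in obs_stratum:
            cand = candidates_for(int(s))
            # rejection sampling for the spacing constraint, widening on failure
            picked = -1
            for attempt in range(30):
                j = int(cand[rng.integers(len(cand))])
                taken = chosen_pos.get(pool_chrom[j], [])
                if all(abs(pool_pos[j] - q) >= min_dist for q in taken):
                    picked = j
                    break
            if picked < 0:
                # fall back to any pool variant satisfying spacing
                order = rng.permutation(len(pool))
                for j in order:
                    taken = chosen_pos.get(pool_chrom[j], [])
                    if all(abs(pool_pos[j] - q) >= min_dist for q in taken):
                        picked = int(j)
                        break
            if picked < 0:
                raise RuntimeError("pool cannot supply spaced resamples")
            chosen_pos.setdefault(pool_chrom[picked], []).append(pool_pos[picked])
            if pool_annot[picked]:
                overlap += 1
        z[it] = overlap

    p_background = float(z.sum()) / (n * n_resamples)
    p_observed = x / n
    fold = p_observed / p_background if p_background > 0 else (0.0 if x == 0 else np.inf)
    j = int(np.sum(z >= x))
    if j > 0:
        p_value, method = j / n_resamples, "empirical"
    else:
        p_value, method = float(stats.binom.sf(x - 1, n, p_background)), "binomial"
    if x == 0:
        fold, p_value, method = 0.0, 1.0, "empirical"
    return SamplingEnrichment(x, n, n_resamples, z, p_background, p_observed,
                              float(fold), float(p_value), method)


@dataclass
class EnrichmentFit:
    annotations: list
    baseline: str
    q_hat: pd.DataFrame        # annotations x bins background proportions
    e_hat: pd.Series           # enrichment per annotation
    ci: pd.DataFrame | None    # 95% bootstrap CI per annotation
    loglik: float
    n_signals: int


def assign_frequency_bins(signals: pd.DataFrame, n_bins: int = 5) -> pd.Series:
    """Equal-count MAF bins from the lead variant of each signal.

    Returns a bin index per signal_id; all variants of a signal inherit the
    lead's bin. Bin sizes differ by at most 1.
    """
    leads = signals[signals["is_lead"]].sort_values("signal_id")
    order = leads["maf"].rank(method="first") - 1
    bins = (order * n_bins // len(leads)).astype(int)
    return pd.Series(bins.to_numpy(), index=leads["signal_id"].to_numpy(), name="bin")


def _signal_loglik(E: np.ndarray, w_list, c_list, qE_denoms) -> float:
    total = 0.0
    for w, c, denom_idx in zip(w_list, c_list, qE_denoms):
        num = float(np.sum(w * E[c]))
        if num <= 0:
            return -np.inf
        total += np.log(num) - np.log(denom_idx @ E)
    return total


def fit_gwa_enrichment(
    signals: pd.DataFrame,
    background: pd.DataFrame,
    n_bins: int = 5,
    baseline: str | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> EnrichmentFit:
    """Maximum-likelihood annotation enrichment among GWA signals.

    ``signals``: one row per signal variant with columns signal_id,
    variant_id, chi2, annotation, is_lead, maf. ``background``: the tested-
    variant table with columns annotation, maf, used to estimate the
    per-frequency-bin background proportions q_hat[c, f]. The per-signal
    log-likelihood is log sum_m w_m E_{c_m} - log sum_k E_k q_hat[k, f(i)]
    with w_m = exp(chi2_m - max chi2 within the signal); this equals the
    product-form likelihood up to additive constants, and subtracting the
    within-signal maximum keeps the exponentials finite. E >= 0 with the
    baseline (largest annotation by default) fixed at 1.
    """
    annotations = sorted(set(background["annotation"]) | set(signals["annotation"]))
    a_index = {a: i for i, a in enumerate(annotations)}
    if baseline is None:
        baseline = background["annotation"].value_counts().idxmax()
    if baseline not in a_index:
        raise ValueError(f"baseline {baseline!r} not among annotations")

    bins = assign_frequency_bins(signals, n_bins)
    # background proportions per bin, using the same equal-count MAF cuts
    lead_mafs = np.sort(signals.loc[signals["is_lead"], "maf"].to_numpy())
    cuts = [lead_mafs[int(round(len(lead_mafs) * (i + 1) / n_bins)) - 1] for i in range(n_bins - 1)]
    bg_bin = np.searchsorted(cuts, background["maf"].to_numpy(), side="left")
    q = np.zeros((len(annotations), n_bins))
    for f in range(n_bins):
        sub = background.loc[bg_bin == f, "annotation"]
        if len(sub) == 0:
            # empty bin: pool over all bins (logged via proportional fallback)
            sub = background["annotation"]
        counts = sub.value_counts()
        for a, cnt in counts.items():
            q[a_index[a], f] = cnt / len(sub)

    w_list, c_list, denom_list = [], [], []
    for sid, grp in signals.groupby("signal_id", sort=True):
        chi2 = grp["chi2"].to_numpy(dtype=float)
        w = np.exp(chi2 - chi2.max())
        c = np.array([a_index[a] for a in grp["annotation"]])
        f = int(bins.loc[sid])
        w_list.append(w)
        c_list.append(c)
        denom_list.append(q[:, f])

    base_i = a_index[baseline]
    free = [i for i in range(len(annotations)) if i != base_i]

    def unpack(eta: np.ndarray) -> np.ndarray:
        E = np.empty(len(annotations))
        E[base_i] = 1.0
        E[free] = np.exp(eta)
        return E

    def neg_loglik(eta: np.ndarray) -> float:
        return -_signal_loglik(unpack(eta), w_list, c_list, denom_list)

    eta0 = np.zeros(len(free))
    res = optimize.minimize(neg_loglik, eta0, method="L-BFGS-B")
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"enrichment optimizer failed: {res.message}")
    E = unpack(res.x)
    e_hat = pd.Series(E, index=annotations, name="enrichment")

    ci = None
    if n_bootstrap > 0:
        rng = spawn_rng(seed, 5)
        n_sig = len(w_list)
        boots = np.zeros((n_bootstrap, len(annotations)))
        for b in range(n_bootstrap):
            idx = rng.integers(0, n_sig, n_sig)
            wl = [w_list[i] for i in idx]
            cl = [c_list[i] for i in idx]
            dl = [denom_list[i] for i in idx]
            rb = optimize.minimize(
                lambda eta: -_signal_loglik(unpack(eta), wl, cl, dl),
                res.x, method="L-BFGS-B",
            )
            boots[b] = unpack(rb.x)
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
        ci = pd.DataFrame({"ci_low": lo, "ci_high": hi}, index=annotations)

    return EnrichmentFit(
        annotations=annotations,
        baseline=baseline,
        q_hat=pd.DataFrame(q, index=annotations, columns=range(n_bins)),
        e_hat=e_hat,
        ci=ci,
        loglik=-float(res.fun),
        n_signals=len(w_list),
    )
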