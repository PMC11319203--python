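"""Direction-of-effect inference between methylation and expression.

For each instrument variant with matched per-haplotype genotype (G),
methylation (M) and expression (E) vectors, the Mendelian-randomization
Steiger test compares |corr(G, M)| with |corr(G, E)|: when the instrument
correlates more strongly with methylation, methylation is the more likely
causal side. A measurement-error sensitivity statistic r asks how much
noisier expression would have to be for the verdict to flip. A separate
identity test discriminates independent-path pleiotropy from shared
mechanism or mediation: with G standardized, Var(M)*beta_ME equals
beta_GM*beta_GE exactly when G affects M and E through independent paths,
and exceeds it under mediation or a common mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import spawn_rng


@dataclass
class CausalTriple:
    """Aligned per-haplotype-observation vectors for one instrument."""

    instrument: str
    G: np.ndarray
    M: np.ndarray
    E: np.ndarray

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if not (len(self.G) == len(self.M) == len(self.E)):
            raise ValueError("G, M, E must be aligned")

    def standardized(self) -> "CausalTriple":
        """Copy with G standardized to mean 0, variance 1."""
        g = self.G - self.G.mean()
        sd = g.std(ddof=0)
        if sd == 0:
            raise ValueError(f"instrument {self.instrument} is monomorphic")
        return CausalTriple(self.instrument, g / sd, self.M, self.E)


def assemble_triples(
    mds_rates: "pd.DataFrame",
    expression: "pd.DataFrame",
    genotypes,
    links: "pd.DataFrame",
    min_obs: int = 30,
) -> list[CausalTriple]:
    """Build (G, M, E) triples from pipeline outputs.

    ``links``: one row per (mds_id, isoform_id, variant_id) trio — typically
    ASM-QTL primaries joined to significant expression-scan pairs.
    ``mds_rates``: long (mds_id, sample, haplotype, rate);
    ``expression``: (sample, isoform_id, total_fragments, paternal_fragments).
    Per haplotype observation, G is the haplotype's allele at the
    instrument, M the MDS 5-mCpG rate, E the fraction of the isoform's
    fragments from that haplotype. Trios with fewer than ``min_obs``
    complete observations or a monomorphic instrument are skipped.
    """
    expr = expression[expression["total_fragments"] > 0].copy()
    expr["paternal_fraction"] = expr["paternal_fragments"] / expr["total_fragments"]
    triples = []
    for row in links.itertuples(index=False):
        mr = mds_rates[mds_rates["mds_id"] == row.mds_id].dropna(subset=["rate"])
        e = expr[expr["isoform_id"] == row.isoform_id]
        merged = mr.merge(e[["sample", "paternal_fraction"]], on="sample")
        merged["efrac"] = np.where(
            merged["haplotype"] == "P",
            merged["paternal_fraction"],
            1.0 - merged["paternal_fraction"],
        )
        if len(merged) < min_obs:
            continue
        idx = merged.set_index(["sample", "haplotype"]).index
        G = genotypes.allele_matrix([row.variant_id], idx)[:, 0]
        if np.std(G) == 0:
            continue
        triples.append(
            CausalTriple(row.variant_id, G, merged["rate"].to_numpy(),
                         merged["efrac"].to_numpy())
        )
    return triples


@dataclass
class SteigerResult:
    per_instrument: pd.DataFrame  # instrument, rho_gm, rho_ge, direction
    proportion_m_to_e: float
    sign_test_p: float
    sensitivity_r: float
    n_skipped: int


def steiger_direction(triples: list[CausalTriple]) -> SteigerResult:
    """MR-Steiger directionality over a set of instruments.

    Per instrument the direction is M->E iff |rho_GM| > |rho_GE|. The
    aggregate proportion of M->E verdicts is tested against 0.5 with a
    two-sided exact binomial sign test. Zero-variance M or E skips the
    triple.
    """
    rows = []
    n_skipped = 0
    for tr in triples:
        if np.std(tr.M) == 0 or np.std(tr.E) == 0 or np.std(tr.G) == 0:
            n_skipped += 1
            continue
        rho_gm = float(np.corrcoef(tr.G, tr.M)[0, 1])
        rho_ge = float(np.corrcoef(tr.G, tr.E)[0, 1])
        direction = "M->E" if abs(rho_gm) > abs(rho_ge) else "E->M"
        rows.append((tr.instrument, rho_gm, rho_ge, direction))
    table = pd.DataFrame(rows, columns=["instrument", "rho_gm", "rho_ge", "direction"])
    if len(table) == 0:
        raise ValueError("no usable instruments")
    n_mtoe = int((table["direction"] == "M->E").sum())
    prop = n_mtoe / len(table)
    p = stats.binomtest(n_mtoe, len(table), 0.5).pvalue
    r = error_sensitivity(table["rho_gm"].to_numpy(), table["rho_ge"].to_numpy())
    return SteigerResult(table, prop, float(p), r, n_skipped)


def error_sensitivity(rho_gm, rho_ge) -> float:
    """Minimum inflation r such that r*|rho_GE| < |rho_GM| half the time.

    This is the median over instruments of |rho_GM| / |rho_GE|: at r equal
    to this value, exactly half the instruments still correlate more
    strongly with methylation. Absolute correlations are used so sign
    conventions cannot flip the answer.
    """
    rho_gm = np.abs(np.asarray(rho_gm, dtype=float))
    rho_ge = np.abs(np.asarray(rho_ge, dtype=float))
    if rho_gm.size == 0:
        raise ValueError("empty input")
    if np.any(rho_ge == 0):
        raise ValueError("rho_GE must be nonzero")
    return float(np.median(rho_gm / rho_ge))


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    return float((x @ (y - y.mean())) / (x @ x))


@dataclass
class IdentityGapResult:
    per_association: pd.DataFrame
    mean_ratio: float
    ci_low: float
    ci_high: float
    n_excluded: int


def identity_gap(
    triples: list[CausalTriple], n_bootstrap: int = 2000, seed: int = 0
) -> IdentityGapResult:
    """Compare Var(M)*beta_ME with beta_GM*beta_GE per association.

    Each triple's G is standardized; the three simple least-squares slopes
    and Var(M) give lhs = Var(M)*beta_ME and rhs = beta_GM*beta_GE. Under
    independent G->M and G->E paths the ratio lhs/rhs has expectation 1;
    mediation or a shared mechanism pushes it above 1. The aggregate is the
    mean ratio with a percentile bootstrap CI over associations.
    """
    rows = []
    n_excluded = 0
    for tr in triples:
        tr = tr.standardized()
        var_m = float(np.var(tr.M, ddof=1))
        beta_me = _slope(tr.M, tr.E)
        beta_gm = _slope(tr.G, tr.M)
        beta_ge = _slope(tr.G, tr.E)
        lhs = var_m * beta_me
        rhs = beta_gm * beta_ge
        if abs(rhs) < 1e-12:
            n_excluded += 1
            continue
        rows.append((tr.instrument, var_m, beta_me, beta_gm, beta_ge, lhs, rhs, lhs / rhs))
    table = pd.DataFrame(
        rows,
        columns=["instrument", "var_m", "beta_me", "beta_gm", "beta_ge", "lhs", "rhs", "ratio"],
    )
    if len(table) == 0:
        raise ValueError("no associations with nonzero beta_GM*beta_GE")
    ratios = table["ratio"].to_numpy()
    mean_ratio = float(ratios.mean())
    rng = spawn_rng(seed, 97)
    boots = np.array(
        [ratios[rng.integers(0, len(ratios), len(ratios))].mean() for _ in range(n_bootstrap)]
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return IdentityGapResult(table, mean_ratio, float(lo), float(hi), n_excluded)
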