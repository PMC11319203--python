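"""End-to-end orchestration of the analysis stages on one cohort.

Chains per-read calls -> unit rates -> MDS catalog -> cis ASM-QTL scan ->
haplotype expression linkage -> causal triples. Each stage is the public
function from its module; this wrapper only wires tables together, so any
stage can be re-run standalone with modified inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import asmqtl, causality, covariates, expression, mds, qc
from .simulate import SimulatedCohort, simulate_expression


@dataclass
class PipelineResult:
    unit_rates: pd.DataFrame
    catalog: list
    mds_rates: pd.DataFrame
    mds_positions: pd.DataFrame
    covariates: pd.DataFrame
    scan: asmqtl.ScanResult
    expression: pd.DataFrame | None = None
    expression_scan: expression.ExpressionScanResult | None = None
    triples: list | None = None


def run_cohort_pipeline(
    cohort: SimulatedCohort,
    phenotypes: pd.DataFrame | None = None,
    min_obs: int | None = None,
    with_expression: bool = True,
    seed: int = 0,
) -> PipelineResult:
    """Run qc -> call-mds -> asmqtl (-> link -> causal triples) on a cohort.

    ``phenotypes``: per-sample covariates (age, sex); generated as nulls
    when absent. ``min_obs`` defaults to 100 haplotypes, lowered to
    0.8 * cohort size for small cohorts so the scan is exercised.
    """
    rates = qc.aggregate_calls(cohort.calls)
    runs = mds.find_depleted_runs(rates)
    catalog = mds.select_mds(runs, rates)
    mds_rates = mds.mds_rate_matrix(catalog, rates)
    positions = pd.DataFrame(
        [{"target_id": m.mds_id, "chrom": m.chrom, "start": m.start, "end": m.end}
         for m in catalog]
    )

    samples = cohort.samples
    if phenotypes is None:
        rng = np.random.default_rng(seed)
        phenotypes = pd.DataFrame(
            {"age": rng.normal(50, 10, len(samples)),
             "sex": rng.integers(0, 2, len(samples))},
            index=pd.Index(samples, name="sample"),
        )
    covar = covariates.build_covariate_frame(phenotypes)

    if min_obs is None:
        min_obs = min(100, int(0.8 * 2 * len(samples)))
    target_rates = mds_rates.rename(columns={"mds_id": "target_id"})
    scan = asmqtl.cis_scan(target_rates, positions, cohort.genotypes, covar,
                           min_obs=min_obs)

    result = PipelineResult(
        unit_rates=rates,
        catalog=catalog,
        mds_rates=mds_rates,
        mds_positions=positions.rename(columns={"target_id": "mds_id"}),
        covariates=covar,
        scan=scan,
    )
    if not with_expression:
        return result

    expr = simulate_expression(cohort)
    escan = expression.haplotype_expression_scan(
        mds_rates, result.mds_positions, expr, covar, min_obs=min_obs
    )
    result.expression = expr
    result.expression_scan = escan

    # causal triples: planted cis variant x overlapping cataloged MDS x isoform
    links = []
    planted = {rid: (chrom, s, e) for rid, chrom, s, e, _ in cohort.truth.planted_mds}
    for rid, vid, _ in cohort.truth.planted_asmqtl:
        chrom, s, e = planted[rid]
        hit = next(
            (m for m in catalog if m.chrom == chrom and m.start < e and m.end > s),
            None,
        )
        if hit is not None:
            links.append({"mds_id": hit.mds_id, "isoform_id": f"iso_{rid}",
                          "variant_id": vid})
    result.triples = causality.assemble_triples(
        mds_rates, expr, cohort.genotypes, pd.DataFrame(links), min_obs=30
    ) if links else []
    return result


def recovery_metrics(catalog: list, planted_mds: list) -> tuple[float, float]:
    """(sensitivity, precision) of a catalog against planted regions."""
    def overlaps(m, p):
        return m.chrom == p[1] and m.start < p[3] and m.end > p[2]

    if not planted_mds or not catalog:
        return 0.0, 0.0
    sens = float(np.mean([any(overlaps(m, p) for m in catalog) for p in planted_mds]))
    prec = float(np.mean([any(overlaps(m, p) for p in planted_mds) for m in catalog]))
    return sens, prec
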