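"""Both enrichment machines: LD-matched resampling and the GWA likelihood.

The resampling machine asks whether observed ASM-QTLs overlap an annotation
more often than LD- and position-matched random variants. The likelihood
machine estimates, within allele-frequency bins, how enriched an annotation
is among the causal variants of GWA signals — without being fooled by
MAF-skewed annotations.
"""

import numpy as np
import pandas as pd

import haplomethyl as hm
from haplomethyl.simulate import simulate_gwa_dataset

rng = np.random.default_rng(47)


def variant_table(n, p_annot):
    return pd.DataFrame({
        "variant_id": [f"p{i}" for i in range(n)],
        "chrom": rng.choice([f"chr{c}" for c in range(1, 10)], n),
        "pos": rng.integers(0, 240_000_000, n),
        "n_proxies": rng.integers(1, 40, n),
        "annotated": rng.random(n) < p_annot,
    })


pool = variant_table(5000, 0.01)          # 1% of the matched pool is annotated
observed = variant_table(40, 0.0)
observed["annotated"] = np.arange(len(observed)) < 4   # 10% of ASM-QTLs overlap
res = hm.matched_sampling_enrichment(observed, pool, n_resamples=5000, seed=47)
print(f"matched resampling: fold = {res.fold:.1f} "
      f"(observed {res.x}/{res.n} vs background p = {res.p_background:.4f}), "
      f"P = {res.p_value:.2g} ({res.p_value_method})")

q = pd.DataFrame({f: [0.85, 0.05, 0.10] for f in range(5)},
                 index=["intronic", "ASM-QTL", "other"])
signals, background = simulate_gwa_dataset(
    q, {"intronic": 1.0, "ASM-QTL": 5.0, "other": 1.0},
    n_signals=1000, variants_per_signal=50, seed=53,
)
fit = hm.fit_gwa_enrichment(signals, background, n_bins=5)
print("GWA enrichment likelihood (baseline = intronic = 1):")
for a, e in fit.e_hat.items():
    print(f"  {a}: E = {e:.2f}")
print("-> the planted 5-fold causal enrichment of 'ASM-QTL' is recovered,")
print("   with frequency bins guarding against MAF-skew inflation")
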