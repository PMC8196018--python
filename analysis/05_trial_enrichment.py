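#!/usr/bin/env python
"""Sample-size enrichment analysis of the simulated prevention trial.

For both trial endpoints (30% slowing of PACC decline; 30% reduction of
AD-conversion hazard; 4 years, 80% power), computes the required total N
without screening and under each screening scheme (per-biomarker positivity
cutoffs, the combined three-biomarker model, SCD status), with a B=1000
subject bootstrap for CIs and P-values.  Writes results/enrichment.csv.
"""

from pathlib import Path

from atnpower.pipeline import RunConfig, run_full_analysis

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1):
    cfg = RunConfig(seed=seed, bootstrap_B=1000, run_auc_bootstrap=False)
    bundle = run_full_analysis(cfg)
    table = bundle.enrichment
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "enrichment.csv", index=False, float_format="%.6g")
    view = table[["endpoint", "scheme", "n_unenriched", "n_enriched",
                  "ss_delta_pct", "ci_lo", "ci_hi", "p_label"]]
    print(view.round(1).to_string(index=False))
    for ep in ("pacc_slope", "ad_conversion"):
        sub = table[(table.endpoint == ep) & (table.scheme.str.startswith("combined"))]
        row = sub.iloc[0]
        print(f"\n{ep}: combined screening cuts the required sample by "
              f"{row.ss_delta_pct:.0f}% [{row.ci_lo:.0f}, {row.ci_hi:.0f}] "
              f"(N {row.n_unenriched} -> {row.n_enriched})")


if __name__ == "__main__":
    main()
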