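"""Distribution-level analyses of the summary table.

Largest-versus-smallest OLS with a slope-vs-one test, skewness of the range
statistic with and without zeros, pairwise KS / centered-F / Spearman
comparisons of the minimum, mean and maximum size distributions, and
intra- versus interspecific ranges up the taxonomic hierarchy.
"""

import json
import pathlib

import numpy as np
import pandas as pd

from sizerange import distribution_tests as dt, trait_table as tt

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    records = tt.read_measurements(BASE / "cohort" / "cohort_measurements.csv")
    annotations = tt.read_annotations(BASE / "cohort" / "cohort_annotations.csv")
    summaries = tt.summarize_species(records)

    log_small = np.array([s.log10_smallest for s in summaries])
    log_large = np.array([s.log10_largest for s in summaries])
    ranges = np.array([s.maxsize_range for s in summaries])

    slope_all = dt.ols_slope_test(log_small, log_large, null_slope=1.0)
    nz = ranges > 0
    slope_nz = dt.ols_slope_test(log_small[nz], log_large[nz], null_slope=1.0)
    print("largest vs smallest reported maximum (log10):")
    print(f"  all species:      slope {slope_all.slope:.3f} "
          f"(t vs 1 = {slope_all.t_ratio:.1f}, p = {slope_all.p_value:.2g})")
    print(f"  non-zero ranges:  slope {slope_nz.slope:.3f} "
          f"(t vs 1 = {slope_nz.t_ratio:.1f})")

    sk_all = dt.dagostino_skewness_test(ranges)
    sk_nz = dt.dagostino_skewness_test(ranges[nz])
    print(f"range skewness: with zeros {sk_all[0]:.2f} (z={sk_all[1]:.1f}); "
          f"non-zeros {sk_nz[0]:.2f} (z={sk_nz[1]:.1f})")

    comps = dt.compare_size_distributions(summaries)
    pd.DataFrame([c.__dict__ for c in comps]).to_csv(
        BASE / "distribution_comparisons.csv", index=False
    )
    for c in comps:
        print(f"  {c.label_a} vs {c.label_b}: KS D={c.ks_D:.4f}, "
              f"F={c.f_stat:.4f}, rho={c.spearman_rho:.3f}")

    rows = []
    for level in ("order", "family", "genus", "species"):
        taxa = dt.taxon_interspecific_ranges(summaries, annotations, level)
        ranges_lv = [t.range for t in taxa]
        rows += [t.__dict__ for t in taxa]
        print(f"  {level}: n={len(taxa)}, mean range {np.mean(ranges_lv):.2f} orders")
    pd.DataFrame(rows).to_csv(BASE / "taxon_ranges.csv", index=False)

    out = {
        "ols_all": slope_all.__dict__,
        "ols_nonzero": slope_nz.__dict__,
        "skew_with_zeros": dict(zip(("skew", "z", "p"), sk_all)),
        "skew_nonzero": dict(zip(("skew", "z", "p"), sk_nz)),
    }
    (BASE / "distribution_tests.json").write_text(json.dumps(out, indent=2, default=float))
    print("tables: distribution_comparisons.csv, taxon_ranges.csv, distribution_tests.json")


if __name__ == "__main__":
    main()
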