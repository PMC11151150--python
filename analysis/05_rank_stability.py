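"""How stable is the across-species body-size ranking?

Draws 1000 pairs of rankings, each formed by picking one reported maximum
per species at random, and summarises the rank agreement (Spearman rho,
median and maximum displacement) and the species that move furthest.
"""

import json
import pathlib
import sys

import pandas as pd

from sizerange import rank_stability as rs, trait_table as tt

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    records = tt.read_measurements(BASE / "cohort" / "cohort_measurements.csv")
    by_species = rs.measurements_by_species(records)
    result = rs.rank_stability(by_species, n_pairs=1000, seed=SEED)

    (BASE / "rank_stability.json").write_text(json.dumps(result.summary(), indent=2))
    pd.DataFrame(
        {
            "pair": range(result.n_pairs),
            "rho": result.rhos,
            "median_displacement": result.median_displacements,
            "max_displacement": result.max_displacements,
            "largest_mover": result.largest_movers,
        }
    ).to_csv(BASE / "rank_stability_pairs.csv", index=False)

    s = result.summary()
    print(f"rank stability over {s['n_pairs']} ranking pairs ({s['n_species']} species):")
    print(f"  mean Spearman rho:            {s['mean_rho']:.4f}")
    print(f"  median rank displacement:     {s['median_of_median_displacements']:.0f} places")
    print(f"  largest single displacement:  {s['max_displacement']:.0f} places")
    movers = rs.top_movers(result, 5)
    print("  most frequent largest movers (species, times, mean displacement):")
    for sp, count, mean_d in movers:
        print(f"    {sp}: {count} pairs, {mean_d:.0f} places on average")


if __name__ == "__main__":
    main()
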