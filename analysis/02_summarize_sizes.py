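"""Per-species size summaries and the range statistic.

Collapses the measurement table to one row per species (smallest, largest
and geometric-mean reported maximum in cm, report count and count class, and
maxsize_range in orders of magnitude), applies the >=100-species phylum
filter, and tallies the magnitude classes.
"""

import pathlib

import numpy as np

from sizerange import trait_table as tt

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    records = tt.read_measurements(BASE / "cohort" / "cohort_measurements.csv")
    annotations = tt.read_annotations(BASE / "cohort" / "cohort_annotations.csv")
    summaries = tt.summarize_species(records)
    tt.write_summaries(summaries, BASE / "species_summaries.csv")
    kept, tally = tt.filter_phyla(summaries, annotations, min_species=100)
    tally.to_csv(BASE / "phylum_tally.csv", index=False)

    ranges = np.array([s.maxsize_range for s in summaries])
    print(f"{len(summaries)} species summarised; {len(kept)} pass the phylum filter")
    print(f"  zero variation:        {100 * np.mean(ranges == 0):.1f}% of species")
    print(f"  > half an order:       {100 * np.mean(ranges > 0.5):.2f}%")
    print(f"  > one order:           {100 * np.mean(ranges > 1.0):.2f}%")
    print(f"  > two orders:          {100 * np.mean(ranges > 2.0):.2f}%")
    print(f"tables: species_summaries.csv, phylum_tally.csv")


if __name__ == "__main__":
    main()
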