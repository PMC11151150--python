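import numpy as np
import pytest

from sizerange import synthetic_cohort as sc
from sizerange.trait_table import MeasurementRecord, SizeUnit


@pytest.fixture(scope="session")
def small_cohort():
    """A default-preset cohort small enough for per-test fits (fixed seed)."""
    truth = sc.default_truth(n_species=1500, seed=42)
    return sc.simulate_cohort(truth)


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort with gross-error injection switched off."""
    truth = sc.default_truth(
        n_species=800, seed=7, unit_factor_rate=0.0, colony_factor_rate=0.0
    )
    return sc.simulate_cohort(truth)


def make_records(sizes_by_species, unit=SizeUnit.CM):
    """Hand-build measurement records from {aphia_id: [sizes]}."""
    records = []
    for aphia, sizes in sizes_by_species.items():
        for j, s in enumerate(sizes):
            records.append(
                MeasurementRecord(
                    species_name=f"sp{aphia}",
                    aphia_id=aphia,
                    size_value=s,
                    size_unit=unit,
                    source_id=f"src{j}",
                )
            )
    return records
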