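import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from poolscan import (
    PopulationMeta,
    SnpCountTable,
    SyntheticConfig,
    TABLE1_POPULATIONS,
    generate_dataset,
)


@pytest.fixture(scope="session")
def table1_meta():
    return list(TABLE1_POPULATIONS)


@pytest.fixture
def two_pops():
    return (
        PopulationMeta("HI", "highland", 4000, 10),
        PopulationMeta("LO", "lowland", 100, 10),
    )


def make_counts(records, populations):
    """Build a SnpCountTable from (chrom, pos, ref, alt, [(ref_reads, alt_reads), ...])."""
    rows = []
    for chrom, pos, ref, alt, pools in records:
        row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
        for pop, (r, a) in zip(populations, pools):
            row[f"{pop.name}_ref"] = r
            row[f"{pop.name}_alt"] = a
        rows.append(row)
    frame = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return SnpCountTable(frame, tuple(populations))


@pytest.fixture(scope="session")
def neutral_dataset():
    """Purely neutral synthetic dataset at the study design's defaults."""
    cfg = SyntheticConfig(n_loci=20000, selected_fraction=0.0, seed=11)
    return cfg, *generate_dataset(cfg)


@pytest.fixture(scope="session")
def selected_dataset():
    """Synthetic dataset with 5% of loci under highland-directional selection."""
    cfg = SyntheticConfig(n_loci=20000, selected_fraction=0.05, s_sel=0.05, seed=5)
    return cfg, *generate_dataset(cfg)
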