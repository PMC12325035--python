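import numpy as np
import pandas as pd
import pytest

from admixaudit import Cohort, VariantTable


def make_cohort(genotypes, populations=None, chrom="1", refs=None, alts=None):
    """Build a small Cohort from a dosage array and optional annotations."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    refs = refs if refs is not None else ["A"] * m
    alts = alts if alts is not None else ["G"] * m
    variants = VariantTable.from_arrays(
        [chrom] * m, np.arange(1, m + 1) * 100, refs, alts
    )
    populations = populations if populations is not None else ["POP"] * n
    samples = pd.DataFrame(
        {"sample_id": [f"s{i:03d}" for i in range(n)], "population": populations}
    )
    return Cohort(genotypes=g, variants=variants, samples=samples)


@pytest.fixture(scope="session")
def small_study():
    """A small but structured synthetic study shared across read-only tests."""
    import admixaudit as aa

    panel = aa.draw_ancestral_frequencies(3000, seed=7)
    cohort = aa.simulate_admixed_cohort(panel, aa.default_populations(6), seed=8)
    cohort = aa.inject_errors_and_missingness(
        cohort, miss_rate=0.002, err_rate=0.0059, seed=9
    )
    design = aa.ArrayDesign()
    array_cohort = aa.ascertain_array_panel(cohort, design, seed=10)
    return cohort, array_cohort, design
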