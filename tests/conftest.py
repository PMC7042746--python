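import numpy as np
import pytest
from hypothesis import settings

from afdld.io_formats import GenotypeMatrix
from afdld.synthetic import SimulationConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def small_sim_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A reduced-scale generator configuration used across the suite."""
    base = dict(
        seed=seed,
        n_snps=1_500,
        n_total=120,
        chrom_lengths={"Chr1": 300_000, "Chr2": 300_000},
        n_planted=10,
        n_genes=20,
        n_peaks=6,
        n_linked_peaks=4,
        n_bg_conserved=10,
        n_lowscore_intervals=10,
        n_list_genes=8,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(small_sim_config())


@pytest.fixture(scope="session")
def bundle_dir(cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    cohort.write(d)
    return d


def toy_matrix(pos, dosage, chrom=None, samples=None, ploidy=1):
    """Single-chromosome GenotypeMatrix from plain lists (None = missing)."""
    dosage = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in dosage]
    )
    n, m = dosage.shape
    return GenotypeMatrix(
        chrom=np.array(chrom or ["chr1"] * n, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        dosage=dosage,
        samples=samples or [f"s{i}" for i in range(m)],
        ploidy=ploidy,
    )
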