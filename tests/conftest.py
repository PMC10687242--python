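import numpy as np
import pandas as pd
import pytest

from phagecosm.tables import CountTable, DensitySeries, SampleFrame


@pytest.fixture
def rng():
    return np.random.default_rng(3003)


@pytest.fixture
def tiny_counts():
    """3 ASVs x 2 samples with taxonomy, used for I/O and scaling checks."""
    counts = pd.DataFrame(
        [[10, 0, 5], [5, 5, 5]],
        index=["s1", "s2"],
        columns=["ASV1", "ASV2", "ASV3"],
    )
    tax = pd.Series(
        [
            "Bacteria;Bacteroidota;Bacteroidia;Flavobacteriales;;Flavobacterium",
            "Bacteria;;Gammaproteobacteria;Pseudomonadales;;Pseudomonas",
            "Bacteria;;Bacteroidia;Cytophagales;;Aquirufa",
        ],
        index=["ASV1", "ASV2", "ASV3"],
    )
    return CountTable(counts, tax)


def random_count_table(rng, n_samples=6, n_asvs=8, depth=500):
    mat = rng.multinomial(depth, rng.dirichlet(np.ones(n_asvs)), size=n_samples)
    counts = pd.DataFrame(
        mat,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"ASV{j}" for j in range(n_asvs)],
    )
    return CountTable(counts)


@pytest.fixture
def small_design():
    """2 groups x 3 replicates x 2 days worth of metadata + densities."""
    rows = []
    dens = []
    for trt in ("none", "antibiotic"):
        for rep in (1, 2, 3):
            m = f"{trt}_{rep}"
            for day in (0, 7):
                rows.append(
                    dict(
                        sample_id=f"{m}_d{day}",
                        microcosm_id=m,
                        replicate=rep,
                        day=day,
                        treatment=trt,
                        invader_level="no",
                    )
                )
                dens.append(dict(microcosm_id=m, day=day, total_density=4e6))
    return SampleFrame(pd.DataFrame(rows)), DensitySeries(pd.DataFrame(dens))
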