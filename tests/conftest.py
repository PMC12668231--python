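import warnings

import numpy as np
import pandas as pd
import pytest

from sedq import synth

warnings.filterwarnings("ignore", category=RuntimeWarning)


def counts_frame(triples, condition="c", replicate=1):
    """Long counts table from (S, P, T) triples, one per gene."""
    rows = []
    for i, (s, p, t) in enumerate(triples):
        for frac, v in (("Total", t), ("Sup", s), ("Pellet", p)):
            rows.append(
                {"gene_id": f"g{i:04d}", "condition": condition,
                 "replicate": replicate, "fraction": frac, "counts": v}
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def annotation_2k():
    return synth.generate_transcriptome(2000, frac_induced=0.05, seed=11)


@pytest.fixture(scope="session")
def study_2k(annotation_2k):
    """Paired control/stress study at the package's default conditions."""
    return synth.simulate_study(
        annotation_2k, n_replicates=2, mean_total_count=1000, seed=12
    )


@pytest.fixture
def exact_counts():
    """Noise-free 3-gene system with (a_S, a_P) = (2.0, 0.5)."""
    return counts_frame([(100, 10, 205), (10, 100, 70), (50, 50, 125)])
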