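import numpy as np
import pytest
from hypothesis import settings

import karyostat as ks

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def templates():
    return ks.builtin_templates()


@pytest.fixture(scope="session")
def noiseless_reports(templates):
    """Full pipeline reports for each species at zero noise."""
    reports = {}
    for slug, t in templates.items():
        records, sites = ks.generate_dataset(t.noiseless())
        reports[slug] = ks.analyze_dataset(records, sites, species=t.name)
    return reports


def random_karyotype(rng, n_pairs=None):
    """Random per-pair (b, B) arm lengths for oracle cross-checks."""
    n = int(n_pairs if n_pairs is not None else rng.integers(2, 13))
    b = rng.uniform(0.5, 5.0, n)
    B = b * rng.uniform(1.0, 8.0, n)
    return b, B


def records_from_arms(b, B, cell_id="c1"):
    """One-cell, two-homolog measurement records from per-pair arm lengths."""
    recs = []
    for i, (s, l) in enumerate(zip(b, B), start=1):
        for h in (1, 2):
            recs.append(ks.ChromosomeRecord(cell_id=cell_id, pair_id=i,
                                            homolog_id=h, short_um=float(s),
                                            long_um=float(l)))
    return recs
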