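import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# property tests are derandomized so the suite is reproducible run to run
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_counts(rows):
    """BaseCountTable from (mag, contig, pos, sample, A, C, G, T) tuples."""
    return pd.DataFrame(
        rows, columns=["mag_id", "contig_id", "position", "sample_id", "A", "C", "G", "T"]
    )


@pytest.fixture
def tiny_counts():
    """Two samples, three positions on one contig of one MAG."""
    return make_counts(
        [
            ("M1", "c1", 0, "s1", 90, 10, 0, 0),
            ("M1", "c1", 5, "s1", 50, 0, 0, 0),
            ("M1", "c1", 9, "s1", 30, 0, 30, 0),
            ("M1", "c1", 0, "s2", 12, 0, 0, 0),
            ("M1", "c1", 5, "s2", 40, 10, 0, 0),
            ("M1", "c1", 9, "s2", 8, 0, 1, 0),
        ]
    )


@pytest.fixture
def metadata_rows():
    header = (
        "sample_id\tsite_id\ttrench_system\trealm\twater_depth_m\tcore_id\t"
        "horizon_top_cm\thorizon_bottom_cm\tgeochem_zone"
    )
    rows = [
        "A7_c1_0_1\tA7\tAtacama\tabyssal\t5500\tc1\t0\t1\toxic",
        "A7_c1_3_5\tA7\tAtacama\tabyssal\t5500\tc1\t3\t5\toxic",
        "A7_c2_0_1\tA7\tAtacama\tabyssal\t5500\tc2\t0\t1\toxic",
        "K6_c1_0_1\tK6\tKermadec\thadal\t9555\tc1\t0\t1\toxic",
    ]
    return header, rows


@pytest.fixture
def metadata_file(tmp_path, metadata_rows):
    header, rows = metadata_rows
    path = tmp_path / "metadata.tsv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


def random_count_fixture(rng, n_sites, n_samples, min_cov=10, max_cov=60):
    """Random per-site count 4-vectors for several samples (always covered)."""
    counts = np.zeros((n_samples, n_sites, 4), dtype=np.int64)
    for s in range(n_samples):
        for p in range(n_sites):
            cov = rng.integers(min_cov, max_cov)
            probs = rng.dirichlet(np.full(4, 0.5))
            counts[s, p] = rng.multinomial(cov, probs)
    return counts
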