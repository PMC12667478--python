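import numpy as np
import pytest

from oncoenh import SimConfig, simulate_cohort, write_fixtures


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 0)."""
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_cohort):
    """The default cohort written to disk in the pipeline's input layout."""
    cohort, truth = default_cohort
    out = tmp_path_factory.mktemp("fixtures")
    write_fixtures(cohort, truth, out)
    return out


# ---------------------------------------------------------------------------
# brute-force per-base oracles used by the interval tests
# ---------------------------------------------------------------------------


def base_union(intervals, chrom_len):
    """Boolean per-base occupancy of a list of (start, end) pairs."""
    occ = np.zeros(chrom_len, dtype=bool)
    for s, e in intervals:
        occ[s:e] = True
    return occ


def runs_of(occ):
    """Maximal True runs of a boolean array as (start, end) half-open pairs."""
    padded = np.concatenate(([False], occ, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def random_intervals(rng, n, chrom_len, max_len=400):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, chrom_len - 1))
        length = int(rng.integers(1, max_len))
        out.append((s, min(s + length, chrom_len)))
    return out
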