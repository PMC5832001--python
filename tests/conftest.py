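"""Shared fixtures: small synthetic datasets and SAM-writing helpers."""
from pathlib import Path

import pytest

from sinescout.simulate import SimConfig, make_synthetic_dataset, simulate_read_alignments

DATA_DIR = Path(__file__).parent / "data"

SAM_HEADER_TEMPLATE = "@HD\tVN:1.6\tSO:coordinate\n{sq}@PG\tID:test\tPN:test\n"


def write_sam(path, chrom_sizes, rows):
    """Write a SAM file from raw alignment rows (tab-joined field tuples)."""
    sq = "".join(f"@SQ\tSN:{c}\tLN:{n}\n" for c, n in chrom_sizes.items())
    with open(path, "w") as out:
        out.write(SAM_HEADER_TEMPLATE.format(sq=sq))
        for row in rows:
            out.write("\t".join(str(f) for f in row) + "\n")
    return str(path)


def mini_config(**overrides) -> SimConfig:
    """One genuine, one exon passenger, one silent locus on a 300-kb genome."""
    kwargs = dict(
        seed=11,
        n_chroms=1,
        chrom_len=300_000,
        n_true_pol3=1,
        n_passenger=1,
        n_silent=1,
        n_fragment=0,
        n_hosts=1,
        host_span=(24_000, 30_000),
        host_exons=(4, 5),
        pol3_fold_median=60.0,
        pol3_fold_sigma=0.05,
        passenger_segments=("exon",),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def easy_config(**overrides) -> SimConfig:
    """High-fold regime: every genuine locus is comfortably recoverable."""
    kwargs = dict(
        seed=7,
        n_chroms=1,
        chrom_len=1_500_000,
        n_true_pol3=15,
        n_passenger=10,
        n_silent=10,
        n_fragment=5,
        n_hosts=4,
        pol3_fold_median=60.0,
        pol3_fold_sigma=0.1,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def mini_dataset():
    return make_synthetic_dataset(mini_config())


@pytest.fixture(scope="session")
def mini_files(mini_dataset, tmp_path_factory):
    """Mini dataset written to disk, reads simulated."""
    out = tmp_path_factory.mktemp("mini")
    paths = mini_dataset.write(out)
    sam = out / "reads.sam"
    stats = simulate_read_alignments(mini_dataset, sam)
    paths["sam"] = str(sam)
    paths["stats"] = stats
    return paths


@pytest.fixture(scope="session")
def easy_dataset():
    return make_synthetic_dataset(easy_config())


@pytest.fixture(scope="session")
def easy_files(easy_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("easy")
    paths = easy_dataset.write(out)
    sam = out / "reads.sam"
    stats = simulate_read_alignments(easy_dataset, sam)
    paths["sam"] = str(sam)
    paths["stats"] = stats
    return paths
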