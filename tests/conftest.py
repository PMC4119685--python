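import random

import pytest

from mirseq.readpro import TrimParams
from mirseq.synthetic import SimConfig, make_toy_references, simulate_library

ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"


@pytest.fixture(scope="session")
def toy_refs():
    return make_toy_references(seed=12, n_hairpins=20, hairpin_len=80)


@pytest.fixture(scope="session")
def trim_params():
    return TrimParams(adaptor=ADAPTOR)


@pytest.fixture(scope="session")
def sim_library(tmp_path_factory, toy_refs):
    """A 10k-read simulated library with its ground truth."""
    out = tmp_path_factory.mktemp("sim") / "reads.fastq"
    config = SimConfig(n_reads=10_000, seed=7)
    truth = simulate_library(config, toy_refs, out)
    return out, truth, config


def write_fastq(path, seqs):
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")
    return path


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
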