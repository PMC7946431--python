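"""Shared fixtures: simulated loci and on-disk fixture bundles."""

import glob

import pytest

from crypticex.cryptic_discovery import build_junction_index
from crypticex.synthetic_data import (
    Condition,
    SimConfig,
    simulate_junction_counts,
    simulate_locus,
)

# independent reverse-complement oracle used across test modules
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc_oracle(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq.upper()))


def all_junctions(per_sample):
    return [j for js in per_sample.values() for j in js]


@pytest.fixture(scope="session")
def plus_locus():
    return simulate_locus(SimConfig(seed=11, strand="+"))


@pytest.fixture(scope="session")
def minus_locus():
    return simulate_locus(SimConfig(seed=11, strand="-"))


@pytest.fixture(scope="session")
def plus_counts(plus_locus):
    per_sample, truths = simulate_junction_counts(plus_locus)
    return per_sample, truths


@pytest.fixture(scope="session")
def plus_index(plus_locus, plus_counts):
    per_sample, _ = plus_counts
    return build_junction_index(all_junctions(per_sample), plus_locus.gene)


@pytest.fixture()
def bundle_dir(tmp_path):
    """Write a fixture bundle and return (dir, config)."""
    from crypticex.synthetic_data import write_fixture_bundle

    cfg = SimConfig(seed=5, strand="+")
    write_fixture_bundle(cfg, tmp_path / "fx")
    return tmp_path / "fx", cfg


def junction_inputs(fxdir):
    out = []
    for p in sorted(glob.glob(str(fxdir / "junctions" / "*.bed"))):
        name = p.split("/")[-1][:-4]
        out.append({"path": p, "sample": name, "condition": name.split("_")[0]})
    return out
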