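import numpy as np
import pytest

from cagekit.ctss import CtssProfile, SampleLibrary
from cagekit.simulate import FixtureGenerator, SimulationConfig


@pytest.fixture(scope="session")
def default_generator() -> FixtureGenerator:
    """One fully-materialized fixture bundle shared by read-only tests."""
    gen = FixtureGenerator(SimulationConfig(seed=7))
    gen.simulate_ctss_profiles()
    return gen


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    from cagekit.simulate import generate_fixture_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    paths = generate_fixture_bundle(SimulationConfig(seed=7), outdir)
    return outdir, paths


def libraries_from_generator(gen: FixtureGenerator) -> list[SampleLibrary]:
    return [
        SampleLibrary(sample_id, CtssProfile.from_records(records))
        for sample_id, records in sorted(gen.ctss_by_sample.items())
    ]


@pytest.fixture(scope="session")
def default_libraries(default_generator):
    return libraries_from_generator(default_generator)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_chain_map(chain) -> dict[int, tuple[int, str]]:
    """Per-base source->dest map built by walking blocks one base at a time."""
    mapping: dict[int, tuple[int, str]] = {}
    t, q = chain.t_start, chain.q_start
    for b in chain.blocks:
        for k in range(b.size):
            qq = q + k
            if chain.q_strand == "+":
                mapping[t + k] = (qq, "+")
            else:
                mapping[t + k] = (chain.q_size - 1 - qq, "-")
        t += b.size + b.dt
        q += b.size + b.dq
    return mapping


def brute_force_project(chains, chrom, start, end, min_match=0.95):
    """Reference projection: per-base dict lookup, best-scoring chain wins."""
    best = None
    for chain in sorted(
        (c for c in chains if c.t_name == chrom), key=lambda c: -c.score
    ):
        m = brute_force_chain_map(chain)
        hits = [m[p] for p in range(start, end) if p in m]
        frac = len(hits) / (end - start)
        if frac >= min_match:
            positions = [h[0] for h in hits]
            return (chain.q_name, min(positions), max(positions) + 1, chain.q_strand, frac)
        best = best or frac
    return None


def brute_force_overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end
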