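"""Shared fixtures: a fast mini-scale synthetic bundle for unit tests and
a session-cached run of the full default bundle for end-to-end checks."""
from __future__ import annotations

import numpy as np
import pytest

from mapweaver.pipeline import PipelineConfig, PipelineInputs, run_pipeline
from mapweaver.simulate import (
    ArrayPlacement,
    ChromPlan,
    ProfileConfig,
    SimConfig,
    default_config,
    simulate_assemblies,
    simulate_genome,
    simulate_markers,
    simulate_optical_maps,
    simulate_reads,
)


def mini_config(seed: int = 0) -> SimConfig:
    """A 3 x 1.5 Mb bundle with the same threshold topology as the default
    (solvable arrays, one unsolvable array, chimeras, collapse, het break)
    but ~3x faster to run."""
    tel, sub = 3000, 6000
    L = 1_500_000

    def mk(name, arrays, het=None, rba=(), rbb=()):
        return ChromPlan(
            name, L,
            arrays=[ArrayPlacement("telomere", 0, tel, 0.01, rc=True),
                    ArrayPlacement("subtelomere", tel, sub, 0.05)]
            + arrays
            + [ArrayPlacement("subtelomere", L - tel - sub, sub, 0.05),
               ArrayPlacement("telomere", L - tel, tel, 0.01)],
            het_region=het, random_breaks_a=list(rba), random_breaks_b=list(rbb))

    chroms = [
        mk("m1", [
            ArrayPlacement("knob180", 400_000, 20_000, 0.08, te_rate=0.06),
            ArrayPlacement("CentC", 750_000, 12_000, 0.08, te_rate=0.05,
                           collapse_frac=0.5),
            ArrayPlacement("TR-1", 1_100_000, 18_000, 0.08, te_rate=0.06),
        ], rba=[200_000], rbb=[300_000, 900_000]),
        mk("m2", [
            ArrayPlacement("knob180", 500_000, 22_000, 0.08, te_rate=0.06),
            ArrayPlacement("CentC", 800_000, 12_000, 0.08, te_rate=0.05),
        ], het=(1_000_000, 1_100_000), rba=[250_000],
            rbb=[400_000, 1_200_000]),
        mk("m3", [
            ArrayPlacement("knob180", 550_000, 90_000, 0.08, te_rate=0.04),
            ArrayPlacement("CentC", 900_000, 12_000, 0.08, te_rate=0.05),
        ], rba=[300_000], rbb=[450_000, 1_150_000]),
    ]
    return SimConfig(
        chromosomes=chroms,
        profile_a=ProfileConfig("pb", break_over=15_000, end_trim=2000,
                                sub_rate=1e-4, break_at_het=True),
        profile_b=ProfileConfig("ont", break_over=40_000, end_trim=1500,
                                sub_rate=5e-4, indel_rate=2e-4, rc_every=3),
        chimera_joins=[
            (("m1", "knob180", 0, "left"), ("m2", "knob180", 0, "right")),
            (("m2", "knob180", 0, "left"), ("m1", "TR-1", 0, "right")),
        ],
        seed=seed,
    )


@pytest.fixture(scope="session")
def mini_bundle():
    cfg = mini_config(seed=7)
    genome, truth = simulate_genome(cfg)
    maps, origins = simulate_optical_maps(genome, cfg)
    a, b, events = simulate_assemblies(genome, truth, cfg)
    return {"cfg": cfg, "genome": genome, "truth": truth, "maps": maps,
            "origins": origins, "a": a, "b": b, "events": events}


@pytest.fixture(scope="session")
def mini_run(mini_bundle):
    cfg = mini_bundle["cfg"]
    reads = (simulate_reads(mini_bundle["genome"], cfg.reads_a, cfg, salt=0,
                            depth=5)
             + simulate_reads(mini_bundle["genome"], cfg.reads_b, cfg, salt=50,
                              depth=5))
    markers = simulate_markers(mini_bundle["truth"], cfg)
    pc = PipelineConfig(seed=cfg.seed)
    res = run_pipeline(pc, PipelineInputs(
        mini_bundle["a"], mini_bundle["b"], mini_bundle["maps"],
        reads=reads, markers=markers, map_origins=mini_bundle["origins"]))
    return {"res": res, "reads": reads, "markers": markers, **mini_bundle}


def run_default_bundle(seed: int):
    cfg = default_config(seed=seed)
    genome, truth = simulate_genome(cfg)
    maps, origins = simulate_optical_maps(genome, cfg)
    a, b, events = simulate_assemblies(genome, truth, cfg)
    reads = (simulate_reads(genome, cfg.reads_a, cfg, salt=0)
             + simulate_reads(genome, cfg.reads_b, cfg, salt=50))
    markers = simulate_markers(truth, cfg)
    pc = PipelineConfig(seed=seed)
    res = run_pipeline(pc, PipelineInputs(a, b, maps, reads=reads,
                                          markers=markers, map_origins=origins))
    return {"cfg": cfg, "genome": genome, "truth": truth, "events": events,
            "res": res}


@pytest.fixture(scope="session")
def default_runs():
    """The default desk-scale bundle run end-to-end at three seeds."""
    return {seed: run_default_bundle(seed) for seed in (1, 2, 3)}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
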