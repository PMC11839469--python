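"""Shared fixtures: one full-scale simulated selection reused across tests.

The session-scoped simulation reproduces the study conditions used for
end-to-end validation: a 30-residue synthetic reference (551 designed
variants), a 3-position dead panel, 20 barcodes per variant, 3 biological
replicates, 6 CO2 levels spanning 0.3-10% and 1e6 reads per condition and
timepoint.
"""

import pytest
from hypothesis import HealthCheck, settings

import rubiscan as rb

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

DESIGN_SEED = 1
SIM_SEED = 2
FIT_SEED = 7
DEAD_POSITIONS = (5, 12, 21)


@pytest.fixture(scope="session")
def e2e():
    """Full-scale simulated titration with known ground truth."""
    design = rb.make_design(length=30, seed=DESIGN_SEED)
    config = rb.SimulationConfig(
        seed=SIM_SEED,
        barcodes_per_variant=20,
        read_depth=1_000_000,
        dead_positions=DEAD_POSITIONS,
    )
    variants, barcodes = rb.generate_library(design, config)
    conditions = rb.default_conditions(replicates=3)
    counts = rb.simulate_selection(variants, barcodes, conditions, config)
    dead = rb.dead_variant_ids(variants)
    enrichments = rb.enrichment_by_replicate(counts, dead)
    return {
        "design": design,
        "config": config,
        "variants": variants,
        "barcodes": barcodes,
        "counts": counts,
        "dead": dead,
        "enrichments": enrichments,
    }


@pytest.fixture(scope="session")
def e2e_fits(e2e):
    """Reliability-swept kinetic fits (reduced 3x3x3 sweep) on the simulation."""
    return rb.reliability_sweep(
        e2e["counts"], e2e["dead"], rb.FitConfig.reduced(seed=FIT_SEED)
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast selection simulation for unit-level pipeline tests."""
    design = rb.make_design(length=12, seed=3)
    config = rb.SimulationConfig(
        seed=4,
        barcodes_per_variant=10,
        read_depth=200_000,
        dead_positions=(5,),
    )
    variants, barcodes = rb.generate_library(design, config)
    counts = rb.simulate_selection(
        variants, barcodes, rb.default_conditions(replicates=3), config
    )
    return {
        "design": design,
        "config": config,
        "variants": variants,
        "barcodes": barcodes,
        "counts": counts,
        "dead": rb.dead_variant_ids(variants),
    }
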