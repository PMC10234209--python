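"""Shared simulation fixtures.

All heavy forward simulations are session-scoped and reused across test
modules. Desk-scale study conditions: a 1-Mb chromosome with an inversion
spanning 250-750 kb, 2N = 200 chromosomes, and flux/recombination rates
chosen so the population-scaled products (4N*mu, 4N*r, 4N*phi) sit in the
regimes the statistics are sensitive to.
"""

from __future__ import annotations

import pytest

from invpayne import (
    SimParams, simulate_inversion_population, simulate_derived_population,
)

BP = (250_000, 750_000)
FLANK = 100_000
CHROM_LEN = 1_000_000
N_SEEDS = 20


def asym_params(seed: int, **overrides) -> SimParams:
    """Balanced inversion with strongly position-dependent flux: scaled
    central flux is high (class-homogenising) while breakpoint flux is two
    orders lower -- the regime that produces the suspension-bridge F_AT
    profile and the breakpoint diversity trough."""
    kw = dict(N=100, q=0.5, L=1000, chrom_length=CHROM_LEN, breakpoints=BP,
              phi_flank=FLANK, mu=2e-5, r_rate=5e-7,
              phi_bp=5e-4, phi_center=0.05, s_bal=0.0, clamp=True,
              T=1200, seed=seed)
    kw.update(overrides)
    return SimParams(**kw)


def lowflux_params(seed: int, **overrides) -> SimParams:
    """Balanced inversion with near-suppressed flux everywhere: karyotype
    classes diverge across the whole inverted segment (the marker-panel /
    clustering / LD-contrast regime). Heterokaryotype advantage keeps the
    polymorphism segregating in daughter populations."""
    kw = dict(N=100, q=0.5, L=2000, chrom_length=CHROM_LEN, breakpoints=BP,
              phi_flank=FLANK, mu=5e-5, r_rate=5e-7,
              phi_bp=1e-7, phi_center=1e-5, s_bal=0.5, clamp=True,
              T=1200, seed=seed)
    kw.update(overrides)
    return SimParams(**kw)


def neutral_params(seed: int, **overrides) -> SimParams:
    """No inversion; population of 100 chromosomes (matched to one
    karyotype class of the inversion runs)."""
    kw = dict(N=50, q=None, breakpoints=None, L=2000, chrom_length=CHROM_LEN,
              mu=5e-5, r_rate=5e-7, s_bal=0.0, clamp=False, T=1000, seed=seed)
    kw.update(overrides)
    return SimParams(**kw)


@pytest.fixture(scope="session")
def asym_pops():
    return [simulate_inversion_population(asym_params(s))
            for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def sym_pops():
    """Flux profile flattened to the central rate everywhere: the oracle
    control in which no breakpoint/center contrast should appear."""
    return [simulate_inversion_population(asym_params(500 + s, phi_bp=0.05))
            for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def lowflux_pops():
    return [simulate_inversion_population(lowflux_params(s))
            for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def neutral_pops():
    return [simulate_inversion_population(neutral_params(700 + s))
            for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def structured_reps(lowflux_pops):
    """Per seed: (ancestral source, two low-latitude daughters that keep
    the inversion, one high-latitude all-standard daughter)."""
    reps = []
    for s, src in enumerate(lowflux_pops):
        low_a = simulate_derived_population(
            src, 100, 150, seed=1000 + s, recovery_size=200,
            require_both_karyotypes=True)
        low_b = simulate_derived_population(
            src, 100, 150, seed=2000 + s, recovery_size=200,
            require_both_karyotypes=True)
        high = simulate_derived_population(
            src, 40, 150, seed=3000 + s, recovery_size=200,
            founder_karyotype="STD")
        reps.append((src, low_a, low_b, high))
    return reps


def karyotype_ids(pop, kary: str, prefix: str | None = None) -> list[str]:
    ids = [s for s, k in zip(pop.haplotypes.sample_ids, pop.karyotypes)
           if k == kary]
    if prefix is not None:
        ids = [f"{prefix}:{s}" for s in ids]
    return ids
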