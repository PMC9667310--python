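"""Reference simulation runs that recompute the headline kinetic quantities.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage, and returns the measured quantity: the WT latency half-life from a
noisy recovery curve, the apparent aggregate library half-life, the
error-prone-PCR substitution load, and a slow variant's deconvolved
half-life under the full 48 h selection design.  They are used by the
acceptance script and the test suite, and double as worked examples of the
API.
"""

from __future__ import annotations

import copy
import math

import numpy as np

from .effects import EffectConfig, generate_effect_map
from .kinetics import (MassivelyParallelKinetics, fit_decay,
                       fit_library_recovery)
from .library import generate_clone_library
from .reference import make_toy_reference
from .selection import (DEFAULT_TIME_GRID_H, SelectionDesign,
                        simulate_selection_timecourse)

__all__ = ["DEFAULT_TIME_GRID_H", "wt_recovery_t_half",
           "aggregate_library_t_half", "mean_substitutions_per_clone",
           "slow_variant_recovered_t_half"]

LN2 = math.log(2.0)


def wt_recovery_t_half(seed: int, noise_sd: float = 0.01) -> float:
    """Fit the WT-only phage recovery time course (1% multiplicative noise).

    Simulates a WT-only library in expected-fraction mode (c = 0) over the
    0-48 h grid, with lognormal noise on the recovered fractions, and
    returns the fitted half-life in hours.
    """
    from .library import Clone

    ref = make_toy_reference(n_residues=30, seed=seed)
    clone = Clone(substitutions=(), abundance=1.0, k_eff=LN2 / 2.1)
    design = SelectionDesign(replicates=3, depth_per_sample=10_000,
                             recovery_noise_sd=noise_sd)
    ds = simulate_selection_timecourse([clone], design, seed=seed,
                                       reference=ref)
    return fit_library_recovery(ds).t_half


def aggregate_library_t_half(seed: int, planted_t_half: float = 11.2,
                             noise_sd: float = 0.01) -> float:
    """Recover a planted apparent library half-life from a noisy decay curve.

    Generates the single-phase recovery curve with rate ln(2)/planted on the
    standard time grid, applies 1% multiplicative noise, fits the one-phase
    model, and returns the fitted half-life in hours.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(DEFAULT_TIME_GRID_H)
    y = np.exp(-LN2 / planted_t_half * t)
    y = y * np.exp(rng.normal(0.0, noise_sd, size=len(t)))
    y = y / y[0]
    return fit_decay(t, y).t_half


def mean_substitutions_per_clone(seed: int, n_clones: int = 100_000,
                                 mutation_mean: float = 4.2) -> float:
    """Empirical mean missense substitutions per clone at library scale."""
    ref = make_toy_reference(n_residues=200, seed=seed)
    emap = generate_effect_map(ref, seed=seed)
    lib = generate_clone_library(emap, n_clones=n_clones,
                                 mutation_mean=mutation_mean, seed=seed + 1)
    return float(np.mean([len(c.substitutions) for c in lib]))


def slow_variant_recovered_t_half(seed: int, planted_t_half: float = 13.1,
                                  n_clones: int = 100_000,
                                  n_residues: int = 100) -> float:
    """Deconvolve one slow variant's half-life under the 48 h design.

    Everything else in the library sits near WT (5% lognormal jitter, all
    functional); one substitution is planted at ``planted_t_half``.  The
    full massively parallel kinetics stage runs at default depth, 3
    replicates and multinomial count noise; returns the planted variant's
    normalized half-life in hours.
    """
    ref = make_toy_reference(n_residues=n_residues, seed=seed)
    near_wt = EffectConfig(stabilized_fraction=0.5, destabilized_fraction=0.5,
                           nonfunctional_fraction=0.0, effect_log_sd=0.05)
    emap = generate_effect_map(ref, near_wt, seed=seed)
    pos = 86 if 86 in ref.positions else ref.offset + n_residues // 2
    mut = "L" if ref.wt_aa(pos) != "L" else "M"
    emap = copy.deepcopy(emap)
    emap.set_effect(pos, mut, planted_t_half)

    lib = generate_clone_library(emap, n_clones=n_clones, mutation_mean=4.2,
                                 seed=seed + 1)
    ds = simulate_selection_timecourse(lib, SelectionDesign(), seed=seed + 2,
                                       reference=ref, truth=emap)
    est = MassivelyParallelKinetics().fit(ds)
    row = est.results_[(est.results_.position == pos)
                       & (est.results_.mut_aa == mut)]
    if row.empty or row.flag.iloc[0] != "ok":
        raise RuntimeError("planted variant did not yield a usable fit")
    return float(row.normalized_t_half.iloc[0])
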