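"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from pai1dms import (EffectConfig, MutationEffectMap, SelectionDesign,
                     default_amplicon_panel, generate_clone_library,
                     generate_effect_map, make_toy_reference,
                     simulate_selection_timecourse)


@pytest.fixture(scope="session")
def toy_ref():
    return make_toy_reference(n_residues=30, offset=1, seed=101)


@pytest.fixture(scope="session")
def toy_panel(toy_ref):
    return default_amplicon_panel(toy_ref, n_amplicons=2, length=60)


@pytest.fixture(scope="session")
def toy_effects(toy_ref):
    return generate_effect_map(toy_ref, EffectConfig(), seed=102)


@pytest.fixture(scope="session")
def toy_library(toy_effects):
    return generate_clone_library(toy_effects, n_clones=300, mutation_mean=2.0,
                                  seed=103)


@pytest.fixture(scope="session")
def small_dataset(toy_library, toy_ref, toy_panel, toy_effects):
    design = SelectionDesign(depth_per_sample=20_000, replicates=2)
    return simulate_selection_timecourse(toy_library, design, seed=104,
                                         reference=toy_ref, panel=toy_panel,
                                         truth=toy_effects)


def wt_only_library(effect_map: MutationEffectMap, n: int = 1):
    """A library of n identical WT clones."""
    from pai1dms.library import LN2, Clone

    k = LN2 / effect_map.wt_t_half
    return [Clone(substitutions=(), abundance=1.0 / n, k_eff=k)
            for _ in range(n)]
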