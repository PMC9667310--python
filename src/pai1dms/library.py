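"""Clone libraries from error-prone PCR mutagenesis.

A clone is a fusion protein carrying zero or more amino-acid substitutions.
Its effective latency rate constant is composed from the planted
per-substitution half-lives; clones carrying any nonfunctional substitution
never form protease complexes and so only appear in unselected samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .effects import MutationEffectMap
from .reference import AA_ALPHABET

LN2 = math.log(2.0)


@dataclass(frozen=True, slots=True)
class Clone:
    """One library member: a substitution set with abundance and kinetics."""

    substitutions: tuple[tuple[int, str], ...]
    abundance: float
    k_eff: float
    functional: bool = True

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")
        positions = [p for p, _ in self.substitutions]
        if len(positions) != len(set(positions)):
            raise ValueError("at most one substitution per position")
        if self.functional and self.k_eff <= 0:
            raise ValueError("functional clones need k_eff > 0")


def compose_rate(t_halves: "list[float] | np.ndarray", wt_t_half: float,
                 composition: str = "multiplicative") -> float:
    """Effective clone rate constant from per-substitution half-lives.

    The default is multiplicative over rate ratios,
    ``k_eff = k_WT * prod(k_sub / k_WT)`` — the neutral log-additive choice
    when epistasis is assumed to average out across backgrounds.  The
    ``additive`` alternative sums rate differences, clipped positive.
    """
    k_wt = LN2 / wt_t_half
    ks = LN2 / np.asarray(t_halves, dtype=float)
    if composition == "multiplicative":
        return float(k_wt * np.prod(ks / k_wt))
    if composition == "additive":
        return float(max(k_wt + np.sum(ks - k_wt), 1e-9))
    raise ValueError(f"unknown composition {composition!r}")


def generate_clone_library(effect_map: MutationEffectMap,
                           n_clones: int,
                           mutation_mean: float = 4.2,
                           seed: int = 0,
                           zero_truncated: bool = False,
                           abundance: str = "dirichlet",
                           composition: str = "multiplicative") -> list[Clone]:
    """Draw a clone library with Poisson-distributed substitution loads.

    Per-clone substitution counts are Poisson(``mutation_mean``) (optionally
    zero-truncated); positions are uniform without replacement; the mutant
    amino acid is uniform over the 19 non-WT identities.  Abundances are
    flat-Dirichlet by default (``abundance="uniform"`` gives equal weights).
    """
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    if mutation_mean < 0:
        raise ValueError("mutation_mean must be non-negative")

    rng = np.random.default_rng(seed)
    reference = effect_map.reference
    positions = np.fromiter(reference.positions, dtype=np.int64)
    wt_aas = np.array([reference.wt_aa(int(p)) for p in positions])

    n_subs = rng.poisson(mutation_mean, size=n_clones)
    if zero_truncated and mutation_mean > 0:
        while True:
            zero = n_subs == 0
            if not zero.any():
                break
            n_subs[zero] = rng.poisson(mutation_mean, size=int(zero.sum()))
    n_subs = np.minimum(n_subs, len(positions))

    if abundance == "dirichlet":
        weights = rng.dirichlet(np.ones(n_clones))
    elif abundance == "uniform":
        weights = np.full(n_clones, 1.0 / n_clones)
    else:
        raise ValueError(f"unknown abundance model {abundance!r}")

    aa_arr = np.frombuffer(AA_ALPHABET.encode(), dtype="S1").astype("U1")
    clones: list[Clone] = []
    for i in range(n_clones):
        m = int(n_subs[i])
        if m == 0:
            clones.append(Clone(substitutions=(), abundance=float(weights[i]),
                                k_eff=LN2 / effect_map.wt_t_half))
            continue
        idx = rng.choice(len(positions), size=m, replace=False)
        subs = []
        t_halves = []
        functional = True
        for j in idx:
            pos = int(positions[j])
            # uniform over the 19 non-WT amino acids
            choices = aa_arr[aa_arr != wt_aas[j]]
            mut = str(choices[rng.integers(len(choices))])
            subs.append((pos, mut))
            t, fn = effect_map.entries[(pos, mut)]
            t_halves.append(t)
            functional &= fn
        k = compose_rate(t_halves, effect_map.wt_t_half, composition)
        clones.append(Clone(substitutions=tuple(sorted(subs)),
                            abundance=float(weights[i]),
                            k_eff=k, functional=functional))
    return clones
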