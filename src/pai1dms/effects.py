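"""Ground-truth mutational effects on the latency transition.

Every amino-acid substitution in the reference is assigned a functional
half-life (hours) for the active-to-latent conversion, or marked
nonfunctional (no protease inhibition, hence never recovered by selection).
These planted truths drive the simulator and are what parameter-recovery
tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import AA_ALPHABET, ReferenceProtein

#: WT latency half-life of the phage-displayed serpin, hours.
WT_T_HALF_H = 2.1


@dataclass(frozen=True)
class EffectConfig:
    """Distribution of planted substitution effects.

    ``stabilized_fraction`` / ``destabilized_fraction`` / ``nonfunctional_fraction``
    partition substitutions (the remainder is WT-like neutral).  Functional
    effects are half-normal in log half-life around WT: stabilized variants
    draw ``t = wt_t_half * exp(+|N(0, effect_log_sd)|)``, destabilized (and
    the nominal half-life of nonfunctional) variants the mirror image, both
    truncated to [``t_half_min``, ``t_half_max``].

    The defaults emulate an error-prone-PCR serpin library in which most
    functional substitutions sit within about two-fold of the WT latency
    half-life (measured library mean/median only slightly above WT), roughly
    a fifth of functional substitutions slow the latency transition, and a
    long right tail reaches the slowest measured variants (~13 h).
    """

    wt_t_half: float = WT_T_HALF_H
    stabilized_fraction: float = 0.15
    destabilized_fraction: float = 0.55
    nonfunctional_fraction: float = 0.30
    effect_log_sd: float = 0.55
    t_half_min: float = 0.5
    t_half_max: float = 15.0

    def __post_init__(self) -> None:
        fracs = (self.stabilized_fraction, self.destabilized_fraction,
                 self.nonfunctional_fraction)
        if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError(f"effect fractions {fracs} must be non-negative "
                             "and sum to at most 1")
        if self.wt_t_half <= 0 or self.t_half_min <= 0 or self.t_half_max <= 0:
            raise ValueError("half-lives must be positive")
        if self.effect_log_sd < 0:
            raise ValueError("effect_log_sd must be non-negative")
        if not self.t_half_min < self.wt_t_half < self.t_half_max:
            raise ValueError("need t_half_min < wt_t_half < t_half_max")


@dataclass
class MutationEffectMap:
    """Planted truth: substitution -> (half-life, functional flag).

    Keys are ``(position, mut_aa)`` with 1-based residue numbers.  The WT
    identity at every position implicitly maps to ``wt_t_half`` and is not
    stored.  Nonfunctional entries carry a nominal half-life but are excluded
    from kinetics ground truth.
    """

    reference: ReferenceProtein
    wt_t_half: float = WT_T_HALF_H
    entries: dict[tuple[int, str], tuple[float, bool]] = field(default_factory=dict)

    def t_half(self, position: int, aa: str) -> float:
        if aa == self.reference.wt_aa(position):
            return self.wt_t_half
        t, _functional = self.entries[(position, aa)]
        return t

    def is_functional(self, position: int, aa: str) -> bool:
        if aa == self.reference.wt_aa(position):
            return True
        return self.entries[(position, aa)][1]

    def set_effect(self, position: int, mut_aa: str, t_half: float,
                   functional: bool = True) -> None:
        if t_half <= 0:
            raise ValueError("t_half must be positive")
        if mut_aa == self.reference.wt_aa(position):
            raise ValueError("cannot plant an effect on the WT identity")
        self.entries[(position, mut_aa)] = (float(t_half), functional)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"position": pos, "wt_aa": self.reference.wt_aa(pos), "mut_aa": aa,
             "t_half_hours": t, "functional": fn}
            for (pos, aa), (t, fn) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["position", "wt_aa", "mut_aa",
                                           "t_half_hours", "functional"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, reference: ReferenceProtein,
                 wt_t_half: float = WT_T_HALF_H) -> "MutationEffectMap":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        entries = {(int(r.position), str(r.mut_aa)): (float(r.t_half_hours), bool(r.functional))
                   for r in df.itertuples()}
        return cls(reference=reference, wt_t_half=wt_t_half, entries=entries)


def generate_effect_map(reference: ReferenceProtein,
                        config: EffectConfig | None = None,
                        seed: int = 0) -> MutationEffectMap:
    """Plant a ground-truth effect for every non-WT substitution.

    Deterministic for a fixed seed.  Category draws and half-life draws are
    independent per substitution; nonfunctional substitutions still receive a
    (destabilized-range) nominal half-life so the truth table is complete, but
    their ``functional`` flag excludes them from kinetics ground truth.
    """
    config = config or EffectConfig()
    rng = np.random.default_rng(seed)
    emap = MutationEffectMap(reference=reference, wt_t_half=config.wt_t_half)

    p_stab = config.stabilized_fraction
    p_dest = config.destabilized_fraction
    p_nonf = config.nonfunctional_fraction

    for position in reference.positions:
        wt = reference.wt_aa(position)
        for aa in AA_ALPHABET:
            if aa == wt:
                continue
            u = rng.random()
            if u < p_stab:
                t = _half_normal_effect(rng, config, sign=+1)
                functional = True
            elif u < p_stab + p_dest:
                t = _half_normal_effect(rng, config, sign=-1)
                functional = True
            elif u < p_stab + p_dest + p_nonf:
                t = _half_normal_effect(rng, config, sign=-1)
                functional = False
            else:
                t = config.wt_t_half
                functional = True
            emap.entries[(position, aa)] = (t, functional)
    return emap


def _half_normal_effect(rng: np.random.Generator, config: EffectConfig,
                        sign: int) -> float:
    t = config.wt_t_half * float(
        np.exp(sign * abs(rng.normal(0.0, config.effect_log_sd))))
    return float(np.clip(t, config.t_half_min, config.t_half_max))
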