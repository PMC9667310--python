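"""Time-course protease-selection simulator.

Active clones decay to a latent, non-inhibitory conformation with first-order
kinetics; at each sampled time the library is selected for protease-complex
formation (only still-active, functional clones are recovered) and sequenced.
The simulator emits per-substitution count tables shaped exactly like the
tables the amplicon counter produces from reads, plus the aggregate
recovered-phage fraction used as the library decay curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .effects import MutationEffectMap
from .library import Clone
from .reference import AmpliconDef, ReferenceProtein, covering_amplicon

#: time grid of the full selection experiment, hours
DEFAULT_TIME_GRID_H = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0)
#: alternative preset omitting the 1 h point (aggregate-curve experiments)
COARSE_TIME_GRID_H = (0.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0)

COUNT_COLUMNS = ["variant", "position", "wt_aa", "mut_aa", "amplicon",
                 "time_h", "replicate", "arm", "count"]


@dataclass(frozen=True)
class SelectionDesign:
    """Design of the latency/selection time course.

    ``selection_model`` chooses between drawing sample counts from the
    expected active fractions ("expected-fraction") and simulating per-phage
    survival before sampling ("bernoulli").  ``recovery_noise_sd`` adds
    multiplicative lognormal noise to the aggregate recovery curve;
    ``count_dispersion`` > 0 switches count sampling from multinomial to a
    gamma-multinomial (negative-binomial-like) model.
    """

    time_points_h: tuple[float, ...] = DEFAULT_TIME_GRID_H
    replicates: int = 3
    depth_per_sample: int = 1_000_000
    include_input_sample: bool = True
    baseline_c: float = 0.0
    selection_model: str = "expected-fraction"
    recovery_noise_sd: float = 0.0
    count_model: str = "multinomial"
    count_dispersion: float = 0.0
    pool_size: int = 10_000_000

    def __post_init__(self) -> None:
        t = self.time_points_h
        if len(t) == 0:
            raise ValueError("design needs at least one time point")
        if t[0] != 0:
            raise ValueError("time course must start at 0 h")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("time points must be strictly increasing")
        if not 0 <= self.baseline_c < 1:
            raise ValueError("baseline_c must lie in [0, 1)")
        if self.replicates < 1 or self.depth_per_sample < 1:
            raise ValueError("replicates and depth_per_sample must be positive")
        if self.selection_model not in ("expected-fraction", "bernoulli"):
            raise ValueError(f"unknown selection model {self.selection_model!r}")
        if self.count_model not in ("multinomial", "expected"):
            raise ValueError(f"unknown count model {self.count_model!r}")


@dataclass
class CountDataset:
    """Per-substitution, per-sample counts plus library recovery fractions.

    ``counts`` is tidy with columns ``variant, position, wt_aa, mut_aa,
    amplicon, time_h, replicate, arm, count``; rows with ``mut_aa == wt_aa``
    are the WT-at-position tallies (reads carrying the reference codon at that
    residue).  ``library_recovery`` has columns ``time_h, replicate,
    recovery`` with recovery normalized to 1 at t = 0.
    """

    counts: pd.DataFrame
    library_recovery: pd.DataFrame
    design: SelectionDesign | None = None
    reference: ReferenceProtein | None = None
    panel: list[AmpliconDef] | None = None
    truth: MutationEffectMap | None = None
    clones: list[Clone] | None = None
    clone_counts: dict[tuple[float, int, str], np.ndarray] = field(default_factory=dict)

    @property
    def time_points_h(self) -> list[float]:
        return sorted(self.counts["time_h"].unique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.counts["replicate"].unique())

    def sample(self, time_h: float, replicate: int, arm: str) -> pd.DataFrame:
        c = self.counts
        return c[(c["time_h"] == time_h) & (c["replicate"] == replicate)
                 & (c["arm"] == arm)]

    def write_counts_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    def write_recovery_tsv(self, path) -> None:
        self.library_recovery.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, recovery_path=None) -> "CountDataset":
        counts = pd.read_csv(counts_path, sep="\t")
        missing = set(COUNT_COLUMNS) - set(counts.columns)
        if missing:
            raise ValueError(f"counts table missing columns {sorted(missing)}")
        if recovery_path is not None:
            recovery = pd.read_csv(recovery_path, sep="\t")
        else:
            recovery = pd.DataFrame(columns=["time_h", "replicate", "recovery"])
        return cls(counts=counts, library_recovery=recovery)


def active_fraction(k: np.ndarray, t: float, c: float) -> np.ndarray:
    """Fraction of initially active molecules still active at time ``t``."""
    return (1.0 - c) * np.exp(-np.asarray(k) * t) + c


def expected_library_recovery(clones: list[Clone], t: float, c: float) -> float:
    """Closed-form aggregate recovery (relative to t = 0) for a clone mix."""
    ab = np.array([cl.abundance for cl in clones])
    k = np.array([cl.k_eff for cl in clones])
    fn = np.array([cl.functional for cl in clones], dtype=float)
    num = float(np.sum(ab * fn * active_fraction(k, t, c)))
    den = float(np.sum(ab * fn))
    return num / den if den > 0 else 0.0


def simulate_selection_timecourse(library: list[Clone],
                                  design: SelectionDesign,
                                  seed: int = 0,
                                  reference: ReferenceProtein | None = None,
                                  panel: list[AmpliconDef] | None = None,
                                  truth: MutationEffectMap | None = None) -> CountDataset:
    """Simulate selection, recovery and sequencing of a clone library.

    Selected-arm counts are multinomial draws with clone probabilities
    proportional to abundance x active fraction (functional clones only);
    input-arm counts are proportional to abundance alone.  Per-substitution
    counts are sums over the clones carrying the substitution; WT-at-position
    counts are reads from clones with the reference codon at that residue.
    Every sampled phage genome is observed on every amplicon covering a
    position, so per-sample totals at any position equal ``depth_per_sample``.
    """
    if not library:
        raise ValueError("library must be non-empty")
    if reference is None and truth is not None:
        reference = truth.reference

    rng = np.random.default_rng(seed)
    n_clones = len(library)
    ab = np.array([cl.abundance for cl in library], dtype=float)
    ab = ab / ab.sum()
    k = np.array([cl.k_eff for cl in library], dtype=float)
    fn = np.array([cl.functional for cl in library], dtype=float)
    c0 = design.baseline_c

    sub_index, S, P, positions = _incidence(library, reference)
    amp_of_pos = _amplicon_lookup(positions, panel, reference)

    times = list(design.time_points_h)
    arms = ["selected"] + (["input"] if design.include_input_sample else [])

    clone_counts: dict[tuple[float, int, str], np.ndarray] = {}
    recovery_rows = []
    frames = []

    for rep in range(1, design.replicates + 1):
        recovery_raw = {}
        for t in times:
            act = fn * active_fraction(k, t, c0)
            if design.selection_model == "expected-fraction":
                w_sel = ab * act
                recovery = float(w_sel.sum())
                sel_counts = _draw_counts(rng, design, w_sel)
            else:  # bernoulli: explicit per-phage survival in a finite pool
                pool = rng.multinomial(design.pool_size, ab)
                survivors = rng.binomial(pool, np.clip(act, 0.0, 1.0))
                recovery = survivors.sum() / design.pool_size
                if survivors.sum() == 0:
                    sel_counts = np.zeros(n_clones, dtype=np.int64)
                else:
                    sel_counts = _draw_counts(rng, design, survivors.astype(float))
            if design.recovery_noise_sd > 0:
                recovery *= float(np.exp(rng.normal(0.0, design.recovery_noise_sd)))
            recovery_raw[t] = recovery
            clone_counts[(t, rep, "selected")] = sel_counts
            if design.include_input_sample:
                clone_counts[(t, rep, "input")] = _draw_counts(rng, design, ab)

        r0 = recovery_raw[0.0]
        for t in times:
            recovery_rows.append({"time_h": t, "replicate": rep,
                                  "recovery": recovery_raw[t] / r0})

    for (t, rep, arm), counts in clone_counts.items():
        frames.append(_sample_frame(counts, sub_index, S, P, positions,
                                    amp_of_pos, reference, t, rep, arm))

    counts_df = pd.concat(frames, ignore_index=True)
    counts_df = counts_df.sort_values(
        ["time_h", "replicate", "arm", "position", "mut_aa"], kind="stable",
    ).reset_index(drop=True)
    recovery_df = pd.DataFrame(recovery_rows).sort_values(
        ["replicate", "time_h"]).reset_index(drop=True)

    return CountDataset(counts=counts_df, library_recovery=recovery_df,
                        design=design, reference=reference, panel=panel,
                        truth=truth, clones=library, clone_counts=clone_counts)


def _draw_counts(rng: np.random.Generator, design: SelectionDesign,
                 weights: np.ndarray) -> np.ndarray:
    total = weights.sum()
    if total <= 0:
        return np.zeros(len(weights), dtype=np.int64)
    p = weights / total
    if design.count_model == "expected":
        # deterministic rounded expected counts (noiseless sequencing)
        return np.floor(p * design.depth_per_sample + 0.5).astype(np.int64)
    if design.count_dispersion > 0:
        shape = 1.0 / design.count_dispersion
        p = p * rng.gamma(shape, 1.0 / shape, size=len(p))
        p = p / p.sum()
    return rng.multinomial(design.depth_per_sample, p)


def _incidence(library: list[Clone], reference: ReferenceProtein | None):
    """Sparse clone-by-substitution and clone-by-position incidence."""
    subs = sorted({s for cl in library for s in cl.substitutions})
    sub_to_col = {s: j for j, s in enumerate(subs)}
    if reference is not None:
        positions = list(reference.positions)
    else:
        positions = sorted({p for p, _ in subs})
    pos_to_col = {p: j for j, p in enumerate(positions)}

    rows_s, cols_s, rows_p, cols_p = [], [], [], []
    for i, cl in enumerate(library):
        for s in cl.substitutions:
            rows_s.append(i)
            cols_s.append(sub_to_col[s])
            rows_p.append(i)
            cols_p.append(pos_to_col[s[0]])
    S = sparse.csr_matrix((np.ones(len(rows_s)), (rows_s, cols_s)),
                          shape=(len(library), len(subs)))
    P = sparse.csr_matrix((np.ones(len(rows_p)), (rows_p, cols_p)),
                          shape=(len(library), len(positions)))
    return subs, S, P, positions


def _amplicon_lookup(positions, panel, reference):
    if panel is None or reference is None:
        return {p: "all" for p in positions}
    return {p: covering_amplicon(p, panel, reference).name for p in positions}


def _sample_frame(counts: np.ndarray, sub_index, S, P, positions, amp_of_pos,
                  reference, t, rep, arm) -> pd.DataFrame:
    sub_counts = np.asarray(S.T @ counts, dtype=np.int64).ravel()
    mutated_at_pos = np.asarray(P.T @ counts, dtype=np.int64).ravel()
    wt_counts = counts.sum() - mutated_at_pos

    def wt_of(p):
        return reference.wt_aa(p) if reference is not None else "X"

    pos_arr = np.array([p for p, _ in sub_index] + positions, dtype=np.int64)
    wt_arr = np.array([wt_of(p) for p, _ in sub_index] + [wt_of(p) for p in positions])
    mut_arr = np.array([a for _, a in sub_index] + [wt_of(p) for p in positions])
    count_arr = np.concatenate([sub_counts, wt_counts])
    amp_arr = np.array([amp_of_pos[p] for p in pos_arr])
    variant = np.char.add(np.char.add(wt_arr, pos_arr.astype(str)), mut_arr)

    return pd.DataFrame({
        "variant": variant, "position": pos_arr, "wt_aa": wt_arr,
        "mut_aa": mut_arr, "amplicon": amp_arr,
        "time_h": t, "replicate": rep, "arm": arm, "count": count_arr,
    })
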