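"""One-phase decay fitting and massively parallel half-life deconvolution.

The latency transition of an active serpin clone is first-order, so the
fraction of library recovered by protease selection decays as

    y(t) = (1 - c) * exp(-k t) + c,        t_1/2 = ln(2) / k

with rate constant ``k`` (per hour) and asymptote ``c``.  (The equivalent
``y = exp(-k t) + c`` parameterization is selectable, but it is inconsistent
with trajectories normalized to 1 at t = 0 unless c = 0, so the
amplitude-normalized form is the default.)

Per-variant kinetics are deconvolved from aggregate library data: the
library's fractional activity at each time point is multiplied by the fraction
of sequencing counts attributable to the variant, the product is normalized to
1 at t = 0, and the resulting trajectory is fitted with the same decay model.
Positional WT trajectories fitted the same way absorb the local mutational
background: each variant's half-life is rescaled so the WT identity at its
position equals the reference WT half-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .effects import WT_T_HALF_H
from .selection import CountDataset

LN2 = math.log(2.0)

K_LOWER = 1e-6
K_UPPER = 50.0


@dataclass(frozen=True)
class DecayFit:
    """A fitted one-phase exponential decay."""

    k: float
    c: float
    rss: float
    n_points: int
    converged: bool
    form: str = "amplitude-normalized"

    @property
    def t_half(self) -> float:
        return half_life(self.k)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.form == "amplitude-normalized":
            return (1.0 - self.c) * np.exp(-self.k * t) + self.c
        return np.exp(-self.k * t) + self.c


def half_life(k: float) -> float:
    """Half-life ln(2)/k of a first-order process with rate constant k > 0."""
    if k <= 0:
        raise ValueError(f"rate constant must be positive, got {k}")
    return LN2 / k


class ExponentialDecayModel(BaseEstimator):
    """Bounded nonlinear least-squares fit of a one-phase decay.

    Parameters
    ----------
    form : {"amplitude-normalized", "as-printed"}
        ``amplitude-normalized`` fits ``y = (1-c) e^(-kt) + c`` (y(0) = 1);
        ``as-printed`` fits ``y = e^(-kt) + c``.
    n_starts : int
        Number of log-spaced initial rate constants (multi-start guards
        against local minima for slow decays).
    tol : float
        Optimizer ftol/xtol/gtol.

    Attributes (after :meth:`fit`)
    ------------------------------
    k_, c_, t_half_, rss_, converged_, n_points_, fit_
    """

    def __init__(self, form: str = "amplitude-normalized", n_starts: int = 5,
                 tol: float = 1e-15, k_min: float = K_LOWER, k_max: float = K_UPPER):
        self.form = form
        self.n_starts = n_starts
        self.tol = tol
        self.k_min = k_min
        self.k_max = k_max

    def fit(self, t, y) -> "ExponentialDecayModel":
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        finite = np.isfinite(t) & np.isfinite(y)
        t, y = t[finite], y[finite]
        if len(t) < 4:
            raise InsufficientDataError(f"need >= 4 finite points, got {len(t)}")
        if t.min() > 0:
            raise InsufficientDataError("time course must include t = 0")
        if y.min() < -0.1 or y.max() > 1.5:
            raise InsufficientDataError(
                f"values outside [-0.1, 1.5] (got [{y.min():.3g}, {y.max():.3g}])")
        if self.form not in ("amplitude-normalized", "as-printed"):
            raise ValueError(f"unknown form {self.form!r}")

        amplitude = self.form == "amplitude-normalized"

        def residuals(params):
            k, c = params
            if amplitude:
                model = (1.0 - c) * np.exp(-k * t) + c
            else:
                model = np.exp(-k * t) + c
            return model - y

        def jacobian(params):
            k, c = params
            e = np.exp(-k * t)
            dk = -t * e * ((1.0 - c) if amplitude else 1.0)
            dc = (1.0 - e) if amplitude else np.ones_like(t)
            return np.column_stack([dk, dc])

        c0 = float(np.clip(y[np.argmax(t)], 0.0, 0.9))
        best = None
        for k0 in np.geomspace(0.02, 10.0, self.n_starts):
            try:
                res = least_squares(
                    residuals, x0=[k0, c0], jac=jacobian,
                    bounds=([self.k_min, 0.0], [self.k_max, 1.0 - 1e-9]),
                    ftol=self.tol, xtol=self.tol, gtol=self.tol)
            except Exception:
                continue
            rss = float(2.0 * res.cost)
            key = (rss, res.x[0])  # ties broken by lowest rss then lowest k
            if best is None or key < best[0]:
                best = (key, res)
        if best is None:
            raise RuntimeError("all optimizer starts failed")

        res = best[1]
        x = self._polish(np.asarray(res.x, dtype=float), residuals, jacobian)
        k, c = float(x[0]), float(x[1])
        at_bound = k <= self.k_min * (1 + 1e-6) or k >= self.k_max * (1 - 1e-6)
        # amplitude (1 - c) ~ 0 leaves k unidentifiable (e.g. a constant series)
        degenerate = self.form == "amplitude-normalized" and (1.0 - c) < 1e-2
        converged = bool(res.success) and not at_bound and not degenerate

        self.k_, self.c_ = k, c
        self.rss_ = float(np.sum(residuals(x) ** 2))
        self.n_points_ = len(t)
        self.converged_ = converged
        self.t_half_ = LN2 / k
        self.fit_ = DecayFit(k=k, c=c, rss=self.rss_, n_points=len(t),
                             converged=converged, form=self.form)
        return self

    def _polish(self, x, residuals, jacobian):
        """A few projected Gauss-Newton steps to machine-precision rss."""
        lo = np.array([self.k_min, 0.0])
        hi = np.array([self.k_max, 1.0 - 1e-9])
        rss = float(np.sum(residuals(x) ** 2))
        for _ in range(5):
            r = residuals(x)
            J = jacobian(x)
            try:
                delta = np.linalg.solve(J.T @ J, -J.T @ r)
            except np.linalg.LinAlgError:
                break
            x_new = np.clip(x + delta, lo, hi)
            rss_new = float(np.sum(residuals(x_new) ** 2))
            if not np.isfinite(rss_new) or rss_new >= rss:
                break
            x, rss = x_new, rss_new
        return x

    def predict(self, t) -> np.ndarray:
        return self.fit_.predict(t)


class InsufficientDataError(ValueError):
    """Raised when a trajectory has too few usable points to fit."""


def fit_decay(times, values, form: str = "amplitude-normalized") -> DecayFit:
    """Fit ``y(t)`` to a one-phase exponential decay; see the module docstring."""
    return ExponentialDecayModel(form=form).fit(times, values).fit_


def fit_library_recovery(dataset: CountDataset,
                         form: str = "amplitude-normalized") -> DecayFit:
    """Fit the replicate-averaged library recovery curve.

    This is the aggregate activity F_lib(t) that per-variant trajectories are
    multiplied by downstream.
    """
    rec = dataset.library_recovery
    if rec.empty:
        raise ValueError("dataset has no library recovery data")
    mean = rec.groupby("time_h")["recovery"].mean()
    if 0.0 not in mean.index:
        raise ValueError("library recovery must include t = 0")
    if len(mean) < 4:
        raise InsufficientDataError("need recovery at >= 4 time points")
    return fit_decay(mean.index.to_numpy(), mean.to_numpy(), form=form)


@dataclass
class VariantKineticsRecord:
    """Deconvolved kinetics of one amino-acid substitution (or WT identity)."""

    variant: str
    position: int
    wt_aa: str
    mut_aa: str
    trajectory: list[tuple[float, float]] = field(default_factory=list)
    raw_t_half: float = float("nan")
    normalized_t_half: float = float("nan")
    position_wt_t_half: float = float("nan")
    flag: str = "ok"
    reason: str = ""
    rss: float = float("nan")
    n_points: int = 0

    @property
    def is_wt(self) -> bool:
        return self.mut_aa == self.wt_aa


def empirical_library_curve(dataset: CountDataset):
    """Replicate-mean recovered fraction per time point, as a step lookup.

    This is the library's measured fractional activity; per-variant
    trajectories multiply it directly, so no functional form is imposed on
    the aggregate before the per-variant fit.
    """
    rec = dataset.library_recovery
    if rec.empty:
        raise ValueError("dataset has no library recovery data")
    mean = rec.groupby("time_h")["recovery"].mean()
    table = dict(zip(mean.index.astype(float), mean.astype(float)))

    def f_lib(t: float) -> float:
        return table[float(t)]

    return f_lib


def variant_trajectory(substitution: tuple[int, str],
                       dataset: CountDataset,
                       library_fit,
                       arm: str = "selected") -> VariantKineticsRecord:
    """Normalized fractional-activity trajectory of one substitution.

    trajectory(t) = F_lib(t) x [count_v(t) / total position counts(t)],
    divided by its t = 0 value; replicates are normalized individually and
    then averaged point-wise.  The denominator is the total reads covering
    the variant's position on its covering amplicon (WT-at-position counts
    plus all substitution counts there).  ``library_fit`` may be a
    :class:`DecayFit` or any callable F_lib(t) (e.g. the empirical per-time
    recovery from :func:`empirical_library_curve`).
    """
    position, mut_aa = substitution
    traj, meta = _trajectories_for(dataset, library_fit, arm,
                                   [(position, mut_aa)])
    rec = _make_record(position, mut_aa, meta[0], traj[0])
    return rec


def massively_parallel_half_lives(dataset: CountDataset,
                                  min_count: float = 10.0,
                                  min_points: int = 4,
                                  wt_reference_t_half: float = WT_T_HALF_H,
                                  library_fit: DecayFit | None = None,
                                  form: str = "amplitude-normalized",
                                  library_curve: str = "empirical"
                                  ) -> list[VariantKineticsRecord]:
    """Functional half-lives for every substitution in a count dataset.

    Convenience wrapper over :class:`MassivelyParallelKinetics`.
    """
    est = MassivelyParallelKinetics(min_count=min_count, min_points=min_points,
                                    wt_reference_t_half=wt_reference_t_half,
                                    form=form, library_curve=library_curve)
    est.fit(dataset, library_fit=library_fit)
    return est.records_


class MassivelyParallelKinetics(BaseEstimator):
    """Per-variant latency half-lives deconvolved from library counts.

    For each substitution with adequate t = 0 coverage the count-fraction
    trajectory is fitted with the one-phase decay model; the WT-at-position
    trajectory is fitted the same way, and the variant half-life is rescaled
    by ``wt_reference_t_half / position_wt_t_half`` so the WT identity at
    every position reads exactly the reference WT half-life.  Failures are
    flagged ``ND`` with a reason code, never dropped.

    Parameters
    ----------
    min_count : float
        Minimum replicate-mean selected-arm count at t = 0 (QC threshold).
    min_points : int
        Minimum finite trajectory points for a fit.
    wt_reference_t_half : float
        Half-life (hours) assigned to the WT identity after renormalization.
    library_curve : {"empirical", "fitted"}
        Aggregate activity used in the deconvolution: the measured per-time
        recovery fractions (default, mirroring multiplication by the
        library's fractional activity at each time point) or the one-phase
        fit of the recovery curve.

    Attributes (after :meth:`fit`)
    ------------------------------
    records_ : list of VariantKineticsRecord
    results_ : tidy DataFrame of the same records
    library_fit_ : DecayFit of the aggregate recovery curve
    """

    def __init__(self, min_count: float = 10.0, min_points: int = 4,
                 wt_reference_t_half: float = WT_T_HALF_H,
                 form: str = "amplitude-normalized",
                 library_curve: str = "empirical"):
        self.min_count = min_count
        self.min_points = min_points
        self.wt_reference_t_half = wt_reference_t_half
        self.form = form
        self.library_curve = library_curve

    def fit(self, dataset: CountDataset,
            library_fit: DecayFit | None = None) -> "MassivelyParallelKinetics":
        times = dataset.time_points_h
        if len(times) < 4:
            raise InsufficientDataError("dataset has fewer than 4 time points")
        if library_fit is None:
            library_fit = fit_library_recovery(dataset, form=self.form)
        self.library_fit_ = library_fit
        if self.library_curve == "empirical":
            f_lib = empirical_library_curve(dataset)
        elif self.library_curve == "fitted":
            f_lib = library_fit
        else:
            raise ValueError(f"unknown library_curve {self.library_curve!r}")

        sel = dataset.counts[dataset.counts["arm"] == "selected"]
        keys = (sel[["position", "wt_aa", "mut_aa"]]
                .drop_duplicates()
                .sort_values(["position", "mut_aa"]))
        subs = [(int(r.position), str(r.mut_aa)) for r in keys.itertuples()]
        trajs, metas = _trajectories_for(dataset, f_lib, "selected", subs)

        # positional WT fits first (needed to renormalize every variant)
        wt_fit: dict[int, VariantKineticsRecord] = {}
        records: list[VariantKineticsRecord] = []
        for (pos, aa), meta, traj in zip(subs, metas, trajs):
            if aa == meta["wt_aa"]:
                rec = self._fit_one(pos, aa, meta, traj)
                wt_fit[pos] = rec
        for (pos, aa), meta, traj in zip(subs, metas, trajs):
            if aa == meta["wt_aa"]:
                rec = wt_fit[pos]
            else:
                rec = self._fit_one(pos, aa, meta, traj)
            wt_rec = wt_fit.get(pos)
            if wt_rec is None or wt_rec.flag != "ok":
                if rec.flag == "ok" and not rec.is_wt:
                    rec.flag, rec.reason = "ND", "no_wt_at_position"
            else:
                rec.position_wt_t_half = wt_rec.raw_t_half
                if rec.is_wt:
                    # WT renormalizes to the reference value exactly
                    rec.normalized_t_half = self.wt_reference_t_half
                elif rec.flag == "ok":
                    rec.normalized_t_half = rec.raw_t_half * (
                        self.wt_reference_t_half / wt_rec.raw_t_half)
            records.append(rec)

        self.records_ = records
        self.results_ = kinetics_frame(records)
        return self

    def _fit_one(self, pos, aa, meta, traj) -> VariantKineticsRecord:
        rec = _make_record(pos, aa, meta, traj)
        if rec.flag != "ok":
            return rec
        if meta["t0_mean_count"] < self.min_count:
            rec.flag, rec.reason = "ND", "low_t0_count"
            return rec
        t = np.array([p[0] for p in rec.trajectory])
        y = np.array([p[1] for p in rec.trajectory])
        finite = np.isfinite(y)
        if finite.sum() < self.min_points:
            rec.flag, rec.reason = "ND", "too_few_points"
            return rec
        try:
            fit = fit_decay(t[finite], y[finite], form=self.form)
        except (InsufficientDataError, RuntimeError) as exc:
            rec.flag, rec.reason = "ND", "fit_failed"
            return rec
        rec.raw_t_half = fit.t_half
        rec.rss = fit.rss
        rec.n_points = fit.n_points
        if not fit.converged:
            rec.flag, rec.reason = "ND", "fit_not_converged"
        return rec


def kinetics_frame(records: list[VariantKineticsRecord]) -> pd.DataFrame:
    rows = [{
        "variant": r.variant, "position": r.position, "wt_aa": r.wt_aa,
        "mut_aa": r.mut_aa, "raw_t_half": r.raw_t_half,
        "normalized_t_half": r.normalized_t_half,
        "position_wt_t_half": r.position_wt_t_half,
        "flag": r.flag, "reason": r.reason, "rss": r.rss,
        "n_points": r.n_points,
    } for r in records]
    return pd.DataFrame(rows, columns=["variant", "position", "wt_aa", "mut_aa",
                                       "raw_t_half", "normalized_t_half",
                                       "position_wt_t_half", "flag", "reason",
                                       "rss", "n_points"])


# ---------------------------------------------------------------------------
# trajectory assembly


def _trajectories_for(dataset: CountDataset, library_fit, arm: str, subs):
    """Replicate-averaged normalized trajectories for the given substitutions.

    Returns (trajectories, metadata): per substitution, a (time, value) array
    (NaN where undefined) and a dict with the WT identity and the t = 0
    replicate-mean count.
    """
    counts = dataset.counts[dataset.counts["arm"] == arm]
    times = np.array(sorted(counts["time_h"].unique()), dtype=float)
    reps = sorted(counts["replicate"].unique())
    f_lib = library_fit.predict(times) if hasattr(library_fit, "predict") \
        else np.asarray([library_fit(t) for t in times], dtype=float)

    wide = counts.pivot_table(index=["position", "wt_aa", "mut_aa"],
                              columns=["time_h", "replicate"], values="count",
                              aggfunc="sum", fill_value=0)
    wide = wide.reindex(columns=pd.MultiIndex.from_product([times, reps]),
                        fill_value=0)
    # denominator: all reads covering each position (WT + every substitution)
    denom = wide.groupby(level="position").sum()

    wt_of = {pos: wt for pos, wt, _ in wide.index}

    arr = wide.to_numpy(dtype=float).reshape(len(wide), len(times), len(reps))
    den = denom.to_numpy(dtype=float).reshape(len(denom), len(times), len(reps))
    pos_row = {p: i for i, p in enumerate(denom.index)}
    key_row = {(p, m): i for i, (p, _w, m) in enumerate(wide.index)}

    trajs, metas = [], []
    for pos, mut in subs:
        wt = wt_of.get(pos, "?")
        meta = {"wt_aa": wt, "t0_mean_count": 0.0}
        i = key_row.get((pos, mut))
        if i is None:
            trajs.append(None)
            metas.append(meta)
            continue
        num = arr[i]                      # (time, rep)
        d = den[pos_row[pos]]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(d > 0, num / d, np.nan)
        traj_r = f_lib[:, None] * frac     # per-replicate trajectory
        t0 = traj_r[0]                     # value at t = 0 per replicate
        valid = t0 > 0
        meta["t0_mean_count"] = float(num[0].mean())
        if not valid.any():
            trajs.append(None)
            metas.append(meta)
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            normed = np.where(valid[None, :], traj_r / t0[None, :], np.nan)
        mean_traj = np.nanmean(normed, axis=1)
        trajs.append(np.column_stack([times, mean_traj]))
        metas.append(meta)
    return trajs, metas


def _make_record(pos, aa, meta, traj) -> VariantKineticsRecord:
    wt = meta["wt_aa"]
    rec = VariantKineticsRecord(variant=f"{wt}{pos}{aa}", position=pos,
                                wt_aa=wt, mut_aa=aa)
    if traj is None:
        rec.flag, rec.reason = "ND", "zero_t0"
        return rec
    rec.trajectory = [(float(t), float(v)) for t, v in traj]
    return rec
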