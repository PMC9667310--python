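"""Functional stability scores from selected vs. unselected counts.

At the endpoint of the latency time course (48 h by default), each
substitution's log2 fold change (protease-selected over unselected input) is
compared with the WT identity at its position; the difference is the
functional stability score.  Counts are depth-normalized with median-of-ratios
size factors, significance uses a Wald-type z on the replicate scores with a
count-based variance floor, and p-values are Benjamini-Hochberg adjusted.
Substitutions depleted already at 0 h (no inhibitory activity) are excluded
before testing.

This is a self-contained, documented analogue of a standard RNA-seq-style
count model: median-of-ratios normalization and a dispersion-aware Wald test,
without negative-binomial dispersion shrinkage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .selection import CountDataset

LN2 = math.log(2.0)

CLASS_INCREASED = "increased"
CLASS_DECREASED = "decreased_or_equal"
CLASS_NOT_SCORED = "not_scored"
CLASS_NONFUNCTIONAL = "nonfunctional_at_0h"


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    ``count_matrix`` is variants x samples.  Variants with a zero count in
    any sample are excluded from the reference set; if none remain, factors
    fall back to relative library sizes with a warning.
    """
    m = count_matrix.to_numpy(dtype=float)
    if m.shape[1] < 2:
        raise ValueError("need at least two samples for size factors")
    all_nonzero = (m > 0).all(axis=1)
    if not all_nonzero.any():
        warnings.warn("no variant has nonzero counts in every sample; "
                      "falling back to library-size factors")
        totals = m.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        ref = m[all_nonzero]
        log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
        log_ratios = np.log(ref) - log_geo
        factors = np.exp(np.median(log_ratios, axis=0))
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=count_matrix.columns, name="size_factor")


class StabilityScorer(BaseEstimator):
    """Functional stability scores and classification for one selection endpoint.

    Parameters
    ----------
    t_select : float
        Time point (hours) whose selected/input samples are scored.
    pseudocount : float
        Added to normalized counts inside the log2 ratio.
    alpha, min_base_mean : float
        Classification thresholds: a substitution is called significantly
        changed only when ``p_adj < alpha`` and ``base_mean > min_base_mean``
        (strict inequality on the base mean).

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : tidy DataFrame (variant, position, wt_aa, mut_aa, log2fc,
        stability_score, base_mean, p_value, p_adj, class), sorted by score
        descending.
    size_factors_ : per-sample factors used for normalization.
    """

    def __init__(self, t_select: float = 48.0, pseudocount: float = 0.5,
                 alpha: float = 0.05, min_base_mean: float = 10.0):
        self.t_select = t_select
        self.pseudocount = pseudocount
        self.alpha = alpha
        self.min_base_mean = min_base_mean

    def fit(self, dataset: CountDataset,
            nonfunctional: set | None = None) -> "StabilityScorer":
        sel, inp, meta = self._matrices(dataset)
        both = pd.concat([sel, inp], axis=1)
        factors = size_factors(both)
        self.size_factors_ = factors
        norm_all = both / factors
        n_rep = sel.shape[1]
        pc = self.pseudocount

        ns = norm_all.iloc[:, :n_rep].to_numpy()
        ni = norm_all.iloc[:, n_rep:].to_numpy()
        log2fc_rep = np.log2((ns + pc) / (ni + pc))
        log2fc = log2fc_rep.mean(axis=1)
        base_mean = norm_all.to_numpy().mean(axis=1)

        res = meta.copy()
        res["log2fc"] = log2fc
        res["base_mean"] = base_mean

        # WT-at-position reference within the covering amplicon
        is_wt = (res["mut_aa"] == res["wt_aa"]).to_numpy()
        wt_log2fc_rep = {pos: log2fc_rep[i] for i, pos in
                         zip(np.flatnonzero(is_wt), res.loc[is_wt, "position"])}

        score_rep = np.full_like(log2fc_rep, np.nan)
        for i in range(len(res)):
            pos = res["position"].iat[i]
            wt_r = wt_log2fc_rep.get(pos)
            if wt_r is not None:
                score_rep[i] = log2fc_rep[i] - wt_r
        res["stability_score"] = np.nanmean(score_rep, axis=1)
        res.loc[is_wt, "stability_score"] = 0.0   # exact self-subtraction

        nonfunctional = nonfunctional or set()
        res["class"] = CLASS_NOT_SCORED
        nf_mask = res.apply(
            lambda r: (int(r["position"]), str(r["mut_aa"])) in nonfunctional,
            axis=1).to_numpy() & ~is_wt

        testable = ~is_wt & ~nf_mask & np.isfinite(res["stability_score"].to_numpy())
        p = np.full(len(res), np.nan)
        if n_rep < 2:
            warnings.warn("single replicate: p-values set to 1, nothing can "
                          "be called significant")
            p[testable] = 1.0
        else:
            se = self._standard_errors(score_rep, ns, ni, res, n_rep)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = res["stability_score"].to_numpy() / se
            p_all = 2.0 * norm.sf(np.abs(z))
            p_all[res["stability_score"].to_numpy() == 0.0] = 1.0
            p[testable] = p_all[testable]

        p_adj = np.full(len(res), np.nan)
        if testable.any():
            p_adj[testable] = multipletests(p[testable], method="fdr_bh")[1]
        res["p_value"] = p
        res["p_adj"] = p_adj

        res.loc[nf_mask, "class"] = CLASS_NONFUNCTIONAL
        significant = (testable & (p_adj < self.alpha)
                       & (res["base_mean"].to_numpy() > self.min_base_mean))
        res.loc[significant & (res["stability_score"] > 0), "class"] = CLASS_INCREASED
        res.loc[significant & (res["stability_score"] <= 0), "class"] = CLASS_DECREASED

        self.results_ = (res.sort_values("stability_score", ascending=False,
                                         kind="stable")
                         .reset_index(drop=True))
        return self

    def _matrices(self, dataset: CountDataset):
        c = dataset.counts
        at_t = c[c["time_h"] == self.t_select]
        arms = set(at_t["arm"].unique())
        if "selected" not in arms or "input" not in arms:
            raise ValueError(f"need selected and input arms at t = "
                             f"{self.t_select} h (found {sorted(arms)})")
        wide = at_t.pivot_table(index=["variant", "position", "wt_aa",
                                       "mut_aa", "amplicon"],
                                columns=["arm", "replicate"], values="count",
                                aggfunc="sum", fill_value=0)
        meta = wide.index.to_frame(index=False)
        sel = wide["selected"].reset_index(drop=True)
        inp = wide["input"].reset_index(drop=True)
        sel.columns = [f"sel_r{r}" for r in sel.columns]
        inp.columns = [f"inp_r{r}" for r in inp.columns]
        return sel, inp, meta

    def _standard_errors(self, score_rep, ns, ni, res, n_rep):
        """Replicate-variance SE with a count-based shrinkage floor.

        The floor is the delta-method variance of the log2 ratios
        (1/count terms, summed over the variant's and the WT reference's
        selected and input normalized counts)."""
        pc = self.pseudocount
        var_rep = np.nanvar(score_rep, axis=1, ddof=1) / n_rep

        # per-row count-based variance of the log2fc
        var_counts = (1.0 / (ns + pc) + 1.0 / (ni + pc)).sum(axis=1) / (
            n_rep ** 2 * LN2 ** 2)
        # add the WT reference's contribution at each row's position
        wt_row_of_pos = {}
        is_wt = (res["mut_aa"] == res["wt_aa"]).to_numpy()
        for i in np.flatnonzero(is_wt):
            wt_row_of_pos[res["position"].iat[i]] = var_counts[i]
        wt_var = np.array([wt_row_of_pos.get(p, 0.0) for p in res["position"]])
        floor = var_counts + wt_var
        return np.sqrt(var_rep + floor)


def stability_scores(dataset: CountDataset, t_select: float = 48.0,
                     pseudocount: float = 0.5,
                     nonfunctional: set | None = None) -> pd.DataFrame:
    """Score all substitutions at the selection endpoint; see
    :class:`StabilityScorer`."""
    scorer = StabilityScorer(t_select=t_select, pseudocount=pseudocount)
    scorer.fit(dataset, nonfunctional=nonfunctional)
    return scorer.results_


def significance(results: pd.DataFrame) -> pd.DataFrame:
    """The (p_value, p_adj) columns of a scored results table."""
    return results[["variant", "p_value", "p_adj"]]


def classify(results: pd.DataFrame, alpha: float = 0.05,
             min_base_mean: float = 10.0,
             nonfunctional: set | None = None) -> pd.DataFrame:
    """(Re-)apply classification thresholds to a scored results table.

    Substitutions in ``nonfunctional`` are labelled and excluded; remaining
    ones are ``increased`` or ``decreased_or_equal`` when ``p_adj < alpha``
    and ``base_mean > min_base_mean`` (strict), else ``not_scored``.
    """
    res = results.copy()
    nonfunctional = nonfunctional or set()
    is_wt = res["mut_aa"] == res["wt_aa"]
    nf = res.apply(lambda r: (int(r["position"]), str(r["mut_aa"])) in nonfunctional,
                   axis=1) & ~is_wt
    res["class"] = CLASS_NOT_SCORED
    res.loc[nf, "class"] = CLASS_NONFUNCTIONAL
    ok = (~is_wt & ~nf & (res["p_adj"] < alpha)
          & (res["base_mean"] > min_base_mean))
    res.loc[ok & (res["stability_score"] > 0), "class"] = CLASS_INCREASED
    res.loc[ok & (res["stability_score"] <= 0), "class"] = CLASS_DECREASED
    return res


def detect_nonfunctional(dataset: CountDataset, log2fc_threshold: float = -1.0,
                         pseudocount: float = 0.5) -> set:
    """Substitutions depleted by selection already at t = 0.

    A substitution whose mean normalized log2 fold change (selected over
    input) at 0 h falls below ``log2fc_threshold`` is called nonfunctional:
    it fails to form a protease complex even before any latency transition.
    """
    scorer = StabilityScorer(t_select=0.0, pseudocount=pseudocount)
    sel, inp, meta = scorer._matrices(dataset)
    both = pd.concat([sel, inp], axis=1)
    factors = size_factors(both)
    norm_all = both / factors
    n_rep = sel.shape[1]
    ns = norm_all.iloc[:, :n_rep].to_numpy()
    ni = norm_all.iloc[:, n_rep:].to_numpy()
    log2fc = np.log2((ns + pseudocount) / (ni + pseudocount)).mean(axis=1)
    out = set()
    for i, fc in enumerate(log2fc):
        if meta["mut_aa"].iat[i] == meta["wt_aa"].iat[i]:
            continue
        if fc < log2fc_threshold:
            out.add((int(meta["position"].iat[i]), str(meta["mut_aa"].iat[i])))
    return out
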