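"""Heatmap matrices, validation regression, and summary statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import AA_ALPHABET

WT = "WT"
MISSING = "MISSING"
ND = "ND"
NONFUNCTIONAL = "NONFUNCTIONAL"

_SENTINELS = {WT, MISSING, ND, NONFUNCTIONAL}


def build_heatmap(records: pd.DataFrame, value: str = "score",
                  row_order: str = AA_ALPHABET) -> pd.DataFrame:
    """Position-by-amino-acid matrix of scores or half-lives.

    ``records`` needs ``position, wt_aa, mut_aa`` plus a value column
    (``stability_score`` for ``value="score"``, ``normalized_t_half`` for
    ``value="t_half"``) and optionally ``flag``/``class`` columns.  Cells are
    floats or the sentinels WT / NONFUNCTIONAL / ND / MISSING, with exactly
    one WT per column.  Sentinel precedence: WT > NONFUNCTIONAL > ND > MISSING.
    """
    col = {"score": "stability_score", "t_half": "normalized_t_half"}.get(value)
    if col is None:
        raise ValueError(f"unknown value kind {value!r}")
    if records.empty:
        raise ValueError("no records to tabulate")

    dup = records.duplicated(subset=["position", "mut_aa"], keep=False)
    if dup.any():
        conflicting = records.loc[dup]
        groups = conflicting.groupby(["position", "mut_aa"])[col].nunique()
        bad = groups[groups > 1]
        if len(bad):
            raise ValueError(f"conflicting duplicate records at {list(bad.index)}")
        records = records.drop_duplicates(subset=["position", "mut_aa"])

    positions = sorted(records["position"].unique())
    wt_of = dict(zip(records["position"], records["wt_aa"]))
    matrix = pd.DataFrame(MISSING, index=list(row_order), columns=positions,
                          dtype=object)
    for pos in positions:
        matrix.loc[wt_of[pos], pos] = WT

    for _, r in records.iterrows():
        pos, aa = r["position"], r["mut_aa"]
        if aa == r["wt_aa"]:
            continue  # WT sentinel takes precedence over any numeric value
        if r.get("class") == "nonfunctional_at_0h":
            matrix.loc[aa, pos] = NONFUNCTIONAL
        elif r.get("flag", "ok") == "ND":
            matrix.loc[aa, pos] = ND
        else:
            val = r[col]
            matrix.loc[aa, pos] = float(val) if np.isfinite(val) else ND
    return matrix


def heatmap_to_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="aa")


def heatmap_from_tsv(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col="aa", dtype=str)
    raw.columns = [int(c) for c in raw.columns]

    def parse(cell):
        return cell if cell in _SENTINELS else float(cell)

    return raw.map(parse)


@dataclass(frozen=True)
class ComparisonResult:
    """OLS of massively parallel half-lives on individually measured ones.

    ``slope``/``intercept``/``pearson_r`` regress parallel (y) on individual
    (x); the reverse direction is reported alongside.
    """

    slope: float
    intercept: float
    pearson_r: float
    n: int
    pairs: list[tuple[float, float]]
    slope_reverse: float
    intercept_reverse: float


def compare_half_lives(parallel: pd.DataFrame,
                       individual: pd.DataFrame) -> ComparisonResult:
    """Validation regression between the two half-life measurements.

    Both tables need ``variant`` plus a half-life column (``normalized_t_half``
    for the parallel table, ``t_half`` for the individual one).  Requires at
    least 3 shared variants.
    """
    par = parallel
    if "flag" in par.columns:
        par = par[par["flag"] == "ok"]
    merged = par.merge(individual, on="variant", suffixes=("_par", "_ind"))
    ycol = "normalized_t_half" if "normalized_t_half" in par.columns else "t_half_par"
    xcol = "t_half" if "t_half" in individual.columns else "t_half_ind"
    merged = merged.dropna(subset=[ycol, xcol])
    if len(merged) < 3:
        raise ValueError(f"need >= 3 shared substitutions, got {len(merged)}")
    x = merged[xcol].to_numpy(dtype=float)
    y = merged[ycol].to_numpy(dtype=float)
    fwd = stats.linregress(x, y)
    rev = stats.linregress(y, x)
    return ComparisonResult(slope=float(fwd.slope), intercept=float(fwd.intercept),
                            pearson_r=float(fwd.rvalue), n=len(merged),
                            pairs=list(zip(y.tolist(), x.tolist())),
                            slope_reverse=float(rev.slope),
                            intercept_reverse=float(rev.intercept))


def summarize(kinetics: pd.DataFrame) -> dict:
    """Mean/median half-life over usable records plus ND bookkeeping."""
    ok = kinetics[(kinetics["flag"] == "ok")
                  & (kinetics["mut_aa"] != kinetics["wt_aa"])]
    n_nd = int((kinetics["flag"] == "ND").sum())
    if ok.empty:
        raise ValueError("no usable (flag == ok) records")
    vals = ok["normalized_t_half"].dropna()
    return {"mean_t_half": float(vals.mean()),
            "median_t_half": float(vals.median()),
            "n": int(len(vals)), "n_ND": n_nd}
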