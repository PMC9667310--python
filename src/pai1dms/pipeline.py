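"""End-to-end pipeline: simulate -> count -> kinetics -> score -> report.

Each stage reads and writes only documented TSV/JSON files inside the output
directory, so stages can be re-run individually (``--resume`` skips stages
whose configuration hash and outputs are unchanged).  All randomness flows
from a single seed, spawned per stage, and the log records seed, package
version and a configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counting import collapse_amplicons, tally, write_qc_report
from .effects import EffectConfig, MutationEffectMap, generate_effect_map
from .kinetics import (MassivelyParallelKinetics, fit_library_recovery,
                       kinetics_frame)
from .library import generate_clone_library
from .reads import emit_reads
from .reference import (ReferenceProtein, default_amplicon_panel,
                        make_toy_reference, read_amplicon_table,
                        write_amplicon_table)
from .reporting import (build_heatmap, compare_half_lives, heatmap_to_tsv,
                        summarize)
from .scoring import StabilityScorer, detect_nonfunctional
from .selection import CountDataset, SelectionDesign, simulate_selection_timecourse

log = logging.getLogger("pai1dms")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "reference": {"fasta": None, "n_residues": 200, "offset": 1},
    "panel": {"n_amplicons": 12, "length": 150},
    "effects": {},            # EffectConfig defaults
    "library": {"n_clones": 100_000, "mutation_mean": 4.2,
                "abundance": "dirichlet"},
    "design": {},             # SelectionDesign defaults
    "reads": {"emit": False, "error_rate": 0.001, "max_mismatch_codons": 6},
    "kinetics": {"min_count": 10, "wt_reference_t_half": 2.1},
    "scoring": {"t_select": 48.0, "pseudocount": 0.5, "alpha": 0.05,
                "min_base_mean": 10.0},
}

STAGES = ("simulate", "count", "kinetics", "score", "report")


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config sections {sorted(unknown)}")
    for key, default in DEFAULT_CONFIG.items():
        if isinstance(default, dict):
            section = dict(default)
            section.update(user.get(key, {}) or {})
            cfg[key] = section
        else:
            cfg[key] = user.get(key, default)
    return cfg


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir, seed: int | None = None,
                 resume: bool = False, stages=STAGES) -> Path:
    """Execute the pipeline and return the output directory.

    Idempotent for a fixed seed: rerunning produces identical tables and an
    identical summary JSON.
    """
    cfg = merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    state_path = outdir / "stage_state.json"
    state = json.loads(state_path.read_text()) if (resume and state_path.exists()) else {}

    _setup_log(outdir)
    log.info("pai1dms %s | seed=%s | config=%s", __version__, cfg["seed"],
             config_hash(cfg))
    seeds = _stage_seeds(cfg["seed"])

    runners = {"simulate": _stage_simulate, "count": _stage_count,
               "kinetics": _stage_kinetics, "score": _stage_score,
               "report": _stage_report}
    for stage in stages:
        h = config_hash({"cfg": cfg, "stage": stage})
        outputs = _stage_outputs(stage, outdir, cfg)
        inputs = _input_hashes(stage, outdir, cfg)
        entry = state.get(stage)
        if (resume and isinstance(entry, dict) and entry.get("hash") == h
                and entry.get("inputs") == inputs
                and all(p.exists() for p in outputs)):
            log.info("stage %s: up to date, skipped", stage)
            continue
        t0 = time.time()
        try:
            runners[stage](cfg, outdir, seeds[stage])
        except Exception as exc:
            (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        state[stage] = {"hash": h, "inputs": _input_hashes(stage, outdir, cfg)}
        state_path.write_text(json.dumps(state, indent=2, sort_keys=True))
        log.info("stage %s: done in %.1f s", stage, time.time() - t0)
    return outdir


def _stage_outputs(stage: str, outdir: Path, cfg: dict) -> list[Path]:
    out = {
        "simulate": ["reference.fasta", "amplicons.tsv", "truth.tsv",
                     "counts.tsv", "recovery.tsv"],
        "count": (["counts_from_reads.tsv", "counting_qc.json"]
                  if cfg["reads"]["emit"] else []),
        "kinetics": ["kinetics.tsv", "fit_diagnostics.json"],
        "score": ["scores.tsv"],
        "report": ["heatmap_scores.tsv", "heatmap_t_half.tsv", "summary.json"],
    }[stage]
    return [outdir / name for name in out]


def _stage_inputs(stage: str, outdir: Path, cfg: dict) -> list[Path]:
    inp = {
        "simulate": [],
        "count": (["reference.fasta", "amplicons.tsv"] if cfg["reads"]["emit"] else []),
        "kinetics": ["counts.tsv", "recovery.tsv"],
        "score": ["counts.tsv"],
        "report": ["kinetics.tsv", "scores.tsv", "truth.tsv"],
    }[stage]
    return [outdir / name for name in inp]


def _input_hashes(stage: str, outdir: Path, cfg: dict) -> dict:
    out = {}
    for path in _stage_inputs(stage, outdir, cfg):
        if path.exists():
            out[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        else:
            out[path.name] = None
    return out


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {stage: int(child.generate_state(1)[0] % (2 ** 31))
            for stage, child in zip(STAGES, children)}


def _setup_log(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler)
               and Path(getattr(h, "baseFilename", "")) == (outdir / "pipeline.log").resolve()
               for h in log.handlers):
        fh = logging.FileHandler(outdir / "pipeline.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)


def _build_reference(cfg) -> ReferenceProtein:
    rc = cfg["reference"]
    if rc.get("fasta"):
        return ReferenceProtein.from_fasta(rc["fasta"], offset=rc.get("offset", 1))
    return make_toy_reference(n_residues=rc["n_residues"], offset=rc["offset"],
                              seed=cfg["seed"])


def _build_panel(cfg, reference):
    pc = cfg["panel"]
    length = min(pc["length"], len(reference.cds))
    n = pc["n_amplicons"]
    return default_amplicon_panel(reference, n_amplicons=n, length=length)


def _stage_simulate(cfg, outdir: Path, seed: int) -> None:
    reference = _build_reference(cfg)
    panel = _build_panel(cfg, reference)
    emap = generate_effect_map(reference, EffectConfig(**cfg["effects"]),
                               seed=seed)
    lib_cfg = cfg["library"]
    clones = generate_clone_library(emap, n_clones=lib_cfg["n_clones"],
                                    mutation_mean=lib_cfg["mutation_mean"],
                                    abundance=lib_cfg["abundance"],
                                    seed=seed + 1)
    design = SelectionDesign(**{k: tuple(v) if k == "time_points_h" else v
                                for k, v in cfg["design"].items()})
    dataset = simulate_selection_timecourse(clones, design, seed=seed + 2,
                                            reference=reference, panel=panel,
                                            truth=emap)
    reference.to_fasta(outdir / "reference.fasta")
    write_amplicon_table(panel, outdir / "amplicons.tsv")
    emap.write_tsv(outdir / "truth.tsv")
    dataset.write_counts_tsv(outdir / "counts.tsv")
    dataset.write_recovery_tsv(outdir / "recovery.tsv")
    if cfg["reads"]["emit"]:
        fastq_dir = outdir / "fastq"
        paths = emit_reads(dataset, reference, panel,
                           error_rate=cfg["reads"]["error_rate"],
                           seed=seed + 3, outdir=fastq_dir)
        manifest = pd.DataFrame(
            [{"file": p.name} for p in paths])
        manifest.to_csv(outdir / "fastq_manifest.tsv", sep="\t", index=False)


def _stage_count(cfg, outdir: Path, seed: int) -> None:
    if not cfg["reads"]["emit"]:
        log.info("stage count: no reads emitted; simulator counts are used directly")
        return
    reference = ReferenceProtein.from_fasta(outdir / "reference.fasta",
                                            offset=cfg["reference"]["offset"])
    panel = read_amplicon_table(outdir / "amplicons.tsv")
    fastqs = sorted((outdir / "fastq").glob("*.fastq*"))
    dataset, qc = tally(fastqs, panel, reference,
                        max_mismatch_codons=cfg["reads"]["max_mismatch_codons"])
    collapsed = collapse_amplicons(dataset.counts)
    collapsed.to_csv(outdir / "counts_from_reads.tsv", sep="\t", index=False)
    write_qc_report(qc, outdir / "counting_qc.json")


def _load_dataset(cfg, outdir: Path) -> CountDataset:
    counts_path = outdir / "counts.tsv"
    if cfg["reads"]["emit"] and (outdir / "counts_from_reads.tsv").exists():
        counts_path = outdir / "counts_from_reads.tsv"
    return CountDataset.from_tsv(counts_path, outdir / "recovery.tsv")


def _stage_kinetics(cfg, outdir: Path, seed: int) -> None:
    dataset = _load_dataset(cfg, outdir)
    kc = cfg["kinetics"]
    est = MassivelyParallelKinetics(min_count=kc["min_count"],
                                    wt_reference_t_half=kc["wt_reference_t_half"])
    est.fit(dataset)
    est.results_.to_csv(outdir / "kinetics.tsv", sep="\t", index=False)
    lf = est.library_fit_
    diagnostics = {
        "library_fit": {"k": lf.k, "c": lf.c, "t_half": lf.t_half,
                        "rss": lf.rss, "converged": lf.converged},
        "n_records": len(est.records_),
        "n_ND": int((est.results_["flag"] == "ND").sum()),
        "nd_reasons": est.results_.loc[est.results_["flag"] == "ND", "reason"]
                      .value_counts().to_dict(),
    }
    (outdir / "fit_diagnostics.json").write_text(
        json.dumps(diagnostics, indent=2, sort_keys=True))


def _stage_score(cfg, outdir: Path, seed: int) -> None:
    dataset = _load_dataset(cfg, outdir)
    sc = cfg["scoring"]
    nonfunctional = detect_nonfunctional(dataset)
    scorer = StabilityScorer(t_select=sc["t_select"],
                             pseudocount=sc["pseudocount"], alpha=sc["alpha"],
                             min_base_mean=sc["min_base_mean"])
    scorer.fit(dataset, nonfunctional=nonfunctional)
    scorer.results_.to_csv(outdir / "scores.tsv", sep="\t", index=False)


def _stage_report(cfg, outdir: Path, seed: int) -> None:
    kinetics = pd.read_csv(outdir / "kinetics.tsv", sep="\t")
    scores = pd.read_csv(outdir / "scores.tsv", sep="\t")
    heatmap_to_tsv(build_heatmap(scores, value="score"),
                   outdir / "heatmap_scores.tsv")
    heatmap_to_tsv(build_heatmap(kinetics, value="t_half"),
                   outdir / "heatmap_t_half.tsv")

    summary = {
        "version": __version__,
        "seed": cfg["seed"],
        "config_hash": config_hash(merge_config(cfg)),
        "kinetics": summarize(kinetics),
        "scores": {
            "n_scored": int((scores["mut_aa"] != scores["wt_aa"]).sum()),
            "n_increased": int((scores["class"] == "increased").sum()),
            "n_decreased_or_equal": int((scores["class"] == "decreased_or_equal").sum()),
            "n_nonfunctional_at_0h": int((scores["class"] == "nonfunctional_at_0h").sum()),
        },
    }
    truth_path = outdir / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        truth["variant"] = truth["wt_aa"] + truth["position"].astype(str) + truth["mut_aa"]
        truth = truth[truth["functional"]].rename(columns={"t_half_hours": "t_half"})
        try:
            cmp_res = compare_half_lives(kinetics, truth[["variant", "t_half"]])
            summary["truth_comparison"] = {
                "slope": cmp_res.slope, "intercept": cmp_res.intercept,
                "pearson_r": cmp_res.pearson_r, "n": cmp_res.n,
            }
        except ValueError:
            summary["truth_comparison"] = None
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True))


SUMMARY_REQUIRED_KEYS = {"version", "seed", "config_hash", "kinetics", "scores"}


def validate_summary(summary: dict) -> None:
    """Schema check for the pipeline summary JSON."""
    missing = SUMMARY_REQUIRED_KEYS - set(summary)
    if missing:
        raise ValueError(f"summary missing keys {sorted(missing)}")
    for key in ("mean_t_half", "median_t_half", "n", "n_ND"):
        if key not in summary["kinetics"]:
            raise ValueError(f"summary.kinetics missing {key!r}")
    for key in ("n_scored", "n_increased", "n_decreased_or_equal"):
        if key not in summary["scores"]:
            raise ValueError(f"summary.scores missing {key!r}")
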