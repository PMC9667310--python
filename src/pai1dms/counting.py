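"""Codon-level variant calling and per-sample count tallies from amplicon reads.

Reads are compared gaplessly to the reference over the full codons of their
amplicon window.  Nonsynonymous codon differences become variant calls;
synonymous differences support WT at their position.  Reads with more changed
codons than a configurable guard are rejected as likely artifacts.
"""

from __future__ import annotations

import gzip
import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .reference import AmpliconDef, ReferenceProtein
from .reads import parse_read_name
from .selection import COUNT_COLUMNS, CountDataset


@dataclass(frozen=True)
class VariantCall:
    position: int          # 1-based residue number
    wt_aa: str
    mut_aa: str
    codon_change: tuple[str, str]
    amplicon: str

    def __post_init__(self) -> None:
        if self.mut_aa == self.wt_aa:
            raise ValueError("a variant call must change the amino acid")


@dataclass
class ReadCall:
    """Outcome of calling one read: either variant/synonymous calls, or a
    rejection with a reason."""

    status: str                      # "ok" or "rejected"
    reason: str = ""
    calls: list[VariantCall] = field(default_factory=list)
    synonymous: list[int] = field(default_factory=list)   # positions
    wt_positions: list[int] = field(default_factory=list)
    n_mismatch_codons: int = 0


def call_read(read: str, amplicon: AmpliconDef, reference: ReferenceProtein,
              max_mismatch_codons: int = 6) -> ReadCall:
    """Call codon changes in a gapless amplicon read.

    Partial codons at the window edges are ignored.  A read is rejected when
    its length differs from the amplicon's, or when more than
    ``max_mismatch_codons`` full codons differ from the reference.
    """
    read = read.upper()
    if len(read) != amplicon.length:
        return ReadCall(status="rejected", reason="length_mismatch")

    calls: list[VariantCall] = []
    synonymous: list[int] = []
    wt_positions: list[int] = []
    n_mismatch = 0
    for ci in amplicon.codon_indices():
        ref_codon = reference.cds[3 * ci: 3 * ci + 3]
        read_codon = read[3 * ci - amplicon.start: 3 * ci + 3 - amplicon.start]
        position = ci + reference.offset
        if read_codon == ref_codon:
            wt_positions.append(position)
            continue
        n_mismatch += 1
        wt_aa = reference.aa_seq[ci]
        mut_aa = str(Seq(read_codon).translate())
        if mut_aa == wt_aa:
            synonymous.append(position)
            wt_positions.append(position)
        else:
            calls.append(VariantCall(position=position, wt_aa=wt_aa,
                                     mut_aa=mut_aa,
                                     codon_change=(ref_codon, read_codon),
                                     amplicon=amplicon.name))
    if n_mismatch > max_mismatch_codons:
        return ReadCall(status="rejected", reason="too_many_mismatches",
                        n_mismatch_codons=n_mismatch)
    return ReadCall(status="ok", calls=calls, synonymous=synonymous,
                    wt_positions=wt_positions, n_mismatch_codons=n_mismatch)


def tally(fastq_paths, panel: list[AmpliconDef], reference: ReferenceProtein,
          manifest: pd.DataFrame | None = None,
          max_mismatch_codons: int = 6,
          wt_mode: str = "positional") -> tuple[CountDataset, dict]:
    """Count substitutions and WT-at-position support across FASTQ samples.

    Sample metadata (amplicon, time, replicate, arm) is parsed from read
    names, or taken from a ``manifest`` DataFrame with columns
    ``file, time_h, replicate, arm`` (amplicon still read-name- or
    length-derived).  Returns a :class:`CountDataset` whose tidy table keeps
    per-amplicon tallies, plus a QC dict with totals and rejection reasons.

    ``wt_mode="positional"`` (default) lets a read support WT at every
    position where its codon is synonymous with the reference, regardless of
    other positions in the window; ``"strict"`` requires the whole window to
    be variant-free.
    """
    if wt_mode not in ("positional", "strict"):
        raise ValueError(f"unknown wt_mode {wt_mode!r}")
    amp_by_name = {a.name: a for a in panel}
    manifest_by_file = None
    if manifest is not None:
        manifest_by_file = {str(r.file): (float(r.time_h), int(r.replicate), str(r.arm))
                            for r in manifest.itertuples()}

    sub_counts: dict = defaultdict(int)   # (sample, amp, pos, mut) -> n
    wt_counts: dict = defaultdict(int)    # (sample, amp, pos) -> n
    qc = {"samples": {}, "rejections": Counter(), "unknown_amplicon": 0}

    for path in fastq_paths:
        path = Path(path)
        file_sample = manifest_by_file.get(path.name) if manifest_by_file else None
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                try:
                    meta = parse_read_name(header[1:].strip())
                except (ValueError, KeyError):
                    if file_sample is None:
                        raise ValueError(
                            f"cannot parse sample metadata from read "
                            f"{header.strip()!r} in {path.name} and no manifest entry")
                    # amplicon may still be recoverable from the name prefix
                    meta = {"amplicon": header[1:].strip().split("|")[0]}
                if file_sample is not None:
                    sample = file_sample
                else:
                    sample = (meta["time_h"], meta["replicate"], meta["arm"])
                amp = amp_by_name.get(meta.get("amplicon"))
                if amp is None:
                    amp = _amplicon_by_length(len(seq), panel)
                if amp is None:
                    qc["unknown_amplicon"] += 1
                    continue
                key = sample
                tot = qc["samples"].setdefault(key, Counter())
                tot["reads"] += 1
                rc = call_read(seq, amp, reference, max_mismatch_codons)
                if rc.status == "rejected":
                    tot["rejected"] += 1
                    qc["rejections"][rc.reason] += 1
                    continue
                if wt_mode == "strict" and rc.calls:
                    covered_wt = []
                else:
                    covered_wt = rc.wt_positions
                for call in rc.calls:
                    sub_counts[(key, amp.name, call.position, call.mut_aa)] += 1
                for pos in covered_wt:
                    wt_counts[(key, amp.name, pos)] += 1

    rows = []
    for (sample, amp, pos, mut), n in sub_counts.items():
        t, rep, arm = sample
        wt = reference.wt_aa(pos)
        rows.append((f"{wt}{pos}{mut}", pos, wt, mut, amp, t, rep, arm, n))
    for (sample, amp, pos), n in wt_counts.items():
        t, rep, arm = sample
        wt = reference.wt_aa(pos)
        rows.append((f"{wt}{pos}{wt}", pos, wt, wt, amp, t, rep, arm, n))
    counts = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    if counts.empty:
        warnings.warn("no reads tallied: the count dataset is empty")
    counts = counts.sort_values(["time_h", "replicate", "arm", "amplicon",
                                 "position", "mut_aa"],
                                kind="stable").reset_index(drop=True)
    qc_out = {
        "samples": {"|".join(map(str, k)): dict(v) for k, v in qc["samples"].items()},
        "rejections": dict(qc["rejections"]),
        "unknown_amplicon": qc["unknown_amplicon"],
    }
    dataset = CountDataset(counts=counts,
                           library_recovery=pd.DataFrame(
                               columns=["time_h", "replicate", "recovery"]),
                           reference=reference, panel=panel)
    return dataset, qc_out


def _amplicon_by_length(length: int, panel: list[AmpliconDef]):
    matches = [a for a in panel if a.length == length]
    return matches[0] if len(matches) == 1 else None


def collapse_amplicons(counts: pd.DataFrame) -> pd.DataFrame:
    """Keep, per position, only the covering amplicon with the highest mean
    depth (ties broken by amplicon name).  Input and output share the tidy
    count schema."""
    depth = counts.groupby("amplicon")["count"].mean()
    best = (counts.groupby(["position", "amplicon"]).size().reset_index()
            [["position", "amplicon"]])
    best["depth"] = best["amplicon"].map(depth)
    best = (best.sort_values(["position", "depth", "amplicon"],
                             ascending=[True, False, True])
            .drop_duplicates("position"))
    chosen = dict(zip(best["position"], best["amplicon"]))
    keep = counts["amplicon"] == counts["position"].map(chosen)
    return counts[keep].reset_index(drop=True)


def write_qc_report(qc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
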