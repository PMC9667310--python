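"""FASTQ emission for simulated selection samples.

Each sampled phage genome is sequenced once per amplicon: a read is the
amplicon-length substring of the clone's mutated CDS, with uniform
substitution sequencing errors added at a configurable rate.  Read names
encode the sample metadata (amplicon, time, replicate, arm) so the counter
needs no separate manifest for simulated data.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

from .reference import AmpliconDef, ReferenceProtein
from .selection import CountDataset

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def read_name(amplicon: str, time_h: float, replicate: int, arm: str,
              serial: int) -> str:
    return f"{amplicon}|t={time_h:g}|rep={replicate}|arm={arm}|{serial}"


def parse_read_name(name: str) -> dict:
    amp, t, rep, arm, serial = name.split("|")
    return {"amplicon": amp, "time_h": float(t.removeprefix("t=")),
            "replicate": int(rep.removeprefix("rep=")),
            "arm": arm.removeprefix("arm="), "serial": int(serial)}


def mutated_cds(clone, reference: ReferenceProtein) -> str:
    """The clone's CDS with each substitution applied as the minimal-Hamming
    codon change."""
    cds = bytearray(reference.cds, "ascii")
    for pos, mut_aa in clone.substitutions:
        i = 3 * (pos - reference.offset)
        cds[i:i + 3] = reference.mutate_codon(pos, mut_aa).encode()
    return cds.decode()


def emit_reads(dataset: CountDataset, reference: ReferenceProtein,
               amplicons: list[AmpliconDef], error_rate: float = 0.0,
               seed: int = 0, outdir: str | Path = ".",
               phred: int = 30, gzipped: bool = False) -> list[Path]:
    """Write one FASTQ per (time point, replicate, arm).

    Deterministic for a fixed seed.  Returns the paths written.
    """
    if not 0 <= error_rate < 0.1:
        raise ValueError("error_rate must lie in [0, 0.1)")
    if dataset.clones is None or not dataset.clone_counts:
        raise ValueError("dataset carries no per-clone sample draws; "
                         "emit_reads needs a simulator-produced dataset")
    for amp in amplicons:
        if amp.end > len(reference.cds):
            raise ValueError(f"amplicon {amp.name} outside CDS bounds")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    qual = chr(33 + phred)
    cds_cache = [mutated_cds(cl, reference) for cl in dataset.clones]

    paths = []
    for (t, rep, arm), counts in sorted(dataset.clone_counts.items()):
        suffix = ".fastq.gz" if gzipped else ".fastq"
        path = outdir / f"{arm}_t{t:g}_rep{rep}{suffix}"
        opener = gzip.open if gzipped else open
        serial = 0
        with opener(path, "wt") as fh:
            for amp in amplicons:
                qline = qual * amp.length
                for ci in np.nonzero(counts)[0]:
                    window = cds_cache[ci][amp.start:amp.end]
                    for _ in range(int(counts[ci])):
                        seq = _with_errors(window, error_rate, rng)
                        fh.write(f"@{read_name(amp.name, t, rep, arm, serial)}\n"
                                 f"{seq}\n+\n{qline}\n")
                        serial += 1
        paths.append(path)
    return paths


def _with_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    sites = rng.choice(len(seq), size=n_err, replace=False)
    for i in sites:
        alts = _BASES[_BASES != arr[i]]
        arr[i] = alts[rng.integers(3)]
    return arr.tobytes().decode()
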