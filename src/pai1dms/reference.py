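"""Reference coding sequence and amplicon panel definitions.

The selection screen sequences a phage-displayed serpin fusion as a set of
overlapping short amplicons tiled across the coding sequence.  This module
holds the reference protein (CDS + translation, with residue numbering that
may start above 1, matching serpin mature-protein conventions) and the
BED-like amplicon definitions used by both the read simulator and the
codon-level variant caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio import SeqIO

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: sense codons of the standard table, sorted for deterministic tie-breaks
_SENSE_CODONS = sorted(standard_dna_table.forward_table)


@dataclass(frozen=True)
class ReferenceProtein:
    """A reference coding sequence with 1-based residue numbering.

    Parameters
    ----------
    name : str
        Identifier used in output tables.
    cds : str
        DNA coding sequence; length must be a multiple of 3 and contain no
        stop codons (the region modelled is internal to a fusion protein).
    offset : int
        Residue number of the first codon (e.g. 1, or higher when the
        reference covers an internal fragment of the mature protein).
    """

    name: str
    cds: str
    offset: int = 1

    def __post_init__(self) -> None:
        cds = self.cds.upper()
        object.__setattr__(self, "cds", cds)
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
        if len(cds) < 30:
            raise ValueError("reference must encode at least 10 residues")
        if not set(cds) <= set("ACGT"):
            raise ValueError("CDS contains non-ACGT characters")
        aa = str(Seq(cds).translate())
        if "*" in aa:
            raise ValueError("CDS contains an internal stop codon")

    @property
    def aa_seq(self) -> str:
        return str(Seq(self.cds).translate())

    @property
    def n_residues(self) -> int:
        return len(self.cds) // 3

    @property
    def positions(self) -> range:
        """Residue numbers covered by the reference."""
        return range(self.offset, self.offset + self.n_residues)

    def codon(self, position: int) -> str:
        """Reference codon at a 1-based residue ``position``."""
        i = self._codon_index(position)
        return self.cds[3 * i : 3 * i + 3]

    def wt_aa(self, position: int) -> str:
        return self.aa_seq[self._codon_index(position)]

    def _codon_index(self, position: int) -> int:
        i = position - self.offset
        if not 0 <= i < self.n_residues:
            raise ValueError(f"residue {position} outside reference range "
                             f"[{self.offset}, {self.offset + self.n_residues - 1}]")
        return i

    def mutate_codon(self, position: int, mut_aa: str) -> str:
        """A codon encoding ``mut_aa`` at minimal Hamming distance from the
        reference codon (alphabetical tie-break, so the choice is
        deterministic)."""
        ref = self.codon(position)
        best = None
        best_d = 4
        for codon in _SENSE_CODONS:
            if standard_dna_table.forward_table[codon] != mut_aa:
                continue
            d = sum(a != b for a, b in zip(codon, ref))
            if d < best_d:
                best, best_d = codon, d
        if best is None:
            raise ValueError(f"no codon encodes {mut_aa!r}")
        return best

    @classmethod
    def from_fasta(cls, path, offset: int = 1) -> "ReferenceProtein":
        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(name=record.id, cds=str(record.seq), offset=offset)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.cds), 60):
                fh.write(self.cds[i : i + 60] + "\n")


@dataclass(frozen=True)
class AmpliconDef:
    """One sequencing amplicon, 0-based half-open on the CDS.

    ``frame_offset`` is the number of bases to skip from ``start`` to reach
    the first complete codon; it is derived from ``start`` and checked if
    supplied explicitly.
    """

    name: str
    start: int
    end: int
    frame_offset: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad amplicon interval [{self.start}, {self.end})")
        derived = (-self.start) % 3
        if self.frame_offset == -1:
            object.__setattr__(self, "frame_offset", derived)
        elif self.frame_offset != derived:
            raise ValueError(
                f"frame_offset {self.frame_offset} inconsistent with start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def codon_indices(self) -> range:
        """0-based indices of codons fully contained in the window."""
        first = (self.start + 2) // 3
        last = self.end // 3  # exclusive
        return range(first, last)

    def residues(self, reference: ReferenceProtein) -> range:
        idx = self.codon_indices()
        return range(idx.start + reference.offset, idx.stop + reference.offset)


def default_amplicon_panel(reference: ReferenceProtein,
                           n_amplicons: int = 12,
                           length: int = 150) -> list[AmpliconDef]:
    """Evenly spaced overlapping amplicons tiling the CDS.

    With the full-length reference the defaults reproduce the 12-amplicon,
    150 bp sequencing panel; shorter toy references may use fewer or shorter
    amplicons as long as every codon is covered by at least one window.
    """
    n_bases = len(reference.cds)
    if length > n_bases:
        raise ValueError(f"amplicon length {length} exceeds CDS length {n_bases}")
    max_start = n_bases - length
    if n_amplicons == 1:
        starts = [0]
    else:
        starts = [round(i * max_start / (n_amplicons - 1)) for i in range(n_amplicons)]
    panel = [AmpliconDef(name=f"amp{i + 1:02d}", start=s, end=s + length)
             for i, s in enumerate(starts)]
    _check_panel_covers(panel, reference)
    return panel


def _check_panel_covers(panel: Sequence[AmpliconDef], reference: ReferenceProtein) -> None:
    covered: set[int] = set()
    for amp in panel:
        if amp.end > len(reference.cds):
            raise ValueError(f"amplicon {amp.name} extends past the CDS end")
        covered.update(amp.residues(reference))
    missing = set(reference.positions) - covered
    if missing:
        raise ValueError(f"panel leaves {len(missing)} residues uncovered "
                         f"(e.g. {sorted(missing)[:3]})")


def covering_amplicon(position: int, panel: Sequence[AmpliconDef],
                      reference: ReferenceProtein,
                      depths: dict[str, float] | None = None) -> AmpliconDef:
    """The amplicon used for counts at ``position``.

    Overlap regions are assigned to the covering amplicon with the highest
    mean depth when per-amplicon depths are known; otherwise (and on ties)
    the earliest-starting amplicon wins, deterministically.
    """
    candidates = [a for a in panel if position in a.residues(reference)]
    if not candidates:
        raise ValueError(f"no amplicon covers residue {position}")
    if depths:
        candidates.sort(key=lambda a: (-depths.get(a.name, 0.0), a.start, a.name))
    else:
        candidates.sort(key=lambda a: (a.start, a.name))
    return candidates[0]


def make_toy_reference(n_residues: int = 60, offset: int = 1,
                       seed: int = 0, name: str = "toyPAI1") -> ReferenceProtein:
    """A random stop-free CDS for tests and demos.

    The sequence is deterministic for a given seed; residue numbering starts
    at ``offset`` so fixtures can place landmarks (an Ile at residue 91, say)
    without simulating a full-length protein.
    """
    rng = np.random.default_rng(seed)
    codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_residues)]
    return ReferenceProtein(name=name, cds="".join(codons), offset=offset)


def write_amplicon_table(panel: Iterable[AmpliconDef], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\tframe_offset\n")
        for amp in panel:
            fh.write(f"{amp.name}\t{amp.start}\t{amp.end}\t{amp.frame_offset}\n")


def read_amplicon_table(path) -> list[AmpliconDef]:
    panel = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            name, start, end, frame = line.rstrip("\n").split("\t")
            panel.append(AmpliconDef(name=name, start=int(start), end=int(end),
                                     frame_offset=int(frame)))
    return panel
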