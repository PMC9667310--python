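import random

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from pai1dms import (SelectionDesign, call_read, collapse_amplicons, emit_reads,
                     simulate_selection_timecourse, tally)
from pai1dms.library import LN2, Clone
from pai1dms.reference import AmpliconDef, ReferenceProtein


def grouped(counts: pd.DataFrame) -> pd.Series:
    return counts.groupby(["position", "mut_aa", "time_h", "replicate",
                           "arm"])["count"].sum()


@pytest.fixture(scope="module")
def emit_dataset(toy_library, toy_ref, toy_panel, toy_effects):
    design = SelectionDesign(time_points_h=(0.0, 2.0, 8.0, 24.0), replicates=1,
                             depth_per_sample=400)
    return simulate_selection_timecourse(toy_library, design, seed=104,
                                         reference=toy_ref, panel=toy_panel,
                                         truth=toy_effects)


@pytest.fixture(scope="module")
def emitted(tmp_path_factory, emit_dataset, toy_ref, toy_panel):
    outdir = tmp_path_factory.mktemp("fastq")
    paths = emit_reads(emit_dataset, toy_ref, toy_panel, error_rate=0.0,
                       seed=11, outdir=outdir)
    return paths


def test_round_trip_identity_error_free(emitted, emit_dataset, toy_ref, toy_panel):
    """Counting error-free simulator reads reproduces the emitted counts."""
    ds, qc = tally(emitted, toy_panel, toy_ref, max_mismatch_codons=30)
    tal = grouped(collapse_amplicons(ds.counts))
    sim = grouped(emit_dataset.counts)
    merged = pd.concat([sim.rename("sim"), tal.rename("tal")], axis=1).fillna(0)
    assert (merged.sim == merged.tal).all()
    assert qc["rejections"] == {}


def test_reads_have_amplicon_length(emitted, toy_panel):
    with open(emitted[0]) as fh:
        name = fh.readline()
        seq = fh.readline().strip()
    amp = next(a for a in toy_panel if a.name in name)
    assert len(seq) == amp.length


def test_identical_read_supports_wt_everywhere(toy_ref, toy_panel):
    amp = toy_panel[0]
    rc = call_read(toy_ref.cds[amp.start:amp.end], amp, toy_ref)
    assert rc.status == "ok"
    assert rc.calls == []
    assert list(rc.wt_positions) == list(amp.residues(toy_ref))


def test_single_codon_change_called_ile91phe():
    # toy reference carrying Ile91 (ATC); an ATC->TTC read calls I91F
    cds = "ATG" + "GCT" * 10 + "ATC" + "GCT" * 9
    ref = ReferenceProtein(name="ile91", cds=cds, offset=80)
    amp = AmpliconDef(name="a1", start=0, end=len(cds))
    assert ref.wt_aa(91) == "I" and ref.codon(91) == "ATC"
    read = cds[:33] + "TTC" + cds[36:]
    rc = call_read(read, amp, ref)
    assert rc.status == "ok"
    (call,) = rc.calls
    assert (call.position, call.wt_aa, call.mut_aa) == (91, "I", "F")
    assert call.codon_change == ("ATC", "TTC")
    assert 91 not in rc.wt_positions


def test_synonymous_change_supports_wt():
    cds = "ATG" + "GCT" * 10 + "ATC" + "GCT" * 9
    ref = ReferenceProtein(name="ile91", cds=cds, offset=80)
    amp = AmpliconDef(name="a1", start=0, end=len(cds))
    read = cds[:33] + "ATT" + cds[36:]          # Ile -> Ile
    rc = call_read(read, amp, ref)
    assert rc.calls == [] and 91 in rc.synonymous and 91 in rc.wt_positions


def test_mismatch_guard_rejects_artifact_reads(toy_ref, toy_panel):
    amp = toy_panel[0]
    window = toy_ref.cds[amp.start:amp.end]
    mutated = bytearray(window, "ascii")
    changed = 0
    for ci in list(amp.codon_indices()):
        ref_codon = toy_ref.cds[3 * ci:3 * ci + 3]
        alt = toy_ref.mutate_codon(ci + toy_ref.offset,
                                   "W" if toy_ref.aa_seq[ci] != "W" else "R")
        mutated[3 * ci - amp.start:3 * ci + 3 - amp.start] = alt.encode()
        changed += 1
        if changed == 7:
            break
    read = mutated.decode()
    assert call_read(read, amp, toy_ref, max_mismatch_codons=6).status == "rejected"
    assert call_read(read, amp, toy_ref, max_mismatch_codons=7).status == "ok"


def test_length_mismatch_rejected_and_tallied(toy_ref, toy_panel):
    rc = call_read("ACGT", toy_panel[0], toy_ref)
    assert rc.status == "rejected" and rc.reason == "length_mismatch"


def test_position_partition_invariant(emitted, emit_dataset, toy_ref, toy_panel):
    """Substitution + WT-at-position counts partition the reads covering a
    position (no rejections at error rate 0)."""
    ds, _qc = tally(emitted, toy_panel, toy_ref, max_mismatch_codons=30)
    depth = emit_dataset.design.depth_per_sample
    c = ds.counts
    one_sample = c[(c.time_h == 0.0) & (c.replicate == 1) & (c.arm == "selected")]
    for amp in toy_panel:
        amp_rows = one_sample[one_sample.amplicon == amp.name]
        for pos in amp.residues(toy_ref):
            total = amp_rows.loc[amp_rows.position == pos, "count"].sum()
            assert total == depth


def test_tally_order_independent(tmp_path, emitted, toy_ref, toy_panel):
    src = emitted[0]
    records = open(src).read().strip().split("\n")
    records = [records[i:i + 4] for i in range(0, len(records), 4)]
    rng = random.Random(5)
    rng.shuffle(records)
    shuffled = tmp_path / "shuffled.fastq"
    shuffled.write_text("\n".join("\n".join(r) for r in records) + "\n")
    a, _ = tally([src], toy_panel, toy_ref, max_mismatch_codons=30)
    b, _ = tally([shuffled], toy_panel, toy_ref, max_mismatch_codons=30)
    pd.testing.assert_series_equal(grouped(a.counts), grouped(b.counts))


def test_empty_fastq_warns_and_returns_empty(tmp_path, toy_ref, toy_panel):
    empty = tmp_path / "empty.fastq"
    empty.write_text("")
    with pytest.warns(UserWarning, match="no reads"):
        ds, _ = tally([empty], toy_panel, toy_ref)
    assert ds.counts.empty


def test_unparseable_read_name_without_manifest_errors(tmp_path, toy_ref, toy_panel):
    bad = tmp_path / "bad.fastq"
    amp = toy_panel[0]
    bad.write_text(f"@not_a_sample_name\n{toy_ref.cds[amp.start:amp.end]}\n+\n"
                   + "I" * amp.length + "\n")
    with pytest.raises(ValueError, match="manifest"):
        tally([bad], toy_panel, toy_ref)


def test_manifest_supplies_sample_metadata(tmp_path, toy_ref, toy_panel):
    amp = toy_panel[0]
    path = tmp_path / "sampleX.fastq"
    path.write_text(f"@{amp.name}|anything\n{toy_ref.cds[amp.start:amp.end]}\n+\n"
                    + "I" * amp.length + "\n")
    manifest = pd.DataFrame([{"file": "sampleX.fastq", "time_h": 4.0,
                              "replicate": 2, "arm": "selected"}])
    ds, _ = tally([path], toy_panel, toy_ref, manifest=manifest)
    row = ds.counts.iloc[0]
    assert (row.time_h, row.replicate, row.arm) == (4.0, 2, "selected")


def test_sequencing_error_rate_expectation(tmp_path, toy_ref):
    """Mean erroneous bases per read matches the binomial expectation."""
    clone = Clone(substitutions=(), abundance=1.0, k_eff=LN2 / 2.1)
    design = SelectionDesign(time_points_h=(0.0, 1.0, 2.0, 4.0), replicates=1,
                             depth_per_sample=10_000, include_input_sample=False)
    ds = simulate_selection_timecourse([clone], design, seed=1, reference=toy_ref)
    amp = AmpliconDef(name="a1", start=0, end=90)
    error_rate = 2e-3
    paths = emit_reads(ds, toy_ref, [amp], error_rate=error_rate, seed=2,
                       outdir=tmp_path)
    n_err = n_reads = 0
    window = toy_ref.cds[amp.start:amp.end]
    for path in paths:
        with open(path) as fh:
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    seq = line.strip()
                    n_err += sum(a != b for a, b in zip(seq, window))
                    n_reads += 1
    expected = amp.length * error_rate
    assert n_reads == 40_000
    assert n_err / n_reads == pytest.approx(expected, rel=0.05)


def test_mistallies_match_per_read_oracle(tmp_path, toy_ref, toy_panel):
    """With sequencing errors, the tally equals an independent per-read
    recount, and spurious calls stay within 3 sigma of binomial expectation."""
    clone = Clone(substitutions=(), abundance=1.0, k_eff=LN2 / 2.1)
    design = SelectionDesign(time_points_h=(0.0, 1.0, 2.0, 4.0), replicates=1,
                             depth_per_sample=1_500, include_input_sample=False)
    ds = simulate_selection_timecourse([clone], design, seed=3, reference=toy_ref)
    error_rate = 1e-3
    paths = emit_reads(ds, toy_ref, toy_panel, error_rate=error_rate, seed=4,
                       outdir=tmp_path)
    tallied, _ = tally(paths, toy_panel, toy_ref, max_mismatch_codons=30)
    mis = tallied.counts
    n_spurious = int(mis.loc[mis.mut_aa != mis.wt_aa, "count"].sum())

    # independent per-read oracle: raw string comparison + Biopython translate
    oracle = 0
    n_reads = 0
    for path in paths:
        lines = open(path).read().strip().split("\n")
        for i in range(0, len(lines), 4):
            amp = next(a for a in toy_panel if a.name == lines[i][1:].split("|")[0])
            seq = lines[i + 1]
            n_reads += 1
            for ci in amp.codon_indices():
                ref_codon = toy_ref.cds[3 * ci:3 * ci + 3]
                alt = seq[3 * ci - amp.start:3 * ci + 3 - amp.start]
                if alt != ref_codon and str(Seq(alt).translate()) != toy_ref.aa_seq[ci]:
                    oracle += 1
    assert n_spurious == oracle

    # binomial expectation: each base errs w.p. error_rate; ~ 0.73 of single-base
    # codon changes are nonsynonymous on average -- use a generous 3 sigma window
    # around the empirical mean instead of an analytic constant
    p_codon_hit = 1 - (1 - error_rate) ** 3
    n_codons = n_reads * len(list(toy_panel[0].codon_indices()))
    upper = n_codons * p_codon_hit
    sigma = np.sqrt(upper)
    assert n_spurious <= upper + 3 * sigma
    assert n_spurious >= 0.25 * upper - 3 * sigma


def test_strict_wt_mode_counts_fewer_wt_reads(emitted, toy_ref, toy_panel):
    pos_mode, _ = tally(emitted, toy_panel, toy_ref, max_mismatch_codons=30,
                        wt_mode="positional")
    strict, _ = tally(emitted, toy_panel, toy_ref, max_mismatch_codons=30,
                      wt_mode="strict")
    wt_pos = pos_mode.counts
    wt_pos = wt_pos.loc[wt_pos.mut_aa == wt_pos.wt_aa, "count"].sum()
    wt_strict = strict.counts
    wt_strict = wt_strict.loc[wt_strict.mut_aa == wt_strict.wt_aa, "count"].sum()
    assert wt_strict <= wt_pos
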