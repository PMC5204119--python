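"""Element extraction from transcript models and lineage classification."""

import itertools

import pytest

from lncestro import io as lio
from lncestro.config import DEFAULT_SPECIES, Species
from lncestro.conservation import (
    MafIndex,
    assess_conservation,
    classify_gene,
    classify_lineage,
    conservation_table,
    extract_elements,
    summarize_set,
)
from lncestro.errors import CoordinateError, EmptySummaryError
from lncestro.features import TranscriptModel, revcomp

HUMAN = "hg19sim"


def _genome_with(intron_seq: dict[tuple[int, int], str], length=400) -> dict[str, str]:
    seq = list("C" * length)  # C background: forms no consensus by itself
    for (s, e), text in intron_seq.items():
        seq[s:e] = list(text)
    return {"chr1": "".join(seq)}


def _model(exons, strand="+", support=2, gene="g1"):
    return TranscriptModel(gene, f"{gene}.1", "chr1", strand, tuple(exons), support)


def test_plus_strand_canonical_intron_yields_donor_and_acceptor():
    genome = _genome_with({(100, 102): "GT", (198, 200): "AG"})
    els = extract_elements([_model([(50, 100), (200, 260)])], genome)
    splice = {(e.kind, e.start, e.end) for e in els}
    assert ("splice_donor", 100, 102) in splice
    assert ("splice_acceptor", 198, 200) in splice


def test_minus_strand_intron_is_read_in_transcript_orientation():
    # forward strand shows CT..AC; the transcript-strand reading is GT..AG
    genome = _genome_with({(100, 102): "CT", (198, 200): "AC"})
    els = extract_elements([_model([(50, 100), (200, 260)], strand="-")], genome)
    kinds = {(e.kind, e.start, e.end) for e in els}
    assert ("splice_donor", 198, 200) in kinds
    assert ("splice_acceptor", 100, 102) in kinds


def test_noncanonical_donor_is_not_emitted():
    genome = _genome_with({(100, 102): "GC", (198, 200): "AG"})
    els = extract_elements([_model([(50, 100), (200, 260)])], genome)
    kinds = [e.kind for e in els]
    assert "splice_donor" not in kinds
    assert "splice_acceptor" in kinds


def test_singleton_isoforms_are_excluded():
    genome = _genome_with({(100, 102): "GT", (198, 200): "AG"})
    els = extract_elements([_model([(50, 100), (200, 260)], support=1)], genome)
    assert els == []


def test_shared_intron_across_isoforms_is_deduplicated():
    genome = _genome_with({(100, 102): "GT", (198, 200): "AG"})
    m1 = _model([(50, 100), (200, 260)])
    m2 = TranscriptModel("g1", "g1.2", "chr1", "+", ((40, 100), (200, 280)), 3)
    els = extract_elements([m1, m2], genome)
    assert len([e for e in els if e.kind == "splice_donor"]) == 1
    assert len([e for e in els if e.kind == "splice_acceptor"]) == 1


def test_three_prime_most_polya_signal_wins():
    # two hexamers in the window; the one closer to the 3' end is reported
    genome = _genome_with({(365, 371): "AATAAA", (380, 386): "ATTAAA"}, length=400)
    els = extract_elements([_model([(200, 400)])], genome)
    polya = [e for e in els if e.kind == "polya_signal"]
    assert len(polya) == 1
    assert (polya[0].start, polya[0].consensus) == (380, "ATTAAA")


def test_out_of_genome_model_raises():
    genome = {"chr1": "ACGT" * 10}
    with pytest.raises(CoordinateError):
        extract_elements([_model([(0, 30), (35, 120)])], genome)


# -- conservation states -----------------------------------------------------

def _donor_block(mouse_text=None, include_mouse=True, treeshrew_text=None,
                 include_treeshrew=True, chimp_text=None):
    """One MAF block over a donor at chr1:[100,102) with 2 bp context."""
    human = "AAGTCC"
    rows = [(f"{HUMAN}.chr1", 98, 6, "+", 1000, human)]
    rows.append((f"panTroSim.chr1", 10, 6, "+", 500, chimp_text or human))
    rows.append((f"rheMacSim.chr1", 10, 6, "+", 500, human))
    if include_treeshrew:
        rows.append((f"tupBelSim.chr1", 10, 6, "+", 500, treeshrew_text or human))
    if include_mouse:
        text = mouse_text or human
        size = 6 - text.count("-")
        rows.append((f"mm10sim.chr1", 10, size, "+", 500, text))
    return lio.maf_block(rows)


def _donor_element():
    from lncestro.conservation import StructureElement

    return StructureElement("splice_donor", "g1", "chr1", "+", 100, 102, "GT")


@pytest.mark.parametrize(
    "mouse_text,expected",
    [
        (None, "consensus_conserved"),
        ("AAG-CC", "unaligned"),
        ("AAGCCC", "diverged"),
    ],
)
def test_species_state_from_alignment_row(mouse_text, expected):
    maf = MafIndex([_donor_block(mouse_text=mouse_text)], ref=HUMAN)
    states = assess_conservation(_donor_element(), maf, DEFAULT_SPECIES)
    assert states["mm10sim"] == expected


def test_uncovered_element_is_unaligned_everywhere():
    maf = MafIndex([], ref=HUMAN)
    states = assess_conservation(_donor_element(), maf, DEFAULT_SPECIES)
    assert all(v == "unaligned" for v in states.values())


def test_absent_species_row_is_unaligned():
    maf = MafIndex([_donor_block(include_mouse=False)], ref=HUMAN)
    states = assess_conservation(_donor_element(), maf, DEFAULT_SPECIES)
    assert states["mm10sim"] == "unaligned"


# -- lineage classes ---------------------------------------------------------

def _states(**overrides):
    base = {
        "panTroSim": "consensus_conserved",
        "rheMacSim": "consensus_conserved",
        "tupBelSim": "diverged",
        "mm10sim": "diverged",
        "canFamSim": "unaligned",
    }
    base.update(overrides)
    return base


def test_primate_only_conservation_is_primate_specific():
    assert classify_lineage(_states(), DEFAULT_SPECIES) == "primate_specific"


def test_treeshrew_exception_class():
    states = _states(tupBelSim="consensus_conserved")
    assert classify_lineage(states, DEFAULT_SPECIES) == "primate_plus_treeshrew"


def test_any_deeper_mammal_conservation_wins():
    states = _states(mm10sim="consensus_conserved")
    assert classify_lineage(states, DEFAULT_SPECIES) == "conserved_beyond_primates"


def test_fully_unaligned_element_is_uninformative():
    states = {k: "unaligned" for k in _states()}
    assert classify_lineage(states, DEFAULT_SPECIES) == "uninformative"


def test_strict_mode_requires_all_primates():
    states = _states(rheMacSim="diverged")
    assert classify_lineage(states, DEFAULT_SPECIES) == "primate_specific"
    assert (
        classify_lineage(states, DEFAULT_SPECIES, strict_all_primates=True)
        == "uninformative"
    )


def test_degrading_nonprimate_rows_never_moves_away_from_primate_specific():
    rank = {
        "conserved_beyond_primates": 0,
        "primate_plus_treeshrew": 1,
        "primate_specific": 2,
    }
    options = ["consensus_conserved", "diverged", "unaligned"]
    nonprimates = ["tupBelSim", "mm10sim", "canFamSim"]
    for combo in itertools.product(options, repeat=3):
        states = _states(**dict(zip(nonprimates, combo)))
        before = classify_lineage(states, DEFAULT_SPECIES)
        for sp in nonprimates:
            if states[sp] != "consensus_conserved":
                continue
            degraded = dict(states)
            degraded[sp] = "unaligned"
            after = classify_lineage(degraded, DEFAULT_SPECIES)
            assert rank[after] >= rank[before]


# -- gene roll-up and set summary -------------------------------------------

def test_gene_rollup_classes():
    all_ps = classify_gene(["primate_specific"] * 3)
    assert all_ps["completely_primate_specific"] and all_ps["has_primate_specific"]
    partial = classify_gene(
        ["primate_specific", "conserved_beyond_primates", "conserved_beyond_primates"]
    )
    assert partial["has_primate_specific"] and not partial["completely_primate_specific"]
    empty = classify_gene([])
    assert empty["unevaluable"]


def test_summary_counts_planted_fractions():
    import pandas as pd

    rows = []
    for i in range(40):
        rows.append(
            {
                "gene_id": f"g{i}",
                "kind": "polya_signal",
                "lineage_class": "primate_specific" if i < 10 else "conserved_beyond_primates",
            }
        )
    summary = summarize_set(pd.DataFrame(rows))
    assert summary["polyadenylated_subset_n"] == 40
    assert summary["polya_primate_specific_fraction"] == pytest.approx(0.25)
    with pytest.raises(EmptySummaryError):
        summarize_set(pd.DataFrame(columns=["gene_id", "kind", "lineage_class"]))


def test_round_trip_recovers_all_planted_labels(bench_study):
    from lncestro.pipeline import LABEL_TO_CLASS, score_lineage

    elements = extract_elements(bench_study.transcripts, bench_study.genome)
    maf = MafIndex(bench_study.maf_blocks, ref=HUMAN)
    lineage = conservation_table(elements, maf, DEFAULT_SPECIES)
    score = score_lineage(lineage, bench_study.truth)
    assert score["label_recovery"] == 1.0
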