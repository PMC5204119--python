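"""Gene-structure elements and their evolutionary lineage from alignments.

A lncRNA gene's "key structure elements" are the canonical splice donors
(intron starts with GT on the transcript strand), canonical splice acceptors
(intron ends with AG), and the canonical polyadenylation signal (AATAAA or
ATTAAA within a 40-nt window upstream of the transcript 3' end, 3'-most match
wins). Elements are extracted only from non-singleton isoforms (supported by
more than one cDNA/EST) and deduplicated across isoforms.

Each element is then looked up in a MultiZ-style multiple alignment. Per
species the element is *unaligned* (no block covers it, the species row is
absent, or any element column is a gap), *consensus_conserved* (the
strand-adjusted aligned bases equal the consensus — for polyA signals either
canonical hexamer counts), or *diverged*. The per-species states plus a
clade taxonomy yield a lineage class:

* ``conserved_beyond_primates`` — conserved in some non-primate other than
  the treeshrew;
* ``primate_plus_treeshrew`` — the only conserved non-primate is the
  treeshrew;
* ``primate_specific`` — conserved in at least one non-human primate (all,
  with ``strict_all_primates``) and in no non-primate;
* ``uninformative`` — no non-human species aligned, or nothing conserved.

A gene with at least one primate-specific element is flagged; a gene whose
elements are *all* primate-specific has a completely primate-specific gene
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .config import Species
from .errors import CoordinateError, EmptySummaryError
from .features import TranscriptModel, revcomp

__all__ = [
    "StructureElement",
    "extract_elements",
    "MafIndex",
    "assess_conservation",
    "classify_lineage",
    "classify_gene",
    "summarize_set",
    "conservation_table",
    "POLYA_HEXAMERS",
]

POLYA_HEXAMERS = ("AATAAA", "ATTAAA")


@dataclass(frozen=True)
class StructureElement:
    kind: str  # splice_donor | splice_acceptor | polya_signal
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    consensus: str

    @property
    def element_id(self) -> str:
        return f"{self.gene_id}_{self.kind}_{self.start}"


def _slice(genome: dict[str, str], chrom: str, start: int, end: int) -> str:
    if chrom not in genome:
        raise CoordinateError(f"unknown chromosome {chrom!r}")
    seq = genome[chrom]
    if start < 0 or end > len(seq):
        raise CoordinateError(f"{chrom}:{start}-{end} outside genome")
    return seq[start:end]


def extract_elements(
    models: list[TranscriptModel],
    genome: dict[str, str],
    polya_window: int = 40,
    min_support: int = 2,
) -> list[StructureElement]:
    """Canonical elements of all non-singleton isoforms, deduplicated.

    Donors/acceptors are emitted per intron end independently, and only when
    the strand-adjusted dinucleotide is canonical (a GC-AG intron yields an
    acceptor but no donor). The polyA signal is the 3'-most canonical hexamer
    fully inside the search window.
    """
    seen: set[tuple] = set()
    out: list[StructureElement] = []

    def emit(el: StructureElement):
        key = (el.kind, el.chrom, el.strand, el.start, el.end)
        if key not in seen:
            seen.add(key)
            out.append(el)

    for m in models:
        if m.support_count < min_support:
            continue
        for i_start, i_end in m.introns:
            if m.strand == "+":
                donor_iv, acceptor_iv = (i_start, i_start + 2), (i_end - 2, i_end)
            else:
                donor_iv, acceptor_iv = (i_end - 2, i_end), (i_start, i_start + 2)
            for kind, (s, e), consensus in (
                ("splice_donor", donor_iv, "GT"),
                ("splice_acceptor", acceptor_iv, "AG"),
            ):
                text = _slice(genome, m.chrom, s, e)
                if m.strand == "-":
                    text = revcomp(text)
                if text == consensus:
                    emit(
                        StructureElement(
                            kind, m.gene_id, m.chrom, m.strand, s, e, consensus
                        )
                    )
        # polyA: scan the transcript-sense window upstream of the 3' end
        w = min(polya_window, m.end - m.start)
        if m.strand == "+":
            g_start = m.end - w
            window = _slice(genome, m.chrom, g_start, m.end)
        else:
            g_start = m.start
            window = revcomp(_slice(genome, m.chrom, m.start, m.start + w))
        best = None
        for off in range(w - 6, -1, -1):  # 3'-most first
            hexamer = window[off : off + 6]
            if hexamer in POLYA_HEXAMERS:
                best = (off, hexamer)
                break
        if best is not None:
            off, hexamer = best
            if m.strand == "+":
                s = g_start + off
            else:
                s = g_start + (w - off - 6)
            emit(
                StructureElement(
                    "polya_signal", m.gene_id, m.chrom, m.strand, s, s + 6, hexamer
                )
            )
    return out


class MafIndex:
    """Alignment blocks indexed by reference-genome coordinates.

    ``ref`` is the reference assembly name as it appears before the dot in
    MAF ``src`` fields. Column lookup walks the (possibly gapped) reference
    row, so blocks with reference-row gaps are handled.
    """

    def __init__(self, blocks, ref: str):
        self.ref = ref
        self._trees: dict[str, IntervalTree] = {}
        self._blocks: list[dict] = []
        for block in blocks:
            ref_rec = None
            rows = {}
            for rec in block:
                assembly, _, chrom = rec.id.partition(".")
                if assembly == ref:
                    ref_rec = (chrom, rec)
                rows[assembly] = str(rec.seq).upper()
            if ref_rec is None:
                continue
            chrom, rec = ref_rec
            start = int(rec.annotations["start"])
            size = int(rec.annotations["size"])
            ref_text = str(rec.seq).upper()
            # map reference genomic position -> alignment column
            col_of = {}
            pos = start
            for col, base in enumerate(ref_text):
                if base != "-":
                    col_of[pos] = col
                    pos += 1
            idx = len(self._blocks)
            self._blocks.append({"rows": rows, "col_of": col_of})
            self._trees.setdefault(chrom, IntervalTree()).addi(start, start + size, idx)

    def column_bases(self, chrom: str, pos: int) -> dict[str, str] | None:
        """Per-assembly base at one reference position, or None if uncovered."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        for iv in tree.overlap(pos, pos + 1):
            block = self._blocks[iv.data]
            col = block["col_of"].get(pos)
            if col is not None:
                return {sp: text[col] for sp, text in block["rows"].items()}
        return None


def assess_conservation(
    element: StructureElement,
    maf: MafIndex,
    species_list: tuple[Species, ...],
) -> dict[str, str]:
    """Per-species state of one element: conserved / diverged / unaligned."""
    human = next(s for s in species_list if s.clade == "human")
    collected: dict[str, list[str]] = {s.name: [] for s in species_list}
    for pos in range(element.start, element.end):
        bases = maf.column_bases(element.chrom, pos)
        for sp in species_list:
            base = None if bases is None else bases.get(sp.name)
            collected[sp.name].append(base if base else None)
    states = {}
    allowed = (
        set(POLYA_HEXAMERS) if element.kind == "polya_signal" else {element.consensus}
    )
    for sp in species_list:
        bases = collected[sp.name]
        if any(b is None or b == "-" for b in bases):
            states[sp.name] = "unaligned"
            continue
        text = "".join(bases)
        if element.strand == "-":
            text = revcomp(text)
        states[sp.name] = "consensus_conserved" if text in allowed else "diverged"
    # an uncovered element is unaligned everywhere (not an error); a covered
    # human row that contradicts the extracted consensus is a real defect
    if states.get(human.name) == "diverged":
        raise CoordinateError(
            f"element {element.element_id} not conserved in the reference row"
        )
    return states


def classify_lineage(
    states: dict[str, str],
    species_list: tuple[Species, ...],
    strict_all_primates: bool = False,
) -> str:
    clade = {s.name: s.clade for s in species_list}
    nonhuman = [s for s in species_list if s.clade != "human"]
    conserved = {
        s.name for s in nonhuman if states.get(s.name) == "consensus_conserved"
    }
    other_conserved = {n for n in conserved if clade[n] == "other"}
    tree_conserved = {n for n in conserved if clade[n] == "treeshrew"}
    primates = [s.name for s in nonhuman if s.clade == "primate"]
    primate_conserved = {n for n in conserved if clade[n] == "primate"}
    primate_ok = (
        set(primates) == primate_conserved if strict_all_primates else bool(primate_conserved)
    )
    if other_conserved:
        return "conserved_beyond_primates"
    if tree_conserved:
        return "primate_plus_treeshrew"
    if primate_ok and primate_conserved:
        return "primate_specific"
    # nothing conserved anywhere: aligned-but-diverged everywhere is as
    # uninformative about lineage as a fully unaligned element
    return "uninformative"


def classify_gene(element_classes: list[str]) -> dict:
    """Gene-level roll-up of its elements' lineage classes."""
    n = len(element_classes)
    if n == 0:
        return {
            "n_elements": 0,
            "has_primate_specific": False,
            "completely_primate_specific": False,
            "unevaluable": True,
        }
    has_ps = any(c == "primate_specific" for c in element_classes)
    all_ps = all(c == "primate_specific" for c in element_classes)
    return {
        "n_elements": n,
        "has_primate_specific": has_ps,
        "completely_primate_specific": all_ps,
        "unevaluable": False,
    }


def conservation_table(
    elements: list[StructureElement],
    maf: MafIndex,
    species_list: tuple[Species, ...],
    strict_all_primates: bool = False,
) -> pd.DataFrame:
    """Lineage class (plus per-species states) for every element."""
    rows = []
    for el in elements:
        states = assess_conservation(el, maf, species_list)
        row = {
            "element_id": el.element_id,
            "gene_id": el.gene_id,
            "kind": el.kind,
            "chrom": el.chrom,
            "strand": el.strand,
            "start": el.start,
            "end": el.end,
            "lineage_class": classify_lineage(states, species_list, strict_all_primates),
        }
        for sp in species_list:
            if sp.clade != "human":
                row[f"state_{sp.name}"] = states[sp.name]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_set(lineage: pd.DataFrame) -> dict:
    """Set-wide primate-specificity summary.

    Over genes with a polyA element: the fraction whose polyA signal is
    primate-specific. Over genes with splice elements: the fraction with at
    least one primate-specific splice site. Plus per-gene structure classes.
    """
    if lineage.empty:
        raise EmptySummaryError("no elements to summarise")
    tagged = lineage.assign(is_ps=lineage["lineage_class"] == "primate_specific")
    polya = tagged[tagged["kind"] == "polya_signal"]
    splice = tagged[tagged["kind"].isin(["splice_donor", "splice_acceptor"])]
    polya_genes = polya.groupby("gene_id")["is_ps"].any()
    splice_genes = splice.groupby("gene_id")["is_ps"].any()
    gene_classes = {
        gid: classify_gene(list(sub["lineage_class"]))
        for gid, sub in lineage.groupby("gene_id")
    }
    n_complete = sum(1 for v in gene_classes.values() if v["completely_primate_specific"])
    n_has = sum(1 for v in gene_classes.values() if v["has_primate_specific"])
    return {
        "n_genes_evaluated": len(gene_classes),
        "n_genes_with_primate_specific_element": n_has,
        "n_genes_completely_primate_specific": n_complete,
        "polyadenylated_subset_n": int(polya_genes.size),
        "polya_primate_specific_n": int(polya_genes.sum()),
        "polya_primate_specific_fraction": (
            float(polya_genes.mean()) if polya_genes.size else None
        ),
        "spliced_subset_n": int(splice_genes.size),
        "splice_primate_specific_n": int(splice_genes.sum()),
        "splice_primate_specific_fraction": (
            float(splice_genes.mean()) if splice_genes.size else None
        ),
    }
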