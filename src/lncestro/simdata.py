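"""Synthetic oestrogen-response study generator with machine-readable truth.

Every input the pipeline consumes is simulated here — two-channel probe
intensities with signal compression and spike-in controls, TaqMan Ct tables,
a genome with transcript models whose splice sites and polyadenylation
signals use the canonical consensi, MultiZ-style multi-species alignment
blocks with planted per-element conservation states, ChIP peak sets, and a
partner gene catalogue for the intersection stage — together with a
:class:`TruthTable` that downstream recovery tests score against.

Model summary
-------------
* Array intensities: per-probe latent control intensity is log-uniform; the
  treated channel multiplies it by ``2**true_log2_fc``; multiplicative
  lognormal noise (Gaussian on the log2 scale) is applied, and the scanner's
  signal compression is emulated as ``observed = (latent * noise)**(1/gamma)``
  so that correcting intensities with exponent ``gamma`` downstream undoes it.
* Spike-in probes carry known nominal log2 ratios and, with six non-DE
  control genes, form the calibration set for exponent recovery.
* qPCR: Ct values are built so the delta-delta-Ct derived log2 fold change
  equals the planted one plus Gaussian cycle noise; a reference gene with
  zero fold change is always included.
* Genome: each gene occupies its own locus slot, far enough from neighbours
  that the +-5 kb evidence windows of the validation-panel genes are private.
  Planted elements use GT/AG intron ends and AATAAA/ATTAAA hexamers placed
  10-30 nt upstream of the transcript 3' end; the 40-nt 3' search window is
  scrubbed of accidental hexamers, and panel-gene windows are scrubbed of
  accidental ERE consensus matches before one exact ERE is planted in
  motif-positive genes.
* MultiZ: one alignment block per element (5 bp context each side). Species
  conserved under the planted lineage label copy the human consensus; others
  either carry a consensus-breaking substitution or are unaligned (row
  omitted, or gapped at the element columns — both encodings occur).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig, Species, stage_rng
from .errors import InvalidConfigError
from .features import GenomicInterval, TranscriptModel, revcomp
from .regulatory import ERE_CONSENSUS, locus_window, scan_ere
from . import io as lio

__all__ = [
    "TruthTable",
    "SimulatedStudy",
    "build_truth",
    "simulate_array_experiment",
    "simulate_qpcr",
    "simulate_genome_and_transcripts",
    "simulate_multiz",
    "simulate_peaks",
    "simulate_partner_catalogue",
    "calibration_set",
    "simulate_study",
    "write_study",
    "benchmark_config",
]

# re-export for convenience: the scaled benchmark lives with the config
from .config import benchmark_config  # noqa: E402,F401

POLYA_HEXAMERS = ("AATAAA", "ATTAAA")
POLYA_SEARCH_WINDOW = 40  # nt upstream of the transcript 3' end
REFERENCE_GENE = "REF18S"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthTable:
    """Planted ground truth: per-gene frame, per-element frame, spike ratios."""

    genes: pd.DataFrame
    elements: pd.DataFrame
    spikes: pd.DataFrame

    def validate(self) -> "TruthTable":
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise InvalidConfigError("duplicate gene ids in truth table")
        zero_iff_none = (g["true_log2_fc"] == 0) == (g["de_direction"] == "none")
        if not zero_iff_none.all():
            raise InvalidConfigError("true_log2_fc must be 0 exactly for non-DE genes")
        return self


@dataclass
class SimulatedStudy:
    """Bundle of all simulated inputs for one pipeline run."""

    config: SimConfig
    truth: TruthTable
    probes: pd.DataFrame
    calibration: pd.DataFrame
    ct: pd.DataFrame
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    loci: pd.DataFrame
    maf_blocks: list
    peaks: pd.DataFrame
    partner: list[TranscriptModel]


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

def build_truth(config: SimConfig) -> TruthTable:
    """Assign DE status, effect sizes, the validation panel and its tiers.

    Deterministic in ``config.seed``; called by every simulate_* entry point
    so the stages agree on the truth without passing state through files.
    """
    config.validate()
    rng = stage_rng(config.seed, "truth")
    n = config.n_genes
    gene_ids = np.array([f"LNC{i + 1:05d}" for i in range(n)])
    perm = rng.permutation(n)
    up = perm[: config.n_up]
    down = perm[config.n_up : config.n_up + config.n_down]
    controls = perm[
        config.n_up + config.n_down : config.n_up + config.n_down + config.n_control_genes
    ]

    direction = np.full(n, "none", dtype=object)
    direction[up] = "up"
    direction[down] = "down"
    lo, hi = config.effect_size_range
    fc = np.zeros(n)
    fc[up] = rng.uniform(lo, hi, size=len(up))
    fc[down] = -rng.uniform(lo, hi, size=len(down))

    is_control = np.zeros(n, dtype=bool)
    is_control[controls] = True

    # validation panel: the top-|FC| DE genes, mirroring "top 25 most
    # significant"; tiers are planted over a random ordering of the panel
    de_idx = np.concatenate([up, down])
    order = np.argsort(-np.abs(fc[de_idx]), kind="stable")
    panel = de_idx[order][: config.panel_size]
    in_panel = np.zeros(n, dtype=bool)
    in_panel[panel] = True

    n_chip, n_motif, n_none = config.tier_counts
    shuffled = rng.permutation(panel)
    chip = shuffled[:n_chip]
    motif = shuffled[n_chip : n_chip + n_motif]
    tier = np.full(n, "", dtype=object)
    tier[chip] = "chip"
    tier[motif] = "motif_only"
    tier[shuffled[n_chip + n_motif :]] = "none"

    has_peak = np.zeros(n, dtype=bool)
    has_peak[chip] = True
    has_foxa1 = np.zeros(n, dtype=bool)
    has_foxa1[chip[: config.n_foxa1_co]] = True
    has_motif = np.zeros(n, dtype=bool)
    has_motif[motif] = True
    # some directly bound genes also carry a motif; the tier is unaffected
    has_motif[chip] = rng.random(len(chip)) < 0.5

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "de_direction": direction,
            "true_log2_fc": fc,
            "is_control": is_control,
            "in_panel": in_panel,
            "true_tier": tier,
            "has_chip_peak": has_peak,
            "has_foxa1_peak": has_foxa1,
            "has_ere_motif": has_motif,
        }
    )
    ratios = np.array(config.spike_in_log2_ratios, dtype=float)
    spikes = pd.DataFrame(
        {
            "probe_id": [f"SPIKE{i + 1:03d}" for i in range(config.n_spike_ins)],
            "reference_log2_fc": ratios[np.arange(config.n_spike_ins) % len(ratios)],
        }
    )
    elements = pd.DataFrame(
        columns=[
            "element_id",
            "gene_id",
            "kind",
            "chrom",
            "strand",
            "start",
            "end",
            "consensus",
            "lineage_label",
        ]
    )
    return TruthTable(genes=genes, elements=elements, spikes=spikes).validate()


# ---------------------------------------------------------------------------
# microarray
# ---------------------------------------------------------------------------

def simulate_array_experiment(
    config: SimConfig, truth: TruthTable | None = None
) -> tuple[pd.DataFrame, TruthTable]:
    """Two-channel probe intensities (long format) plus the truth table."""
    config.validate()
    if truth is None:
        truth = build_truth(config)
    rng = stage_rng(config.seed, "array")
    G, K, R = config.n_genes, config.probes_per_gene, config.n_replicates
    gamma = config.compression_exponent

    base = rng.uniform(8.0, 12.0, size=G)[:, None] + rng.uniform(-0.5, 0.5, size=(G, K))
    fc = truth.genes["true_log2_fc"].to_numpy()
    latent = np.stack([base + fc[:, None], base], axis=2)  # (G, K, cond)
    eps = rng.normal(0.0, config.noise_sd, size=(G, K, 2, R))
    obs_log2 = (latent[..., None] + eps) / gamma  # (G, K, cond, rep)

    S = config.n_spike_ins
    s_base = rng.uniform(8.0, 12.0, size=S)
    s_ratio = truth.spikes["reference_log2_fc"].to_numpy()
    s_latent = np.stack([s_base + s_ratio, s_base], axis=1)  # (S, cond)
    s_eps = rng.normal(0.0, config.noise_sd, size=(S, 2, R))
    s_obs = (s_latent[..., None] + s_eps) / gamma

    gene_ids = truth.genes["gene_id"].to_numpy()
    conditions = np.array(["treated", "control"])
    frame = pd.DataFrame(
        {
            "probe_id": np.repeat(
                [f"{g}_p{k + 1}" for g in gene_ids for k in range(K)], 2 * R
            ),
            "gene_id": np.repeat(gene_ids, K * 2 * R),
            "probe_index": np.repeat(np.tile(np.arange(1, K + 1), G), 2 * R),
            "is_spike_in": False,
            "condition": np.tile(np.repeat(conditions, R), G * K),
            "replicate": np.tile(np.arange(1, R + 1), G * K * 2),
            "intensity": np.power(2.0, obs_log2).ravel(),
        }
    )
    spike_ids = truth.spikes["probe_id"].to_numpy()
    s_frame = pd.DataFrame(
        {
            "probe_id": np.repeat(spike_ids, 2 * R),
            "gene_id": np.repeat(spike_ids, 2 * R),
            "probe_index": 1,
            "is_spike_in": True,
            "condition": np.tile(np.repeat(conditions, R), S),
            "replicate": np.tile(np.arange(1, R + 1), S * 2),
            "intensity": np.power(2.0, s_obs).ravel(),
        }
    )
    probes = pd.concat([frame, s_frame], ignore_index=True)
    assert (probes["intensity"] > 0).all()
    return probes, truth


def calibration_set(truth: TruthTable) -> pd.DataFrame:
    """Spike-in probes plus zero-FC control genes, with reference ratios."""
    spikes = pd.DataFrame(
        {
            "unit_id": truth.spikes["probe_id"],
            "unit_type": "spike_probe",
            "reference_log2_fc": truth.spikes["reference_log2_fc"],
        }
    )
    ctrl = truth.genes.loc[truth.genes["is_control"], "gene_id"]
    controls = pd.DataFrame(
        {
            "unit_id": ctrl,
            "unit_type": "control_gene",
            "reference_log2_fc": 0.0,
        }
    )
    return pd.concat([spikes, controls], ignore_index=True)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    truth: TruthTable,
    noise_sd: float,
    seed: int,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Ct table for the validation panel plus the reference gene.

    Ct decreases by one cycle per doubling of template, so the treated-channel
    Ct of a gene is its baseline minus the planted log2 fold change; per-Ct
    Gaussian noise emulates pipetting/detection variation.
    """
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be >= 0")
    if len(truth.genes) == 0:
        raise InvalidConfigError("empty truth table")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    panel = truth.genes[truth.genes["in_panel"]]
    if panel.empty:  # degenerate configs: fall back to every DE gene
        panel = truth.genes[truth.genes["de_direction"] != "none"]
    rows = []
    for _, g in panel.iterrows():
        base = rng.uniform(22.0, 30.0)
        for cond, shift in (("control", 0.0), ("treated", -g.true_log2_fc)):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (g.gene_id, cond, rep, base + shift + rng.normal(0, noise_sd), False)
                )
    ref_base = 15.0
    for cond in ("control", "treated"):
        for rep in range(1, n_replicates + 1):
            rows.append(
                (REFERENCE_GENE, cond, rep, ref_base + rng.normal(0, noise_sd), True)
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "condition", "replicate", "ct", "is_reference"]
    )


# ---------------------------------------------------------------------------
# genome and transcript models
# ---------------------------------------------------------------------------

def _random_bases(rng, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]

_HEX_SET = set(POLYA_HEXAMERS)


def _count_hexamers(seq: str) -> list[int]:
    return [i for i in range(len(seq) - 5) if seq[i : i + 6] in _HEX_SET]


def _fill_polya_window(rng, plant_offset: int | None, hexamer: str | None) -> str:
    """A 40-nt transcript-sense window with exactly the requested signal."""
    for _ in range(200):
        w = _random_bases(rng, POLYA_SEARCH_WINDOW).tobytes().decode()
        if plant_offset is not None:
            w = w[:plant_offset] + hexamer + w[plant_offset + 6 :]
            if _count_hexamers(w) == [plant_offset]:
                return w
        elif not _count_hexamers(w):
            return w
    raise AssertionError("polyA window rejection sampling did not converge")


def simulate_genome_and_transcripts(
    config: SimConfig, truth: TruthTable | None = None
) -> tuple[dict[str, str], list[TranscriptModel], pd.DataFrame, TruthTable]:
    """Genome FASTA contents, transcript models, locus layout, element truth."""
    config.validate()
    if truth is None:
        truth = build_truth(config)
    rng = stage_rng(config.seed, "genome")
    genes = truth.genes

    slot_sizes = np.where(genes["in_panel"], config.panel_slot_size, config.slot_size)
    slot_starts = np.concatenate([[0], np.cumsum(slot_sizes)[:-1]])
    total = int(slot_sizes.sum()) + 1000
    chrom = "chr1"
    arr = _random_bases(rng, total)

    transcripts: list[TranscriptModel] = []
    loci_rows = []
    element_rows = []
    protected: set[int] = set()  # genomic positions the ERE scrub must not touch
    polya_windows: dict[str, tuple[int, str, list[int]]] = {}
    lineage_classes = ("conserved", "primate_specific", "primate_plus_treeshrew")
    probs = np.array(config.lineage_probs)

    def add_element(gene_id, kind, strand, start, end, consensus):
        label = lineage_classes[rng.choice(3, p=probs)]
        element_rows.append(
            {
                "element_id": f"{gene_id}_{kind}_{start}",
                "gene_id": gene_id,
                "kind": kind,
                "chrom": chrom,
                "strand": strand,
                "start": int(start),
                "end": int(end),
                "consensus": consensus,
                "lineage_label": label,
            }
        )
        protected.update(range(start, end))

    for gi, g in genes.iterrows():
        slot_start = int(slot_starts[gi])
        offset = 7000 if g.in_panel else 1000
        gene_start = slot_start + offset
        strand = "+" if rng.random() < 0.5 else "-"
        spliced = rng.random() < config.fraction_spliced
        if spliced:
            n_exons = int(rng.integers(2, 4))
            exon_lens = rng.integers(200, 401, size=n_exons)
            intron_lens = rng.integers(300, 701, size=n_exons - 1)
        else:
            n_exons = 1
            exon_lens = rng.integers(400, 1001, size=1)
            intron_lens = np.array([], dtype=int)
        exons = []
        pos = gene_start
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        model = TranscriptModel(
            gene_id=g.gene_id,
            transcript_id=f"{g.gene_id}.1",
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            support_count=2,
        )
        transcripts.append(model)

        for i_start, i_end in model.introns:
            if strand == "+":
                arr[i_start : i_start + 2] = np.frombuffer(b"GT", np.uint8)
                arr[i_end - 2 : i_end] = np.frombuffer(b"AG", np.uint8)
                add_element(g.gene_id, "splice_donor", "+", i_start, i_start + 2, "GT")
                add_element(g.gene_id, "splice_acceptor", "+", i_end - 2, i_end, "AG")
            else:
                arr[i_end - 2 : i_end] = np.frombuffer(b"AC", np.uint8)  # revcomp(GT)
                arr[i_start : i_start + 2] = np.frombuffer(b"CT", np.uint8)  # revcomp(AG)
                add_element(g.gene_id, "splice_donor", "-", i_end - 2, i_end, "GT")
                add_element(g.gene_id, "splice_acceptor", "-", i_start, i_start + 2, "AG")

        # 3' end window: scrub accidental hexamers; plant one signal if the
        # gene is polyadenylated (signal end 10-30 nt upstream of the 3' end)
        polyadenylated = rng.random() < config.fraction_polyadenylated
        if polyadenylated:
            d = int(rng.integers(10, 31))
            plant_offset = POLYA_SEARCH_WINDOW - d - 6
            hexamer = POLYA_HEXAMERS[int(rng.integers(0, 2))]
        else:
            plant_offset, hexamer = None, None
        window = _fill_polya_window(rng, plant_offset, hexamer)
        if strand == "+":
            w_start = model.end - POLYA_SEARCH_WINDOW
            arr[w_start : model.end] = np.frombuffer(window.encode(), np.uint8)
        else:
            w_start = model.start
            arr[w_start : w_start + POLYA_SEARCH_WINDOW] = np.frombuffer(
                revcomp(window).encode(), np.uint8
            )
        polya_windows[g.gene_id] = (
            w_start,
            strand,
            [plant_offset] if polyadenylated else [],
        )
        if polyadenylated:
            if strand == "+":
                e_start = model.end - d - 6
            else:
                e_start = model.start + d
            add_element(g.gene_id, "polya_signal", strand, e_start, e_start + 6, hexamer)

        loci_rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": chrom,
                "slot_start": slot_start,
                "slot_end": slot_start + int(slot_sizes[gi]),
                "start": model.start,
                "end": model.end,
                "strand": strand,
                "in_panel": bool(g.in_panel),
            }
        )

    loci = pd.DataFrame(loci_rows)

    # plant exact EREs for motif-positive panel genes, then scrub every panel
    # window of accidental consensus matches
    planted_ere: dict[str, tuple[int, int]] = {}
    for _, loc in loci[loci["in_panel"]].iterrows():
        wants_motif = bool(
            truth.genes.set_index("gene_id").loc[loc.gene_id, "has_ere_motif"]
        )
        if wants_motif:
            pos = int(loc.start) - 2000
            spacer = _random_bases(rng, 3).tobytes().decode()
            motif = "GGTCA" + spacer + "TGACC"
            arr[pos : pos + 13] = np.frombuffer(motif.encode(), np.uint8)
            planted_ere[loc.gene_id] = (pos, pos + 13)
            protected.update(range(pos, pos + 13))

    # the ERE scrub and the polyA-window guarantee can perturb each other
    # (a disruption substitution can create a hexamer and vice versa), so
    # alternate until both are stable
    for _, loc in loci[loci["in_panel"]].iterrows():
        for _ in range(20):
            changed = _scrub_ere_window(
                arr, loc, planted_ere.get(loc.gene_id), protected
            )
            changed |= _fix_polya_window(
                arr, polya_windows[loc.gene_id], protected
            )
            if not changed:
                break
        else:
            raise AssertionError("ERE/polyA scrubbing did not converge")

    genome = {chrom: arr.tobytes().decode()}
    elements = (
        pd.DataFrame(element_rows)
        .drop_duplicates(subset=["kind", "chrom", "strand", "start", "end"])
        .reset_index(drop=True)
    )
    truth = replace(truth, elements=elements)
    return genome, transcripts, loci, truth


_FLIP = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _scrub_ere_window(
    arr, loc, planted: tuple[int, int] | None, protected: set[int]
) -> bool:
    """One pass removing accidental ERE matches from a panel gene's window.

    Returns True if any base was changed (callers loop until stable).
    Disruption adds substitutions at consensus-matching positions until one
    half-site exceeds the mismatch allowance, never touching planted elements.
    """
    w_start = max(0, int(loc.start) - 5000)
    w_end = min(len(arr), int(loc.end) + 5000)
    seq = arr[w_start:w_end].tobytes().decode()
    hits = scan_ere(seq, max_mismatch_per_halfsite=1)
    changed = False
    for h in hits.itertuples():
        if planted is not None and (w_start + h.start, w_start + h.end) == planted:
            continue
        for half in ([0, 1, 2, 3, 4], [8, 9, 10, 11, 12]):
            mutated = 0
            for i in half:
                gpos = w_start + int(h.start) + i
                if gpos in protected:
                    continue
                if chr(arr[gpos]) == ERE_CONSENSUS[i]:
                    arr[gpos] = ord(_FLIP[ERE_CONSENSUS[i]])
                    mutated += 1
                    changed = True
                if mutated >= 2:
                    break
            if mutated >= 2:
                break
    return changed


def _fix_polya_window(
    arr, window: tuple[int, str, list[int]], protected: set[int]
) -> bool:
    """Restore the planted-hexamer guarantee of one 3' search window.

    Any accidental AATAAA/ATTAAA introduced by other scrubbing is broken by
    rewriting its middle base to C (which can create neither hexamer nor be
    part of one). Returns True if a base was changed.
    """
    w_start, strand, expected = window
    g_seq = arr[w_start : w_start + POLYA_SEARCH_WINDOW].tobytes().decode()
    sense = revcomp(g_seq) if strand == "-" else g_seq
    changed = False
    for off in _count_hexamers(sense):
        if off in expected:
            continue
        j = off + 2  # transcript-sense index to rewrite
        gpos = w_start + (POLYA_SEARCH_WINDOW - 1 - j) if strand == "-" else w_start + j
        if gpos in protected:
            j = off + 3
            gpos = (
                w_start + (POLYA_SEARCH_WINDOW - 1 - j)
                if strand == "-"
                else w_start + j
            )
            if gpos in protected:  # would silently break the truth table
                raise AssertionError("accidental hexamer fully inside planted element")
        arr[gpos] = ord("G") if strand == "-" else ord("C")
        changed = True
    return changed


# ---------------------------------------------------------------------------
# MultiZ-style alignments
# ---------------------------------------------------------------------------

def _conserved_in(label: str, clade: str) -> bool:
    if label == "conserved":
        return True
    if label == "primate_specific":
        return clade == "primate"
    if label == "primate_plus_treeshrew":
        return clade in ("primate", "treeshrew")
    raise InvalidConfigError(f"unknown lineage label {label!r}")


def _diverge(plus_text: str, kind: str, strand: str) -> str:
    """Break the element consensus with a single substitution (plus-strand)."""
    sense = revcomp(plus_text) if strand == "-" else plus_text
    if kind == "splice_donor":  # GT -> GC
        sense = sense[0] + "C"
    elif kind == "splice_acceptor":  # AG -> GG
        sense = "G" + sense[1]
    else:  # AATAAA/ATTAAA -> ...G, matching neither hexamer
        sense = sense[:5] + "G"
    return revcomp(sense) if strand == "-" else sense


def simulate_multiz(
    transcripts: list[TranscriptModel],
    truth: TruthTable,
    species_list: tuple[Species, ...],
    genome: dict[str, str],
    seed: int,
    context: int = 5,
) -> list:
    """One MultiZ-style block per structure element, per planted labels."""
    clades = {s.clade for s in species_list}
    if "primate" not in clades or not ({"treeshrew", "other"} & clades):
        raise InvalidConfigError("need at least one primate and one non-primate")
    if truth.elements.empty:
        return []
    if truth.elements["lineage_label"].isna().any():
        raise InvalidConfigError("every element needs a lineage_label")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    human = next(s for s in species_list if s.clade == "human")
    others = [s for s in species_list if s.clade != "human"]
    cursor = {s.name: 1000 for s in others}
    blocks = []
    for el in truth.elements.sort_values(["chrom", "start"]).itertuples():
        chrom_seq = genome[el.chrom]
        b_start = max(0, el.start - context)
        b_end = min(len(chrom_seq), el.end + context)
        human_text = chrom_seq[b_start:b_end]
        e_lo, e_hi = el.start - b_start, el.end - b_start
        elem_plus = human_text[e_lo:e_hi]
        rows = [
            (
                f"{human.name}.{el.chrom}",
                b_start,
                len(human_text),
                "+",
                len(chrom_seq),
                human_text,
            )
        ]
        for sp in others:
            if _conserved_in(el.lineage_label, sp.clade):
                text = _mutate_context(rng, human_text, e_lo, e_hi)
            else:
                mode = rng.choice(["diverged", "omit", "gap"], p=[0.5, 0.25, 0.25])
                if mode == "omit":
                    continue
                if mode == "gap":
                    text = human_text[:e_lo] + "-" * (e_hi - e_lo) + human_text[e_hi:]
                else:
                    text = (
                        human_text[:e_lo]
                        + _diverge(elem_plus, el.kind, el.strand)
                        + human_text[e_hi:]
                    )
                    text = _mutate_context(rng, text, e_lo, e_hi)
            size = len(text) - text.count("-")
            start = cursor[sp.name]
            cursor[sp.name] = start + size + int(rng.integers(50, 500))
            rows.append((f"{sp.name}.{el.chrom}", start, size, "+", 10_000_000, text))
        blocks.append(lio.maf_block(rows))
    return blocks


def _mutate_context(rng, text: str, e_lo: int, e_hi: int, rate: float = 0.1) -> str:
    """Random substitutions outside the element columns, for realism."""
    out = list(text)
    for i in range(len(out)):
        if e_lo <= i < e_hi or out[i] == "-":
            continue
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(out)


# ---------------------------------------------------------------------------
# ChIP peaks and partner catalogue
# ---------------------------------------------------------------------------

def simulate_peaks(loci: pd.DataFrame, truth: TruthTable, seed: int) -> pd.DataFrame:
    """BED6-style peaks: planted ER-alpha/FOXA1 peaks plus unrelated decoys."""
    if loci.empty:
        raise InvalidConfigError("empty locus table")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))
    flags = truth.genes.set_index("gene_id")
    rows = []
    for loc in loci.itertuples():
        if not loc.in_panel:
            continue
        g = flags.loc[loc.gene_id]
        for factor, wanted in (("ERalpha", g.has_chip_peak), ("FOXA1", g.has_foxa1_peak)):
            if not wanted:
                continue
            length = int(rng.integers(200, 401))
            lo = int(loc.start)
            hi = max(lo + 1, int(loc.end) - length)
            start = int(rng.integers(lo, hi))
            rows.append((loc.chrom, start, start + length, factor, 0.0, "."))
    # decoy peaks of an unrelated factor, placed in ordinary gene slots so
    # they never touch a panel window
    decoy_slots = loci[~loci["in_panel"]].head(5)
    for loc in decoy_slots.itertuples():
        start = int(loc.slot_start) + 4500
        rows.append((loc.chrom, start, start + 200, "CTCF", 0.0, "."))
    return pd.DataFrame(rows, columns=lio.PEAK_COLUMNS)


def simulate_partner_catalogue(
    transcripts: list[TranscriptModel],
    loci: pd.DataFrame,
    truth: TruthTable,
    seed: int,
    fraction: float = 0.4,
    n_decoys: int = 25,
) -> tuple[list[TranscriptModel], TruthTable]:
    """An external-style catalogue sharing a planted subset of our genes.

    A random fraction of genes reappears under new identifiers with slightly
    extended first exons (still overlapping); decoy single-exon genes sit in
    unused locus-slot space so they overlap nothing. Adds an ``in_partner``
    column to the gene truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    by_gene = {t.gene_id: t for t in transcripts}
    gene_ids = truth.genes["gene_id"].to_numpy()
    chosen = set(
        rng.choice(gene_ids, size=int(round(fraction * len(gene_ids))), replace=False)
    )
    partner = []
    for gid in gene_ids:
        if gid not in chosen:
            continue
        t = by_gene[gid]
        exons = list(t.exons)
        s, e = exons[0]
        exons[0] = (max(0, s - 50), e)
        partner.append(
            TranscriptModel(
                gene_id=f"EXT_{gid}",
                transcript_id=f"EXT_{gid}.1",
                chrom=t.chrom,
                strand=t.strand,
                exons=tuple(exons),
                support_count=2,
            )
        )
    for i, loc in enumerate(loci.head(n_decoys).itertuples()):
        start = int(loc.slot_end) - 1500
        partner.append(
            TranscriptModel(
                gene_id=f"DECOY{i + 1:03d}",
                transcript_id=f"DECOY{i + 1:03d}.1",
                chrom=loc.chrom,
                strand="+" if i % 2 == 0 else "-",
                exons=((start, start + 300),),
                support_count=2,
            )
        )
    genes = truth.genes.copy()
    genes["in_partner"] = genes["gene_id"].isin(chosen)
    return partner, replace(truth, genes=genes)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run every generator with substreams of ``config.seed``."""
    config.validate()
    truth = build_truth(config)
    probes, truth = simulate_array_experiment(config, truth)
    genome, transcripts, loci, truth = simulate_genome_and_transcripts(config, truth)
    maf_blocks = simulate_multiz(
        transcripts, truth, config.species_list, genome, config.seed
    )
    peaks = simulate_peaks(loci, truth, config.seed)
    partner, truth = simulate_partner_catalogue(
        transcripts, loci, truth, config.seed
    )
    ct = simulate_qpcr(
        truth, config.qpcr_noise_sd, config.seed, config.qpcr_replicates
    )
    return SimulatedStudy(
        config=config,
        truth=truth,
        probes=probes,
        calibration=calibration_set(truth),
        ct=ct,
        genome=genome,
        transcripts=transcripts,
        loci=loci,
        maf_blocks=maf_blocks,
        peaks=peaks,
        partner=partner,
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Serialize every simulated input; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "transcripts": out / "transcripts.bed",
        "alignments": out / "alignments.maf",
        "peaks": out / "peaks.bed",
        "probes": out / "probes.tsv",
        "calibration": out / "calibration.tsv",
        "qpcr": out / "qpcr.tsv",
        "partner": out / "partner_catalogue.bed",
        "truth_genes": out / "truth_genes.tsv",
        "truth_elements": out / "truth_elements.tsv",
        "truth_spikes": out / "truth_spikes.tsv",
    }
    lio.write_fasta(study.genome, paths["genome"])
    lio.write_bed12(study.transcripts, paths["transcripts"])
    lio.write_maf(study.maf_blocks, paths["alignments"])
    lio.write_bed6(study.peaks, paths["peaks"])
    lio.write_tsv(study.probes, paths["probes"])
    lio.write_tsv(study.calibration, paths["calibration"])
    lio.write_tsv(study.ct, paths["qpcr"])
    lio.write_bed12(study.partner, paths["partner"])
    lio.write_tsv(study.truth.genes, paths["truth_genes"])
    lio.write_tsv(study.truth.elements, paths["truth_elements"])
    lio.write_tsv(study.truth.spikes, paths["truth_spikes"])
    return {k: str(v) for k, v in paths.items()}
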