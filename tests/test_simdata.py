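"""Generator contracts: noiseless identities, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

from lncestro import io as lio
from lncestro.config import SimConfig, benchmark_config
from lncestro.errors import InvalidConfigError
from lncestro.features import revcomp
from lncestro.qpcr import ddct_log2_fc
from lncestro.simdata import (
    POLYA_HEXAMERS,
    build_truth,
    calibration_set,
    simulate_array_experiment,
    simulate_genome_and_transcripts,
    simulate_peaks,
    simulate_qpcr,
    write_study,
)


def _noiseless(seed=5, gamma=1.0, **kw):
    return benchmark_config(
        seed=seed, noise_sd=0.0, compression_exponent=gamma, **kw
    )


def _probe_ratios(probes: pd.DataFrame, gene_id: str) -> np.ndarray:
    sub = probes[probes["gene_id"] == gene_id]
    wide = sub.pivot_table(
        index=["probe_id", "replicate"], columns="condition", values="intensity"
    )
    return (wide["treated"] / wide["control"]).to_numpy()


def test_noiseless_unit_gamma_reproduces_planted_ratio_exactly():
    probes, truth = simulate_array_experiment(_noiseless())
    gene = truth.genes[truth.genes["true_log2_fc"] != 0].iloc[0]
    ratios = _probe_ratios(probes, gene.gene_id)
    assert np.allclose(ratios, 2.0 ** gene.true_log2_fc, rtol=1e-9)


def test_compression_shrinks_observed_ratio_by_the_exponent():
    # a true 2-fold change observed through gamma=1.125 compression
    probes, truth = simulate_array_experiment(_noiseless(gamma=1.125))
    gene = truth.genes[truth.genes["true_log2_fc"] != 0].iloc[0]
    ratios = _probe_ratios(probes, gene.gene_id)
    expected = (2.0 ** gene.true_log2_fc) ** (1 / 1.125)
    assert np.allclose(ratios, expected, rtol=1e-9)
    # the spec case: true ratio 2 -> observed 2**(1/1.125) ~= 1.852
    assert 2 ** (1 / 1.125) == pytest.approx(1.8517, abs=1e-4)


def test_same_seed_gives_byte_identical_outputs(tmp_path, tiny_config):
    from lncestro.simdata import simulate_study

    for d in ("a", "b"):
        write_study(simulate_study(tiny_config), tmp_path / d)
    for name in ("probes.tsv", "genome.fa", "alignments.maf", "peaks.bed",
                 "transcripts.bed", "qpcr.tsv", "truth_genes.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes(), name


def test_overfull_de_assignment_is_rejected():
    with pytest.raises(InvalidConfigError):
        SimConfig(n_genes=10, n_up=8, n_down=8).validate()


def test_truth_table_invariants(bench_study):
    g = bench_study.truth.genes
    assert g["gene_id"].is_unique
    de = g["de_direction"] != "none"
    assert (g.loc[de, "true_log2_fc"].abs() >= 1.0).all()
    assert (g.loc[~de, "true_log2_fc"] == 0).all()
    assert g["in_panel"].sum() == 25


def test_qpcr_noiseless_ddct_matches_planted_fold_change():
    cfg = _noiseless(seed=9)
    truth = build_truth(cfg)
    ct = simulate_qpcr(truth, noise_sd=0.0, seed=cfg.seed)
    panel = truth.genes[truth.genes["in_panel"]]
    for g in panel.itertuples():
        assert ddct_log2_fc(ct, g.gene_id) == pytest.approx(g.true_log2_fc, abs=1e-9)
    # the reference gene has identical delta-Ct in both conditions
    ref = ct[ct["is_reference"]]
    assert ref.groupby("condition")["ct"].mean().nunique() == 1


def test_qpcr_rejects_negative_noise(bench_study):
    with pytest.raises(InvalidConfigError):
        simulate_qpcr(bench_study.truth, noise_sd=-0.1, seed=0)


def test_unspliced_config_yields_single_exon_transcripts():
    cfg = benchmark_config(seed=4, n_genes=40, n_up=10, n_down=15,
                           fraction_spliced=0.0)
    _, transcripts, _, _ = simulate_genome_and_transcripts(cfg)
    assert all(len(t.exons) == 1 for t in transcripts)


def test_minus_strand_introns_show_ct_ac_on_forward_strand(bench_study):
    genome = bench_study.genome
    checked = 0
    for t in bench_study.transcripts:
        if t.strand != "-" or len(t.exons) == 1:
            continue
        for i_start, i_end in t.introns:
            assert genome[t.chrom][i_start : i_start + 2] == "CT"
            assert genome[t.chrom][i_end - 2 : i_end] == "AC"
            checked += 1
    assert checked > 0


def test_planted_polya_signal_is_unique_in_search_window(bench_study):
    elements = bench_study.truth.elements
    polya = elements[elements["kind"] == "polya_signal"]
    assert len(polya) > 0
    by_gene = {t.gene_id: t for t in bench_study.transcripts}
    for el in polya.itertuples():
        t = by_gene[el.gene_id]
        seq = t.spliced_sequence(bench_study.genome)
        window = seq[-40:]
        hits = [
            i for i in range(len(window) - 5) if window[i : i + 6] in POLYA_HEXAMERS
        ]
        assert len(hits) == 1, el.gene_id


def test_peaks_respect_planted_flags(bench_study):
    peaks = bench_study.peaks
    loci = bench_study.loci.set_index("gene_id")
    for g in bench_study.truth.genes[bench_study.truth.genes["in_panel"]].itertuples():
        loc = loci.loc[g.gene_id]
        w_lo, w_hi = loc.start - 5000, loc.end + 5000
        er = peaks[(peaks["name"] == "ERalpha")
                   & (peaks["end"] > w_lo) & (peaks["start"] < w_hi)]
        assert (len(er) >= 1) == g.has_chip_peak


def test_formats_round_trip_through_own_readers(tmp_path, bench_study):
    paths = write_study(bench_study, tmp_path)
    genome = lio.read_fasta(paths["genome"])
    assert genome == bench_study.genome
    models = lio.read_bed12(paths["transcripts"])
    assert [(m.gene_id, m.exons, m.strand) for m in models] == [
        (m.gene_id, m.exons, m.strand) for m in bench_study.transcripts
    ]
    blocks = lio.read_maf(paths["alignments"])
    assert len(blocks) == len(bench_study.maf_blocks)
    first, orig = blocks[0], bench_study.maf_blocks[0]
    assert [str(r.seq) for r in first] == [str(r.seq) for r in orig]
    assert [r.annotations["start"] for r in first] == [
        r.annotations["start"] for r in orig
    ]
    peaks = lio.read_bed6(paths["peaks"])
    pd.testing.assert_frame_equal(peaks, bench_study.peaks)


def test_calibration_set_spans_distinct_ratios(bench_study):
    calib = calibration_set(bench_study.truth)
    assert calib["reference_log2_fc"].nunique() >= 2
    assert (calib["unit_type"] == "control_gene").sum() == 6


def test_multiz_requires_a_primate_and_a_nonprimate():
    from lncestro.config import Species
    from lncestro.simdata import simulate_multiz, simulate_study

    study = simulate_study(benchmark_config(seed=6, n_genes=40, n_up=10, n_down=15))
    humans_only = (Species("hg19sim", "human"), Species("panTroSim", "primate"))
    with pytest.raises(InvalidConfigError):
        simulate_multiz(
            study.transcripts, study.truth, humans_only, study.genome, seed=0
        )
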