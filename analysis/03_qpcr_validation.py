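"""qPCR validation of the array calls on the 25-gene panel.

Computes delta-delta-Ct log2 fold changes from the simulated Ct table,
validates each panel gene (sign agreement + magnitude floor), and reports
the microarray-qPCR Pearson concordance over all tested genes and over the
validated subset.
"""

from _common import RESULTS, STUDY, load_truth, parse_seed

from lncestro import io as lio, qpcr


def main():
    parse_seed(__doc__)
    ct = lio.read_tsv(STUDY / "qpcr.tsv")
    de = lio.read_tsv(RESULTS / "de_results.tsv")
    truth = load_truth()
    panel = truth.genes.loc[truth.genes["in_panel"], "gene_id"]
    report = qpcr.concordance(
        de[de["gene_id"].isin(panel)], qpcr.qpcr_log2_fc_table(ct)
    )
    lio.write_tsv(report.per_gene, RESULTS / "concordance.tsv")
    lio.write_json(report.summary(), RESULTS / "concordance_summary.json")
    print(f"validated {report.n_validated}/{report.n_tested} panel genes "
          f"({100 * report.validation_rate:.0f}%)")
    print(f"Pearson r (all tested)  = {report.pearson_all:+.3f}")
    print(f"Pearson r (validated)   = {report.pearson_validated:+.3f}")


if __name__ == "__main__":
    main()
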