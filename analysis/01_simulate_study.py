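"""Generate the synthetic oestrogen-response study with its truth table.

Writes every pipeline input (probe intensities, Ct table, genome, transcript
models, MultiZ-style alignments, peak set, partner catalogue) under
results/study/ at the benchmark conditions: 500 genes x 7 probes, 20 induced
and 30 repressed, three replicate hybridisations, compression exponent 1.125.
"""

from _common import STUDY, parse_seed

from lncestro.config import benchmark_config
from lncestro.simdata import simulate_study, write_study


def main():
    seed = parse_seed(__doc__)
    study = simulate_study(benchmark_config(seed=seed))
    paths = write_study(study, STUDY)
    g = study.truth.genes
    print(f"seed {seed}: simulated {len(g)} genes "
          f"({(g.de_direction == 'up').sum()} up, {(g.de_direction == 'down').sum()} down), "
          f"{len(study.truth.elements)} structure elements, "
          f"{g.in_panel.sum()}-gene validation panel")
    for k, v in paths.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
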