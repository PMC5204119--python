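"""Shared paths and study loading for the numbered analysis scripts."""

import argparse
from pathlib import Path

from lncestro import io as lio
from lncestro.simdata import TruthTable

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
STUDY = RESULTS / "study"


def parse_seed(description: str) -> int:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    return ap.parse_args().seed


def load_truth() -> TruthTable:
    return TruthTable(
        genes=lio.read_tsv(STUDY / "truth_genes.tsv"),
        elements=lio.read_tsv(STUDY / "truth_elements.tsv"),
        spikes=lio.read_tsv(STUDY / "truth_spikes.tsv"),
    )
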