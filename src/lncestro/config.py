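"""Study configuration for the synthetic oestrogen-response experiment.

The defaults describe the study this pipeline emulates: a two-channel custom
microarray interrogating 5586 lncRNA genes with seven strand-specific 60-mer
probes each, hybridised in duplicate, with Agilent-style spike-in controls and
six qPCR-anchored control mRNAs used to calibrate a mild signal-compression
exponent (1.125); 44 genes induced and 83 repressed by 17beta-oestradiol; a
25-gene validation panel carrying a planted 7/15/3 split of regulatory
evidence (ChIP peak / ERE motif only / neither); and gene structures in which
roughly 43/127 of genes are canonically spliced and 86/127 carry a canonical
polyadenylation signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidConfigError

__all__ = [
    "Species",
    "DEFAULT_SPECIES",
    "SimConfig",
    "benchmark_config",
    "stage_rng",
]


@dataclass(frozen=True)
class Species:
    """A genome in the multi-species alignment, tagged by clade."""

    name: str
    clade: str  # one of: human, primate, treeshrew, other

    def __post_init__(self):
        if self.clade not in {"human", "primate", "treeshrew", "other"}:
            raise InvalidConfigError(f"unknown clade {self.clade!r} for {self.name}")


#: A minimal MultiZ-like panel: reference, two non-human primates, the
#: treeshrew (closest non-primate), and two outgroup mammals.
DEFAULT_SPECIES: tuple[Species, ...] = (
    Species("hg19sim", "human"),
    Species("panTroSim", "primate"),
    Species("rheMacSim", "primate"),
    Species("tupBelSim", "treeshrew"),
    Species("mm10sim", "other"),
    Species("canFamSim", "other"),
)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study; ``seed`` fully determines outputs."""

    n_genes: int = 5586
    n_up: int = 44
    n_down: int = 83
    probes_per_gene: int = 7
    n_replicates: int = 2
    noise_sd: float = 0.25  # log2 units, per intensity measurement
    compression_exponent: float = 1.125  # gamma_true; observed I = latent**(1/gamma)
    n_spike_ins: int = 20
    spike_in_log2_ratios: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    n_control_genes: int = 6  # non-DE mRNA controls anchoring the calibration
    effect_size_range: tuple[float, float] = (1.0, 2.5)  # |log2 FC| of DE genes
    fraction_spliced: float = 43 / 127
    fraction_polyadenylated: float = 86 / 127
    panel_size: int = 25  # top-|FC| DE genes carried into validation stages
    tier_counts: tuple[int, int, int] = (7, 15, 3)  # chip / motif_only / none
    n_foxa1_co: int = 3  # ChIP-tier genes that also carry a FOXA1 peak
    lineage_probs: tuple[float, float, float] = (0.5, 0.35, 0.15)
    # probabilities of (conserved, primate_specific, primate_plus_treeshrew)
    species_list: tuple[Species, ...] = DEFAULT_SPECIES
    qpcr_noise_sd: float = 0.25  # cycles, per Ct measurement
    qpcr_replicates: int = 3
    # genome layout (bp)
    slot_size: int = 6000  # locus slot for ordinary genes
    panel_slot_size: int = 20000  # panel genes get room for the +-5 kb window
    flank: int = 5000
    seed: int = 0

    def validate(self) -> "SimConfig":
        c = self
        if c.n_genes < 1:
            raise InvalidConfigError("n_genes must be >= 1")
        if c.n_up < 0 or c.n_down < 0 or c.n_up + c.n_down > c.n_genes:
            raise InvalidConfigError("need n_up + n_down <= n_genes")
        if c.probes_per_gene < 1:
            raise InvalidConfigError("probes_per_gene must be >= 1")
        if c.n_replicates < 1:
            raise InvalidConfigError("n_replicates must be >= 1")
        if c.noise_sd < 0 or c.qpcr_noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if c.compression_exponent <= 0:
            raise InvalidConfigError("compression_exponent must be > 0")
        if not (0 <= c.fraction_spliced <= 1 and 0 <= c.fraction_polyadenylated <= 1):
            raise InvalidConfigError("splicing/polyA fractions must lie in [0, 1]")
        lo, hi = c.effect_size_range
        if not (0 < lo <= hi):
            raise InvalidConfigError("effect_size_range must satisfy 0 < lo <= hi")
        if sum(c.tier_counts) != c.panel_size:
            raise InvalidConfigError("tier_counts must sum to panel_size")
        if c.panel_size > c.n_up + c.n_down:
            raise InvalidConfigError("panel_size exceeds the number of DE genes")
        if c.n_foxa1_co > c.tier_counts[0]:
            raise InvalidConfigError("n_foxa1_co exceeds the ChIP tier count")
        if abs(sum(c.lineage_probs) - 1.0) > 1e-9:
            raise InvalidConfigError("lineage_probs must sum to 1")
        if c.n_control_genes + c.n_up + c.n_down > c.n_genes:
            raise InvalidConfigError("not enough non-DE genes for controls")
        clades = {s.clade for s in c.species_list}
        if "human" not in clades:
            raise InvalidConfigError("species_list must contain the human reference")
        if not ({"primate"} & clades) or not ({"treeshrew", "other"} & clades):
            raise InvalidConfigError(
                "species_list needs at least one primate and one non-primate"
            )
        if len({s.name for s in c.species_list}) != len(c.species_list):
            raise InvalidConfigError("duplicate species names")
        return c

    @property
    def human(self) -> Species:
        return next(s for s in self.species_list if s.clade == "human")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


def benchmark_config(seed: int = 0, **overrides) -> SimConfig:
    """The seeded 500-gene benchmark used for recovery checks.

    Smaller than the full array (500 genes, 20 up / 30 down, three replicate
    hybridisations) but with the same probe layout, noise level, and planted
    evidence tiers, so every stage of the pipeline can be scored against the
    truth table in seconds.
    """
    base = dict(
        n_genes=500,
        n_up=20,
        n_down=30,
        n_replicates=3,
        noise_sd=0.25,
        seed=int(seed),
    )
    base.update(overrides)
    return SimConfig(**base).validate()


_STAGE_IDS = {
    "truth": 1,
    "array": 2,
    "qpcr": 3,
    "genome": 4,
    "multiz": 5,
    "peaks": 6,
    "partner": 7,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named deterministic substream so stages are individually rerunnable."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_IDS[stage]]))
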