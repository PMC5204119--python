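"""qPCR fold changes, validation calls, and array concordance.

Relative quantification uses the delta-delta-Ct method under the assumption
of 100% amplification efficiency (one cycle per doubling): with
``dCt = Ct_target - Ct_reference`` averaged over replicates in each
condition, ``ddCt = dCt_treated - dCt_control`` and the log2 fold change is
``-ddCt``. A gene "validates" the array call when the qPCR fold change
agrees in sign and clears a small magnitude floor (default FC 1.2).
Concordance between platforms is the Pearson correlation of log2 fold
changes, reported both over all tested genes and over the validated subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, NormalizationError

__all__ = [
    "ddct_log2_fc",
    "qpcr_log2_fc_table",
    "validate_gene",
    "pearson",
    "ConcordanceReport",
    "concordance",
    "DEFAULT_MIN_MAGNITUDE",
]

DEFAULT_MIN_MAGNITUDE = float(np.log2(1.2))


def _dct(ct: pd.DataFrame, gene_id: str, condition: str) -> float:
    ref = ct[(ct["is_reference"]) & (ct["condition"] == condition)]["ct"]
    if ref.empty:
        raise NormalizationError(f"reference gene missing in condition {condition!r}")
    target = ct[(ct["gene_id"] == gene_id) & (ct["condition"] == condition)]["ct"]
    if target.empty:
        raise NormalizationError(f"gene {gene_id!r} missing in condition {condition!r}")
    return float(target.mean() - ref.mean())


def ddct_log2_fc(ct: pd.DataFrame, gene_id: str) -> float:
    """log2 fold change of one gene by delta-delta-Ct (means over replicates)."""
    ddct = _dct(ct, gene_id, "treated") - _dct(ct, gene_id, "control")
    return -ddct


def qpcr_log2_fc_table(ct: pd.DataFrame) -> pd.DataFrame:
    """delta-delta-Ct log2 fold changes for every non-reference gene."""
    genes = ct.loc[~ct["is_reference"], "gene_id"].unique()
    return pd.DataFrame(
        {
            "gene_id": genes,
            "qpcr_log2_fc": [ddct_log2_fc(ct, g) for g in genes],
        }
    )


def validate_gene(
    array_log2_fc: float,
    qpcr_log2_fc: float,
    min_magnitude: float = DEFAULT_MIN_MAGNITUDE,
) -> bool:
    """Same direction on both platforms and a qPCR magnitude above the floor."""
    if not (np.isfinite(array_log2_fc) and np.isfinite(qpcr_log2_fc)):
        raise DegenerateInputError("fold changes must be finite")
    return bool(
        np.sign(array_log2_fc) == np.sign(qpcr_log2_fc)
        and abs(qpcr_log2_fc) >= min_magnitude
    )


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateInputError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class ConcordanceReport:
    per_gene: pd.DataFrame  # gene_id, array_log2_fc, qpcr_log2_fc, validated
    n_tested: int
    n_validated: int
    pearson_all: float | None
    pearson_all_p: float | None
    pearson_validated: float | None
    pearson_validated_p: float | None

    @property
    def validation_rate(self) -> float:
        return self.n_validated / self.n_tested if self.n_tested else float("nan")

    def summary(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_validated": self.n_validated,
            "validation_rate": self.validation_rate,
            "pearson_all": self.pearson_all,
            "pearson_all_p": self.pearson_all_p,
            "pearson_validated": self.pearson_validated,
            "pearson_validated_p": self.pearson_validated_p,
        }


def _maybe_pearson(x, y) -> tuple[float | None, float | None]:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None, None  # undefined below n=3; reported as missing
    return pearson(x, y)


def concordance(
    array_fc: pd.DataFrame,
    qpcr_fc: pd.DataFrame,
    min_magnitude: float = DEFAULT_MIN_MAGNITUDE,
) -> ConcordanceReport:
    """Join per-gene fold changes from both platforms and score agreement.

    ``array_fc`` needs gene_id + array_log2_fc (or gene_log2_fc);
    ``qpcr_fc`` needs gene_id + qpcr_log2_fc. Only genes present on both
    platforms are tested.
    """
    a = array_fc.rename(columns={"gene_log2_fc": "array_log2_fc"})[
        ["gene_id", "array_log2_fc"]
    ]
    merged = a.merge(qpcr_fc[["gene_id", "qpcr_log2_fc"]], on="gene_id")
    merged["validated"] = [
        validate_gene(r.array_log2_fc, r.qpcr_log2_fc, min_magnitude)
        for r in merged.itertuples()
    ]
    val = merged[merged["validated"]]
    r_all, p_all = _maybe_pearson(merged["array_log2_fc"], merged["qpcr_log2_fc"])
    r_val, p_val = _maybe_pearson(val["array_log2_fc"], val["qpcr_log2_fc"])
    return ConcordanceReport(
        per_gene=merged,
        n_tested=len(merged),
        n_validated=int(merged["validated"].sum()),
        pearson_all=r_all,
        pearson_all_p=p_all,
        pearson_validated=r_val,
        pearson_validated_p=p_val,
    )
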