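"""Gene-level differential-expression tiering and blood-signature selection.

Consumes Cuffdiff-style gene statistics tables (gene id, FPKM in case and
control, log2 fold change case/control, p, q).  Three operations:

* three-tier grouping — strict (p < 5e-5, |log2FC| > 2), moderate
  (p < 0.05, |log2FC| > 2, not strict), unchanged (everything else);
* blood-signature selection — genes over-expressed in patient blood with
  a minimum absolute expression (FPKM > 5 in cases), significance and
  fold-change gate;
* Venn arithmetic between the tissue and blood differential gene sets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

STRICT_P = 5e-5
DEFAULT_ALPHA = 0.05
MIN_ABS_LOG2FC = 2.0

TIERS = ("strict", "moderate", "unchanged")

REQUIRED_COLUMNS = ("gene_id", "log2fc", "p")


@dataclass(frozen=True)
class SignatureConfig:
    """Gates for the blood-signature filter (up-regulated genes only)."""

    min_fpkm: float = 5.0
    min_log2fc: float = MIN_ABS_LOG2FC
    alpha: float = DEFAULT_ALPHA
    use_q: bool = False  # gate on q (FDR) instead of p when True

    def __post_init__(self) -> None:
        if min(self.min_fpkm, self.min_log2fc, self.alpha) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class VennCounts:
    tissue_only: int
    blood_only: int
    shared: int

    @property
    def tissue_total(self) -> int:
        return self.tissue_only + self.shared

    @property
    def blood_total(self) -> int:
        return self.blood_only + self.shared


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"gene table lacks columns: {missing}")
    bad = table["p"].isna() | table["log2fc"].isna()
    if bad.any():
        logger.warning("rejected %d rows with missing p or log2fc", int(bad.sum()))
    return table[~bad]


def tier_genes(
    table: pd.DataFrame,
    strict_p: float = STRICT_P,
    alpha: float = DEFAULT_ALPHA,
    min_abs_log2fc: float = MIN_ABS_LOG2FC,
) -> pd.Series:
    """Partition genes into strict / moderate / unchanged tiers.

    Returns a Series indexed by gene_id.  Every gene lands in exactly one
    tier; rows missing p or log2fc are dropped with a logged count.
    """
    t = _validate(table)
    big_fc = t["log2fc"].abs() > min_abs_log2fc
    strict = (t["p"] < strict_p) & big_fc
    moderate = (t["p"] < alpha) & big_fc & ~strict
    tier = pd.Series("unchanged", index=t["gene_id"].to_numpy(), name="tier")
    tier[strict.to_numpy()] = "strict"
    tier[moderate.to_numpy()] = "moderate"
    return tier


def de_genes(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_abs_log2fc: float = MIN_ABS_LOG2FC,
) -> set[str]:
    """Differentially expressed genes: p < alpha and |log2FC| > threshold.

    This is the union of the strict and moderate tiers and defines the
    per-compartment sets entering the Venn arithmetic.
    """
    tier = tier_genes(table, alpha=alpha, min_abs_log2fc=min_abs_log2fc)
    return set(tier.index[tier != "unchanged"])


def select_blood_signature(
    blood: pd.DataFrame,
    cfg: SignatureConfig | None = None,
) -> list[str]:
    """Genes over-expressed in patient blood passing all three gates.

    A gene qualifies when fpkm_case > min_fpkm, its significance value
    (p, or q when ``cfg.use_q``) is below alpha, and log2fc > min_log2fc
    (up-regulation in tumour vs control only).  Returns a sorted gene list.
    """
    cfg = cfg or SignatureConfig()
    t = _validate(blood)
    if "fpkm_case" not in t.columns:
        raise ValueError("gene table lacks columns: ['fpkm_case']")
    sig_col = "q" if cfg.use_q else "p"
    keep = (
        (t["fpkm_case"] > cfg.min_fpkm)
        & (t[sig_col] < cfg.alpha)
        & (t["log2fc"] > cfg.min_log2fc)
    )
    return sorted(t.loc[keep, "gene_id"])


def venn_counts(tissue_set: Iterable[str], blood_set: Iterable[str]) -> VennCounts:
    """Exclusive and shared counts of the tissue and blood DE gene sets."""
    tissue = set(tissue_set)
    blood = set(blood_set)
    shared = len(tissue & blood)
    return VennCounts(
        tissue_only=len(tissue) - shared,
        blood_only=len(blood) - shared,
        shared=shared,
    )
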