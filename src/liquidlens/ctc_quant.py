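"""Circulating-tumour-cell (CTC) enumeration statistics.

Events exported from an imaging flow cytometer arrive as per-event feature
tables: AF488 (pan-cytokeratin, epithelial marker), CD45 (leukocyte
marker), DRAQ5 (nuclear stain) intensities plus a pixel area.  A CTC is an
event positive for AF488, negative for CD45 and positive for DRAQ5.
Counts are normalised per 10,000 captured cells; spike-in recovery, pixel
to µm² conversion, ROC/AUC over per-sample counts, and the one-way
ANOVA + Tukey group comparison round out the module.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from statsmodels.stats.multicomp import pairwise_tukeyhsd

#: ImageStream pixel scale: 1 pixel = 0.25 µm².
UM2_PER_PIXEL = 0.25

EVENT_COLUMNS = ("i_af488", "i_cd45", "i_draq5", "area_px")


@dataclass(frozen=True)
class GateConfig:
    """Intensity gates defining CTC positivity.

    Numeric defaults are calibrated to the synthetic event generator's
    planted populations (separated by well over 4 SDs); real instruments
    need instrument- and panel-specific values.  CD45-"negative" means
    intensity <= t_cd45 (inclusive), so the rule partitions events.  An
    optional area filter (µm²) is off by default.
    """

    t_af488: float = 300.0
    t_cd45: float = 300.0
    t_draq5: float = 200.0
    min_area_um2: float | None = None
    max_area_um2: float | None = None

    def __post_init__(self) -> None:
        if min(self.t_af488, self.t_cd45, self.t_draq5) < 0:
            raise ValueError("gate thresholds must be non-negative")


@dataclass(frozen=True)
class CTCCountResult:
    n_ctc: int
    n_captured: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_ctc <= self.n_captured:
            raise ValueError("need 0 <= n_ctc <= n_captured")

    @property
    def per_10k(self) -> float:
        return per_10k(self.n_ctc, self.n_captured)


@dataclass(frozen=True)
class RecoveryResult:
    spiked: int
    retrieved: int

    @property
    def percent(self) -> float:
        return 100.0 * self.retrieved / self.spiked


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class GroupTestResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


def classify_events(
    table: pd.DataFrame,
    gates: GateConfig | None = None,
    n_captured: int | None = None,
) -> tuple[pd.Series, CTCCountResult]:
    """Apply the positivity rule AF488+ / CD45- / DRAQ5+ to each event.

    Returns the per-event boolean flags and the count result.  The rule is
    a pure function of each row.  ``n_captured`` defaults to the number of
    rows (each row one captured event).
    """
    gates = gates or GateConfig()
    missing = [c for c in EVENT_COLUMNS[:3] if c not in table.columns]
    if missing:
        raise ValueError(f"event table lacks columns: {missing}")
    n_captured = len(table) if n_captured is None else n_captured
    if n_captured == 0:
        raise ValueError("n_captured must be positive")
    if n_captured < len(table):
        raise ValueError("n_captured is smaller than the number of events")
    flags = (
        (table["i_af488"] > gates.t_af488)
        & (table["i_cd45"] <= gates.t_cd45)
        & (table["i_draq5"] > gates.t_draq5)
    )
    if gates.min_area_um2 is not None or gates.max_area_um2 is not None:
        area = pixels_to_area(table["area_px"].to_numpy())
        if gates.min_area_um2 is not None:
            flags &= area >= gates.min_area_um2
        if gates.max_area_um2 is not None:
            flags &= area <= gates.max_area_um2
    return flags, CTCCountResult(n_ctc=int(flags.sum()), n_captured=n_captured)


def per_10k(n_ctc: int, n_captured: int) -> float:
    """CTCs per 10,000 captured cells."""
    if n_captured <= 0:
        raise ZeroDivisionError("n_captured must be positive")
    return 10000.0 * n_ctc / n_captured


def recovery_percent(retrieved: int, spiked: int) -> RecoveryResult:
    """Spike-in recovery: percentage of added cells the pipeline retrieves."""
    if spiked <= 0:
        raise ValueError("spiked must be positive")
    if retrieved > spiked:
        warnings.warn(
            "retrieved exceeds spiked (possible double counting)",
            stacklevel=2,
        )
    return RecoveryResult(spiked=spiked, retrieved=retrieved)


def pixels_to_area(area_px):
    """Convert a pixel area to µm² (1 pixel = 0.25 µm²)."""
    area_px = np.asarray(area_px, dtype=float)
    if np.any(area_px < 0):
        raise ValueError("pixel areas must be non-negative")
    out = UM2_PER_PIXEL * area_px
    return float(out) if out.ndim == 0 else out


def roc_auc(values: Sequence[float], labels: Sequence) -> ROCResult:
    """ROC over a threshold sweep of per-sample values; AUC by trapezoid.

    ``labels`` are truthy for the positive (cancer) class.  Ties are
    handled by the sweep over unique values, making the AUC equal to the
    Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    y = np.asarray([bool(l) for l in labels])
    v = np.asarray(values, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(y, v)
    return ROCResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
    )


def group_test(
    values_by_group: Mapping[str, Sequence[float]],
    method: str = "anova",
) -> GroupTestResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons across groups.

    ``method="mannwhitney"`` substitutes a two-group Mann-Whitney U test
    (rank-based; suited to skewed count data); the omnibus ANOVA remains
    the default.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every group needs at least 2 values")

    if method == "mannwhitney":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney applies to exactly 2 groups")
        (ka, va), (kb, vb) = groups.items()
        u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        tukey = pd.DataFrame(
            [{"group1": ka, "group2": kb,
              "meandiff": float(vb.mean() - va.mean()),
              "p_adj": float(p), "reject": bool(p < 0.05)}]
        )
        return GroupTestResult(f_statistic=float(u), p_value=float(p),
                               tukey=tukey)
    if method != "anova":
        raise ValueError(f"unknown method {method!r}")

    f, p = stats.f_oneway(*groups.values())
    flat = np.concatenate(list(groups.values()))
    labels = np.concatenate(
        [np.full(len(v), k, dtype=object) for k, v in groups.items()]
    )
    hsd = pairwise_tukeyhsd(flat, labels)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=hsd.summary().data[0]
    )[["group1", "group2", "meandiff", "p-adj", "reject"]].rename(
        columns={"p-adj": "p_adj"}
    )
    return GroupTestResult(f_statistic=float(f), p_value=float(p), tukey=tukey)
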