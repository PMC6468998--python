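"""Seeded synthetic-data generators for every analysis stage.

Each generator is a pure function of its parameter object (which carries
the seed): identical parameters give identical outputs.  Ground-truth
labels are returned alongside every dataset and are never consumed by the
analysis code.

The defaults encode the study design the analyses assume: a 701-window
genome at a 133-sample normal reference panel for cfDNA; a 20-cancer /
10-control participant hierarchy with 3 drops x 2 maps per participant for
Raman; spike-in style event tables for CTC counting; and expression tables
with 293 tissue- and 356 blood-DE genes sharing 21, of which 18 blood
genes qualify for the signature filter.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ctc_quant import GateConfig
from .genome_cni import (
    GenomeWindows,
    WindowCounts,
    load_packaged_chrom_sizes,
    partition_genome,
)
from .raman_classify import CANCER, CONTROL, SpectralDataset, Spectrum

# ---------------------------------------------------------------------------
# cfDNA read-count profiles


@dataclass(frozen=True)
class Aberration:
    """A contiguous run of windows at a tumour copy ratio (2 copies = 1.0)."""

    start_window: int
    end_window: int  # exclusive
    copy_ratio: float

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ValueError("copy_ratio must be positive")
        if self.end_window <= self.start_window:
            raise ValueError("empty window range")


@dataclass(frozen=True)
class CfdnaSimParams:
    """cfDNA simulation: Poisson counts around length-proportional rates.

    ``depth_reads`` defaults to 1e6 for desk-speed runs; the study-scale
    depth is 30e6.  ``window_noise_sd`` is the per-window, per-sample
    biological SD on the log2 scale (lognormal rate multiplier).  In
    aberrant windows the rate is multiplied by
    ``1 + tumour_fraction * (copy_ratio - 1)``.
    """

    n_windows: int = 701
    depth_reads: float = 1e6
    panel_n: int = 133
    window_noise_sd: float = 0.05
    aberrations: tuple[Aberration, ...] = ()
    tumour_fraction: float = 0.0
    n_samples: int = 1
    include_sex: bool = False
    seed: int = 20190311

    def __post_init__(self) -> None:
        if not 0 <= self.tumour_fraction <= 1:
            raise ValueError("tumour_fraction must lie in [0, 1]")
        if self.depth_reads <= 0:
            raise ValueError("depth_reads must be positive")


@dataclass(frozen=True)
class CfdnaSim:
    windows: GenomeWindows
    panel: list[WindowCounts]
    samples: list[WindowCounts]
    truth: pd.DataFrame  # window, copy_ratio, rate_multiplier


def aberration_rate_multiplier(params: CfdnaSimParams) -> np.ndarray:
    """Per-window expected-rate multiplier implied by the implanted CNAs."""
    mult = np.ones(params.n_windows)
    for ab in params.aberrations:
        mult[ab.start_window:ab.end_window] = (
            1 + params.tumour_fraction * (ab.copy_ratio - 1)
        )
    return mult


def _draw_counts(
    rng: np.random.Generator,
    base_rate: np.ndarray,
    mult: np.ndarray,
    params: CfdnaSimParams,
    sample_id: str,
    wsid: str,
) -> WindowCounts:
    noise = 2.0 ** rng.normal(0.0, params.window_noise_sd, len(base_rate))
    rate = base_rate * noise * mult
    lam = params.depth_reads * rate / rate.sum()
    return WindowCounts(
        sample_id=sample_id,
        counts=rng.poisson(lam).astype(np.int64),
        window_set_id=wsid,
    )


def gen_cfdna(params: CfdnaSimParams) -> CfdnaSim:
    """Simulate a normal reference panel plus tumour (or null) samples."""
    rng = np.random.default_rng(params.seed)
    windows = partition_genome(
        load_packaged_chrom_sizes(),
        n_windows=params.n_windows,
        include_sex=params.include_sex,
    )
    base = windows.lengths.astype(float)
    flat = np.ones(params.n_windows)
    mult = aberration_rate_multiplier(params)
    panel = [
        _draw_counts(rng, base, flat, params, f"panel{i:03d}",
                     windows.window_set_id)
        for i in range(params.panel_n)
    ]
    samples = [
        _draw_counts(rng, base, mult, params, f"sample{i:03d}",
                     windows.window_set_id)
        for i in range(params.n_samples)
    ]
    cr = np.ones(params.n_windows)
    for ab in params.aberrations:
        cr[ab.start_window:ab.end_window] = ab.copy_ratio
    truth = pd.DataFrame(
        {"window": np.arange(params.n_windows), "copy_ratio": cr,
         "rate_multiplier": mult}
    )
    return CfdnaSim(windows=windows, panel=panel, samples=samples, truth=truth)


def expected_counts(params: CfdnaSimParams, sample_id: str = "expectation") -> WindowCounts:
    """Noise-free expectation profile of a tumour sample (rounded Poisson means)."""
    windows = partition_genome(
        load_packaged_chrom_sizes(),
        n_windows=params.n_windows,
        include_sex=params.include_sex,
    )
    rate = windows.lengths * aberration_rate_multiplier(params)
    lam = params.depth_reads * rate / rate.sum()
    return WindowCounts(
        sample_id=sample_id,
        counts=np.round(lam).astype(np.int64),
        window_set_id=windows.window_set_id,
    )


# ---------------------------------------------------------------------------
# Raman spectra

#: Canonical carotenoid Raman bands (cm^-1); fixture constants.
CAROTENOID_BANDS = (1008.0, 1158.0, 1524.0)

# (centre cm^-1, sigma cm^-1, amplitude) of the fixed biological peak set
_BIO_PEAKS = (
    (621, 6, 0.20), (643, 6, 0.15), (760, 7, 0.25), (830, 8, 0.30),
    (852, 8, 0.35), (940, 10, 0.30), (1003, 5, 0.90), (1031, 7, 0.35),
    (1080, 10, 0.40), (1208, 9, 0.25), (1250, 12, 0.50), (1320, 10, 0.30),
    (1340, 10, 0.30), (1450, 12, 0.80), (1550, 10, 0.20), (1660, 14, 0.90),
)
_CAROTENOID_PEAKS = ((1008.0, 6, 0.50), (1158.0, 7, 0.90), (1524.0, 8, 1.00))


@dataclass(frozen=True)
class RamanSimParams:
    """Synthetic dried-plasma Raman maps with class-dependent carotenoid loss.

    Cancer spectra carry carotenoid band amplitudes multiplied by
    ``1 - depletion_effect``.  ``participant_sd`` is the per-participant,
    per-band fractional amplitude jitter (shared by all six of a
    participant's spectra, which is what makes participant-level
    cross-validation meaningful); ``map_noise_sd`` is additive white noise
    per spectrum.
    """

    n_cancer_participants: int = 20
    n_control_participants: int = 10
    drops_per_participant: int = 3
    maps_per_drop: int = 2
    wavenumber_start: float = 600.0
    wavenumber_stop: float = 1800.0
    n_points: int = 601
    band_centres: tuple[float, ...] = CAROTENOID_BANDS
    depletion_effect: float = 0.30
    participant_sd: float = 0.08
    drop_sd: float = 0.03
    map_noise_sd: float = 0.02
    baseline_amplitude: float = 2.0
    seed: int = 830

    def __post_init__(self) -> None:
        if not 0 <= self.depletion_effect <= 1:
            raise ValueError("depletion_effect must lie in [0, 1]")


def _gaussian(x: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - centre) / sigma) ** 2)


def gen_raman(params: RamanSimParams) -> tuple[SpectralDataset, pd.DataFrame]:
    """Generate map-average spectra following the participant/drop/map design.

    Returns the dataset plus a truth table of per-participant class and
    carotenoid band scales.
    """
    rng = np.random.default_rng(params.seed)
    x = np.linspace(params.wavenumber_start, params.wavenumber_stop,
                    params.n_points)
    bio = sum(a * _gaussian(x, c, s) for c, s, a in _BIO_PEAKS)

    spectra: list[Spectrum] = []
    truth_rows = []
    design = [(f"LC{i:02d}", CANCER) for i in range(params.n_cancer_participants)]
    design += [(f"CT{i:02d}", CONTROL) for i in range(params.n_control_participants)]
    for pid, label in design:
        depletion = params.depletion_effect if label == CANCER else 0.0
        band_scale = (1 - depletion) * (
            1 + rng.normal(0.0, params.participant_sd, len(_CAROTENOID_PEAKS))
        )
        band_scale = np.clip(band_scale, 0.05, None)
        protein_scale = 1 + rng.normal(0.0, 0.05)
        carot = sum(
            sc * a * _gaussian(x, c, s)
            for sc, (c, s, a) in zip(band_scale, _CAROTENOID_PEAKS)
        )
        clean = protein_scale * bio + carot
        truth_rows.append(
            {"participant": pid, "class": label,
             **{f"band_{int(c)}": sc
                for sc, (c, _, _) in zip(band_scale, _CAROTENOID_PEAKS)}}
        )
        for drop in range(params.drops_per_participant):
            drop_scale = 1 + rng.normal(0.0, params.drop_sd)
            for map_i in range(params.maps_per_drop):
                baseline = (
                    params.baseline_amplitude * (0.5 + rng.uniform())
                    * np.exp(-(x - x[0]) / 900.0)
                    + 0.5
                )
                y = (
                    drop_scale * clean
                    + baseline
                    + rng.normal(0.0, params.map_noise_sd, len(x))
                )
                spectra.append(
                    Spectrum(
                        wavenumbers=x,
                        intensities=y,
                        participant_id=pid,
                        class_label=label,
                        drop_index=drop,
                        map_index=map_i,
                    )
                )
    dataset = SpectralDataset(
        spectra=spectra,
        design={
            "n_cancer_participants": params.n_cancer_participants,
            "n_control_participants": params.n_control_participants,
            "drops_per_participant": params.drops_per_participant,
            "maps_per_drop": params.maps_per_drop,
        },
    )
    return dataset, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Cytometry event tables


@dataclass(frozen=True)
class ChannelStats:
    mean: float
    sd: float


@dataclass(frozen=True)
class EventSimParams:
    """Planted CTC-like events among a leukocyte background.

    Default populations are separated from the default gates by well over
    4 SDs in every discriminating channel, so classification of planted
    events is essentially deterministic.
    """

    n_captured: int = 10000
    n_planted_ctc: int = 7
    ctc_af488: ChannelStats = field(default_factory=lambda: ChannelStats(800, 100))
    ctc_cd45: ChannelStats = field(default_factory=lambda: ChannelStats(50, 30))
    ctc_draq5: ChannelStats = field(default_factory=lambda: ChannelStats(700, 100))
    bg_af488: ChannelStats = field(default_factory=lambda: ChannelStats(50, 30))
    bg_cd45: ChannelStats = field(default_factory=lambda: ChannelStats(900, 120))
    bg_draq5: ChannelStats = field(default_factory=lambda: ChannelStats(600, 100))
    ctc_area_px: ChannelStats = field(default_factory=lambda: ChannelStats(2400, 600))
    bg_area_px: ChannelStats = field(default_factory=lambda: ChannelStats(300, 80))
    seed: int = 4881

    def __post_init__(self) -> None:
        if self.n_planted_ctc > self.n_captured:
            raise ValueError("cannot plant more CTCs than captured events")


def default_gates() -> GateConfig:
    """Gates separating the default planted populations (fixture values)."""
    return GateConfig(t_af488=300.0, t_cd45=300.0, t_draq5=200.0)


def gen_events(params: EventSimParams) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate one per-event feature table plus boolean truth flags."""
    rng = np.random.default_rng(params.seed)
    n_bg = params.n_captured - params.n_planted_ctc
    truth = np.zeros(params.n_captured, dtype=bool)
    truth[:params.n_planted_ctc] = True

    def draw(stats_ctc: ChannelStats, stats_bg: ChannelStats) -> np.ndarray:
        vals = np.concatenate(
            [
                rng.normal(stats_ctc.mean, stats_ctc.sd, params.n_planted_ctc),
                rng.normal(stats_bg.mean, stats_bg.sd, n_bg),
            ]
        )
        return np.clip(vals, 0.0, None)

    table = pd.DataFrame(
        {
            "event_id": [f"ev{i:06d}" for i in range(params.n_captured)],
            "i_af488": draw(params.ctc_af488, params.bg_af488),
            "i_cd45": draw(params.ctc_cd45, params.bg_cd45),
            "i_draq5": draw(params.ctc_draq5, params.bg_draq5),
            "area_px": draw(params.ctc_area_px, params.bg_area_px),
        }
    )
    # shuffle so planted events are not positionally identifiable
    order = rng.permutation(params.n_captured)
    table = table.iloc[order].reset_index(drop=True)
    return table, truth[order]


# ---------------------------------------------------------------------------
# Expression tables


@dataclass(frozen=True)
class ExprSimParams:
    """Gene statistics tables with planted DE structure.

    Defaults mirror the study arithmetic: 356 blood-DE and 293 tissue-DE
    genes sharing 21, with 18 blood genes passing every signature gate
    (FPKM > 5 in cases, p < 0.05, log2FC > 2).  Other blood-DE genes are
    constructed to fail at least one signature gate; null genes fail the
    DE definition itself.
    """

    n_genes: int = 2000
    n_signature: int = 18
    n_shared: int = 21
    blood_de_total: int = 356
    tissue_de_total: int = 293
    seed: int = 331

    def __post_init__(self) -> None:
        if self.n_signature + self.n_shared > self.blood_de_total:
            raise ValueError("blood DE total too small for planted sets")
        if self.n_shared > self.tissue_de_total:
            raise ValueError("tissue DE total too small for shared set")
        if self.blood_de_total > self.n_genes or self.tissue_de_total > self.n_genes:
            raise ValueError("n_genes too small for the DE sets")


@dataclass(frozen=True)
class ExprSim:
    blood: pd.DataFrame
    tissue: pd.DataFrame
    signature_genes: list[str]
    shared_genes: list[str]
    blood_de: set[str]
    tissue_de: set[str]


def _de_rows(rng, gene_ids, up: bool, fpkm_lo: float, fpkm_hi: float):
    rows = []
    for g in gene_ids:
        lfc = rng.uniform(2.5, 6.0)
        if not up:
            lfc = -lfc
        p = 10.0 ** rng.uniform(-8, np.log10(0.04))
        fpkm_case = rng.uniform(fpkm_lo, fpkm_hi)
        fpkm_control = fpkm_case / 2.0 ** lfc
        rows.append((g, fpkm_case, fpkm_control, lfc, p, min(1.0, p * 3)))
    return rows


def _null_rows(rng, gene_ids):
    rows = []
    for g in gene_ids:
        lfc = float(np.clip(rng.normal(0.0, 0.5), -1.9, 1.9))
        p = rng.uniform(0.0, 1.0)
        fpkm_case = rng.uniform(0.1, 200.0)
        rows.append((g, fpkm_case, fpkm_case / 2.0 ** lfc, lfc, p,
                     min(1.0, p * 1.5)))
    return rows


_COLS = ["gene_id", "fpkm_case", "fpkm_control", "log2fc", "p", "q"]


def gen_expression(params: ExprSimParams) -> ExprSim:
    """Generate blood and tissue gene tables plus the planted truth sets."""
    rng = np.random.default_rng(params.seed)

    shared = [f"SHARED{i:04d}" for i in range(params.n_shared)]
    signature = [f"SIG{i:04d}" for i in range(params.n_signature)]
    n_blood_other = params.blood_de_total - params.n_shared - params.n_signature
    n_blood_lowfpkm = n_blood_other // 3
    blood_other_down = [f"BDN{i:04d}" for i in range(n_blood_other - n_blood_lowfpkm)]
    blood_other_low = [f"BLF{i:04d}" for i in range(n_blood_lowfpkm)]
    n_tissue_only = params.tissue_de_total - params.n_shared
    tissue_only = [f"TDE{i:04d}" for i in range(n_tissue_only)]

    # blood table ----------------------------------------------------------
    blood_rows = []
    blood_rows += _de_rows(rng, signature, up=True, fpkm_lo=8.0, fpkm_hi=200.0)
    blood_rows += _de_rows(rng, shared, up=False, fpkm_lo=1.0, fpkm_hi=100.0)
    blood_rows += _de_rows(rng, blood_other_down, up=False, fpkm_lo=0.5,
                           fpkm_hi=150.0)
    blood_rows += _de_rows(rng, blood_other_low, up=True, fpkm_lo=0.2,
                           fpkm_hi=4.9)
    n_null_blood = params.n_genes - len(blood_rows)
    blood_rows += _null_rows(rng, [f"BNULL{i:04d}" for i in range(n_null_blood)])
    blood = pd.DataFrame(blood_rows, columns=_COLS)

    # tissue table ---------------------------------------------------------
    tissue_rows = []
    tissue_rows += _de_rows(rng, shared, up=False, fpkm_lo=1.0, fpkm_hi=100.0)
    tissue_rows += _de_rows(rng, tissue_only, up=False, fpkm_lo=0.5,
                            fpkm_hi=150.0)
    n_null_tissue = params.n_genes - len(tissue_rows)
    tissue_rows += _null_rows(rng, [f"TNULL{i:04d}" for i in range(n_null_tissue)])
    tissue = pd.DataFrame(tissue_rows, columns=_COLS)

    blood_de = set(signature) | set(shared) | set(blood_other_down) | set(blood_other_low)
    tissue_de = set(shared) | set(tissue_only)
    return ExprSim(
        blood=blood.sample(frac=1.0, random_state=int(rng.integers(2**31))
                           ).reset_index(drop=True),
        tissue=tissue.sample(frac=1.0, random_state=int(rng.integers(2**31))
                             ).reset_index(drop=True),
        signature_genes=sorted(signature),
        shared_genes=sorted(shared),
        blood_de=blood_de,
        tissue_de=tissue_de,
    )
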