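"""Raman plasma-spectrum classification: preprocessing + PCA-LDA with
leave-one-participant-out cross-validation.

Dried plasma drops yield Raman maps; each map is averaged to one spectrum.
Spectra are baseline-subtracted (fluorescence background), normalised by
the standard normal variate (SNV) transform, reduced by PCA, and classified
by a Fisher linear discriminant on the PC scores.  Cross-validation leaves
all spectra of one participant out per fold so that within-participant
correlation cannot leak into the model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve
from sklearn.decomposition import PCA

CANCER, CONTROL = "cancer", "control"

#: Grid mismatch below this (cm^-1) is bridged by linear interpolation.
AXIS_TOLERANCE = 1.0


@dataclass(frozen=True)
class Spectrum:
    """One spectrum (typically a map average) on an ascending wavenumber axis."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    participant_id: str = ""
    class_label: str = ""
    drop_index: int = 0
    map_index: int = 0

    def __post_init__(self) -> None:
        if len(self.wavenumbers) != len(self.intensities):
            raise ValueError("axis and intensity lengths differ")
        if len(self.wavenumbers) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(y, dtype=float))


@dataclass(frozen=True)
class SpectralDataset:
    """Spectra on a common axis with the participant/drop/map design."""

    spectra: list[Spectrum]
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        axis = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if len(s.wavenumbers) != len(axis) or not np.allclose(
                s.wavenumbers, axis
            ):
                raise ValueError("spectra do not share a common axis")

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.participant_id)
        return list(seen)

    def by_class(self, label: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.class_label == label]


@dataclass(frozen=True)
class PreprocessConfig:
    baseline: Literal["als", "poly", "none"] = "als"
    als_lam: float = 1e5
    als_p: float = 0.01
    als_n_iter: int = 10
    poly_order: int = 5
    snv: bool = True


@dataclass(frozen=True)
class PCAModel:
    mean: np.ndarray
    components: np.ndarray          # (k, n_points), orthonormal rows
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.mean) @ self.components.T


@dataclass(frozen=True)
class LDAModel:
    """Fisher discriminant: project on w, threshold at the class-mean midpoint.

    A score strictly above the threshold predicts cancer; a score exactly
    at the threshold predicts control (conservative tie-break).
    """

    w: np.ndarray
    threshold: float

    def decision(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(scores) @ self.w

    def predict(self, scores: np.ndarray) -> np.ndarray:
        d = self.decision(scores)
        return np.where(d > self.threshold, CANCER, CONTROL)


@dataclass(frozen=True)
class ClassifierResult:
    predictions: pd.DataFrame       # participant, class, drop, map, predicted
    confusion: np.ndarray           # rows true (cancer, control), cols predicted
    sensitivity: float
    specificity: float
    n_folds: int
    pc_count_per_fold: list[int]
    fold_weights: dict[str, np.ndarray]
    skipped_participants: list[str] = field(default_factory=list)


def _common_axis(spectra: Sequence[Spectrum]) -> list[Spectrum]:
    """Interpolate onto the first spectrum's axis if grids differ by < 1 cm^-1."""
    axis = spectra[0].wavenumbers
    out = []
    for s in spectra:
        if len(s.wavenumbers) == len(axis) and np.allclose(s.wavenumbers, axis):
            out.append(s)
            continue
        if (
            len(s.wavenumbers) != len(axis)
            or np.max(np.abs(s.wavenumbers - axis)) >= AXIS_TOLERANCE
        ):
            raise ValueError("wavenumber axes differ by more than 1 cm^-1")
        y = np.interp(axis, s.wavenumbers, s.intensities)
        out.append(replace(s, wavenumbers=axis, intensities=y))
    return out


def average_map(map_spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of the spectra of one Raman map; metadata inherited."""
    if not map_spectra:
        raise ValueError("cannot average zero spectra")
    spectra = _common_axis(list(map_spectra))
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return spectra[0].with_intensities(mean)


def als_baseline(
    y: np.ndarray, lam: float = 1e5, p: float = 0.01, n_iter: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares baseline (Eilers & Boelens style).

    Minimises sum(w_i (y_i - b_i)^2) + lam * sum((Δ²b)²) with asymmetric
    weights p above / 1-p below the baseline, iterated to convergence.
    Suited to the broad fluorescence background of NIR-excited biofluids.
    """
    n = len(y)
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    b = y
    for _ in range(n_iter):
        W = sparse.diags(w)
        b = spsolve((W + dtd).tocsc(), w * y)
        w_new = np.where(y > b, p, 1 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return b


def subtract_baseline(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Remove the smooth background; peak positions are unchanged."""
    cfg = cfg or PreprocessConfig()
    y = s.intensities
    if cfg.baseline == "none":
        return s
    if cfg.baseline == "als":
        if len(y) < 4:
            raise ValueError("too few points for the ALS baseline")
        base = als_baseline(y, cfg.als_lam, cfg.als_p, cfg.als_n_iter)
    elif cfg.baseline == "poly":
        if len(y) <= cfg.poly_order:
            raise ValueError("too few points for the polynomial order")
        x = s.wavenumbers
        coef = np.polynomial.polynomial.polyfit(x, y, cfg.poly_order)
        base = np.polynomial.polynomial.polyval(x, coef)
    else:
        raise ValueError(f"unknown baseline method {cfg.baseline!r}")
    return s.with_intensities(y - base)


def snv_normalize(s: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum (x - mean) / SD."""
    y = s.intensities
    sd = y.std()
    if sd == 0:
        raise ValueError("SNV is undefined for a constant spectrum")
    return s.with_intensities((y - y.mean()) / sd)


def preprocess(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    cfg = cfg or PreprocessConfig()
    out = subtract_baseline(s, cfg)
    if cfg.snv:
        out = snv_normalize(out)
    return out


def difference_spectrum(
    group_a: Sequence[Spectrum], group_b: Sequence[Spectrum]
) -> Spectrum:
    """mean(group_a) - mean(group_b), pointwise on the common axis."""
    ma = average_map(group_a)
    mb = average_map(group_b)
    if not np.allclose(ma.wavenumbers, mb.wavenumbers):
        raise ValueError("groups are not on a common axis")
    return ma.with_intensities(ma.intensities - mb.intensities)


def fit_pca(
    train: Sequence[Spectrum],
    k: int | None = None,
    variance_fraction: float = 0.95,
    max_k: int = 20,
) -> PCAModel:
    """PCA of the training spectra.

    ``k`` fixes the component count; otherwise the smallest count
    explaining at least ``variance_fraction`` of the training variance is
    used, capped at ``max_k``.
    """
    if len(train) < 2:
        raise ValueError("PCA needs at least 2 training spectra")
    X = np.vstack([s.intensities for s in train])
    if np.allclose(X, X[0]):
        raise ValueError("degenerate (rank-0) training data")
    full = PCA().fit(X)
    if k is None:
        cum = np.cumsum(full.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_fraction) + 1)
        k = min(k, max_k, len(cum))
    return PCAModel(
        mean=full.mean_,
        components=full.components_[:k],
        explained_variance_ratio=full.explained_variance_ratio_[:k],
    )


def fit_lda(
    scores: np.ndarray,
    labels: Sequence[str],
    ridge: float = 1e-6,
) -> LDAModel:
    """Fisher LDA on PC scores: w ∝ Sw^-1 (mu_cancer - mu_control).

    The pooled within-class scatter is regularised by adding
    ``ridge * trace(Sw)/dim`` to its diagonal so small folds stay
    invertible; the decision threshold sits at the midpoint of the
    projected class means.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    classes = set(labels)
    if classes != {CANCER, CONTROL}:
        raise ValueError("both classes (cancer, control) must be present")
    x1 = scores[labels == CANCER]
    x0 = scores[labels == CONTROL]
    mu1, mu0 = x1.mean(axis=0), x0.mean(axis=0)
    c1 = x1 - mu1
    c0 = x0 - mu0
    sw = c1.T @ c1 + c0.T @ c0
    dim = sw.shape[0]
    sw_reg = sw + np.eye(dim) * (ridge * np.trace(sw) / dim + 1e-300)
    w = np.linalg.solve(sw_reg, mu1 - mu0)
    threshold = float(w @ (mu1 + mu0) / 2)
    return LDAModel(w=w, threshold=threshold)


def loocv_by_participant(
    data: SpectralDataset,
    cfg: PreprocessConfig | None = None,
    k: int | None = None,
    variance_fraction: float = 0.95,
    max_k: int = 20,
) -> ClassifierResult:
    """Leave-one-participant-out cross-validation of the PCA-LDA pipeline.

    One fold per participant; each fold fits PCA and LDA on the remaining
    participants only (baseline subtraction and SNV are per-spectrum
    transforms carrying no training statistics), then predicts every
    held-out spectrum.  Sensitivity is the cancer-class recall over all
    per-spectrum predictions, specificity the control-class recall.
    """
    cfg = cfg or PreprocessConfig()
    pre = [preprocess(s, cfg) for s in data.spectra]
    parts = data.participants
    if len(parts) < 3:
        raise ValueError("LOOCV needs at least 3 participants")

    rows = []
    pc_counts: list[int] = []
    fold_weights: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for held in parts:
        train = [s for s in pre if s.participant_id != held]
        test = [s for s in pre if s.participant_id == held]
        train_labels = {s.class_label for s in train}
        if train_labels != {CANCER, CONTROL}:
            warnings.warn(
                f"fold {held!r} skipped: training set lacks a class",
                stacklevel=2,
            )
            skipped.append(held)
            continue
        pca = fit_pca(train, k=k, variance_fraction=variance_fraction,
                      max_k=max_k)
        scores = pca.transform(np.vstack([s.intensities for s in train]))
        lda = fit_lda(scores, [s.class_label for s in train])
        pc_counts.append(pca.k)
        fold_weights[held] = lda.w.copy()
        test_scores = pca.transform(np.vstack([s.intensities for s in test]))
        preds = lda.predict(test_scores)
        for s, p in zip(test, preds):
            rows.append(
                {
                    "participant": s.participant_id,
                    "class": s.class_label,
                    "drop": s.drop_index,
                    "map": s.map_index,
                    "predicted": p,
                }
            )

    predictions = pd.DataFrame(rows)
    confusion = np.zeros((2, 2), dtype=int)
    for true_i, true_lab in enumerate((CANCER, CONTROL)):
        for pred_j, pred_lab in enumerate((CANCER, CONTROL)):
            confusion[true_i, pred_j] = int(
                (
                    (predictions["class"] == true_lab)
                    & (predictions["predicted"] == pred_lab)
                ).sum()
            )
    tp, fn = confusion[0, 0], confusion[0, 1]
    fp, tn = confusion[1, 0], confusion[1, 1]
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    return ClassifierResult(
        predictions=predictions,
        confusion=confusion,
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        n_folds=len(parts) - len(skipped),
        pc_count_per_fold=pc_counts,
        fold_weights=fold_weights,
        skipped_participants=skipped,
    )
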