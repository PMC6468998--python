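"""Copy-number instability (CNI) scoring from binned cfDNA read counts.

Shallow whole-genome sequencing of plasma cell-free DNA is summarised as
read counts in a fixed set of genomic windows tiling the reference.  Counts
are turned into log2 read ratios against the expectation under a flat
genome, standardised into per-window Z values using a reference panel of
normal cfDNA profiles, and windows whose Z exceeds a two-sided threshold at
a small false-positive rate contribute to a single genome-instability
scalar, the CNI score.  A second, panel-free "tissue mode" normalises
counts to the per-sample median and flags gains/losses at a fixed log2
threshold.

Coordinates are 0-based, half-open (BED dialect) throughout.
"""
from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Default two-sided false-positive rate for window rejection (0.2%).
DEFAULT_ALPHA = 0.002
#: Default gain/loss threshold on median-normalised log2 ratios.
TISSUE_LOG2_THRESHOLD = 0.15
#: Pseudocount keeping zero-count windows finite on the log2 scale.
DEFAULT_PSEUDOCOUNT = 0.5
#: Floor applied to per-window panel SD to avoid division blow-ups.
SIGMA_FLOOR = 1e-4

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})

CNI_CONVENTIONS = ("cdf_sum", "abs_z_sum")


def load_packaged_chrom_sizes() -> pd.DataFrame:
    """Return the packaged hg19 chromosome-sizes table (chrom, length)."""
    ref = resources.files("liquidlens.data") / "hg19_chrom_sizes.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", names=["chrom", "length"])


@dataclass(frozen=True)
class GenomeWindows:
    """Ordered, disjoint windows jointly covering every included chromosome.

    ``span_bp`` is the nominal window size (the largest emitted window);
    individual windows, in particular the last window of each chromosome,
    may be shorter.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    span_bp: int

    def __post_init__(self) -> None:
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends must have equal length")
        lengths = self.ends - self.starts
        if np.any(lengths <= 0):
            raise ValueError("every window must satisfy end > start")
        if np.any(lengths > self.span_bp):
            raise ValueError("window longer than nominal span_bp")
        # disjoint, sorted, end-to-end coverage within each chromosome
        for chrom in pd.unique(self.chroms):
            sel = self.chroms == chrom
            s, e = self.starts[sel], self.ends[sel]
            if s[0] != 0 or np.any(s[1:] != e[:-1]):
                raise ValueError(f"windows on {chrom} do not tile from 0")

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.chroms))

    @property
    def window_set_id(self) -> str:
        h = hashlib.md5()
        h.update("|".join(map(str, self.chroms)).encode())
        h.update(np.ascontiguousarray(self.starts, dtype=np.int64).tobytes())
        h.update(np.ascontiguousarray(self.ends, dtype=np.int64).tobytes())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        )


@dataclass(frozen=True)
class WindowCounts:
    """Per-window read counts for one sample, aligned to a window set."""

    sample_id: str
    counts: np.ndarray
    window_set_id: str

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(np.sum(self.counts))


@dataclass(frozen=True)
class Log2RatioProfile:
    sample_id: str
    ratios: np.ndarray
    pseudocount: float
    window_set_id: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.ratios)):
            raise ValueError("log2 ratios must be finite")


@dataclass(frozen=True)
class ReferencePanel:
    """Per-window null mean/SD of log2 ratios from normal cfDNA profiles."""

    n_samples: int
    mu: np.ndarray
    sigma: np.ndarray
    window_set_id: str

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("a reference panel needs at least 2 samples")
        if np.any(self.sigma <= 0):
            raise ValueError("panel sigma must be strictly positive")


@dataclass(frozen=True)
class ZProfile:
    sample_id: str
    z: np.ndarray
    window_set_id: str


@dataclass(frozen=True)
class CNIResult:
    """CNI score plus the rejected-window set and scoring convention."""

    sample_id: str
    cni: float
    alpha: float
    z_critical: float
    rejected: np.ndarray
    convention: str
    panel_n: int | None = None

    def __post_init__(self) -> None:
        if (self.cni == 0) != (len(self.rejected) == 0):
            raise ValueError("cni must be zero iff no window is rejected")


@dataclass(frozen=True)
class TissueCNProfile:
    sample_id: str
    log2_vs_median: np.ndarray
    gain_flags: np.ndarray
    loss_flags: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if np.any(self.gain_flags & self.loss_flags):
            raise ValueError("a window cannot be both gain and loss")


def _apportion(lengths: np.ndarray, n_windows: int) -> np.ndarray:
    """Largest-remainder apportionment of windows across chromosomes."""
    quotas = n_windows * lengths / lengths.sum()
    alloc = np.floor(quotas).astype(int)
    remainder = n_windows - alloc.sum()
    order = np.argsort(-(quotas - alloc), kind="stable")
    alloc[order[:remainder]] += 1
    # every chromosome gets at least one window
    while np.any(alloc == 0):
        alloc[np.argmax(alloc)] -= 1
        alloc[np.argmin(alloc)] += 1
    return alloc


def partition_genome(
    chrom_sizes: Mapping[str, int] | pd.DataFrame,
    *,
    n_windows: int | None = 701,
    span_bp: int | None = None,
    include_sex: bool = False,
) -> GenomeWindows:
    """Tile the genome into ordered, disjoint windows.

    Exactly one of ``n_windows`` / ``span_bp`` must be given.  With
    ``n_windows``, windows are apportioned across chromosomes in proportion
    to length (largest-remainder rule) and each chromosome is tiled with
    equal windows, the last one truncated, so the emitted count equals
    ``n_windows`` exactly.  With ``span_bp``, every chromosome is tiled at
    that span and the count falls out of the arithmetic.

    Sex chromosomes are excluded by default: mixed-sex reference panels
    make X/Y read ratios bimodal.
    """
    if isinstance(chrom_sizes, pd.DataFrame):
        table = dict(zip(chrom_sizes["chrom"], chrom_sizes["length"]))
    else:
        table = dict(chrom_sizes)
    if not include_sex:
        table = {c: l for c, l in table.items() if c not in SEX_CHROMS}
    if not table:
        raise ValueError("chromosome size table is empty")
    if any(l <= 0 for l in table.values()):
        raise ValueError("chromosome lengths must be positive")
    if (n_windows is None) == (span_bp is None):
        raise ValueError("give exactly one of n_windows / span_bp")

    names = list(table)
    lengths = np.array([table[c] for c in names], dtype=np.int64)

    if span_bp is not None:
        if span_bp > lengths.max():
            raise ValueError(
                f"span_bp={span_bp} exceeds the longest chromosome "
                f"({lengths.max()} bp)"
            )
        alloc = np.ceil(lengths / span_bp).astype(int)
    else:
        if n_windows < len(names):
            raise ValueError("n_windows smaller than the chromosome count")
        alloc = _apportion(lengths, n_windows)

    chroms, starts, ends = [], [], []
    for name, length, k in zip(names, lengths, alloc):
        if span_bp is not None:
            edges = np.minimum(
                np.arange(k + 1, dtype=np.int64) * span_bp, length
            )
        else:
            # balanced tiling: k windows of length floor or ceil of L/k
            edges = np.arange(k + 1, dtype=np.int64) * int(length) // k
        chroms.extend([name] * k)
        starts.extend(edges[:-1])
        ends.extend(edges[1:])
    spans = np.ceil(lengths / alloc).astype(np.int64)
    return GenomeWindows(
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        span_bp=int(spans.max()),
    )


def count_reads(
    windows: GenomeWindows,
    fragments: pd.DataFrame | Iterable[tuple],
    sample_id: str = "sample",
) -> WindowCounts:
    """Assign each fragment to the window containing its midpoint.

    ``fragments`` is a DataFrame (or iterable of tuples) with columns
    ``chrom, start, end`` (BED intervals) or ``chrom, midpoint``.
    Fragments on chromosomes outside the window set, and malformed
    intervals (end <= start), are skipped with a logged count.
    """
    if not isinstance(fragments, pd.DataFrame):
        fragments = pd.DataFrame(list(fragments))
        fragments.columns = (
            ["chrom", "start", "end"] if fragments.shape[1] >= 3
            else ["chrom", "midpoint"]
        )
    if "midpoint" in fragments.columns:
        mids = fragments["midpoint"].to_numpy(dtype=np.int64)
        valid = np.ones(len(fragments), dtype=bool)
    else:
        s = fragments["start"].to_numpy(dtype=np.int64)
        e = fragments["end"].to_numpy(dtype=np.int64)
        valid = e > s
        n_bad = int((~valid).sum())
        if n_bad:
            logger.warning("skipped %d malformed intervals (end <= start)", n_bad)
        mids = (s + e) // 2

    counts = np.zeros(windows.n_windows, dtype=np.int64)
    chrom_arr = fragments["chrom"].to_numpy()
    n_off = 0
    for chrom in pd.unique(chrom_arr):
        sel = (chrom_arr == chrom) & valid
        n = int(sel.sum())
        if n == 0:
            continue
        widx = np.flatnonzero(windows.chroms == chrom)
        if len(widx) == 0:
            n_off += n
            continue
        m = mids[sel]
        # windows tile [0, chrom_length); clamp midpoints into range
        pos = np.searchsorted(windows.ends[widx], m, side="right")
        inside = pos < len(widx)
        n_off += int((~inside).sum())
        np.add.at(counts, widx[pos[inside]], 1)
    if n_off:
        logger.warning("skipped %d fragments outside the window set", n_off)
    return WindowCounts(sample_id=sample_id, counts=counts,
                        window_set_id=windows.window_set_id)


def log2_ratio_profile(
    counts: WindowCounts,
    windows: GenomeWindows,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Log2RatioProfile:
    """log2 of observed over expected counts, expectation ∝ window length."""
    total = counts.total_reads
    if total <= 0:
        raise ValueError("total_reads must be positive")
    expected = total * windows.lengths / windows.lengths.sum()
    ratios = np.log2((counts.counts + pseudocount) / (expected + pseudocount))
    return Log2RatioProfile(
        sample_id=counts.sample_id,
        ratios=ratios,
        pseudocount=pseudocount,
        window_set_id=counts.window_set_id,
    )


def build_reference(
    profiles: Sequence[Log2RatioProfile],
    sigma_floor: float = SIGMA_FLOOR,
) -> ReferencePanel:
    """Per-window mean/SD across normal cfDNA log2-ratio profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to build a panel")
    wsid = profiles[0].window_set_id
    if any(p.window_set_id != wsid for p in profiles):
        raise ValueError("profiles are not on the same window set")
    mat = np.vstack([p.ratios for p in profiles])
    mu = mat.mean(axis=0)
    sigma = np.maximum(mat.std(axis=0, ddof=1), sigma_floor)
    return ReferencePanel(
        n_samples=len(profiles), mu=mu, sigma=sigma, window_set_id=wsid
    )


def z_profile(profile: Log2RatioProfile, panel: ReferencePanel) -> ZProfile:
    """Standardise a sample's log2 ratios against the reference panel."""
    if profile.window_set_id != panel.window_set_id:
        raise ValueError("profile and panel are on different window sets")
    return ZProfile(
        sample_id=profile.sample_id,
        z=(profile.ratios - panel.mu) / panel.sigma,
        window_set_id=profile.window_set_id,
    )


def z_critical_value(alpha: float, panel_n: int | None = None) -> float:
    """Two-sided rejection threshold at false-positive rate ``alpha``.

    With ``panel_n`` given, uses the predictive distribution of a fresh
    null sample standardised by a panel mean/SD estimated from ``panel_n``
    normals — t with ``panel_n - 1`` df scaled by sqrt(1 + 1/panel_n) —
    so the realised per-window false-positive rate is alpha, not merely
    its large-panel limit.  Without it, the standard-normal quantile.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if panel_n is None:
        return float(stats.norm.ppf(1 - alpha / 2))
    return float(
        stats.t.ppf(1 - alpha / 2, panel_n - 1) * math.sqrt(1 + 1 / panel_n)
    )


def cni_score(
    zp: ZProfile,
    alpha: float = DEFAULT_ALPHA,
    convention: str = "cdf_sum",
    panel_n: int | None = None,
) -> CNIResult:
    """Sum evidence over windows rejected at a two-sided FPR ``alpha``.

    ``cdf_sum`` sums Φ(|z|) over rejected windows; ``abs_z_sum`` sums |z|.
    Both conventions are exposed because published descriptions of the
    score are ambiguous between them; cdf_sum is the default.
    """
    if convention not in CNI_CONVENTIONS:
        raise ValueError(f"convention must be one of {CNI_CONVENTIONS}")
    zc = z_critical_value(alpha, panel_n)
    absz = np.abs(zp.z)
    rejected = np.flatnonzero(absz > zc)
    if convention == "cdf_sum":
        score = float(np.sum(stats.norm.cdf(absz[rejected])))
    else:
        score = float(np.sum(absz[rejected]))
    return CNIResult(
        sample_id=zp.sample_id,
        cni=score,
        alpha=alpha,
        z_critical=zc,
        rejected=rejected,
        convention=convention,
        panel_n=panel_n,
    )


def score_sample(
    counts: WindowCounts,
    windows: GenomeWindows,
    panel: ReferencePanel,
    alpha: float = DEFAULT_ALPHA,
    convention: str = "cdf_sum",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[CNIResult, ZProfile]:
    """Counts -> log2 ratios -> Z values -> CNI, in one call.

    Uses the panel-size-aware rejection threshold by default.
    """
    prof = log2_ratio_profile(counts, windows, pseudocount)
    zp = z_profile(prof, panel)
    return cni_score(zp, alpha, convention, panel_n=panel.n_samples), zp


def tissue_profile(
    counts: WindowCounts,
    threshold: float = TISSUE_LOG2_THRESHOLD,
) -> TissueCNProfile:
    """Median-normalised log2 profile with gain/loss flags (tissue mode)."""
    c = np.asarray(counts.counts, dtype=float)
    if counts.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    med = float(np.median(c))
    if med <= 0:
        raise ValueError("median window count must be positive")
    with np.errstate(divide="ignore"):
        log2r = np.log2(c / med)
    return TissueCNProfile(
        sample_id=counts.sample_id,
        log2_vs_median=log2r,
        gain_flags=log2r > threshold,
        loss_flags=log2r < -threshold,
        threshold=threshold,
    )


def export_cn_table(
    result: CNIResult | TissueCNProfile,
    windows: GenomeWindows,
    zp: ZProfile | None = None,
) -> pd.DataFrame:
    """Per-window annotated table: chrom, start, end, value, flag.

    For a CNI result, ``value`` is the window Z value (``zp`` required)
    and ``flag`` marks rejected windows as gain/loss by Z sign.  For a
    tissue profile, ``value`` is the median-normalised log2 ratio and
    flags follow the ±threshold rule.
    """
    df = windows.to_frame()
    if isinstance(result, TissueCNProfile):
        df["value"] = result.log2_vs_median
        flag = np.where(result.gain_flags, "gain",
                        np.where(result.loss_flags, "loss", "."))
    else:
        if zp is None:
            raise ValueError("a ZProfile is required to export a CNI result")
        if len(zp.z) != windows.n_windows:
            raise ValueError("z profile does not match the window set")
        df["value"] = zp.z
        flag = np.full(windows.n_windows, ".", dtype=object)
        flag[result.rejected] = np.where(
            zp.z[result.rejected] > 0, "gain", "loss"
        )
    df["flag"] = flag
    return df


def plot_genome(df: pd.DataFrame, path: str, title: str = "") -> None:
    """Linear genome plot of a per-window table from :func:`export_cn_table`."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(df))
    colors = df["flag"].map({"gain": "crimson", "loss": "purple"}).fillna("0.6")
    fig, ax = plt.subplots(figsize=(12, 3))
    ax.scatter(x, df["value"], s=6, c=colors)
    bounds = np.flatnonzero(df["chrom"].ne(df["chrom"].shift()).to_numpy())
    for b in bounds[1:]:
        ax.axvline(b - 0.5, color="0.85", lw=0.5)
    ax.set_xlabel("window index (genome order)")
    ax.set_ylabel("value")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
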