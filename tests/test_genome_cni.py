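"""Unit and property tests for cfDNA copy-number instability scoring."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liquidlens import genome_cni as gc
from liquidlens import synthetic_data as sd


# ---------------------------------------------------------------------------
# genome partitioning


def test_exact_tiling_of_a_toy_chromosome(toy_windows):
    assert toy_windows.n_windows == 10
    assert list(toy_windows.starts) == list(range(0, 100, 10))
    assert list(toy_windows.ends) == list(range(10, 101, 10))


def test_default_partition_emits_701_autosomal_windows(hg19_windows):
    sizes = gc.load_packaged_chrom_sizes()
    autosomal = sizes[~sizes["chrom"].isin(gc.SEX_CHROMS)]["length"].sum()
    assert hg19_windows.n_windows == 701
    assert hg19_windows.lengths.sum() == autosomal
    assert "chrX" not in hg19_windows.chromosomes
    # derived span is close to total/701 and no window exceeds the nominal span
    assert hg19_windows.span_bp == pytest.approx(autosomal / 701, rel=0.05)
    assert np.all(hg19_windows.lengths <= hg19_windows.span_bp)


def test_partition_with_sex_chromosomes_included():
    w = gc.partition_genome(gc.load_packaged_chrom_sizes(), include_sex=True)
    assert w.n_windows == 701
    assert "chrX" in w.chromosomes and "chrY" in w.chromosomes


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.dictionaries(
        st.sampled_from([f"c{i}" for i in range(8)]),
        st.integers(min_value=500, max_value=50_000),
        min_size=1,
        max_size=8,
    ),
    st.integers(min_value=10, max_value=120),
)
def test_partition_disjoint_cover_property(sizes, n_windows):
    """Windows are disjoint and their lengths sum to the genome length."""
    n_windows = max(n_windows, len(sizes))
    w = gc.partition_genome(sizes, n_windows=n_windows)
    assert w.n_windows == n_windows
    assert int(w.lengths.sum()) == sum(sizes.values())
    for chrom, length in sizes.items():
        sel = w.chroms == chrom
        assert w.starts[sel][0] == 0 and w.ends[sel][-1] == length
        assert np.all(w.starts[sel][1:] == w.ends[sel][:-1])


def test_partition_rejects_bad_inputs():
    with pytest.raises(ValueError, match="empty"):
        gc.partition_genome({}, n_windows=10)
    with pytest.raises(ValueError, match="span"):
        gc.partition_genome({"chr1": 100}, n_windows=None, span_bp=1000)
    with pytest.raises(ValueError):
        gc.partition_genome({"chr1": 100}, n_windows=10, span_bp=10)


# ---------------------------------------------------------------------------
# read counting


def test_fragments_assigned_by_midpoint(toy_windows):
    frags = pd.DataFrame(
        {"chrom": ["chr1"] * 10, "start": [30] * 10, "end": [38] * 10}
    )
    counts = gc.count_reads(toy_windows, frags)
    assert counts.counts[3] == 10 and counts.total_reads == 10


def test_boundary_spanning_fragment_counted_by_midpoint(toy_windows):
    # interval [36, 42) has midpoint 39 -> left window 3
    counts = gc.count_reads(
        toy_windows, pd.DataFrame({"chrom": ["chr1"], "start": [36], "end": [42]})
    )
    assert counts.counts[3] == 1 and counts.counts[4] == 0


def test_malformed_and_off_reference_fragments_skipped(toy_windows):
    frags = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chrUn"],
            "start": [10, 20, 5],
            "end": [5, 28, 9],  # first is malformed (end <= start)
        }
    )
    counts = gc.count_reads(toy_windows, frags)
    assert counts.total_reads == 1


def test_uniform_fragments_match_poisson_expectation(toy_windows, rng):
    """Uniform midpoints give near-uniform counts within Poisson error."""
    n = 200_000
    mids = rng.integers(0, 100, n)
    counts = gc.count_reads(
        toy_windows, pd.DataFrame({"chrom": "chr1", "midpoint": mids})
    )
    expected = n / 10
    assert counts.total_reads == n
    assert np.all(np.abs(counts.counts - expected) < 6 * math.sqrt(expected))


# ---------------------------------------------------------------------------
# log2 ratios, panel, z values


def _counts(values, windows):
    return gc.WindowCounts("s", np.asarray(values, dtype=np.int64),
                           windows.window_set_id)


def test_uniform_counts_give_zero_ratios(toy_windows):
    prof = gc.log2_ratio_profile(_counts([50] * 10, toy_windows), toy_windows,
                                 pseudocount=0.0)
    assert np.allclose(prof.ratios, 0.0)


def test_elevated_window_matches_hand_formula(toy_windows):
    # ten equal windows; expected per window = total / 10
    counts = _counts([10, 10, 10, 10, 22, 10, 9, 10, 10, 10], toy_windows)
    prof = gc.log2_ratio_profile(counts, toy_windows, pseudocount=0.0)
    expected = counts.total_reads / 10
    assert prof.ratios[4] == pytest.approx(math.log2(22 / expected))


def test_zero_count_window_finite_with_pseudocount(toy_windows):
    counts = _counts([10] * 9 + [0], toy_windows)
    prof = gc.log2_ratio_profile(counts, toy_windows, pseudocount=0.5)
    expected = counts.total_reads / 10
    assert prof.ratios[-1] == pytest.approx(math.log2(0.5 / (expected + 0.5)))
    assert np.isfinite(prof.ratios).all()


def test_panel_of_identical_profiles_hits_sigma_floor(toy_windows):
    counts = _counts([10] * 10, toy_windows)
    prof = gc.log2_ratio_profile(counts, toy_windows)
    panel = gc.build_reference([prof, prof, prof])
    assert np.allclose(panel.mu, prof.ratios)
    assert np.allclose(panel.sigma, gc.SIGMA_FLOOR)


def test_panel_of_zero_profiles_has_zero_mean(toy_windows):
    prof = gc.log2_ratio_profile(_counts([7] * 10, toy_windows), toy_windows,
                                 pseudocount=0.0)
    panel = gc.build_reference([prof, prof])
    assert np.allclose(panel.mu, 0.0)


def test_panel_rejects_mismatched_window_sets(toy_windows, hg19_windows):
    p1 = gc.log2_ratio_profile(_counts([10] * 10, toy_windows), toy_windows)
    p2 = gc.Log2RatioProfile("x", np.zeros(10), 0.5, hg19_windows.window_set_id)
    with pytest.raises(ValueError, match="window set"):
        gc.build_reference([p1, p2])
    with pytest.raises(ValueError, match="window set"):
        gc.z_profile(p2, gc.build_reference([p1, p1]))


def test_simulated_panel_sigma_tracks_generator_noise(rng):
    """Panel SD estimated from 133 normal draws stays close to the truth."""
    truth_sd = 0.05
    profiles = [
        gc.Log2RatioProfile(f"n{i}", rng.normal(0, truth_sd, 200), 0.5, "w")
        for i in range(133)
    ]
    panel = gc.build_reference(profiles)
    rel_err = np.abs(panel.sigma - truth_sd) / truth_sd
    # estimator SE is ~1/sqrt(2*132) ~ 6%; nearly all windows within 15%
    assert np.mean(rel_err < 0.15) > 0.95
    assert rel_err.max() < 0.35


def test_z_profile_standardisation(toy_windows):
    base = gc.log2_ratio_profile(_counts([10] * 10, toy_windows), toy_windows)
    panel = gc.ReferencePanel(5, base.ratios, np.full(10, 0.1),
                              toy_windows.window_set_id)
    assert np.allclose(gc.z_profile(base, panel).z, 0.0)
    shifted = gc.Log2RatioProfile("s", base.ratios + 0.2, 0.5,
                                  toy_windows.window_set_id)
    assert np.allclose(gc.z_profile(shifted, panel).z, 2.0)


def test_null_sample_z_is_approximately_standard_normal(null_cfdna, null_panel):
    zs = []
    for c in null_cfdna.samples:
        prof = gc.log2_ratio_profile(c, null_cfdna.windows)
        zs.append(gc.z_profile(prof, null_panel).z)
    z = np.concatenate(zs)
    assert abs(z.mean()) < 3 / math.sqrt(len(z))
    assert z.std() == pytest.approx(1.0, abs=0.05)


# ---------------------------------------------------------------------------
# CNI score


def test_all_zero_z_scores_zero(toy_windows):
    res = gc.cni_score(gc.ZProfile("s", np.zeros(10), "w"))
    assert res.cni == 0.0 and len(res.rejected) == 0


def test_single_rejected_window_contributes_its_cdf():
    z = np.zeros(10)
    z[3] = 4.0
    res = gc.cni_score(gc.ZProfile("s", z, "w"))
    phi4 = 0.5 * (1 + math.erf(4 / math.sqrt(2)))  # independent normal CDF
    assert list(res.rejected) == [3]
    assert res.cni == pytest.approx(phi4, abs=1e-12)


def _brute_force_cni(z, alpha, convention):
    """Independent loop re-implementation using math.erf only."""
    # inverse normal CDF by bisection on erf
    lo, hi = 0.0, 10.0
    target = 1 - alpha / 2
    for _ in range(200):
        mid = (lo + hi) / 2
        if 0.5 * (1 + math.erf(mid / math.sqrt(2))) < target:
            lo = mid
        else:
            hi = mid
    zc = (lo + hi) / 2
    total = 0.0
    rejected = []
    for i, v in enumerate(z):
        if abs(v) > zc:
            rejected.append(i)
            if convention == "cdf_sum":
                total += 0.5 * (1 + math.erf(abs(v) / math.sqrt(2)))
            else:
                total += abs(v)
    return total, rejected


@pytest.mark.parametrize("convention", ["cdf_sum", "abs_z_sum"])
def test_cni_matches_brute_force_oracle(convention, rng):
    for _ in range(20):
        z = rng.normal(0, 2, 300)
        res = gc.cni_score(gc.ZProfile("s", z, "w"), convention=convention)
        oracle, rej = _brute_force_cni(z, 0.002, convention)
        assert res.cni == pytest.approx(oracle, abs=1e-10)
        assert list(res.rejected) == rej


def test_cni_zero_iff_no_rejection_and_monotone_in_rejections(rng):
    z = rng.normal(0, 0.5, 100)  # all well below threshold
    res = gc.cni_score(gc.ZProfile("s", z, "w"))
    assert res.cni == 0.0
    prev = 0.0
    for k in (1, 3, 5):
        z2 = z.copy()
        z2[:k] = 5.0
        cur = gc.cni_score(gc.ZProfile("s", z2, "w")).cni
        assert cur > prev
        prev = cur


def test_cni_nondecreasing_in_aberrant_segment_width(null_cfdna, null_panel):
    """Widening an implanted gain never lowers the score (expectation profiles)."""
    scores = []
    for width in (0, 5, 15, 30):
        params = sd.CfdnaSimParams(
            aberrations=(sd.Aberration(200, 200 + width, 2.5),) if width else (),
            tumour_fraction=0.4,
            seed=101,
        )
        exp = sd.expected_counts(params)
        res, _ = gc.score_sample(exp, null_cfdna.windows, null_panel)
        scores.append(res.cni)
    assert all(a <= b for a, b in zip(scores, scores[1:]))
    assert scores[-1] > scores[0]


def test_implanted_single_copy_gain_recovered_in_95pct_of_replicates():
    """A 5-window single-copy gain at tumour fraction 0.5 is reliably flagged."""
    segment = slice(350, 355)
    params = sd.CfdnaSimParams(
        aberrations=(sd.Aberration(350, 355, 1.5),),
        tumour_fraction=0.5,
        n_samples=40,
        seed=424242,
    )
    sim = sd.gen_cfdna(params)
    panel = gc.build_reference(
        [gc.log2_ratio_profile(c, sim.windows) for c in sim.panel]
    )
    detected = 0
    for c in sim.samples:
        res, _ = gc.score_sample(c, sim.windows, panel)
        hits = np.intersect1d(res.rejected, np.arange(350, 355))
        detected += len(hits) >= 3  # majority of the segment rejected
    assert detected / len(sim.samples) >= 0.95


# ---------------------------------------------------------------------------
# tissue mode and export


def test_tissue_profile_flags():
    wsid = "w"
    counts = gc.WindowCounts("t", np.array([100] * 8 + [100, 100]), wsid)
    prof = gc.tissue_profile(counts)
    assert not prof.gain_flags.any() and not prof.loss_flags.any()

    c2 = np.full(11, 100)
    c2[0] = int(round(100 * 2 ** 0.2))   # log2 ~ +0.2 -> gain
    c2[1] = int(round(100 * 2 ** -0.2))  # log2 ~ -0.2 -> loss
    prof2 = gc.tissue_profile(gc.WindowCounts("t", c2, wsid))
    assert prof2.gain_flags[0] and not prof2.loss_flags[0]
    assert prof2.loss_flags[1] and not prof2.gain_flags[1]
    assert not (prof2.gain_flags & prof2.loss_flags).any()


def test_tissue_profile_rejects_all_zero_counts():
    with pytest.raises(ValueError):
        gc.tissue_profile(gc.WindowCounts("t", np.zeros(5, dtype=int), "w"))


def test_export_cn_table_cardinality_and_flags(hg19_windows, rng):
    z = rng.normal(0, 1, 701)
    res = gc.cni_score(gc.ZProfile("s", z, hg19_windows.window_set_id))
    table = gc.export_cn_table(res, hg19_windows,
                               gc.ZProfile("s", z, hg19_windows.window_set_id))
    assert len(table) == 701
    assert (table["flag"] != ".").sum() == len(res.rejected)


def test_export_round_trip(tmp_path, toy_windows):
    from liquidlens import cli_io

    counts = gc.WindowCounts("t", np.arange(10, 20, dtype=np.int64),
                             toy_windows.window_set_id)
    prof = gc.tissue_profile(counts)
    table = gc.export_cn_table(prof, toy_windows)
    path = tmp_path / "cn.tsv"
    cli_io.write_table(table, path)
    back = cli_io.read_table(path, {"chrom": str, "start": np.int64,
                                    "end": np.int64, "value": float})
    assert np.allclose(back["value"], table["value"])
    assert (back["start"] == table["start"]).all()
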