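"""Per-locus nucleosome features: depletion, occupancy, arrays, position
calling, linker statistics and the TSS/DHS tables."""

import numpy as np
import pandas as pd
import pytest

import nucqc as nq
from nucqc.features import (NucleosomePositionList, call_positions_from_profile,
                            depletion_level, linker_stats, occupancy_at_site,
                            array_score, _local_maxima, _smooth)

from conftest import gaussian_bumps, make_track


# ---------------------------------------------------------------------------
# depletion level

def test_depletion_flat_track_is_zero():
    occ = make_track({"chr1": np.full(2_000, 3.0)})
    assert depletion_level(occ, "chr1", 1_000) == 0.0


def test_depletion_formula_arithmetic():
    v = np.full(2_000, 8.0)
    v[900:1100] = 2.0  # central bin max 2, background max 8
    occ = make_track({"chr1": v})
    assert depletion_level(occ, "chr1", 1_000) == pytest.approx(0.75)


def test_depletion_clamped_to_zero_when_center_exceeds_background():
    v = np.full(2_000, 2.0)
    v[950:1050] = 8.0
    occ = make_track({"chr1": v})
    assert depletion_level(occ, "chr1", 1_000) == 0.0


def test_depletion_zero_background_returns_zero():
    occ = make_track({"chr1": np.zeros(2_000)})
    assert depletion_level(occ, "chr1", 1_000) == 0.0


def test_depletion_off_chromosome_is_none():
    occ = make_track({"chr1": np.ones(2_000)})
    assert depletion_level(occ, "chr1", 100) is None


def test_depletion_always_in_unit_interval():
    rng = np.random.default_rng(14)
    occ = make_track({"chr1": rng.random(4_000) * 5})
    for pos in rng.integers(300, 3_700, 50):
        d = depletion_level(occ, "chr1", int(pos))
        assert 0.0 <= d < 1.0


# ---------------------------------------------------------------------------
# occupancy at site / array score

def test_occupancy_at_site_examples():
    occ = make_track({"chr1": np.ones(2_000)})
    assert occupancy_at_site(occ, "chr1", 1_000) == 1.0
    step = np.zeros(2_000)
    step[1_000:] = 2.0
    occ = make_track({"chr1": step})
    assert occupancy_at_site(occ, "chr1", 1_000) == pytest.approx(1.0)


def test_occupancy_at_site_matches_window_mean():
    rng = np.random.default_rng(6)
    v = rng.random(2_000)
    occ = make_track({"chr1": v})
    assert occupancy_at_site(occ, "chr1", 700) == pytest.approx(
        v[650:750].mean())


def test_array_score_ratio_and_uniform():
    sig = np.full(10_000, 0.4)
    sig[5_000:6_000] = 0.8
    arr = make_track({"chr1": sig}, role="array")
    gm = sig.mean()
    assert array_score(arr, "chr1", 5_000, side="down") == pytest.approx(0.8 / gm)
    uniform = make_track({"chr1": np.full(10_000, 0.4)}, role="array")
    assert array_score(uniform, "chr1", 5_000, side="down") == pytest.approx(1.0)


def test_array_score_minus_strand_uses_upstream_window():
    sig = np.full(10_000, 0.4)
    sig[4_000:5_000] = 0.8  # [site-1000, site)
    arr = make_track({"chr1": sig}, role="array")
    plus = array_score(arr, "chr1", 5_000, side="down", strand="+")
    minus = array_score(arr, "chr1", 5_000, side="down", strand="-")
    assert minus == pytest.approx(0.8 / sig.mean())
    assert plus == pytest.approx(0.4 / sig.mean())


def test_array_score_zero_genome_mean_fatal():
    arr = make_track({"chr1": np.zeros(10_000)}, role="array")
    with pytest.raises(ValueError):
        array_score(arr, "chr1", 5_000)


# ---------------------------------------------------------------------------
# position calling

def test_single_triangular_peak():
    prof = np.concatenate([np.arange(200.0), np.arange(200.0)[::-1],
                           np.zeros(600)])
    calls = call_positions_from_profile(prof, smooth_window=1)
    assert calls.offsets == [199]


def test_equal_peaks_150_apart_both_retained():
    prof = np.zeros(1_000)
    prof[300] = prof[450] = 5.0
    calls = call_positions_from_profile(prof, smooth_window=1)
    assert calls.offsets == [300, 450]


def test_merge_keeps_higher_occupancy_peak():
    prof = np.zeros(1_000)
    prof[200] = 5.0
    prof[280] = 7.0
    calls = call_positions_from_profile(prof, smooth_window=1)
    assert calls.offsets == [280]


def test_merge_boundary_at_100bp():
    for sep, expected in ((100, 2), (99, 1)):
        prof = np.zeros(1_000)
        prof[300] = prof[300 + sep] = 5.0
        calls = call_positions_from_profile(prof, smooth_window=1)
        assert len(calls) == expected


def test_plateau_yields_leftmost_index():
    prof = np.zeros(1_000)
    prof[400:420] = 3.0
    calls = call_positions_from_profile(prof, smooth_window=1)
    assert calls.offsets == [400]


def test_offset_zero_excluded_from_plus1_search():
    prof = np.zeros(1_000)
    prof[0] = 9.0
    prof[500] = 1.0
    calls = call_positions_from_profile(prof, smooth_window=1)
    assert calls.offsets == [500]


def _oracle_calls(profile, smooth_window, merge_dist, min_rel_height=0.25):
    """Independent brute-force implementation of smoothing + maxima + merge."""
    n = profile.size
    sm = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - smooth_window // 2), min(n, i + (smooth_window + 1) // 2)
        sm[i] = profile[lo:hi].mean()
    peaks = []
    # strict maxima, plateaus -> leftmost
    for i in range(n):
        j = i
        while j + 1 < n and sm[j + 1] == sm[i]:
            j += 1
        if (i == 0 or sm[i - 1] < sm[i]) and (j == n - 1 or sm[j + 1] < sm[i]):
            if i >= 1:
                peaks.append([i, sm[i]])
    if peaks:
        floor = min_rel_height * max(h for _, h in peaks)
        peaks = [p for p in peaks if p[1] >= floor]
    # drop globally lowest violator until spacings are legal
    while True:
        bad = [k for k in range(len(peaks) - 1)
               if peaks[k + 1][0] - peaks[k][0] < merge_dist]
        if not bad:
            break
        cands = []
        for k in bad:
            if peaks[k][1] < peaks[k + 1][1]:
                cands.append(k)
            else:
                cands.append(k + 1)
        worst = min(cands, key=lambda k: (peaks[k][1], peaks[k][0]))
        peaks.pop(worst)
    return [p[0] for p in peaks]


def test_random_profiles_match_brute_force_oracle():
    rng = np.random.default_rng(77)
    for _ in range(20):
        prof = rng.random(1_000) ** 3 * 10
        got = call_positions_from_profile(prof, smooth_window=50).offsets
        oracle = _oracle_calls(prof, 50, 100)
        assert got == oracle
        # post-merge spacing invariant
        assert all(b - a >= 100 for a, b in zip(got, got[1:]))


# ---------------------------------------------------------------------------
# linker statistics

def positions(offsets):
    return NucleosomePositionList("s", "chr1", 0, "+", list(offsets),
                                  [1.0] * len(offsets))


@pytest.mark.parametrize("offs,expected", [
    ([300, 500, 700], (300, 53.0, 0.0, 3)),
    ([250], (250, -1.0, -1.0, 1)),
    ([], (-1, -1.0, -1.0, 0)),
    ([200, 320], (200, -27.0, -1.0, 2)),  # negative linker reported as computed
])
def test_linker_stats_examples(offs, expected):
    assert linker_stats(positions(offs)) == expected


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=100, max_value=500), min_size=0,
                max_size=6))
def test_linker_identity_property(steps):
    """Mean spacing minus linker length is exactly the 147 bp nucleosomal
    DNA constant whenever the linker is defined, for any position list."""
    offs = list(np.cumsum(steps)) if steps else []
    plus1, linker, sd, count = linker_stats(positions(offs))
    assert count == len(offs)
    if count >= 2:
        assert np.diff(offs).mean() - linker == pytest.approx(147.0)
    else:
        assert linker == -1.0
    if count < 3:
        assert sd == -1.0
    if count == 0:
        assert plus1 == -1


def test_linker_identity_and_sentinel_closure():
    rng = np.random.default_rng(55)
    for _ in range(50):
        k = int(rng.integers(0, 6))
        offs = np.cumsum(rng.integers(100, 400, k)).tolist() if k else []
        plus1, linker, sd, count = linker_stats(positions(offs))
        assert count == k
        if count < 2:
            assert linker == -1.0 and sd == -1.0
        else:
            spacing = np.diff(offs).mean()
            assert spacing - linker == pytest.approx(147.0)
        if count < 3:
            assert sd == -1.0
        if count == 0:
            assert plus1 == -1


# ---------------------------------------------------------------------------
# feature tables

def phased_tss_track(tss=5_000, nfr=250, spacing=190, n=5, length=20_000,
                     background=0.2):
    plus1 = tss + nfr // 2 + 73
    centers = [plus1 + i * spacing for i in range(n)]
    centers += [tss - nfr // 2 - 73 - i * spacing for i in range(2)]
    return make_track({"chr1": gaussian_bumps(length, centers, sigma=25,
                                              heights=[5.0] * len(centers),
                                              baseline=background)})


def test_tss_table_on_phased_array():
    occ = phased_tss_track()
    arr = nq.build_array_track(occ)
    tss = pd.DataFrame([{"chrom": "chr1", "start": 5_000, "name": "g1",
                         "strand": "+"}])
    rec = nq.tss_feature_table(occ, arr, tss)[0]
    assert rec.depletion_level > 0.9
    assert rec.nucleosome_count == 5
    assert rec.linker_length == pytest.approx(190 - 147, abs=3)
    assert rec.plus1_position == pytest.approx(250 // 2 + 73, abs=5)


def test_tss_table_flat_track_all_sentinels():
    occ = make_track({"chr1": np.full(20_000, 1.0)})
    arr = make_track({"chr1": np.full(20_000, 0.5)}, role="array")
    tss = pd.DataFrame([{"chrom": "chr1", "start": 5_000, "name": "g1",
                         "strand": "+"}])
    rec = nq.tss_feature_table(occ, arr, tss)[0]
    assert rec.depletion_level == 0.0
    assert rec.nucleosome_count == 0
    assert rec.plus1_position == -1
    assert rec.linker_length == -1.0
    assert rec.linker_sd == -1.0


def test_minus_strand_record_mirrors_plus_strand():
    occ = phased_tss_track()
    arr = nq.build_array_track(occ)
    length = 20_000
    occ_m = make_track({"chr1": occ.data["chr1"][::-1].copy()})
    arr_m = nq.build_array_track(occ_m)
    plus = nq.tss_feature_table(
        occ, arr, pd.DataFrame([{"chrom": "chr1", "start": 5_000,
                                 "name": "g", "strand": "+"}]))[0]
    minus = nq.tss_feature_table(
        occ_m, arr_m, pd.DataFrame([{"chrom": "chr1", "start": length - 5_000,
                                     "name": "g", "strand": "-"}]))[0]
    assert minus.depletion_level == pytest.approx(plus.depletion_level, abs=1e-6)
    assert minus.nucleosome_count == plus.nucleosome_count
    assert minus.plus1_position == pytest.approx(plus.plus1_position, abs=1)
    assert minus.linker_length == pytest.approx(plus.linker_length, abs=1)


def test_dhs_table_symmetric_profile_mirrors_up_down():
    center = 10_000
    centers = ([center + 198 + i * 190 for i in range(4)]
               + [center - 198 - i * 190 for i in range(4)])
    occ = make_track({"chr1": gaussian_bumps(20_000, centers, sigma=25,
                                             heights=[5.0] * 8, baseline=0.2)})
    arr = nq.build_array_track(occ)
    dhs = pd.DataFrame([{"chrom": "chr1", "start": center - 75,
                         "end": center + 75, "name": "d1"}])
    rec = nq.dhs_feature_table(occ, arr, dhs)[0]
    assert rec.array_score_up > 1.0 and rec.array_score_down > 1.0
    assert rec.up_nucleosome_count == rec.nucleosome_count
    assert rec.minus1_position == pytest.approx(rec.plus1_position, abs=1)
    assert rec.up_linker_length == pytest.approx(rec.linker_length, abs=1)


def test_dhs_at_chromosome_edge_is_na_record():
    occ = make_track({"chr1": np.full(2_000, 1.0)})
    arr = make_track({"chr1": np.full(2_000, 0.5)}, role="array")
    dhs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100,
                         "name": "edge"}])
    rec = nq.dhs_feature_table(occ, arr, dhs)[0]
    assert not rec.valid


def test_narrowpeak_summit_sets_anchor(tmp_path):
    p = tmp_path / "d.narrowPeak"
    p.write_text("chr1\t100\t400\td1\t0\t.\t5.0\t-1\t-1\t50\n"
                 "chr1\t600\t800\td2\t0\t.\t5.0\t-1\t-1\t-1\n")
    df = nq.read_dhs_bed(p)
    assert df.loc[0, "anchor"] == 150   # start + summit offset
    assert df.loc[1, "anchor"] == 700   # invalid summit -> midpoint
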