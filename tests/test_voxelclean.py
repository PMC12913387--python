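"""Voxel cleaning: thresholding, flattening, CNR, borders, Cook's."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melomap.config import CleaningParams
from melomap.voxelclean import (
    REASON_CODES,
    UnimodalHistogramError,
    compute_cnr,
    cooks_distance_constant,
    cooks_outlier_filter,
    flatten,
    low_signal_threshold,
    low_signal_distance,
    mode_of,
    remove_edge_artifacts,
)

PARAMS = CleaningParams()


# ----------------------------------------------------------------------
# low-signal threshold
# ----------------------------------------------------------------------

def test_threshold_between_two_narrow_peaks():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(100, 1, 5000), rng.normal(1000, 1, 5000)])
    thr = low_signal_threshold(x, PARAMS)
    assert 100 < thr < 1000


def test_threshold_matches_grid_scan_oracle():
    """Threshold equals the argmin of the same smoothed density found by
    an exhaustive fine-grid scan between the two mode locations."""
    rng = np.random.default_rng(42)
    x = np.concatenate([rng.normal(20, 5, 40_000), rng.normal(80, 5, 60_000)])
    thr = low_signal_threshold(x, PARAMS)

    # independent oracle: manual Gaussian-kernel density on a 0.1-step grid
    sd = x.std(ddof=1)
    bw = sd * (4.0 / (3.0 * x.size)) ** 0.2          # Silverman, 1D
    grid = np.arange(20.0, 80.0 + 1e-9, 0.1)
    sub = rng.choice(x, 20_000, replace=False)       # keep the scan cheap
    dens = np.exp(-0.5 * ((grid[:, None] - sub[None, :]) / bw) ** 2).sum(axis=1)
    oracle = grid[np.argmin(dens)]
    assert thr == pytest.approx(oracle, abs=0.5)


def test_constant_image_raises_unimodal_error():
    with pytest.raises(UnimodalHistogramError):
        low_signal_threshold(np.full((4, 4, 4), 7.0), PARAMS)


def test_single_mode_raises():
    rng = np.random.default_rng(1)
    with pytest.raises(UnimodalHistogramError):
        low_signal_threshold(rng.normal(50, 5, 10_000), PARAMS)


# ----------------------------------------------------------------------
# flattening
# ----------------------------------------------------------------------

def test_flatten_constant_volume():
    vol = np.full((3, 5, 5), 7.0)
    mean, counts = flatten(vol, np.ones_like(vol, bool))
    assert np.allclose(mean, 7.0)
    assert np.all(counts == 3)


def test_flatten_masked_column_mean():
    vol = np.zeros((3, 1, 1))
    vol[:, 0, 0] = [10.0, 20.0, 999.0]
    valid = np.ones_like(vol, bool)
    valid[2] = False                      # dropout slice
    mean, counts = flatten(vol, valid)
    assert mean[0, 0] == 15.0
    assert counts[0, 0] == 2


def test_flatten_all_invalid_column_is_nan():
    vol = np.ones((2, 2, 2))
    valid = np.ones_like(vol, bool)
    valid[:, 0, 0] = False
    mean, counts = flatten(vol, valid)
    assert np.isnan(mean[0, 0]) and counts[0, 0] == 0


def test_flatten_matches_bruteforce_masked_average(rng):
    vol = rng.normal(1000, 50, (5, 12, 17))
    valid = rng.random(vol.shape) > 0.3
    mean, _ = flatten(vol, valid)
    for i in range(12):
        for j in range(17):
            v = vol[valid[:, i, j], i, j]
            if v.size:
                assert mean[i, j] == pytest.approx(v.mean())
            else:
                assert np.isnan(mean[i, j])


def test_flatten_empty_volume_raises():
    with pytest.raises(ValueError):
        flatten(np.empty((0, 2, 2)), np.empty((0, 2, 2), bool))


# ----------------------------------------------------------------------
# CNR
# ----------------------------------------------------------------------

def test_cnr_definition_at_mode_and_ten_percent():
    intensity = np.full((6, 6), 1000.0)
    intensity[0, 0] = 1100.0              # 10 % above the reference mode
    valid = np.ones((6, 6), bool)
    ref = np.zeros((6, 6), bool)
    ref[3:, 3:] = True
    cnr, mode = compute_cnr(intensity, valid, ref, PARAMS)
    assert mode == pytest.approx(1000.0)
    assert cnr[1, 1] == pytest.approx(0.0, abs=1e-9)
    assert cnr[0, 0] == pytest.approx(10.0, abs=1e-9)  # SN-voxel cutoff


def test_reference_mode_matches_grid_scan_kde_oracle(rng):
    sample = rng.normal(1000, 20, 4000)
    mode = mode_of(sample, "silverman", 512)
    bw = sample.std(ddof=1) * (4.0 / (3.0 * sample.size)) ** 0.2
    grid = np.arange(sample.min(), sample.max(), 0.1)
    dens = np.exp(-0.5 * ((grid[:, None] - sample[None, :]) / bw) ** 2
                  ).sum(axis=1)
    assert mode == pytest.approx(grid[np.argmax(dens)], abs=0.5)


def test_cnr_errors():
    intensity = np.full((4, 4), 10.0)
    valid = np.ones((4, 4), bool)
    with pytest.raises(ValueError):
        compute_cnr(intensity, valid, np.zeros((4, 4), bool), PARAMS)
    with pytest.raises(ValueError):
        compute_cnr(-intensity, valid, np.ones((4, 4), bool), PARAMS)


def test_cnr_invariant_under_global_rescaling(rng):
    intensity = rng.normal(1000, 60, (20, 20))
    valid = rng.random((20, 20)) > 0.1
    ref = np.zeros((20, 20), bool)
    ref[5:15, 5:15] = True
    cnr1, _ = compute_cnr(intensity, valid, ref, PARAMS)
    cnr2, _ = compute_cnr(3.7 * intensity, valid, ref, PARAMS)
    assert np.allclose(cnr1[valid], cnr2[valid], atol=1e-7)


# ----------------------------------------------------------------------
# edge-artifact removal
# ----------------------------------------------------------------------

def _reasons_from_valid(valid):
    reasons = np.zeros(valid.shape, dtype=int)
    reasons[~valid] = REASON_CODES["outside"]
    return reasons


def test_border_removal_strips_three_voxel_frame():
    """10x10 valid square: perimeter + 2 dilations = outer 3 rings."""
    valid = np.zeros((14, 14), bool)
    valid[2:12, 2:12] = True
    reasons = remove_edge_artifacts(_reasons_from_valid(valid), None,
                                    np.zeros_like(valid), PARAMS,
                                    apply_band=False)
    removed = reasons == REASON_CODES["border2"]
    expected = valid & ~np.pad(np.ones((4, 4), bool), 5, constant_values=False)
    assert np.array_equal(removed, expected)
    assert np.array_equal(reasons == 0,
                          np.pad(np.ones((4, 4), bool), 5,
                                 constant_values=False))


def test_band_removal_respects_sn_sparing():
    valid = np.zeros((24, 24), bool)
    valid[2:22, 2:22] = True
    cnr = np.full(valid.shape, 50.0)      # every band voxel is "hot"
    sn = np.zeros_like(valid)
    sn[:, :12] = True                     # left half flagged SN
    reasons = remove_edge_artifacts(_reasons_from_valid(valid), cnr, sn,
                                    PARAMS)
    d = low_signal_distance(_reasons_from_valid(valid))
    band = valid & (d >= 4) & (d <= 8)
    hot = reasons == REASON_CODES["border5_cnr"]
    assert np.array_equal(hot, band & ~sn)
    assert not np.any(hot & sn)
    # same voxel with CNR below the cutoff survives
    reasons2 = remove_edge_artifacts(_reasons_from_valid(valid),
                                     np.full(valid.shape, 30.0),
                                     np.zeros_like(valid), PARAMS)
    assert not np.any(reasons2 == REASON_CODES["border5_cnr"])


def _bfs_cityblock_distance(valid):
    """Brute-force BFS distance to the nearest invalid pixel (the image
    frame counts as invalid)."""
    from collections import deque

    h, w = valid.shape
    dist = np.full((h, w), np.inf)
    dq = deque()
    for i in range(h):
        for j in range(w):
            if not valid[i, j]:
                dist[i, j] = 0
                dq.append((i, j))
    # frame beyond the array: seed border pixels with distance 1 candidates
    for i in range(h):
        for j in (0, w - 1):
            if valid[i, j] and dist[i, j] > 1:
                dist[i, j] = 1
                dq.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if valid[i, j] and dist[i, j] > 1:
                dist[i, j] = 1
                dq.append((i, j))
    while dq:
        i, j = dq.popleft()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and dist[ni, nj] > dist[i, j] + 1:
                dist[ni, nj] = dist[i, j] + 1
                dq.append((ni, nj))
    return dist


def test_edge_removal_set_matches_distance_oracle(rng):
    """Removal set equals a brute-force city-block distance labeling on
    random masks."""
    for _ in range(8):
        valid = rng.random((20, 22)) > 0.25
        cnr = rng.normal(20, 25, valid.shape)
        sn = rng.random(valid.shape) > 0.7
        reasons = remove_edge_artifacts(_reasons_from_valid(valid), cnr, sn,
                                        PARAMS)
        dist = _bfs_cityblock_distance(valid)
        exp_border = valid & (dist >= 1) & (dist <= 3)
        exp_hot = (valid & ~exp_border & (dist >= 4) & (dist <= 8)
                   & (cnr > PARAMS.edge_cnr_max_pct) & ~sn)
        assert np.array_equal(reasons == REASON_CODES["border2"], exp_border)
        assert np.array_equal(reasons == REASON_CODES["border5_cnr"], exp_hot)


def test_geometric_cleaning_is_idempotent(rng):
    """Reapplying the border stages to a cleaned image changes nothing:
    border geometry is keyed on distance to the low-signal set."""
    valid = rng.random((30, 30)) > 0.2
    cnr = rng.normal(20, 25, valid.shape)
    sn = np.zeros_like(valid)
    r1 = remove_edge_artifacts(_reasons_from_valid(valid), cnr, sn, PARAMS)
    r2 = remove_edge_artifacts(r1, cnr, sn, PARAMS)
    assert np.array_equal(r1, r2)


# ----------------------------------------------------------------------
# Cook's-distance filtering
# ----------------------------------------------------------------------

def _cooks_loo_oracle(y):
    """Brute-force leave-one-out Cook's distance:
    D_i = sum_j (yhat_j - yhat_j(i))^2 / (p * s^2)."""
    y = np.asarray(y, float)
    n = y.size
    s2 = np.sum((y - y.mean()) ** 2) / (n - 1)
    if s2 == 0:
        return np.zeros(n)
    out = np.empty(n)
    for i in range(n):
        loo_mean = np.delete(y, i).mean()
        out[i] = n * (y.mean() - loo_mean) ** 2 / s2
    return out


def test_cooks_all_equal_flags_nothing():
    keep = cooks_outlier_filter(np.full(10, 3.3))
    assert keep.all()


def test_cooks_flags_single_outlier_per_loo_oracle():
    y = np.array([1.0, 1.0, 1.0, 1.0, 10.0])
    d_oracle = _cooks_loo_oracle(y)
    keep = cooks_outlier_filter(y)
    assert np.array_equal(keep, d_oracle <= 4 / 5)
    assert not keep[-1] and keep[:-1].all()


def test_cooks_formula_equals_loo_oracle_on_100_random_vectors(rng):
    """Hat-matrix closed form == leave-one-out definition (h = 1/n)."""
    for _ in range(100):
        n = int(rng.integers(3, 40))
        y = rng.normal(0, rng.uniform(0.5, 5), n)
        assert np.allclose(cooks_distance_constant(y), _cooks_loo_oracle(y),
                           rtol=1e-9, atol=1e-12)


def test_cooks_small_section_passes_with_warning():
    with pytest.warns(UserWarning):
        keep = cooks_outlier_filter(np.array([1.0, 99.0]))
    assert keep.all()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(-8000, 8000), min_size=3, max_size=30))
def test_cooks_distance_nonnegative_and_scale_invariant(values):
    # eighths are exact binary floats, so the affine map below is exact
    y = np.asarray(values, dtype=float) / 8.0
    d = cooks_distance_constant(y)
    assert np.all(d >= 0)
    d2 = cooks_distance_constant(2.5 * y + 7.0)
    assert np.allclose(d, d2, rtol=1e-8, atol=1e-8)
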