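"""Single-level detail-coefficient transform against independent oracles."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from mbhis import (
    DataError,
    FeatureMatrix,
    WaveletFilter,
    detail_length,
    dwt_detail_level1,
    stf_transform,
)
from mbhis.wavelet import dwt_approx_level1, reconstruct_level1


def naive_detail(x: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Extend, convolve and downsample with explicit loops (the oracle)."""
    L = len(hi)
    n = len(x)

    def reflect(p: int) -> float:
        # half-point mirror: ... x1 x0 | x0 .. x_{n-1} | x_{n-1} ...
        while not 0 <= p < n:
            if p < 0:
                p = -p - 1
            else:
                p = 2 * n - 1 - p
        return x[p]

    ext = np.array([reflect(p) for p in range(-(L - 1), n + L - 1)])
    full = np.zeros(len(ext) + L - 1)
    for i in range(len(full)):
        for j in range(L):
            k = i - j
            if 0 <= k < len(ext):
                full[i] += hi[j] * ext[k]
    ncd = (n + L - 1) // 2
    return full[L : L + 2 * ncd : 2][:ncd]


@pytest.mark.parametrize(
    "n,expected",
    [(2048, 1074), (1920, 1010), (1280, 690)],
)
def test_dmey_detail_lengths_match_backbone_widths(n, expected):
    filt = WaveletFilter("dmey")
    assert filt.length == 102
    cd = dwt_detail_level1(np.arange(n, dtype=float), filt)
    assert len(cd) == expected
    assert detail_length(n, filt.length) == expected


@pytest.mark.parametrize("name", ["haar", "db4", "dmey"])
def test_matches_naive_oracle_and_reference_dwt(name, rng):
    filt = WaveletFilter(name)
    n = 256
    x = rng.normal(size=n)
    cd = dwt_detail_level1(x, filt)
    np.testing.assert_allclose(cd, naive_detail(x, filt.highpass_dec), atol=1e-10)
    wav = pywt.Wavelet(
        "custom",
        filter_bank=(
            filt.lowpass_dec.tolist(),
            filt.highpass_dec.tolist(),
            filt.lowpass_dec[::-1].tolist(),
            filt.highpass_dec[::-1].tolist(),
        ),
    )
    _, cd_ref = pywt.dwt(x, wav, mode="symmetric")
    np.testing.assert_allclose(cd, cd_ref, atol=1e-10)


def test_haar_hand_computed_example():
    """x = 1..8 under Haar: every detail coefficient is -1/sqrt(2)."""
    filt = WaveletFilter("haar")
    cd = dwt_detail_level1(np.arange(1.0, 9.0), filt)
    np.testing.assert_allclose(cd, np.full(4, -1 / np.sqrt(2)), atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    n=st.integers(min_value=8, max_value=300),
    name=st.sampled_from(["haar", "db2", "db4", "sym5"]),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_length_formula_and_linearity(n, name, seed):
    filt = WaveletFilter(name)
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=(2, n))
    cdx = dwt_detail_level1(x, filt)
    assert len(cdx) == (n + filt.length - 1) // 2
    lhs = dwt_detail_level1(2.5 * x - 0.5 * y, filt)
    np.testing.assert_allclose(lhs, 2.5 * cdx - 0.5 * dwt_detail_level1(y, filt), atol=1e-9)


def test_zero_signal_gives_zero_details():
    cd = dwt_detail_level1(np.zeros(512), WaveletFilter("dmey"))
    assert len(cd) == detail_length(512, 102)
    assert np.all(cd == 0)


@pytest.mark.parametrize("name,tol", [("haar", 1e-8), ("db4", 1e-8), ("dmey", 2e-2)])
def test_round_trip_reconstruction(name, tol, rng):
    """CA1 + CD1 reconstruct the signal; dmey only approximately (FIR Meyer)."""
    filt = WaveletFilter(name)
    x = rng.normal(size=300)
    ca = dwt_approx_level1(x, filt)
    cd = dwt_detail_level1(x, filt)
    xr = reconstruct_level1(ca, cd, filt, len(x))
    np.testing.assert_allclose(xr, x, atol=tol)


@pytest.mark.parametrize("name,hi_tol", [("haar", 1e-6), ("db4", 1e-6), ("dmey", 2e-3)])
def test_filter_invariants(name, hi_tol):
    filt = WaveletFilter(name)
    assert abs(filt.lowpass_dec.sum() - np.sqrt(2)) < 1e-6
    assert abs(filt.highpass_dec.sum()) < hi_tol
    assert filt.qmf_error() < 1e-12


def test_short_signal_is_rejected():
    with pytest.raises(DataError):
        dwt_detail_level1(np.array([1.0]), WaveletFilter("haar"))


class TestStfTransform:
    def test_shapes_and_provenance(self, rng):
        fm = FeatureMatrix(rng.normal(size=(10, 1280)), [f"s{i}" for i in range(10)],
                           "spatial", "mobilenet")
        out = stf_transform(fm)
        assert out.values.shape == (10, 690)
        assert out.provenance == "stf"
        assert out.backbone == "mobilenet"
        assert out.sample_ids == fm.sample_ids

    def test_zero_row_stays_zero(self):
        vals = np.zeros((2, 2048))
        vals[1] = np.random.default_rng(1).normal(size=2048)
        fm = FeatureMatrix(vals, ["a", "b"], "spatial", "resnet50")
        out = stf_transform(fm)
        assert out.values.shape == (2, 1074)
        assert np.all(out.values[0] == 0)
        assert np.any(out.values[1] != 0)

    def test_requires_spatial_provenance(self, rng):
        fm = FeatureMatrix(rng.normal(size=(3, 256)), list("abc"), "stf")
        with pytest.raises(DataError):
            stf_transform(fm)
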