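"""Level-1 wavelet detail coefficients of deep-feature vectors.

Each spatial embedding vector is run through a single level of the discrete
wavelet transform and only the detail (highpass) coefficients CD1 are kept —
the "spatial-time-frequency" representation. The default basis is the
discrete Meyer wavelet (``dmey``) in its 102-tap convention, under which the
output lengths for 2048-, 1920- and 1280-dimensional inputs are 1074, 1010
and 690 coefficients.

Boundary handling is symmetric half-point extension (the signal is mirrored
about the edge, repeating the edge sample), the convention behind those
printed lengths: for a length-``N`` input and length-``L`` filter the detail
vector has ``floor((N + L - 1) / 2)`` entries.

The widely distributed dmey filter has 62 non-negligible taps; the 102-tap
convention is obtained by symmetric zero-padding (20 zeros per side), which
leaves every convolution product unchanged while fixing the length contract.
Note that dmey is a finite-impulse-response *approximation* of the Meyer
wavelet: its highpass taps sum to ~1.1e-3 rather than 0, and single-level
reconstruction is accurate to ~1e-2, not machine precision. Truly orthogonal
bases (Haar, Daubechies) meet the tight tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .exceptions import ConfigurationError, DataError
from .features import FeatureMatrix

DMEY_CONVENTIONAL_LENGTH = 102


@dataclass
class WaveletFilter:
    """Decomposition filter pair + boundary-extension mode."""

    name: str = "dmey"
    lowpass_dec: np.ndarray = None
    highpass_dec: np.ndarray = None
    extension: str = "symmetric_half_point"

    def __post_init__(self) -> None:
        if self.lowpass_dec is None or self.highpass_dec is None:
            lo, hi = _load_filter_taps(self.name)
            if self.lowpass_dec is None:
                self.lowpass_dec = lo
            if self.highpass_dec is None:
                self.highpass_dec = hi
        self.lowpass_dec = np.asarray(self.lowpass_dec, dtype=np.float64)
        self.highpass_dec = np.asarray(self.highpass_dec, dtype=np.float64)
        if self.lowpass_dec.shape != self.highpass_dec.shape:
            raise ConfigurationError("lowpass and highpass filters must have equal length")
        if self.extension != "symmetric_half_point":
            raise ConfigurationError(
                f"unsupported extension {self.extension!r}; only symmetric half-point "
                "reproduces the contractual output lengths"
            )

    @property
    def length(self) -> int:
        return len(self.lowpass_dec)

    def qmf_error(self) -> float:
        """Max deviation from hi[k] = -(-1)^k lo[L-1-k]."""
        k = np.arange(self.length)
        return float(np.max(np.abs(self.highpass_dec + (-1.0) ** k * self.lowpass_dec[::-1])))


def _load_filter_taps(name: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(name)
    lo = np.asarray(w.dec_lo, dtype=np.float64)
    hi = np.asarray(w.dec_hi, dtype=np.float64)
    if name == "dmey" and len(lo) < DMEY_CONVENTIONAL_LENGTH:
        pad = (DMEY_CONVENTIONAL_LENGTH - len(lo)) // 2
        lo = np.pad(lo, (pad, pad))
        hi = np.pad(hi, (pad, pad))
    return lo, hi


def detail_length(n: int, filter_length: int) -> int:
    """CD1 length under symmetric half-point extension: floor((N+L-1)/2)."""
    return (n + filter_length - 1) // 2


def dwt_detail_level1(x: np.ndarray, filt: WaveletFilter | None = None) -> np.ndarray:
    """Level-1 detail coefficients of a 1-D signal (or stacked rows).

    Symmetric half-point extension by ``L - 1`` samples per side, full
    convolution with the decomposition highpass filter, dyadic downsampling.
    Output length is ``floor((N + L - 1) / 2)``.
    """
    filt = filt or WaveletFilter()
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if n < 2:
        raise DataError(f"signal must have length >= 2, got {n}")
    L = filt.length
    # half-point symmetric extension by L-1 per side; signals shorter than the
    # filter are handled by periodic reflection (period 2N)
    pos = np.arange(-(L - 1), n + L - 1)
    m = np.mod(pos, 2 * n)
    idx = np.where(m < n, m, 2 * n - 1 - m)
    ext = x[..., idx]
    if x.ndim == 1:
        full = np.convolve(ext, filt.highpass_dec, mode="full")
    else:
        full = np.apply_along_axis(np.convolve, -1, ext, filt.highpass_dec)
    ncd = detail_length(n, L)
    return full[..., L : L + 2 * ncd : 2][..., :ncd]


def dwt_approx_level1(x: np.ndarray, filt: WaveletFilter | None = None) -> np.ndarray:
    """Level-1 approximation coefficients (lowpass branch, same convention)."""
    filt = filt or WaveletFilter()
    hp = WaveletFilter(filt.name, filt.lowpass_dec, filt.lowpass_dec, filt.extension)
    return dwt_detail_level1(x, hp)


def reconstruct_level1(ca: np.ndarray, cd: np.ndarray, filt: WaveletFilter | None, n: int) -> np.ndarray:
    """Inverse single-level transform (sanity check for the round trip)."""
    filt = filt or WaveletFilter()
    wav = pywt.Wavelet(
        filt.name + "_custom",
        filter_bank=(
            filt.lowpass_dec.tolist(),
            filt.highpass_dec.tolist(),
            filt.lowpass_dec[::-1].tolist(),
            filt.highpass_dec[::-1].tolist(),
        ),
    )
    return pywt.idwt(ca, cd, wav, mode="symmetric")[:n]


def stf_transform(feats: FeatureMatrix, filt: WaveletFilter | None = None) -> FeatureMatrix:
    """Row-wise CD1 of a spatial feature matrix; provenance becomes ``stf``."""
    if feats.provenance != "spatial":
        raise DataError(f"stf_transform expects spatial features, got {feats.provenance!r}")
    filt = filt or WaveletFilter()
    values = dwt_detail_level1(feats.values, filt)
    return FeatureMatrix(values, list(feats.sample_ids), "stf", feats.backbone)
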