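"""Weighted phase lag index (wPLI) functional connectivity.

The wPLI of a channel pair at frequency bin k is

    wPLI_k = | E[ Im S_ij(k) ] | / E[ |Im S_ij(k)| ]

with the expectation taken over Welch segments and S_ij the segment
cross-spectrum; 0/0 is defined as 0. The band value is the unweighted
mean over the bins inside the (closed) band. Because the estimator uses
only the imaginary cross-spectrum, instantaneous (zero-lag) linear
mixing — the scalp volume-conduction confound — contributes nothing in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from netsig.errors import EstimatorError, ParameterError
from netsig.io import EpochSet, Recording
from netsig.spectral import DEFAULT_BANDS, _band_bins, segment_ffts


@dataclass
class CrossSpectra:
    """Segment-wise cross-spectra, held in factored form.

    Stores the tapered segment FFTs ``X`` [n_segments, n_channels,
    n_freqs] plus the one-sided density scale; the full Hermitian tensor
    S[s, i, j, f] = X[s, i, f] · conj(X[s, j, f]) · scale[f] is
    materialized on demand (``tensor()``) — its diagonal is the
    per-segment periodogram.
    """

    freqs: np.ndarray
    X: np.ndarray
    scale: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def tensor(self) -> np.ndarray:
        """Full [n_segments, n_ch, n_ch, n_freqs] cross-spectral tensor."""
        return (self.X[:, :, None, :] * np.conj(self.X[:, None, :, :])
                ) * self.scale


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band wPLI matrix with zero diagonal, values in [0, 1]."""

    band: tuple[float, float]
    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        m = self.matrix
        if not np.allclose(m, m.T):
            raise ParameterError("connectivity matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ParameterError("diagonal must be zero")
        if np.any((m < 0) | (m > 1)):
            raise ParameterError("wPLI values must lie in [0, 1]")


def cross_spectra(rec: Recording, epochs: EpochSet | None = None,
                  window: float = 2.0, overlap: float = 0.5) -> CrossSpectra:
    """Per-segment tapered cross-spectra on the Welch segmentation."""
    if epochs is None:
        epochs = EpochSet(epochs=[(0, rec.n_samples)], fs=rec.fs)
    freqs, X, scale = segment_ffts(rec, epochs, window, overlap)
    return CrossSpectra(freqs=freqs, X=X, scale=scale, labels=list(rec.labels))


def wpli(cs: CrossSpectra, band: tuple[float, float],
         debiased: bool = False) -> ConnectivityMatrix:
    """Band wPLI matrix from segment-wise cross-spectra.

    ``debiased=True`` returns the debiased squared estimator instead of
    the plain ratio (offered for sensitivity analyses).
    """
    if cs.n_segments < 2:
        raise EstimatorError("wPLI needs at least 2 segments")
    bins = _band_bins(cs.freqs, band)
    if bins.size == 0:
        raise ParameterError(f"band {band} contains no frequency bins")
    Xb = cs.X[:, :, bins]                                   # [S, C, B]
    # Im(S_ij) per segment; the real density scale cancels in the ratio
    imS = np.imag(Xb[:, :, None, :] * np.conj(Xb[:, None, :, :]))  # [S,C,C,B]
    num = np.abs(imS.sum(axis=0))
    den = np.abs(imS).sum(axis=0)
    if debiased:
        sq = (imS ** 2).sum(axis=0)
        dnum = num ** 2 - sq
        dden = den ** 2 - sq
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(dden > 0, dnum / dden, 0.0)
        w = np.clip(w, 0.0, 1.0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(den > 0, num / den, 0.0)
    band_w = w.mean(axis=-1)
    band_w = (band_w + band_w.T) / 2.0
    np.fill_diagonal(band_w, 0.0)
    band_w = np.clip(band_w, 0.0, 1.0)
    return ConnectivityMatrix(band=tuple(band), matrix=band_w,
                              labels=list(cs.labels))


def band_wpli(rec: Recording, epochs: EpochSet | None = None,
              bands: dict[str, tuple[float, float]] | None = None,
              window: float = 2.0, overlap: float = 0.5,
              ) -> dict[str, ConnectivityMatrix]:
    """Convenience: wPLI matrices for every analysis band."""
    bands = dict(bands or DEFAULT_BANDS)
    cs = cross_spectra(rec, epochs, window, overlap)
    return {name: wpli(cs, band) for name, band in bands.items()}


def global_wpli(cm: ConnectivityMatrix) -> float:
    """Global connectivity scalar: mean of the strictly-upper triangle."""
    iu = np.triu_indices_from(cm.matrix, k=1)
    return float(cm.matrix[iu].mean())
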