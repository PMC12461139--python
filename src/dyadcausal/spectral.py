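"""Spectral decomposition of dyadic coupling into directed and instantaneous parts.

For the joint process X = [X_M, X_I] (Model channels first) with PSD matrix
S_X(omega) = H Sigma_W H*, the total spectral interdependence is the Geweke
log-determinant measure

    f_total(omega) = log( |S_M| |S_I| / |S_X| ),

which factorizes into two directed transfer densities and an instantaneous
term,

    f_total = f_{M->I} + f_{I->M} + f_{M.I}.

Each directed term compares the full spectrum of the target block with its
*intrinsic* part, obtained after decorrelating the source innovations from
the target innovations (the standard Geweke normalization):

    f_{M->I}(omega) = log |S_I| - log | Ht_II Sigma_II Ht_II* |,

where Ht_II = H_II + H_IM Sigma_MI' Sigma_II^{-1} is the target row-block of
the transfer function after the innovations rotation that zeroes the
cross-block covariance, and Sigma_II is the target innovation covariance.
The instantaneous term uses the two intrinsic blocks directly, so the
three-way identity holds algebraically and its numerical residual is a
self-check of the implementation.

All spectra are in natural-log units (nats per unit normalized frequency).
Band integration follows

    C_{M->I} = (1/4pi) \\int_{w1}^{w2} C(omega) d omega,

with C(omega) = f_{M->I}(omega) - f_{I->M}(omega), the band entered in Hz
and converted to normalized angular frequency internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .var import FrequencyGrid, StateSpaceModel, ridge_floor, transfer_function

__all__ = [
    "SpectralDecomposition",
    "CausalSpectrum",
    "BandCausalIntensity",
    "decompose",
    "causal_spectrum",
    "band_integrate",
]

logger = logging.getLogger(__name__)

# Directed terms are nonnegative in exact arithmetic; anything below this is
# a numerical pathology rather than roundoff.
_NEGATIVE_TOL = -1e-6


@dataclass(frozen=True)
class SpectralDecomposition:
    """Per-frequency total coupling and its three components (nats)."""

    grid: FrequencyGrid
    f_total: np.ndarray
    f_m_to_i: np.ndarray
    f_i_to_m: np.ndarray
    f_inst: np.ndarray

    def identity_residual(self) -> float:
        """Max over frequencies of |f_total - (f_M->I + f_I->M + f_inst)|."""
        return float(np.max(np.abs(
            self.f_total - (self.f_m_to_i + self.f_i_to_m + self.f_inst))))

    def clamped(self) -> "SpectralDecomposition":
        """Copy with directed terms clamped to zero from below (reporting)."""
        return replace(self,
                       f_m_to_i=np.maximum(self.f_m_to_i, 0.0),
                       f_i_to_m=np.maximum(self.f_i_to_m, 0.0))


@dataclass(frozen=True)
class CausalSpectrum:
    """Signed causal-intensity spectrum C(omega) with optional significance masks."""

    grid: FrequencyGrid
    c: np.ndarray
    f_m_to_i: np.ndarray
    f_i_to_m: np.ndarray
    mask_m_to_i: np.ndarray | None = None
    mask_i_to_m: np.ndarray | None = None

    @property
    def has_masks(self) -> bool:
        return self.mask_m_to_i is not None and self.mask_i_to_m is not None


@dataclass(frozen=True)
class BandCausalIntensity:
    """Band-integrated signed causal value; intensity is its absolute value."""

    value: float
    band: tuple[float, float]
    masked: bool

    @property
    def intensity(self) -> float:
        return abs(self.value)


def _logdet_hermitian(mats: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Log-determinants of a stack of Hermitian PD matrices via Cholesky.

    Accumulates 2*sum(log diag(chol)); raises naming the first offending
    frequency index when a matrix is not positive definite or non-finite.
    """
    mats = np.asarray(mats)
    if mats.ndim == 2:
        mats = mats[None]
    if not np.all(np.isfinite(mats)):
        bad = int(np.where(~np.isfinite(mats).all(axis=(1, 2)))[0][0])
        raise FloatingPointError(f"non-finite {name} at frequency index {bad}")
    try:
        chol = np.linalg.cholesky(mats)
    except np.linalg.LinAlgError:
        # locate the first failure for the error message
        for i, m in enumerate(mats):
            try:
                np.linalg.cholesky(m)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"{name} not positive definite at frequency index {i}"
                ) from None
        raise
    diag = np.einsum("fii->fi", chol).real
    return 2.0 * np.sum(np.log(diag), axis=1)


def decompose(ssm: StateSpaceModel, grid: FrequencyGrid,
              n_model: int | None = None,
              sigma_ridge: float = 1e-8) -> SpectralDecomposition:
    """Three-way spectral decomposition of the Model/Imitator interdependence.

    Parameters
    ----------
    ssm
        Stable innovations-form model of the stacked dyad (Model block first).
    grid
        Frequency grid on [0, fs/2].
    n_model
        Number of Model channels (first ``n_model`` observation indices);
        defaults to half the observation dimension.
    sigma_ridge
        Relative diagonal floor applied to the innovation covariance before
        any determinant (short epochs can make it near-singular).
    """
    d = ssm.dim
    n_model = d // 2 if n_model is None else n_model
    if not 0 < n_model < d:
        raise ValueError("n_model must split the channels into two non-empty blocks")
    a = slice(0, n_model)          # Model block
    b = slice(n_model, d)          # Imitator block

    sigma = ridge_floor(ssm.sigma_w, rel=sigma_ridge)
    H = transfer_function(ssm, grid)
    S = np.einsum("fab,bc,fdc->fad", H, sigma, H.conj(), optimize=True)
    S = 0.5 * (S + np.conj(np.transpose(S, (0, 2, 1))))

    logdet_S = _logdet_hermitian(S, "joint PSD")
    logdet_Sm = _logdet_hermitian(S[:, a, a], "Model PSD block")
    logdet_Si = _logdet_hermitian(S[:, b, b], "Imitator PSD block")
    f_total = logdet_Sm + logdet_Si - logdet_S

    def intrinsic_logdet(tgt: slice, src: slice) -> np.ndarray:
        # Decorrelate source innovations from target innovations:
        # W_src_adj = W_src - Sigma_src,tgt Sigma_tgt^{-1} W_tgt, after which
        # the intrinsic part of S_tgt is Ht_tt Sigma_tt Ht_tt* with
        # Ht_tt = H_tt + H_t,src (Sigma_src,tgt Sigma_tgt,tgt^{-1}).
        sig_tt = sigma[tgt, tgt]
        # gain = Sigma_{src,tgt} Sigma_{tgt,tgt}^{-1}, via a solve (no inverse)
        gain = np.linalg.solve(sig_tt.T, sigma[src, tgt].T).T
        Ht_tt = H[:, tgt, tgt] + H[:, tgt, src] @ gain
        intrinsic = np.einsum("fab,bc,fdc->fad", Ht_tt, sig_tt, Ht_tt.conj(),
                              optimize=True)
        intrinsic = 0.5 * (intrinsic + np.conj(np.transpose(intrinsic, (0, 2, 1))))
        return _logdet_hermitian(intrinsic, "intrinsic PSD block")

    logdet_intr_i = intrinsic_logdet(b, a)     # target Imitator, source Model
    logdet_intr_m = intrinsic_logdet(a, b)     # target Model, source Imitator

    f_m_to_i = logdet_Si - logdet_intr_i
    f_i_to_m = logdet_Sm - logdet_intr_m
    f_inst = logdet_intr_m + logdet_intr_i - logdet_S

    for name, arr in (("f_M_to_I", f_m_to_i), ("f_I_to_M", f_i_to_m)):
        low = float(arr.min())
        if low < _NEGATIVE_TOL:
            idx = int(np.argmin(arr))
            raise FloatingPointError(
                f"{name} is {low:.3e} at frequency index {idx}: "
                "directed spectral density should be nonnegative"
            )
    return SpectralDecomposition(grid=grid, f_total=f_total,
                                 f_m_to_i=f_m_to_i, f_i_to_m=f_i_to_m,
                                 f_inst=f_inst)


def causal_spectrum(dec: SpectralDecomposition) -> CausalSpectrum:
    """Signed causal-intensity spectrum C(omega) = f_{M->I} - f_{I->M}.

    Significance masks are unset until surrogate thresholding is applied.
    """
    return CausalSpectrum(grid=dec.grid, c=dec.f_m_to_i - dec.f_i_to_m,
                          f_m_to_i=dec.f_m_to_i, f_i_to_m=dec.f_i_to_m)


def band_integrate(cs: CausalSpectrum, band_hz: tuple[float, float] = (0.008, 0.08),
                   use_mask: bool = True) -> BandCausalIntensity:
    """Band-integrated causal value, (1/4pi) * trapezoid over the band.

    With ``use_mask`` the integrand is f_{M->I}*mask_{M->I} -
    f_{I->M}*mask_{I->M} (per-term masking; insignificant frequencies
    contribute zero); without it the raw difference C(omega) is integrated.
    Band limits are in Hz; integration is over normalized angular frequency.
    """
    f1, f2 = band_hz
    fs = cs.grid.fs
    if not (0.0 <= f1 < f2 <= fs / 2.0):
        raise ValueError(f"band {band_hz} must satisfy 0 <= f1 < f2 <= fs/2")
    if use_mask:
        if not cs.has_masks:
            raise ValueError("use_mask=True but significance masks are unset")
        integrand = (cs.f_m_to_i * cs.mask_m_to_i
                     - cs.f_i_to_m * cs.mask_i_to_m)
    else:
        integrand = cs.c
    freqs = cs.grid.frequencies
    inside = (freqs > f1) & (freqs < f2)
    if int(inside.sum()) < 1:
        logger.warning("band %s contains no interior grid points; value 0", band_hz)
        return BandCausalIntensity(value=0.0, band=(f1, f2), masked=use_mask)
    # integrate between the exact band edges: interior grid points plus
    # linearly interpolated endpoint values
    f_nodes = np.concatenate([[f1], freqs[inside], [f2]])
    y_nodes = np.concatenate([[np.interp(f1, freqs, integrand)],
                              integrand[inside],
                              [np.interp(f2, freqs, integrand)]])
    omega = 2.0 * np.pi * f_nodes / fs
    value = float(np.trapezoid(y_nodes, omega) / (4.0 * np.pi))
    if use_mask and not (cs.mask_m_to_i[inside].any()
                         or cs.mask_i_to_m[inside].any()):
        logger.debug("no significant frequencies in band %s", band_hz)
    return BandCausalIntensity(value=value, band=(f1, f2), masked=use_mask)
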