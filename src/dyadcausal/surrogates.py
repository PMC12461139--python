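"""Phase-randomization surrogates and per-frequency significance thresholds.

A surrogate keeps each channel's amplitude spectrum (hence its power
spectrum and autocorrelation) but replaces the phase of every non-DC,
non-Nyquist Fourier coefficient with an independent uniform draw.  Phases
are drawn independently per channel, which destroys all cross-channel phase
relations — the null hypothesis of no dependence between the participants.

Each surrogate is pushed through the identical model-fitting and spectral
decomposition path as the original epoch; the ensemble mean of the directed
spectra is the per-frequency significance threshold: an original directed
value is significant where it exceeds the surrogate mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import CausalSpectrum, SpectralDecomposition, causal_spectrum, decompose
from .var import FrequencyGrid, refit_stable, select_order_mdl, var_to_state_space

__all__ = [
    "SurrogateEnsemble",
    "phase_randomize",
    "surrogate_threshold",
    "apply_significance",
]


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Directed spectra of an ensemble of phase-randomized surrogates."""

    grid: FrequencyGrid
    members: tuple[SpectralDecomposition, ...]
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one surrogate")

    @property
    def n_surrogates(self) -> int:
        return len(self.members)

    def _aggregate(self, stack: np.ndarray) -> np.ndarray:
        if self.statistic == "mean":
            return stack.mean(axis=0)
        if self.statistic == "percentile95":
            return np.percentile(stack, 95.0, axis=0)
        raise ValueError(f"unknown surrogate statistic {self.statistic!r}")

    @property
    def mean_f_m_to_i(self) -> np.ndarray:
        return self._aggregate(np.stack([m.f_m_to_i for m in self.members]))

    @property
    def mean_f_i_to_m(self) -> np.ndarray:
        return self._aggregate(np.stack([m.f_i_to_m for m in self.members]))


def phase_randomize(x: np.ndarray, seed) -> np.ndarray:
    """Phase-randomized copy of each column of ``x`` (L x C), amplitude preserved.

    ``seed`` may be an int, a numpy SeedSequence, or a Generator.  Phases are
    drawn channel by channel in column order, so a fixed seed gives a
    bit-reproducible surrogate.  The DC bin is untouched (column means are
    preserved) and, for even length, the Nyquist bin phase is fixed at 0 so
    the inverse transform is exactly real.
    """
    x = np.asarray(x)
    if np.iscomplexobj(x):
        raise TypeError("phase randomization is defined for real time series")
    x = x.astype(float, copy=False)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    L = x.shape[0]
    if L < 4:
        raise ValueError("need at least 4 samples to randomize phases")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = np.fft.rfft(x, axis=0)
    n_bins = spec.shape[0]
    # bins 1..n_bins-2 for even L (last bin is Nyquist), 1..n_bins-1 for odd L
    free = slice(1, n_bins - 1) if L % 2 == 0 else slice(1, n_bins)
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=spec[free, c].shape)
        new = spec[:, c].copy()
        new[free] = np.abs(spec[free, c]) * np.exp(1j * phases)
        if L % 2 == 0:
            new[-1] = np.abs(spec[-1, c])      # real Nyquist coefficient
        out[:, c] = np.fft.irfft(new, n=L)
    return out[:, 0] if squeeze else out


def surrogate_threshold(epoch, n_surrogates: int = 10, seed=0,
                        grid: FrequencyGrid | None = None,
                        p_max: int = 2, p_policy: str = "mdl",
                        n_model: int | None = None,
                        statistic: str = "mean",
                        sigma_ridge: float = 1e-8) -> SurrogateEnsemble:
    """Decompose an ensemble of surrogates of ``epoch`` with the original pipeline.

    Each surrogate is re-fitted from scratch — including the model-order
    selection policy (``"mdl"`` re-selects per surrogate; an integer-valued
    ``p_policy`` pins the order) — so the threshold reflects the full
    estimation chain, not just the decomposition.  Unstable surrogate fits
    are dropped; it is an error if none survives.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if isinstance(epoch, np.ndarray):
        data = epoch
    else:
        data = epoch.data if hasattr(epoch, "data") else np.asarray(epoch, dtype=float)
    fs = getattr(epoch, "fs", 1.0)
    if grid is None:
        grid = FrequencyGrid.linspace(fs)
    n_model = data.shape[1] // 2 if n_model is None else n_model
    seq = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    streams = seq.spawn(n_surrogates)
    members = []
    for stream in streams:
        surr = phase_randomize(data, np.random.default_rng(stream))
        if p_policy == "mdl":
            p = select_order_mdl(surr, p_max=p_max)
        else:
            p = int(p_policy)
        var = refit_stable(surr, p)
        if var is None:
            continue
        ssm = var_to_state_space(var, fs=fs)
        members.append(decompose(ssm, grid, n_model=n_model,
                                 sigma_ridge=sigma_ridge))
    if not members:
        raise RuntimeError("all surrogate fits were unstable")
    return SurrogateEnsemble(grid=grid, members=tuple(members),
                             statistic=statistic)


def apply_significance(dec: SpectralDecomposition,
                       ens: SurrogateEnsemble) -> CausalSpectrum:
    """Mask each directed spectrum where it exceeds the surrogate threshold.

    mask_{M->I}(omega) = [ f_{M->I}(omega) > threshold_{M->I}(omega) ], and
    likewise for the opposite direction; C(omega) is the raw signed
    difference, unchanged by masking.
    """
    if len(dec.grid) != len(ens.grid) or not np.allclose(
            dec.grid.frequencies, ens.grid.frequencies):
        raise ValueError("decomposition and ensemble use different frequency grids")
    cs = causal_spectrum(dec)
    return CausalSpectrum(
        grid=cs.grid, c=cs.c, f_m_to_i=cs.f_m_to_i, f_i_to_m=cs.f_i_to_m,
        mask_m_to_i=dec.f_m_to_i > ens.mean_f_m_to_i,
        mask_i_to_m=dec.f_i_to_m > ens.mean_f_i_to_m,
    )
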