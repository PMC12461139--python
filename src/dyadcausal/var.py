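"""Linear dynamic modelling of a dyad epoch and its frequency-domain quantities.

A :class:`DyadEpoch` (Model channels stacked before Imitator channels) is
modelled as a vector autoregression

    x(t) = A_1 x(t-1) + ... + A_p x(t-p) + w(t),      cov(w) = Sigma,

fitted by ordinary least squares.  The VAR is then rewritten in innovations
state-space form

    s(t+1) = A s(t) + K w(t),       x(t) = C s(t) + w(t),

(companion state s(t) = [x(t-1); ...; x(t-p)]) whose transfer function

    H(omega) = I + C (I - A e^{-i omega})^{-1} K e^{-i omega}

and spectral factorization  S_X(omega) = H Sigma_W H*  supply everything the
spectral causality decomposition needs.  omega is normalized angular
frequency (omega = 2 pi f / fs, Nyquist at pi).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

__all__ = [
    "VARModel",
    "StateSpaceModel",
    "FrequencyGrid",
    "fit_var",
    "select_order_mdl",
    "var_to_state_space",
    "transfer_function",
    "psd_matrix",
    "state_covariance",
    "implied_autocovariance",
    "ridge_floor",
]


@dataclass(frozen=True)
class VARModel:
    """Fitted VAR(p): coefficient stack and residual covariance.

    ``coeffs`` has shape (p, d, d); ``coeffs[k]`` is A_{k+1}, the matrix
    multiplying x(t-k-1).  ``sigma`` is the residual covariance with
    denominator ``n_effective = L - p``.
    """

    coeffs: np.ndarray
    sigma: np.ndarray
    order: int
    n_effective: int

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("VAR order must be >= 1")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("residual covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """Companion matrix (d*p x d*p) whose eigenvalues decide stability."""
        d, p = self.dim, self.order
        top = np.concatenate(list(self.coeffs), axis=1)
        comp = np.zeros((d * p, d * p))
        comp[:d, :] = top
        if p > 1:
            comp[d:, : d * (p - 1)] = np.eye(d * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self, tol: float = 1.0) -> bool:
        return self.spectral_radius() < tol


@dataclass(frozen=True)
class StateSpaceModel:
    """Innovations-form state-space model (A, C, K, Sigma_W)."""

    A: np.ndarray
    C: np.ndarray
    K: np.ndarray
    sigma_w: np.ndarray
    order: int
    fs: float

    def __post_init__(self) -> None:
        m = self.A.shape[0]
        d = self.C.shape[0]
        if self.A.shape != (m, m) or self.C.shape != (d, m) or self.K.shape != (m, d):
            raise ValueError("inconsistent state-space dimensions")
        if not np.allclose(self.sigma_w, self.sigma_w.T, atol=1e-10):
            raise ValueError("innovation covariance must be symmetric")

    @property
    def dim(self) -> int:
        """Observation dimension (2N for a dyad epoch)."""
        return self.C.shape[0]

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform grid of frequencies from 0 to Nyquist (inclusive)."""

    frequencies: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("frequency grid needs at least two points")
        if not (np.all(np.diff(f) > 0) and np.isclose(f[0], 0.0)
                and np.isclose(f[-1], self.fs / 2)):
            raise ValueError("grid must increase from 0 to fs/2")
        step = np.diff(f)
        if not np.allclose(step, step[0], rtol=1e-8):
            raise ValueError("grid must be uniformly spaced")

    @classmethod
    def linspace(cls, fs: float, n_freq: int = 513) -> "FrequencyGrid":
        return cls(np.linspace(0.0, fs / 2.0, n_freq), fs)

    @property
    def omega(self) -> np.ndarray:
        """Normalized angular frequencies, 2*pi*f/fs in [0, pi]."""
        return 2.0 * np.pi * self.frequencies / self.fs

    def __len__(self) -> int:
        return self.frequencies.size


def ridge_floor(sigma: np.ndarray, rel: float = 1e-8) -> np.ndarray:
    """Regularize a covariance before determinants: add rel*trace/d on the diagonal.

    Short epochs can produce numerically singular residual covariances on
    which the log-determinant measures diverge; the floor is relative to the
    average channel variance so it is scale-equivariant.
    """
    d = sigma.shape[0]
    delta = rel * float(np.trace(sigma)) / d
    return sigma + delta * np.eye(d)


def _epoch_data(epoch) -> np.ndarray:
    if isinstance(epoch, np.ndarray):
        data = epoch
    else:
        data = epoch.data if hasattr(epoch, "data") else epoch
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a 2-D (samples x channels) array")
    return data


def fit_var(epoch, p: int, ridge: float = 0.0) -> VARModel:
    """Fit a VAR(p) by ordinary least squares (no intercept).

    Parameters
    ----------
    epoch
        DyadEpoch or plain (L x d) array.  Channels are assumed centred
        (the pipeline z-normalizes each epoch first), so no intercept is
        estimated.
    p
        Model order (>= 1).
    ridge
        Optional Tikhonov penalty added to the normal equations
        (``ridge * I``); 0 means plain OLS via lstsq.

    Returns
    -------
    VARModel with residual covariance Sigma = E'E / (L - p).
    """
    x = _epoch_data(epoch)
    L, d = x.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    if L - p <= d * p:
        raise ValueError(
            f"not enough samples to fit VAR({p}) in dimension {d}: "
            f"need L - p > d*p, got L={L}"
        )
    y = x[p:]                                    # (L-p, d)
    z = np.concatenate([x[p - k - 1 : L - k - 1] for k in range(p)], axis=1)
    if ridge > 0.0:
        g = z.T @ z + ridge * np.eye(d * p)
        b = np.linalg.solve(g, z.T @ y)
    else:
        b, _, rank, _ = np.linalg.lstsq(z, y, rcond=None)
        if rank < d * p:
            raise np.linalg.LinAlgError(
                "rank-deficient regressor matrix; consider refitting with a "
                "small ridge penalty (fit_var(..., ridge=1e-6))"
            )
    resid = y - z @ b
    n_eff = L - p
    sigma = resid.T @ resid / n_eff
    coeffs = np.stack([b[k * d : (k + 1) * d].T for k in range(p)])
    return VARModel(coeffs=coeffs, sigma=0.5 * (sigma + sigma.T), order=p,
                    n_effective=n_eff)


def mdl_score(model: VARModel) -> float:
    """Minimum Description Length score of a fitted VAR.

    MDL(p) = log det Sigma_hat(p) + p * d^2 * log(n_eff) / n_eff,
    the Rissanen penalty with one parameter per autoregressive coefficient.
    """
    d = model.dim
    sigma = ridge_floor(model.sigma)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("residual covariance is not positive definite")
    n = model.n_effective
    k = model.order * d * d
    return float(logdet + k * np.log(n) / n)


def select_order_mdl(epoch, p_max: int = 2, ridge: float = 0.0) -> int:
    """Pick the VAR order in {1..p_max} minimizing the MDL criterion."""
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if p_max == 1:
        return 1
    scores = {p: mdl_score(fit_var(epoch, p, ridge=ridge)) for p in range(1, p_max + 1)}
    return min(scores, key=scores.get)


def var_to_state_space(var: VARModel, fs: float = 1.0) -> StateSpaceModel:
    """Rewrite a stable VAR(p) in companion innovations form.

    State s(t) = [x(t-1); ...; x(t-p)] gives A = companion matrix,
    C = [A_1 ... A_p], K = [I; 0; ...; 0] and Sigma_W = Sigma; the implied
    second-order statistics coincide with the source VAR's.
    """
    rho = var.spectral_radius()
    if rho >= 1.0:
        raise ValueError(f"unstable VAR: companion spectral radius {rho:.6f} >= 1")
    d, p = var.dim, var.order
    m = d * p
    A = var.companion()
    C = np.concatenate(list(var.coeffs), axis=1)      # (d, m)
    K = np.zeros((m, d))
    K[:d, :] = np.eye(d)
    return StateSpaceModel(A=A, C=C, K=K, sigma_w=var.sigma.copy(), order=p, fs=fs)


def transfer_function(ssm: StateSpaceModel, grid: FrequencyGrid) -> np.ndarray:
    """Evaluate H(omega) = I + C (I - A e^{-i w})^{-1} K e^{-i w} on the grid.

    Returns a complex array of shape (n_freq, d, d).
    """
    rho = ssm.spectral_radius()
    if rho >= 1.0:
        raise ValueError(f"unstable state matrix: spectral radius {rho:.6f} >= 1")
    z = np.exp(-1j * grid.omega)                       # (F,)
    m = ssm.state_dim
    eye_m = np.eye(m)
    # (F, m, m): I - A * z, batch-inverted
    resolvent = np.linalg.inv(eye_m[None, :, :] - ssm.A[None, :, :] * z[:, None, None])
    H = np.einsum("cm,fmn,nd,f->fcd", ssm.C, resolvent, ssm.K, z, optimize=True)
    H += np.eye(ssm.dim)[None, :, :]
    return H


def psd_matrix(ssm: StateSpaceModel, grid: FrequencyGrid) -> np.ndarray:
    """Spectral factorization S_X(omega) = H Sigma_W H* (one-sided grid).

    Hermitian positive semidefinite at every frequency.  With the
    normalized-angular-frequency convention, the process covariance is
    Gamma_0 = (1/2pi) \\int_{-pi}^{pi} S_X(omega) d omega.
    """
    H = transfer_function(ssm, grid)
    S = np.einsum("fab,bc,fdc->fad", H, ssm.sigma_w, H.conj(), optimize=True)
    return 0.5 * (S + np.conj(np.transpose(S, (0, 2, 1))))


def state_covariance(ssm: StateSpaceModel) -> np.ndarray:
    """Stationary state covariance P solving P = A P A' + K Sigma_W K'."""
    q = ssm.K @ ssm.sigma_w @ ssm.K.T
    return sla.solve_discrete_lyapunov(ssm.A, q)


def implied_autocovariance(ssm: StateSpaceModel, max_lag: int = 1) -> np.ndarray:
    """Model-implied autocovariances Gamma_0..Gamma_max_lag of the observations.

    Gamma_0 = C P C' + Sigma_W; Gamma_k = C A^{k-1} (A P C' + K Sigma_W)
    for k >= 1, where P is the stationary state covariance.  This is the
    Lyapunov-equation oracle against which the frequency-domain integral of
    the PSD can be checked (Parseval).
    """
    P = state_covariance(ssm)
    C, A, K, Sw = ssm.C, ssm.A, ssm.K, ssm.sigma_w
    gammas = [C @ P @ C.T + Sw]
    cross = A @ P @ C.T + K @ Sw          # cov(s(t+1), x(t))
    Ak = np.eye(A.shape[0])
    for _ in range(max_lag):
        gammas.append(C @ Ak @ cross)
        Ak = A @ Ak
    return np.stack(gammas)


def refit_stable(epoch, p: int, ridge: float = 1e-6,
                 max_steps: int = 16) -> VARModel | None:
    """OLS fit with an escalating ridge refit on instability.

    Band-limited, heavily oversampled signals put the true VAR poles close
    to the unit circle, so plain OLS lands slightly outside it for a large
    fraction of short epochs.  Starting from ``ridge`` the penalty is grown
    geometrically (x10 per step) until the fit is stable; shrinkage pulls
    the companion spectrum inside the circle while leaving the passband
    shape of the spectrum essentially unchanged at the penalties this
    typically needs.  Returns None if no penalty in the schedule stabilizes
    the fit (the epoch is then excluded downstream).
    """
    model = fit_var(epoch, p)
    if model.is_stable():
        return model
    lam = ridge
    for _ in range(max_steps):
        model = fit_var(epoch, p, ridge=lam)
        if model.is_stable():
            return model
        lam *= 10.0
    return None


def random_stable_var(dim: int, order: int, rng: np.random.Generator,
                      radius: float = 0.8) -> VARModel:
    """Draw a random stable VAR for property tests and self-checks.

    Coefficients are sampled i.i.d. Gaussian and the companion matrix is
    rescaled so its spectral radius equals ``radius``; Sigma is a random SPD
    matrix with unit-scale diagonal.
    """
    coeffs = rng.normal(scale=0.5 / np.sqrt(dim * order), size=(order, dim, dim))
    model = VARModel(coeffs=coeffs, sigma=np.eye(dim), order=order,
                     n_effective=10 * dim * order)
    rho = model.spectral_radius()
    if rho > 0:
        scale = radius / rho
        coeffs = np.stack([coeffs[k] * scale ** (k + 1) for k in range(order)])
    b = rng.normal(size=(dim, dim)) / np.sqrt(dim)
    sigma = b @ b.T + 0.5 * np.eye(dim)
    return dataclasses.replace(model, coeffs=coeffs, sigma=sigma)


def simulate_var(var: VARModel, n: int, rng: np.random.Generator,
                 burn_in: int = 500) -> np.ndarray:
    """Simulate n samples from a stable VAR (Gaussian innovations)."""
    if not var.is_stable():
        raise ValueError("cannot simulate an unstable VAR")
    d, p = var.dim, var.order
    chol = np.linalg.cholesky(ridge_floor(var.sigma, rel=1e-12))
    total = n + burn_in + p
    w = rng.standard_normal((total, d)) @ chol.T
    x = np.zeros((total, d))
    for t in range(p, total):
        acc = w[t].copy()
        for k in range(p):
            acc += var.coeffs[k] @ x[t - k - 1]
        x[t] = acc
    return x[burn_in + p :]
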