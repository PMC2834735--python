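"""Equilibrium, linearization, transfer function and Bode analysis.

A pathway model dx/dt = F(x, u), y = G(x, u) is reduced, near an
equilibrium (x*, u*), to the state-space form

    dδx/dt = A δx + B δu,   δy = C δx + D δu

with A = ∂F/∂x, B = ∂F/∂u, C = ∂G/∂x, D = ∂G/∂u evaluated at the
equilibrium, and then to the rational transfer function
H(s) = C (sI - A)^{-1} B + D.  The Bode representation reports
20·log10|H(iω)| in dB and the unwrapped phase in degrees, with ω an
angular frequency in s⁻¹ throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .pathways import PathwayModel

__all__ = [
    "StateSpaceModel",
    "RationalTransferFunction",
    "BodeTable",
    "find_equilibrium",
    "linearize_model",
    "transfer_function",
    "freq_response",
    "bode_table",
    "classify_filter",
    "EquilibriumError",
]

NEG_INF_DB = -np.inf  # sentinel magnitude for |H| = 0


class EquilibriumError(RuntimeError):
    """Newton iteration failed to find a pathway equilibrium."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class StateSpaceModel:
    A_mat: np.ndarray
    B_mat: np.ndarray
    C_mat: np.ndarray
    D_mat: np.ndarray
    x_eq: np.ndarray
    u_eq: float


@dataclass(frozen=True)
class RationalTransferFunction:
    """H(s) = num(s)/den(s) with real polynomial coefficients.

    Coefficients are in descending powers of s (numpy convention).
    """

    num: np.ndarray
    den: np.ndarray

    def __post_init__(self):
        num = np.trim_zeros(np.atleast_1d(np.asarray(self.num, float)), "f")
        den = np.trim_zeros(np.atleast_1d(np.asarray(self.den, float)), "f")
        if den.size == 0 or not np.any(den):
            raise ValueError("denominator is identically zero")
        if num.size == 0:
            num = np.zeros(1)
        if num.size > den.size:
            raise ValueError("improper transfer function (num degree > den degree)")
        object.__setattr__(self, "num", num)
        object.__setattr__(self, "den", den)

    def __call__(self, s):
        s = np.asarray(s, dtype=complex)
        return np.polyval(self.num, s) / np.polyval(self.den, s)

    @property
    def poles(self) -> np.ndarray:
        return np.roots(self.den)

    @property
    def zeros(self) -> np.ndarray:
        return np.roots(self.num)

    def dc_gain(self) -> float:
        return float(np.real(self(0.0)))

    def peak_gain(self, omega=None) -> float:
        """max over a log grid of |H(iω)|, including the ω→0 limit."""
        if omega is None:
            omega = np.logspace(-6, 5, 4000)
        mags = np.abs(self(1j * np.asarray(omega)))
        return float(max(mags.max(), abs(self.dc_gain())))


@dataclass(frozen=True)
class BodeTable:
    """Frequency response sampled on a grid: (ω s⁻¹, dB, unwrapped deg)."""

    omega: np.ndarray
    magnitude_db: np.ndarray
    phase_deg: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "omega_per_s": self.omega,
                "magnitude_db": self.magnitude_db,
                "phase_deg": self.phase_deg,
            }
        )


def _numeric_jacobian(f, x0, scale=1.0):
    """Central-difference Jacobian with per-component adaptive step."""
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    f0 = np.atleast_1d(np.asarray(f(x0), dtype=float))
    J = np.empty((f0.size, x0.size))
    for j in range(x0.size):
        h = 1e-6 * max(abs(x0[j]), scale)
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (np.atleast_1d(f(xp)) - np.atleast_1d(f(xm))) / (2 * h)
    return J


def find_equilibrium(model: PathwayModel, u0: float, guess=None,
                     max_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Solve F(x, u0) = 0 by damped Newton iteration.

    Converges when ||F|| <= tol * (1 + ||x||).  Raises
    :class:`EquilibriumError` (carrying the last residual) after
    ``max_iter`` iterations without convergence.
    """
    x = np.atleast_1d(np.asarray(
        guess if guess is not None else np.zeros(model.state_dim), dtype=float))
    F = lambda z: np.atleast_1d(np.asarray(model.deriv(z, u0), dtype=float))
    res = np.linalg.norm(F(x))
    for _ in range(max_iter):
        if res <= tol * (1 + np.linalg.norm(x)):
            return x
        J = _numeric_jacobian(F, x)
        try:
            step = np.linalg.solve(J, -F(x))
        except np.linalg.LinAlgError:
            step = -np.linalg.lstsq(J, F(x), rcond=None)[0]
        # backtracking damping on the residual norm
        lam = 1.0
        for _ in range(40):
            x_new = x + lam * step
            res_new = np.linalg.norm(F(x_new))
            if res_new < res:
                break
            lam *= 0.5
        else:
            raise EquilibriumError(
                f"Newton damping stalled at residual {res:.3e}", residual=res)
        x, res = x_new, res_new
    if res <= tol * (1 + np.linalg.norm(x)):
        return x
    raise EquilibriumError(
        f"no convergence in {max_iter} iterations; residual {res:.3e}",
        residual=res)


def linearize_model(model: PathwayModel, u0: float, guess=None) -> StateSpaceModel:
    """Linearize a pathway model about its equilibrium at input ``u0``."""
    x_eq = find_equilibrium(model, u0, guess=guess)
    F = lambda z: np.atleast_1d(np.asarray(model.deriv(z, u0), dtype=float))
    A = _numeric_jacobian(F, x_eq)
    hu = 1e-6 * max(abs(u0), 1.0)
    B = (np.atleast_1d(model.deriv(x_eq, u0 + hu))
         - np.atleast_1d(model.deriv(x_eq, u0 - hu))) / (2 * hu)
    B = np.asarray(B, dtype=float).reshape(-1, 1)
    G = lambda z: np.atleast_1d(float(model.output(z, u0)))
    C = _numeric_jacobian(G, x_eq)
    D = np.array([[(model.output(x_eq, u0 + hu)
                    - model.output(x_eq, u0 - hu)) / (2 * hu)]])
    return StateSpaceModel(A_mat=A, B_mat=B, C_mat=C, D_mat=D,
                           x_eq=x_eq, u_eq=float(u0))


def transfer_function(ss: StateSpaceModel) -> RationalTransferFunction:
    """H(s) = C (sI - A)^{-1} B + D in expanded polynomial form."""
    num, den = signal.ss2tf(ss.A_mat, ss.B_mat, ss.C_mat, ss.D_mat)
    num = np.atleast_2d(num)[0]
    # ss2tf leaves coefficients at round-off level; scrub them so that
    # structural zeros (e.g. H(0)=0 for adaptive pathways) are exact
    scale = max(np.abs(num).max(), 1e-300)
    num = np.where(np.abs(num) > 1e-9 * scale, num, 0.0)
    return RationalTransferFunction(num=num, den=den)


def freq_response(tf: RationalTransferFunction, omega) -> tuple:
    """(magnitude dB, phase deg) at angular frequency ``omega`` (s⁻¹).

    ω = 0 is only meaningful when |H(0)| > 0; a zero response yields the
    -inf dB sentinel.
    """
    H = tf(1j * np.asarray(omega, dtype=float))
    mag = np.abs(H)
    with np.errstate(divide="ignore"):
        mag_db = np.where(mag > 0, 20 * np.log10(np.where(mag > 0, mag, 1.0)),
                          NEG_INF_DB)
    phase = np.degrees(np.angle(H))
    if np.ndim(omega) == 0:
        return float(mag_db), float(phase)
    return mag_db, phase


def bode_table(tf: RationalTransferFunction, omega=None) -> BodeTable:
    """Sample H(iω) on a grid; phase is unwrapped, in degrees.

    Default grid: 200 log-spaced points over [1e-4, 1e3] s⁻¹.
    """
    if omega is None:
        omega = np.logspace(-4, 3, 200)
    omega = np.asarray(omega, dtype=float)
    H = tf(1j * omega)
    mag = np.abs(H)
    with np.errstate(divide="ignore"):
        mag_db = np.where(mag > 0, 20 * np.log10(np.where(mag > 0, mag, 1.0)),
                          NEG_INF_DB)
    phase = np.degrees(np.unwrap(np.angle(H)))
    return BodeTable(omega=omega, magnitude_db=mag_db, phase_deg=phase)


def classify_filter(tf: RationalTransferFunction) -> str:
    """Classify as ``band_pass``, ``low_pass`` or ``other``.

    band_pass: zero DC gain relative to a finite positive peak, decaying
    again at high frequency.  low_pass: DC gain equals the peak and the
    magnitude is non-increasing with frequency.  Anything else (e.g. a
    pure gain, or a high-pass) is ``other``.  Raises on unstable systems.
    """
    poles = tf.poles
    if poles.size and np.any(np.real(poles) >= 0):
        raise ValueError("transfer function is not stable")
    omega = np.logspace(-6, 6, 2000)
    mags = np.abs(tf(1j * omega))
    peak = mags.max()
    dc = abs(tf.dc_gain())
    if peak <= 0:
        return "other"
    hi = mags[-1]
    strictly_proper = tf.num.size < tf.den.size  # |H| -> 0 as omega -> inf
    if dc <= 1e-9 * peak:
        return "band_pass" if strictly_proper else "other"
    if abs(dc - peak) <= 1e-6 * peak and np.all(np.diff(mags) <= 1e-12 * peak):
        # constant magnitude (pure gain / all-pass) is not a low-pass
        return "low_pass" if hi < (1 - 1e-6) * peak else "other"
    return "other"
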