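"""Canonical chemotaxis controller filters and their exact time stepping.

The controller maps receptor occupancy (input, dimensionless) to a
[CheY-P] deviation from baseline (output, µM).  Two canonical forms are
provided, each normalized so that the *peak* Bode magnitude equals the
max amplification A:

* low-pass (non-adaptive, a first-order inertia link):
      H(s) = A ω0 / (s + ω0)
* band-pass (adaptive, a differential link feeding two inertia links):
      rank 2:  H(s) = A (ω1 + ω2) s / ((s + ω1)(s + ω2))
      rank 4:  H(s) = A (ω1 + ω2)² s² / ((s + ω1)² (s + ω2)²)
  both peak at ω = √(ω1 ω2) with |H| = A, and have H(0) = 0, the
  frequency-domain signature of perfect adaptation.

Time stepping uses the controllable-canonical state-space realization
advanced by zero-order-hold discretization, which is *exact* for
piecewise-constant input — there is no integration error at the motor
time scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .linearize import RationalTransferFunction

__all__ = [
    "ControllerFilter",
    "StepResponseSummary",
    "make_lowpass",
    "make_bandpass",
    "zoh_discretize",
    "lti_step_update",
    "step_response",
    "timing_summary",
]

CHEYP_BASELINE = 2.71  # µM, the unstimulated [CheY-P] (20% CW bias)


def make_lowpass(A: float, omega0: float) -> RationalTransferFunction:
    """First-order low-pass H(s) = A·ω0/(s + ω0); DC gain A."""
    if A < 0:
        raise ValueError("A must be non-negative")
    if omega0 <= 0:
        raise ValueError("omega0 must be positive")
    return RationalTransferFunction(num=[A * omega0], den=[1.0, omega0])


def make_bandpass(A: float, omega1: float, omega2: float,
                  rank: int = 2) -> RationalTransferFunction:
    """Band-pass with peak gain A at ω = √(ω1·ω2) and H(0) = 0.

    ``rank`` 2 uses one differentiator and two first-order lags; rank 4
    squares the whole form (same cut-offs, steeper ±40 dB/decade skirts).
    """
    if not 0 < omega1 < omega2:
        raise ValueError("need 0 < omega1 < omega2")
    if A < 0:
        raise ValueError("A must be non-negative")
    if rank == 2:
        K = A * (omega1 + omega2)
        den = np.convolve([1.0, omega1], [1.0, omega2])
        return RationalTransferFunction(num=[K, 0.0], den=den)
    if rank == 4:
        K = A * (omega1 + omega2) ** 2
        lag = np.convolve([1.0, omega1], [1.0, omega2])
        den = np.convolve(lag, lag)
        return RationalTransferFunction(num=[K, 0.0, 0.0], den=den)
    raise ValueError(f"rank must be 2 or 4, got {rank}")


def zoh_discretize(tf: RationalTransferFunction, dt: float):
    """Exact zero-order-hold discretization of H(s) over step ``dt``.

    Returns (Ad, Bd, C, D) of the controllable-canonical realization;
    with piecewise-constant input u_k the recursion
    x_{k+1} = Ad x_k + Bd u_k, y_k = C x_k + D u_k reproduces the
    continuous response at the sample times exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.any(tf.num):  # zero system: keep the realization, null output
        A, B, C, D = signal.tf2ss(np.ones(1), tf.den)
        C = np.zeros_like(C)
        D = np.zeros_like(D)
    else:
        A, B, C, D = signal.tf2ss(tf.num, tf.den)
    Ad, Bd, Cd, Dd, _ = signal.cont2discrete((A, B, C, D), dt, method="zoh")
    return Ad, Bd, Cd, Dd


@dataclass
class ControllerFilter:
    """A controller filter with internal LTI state for time stepping.

    ``sign`` sets the output convention: for attractant chemotaxis a rise
    in occupancy must *lower* [CheY-P] (suppress tumbling while running up
    the gradient), so the realized response is subtracted from baseline;
    the repellent convention adds it.
    """

    kind: str = "band_pass"          # "low_pass" | "band_pass"
    A: float = 16.0                  # µM CheY-P deviation per unit occupancy
    omega0: float = 5.0              # /s, low-pass cut-off
    omega1: float = 0.02             # /s, band-pass down cut-off
    omega2: float = 5.0              # /s, band-pass up cut-off
    rank: int = 2
    sign: str = "attractant"         # "attractant" | "repellent"
    baseline: float = CHEYP_BASELINE  # µM
    state: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.kind not in ("low_pass", "band_pass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.sign not in ("attractant", "repellent"):
            raise ValueError(f"unknown sign convention {self.sign!r}")
        tf = self.tf
        if self.state is None:
            self.state = np.zeros(len(tf.den) - 1)
        self._zoh_cache = {}

    @property
    def tf(self) -> RationalTransferFunction:
        if self.kind == "low_pass":
            return make_lowpass(self.A, self.omega0)
        return make_bandpass(self.A, self.omega1, self.omega2, self.rank)

    @property
    def sign_factor(self) -> float:
        return -1.0 if self.sign == "attractant" else 1.0

    def discretized(self, dt: float):
        if dt not in self._zoh_cache:
            self._zoh_cache[dt] = zoh_discretize(self.tf, dt)
        return self._zoh_cache[dt]

    def reset(self) -> None:
        self.state = np.zeros_like(self.state)

    def cheyp(self, deviation: float) -> float:
        """[CheY-P] = baseline + deviation, clipped below at zero."""
        return max(self.baseline + deviation, 0.0)


def lti_step_update(filt: ControllerFilter, u: float, dt: float) -> float:
    """Advance the filter state by one ZOH step; return the output deviation.

    ``u`` is the occupancy input held constant over ``dt``.  The returned
    deviation already carries the attractant/repellent sign.
    """
    Ad, Bd, C, D = filt.discretized(dt)
    x = filt.state.reshape(-1, 1)
    y = (C @ x + D * u).item()
    filt.state = (Ad @ x + Bd * u).ravel()
    return filt.sign_factor * y


def step_response(filt: ControllerFilter, step: float, T: float,
                  dt: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """[CheY-P] deviation response to an occupancy step of size ``step``.

    The input jumps from 0 to ``step`` at t = 0 (a negative ``step``
    models attractant removal).  Returns (times, deviation series); by
    strict properness the deviation at t = 0 is 0.  Sampling is exact at
    the grid points (ZOH on constant input).
    """
    n = int(round(T / dt))
    t = np.arange(n + 1) * dt
    Ad, Bd, C, D = filt.discretized(dt)
    x = np.zeros((Ad.shape[0], 1))
    out = np.empty(n + 1)
    for k in range(n + 1):
        out[k] = (C @ x + D * step).item()
        x = Ad @ x + Bd * step
    return t, filt.sign_factor * out


@dataclass(frozen=True)
class StepResponseSummary:
    """Timing summary of a single-peaked step response.

    tau2 (response time): stimulus to half-peak on the rising side.
    tau1 (adaptation time): stimulus to half-peak on the falling side.
    """

    tau1: float
    tau2: float
    peak: float
    peak_time: float


def _interp_crossing(t, y, level, lo, hi):
    """First crossing of ``level`` by y(t) on index range [lo, hi)."""
    seg_t, seg_y = t[lo:hi], y[lo:hi]
    above = seg_y >= level
    idx = np.nonzero(above[:-1] != above[1:])[0]
    if idx.size == 0:
        return None
    i = idx[0]
    t0, t1, y0, y1 = seg_t[i], seg_t[i + 1], seg_y[i], seg_y[i + 1]
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def timing_summary(t, deviation) -> StepResponseSummary:
    """Extract τ1/τ2 from a step-response trajectory.

    Works on the magnitude of the deviation, so either sign convention is
    accepted.  Raises if the trajectory is too short to contain the
    falling half-peak crossing (adaptation incomplete).
    """
    t = np.asarray(t, dtype=float)
    y = np.abs(np.asarray(deviation, dtype=float))
    k = int(np.argmax(y))
    peak = y[k]
    if peak <= 0:
        raise ValueError("flat trajectory: no peak to time against")
    half = peak / 2
    tau2 = _interp_crossing(t, y, half, 0, k + 1)
    tau1 = _interp_crossing(t, y, half, k, len(t))
    if tau2 is None:
        raise ValueError("no rising half-peak crossing found")
    if tau1 is None:
        raise ValueError(
            "no falling half-peak crossing: trajectory too short for tau1")
    return StepResponseSummary(tau1=float(tau1), tau2=float(tau2),
                               peak=float(peak), peak_time=float(t[k]))
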