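"""Chemotaxis pathway ODE models.

Two families of models are defined here:

* the designed three-molecule pathways (positive, negative and pseudo
  chemotaxis), in which ligand-bound receptor ``u`` drives an intermediate
  messenger ``v`` and the two together set the phosphorylation state of
  CheY; and
* a universal activation/deactivation network of ``n`` molecules, each
  switching between an inactive and an active form, with arbitrary
  cross-activation and cross-deactivation rates.

Both are exposed through the common :class:`PathwayModel` interface —
``deriv(state, u)`` and ``output(state, u)`` — which the linearization
machinery consumes.  The input convention throughout is receptor occupancy
``u = [L]/([L] + K_L)`` in [0, 1]; the output is [CheY-P] in µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

__all__ = [
    "Receptor",
    "DesignedPathway",
    "UniversalPathway",
    "PathwayModel",
    "receptor_occupancy",
    "designed_derivs",
    "designed_equilibrium",
    "universal_derivs",
    "embed_designed_in_universal",
]

Variant = Literal["positive", "negative", "pseudo"]

# Defaults reproduce, for every variant, the reference operating point:
# CheY-P equilibrium 2.71 µM (20% CW bias) out of Y_T = 6 µM total at the
# reference occupancy u* = 0.5, messenger deactivation rate (= down
# cut-off) 0.02 /s, and a denominator rate of the CheY equation of 5 /s.
# The positive and negative variants swap which arm is the strong one,
# so their default c_v / k_dephos values swap accordingly.
_YSTAR = 2.71
_YT = 6.0
_DV = 0.02
_KPHOS = 1.0
_RATE_SUM = 10.0  # k_phos*(c_v/d_v) + k_dephos
_KPHOS_R = _RATE_SUM * _YSTAR / _YT   # slow-arm strength, positive variant
_KDEPHOS = _RATE_SUM - _KPHOS_R
_CV = _DV * _KPHOS_R / _KPHOS
# pseudo variant: basal autophosphorylation tuned so that its equilibrium
# output matches 2.71 µM at u = 0.5 (comparable baseline motility)
_KAUTO = _YSTAR * _KPHOS * (_KPHOS_R * 0.5) / (_YT - _YSTAR)
_VARIANT_DEFAULTS = {
    # c_v, k_dephos per variant, all giving y* = 2.71 µM at u* = 0.5
    "positive": (_CV, _KDEPHOS),
    "negative": (_DV * _KDEPHOS / _KPHOS, _KPHOS_R),
    "pseudo": (_CV, _KDEPHOS),
}


@dataclass(frozen=True)
class Receptor:
    """Single-site ligand binding with dissociation scale ``K_L`` (µM)."""

    K_L: float = 1.0

    def __post_init__(self) -> None:
        if not self.K_L > 0:
            raise ValueError(f"K_L must be positive, got {self.K_L}")


def receptor_occupancy(L, receptor: Receptor | None = None):
    """Fraction of ligand-bound receptors, ``L / (L + K_L)``.

    Parameters
    ----------
    L : float or array
        Ligand concentration in µM; must be non-negative.
    receptor : Receptor, optional
        Binding model; defaults to ``K_L = 1`` µM.
    """
    receptor = receptor or Receptor()
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be non-negative")
    out = L / (L + receptor.K_L)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DesignedPathway:
    """Three-molecule designed chemotaxis pathway (u → v → CheY).

    ``variant`` selects the wiring:

    positive
        u produces active v and dephosphorylates CheY-P; v phosphorylates
        CheY.  The fast (direct) and slow (via v) arms cancel at steady
        state, so the equilibrium [CheY-P] is independent of u — a
        feedback-free "asymmetric clamp" with robust perfect adaptation.
    negative
        phosphorylation/dephosphorylation roles of u and v swapped;
        occupancy increases drive [CheY-P] up (repellent response).
    pseudo
        v dephosphorylates CheY-P against a constant basal
        autophosphorylation ``k_auto``; no fast arm, hence non-adaptive.
    """

    variant: Variant = "positive"
    c_v: float | None = None   # µM/s per unit occupancy
    d_v: float = _DV           # /s   (down cut-off of the linearization)
    k_phos: float = _KPHOS     # /µM/s
    k_dephos: float | None = None  # /s per unit occupancy
    Y_T: float = _YT           # µM total CheY
    k_auto: float = _KAUTO     # /s, pseudo variant only
    receptor: Receptor = field(default_factory=Receptor)

    def __post_init__(self) -> None:
        if self.variant not in ("positive", "negative", "pseudo"):
            raise ValueError(f"unknown variant {self.variant!r}")
        cv_default, kd_default = _VARIANT_DEFAULTS[self.variant]
        if self.c_v is None:
            object.__setattr__(self, "c_v", cv_default)
        if self.k_dephos is None:
            object.__setattr__(self, "k_dephos", kd_default)
        for name in ("c_v", "d_v", "k_phos", "k_dephos", "k_auto"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.Y_T > 0:
            raise ValueError("Y_T must be positive")

    def as_model(self) -> "PathwayModel":
        return PathwayModel(
            deriv=lambda x, u: np.asarray(designed_derivs(x, u, self)),
            output=lambda x, u: float(np.asarray(x)[..., 1]),
            state_dim=2,
            name=f"designed-{self.variant}",
        )


def designed_derivs(state, u, p: DesignedPathway):
    """Right-hand side ``(dv/dt, dy/dt)`` of the designed pathway.

    ``state`` is ``(v, y)`` with v the active-messenger concentration and
    y = [CheY-P], both µM; ``u`` is receptor occupancy.  Vectorized over
    leading axes of ``state``/``u``.
    """
    state = np.asarray(state, dtype=float)
    v, y = state[..., 0], state[..., 1]
    u = np.asarray(u, dtype=float)
    dv = p.c_v * u - p.d_v * v
    if p.variant == "positive":
        dy = p.k_phos * v * (p.Y_T - y) - p.k_dephos * u * y
    elif p.variant == "negative":
        dy = p.k_dephos * u * (p.Y_T - y) - p.k_phos * v * y
    elif p.variant == "pseudo":
        dy = p.k_auto * (p.Y_T - y) - p.k_phos * v * y
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown variant {p.variant!r}")
    return np.stack([dv, dy], axis=-1) if state.ndim > 1 else (float(dv), float(dy))


def designed_equilibrium(u: float, p: DesignedPathway) -> tuple[float, float]:
    """Closed-form equilibrium ``(v*, y*)`` at constant occupancy ``u``.

    For the positive and negative variants y* is independent of u (perfect
    adaptation); for the pseudo variant it is not.
    """
    if p.d_v == 0:
        raise ValueError("d_v = 0: messenger v has no equilibrium")
    vstar = p.c_v * u / p.d_v
    R = p.c_v / p.d_v  # v* per unit occupancy
    if p.variant == "positive":
        ystar = p.Y_T * p.k_phos * R / (p.k_phos * R + p.k_dephos)
    elif p.variant == "negative":
        ystar = p.Y_T * p.k_dephos / (p.k_dephos + p.k_phos * R)
    else:  # pseudo
        ystar = p.k_auto * p.Y_T / (p.k_auto + p.k_phos * vstar)
    return vstar, ystar


@dataclass(frozen=True)
class UniversalPathway:
    """Activation/deactivation network of ``n`` molecules.

    dy_i/dt = (y_it - y_i) * (C_ii + C_i u + sum_{j!=i} C_ij y_j)
              - y_i * (D_ii + D_i u + sum_{j!=i} D_ij y_j)

    ``C``/``D`` are (n, n) cross-(de)activation rate matrices whose
    diagonals are ignored (self rates live in ``C_self``/``D_self``);
    ``C_u``/``D_u`` are the receptor-driven rates.  The last molecule is
    CheY by convention (``output_index``).
    """

    y_t: np.ndarray
    C: np.ndarray
    D: np.ndarray
    C_self: np.ndarray
    D_self: np.ndarray
    C_u: np.ndarray
    D_u: np.ndarray
    receptor: Receptor = field(default_factory=Receptor)
    output_index: int = -1

    def __post_init__(self) -> None:
        n = len(np.atleast_1d(self.y_t))
        for name in ("C", "D"):
            if np.shape(getattr(self, name)) != (n, n):
                raise ValueError(f"{name} must be ({n}, {n})")
        for name in ("C_self", "D_self", "C_u", "D_u"):
            if np.shape(np.atleast_1d(getattr(self, name))) != (n,):
                raise ValueError(f"{name} must have length {n}")
        for name in ("C", "D", "C_self", "D_self", "C_u", "D_u"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} has negative rates")

    @property
    def n(self) -> int:
        return len(np.atleast_1d(self.y_t))

    def as_model(self) -> "PathwayModel":
        idx = self.output_index
        return PathwayModel(
            deriv=lambda x, u: universal_derivs(x, u, self),
            output=lambda x, u: float(np.asarray(x)[idx]),
            state_dim=self.n,
            name="universal",
        )


def universal_derivs(state, u, m: UniversalPathway) -> np.ndarray:
    """Derivative vector of the universal activation/deactivation model."""
    y = np.asarray(state, dtype=float)
    if y.shape[-1] != m.n:
        raise ValueError(f"state has {y.shape[-1]} entries, model has {m.n}")
    C = np.asarray(m.C, float).copy()
    D = np.asarray(m.D, float).copy()
    np.fill_diagonal(C, 0.0)
    np.fill_diagonal(D, 0.0)
    act = np.asarray(m.C_self, float) + np.asarray(m.C_u, float) * u + y @ C.T
    deact = np.asarray(m.D_self, float) + np.asarray(m.D_u, float) * u + y @ D.T
    return (np.asarray(m.y_t, float) - y) * act - y * deact


def embed_designed_in_universal(
    p: DesignedPathway, v_total: float = 1e15
) -> UniversalPathway:
    """Express a designed pathway as a 2-molecule universal network.

    The CheY equation maps exactly.  The messenger production c_v*u is
    zeroth order in v, i.e. the infinite-pool limit of the universal form
    (v_t - v)*C_u*u; with the default ``v_total`` the relative mismatch is
    below 1e-14 for states of order unity.
    """
    n = 2
    C = np.zeros((n, n))
    D = np.zeros((n, n))
    C_self = np.zeros(n)
    D_self = np.zeros(n)
    C_u = np.zeros(n)
    D_u = np.zeros(n)
    y_t = np.array([v_total, p.Y_T])
    C_u[0] = p.c_v / v_total
    D_self[0] = p.d_v
    if p.variant == "positive":
        C[1, 0] = p.k_phos     # v activates CheY
        D_u[1] = p.k_dephos    # receptor deactivates CheY
    elif p.variant == "negative":
        C_u[1] = p.k_dephos
        D[1, 0] = p.k_phos
    else:  # pseudo
        C_self[1] = p.k_auto
        D[1, 0] = p.k_phos
    return UniversalPathway(
        y_t=y_t, C=C, D=D, C_self=C_self, D_self=D_self,
        C_u=C_u, D_u=D_u, receptor=p.receptor,
    )


@dataclass(frozen=True)
class PathwayModel:
    """Generic input-driven ODE system dx/dt = F(x, u), y = G(x, u)."""

    deriv: Callable[[np.ndarray, float], np.ndarray]
    output: Callable[[np.ndarray, float], float]
    state_dim: int
    name: str = "pathway"
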