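"""Transient-structured stage-based projection matrix and its analysis.

The life cycle (pre-breeding census, annual time step) for a long-lived
colonial bird with delayed, age-spread recruitment and a survival cost of
first reproduction:

* ``N1`` (1-year-olds) survive to ``N2`` with ``phi2``;
* from ``N2`` onward, pre-breeders survive with adult survival ``phiA``
  and recruit at age ``i`` (3..7) with conditional probability
  ``gamma_i``; non-recruits move to the non-breeder state ``N_iNB``;
* every recruit spends its first breeding season in the first-time-breeder
  state ``N_iT``, where fertility is the reduced ``F'``; it survives out
  of that state to the experienced-breeder chain with ``phiA * (1 - tau_i)``
  — ``tau_i`` is the transient probability for animals first breeding at
  age ``i``, the matrix analogue of the reduced first-interval apparent
  survival of the capture-recapture transient model;
* experienced breeders ``N_iB`` survive with ``phiA`` (the age-7 breeder
  and non-breeder states are absorbing 7+ classes);
* pre-breeding-census fertility credits ``F * x * phi1`` (experienced) or
  ``F' * x * phi1`` (first-time) yearlings to ``N1``, with ``x`` the sex
  ratio and ``phi1`` first-year survival.

17 states: N1, N2, and (B, T, NB) for each age 3..7.

Asymptotics: dominant eigenvalue ``lambda`` (population growth rate),
stable stage structure ``w``, reproductive values ``v``, entry-level
sensitivities ``s_ij = v_i w_j`` and elasticities ``e_ij = a_ij s_ij /
lambda``, and lower-level (vital-rate) sensitivities by the chain rule
``dlambda/dp = sum_ij (da_ij/dp) s_ij``.  Every matrix entry is linear in
each scalar vital rate, so the entry derivatives obtained by central
differencing of the matrix builder are exact.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VitalRates",
    "ProjectionMatrix",
    "AsymptoticAnalysis",
    "build_matrix",
    "asymptotic_analysis",
    "vital_rate_sensitivities",
    "mean_rates",
    "GOOD_SEASON",
    "BAD_SEASON",
    "AGES",
    "SCALAR_RATES",
]

AGES = (3, 4, 5, 6, 7)
SCALAR_RATES = ("phi1", "phi2", "phiA", "F", "Fprime", "x")


@dataclass(frozen=True)
class VitalRates:
    """Complete parameter set of the transient-structured life cycle.

    ``phi1``/``phi2``/``phiA``: first-year, second-year and adult annual
    survival; ``tau``: transient probability by age at first breeding
    (3..7, 7 standing for 7+); ``gamma``: conditional probability of first
    breeding at age ``i`` given not yet recruited (values may sum past 1
    across ages — they are conditional, not a distribution); ``F`` and
    ``Fprime``: fledglings per breeding pair for experienced and
    first-time breeders; ``x``: sex ratio.
    """

    phi1: float
    phi2: float
    phiA: float
    tau: dict[int, float]
    gamma: dict[int, float]
    F: float
    Fprime: float
    x: float = 0.5

    def __post_init__(self):
        for name in ("phi1", "phi2", "phiA", "x"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.F < 0 or self.Fprime < 0:
            raise ValueError("fertilities must be non-negative")
        for name in ("tau", "gamma"):
            d = getattr(self, name)
            if set(d) != set(AGES):
                raise ValueError(f"{name} must be keyed by ages {AGES}")
            for i, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{i}]={v} outside [0, 1]")
        object.__setattr__(self, "tau", dict(self.tau))
        object.__setattr__(self, "gamma", dict(self.gamma))

    # -- flat parameter access (for sensitivities and LTRE) ------------------
    @staticmethod
    def parameter_names() -> list[str]:
        return (
            ["phi1", "phi2", "phiA"]
            + [f"tau{i}" for i in AGES]
            + [f"gamma{i}" for i in AGES]
            + ["F", "Fprime", "x"]
        )

    def get(self, name: str) -> float:
        if name.startswith("tau"):
            return self.tau[int(name[3:])]
        if name.startswith("gamma"):
            return self.gamma[int(name[5:])]
        return getattr(self, name)

    def with_value(self, name: str, value: float) -> "VitalRates":
        if name.startswith("tau"):
            d = dict(self.tau)
            d[int(name[3:])] = value
            return replace(self, tau=d)
        if name.startswith("gamma"):
            d = dict(self.gamma)
            d[int(name[5:])] = value
            return replace(self, gamma=d)
        return replace(self, **{name: value})

    def to_series(self) -> pd.Series:
        return pd.Series({n: self.get(n) for n in self.parameter_names()})


#: Point estimates for the two contrasted seasons of the gull case study
#: (best and worst environmental conditions observed over the monitoring
#: period).  gamma7 is a numerical placeholder (~0): recruitment above age
#: 6 is negligible and the 7+ classes are terminal conventions.
GOOD_SEASON = VitalRates(
    phi1=0.919, phi2=0.867, phiA=0.976,
    tau={3: 0.001, 4: 0.140, 5: 0.189, 6: 0.277, 7: 0.441},
    gamma={3: 0.389, 4: 0.483, 5: 0.369, 6: 0.201, 7: 1.0e-9},
    F=0.501, Fprime=0.262, x=0.5,
)

BAD_SEASON = VitalRates(
    phi1=0.653, phi2=0.867, phiA=0.912,
    tau={3: 0.022, 4: 0.150, 5: 0.446, 6: 0.616, 7: 0.853},
    gamma={3: 0.198, 4: 0.328, 5: 0.392, 6: 0.130, 7: 1.0e-9},
    F=0.212, Fprime=0.102, x=0.5,
)


def mean_rates(a: VitalRates, b: VitalRates) -> VitalRates:
    """Parameter-wise midpoint of two scenarios (the LTRE reference)."""
    out = a
    for name in VitalRates.parameter_names():
        out = out.with_value(name, 0.5 * (a.get(name) + b.get(name)))
    return out


STATE_LABELS = tuple(
    ["N1", "N2"] + [f"N{i}{s}" for i in AGES for s in ("B", "T", "NB")]
)
_IDX = {s: i for i, s in enumerate(STATE_LABELS)}


@dataclass
class ProjectionMatrix:
    """Labelled 17x17 yearly projection matrix (pre-breeding census)."""

    A: np.ndarray
    labels: tuple[str, ...] = STATE_LABELS
    census: str = "pre-breeding"

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.labels)
        if self.A.shape != (n, n):
            raise ValueError(f"matrix must be {n}x{n}")
        if (self.A < 0).any():
            raise ValueError("projection matrix entries must be non-negative")
        # survival outflow (everything except the fertility row) cannot
        # exceed 1 per column
        outflow = self.A[1:, :].sum(axis=0)
        if (outflow > 1.0 + 1e-9).any():
            raise ValueError("survival column sums exceed 1")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=list(self.labels),
                            columns=list(self.labels))


def build_matrix(vr: VitalRates) -> ProjectionMatrix:
    """Assemble the transient-structured projection matrix from vital rates."""
    n = len(STATE_LABELS)
    A = np.zeros((n, n))
    A[_IDX["N2"], _IDX["N1"]] = vr.phi2
    # N2 -> age-3 states (third-year survival maps to adult survival)
    A[_IDX["N3T"], _IDX["N2"]] = vr.phiA * vr.gamma[3]
    A[_IDX["N3NB"], _IDX["N2"]] = vr.phiA * (1.0 - vr.gamma[3])
    for i in AGES[:-1]:  # 3..6
        A[_IDX[f"N{i+1}T"], _IDX[f"N{i}NB"]] = vr.phiA * vr.gamma[i + 1]
        A[_IDX[f"N{i+1}NB"], _IDX[f"N{i}NB"]] = vr.phiA * (1.0 - vr.gamma[i + 1])
        A[_IDX[f"N{i+1}B"], _IDX[f"N{i}B"]] = vr.phiA
        A[_IDX[f"N{i+1}B"], _IDX[f"N{i}T"]] = vr.phiA * (1.0 - vr.tau[i])
    # 7+ terminal classes
    A[_IDX["N7B"], _IDX["N7B"]] = vr.phiA
    A[_IDX["N7B"], _IDX["N7T"]] = vr.phiA * (1.0 - vr.tau[7])
    A[_IDX["N7NB"], _IDX["N7NB"]] = vr.phiA * (1.0 - vr.gamma[7])
    A[_IDX["N7T"], _IDX["N7NB"]] = vr.phiA * vr.gamma[7]
    # pre-breeding-census fertilities into N1
    for i in AGES:
        A[_IDX["N1"], _IDX[f"N{i}B"]] = vr.F * vr.x * vr.phi1
        A[_IDX["N1"], _IDX[f"N{i}T"]] = vr.Fprime * vr.x * vr.phi1
    return ProjectionMatrix(A)


class DegenerateSpectrumError(RuntimeError):
    """Dominant eigenvalue is complex or not well separated."""


@dataclass
class AsymptoticAnalysis:
    """Eigenstructure and perturbation analysis of a projection matrix."""

    lam: float
    w: np.ndarray                 # stable stage distribution, sums to 1
    v: np.ndarray                 # reproductive values, <v, w> = 1
    entry_sensitivity: np.ndarray
    entry_elasticity: np.ndarray
    labels: tuple[str, ...]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        idx = list(self.labels)
        return {
            "w": pd.DataFrame({"state": idx, "w": self.w}),
            "v": pd.DataFrame({"state": idx, "v": self.v}),
            "sensitivity": pd.DataFrame(self.entry_sensitivity, index=idx, columns=idx),
            "elasticity": pd.DataFrame(self.entry_elasticity, index=idx, columns=idx),
        }


def asymptotic_analysis(M: ProjectionMatrix, tol: float = 1e-8) -> AsymptoticAnalysis:
    """Dominant eigenstructure, entry sensitivities and elasticities.

    Raises
    ------
    DegenerateSpectrumError
        If the dominant root has a non-negligible imaginary part or is not
        simple within tolerance.
    """
    A = M.A
    n = A.shape[0]
    eigvals, V = np.linalg.eig(A)
    rho = float(np.abs(eigvals).max())
    if rho < tol:
        # nilpotent limit: growth rate 0, structure degenerate but harmless
        w = np.full(n, 1.0 / n)
        v = np.ones(n)
        S = np.outer(v, w)
        return AsymptoticAnalysis(0.0, w, v, S, np.zeros_like(S), M.labels)
    # Perron root: the spectral radius itself must be an eigenvalue
    # (real, positive) and simple within tolerance.
    dist = np.abs(eigvals - rho)
    k = int(np.argmin(dist))
    if dist[k] > tol * max(rho, 1.0):
        raise DegenerateSpectrumError(
            f"spectral radius {rho} is not attained by a real eigenvalue"
        )
    # a *numerically identical* second root means a genuinely repeated
    # dominant eigenvalue; nearly-coincident but distinct roots (e.g. the
    # 7+ self-loops when fertility vanishes) are still analyzable
    rep_tol = 1e-12 * max(rho, 1.0)
    if int((dist <= rep_tol).sum()) > 1:
        raise DegenerateSpectrumError("dominant eigenvalue is repeated")
    lam = float(eigvals[k].real)
    w = V[:, k].real
    if w.sum() < 0:
        w = -w
    if (w < -tol).any():
        raise DegenerateSpectrumError("dominant right eigenvector changes sign")
    w = np.clip(w, 0.0, None)
    w = w / w.sum()

    eigvals_l, U = np.linalg.eig(A.T)
    kl = int(np.argmin(np.abs(eigvals_l - lam)))
    v = U[:, kl].real
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    v = v / (v @ w)

    S = np.outer(v, w)
    if lam == 0:
        E = np.zeros_like(S)
    else:
        E = A * S / lam
    return AsymptoticAnalysis(lam, w, v, S, E, M.labels)


def _dA_dp(vr: VitalRates, name: str, h: float = 1e-7) -> np.ndarray:
    """Entry-wise derivative of the matrix wrt one vital rate.

    Exact (to rounding) because every entry is multilinear in the scalar
    rates, so the central difference has no truncation error.
    """
    v0 = vr.get(name)
    step = h * (1.0 + abs(v0))
    lo = max(v0 - step, 0.0)
    hi = v0 + step
    if name not in ("F", "Fprime"):
        hi = min(hi, 1.0)
    up = build_matrix(vr.with_value(name, hi)).A
    dn = build_matrix(vr.with_value(name, lo)).A
    return (up - dn) / (hi - lo)


def vital_rate_sensitivities(
    vr: VitalRates,
    analysis: AsymptoticAnalysis | None = None,
) -> pd.DataFrame:
    """Lower-level sensitivity and elasticity of lambda to every vital rate.

    Chain rule over entries: ``dlambda/dp = sum_ij (da_ij/dp) v_i w_j``;
    elasticity ``(p / lambda) dlambda/dp``.  Aggregate rows ``tau_total``
    and ``gamma_total`` sum the per-age sensitivities (elasticities sum
    likewise).
    """
    if analysis is None:
        analysis = asymptotic_analysis(build_matrix(vr))
    S = analysis.entry_sensitivity
    lam = analysis.lam
    rows = {}
    for name in VitalRates.parameter_names():
        dA = _dA_dp(vr, name)
        sens = float((dA * S).sum())
        value = vr.get(name)
        elas = sens * value / lam if lam != 0 else np.nan
        rows[name] = {"value": value, "sensitivity": sens, "elasticity": elas}
    for agg, prefix in (("tau_total", "tau"), ("gamma_total", "gamma")):
        sub = [rows[f"{prefix}{i}"] for i in AGES]
        rows[agg] = {
            "value": sum(r["value"] for r in sub),
            "sensitivity": sum(r["sensitivity"] for r in sub),
            "elasticity": sum(r["elasticity"] for r in sub),
        }
    df = pd.DataFrame(rows).T
    df.index.name = "parameter"
    return df
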