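"""Linear stability and Hopf-bifurcation analysis of the myelosuppression model.

At the homeostatic equilibrium the Jacobian of the transit-compartment model
has characteristic relation

    mu * (mu + 1) ** (n_transit + 1) = -gamma,      mu = lambda / k,

which is dimensionless in ``mu``: the critical feedback exponent therefore
depends only on the chain length, never on ``circ0`` or ``mtt``.  The Hopf
condition (purely imaginary dominant pair, mu = i*omega) has the closed form

    omega   = tan(pi / (2 * (n_transit + 1)))
    gamma*  = omega * (1 + omega**2) ** ((n_transit + 1) / 2)

giving gamma* ~= 0.568542 for the standard three-transit chain.  Below gamma*
the equilibrium is asymptotically stable (monotone or damped-oscillatory
recovery after an insult); above it blood counts oscillate without settling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .hematopoiesis import ModelParams, steady_state

__all__ = [
    "StabilityReport",
    "jacobian_at_equilibrium",
    "eigenvalues",
    "characteristic_roots",
    "max_real_part",
    "classify",
    "hopf_gamma",
    "hopf_gamma_closed_form",
    "gamma_scan",
]

#: |Re lambda| below this (per hour) is treated as marginal rather than
#: stable/unstable; separates the measure-zero exact-Hopf case from numerics.
TOL_MARGINAL = 1e-9

CLASS_STABLE = "asymptotically stable (non-oscillatory)"
CLASS_STABLE_OSC = "asymptotically stable (damped oscillations)"
CLASS_MARGINAL = "marginal"
CLASS_UNSTABLE = "unstable (sustained/growing oscillations)"


@dataclass(frozen=True)
class StabilityReport:
    equilibrium: np.ndarray
    eigenvalues: np.ndarray
    max_real_part: float
    dominant_frequency: float
    classification: str
    gamma_star: float
    degenerate: bool = False  # gamma == 0: zero eigenvalue, decoupled pool

    def to_dict(self) -> dict:
        return {
            "equilibrium": self.equilibrium.tolist(),
            "eigenvalues": [[z.real, z.imag] for z in self.eigenvalues],
            "max_real_part_per_h": self.max_real_part,
            "dominant_frequency_per_h": self.dominant_frequency,
            "classification": self.classification,
            "gamma_star": self.gamma_star,
            "degenerate": self.degenerate,
        }


def jacobian_at_equilibrium(params: ModelParams) -> np.ndarray:
    """Jacobian of the model right-hand side at the homeostatic equilibrium.

    The proliferating row has zero self-term (production and exit cancel at
    equilibrium) and a ``-k * gamma`` coupling from the circulating pool; the
    remaining rows form the usual bidiagonal first-order chain.
    """
    k = params.k
    n = params.n_states
    J = np.zeros((n, n))
    J[0, -1] = -k * params.gamma
    for i in range(1, n):
        J[i, i - 1] = k
        J[i, i] = -k
    return J


def eigenvalues(params: ModelParams) -> np.ndarray:
    """Eigenvalues of the equilibrium Jacobian, per hour."""
    return np.linalg.eigvals(jacobian_at_equilibrium(params))


def characteristic_roots(gamma: float, n_transit: int, k: float = 1.0) -> np.ndarray:
    """Roots of mu (mu+1)^(n_transit+1) = -gamma, scaled by k.

    Independent route to the spectrum via the characteristic polynomial;
    used as the oracle against :func:`eigenvalues`.
    """
    m = n_transit + 1
    # mu * (mu + 1)^m + gamma = 0
    chain = np.polynomial.polynomial.polypow([1.0, 1.0], m)  # (1 + mu)^m, low->high
    poly = np.concatenate(([0.0], chain))  # multiply by mu
    poly[0] += gamma
    return k * np.polynomial.polynomial.polyroots(poly)


def max_real_part(params: ModelParams) -> float:
    return float(np.max(eigenvalues(params).real))


def _dominant(eigs: np.ndarray) -> complex:
    return eigs[int(np.argmax(eigs.real))]


def hopf_gamma_closed_form(n_transit: int) -> float:
    """Closed-form critical feedback exponent for a chain of given length."""
    if n_transit < 0:
        raise ValueError("n_transit must be >= 0")
    m = n_transit + 1
    omega = np.tan(np.pi / (2.0 * m))
    return float(omega * (1.0 + omega**2) ** (m / 2.0))


def hopf_gamma(
    params: ModelParams | None = None,
    n_transit: int | None = None,
    bracket: tuple[float, float] = (1e-3, 10.0),
    xtol: float = 1e-6,
) -> float:
    """Critical gamma* located by bracketed root-finding on max Re(lambda).

    The maximal real part is monotone increasing in gamma on the bracket for
    chains up to length ~10, so the smallest positive zero crossing is the
    Hopf point.  Independent of circ0 and mtt.
    """
    if params is None and n_transit is None:
        raise ValueError("provide params or n_transit")
    nt = params.n_transit if n_transit is None else n_transit
    base = ModelParams(circ0=1.0, mtt=float(nt + 1), gamma=0.0, n_transit=nt)  # k = 1

    def f(g: float) -> float:
        return max_real_part(ModelParams(circ0=1.0, mtt=base.mtt, gamma=g, n_transit=nt))

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise RuntimeError(
            f"no sign change of max Re(lambda) on gamma bracket {bracket} (n_transit={nt})"
        )
    return float(brentq(f, lo, hi, xtol=xtol))


def classify(params: ModelParams, tol_marginal: float = TOL_MARGINAL) -> StabilityReport:
    """Classify the equilibrium by its dominant eigenvalue pair."""
    eq = steady_state(params)
    eigs = eigenvalues(params)
    dom = _dominant(eigs)
    max_re = float(dom.real)
    freq = float(abs(dom.imag))
    degenerate = params.gamma == 0.0
    if abs(max_re) <= tol_marginal:
        cls = CLASS_MARGINAL
    elif max_re < 0:
        cls = CLASS_STABLE_OSC if freq > tol_marginal else CLASS_STABLE
    else:
        cls = CLASS_UNSTABLE
    return StabilityReport(
        equilibrium=eq,
        eigenvalues=eigs,
        max_real_part=max_re,
        dominant_frequency=freq,
        classification=cls,
        gamma_star=hopf_gamma(params),
        degenerate=degenerate,
    )


def gamma_scan(params: ModelParams, gamma_grid) -> pd.DataFrame:
    """Tabulate stability versus gamma at fixed chain and timing parameters.

    Returns one row per gamma with the maximal real part (per hour), dominant
    frequency (per hour), classification, and a degeneracy flag for gamma = 0.
    """
    rows = []
    for g in gamma_grid:
        if g < 0:
            raise ValueError("gamma grid values must be >= 0")
        p = ModelParams(circ0=params.circ0, mtt=params.mtt, gamma=float(g),
                        n_transit=params.n_transit)
        eigs = eigenvalues(p)
        dom = _dominant(eigs)
        max_re = float(dom.real)
        freq = float(abs(dom.imag))
        if g == 0 or abs(max_re) <= TOL_MARGINAL:
            cls = CLASS_MARGINAL
        elif max_re < 0:
            cls = CLASS_STABLE_OSC if freq > TOL_MARGINAL else CLASS_STABLE
        else:
            cls = CLASS_UNSTABLE
        rows.append(
            {
                "gamma": float(g),
                "max_re_per_h": max_re,
                "freq_per_h": freq,
                "classification": cls,
                "degenerate": bool(g == 0),
            }
        )
    return pd.DataFrame(rows)
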