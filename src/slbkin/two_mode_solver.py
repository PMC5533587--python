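"""Coupled two-mode thermodynamic model of receptor-membrane interaction.

A receptor samples two solution conformations that bind the membrane in a
Dynamic (mode 1) or Stable (mode 2) fashion, with per-mode binding
equilibrium constants K_x = k_x / k_off_x.  Measured apparent association
rates are k_x,app = f_x * k_x, where f_x is the solution fraction of
conformation x and f1 + f2 = 1 (mass conservation) for both the free
receptor and the SRP-bound complex.  Substituting gives one linear relation
per condition:

    1 = k1,app / (K1 * k_off1) + k2,app / (K2 * k_off2)

and the two conditions together form a 2x2 linear system in
x = 1/(K1*k_off1) and y = 1/(K2*k_off2), provided the two apparent-rate
vectors are not proportional.  The conformational equilibria follow as
K_cyto = f2/f1 (solution) and K_mem = P2/P1 (membrane populations), with
f_x recovered from f_x = P_x/K_x up to normalization; the construction
closes the thermodynamic cycle K_cyto * K2 = K_mem * K1 identically.

Unit convention: all K_x are dimensionless ratios of the apparent rates to
the dissociation rates at the reference condition of the measurements
(1 µM protein over a 6 µm² observation area); only ratios of K's enter the
reported quantities, so the convention cancels there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "TwoModeSolution",
    "FoldChangeReport",
    "solve_two_mode",
    "compute_equilibria",
    "summarize_fold_changes",
    "membrane_mode_bias",
]

CONDITION_NUMBER_CEILING = 1e6


@dataclass
class TwoModeSolution:
    """Solved per-mode equilibria and conformational fractions."""

    K1: float
    K2: float
    k1: float
    k2: float
    condition_number: float
    f1: float | None = None
    f2: float | None = None
    f1p: float | None = None
    f2p: float | None = None
    K_cyto: float | None = None
    K_cyto_complex: float | None = None
    K_mem: float | None = None
    K_mem_complex: float | None = None
    cycle_closure_residual: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TwoModeSolution":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rates(obj) -> tuple[float, float]:
    if hasattr(obj, "k1_app"):
        return float(obj.k1_app), float(obj.k2_app)
    k1, k2 = obj
    return float(k1), float(k2)


def solve_two_mode(free_rates, complex_rates, k_off1: float, k_off2: float) -> TwoModeSolution:
    """Solve the 2x2 linear system for K1, K2 (and k1, k2) from two conditions.

    ``free_rates`` / ``complex_rates`` provide (k1_app, k2_app) for the free
    receptor and the SRP-bound complex (ApparentAssociationRates or 2-tuples).
    """
    k1a, k2a = _rates(free_rates)
    k1ap, k2ap = _rates(complex_rates)
    if min(k1a, k2a, k1ap, k2ap) < 0 or k_off1 <= 0 or k_off2 <= 0:
        raise ValueError("apparent rates must be >= 0 and dissociation rates > 0")
    if k2a == 0 and k2ap == 0:
        raise ValueError("Stable mode unobserved in both conditions: K2 indeterminate")
    if k1a == 0 and k1ap == 0:
        raise ValueError("Dynamic mode unobserved in both conditions: K1 indeterminate")

    A = np.array([[k1a, k2a], [k1ap, k2ap]], dtype=float)
    cond = float(np.linalg.cond(A))
    if not np.isfinite(cond) or cond > CONDITION_NUMBER_CEILING:
        raise ValueError(
            "free and complex apparent-rate vectors are (near-)proportional: "
            f"2x2 system is degenerate (condition number {cond:.3g})"
        )
    x, y = np.linalg.solve(A, np.ones(2))
    if x <= 0 or y <= 0:
        raise ValueError(
            "model-inconsistent data: solved 1/(K*k_off) components are not positive"
        )
    K1 = 1.0 / (x * k_off1)
    K2 = 1.0 / (y * k_off2)
    return TwoModeSolution(
        K1=K1, K2=K2, k1=K1 * k_off1, k2=K2 * k_off2, condition_number=cond
    )


def compute_equilibria(sol: TwoModeSolution, free_pops, complex_pops) -> TwoModeSolution:
    """Fill in the conformational equilibria from membrane mode populations.

    ``free_pops`` / ``complex_pops`` carry the membrane-bound Dynamic/Stable
    fractions (P1, P2) for each condition.  Solution fractions are
    f_x = (P_x/K_x) / sum(P/K) — the normalization enforces mass conservation
    on top of the raw f_x = P_x/K_x relation.
    """
    for pops, tag in ((free_pops, "free"), (complex_pops, "complex")):
        if pops.P1 <= 0:
            raise ValueError(f"{tag} condition has P1 = 0: K_mem undefined")

    def fractions(pops):
        raw = np.array([pops.P1 / sol.K1, pops.P2 / sol.K2])
        return raw / raw.sum()

    f = fractions(free_pops)
    fp = fractions(complex_pops)
    sol.f1, sol.f2 = float(f[0]), float(f[1])
    sol.f1p, sol.f2p = float(fp[0]), float(fp[1])
    sol.K_cyto = sol.f2 / sol.f1
    sol.K_cyto_complex = sol.f2p / sol.f1p
    sol.K_mem = free_pops.P2 / free_pops.P1
    sol.K_mem_complex = complex_pops.P2 / complex_pops.P1
    sol.cycle_closure_residual = abs(sol.K_cyto * sol.K2 / (sol.K_mem * sol.K1) - 1.0)
    return sol


@dataclass
class FoldChangeReport:
    """SRP-induced shifts of the conformational equilibria and the mode-rate ratio."""

    K_cyto_fold: float
    K_mem_fold: float
    k1_over_k2: float


def summarize_fold_changes(free: TwoModeSolution, complex: TwoModeSolution | None = None) -> FoldChangeReport:
    """Fold changes between conditions.

    With a single fully solved ``TwoModeSolution`` (both conditions filled in),
    pass it alone; alternatively pass two solutions solved separately.
    """
    if complex is None:
        if free.K_cyto is None or free.K_cyto_complex is None:
            raise ValueError("solution lacks equilibria; run compute_equilibria first")
        return FoldChangeReport(
            K_cyto_fold=free.K_cyto_complex / free.K_cyto,
            K_mem_fold=free.K_mem_complex / free.K_mem,
            k1_over_k2=free.k1 / free.k2,
        )
    return FoldChangeReport(
        K_cyto_fold=complex.K_cyto / free.K_cyto,
        K_mem_fold=complex.K_mem / free.K_mem,
        k1_over_k2=free.k1 / free.k2,
    )


def membrane_mode_bias(k1_app: float, k2_app: float, k_off1: float, k_off2: float) -> float:
    """Membrane enhancement of the Dynamic-to-Stable equilibrium, K_mem/K_cyto.

    By cycle closure K_mem/K_cyto = K2/K1; evaluated from apparent rates this
    is (k2_app/k_off2) / (k1_app/k_off1).
    """
    return (k2_app / k_off2) / (k1_app / k_off1)
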