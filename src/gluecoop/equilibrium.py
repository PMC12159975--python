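"""Three-body binding equilibrium: species concentrations, kinetics, titration.

The mass-action system of the six reversible associations couples seven
species (A, L, B, AL, LB, AB, ALB).  At equilibrium every complex is a
rational function of the free monomer concentrations:

    [AL]  = [A][L] / kd_A_L          [LB] = [L][B] / kd_L_B
    [AB]  = [A][B] / kd_A_B          [ALB] = [A][L][B] / K_ALB

with K_ALB = [A][L][B]/[ALB] the ternary formation product (equal along all
three paths when the cycle closes).  Mass conservation then reduces the
problem to three unknowns — the free monomers — solved here by a damped
Newton iteration in log-concentration space (which keeps every concentration
strictly positive), with a quasi-Newton fallback.

``integrate_kinetics`` integrates the full 7-species ODE system from the
rate constants and serves as an independent brute-force oracle for the
algebraic solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .constants import DEFAULT_TEMPERATURE, R_KCAL
from .thermo import BindingConstants, RateConstants

__all__ = [
    "Totals",
    "SpeciesState",
    "TitrationCurve",
    "RecruitmentSummary",
    "EquilibriumError",
    "solve_equilibrium",
    "integrate_kinetics",
    "titration_curve",
    "recruitment_summary",
    "alpha_from_state",
]

SPECIES = ("A", "L", "B", "AL", "LB", "AB", "ALB")


class EquilibriumError(RuntimeError):
    """Equilibrium solver failed to converge; carries final residuals."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class Totals:
    """Total (analytic) concentrations of the three components, molar."""

    a_total: float
    l_total: float
    b_total: float

    def __post_init__(self):
        for name in ("a_total", "l_total", "b_total"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"Totals.{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium (or instantaneous) concentrations of the seven species."""

    conc_A: float
    conc_L: float
    conc_B: float
    conc_AL: float
    conc_LB: float
    conc_AB: float
    conc_ALB: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.conc_A, self.conc_L, self.conc_B, self.conc_AL,
             self.conc_LB, self.conc_AB, self.conc_ALB]
        )

    def totals(self) -> Totals:
        """Component totals implied by this state (mass-balance sums)."""
        return Totals(
            a_total=self.conc_A + self.conc_AL + self.conc_AB + self.conc_ALB,
            l_total=self.conc_L + self.conc_AL + self.conc_LB + self.conc_ALB,
            b_total=self.conc_B + self.conc_LB + self.conc_AB + self.conc_ALB,
        )

    @staticmethod
    def from_array(y: Sequence[float]) -> "SpeciesState":
        return SpeciesState(*[float(v) for v in y])


@dataclass(frozen=True)
class RecruitmentSummary:
    """Summary of a recruitment (titration) curve.

    ``a_max_pct`` is the maximal ternary concentration as a percentage of the
    ligand-free baseline; ``c_at_threshold_M`` the smallest total ligand
    concentration at which the percentage first crosses the threshold (None
    if never reached), and ``rt_ln_c`` its RT ln C transform (C in molar).
    ``baseline_mode`` records which ligand-free species served as baseline.
    """

    a_max_pct: float
    threshold_pct: float
    c_at_threshold_M: float | None
    rt_ln_c: float | None
    baseline_mode: str
    baseline_conc_M: float
    temperature: float


@dataclass(frozen=True)
class TitrationCurve:
    """Equilibrium states along a total-ligand grid at fixed protein totals."""

    a_total: float
    b_total: float
    l_totals: tuple[float, ...]
    states: tuple[SpeciesState, ...]
    constants: BindingConstants
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if len(self.l_totals) != len(self.states):
            raise ValueError("l_totals and states must have equal length")
        grid = np.asarray(self.l_totals)
        if len(grid) >= 2 and not np.all(np.diff(grid) > 0):
            raise ValueError("l_totals must be strictly increasing")

    @property
    def alb(self) -> np.ndarray:
        return np.array([s.conc_ALB for s in self.states])


def _reduced_residual(log_free, totals_vec, kd_al, kd_lb, kd_ab, k_alb):
    """Mass-balance residuals and Jacobian in log free-monomer space.

    Residuals are scaled by each component's total, so convergence is
    relative.  Only components with nonzero totals appear.
    """
    a, l, b = np.exp(log_free)
    c_al = a * l / kd_al
    c_lb = l * b / kd_lb
    c_ab = a * b / kd_ab
    c_alb = a * l * b / k_alb
    f = np.array(
        [
            a + c_al + c_ab + c_alb - totals_vec[0],
            l + c_al + c_lb + c_alb - totals_vec[1],
            b + c_lb + c_ab + c_alb - totals_vec[2],
        ]
    )
    # d residual_i / d log(monomer_j): each complex term contributes itself
    # for every monomer it contains.
    jac = np.array(
        [
            [a + c_al + c_ab + c_alb, c_al + c_alb, c_ab + c_alb],
            [c_al + c_alb, l + c_al + c_lb + c_alb, c_lb + c_alb],
            [c_ab + c_alb, c_lb + c_alb, b + c_lb + c_ab + c_alb],
        ]
    )
    return f / totals_vec, jac / totals_vec[:, None]


def _assemble_state(a, l, b, kd_al, kd_lb, kd_ab, k_alb) -> SpeciesState:
    return SpeciesState(
        conc_A=a,
        conc_L=l,
        conc_B=b,
        conc_AL=a * l / kd_al,
        conc_LB=l * b / kd_lb,
        conc_AB=a * b / kd_ab,
        conc_ALB=a * l * b / k_alb,
    )


def solve_equilibrium(
    totals: Totals,
    constants: BindingConstants,
    rtol: float = 1e-12,
    max_iter: int = 200,
) -> SpeciesState:
    """Equilibrium species concentrations from totals and binding constants.

    Reduces the system to the three free monomer concentrations and solves
    the scaled mass-balance equations by damped Newton iteration in log
    space; falls back to scipy's hybrid Powell method if Newton stalls.
    Components with zero total are eliminated analytically.

    Raises
    ------
    EquilibriumError
        If the residual infinity-norm does not fall below ``rtol`` within
        ``max_iter`` Newton iterations nor via the fallback solver.
    """
    tot = np.array([totals.a_total, totals.l_total, totals.b_total])
    kd_al, kd_lb, kd_ab = constants.kd_A_L, constants.kd_L_B, constants.kd_A_B
    k_alb = constants.ternary_formation_product()

    if np.all(tot == 0):
        return SpeciesState(0, 0, 0, 0, 0, 0, 0)

    present = tot > 0
    # Zero-total components: free conc is 0; treat them by collapsing to a
    # smaller system with their Kd couplings switched off.
    eff_tot = np.where(present, tot, 1.0)  # placeholder scale for absent ones

    def residual_full(log_free):
        f, jac = _reduced_residual(log_free, eff_tot, kd_al, kd_lb, kd_ab, k_alb)
        return f, jac

    # Absent components are pinned far below everything else so their
    # contributions vanish numerically; solve only the present block.
    scale = max(tot.max(), 1e-30)
    log_free = np.log(np.where(present, np.maximum(tot, 1e-300), 1e-300))
    pinned = np.log(1e-300)

    def masked_residual(x_present):
        full = np.where(present, 0.0, pinned)
        full[present] = x_present
        f, jac = residual_full(full)
        return f[present], jac[np.ix_(present, present)]

    x = log_free[present]
    f, jac = masked_residual(x)
    norm = np.max(np.abs(f))
    for _ in range(max_iter):
        if norm < rtol:
            break
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            step = -f
        # Damped line search on the residual norm; cap the log-step to keep
        # the iteration inside representable range.
        step = np.clip(step, -50, 50)
        lam = 1.0
        for _ in range(60):
            x_new = x + lam * step
            f_new, jac_new = masked_residual(x_new)
            if np.max(np.abs(f_new)) < norm:
                break
            lam *= 0.5
        else:
            break  # no descent; go to fallback
        x, f, jac = x_new, f_new, jac_new
        norm = np.max(np.abs(f))

    if norm >= rtol:
        sol = root(lambda v: masked_residual(v)[0], x, jac=lambda v: masked_residual(v)[1],
                   method="hybr", tol=1e-15)
        if sol.success:
            x = sol.x
            f, _ = masked_residual(x)
            norm = np.max(np.abs(f))
    if norm >= rtol:
        raise EquilibriumError(
            f"equilibrium solver did not converge (residual {norm:.3e}, "
            f"target {rtol:.1e})",
            residuals=f,
        )

    full = np.where(present, 0.0, -np.inf)
    full[present] = x
    a, l, b = np.exp(full)
    state = _assemble_state(a, l, b, kd_al, kd_lb, kd_ab, k_alb)
    if min(state.as_array()) < 0:
        raise EquilibriumError("internal error: negative concentration at solution")
    return state


def _rhs_factory(rates: RateConstants):
    v1p, v1m = rates.v1_on, rates.v1_off
    u1p, u1m = rates.u1_on, rates.u1_off
    r1p, r1m = rates.r1_on, rates.r1_off
    v2p, v2m = rates.v2_on, rates.v2_off
    u2p, u2m = rates.u2_on, rates.u2_off
    r2p, r2m = rates.r2_on, rates.r2_off

    def rhs(_t, y):
        a, l, b, al, lb, ab, alb = y
        f1 = v1p * a * l - v1m * al        # A + L <-> AL
        f2 = u1p * l * b - u1m * lb        # L + B <-> LB
        f3 = r1p * a * b - r1m * ab        # A + B <-> AB
        f4 = v2p * al * b - v2m * alb      # AL + B <-> ALB
        f5 = u2p * lb * a - u2m * alb      # LB + A <-> ALB
        f6 = r2p * ab * l - r2m * alb      # AB + L <-> ALB
        return np.array(
            [
                -f1 - f3 - f5,
                -f1 - f2 - f6,
                -f2 - f3 - f4,
                f1 - f4,
                f2 - f5,
                f3 - f6,
                f4 + f5 + f6,
            ]
        )

    def jac(_t, y):
        a, l, b, al, lb, ab, alb = y
        d = np.zeros((7, 7))
        # flux derivatives
        rows = [
            (0, [(0, v1p * l), (1, v1p * a), (3, -v1m)]),                  # f1
            (1, [(1, u1p * b), (2, u1p * l), (4, -u1m)]),                  # f2
            (2, [(0, r1p * b), (2, r1p * a), (5, -r1m)]),                  # f3
            (3, [(3, v2p * b), (2, v2p * al), (6, -v2m)]),                 # f4
            (4, [(4, u2p * a), (0, u2p * lb), (6, -u2m)]),                 # f5
            (5, [(5, r2p * l), (1, r2p * ab), (6, -r2m)]),                 # f6
        ]
        dflux = np.zeros((6, 7))
        for i, entries in rows:
            for j, val in entries:
                dflux[i, j] = val
        mat = np.array(
            [
                [-1, 0, -1, 0, -1, 0],
                [-1, -1, 0, 0, 0, -1],
                [0, -1, -1, -1, 0, 0],
                [1, 0, 0, -1, 0, 0],
                [0, 1, 0, 0, -1, 0],
                [0, 0, 1, 0, 0, -1],
                [0, 0, 0, 1, 1, 1],
            ],
            dtype=float,
        )
        return mat @ dflux

    return rhs, jac


def integrate_kinetics(
    totals: Totals,
    rates: RateConstants,
    t_end: float,
    n_points: int = 50,
    initial_state: SpeciesState | None = None,
    rtol: float = 1e-10,
    atol_scale: float = 1e-16,
) -> tuple[np.ndarray, list[SpeciesState]]:
    """Integrate the 7-species mass-action ODE system.

    Starts from free monomers at their totals (or from ``initial_state``) and
    returns ``n_points`` states sampled on a geometric time grid up to
    ``t_end``.  Uses a stiff (BDF) integrator with an analytic Jacobian.
    """
    if not (math.isfinite(t_end) and t_end > 0):
        raise ValueError(f"t_end must be positive, got {t_end!r}")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if initial_state is None:
        y0 = np.array([totals.a_total, totals.l_total, totals.b_total, 0, 0, 0, 0],
                      dtype=float)
    else:
        y0 = initial_state.as_array()
    scale = max(totals.a_total, totals.l_total, totals.b_total, 1e-30)
    rhs, jac = _rhs_factory(rates)
    t_eval = np.geomspace(t_end * 1e-6, t_end, n_points - 1)
    t_eval = np.concatenate([[0.0], t_eval])
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="BDF", jac=jac, t_eval=t_eval,
        rtol=rtol, atol=atol_scale * scale,
    )
    if not sol.success:
        raise EquilibriumError(
            "stiff integration failed: " + sol.message
            + " (consider loosening rtol/atol or shortening t_end)"
        )
    states = [SpeciesState.from_array(np.clip(y, 0, None)) for y in sol.y.T]
    return sol.t, states


def kinetic_steady_state(
    totals: Totals,
    rates: RateConstants,
    t_start: float | None = None,
    rel_change_tol: float = 1e-9,
    max_decades: int = 30,
) -> SpeciesState:
    """Steady state of the kinetic model, by integrating until relaxation.

    Doubles the integration horizon decade by decade until the relative state
    change per decade of time falls below ``rel_change_tol``.
    """
    scale = max(totals.a_total, totals.l_total, totals.b_total, 1e-30)
    if t_start is None:
        # Rough association timescale: 1/(fastest on-rate * concentration).
        fastest = max(rates.v1_on, rates.u1_on, rates.r1_on,
                      rates.v2_on, rates.u2_on, rates.r2_on)
        t_start = 1.0 / (fastest * scale)
    t_end = t_start
    _, states = integrate_kinetics(totals, rates, t_end, n_points=5)
    prev = states[-1].as_array()
    for _ in range(max_decades):
        t_end *= 10.0
        _, states = integrate_kinetics(
            totals, rates, t_end, n_points=5, initial_state=states[-1]
        )
        cur = states[-1].as_array()
        if np.max(np.abs(cur - prev)) < rel_change_tol * scale:
            return states[-1]
        prev = cur
    raise EquilibriumError(
        f"kinetic steady state not reached within {max_decades} decades of time"
    )


def titration_curve(
    a_total: float,
    b_total: float,
    l_grid: Sequence[float],
    constants: BindingConstants,
    temperature: float = DEFAULT_TEMPERATURE,
) -> TitrationCurve:
    """Equilibrium solved at each total-ligand concentration of the grid."""
    grid = [float(v) for v in l_grid]
    if len(grid) < 3:
        raise ValueError("l_grid must contain at least 3 points")
    if not all(b > a for a, b in zip(grid, grid[1:])):
        raise ValueError("l_grid must be strictly increasing")
    states = []
    for l_tot in grid:
        try:
            states.append(
                solve_equilibrium(Totals(a_total, l_tot, b_total), constants)
            )
        except EquilibriumError as exc:
            raise EquilibriumError(
                f"titration failed at l_total={l_tot:g} M: {exc}"
            ) from exc
    return TitrationCurve(
        a_total=a_total,
        b_total=b_total,
        l_totals=tuple(grid),
        states=tuple(states),
        constants=constants,
        temperature=temperature,
    )


def recruitment_summary(
    curve: TitrationCurve, threshold_pct: float = 400.0
) -> RecruitmentSummary:
    """A_max-style summary of a recruitment curve.

    The percentage scale is ternary-complex concentration relative to the
    ligand-free baseline.  The ligand-free ternary concentration is exactly
    zero in this model (ALB requires L), so the baseline defaults to the
    ligand-free protein-protein complex AB — the glue-free recruitment level
    — recorded as ``baseline_mode="AB"``.
    """
    baseline_state = solve_equilibrium(
        Totals(curve.a_total, 0.0, curve.b_total), curve.constants
    )
    if baseline_state.conc_ALB > 0:
        baseline = baseline_state.conc_ALB
        mode = "ALB"
    else:
        baseline = baseline_state.conc_AB
        mode = "AB"
    if baseline <= 0:
        raise ValueError(
            "ligand-free baseline is zero (no A-B affinity); report absolute "
            "concentrations instead of percent recruitment"
        )
    pct = 100.0 * curve.alb / baseline
    a_max = float(np.max(pct))
    c_at = None
    rt_ln_c = None
    if a_max >= threshold_pct:
        idx = int(np.argmax(pct >= threshold_pct))
        if idx == 0:
            c_at = curve.l_totals[0]
        else:
            # linear interpolation between the bracketing grid points
            x0, x1 = curve.l_totals[idx - 1], curve.l_totals[idx]
            y0, y1 = pct[idx - 1], pct[idx]
            c_at = x0 + (threshold_pct - y0) * (x1 - x0) / (y1 - y0)
        if c_at > 0:
            rt_ln_c = R_KCAL * curve.temperature * math.log(c_at)
    return RecruitmentSummary(
        a_max_pct=a_max,
        threshold_pct=threshold_pct,
        c_at_threshold_M=c_at,
        rt_ln_c=rt_ln_c,
        baseline_mode=mode,
        baseline_conc_M=baseline,
        temperature=curve.temperature,
    )


def alpha_from_state(
    state: SpeciesState, constants: BindingConstants
) -> tuple[float, float, float]:
    """The concentration-based cooperativity expressions.

    alpha_1 = kd_A_L * kd_L_B * [ALB] / ([A][L][B]), and analogously with
    kd_A_L * kd_A_B (alpha_2) and kd_L_B * kd_A_B (alpha_3).  For a state
    produced by :func:`solve_equilibrium` these coincide with the Kd-ratio
    alphas — the numerical statement of pathway independence.
    """
    a, l, b = state.conc_A, state.conc_L, state.conc_B
    if min(a, l, b) <= 0:
        raise ValueError("free monomer concentrations must all be positive")
    core = state.conc_ALB / (a * l * b)
    return (
        constants.kd_A_L * constants.kd_L_B * core,
        constants.kd_A_L * constants.kd_A_B * core,
        constants.kd_L_B * constants.kd_A_B * core,
    )
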