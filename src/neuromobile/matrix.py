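"""The neurochemical interaction matrix: a six-transmitter power-law ODE system.

Following Biochemical Systems Theory, each transmitter ``i`` obeys a
generalized-mass-action equation

    dX_i/dt = p_i * prod_j X_j ** g[i, j]  -  d_i * k_i * X_i

where ``g`` is the kinetic-order matrix (sign encodes activation / inhibition),
``k_i`` a first-order degradation rate constant, and ``p_i``, ``d_i``
piecewise-constant multiplicative modifiers representing perturbations such as
alcohol exposure or drugs (both 1 in the unperturbed system).  The production
rate coefficient is 1; all scale is carried by the degradation constants,
which are calibrated so that the reference intensity profile is a steady state:

    k_i = prod_j X_j(baseline) ** g[i, j] / X_i(baseline)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .transmitters import (
    N_TRANSMITTERS,
    TRANSMITTER_INDEX,
    TRANSMITTERS,
    TransmitterProfile,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for typing only
    from .scenarios import ModifierSchedule, ModifierSet

__all__ = [
    "DEFAULT_KINETIC_ORDERS",
    "DEFAULT_BASELINE",
    "PRINTED_DEGRADATION_RATES",
    "MatrixModel",
    "Trajectory",
    "IntegrationError",
    "SteadyStateError",
    "kinetic_orders_from_dict",
    "production_flux",
    "derivatives",
    "calibrate_degradation",
    "integrate",
    "find_steady_state",
]


def _orders_array(spec: Mapping[str, Mapping[str, float]]) -> np.ndarray:
    g = np.zeros((N_TRANSMITTERS, N_TRANSMITTERS))
    for target, row in spec.items():
        i = TRANSMITTER_INDEX[target]
        for source, exponent in row.items():
            j = TRANSMITTER_INDEX[source]
            if i == j and exponent != 0:
                raise ValueError(
                    f"self kinetic order for {target} must be 0 "
                    "(no production term contains its own product)"
                )
            g[i, j] = float(exponent)
    return g


def kinetic_orders_from_dict(
    spec: Mapping[str, Mapping[str, float]]
) -> np.ndarray:
    """Build a kinetic-order matrix from ``{target: {source: exponent}}``.

    Row ``i`` holds the exponents of every transmitter in the production term
    of transmitter ``i``; the diagonal must be zero.
    """
    return _orders_array(spec)


#: Kinetic orders of the interaction network: row = produced transmitter,
#: column = regulating transmitter.  Positive = activation, negative =
#: inhibition; the network is fully connected apart from self-terms.
DEFAULT_KINETIC_ORDERS: np.ndarray = _orders_array(
    {
        "DA": {"ACh": 0.5, "HT": 0.2, "Glu": 0.5, "NA": 0.5, "GABA": -0.3},
        "ACh": {"DA": -0.3, "HT": -0.3, "Glu": 0.5, "NA": -0.3, "GABA": -0.3},
        "HT": {"DA": -0.2, "ACh": 0.5, "Glu": 0.5, "NA": -0.3, "GABA": -0.3},
        "Glu": {"DA": -0.3, "ACh": 0.5, "HT": 0.5, "NA": 0.5, "GABA": -0.3},
        "NA": {"DA": 0.5, "ACh": 0.5, "HT": 0.5, "Glu": 0.5, "GABA": -0.3},
        "GABA": {"DA": -0.3, "ACh": 0.5, "HT": -0.3, "Glu": 0.5, "NA": -0.3},
    }
)
DEFAULT_KINETIC_ORDERS.flags.writeable = False

#: Reference intensities under the categorized weighting scheme
#: (low = 100, medium = 150, high = 200).
DEFAULT_BASELINE = TransmitterProfile([100.0, 100.0, 100.0, 100.0, 200.0, 150.0])

#: Degradation rate constants as printed in the source model description
#: (rounded there to 7 significant digits); the package's own calibration
#: reproduces them to better than 1e-6 relative.
PRINTED_DEGRADATION_RATES: dict[str, float] = {
    "HT": 0.03145485,
    "DA": 7.901101,
    "NA": 31.45485,
    "ACh": 0.0004985258,
    "Glu": 0.2793461,
    "GABA": 0.01494252,
}


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails within a schedule phase."""


class SteadyStateError(RuntimeError):
    """Raised when steady-state iteration does not converge."""


def production_flux(
    profile: TransmitterProfile,
    orders: np.ndarray,
    target: str,
) -> float:
    """Power-law production flux of ``target`` at the given intensities.

    Returns ``prod_j X_j ** g[target, j]`` (rate coefficient 1).
    """
    i = TRANSMITTER_INDEX[target]
    x = profile.values
    return float(np.exp(np.dot(np.asarray(orders)[i], np.log(x))))


def _production_all(x: np.ndarray, orders: np.ndarray) -> np.ndarray:
    return np.exp(orders @ np.log(x))


def calibrate_degradation(
    baseline: TransmitterProfile, orders: np.ndarray
) -> np.ndarray:
    """Degradation rate constants that make ``baseline`` a fixed point.

    At steady state production equals degradation, so
    ``k_i = flux_i(baseline) / baseline_i`` for each transmitter.
    """
    x = baseline.values
    return _production_all(x, np.asarray(orders, dtype=float)) / x


@dataclass(frozen=True)
class MatrixModel:
    """Kinetic orders, degradation rates and baseline of the interaction matrix.

    By construction of :func:`calibrate_degradation` the baseline is a steady
    state of the unperturbed system; this is validated on construction.
    """

    orders: np.ndarray
    rates: np.ndarray
    baseline: TransmitterProfile

    def __post_init__(self) -> None:
        orders = np.asarray(self.orders, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if orders.shape != (N_TRANSMITTERS, N_TRANSMITTERS):
            raise ValueError("kinetic-order matrix must be 6x6")
        if np.any(np.diag(orders) != 0):
            raise ValueError("diagonal kinetic orders must be 0")
        if rates.shape != (N_TRANSMITTERS,) or np.any(rates <= 0):
            raise ValueError("degradation rates must be 6 strictly positive values")
        object.__setattr__(self, "orders", orders)
        object.__setattr__(self, "rates", rates)
        x = self.baseline.values
        resid = _production_all(x, orders) - rates * x
        if np.any(np.abs(resid) >= 1e-6 * x):
            raise ValueError(
                "baseline is not a steady state of the model "
                f"(residuals {resid}); re-calibrate the degradation rates"
            )

    @classmethod
    def from_baseline(
        cls,
        baseline: TransmitterProfile = DEFAULT_BASELINE,
        orders: Optional[np.ndarray] = None,
    ) -> "MatrixModel":
        """Calibrate degradation rates so ``baseline`` is a fixed point."""
        g = DEFAULT_KINETIC_ORDERS if orders is None else np.asarray(orders, float)
        return cls(orders=g, rates=calibrate_degradation(baseline, g), baseline=baseline)

    @classmethod
    def default(cls) -> "MatrixModel":
        return cls.from_baseline()

    def rates_dict(self) -> dict[str, float]:
        return {t: float(k) for t, k in zip(TRANSMITTERS, self.rates)}


def _resolve_modifiers(modifiers: "Optional[ModifierSet]"):
    if modifiers is None:
        ones = np.ones(N_TRANSMITTERS)
        return ones, ones
    return modifiers.production, modifiers.degradation


def derivatives(
    profile: TransmitterProfile,
    model: MatrixModel,
    modifiers: "Optional[ModifierSet]" = None,
) -> np.ndarray:
    """Time derivatives dX_i/dt under the given multiplicative modifiers."""
    p, d = _resolve_modifiers(modifiers)
    x = profile.values
    return p * _production_all(x, model.orders) - d * model.rates * x


@dataclass(frozen=True)
class Trajectory:
    """A solution of the interaction matrix on a stored time grid."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, 6), canonical transmitter order

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or y.shape != (t.size, N_TRANSMITTERS):
            raise ValueError("times must be 1-D and values (n_times, 6)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(y <= 0):
            raise ValueError("trajectory intensities must stay strictly positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", y)

    def profile_at(self, t: float) -> TransmitterProfile:
        """Profile at the stored grid point closest to ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        return TransmitterProfile(self.values[i])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(TRANSMITTERS))
        frame.insert(0, "time", self.times)
        return frame


def _phase_grid(start: float, end: float, dt: float) -> np.ndarray:
    n = max(1, int(round((end - start) / dt)))
    return np.linspace(start, end, n + 1)


def integrate(
    model: MatrixModel,
    schedule: "ModifierSchedule",
    *,
    grid_dt: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    initial: Optional[TransmitterProfile] = None,
) -> Trajectory:
    """Integrate the system piecewise over the phases of ``schedule``.

    The solver restarts at every phase boundary from the end state of the
    previous phase (modifiers switch instantaneously, without ramping).  The
    stored grid is uniform with spacing ``grid_dt`` within each phase and
    always contains every phase boundary.  The system is stiff — the
    degradation constants span roughly five orders of magnitude — so a
    stiff-capable method is used by default.
    """
    if grid_dt <= 0:
        raise ValueError("grid_dt must be positive")
    x = (initial or model.baseline).values.copy()
    orders, rates = model.orders, model.rates

    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    for phase_idx, phase in enumerate(schedule.phases):
        p, d = phase.modifiers.production, phase.modifiers.degradation

        def rhs(t, y, p=p, d=d):
            return p * np.exp(orders @ np.log(y)) - d * rates * y

        t_eval = _phase_grid(phase.start, phase.end, grid_dt)
        sol = solve_ivp(
            rhs,
            (phase.start, phase.end),
            x,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed in phase {phase.name!r} "
                f"([{phase.start}, {phase.end}]) near t={sol.t[-1]:g}: {sol.message}"
            )
        x = sol.y[:, -1].copy()
        if phase_idx == 0:
            all_t.append(sol.t)
            all_y.append(sol.y.T)
        else:  # drop duplicated boundary point
            all_t.append(sol.t[1:])
            all_y.append(sol.y.T[1:])
    return Trajectory(np.concatenate(all_t), np.vstack(all_y))


def find_steady_state(
    model: MatrixModel,
    modifiers: "Optional[ModifierSet]" = None,
    *,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> TransmitterProfile:
    """Steady state of the modified system, by damped Newton in log space.

    Solves ``p_i * flux_i(X) = d_i * k_i * X_i`` for the intensities,
    iterating on ``u = log X`` seeded at the baseline.  Convergence is
    declared when ``max_i |dX_i/dt| / X_i < tol``; non-convergence raises
    :class:`SteadyStateError` rather than returning an unconverged state.
    """
    p, d = _resolve_modifiers(modifiers)
    g = model.orders
    k = model.rates
    u = np.log(model.baseline.values)

    def residual(u):
        # per-transmitter relative rate of change dX/dt / X
        return p * np.exp(g @ u - u) - d * k

    r = residual(u)
    for _ in range(max_iter):
        if np.max(np.abs(r)) < tol:
            return TransmitterProfile(np.exp(u))
        prod = p * np.exp(g @ u - u)
        jac = prod[:, None] * (g - np.eye(N_TRANSMITTERS))
        step = np.linalg.solve(jac, -r)
        # damping: halve the step until the residual norm decreases
        lam = 1.0
        for _ in range(40):
            r_new = residual(u + lam * step)
            if np.linalg.norm(r_new) < np.linalg.norm(r):
                break
            lam *= 0.5
        u = u + lam * step
        r = residual(u)
    if np.max(np.abs(r)) < tol:
        return TransmitterProfile(np.exp(u))
    raise SteadyStateError(
        f"steady-state iteration did not converge within {max_iter} iterations "
        f"(max relative rate {np.max(np.abs(r)):.3e} >= {tol:g})"
    )
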