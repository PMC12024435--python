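"""ODE integration of the metabolic network and extraction of the five
measured metabolite profiles (glutamine, glutamic acid, glucose, lactate,
ammonium).

The mass balances dC/dt = S @ v(C) are stiff — cofactor pools span five
orders of magnitude — so a stiff-capable solver (LSODA) with tight
tolerances is the default.  Fluxes are evaluated with concentrations
floored at 0 inside the right-hand side, which makes Michaelis-Menten
terms vanish for depleted substrates instead of turning negative under
integrator overshoot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import MetabolicModel, ParameterSet

__all__ = ["IntegrationError", "Trajectory", "ObservedProfiles", "simulate", "observe"]

DEFAULT_T_GRID = np.arange(0.0, 121.0, 24.0)  # 24 h sampling over a 5-day culture


class IntegrationError(RuntimeError):
    """Solver failure; carries the last time the integrator reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time:.4g} h)")
        self.last_time = last_time


@dataclass
class Trajectory:
    """Time grid x state matrix (mM); optionally the flux history (mM/h)."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species + n_auxiliary)
    state_ids: list[str]
    flux_history: np.ndarray | None = None
    flux_ids: list[str] | None = None

    def column(self, state_id: str) -> np.ndarray:
        return self.states[:, self.state_ids.index(state_id)]


@dataclass
class ObservedProfiles:
    """Measured-species profiles in fixed order (Gln, GluAc, Glc, Lac, NH4)."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_observed), mM
    species: list[str]

    @property
    def n_points(self) -> int:
        return self.values.size

    def column(self, species_id: str) -> np.ndarray:
        return self.values[:, self.species.index(species_id)]


def simulate(
    model: MetabolicModel,
    params: ParameterSet,
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    method: str = "LSODA",
    with_fluxes: bool = False,
) -> Trajectory:
    """Integrate the model from its initial-concentration parameters.

    Parameters
    ----------
    t_grid
        Strictly increasing output times (h) starting at 0; defaults to
        0:24:120.
    rtol, atol
        Solver tolerances (atol in mM).

    Raises
    ------
    IntegrationError
        If the solver cannot meet tolerances or stalls.
    """
    t = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 1 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing and start at 0")

    km, vmax = model._param_arrays(params)
    y0 = model.initial_state(params)

    def rhs(_t, y):
        return model.rates(y, km, vmax)

    def jac(_t, y):
        return model.rates_jacobian(y, km, vmax)

    if len(t) == 1:
        states = y0[None, :]
    else:
        sol = solve_ivp(
            rhs, (t[0], t[-1]), y0, method=method, t_eval=t,
            rtol=rtol, atol=atol, jac=jac,
        )
        if not sol.success:
            last = sol.t[-1] if len(sol.t) else t[0]
            raise IntegrationError(f"integration failed: {sol.message}", last)
        states = sol.y.T
    # report physically: tiny negative overshoot clipped to 0
    states = np.maximum(states, 0.0)
    if not np.all(np.isfinite(states)):
        raise IntegrationError("non-finite state encountered", float(t[0]))

    flux_history = flux_ids = None
    if with_fluxes:
        flux_history = np.vstack([model.flux_vector(s, km, vmax) for s in states])
        flux_ids = [law.id for law in model.flux_laws]
    return Trajectory(t, states, list(model.state_ids), flux_history, flux_ids)


def observe(traj: Trajectory, order: list[str] | None = None) -> ObservedProfiles:
    """Restrict a trajectory to the observed metabolites, in fixed order."""
    if order is None:
        order = ["Gln", "GluAc", "Glc", "Lac", "NH4"]
    missing = [s for s in order if s not in traj.state_ids]
    if missing:
        raise KeyError(f"trajectory lacks observed species: {missing}")
    cols = [traj.state_ids.index(s) for s in order]
    return ObservedProfiles(traj.times.copy(), traj.states[:, cols].copy(), list(order))
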