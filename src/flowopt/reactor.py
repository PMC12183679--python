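"""Plug-flow reactor model for continuous imine synthesis.

The environment physics for the self-optimization problem: benzylamine (1)
and benzaldehyde (2) stock solutions in methanol are mixed at the reactor
inlet and react irreversibly (1:1:1 stoichiometry) to the imine
N-benzylidenebenzylamine (3) while flowing through a tubular reactor.

Two solution routes are provided and cross-validated against each other and
against the analytic bimolecular closed form:

* :func:`simulate` -- transient method-of-lines semi-discretization
  (first-order upwind advection) integrated to steady state with a stiff
  BDF integrator; returns the full spatial profile.
* :func:`steady_state_outlet` -- direct integration of the steady-state
  axial ODEs in ``z`` (fast path used by the optimizers and the RL agent).

Internal unit conventions: concentrations mol/L, time minutes, length m,
temperature K.  Conversions (e.g. flow rates in mL/min) happen only at the
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

__all__ = [
    "R_GAS",
    "KineticParameters",
    "ReactorModel",
    "ReactionConditions",
    "ConditionBounds",
    "NumericsConfig",
    "SpatialProfile",
    "SimulationResult",
    "flow_from_residence_time",
    "residence_time_from_flow",
    "feed_concentrations",
    "rate_constant",
    "reaction_rate",
    "analytic_isothermal_outlet",
    "bimolecular_conversion",
    "steady_state_outlet",
    "simulate",
]

#: Universal gas constant (J mol^-1 K^-1).
R_GAS = 8.314


@dataclass(frozen=True)
class KineticParameters:
    """Arrhenius parameters of the bimolecular condensation.

    Parameters
    ----------
    ea : float
        Activation energy (kJ/mol), > 0.
    kref : float
        Rate coefficient at the reference temperature (L mol^-1 min^-1), > 0.
    tref : float
        Reference temperature (K).  The original study never states it;
        298.15 K is the package default and ``kref`` is defined relative
        to whatever value is used.
    """

    ea: float = 21.57
    kref: float = 0.413
    tref: float = 298.15

    def __post_init__(self) -> None:
        if self.ea <= 0:
            raise ValueError(f"activation energy must be positive, got {self.ea}")
        if self.kref <= 0:
            raise ValueError(f"kref must be positive, got {self.kref}")
        if not 250.0 <= self.tref <= 400.0:
            raise ValueError(f"tref must be within [250, 400] K, got {self.tref}")


@dataclass(frozen=True)
class ConditionBounds:
    """Box bounds of the decision space (residence time, equivalent ratio,
    set temperature)."""

    res_t: tuple[float, float] = (0.5, 8.0)
    er: tuple[float, float] = (0.1, 2.0)
    temp: tuple[float, float] = (278.0, 330.0)

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.res_t[0], self.er[0], self.temp[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.res_t[1], self.er[1], self.temp[1]])

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(x, dtype=float), self.lower, self.upper)

    def contains(self, x: np.ndarray, atol: float = 1e-9) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol))


DEFAULT_BOUNDS = ConditionBounds()


@dataclass(frozen=True)
class ReactionConditions:
    """A point of the decision space.

    Attributes
    ----------
    res_t : float
        Residence time (min).
    er : float
        Equivalent ratio Q1/Q2 of the benzylamine to benzaldehyde feed
        flows (dimensionless).
    temp : float
        Set temperature (K); used both as feed temperature Tf and coolant
        temperature Tc (the jacket maintains the set point).
    """

    res_t: float
    er: float
    temp: float

    def __post_init__(self) -> None:
        if self.res_t <= 0:
            raise ValueError(f"residence time must be positive, got {self.res_t}")
        if self.er <= 0:
            raise ValueError(f"equivalent ratio must be positive, got {self.er}")
        if self.temp <= 0:
            raise ValueError(f"temperature must be positive, got {self.temp}")

    def as_array(self) -> np.ndarray:
        return np.array([self.res_t, self.er, self.temp])

    @staticmethod
    def from_array(x: np.ndarray) -> "ReactionConditions":
        return ReactionConditions(res_t=float(x[0]), er=float(x[1]), temp=float(x[2]))


@dataclass(frozen=True)
class ReactorModel:
    """Geometry, thermophysical properties, feeds and kinetics of the
    tubular reactor.

    Species index order everywhere: benzylamine (1), benzaldehyde (2),
    imine (3), solvent (methanol).
    """

    length: float = 0.15  # m
    volume: float = 1.32e-6  # m^3
    ua: float = 100.0  # W/K, overall heat-transfer coefficient
    dh_react: float = 160.0  # kJ/mol released (exothermic magnitude)
    rho: float = 800.0  # kg/m^3
    cp_species: tuple[float, float, float, float] = (172.0, 207.2, 165.7, 81.2)  # J/mol/K
    mw_species: tuple[float, float, float, float] = (107.15, 106.12, 195.26, 32.04)  # g/mol
    cs1: float = 4.0  # mol/L benzylamine stock
    cs2: float = 4.0  # mol/L benzaldehyde stock
    kinetics: KineticParameters = field(default_factory=KineticParameters)
    arrhenius_mode: str = "local-temperature"  # or "feed-temperature"
    energy_coupling: bool = True
    heat_capacity_vol: float | None = None  # J/(L K) override; None -> composition-based
    bounds: ConditionBounds = field(default_factory=ConditionBounds)

    def __post_init__(self) -> None:
        for name in ("length", "volume", "ua", "dh_react", "rho", "cs1", "cs2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(c <= 0 for c in self.cp_species) or any(m <= 0 for m in self.mw_species):
            raise ValueError("heat capacities and molar masses must be positive")
        if self.arrhenius_mode not in ("local-temperature", "feed-temperature"):
            raise ValueError(f"unknown arrhenius_mode {self.arrhenius_mode!r}")

    @property
    def cross_section(self) -> float:
        """Cross-sectional area V/L (m^2)."""
        return self.volume / self.length

    @property
    def volume_l(self) -> float:
        return self.volume * 1000.0

    def isothermal(self) -> "ReactorModel":
        """A copy with the energy balance switched off."""
        return replace(self, energy_coupling=False)

    def feed_concentrations(self, er: float) -> tuple[float, float]:
        return feed_concentrations(er, self.cs1, self.cs2)

    def volumetric_heat_capacity(self, c1, c2, c3):
        """Volumetric heat capacity of the mixture (J L^-1 K^-1).

        Mole-fraction-weighted molar heat capacity times total molar
        concentration, which reduces to sum(c_i * Cp_i) over all species.
        The solvent concentration is obtained by mass difference from the
        (constant) mixture density.
        """
        if self.heat_capacity_vol is not None:
            return self.heat_capacity_vol
        mw1, mw2, mw3, mws = self.mw_species
        rho_g_l = self.rho  # kg/m^3 == g/L
        c_solv = (rho_g_l - c1 * mw1 - c2 * mw2 - c3 * mw3) / mws
        c_solv = np.maximum(c_solv, 0.0)
        cp1, cp2, cp3, cps = self.cp_species
        return c1 * cp1 + c2 * cp2 + c3 * cp3 + c_solv * cps


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization and tolerance settings for the PDE/ODE solvers."""

    n_nodes: int = 400
    rtol: float = 1e-7
    atol: float = 1e-9
    steady_tol: float = 1e-8  # max |d(state)/dt| declaring steady state
    max_residence_times: float = 10.0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 axial nodes")


@dataclass
class SpatialProfile:
    """Axial steady-state profile. ``z`` runs from 0 (inlet) to L (outlet)."""

    z: np.ndarray  # m
    c1: np.ndarray  # mol/L
    c2: np.ndarray
    c3: np.ndarray
    temp: np.ndarray  # K
    vz: float  # m/min


@dataclass
class SimulationResult:
    outlet_c: tuple[float, float, float]
    outlet_temp: float
    profile: SpatialProfile
    converged: bool
    n_rhs_evals: int

    @property
    def outlet_c3(self) -> float:
        return self.outlet_c[2]


# ---------------------------------------------------------------------------
# elementary operations


def flow_from_residence_time(res_t: float, volume: float) -> float:
    """Total volumetric flow rate Q (mL/min) from residence time (min) and
    reactor volume (m^3):  Res_t = V / Q."""
    if res_t <= 0 or volume <= 0:
        raise ValueError("residence time and volume must be positive")
    return volume * 1.0e6 / res_t


def residence_time_from_flow(q_ml_min: float, volume: float) -> float:
    """Inverse of :func:`flow_from_residence_time`."""
    if q_ml_min <= 0 or volume <= 0:
        raise ValueError("flow rate and volume must be positive")
    return volume * 1.0e6 / q_ml_min


def feed_concentrations(er: float, cs1: float, cs2: float) -> tuple[float, float]:
    """Inlet concentrations after mixing the two stocks.

    ``er = Q1/Q2`` so the benzylamine stream carries a fraction
    ``er/(1+er)`` of the total flow:  c1f = Cs1*er/(1+er), c2f = Cs2/(1+er).
    """
    if er <= 0:
        raise ValueError(f"equivalent ratio must be positive, got {er}")
    return cs1 * er / (1.0 + er), cs2 / (1.0 + er)


def rate_constant(temp, kin: KineticParameters):
    """Arrhenius rate coefficient (L mol^-1 min^-1) relative to ``kref`` at
    ``tref``:  k = kref * exp(-Ea/R * (1/T - 1/Tref))."""
    temp = np.asarray(temp, dtype=float)
    if np.any(temp <= 0):
        raise ValueError("temperature must be positive")
    ea_j = kin.ea * 1000.0
    k = kin.kref * np.exp(-ea_j / R_GAS * (1.0 / temp - 1.0 / kin.tref))
    return float(k) if np.isscalar(temp) or temp.ndim == 0 else k


def reaction_rate(k, c1, c2):
    """Second-order rate r = k*c1*c2 (mol L^-1 min^-1)."""
    if np.any(np.asarray(c1) < 0) or np.any(np.asarray(c2) < 0):
        raise ValueError("concentrations must be non-negative")
    return k * np.asarray(c1, dtype=float) * np.asarray(c2, dtype=float)


def bimolecular_conversion(c1f, c2f, k, t):
    """Closed-form extent x (= product concentration) of A + B -> C after
    contact time ``t`` starting from (c1f, c2f), vectorized over any of the
    arguments.

    Unequal feeds use the logarithmic closed form written via ``expm1`` for
    stability; equal feeds use x = a0 - a0/(1 + a0*k*t).
    """
    c1f = np.asarray(c1f, dtype=float)
    c2f = np.asarray(c2f, dtype=float)
    kt = np.asarray(k, dtype=float) * np.asarray(t, dtype=float)
    c1f, c2f, kt = np.broadcast_arrays(c1f, c2f, kt)
    diff = c1f - c2f
    out = np.empty_like(diff, dtype=float)

    near = np.abs(diff) < 1e-10
    # equal-concentration second-order kinetics
    a0 = c1f[near]
    out[near] = a0 - a0 / (1.0 + a0 * kt[near])
    # general case: x = a*b*(E-1) / (a*E - b), E = exp((a-b) k t)
    a, b, d, s = c1f[~near], c2f[~near], diff[~near], kt[~near]
    em1 = np.expm1(d * s)
    out[~near] = a * b * em1 / (a * (em1 + 1.0) - b)
    out = np.clip(out, 0.0, np.minimum(c1f, c2f))
    return float(out) if out.ndim == 0 else out


def analytic_isothermal_outlet(
    cond: ReactionConditions, k: float, cs1: float = 4.0, cs2: float = 4.0
) -> float:
    """Closed-form outlet product concentration under the isothermal
    assumption -- the verification oracle for the PDE/ODE solvers."""
    c1f, c2f = feed_concentrations(cond.er, cs1, cs2)
    return bimolecular_conversion(c1f, c2f, k, cond.res_t)


# ---------------------------------------------------------------------------
# solvers


def _check_bounds(cond: ReactionConditions, model: ReactorModel) -> None:
    if not model.bounds.contains(cond.as_array()):
        raise ValueError(
            f"conditions {cond} outside decision-space bounds "
            f"res_t {model.bounds.res_t}, er {model.bounds.er}, T {model.bounds.temp}"
        )


def _energy_terms(model: ReactorModel):
    """(dH in J/mol, UA per reactor liter in J min^-1 L^-1 K^-1)."""
    dh_j = model.dh_react * 1000.0
    ua_vol = model.ua * 60.0 / model.volume_l
    return dh_j, ua_vol


def steady_state_outlet(
    cond: ReactionConditions,
    model: ReactorModel,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[float, float, float, float]:
    """Outlet (c1, c2, c3, T) from direct integration of the steady-state
    axial balances dci/dz = +/- r/vz (and the temperature analogue when the
    energy balance is coupled).

    This is the fast evaluation path used by every optimizer; it agrees
    with the transient route well within 0.5% on the outlet c3.
    """
    _check_bounds(cond, model)
    c1f, c2f = model.feed_concentrations(cond.er)
    vz = model.length / cond.res_t  # m/min
    tf = cond.temp
    kin = model.kinetics
    dh_j, ua_vol = _energy_terms(model)
    feed_k = rate_constant(tf, kin)
    local_arrh = model.arrhenius_mode == "local-temperature"

    if model.energy_coupling:

        def rhs(z, y):
            c1, c2, c3, temp = y
            k = rate_constant(max(temp, 1.0), kin) if local_arrh else feed_k
            r = k * max(c1, 0.0) * max(c2, 0.0)
            cvol = model.volumetric_heat_capacity(max(c1, 0.0), max(c2, 0.0), max(c3, 0.0))
            dtdz = (r * dh_j + ua_vol * (tf - temp)) / (vz * cvol)
            return [-r / vz, -r / vz, r / vz, dtdz]

        y0 = [c1f, c2f, 0.0, tf]
    else:

        def rhs(z, y):
            c1, c2, c3 = y
            k = feed_k  # isothermal: local T == Tf
            r = k * max(c1, 0.0) * max(c2, 0.0)
            return [-r / vz, -r / vz, r / vz]

        y0 = [c1f, c2f, 0.0]

    sol = solve_ivp(rhs, (0.0, model.length), y0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"steady-state axial integration failed: {sol.message}")
    yL = sol.y[:, -1]
    if np.any(~np.isfinite(yL)):
        raise FloatingPointError("non-finite state in steady-state integration")
    c1, c2, c3 = (float(max(v, 0.0)) for v in yL[:3])
    temp = float(yL[3]) if model.energy_coupling else tf
    return c1, c2, c3, temp


def _mol_sparsity(n: int, nvar: int):
    """Jacobian sparsity of the upwind method-of-lines system: each node
    couples to itself (dense nvar block) and to the upstream node."""
    m = lil_matrix((n * nvar, n * nvar), dtype=np.int8)
    for j in range(n):
        lo = j * nvar
        m[lo : lo + nvar, lo : lo + nvar] = 1
        if j > 0:
            m[lo : lo + nvar, lo - nvar : lo] = 1
    return m.tocsr()


def simulate(
    cond: ReactionConditions,
    model: ReactorModel,
    numerics: NumericsConfig | None = None,
) -> SimulationResult:
    """Transient method-of-lines simulation to steady state.

    Species balances dc/dt = -vz dc/dz +/- r (and the energy balance when
    coupled) are semi-discretized with first-order upwind differences on a
    uniform axial grid, the inlet node held at the feed state, and
    integrated with a stiff BDF method.  Integration proceeds in chunks of
    one residence time; steady state is declared when the max time
    derivative falls below ``steady_tol`` (or after ``max_residence_times``
    residence times, in which case ``converged`` is False unless the
    criterion is met).
    """
    numerics = numerics or NumericsConfig()
    _check_bounds(cond, model)
    n = numerics.n_nodes
    dz = model.length / n
    vz = model.length / cond.res_t
    c1f, c2f = model.feed_concentrations(cond.er)
    tf = cond.temp
    kin = model.kinetics
    dh_j, ua_vol = _energy_terms(model)
    feed_k = rate_constant(tf, kin)
    local_arrh = model.arrhenius_mode == "local-temperature"
    coupled = model.energy_coupling
    nvar = 4 if coupled else 3
    adv = vz / dz

    def unpack(y):
        y = y.reshape(n, nvar)
        return (y[:, 0], y[:, 1], y[:, 2]) + ((y[:, 3],) if coupled else ())

    def rhs(t, y):
        sp = unpack(y)
        c1, c2, c3 = sp[0], sp[1], sp[2]
        temp = sp[3] if coupled else None
        if coupled and local_arrh:
            k = rate_constant(np.maximum(temp, 1.0), kin)
        else:
            k = feed_k
        r = k * np.maximum(c1, 0.0) * np.maximum(c2, 0.0)
        out = np.empty((n, nvar))
        # upwind advection with the inlet boundary value at node -1
        out[:, 0] = -adv * (c1 - np.concatenate(([c1f], c1[:-1]))) - r
        out[:, 1] = -adv * (c2 - np.concatenate(([c2f], c2[:-1]))) - r
        out[:, 2] = -adv * (c3 - np.concatenate(([0.0], c3[:-1]))) + r
        if coupled:
            cvol = model.volumetric_heat_capacity(
                np.maximum(c1, 0.0), np.maximum(c2, 0.0), np.maximum(c3, 0.0)
            )
            out[:, 3] = (
                -adv * (temp - np.concatenate(([tf], temp[:-1])))
                + (r * dh_j + ua_vol * (tf - temp)) / cvol
            )
        return out.ravel()

    # initial state: reactor filled with fresh feed at the feed temperature
    y0 = np.zeros((n, nvar))
    y0[:, 0], y0[:, 1] = c1f, c2f
    if coupled:
        y0[:, 3] = tf
    y = y0.ravel()

    sparsity = _mol_sparsity(n, nvar)
    n_evals = 0
    converged = False
    t_now = 0.0
    chunk = cond.res_t
    max_t = numerics.max_residence_times * cond.res_t
    while t_now < max_t - 1e-12:
        sol = solve_ivp(
            rhs,
            (t_now, t_now + chunk),
            y,
            method="BDF",
            rtol=numerics.rtol,
            atol=numerics.atol,
            jac_sparsity=sparsity,
        )
        n_evals += sol.nfev
        if not sol.success:
            raise RuntimeError(f"transient integration failed: {sol.message}")
        y = sol.y[:, -1]
        if np.any(~np.isfinite(y)):
            raise FloatingPointError("non-finite state in transient simulation")
        t_now = sol.t[-1]
        if np.max(np.abs(rhs(t_now, y))) < numerics.steady_tol:
            converged = True
            break

    sp = unpack(y)
    z = np.linspace(0.0, model.length, n + 1)
    prof = SpatialProfile(
        z=z,
        c1=np.concatenate(([c1f], sp[0])),
        c2=np.concatenate(([c2f], sp[1])),
        c3=np.concatenate(([0.0], sp[2])),
        temp=np.concatenate(([tf], sp[3])) if coupled else np.full(n + 1, tf),
        vz=vz,
    )
    outlet = (float(sp[0][-1]), float(sp[1][-1]), float(sp[2][-1]))
    outlet_t = float(sp[3][-1]) if coupled else tf
    return SimulationResult(
        outlet_c=outlet,
        outlet_temp=outlet_t,
        profile=prof,
        converged=converged,
        n_rhs_evals=n_evals,
    )
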