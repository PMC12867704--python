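"""Flagellar cAMP budget and the spawning cascade.

The sperm flagellum carries a fixed complement of membrane-associated sAC
molecules (default 7,000) in a tiny volume (default 2 fL).  A rise of
intracellular pH increases each enzyme's turnover number k(pH); the net
synthesis rate N x (k_high - k_low) sets the flagellar cAMP budget, which
is balanced by phosphodiesterase hydrolysis with time constant tau.  This
module computes that budget, converts molecule counts to concentrations,
evaluates fractional occupancy of cAMP targets (PKA, HCN), and integrates a
minimal deterministic model of the spawning cascade:

    K+ drop -> hyperpolarization (Nernst relaxation) -> SLC9C1 gate opens
    -> intracellular alkalization -> sAC activation -> cAMP rise -> motility

The cascade's first-order forms, the voltage-threshold gate, and the
occupancy-threshold-plus-delay motility rule are model definitions of this
package (the underlying study reports the event sequence and timings, not
differential equations); every rate constant is a surfaced parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

AVOGADRO = 6.02214076e23
GAS_CONSTANT = 8.314462618   # J mol-1 K-1
FARADAY = 96485.33212        # C mol-1


class InputError(ValueError):
    pass


class IntegrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Compartment and budget arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentParams:
    """Flagellar compartment: sAC copy number and volume."""

    n_sac: float = 7000.0     # sAC molecules per flagellum
    volume_L: float = 2e-15   # flagellar volume, 2 fL

    def __post_init__(self):
        if self.n_sac < 0:
            raise InputError("copy number must be nonnegative")
        if self.volume_L <= 0:
            raise InputError("volume must be positive")


def synthesis_rate(
    comp: CompartmentParams, k_low: float, k_high: float,
) -> float:
    """Net cAMP synthesis rate N x (k_high - k_low), molecules per second."""
    if k_low < 0 or k_high < k_low:
        raise InputError("require k_high >= k_low >= 0")
    return comp.n_sac * (k_high - k_low)


def molecules_to_concentration(
    count: float, comp: CompartmentParams, paper_convention: bool = False,
) -> float:
    """Concentration (nM) of ``count`` molecules in the compartment.

    Exact by default: count / (N_A x V), i.e. 0.830 nM per molecule in
    2 fL.  ``paper_convention=True`` applies the rounded 1 molecule == 1 nM
    convention used in the prose arithmetic of the source study.
    """
    if count < 0:
        raise InputError("count must be nonnegative")
    if paper_convention:
        return float(count)
    return count / (AVOGADRO * comp.volume_L) * 1e9


@dataclass(frozen=True)
class TargetAffinity:
    """A cAMP target: half-activation constant K (nM) and Hill coefficient."""

    name: str
    k_nM: float
    hill: float = 1.0

    def __post_init__(self):
        if self.k_nM <= 0 or self.hill <= 0:
            raise InputError("K and Hill coefficient must be positive")


# literature target affinities (documented defaults)
PKA = TargetAffinity("PKA", k_nM=10.0)       # K_D 2-10 nM; upper bound used
HCN = TargetAffinity("HCN", k_nM=740.0)      # K_1/2 0.74 uM


def fractional_occupancy(conc_nM: float, target: TargetAffinity) -> float:
    """Hill occupancy c^n / (c^n + K^n), in [0, 1], monotone in c."""
    if conc_nM < 0:
        raise InputError("concentration must be nonnegative")
    if conc_nM == 0:
        return 0.0
    cn = conc_nM ** target.hill
    return cn / (cn + target.k_nM ** target.hill)


def nernst(k_out_mM: float, k_in_mM: float, temperature_K: float = 291.15
           ) -> float:
    """K+ equilibrium potential (RT/F) ln([K+]o/[K+]i), in mV."""
    if k_out_mM <= 0 or k_in_mM <= 0:
        raise InputError("concentrations must be positive")
    return (GAS_CONSTANT * temperature_K / FARADAY
            * math.log(k_out_mM / k_in_mM) * 1e3)


def steady_state_camp(
    rate_molecules_s: float, tau_s: float, comp: CompartmentParams,
    paper_convention: bool = False,
) -> float:
    """Fixed point of dc/dt = s - c/tau, as a concentration in nM."""
    if rate_molecules_s < 0:
        raise InputError("rate must be nonnegative")
    if tau_s <= 0:
        raise InputError("tau must be positive")
    return molecules_to_concentration(
        rate_molecules_s * tau_s, comp, paper_convention=paper_convention)


# ---------------------------------------------------------------------------
# pH-activity curve
# ---------------------------------------------------------------------------

@dataclass
class PHActivityCurve:
    """Piecewise-linear interpolant of turnover number k(pH), s^-1/enzyme."""

    ph: np.ndarray
    k: np.ndarray

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if np.any(np.diff(self.ph) <= 0):
            raise InputError("pH anchors must be strictly increasing")
        if np.any(self.k < 0):
            raise InputError("turnover must be nonnegative")

    def __call__(self, ph):
        return np.interp(ph, self.ph, self.k)


def purified_enzyme_curve() -> PHActivityCurve:
    """Biphasic pH profile of the purified sea urchin enzyme (MgATP).

    Anchors at pH 7.2 (0.035 s^-1) and 8.0 (0.106 s^-1) are measured means;
    pH 6.5-7.0 anchors follow the reported narrative shape (twofold rise to
    a local peak at 7.0, return to baseline at 7.2, surge above 7.8).
    """
    return PHActivityCurve(
        ph=[6.5, 6.7, 7.0, 7.2, 7.8, 8.0],
        k=[0.035, 0.050, 0.070, 0.035, 0.045, 0.106],
    )


def spawning_curve() -> PHActivityCurve:
    """Monotone k(pH) used by the default spawning scenario.

    Anchored at the measured pH 7.2 and 8.0 turnover numbers, with a low
    resting anchor at pH 6.84 so that alkalization from rest raises free
    cAMP (the biphasic purified-enzyme profile would predict a cAMP *drop*
    from 6.84 to 7.2 under a fast-hydrolysis steady state, which
    contradicts the observed whole-cell cAMP rise; see the methods note).
    """
    return PHActivityCurve(
        ph=[6.84, 7.2, 8.0],
        k=[0.0005, 0.035, 0.106],
    )


# ---------------------------------------------------------------------------
# Spawning cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CascadeParams:
    """Parameters of the spawning-cascade model.

    External K+ steps from ``k_out_before`` (artificial seminal fluid,
    27 mM) to ``k_out_after`` at t = 0 (10 mM after 1:2 mixing with K+-free
    sea water; 30 mM in the high-K+ control).  Internal K+ is not measured
    in the study; the default 300 mM yields a plausible resting potential
    near -61 mV.
    """

    k_out_before_mM: float = 27.0
    k_out_after_mM: float = 10.0
    k_in_mM: float = 300.0
    temperature_K: float = 291.15          # 18 C, sea water
    tau_vm_s: float = 0.2                  # V_m relaxation
    slc9c1_threshold_mV: float = -70.0     # gate opens below this V_m
    ph_rest: float = 6.84
    ph_post: float = 7.2
    tau_ph_s: float = 72.13                # alkalization time constant
    tau_pde_s: float = 0.35                # cAMP hydrolysis time constant
    pka_k_nM: float = 10.0
    pka_hill: float = 1.0
    motility_occupancy_threshold: float = 0.8
    phosphorylation_delay_s: float = 10.0
    # optional cAMP feedback: linear shift of the gate threshold with
    # PKA occupancy (mV per unit occupancy); off by default
    gate_shift_mV_per_occupancy: float = 0.0
    t_end_s: float = 180.0
    dt_s: float = 0.005

    def __post_init__(self):
        for name in ("tau_vm_s", "tau_ph_s", "tau_pde_s", "dt_s", "t_end_s"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        for name in ("ph_rest", "ph_post"):
            if not 6.0 <= getattr(self, name) <= 9.0:
                raise InputError(f"{name} outside [6, 9]")


@dataclass
class CascadeTrace:
    """Simulated time courses and event timestamps of the cascade."""

    time_s: np.ndarray
    vm_mV: np.ndarray
    ph_i: np.ndarray
    camp_molecules: np.ndarray
    camp_nM: np.ndarray
    motile: np.ndarray            # boolean state
    events: dict                  # name -> time (s) or None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s, "vm_mV": self.vm_mV, "ph_i": self.ph_i,
            "camp_molecules": self.camp_molecules, "camp_nM": self.camp_nM,
            "motile": self.motile,
        })


def simulate_spawning(
    params: CascadeParams | None = None,
    curve: PHActivityCurve | None = None,
    comp: CompartmentParams | None = None,
) -> CascadeTrace:
    """Deterministic fixed-step integration of the spawning cascade.

    V_m relaxes first-order toward the Nernst potential of the current
    external K+; the SLC9C1 exchanger gate opens while V_m is below
    threshold, letting pH_i relax toward its post-spawn value; cAMP obeys
    dc/dt = N k(pH_i) - c/tau; motility switches on once PKA occupancy has
    exceeded its threshold continuously for the phosphorylation delay.

    Event timestamps recorded: ``hyperpolarization_onset`` (V_m 2 mV below
    rest), ``alkalization_onset`` (pH_i 0.01 above rest), ``camp_half_rise``
    (cAMP crosses the midpoint of its initial-to-final span, only if the
    trace rises by more than 5%), ``motility_onset``.
    """
    params = params or CascadeParams()
    curve = curve or spawning_curve()
    comp = comp or CompartmentParams()

    n_steps = int(round(params.t_end_s / params.dt_s))
    dt = params.dt_s
    t = np.arange(n_steps + 1) * dt
    vm = np.empty(n_steps + 1)
    ph = np.empty(n_steps + 1)
    camp = np.empty(n_steps + 1)
    motile = np.zeros(n_steps + 1, dtype=bool)

    vm_rest = nernst(params.k_out_before_mM, params.k_in_mM,
                     params.temperature_K)
    vm_target = nernst(params.k_out_after_mM, params.k_in_mM,
                       params.temperature_K)
    vm[0] = vm_rest
    ph[0] = params.ph_rest
    # resting cAMP at the steady state of the resting pH (zero when
    # hydrolysis is switched off, i.e. tau infinite)
    camp[0] = (0.0 if math.isinf(params.tau_pde_s)
               else comp.n_sac * float(curve(params.ph_rest))
               * params.tau_pde_s)

    pka = TargetAffinity("PKA", params.pka_k_nM, params.pka_hill)
    above_since: float | None = None
    events: dict[str, float | None] = {
        "hyperpolarization_onset": None, "alkalization_onset": None,
        "camp_half_rise": None, "motility_onset": None,
    }
    inv_tau_pde = 0.0 if math.isinf(params.tau_pde_s) else 1.0 / params.tau_pde_s

    for i in range(n_steps):
        occ = fractional_occupancy(
            molecules_to_concentration(camp[i], comp), pka)
        threshold = (params.slc9c1_threshold_mV
                     + params.gate_shift_mV_per_occupancy * occ)
        gate_open = vm[i] < threshold

        vm[i + 1] = vm[i] + dt * (vm_target - vm[i]) / params.tau_vm_s
        ph_target = params.ph_post if gate_open else params.ph_rest
        ph[i + 1] = ph[i] + dt * (ph_target - ph[i]) / params.tau_ph_s
        dcdt = comp.n_sac * float(curve(ph[i])) - camp[i] * inv_tau_pde
        camp[i + 1] = max(camp[i] + dt * dcdt, 0.0)
        if not np.isfinite(camp[i + 1]):
            raise IntegrationError(
                f"cAMP diverged at t={t[i + 1]:.3f}s; reduce dt")

        tnow = t[i + 1]
        if (events["hyperpolarization_onset"] is None
                and vm[i + 1] < vm_rest - 2.0):
            events["hyperpolarization_onset"] = tnow
        if (events["alkalization_onset"] is None
                and ph[i + 1] > params.ph_rest + 0.01):
            events["alkalization_onset"] = tnow

        occ_next = fractional_occupancy(
            molecules_to_concentration(camp[i + 1], comp), pka)
        if occ_next >= params.motility_occupancy_threshold:
            if above_since is None:
                above_since = tnow
            if (not motile[i]
                    and tnow - above_since >= params.phosphorylation_delay_s):
                motile[i + 1:] = True
                events["motility_onset"] = tnow
        else:
            above_since = None
        if motile[i] and events["motility_onset"] is not None:
            motile[i + 1] = True

    camp_nM = camp / (AVOGADRO * comp.volume_L) * 1e9
    c0, cf = camp[0], camp[-1]
    if cf > c0 * 1.05 + 1e-9:
        half = 0.5 * (c0 + cf)
        crossed = np.nonzero(camp >= half)[0]
        if crossed.size:
            events["camp_half_rise"] = float(t[crossed[0]])
    return CascadeTrace(
        time_s=t, vm_mV=vm, ph_i=ph, camp_molecules=camp, camp_nM=camp_nM,
        motile=motile, events=events,
    )


def convergence_check(
    params: CascadeParams | None = None, **kwargs
) -> float:
    """Relative change of the final cAMP level when the step is halved."""
    params = params or CascadeParams()
    coarse = simulate_spawning(params, **kwargs)
    fine = simulate_spawning(replace(params, dt_s=params.dt_s / 2), **kwargs)
    ref = max(abs(fine.camp_molecules[-1]), 1e-12)
    return abs(coarse.camp_molecules[-1] - fine.camp_molecules[-1]) / ref


# ---------------------------------------------------------------------------
# Half-time fitting
# ---------------------------------------------------------------------------

def fit_halftime(time_s, values) -> dict:
    """Single-exponential fit c(t) = base + span (1 - exp(-t/tau)).

    Returns the half-time ln2 x tau with fitted baseline/plateau and a
    quality flag; flat or plateau-free traces are flagged instead of fitted.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise InputError("need at least 4 points")
    span = y.max() - y.min()
    if span <= 0 or span < 0.05 * max(abs(y).max(), 1e-12):
        return {"halftime_s": None, "flag": "flat"}

    def model(tt, base, plateau, tau):
        return base + (plateau - base) * (1.0 - np.exp(-tt / tau))

    tau0 = max(t[-1] / 3.0, 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[y[0], y[-1], tau0],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError:
        return {"halftime_s": None, "flag": "fit-failed"}
    base, plateau, tau = popt
    # plateau must be approached within the record for a trustworthy tau
    flag = "ok" if t[-1] >= 1.5 * tau else "no-plateau"
    return {"halftime_s": float(math.log(2) * tau), "tau_s": float(tau),
            "baseline": float(base), "plateau": float(plateau), "flag": flag}


# ---------------------------------------------------------------------------
# Caged-cAMP photorelease
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncagingParams:
    """Saturating photorelease model: released = c_max (1 - exp(-alpha E)).

    Calibrated so the default flash-energy range [1, saturating] spans the
    reported 5.3-342 nM released-concentration window.  The underlying
    photochemistry is abstracted to this declared saturating form.
    """

    loaded_uM: float = 20.0
    c_max_nM: float = 342.0
    c_min_nM: float = 5.3
    alpha_per_energy: float = field(default=0.0)

    def __post_init__(self):
        if self.c_max_nM <= self.c_min_nM or self.c_min_nM <= 0:
            raise InputError("need c_max > c_min > 0")
        if self.alpha_per_energy == 0.0:
            # calibrate: E = 1 releases c_min
            object.__setattr__(
                self, "alpha_per_energy",
                -math.log(1.0 - self.c_min_nM / self.c_max_nM))
        if self.alpha_per_energy <= 0:
            raise InputError("alpha must be positive")


def uncaging_release(flash_energy: float,
                     params: UncagingParams | None = None) -> float:
    """Released cAMP (nM) for a flash of the given energy (arbitrary units)."""
    params = params or UncagingParams()
    if flash_energy < 0:
        raise InputError("flash energy must be nonnegative")
    return params.c_max_nM * (1.0 - math.exp(
        -params.alpha_per_energy * flash_energy))


def motility_latency(
    released_nM: float,
    pka: TargetAffinity = PKA,
    tau_decay_s: float = 0.35,
    phosphorylation_time_s: float = 0.1,
    dt_s: float = 0.001,
    t_max_s: float = 30.0,
) -> float:
    """Latency to motility after an instantaneous cAMP release.

    The released cAMP decays exponentially (PDE, tau_decay); PKA
    phosphorylates motor proteins at a rate proportional to its occupancy,
    and motility starts once the accumulated occupancy-time reaches the
    phosphorylation time.  Non-responders (integral never reaches it)
    return ``inf``.  Latency is monotone nonincreasing in the released
    amount.
    """
    if released_nM < 0:
        raise InputError("released amount must be nonnegative")
    if released_nM == 0:
        return math.inf
    accum = 0.0
    t = 0.0
    while t < t_max_s:
        c = released_nM * math.exp(-t / tau_decay_s)
        occ = fractional_occupancy(c, pka)
        accum += occ * dt_s
        t += dt_s
        if accum >= phosphorylation_time_s:
            return t
        if occ < 1e-9 and accum < phosphorylation_time_s:
            return math.inf
    return math.inf
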