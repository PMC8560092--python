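"""Stiff integration of the mass-action ODEs and AKAR4 readout extraction.

Every reaction channel contributes a flux v = k·∏[reactants]; the state
derivative is the stoichiometry matrix applied to the channel flux vector.
Rate constants span several orders of magnitude, so integration uses LSODA
(automatic stiff/non-stiff switching) with an analytic Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import Condition, ParameterSet, ReactionNetwork, initial_state

__all__ = [
    "Trajectory",
    "EmissionTrace",
    "SimulationError",
    "compile_channels",
    "simulate",
    "akar4_readout",
    "peak_rate",
    "ensemble_simulate",
    "free_c_fraction",
]

AKAR4_GAIN_PERCENT = 72.0  # full phosphorylation raises the 520/485 ratio by 72%
BASELINE_TIMES = (-15.0, -10.0, -5.0)  # three pre-injection samples


class SimulationError(RuntimeError):
    """Integration failure, carrying parameter provenance for diagnosis."""


@dataclass
class Trajectory:
    """Time-resolved species concentrations for one condition."""

    times: np.ndarray           # s
    concentrations: np.ndarray  # (n_times, n_species), µM
    network: ReactionNetwork
    condition: Condition
    params: ParameterSet

    def conc(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.network.index(name)]

    def moiety_total(self, name: str) -> np.ndarray:
        vec = self.network.moiety_vector(name)
        return self.concentrations @ vec


@dataclass
class EmissionTrace:
    """AKAR4 520/485 emission-ratio time series.

    ``times`` includes pre-injection baseline points at negative times;
    ``percent_full_scale`` is the phospho-fraction of the reporter on a
    0–100 scale.
    """

    times: np.ndarray
    ratio: np.ndarray
    percent_full_scale: np.ndarray
    condition: Condition | None = None
    gain: float = AKAR4_GAIN_PERCENT
    baseline_ratio: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def camp_dose(self) -> float:
        if self.condition is not None:
            return self.condition.camp_dose
        return float(self.meta.get("camp_dose", np.nan))

    def post_injection(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, ratio) restricted to t ≥ 0."""
        m = self.times >= 0
        return self.times[m], self.ratio[m]


@dataclass
class _Compiled:
    k: np.ndarray        # (n_channels,)
    idx1: np.ndarray     # first reactant index
    idx2: np.ndarray     # second reactant index, or dummy (points at the appended 1.0)
    N: np.ndarray        # (n_species, n_channels) net stoichiometry


def compile_channels(
    network: ReactionNetwork,
    params: ParameterSet,
    with_akap: bool | None = None,
) -> _Compiled:
    """Flatten reactions into irreversible flux channels with resolved rates."""
    ns = network.n_species
    k, i1, i2, cols = [], [], [], []

    def add(rate: float, reactants: tuple[int, ...], products: tuple[int, ...]) -> None:
        if len(reactants) > 2:
            raise ValueError("mass-action channels support at most 2 reactants")
        col = np.zeros(ns)
        for sid in reactants:
            col[sid - 1] -= 1
        for sid in products:
            col[sid - 1] += 1
        k.append(rate)
        i1.append(reactants[0] - 1)
        i2.append(reactants[1] - 1 if len(reactants) == 2 else ns)  # ns -> dummy 1.0
        cols.append(col)

    for rxn in network.reactions:
        kf = params.resolve(rxn.kf, with_akap)
        if kf < 0:
            raise ValueError(f"negative rate for {rxn.kf}")
        add(kf, rxn.reactants, rxn.products)
        if rxn.kind == "binding":
            kr = params.resolve(rxn.kr, with_akap)
            if kr < 0:
                raise ValueError(f"negative rate for {rxn.kr}")
            add(kr, rxn.products, rxn.reactants)

    return _Compiled(np.array(k), np.array(i1), np.array(i2),
                     np.column_stack(cols))


def _make_rhs_jac(c: _Compiled, ns: int):
    k, i1, i2, N = c.k, c.idx1, c.idx2, c.N
    nc = k.size
    bi = i2 < ns  # bimolecular channels

    def rhs(t, x):
        xx = np.empty(ns + 1)
        xx[:ns] = x
        xx[ns] = 1.0
        return N @ (k * xx[i1] * xx[i2])

    rows = np.arange(nc)

    def jac(t, x):
        xx = np.empty(ns + 1)
        xx[:ns] = x
        xx[ns] = 1.0
        dv = np.zeros((nc, ns + 1))
        dv[rows, i1] += k * xx[i2]
        dv[rows[bi], i2[bi]] += k[bi] * xx[i1[bi]]
        return N @ dv[:, :ns]

    return rhs, jac


def simulate(
    network: ReactionNetwork,
    params: ParameterSet,
    condition: Condition,
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-10,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the network ODEs from the pre-stimulus equilibrium.

    The cAMP dose enters as free cAMP at t = 0; ``x0`` overrides the
    equilibrium initial state when supplied.  Concentrations more negative
    than −1e-9 µM trigger a warning; small negatives are clipped.
    """
    if t_grid is None:
        t_grid = condition.time_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    if x0 is None:
        x0 = initial_state(network, condition, params)
    compiled = compile_channels(network, params, condition.with_akap)
    rhs, jac = _make_rhs_jac(compiled, network.n_species)

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), x0, method="LSODA", jac=jac,
        t_eval=t_grid, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed ({sol.message}) for condition "
            f"{condition.label!r}; parameters: {params.values}"
        )
    X = sol.y.T
    if X.min() < -1e-9:
        warnings.warn(
            f"negative concentration {X.min():.3e} µM clipped", RuntimeWarning
        )
    X = np.clip(X, 0.0, None)
    return Trajectory(t_grid, X, network, condition, params)


def akar4_readout(
    trajectory: Trajectory,
    gain: float = AKAR4_GAIN_PERCENT,
    baseline_ratio: float = 1.0,
    baseline_times: tuple[float, ...] = BASELINE_TIMES,
) -> EmissionTrace:
    """Map a trajectory to the 520/485 emission-ratio readout.

    ratio(t) = baseline × (1 + gain/100 × f(t)) with f the phospho-fraction
    pAKAR4 / (AKAR4 + AKAR4·C + pAKAR4); fully phosphorylated reporter gives
    a 72% ratio increase by default.  Baseline samples with f = 0 are
    prepended at negative times.
    """
    net = trajectory.network
    total = (trajectory.conc("AKAR4") + trajectory.conc("AKAR4.C")
             + trajectory.conc("pAKAR4"))
    if np.any(total <= 0):
        raise ValueError("zero reporter total: AKAR4 readout undefined")
    f = trajectory.conc("pAKAR4") / total
    nb = len(baseline_times)
    times = np.concatenate([np.asarray(baseline_times), trajectory.times])
    f_full = np.concatenate([np.zeros(nb), f])
    ratio = baseline_ratio * (1.0 + gain / 100.0 * f_full)
    return EmissionTrace(times, ratio, 100.0 * f_full, trajectory.condition,
                         gain, baseline_ratio)


def peak_rate(
    trace: EmissionTrace,
    camp_dose: float | None = None,
    slow_dose_threshold: float = 0.1,
) -> float:
    """Early linear-phase slope of percent-of-full-scale, in % per minute.

    The slope is fitted over 30–90 s, except at low cAMP doses
    (≤ 0.1 µM) where the slower response is fitted over 30–330 s.
    """
    if camp_dose is None:
        camp_dose = trace.camp_dose
    lo, hi = (30.0, 330.0) if camp_dose <= slow_dose_threshold else (30.0, 90.0)
    m = (trace.times >= lo) & (trace.times <= hi)
    if m.sum() < 3:
        raise ValueError(f"fewer than 3 samples in the [{lo}, {hi}] s window")
    slope_per_s = np.polyfit(trace.times[m], trace.percent_full_scale[m], 1)[0]
    return slope_per_s * 60.0


def ensemble_simulate(
    network: ReactionNetwork,
    ensemble,
    condition: Condition,
    gain: float = AKAR4_GAIN_PERCENT,
) -> tuple[list[EmissionTrace], dict[str, np.ndarray]]:
    """Simulate one emission trace per accepted parameter set.

    Returns the traces (in ensemble order) and a pointwise envelope
    {"times", "lo", "hi", "median"} over the ratio series.
    """
    traces = [
        akar4_readout(simulate(network, ps, condition), gain=gain)
        for ps in ensemble.parameter_sets()
    ]
    if not traces:
        raise ValueError("empty ensemble")
    R = np.vstack([tr.ratio for tr in traces])
    envelope = {
        "times": traces[0].times,
        "lo": R.min(axis=0),
        "hi": R.max(axis=0),
        "median": np.median(R, axis=0),
    }
    return traces, envelope


def free_c_fraction(
    trajectory: Trajectory, window: tuple[float, float] = (30.0, 90.0)
) -> tuple[np.ndarray, float]:
    """Free C / C_total per time point, plus the window average.

    Free C counts catalytic subunits not bound to any RII species, CN
    complex, or the reporter.
    """
    c_total = trajectory.moiety_total("C")[0]
    if c_total <= 0:
        raise ValueError("zero total C: free fraction undefined")
    frac = trajectory.conc("C") / c_total
    m = (trajectory.times >= window[0]) & (trajectory.times <= window[1])
    return frac, float(frac[m].mean())
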