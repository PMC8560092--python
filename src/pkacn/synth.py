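"""Synthetic-data generators with known ground truth.

Every generator emulates one of the pipeline's input types — AKAR4
plate-reader traces (3 baseline points, injection at t = 0, 5 s sampling,
605 s, 72% full-scale ratio gain, additive Gaussian ratio noise), reporter
calibration traces with C subunit only, Michaelis–Menten velocity tables,
³²P release count records, and Hill-shaped immunoblot reference series —
and returns the generating truth alongside the data so every downstream
analysis can be closed-loop tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    ParameterSet,
    ReactionNetwork,
    apply_variant,
    default_parameters,
    make_condition,
)
from .simulate import (
    AKAR4_GAIN_PERCENT,
    EmissionTrace,
    akar4_readout,
    free_c_fraction,
    peak_rate,
    simulate,
)

__all__ = [
    "GeneratorConfig",
    "ReleaseRecord",
    "gen_akar4_dataset",
    "gen_calibration_dataset",
    "gen_mm_dataset",
    "gen_release_records",
    "gen_immunoblot",
]

#: cAMP doses of the full plate layout (µM)
FULL_DOSES = (0.0, 0.1, 0.2, 0.5, 1.0, 2.0)
#: the four doses used for parameter estimation (µM)
ABC_DOSES = (0.0, 0.2, 1.0, 2.0)
#: the three protein mixtures
MIXTURES = ("pka", "pka+cn", "pka+cn+akap")


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the AKAR4 trace generator."""

    seed: int = 0
    sigma_ratio: float = 0.005   # additive Gaussian noise on the emission ratio
    doses: tuple[float, ...] = ABC_DOSES
    mixtures: tuple[str, ...] = MIXTURES
    rii_variant: str = "WT"
    sample_interval: float = 5.0
    t_end: float = 605.0
    n_baseline: int = 3
    gain: float = AKAR4_GAIN_PERCENT
    baseline_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_ratio < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass(frozen=True)
class ReleaseRecord:
    """One ³²P phosphatase assay observation."""

    cpm_supernatant: float
    cpm_pellet: float
    substrate_conc: float  # µM
    enzyme_conc: float     # µM
    reaction_time: float   # s

    def __post_init__(self) -> None:
        if self.cpm_supernatant < 0 or self.cpm_pellet < 0:
            raise ValueError("counts must be non-negative")
        if self.reaction_time <= 0:
            raise ValueError("reaction time must be positive")


def _mixture_flags(mixture: str) -> tuple[bool, bool]:
    return {
        "pka": (False, False),
        "pka+cn": (True, False),
        "pka+cn+akap": (True, True),
    }[mixture]


def gen_akar4_dataset(
    network: ReactionNetwork,
    true_params: ParameterSet,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[EmissionTrace], dict]:
    """Simulate the condition grid and emit noisy traces plus the truth.

    The hidden-truth record carries the generating parameters and, per
    condition, the noiseless ratio series, the in-window peak rate, and the
    30–90 s window-average free-C fraction.
    """
    if config is None:
        config = GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    split = network.variant == "extended"
    params = true_params
    traces: list[EmissionTrace] = []
    truth: dict = {"params": dict(params.values), "conditions": {}}
    for mixture in config.mixtures:
        with_cn, with_akap = _mixture_flags(mixture)
        for dose in config.doses:
            label = f"{mixture}@{dose:g}uM"
            cond = make_condition(
                "spine_mimic", camp=dose, with_cn=with_cn, with_akap=with_akap,
                rii_variant=config.rii_variant, split=split,
                t_end=config.t_end, sample_interval=config.sample_interval,
                label=label,
            )
            sim_params = params
            if config.rii_variant != "WT":
                sim_params, _ = apply_variant(params, network, config.rii_variant)
            traj = simulate(network, sim_params, cond)
            clean = akar4_readout(
                traj, gain=config.gain, baseline_ratio=config.baseline_ratio
            )
            frac, favg = free_c_fraction(traj)
            noisy_ratio = clean.ratio + rng.normal(0, config.sigma_ratio,
                                                   clean.ratio.size)
            scale = config.baseline_ratio * config.gain / 100.0
            noisy = EmissionTrace(
                clean.times, noisy_ratio,
                100.0 * (noisy_ratio / config.baseline_ratio - 1.0)
                / (config.gain / 100.0),
                cond, config.gain, config.baseline_ratio,
                meta={"mixture": mixture, "camp_dose": dose},
            )
            traces.append(noisy)
            truth["conditions"][label] = {
                "ratio_clean": clean.ratio.copy(),
                "times": clean.times.copy(),
                "peak_rate": peak_rate(clean),
                "free_c_window_avg": favg,
            }
    return traces, truth


def gen_calibration_dataset(
    C_concs: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4),
    akar4_params: ParameterSet | None = None,
    config: GeneratorConfig | None = None,
    network: ReactionNetwork | None = None,
) -> tuple[list[EmissionTrace], dict]:
    """Reporter calibration traces: AKAR4 plus C subunit only.

    With saturating C the phospho plateau approaches a 72% ratio increase;
    the initial phosphorylation rate is close to linear in [C] up to
    0.4 µM for the default reporter parameters.
    """
    if len(C_concs) < 2:
        raise ValueError("need at least 2 C concentrations")
    if config is None:
        config = GeneratorConfig()
    if akar4_params is None:
        akar4_params = default_parameters()
    if network is None:
        from .network import build_base_network
        network = build_base_network()
    rng = np.random.default_rng(config.seed)
    traces, truth = [], {"params": dict(akar4_params.values), "conditions": {}}
    for c in C_concs:
        label = f"calibration@{c:g}uM"
        cond = make_condition(
            "calibration", totals={"C": c}, t_end=config.t_end,
            sample_interval=config.sample_interval, label=label,
        )
        traj = simulate(network, akar4_params, cond)
        clean = akar4_readout(traj, gain=config.gain,
                              baseline_ratio=config.baseline_ratio)
        noisy_ratio = clean.ratio + rng.normal(0, config.sigma_ratio,
                                               clean.ratio.size)
        noisy = EmissionTrace(
            clean.times, noisy_ratio,
            100.0 * (noisy_ratio / config.baseline_ratio - 1.0)
            / (config.gain / 100.0),
            cond, config.gain, config.baseline_ratio,
            meta={"C_conc": c},
        )
        traces.append(noisy)
        truth["conditions"][label] = {
            "ratio_clean": clean.ratio.copy(),
            "initial_rate": peak_rate(clean, camp_dose=1.0),  # 30-90 s window
        }
    return traces, truth


DEFAULT_MM_GRID = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)  # µM


def gen_mm_dataset(
    K_m: float,
    k_cat: float,
    S_grid: tuple[float, ...] = DEFAULT_MM_GRID,
    enzyme_conc: float = 0.01,
    reps: int = 3,
    noise: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Michaelis–Menten velocity table with multiplicative Gaussian noise.

    Velocities are per-enzyme turnover (s⁻¹): v = k_cat·S/(K_m+S), measured
    in ``reps`` replicates per substrate concentration.
    """
    if K_m <= 0 or k_cat <= 0:
        raise ValueError("K_m and k_cat must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for S in S_grid:
        v_true = k_cat * S / (K_m + S)
        for rep in range(reps):
            v = v_true * (1.0 + noise * rng.standard_normal())
            rows.append({"substrate_uM": S, "replicate": rep,
                         "velocity_per_s": max(v, 0.0),
                         "enzyme_uM": enzyme_conc})
    return pd.DataFrame(rows)


def gen_release_records(
    true_fraction: float,
    total_cpm: float = 20000.0,
    n: int = 3,
    seed: int = 0,
    substrate_conc: float = 0.4,
    enzyme_conc: float = 0.01,
    reaction_time: float = 30.0,
) -> list[ReleaseRecord]:
    """³²P release counts: Poisson supernatant/pellet split of total counts."""
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n):
        sup = rng.poisson(true_fraction * total_cpm)
        pel = rng.poisson((1.0 - true_fraction) * total_cpm)
        records.append(ReleaseRecord(float(sup), float(pel), substrate_conc,
                                     enzyme_conc, reaction_time))
    return records


DEFAULT_REFERENCE_AMOUNTS = (5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0)  # ng


def gen_immunoblot(
    reference_amounts: tuple[float, ...] = DEFAULT_REFERENCE_AMOUNTS,
    hill_params: tuple[float, float, float] = (1.0, 40.0, 1.2),
    extract_true_percent: float = 0.32,
    loaded_ug: float = 15.0,
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, dict]:
    """Reference-series intensities plus one extract lane.

    ``hill_params`` = (Imax, K, h) of intensity vs loaded amount (ng).  The
    extract lane's band mass is ``extract_true_percent``% of ``loaded_ug``
    µg total protein; defaults emulate a 15 µg extract lane (10 µg is used
    for anti-C blots).  Noise is multiplicative Gaussian.
    """
    imax, K, h = hill_params
    if min(imax, K, h) <= 0:
        raise ValueError("Hill parameters must be positive")
    rng = np.random.default_rng(seed)

    def hill(c):
        c = np.asarray(c, dtype=float)
        return imax * c ** h / (K ** h + c ** h)

    amounts = np.asarray(reference_amounts, dtype=float)
    ref_int = hill(amounts) * (1.0 + noise * rng.standard_normal(amounts.size))
    extract_mass_ng = extract_true_percent / 100.0 * loaded_ug * 1000.0
    flagged = not (amounts.min() <= extract_mass_ng <= amounts.max())
    extract_int = float(hill(extract_mass_ng)
                        * (1.0 + noise * rng.standard_normal()))
    ref = pd.DataFrame({"amount_ng": amounts, "intensity": ref_int})
    truth = {
        "hill_params": {"Imax": imax, "K": K, "h": h},
        "extract_true_percent": extract_true_percent,
        "extract_mass_ng": extract_mass_ng,
        "loaded_ug": loaded_ug,
        "outside_reference_range": flagged,
    }
    return ref, extract_int, truth
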