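"""Reaction network for type II PKA regulation by AKAP79-anchored calcineurin.

The base model describes a well-mixed reaction compartment containing PKA
regulatory (RII) and catalytic (C) subunits, cAMP, the phosphatase
calcineurin (CN), and the FRET reporter AKAR4.  RII subunits cycle between
an IS-phosphorylated "slow capture" square (pRII, pRII·C, pRII·cAMP,
pRII·cAMP·C) and an unphosphorylated "fast capture" square (RII, RII·C,
RII·cAMP, RII·cAMP·C): eight reversible binding edges, two intramolecular
autophosphorylation steps carrying complexes from the right (RII) square to
the left (pRII) square, and CN-catalysed dephosphorylation of the C-free
phospho-species carrying material back.  AKAR4 is phosphorylated by free C
subunits through an explicit binding + catalysis mechanism.

Species numbering (fixed, canonical)::

    1 pRII         5 RII·C          9 C           13 CN·pRII·cAMP
    2 pRII·C       6 RII·cAMP·C    10 cAMP        14 AKAR4
    3 pRII·cAMP    7 RII·cAMP      11 CN          15 AKAR4·C
    4 pRII·cAMP·C  8 RII           12 CN·pRII     16 pAKAR4

so that the dissociation constant of the RII·C + cAMP edge is K_D56 and
that of the RII·cAMP + C edge is K_D76.

AKAP79 is represented as a parameter regime, not a species: anchoring
changes the effective CN↔pRII Michaelis parameters, so every CN rate
constant exists in a ``_wA`` (with AKAP79) and ``_nA`` (without) version and
the condition's AKAP flag selects which set is compiled into the ODEs.

Concentration units are µM throughout; time is in seconds.  Bimolecular
rate constants are µM⁻¹ s⁻¹, unimolecular ones s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ParameterSet",
    "Condition",
    "build_base_network",
    "build_extended_network",
    "default_parameters",
    "extend_parameters",
    "apply_variant",
    "make_condition",
    "initial_state",
    "derive_kds",
    "AKAR4_PARAM_NAMES",
    "CN_PARAM_STEMS",
]

VARIANTS = ("WT", "S98A", "S98E")

# parameter stems whose concrete value depends on the AKAP79 regime
CN_PARAM_STEMS = (
    "kf_CN_pRII", "kr_CN_pRII", "kcat_CN_pRII",
    "kf_CN_pRIIcAMP", "kr_CN_pRIIcAMP", "kcat_CN_pRIIcAMP",
)

# reporter parameters, frozen after calibration against C-only traces
AKAR4_PARAM_NAMES = ("kf_AKAR4_C", "kr_AKAR4_C", "kcat_AKAR4")


@dataclass(frozen=True)
class Species:
    """A chemical species: 1-based id, display name, and pool membership.

    ``pool`` is ``"RII"`` for RII-containing species (duplicated when the
    model is split into α/β isoform pools) and ``"shared"`` otherwise.
    """

    id: int
    name: str
    pool: str = "shared"


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction.

    ``kind`` is ``"binding"`` (reversible, parameters ``kf``/``kr``) or
    ``"catalysis"`` (irreversible, single parameter stored in ``kf``).
    Reactants/products are species ids.  Parameter fields hold *names* that
    are resolved against a :class:`ParameterSet` at compile time.
    """

    name: str
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    kind: str
    kf: str
    kr: str | None = None


@dataclass
class ReactionNetwork:
    """Species, reactions and conserved moieties for one model variant."""

    species: list[Species]
    reactions: list[Reaction]
    conserved_moieties: list[tuple[str, np.ndarray]]
    variant: str = "base"  # "base" or "extended"
    kd_edges: dict[str, str] = field(default_factory=dict)  # K_D key -> reaction name

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("species ids must be unique and contiguous from 1")
        self._index = {s.name: s.id - 1 for s in self.species}

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def index(self, name: str) -> int:
        """0-based state-vector index of a species name."""
        return self._index[name]

    def has_species(self, name: str) -> bool:
        return name in self._index

    def stoichiometric_matrix(self) -> np.ndarray:
        """Net stoichiometry, one column per reaction (products − reactants)."""
        S = np.zeros((self.n_species, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for sid in rxn.reactants:
                S[sid - 1, j] -= 1
            for sid in rxn.products:
                S[sid - 1, j] += 1
        return S

    def moiety_vector(self, name: str) -> np.ndarray:
        for label, vec in self.conserved_moieties:
            if label == name:
                return vec
        raise KeyError(name)


def _moiety_vectors(species: list[Species]) -> list[tuple[str, np.ndarray]]:
    """Conservation vectors from substring structure of species names."""
    n = len(species)

    def vec(pred) -> np.ndarray:
        v = np.zeros(n)
        for s in species:
            v[s.id - 1] = 1.0 if pred(s.name) else 0.0
        return v

    out = [
        ("RII", vec(lambda nm: "RII" in nm)),
        ("C", vec(lambda nm: nm == "C" or nm.endswith(".C") or nm == "AKAR4.C")),
        ("CN", vec(lambda nm: nm == "CN" or nm.startswith("CN."))),
        ("cAMP", vec(lambda nm: "cAMP" in nm)),
        ("AKAR4", vec(lambda nm: "AKAR4" in nm)),
    ]
    return out


def _base_species() -> list[Species]:
    names = [
        "pRII", "pRII.C", "pRII.cAMP", "pRII.cAMP.C",
        "RII.C", "RII.cAMP.C", "RII.cAMP", "RII",
        "C", "cAMP", "CN", "CN.pRII", "CN.pRII.cAMP",
        "AKAR4", "AKAR4.C", "pAKAR4",
    ]
    return [
        Species(i + 1, nm, "RII" if "RII" in nm else "shared")
        for i, nm in enumerate(names)
    ]


def build_base_network() -> ReactionNetwork:
    """Canonical 16-species / 16-reaction base model.

    Two four-corner binding squares (8 reversible edges), two
    autophosphorylation steps, CN dephosphorylation of pRII and pRII·cAMP
    as binding + catalysis (4 reactions), and the AKAR4 reporter module
    (binding + catalysis, 2 reactions).
    """
    sp = _base_species()
    ix = {s.name: s.id for s in sp}

    def b(name, a1, a2, c, kf, kr):
        return Reaction(name, (ix[a1], ix[a2]), (ix[c],), "binding", kf, kr)

    rxns = [
        # phospho (left) square
        b("pRII+C", "pRII", "C", "pRII.C", "kf_pRII_C", "kr_pRII_C"),
        b("pRII+cAMP", "pRII", "cAMP", "pRII.cAMP", "kf_pRII_cAMP", "kr_pRII_cAMP"),
        b("pRII.C+cAMP", "pRII.C", "cAMP", "pRII.cAMP.C", "kf_pRIIC_cAMP", "kr_pRIIC_cAMP"),
        b("pRII.cAMP+C", "pRII.cAMP", "C", "pRII.cAMP.C", "kf_pRIIcAMP_C", "kr_pRIIcAMP_C"),
        # dephospho (right) square
        b("RII+C", "RII", "C", "RII.C", "kf_RII_C", "kr_RII_C"),
        b("RII+cAMP", "RII", "cAMP", "RII.cAMP", "kf_RII_cAMP", "kr_RII_cAMP"),
        b("RII.C+cAMP", "RII.C", "cAMP", "RII.cAMP.C", "kf_RIIC_cAMP", "kr_RIIC_cAMP"),
        b("RII.cAMP+C", "RII.cAMP", "C", "RII.cAMP.C", "kf_RIIcAMP_C", "kr_RIIcAMP_C"),
        # intramolecular autophosphorylation (right square -> left square)
        Reaction("phos:RII.C", (ix["RII.C"],), (ix["pRII.C"],), "catalysis", "kphos_RIIC"),
        Reaction("phos:RII.cAMP.C", (ix["RII.cAMP.C"],), (ix["pRII.cAMP.C"],),
                 "catalysis", "kphos_RIIcAMPC"),
        # CN dephosphorylation: three elementary steps (binding, dissociation, catalysis)
        b("CN+pRII", "CN", "pRII", "CN.pRII", "kf_CN_pRII", "kr_CN_pRII"),
        Reaction("cat:CN.pRII", (ix["CN.pRII"],), (ix["CN"], ix["RII"]),
                 "catalysis", "kcat_CN_pRII"),
        b("CN+pRII.cAMP", "CN", "pRII.cAMP", "CN.pRII.cAMP",
          "kf_CN_pRIIcAMP", "kr_CN_pRIIcAMP"),
        Reaction("cat:CN.pRII.cAMP", (ix["CN.pRII.cAMP"],), (ix["CN"], ix["RII.cAMP"]),
                 "catalysis", "kcat_CN_pRIIcAMP"),
        # AKAR4 reporter
        b("AKAR4+C", "AKAR4", "C", "AKAR4.C", "kf_AKAR4_C", "kr_AKAR4_C"),
        Reaction("cat:AKAR4.C", (ix["AKAR4.C"],), (ix["pAKAR4"], ix["C"]),
                 "catalysis", "kcat_AKAR4"),
    ]
    kd_edges = {
        "K_D12": "pRII+C",
        "K_D13": "pRII+cAMP",
        "K_D24": "pRII.C+cAMP",
        "K_D34": "pRII.cAMP+C",
        "K_D85": "RII+C",
        "K_D87": "RII+cAMP",
        "K_D56": "RII.C+cAMP",
        "K_D76": "RII.cAMP+C",
    }
    return ReactionNetwork(sp, rxns, _moiety_vectors(sp), "base", kd_edges)


def build_extended_network(alpha_fraction: float = 0.85) -> ReactionNetwork:
    """Split every RII-containing species into RIIα / RIIβ pools.

    The two pools share C, cAMP, CN and the reporter species.  Reaction
    parameters get ``_a`` / ``_b`` suffixes so isoform-specific mutations
    (S98A, S98E) can zero α-pool rates only.  ``alpha_fraction`` records the
    fraction of total RII assigned to the α pool (85% in CA1 neuropil).
    """
    if not 0.0 <= alpha_fraction <= 1.0:
        raise ValueError("alpha_fraction must lie in [0, 1]")
    base = build_base_network()

    species: list[Species] = []
    for tag in ("a", "b"):
        for s in base.species:
            if s.pool == "RII":
                species.append(Species(len(species) + 1, _pool_name(s.name, tag), "RII"))
    for s in base.species:
        if s.pool == "shared":
            species.append(Species(len(species) + 1, s.name, "shared"))
    ix = {s.name: s.id for s in species}

    rxns: list[Reaction] = []
    for tag in ("a", "b"):
        for rxn in base.reactions:
            involved = any(
                base.species[sid - 1].pool == "RII"
                for sid in rxn.reactants + rxn.products
            )
            if not involved:
                continue
            rename = lambda sid: ix[_pool_name(base.species[sid - 1].name, tag)
                                    if base.species[sid - 1].pool == "RII"
                                    else base.species[sid - 1].name]
            rxns.append(Reaction(
                f"{rxn.name}@{tag}",
                tuple(rename(s) for s in rxn.reactants),
                tuple(rename(s) for s in rxn.products),
                rxn.kind,
                f"{rxn.kf}_{tag}",
                None if rxn.kr is None else f"{rxn.kr}_{tag}",
            ))
    for rxn in base.reactions:
        involved = any(
            base.species[sid - 1].pool == "RII"
            for sid in rxn.reactants + rxn.products
        )
        if involved:
            continue
        rename = lambda sid: ix[base.species[sid - 1].name]
        rxns.append(Reaction(
            rxn.name,
            tuple(rename(s) for s in rxn.reactants),
            tuple(rename(s) for s in rxn.products),
            rxn.kind, rxn.kf, rxn.kr,
        ))

    net = ReactionNetwork(species, rxns, _moiety_vectors(species), "extended")
    net.alpha_fraction = alpha_fraction
    return net


def _pool_name(name: str, tag: str) -> str:
    """pRII.cAMP.C -> pRIIa.cAMP.C for tag 'a' (suffix goes on the RII token)."""
    parts = name.split(".")
    parts = [p + tag if p in ("RII", "pRII") else p for p in parts]
    return ".".join(parts)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class ParameterSet:
    """Named rate constants for one model variant.

    ``values`` maps parameter names to non-negative rates.  CN parameters
    are stored per AKAP79 regime (``_wA`` / ``_nA`` suffix); ``akap_mode``
    is the default regime used when no condition supplies one.
    """

    values: dict[str, float]
    akap_mode: str = "with_AKAP79"

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __setitem__(self, key: str, value: float) -> None:
        self.values[key] = value

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), self.akap_mode)

    def resolve(self, name: str, with_akap: bool | None = None) -> float:
        """Concrete value for a reaction-parameter name.

        CN parameter stems are resolved through the AKAP79 regime suffix.
        """
        if name in self.values:
            return self.values[name]
        if with_akap is None:
            with_akap = self.akap_mode == "with_AKAP79"
        suffix = "_wA" if with_akap else "_nA"
        stem, pool = _split_pool_suffix(name)
        cand = stem + suffix + (f"_{pool}" if pool else "")
        if cand in self.values:
            return self.values[cand]
        raise KeyError(name)

    def vector(self, names: list[str]) -> np.ndarray:
        return np.array([self.values[n] for n in names])


def _split_pool_suffix(name: str) -> tuple[str, str | None]:
    for pool in ("a", "b"):
        if name.endswith(f"_{pool}"):
            return name[:-2], pool
    return name, None


#: Default rate constants (µM, s).  CN kinetics reproduce the measured
#: Michaelis parameters for pRII-AKAP79c97 complexes (K_m 1.36 µM,
#: k_cat 0.45 s⁻¹) in the with-AKAP regime, and a low-affinity regime
#: (K_m 94 µM, activity < 0.03 s⁻¹ below 5 µM substrate) without the
#: anchor.  C-subunit association with unphosphorylated RII is 50-fold
#: faster than with pRII.  See docs/methods.md for the full rationale.
_DEFAULTS = {
    # phospho (left, slow-capture) square
    "kf_pRII_C": 0.004, "kr_pRII_C": 0.02,       # K_D12 = 5 µM
    "kf_pRII_cAMP": 0.1, "kr_pRII_cAMP": 1.0,    # K_D13 = 10 µM
    "kf_pRIIC_cAMP": 1.0, "kr_pRIIC_cAMP": 0.1,  # K_D24 = 0.1 µM
    "kf_pRIIcAMP_C": 0.02, "kr_pRIIcAMP_C": 0.5, # K_D34 = 25 µM
    # dephospho (right, fast-capture) square; C association 50× faster than pRII
    "kf_RII_C": 0.2, "kr_RII_C": 2e-4,           # K_D85 = 1e-3 µM
    "kf_RII_cAMP": 0.1, "kr_RII_cAMP": 1.0,      # K_D87 = 10 µM
    "kf_RIIC_cAMP": 1.0, "kr_RIIC_cAMP": 0.1,    # K_D56 = 0.1 µM (low)
    "kf_RIIcAMP_C": 1.0, "kr_RIIcAMP_C": 10.0,   # K_D76 = 10 µM (high)
    # autophosphorylation of bound C's own RII
    "kphos_RIIC": 5.0, "kphos_RIIcAMPC": 5.0,
    # CN dephosphorylation, with AKAP79 anchoring (K_m 1.36 µM, k_cat 0.45/s)
    "kf_CN_pRII_wA": 1.0, "kr_CN_pRII_wA": 0.91, "kcat_CN_pRII_wA": 0.45,
    "kf_CN_pRIIcAMP_wA": 1.0, "kr_CN_pRIIcAMP_wA": 0.91, "kcat_CN_pRIIcAMP_wA": 0.45,
    # CN dephosphorylation, no anchor (K_m 94 µM, activity < 0.03/s below 5 µM)
    "kf_CN_pRII_nA": 0.01, "kr_CN_pRII_nA": 0.74, "kcat_CN_pRII_nA": 0.2,
    "kf_CN_pRIIcAMP_nA": 0.01, "kr_CN_pRIIcAMP_nA": 0.74, "kcat_CN_pRIIcAMP_nA": 0.2,
    # AKAR4 reporter (K_m ≈ 10 µM, k_cat/K_m ≈ 0.012 µM⁻¹s⁻¹)
    "kf_AKAR4_C": 0.1, "kr_AKAR4_C": 0.9, "kcat_AKAR4": 0.12,
}


def default_parameters(akap_mode: str = "with_AKAP79") -> ParameterSet:
    """Package default rate table for the base model."""
    if akap_mode not in ("with_AKAP79", "without_AKAP79"):
        raise ValueError(f"unknown akap_mode {akap_mode!r}")
    return ParameterSet(dict(_DEFAULTS), akap_mode)


def extend_parameters(params: ParameterSet) -> ParameterSet:
    """Duplicate RII-reaction parameters into α/β pool copies.

    Shared AKAR4 parameters keep their names; every other parameter gets
    ``_a`` and ``_b`` copies with identical values (the extended model keeps
    the base parameter distribution).
    """
    out: dict[str, float] = {}
    for name, val in params.values.items():
        if name in AKAR4_PARAM_NAMES:
            out[name] = val
        else:
            out[f"{name}_a"] = val
            out[f"{name}_b"] = val
    return ParameterSet(out, params.akap_mode)


def apply_variant(
    params: ParameterSet, network: ReactionNetwork, variant: str
) -> tuple[ParameterSet, str]:
    """Impose an RIIα IS-mutant on an extended parameter set.

    S98A (non-phosphorylatable) zeroes the two α-pool autophosphorylation
    rates; S98E (phospho-mimetic) zeroes the two α-pool CN turnover numbers
    in both AKAP regimes and switches the α initial condition to fully
    phosphorylated.  Returns the modified parameters and the initial-
    condition rule (``"default"`` or ``"phospho_alpha"``).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "WT":
        return params.copy(), "default"
    if network.variant != "extended":
        raise ValueError(f"{variant} requires the extended (α/β-split) network")
    out = params.copy()
    if variant == "S98A":
        out["kphos_RIIC_a"] = 0.0
        out["kphos_RIIcAMPC_a"] = 0.0
        return out, "default"
    # S98E
    for regime in ("_wA", "_nA"):
        out[f"kcat_CN_pRII{regime}_a"] = 0.0
        out[f"kcat_CN_pRIIcAMP{regime}_a"] = 0.0
    return out, "phospho_alpha"


def derive_kds(params: ParameterSet, pool: str | None = None) -> dict[str, float]:
    """Dissociation constants K_D = kr/kf of the eight square-edge bindings.

    Keys follow the species-index pairing, e.g. K_D56 for RII·C + cAMP and
    K_D76 for RII·cAMP + C.  ``pool`` ('a' or 'b') selects an isoform copy
    from an extended parameter set.
    """
    base = build_base_network()
    suffix = f"_{pool}" if pool else ""
    out: dict[str, float] = {}
    for key, rname in base.kd_edges.items():
        rxn = next(r for r in base.reactions if r.name == rname)
        kf = params[rxn.kf + suffix]
        kr = params[rxn.kr + suffix]
        if kf <= 0:
            raise ValueError(f"K_D undefined for {rname}: kf = {kf}")
        out[key] = kr / kf
    return out


# ---------------------------------------------------------------------------
# conditions and initial states


@dataclass
class Condition:
    """Initial protein totals, cAMP dose and experiment flags (all µM, s)."""

    totals: dict[str, float]
    camp_dose: float = 0.0
    with_cn: bool = False
    with_akap: bool = False
    rii_variant: str = "WT"
    t_end: float = 605.0
    sample_interval: float = 5.0
    label: str = ""

    def __post_init__(self) -> None:
        for key, val in self.totals.items():
            if val < 0:
                raise ValueError(f"negative total for {key}: {val}")
        if self.camp_dose < 0:
            raise ValueError("negative cAMP dose")
        if self.rii_variant not in VARIANTS:
            raise ValueError(f"unknown RII variant {self.rii_variant!r}")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.sample_interval))
        return np.linspace(0.0, n * self.sample_interval, n + 1)


# Spine-mimic totals: RIIα/RIIβ from quantitative immunoblots of CA1
# neuropil, C from the 9.4-fold RIIα:C molar ratio, CN 1.5 µM, AKAR4 0.2 µM.
SPINE_RII_ALPHA = 5.9
SPINE_RII_BETA = 1.03
SPINE_C = SPINE_RII_ALPHA / 9.4  # ≈ 0.63 µM
SPINE_CN = 1.5
AKAR4_TOTAL = 0.2


def make_condition(
    preset: str | None = None,
    *,
    camp: float = 0.0,
    with_cn: bool = False,
    with_akap: bool = False,
    rii_variant: str = "WT",
    split: bool = False,
    totals: dict[str, float] | None = None,
    t_end: float = 605.0,
    sample_interval: float = 5.0,
    label: str = "",
) -> Condition:
    """Build a condition from a named preset or explicit totals.

    Presets: ``"spine_mimic"`` (the in-vitro mixture emulating CA1 spine
    concentrations) and ``"calibration"`` (C subunit + AKAR4 only; pass the
    C concentration via ``totals={"C": ...}``).  ``split=True`` partitions
    RII into α/β totals for the extended network.
    """
    if preset is None:
        if totals is None:
            raise ValueError("either a preset or explicit totals is required")
        tot = dict(totals)
    elif preset == "spine_mimic":
        tot = {"C": SPINE_C, "AKAR4": AKAR4_TOTAL}
        if split:
            tot["RIIalpha"] = SPINE_RII_ALPHA
            tot["RIIbeta"] = SPINE_RII_BETA
        else:
            tot["RII"] = SPINE_RII_ALPHA + SPINE_RII_BETA
        tot["CN"] = SPINE_CN if with_cn else 0.0
        if totals:
            tot.update(totals)
    elif preset == "calibration":
        tot = {"RII": 0.0, "C": 0.0, "CN": 0.0, "AKAR4": AKAR4_TOTAL}
        if totals:
            tot.update(totals)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    if not label:
        label = preset or "custom"
    return Condition(tot, camp, with_cn, with_akap, rii_variant,
                     t_end, sample_interval, label)


def _binding_pools(
    network: ReactionNetwork, condition: Condition, params: ParameterSet
) -> list[tuple[str, str, float, float]]:
    """(free species, C-bound species, pool total, K_D) for each RII pool.

    WT/S98A pools start unphosphorylated; the S98E α pool starts fully
    phosphorylated and equilibrates through the pRII·C edge.
    """
    def kd(kf_name, kr_name):
        kf, kr = params[kf_name], params[kr_name]
        return math.inf if kf == 0 else kr / kf

    pools = []
    if network.variant == "base":
        total = condition.totals.get("RII", 0.0)
        pools.append(("RII", "RII.C", total, kd("kf_RII_C", "kr_RII_C")))
    else:
        for tag, key in (("a", "RIIalpha"), ("b", "RIIbeta")):
            total = condition.totals.get(key, 0.0)
            if tag == "a" and condition.rii_variant == "S98E":
                pools.append((f"pRII{tag}", f"pRII{tag}.C", total,
                              kd(f"kf_pRII_C_{tag}", f"kr_pRII_C_{tag}")))
            else:
                pools.append((f"RII{tag}", f"RII{tag}.C", total,
                              kd(f"kf_RII_C_{tag}", f"kr_RII_C_{tag}")))
    return pools


def initial_state(
    network: ReactionNetwork, condition: Condition, params: ParameterSet
) -> np.ndarray:
    """Pre-stimulus state vector: C equilibrated over cAMP-free RII pools.

    Free C is the root of c + Σᵢ Tᵢ·c/(Kᵢ + c) = C_total, found by bracketed
    root solving (reduces to the standard quadratic for a single pool).  The
    cAMP dose appears as free cAMP at t = 0; CN and AKAR4 start free.
    """
    x0 = np.zeros(network.n_species)
    # K = 0 (irreversible capture) is floored to keep the root bracketed
    pools = [(f, b, T, max(K, 1e-12)) for f, b, T, K in
             _binding_pools(network, condition, params)]
    c_total = condition.totals.get("C", 0.0)

    def excess(c: float) -> float:
        tot = c
        for _, _, T, K in pools:
            if T > 0 and np.isfinite(K):
                tot += T * c / (K + c)
        return tot - c_total

    if c_total <= 0:
        c_free = 0.0
    elif all(T <= 0 or not np.isfinite(K) for _, _, T, K in pools):
        c_free = c_total
    else:
        c_free = brentq(excess, 0.0, c_total, xtol=1e-15, maxiter=300)

    total_bound = 0.0
    for free_name, bound_name, T, K in pools:
        if T <= 0:
            continue
        bound = 0.0 if not np.isfinite(K) else T * c_free / (K + c_free)
        x0[network.index(bound_name)] = bound
        x0[network.index(free_name)] = T - bound
        total_bound += bound

    # assign the remainder to free C so the moiety total is exact
    x0[network.index("C")] = max(0.0, c_total - total_bound)
    x0[network.index("cAMP")] = condition.camp_dose
    x0[network.index("CN")] = condition.totals.get("CN", 0.0)
    x0[network.index("AKAR4")] = condition.totals.get("AKAR4", 0.0)
    return x0
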