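"""Mass-action kinetic models of the GTPase activation/deactivation cycle.

The models describe a small GTPase (Ras) cycling between an empty
nucleotide-free state ``G``, the active GTP-loaded state ``GT``, the
inactive GDP-loaded state ``GD`` and, in the three-state variant, a
post-hydrolysis state ``GI`` that is refractory to GEF-driven exchange.
Effectors (Ras-binding domains) and GAPs bind ``GT`` competitively; the
system output is the concentration of effector-bound active GTPase.

Conventions: time in seconds, concentrations in nM, bimolecular rate
constants in nM^-1 s^-1, unimolecular in s^-1.  GEF activity is not a
species by default: it is folded into the nucleotide-release rate constant
``k_exch`` acting on ``GD`` (``k_exch = k_per_gef * [GEF]``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "MutantSpec",
    "WILD_TYPE",
    "G12V",
    "GIRouting",
    "Reaction",
    "ReactionNetwork",
    "SimulationResult",
    "SteadyStateResult",
    "SimulationError",
    "ParameterError",
    "CANONICAL_INITIAL_STATE",
    "NF1_LIKE_GAP",
    "P120_LIKE_GAP",
    "NONPHYSIOLOGIC_GAP",
    "build_two_state_model",
    "build_competition_model",
    "build_three_state_model",
    "apply_mutant",
    "add_effector",
    "simulate",
    "steady_state",
]


class ParameterError(ValueError):
    """A rate constant or concentration is out of its admissible range."""


class SimulationError(RuntimeError):
    """The integrator failed or produced an inadmissible trajectory."""


# Canonical step-input initial condition: 10 nM GDP-loaded Ras, 50 nM
# effector, effectively infinite nucleotide supply.
CANONICAL_INITIAL_STATE: dict[str, float] = {"GD": 10.0, "EFF": 50.0, "T": 100000.0}

#: GAP kinetic presets (k_gap_off s^-1, k_gap_cat s^-1); k_gap_on is common.
NF1_LIKE_GAP = {"k_gap_off": 0.01, "k_gap_cat": 0.1}
P120_LIKE_GAP = {"k_gap_off": 0.25, "k_gap_cat": 0.4}
#: Parameter set under which a two-state + competition model can overshoot,
#: but which is inconsistent with measured GAP kinetics.
NONPHYSIOLOGIC_GAP = {"k_gap_off": 1e-4, "k_gap_cat": 1e-4}

#: Exchange rate constant used by the plain two-state model.
TWO_STATE_EXCHANGE = 0.05

# Default tolerances for the stiff integrator. Bimolecular nucleotide
# binding at 1 nM^-1 s^-1 against a 1e5 nM nucleotide pool makes the system
# genuinely stiff; tolerances are kept tight rather than softening rates.
RTOL = 1e-8
ATOL = 1e-12
NEGATIVE_TOL = 1e-9
CONSERVATION_RTOL = 1e-6


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the GTPase cycle (defaults = three-state model).

    ``k_exch`` is the GEF-folded nucleotide-release rate on GD; use
    :meth:`with_gef` to derive it from a GEF concentration.
    """

    k_nt_on: float = 1.0          # nM^-1 s^-1, nucleotide binding G + T -> GT
    k_exch: float = 0.005         # s^-1, GD -> G + D (GEF activity folded in)
    k_hyd: float = 1e-4           # s^-1, intrinsic hydrolysis from GT
    k_hyd_eff: float = 1e-4       # s^-1, hydrolysis from the effector-bound state
    k_eff_on: float = 1e-4        # nM^-1 s^-1
    k_eff_off: float = 1e-3       # s^-1
    k_gap_on: float = 1e-4        # nM^-1 s^-1
    k_gap_off: float = 0.01       # s^-1
    k_gap_cat: float = 1.0        # s^-1, committed hydrolysis from GT_GAP
    k_gi_reset: float = 1e-4      # s^-1, GI -> GD relaxation
    k_per_gef: float = 5e-6       # nM^-1 s^-1, conversion [GEF] -> k_exch

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value < 0:
                raise ParameterError(f"rate constant {name} must be >= 0, got {value}")

    def with_gef(self, gef_nM: float) -> "RateConstants":
        """Return a copy with ``k_exch`` set from a GEF concentration."""
        if gef_nM < 0:
            raise ParameterError(f"GEF concentration must be >= 0, got {gef_nM}")
        return replace(self, k_exch=self.k_per_gef * gef_nM)

    def with_gap_preset(self, preset: Mapping[str, float]) -> "RateConstants":
        return replace(self, **dict(preset))


@dataclass(frozen=True)
class MutantSpec:
    """Multiplicative perturbation of the cycle, e.g. an oncogenic allele.

    Wild type is (1, 1, 1).  The default G12V encoding abolishes
    GAP-stimulated catalysis (the GAP still binds) and leaves intrinsic
    hydrolysis and effector interaction untouched.
    """

    gap_cat_factor: float = 1.0
    hyd_factor: float = 1.0
    effector_affinity_factor: float = 1.0

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value < 0:
                raise ParameterError(f"{name} must be >= 0, got {value}")


WILD_TYPE = MutantSpec(1.0, 1.0, 1.0)
G12V = MutantSpec(gap_cat_factor=0.0)


@dataclass(frozen=True)
class GIRouting:
    """Which hydrolysis channels feed the refractory GI state.

    GI is the post-hydrolysis state that cannot be re-activated by GEF
    until it relaxes to GD.  By default only GAP-catalysed hydrolysis
    produces GI: routing the slow intrinsic channels there as well makes
    even GAP-free networks overshoot strongly, which is not what GAP-free
    systems do; with GAP-only routing the model is monotone at zero GAP
    and transient at high GAP, as observed.
    """

    intrinsic: bool = False
    gap: bool = True
    effector: bool = False


@dataclass(frozen=True)
class Reaction:
    """Uni- or bimolecular mass-action reaction, optionally reversible.

    ``modifier`` (if set) multiplies the forward rate by a state-dependent
    factor; this is how non-mass-action rate laws (allosteric/recruitment
    GEF feedback) are expressed without changing the simulator.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k_fwd: float
    k_rev: float = 0.0
    role: str = ""
    modifier: Callable[[np.ndarray, Mapping[str, int]], float] | None = None

    def __post_init__(self) -> None:
        if len(self.reactants) > 2 or len(self.products) > 2:
            raise ParameterError("reactions are at most bimolecular on each side")
        if self.k_fwd < 0 or self.k_rev < 0:
            raise ParameterError(
                f"negative rate constant in reaction {self.reactants} -> {self.products}"
            )


def _gtpase_species(name: str) -> bool:
    return name in {"G", "GT", "GD", "GI"} or name.startswith("GT_")


@dataclass
class ReactionNetwork:
    """A species list plus mass-action reactions; the simulator's substrate."""

    species: list[str]
    reactions: list[Reaction]
    default_initial: dict[str, float] = field(default_factory=dict)
    effectors: list[str] = field(default_factory=list)
    kind: str = ""
    rates: RateConstants = field(default_factory=RateConstants)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ParameterError("duplicate species names")
        known = set(self.species)
        for r in self.reactions:
            missing = (set(r.reactants) | set(r.products)) - known
            if missing:
                raise ParameterError(f"reaction references unknown species {missing}")

    # -- composition -----------------------------------------------------
    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            species=list(self.species),
            reactions=list(self.reactions),
            default_initial=dict(self.default_initial),
            effectors=list(self.effectors),
            kind=self.kind,
            rates=self.rates,
        )

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def conserved_groups(self) -> dict[str, list[str]]:
        """Totals that mass-action stoichiometry keeps constant."""
        groups: dict[str, list[str]] = {
            "gtpase": [s for s in self.species if _gtpase_species(s)]
        }
        for eff in self.effectors:
            free = "EFF" if eff == "" else f"EFF_{eff}"
            bound = "GT_EFF" if eff == "" else f"GT_EFF_{eff}"
            groups[f"effector:{free}"] = [free, bound]
        if "GAP" in self.species:
            groups["gap"] = ["GAP", "GT_GAP"]
        if "GEF" in self.species:
            groups["gef"] = ["GEF", "GT_GEF"]
        return groups

    # -- compiled ODE ----------------------------------------------------
    def _compile(self):
        idx = self.index
        n = len(self.species)
        flux_reac: list[tuple[int, ...]] = []
        flux_k: list[float] = []
        flux_mod: list[Callable | None] = []
        stoich_cols: list[np.ndarray] = []
        for r in self.reactions:
            col = np.zeros(n)
            for s in r.reactants:
                col[idx[s]] -= 1
            for s in r.products:
                col[idx[s]] += 1
            flux_reac.append(tuple(idx[s] for s in r.reactants))
            flux_k.append(r.k_fwd)
            flux_mod.append(r.modifier)
            stoich_cols.append(col)
            if r.k_rev > 0:
                flux_reac.append(tuple(idx[s] for s in r.products))
                flux_k.append(r.k_rev)
                flux_mod.append(None)
                stoich_cols.append(-col)
        stoich = np.column_stack(stoich_cols) if stoich_cols else np.zeros((n, 0))
        ks = np.asarray(flux_k)
        has_mod = any(m is not None for m in flux_mod)

        def rates_of(x: np.ndarray) -> np.ndarray:
            v = ks.copy()
            for j, ri in enumerate(flux_reac):
                for i in ri:
                    v[j] *= x[i]
                m = flux_mod[j]
                if m is not None:
                    v[j] *= m(x, idx)
            return v

        def rhs(t: float, x: np.ndarray) -> np.ndarray:
            return stoich @ rates_of(x)

        jac = None
        if not has_mod:
            def jac(t: float, x: np.ndarray) -> np.ndarray:  # noqa: ARG001
                J = np.zeros((n, len(ks)))
                for j, ri in enumerate(flux_reac):
                    if len(ri) == 1:
                        J[ri[0], j] = ks[j]
                    elif len(ri) == 2:
                        a, b = ri
                        J[a, j] += ks[j] * x[b]
                        J[b, j] += ks[j] * x[a]
                return stoich @ J.T
        return rhs, jac


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------

def _core_reactions(k: RateConstants) -> list[Reaction]:
    return [
        Reaction(("G", "T"), ("GT",), k.k_nt_on, role="nt_on"),
        Reaction(("GD",), ("G", "D"), k.k_exch, role="exchange"),
        Reaction(("GT", "EFF"), ("GT_EFF",), k.k_eff_on, k.k_eff_off, role="eff_bind:"),
    ]


def build_two_state_model(
    k: RateConstants | None = None, gap_level: float = 0.0
) -> ReactionNetwork:
    """Two-state ON/OFF cycle without explicit GAP competition.

    GAP activity enters only as a dimensionless multiplier on the
    GT -> GD hydrolysis rate constant (1e-4 s^-1 at ``gap_level`` = 1).
    """
    if gap_level < 0:
        raise ParameterError(f"gap_level must be >= 0, got {gap_level}")
    if k is None:
        k = RateConstants(k_exch=TWO_STATE_EXCHANGE)
    rxns = _core_reactions(k) + [
        Reaction(("GT",), ("GD",), k.k_hyd * gap_level, role="hyd"),
        Reaction(("GT_EFF",), ("GD", "EFF"), k.k_hyd_eff, role="hyd_eff:"),
    ]
    return ReactionNetwork(
        species=["G", "GT", "GD", "T", "D", "EFF", "GT_EFF"],
        reactions=rxns,
        default_initial=dict(CANONICAL_INITIAL_STATE),
        effectors=[""],
        kind="two_state",
        rates=k,
    )


def _gap_reactions(k: RateConstants) -> list[Reaction]:
    return [
        Reaction(("GT", "GAP"), ("GT_GAP",), k.k_gap_on, k.k_gap_off, role="gap_bind"),
    ]


def build_competition_model(k: RateConstants | None = None) -> ReactionNetwork:
    """Two-state cycle with an explicit GAP species competing with effector."""
    if k is None:
        k = RateConstants()
    rxns = _core_reactions(k) + [
        Reaction(("GT",), ("GD",), k.k_hyd, role="hyd"),
        Reaction(("GT_EFF",), ("GD", "EFF"), k.k_hyd_eff, role="hyd_eff:"),
        *_gap_reactions(k),
        Reaction(("GT_GAP",), ("GD", "GAP"), k.k_gap_cat, role="gap_cat"),
    ]
    return ReactionNetwork(
        species=["G", "GT", "GD", "T", "D", "EFF", "GT_EFF", "GAP", "GT_GAP"],
        reactions=rxns,
        default_initial=dict(CANONICAL_INITIAL_STATE),
        effectors=[""],
        kind="competition",
        rates=k,
    )


def build_three_state_model(
    k: RateConstants | None = None, routing: GIRouting = GIRouting()
) -> ReactionNetwork:
    """Competition model with a GEF-refractory post-hydrolysis state GI.

    Hydrolysis products are routed to GI (per-channel flags) and GI relaxes
    to GD at ``k_gi_reset``; only GD is a substrate for exchange, so GI is
    refractory to GEF by construction.
    """
    if k is None:
        k = RateConstants()
    hyd_to = "GI" if routing.intrinsic else "GD"
    gap_to = "GI" if routing.gap else "GD"
    eff_to = "GI" if routing.effector else "GD"
    rxns = _core_reactions(k) + [
        Reaction(("GT",), (hyd_to,), k.k_hyd, role="hyd"),
        Reaction(("GT_EFF",), (eff_to, "EFF"), k.k_hyd_eff, role="hyd_eff:"),
        *_gap_reactions(k),
        Reaction(("GT_GAP",), (gap_to, "GAP"), k.k_gap_cat, role="gap_cat"),
        Reaction(("GI",), ("GD",), k.k_gi_reset, role="gi_reset"),
    ]
    return ReactionNetwork(
        species=["G", "GT", "GD", "GI", "T", "D", "EFF", "GT_EFF", "GAP", "GT_GAP"],
        reactions=rxns,
        default_initial=dict(CANONICAL_INITIAL_STATE),
        effectors=[""],
        kind="three_state",
        rates=k,
    )


def apply_mutant(net: ReactionNetwork, m: MutantSpec) -> ReactionNetwork:
    """Return a copy of ``net`` with mutant scaling factors applied.

    GAP-binding reactions are retained even at ``gap_cat_factor`` = 0: a
    GAP-insensitive allele still binds (and sequesters) GAP.
    """
    out = net.copy()
    new_rxns = []
    for r in out.reactions:
        if r.role == "gap_cat":
            r = replace(r, k_fwd=r.k_fwd * m.gap_cat_factor)
        elif r.role == "hyd" or r.role.startswith("hyd_eff:"):
            r = replace(r, k_fwd=r.k_fwd * m.hyd_factor)
        elif r.role.startswith("eff_bind:"):
            r = replace(r, k_rev=r.k_rev * m.effector_affinity_factor)
        new_rxns.append(r)
    out.reactions = new_rxns
    return out


def add_effector(
    net: ReactionNetwork,
    name: str,
    conc: float,
    k_on: float,
    k_off: float,
    k_hyd_eff: float | None = None,
) -> ReactionNetwork:
    """Add a second (third, ...) effector competing for the same GT pool."""
    if name in net.effectors:
        raise ParameterError(f"duplicate effector name {name!r}")
    if conc < 0 or k_on < 0 or k_off < 0:
        raise ParameterError("effector parameters must be >= 0")
    if k_hyd_eff is None:
        k_hyd_eff = net.rates.k_hyd_eff
    free, bound = f"EFF_{name}", f"GT_EFF_{name}"
    # route hydrolysis from the new bound state the same way the base
    # model routes its effector channel
    eff_to = "GD"
    for r in net.reactions:
        if r.role.startswith("hyd_eff:"):
            eff_to = r.products[0]
            break
    out = net.copy()
    out.species = out.species + [free, bound]
    out.reactions = out.reactions + [
        Reaction(("GT", free), (bound,), k_on, k_off, role=f"eff_bind:{name}"),
        Reaction((bound,), (eff_to, free), k_hyd_eff, role=f"hyd_eff:{name}"),
    ]
    out.effectors = out.effectors + [name]
    out.default_initial[free] = conc
    return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Trajectories on the sample grid plus named observables."""

    times: np.ndarray
    species_names: list[str]
    concentrations: np.ndarray  # (n_species, n_times), nM
    observables: dict[str, np.ndarray]

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[self.species_names.index(name)]

    def bound_effector(self, name: str = "") -> np.ndarray:
        key = "bound_effector" if name == "" else f"bound_effector_{name}"
        return self.observables[key]

    def to_frame(self, tidy: bool = True) -> pd.DataFrame:
        """Tidy (time_s, species, conc_nM) or wide (one column per species)."""
        if tidy:
            n_t = len(self.times)
            return pd.DataFrame(
                {
                    "time_s": np.repeat(self.times, len(self.species_names)),
                    "species": np.tile(self.species_names, n_t),
                    "conc_nM": self.concentrations.T.ravel(),
                }
            )
        df = pd.DataFrame(self.concentrations.T, columns=self.species_names)
        df.insert(0, "time_s", self.times)
        for k, v in self.observables.items():
            df[k] = v
        return df


@dataclass
class SteadyStateResult:
    state: dict[str, float]
    converged: bool
    t_final: float

    def __getitem__(self, name: str) -> float:
        return self.state[name]


def _initial_vector(net: ReactionNetwork, ic: Mapping[str, float]) -> np.ndarray:
    unknown = set(ic) - set(net.species)
    if unknown:
        raise ParameterError(f"initial state references unknown species {unknown}")
    x0 = np.zeros(len(net.species))
    for s, c in ic.items():
        if c < 0:
            raise ParameterError(f"negative initial concentration for {s}")
        x0[net.index[s]] = c
    return x0


def _observables(net: ReactionNetwork, y: np.ndarray) -> dict[str, np.ndarray]:
    idx = net.index
    obs: dict[str, np.ndarray] = {}
    total = np.zeros(y.shape[1])
    for eff in net.effectors:
        bound = "GT_EFF" if eff == "" else f"GT_EFF_{eff}"
        key = "bound_effector" if eff == "" else f"bound_effector_{eff}"
        obs[key] = y[idx[bound]]
        total = total + y[idx[bound]]
    obs.setdefault("bound_effector", total)
    obs["bound_effector_total"] = total
    gt_tot = np.zeros(y.shape[1])
    for s in net.species:
        if s == "GT" or s.startswith("GT_"):
            gt_tot = gt_tot + y[idx[s]]
    obs["gt_total"] = gt_tot
    return obs


def _check_invariants(net: ReactionNetwork, x0: np.ndarray, y: np.ndarray) -> None:
    if y.min() < -NEGATIVE_TOL:
        raise SimulationError(
            f"negative concentration {y.min():.3e} nM beyond tolerance {NEGATIVE_TOL}"
        )
    idx = net.index
    for gname, members in net.conserved_groups().items():
        rows = [idx[s] for s in members]
        tot0 = float(sum(x0[r] for r in rows))
        tot = y[rows].sum(axis=0)
        scale = max(abs(tot0), ATOL)
        err = np.abs(tot - tot0).max() / scale
        if err > CONSERVATION_RTOL:
            raise SimulationError(
                f"conserved total {gname!r} drifts by relative {err:.2e}"
            )


def simulate(
    net: ReactionNetwork,
    ic: Mapping[str, float] | None = None,
    t_end: float = 42000.0,
    sample_dt: float = 900.0,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "LSODA",
    check: bool = True,
) -> SimulationResult:
    """Integrate the mass-action ODE system on a regular sample grid.

    Defaults mirror the study conditions: 42000 s (~700 min) horizon
    sampled every 900 s (the 15-min imaging interval).
    """
    if ic is None:
        ic = net.default_initial
    x0 = _initial_vector(net, ic)
    t_eval = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    t_eval = t_eval[t_eval <= t_end]
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)
    rhs, jac = net._compile()
    sol = solve_ivp(
        rhs, (0.0, t_end), x0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol, jac=jac,
    )
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message} (rtol={rtol}, atol={atol})")
    y = np.clip(sol.y, 0.0, None) if sol.y.min() > -NEGATIVE_TOL else sol.y
    if check:
        _check_invariants(net, x0, sol.y)
    return SimulationResult(
        times=sol.t,
        species_names=list(net.species),
        concentrations=y,
        observables=_observables(net, y),
    )


def steady_state(
    net: ReactionNetwork,
    ic: Mapping[str, float] | None = None,
    deriv_tol: float = 1e-9,
    t_cap: float = 10 * 42000.0,
) -> SteadyStateResult:
    """Integrate until max |dx/dt| < ``deriv_tol`` nM/s (or the time cap).

    The free-nucleotide pools T and D are excluded from the convergence
    criterion: with an effectively infinite nucleotide supply the cycle
    consumes GTP (and accumulates GDP) at the steady cycle flux forever,
    while every GTPase/effector/GAP species settles.
    """
    if ic is None:
        ic = net.default_initial
    x0 = _initial_vector(net, ic)
    rhs, jac = net._compile()
    watched = np.array([s not in {"T", "D"} for s in net.species])
    t, x = 0.0, x0
    converged = False
    chunk = 42000.0
    while t < t_cap:
        sol = solve_ivp(
            rhs, (t, t + chunk), x, method="LSODA", rtol=RTOL, atol=ATOL, jac=jac
        )
        if not sol.success:
            # near equilibrium LSODA can stall against the absolute
            # tolerance; retry the chunk with BDF, then relaxed atol
            sol = solve_ivp(
                rhs, (t, t + chunk), x, method="BDF", rtol=RTOL, atol=ATOL, jac=jac
            )
        if not sol.success:
            sol = solve_ivp(
                rhs, (t, t + chunk), x, method="BDF", rtol=RTOL, atol=1e-10, jac=jac
            )
        if not sol.success:
            raise SimulationError(f"integrator failed: {sol.message}")
        x = sol.y[:, -1]
        t = sol.t[-1]
        if np.abs(rhs(t, x)[watched]).max() < deriv_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"steady_state did not reach |dx/dt| < {deriv_tol} nM/s by t = {t:.0f} s",
            RuntimeWarning,
            stacklevel=2,
        )
    state = {s: max(float(v), 0.0) for s, v in zip(net.species, x)}
    return SteadyStateResult(state=state, converged=converged, t_final=t)
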