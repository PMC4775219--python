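"""Flat YAML model/scan configuration files.

A model config names the builder, rate overrides, initial state, optional
mutant and feedback blocks, and the simulation horizon, e.g.::

    model: three_state
    gef_nM: 1000
    gap_preset: nf1          # nf1 | p120 | nonphysiologic
    rates: {k_eff_off: 1.0e-3}
    initial: {GD: 10, EFF: 50, T: 100000, GAP: 1000}
    mutant: {gap_cat_factor: 0}
    effectors:
      - {name: braf, conc: 50, k_on: 1.0e-4, k_off: 2.5e-4}
    feedback: {type: recruitment, gef_conc: 20, alpha: 1.0e6}
    t_end: 42000
    sample_dt: 900
    seed: 0
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import yaml

from . import feedback as fb
from .kinetics import (
    CANONICAL_INITIAL_STATE,
    MutantSpec,
    RateConstants,
    ReactionNetwork,
    NF1_LIKE_GAP,
    NONPHYSIOLOGIC_GAP,
    P120_LIKE_GAP,
    build_competition_model,
    build_three_state_model,
    build_two_state_model,
)

__all__ = ["ModelConfig", "load_model_config", "build_model"]

_GAP_PRESETS = {
    "nf1": NF1_LIKE_GAP,
    "p120": P120_LIKE_GAP,
    "nonphysiologic": NONPHYSIOLOGIC_GAP,
}

_BUILDERS = {
    "two_state": build_two_state_model,
    "competition": build_competition_model,
    "three_state": build_three_state_model,
}


@dataclass(frozen=True)
class ModelConfig:
    model: str = "three_state"
    rates: dict[str, float] = field(default_factory=dict)
    gef_nM: float | None = None
    gap_preset: str | None = None
    gap_level: float = 0.0                 # two-state model only
    initial: dict[str, float] = field(default_factory=lambda: dict(CANONICAL_INITIAL_STATE))
    mutant: dict[str, float] | None = None
    effectors: tuple[dict, ...] = ()
    feedback: dict[str, Any] | None = None
    t_end: float = 42000.0
    sample_dt: float = 900.0
    seed: int = 0

    def with_ras_nM(self, ras_nM: float) -> "ModelConfig":
        """Copy with the total (GDP-loaded) Ras pool replaced."""
        ic = dict(self.initial)
        ic["GD"] = ras_nM
        return replace(self, initial=ic)


def load_model_config(path) -> ModelConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: expected a mapping at top level")
    known = set(ModelConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "effectors" in raw:
        raw = dict(raw)
        raw["effectors"] = tuple(raw["effectors"])
    return ModelConfig(**raw)


def build_model(cfg: ModelConfig) -> tuple[ReactionNetwork, dict[str, float]]:
    """Instantiate (network, initial state) from a config."""
    from .kinetics import add_effector, apply_mutant

    if cfg.model not in _BUILDERS:
        raise ValueError(f"unknown model {cfg.model!r}; one of {sorted(_BUILDERS)}")
    rates = RateConstants()
    if cfg.gap_preset is not None:
        rates = rates.with_gap_preset(_GAP_PRESETS[cfg.gap_preset])
    if cfg.rates:
        rates = replace(rates, **cfg.rates)
    if cfg.gef_nM is not None:
        rates = rates.with_gef(cfg.gef_nM)
    if cfg.model == "two_state":
        net = build_two_state_model(rates, gap_level=cfg.gap_level)
    else:
        net = _BUILDERS[cfg.model](rates)
    for eff in cfg.effectors:
        net = add_effector(
            net, eff["name"], eff["conc"], eff["k_on"], eff["k_off"],
            k_hyd_eff=eff.get("k_hyd_eff"),
        )
    if cfg.mutant is not None:
        net = apply_mutant(net, MutantSpec(**cfg.mutant))
    if cfg.feedback is not None:
        spec = dict(cfg.feedback)
        kind = spec.pop("type")
        if kind == "recruitment":
            net = fb.build_recruitment_feedback_model(
                net, fb.RecruitmentFeedbackParams(**spec)
            )
        elif kind == "allosteric":
            net = fb.build_allosteric_feedback_model(
                net, fb.AllostericFeedbackParams(**spec)
            )
        else:
            raise ValueError(f"unknown feedback type {kind!r}")
    ic = {s: c for s, c in cfg.initial.items() if s in net.species}
    for eff in cfg.effectors:
        ic[f"EFF_{eff['name']}"] = eff["conc"]
    return net, ic
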