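"""GTPase -> GEF positive-feedback architectures.

Two feedback designs close the loop from active GTPase back onto exchange
activity:

* **Recruitment feedback** (a GEF fused to a Ras-binding domain): active
  Ras-GTP captures the GEF fusion on the bead surface, where its effective
  exchange activity on neighbouring Ras is enhanced by a surface factor
  ``alpha``.  The GEF is an explicit species competing with effectors and
  GAP for the GT pool; the nucleotide-release flux on GD becomes
  ``k_per_gef * ([GEF_free] + alpha * [GT_GEF]) * [GD]``.

* **Allosteric feedback** (a SOS-like GEF with a distal Ras-GTP site):
  exchange activity itself is state-dependent,
  ``k_exch = k_basal + (k_max - k_basal) * GT_tot / (K_A + GT_tot)``,
  so a step input of GEF protein behaves as a ramp input of GEF activity.

Neither rate law is taken from a measurement; both are this package's
minimal mechanistic encodings of the designs, with every constant exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kinetics import ParameterError, Reaction, ReactionNetwork

__all__ = [
    "RecruitmentFeedbackParams",
    "AllostericFeedbackParams",
    "build_recruitment_feedback_model",
    "build_allosteric_feedback_model",
]


@dataclass(frozen=True)
class RecruitmentFeedbackParams:
    """Parameters of the RBD-fused GEF.

    The RBD arm is deliberately weak and fast-exchanging (Kd ~ 3.3 uM) so
    the fusion samples the Ras-GTP pool without sequestering it from the
    effector; the surface-enhancement factor ``alpha`` carries the strength
    of the feedback (a single bead-bound GEF sees its 2-D-confined
    substrate at an enormously increased effective concentration).
    """

    gef_conc: float               # nM
    k_gef_on: float = 1e-4        # nM^-1 s^-1, RBD arm binding GT
    k_gef_off: float = 0.33       # s^-1
    alpha: float = 1e6            # dimensionless surface enhancement

    def __post_init__(self) -> None:
        if min(self.gef_conc, self.k_gef_on, self.k_gef_off) < 0:
            raise ParameterError("recruitment feedback parameters must be >= 0")
        if self.alpha < 1:
            raise ParameterError(f"alpha must be >= 1, got {self.alpha}")


@dataclass(frozen=True)
class AllostericFeedbackParams:
    """Parameters of the SOS-like allosterically activated GEF."""

    k_exch_max: float             # s^-1, fully activated exchange rate
    k_exch_basal: float | None = None   # s^-1; default 0.1 * k_exch_max
    K_A: float = 5.0              # nM Ras-GTP at half-activation

    def __post_init__(self) -> None:
        if self.k_exch_basal is None:
            object.__setattr__(self, "k_exch_basal", 0.1 * self.k_exch_max)
        if not (self.k_exch_max >= self.k_exch_basal >= 0):
            raise ParameterError("need k_exch_max >= k_exch_basal >= 0")
        if self.K_A <= 0:
            raise ParameterError(f"K_A must be > 0, got {self.K_A}")


def _require_three_state(base: ReactionNetwork, what: str) -> None:
    if base.kind != "three_state":
        raise ParameterError(f"{what} expects a three-state base network")


def build_recruitment_feedback_model(
    base: ReactionNetwork, p: RecruitmentFeedbackParams
) -> ReactionNetwork:
    """Attach a recruitment-feedback GEF species to a three-state network."""
    _require_three_state(base, "build_recruitment_feedback_model")
    out = base.copy()
    out.kind = "three_state+recruitment_feedback"
    out.species = out.species + ["GEF", "GT_GEF"]
    out.default_initial["GEF"] = p.gef_conc
    k_per_gef = out.rates.k_per_gef
    alpha = p.alpha

    def gef_activity(x: np.ndarray, idx) -> float:
        return x[idx["GEF"]] + alpha * x[idx["GT_GEF"]]

    new_rxns = []
    for r in out.reactions:
        if r.role == "exchange":
            # flux = k_per_gef * (GEF_free + alpha * GT_GEF) * [GD]
            r = replace(r, k_fwd=k_per_gef, modifier=gef_activity)
        new_rxns.append(r)
    new_rxns.append(
        Reaction(("GT", "GEF"), ("GT_GEF",), p.k_gef_on, p.k_gef_off, role="gef_bind")
    )
    out.reactions = new_rxns
    return out


def build_allosteric_feedback_model(
    base: ReactionNetwork, p: AllostericFeedbackParams
) -> ReactionNetwork:
    """Make the exchange rate a saturating function of total Ras-GTP."""
    _require_three_state(base, "build_allosteric_feedback_model")
    out = base.copy()
    out.kind = "three_state+allosteric_feedback"
    gt_species = [s for s in out.species if s == "GT" or s.startswith("GT_")]
    k_basal, k_max, K_A = p.k_exch_basal, p.k_exch_max, p.K_A

    def activation(x: np.ndarray, idx) -> float:
        gt_tot = sum(x[idx[s]] for s in gt_species)
        return k_basal + (k_max - k_basal) * gt_tot / (K_A + gt_tot)

    new_rxns = []
    for r in out.reactions:
        if r.role == "exchange":
            # flux = k_exch(GT_tot) * [GD]; unit base constant, modifier
            # carries the whole state-dependent rate
            r = replace(r, k_fwd=1.0, modifier=activation)
        new_rxns.append(r)
    out.reactions = new_rxns
    return out
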