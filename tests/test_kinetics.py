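"""Unit and property tests for the GTPase-cycle models and integrator."""

import numpy as np
import pytest

from rascycle.features import Timecourse, transient_score
from rascycle.kinetics import (
    CANONICAL_INITIAL_STATE,
    G12V,
    GIRouting,
    MutantSpec,
    NONPHYSIOLOGIC_GAP,
    ParameterError,
    RateConstants,
    WILD_TYPE,
    add_effector,
    apply_mutant,
    build_competition_model,
    build_three_state_model,
    build_two_state_model,
    simulate,
    steady_state,
)
from conftest import euler_simulate


def _bound(res):
    return res.observables["bound_effector_total"]


class TestBuilders:
    def test_two_state_zero_gap_has_no_direct_gt_sink(self):
        net = build_two_state_model(gap_level=0.0)
        hyd = [r for r in net.reactions if r.role == "hyd"]
        assert hyd[0].k_fwd == 0.0
        hyd_eff = [r for r in net.reactions if r.role.startswith("hyd_eff")]
        assert hyd_eff[0].k_fwd == pytest.approx(1e-4)
        assert "GAP" not in net.species

    def test_negative_parameters_rejected(self):
        with pytest.raises(ParameterError):
            build_two_state_model(gap_level=-1.0)
        with pytest.raises(ParameterError):
            RateConstants(k_exch=-0.1)
        with pytest.raises(ParameterError):
            MutantSpec(gap_cat_factor=-1.0)

    def test_competition_includes_gap_cycle(self):
        net = build_competition_model()
        roles = {r.role for r in net.reactions}
        assert {"gap_bind", "gap_cat"} <= roles
        assert {"GAP", "GT_GAP"} <= set(net.species)

    def test_three_state_gi_is_gef_refractory(self):
        """Exchange acts on GD only; GI drains to GD at k_gi_reset."""
        net = build_three_state_model()
        exch = [r for r in net.reactions if r.role == "exchange"][0]
        assert exch.reactants == ("GD",)
        reset = [r for r in net.reactions if r.role == "gi_reset"][0]
        assert reset.reactants == ("GI",) and reset.products == ("GD",)

    def test_gi_routing_flags(self):
        net = build_three_state_model(routing=GIRouting(True, True, True))
        for role in ["hyd", "gap_cat"]:
            rxn = [r for r in net.reactions if r.role == role][0]
            assert "GI" in rxn.products
        rxn = [r for r in net.reactions if r.role.startswith("hyd_eff")][0]
        assert "GI" in rxn.products


class TestSimulate:
    def test_all_zero_rates_keeps_initial_state(self, canonical_ic):
        k = RateConstants(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
        net = build_two_state_model(k, gap_level=0.0)
        res = simulate(net, canonical_ic, t_end=9000)
        for s, c in canonical_ic.items():
            assert res.species(s) == pytest.approx([c] * len(res.times))

    def test_frozen_gd_state_without_exchange(self):
        net = build_two_state_model(RateConstants(k_exch=0.0), gap_level=0.0)
        res = simulate(net, {"GD": 10.0, "EFF": 50.0, "T": 1e5})
        assert res.species("GD") == pytest.approx([10.0] * len(res.times))
        assert np.all(_bound(res) == 0)

    def test_mass_conservation_across_models(self, canonical_ic):
        rng = np.random.default_rng(7)
        for _ in range(5):
            f = lambda: 10 ** rng.uniform(-1, 1)
            k = RateConstants(
                k_exch=0.005 * f(), k_hyd=1e-4 * f(), k_eff_on=1e-4 * f(),
                k_eff_off=1e-3 * f(), k_gap_cat=f(),
            )
            net = build_three_state_model(k)
            ic = dict(canonical_ic)
            ic["GAP"] = float(rng.uniform(0, 2000))
            res = simulate(net, ic)  # raises if totals drift > 1e-6 relative
            gt_rows = [s for s in net.species if s in {"G", "GT", "GD", "GI"} or s.startswith("GT_")]
            total = sum(res.species(s) for s in gt_rows)
            assert total == pytest.approx(ic["GD"], rel=1e-6)

    def test_trajectories_nonnegative(self, canonical_ic):
        ic = dict(canonical_ic)
        ic["GAP"] = 1000.0
        res = simulate(build_three_state_model(), ic)
        assert res.concentrations.min() >= -1e-9

    def test_sample_grid(self, canonical_ic):
        res = simulate(build_three_state_model(), canonical_ic, t_end=42000, sample_dt=900)
        assert res.times[0] == 0.0
        assert res.times[-1] == 42000.0  # horizon kept even though 42000 % 900 != 0
        assert np.all(np.diff(res.times[:-1]) == 900.0)
        assert np.all(np.diff(res.times) > 0)

    def test_export_frames(self, canonical_ic):
        res = simulate(build_three_state_model(), canonical_ic, t_end=1800)
        tidy = res.to_frame(tidy=True)
        assert set(tidy.columns) == {"time_s", "species", "conc_nM"}
        wide = res.to_frame(tidy=False)
        assert "bound_effector" in wide.columns
        assert len(wide) == len(res.times)


class TestOracle:
    """Adaptive integration vs an independent fixed-step explicit Euler.

    Scenarios use a 200 nM nucleotide pool so the fast bimolecular binding
    mode stays inside Euler's stability region at dt = 2e-4 s.
    """

    @pytest.mark.parametrize(
        "builder_kw, gap",
        [
            ({"gap_level": 10.0}, None),          # two-state
            ({}, 100.0),                          # competition
            ({}, 1000.0),                         # three-state
        ],
        ids=["two_state", "competition", "three_state"],
    )
    def test_matches_euler(self, builder_kw, gap):
        if gap is None:
            net = build_two_state_model(**builder_kw)
            ic = {"GD": 10.0, "EFF": 50.0, "T": 200.0}
        elif gap == 100.0:
            net = build_competition_model()
            ic = {"GD": 10.0, "EFF": 50.0, "T": 200.0, "GAP": gap}
        else:
            net = build_three_state_model()
            ic = {"GD": 10.0, "EFF": 50.0, "T": 200.0, "GAP": gap}
        t_end, dt, sample_dt = 3600.0, 2e-4, 900.0
        _, oracle = euler_simulate(net, ic, t_end, dt, sample_dt)
        res = simulate(net, ic, t_end=t_end, sample_dt=sample_dt)
        for s in net.species:
            ref = oracle[s]
            scale = np.maximum(np.abs(ref), 1e-6 * max(ref.max(), 1.0))
            assert np.max(np.abs(res.species(s) - ref) / scale) < 1e-3


class TestOvershoot:
    def test_two_state_cannot_overshoot(self, canonical_ic):
        """100 random draws (+-2 decades) all rise monotonically."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            f = lambda: 10 ** rng.uniform(-2, 2)
            k = RateConstants(
                k_exch=0.05 * f(), k_hyd=1e-4 * f(), k_hyd_eff=1e-4 * f(),
                k_eff_on=1e-4 * f(), k_eff_off=1e-3 * f(),
            )
            net = build_two_state_model(k, gap_level=10 ** rng.uniform(-1, 3))
            res = simulate(net, canonical_ic)
            be = _bound(res)
            if be.max() > 0:
                assert transient_score(Timecourse(res.times, be)) < 0.01

    def test_competition_overshoot_needs_nonphysiologic_gap(self, canonical_ic):
        phys = build_competition_model()
        nonphys = build_competition_model(
            RateConstants().with_gap_preset(NONPHYSIOLOGIC_GAP)
        )
        for gap in [0.0, 10.0, 100.0, 1000.0, 10000.0, 100000.0]:
            ic = dict(canonical_ic)
            ic["GAP"] = gap
            res = simulate(phys, ic)
            assert transient_score(Timecourse(res.times, _bound(res))) < 0.01
        ic = dict(canonical_ic)
        ic["GAP"] = 1000.0
        res = simulate(nonphys, ic)
        assert transient_score(Timecourse(res.times, _bound(res))) > 0.1

    def test_three_state_overshoot_tracks_gap(self, canonical_ic):
        net = build_three_state_model()
        ic_hi = dict(canonical_ic)
        ic_hi["GAP"] = 1000.0
        hi = simulate(net, ic_hi)
        ic_lo = dict(canonical_ic)
        ic_lo["GAP"] = 0.0
        lo = simulate(net, ic_lo)
        assert transient_score(Timecourse(hi.times, _bound(hi))) > 0.1
        assert transient_score(Timecourse(lo.times, _bound(lo))) < 0.02


class TestLimits:
    def test_competition_reduces_to_two_state_without_gap(self, canonical_ic):
        """With k_hyd matched and [GAP] = 0 the GAP cycle carries no flux."""
        k = RateConstants()
        comp = build_competition_model(k)
        # two-state folds intrinsic hydrolysis into the gap_level term
        two = build_two_state_model(k, gap_level=1.0)
        rc_ = simulate(comp, canonical_ic)
        rt = simulate(two, canonical_ic)
        assert _bound(rc_) == pytest.approx(_bound(rt), rel=1e-6, abs=1e-9)

    def test_three_state_limits_to_competition_at_fast_reset(self, canonical_ic):
        """k_gi_reset -> inf makes GI a fleeting intermediate."""
        ic = dict(canonical_ic)
        ic["GAP"] = 1000.0
        fast = build_three_state_model(
            RateConstants(k_gi_reset=1e4), routing=GIRouting(True, True, True)
        )
        comp = build_competition_model()
        rf = simulate(fast, ic)
        rc_ = simulate(comp, ic)
        assert _bound(rf) == pytest.approx(_bound(rc_), rel=1e-3, abs=1e-6)


class TestMutants:
    def test_wild_type_is_identity(self):
        net = build_three_state_model()
        same = apply_mutant(net, WILD_TYPE)
        for a, b in zip(net.reactions, same.reactions):
            assert a == b

    def test_g12v_keeps_gap_binding(self):
        net = apply_mutant(build_three_state_model(), G12V)
        gap_bind = [r for r in net.reactions if r.role == "gap_bind"][0]
        assert gap_bind.k_fwd > 0
        gap_cat = [r for r in net.reactions if r.role == "gap_cat"][0]
        assert gap_cat.k_fwd == 0.0

    def test_g12v_sustained_in_high_gap_context(self, canonical_ic):
        k = RateConstants().with_gef(2000)
        wt = build_three_state_model(k)
        mu = apply_mutant(wt, G12V)
        ic = dict(canonical_ic)
        ic["GAP"] = 1000.0
        ss_wt = steady_state(wt, ic)
        ss_mu = steady_state(mu, ic)
        assert ss_mu["GT_EFF"] > ss_wt["GT_EFF"]

    def test_g12v_inert_without_gap(self, canonical_ic):
        k = RateConstants().with_gef(2000)
        wt = build_three_state_model(k)
        mu = apply_mutant(wt, G12V)
        r_wt = simulate(wt, canonical_ic)
        r_mu = simulate(mu, canonical_ic)
        assert _bound(r_mu) == pytest.approx(_bound(r_wt), rel=0.10, abs=1e-6)


class TestEffectors:
    def test_duplicate_name_rejected(self):
        net = build_three_state_model()
        net = add_effector(net, "braf", 50.0, 1e-4, 2.5e-4)
        with pytest.raises(ParameterError):
            add_effector(net, "braf", 50.0, 1e-4, 2.5e-4)

    def test_zero_concentration_effector_is_inert(self, canonical_ic):
        base = build_three_state_model()
        plus = add_effector(base, "ghost", 0.0, 1e-4, 2.5e-4)
        ic = dict(canonical_ic)
        ic["GAP"] = 1000.0
        rb = simulate(base, ic)
        ic2 = dict(ic)
        ic2["EFF_ghost"] = 0.0
        rp = simulate(plus, ic2)
        for s in base.species:
            assert rp.species(s) == pytest.approx(rb.species(s), rel=1e-6, abs=1e-9)

    def test_craf_transient_braf_sustained(self, canonical_ic):
        """With both at 50 nM in a 1 uM GAP network, the slow-off B-Raf-like
        effector retains a much larger fraction of its peak output."""
        net = build_three_state_model(RateConstants().with_gef(1000))
        net = add_effector(net, "braf", 50.0, 1e-4, 2.5e-4)
        ic = dict(canonical_ic)
        ic["GAP"] = 1000.0
        ic["EFF_braf"] = 50.0
        res = simulate(net, ic)
        ts_craf = transient_score(Timecourse(res.times, res.bound_effector("")))
        ts_braf = transient_score(Timecourse(res.times, res.bound_effector("braf")))
        # transient c-Raf output, clearly more sustained B-Raf output
        assert ts_craf > 0.5
        assert ts_braf < ts_craf - 0.15
        assert (1.0 - ts_braf) > 0.25  # B-Raf keeps >25% of its peak

    def test_staggered_effectors_peak_in_sequence(self, canonical_ic):
        """Fast-off effectors track the early GTPase pulse, slow-off ones
        lag: 3 THEN 2 THEN 1."""
        net = build_three_state_model(RateConstants().with_gef(1000))
        net = add_effector(net, "e2", 150.0, 1e-4, 3e-3)
        net = add_effector(net, "e3", 500.0, 1e-4, 1e-2)
        ic = dict(canonical_ic)
        ic.update(GAP=1000.0, EFF_e2=150.0, EFF_e3=500.0)
        res = simulate(net, ic, sample_dt=120.0)
        peak = {
            n: res.times[np.argmax(res.bound_effector(n))] for n in ["e3", "e2", ""]
        }
        assert peak["e3"] < peak["e2"] < peak[""]


class TestSteadyState:
    def test_no_source_means_initial_state(self):
        net = build_two_state_model(RateConstants(k_exch=0.0), gap_level=0.0)
        ss = steady_state(net, {"GD": 10.0, "EFF": 50.0, "T": 1e5})
        assert ss.converged
        assert ss["GD"] == pytest.approx(10.0)

    def test_two_state_linear_cycle_closed_form(self):
        """Effector decoupled: GT fraction = k_exch / (k_exch + k_hyd_app)."""
        k = RateConstants(k_exch=0.05, k_eff_on=0.0)
        gap_level = 10.0
        net = build_two_state_model(k, gap_level=gap_level)
        ss = steady_state(net, {"GD": 10.0, "T": 1e5})
        k_hyd_app = 1e-4 * gap_level
        expect = 0.05 / (0.05 + k_hyd_app)
        frac = ss["GT"] / (ss["GT"] + ss["GD"] + ss["G"])
        assert frac == pytest.approx(expect, rel=1e-4)

    def test_start_state_independence(self, canonical_ic):
        net = build_three_state_model()
        ic_gd = dict(canonical_ic)
        ic_gd["GAP"] = 1000.0
        ic_gt = dict(ic_gd)
        ic_gt["GT"] = ic_gt.pop("GD")
        a = steady_state(net, ic_gd)
        b = steady_state(net, ic_gt)
        for s in net.species:
            if s in {"T", "D"}:
                continue  # nucleotide consumed/produced is path-dependent
            ref = max(abs(a[s]), 1e-6)
            assert abs(a[s] - b[s]) / ref < 1e-4

    def test_high_gap_steady_below_peak(self, canonical_ic):
        net = build_three_state_model()
        ic = dict(canonical_ic)
        ic["GAP"] = 1000.0
        res = simulate(net, ic)
        ss = steady_state(net, ic)
        assert ss["GT_EFF"] < _bound(res).max()


class TestParameterRecovery:
    def test_hydrolysis_rate_from_turn_off_fit(self):
        """GAP-free turn-off decays single-exponentially at k_hyd."""
        k_hyd = 2.5e-4
        k = RateConstants(k_exch=0.0, k_hyd=k_hyd, k_hyd_eff=k_hyd)
        net = build_three_state_model(k)
        res = simulate(net, {"GT": 10.0, "EFF": 2500.0}, t_end=18000)
        be = _bound(res)
        m = be > 0  # t=0 precedes effector binding
        slope = np.polyfit(res.times[m], np.log(be[m]), 1)[0]
        assert -slope == pytest.approx(k_hyd, rel=0.10)
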