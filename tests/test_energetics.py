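"""Reaction thermodynamics, activity model and down-core energy profiles."""

import numpy as np
import pandas as pd
import pytest

import methanesource as ms
from methanesource.energetics import (
    R_KJ,
    T0_K,
    SPECIES_FORMULA,
    below_detection_policy,
    co2_fraction,
    load_species_thermo,
    load_substrate_ranges,
)


@pytest.fixture(scope="module")
def thermo():
    return load_species_thermo()


@pytest.fixture(scope="module")
def reactions():
    return {r.id: r for r in ms.reaction_library()}


class TestReactionLibrary:
    def test_all_nine_balanced(self, reactions):
        """Automated element/charge balance audit of every reaction."""
        assert len(reactions) == 9
        for r in reactions.values():
            assert r.is_balanced(), f"reaction {r.id} unbalanced: {r.balance()}"

    def test_carbon_transferred(self, reactions):
        expected = {1: 1, 2: 2, 3: 4, 4: 1, 5: 4, 6: 4, 7: 4, 8: 12, 9: 4}
        assert {i: r.carbon_transferred for i, r in reactions.items()} == expected

    def test_trimethylamine_stoichiometry(self, reactions):
        """4 TMA give 9 CH4 + 3 CO2: 12 carbons moved per formula unit."""
        r8 = reactions[8]
        assert r8.stoichiometry["CH4"] == 9
        assert r8.stoichiometry["CO2"] == 3
        assert r8.stoichiometry["trimethylamine"] == -4
        assert r8.carbon_transferred == 12

    def test_methanol_disproportionation(self, reactions):
        r5 = reactions[5]
        assert r5.stoichiometry == {
            "methanol": -4, "CH4": 3, "CO2": 1, "H2O": 2
        }

    def test_carbon_count_matches_stoichiometry(self, reactions):
        """carbon_transferred equals the carbon actually moved."""
        for r in reactions.values():
            moved = sum(
                c * SPECIES_FORMULA[sp].get("C", 0)
                for sp, c in r.stoichiometry.items()
                if c > 0
            )
            assert moved == r.carbon_transferred


class TestStandardGibbs:
    def test_null_reaction_is_zero(self, thermo):
        null = ms.ReactionSpec(99, "null", {}, 1)
        for T in (273.15, 298.15, 373.15):
            assert ms.standard_gibbs(null, T, thermo) == 0.0

    def test_hess_law_oracle_R1(self, reactions, thermo):
        """ΔG°(25 °C) of CO₂ reduction by independent hand summation."""
        hand = (
            thermo["CH4"].dG_f + 2 * thermo["H2O"].dG_f
            - 4 * thermo["H2"].dG_f - thermo["CO2"].dG_f
        )
        assert ms.standard_gibbs(reactions[1], T0_K, thermo) == pytest.approx(
            hand, abs=1e-9
        )
        assert hand == pytest.approx(-193.72, abs=0.01)

    def test_vant_hoff_correction_analytic(self, reactions, thermo):
        """ΔG°(T) − ΔG°(T0) = −ΔS°·(T−T0) under constant ΔH°."""
        r1 = reactions[1]
        dG0 = ms.standard_gibbs(r1, T0_K, thermo)
        dH0 = sum(c * thermo[sp].dH_f for sp, c in r1.stoichiometry.items())
        dS0 = (dH0 - dG0) / T0_K
        T = 323.15
        assert ms.standard_gibbs(r1, T, thermo) == pytest.approx(
            dG0 - dS0 * (T - T0_K), abs=1e-9
        )

    def test_missing_species_reported(self, thermo):
        rxn = ms.ReactionSpec(98, "exotic", {"unobtainium": -1, "CH4": 1}, 1)
        with pytest.raises(KeyError, match="unobtainium"):
            ms.standard_gibbs(rxn, 298.15, thermo)


class TestActivityCoefficient:
    def test_infinite_dilution(self):
        assert ms.activity_coefficient(-2, 0.0) == 1.0

    def test_neutral_species_unity(self):
        assert ms.activity_coefficient(0, 0.7) == 1.0

    def test_davies_value_independent_evaluation(self):
        """γ(z=−1, I=0.7, 25 °C) re-derived from the Davies formula."""
        I = 0.7
        expected = 10 ** (-0.509 * (np.sqrt(I) / (1 + np.sqrt(I)) - 0.3 * I))
        got = ms.activity_coefficient(-1, I, 298.15)
        assert got == pytest.approx(expected, abs=0.005)
        assert got < 1.0

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            ms.activity_coefficient(1, -0.1)


class TestGibbsEnergy:
    def test_zero_at_equilibrium(self, reactions, thermo):
        """Choosing activities so that Q = K gives ΔG_r = 0 exactly."""
        for T in (273.15, 298.15, 323.15, 373.15):
            for r in reactions.values():
                lnK = -ms.standard_gibbs(r, T, thermo) / (R_KJ * T)
                # put the whole quotient on a single species
                sp = next(iter(r.stoichiometry))
                acts = {s: 1.0 for s in r.stoichiometry}
                acts[sp] = float(np.exp(lnK / r.stoichiometry[sp]))
                assert ms.gibbs_energy(r, T, activities=acts, table=thermo) == (
                    pytest.approx(0.0, abs=1e-9)
                )

    def test_scaling_invariance(self, reactions, thermo):
        """Doubling all coefficients leaves kJ/mol C unchanged."""
        r2 = reactions[2]
        doubled = ms.ReactionSpec(
            2, "x2", {s: 2 * c for s, c in r2.stoichiometry.items()},
            2 * r2.carbon_transferred,
        )
        acts = {"acetate": 1e-5, "H+": 10**-7.8, "CH4": 1e-3, "CO2": 1e-3}
        a = ms.gibbs_energy(r2, 298.15, activities=acts, table=thermo)
        b = ms.gibbs_energy(doubled, 298.15, activities=acts, table=thermo)
        assert a == pytest.approx(b, rel=1e-12)

    def test_unit_activities_recover_standard_state(self, reactions, thermo):
        r1 = reactions[1]
        acts = {s: 1.0 for s in r1.stoichiometry}
        assert ms.gibbs_energy(r1, 298.15, activities=acts, table=thermo) == (
            pytest.approx(ms.standard_gibbs(r1, 298.15, thermo) / 1.0)
        )

    def test_forward_backward_antisymmetry(self, reactions, thermo):
        """A reaction and its reverse sum to ΔG = 0."""
        r4 = reactions[4]
        rev = ms.ReactionSpec(
            4, "reverse", {s: -c for s, c in r4.stoichiometry.items()},
            r4.carbon_transferred,
        )
        acts = {"methanol": 1e-6, "H2": 1e-8, "CH4": 1e-3}
        fwd = ms.gibbs_energy(r4, 310.0, activities=acts, table=thermo)
        bwd = ms.gibbs_energy(rev, 310.0, activities=acts, table=thermo)
        assert fwd + bwd == pytest.approx(0.0, abs=1e-12)

    def test_slope_in_lnQ(self, reactions, thermo):
        """ΔG rises with ln Q at slope RT/n_C."""
        r1, T = reactions[1], 298.15
        acts = {"H2": 1e-8, "CO2": 1e-3, "CH4": 1e-4}
        g1 = ms.gibbs_energy(r1, T, activities=acts, table=thermo)
        acts2 = dict(acts, CH4=acts["CH4"] * np.e)  # lnQ + 1
        g2 = ms.gibbs_energy(r1, T, activities=acts2, table=thermo)
        assert g2 - g1 == pytest.approx(R_KJ * T / r1.carbon_transferred, rel=1e-9)

    def test_nonpositive_activity_rejected(self, reactions, thermo):
        with pytest.raises(ValueError, match="CH4"):
            ms.gibbs_energy(
                reactions[1], 298.15,
                activities={"H2": 1e-8, "CO2": 1e-3, "CH4": 0.0}, table=thermo,
            )


class TestEnvelope:
    def test_zero_width_range_collapses(self, reactions, thermo):
        r5 = reactions[5]
        rr = {"methanol": ms.SubstrateRange("methanol", 1e-6, 1e-6)}
        acts = {"CH4": 1e-3, "CO2": 1e-3}
        lo, mid, hi = ms.gibbs_envelope(r5, 298.15, acts, rr, table=thermo)
        assert lo == mid == hi

    def test_ordering_and_monotone_widening(self, reactions, thermo):
        r5 = reactions[5]
        acts = {"CH4": 1e-3, "CO2": 1e-3}
        narrow = {"methanol": ms.SubstrateRange("methanol", 1e-7, 1e-5)}
        wide = {"methanol": ms.SubstrateRange("methanol", 1e-8, 1e-4)}
        lo_n, mid_n, hi_n = ms.gibbs_envelope(r5, 298.15, acts, narrow, table=thermo)
        lo_w, mid_w, hi_w = ms.gibbs_envelope(r5, 298.15, acts, wide, table=thermo)
        assert lo_n <= mid_n <= hi_n
        assert lo_w < lo_n and hi_w > hi_n  # strictly wider box, wider envelope
        assert mid_w == pytest.approx(mid_n)  # same geometric centre

    def test_hydrogenotrophic_has_no_envelope(self, reactions, thermo):
        """All reaction-1 species are measured: single line, zero width."""
        r1 = reactions[1]
        assert r1.unmeasured_substrates() == []
        acts = {"H2": 1e-8, "CO2": 1e-3, "CH4": 1e-4}
        lo, mid, hi = ms.gibbs_envelope(r1, 298.15, acts, {}, table=thermo)
        assert lo == mid == hi

    def test_missing_range_is_configuration_error(self, reactions, thermo):
        with pytest.raises(KeyError, match="methanol"):
            ms.gibbs_envelope(
                reactions[5], 298.15, {"CH4": 1e-3, "CO2": 1e-3}, {},
                table=thermo,
            )


class TestBelowDetection:
    def test_standin_default(self):
        assert below_detection_policy(True) == (1e-7, True)

    def test_override(self):
        assert below_detection_policy(True, standin_activity=1e-8) == (1e-8, True)

    def test_measured_passthrough(self):
        assert below_detection_policy(False, 3.3e-4) == (3.3e-4, False)


class TestDowncore:
    def test_unit_activity_profile_recovers_standard_state(self, thermo):
        """With all activities forced to 1, ΔG = ΔG°(T)/n_C for all 9."""
        row = dict(site="s", depth_mbsf=10.0, temperature_C=25.0, pH=0.0,
                   ionic_strength=0.0, CH4_molkg=1.0, DIC_molkg=1.0,
                   H2_molkg=1.0, NH4_molkg=1.0, HS_molkg=1.0)
        ranges = {
            sp: ms.SubstrateRange(sp, 1.0, 1.0)
            for sp in load_substrate_ranges()
        }
        # pH 0 gives a(H+) = 1; DIC needs rescaling so CO2(aq) activity is 1
        row["DIC_molkg"] = 1.0 / co2_fraction(0.0)
        out = ms.downcore_energetics(pd.DataFrame([row]), ranges=ranges,
                                     table=thermo)
        assert len(out) == 9
        for r in ms.reaction_library():
            got = out.loc[out.reaction_id == r.id, "dG_mean"].iloc[0]
            expect = ms.standard_gibbs(r, 298.15, thermo) / r.carbon_transferred
            assert got == pytest.approx(expect, rel=1e-9)

    def test_methylotrophic_dominance_and_R1_crossing(self, templates):
        """Down-core pattern: methylotrophic reactions 5–8 beat 1–3
        everywhere, and CO₂ reduction turns endergonic below the SMTZ of the
        hot-sill site."""
        for name, t in templates.items():
            prof = ms.generate_profile(t, 20, seed=1)
            out = ms.downcore_energetics(prof)
            piv = out.pivot_table(index="depth_mbsf", columns="reaction_id",
                                  values="dG_mean")
            assert (piv[[5, 6, 7, 8]].max(axis=1)
                    < piv[[1, 2, 3]].min(axis=1)).all(), name
        hot = templates["shallow_hot_sill"]
        out = ms.downcore_energetics(ms.generate_profile(hot, 20, seed=1))
        r1 = out[out.reaction_id == 1]
        crossing = ms.find_zero_crossing(r1["depth_mbsf"], r1["dG_mean"])
        assert crossing is not None and crossing > hot.smtz_depth

    def test_empty_profile(self):
        out = ms.downcore_energetics(pd.DataFrame(
            columns=["depth_mbsf", "temperature_C", "pH", "ionic_strength",
                     "CH4_molkg", "DIC_molkg", "H2_molkg", "NH4_molkg",
                     "HS_molkg"]))
        assert out.empty

    def test_envelope_ordering_everywhere(self, templates):
        out = ms.downcore_energetics(
            ms.generate_profile(templates["no_sill"], 12, seed=5))
        ok = out[out.error == ""]
        assert (ok.dG_min <= ok.dG_mean).all() and (ok.dG_mean <= ok.dG_max).all()


class TestZeroCrossing:
    def test_linear_interpolation(self):
        assert ms.find_zero_crossing([90.0, 110.0], [-5.0, 5.0]) == pytest.approx(100.0)

    def test_all_negative_returns_none(self):
        assert ms.find_zero_crossing([0, 50, 100], [-3, -2, -1]) is None

    def test_multi_crossing_returns_shallowest(self, rng):
        """Agreement with an exhaustive pairwise scan on wiggly series."""
        for _ in range(50):
            d = np.sort(rng.uniform(0, 300, 12))
            g = rng.normal(0, 5, 12)
            got = ms.find_zero_crossing(d, g)
            brute = None
            for i in range(11):
                if g[i] < 0 <= g[i + 1]:
                    brute = d[i] + (d[i + 1] - d[i]) * (-g[i]) / (g[i + 1] - g[i])
                    break
                if g[i] == 0 and g[i + 1] > 0:
                    brute = d[i]
                    break
            if brute is None:
                assert got is None
            else:
                assert got == pytest.approx(brute)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ms.find_zero_crossing([10.0], [-1.0])
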