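"""Condition scans, the flux variation coefficient, and net-flux records."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxsense.netcore import Condition
from fluxsense.sensitivity import (
    SensitivityError,
    SensitivityTable,
    aggregate,
    build_sensitivity_table,
    classify_sensitive,
    default_conditions,
    flux_ratio_low_high,
    flux_variation_coefficient,
    net_metabolite_flux,
    scan_conditions,
)
from fluxsense.synthdata import NetworkBlueprint, generate_network


@pytest.fixture(scope="module")
def scanned():
    net, truth = generate_network(NetworkBlueprint(seed=7))
    sols = scan_conditions(net, default_conditions())
    table = classify_sensitive(build_sensitivity_table(net, sols))
    return net, truth, sols, table


class TestScan:
    def test_five_conditions_all_optimal(self, scanned):
        _, _, sols, _ = scanned
        assert len(sols) == 5
        assert all(s.status == "optimal" for s in sols.values())

    def test_objectives_track_co2_bound(self, scanned):
        # CO2 is the only bottleneck by construction, so the biomass
        # optimum equals the CO2 exchange bound at every level
        _, _, sols, _ = scanned
        for cond in default_conditions():
            assert sols[cond.name].objective == pytest.approx(
                cond.co2_flux_ub, abs=1e-6
            )

    def test_duplicate_condition_names_rejected(self, scanned):
        net = scanned[0]
        conds = default_conditions()[:2]
        with pytest.raises(SensitivityError, match="duplicate"):
            scan_conditions(net, [conds[0], conds[0]])

    def test_fewer_than_two_conditions_rejected(self, scanned):
        with pytest.raises(SensitivityError):
            scan_conditions(scanned[0], default_conditions()[:1])

    def test_infeasible_condition_named(self, scanned):
        net = scanned[0].copy()
        # demand more growth than low CO2 can support: only the 10% level
        # stays feasible, so the scan must abort naming the starved one
        net.reactions["BIOMASS"].lb = 7.0
        starved = Condition("starved", 5, 5.0, 57.54)
        with pytest.raises(SensitivityError, match="starved"):
            scan_conditions(net, [default_conditions()[-1], starved])


class TestRho:
    def test_hand_arithmetic_example(self):
        # sd(1,1,1,1,3)=0.8944, mean=1.4 -> rho=0.6389
        assert flux_variation_coefficient([1, 1, 1, 1, 3]) == pytest.approx(
            0.6389, abs=1e-4
        )

    def test_constant_vector_is_zero(self):
        assert flux_variation_coefficient([2, 2, 2, 2, 2]) == 0.0

    def test_all_zero_guarded(self):
        assert flux_variation_coefficient([0, 0, 0, 0, 0]) == 0.0

    def test_requires_two_values(self):
        with pytest.raises(SensitivityError):
            flux_variation_coefficient([1.0])

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, fluxes, k):
        base = flux_variation_coefficient(fluxes)
        scaled_up = flux_variation_coefficient([k * f for f in fluxes])
        flipped = flux_variation_coefficient([-k * f for f in fluxes])
        if abs(np.mean(fluxes)) > 1e-6 and base < 1e6:
            assert scaled_up == pytest.approx(base, rel=1e-6)
            assert flipped == pytest.approx(base, rel=1e-6)
        assert base >= 0 and scaled_up >= 0


class TestClassification:
    def _table(self, rows: dict) -> SensitivityTable:
        fluxes = pd.DataFrame.from_dict(rows, orient="index",
                                        columns=["c1", "c2", "c3", "c4", "c5"])
        return SensitivityTable(condition_names=list(fluxes.columns), fluxes=fluxes)

    def test_threshold_comparison_is_inclusive(self):
        # a reaction whose rho lands exactly on the threshold is sensitive
        vals = [1.02, 0.98, 1.02, 0.98, 1.0]
        rho = flux_variation_coefficient(vals)
        table = self._table({"r": vals})
        classify_sensitive(table, rho_threshold=rho)
        assert bool(table.sensitive["r"])

    def test_just_below_threshold_not_sensitive(self):
        vals = [1.02, 0.98, 1.02, 0.98, 1.0]
        rho = flux_variation_coefficient(vals)
        table = self._table({"r": vals})
        classify_sensitive(table, rho_threshold=float(np.nextafter(rho, np.inf)))
        assert not bool(table.sensitive["r"])
        # and the default fixed threshold: 0.0099 < 0.01 is not flagged
        table2 = self._table({"r": [1.0 + 0.0099 * 1.4 / 0.8944, 1.0, 1.0, 1.0, 1.0]})
        classify_sensitive(table2)
        assert float(table2.rho["r"]) < 0.01
        assert not bool(table2.sensitive["r"])

    def test_constant_table_has_no_sensitives(self):
        table = self._table({"a": [3] * 5, "b": [0] * 5})
        classify_sensitive(table)
        assert not table.sensitive.any()

    def test_planted_recovery_single_network(self, scanned):
        _, truth, _, table = scanned
        recovered = set(table.sensitive_ids()) - set(truth["scaffold"])
        assert recovered == set(truth["sensitive"])
        assert not set(truth["pinned"]) & set(table.sensitive_ids())


class TestAggregation:
    def test_counts_match_construction(self, scanned):
        net, truth, _, table = scanned
        pathway_summary, compartment_summary = aggregate(table)
        expected = (
            table.pathway.loc[table.sensitive[table.sensitive].index]
            .value_counts()
            .sort_index()
        )
        assert (pathway_summary["count"] == expected).all()
        assert pathway_summary["percent"].sum() == pytest.approx(100.0, abs=0.01)
        assert compartment_summary["percent"].sum() == pytest.approx(100.0, abs=0.01)

    def test_empty_when_nothing_sensitive(self):
        fluxes = pd.DataFrame({"c1": [1.0], "c2": [1.0]}, index=["r"])
        table = SensitivityTable(condition_names=["c1", "c2"], fluxes=fluxes)
        classify_sensitive(table)
        pathway_summary, compartment_summary = aggregate(table)
        assert pathway_summary.empty and compartment_summary.empty


class TestNetFlux:
    @pytest.fixture
    def small_table(self, fixture_4x5):
        net, _ = fixture_4x5
        fluxes = pd.DataFrame(
            {"low": [3.0, 1.0, 0.5, 4.0, 0.5], "high": [6.0, 2.0, 1.0, 8.0, 1.0]},
            index=["r1", "r2", "r3", "r4", "r5"],
        )
        table = SensitivityTable(condition_names=["low", "high"], fluxes=fluxes)
        table.sensitive = pd.Series(
            {"r1": True, "r2": True, "r3": False, "r4": False, "r5": False}
        )
        return net, table

    def test_producer_minus_consumer(self, small_table):
        net, table = small_table
        # B: +1*r1 -2*r2 at low = 3 - 2 = 1 (hand dot product)
        assert net_metabolite_flux(table, net, "B[c]", "low") == pytest.approx(1.0)

    def test_untouched_metabolite_zero(self, small_table):
        net, table = small_table
        assert net_metabolite_flux(table, net, "D[c]", "low") == 0.0

    def test_unknown_metabolite_raises(self, small_table):
        net, table = small_table
        with pytest.raises(SensitivityError):
            net_metabolite_flux(table, net, "Z[c]", "low")

    def test_totals_identity_over_metabolites(self, small_table):
        # sum over metabolites of net flux equals sum over sensitive
        # columns of column-sum(S) * v
        net, table = small_table
        from fluxsense.netcore import build_stoich_matrix

        total = sum(
            net_metabolite_flux(table, net, m, "low") for m in net.metabolites
        )
        s = build_stoich_matrix(net).to_dense()
        ids = sorted(net.reactions)
        v = np.array([
            table.fluxes.at[r, "low"] if bool(table.sensitive.get(r)) else 0.0
            for r in ids
        ])
        assert total == pytest.approx(float(s.sum(axis=0) @ v))

    @pytest.mark.parametrize(
        "low,high,ratio",
        [(2.0, 4.0, 0.5), (-1.0, 2.0, -0.5), (3.0, 0.0, None)],
    )
    def test_low_high_ratio(self, low, high, ratio):
        rec = flux_ratio_low_high("met", low, high)
        if ratio is None:
            assert rec.ratio is None
        else:
            assert rec.ratio == pytest.approx(ratio)
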