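"""qPCR efficiency/ratio computation and metabolomics normalization."""

import numpy as np
import pandas as pd
import pytest

from fluxsense.sensitivity import NetFluxRecord
from fluxsense.validation import (
    FluorescenceCurve,
    MetaboliteTable,
    QpcrRecord,
    ValidationError,
    concordance,
    estimate_efficiency,
    log2_fold_change,
    normalize_metabolites,
    pfaffl_ratio,
)
from fluxsense.synthdata import OmicsBlueprint, generate_metabolites, generate_qpcr


def _curve(readings, well="w1"):
    return FluorescenceCurve(
        well=well, gene="g", condition="low", replicate=1,
        cycles=np.arange(1, len(readings) + 1, dtype=float),
        readings=np.asarray(readings, dtype=float),
    )


class TestEfficiency:
    def test_perfect_doubling_curve(self):
        cycles = np.arange(1, 41)
        curve = _curve(100.0 * 2.0**cycles)
        assert estimate_efficiency(curve) == pytest.approx(2.0, abs=1e-6)

    def test_planted_efficiency_with_plateau(self):
        cycles = np.arange(1, 41)
        readings = 20.0 + np.minimum(50.0 * 1.8**cycles, 1e7)
        curve = _curve(readings)
        assert estimate_efficiency(curve) == pytest.approx(1.8, abs=0.01)

    def test_flat_curve_flags_failure(self):
        with pytest.raises(ValidationError):
            estimate_efficiency(_curve(np.full(40, 100.0)))

    def test_clipped_at_upper_bound(self):
        cycles = np.arange(1, 41)
        curve = _curve(np.minimum(1e-4 * 3.0**cycles, 1e7) + 10.0)
        assert estimate_efficiency(curve) == 2.2

    def test_generator_truth_recovered_noise_free(self):
        bp = OmicsBlueprint(seed=3)
        curves, _, truth = generate_qpcr(bp)
        for c in curves[:10]:
            e = estimate_efficiency(c)
            assert e == pytest.approx(truth["efficiencies"][c.gene], abs=0.01)


def _recs(gene, e, ct_low, ct_high, melt_ok=True):
    return [
        QpcrRecord(gene=gene, condition="low", ct=ct_low, efficiency=e,
                   melt_ok=melt_ok),
        QpcrRecord(gene=gene, condition="high", ct=ct_high, efficiency=e,
                   melt_ok=melt_ok),
    ]


class TestPfaffl:
    def test_equal_efficiencies_simple_case(self):
        # E_t = E_ref = 2, dCt_t = 1, dCt_ref = 0 -> 2.0
        er = pfaffl_ratio(_recs("g", 2.0, 20, 21), {"ACT": _recs("ACT", 2.0, 20, 20)})
        assert er.ratio == pytest.approx(2.0)

    def test_worked_example_mixed_efficiencies(self):
        # 1.8^2 / 2.0^1 = 1.62
        er = pfaffl_ratio(_recs("g", 1.8, 20, 22), {"ACT": _recs("ACT", 2.0, 20, 21)})
        assert er.ratio == pytest.approx(1.62, abs=1e-12)

    def test_unchanged_gene_is_unity(self):
        er = pfaffl_ratio(_recs("g", 1.9, 20, 20), {"ACT": _recs("ACT", 2.0, 22, 22)})
        assert er.ratio == pytest.approx(1.0)

    def test_identity_with_classical_ddct(self):
        # with all efficiencies 2 the Pfaffl ratio equals 2^(-ddCt)
        rng = np.random.default_rng(0)
        for _ in range(20):
            ct = rng.uniform(15, 30, size=4)  # t_low, t_high, r_low, r_high
            er = pfaffl_ratio(
                _recs("g", 2.0, ct[0], ct[1]), {"ACT": _recs("ACT", 2.0, ct[2], ct[3])}
            )
            ddct = (ct[0] - ct[2]) - (ct[1] - ct[3])
            assert er.ratio == pytest.approx(2.0 ** (-ddct), rel=1e-12)

    def test_two_reference_genes_geometric_mean(self):
        refs = {
            "ACT": _recs("ACT", 2.0, 20, 21),  # E^dCt = 2
            "UBQ": _recs("UBQ", 2.0, 20, 23),  # E^dCt = 8
        }
        er = pfaffl_ratio(_recs("g", 2.0, 20, 22), refs)
        # denominator = sqrt(2 * 8) = 4; numerator = 4
        assert er.ratio == pytest.approx(1.0)
        assert er.reference_genes == ("ACT", "UBQ")

    def test_melt_failures_excluded(self):
        target = _recs("g", 2.0, 20, 21) + _recs("g", 2.0, 10, 10, melt_ok=False)
        with pytest.warns(UserWarning, match="melt"):
            er = pfaffl_ratio(target, {"ACT": _recs("ACT", 2.0, 20, 20)})
        assert er.ratio == pytest.approx(2.0)

    def test_missing_condition_raises(self):
        target = [QpcrRecord(gene="g", condition="low", ct=20, efficiency=2.0)]
        with pytest.raises(ValidationError):
            pfaffl_ratio(target, {"ACT": _recs("ACT", 2.0, 20, 20)})

    def test_generator_truth_recovered(self):
        bp = OmicsBlueprint(seed=11, ct_sd=0.0)
        _, records, truth = generate_qpcr(bp)
        by_gene = {}
        for r in records:
            by_gene.setdefault(r.gene, []).append(r)
        refs = {"ACT": by_gene["ACT"]}
        for gene, true_ratio in truth["expression_ratios"].items():
            er = pfaffl_ratio(by_gene[gene], refs)
            assert er.ratio == pytest.approx(true_ratio, rel=1e-6)


class TestNormalization:
    @pytest.fixture
    def table(self):
        table, _ = generate_metabolites(OmicsBlueprint(seed=2))
        return table

    def test_rows_sum_to_one(self, table):
        norm = normalize_metabolites(table)
        assert np.allclose(norm.sum(axis=1), 1.0, atol=1e-12)

    def test_per_sample_rescale_invariance(self, table):
        norm = normalize_metabolites(table)
        scaled = MetaboliteTable(
            intensities=table.intensities.mul(
                pd.Series(np.linspace(2, 7, len(table.intensities)),
                          index=table.intensities.index), axis=0),
            cell_counts=table.cell_counts,
            conditions=table.conditions,
        )
        assert np.allclose(normalize_metabolites(scaled), norm)

    def test_equal_cell_counts_are_noop(self, table):
        flat = MetaboliteTable(
            intensities=table.intensities,
            cell_counts=pd.Series(1.0, index=table.cell_counts.index),
            conditions=table.conditions,
        )
        # cell-count division cancels in the TIC step when counts are equal
        direct = table.intensities.div(table.intensities.sum(axis=1), axis=0)
        assert np.allclose(normalize_metabolites(flat), direct)

    def test_zero_cell_count_rejected(self, table):
        with pytest.raises(ValidationError):
            MetaboliteTable(
                intensities=table.intensities,
                cell_counts=pd.Series(0.0, index=table.cell_counts.index),
                conditions=table.conditions,
            )


class TestFoldChange:
    def test_equal_means_zero(self):
        intens = pd.DataFrame(
            {"a": [1.0, 1.0, 1.0, 1.0]},
            index=["l1", "l2", "h1", "h2"],
        )
        conditions = pd.Series(["low", "low", "high", "high"], index=intens.index)
        df = log2_fold_change(intens, conditions)
        assert df.at["a", "log2fc"] == pytest.approx(0.0)

    def test_planted_five_fold_recovered(self):
        bp = OmicsBlueprint(seed=4)
        table, truth = generate_metabolites(bp)
        fc = log2_fold_change(normalize_metabolites(table), table.conditions)
        assert fc.at["xylose", "log2fc"] == pytest.approx(np.log2(5.5), abs=0.5)
        assert fc.at["xylose", "log2fc"] >= 2.0

    def test_zero_intensity_flagged_not_dropped(self):
        intens = pd.DataFrame(
            {"a": [1.0, 1.0, 0.0, 1.0], "b": [1.0, 2.0, 1.5, 1.2]},
            index=["l1", "l2", "h1", "h2"],
        )
        conditions = pd.Series(["low", "low", "high", "high"], index=intens.index)
        df = log2_fold_change(intens, conditions)
        assert bool(df.at["a", "flagged"])
        assert "a" in df.index

    def test_too_few_replicates_rejected(self):
        intens = pd.DataFrame({"a": [1.0, 2.0]}, index=["l1", "h1"])
        conditions = pd.Series(["low", "high"], index=intens.index)
        with pytest.raises(ValidationError):
            log2_fold_change(intens, conditions)


class TestConcordance:
    def _fc(self, values: dict) -> pd.DataFrame:
        return pd.DataFrame(
            {"log2fc": pd.Series(values), "pvalue": 0.01, "padj": 0.01,
             "significant": True, "flagged": False}
        )

    def test_matching_direction_concordant(self):
        recs = [NetFluxRecord("x", net_flux_low=1.0, net_flux_high=2.0, ratio=0.5)]
        rep = concordance(recs, self._fc({"x": 1.0}))
        assert rep.concordant == 1 and rep.discordant == 0

    def test_opposite_direction_discordant(self):
        recs = [NetFluxRecord("x", net_flux_low=2.0, net_flux_high=1.0, ratio=2.0)]
        rep = concordance(recs, self._fc({"x": 1.0}))
        assert rep.discordant == 1

    def test_undefined_ratio_unevaluable(self):
        recs = [NetFluxRecord("x", net_flux_low=1.0, net_flux_high=0.0, ratio=None)]
        rep = concordance(recs, self._fc({"x": 1.0}))
        assert rep.unevaluable == 1 and rep.evaluable == 0

    def test_no_shared_metabolites_warns(self):
        recs = [NetFluxRecord("x", net_flux_low=1.0, net_flux_high=2.0, ratio=0.5)]
        with pytest.warns(UserWarning, match="no shared"):
            rep = concordance(recs, self._fc({"y": 1.0}))
        assert rep.unevaluable == 1
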