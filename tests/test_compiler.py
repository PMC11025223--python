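import numpy as np
import pytest

from molclass import compiler, crn
from molclass.compiler import (
    INDETERMINATE,
    AnnihilatorSpec,
    InputScale,
    LinearClassifierSpec,
    LinearRegimeWarning,
    build_annihilator,
    closed_form_output,
    closed_form_signal,
    compile_classifier,
    evaluate_in_silico,
    predict_in_silico,
)
from molclass.crn import ReactionNetwork, Species, ValidationError


class TestClosedForms:
    @pytest.mark.parametrize(
        "input0,amp0,inh0,expected",
        [(2.0, 100.0, 50.0, 4.0), (0.0, 100.0, 40.0, 0.0), (4.0, 100.0, 40.0, 10.0)],
    )
    def test_output_ratio(self, input0, amp0, inh0, expected):
        assert closed_form_output(input0, amp0, inh0) == pytest.approx(expected)

    def test_saturation_outside_linear_regime(self):
        with pytest.raises(ValidationError):
            closed_form_output(60.0, 100.0, 50.0)

    @pytest.mark.parametrize(
        "weights,inputs,pos,neg",
        [
            ((1.5, 2.5), (2.0, 2.0), 8.0, 0.0),  # published two-input summation pair
            ((1.5, -2.0), (4.0, 2.0), 6.0, 4.0),  # published demo classifier
            ((1.0, -1.0), (0.0, 0.0), 0.0, 0.0),
        ],
    )
    def test_signal_channel_totals(self, weights, inputs, pos, neg):
        assert closed_form_signal(weights, inputs) == pytest.approx((pos, neg))

    def test_signal_length_mismatch(self):
        with pytest.raises(ValidationError):
            closed_form_signal((1.0,), (1.0, 2.0))


class TestSpec:
    def test_one_decimal_weights_enforced(self):
        with pytest.raises(ValidationError):
            LinearClassifierSpec(("a",), (1.25,), 0.0)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValidationError):
            LinearClassifierSpec(("a",), (0.0,), 0.0)

    def test_json_round_trip(self, tmp_path):
        spec = LinearClassifierSpec(
            ("a", "b"), (2.4, -2.6), -0.5, input_scale=InputScale(-3.3, 3.3)
        )
        path = tmp_path / "clf.json"
        spec.to_json(path)
        back = LinearClassifierSpec.from_json(path)
        assert back == spec

    def test_input_scale_round_trip(self):
        scale = InputScale(x_min=-3.32, x_max=3.32)
        x = np.array([-3.32, 0.0, 3.32])
        np.testing.assert_allclose(scale.to_raw(scale.to_nM(x)), x, atol=1e-12)
        np.testing.assert_allclose(scale.to_nM(x)[[0, -1]], [1.0, 6.0], atol=1e-12)


class TestCompile:
    def test_ideal_inhibitor_mapping(self):
        # published weight extremes +2.4 / -2.6 at amplifier 100 nM
        spec = LinearClassifierSpec(("up", "down"), (2.4, -2.6), 0.0)
        cc = compile_classifier(spec)
        by_feature = {u.feature: u for u in cc.weight_units}
        assert by_feature["up"].inhibitor0 == pytest.approx(100 / 2.4)
        assert by_feature["down"].inhibitor0 == pytest.approx(100 / 2.6)
        assert by_feature["up"].output_species == "out_pos"
        assert by_feature["down"].output_species == "out_neg"

    def test_identity_weight(self):
        spec = LinearClassifierSpec(("a",), (1.0,), 0.0)
        cc = compile_classifier(spec)
        assert cc.weight_units[0].inhibitor0 == pytest.approx(100.0)

    def test_structure_counts_five_feature_panel(self, molecular_spec):
        cc = compile_classifier(molecular_spec)
        n_units = len(cc.weight_units)  # five features + bias unit
        assert n_units == len(molecular_spec.features) + (
            1 if molecular_spec.bias != 0 else 0
        )
        # per unit: in/amp/inh species and 2 reactions; plus 2 outputs, waste,
        # annihilator + intermediate, 2 reporters, 2 fluorophores; 3 annihilation
        # and 2 reporter reactions
        assert len(cc.network.species) == 3 * n_units + 9
        assert len(cc.network.reactions) == 2 * n_units + 5
        assert cc.annihilator.annihilator0 >= 2 * min(
            sum(w for w in molecular_spec.weights if w > 0) * cc.input_max,
            -sum(w for w in molecular_spec.weights if w < 0) * cc.input_max,
        )

    def test_calibration_table_override(self):
        spec = LinearClassifierSpec(
            ("a",), (2.5,), 0.0, calibration_table={2.5: 38.5}
        )
        cc = compile_classifier(spec)
        assert cc.weight_units[0].inhibitor0 == pytest.approx(38.5)

    def test_low_inhibitor_triggers_linear_regime_warning(self):
        spec = LinearClassifierSpec(("a",), (4.5,), 0.0, amplifier0=10.0)
        with pytest.warns(LinearRegimeWarning):
            compile_classifier(spec)  # inhibitor 2.2 nM < 6 nM input range


class TestWeightAccuracy:
    @pytest.mark.parametrize("weight", [2.5, 3.5, 4.5])
    def test_ode_endpoint_matches_closed_form(self, weight):
        # the published weight set at inputs 1-4 nM, amplifier 100 nM
        for input0 in (1.0, 2.0, 3.0, 4.0):
            net = compiler.build_weight_unit_network(weight, input0, 100.0)
            trace = crn.simulate(net, 2e5)
            expected = closed_form_output(input0, 100.0, 100.0 / weight)
            assert trace.endpoint["output"] == pytest.approx(expected, rel=5e-3)

    def test_weight_fit_r2_above_published_bound(self):
        # fitting Signal = W * Input per weight: R^2 > 0.98 for all weights
        inputs = np.array([1.0, 2.0, 3.0, 4.0])
        for weight in (2.5, 3.5, 4.5):
            outputs = []
            for input0 in inputs:
                net = compiler.build_weight_unit_network(weight, input0, 100.0)
                outputs.append(crn.simulate(net, 2e5).endpoint["output"])
            outputs = np.array(outputs)
            w_hat = float(inputs @ outputs / (inputs @ inputs))
            ss_res = float(np.sum((outputs - w_hat * inputs) ** 2))
            ss_tot = float(np.sum((outputs - outputs.mean()) ** 2))
            assert 1 - ss_res / ss_tot > 0.98
            assert w_hat == pytest.approx(weight, rel=0.01)

    def test_saturation_regime_output_approaches_amplifier(self):
        # input above inhibitor: inhibitor exhausts, catalysis runs to the
        # amplifier ceiling
        net = compiler.build_weight_unit_network(4.0, 30.0, 100.0)  # inhibitor 25
        trace = crn.simulate(net, 5e5)
        assert trace.endpoint["output"] > 95.0


class TestSummation:
    def test_multi_unit_positive_channel_sums(self, printed_two_input_spec):
        # two positive units: channel endpoint equals the closed-form sum
        spec = LinearClassifierSpec(("i1", "i2"), (1.5, 2.5), 0.0)
        cc = compile_classifier(spec)
        # measure before annihilation/reporting by summing output + reporter products
        trace = cc.simulate({"i1": 2.0, "i2": 2.0})
        total_pos = trace.endpoint["out_pos"] + trace.endpoint["fluor_hex"]
        # annihilator leaves positive-only signal intact
        assert total_pos == pytest.approx(8.0, rel=0.01)


class TestAnnihilator:
    def run_annihilation(self, pos0, neg0, annihilator0, t_end=2e5):
        spec = AnnihilatorSpec(annihilator0=annihilator0)
        species = [
            Species("out_pos", "output_pos"),
            Species("out_neg", "output_neg"),
            Species("annihilator", "annihilator"),
            Species("ann_intermediate"),
            Species("waste", "waste"),
        ]
        net = ReactionNetwork(
            species,
            build_annihilator(spec),
            {"out_pos": pos0, "out_neg": neg0, "annihilator": annihilator0},
        )
        return crn.simulate(net, t_end)

    def test_majority_survives_minority_vanishes(self):
        trace = self.run_annihilation(10.0, 6.0, 50.0)
        assert trace.endpoint["out_pos"] == pytest.approx(4.0, abs=0.05)
        assert trace.endpoint["out_neg"] < 0.05

    def test_diagonal_case_both_low(self):
        trace = self.run_annihilation(5.0, 5.0, 50.0, t_end=1e6)
        assert trace.endpoint["out_pos"] < 0.05
        assert trace.endpoint["out_neg"] < 0.05

    def test_nothing_to_annihilate(self):
        trace = self.run_annihilation(8.0, 0.0, 50.0)
        assert trace.endpoint["out_pos"] == pytest.approx(8.0, rel=0.01)


class TestWinnerTakeAll:
    def test_truth_table_sample_cells(self, printed_two_input_spec):
        # spot-check the published demo classifier 1.5*I1 - 2*I4 on three
        # representative cells (full 6x6 grid exercised in the acceptance suite)
        cc = compile_classifier(printed_two_input_spec)
        delta = cc.delta()
        for i1, i4 in ((5.0, 1.0), (1.0, 5.0), (4.0, 3.0)):
            margin = 1.5 * i1 - 2.0 * i4
            trace = cc.simulate({"Input1": i1, "Input4": i4})
            hex_sig = trace.endpoint["fluor_hex"]
            rox_sig = trace.endpoint["fluor_rox"]
            if margin > delta:
                assert hex_sig > delta and rox_sig < delta
            elif margin < -delta:
                assert rox_sig > delta and hex_sig < delta
            else:
                assert hex_sig < delta and rox_sig < delta


class TestInSilico:
    def test_published_example_negative_call(self, printed_two_input_spec):
        # (I1=2, I4=3): 1.5*2 - 2*3 = -3 -> negative class
        score = evaluate_in_silico(
            printed_two_input_spec, {"Input1": 2.0, "Input4": 3.0}
        )
        assert score == pytest.approx(-3.0)
        assert (
            predict_in_silico(printed_two_input_spec, {"Input1": 2.0, "Input4": 3.0})
            == "negative"
        )

    def test_zero_score_indeterminate(self, printed_two_input_spec):
        assert (
            predict_in_silico(printed_two_input_spec, {"Input1": 4.0, "Input4": 3.0})
            == INDETERMINATE
        )

    def test_missing_feature_rejected(self, printed_two_input_spec):
        with pytest.raises(ValidationError):
            evaluate_in_silico(printed_two_input_spec, {"Input1": 2.0})

    def test_raw_space_goes_through_input_scale(self):
        spec = LinearClassifierSpec(
            ("a",), (2.0,), 0.0, input_scale=InputScale(0.0, 10.0)
        )
        # x=10 -> u=6 nM -> score 12
        assert evaluate_in_silico(spec, {"a": 10.0}, space="raw") == pytest.approx(12.0)
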