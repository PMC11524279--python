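"""Unit tests for the Ct-based estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcep.quant import (
    CtRecord,
    NormalizationError,
    QuantError,
    Role,
    Template,
    UndeterminedCtError,
    broken_dna_abundance,
    cas9_abundance,
    delta_delta_ct,
    in_vitro_efficiency,
    normalize_to_lowest,
    quantify_experiment,
    quantify_invitro,
    relative_cutting_efficiency,
    students_t,
)

from conftest import make_invivo_records

ct_values = st.floats(min_value=5.0, max_value=40.0)


class TestBrokenDnaAbundance:
    @pytest.mark.parametrize(
        "cts, mode, expected",
        [
            ((24, 20, 22, 20), "canonical", 0.75),
            ((24, 20, 22, 20), "literal", 0.25),
            ((22, 20, 22, 20), "canonical", 0.0),
        ],
    )
    def test_examples(self, cts, mode, expected):
        assert broken_dna_abundance(*cts, mode=mode) == pytest.approx(expected)

    def test_modes_are_complements(self):
        cts = (23.7, 20.1, 21.9, 20.4)
        assert broken_dna_abundance(*cts) + broken_dna_abundance(
            *cts, mode="literal"
        ) == pytest.approx(1.0)

    def test_undetermined_ct_names_the_well(self):
        with pytest.raises(UndeterminedCtError, match="Ct\\(T-inter\\)"):
            broken_dna_abundance(24, None, 22, 20)

    def test_unknown_mode_rejected(self):
        with pytest.raises(QuantError, match="mode"):
            broken_dna_abundance(24, 20, 22, 20, mode="bogus")

    @given(ct_t=ct_values, ct_ref=ct_values, shift=st.floats(-5, 5))
    @settings(max_examples=50, derandomize=True)
    def test_reference_shift_invariance(self, ct_t, ct_ref, shift):
        """Adding a constant to both wells of a sample cancels in ddCt."""
        base = delta_delta_ct(ct_t, ct_ref, 20.0, 20.0)
        shifted = delta_delta_ct(ct_t + shift, ct_ref + shift, 20.0, 20.0)
        assert shifted == pytest.approx(base, abs=1e-9)

    @given(d1=st.floats(-3, 3), d2=st.floats(-3, 3))
    @settings(max_examples=50, derandomize=True)
    def test_canonical_monotone_in_test_ct(self, d1, d2):
        lo, hi = sorted([d1, d2])
        b_lo = broken_dna_abundance(20 + lo, 20, 20, 20)
        b_hi = broken_dna_abundance(20 + hi, 20, 20, 20)
        assert b_lo <= b_hi <= 1.0
        if hi - lo > 1e-6:  # resolvable gap in double precision
            assert b_hi > b_lo


class TestCas9Abundance:
    @pytest.mark.parametrize(
        "ct_cas, ct_ref, expected", [(20, 20, 1.0), (23, 20, 0.125), (18, 20, 4.0)]
    )
    def test_examples(self, ct_cas, ct_ref, expected):
        assert cas9_abundance(ct_cas, ct_ref) == pytest.approx(expected)

    def test_undetermined_means_undefined_not_zero(self):
        with pytest.raises(UndeterminedCtError, match="not expressed"):
            cas9_abundance(None, 20)


class TestRelativeCuttingEfficiency:
    @pytest.mark.parametrize(
        "broken, cas9, expected", [(0.75, 0.5, 1.5), (0.0, 2.0, 0.0), (0.75, 1.0, 0.75)]
    )
    def test_examples(self, broken, cas9, expected):
        assert relative_cutting_efficiency(broken, cas9) == pytest.approx(expected)

    def test_nonpositive_cas9_rejected(self):
        with pytest.raises(QuantError):
            relative_cutting_efficiency(0.5, 0.0)


class TestInVitroEfficiency:
    @pytest.mark.parametrize(
        "ct_a, ct_ref, expected", [(20, 20, 0.0), (22, 20, 0.75), (21, 20, 0.5)]
    )
    def test_examples(self, ct_a, ct_ref, expected):
        assert in_vitro_efficiency(ct_a, ct_ref).value == pytest.approx(expected)

    def test_negative_raw_value_kept_and_clamped(self):
        eff = in_vitro_efficiency(19, 20)
        assert eff.value == pytest.approx(-1.0)
        assert eff.clamped == 0.0

    def test_undetermined_target_is_complete_digestion(self):
        eff = in_vitro_efficiency(None, 20)
        assert eff.value == 1.0 and eff.complete_digestion

    def test_undetermined_reference_is_an_error(self):
        with pytest.raises(UndeterminedCtError):
            in_vitro_efficiency(20, None)

    @given(d=st.floats(-3, 6))
    @settings(max_examples=50, derandomize=True)
    def test_matches_in_vivo_closed_form(self, d):
        """In vitro and canonical in vivo estimators share one closed form."""
        invitro = in_vitro_efficiency(20 + d, 20).value
        invivo = broken_dna_abundance(20 + d, 20, 20, 20, mode="canonical")
        assert invitro == pytest.approx(invivo, abs=1e-12)


class TestNormalizeToLowest:
    @pytest.mark.parametrize(
        "effs, expected",
        [
            ({"a": 0.2, "b": 0.6, "c": 1.3}, {"a": 1.0, "b": 3.0, "c": 6.5}),
            ({"a": 0.4}, {"a": 1.0}),
            ({"a": 0.08, "b": 0.52}, {"a": 1.0, "b": 6.5}),
        ],
    )
    def test_examples(self, effs, expected):
        result = normalize_to_lowest(effs)
        assert list(result) == list(effs)  # order preserved
        for key, value in expected.items():
            assert result[key] == pytest.approx(value)

    def test_minimum_maps_to_exactly_one_even_with_ties(self):
        result = normalize_to_lowest({"a": 0.3, "b": 0.3, "c": 0.9})
        assert result["a"] == 1.0 and result["b"] == 1.0

    def test_nonpositive_rejected_with_instruction(self):
        with pytest.raises(QuantError, match="clamp"):
            normalize_to_lowest({"a": 0.0, "b": 0.5})

    def test_empty_rejected(self):
        with pytest.raises(QuantError):
            normalize_to_lowest({})


class TestCtRecord:
    def test_template_derived_from_role(self):
        rec = CtRecord("s", "t", "a", Role.CAS9_TRANSCRIPT, "test", 1, 20.0)
        assert rec.template is Template.CDNA

    def test_inconsistent_role_template_rejected(self):
        with pytest.raises(QuantError, match="requires template"):
            CtRecord(
                "s", "t", "a", Role.TARGET_REGION, "test", 1, 20.0, template="cdna"
            )

    @pytest.mark.parametrize("bad_ct", [0.0, -1.0, math.inf, math.nan])
    def test_nonpositive_or_nonfinite_ct_rejected(self, bad_ct):
        with pytest.raises(QuantError):
            CtRecord("s", "t", "a", Role.TARGET_REGION, "test", 1, bad_ct)

    def test_undetermined_is_none_not_a_number(self):
        rec = CtRecord("s", "t", "a", Role.TARGET_REGION, "test", 1, None)
        assert rec.ct is None


class TestQuantifyExperiment:
    def test_noiseless_two_targets(self):
        """ddCt 1 vs 2 at equal Cas9 gives brokens 0.5/0.75, normalized 1.0/1.5."""
        records = make_invivo_records({"t1": (1.0, 0.0), "t2": (2.0, 0.0)})
        results = {r.target_id: r for r in quantify_experiment(records)}
        assert results["t1"].broken_fraction == pytest.approx(0.5)
        assert results["t2"].broken_fraction == pytest.approx(0.75)
        assert results["t1"].normalized_efficiency == pytest.approx(1.0)
        assert results["t2"].normalized_efficiency == pytest.approx(1.5)
        assert results["t1"].is_reference and not results["t2"].is_reference

    def test_result_invariants(self):
        records = make_invivo_records({"a": (0.8, -0.5), "b": (1.7, 0.3)}, n_replicates=3)
        for r in quantify_experiment(records):
            assert r.intact_fraction == pytest.approx(2.0 ** (-r.ddct))
            assert r.intact_fraction + r.broken_fraction == pytest.approx(1.0)
            assert r.normalized_efficiency >= 1.0
            assert r.n_replicates == 3

    def test_cas9_normalisation_divides(self):
        # one extra Cas9 cycle (half the transcript) doubles the efficiency
        records = make_invivo_records({"t1": (1.0, 0.0), "t2": (1.0, 1.0)})
        results = {r.target_id: r for r in quantify_experiment(records)}
        assert results["t2"].relative_efficiency == pytest.approx(
            2 * results["t1"].relative_efficiency
        )

    def test_null_experiment_raises_normalization_error(self):
        records = make_invivo_records({"t1": (0.0, 0.0), "t2": (0.0, 0.0)})
        with pytest.raises(NormalizationError) as err:
            quantify_experiment(records)
        assert {r.target_id for r in err.value.results} == {"t1", "t2"}
        for r in err.value.results:
            assert r.broken_fraction == pytest.approx(0.0)
            assert r.normalized_efficiency is None

    def test_single_negative_target_clamped_and_flagged(self):
        records = make_invivo_records({"lo": (-0.3, 0.0), "hi": (2.0, 0.0)})
        results = {r.target_id: r for r in quantify_experiment(records)}
        assert results["lo"].clamped and not results["hi"].clamped
        assert results["lo"].normalized_efficiency == pytest.approx(1.0)

    def test_literal_mode_reports_printed_formula_value(self):
        records = make_invivo_records({"t1": (2.0, 0.0), "t2": (1.0, 0.0)})
        results = {r.target_id: r for r in quantify_experiment(records, mode="literal")}
        assert results["t1"].relative_efficiency == pytest.approx(0.25)
        assert results["t2"].relative_efficiency == pytest.approx(0.5)
        # broken_fraction stays the canonical complement either way
        assert results["t1"].broken_fraction == pytest.approx(0.75)

    def test_replicate_missing_role_dropped_with_warning(self, caplog):
        records = make_invivo_records({"t": (1.0, 0.0)}, n_replicates=3)
        records = [
            r
            for r in records
            if not (r.replicate == 2 and r.role is Role.CAS9_TRANSCRIPT)
        ]
        with caplog.at_level("WARNING"):
            (result,) = quantify_experiment(records)
        assert result.n_replicates == 2
        assert "replicate 2" in caplog.text

    def test_no_usable_targets_is_an_error(self):
        records = make_invivo_records({"t": (1.0, 0.0)})
        records = [r for r in records if r.role is not Role.CAS9_TRANSCRIPT]
        with pytest.raises(QuantError, match="no usable replicates"):
            quantify_experiment(records)

    def test_pairing_modes_agree_on_constant_controls(self):
        records = make_invivo_records({"t": (1.4, 0.2)}, n_replicates=3)
        (mean_ctrl,) = quantify_experiment(records, pairing="mean_control")
        (per_rep,) = quantify_experiment(records, pairing="per_replicate")
        assert mean_ctrl.relative_efficiency == pytest.approx(
            per_rep.relative_efficiency
        )

    def test_compare_identical_conditions_not_significant(self):
        records = make_invivo_records(
            {"t": (1.0, 0.0)}, n_replicates=3, condition="heat"
        ) + make_invivo_records({"t": (1.0, 0.0)}, n_replicates=3, condition="ctrl")
        results = quantify_experiment(records, compare=("heat", "ctrl"))
        assert all(r.p_value == pytest.approx(1.0) for r in results)


class TestStudentsT:
    def test_identical_samples_give_t_zero(self):
        t, p = students_t([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_on_regular_data(self):
        from scipy import stats

        a, b = [0.1, 0.2, 0.3], [0.4, 0.5, 0.7]
        t, p = students_t(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(float(t_ref)) and p == pytest.approx(float(p_ref))


class TestQuantifyInvitro:
    def test_round_trip_aggregation(self):
        records = []
        for rep, (ct_a, ct_ref) in enumerate([(22.0, 20.0), (22.0, 20.0)], start=1):
            records += [
                CtRecord("s", "t1", "a", Role.INVITRO_TARGET, "test", rep, ct_a),
                CtRecord("s", "t1", "r", Role.INVITRO_REFERENCE, "test", rep, ct_ref),
            ]
        (res,) = quantify_invitro(records)
        assert res.efficiency == pytest.approx(0.75)
        assert res.n_replicates == 2 and res.sd == 0.0

    def test_undetermined_target_flags_complete_digestion(self):
        records = [
            CtRecord("s", "t1", "a", Role.INVITRO_TARGET, "test", 1, None),
            CtRecord("s", "t1", "r", Role.INVITRO_REFERENCE, "test", 1, 20.0),
        ]
        (res,) = quantify_invitro(records)
        assert res.efficiency == 1.0 and res.complete_digestion
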