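"""Amino-acid isotope metrics: worked values, identities and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csiaa import (AminoAcidSample, DomainError, SigmaVClass,
                   UndefinedResultError, classify_sigma_v, compute_metrics,
                   epsilon_to_glu, group_amino_acids, phe_normalize, sigma_v,
                   thaa_weighted, tp_metazoan, tp_protozoan)
from csiaa.amino_acids import SIGMA_V_AA


def _sample(d15n, mol_pct=None, d13c=None):
    return AminoAcidSample("S", "MB", "E1", 5.0, "suspended",
                           d15n=d15n, mol_pct=mol_pct, d13c=d13c)


class TestGrouping:
    def test_full_panel_grouping(self, full_sample):
        trophic, source, other = group_amino_acids(full_sample)
        assert trophic == {"Ala", "Val", "Leu", "Ile", "Pro", "Asp", "Glu"}
        assert source == {"Ser", "Phe", "Lys", "Tyr"}
        assert other == {"Gly", "Thr"}

    @pytest.mark.parametrize("codes, expected", [
        ({"Phe"}, (set(), {"Phe"}, set())),
        ({"Gly"}, (set(), set(), {"Gly"})),
        ({"Glu", "Thr"}, ({"Glu"}, set(), {"Thr"})),
    ])
    def test_partial_panels(self, codes, expected):
        assert group_amino_acids(_sample({aa: 10.0 for aa in codes})) == expected


class TestTrophicPosition:
    @pytest.mark.parametrize("glu, phe, expected", [
        (26.3, 16.2, 1.8815789473684212),   # rounds to the published 1.9
        (10.0, 6.6, 1.0),                   # primary-producer identity
        (14.4, 3.4, 2.0),                   # exactly one trophic step
    ])
    def test_metazoan(self, glu, phe, expected):
        assert tp_metazoan(glu, phe) == pytest.approx(expected, abs=1e-12)

    def test_metazoan_published_rounding(self):
        assert round(tp_metazoan(26.3, 16.2), 1) == 1.9

    @pytest.mark.parametrize("ala, phe, expected", [
        (22.6, 15.1, 1.9555555555555557),
        (13.2, 10.0, 1.0),
        (17.7, 10.0, 2.0),
    ])
    def test_protozoan(self, ala, phe, expected):
        assert tp_protozoan(ala, phe) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("fn", [tp_metazoan, tp_protozoan])
    def test_nonfinite_rejected(self, fn):
        with pytest.raises(DomainError):
            fn(float("nan"), 10.0)

    @given(delta=st.floats(-20, 20), shift=st.floats(-30, 30))
    @settings(max_examples=50, derandomize=True)
    def test_translation_invariance(self, delta, shift):
        base = tp_metazoan(10.0 + delta, 10.0)
        assert tp_metazoan(10.0 + delta + shift, 10.0 + shift) == pytest.approx(base, abs=1e-9)


class TestSigmaV:
    def test_no_dispersion_is_zero(self):
        assert sigma_v({aa: 14.0 for aa in SIGMA_V_AA}) == 0.0

    def test_symmetric_two_point(self):
        assert sigma_v({"Ala": 20.0, "Val": 22.0}, min_aa=2) == 1.0

    def test_seven_aa_worked_value(self):
        values = dict(zip(sorted(SIGMA_V_AA), [24.8, 19.4, 21.0, 26.3, 19.1, 17.9, 23.0]))
        # hand oracle: mean 21.642857..., Σ|dev| = 18.342857...
        vals = list(values.values())
        mean = sum(vals) / 7
        expected = sum(abs(v - mean) for v in vals) / 7
        assert sigma_v(values) == pytest.approx(expected, abs=1e-12)
        assert sigma_v(values) == pytest.approx(2.62, abs=0.005)

    def test_too_few_amino_acids_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            sigma_v({"Ala": 20.0, "Val": 22.0}, min_aa=3)

    def test_non_trophic_amino_acids_ignored(self):
        base = {aa: v for aa, v in zip(sorted(SIGMA_V_AA), range(10, 17))}
        with_src = dict(base, Phe=40.0, Gly=-20.0)
        assert sigma_v(with_src) == sigma_v(base)

    @given(shift=st.floats(-20, 20), scale=st.floats(0.1, 5))
    @settings(max_examples=50, derandomize=True)
    def test_affine_behaviour(self, shift, scale):
        values = dict(zip(sorted(SIGMA_V_AA), [24.8, 19.4, 21.0, 26.3, 19.1, 17.9, 23.0]))
        base = sigma_v(values)
        shifted = {aa: shift + scale * v for aa, v in values.items()}
        assert sigma_v(shifted) == pytest.approx(scale * base, rel=1e-9)

    @pytest.mark.parametrize("value, expected", [
        (0.5, SigmaVClass.NON_DEGRADED),
        (0.999, SigmaVClass.NON_DEGRADED),
        (1.0, SigmaVClass.METAZOAN_RESYNTHESIS),    # closed interval boundary
        (2.0, SigmaVClass.METAZOAN_RESYNTHESIS),
        (2.3, SigmaVClass.MICROBIAL_RESYNTHESIS),
    ])
    def test_classification_thresholds(self, value, expected):
        assert classify_sigma_v(value) is expected

    def test_negative_sigma_v_rejected(self):
        with pytest.raises(DomainError):
            classify_sigma_v(-0.1)

    def test_classify_matches_brute_force_on_random_panels(self, rng):
        for _ in range(200):
            values = dict(zip(sorted(SIGMA_V_AA), rng.uniform(5, 30, 7)))
            v = sigma_v(values)
            raw = np.array(list(values.values()))
            brute = np.mean(np.abs(raw - raw.mean()))
            assert v == pytest.approx(brute, rel=1e-12)
            expected = (SigmaVClass.NON_DEGRADED if brute < 1
                        else SigmaVClass.METAZOAN_RESYNTHESIS if brute <= 2
                        else SigmaVClass.MICROBIAL_RESYNTHESIS)
            assert classify_sigma_v(v) is expected


class TestThaa:
    @pytest.mark.parametrize("d15n, mol, expected", [
        ({"Glu": 12.0}, {"Glu": 100.0}, 12.0),
        ({"Glu": 10.0, "Phe": 20.0}, {"Glu": 50.0, "Phe": 50.0}, 15.0),
        ({"Glu": 25.0, "Phe": 15.0, "Gly": 11.0},
         {"Glu": 40.0, "Phe": 35.0, "Gly": 25.0}, 18.0),
    ])
    def test_weighted_mean(self, d15n, mol, expected):
        assert thaa_weighted(_sample(d15n, mol)) == pytest.approx(expected, abs=1e-12)

    def test_renormalizes_over_available_panel(self):
        # mol% covers three amino acids but δ¹⁵N only two: weights renormalize
        s = _sample({"Glu": 10.0, "Phe": 20.0},
                    mol_pct={"Glu": 30.0, "Phe": 30.0, "Gly": 40.0})
        assert thaa_weighted(s) == pytest.approx(15.0)

    def test_missing_mol_pct_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            thaa_weighted(_sample({"Glu": 10.0}))

    def test_d13c_variant(self):
        s = _sample({"Glu": 10.0}, mol_pct={"Glu": 50.0, "Phe": 50.0},
                    d13c={"Glu": -20.0, "Phe": -24.0})
        assert thaa_weighted(s, "d13C") == pytest.approx(-22.0)


class TestNormalizations:
    def test_phe_normalize(self):
        out = phe_normalize({"Phe": 15.1, "Ala": 22.6})
        assert out["Phe"] == 0.0
        assert out["Ala"] == pytest.approx(7.5)

    def test_phe_alone(self):
        assert phe_normalize({"Phe": -3.7}) == {"Phe": 0.0}

    def test_phe_absent_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            phe_normalize({"Ala": 22.6})

    @given(shift=st.floats(-25, 25))
    @settings(max_examples=50, derandomize=True)
    def test_phe_translation_invariance(self, shift):
        base = {"Phe": 15.1, "Ala": 22.6, "Thr": 8.8}
        out0 = phe_normalize(base)
        out1 = phe_normalize({aa: v + shift for aa, v in base.items()})
        for aa in base:
            assert out1[aa] == pytest.approx(out0[aa], abs=1e-9)

    def test_epsilon_to_glu(self):
        out = epsilon_to_glu({"Glu": 23.0, "Gly": 11.4, "Ser": 11.3})
        assert out["Glu"] == 0.0
        assert out["Gly"] == pytest.approx(-11.6)
        assert out["Ser"] == pytest.approx(-11.7)

    def test_glu_absent_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            epsilon_to_glu({"Ala": 22.6})


class TestComputeMetrics:
    def test_full_sample_all_defined(self, full_sample):
        res = compute_metrics(full_sample)
        assert res.tp_metazoan == pytest.approx(tp_metazoan(26.3, 16.2))
        assert res.tp_protozoan is not None
        assert res.sigma_v is not None and res.sigma_v_n == 7
        assert res.sigma_v_class is not None
        assert res.d15n_thaa is not None
        assert res.phe_normalized["Phe"] == 0.0
        assert res.epsilon_to_glu["Glu"] == 0.0

    def test_partial_sample_leaves_undefined_as_none(self):
        res = compute_metrics(_sample({"Gly": 10.0}))
        assert res.tp_metazoan is None
        assert res.sigma_v is None
        assert res.phe_normalized == {}

    def test_pristine_panels_classify_non_degraded(self, rng):
        """Producer-like panels at measurement-noise dispersion stay below ΣV = 1."""
        draws = rng.normal(14.0, 0.3, size=(1000, 7))
        count = sum(sigma_v(dict(zip(sorted(SIGMA_V_AA), row))) < 1.0 for row in draws)
        assert count >= 990
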