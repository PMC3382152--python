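import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from carboxmeta import fermentation as ferm
from carboxmeta import synthetic as syn


class TestVolatileSolids:
    def test_difference(self):
        assert ferm.volatile_solids(50.0, 10.0) == 40.0

    def test_all_ash(self):
        assert ferm.volatile_solids(10.0, 10.0) == 0.0

    @pytest.mark.parametrize("args", [(-1.0, 0.0), (5.0, -1.0), (5.0, 6.0)])
    def test_invalid_masses_rejected(self, args):
        with pytest.raises(ValueError):
            ferm.volatile_solids(*args)


def _batch(vs_loaded=40.0, vs_remaining=24.0, acids=8.0, volume=1.0, days=1.0):
    return ferm.FermentationBatch(
        "r1",
        oven_dry_g=5.0 + vs_remaining,
        ashed_g=5.0,
        vs_loaded_g=vs_loaded,
        acid_masses_g={"acetic": acids},
        liquid_volume_L=volume,
        duration_d=days,
    )


class TestPerformance:
    def test_forced_arithmetic(self):
        m = ferm.performance(_batch())
        assert m.conversion == pytest.approx(0.40)
        assert m.selectivity == pytest.approx(0.50)
        assert m.yield_ == pytest.approx(0.20)
        assert m.yield_ == pytest.approx(m.conversion * m.selectivity, abs=1e-12)

    def test_zero_acids(self):
        m = ferm.performance(_batch(acids=0.0))
        assert m.selectivity == 0.0 and m.yield_ == 0.0

    def test_zero_digestion_with_acids_flags_inconsistency(self):
        with pytest.warns(UserWarning):
            m = ferm.performance(_batch(vs_remaining=40.0, acids=2.0))
        assert m.selectivity is None and m.inconsistent

    def test_productivity_units(self):
        m = ferm.performance(_batch(acids=8.0, volume=0.4, days=16.0))
        assert m.productivity == pytest.approx(8.0 / (0.4 * 16.0))

    @settings(deadline=None, max_examples=1000)
    @given(
        vs_loaded=st.floats(1.0, 100.0),
        digested_frac=st.floats(0.01, 1.0),
        acids=st.floats(0.0, 50.0),
    )
    def test_yield_identity_on_random_batches(self, vs_loaded, digested_frac, acids):
        remaining = vs_loaded * (1.0 - digested_frac)
        m = ferm.performance(_batch(vs_loaded, remaining, acids))
        assert m.selectivity is not None
        assert abs(m.yield_ - m.conversion * m.selectivity) < 1e-12


class TestProductSpectrum:
    THERMO = {"acetic": 58.69, "propionic": 1.38, "butyric": 39.52, "valeric": 0.42, "caproic": 0.0}

    def _masses(self, pcts, replicate="r1", scale=0.08):
        return pd.DataFrame(
            [(replicate, acid, pct * scale) for acid, pct in pcts.items()],
            columns=["replicate", "acid", "mass_g"],
        )

    def test_single_replicate_percentages_match_masses(self):
        spectrum = ferm.product_spectrum(self._masses(self.THERMO))
        row = spectrum.per_replicate.iloc[0]
        total = sum(self.THERMO.values())
        for acid, chain in [("acetic", "C2"), ("propionic", "C3"), ("butyric", "C4"), ("valeric", "C5")]:
            assert row[chain] == pytest.approx(100 * self.THERMO[acid] / total, abs=1e-9)

    def test_undetected_acid_marked_nd(self):
        spectrum = ferm.product_spectrum(self._masses(self.THERMO))
        assert "C6" in spectrum.not_detected
        table = ferm.spectrum_table(spectrum).set_index("chain")
        assert table.loc["C6", "display"] == "ND"

    def test_isomers_summed_into_chain_class(self):
        masses = pd.DataFrame(
            [("r1", "butyric", 1.0), ("r1", "isobutyric", 1.0), ("r1", "acetic", 2.0)],
            columns=["replicate", "acid", "mass_g"],
        )
        spectrum = ferm.product_spectrum(masses)
        assert spectrum.per_replicate.iloc[0]["C4"] == pytest.approx(50.0)

    def test_scale_invariance(self):
        a = ferm.product_spectrum(self._masses(self.THERMO, scale=0.08))
        b = ferm.product_spectrum(self._masses(self.THERMO, scale=8.0))
        pd.testing.assert_frame_equal(a.per_replicate, b.per_replicate)

    def test_zero_total_replicate_rejected(self):
        masses = pd.DataFrame([("r1", "acetic", 0.0)], columns=["replicate", "acid", "mass_g"])
        with pytest.raises(ValueError):
            ferm.product_spectrum(masses)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            (f"r{r}", acid, float(m))
            for r in range(3)
            for acid, m in zip(ferm.ACID_CHAIN, rng.uniform(0.01, 5.0, len(ferm.ACID_CHAIN)))
        ]
        spectrum = ferm.product_spectrum(pd.DataFrame(rows, columns=["replicate", "acid", "mass_g"]))
        assert np.allclose(spectrum.per_replicate.sum(axis=1), 100.0, atol=0.05)

    def test_se_is_sample_sd_over_sqrt_n(self):
        out = syn.generate_fermentation_replicates(syn.mesophilic_spectrum_spec(1))
        spectrum = ferm.product_spectrum(out.measurements[["replicate", "acid", "mass_g"]])
        manual = spectrum.per_replicate["C3"].std(ddof=1) / math.sqrt(3)
        assert spectrum.se["C3"] == pytest.approx(manual)


class TestCompareSpectra:
    def _spectrum(self, wide):
        df = pd.DataFrame(wide, columns=ferm.CHAIN_ORDER)
        mean = df.mean()
        se = df.std(ddof=1) / math.sqrt(len(df))
        return ferm.ProductSpectrum(df, mean, se, frozenset())

    def test_identical_spectra_p_one_same_letter(self):
        s = self._spectrum([[50, 10, 30, 5, 5], [52, 9, 29, 5, 5], [51, 11, 28, 5, 5]])
        out = ferm.compare_spectra(s, s, mode="paired")
        assert (out["p"] == 1.0).all()
        assert (out["letter_a"] == out["letter_b"]).all()

    def test_summary_mode_propionic_style_comparison(self):
        a = {c: (12.81, 2.06, 3) for c in ["C3"]}
        b = {c: (1.38, 0.69, 3) for c in ["C3"]}
        out = ferm.compare_spectra(a, b, mode="welch_from_summary")
        assert out.loc[0, "p"] < 0.05
        assert out.loc[0, "letter_b"] == "b"

    def test_paired_mode_matches_one_sample_t_oracle(self):
        rng = np.random.default_rng(8)
        base = np.array([[50, 10, 30, 5, 5]] * 4, dtype=float)
        noise = rng.normal(0, 0.5, size=base.shape)
        a = self._spectrum(base + noise)
        b = self._spectrum(base)
        out = ferm.compare_spectra(a, b, mode="paired").set_index("chain")
        for i, chain in enumerate(ferm.CHAIN_ORDER):
            diff = (base + noise)[:, i] - base[:, i]
            t = diff.mean() / (diff.std(ddof=1) / math.sqrt(len(diff)))
            p = 2 * stats.t.sf(abs(t), df=len(diff) - 1)
            assert out.loc[chain, "p"] == pytest.approx(p, abs=1e-12)

    def test_paired_mode_unequal_n_rejected(self):
        a = self._spectrum([[50, 10, 30, 5, 5]] * 3)
        b = self._spectrum([[50, 10, 30, 5, 5]] * 2)
        with pytest.raises(ValueError):
            ferm.compare_spectra(a, b, mode="paired")

    def test_welch_replicate_mode_agrees_with_scipy(self):
        a = self._spectrum([[50, 10, 30, 5, 5], [55, 12, 25, 4, 4], [52, 11, 28, 5, 4]])
        b = self._spectrum([[60, 2, 33, 3, 2], [58, 1, 36, 3, 2], [59, 2, 34, 3, 2]])
        out = ferm.compare_spectra(a, b, mode="welch_from_replicates").set_index("chain")
        p = stats.ttest_ind(
            a.per_replicate["C3"], b.per_replicate["C3"], equal_var=False
        ).pvalue
        assert out.loc["C3", "p"] == pytest.approx(float(p), abs=1e-12)


class TestAcidChainClass:
    @pytest.mark.parametrize(
        "name,chain",
        [("acetic", "C2"), ("Propionic", "C3"), ("n-butyric", "C4"),
         ("isovaleric", "C5"), ("caproic acid", "C6"), ("C4", "C4")],
    )
    def test_names_collapse(self, name, chain):
        assert ferm.acid_chain_class(name) == chain

    def test_unknown_acid_rejected(self):
        with pytest.raises(ValueError):
            ferm.acid_chain_class("oxalic")
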