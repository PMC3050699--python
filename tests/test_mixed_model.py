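import math

import numpy as np
import pandas as pd
import pytest

from gmoequiv.mixed_model import (
    VarianceComponents,
    balanced_anova_fit,
    balanced_contrasts,
    balanced_sed,
    fit_model,
    wald_test_gxe,
)
from gmoequiv.simulation import (
    DEFAULT_VC,
    SimulationSpec,
    _batch_statistics,
    _simulate_responses,
    generate_trial,
    generate_trial_from_design,
    example_field_design,
)
from gmoequiv.trial_data import AnalyteDataset, DesignSummary


class TestBalancedSed:
    design = DesignSummary(8, 4, 6, True, {})

    def test_gr2_hand_value(self):
        vc = VarianceComponents(0.0029, 0.0008, 0.0127, 0.0073)
        assert balanced_sed(vc, self.design, "GR", 2) == pytest.approx(
            0.12281, abs=1e-5
        )

    def test_gc1_hand_value(self):
        vc = VarianceComponents(0.0, 0.0, 0.0127, 0.0073)
        assert balanced_sed(vc, self.design, "GC", 1) == pytest.approx(
            math.sqrt(2 * 0.0073 / 32), abs=1e-6
        )

    def test_zero_genotype_variance_collapses_variants(self):
        vc = VarianceComponents(0.001, 0.001, 0.0, 0.0073)
        for contrast in ("GC", "GR"):
            assert balanced_sed(vc, self.design, contrast, 1) == pytest.approx(
                balanced_sed(vc, self.design, contrast, 2)
            )

    def test_refuses_unbalanced(self):
        design = DesignSummary(4, 3, 13, False, {})
        with pytest.raises(ValueError, match="balanced"):
            balanced_sed(DEFAULT_VC, design, "GC", 1)


class TestRemlFit:
    def test_constant_response(self):
        ds = generate_trial(SimulationSpec(seed=1), 0)
        ds.data["y"] = 3.14
        fit = fit_model(ds, 1)
        assert fit.vc.as_tuple() == (0.0, 0.0, 0.0, 0.0)
        assert fit.m_c == fit.m_g == fit.m_r == pytest.approx(3.14)

    def test_variants_share_means_and_components(self, balanced_fits):
        f1, f2 = balanced_fits
        assert f1.m_c == pytest.approx(f2.m_c, abs=1e-10)
        assert f1.m_g == pytest.approx(f2.m_g, abs=1e-10)
        assert f1.m_r == pytest.approx(f2.m_r, abs=1e-10)
        assert np.allclose(f1.vc.as_tuple(), f2.vc.as_tuple(), atol=1e-10)

    def test_sed_relation_identities(self, balanced_fits):
        f1, f2 = balanced_fits
        vg = f1.vc.genotype
        assert f2.contrasts["GC"].sed ** 2 - f1.contrasts["GC"].sed ** 2 == (
            pytest.approx(2 * vg, abs=1e-8)
        )
        assert f2.contrasts["GR"].sed ** 2 - f1.contrasts["GR"].sed ** 2 == (
            pytest.approx(vg, abs=1e-8)
        )

    def test_sed_relation_identities_unbalanced(self, unbalanced_fits):
        # the aliasing argument is layout-free, so the identity is exact
        # on unbalanced data too
        f1, f2 = unbalanced_fits
        vg = f1.vc.genotype
        assert f2.contrasts["GR"].sed ** 2 - f1.contrasts["GR"].sed ** 2 == (
            pytest.approx(vg, abs=1e-8)
        )

    def test_reml_matches_balanced_anova(self, balanced_dataset, balanced_fits):
        f1, _ = balanced_fits
        an = balanced_anova_fit(balanced_dataset)
        assert np.allclose(f1.vc.as_tuple(), an.vc.as_tuple(), atol=1e-6)
        for variant, fit in zip((1, 2), balanced_fits):
            closed = balanced_contrasts(an, variant)
            for label in ("GC", "GR"):
                assert fit.contrasts[label].sed == pytest.approx(
                    closed[label].sed, abs=1e-6
                )
                assert fit.contrasts[label].estimate == pytest.approx(
                    closed[label].estimate, abs=1e-8
                )

    def test_generic_sed_matches_closed_form(self, balanced_dataset, balanced_fits):
        for variant, fit in zip((1, 2), balanced_fits):
            for label in ("GC", "GR"):
                assert fit.contrasts[label].sed == pytest.approx(
                    balanced_sed(fit.vc, balanced_dataset.design, label, variant),
                    abs=1e-6,
                )

    def test_invariance_to_relabeling_and_shift(self, balanced_dataset):
        base = fit_model(balanced_dataset, 1)
        # relabel reference genotypes
        perm = {f"ref{i+1}": f"ref{(i+3) % 6 + 1}" for i in range(6)}
        ds2 = AnalyteDataset(
            analyte=balanced_dataset.analyte,
            data=balanced_dataset.data.assign(
                genotype=balanced_dataset.data["genotype"].replace(perm)
            ),
            exclusions=balanced_dataset.exclusions,
            design=balanced_dataset.design,
            transform="ln",
        )
        f2 = fit_model(ds2, 1)
        assert f2.contrasts["GC"].sed == pytest.approx(base.contrasts["GC"].sed, rel=1e-8)
        assert f2.contrasts["GR"].df == pytest.approx(base.contrasts["GR"].df, rel=1e-6)
        # add a constant
        ds3 = AnalyteDataset(
            analyte=balanced_dataset.analyte,
            data=balanced_dataset.data.assign(y=balanced_dataset.data["y"] + 5.0),
            exclusions=balanced_dataset.exclusions,
            design=balanced_dataset.design,
            transform="ln",
        )
        f3 = fit_model(ds3, 1)
        assert f3.m_g - base.m_g == pytest.approx(5.0, abs=1e-8)
        assert f3.contrasts["GC"].estimate == pytest.approx(
            base.contrasts["GC"].estimate, abs=1e-8
        )
        assert f3.contrasts["GC"].sed == pytest.approx(base.contrasts["GC"].sed, rel=1e-8)

    def test_parameter_recovery_on_average(self):
        # 500 balanced trials through the closed-form path (identical to
        # REML on balanced data): mean estimates near the generating values
        spec = SimulationSpec(seed=4242, n_iter=500)
        rng = np.random.Generator(np.random.Philox(key=[spec.seed, 7]))
        y = _simulate_responses(spec, rng, 500)
        *_, ms_gen, ms_res, df_res = _batch_statistics(spec, y)
        vg = np.maximum((ms_gen - ms_res) / 32.0, 0.0)
        assert vg.mean() == pytest.approx(0.0127, rel=0.10)
        assert ms_res.mean() == pytest.approx(0.0073, rel=0.10)


class TestDegreesOfFreedom:
    def test_gc1_df_is_residual_dominated(self, balanced_fits):
        f1, _ = balanced_fits
        assert f1.contrasts["GC"].df == pytest.approx(217.0, abs=0.5)

    def test_gc1_df_on_example_layout(self, unbalanced_fits):
        # four-site, 67-plot layout: residual-dominated df in the 30-60 range
        f1, _ = unbalanced_fits
        assert 30.0 <= f1.contrasts["GC"].df <= 60.0

    def test_gr2_df_is_genotype_dominated(self, balanced_fits):
        _, f2 = balanced_fits
        assert f2.contrasts["GR"].df == pytest.approx(5.0, abs=0.2)

    def test_satterthwaite_close_to_kr_here(self, balanced_dataset):
        fs = fit_model(balanced_dataset, 1, df_method="satterthwaite")
        fk = fit_model(balanced_dataset, 1)
        assert fs.contrasts["GR"].df == pytest.approx(fk.contrasts["GR"].df, rel=0.05)

    def test_single_variance_model_recovers_residual_df(self):
        # pure residual-error model: the small-sample df is the classical
        # residual df, exactly
        from gmoequiv.mixed_model import _kr_df_and_vcov

        rng = np.random.default_rng(3)
        n, X = 24, np.column_stack([np.ones(24), rng.normal(size=24)])
        V = 2.0 * np.eye(n)
        df, _ = _kr_df_and_vcov(V, X, [np.eye(n)], np.array([0.0, 1.0]))
        assert df == pytest.approx(n - 2, abs=1e-6)

    def test_all_structural_variances_zero_gives_classical_df(self):
        # site/block/genotype all generated (and estimated) at zero: the
        # contrast df is the classical residual df of the site+block+group
        # analysis of variance, 256 - 3 - 7 - 24 = 222
        spec = SimulationSpec(
            seed=77, vc=VarianceComponents(0.0, 0.0, 0.0, 0.01)
        )
        ds = generate_trial(spec, 0)
        fit = fit_model(ds, 1)
        assert fit.degenerate_vg
        assert fit.contrasts["GC"].df == pytest.approx(222.0, abs=0.5)

    def test_boundary_vg_inflates_gr2_df(self):
        # with no observable genotype variation the reduced model assigns
        # residual-order dfs to the GMO-vs-reference contrast
        spec = SimulationSpec(seed=91, vc=VarianceComponents(0.002, 0.001, 0.0, 0.008))
        ds = generate_trial(spec, 2)
        f2 = fit_model(ds, 2)
        assert f2.degenerate_vg
        assert f2.contrasts["GR"].df > 30.0


class TestWaldGxE:
    small = SimulationSpec(n_sites=4, n_blocks=2, n_ref=4, seed=99)

    def test_size_calibration(self):
        n, rej = 250, 0
        for i in range(n):
            rej += wald_test_gxe(generate_trial(self.small, i)) < 0.05
        # nominal 0.05; chi-square Wald runs slightly liberal in small samples
        assert 0.02 <= rej / n <= 0.105

    def test_power_against_injected_interaction(self):
        ds = generate_trial(self.small, 0)
        d = ds.data.copy()
        shift = {"S1": 0.5, "S2": -0.5, "S3": 0.5, "S4": -0.5}
        mask = d["group"] == "gmo"
        d.loc[mask, "y"] += d.loc[mask, "site"].map(shift)
        ds2 = AnalyteDataset(ds.analyte, d, ds.exclusions, ds.design, "ln")
        assert wald_test_gxe(ds2) < 0.001

    def test_constant_response(self):
        ds = generate_trial(self.small, 0)
        ds.data["y"] = 1.0
        assert wald_test_gxe(ds) == 1.0

    def test_single_site_not_applicable(self):
        ds = generate_trial(self.small, 0)
        sub = ds.data[ds.data["site"] == "S1"].reset_index(drop=True)
        ds1 = AnalyteDataset(ds.analyte, sub, ds.exclusions, ds.design, "ln")
        with pytest.raises(ValueError, match="two sites"):
            wald_test_gxe(ds1)
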