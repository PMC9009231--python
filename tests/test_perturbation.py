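import math

import numpy as np
import pytest

import kinflux as kf
from kinflux.gpr import UNLIMITED
from kinflux.perturbation import PerturbationSpec


@pytest.fixture(scope="module")
def toy_context():
    model, kcats, expression = kf.make_toy_model(kf.ToySpec(seed=1))
    ratios = kf.toy_ratio_table()
    abundance = kf.estimate_enzyme_abundance(expression.to_dict(), ratios)
    context = kf.reaction_vmax(model, abundance, kcats)
    return model, kcats, abundance, context


class TestSpecValidation:
    def test_inhibit_needs_strength_in_unit_interval(self):
        with pytest.raises(ValueError):
            PerturbationSpec(targets=("FERM",), mode="inhibit")
        with pytest.raises(ValueError):
            PerturbationSpec(targets=("FERM",), mode="inhibit", strength=1.5)

    def test_activate_needs_nonnegative_fold(self):
        with pytest.raises(ValueError):
            PerturbationSpec(targets=("FERM",), mode="activate", fold=-1.0)

    def test_knockin_needs_vmax(self):
        with pytest.raises(ValueError):
            PerturbationSpec(targets=("NEW",), mode="knockin")

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec(targets=(), mode="knockout")


class TestKnockout:
    def test_isozyme_knockout_reduces_but_keeps_vmax(self, toy_context):
        model, kcats, abundance, context = toy_context
        spec = PerturbationSpec(targets=("g_ferm2",), mode="knockout")
        ctx, _ = kf.perturb_context(context, model, spec, kcats)
        # FERM has GPR "g_ferm1 or g_ferm2": knocking out one isozyme
        # leaves Vmax = kcat * 60 * E(g_ferm1) * 1e-6
        expected = 300.0 * 60.0 * abundance["g_ferm1"] * 1e-6
        assert math.isclose(ctx.vmax["FERM"], expected)
        assert 0 < ctx.vmax["FERM"] < context.vmax["FERM"]

    def test_double_isozyme_knockout_silences_reaction(self, toy_context):
        model, kcats, _, context = toy_context
        spec = PerturbationSpec(targets=("g_ferm1", "g_ferm2"), mode="knockout")
        ctx, _ = kf.perturb_context(context, model, spec, kcats)
        assert ctx.vmax["FERM"] == 0.0

    def test_respiration_knockout_forces_fermentation(self, toy_context):
        model, kcats, _, context = toy_context
        base = kf.fba(kf.apply_kinetic_bounds(model, context)).objective_value
        spec = PerturbationSpec(targets=("g_resp1",), mode="knockout")
        ctx, _ = kf.perturb_context(context, model, spec, kcats)
        knocked = kf.fba(kf.apply_kinetic_bounds(model, ctx)).objective_value
        assert knocked < base
        # with respiration silenced ATP comes only through fermentation,
        # itself capped by the FERM Vmax
        ferm_cap = ctx.vmax["FERM"]
        assert knocked <= 2.0 * min(10.0, ferm_cap) + 1e-9

    def test_unknown_gene_raises(self, toy_context):
        model, kcats, _, context = toy_context
        spec = PerturbationSpec(targets=("g_nope",), mode="knockout")
        with pytest.raises(KeyError, match="g_nope"):
            kf.perturb_context(context, model, spec, kcats)

    def test_requires_kcat_table(self, toy_context):
        model, _, _, context = toy_context
        spec = PerturbationSpec(targets=("g_resp1",), mode="knockout")
        with pytest.raises(ValueError, match="Kcat"):
            kf.perturb_context(context, model, spec, kcats=None)


class TestInhibitActivate:
    def test_inhibition_scales_vmax(self, toy_context):
        model, kcats, _, context = toy_context
        spec = PerturbationSpec(targets=("FERM",), mode="inhibit", strength=0.25)
        ctx, _ = kf.perturb_context(context, model, spec)
        assert math.isclose(ctx.vmax["FERM"], 0.75 * context.vmax["FERM"])

    def test_full_inhibition_is_zero(self, toy_context):
        model, kcats, _, context = toy_context
        spec = PerturbationSpec(targets=("FERM",), mode="inhibit", strength=1.0)
        ctx, _ = kf.perturb_context(context, model, spec)
        assert ctx.vmax["FERM"] == 0.0

    def test_zero_inhibition_is_identity(self, toy_context):
        model, kcats, _, context = toy_context
        spec = PerturbationSpec(targets=("FERM",), mode="inhibit", strength=0.0)
        ctx, _ = kf.perturb_context(context, model, spec)
        assert ctx.vmax == context.vmax

    def test_objective_monotone_in_inhibition_strength(self, toy_context):
        model, kcats, _, context = toy_context
        values = []
        for s in (0.0, 0.3, 0.6, 0.9, 1.0):
            spec = PerturbationSpec(targets=("RESP",), mode="inhibit", strength=s)
            ctx, _ = kf.perturb_context(context, model, spec)
            values.append(kf.fba(kf.apply_kinetic_bounds(model, ctx)).objective_value)
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_activation_multiplies_finite_caps_only(self, toy_context):
        model, kcats, _, context = toy_context
        spec = PerturbationSpec(targets=("FERM", "GLCt"), mode="activate", fold=2.0)
        ctx, _ = kf.perturb_context(context, model, spec)
        assert math.isclose(ctx.vmax["FERM"], 2.0 * context.vmax["FERM"])
        assert ctx.vmax["GLCt"] == UNLIMITED  # no kcat -> unlimited stays so

    def test_whitelisted_reaction_untouched(self, toy_context):
        model, kcats, _, context = toy_context
        spec = PerturbationSpec(targets=("FERM",), mode="inhibit", strength=0.5)
        ctx, _ = kf.perturb_context(context, model, spec, whitelist={"FERM"})
        assert ctx.vmax["FERM"] == context.vmax["FERM"]


class TestKnockin:
    def test_reset_existing_reaction(self, toy_context):
        model, kcats, _, context = toy_context
        spec = PerturbationSpec(targets=("FERM",), mode="knockin", vmax=42.0)
        ctx, mdl = kf.perturb_context(context, model, spec)
        assert ctx.vmax["FERM"] == 42.0
        assert mdl is model

    def test_insert_new_reaction(self, toy_context):
        from cobra import Reaction

        model, kcats, _, context = toy_context
        rxn = Reaction("BYPASS")
        rxn.add_metabolites({
            model.metabolites.get_by_id("glc_c"): -1,
            model.metabolites.get_by_id("atp_c"): 5,
        })
        rxn.bounds = (0, 1000)
        spec = PerturbationSpec(
            targets=("BYPASS",), mode="knockin", vmax=1.0, insert=(rxn,)
        )
        ctx, mdl = kf.perturb_context(context, model, spec)
        assert "BYPASS" in [r.id for r in mdl.reactions]
        assert "BYPASS" not in [r.id for r in model.reactions]  # original intact
        assert ctx.vmax["BYPASS"] == 1.0

    def test_missing_insert_object_raises(self, toy_context):
        model, kcats, _, context = toy_context
        spec = PerturbationSpec(targets=("NEW",), mode="knockin", vmax=1.0)
        with pytest.raises(KeyError, match="NEW"):
            kf.perturb_context(context, model, spec)


class TestScreen:
    def test_single_gene_screen_shape_and_order(self, toy_context):
        model, kcats, _, context = toy_context
        genes = ["g_resp1", "g_ferm1", "g_ferm2"]
        table = kf.screen(context, model, genes, "ATPM", kcats)
        assert list(table.index) == sorted(genes)
        assert set(table.columns) >= {
            "objective_value", "absolute_change", "relative_change", "infeasible"
        }
        assert not table["infeasible"].any()
        # every knockout can only lower a maximisation objective
        assert (table["absolute_change"] <= 1e-9).all()

    def test_pairwise_screen(self, toy_context):
        model, kcats, _, context = toy_context
        genes = ["g_ferm1", "g_ferm2", "g_resp1"]
        table = kf.screen(context, model, genes, "ATPM", kcats, pairs=True)
        assert len(table) == 3  # C(3, 2)
        # knocking out both fermentation isozymes leaves respiration only
        both = table.loc["g_ferm1+g_ferm2", "objective_value"]
        single = kf.screen(context, model, ["g_ferm1"], "ATPM", kcats).loc[
            "g_ferm1", "objective_value"
        ]
        assert both <= single + 1e-9

    def test_deterministic(self, toy_context):
        model, kcats, _, context = toy_context
        genes = ["g_resp1", "g_ferm1"]
        a = kf.screen(context, model, genes, "ATPM", kcats)
        b = kf.screen(context, model, genes, "ATPM", kcats)
        assert a.equals(b)

    def test_unknown_gene_rejected(self, toy_context):
        model, kcats, _, context = toy_context
        with pytest.raises(KeyError):
            kf.screen(context, model, ["g_nope"], "ATPM", kcats)
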