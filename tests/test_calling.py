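import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from interactome_kit.calling import (
    EbayesFit,
    QuantTable,
    adjust_bh,
    call_interactome,
    fit_moderated_ttest,
    map_protein_groups,
)
from interactome_kit.synthetic_data import SimulationConfig, simulate_quant_experiment

from oracles import bh_stepup_oracle, moderated_p_oracle


def make_table(ratios, genes=None):
    index = pd.Index([f"PG{i}" for i in range(len(ratios))], name="group_id")
    ratios = pd.DataFrame(
        ratios, index=index, columns=[f"CL_rep{j+1}_logratio" for j in range(len(ratios[0]))]
    )
    genes = genes or [f"gene{i}" for i in range(len(ratios))]
    return QuantTable(
        ratios=ratios,
        accessions=pd.Series([[f"P{i}"] for i in range(len(ratios))], index=index),
        gene=pd.Series(genes, index=index),
    )


class TestMapProteinGroups:
    def make(self, accessions):
        index = pd.Index([f"PG{i}" for i in range(len(accessions))], name="group_id")
        ratios = pd.DataFrame(
            np.ones((len(accessions), 3)),
            index=index,
            columns=["CL_rep1_logratio", "CL_rep2_logratio", "CL_rep3_logratio"],
        )
        return QuantTable(
            ratios=ratios,
            accessions=pd.Series(accessions, index=index),
            gene=pd.Series([None] * len(accessions), index=index, dtype=object),
        )

    def test_resolution_rules(self):
        """Single-gene groups survive; multi-gene groups are ambiguous."""
        table = self.make([["P1"], ["P2", "P3"], ["P4", "P5"], ["P9"]])
        mapping = pd.Series(
            {"P1": "geneA", "P2": "geneB", "P3": "geneC", "P4": "geneD", "P5": "geneD"}
        )
        out = map_protein_groups(table, mapping)
        assert sorted(out.gene) == ["geneA", "geneD"]  # PG1 ambiguous, PG3 unmapped

    def test_empty_table_errors(self):
        table = self.make([["P1"]])
        empty = QuantTable(
            ratios=table.ratios.iloc[:0],
            accessions=table.accessions.iloc[:0],
            gene=table.gene.iloc[:0],
        )
        with pytest.raises(ValueError):
            map_protein_groups(empty, pd.Series({"P1": "geneA"}))

    def test_duplicate_gene_keeps_best_quantified(self):
        table = self.make([["P1"], ["P2"]])
        table.ratios.iloc[0, 2] = np.nan
        out = map_protein_groups(table, pd.Series({"P1": "geneA", "P2": "geneA"}))
        assert list(out.ratios.index) == ["PG1"]


class TestModeratedTTest:
    def test_zero_ratios_give_null_statistic(self):
        table = make_table([[0.0, 0.0, 0.0], [1.0, 1.5, 0.5], [0.3, 0.1, 0.2]])
        fit = fit_moderated_ttest(table)
        row = fit.table.loc["gene0"]
        assert row["beta_hat"] == 0.0
        assert row["t_mod"] == 0.0
        assert row["p_raw"] == 1.0

    def test_equal_variances_reduce_to_ordinary_t(self):
        """With identical sample variances there is nothing to shrink."""
        rng = np.random.default_rng(0)
        mus = rng.normal(0, 1, size=20)
        ratios = [[m - 0.3, m, m + 0.3] for m in mus]  # every s_sq = 0.09
        fit = fit_moderated_ttest(make_table(ratios))
        assert np.isinf(fit.d0)
        s_sq = fit.table["s_sq"].to_numpy()
        n = 3
        ordinary_t = fit.table["beta_hat"] / np.sqrt(s_sq / n)
        np.testing.assert_allclose(fit.table["t_mod"], ordinary_t, rtol=1e-10)

    def test_matches_exact_arithmetic_oracle(self):
        """p-values agree with direct rational evaluation of the closed forms."""
        cfg = SimulationConfig(seed=7, n_proteins=200, n_true_rbps=20)
        table, _ = simulate_quant_experiment(cfg)
        fit = fit_moderated_ttest(table)
        tested = fit.table.index
        raw = table.ratios.set_axis(table.gene, axis=0)
        for gene in tested[:50]:
            expected = moderated_p_oracle(
                raw.loc[gene].to_numpy(), fit.d0, fit.s0_sq
            )
            assert fit.table.loc[gene, "p_raw"] == pytest.approx(expected, abs=1e-8)

    def test_shrinkage_bounds(self):
        """Posterior variance lies between the sample and prior variances."""
        cfg = SimulationConfig(seed=3, n_proteins=300, n_true_rbps=30)
        table, _ = simulate_quant_experiment(cfg)
        fit = fit_moderated_ttest(table)
        lo = np.minimum(fit.table["s_sq"], fit.s0_sq)
        hi = np.maximum(fit.table["s_sq"], fit.s0_sq)
        assert ((fit.table["s_tilde_sq"] >= lo - 1e-12) & (fit.table["s_tilde_sq"] <= hi + 1e-12)).all()

    def test_underquantified_genes_excluded(self):
        table = make_table([[1.0, np.nan, np.nan], [1.0, 1.2, 0.8], [0.1, 0.2, 0.3]])
        fit = fit_moderated_ttest(table)
        assert fit.excluded == ["gene0"]
        assert "gene0" not in fit.table.index

    def test_too_few_genes_error(self):
        with pytest.raises(ValueError):
            fit_moderated_ttest(make_table([[1.0, 1.1, 0.9]]))


class TestAdjustBH:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.03]) == pytest.approx([0.03])

    def test_full_rank_ties_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.05] * 10), [0.05] * 10)

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(11)
        p = rng.random(100)
        np.testing.assert_allclose(adjust_bh(p), bh_stepup_oracle(p), atol=1e-15)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])
        with pytest.raises(ValueError):
            adjust_bh([-0.1])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_permutation_invariant_and_monotone(self, p):
        """Adjustment commutes with permutation and preserves p-rank order."""
        p = np.asarray(p)
        adj = adjust_bh(p)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(adjust_bh(p[perm]), adj[perm])
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


class TestCallInteractome:
    def make_fit(self, p_adj, beta):
        table = pd.DataFrame(
            {"beta_hat": beta, "p_adj": p_adj},
            index=pd.Index([f"g{i}" for i in range(len(beta))], name="gene"),
        )
        return EbayesFit(d0=4.0, s0_sq=0.05, table=table)

    def test_all_null_empty(self):
        fit = self.make_fit([1.0, 1.0], [2.0, 1.0])
        calls = call_interactome(fit)
        assert calls["high_confidence"] == set() and calls["candidate"] == set()

    def test_direction_rule_excludes_depleted(self):
        fit = self.make_fit([0.005, 0.005, 0.03], [-1.0, 2.0, 1.0])
        calls = call_interactome(fit)
        assert calls["high_confidence"] == {"g1"}
        assert calls["candidate"] == {"g2"}

    def test_realized_fdp_controlled(self):
        """Average false-discovery proportion stays near the nominal level."""
        fdps = []
        for seed in range(15):
            cfg = SimulationConfig(seed=seed, n_proteins=800, n_true_rbps=80)
            table, truth = simulate_quant_experiment(cfg)
            calls = call_interactome(fit_moderated_ttest(table))["high_confidence"]
            if calls:
                fdps.append(len(calls - truth) / len(calls))
            else:
                fdps.append(0.0)
        assert np.mean(fdps) <= 0.05
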