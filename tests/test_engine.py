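"""Covariate adjustment, PCA, the three test modes, FDR, and the screen driver."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from wustat.core import (
    ExpressionVector,
    GenotypeMatrix,
    KernelConfig,
    rank_phenotype,
)
from wustat.engine import (
    PhenotypeTable,
    SampleMisalignmentError,
    fdr_adjust,
    genotype_pca,
    qq_table,
    records_to_frame,
    residualize_and_rank,
    run_gene_test,
    screen,
)
from wustat.simulate import SimConfig, simulate_gene, simulate_study, two_population_dosages


def _pt(values, ids=None, cov=None, name="y"):
    ids = ids or [f"S{i}" for i in range(len(values))]
    return PhenotypeTable(sample_ids=ids, phenotype=np.asarray(values, float),
                          covariates=cov, name=name)


class TestResidualizeAndRank:
    def test_no_covariates_reduces_to_plain_ranking(self):
        rp = residualize_and_rank(_pt([3.1, 9.9, 5.0]))
        np.testing.assert_array_equal(rp.ranks, [1, 3, 2])

    def test_collinear_covariates_rejected(self, rng):
        n = 20
        x = rng.normal(size=n)
        cov = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            residualize_and_rank(_pt(rng.normal(size=n), cov=cov))

    def test_residual_ranks_uncorrelated_with_covariate(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(size=n)
        rp = residualize_and_rank(_pt(y, cov=pd.DataFrame({"x": x})))
        rho = abs(spearmanr(rp.ranks, x).statistic)
        assert rho < 3 / np.sqrt(n)

    def test_binary_phenotype_residualized_and_ranked(self, rng):
        n = 50
        y = (rng.random(n) < 0.3).astype(float)
        cov = pd.DataFrame({"age": rng.normal(50, 10, n)})
        rp = residualize_and_rank(_pt(y, cov=cov))
        assert rp.n == n and rp.variance > 0


class TestGenotypePca:
    def test_k_zero_gives_empty_matrix(self, rng):
        scores = genotype_pca(rng.binomial(2, 0.3, size=(10, 40)).astype(float), 0)
        assert scores.shape == (10, 0)

    def test_two_populations_separate_on_pc1(self, rng):
        dosages, labels = two_population_dosages(60, 500, 0.25, rng)
        scores = genotype_pca(dosages, 2)
        r = np.corrcoef(scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_scores_orthogonal(self, rng):
        dosages = rng.binomial(2, rng.uniform(0.05, 0.5, 80), size=(50, 80)).astype(float)
        scores = genotype_pca(dosages, 5)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_sign_deterministic(self, rng):
        dosages = rng.binomial(2, 0.3, size=(30, 50)).astype(float)
        s1 = genotype_pca(dosages, 3)
        s2 = genotype_pca(dosages.copy(), 3)
        np.testing.assert_array_equal(s1, s2)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            genotype_pca(rng.binomial(2, 0.3, size=(10, 5)).astype(float), 10)


def _sim_inputs(rng, n=60, causal=True, cfg=None):
    cfg = cfg or SimConfig(n=n, snvs_per_gene=(20, 40), seed=0)
    sim = simulate_gene(cfg, causal, rng)
    k = sim.dosages.shape[1]
    ids = [f"S{i}" for i in range(n)]
    gm = GenotypeMatrix(sim.dosages, [f"v{j}" for j in range(k)],
                        np.arange(1, k + 1), "1", sample_ids=ids)
    ev = ExpressionVector(t=sim.expression, probe_id="p0", sample_ids=ids)
    y = sim.phenotype_part + rng.normal(size=n)
    rp = rank_phenotype(y)
    rp.sample_ids = ids
    return gm, ev, rp


class TestRunGeneTest:
    def test_g_mode_equals_gt_with_constant_expression(self, rng):
        gm, _, rp = _sim_inputs(rng)
        const = ExpressionVector(t=np.full(rp.n, 5.5), probe_id="c",
                                 sample_ids=gm.sample_ids)
        res_g, p_g = run_gene_test(gm, None, rp, "G")
        res_gt, p_gt = run_gene_test(gm, const, rp, "GT")
        assert res_g.u == res_gt.u          # bitwise identical statistic
        assert p_g.p == p_gt.p

    def test_t_mode_ignores_genotypes(self, rng):
        gm, ev, rp = _sim_inputs(rng)
        _, p1 = run_gene_test(gm, ev, rp, "T")
        perturbed = GenotypeMatrix(
            np.clip(gm.dosages + 1, 0, 2), gm.snv_ids, gm.positions, gm.chrom,
            gm.sample_ids)
        _, p2 = run_gene_test(perturbed, ev, rp, "T")
        assert p1.p == p2.p

    def test_misaligned_samples_hard_error(self, rng):
        gm, ev, rp = _sim_inputs(rng)
        ev_bad = ExpressionVector(t=ev.t, probe_id="p0",
                                  sample_ids=list(reversed(ev.sample_ids)))
        with pytest.raises(SampleMisalignmentError):
            run_gene_test(gm, ev_bad, rp, "T")

    def test_genetic_signal_found_by_g_not_by_t(self, rng):
        """A gene acting only through genotype: G beats T in median p."""
        cfg = SimConfig(n=100, snvs_per_gene=(20, 40), gamma=0.0, beta_t=0.0,
                        beta_g=0.35, seed=0)
        p_g, p_t = [], []
        for _ in range(60):
            gm, ev, rp = _sim_inputs(rng, n=100, causal=True, cfg=cfg)
            _, rg = run_gene_test(gm, ev, rp, "G")
            _, rt = run_gene_test(gm, ev, rp, "T")
            p_g.append(rg.p)
            p_t.append(rt.p)
        assert np.median(p_g) < np.median(p_t)

    def test_invalid_mode(self, rng):
        gm, ev, rp = _sim_inputs(rng)
        with pytest.raises(ValueError):
            run_gene_test(gm, ev, rp, "X")


class TestFdrAdjust:
    def test_hand_bh(self):
        np.testing.assert_allclose(
            fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_all_ones(self):
        assert fdr_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_array_equal(fdr_adjust(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.5]))

    def test_matches_brute_force_oracle(self, rng):
        def brute_bh(p):
            m = len(p)
            order = np.argsort(p)
            scaled = p[order] * m / np.arange(1, m + 1)
            q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
            q = np.empty(m)
            q[order] = np.minimum(q_sorted, 1.0)
            return q

        for m in (1, 7, 100, 1000):
            p = rng.random(m)
            np.testing.assert_allclose(fdr_adjust(p), brute_bh(p), atol=1e-12)

    def test_nan_passthrough(self):
        q = fdr_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and np.isfinite(q[0]) and np.isfinite(q[2])


class TestScreen:
    def _study(self, seed=3, **kw):
        cfg = SimConfig(n=40, n_genes=10, n_causal=0, snvs_per_gene=(8, 15),
                        seed=seed, **kw)
        return simulate_study(cfg)

    def _pt(self, ds, name="quant"):
        return PhenotypeTable(
            sample_ids=ds.sample_ids,
            phenotype=ds.phenotype[name].to_numpy(float),
            covariates=ds.phenotype[["age", "sex"]],
            name=name,
        )

    def test_null_screen_structure(self):
        ds = self._study()
        records = screen(ds.regions, ds.genotypes, ds.expression, self._pt(ds))
        assert len(records) == 10
        df = records_to_frame(records)
        for mode in ("G", "T", "GT"):
            assert df[f"P_{mode}"].notna().all()
            assert (df[f"Q_{mode}"] >= df[f"P_{mode}"] - 1e-12).all()
            assert df[f"P_{mode}"].between(0, 1).all()
        assert (df["N_SNV"] >= 1).all()

    def test_deterministic_rerun(self):
        ds = self._study()
        df1 = records_to_frame(screen(ds.regions, ds.genotypes, ds.expression, self._pt(ds)))
        df2 = records_to_frame(screen(ds.regions, ds.genotypes, ds.expression, self._pt(ds)))
        pd.testing.assert_frame_equal(df1, df2)

    def test_region_order_invariance(self):
        ds = self._study()
        df1 = records_to_frame(screen(ds.regions, ds.genotypes, ds.expression, self._pt(ds)))
        df2 = records_to_frame(screen(list(reversed(ds.regions)), ds.genotypes,
                                      ds.expression, self._pt(ds)))
        pd.testing.assert_frame_equal(df1, df2)

    def test_sample_order_invariance(self, rng):
        ds = self._study()
        df1 = records_to_frame(screen(ds.regions, ds.genotypes, ds.expression, self._pt(ds)))
        perm = rng.permutation(len(ds.sample_ids))
        ids2 = [ds.sample_ids[i] for i in perm]
        genotypes2 = {
            g: GenotypeMatrix(m.dosages[perm], m.snv_ids, m.positions, m.chrom, ids2)
            for g, m in ds.genotypes.items()
        }
        expr2 = ds.expression.iloc[:, perm]
        ph2 = ds.phenotype.iloc[perm]
        pt2 = PhenotypeTable(sample_ids=ids2, phenotype=ph2["quant"].to_numpy(float),
                             covariates=ph2[["age", "sex"]].reset_index(drop=True),
                             name="quant")
        df2 = records_to_frame(screen(ds.regions, genotypes2, expr2, pt2))
        for mode in ("G", "T", "GT"):
            np.testing.assert_allclose(df1[f"P_{mode}"], df2[f"P_{mode}"], rtol=1e-9)

    def test_degenerate_region_logged_not_fatal(self):
        ds = self._study()
        # constant expression makes mode T carry no information for that probe
        probe = ds.regions[0].probe_ids[0]
        ds.expression.loc[probe] = 1.0
        records = screen(ds.regions, ds.genotypes, ds.expression, self._pt(ds))
        assert len(records) == 10
        rec = next(r for r in records if r.probe_id == probe)
        assert np.isnan(rec.p["T"]) and rec.note
        assert np.isfinite(rec.p["G"])

    def test_planted_gene_has_smallest_joint_p(self):
        """A strongly associated gene among nulls is ranked first by the joint test."""
        hits = 0
        for rep in range(10):
            cfg = SimConfig(n=100, n_genes=20, n_causal=1, snvs_per_gene=(20, 40),
                            beta_g=0.4, beta_t=0.4, gamma=0.7, seed=500 + rep)
            ds = simulate_study(cfg)
            records = screen(ds.regions, ds.genotypes, ds.expression,
                             self._pt(ds), modes=("GT",))
            df = records_to_frame(records, ("GT",))
            hits += df.loc[df["P_GT"].idxmin(), "Gene"] == "GENE0000"
        assert hits >= 8


def test_qq_table_shape_and_monotonicity(rng):
    p = rng.random(100)
    qq = qq_table(p)
    assert len(qq) == 100
    assert (np.diff(qq["expected"]) >= 0).all()
    assert qq["observed"].iloc[0] == pytest.approx(-np.log10(np.max(p)), abs=1e-9)
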