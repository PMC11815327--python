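"""Genotype QC, Hardy-Weinberg exact test, kinship, PCs and mQTL mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from comethnet.mqtl import (
    genotype_pcs,
    hwe_exact_test,
    kinship_filter,
    map_mqtls,
    mqtl_stats_for_cpg,
    snp_qc,
)
from comethnet.preprocess import residualize
from comethnet.simulate import plant_mqtl_effects, simulate_cohort, simulate_genotypes
from comethnet.types import GenotypeSet, ModuleSpec, MqtlSpec, SimulationConfig


def enumerate_hwe_p(n_aa, n_ab, n_bb):
    """Independent enumeration oracle for the conditional HWE exact test."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab

    def log_prob(het):
        hom_a = (na - het) // 2
        hom_b = n - het - hom_a
        return (
            gammaln(n + 1) - gammaln(hom_a + 1) - gammaln(het + 1)
            - gammaln(hom_b + 1) + het * np.log(2)
            + gammaln(na + 1) + gammaln(2 * n - na + 1) - gammaln(2 * n + 1)
        )

    feasible = [h for h in range(min(na, 2 * n - na) + 1)
                if (na - h) % 2 == 0 and h % 2 == na % 2]
    probs = np.exp([log_prob(h) for h in feasible])
    probs /= probs.sum()
    obs = probs[feasible.index(n_ab)]
    return probs[probs <= obs * (1 + 1e-12)].sum()


def _geno(dosages, chrom=None, pos=None):
    dosages = np.asarray(dosages, dtype=float)
    m, n = dosages.shape
    snp_map = pd.DataFrame(
        {
            "chrom": chrom or ["chr1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index([f"rs{i:05d}" for i in range(m)], name="snp"),
    )
    return GenotypeSet(dosages, snp_map, pd.Index([f"S{j:04d}" for j in range(n)]))


class TestHwe:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (0, 50, 0), (10, 20, 5), (40, 10, 3), (7, 0, 7)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert abs(hwe_exact_test(*counts) - enumerate_hwe_p(*counts)) < 1e-12

    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(30, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 12) == 1.0

    def test_all_het_extreme_tail(self):
        p = hwe_exact_test(0, 50, 0)
        assert p == pytest.approx(enumerate_hwe_p(0, 50, 0), abs=1e-15)
        assert p < 1e-5  # qualifies for the QC exclusion rule

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestSnpQc:
    def test_snp_missingness_boundary(self):
        rng = np.random.default_rng(8)
        clean = rng.integers(0, 3, size=(99, 100)).astype(float)
        bad = rng.integers(0, 3, size=100).astype(float)
        bad[:2] = np.nan  # 2% missing > 1% threshold (samples stay < 5%)
        g = _geno(np.vstack([clean, bad[None, :]]))
        out = snp_qc(g, min_maf=0.0, hwe_alpha=0.0)
        assert "rs00099" not in out.snp_ids
        assert len(out.snp_ids) == 99

    def test_maf_boundary_inclusive(self):
        rng = np.random.default_rng(0)
        n = 100
        # exactly 10 alt alleles in 200 -> MAF 0.05 kept; 8 -> 0.04 dropped
        keep = np.zeros(n)
        keep[:10] = 1
        drop = np.zeros(n)
        drop[:8] = 1
        g = _geno(np.vstack([keep, drop]))
        out = snp_qc(g)
        assert list(out.snp_ids) == ["rs00000"]

    def test_hwe_violation_dropped_and_clean_kept(self):
        clean = np.tile([0.0, 1.0, 1.0, 2.0], 25).reshape(1, 100)  # HWE-ish
        violating = np.ones((1, 100))  # all heterozygous
        g = _geno(np.vstack([clean, violating]))
        out = snp_qc(g)
        assert "rs00001" not in out.snp_ids
        assert "rs00000" in out.snp_ids

    def test_sample_missingness_first(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(50, 40)).astype(float)
        d[:, 0] = np.nan  # sample 0 fully missing
        out = snp_qc(_geno(d))
        assert "S0000" not in out.sample_ids


class TestKinship:
    def test_duplicate_sample_removed(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(500, 30)).astype(float)
        d[:, 10] = d[:, 3]  # exact duplicate pair
        out = kinship_filter(_geno(d))
        assert len(out.sample_ids) == 29
        assert ("S0003" in out.sample_ids) != ("S0010" in out.sample_ids)

    def test_unrelated_samples_kept(self):
        removed = 0
        for seed in range(10):
            config = SimulationConfig(n_samples=100, n_snps=2000, seed=seed)
            g = simulate_genotypes(config)
            removed += len(g.sample_ids) - len(kinship_filter(g).sample_ids)
        assert removed == 0

    def test_threshold_one_removes_nothing(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(100, 10)).astype(float)
        d[:, 1] = d[:, 0]
        out = kinship_filter(_geno(d), threshold=1.0)
        assert len(out.sample_ids) == 10


class TestGenotypePcs:
    def test_population_structure_on_pc1(self):
        rng = np.random.default_rng(4)
        n, m = 100, 400
        pop = np.repeat([0, 1], n // 2)
        maf = np.where(
            rng.random((m, 1)) < 0.5,
            np.where(pop[None, :] == 0, 0.1, 0.4),
            np.where(pop[None, :] == 0, 0.4, 0.1),
        )
        d = rng.binomial(2, maf).astype(float)
        pcs = genotype_pcs(_geno(d), k=3)
        r = np.corrcoef(pcs["PC1"], pop)[0, 1]
        assert abs(r) >= 0.9

    def test_orthogonal_columns_and_duplicate_scores(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(200, 30)).astype(float)
        dd = np.hstack([d, d])  # every sample duplicated
        g = GenotypeSet(
            dd,
            _geno(d).snp_map,
            pd.Index([f"S{j:04d}" for j in range(60)]),
        )
        pcs = genotype_pcs(g, k=3)
        gram = pcs.to_numpy().T @ pcs.to_numpy()
        assert np.abs(gram - np.diag(np.diag(gram))).max() < 1e-6
        np.testing.assert_allclose(
            pcs.iloc[:30].to_numpy(), pcs.iloc[30:].to_numpy(), atol=1e-8
        )

    def test_k_bound(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(5, 10)).astype(float)
        with pytest.raises(ValueError):
            genotype_pcs(_geno(d), k=5)


def _mapping_setup(seed, n_samples=150, r2=0.2, snp_idx=100, cpg_idx=10):
    # panel large enough that ancestry PCs are not collinear with any
    # single LD block
    config = SimulationConfig(
        n_samples=n_samples, n_cpgs=200, n_snps=2000,
        module_spec=[ModuleSpec(50, 0.7, 0.0)],
        mqtl_spec=[MqtlSpec(snp_idx, cpg_idx, r2)],
        seed=seed,
    )
    beta, samples, _ = simulate_cohort(config)
    geno = simulate_genotypes(config)
    beta, pairs = plant_mqtl_effects(beta, geno, config.mqtl_spec)
    resid = residualize(beta, samples[["age", "sex", "braak", "prop_neuron", "plate"]])
    pcs = genotype_pcs(geno, k=3)
    return resid, geno, pcs, pairs


class TestMapMqtls:
    def test_fast_path_matches_per_pair_ols_oracle(self):
        resid, geno, pcs, _ = _mapping_setup(0, n_samples=60)
        table = map_mqtls(resid, geno, pcs, p_threshold=1.0)
        rng = np.random.default_rng(0)
        pick = rng.choice(len(table), size=100, replace=False)
        x_pcs = pcs.to_numpy()
        for i in pick:
            row = table.iloc[i]
            y = resid.values[resid.cpg_ids.get_loc(row["cpg"])]
            d = geno.dosages[geno.snp_map.index.get_loc(row["snp"])]
            design = np.column_stack([np.ones(len(y)), d, x_pcs])
            coef, res_ss, *_ = np.linalg.lstsq(design, y, rcond=None)
            df = len(y) - design.shape[1]
            xtx_inv = np.linalg.inv(design.T @ design)
            resid_y = y - design @ coef
            se = np.sqrt(resid_y @ resid_y / df * xtx_inv[1, 1])
            assert abs(row["beta"] - coef[1]) < 1e-8
            assert abs(row["se"] - se) < 1e-8
            t = coef[1] / se
            assert abs(row["t"] - t) < 1e-6
            assert abs(row["p"] - 2 * stats.t.sf(abs(t), df)) < 1e-8

    def test_planted_cis_effect_power(self):
        hits = 0
        for seed in range(20):
            resid, geno, pcs, pairs = _mapping_setup(seed)
            table = map_mqtls(resid, geno, pcs, p_threshold=1e-5)
            snp, cpg = pairs[0]
            hits += ((table["snp"] == snp) & (table["cpg"] == cpg)).any()
        assert hits >= 18

    def test_cis_trans_boundary(self):
        # SNP at CpG position + exactly 1 Mb -> cis; +1 Mb + 1 -> trans
        rng = np.random.default_rng(7)
        n = 60
        d = rng.integers(0, 3, size=(2, n)).astype(float)
        geno = _geno(d, pos=[1_001_000, 1_001_001])
        from conftest import make_residual_matrix

        resid = make_residual_matrix(rng.normal(size=(1, n)))
        resid.cpg_map = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1000], "genes": [[]]}, index=resid.cpg_ids
        )
        pcs = pd.DataFrame(
            rng.normal(size=(n, 3)), index=resid.sample_ids,
            columns=["PC1", "PC2", "PC3"],
        )
        geno = GenotypeSet(d, geno.snp_map, resid.sample_ids)
        table = map_mqtls(resid, geno, pcs, p_threshold=1.0)
        rel = table.set_index("snp")["relation"]
        assert rel["rs00000"] == "cis"      # distance exactly 1,000,000
        assert rel["rs00001"] == "trans"    # 1,000,001

    def test_null_calibration_at_threshold(self):
        # ~180k same-chromosome null tests; expect ~alpha * n hits
        total, hits = 0, 0
        for seed in range(3):
            config = SimulationConfig(
                n_samples=100, n_cpgs=300, n_snps=600, module_spec=[], seed=seed
            )
            beta, samples, _ = simulate_cohort(config)
            geno = simulate_genotypes(config)
            resid = residualize(
                beta, samples[["age", "sex", "braak", "prop_neuron", "plate"]]
            )
            pcs = genotype_pcs(geno, k=3)
            table = map_mqtls(resid, geno, pcs, p_threshold=1e-3)
            from comethnet.mqtl import _pair_relations

            total += len(_pair_relations(geno.snp_map, resid.cpg_map))
            hits += len(table)
        rate = hits / total
        assert rate < 1e-3 + 3 * np.sqrt(1e-3 / total)

    def test_missing_dosages_complete_case(self):
        config = SimulationConfig(
            n_samples=120, n_cpgs=50, n_snps=60, module_spec=[],
            missing_rate=0.05, seed=9,
        )
        beta, samples, _ = simulate_cohort(config)
        geno = simulate_genotypes(config)
        resid = residualize(
            beta, samples[["age", "sex", "braak", "prop_neuron", "plate"]]
        )
        pcs = genotype_pcs(geno, k=3)
        table = map_mqtls(resid, geno, pcs, p_threshold=1.0)
        # spot-check one SNP with missing values against a complete-case fit
        snp_i = next(
            i for i in range(60) if np.isnan(geno.dosages[i]).any()
        )
        snp = geno.snp_ids[snp_i]
        sub = table[table["snp"] == snp]
        assert len(sub) > 0
        row = sub.iloc[0]
        y = resid.values[resid.cpg_ids.get_loc(row["cpg"])]
        d = geno.dosages[snp_i]
        ok = ~np.isnan(d)
        design = np.column_stack([np.ones(ok.sum()), d[ok], pcs.to_numpy()[ok]])
        coef, *_ = np.linalg.lstsq(design, y[ok], rcond=None)
        assert abs(row["beta"] - coef[1]) < 1e-8

    def test_stats_for_cpg_consistent_with_scan(self):
        resid, geno, pcs, pairs = _mapping_setup(3)
        table = map_mqtls(resid, geno, pcs, p_threshold=1.0)
        cpg = pairs[0][1]
        full = mqtl_stats_for_cpg(resid, geno, pcs, cpg, geno.snp_map.index[:20])
        sub = table[table["cpg"] == cpg].set_index("snp")
        for snp in full.index:
            if snp in sub.index:
                assert abs(full.loc[snp, "beta"] - sub.loc[snp, "beta"]) < 1e-10
                assert abs(full.loc[snp, "p"] - sub.loc[snp, "p"]) < 1e-10
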