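import numpy as np
import pandas as pd
import pytest

from hapwin import popgen
from hapwin.phasing import HAP_ALLELES, HAP_LABELS
from hapwin.sim import (QtlSpec, SimulationConfig, WindowSpec, _spread_freqs,
                        degrade, gene_drop, default_study_config,
                        simulate_breed_freqs, simulate_pedigree,
                        simulate_phenotypes, simulate_study)

from conftest import small_test_config


class TestSimulateBreedFreqs:
    def test_zero_divergence_returns_base(self):
        base = _spread_freqs(range(8))
        out = simulate_breed_freqs(base, 5, 0.0, seed=1)
        np.testing.assert_array_equal(out, np.tile(base, (5, 1)))

    def test_degenerate_base_stays_fixed(self):
        base = np.eye(8)[0]
        out = simulate_breed_freqs(base, 4, 0.3, seed=1)
        np.testing.assert_allclose(out, np.tile(base, (4, 1)))

    def test_negative_f_rejected(self):
        with pytest.raises(ValueError):
            simulate_breed_freqs(_spread_freqs(range(8)), 3, -0.1)

    def test_rows_sum_to_one(self):
        out = simulate_breed_freqs(_spread_freqs(range(8)), 7, 0.13, seed=2)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_realized_fst_matches_target(self):
        """Weir-Cockerham F_ST over many simulated windows averages to the
        Balding-Nichols target within 2 Monte-Carlo SE."""
        rng = np.random.default_rng(123)
        target = 0.13
        base_allele = _spread_freqs(range(8))
        loci = []
        thetas = []
        n = 100  # individuals per breed
        for _ in range(400):
            freqs = simulate_breed_freqs(base_allele, 7, target, rng)
            # collapse each breed's haplotype vector to the SNP1 B frequency
            p = freqs[:, HAP_ALLELES[:, 0] == 1].sum(axis=1)
            counts = [(int(rng.binomial(2 * n, pb)), 2 * n) for pb in p]
            total_b = sum(b for b, _ in counts)
            if not 0 < total_b < 2 * n * 7:
                continue
            loci.append(counts)
            thetas.append(popgen.fst_weir_cockerham(counts).theta)
        multi = popgen.fst_multilocus(loci)
        mc_se = np.std(thetas) / np.sqrt(len(thetas))
        assert abs(multi - target) < 2 * mc_se + 0.01


class TestSimulatePedigree:
    def test_study_scale_family_sizes(self):
        cfg = default_study_config(seed=0)
        ped = simulate_pedigree(cfg, seed=0)
        counts = ped.df.loc[ped.df["sire"] != ""].groupby("sire").size()
        assert len(counts) == 246
        assert 3.6 <= counts.mean() <= 4.0
        assert counts.min() >= 1 and counts.max() <= 15
        offspring = ped.df[(ped.df["sire"] != "")]
        assert len(offspring) == 940

    def test_exact_family_size_when_forced(self):
        cfg = SimulationConfig(breeds={"A": 2}, crossbreds=[], n_sires=1,
                               offspring_mean=2, offspring_min=2,
                               offspring_max=2, windows=[], qtls=[])
        ped = simulate_pedigree(cfg, seed=0)
        assert (ped.df["sire"] != "").sum() == 2

    def test_impossible_family_spec_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            SimulationConfig(offspring_mean=20, offspring_min=1,
                             offspring_max=15, windows=[], qtls=[])

    def test_crossbreds_have_two_parent_breeds(self):
        cfg = small_test_config()
        ped = simulate_pedigree(cfg, seed=1)
        breeds = ped.breeds()
        cross = ped.df[ped.df["breed"] == "AXB"]
        cross = cross[cross["sire"] != ""]
        assert len(cross) == 20
        assert {breeds[s] for s in cross["sire"]} == {"A"}
        assert {breeds[d] for d in cross["dam"]} == {"B"}

    def test_parents_precede_offspring_topologically(self):
        ped = simulate_pedigree(small_test_config(), seed=2)
        seen = set()
        for ind in ped.topological_order:
            s, d = ped.parents(ind)
            assert (not s or s in seen) and (not d or d in seen)
            seen.add(ind)


class TestGeneDrop:
    def test_fixed_parents_give_fixed_offspring(self):
        from hapwin.io import PedigreeTable

        ped = PedigreeTable(pd.DataFrame(
            [("S", "", "", "A"), ("D", "", "", "A"), ("O", "S", "D", "A")],
            columns=["individual", "sire", "dam", "breed"]))
        w = WindowSpec(gene="G", chrom="chr1", positions=(1, 2, 3),
                       base_freqs=np.eye(8)[0])
        truth, gm = gene_drop(ped, [w], {"G": {"A": np.eye(8)[0]}}, seed=0)
        np.testing.assert_array_equal(gm.data, 0)
        assert (truth.diplotypes == 0).all()

    def test_genotypes_equal_diplotype_allele_sums(self, small_study):
        truth = small_study.truth
        for w_idx, w in enumerate(small_study.config.windows):
            sub = small_study.genotypes.window(w.snp_ids)
            expect = (HAP_ALLELES[truth.diplotypes[:, w_idx, 0]]
                      + HAP_ALLELES[truth.diplotypes[:, w_idx, 1]])
            np.testing.assert_array_equal(sub.data, expect)

    def test_founder_frequencies_match_multinomial(self):
        """Realized founder haplotype counts stay within 4 binomial SE of
        the input frequencies in a large founder cohort."""
        from hapwin.io import PedigreeTable

        n = 2000
        ped = PedigreeTable(pd.DataFrame(
            [(f"F{i}", "", "", "A") for i in range(n)],
            columns=["individual", "sire", "dam", "breed"]))
        f = _spread_freqs(range(8))
        w = WindowSpec(gene="G", chrom="chr1", positions=(1, 2, 3),
                       base_freqs=f)
        truth, _ = gene_drop(ped, [w], {"G": {"A": f}}, seed=3)
        realized = truth.breed_hap_freqs["G"]["A"]
        se = np.sqrt(f * (1 - f) / (2 * n))
        assert np.all(np.abs(realized - f) < 4 * se + 1e-12)

    def test_missing_breed_frequency_raises(self):
        from hapwin.io import PedigreeTable

        ped = PedigreeTable(pd.DataFrame([("F", "", "", "ZZZ")],
                            columns=["individual", "sire", "dam", "breed"]))
        w = WindowSpec(gene="G", chrom="chr1", positions=(1, 2, 3),
                       base_freqs=np.eye(8)[0])
        with pytest.raises(ValueError, match="ZZZ"):
            gene_drop(ped, [w], {"G": {"A": np.eye(8)[0]}}, seed=0)


class TestSimulatePhenotypes:
    def test_variance_decomposition(self):
        """With fixed effects silenced, Var(y) ~= sigma2_a + sigma2_e and
        founder breeding values have variance sigma2_a."""
        cfg = SimulationConfig(
            seed=5, breeds={"A": 800}, crossbreds=[], n_sires=200,
            n_herds=2, n_measurement_days=2, h2=0.47,
            fixed_effect_sds={"breed": 0, "herd": 0, "sex": 0, "day": 0},
            age_slope=0.0, windows=[], qtls=[])
        study = simulate_study(cfg)
        y = study.phenotypes["trait"]
        assert np.var(y) == pytest.approx(1.0, abs=0.15)
        ped = study.pedigree
        founders = ped.founders
        u = study.truth.u
        assert np.var(u.loc[founders]) == pytest.approx(cfg.sigma2_a, rel=0.2)
        # offspring Mendelian deviation variance = sigma2_a / 2
        off = [i for i in ped.individuals if i not in set(founders)]
        mid = np.array([(u[ped.parents(i)[0]] + u[ped.parents(i)[1]]) / 2
                        for i in off])
        dev = u.loc[off].to_numpy() - mid
        assert np.var(dev) == pytest.approx(cfg.sigma2_a / 2, rel=0.2)

    def test_half_sib_correlation_vanishes_without_genetics(self):
        cfg = SimulationConfig(
            seed=6, breeds={"A": 600}, crossbreds=[], n_sires=100,
            n_herds=2, n_measurement_days=2, h2=1e-6,
            fixed_effect_sds={"breed": 0, "herd": 0, "sex": 0, "day": 0},
            age_slope=0.0, windows=[], qtls=[])
        study = simulate_study(cfg)
        phen = study.phenotypes.copy()
        sires = {i: study.pedigree.parents(i)[0] for i in phen["individual"]}
        phen["sire"] = phen["individual"].map(sires)
        grand = phen["trait"].mean()
        between = phen.groupby("sire")["trait"].mean() - grand
        sizes = phen.groupby("sire").size()
        # intraclass correlation via one-way ANOVA components
        msb = float((sizes * between ** 2).sum() / (len(sizes) - 1))
        msw = float(phen.groupby("sire")["trait"].var(ddof=1).mean())
        k = float(sizes.mean())
        icc = (msb - msw) / k / ((msb - msw) / k + msw)
        assert abs(icc) < 0.05

    def test_null_qtl_leaves_no_window_signal(self, small_config):
        """Zero QTL effects: downstream haplotype R^2 stays below 0.5%."""
        import dataclasses

        from hapwin.mixed_model import build_numerator_matrix, rss_r2
        from hapwin.pipeline import base_model, haplotype_assoc, phase_window
        from hapwin.phasing import DosageMatrix

        cfg = dataclasses.replace(
            small_test_config(seed=21),
            qtls=[dataclasses.replace(q, effect=0.0)
                  for q in small_test_config().qtls])
        study = simulate_study(cfg)
        amat = build_numerator_matrix(study.pedigree)
        phen = study.phenotypes
        ids = phen["individual"].tolist()
        eig = amat.eigen(ids)
        base = base_model(phen, eig)
        breeds = study.pedigree.breeds()
        strata = [breeds[i] for i in study.genotypes.ids]
        pw = phase_window(study.genotypes, cfg.windows[0].snp_ids, strata,
                          gene="G1", seed=0)
        dm = DosageMatrix(ids=ids, labels=pw.dosage.labels,
                          entries=pw.dosage.frame.loc[ids].to_numpy(),
                          mhf=0.05, freqs=pw.dosage.freqs)
        tab = haplotype_assoc("G1", dm, phen, eig, base)
        # with no QTL the haplotype R^2 stays at the chance-capture level
        # of k fitted marker columns, E[R^2] ~= k/n
        k = int(tab["estimable"].sum())
        assert tab["r2_pct"].iloc[0] < 100.0 * 3.0 * k / len(ids)


class TestDegrade:
    def test_rate_zero_identity(self, small_study):
        assert degrade(small_study.genotypes, 0.0, seed=0) is small_study.genotypes

    def test_rate_one_rejected(self, small_study):
        with pytest.raises(ValueError):
            degrade(small_study.genotypes, 1.0, seed=0)

    def test_missing_count_within_binomial_bounds(self):
        from scipy import stats

        rng_matrix = np.zeros((940, 3), dtype=np.int8)
        from hapwin.io import GenotypeMatrix, SnpRecord

        snps = [SnpRecord(f"s{k}", "1", k + 1, "A", "G") for k in range(3)]
        gm = GenotypeMatrix([str(i) for i in range(940)], snps, rng_matrix)
        out = degrade(gm, 0.02, seed=9)
        n_missing = int((out.data == -1).sum())
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 940 * 3, 0.02)
        assert lo <= n_missing <= hi


class TestReproducibility:
    def test_same_seed_bitwise_identical(self, small_config):
        a = simulate_study(small_config)
        b = simulate_study(small_config)
        assert a.genotypes == b.genotypes
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        np.testing.assert_array_equal(a.truth.diplotypes, b.truth.diplotypes)

    def test_different_seed_differs(self, small_config):
        a = simulate_study(small_config)
        b = simulate_study(small_config, seed=small_config.seed + 1)
        assert not np.array_equal(a.genotypes.data, b.genotypes.data)


class TestConfigValidation:
    def test_bad_base_freqs_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            WindowSpec(gene="G", chrom="c", positions=(1, 2, 3),
                       base_freqs=np.full(8, 0.2))

    def test_h2_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(h2=1.2, windows=[], qtls=[])

    def test_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.breeds == small_config.breeds
        assert back.h2 == small_config.h2
        assert [w.gene for w in back.windows] == [w.gene for w in
                                                  small_config.windows]
        assert back.windows[0].flank_right.coupling == pytest.approx(0.6)
        a = simulate_study(small_config)
        b = simulate_study(back)
        assert a.genotypes == b.genotypes
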