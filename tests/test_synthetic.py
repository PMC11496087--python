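import numpy as np
import pytest

from mrmediate.harmonize import harmonize_studies, kept_instruments
from mrmediate.instruments import filter_genome_wide_significant, ld_clump
from mrmediate.mr import mr_estimate
from mrmediate.synthetic import (
    ColocScenario,
    MediationScenario,
    ScenarioError,
    make_ld_blocks,
    simulate_coloc_region,
    simulate_mediation_scenario,
)


class TestMakeLDBlocks:
    def test_rho_zero_gives_identity(self):
        ld = make_ld_blocks(3, 4, 0.0)
        np.testing.assert_array_equal(ld.r, np.eye(12))

    def test_pair_block_off_diagonal(self):
        ld = make_ld_blocks(1, 2, 0.9)
        assert ld.r[0, 1] == pytest.approx(0.9)

    def test_blocks_are_uncorrelated(self):
        ld = make_ld_blocks(2, 3, 0.5)
        assert np.all(ld.r[:3, 3:] == 0)

    def test_positive_definite_at_high_rho(self):
        ld = make_ld_blocks(5, 20, 0.95)
        assert np.linalg.eigvalsh(ld.r).min() > 0

    def test_rho_out_of_range_fails(self):
        with pytest.raises(ScenarioError):
            make_ld_blocks(1, 2, 1.0)


class TestMediationScenario:
    def test_true_proportion_formula(self):
        s = MediationScenario()
        expected = 0.066 * 0.2979 / (0.0847 + 0.066 * 0.2979)
        assert s.true_proportion == pytest.approx(expected)
        assert s.true_proportion == pytest.approx(0.188, abs=0.001)

    def test_invalid_maf_range_fails(self):
        with pytest.raises(ScenarioError):
            MediationScenario(maf_range=(0.0, 0.6))

    def test_small_samples_fail(self):
        with pytest.raises(ScenarioError):
            MediationScenario(n_med=50)

    def test_pleiotropic_loci_spread_keeps_valid_majority(self):
        s = MediationScenario(n_pleiotropic=5)
        loci = s.pleiotropic_loci()
        assert len(loci) == 5 and loci == sorted(set(loci))
        # the planted-invalid loci avoid the strongest instruments
        f = np.linspace(*s.f_range, s.n_exposure_loci)
        assert f[loci].sum() < 0.5 * f.sum()


class TestSimulateMediation:
    def test_same_seed_identical_output(self):
        a = simulate_mediation_scenario(MediationScenario(seed=7))
        b = simulate_mediation_scenario(MediationScenario(seed=7))
        assert a.exposure == b.exposure
        assert a.mediator == b.mediator
        assert a.outcome == b.outcome
        np.testing.assert_array_equal(a.ld.r, b.ld.r)
        assert a.truth == b.truth

    def test_studies_share_variants_and_alleles(self, default_sim):
        d = default_sim
        assert set(d.exposure.records) == set(d.mediator.records) == set(d.outcome.records)
        for vid, rec in d.exposure.records.items():
            pair = {rec.effect_allele, rec.other_allele}
            med = d.mediator.records[vid]
            # representation may be swapped or strand-complemented, but the
            # variant is the same biallelic SNP
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            med_pair = {med.effect_allele, med.other_allele}
            assert med_pair == pair or med_pair == {comp[a] for a in pair}

    def test_palindromic_variants_have_at_cg_alleles(self, default_sim):
        pal = set(default_sim.truth["palindromic_variants"])
        assert pal  # default fraction 0.1 plants some
        for vid in pal:
            rec = default_sim.exposure.records[vid]
            assert {rec.effect_allele, rec.other_allele} in ({"A", "T"}, {"C", "G"})
        for rec in default_sim.exposure:
            if rec.variant_id not in pal:
                assert {rec.effect_allele, rec.other_allele} not in (
                    {"A", "T"},
                    {"C", "G"},
                )

    def test_cis_region_on_distinct_chromosome(self, default_sim):
        cis_chrom = default_sim.gene_region.chrom
        lead_chroms = {
            default_sim.exposure.records[v].chrom
            for v in default_sim.truth["lead_variants"]
        }
        assert cis_chrom not in lead_chroms

    def test_reported_se_matches_empirical_se(self):
        """Across replicates, the SD of each beta-hat matches the se column within 15%."""
        # fixed MAF so the expected beta and se are identical across
        # replicates and the empirical SD isolates the sampling noise
        sims = [
            simulate_mediation_scenario(
                MediationScenario(
                    seed=30_000 + i,
                    maf_range=(0.3, 0.3),
                    frac_allele_swap=0.0,
                    frac_strand_flip=0.0,
                )
            )
            for i in range(500)
        ]
        vids = list(sims[0].exposure.records)[::7]
        for study_attr in ("exposure", "mediator", "outcome"):
            for vid in vids:
                recs = [getattr(s, study_attr).records[vid] for s in sims]
                emp = np.std([r.beta for r in recs], ddof=1)
                rep = np.median([r.se for r in recs])
                assert emp == pytest.approx(rep, rel=0.15), (study_attr, vid)

    def test_f_statistics_span_target_band(self):
        """Selected instrument strengths cover roughly the 29-101 band."""
        f_all = []
        for i in range(30):
            d = simulate_mediation_scenario(MediationScenario(seed=40_000 + i))
            sig = filter_genome_wide_significant(d.exposure)
            clumped = ld_clump(d.exposure, sig, d.ld)
            f_all.extend(
                (d.exposure.records[v].beta / d.exposure.records[v].se) ** 2
                for v in clumped
            )
        f_all = np.array(f_all)
        assert np.percentile(f_all, 5) < 45  # weak end near ~30
        assert np.percentile(f_all, 95) > 85  # strong end near ~100
        assert f_all.min() > 10  # no weak instruments

    def test_null_alpha_gives_null_step1(self):
        """With alpha=0 the mediator shows no exposure-locus signal: the
        estimated exposure->mediator effect over replicates averages 0."""
        betas = []
        for i in range(200):
            d = simulate_mediation_scenario(
                MediationScenario(seed=20_000 + i, alpha=0.0)
            )
            sig = filter_genome_wide_significant(d.exposure)
            clumped = ld_clump(d.exposure, sig, d.ld)
            kept = kept_instruments(harmonize_studies(d.exposure, d.mediator, clumped))
            if len(kept) >= 2:
                betas.append(mr_estimate(kept).beta)
        betas = np.array(betas)
        mc_se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean()) < 3 * mc_se + 1e-12


class TestSimulateColoc:
    def test_same_seed_identical(self):
        a1, a2, _ = simulate_coloc_region(ColocScenario(seed=3))
        b1, b2, _ = simulate_coloc_region(ColocScenario(seed=3))
        assert a1 == b1 and a2 == b2

    def test_null_mode_max_z_small(self):
        """Under the null both traits' max |z| stays below 4 in >=95% of reps."""
        ok = 0
        for i in range(100):
            s1, s2, _ = simulate_coloc_region(
                ColocScenario(mode="null", seed=60_000 + i)
            )
            z1 = max(abs(r.beta / r.se) for r in s1)
            z2 = max(abs(r.beta / r.se) for r in s2)
            ok += (z1 < 4) and (z2 < 4)
        assert ok >= 95

    def test_shared_mode_lead_significant(self):
        s1, s2, _ = simulate_coloc_region(ColocScenario(mode="shared", seed=5))
        lead = "rs80025"  # center of the 50-SNP region
        assert s1.records[lead].pval < 5e-8
        assert s2.records[lead].pval < 5e-8

    def test_bad_mode_rejected(self):
        with pytest.raises(ScenarioError):
            ColocScenario(mode="both")
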