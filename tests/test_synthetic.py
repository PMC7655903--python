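"""Simulator contracts: determinism, Mendelian consistency, calibration."""

import numpy as np
import pandas as pd
import pytest

import popgs
from popgs import synthetic_data as sd
from popgs.core import InvalidParameterError, PedigreeError, Pedigree, UNKNOWN


class TestSimulateFounders:
    def test_symmetric_frequency_mean_dosage(self):
        g = sd.simulate_founders(50, 50, 400, maf_range=(0.5, 0.5),
                                 n_chromosomes=2, seed=0)
        # p = 0.5 everywhere: mean dosage 1.0, per-marker SE sqrt(0.5/n)
        se = np.sqrt(0.5 / g.n_individuals)
        mean_over_markers = g.dosages.mean()
        assert abs(mean_over_markers - 1.0) < 3 * se / np.sqrt(g.n_markers)

    def test_determinism(self):
        a = sd.simulate_founders(5, 5, 100, seed=7, n_chromosomes=3)
        b = sd.simulate_founders(5, 5, 100, seed=7, n_chromosomes=3)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.markers.equals(b.markers)

    def test_empirical_maf_against_monte_carlo_oracle(self):
        n_ind, n_mark = 40, 1000
        g = sd.simulate_founders(n_ind // 2, n_ind // 2, n_mark,
                                 maf_range=(0.05, 0.5), n_chromosomes=5,
                                 seed=3)
        freq = g.allele_freq()
        emp_maf = np.minimum(freq, 1 - freq)
        assert (emp_maf >= 0).all() and (emp_maf <= 0.5).all()
        # brute-force Monte-Carlo oracle for the mean empirical MAF
        rng = np.random.default_rng(99)
        draws = 10_000
        p = rng.uniform(0.05, 0.5, size=draws)
        counts = rng.binomial(2 * n_ind, p) / (2 * n_ind)
        oracle = np.minimum(counts, 1 - counts)
        se = oracle.std() * np.sqrt(1 / n_mark + 1 / draws)
        assert abs(emp_maf.mean() - oracle.mean()) < 3 * se

    def test_positions_strictly_increasing_within_chromosome(self):
        g = sd.simulate_founders(3, 3, 500, n_chromosomes=4, seed=1)
        for _, grp in g.markers.groupby("chrom"):
            assert (np.diff(grp["pos_bp"]) > 0).all()

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            sd.simulate_founders(0, 5, 100)
        with pytest.raises(InvalidParameterError):
            sd.simulate_founders(2, 2, 100, maf_range=(0.0, 0.5))
        with pytest.raises(InvalidParameterError):
            sd.simulate_founders(2, 2, 2, n_chromosomes=5)


class TestSimulatePedigree:
    def test_factorial_counting(self):
        des = sd.MatingDesign.factorial([f"s{i}" for i in range(4)],
                                        [f"d{i}" for i in range(4)], 10)
        ped = sd.simulate_pedigree(des)
        assert len(ped.families()) == 16
        assert len(ped.offspring()) == 160
        # founders listed first
        assert ped.ids[:8] == des.founders

    def test_empty_cross_list_gives_founders_only(self):
        des = sd.MatingDesign(sires=["s"], dams=["d"], crosses=[])
        ped = sd.simulate_pedigree(des)
        assert ped.offspring() == []
        assert set(ped.founders()) == {"s", "d"}

    def test_study_design_matches_reference_bookkeeping(self, study_design):
        ped = sd.simulate_pedigree(study_design)
        fams = ped.families()
        assert len(fams) == 35
        assert sum(len(m) for m in fams.values()) == 1011
        sizes = [len(m) for m in fams.values()]
        assert max(sizes) == 118
        assert min(sizes) == 11  # smallest corrected family
        assert len(study_design.founders) == 23

    def test_shared_founder_id_rejected(self):
        with pytest.raises(InvalidParameterError):
            sd.MatingDesign(sires=["x"], dams=["x"], crosses=[("x", "x", 2)])


class TestDropGenes:
    def test_zero_recombination_transmits_unbroken_haplotypes(self):
        des = sd.MatingDesign(sires=["s"], dams=["d"], crosses=[("s", "d", 8)])
        ped = sd.simulate_pedigree(des)
        founders = sd.simulate_founders(1, 1, 300, n_chromosomes=1, seed=2,
                                        sire_ids=["s"], dam_ids=["d"])
        geno = sd.drop_genes(ped, founders, recomb_rate_per_mb=0.0, seed=3)
        sire_h = founders.haplotypes[0]
        for k, iid in enumerate(ped.offspring()):
            pat = geno.haplotypes[geno.ids.index(iid), :, 0]
            assert (np.array_equal(pat, sire_h[:, 0])
                    or np.array_equal(pat, sire_h[:, 1]))

    def test_mendelian_consistency_zero_opposing_homozygotes(self, popdata):
        ped, geno = popdata["ped"], popdata["geno"]
        rng = np.random.default_rng(0)
        for iid in rng.choice(ped.offspring(), 25, replace=False):
            s, d = ped.parents_of(iid)
            assert popgs.opposing_homozygotes(geno, iid, s) == 0
            assert popgs.opposing_homozygotes(geno, iid, d) == 0

    def test_determinism(self, popdata):
        ped, founders = popdata["ped"], popdata["founders"]
        a = sd.drop_genes(ped, founders, seed=11)
        b = sd.drop_genes(ped, founders, seed=11)
        assert np.array_equal(a.dosages, b.dosages)

    def test_unknown_parent_in_non_founder_raises(self):
        ped = Pedigree([("s", "0", "0"), ("d", "0", "0"),
                        ("k", "s", UNKNOWN)])
        founders = sd.simulate_founders(1, 1, 50, n_chromosomes=1, seed=0,
                                        sire_ids=["s"], dam_ids=["d"])
        with pytest.raises(PedigreeError, match="unknown parent"):
            sd.drop_genes(ped, founders)


class TestSimulateTraits:
    def test_zero_dominance_ratio_gives_zero_tdv(self, popdata):
        arch = sd.TraitArchitecture(n_traits=2, n_qtl=40,
                                    dominance_ratio=0.0,
                                    genetic_correlation=np.eye(2))
        truth = sd.simulate_traits(popdata["geno"], arch, seed=1)
        assert np.all(truth.tdv == 0.0)
        assert truth.tbv.mean(axis=0) == pytest.approx([0, 0], abs=1e-10)

    def test_dominance_ratio_scales_tdv_variance(self, popdata):
        arch = sd.TraitArchitecture(n_traits=1, n_qtl=40,
                                    dominance_ratio=0.25,
                                    genetic_correlation=np.eye(1))
        truth = sd.simulate_traits(popdata["geno"], arch, seed=1)
        ratio = truth.tdv.var(axis=0) / truth.tbv.var(axis=0)
        assert ratio == pytest.approx(0.25, rel=1e-6)

    def test_identity_correlation_gives_independent_tbv(self, popdata):
        arch = sd.TraitArchitecture(n_traits=2, n_qtl=100,
                                    genetic_correlation=np.eye(2))
        truth = sd.simulate_traits(popdata["geno"], arch, seed=2)
        r = np.corrcoef(truth.tbv.T)[0, 1]
        assert abs(r) < 0.15

    def test_strong_correlation_recovered(self, popdata):
        C = np.array([[1.0, 0.9], [0.9, 1.0]])
        arch = sd.TraitArchitecture(n_traits=2, n_qtl=100,
                                    genetic_correlation=C)
        rs = [np.corrcoef(sd.simulate_traits(popdata["geno"], arch,
                                             seed=s).tbv.T)[0, 1]
              for s in range(12)]
        rs = np.array(rs)
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean() - 0.9) < 3 * se + 0.02

    def test_non_pd_correlation_rejected(self):
        C = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(InvalidParameterError):
            sd.TraitArchitecture(n_traits=2, genetic_correlation=C)

    def test_too_many_qtl_rejected(self, popdata):
        arch = sd.TraitArchitecture(n_traits=1, n_qtl=10 ** 6,
                                    genetic_correlation=np.eye(1))
        with pytest.raises(InvalidParameterError):
            sd.simulate_traits(popdata["geno"], arch, seed=0)


class TestSimulateFieldTrial:
    def _truth(self, n=120, seed=4):
        rng = np.random.default_rng(seed)
        tbv = rng.normal(size=(n, 1))
        tbv -= tbv.mean()
        return sd.TruthRecord(ids=[f"g{i}" for i in range(n)],
                              traits=["trait1"], tbv=tbv,
                              tdv=np.zeros_like(tbv))

    def test_no_spatial_leaves_iid_residual_of_calibrated_variance(self):
        truth = self._truth()
        arch = sd.TraitArchitecture(n_traits=1, target_h2=[0.5],
                                    genetic_correlation=np.eye(1),
                                    spatial_variance_fraction=0.0, n_blocks=6)
        obs = sd.simulate_field_trial(truth, (36, 20), 6, arch, seed=5)
        assert (obs["true_surface"] == 0).all()
        var_g = truth.tbv[:, 0].var()
        var_e_expected = 6 * var_g * (1 - 0.5) / 0.5
        piv = obs.pivot_table(index="genotype", columns="block",
                              values="value")
        gv = pd.Series(truth.tbv[:, 0], index=truth.ids)
        resid = piv.sub(gv.loc[piv.index], axis=0) - 10.0
        assert resid.to_numpy().var() == pytest.approx(var_e_expected,
                                                       rel=0.15)
        # replicate means: variance of the mean residual ~ var_e / n_blocks
        assert resid.mean(axis=1).var() == pytest.approx(var_e_expected / 6,
                                                         rel=0.30)

    def test_unit_heritability_gives_identical_replicates_up_to_surface(self):
        truth = self._truth()
        arch = sd.TraitArchitecture(n_traits=1, target_h2=[1.0],
                                    genetic_correlation=np.eye(1),
                                    spatial_variance_fraction=0.2, n_blocks=4)
        obs = sd.simulate_field_trial(truth, (24, 20), 4, arch, seed=6)
        desurf = obs["value"] - obs["true_surface"]
        spread = (obs.assign(v=desurf)
                  .groupby("genotype")["v"].agg(np.ptp))
        assert spread.max() < 1e-9

    def test_each_block_is_a_complete_replicate(self):
        truth = self._truth()
        obs = sd.simulate_field_trial(
            truth, (36, 20), 6,
            sd.TraitArchitecture(n_traits=1, genetic_correlation=np.eye(1)),
            seed=7)
        counts = obs.groupby(["block", "genotype"]).size()
        assert (counts == 1).all()
        assert obs.groupby("block")["genotype"].nunique().eq(120).all()

    def test_layout_too_small_raises(self):
        truth = self._truth()
        with pytest.raises(InvalidParameterError, match="layout"):
            sd.simulate_field_trial(
                truth, (6, 10), 6,
                sd.TraitArchitecture(n_traits=1,
                                     genetic_correlation=np.eye(1)), seed=0)

    def test_calibrated_clonal_mean_heritability(self):
        """Realized broad-sense clonal-mean heritability matches target."""
        truth = self._truth(n=400, seed=8)
        arch = sd.TraitArchitecture(n_traits=1, target_h2=[0.5],
                                    genetic_correlation=np.eye(1),
                                    spatial_variance_fraction=0.10,
                                    n_blocks=6)
        obs = sd.simulate_field_trial(truth, (120, 20), 6, arch, seed=9)
        adj = obs["value"] - obs["true_surface"]
        cm = obs.assign(v=adj).groupby("genotype")["v"].mean()
        gv = pd.Series(truth.tbv[:, 0], index=truth.ids)
        var_g = gv.var()
        var_resid = (cm - gv.loc[cm.index] - 10.0).var()
        h2 = var_g / (var_g + var_resid)
        assert h2 == pytest.approx(0.5, abs=0.05)


class TestCorruptPedigree:
    def test_zero_rate_identity(self, popdata):
        out, log = sd.corrupt_pedigree(popdata["ped"], 0.0, seed=1)
        assert out == popdata["ped"]
        assert len(log) == 0

    def test_full_rate_changes_every_sire(self, popdata):
        out, log = sd.corrupt_pedigree(popdata["ped"], 1.0, seed=1)
        for iid, s, d in out.records:
            if d != UNKNOWN:
                assert s != popdata["ped"].parents_of(iid)[0]

    def test_fraction_within_block_granularity_bounds(self, study_design):
        ped = sd.simulate_pedigree(study_design)
        for seed in range(5):
            out, log = sd.corrupt_pedigree(ped, 0.15, seed=seed)
            frac = len(log) / len(ped.offspring())
            assert 0.10 <= frac <= 0.20

    def test_errors_are_contiguous_family_runs(self, popdata):
        ped = popdata["ped"]
        out, log = sd.corrupt_pedigree(ped, 0.10, seed=4)
        fams = ped.families()
        for (s, d), members in fams.items():
            flags = [iid in set(log["id"]) for iid in members]
            # corrupted members of a family form one contiguous run
            runs = np.flatnonzero(np.diff(np.r_[0, flags, 0]) == 1)
            assert len(runs) <= 1

    def test_single_sire_rejected(self):
        ped = Pedigree([("s", "0", "0"), ("d", "0", "0"), ("k", "s", "d")])
        with pytest.raises(InvalidParameterError, match="single"):
            sd.corrupt_pedigree(ped, 0.5, seed=0)


class TestExportDataset:
    def test_files_written_and_readable(self, tmp_path, popdata):
        arch = sd.TraitArchitecture(n_traits=1, n_qtl=20,
                                    genetic_correlation=np.eye(1))
        geno = popdata["geno"].subset(ids=popdata["geno"].ids[:40],
                                      marker_mask=np.arange(60))
        truth = sd.simulate_traits(geno, arch, seed=0)
        obs = sd.simulate_field_trial(truth, (8, 30), 2, arch, seed=1)
        sd.export_dataset(tmp_path, popdata["ped"], geno, obs, truth,
                          params={"seed": 0})
        for name in ("pedigree.csv", "genotypes.tsv", "marker_map.tsv",
                     "genotypes.vcf", "observations.csv", "truth.csv",
                     "params.json"):
            assert (tmp_path / name).exists()
        back = popgs.read_genotypes_tsv(tmp_path / "genotypes.tsv",
                                        tmp_path / "marker_map.tsv")
        assert np.array_equal(back.dosages, geno.dosages)
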