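"""Generator behaviour: determinism, planted-motif recovery, Poisson
means, induction ratios against the analytic oracle, mutation and
accessibility models."""

import numpy as np
import pandas as pd
import pytest

import uvhotspot as uv
from uvhotspot.genome import ReferenceGenome
from uvhotspot.synthetic import (DamageModelParams, GenomeSpec,
                                 PlantedMotif, default_cohort,
                                 expected_position_lambda, make_genome,
                                 simulate_dnase, simulate_mutations,
                                 simulate_reads, variant_cohort_spec)
from uvhotspot.tracks import LesionTrack


class TestMakeGenome:
    def test_single_variant_site_truth(self):
        spec = GenomeSpec(n_regions=1, region_length=720, planted_motifs=[
            PlantedMotif(0, 300, "ETS_variant", True, "+", "TC")], seed=4)
        genome, regions, truth = make_genome(spec)
        assert len(truth) == 1
        assert bool(truth.loc[0, "variant"]) is True
        assert truth.loc[0, "midpoint"] == 300

    def test_planted_context_recovered_by_scan(self):
        """The pyrimidine-strand context around a planted variant site
        carries the TCTTCCG signature (dipyrimidine TC at -4/-3), and the
        motif scanner recovers it as a variant site."""
        spec = GenomeSpec(n_regions=1, region_length=100, planted_motifs=[
            PlantedMotif(0, 50, "ETS_variant", True, "+", "TC")], seed=4)
        genome, _, _ = make_genome(spec)
        assert genome["region_00000"][46:53] == "TCTTCCG"
        sites = uv.scan_genome(genome)
        hit = sites[(sites["midpoint"] == 50) & (sites["strand"] == "+")]
        assert len(hit) == 1 and bool(hit["variant"].iloc[0])

    def test_determinism(self):
        spec = variant_cohort_spec(n_sites=5, seed=77, region_length=200)
        g1, r1, t1 = make_genome(spec)
        g2, r2, t2 = make_genome(spec)
        assert dict(g1) == dict(g2)
        assert t1.equals(t2) and r1.equals(r2)

    def test_overlapping_motifs_rejected(self):
        spec = GenomeSpec.__new__(GenomeSpec)  # bypass fit check to hit
        GenomeSpec.__init__(spec, n_regions=1, region_length=100,
                            planted_motifs=[
                                PlantedMotif(0, 50, "ETS_variant"),
                                PlantedMotif(0, 53, "ETS_canonical")])
        with pytest.raises(ValueError, match="[Oo]verlap"):
            make_genome(spec)

    def test_motif_outside_region_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            GenomeSpec(n_regions=1, region_length=100,
                       planted_motifs=[PlantedMotif(0, 2, "ETS_variant")])

    def test_short_region_rejected(self):
        with pytest.raises(ValueError, match="41"):
            GenomeSpec(n_regions=1, region_length=40)


class TestSimulateReads:
    def test_unknown_condition(self):
        spec = variant_cohort_spec(n_sites=2, seed=1, region_length=100)
        genome, _, truth = make_genome(spec)
        with pytest.raises(ValueError, match="condition"):
            simulate_reads(genome, truth, DamageModelParams(), "wet")

    def test_determinism(self):
        spec = variant_cohort_spec(n_sites=3, seed=2, region_length=150)
        genome, _, truth = make_genome(spec)
        params = DamageModelParams(seed=2, sequencing_depth=300)
        r1 = simulate_reads(genome, truth, params, "cellular")
        r2 = simulate_reads(genome, truth, params, "cellular")
        pd.testing.assert_frame_equal(r1, r2)

    def test_single_tt_poisson_mean(self):
        """One TT dipyrimidine, TT-only rates: the read count at that
        pair is Poisson with mean = sequencing depth."""
        genome = ReferenceGenome({"r": "AGAGATTAGAGAGA"})
        truth = pd.DataFrame(columns=["contig", "midpoint", "strand",
                                      "kind", "variant", "bound", "dinuc"])
        depth = 400.0
        params = DamageModelParams(
            seed=8, sequencing_depth=depth, background_rate=0.0,
            efficiency_sigma=0.0,
            base_rate={"TT": 1.0, "TC": 0.0, "CT": 0.0, "CC": 0.0})
        reads = simulate_reads(genome, truth, params, "cellular")
        assert abs(len(reads) - depth) < 3 * np.sqrt(depth)
        track = uv.call_lesions(reads, genome)
        assert track.total_dipyrimidine_reads == len(reads)  # round trip
        assert track.contig("r")[0, 5] == len(reads)

    def test_bound_site_induction_ratio_matches_analytic_oracle(self):
        """Monte-Carlo mean cellular:naked ratio at the -4/-3 pair of a
        bound variant site matches the induction factor, via the
        analytic per-position expectation."""
        spec = GenomeSpec(n_regions=1, region_length=100, planted_motifs=[
            PlantedMotif(0, 50, "ETS_variant", True, "+", "TC")], seed=6)
        genome, _, truth = make_genome(spec)
        f = 9.0
        params = DamageModelParams(
            seed=6, sequencing_depth=50, background_rate=0.0,
            efficiency_sigma=0.0,
            induction={("ETS_variant", -4): f})
        lam_c = expected_position_lambda(genome, truth, params, "cellular")
        lam_n = expected_position_lambda(genome, truth, params, "naked")
        # oracle: per-position expectation ratio at -4/-3 equals f exactly
        # (pair isolated from neighbours at -4; -3 shares the CT pair)
        assert lam_c[0, 46] / lam_n[0, 46] == pytest.approx(f)

        tot_c = np.zeros(2)
        tot_n = np.zeros(2)
        for rep in range(300):
            p = DamageModelParams(**{**params.__dict__, "seed": rep})
            rc = simulate_reads(genome, truth, p, "cellular")
            rn = simulate_reads(genome, truth, p, "naked")
            tc = uv.call_lesions(rc, genome).contig("region_00000")
            tn = uv.call_lesions(rn, genome).contig("region_00000")
            tot_c += tc[0, [46, 47]]
            tot_n += tn[0, [46, 47]]
        ratio = tot_c[0] / tot_n[0]
        assert ratio == pytest.approx(f, rel=0.12)

    def test_matched_libraries_agree_off_motif(self):
        """Away from bound motifs, cellular and naked rates are equal:
        per-position conditional binomial tests (BH-corrected) find no
        significant difference in a multi-seed aggregate."""
        import scipy.stats

        spec = variant_cohort_spec(n_sites=4, seed=21, region_length=200)
        genome, regions, truth = make_genome(spec)
        cell = np.zeros(genome.index.total)
        naked = np.zeros(genome.index.total)
        for rep in range(30):
            params = DamageModelParams(seed=1000 + rep,
                                       sequencing_depth=2000,
                                       background_rate=0.0)
            rc = simulate_reads(genome, truth, params, "cellular")
            rn = simulate_reads(genome, truth, params, "naked")
            cell += uv.call_lesions(rc, genome).data.sum(axis=0)
            naked += uv.call_lesions(rn, genome).data.sum(axis=0)
        # mask out motif footprints (midpoint +/- 8)
        mask = np.ones(genome.index.total, dtype=bool)
        for site in truth.itertuples():
            off = genome.index.global_pos(site.contig, site.midpoint)
            mask[off - 8: off + 9] = False
        test_pos = np.flatnonzero(mask & ((cell + naked) > 50))
        pvals = [scipy.stats.binomtest(
            int(cell[g]), int(cell[g] + naked[g]), 0.5).pvalue
            for g in test_pos]
        q = scipy.stats.false_discovery_control(np.array(pvals))
        assert (q >= 0.01).all()


class TestSimulateMutations:
    @staticmethod
    def _cohort(seed=13, n=30):
        spec = variant_cohort_spec(n_sites=n, seed=seed, region_length=200)
        genome, regions, truth = make_genome(spec)
        return genome, regions, truth

    def test_zero_betas_mean_is_exp_beta0(self):
        genome, regions, truth = self._cohort()
        zero = LesionTrack.zeros(genome.index)
        params = DamageModelParams(seed=13, glm_beta0=np.log(2.0),
                                   glm_beta_cell=0.0, glm_beta_naked=0.0,
                                   mutation_background=0.0)
        counts = []
        for rep in range(40):
            with pytest.warns(UserWarning, match="coverage"):
                cat = simulate_mutations(zero, zero, truth, genome,
                                         regions, params, seed=rep)
            counts.append(cat["tumor_count"].sum())
        mean = np.mean(counts) / len(truth)
        assert mean == pytest.approx(2.0, rel=0.15)

    def test_catalog_schema_and_positivity(self):
        genome, regions, truth = self._cohort()
        params = DamageModelParams(seed=13, sequencing_depth=500)
        rc = simulate_reads(genome, truth, params, "cellular")
        rn = simulate_reads(genome, truth, params, "naked")
        cell = uv.call_lesions(rc, genome)
        naked = uv.call_lesions(rn, genome)
        cat = simulate_mutations(cell, naked, truth, genome, regions,
                                 params)
        assert (cat["tumor_count"] >= 1).all()
        for m in cat.itertuples():
            assert genome[m.contig][m.position] == m.ref
            assert m.ref != m.alt


class TestSimulateDnase:
    TRUTH = pd.DataFrame({
        "contig": [f"r{i}" for i in range(20)],
        "midpoint": [100] * 20,
    })

    def test_rho_one_is_monotone(self):
        ind = np.random.default_rng(0).normal(size=20)
        table, _ = simulate_dnase(self.TRUTH, ind, 1.0, seed=5)
        order = np.argsort(ind)
        assert (np.diff(table["density"].to_numpy()[order]) > 0).all()

    def test_replicates_sum_to_density(self):
        ind = np.arange(20.0)
        table, _ = simulate_dnase(self.TRUTH, ind, 0.5, seed=5)
        reps = table[["rep1", "rep2", "rep3"]].sum(axis=1)
        assert np.allclose(reps, table["density"])

    def test_too_few_sites_refused(self):
        with pytest.raises(ValueError, match="10"):
            simulate_dnase(self.TRUTH.head(5), np.arange(5.0), 0.4, seed=1)

    def test_seeds_differ(self):
        ind = np.arange(20.0)
        t1, _ = simulate_dnase(self.TRUTH, ind, 0.5, seed=1)
        t2, _ = simulate_dnase(self.TRUTH, ind, 0.5, seed=2)
        assert not np.allclose(t1["density"], t2["density"])


def test_default_cohort_round_trip_conservation():
    """Every simulated lesion read is retained by lesion calling (the
    placement convention inverts the generator) and contributes exactly
    two position counts."""
    genome, regions, truth, params, cellular, naked = default_cohort(
        seed=19, n_sites=10)
    # background reads may fall on non-dipyrimidines; lesion reads never do
    assert cellular.dropped_reads + cellular.off_contig_reads \
        < 0.01 * cellular.total_input_reads
    assert cellular.data.sum() == 2 * cellular.total_dipyrimidine_reads
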