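"""Filter-cascade behaviour: per-stage rules, monotonicity, truth recovery
on simulated data, and the mismatch-spectrum FDR estimate."""

import pytest

from edikit.formats_io import GenomeRef, SiteCatalog, SiteCatalogEntry, SnpSet
from edikit.pileup_engine import BaseCount, BaseFilterConfig, count_at_sites, pileup
from edikit.variant_calling import (
    CascadeConfig,
    SiteCall,
    apply_stage_B,
    apply_stage_C,
    apply_stage_D,
    apply_stage_E,
    call_stage_A,
    homopolymer_run,
    run_cascade,
    spectrum,
)


def bc(pos, ref, counts, chrom="chr1"):
    out = BaseCount(chrom, pos, ref)
    out.counts_fwd = dict(counts)
    return out


def call(pos, ref="A", variant="G", freq=0.2, coverage=20, chrom="chr1"):
    counts = {ref: int(coverage * (1 - freq)), variant: int(coverage * freq)}
    return SiteCall(chrom, pos, ref, "+", counts, coverage, variant, freq,
                    {"A"}, ref + variant)


@pytest.fixture
def genome():
    # position 10 sits in a 6-run of A, position 30 in a 5-run; the
    # alternating background has no other runs
    seq = list("ACGT" * 25)
    seq[8:14] = "AAAAAA"
    seq[28:33] = "AAAAA"
    return GenomeRef({"chr1": "".join(seq)})


class TestStageA:
    def test_mismatch_position_called_with_class_and_freq(self, genome):
        calls = call_stage_A([bc(50, "A", {"A": 9, "G": 1})], genome)
        assert len(calls) == 1
        c = calls[0]
        assert c.sub_class == "AG" and c.strand == "+"
        assert c.frequency == pytest.approx(0.1)

    def test_pure_reference_position_not_called(self, genome):
        assert call_stage_A([bc(50, "A", {"A": 12})], genome) == []

    def test_reverse_strand_editing_inferred(self, genome):
        c = call_stage_A([bc(50, "T", {"T": 7, "C": 3})], genome)[0]
        assert c.sub_class == "TC" and c.strand == "-"

    def test_call_count_equals_mismatch_scan(self, sim_bundle):
        genome, reads = sim_bundle["genome"], sim_bundle["rna"]
        counts = list(pileup(reads, genome))
        expected = sum(
            1 for b in counts
            if any(base != b.ref and n > 0 for base, n in b.counts.items())
        )
        assert len(call_stage_A(iter(counts), genome)) == expected


class TestStageB:
    def _wgs(self, pos, counts):
        return {("chr1", pos): bc(pos, "A", counts)}

    def test_snp_position_removed(self):
        calls = [call(50)]
        out = apply_stage_B(calls, self._wgs(50, {"A": 20}), SnpSet({("chr1", 50)}),
                            CascadeConfig())
        assert out == []

    def test_thin_wgs_coverage_removed(self):
        out = apply_stage_B([call(50)], self._wgs(50, {"A": 9}), SnpSet(), CascadeConfig())
        assert out == []
        kept = apply_stage_B([call(50)], self._wgs(50, {"A": 10}), SnpSet(), CascadeConfig())
        assert len(kept) == 1 and "B" in kept[0].stage_flags

    def test_heterozygous_wgs_signal_removed(self):
        out = apply_stage_B([call(50)], self._wgs(50, {"A": 6, "G": 6}), SnpSet(),
                            CascadeConfig())
        assert out == []

    def test_missing_wgs_with_stage_enabled_errors(self):
        with pytest.raises(ValueError, match="WGS"):
            apply_stage_B([call(50)], None, SnpSet(), CascadeConfig())


class TestStageC:
    def test_homopolymer_run_boundary(self, genome):
        assert homopolymer_run(genome, "chr1", 10) == 6
        assert homopolymer_run(genome, "chr1", 30) == 5
        assert apply_stage_C([call(10)], genome, CascadeConfig()) == []
        assert len(apply_stage_C([call(30)], genome, CascadeConfig())) == 1

    def test_coverage_boundary_at_least_10(self, genome):
        assert len(apply_stage_C([call(50, coverage=10)], genome, CascadeConfig())) == 1
        assert apply_stage_C([call(50, coverage=9)], genome, CascadeConfig()) == []


class TestStageD:
    def test_frequency_boundary(self):
        assert len(apply_stage_D([call(50, freq=0.1, coverage=100)], CascadeConfig())) == 1
        kept = apply_stage_D([call(50, freq=0.0999, coverage=10000)], CascadeConfig())
        assert kept == []


class TestStageE:
    def test_junction_window_removal(self):
        from edikit.formats_io import RegionSet

        junctions = RegionSet([("chr1", 52, 53, "+")])
        out = apply_stage_E([call(50)], [], junctions,
                            CascadeConfig(splice_window=4))
        assert out == []
        far = apply_stage_E([call(40)], [], junctions, CascadeConfig(splice_window=4))
        assert len(far) == 1

    def test_multimapper_locus_removed(self, sim_bundle):
        from edikit.synthetic_data import SimConfig, as_aligned, make_genome, simulate_reads

        cfg = SimConfig(seed=23, genome_length=20_000, depth=80, n_editing_sites=10,
                        level_dist=("fixed", 0.5), n_recoding_sites=0, n_het_snps=0,
                        n_hyper_reads=0, n_multimap_reads=40, base_error_rate=0.0)
        genome, truth = make_genome(cfg)
        simulate_reads(genome, truth, cfg)
        reads = as_aligned(truth.rna_reads)
        calls, _ = run_cascade(reads, genome,
                               cfg=CascadeConfig(enabled_stages=frozenset("ACDE")))
        target = truth.sites[0]
        with_e = {c.key for c in calls}
        no_e_calls, _ = run_cascade(reads, genome,
                                    cfg=CascadeConfig(enabled_stages=frozenset("ACD")))
        no_e = {c.key for c in no_e_calls}
        assert (target.chrom, target.pos) in no_e
        assert (target.chrom, target.pos) not in with_e

    def test_clean_unique_reads_kept(self, clean_bundle):
        genome, reads = clean_bundle["genome"], clean_bundle["rna"]
        calls, _ = run_cascade(reads, genome,
                               cfg=CascadeConfig(enabled_stages=frozenset("ACDE")))
        assert all("E" in c.stage_flags for c in calls)


class TestCascadeOnTruth:
    def _wgs_counts(self, bundle):
        genome, rna, wgs = bundle["genome"], bundle["rna"], bundle["wgs"]
        pre = call_stage_A(pileup(rna, genome), genome)
        cat = SiteCatalog([SiteCatalogEntry(c.chrom, c.pos, "+") for c in pre])
        return count_at_sites(wgs, genome, cat, BaseFilterConfig())

    def test_monotone_survivor_counts(self, sim_bundle):
        genome, rna = sim_bundle["genome"], sim_bundle["rna"]
        _, surv = run_cascade(rna, genome, wgs_counts=self._wgs_counts(sim_bundle),
                              snps=sim_bundle["truth"].snp_set())
        assert surv["A"] >= surv["B"] >= surv["C"] >= surv["D"] >= surv["E"]

    def test_eligible_truth_sites_fully_recovered_and_snps_removed(self, sim_bundle):
        genome, rna, truth = sim_bundle["genome"], sim_bundle["rna"], sim_bundle["truth"]
        site_counts = count_at_sites(rna, genome, truth.catalog())
        from edikit.editing_indices import site_level

        calls, _ = run_cascade(rna, genome, wgs_counts=self._wgs_counts(sim_bundle),
                               snps=truth.snp_set())
        called = {c.key for c in calls}
        cfg = CascadeConfig()
        for site in truth.sites:
            bcnt = site_counts[(site.chrom, site.pos)]
            lv = site_level(bcnt, site.strand)
            eligible = (
                bcnt.total_reads >= cfg.min_rna_cov
                and lv is not None and lv >= cfg.min_freq
                and homopolymer_run(genome, site.chrom, site.pos) <= cfg.max_homopolymer
            )
            if eligible:
                assert (site.chrom, site.pos) in called
        for snp in truth.snps:
            assert (snp.chrom, snp.pos) not in called


class TestSpectrum:
    def test_arithmetic_by_definition(self):
        calls = [call(i, freq=0.5, coverage=10) for i in range(100)]  # AG
        calls += [SiteCall("chr1", 200 + i, "T", "-", {"T": 5, "C": 5}, 10, "C",
                           0.5, {"A"}, "TC") for i in range(10)]
        others = [c for c in ("AC", "AT", "CA", "CG", "CT", "GA", "GC", "GT", "TA", "TG")]
        for j, cls in enumerate(others):
            calls.append(SiteCall("chr1", 300 + j, cls[0], "?",
                                  {cls[0]: 5, cls[1]: 5}, 10, cls[1], 0.5, {"A"}, cls))
        s = spectrum(calls)
        assert s.AG_TC_fraction == pytest.approx(110 / 120)
        assert s.fdr_estimate == pytest.approx((10 * 1 / 10) / 110)

    def test_pure_signal(self):
        s = spectrum([call(i) for i in range(5)])
        assert s.AG_TC_fraction == 1.0 and s.fdr_estimate == 0.0

    def test_empty_input_undefined(self):
        s = spectrum([])
        assert s.AG_TC_fraction is None and s.fdr_estimate is None

    def test_error_free_simulation_has_zero_fdr(self, clean_bundle):
        genome, rna, wgs = clean_bundle["genome"], clean_bundle["rna"], clean_bundle["wgs"]
        truth = clean_bundle["truth"]
        pre = call_stage_A(pileup(rna, genome), genome)
        cat = SiteCatalog([SiteCatalogEntry(c.chrom, c.pos, "+") for c in pre])
        wgs_counts = count_at_sites(wgs, genome, cat, BaseFilterConfig())
        calls, _ = run_cascade(rna, genome, wgs_counts=wgs_counts, snps=truth.snp_set())
        s = spectrum(calls)
        assert s.fdr_estimate == 0.0
        assert s.AG_TC_fraction == 1.0
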