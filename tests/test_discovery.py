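"""Filter-by-filter and end-to-end checks of the discovery cascade."""

import itertools

import pandas as pd
import pytest

from trisnp import CandidateSite, GenotypeCall, SpeciesRole, discovery
from trisnp.discovery import (
    BinConfig,
    FineFilterConfig,
    MaskConfig,
    TriallelicMarker,
    assign_bins,
    coarse_filter_site,
    drop_monomorphic,
    extract_masked_flanks,
    fine_filter_cattle,
    flanks_assay_feasible,
    run_discovery,
    tiling_bin_count,
    unique_mapping_filter,
)


def make_site(ref="A", ref_yaks=("CT", "CT"), outgroups=("CC",) * 5, cattle=(),
              pos=500):
    """Hand-built candidate site; genotype strings are two bases."""
    genotypes, roles = {}, {}
    for i, g in enumerate(ref_yaks):
        name = f"ry{i}"
        genotypes[name] = GenotypeCall(g[0], g[1])
        roles[name] = SpeciesRole.REFERENCE_YAK
    for i, g in enumerate(outgroups):
        name = f"og{i}"
        genotypes[name] = GenotypeCall(g[0], g[1]) if g else GenotypeCall.missing()
        roles[name] = SpeciesRole.OUTGROUP
    for i, g in enumerate(cattle):
        name = f"c{i}"
        genotypes[name] = GenotypeCall(g[0], g[1]) if g else GenotypeCall.missing()
        roles[name] = SpeciesRole.CATTLE_PANEL
    return CandidateSite(chrom="chr1", pos=pos, ref_allele=ref,
                         genotypes=genotypes, species_role=roles)


class TestCoarseFilter:
    def test_textbook_site_passes_and_roles_inferred(self):
        res = coarse_filter_site(make_site())
        assert res.passed
        assert res.ancestral_allele == "C" and res.yak_allele == "T"

    @pytest.mark.parametrize(
        "kwargs,reason_part",
        [
            # an outgroup carrying the yak allele
            ({"outgroups": ("CC", "CC", "CC", "CC", "CT")}, "outgroup"),
            # ancestral allele identical to the reference base
            ({"ref": "C"}, "reference base"),
            # reference yak homozygous
            ({"ref_yaks": ("CC", "CT")}, "heterozygous"),
            # yak allele equals the reference base
            ({"ref": "T"}, "reference base"),
            # outgroups split between two alleles
            ({"outgroups": ("CC", "CC", "GG", "CC", "CC")}, "homozygous"),
            # reference yaks disagree on the yak allele
            ({"ref_yaks": ("CT", "CG")}, "disagree"),
            # fourth allele in an outgroup
            ({"outgroups": ("CC", "CC", "CC", "CC", "CG")}, "homozygous"),
        ],
    )
    def test_violations_fail_with_reason(self, kwargs, reason_part):
        res = coarse_filter_site(make_site(**kwargs))
        assert not res.passed
        assert reason_part in res.reason

    def test_missing_outgroup_call_fails_insufficient(self):
        res = coarse_filter_site(make_site(outgroups=("CC", "CC", "CC", "CC", "")))
        assert not res.passed and res.reason == "insufficient calls"


class TestFineFilter:
    def _site(self, n_ref_alleles, n_cattle=96, n_missing=0):
        called = n_cattle - n_missing
        genos = []
        remaining = n_ref_alleles
        for _ in range(called):
            take = min(2, remaining)
            genos.append({2: "AA", 1: "AC", 0: "CC"}[take])
            remaining -= take
        genos += [""] * n_missing
        return make_site(ref="A", cattle=tuple(genos))

    @pytest.mark.parametrize("n_ref,expected", [(183, True), (182, False), (192, True)])
    def test_threshold_boundary(self, n_ref, expected):
        assert fine_filter_cattle(self._site(n_ref)) is expected

    def test_missing_calls_count_against_passing(self):
        # 180 reference alleles among 186 called: below the fixed 183/192 bar
        site = self._site(180, n_missing=3)
        assert fine_filter_cattle(site) is False

    def test_no_cattle_panel_raises(self):
        with pytest.raises(ValueError, match="no cattle panel"):
            fine_filter_cattle(make_site(cattle=()))

    def test_from_panel_size_scales_denominator(self):
        cfg = FineFilterConfig.from_panel_size(96)
        assert (cfg.min_ref_alleles, cfg.possible_alleles) == (183, 192)


class TestMaskedFlanks:
    REF = {"chr1": "".join("ACGT"[(i // 3) % 4] for i in range(1200))}

    def _site(self):
        s = make_site(pos=600)
        s.ancestral_allele, s.yak_allele = "C", "T"
        return s

    def test_no_variants_reproduces_reference_verbatim(self):
        cfg = MaskConfig()
        left, right = extract_masked_flanks(self._site(), self.REF, None, cfg)
        seq = self.REF["chr1"]
        assert left == seq[499:599] and right == seq[600:700]

    def test_cattle_variant_at_threshold_masked(self):
        fv = pd.DataFrame(
            [("chr1", 612, "cattle", 9)],
            columns=["chrom", "pos", "population", "allele_count"],
        )
        left, right = extract_masked_flanks(self._site(), self.REF, fv)
        assert right[11] == "N" and left.count("N") == 0 and right.count("N") == 1

    def test_subthreshold_cattle_unmasked_but_any_yak_masked(self):
        fv = pd.DataFrame(
            [("chr1", 612, "cattle", 8), ("chr1", 570, "yak", 1)],
            columns=["chrom", "pos", "population", "allele_count"],
        )
        left, right = extract_masked_flanks(self._site(), self.REF, fv)
        assert right.count("N") == 0
        # position 570 sits 30 bp left of the marker: left-flank index 70
        assert left[70] == "N" and left.count("N") == 1

    def test_masking_preserves_length_and_untouched_positions(self):
        fv = pd.DataFrame(
            [("chr1", 640, "yak", 2), ("chr1", 550, "cattle", 40)],
            columns=["chrom", "pos", "population", "allele_count"],
        )
        cfg = MaskConfig()
        left, right = extract_masked_flanks(self._site(), self.REF, fv, cfg)
        seq = self.REF["chr1"]
        assert len(left) == len(right) == cfg.flank_bp
        for i, (a, b) in enumerate(zip(left, seq[499:599])):
            assert a == b or a == "N"
        marker = TriallelicMarker("m", "chr1", 600, "C", "T", "A", left, right)
        assert marker.masked_flanks == left + "[C/T/A]" + right

    def test_flank_window_off_contig_raises(self):
        s = make_site(pos=50)
        with pytest.raises(ValueError, match="flank out of range"):
            extract_masked_flanks(s, self.REF, None)

    def test_feasibility_cap(self):
        assert flanks_assay_feasible("ACGT" * 25, "ACGT" * 25)
        assert not flanks_assay_feasible("N" * 30 + "A" * 70, "A" * 100)


class TestUniqueAndMonomorphic:
    def _markers(self, ids):
        return [TriallelicMarker(i, "chr1", 100, "C", "T", "A") for i in ids]

    def test_only_single_hit_retained(self):
        markers = self._markers(["a", "b", "c"])
        kept = unique_mapping_filter(markers, {"a": 1, "b": 0, "c": 2})
        assert [m.marker_id for m in kept] == ["a"]

    def test_missing_hits_entry_raises_with_ids(self):
        with pytest.raises(KeyError, match="b"):
            unique_mapping_filter(self._markers(["a", "b"]), {"a": 1})

    def test_monomorphic_and_uncalled_markers_removed(self, cohort_bundle):
        truth = cohort_bundle.truth
        mono = truth.loc[truth["class"] == "monomorphic", "site_id"]
        poly = truth.loc[truth["class"] == "true", "site_id"]
        markers = self._markers(list(mono) + list(poly))
        kept = drop_monomorphic(markers, cohort_bundle.population)
        assert {m.marker_id for m in kept} == set(poly)


class TestBins:
    def _marker(self, chrom, pos):
        return TriallelicMarker(f"{chrom}_{pos}", chrom, pos, "C", "T", "A")

    def test_greedy_clustering_by_hand(self):
        markers = [self._marker("chr1", p) for p in (1_000_000, 1_500_000, 7_000_000)]
        binned, summary = assign_bins(markers)
        assert [m.bin_id for m in binned] == [1, 1, 2]
        assert summary.n_bins == 2
        # representatives: median(1.0, 1.5) = 1.25 Mb and 7.0 Mb
        assert summary.mean_interbin_distance_bp == pytest.approx(5_750_000)

    def test_single_marker_single_bin(self):
        binned, summary = assign_bins([self._marker("chr1", 42)])
        assert binned[0].bin_id == 1 and summary.n_bins == 1
        assert summary.mean_interbin_distance_bp is None

    def test_chromosome_change_opens_new_bin(self):
        markers = [self._marker("chr1", 100), self._marker("chr2", 150)]
        binned, summary = assign_bins(markers)
        assert [m.bin_id for m in binned] == [1, 2]
        assert summary.mean_interbin_distance_bp is None  # no within-chrom pair

    def test_unsorted_input_raises(self):
        with pytest.raises(ValueError, match="sorted"):
            assign_bins([self._marker("chr1", 500), self._marker("chr1", 100)])

    def test_perfect_tiling_arithmetic(self):
        interior, ends = tiling_bin_count(2_479_000_000, 5_000_000, 29)
        assert interior == 496 and ends == 29

    def test_bin_config_validation(self):
        with pytest.raises(ValueError):
            BinConfig(cluster_gap_bp=5_000_000, target_spacing_bp=1_000_000)


class TestRunDiscovery:
    def test_recovers_exactly_the_planted_markers(self, cohort_bundle):
        res = run_discovery(
            cohort_bundle.cohort, cohort_bundle.population, cohort_bundle.hits,
            reference=cohort_bundle.reference,
            flank_variants=cohort_bundle.flank_variants,
        )
        planted = set(
            cohort_bundle.truth.loc[cohort_bundle.truth["class"] == "true", "site_id"]
        )
        assert {m.marker_id for m in res.panel} == planted
        assert res.stage_counts["binned"] == 20

    def test_stage_counts_decrease_monotonically(self, cohort_bundle):
        res = run_discovery(
            cohort_bundle.cohort, cohort_bundle.population, cohort_bundle.hits,
            reference=cohort_bundle.reference,
            flank_variants=cohort_bundle.flank_variants,
        )
        order = ["input", "coarse", "fine", "mask", "unique", "monomorphic"]
        counts = [res.stage_counts[s] for s in order]
        assert counts == sorted(counts, reverse=True)
        # each decoy class removes its own six sites
        assert counts == [50, 44, 38, 32, 26, 20]

    def test_empty_cohort_gives_empty_panel(self):
        from trisnp import synthetic

        bundle = synthetic.generate_discovery_cohort(synthetic.CohortSpec(n_markers=0))
        res = run_discovery(bundle.cohort, bundle.population, bundle.hits,
                            reference=bundle.reference)
        assert res.panel == [] and res.stage_counts["binned"] == 0

    def test_perturbing_one_marker_to_monomorphic_drops_it(self, cohort_bundle):
        import numpy as np

        from trisnp import ANCESTRAL, GenotypeMatrix

        pop = cohort_bundle.population
        planted = list(
            cohort_bundle.truth.loc[cohort_bundle.truth["class"] == "true", "site_id"]
        )
        j = list(pop.markers.index).index(planted[0])
        calls = pop.calls.copy()
        calls[:, j, :] = ANCESTRAL
        perturbed = GenotypeMatrix(calls, pop.animals, pop.markers)
        res = run_discovery(
            cohort_bundle.cohort, perturbed, cohort_bundle.hits,
            reference=cohort_bundle.reference,
            flank_variants=cohort_bundle.flank_variants,
        )
        assert len(res.panel) == 19
        assert planted[0] not in {m.marker_id for m in res.panel}

    def test_survivor_set_is_order_independent(self, cohort_bundle):
        """Filters are pure predicates: applying them site-wise in any
        order yields the same survivors as the staged cascade."""
        from trisnp.discovery import MaskConfig, site_is_snv

        survivors = set()
        mask_cfg = MaskConfig()
        freq_ok = {
            m.marker_id
            for m in drop_monomorphic(
                [TriallelicMarker(s.site_id, s.chrom, s.pos, "C", "T", "A")
                 for s in cohort_bundle.cohort.sites],
                cohort_bundle.population,
            )
        }
        for s in cohort_bundle.cohort.sites:
            # evaluate predicates in reverse order of the cascade
            if cohort_bundle.hits[s.site_id] != 1:
                continue
            if s.site_id not in freq_ok:
                continue
            if not site_is_snv(s).passed:
                continue
            left, right = extract_masked_flanks(
                s, cohort_bundle.reference, cohort_bundle.flank_variants, mask_cfg
            )
            if not flanks_assay_feasible(left, right, mask_cfg):
                continue
            if not fine_filter_cattle(s):
                continue
            if not coarse_filter_site(s).passed:
                continue
            survivors.add(s.site_id)
        res = run_discovery(
            cohort_bundle.cohort, cohort_bundle.population, cohort_bundle.hits,
            reference=cohort_bundle.reference,
            flank_variants=cohort_bundle.flank_variants,
        )
        assert survivors == {m.marker_id for m in res.panel}
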