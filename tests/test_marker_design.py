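import pytest

from fleshmark.io_core import revcomp
from fleshmark.marker_design import (
    DesignError,
    PrimerConstraints,
    compute_tm,
    design_length_marker,
    design_marker_suite,
    expected_length_difference,
    gc_fraction,
    max_mononucleotide_run,
)
from fleshmark.insilico_genotyping import simulate_pcr
from fleshmark.synthetic_panel import (
    GeneratorConfig,
    default_spec_table,
    simulate_experiment,
)
from fleshmark.variant_analysis import PanelAlignment, call_variants


class TestTm:
    def test_wallace_rule_arithmetic(self):
        assert compute_tm("GC" * 5 + "AT" * 5) == 60.0  # 4*10 + 2*10
        assert compute_tm("AAAAAAAA") == 16.0

    def test_reverse_complement_invariance(self):
        p = "ACGTTGCAGGCTAATCGG"
        assert compute_tm(p) == compute_tm(revcomp(p))

    def test_nn_model_available(self):
        p = "ACGTTGCAGGCTAATCGG"
        assert 40 < compute_tm(p, method="nn") < 75

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            compute_tm("ACGTNACGTACG")

    def test_helpers(self):
        assert gc_fraction("GGCC") == 1.0
        assert max_mononucleotide_run("AATTTTGC") == 4


class TestConstraints:
    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            PrimerConstraints(tm=(65.0, 55.0))


class TestLengthMarkers:
    def test_idp_size_difference_is_fourteen(self, pipeline_result):
        idp = next(m for m in pipeline_result.markers if m.marker_name == "ID-P")
        assert idp.mode == "codominant_length"
        assert abs(idp.expected_sizes["Wf"] - idp.expected_sizes["Rf"]) == 14

    def test_ssr_size_difference_matches_repeat_counts(self, pipeline_result):
        ssr = next(m for m in pipeline_result.markers if m.marker_name == "SSR-P")
        target = next(
            v
            for v in pipeline_result.discovery_variants
            if v.kind == "SSR" and v.specificity == "Rf_vs_Wf"
            and expected_length_difference(v)
            == abs(ssr.expected_sizes["Wf"] - ssr.expected_sizes["Rf"])
        )
        counts = [int(s) for s in target.states.values() if s is not None]
        assert abs(ssr.expected_sizes["Wf"] - ssr.expected_sizes["Rf"]) == (
            max(counts) - min(counts)
        ) * len(target.unit)

    def test_length_primers_bind_identically_in_all_alleles(self, pipeline_result, experiment):
        pa = PanelAlignment(
            experiment.discovery.alleles + experiment.validation.alleles,
            reference_id=experiment.reference_id,
        )
        for marker in pipeline_result.markers:
            if marker.mode != "codominant_length":
                continue
            fw, rv = marker.pairs["band"]
            for allele in pa.panel:
                amps = simulate_pcr(fw.sequence, rv.sequence, allele.sequence, (50, 5000))
                assert len(amps) == 1, (marker.marker_name, allele.allele_id)

    def test_size_arithmetic_on_reference(self, pipeline_result, experiment):
        ref = {a.allele_id: a for a in experiment.discovery.alleles}[
            experiment.reference_id
        ]
        for marker in pipeline_result.markers:
            if marker.mode != "codominant_length":
                continue
            fw, rv = marker.pairs["band"]
            amps = simulate_pcr(fw.sequence, rv.sequence, ref.sequence, (50, 5000))
            assert amps[0].size == amps[0].end - amps[0].start + 1
            # reference allele is red-flesh: band must match the Rf class size
            assert amps[0].size == marker.expected_sizes["Rf"]

    def test_snp_target_rejected(self, discovery_variants, experiment):
        pa = PanelAlignment(
            experiment.discovery.alleles, reference_id=experiment.reference_id
        )
        snp = next(v for v in discovery_variants if v.kind == "SNP")
        with pytest.raises(DesignError, match="InDel or SSR"):
            design_length_marker(snp, pa)


class TestAlleleSpecificPairs:
    def test_each_pair_amplifies_only_its_own_group(self, pipeline_result, experiment):
        alleles = experiment.discovery.alleles + experiment.validation.alleles
        from fleshmark.io_core import group_of

        for marker in pipeline_result.markers:
            if marker.mode != "dominant_allele_specific_pair":
                continue
            for own, (fw, rv) in marker.pairs.items():
                for allele in alleles:
                    g = group_of(allele)
                    n = len(
                        simulate_pcr(fw.sequence, rv.sequence, allele.sequence, (100, 1200))
                    )
                    assert n == (1 if g == own else 0), (
                        marker.marker_name, own, allele.allele_id,
                    )

    def test_three_prime_terminus_discriminates(self, pipeline_result, experiment):
        """The other group's haplotype must mismatch at least one primer within
        its 3'-terminal bases at the design site (exact-match scan)."""
        from fleshmark.insilico_genotyping import BindingModel, find_binding_sites
        from fleshmark.io_core import group_of

        strict = BindingModel(max_mismatch=2, exact_3prime_bases=3)
        for marker in pipeline_result.markers:
            if marker.mode != "dominant_allele_specific_pair":
                continue
            for own, (fw, rv) in marker.pairs.items():
                other = [a for a in experiment.discovery.alleles if group_of(a) != own]
                own_alleles = [a for a in experiment.discovery.alleles if group_of(a) == own]
                for a in own_alleles:
                    assert find_binding_sites(fw.sequence, a.sequence, strict)
                # on the other group at least one of fw/rv finds no site at all
                for a in other:
                    sites_fw = find_binding_sites(fw.sequence, a.sequence, strict)
                    sites_rv = find_binding_sites(rv.sequence, a.sequence, strict)
                    assert not (sites_fw and sites_rv)


class TestMarkerSuite:
    def test_default_panel_yields_four_markers(self, pipeline_result):
        assert sorted(m.marker_name for m in pipeline_result.markers) == [
            "ID-P", "PS-P", "SSR-P", "WD/AD-P",
        ]
        assert pipeline_result.failures == []

    def test_panel_without_ssrs_fails_only_ssr_marker(self):
        table = tuple(s for s in default_spec_table() if s.kind != "SSR")
        exp = simulate_experiment(GeneratorConfig(seed=5, spec_table=table))
        pa = PanelAlignment(exp.discovery.alleles, reference_id=exp.reference_id)
        variants = call_variants(pa, exp.model)
        sets, failures = design_marker_suite(variants, pa, exp.model)
        assert sorted(m.marker_name for m in sets) == ["ID-P", "PS-P", "WD/AD-P"]
        assert [f.marker_name for f in failures] == ["SSR-P"]
        assert "no diagnostic SSR" in failures[0].reason

    def test_impossible_constraints_fail_all_four(self, discovery_variants, experiment):
        pa = PanelAlignment(
            experiment.discovery.alleles, reference_id=experiment.reference_id
        )
        impossible = PrimerConstraints(length=(18, 20), tm=(70.0, 71.0))
        sets, failures = design_marker_suite(
            discovery_variants, pa, experiment.model, impossible
        )
        assert sets == []
        assert len(failures) == 4

    def test_determinism(self, discovery_variants, experiment, pipeline_result):
        pa = PanelAlignment(
            experiment.discovery.alleles + experiment.validation.alleles,
            reference_id=experiment.reference_id,
        )
        sets, _ = design_marker_suite(
            discovery_variants, pa, experiment.model,
            mask_variants=pipeline_result.union_variants,
        )
        seqs = {
            (m.marker_name, k): (fw.sequence, rv.sequence)
            for m in sets
            for k, (fw, rv) in m.pairs.items()
        }
        seqs2 = {
            (m.marker_name, k): (fw.sequence, rv.sequence)
            for m in pipeline_result.markers
            for k, (fw, rv) in m.pairs.items()
        }
        assert seqs == seqs2
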