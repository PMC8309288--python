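import numpy as np
import pytest

from fleshmark.io_core import AlleleRecord, revcomp
from fleshmark.insilico_genotyping import (
    BindingModel,
    calls_to_frame,
    call_marker_genotype,
    find_binding_sites,
    genotype_panel,
    predict_phenotype,
    simulate_pcr,
)
from fleshmark.io_core import AccessionMeta

RNG = np.random.default_rng(77)


def _rand(n):
    return "".join(RNG.choice(list("ACGT"), size=n))


class TestBindingSites:
    def test_exact_match_single_site(self):
        t = _rand(200)
        p = t[50:70]
        sites = find_binding_sites(p, t)
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].start, plus[0].end, plus[0].mismatches) == (51, 70, 0)
        assert plus[0].three_prime_pos == 70

    def test_three_prime_terminal_mismatch_blocks_binding(self):
        t = _rand(200)
        p = list(t[50:70])
        p[-1] = next(b for b in "ACGT" if b != p[-1])
        sites = [s for s in find_binding_sites("".join(p), t) if s.strand == "+"]
        assert sites == []

    def test_internal_mismatch_tolerated_and_counted(self):
        t = _rand(200)
        p = list(t[50:70])
        p[5] = next(b for b in "ACGT" if b != p[5])
        sites = [s for s in find_binding_sites("".join(p), t) if s.strand == "+"]
        assert len(sites) == 1 and sites[0].mismatches == 1

    def test_reverse_strand_three_prime_is_leftmost(self):
        t = _rand(200)
        p = revcomp(t[50:70])
        sites = [s for s in find_binding_sites(p, t) if s.strand == "-"]
        assert len(sites) == 1
        assert sites[0].three_prime_pos == 51

    def test_primer_longer_than_template_warns_empty(self):
        assert find_binding_sites("ACGTACGTACGT", "ACGT") == []

    def test_template_n_counts_as_mismatch(self):
        t = _rand(200)
        p = t[50:70]
        tn = t[:55] + "N" + t[56:]
        sites = [s for s in find_binding_sites(p, tn) if s.strand == "+"]
        assert len(sites) == 1 and sites[0].mismatches == 1

    @pytest.mark.parametrize("trial", range(5))
    def test_monotone_in_max_mismatch(self, trial):
        rng = np.random.default_rng(trial)
        t = "".join(rng.choice(list("ACGT"), size=500))
        p = t[100:120]
        prev: set = set()
        for mm in range(0, 4):
            sites = {
                (s.strand, s.start)
                for s in find_binding_sites(p, t, BindingModel(max_mismatch=mm))
            }
            assert prev <= sites
            prev = sites


class TestSimulatePcr:
    def test_amplicon_size_is_five_prime_distance_inclusive(self):
        t = _rand(500)
        fw = t[99:119]  # 5' at 100
        rv = revcomp(t[380:400])  # 5' at 400... rv footprint 381..400
        amps = simulate_pcr(fw, rv, t, (50, 5000))
        assert len(amps) == 1
        assert amps[0] .size == 400 - 100 + 1
        assert (amps[0].start, amps[0].end) == (100, 400)

    def test_divergent_orientation_yields_nothing(self):
        t = _rand(500)
        fw = revcomp(t[99:119])  # points leftward at position 100
        rv = t[380:400]  # points rightward at 381
        assert simulate_pcr(fw, rv, t, (50, 5000)) == []

    def test_size_range_filters(self):
        t = _rand(500)
        fw, rv = t[99:119], revcomp(t[380:400])
        assert simulate_pcr(fw, rv, t, (50, 200)) == []


class TestCalls:
    def test_heterozygote_shows_both_bands(self, pipeline_result, experiment):
        idp = next(m for m in pipeline_result.markers if m.marker_name == "ID-P")
        het = [a for a in experiment.validation.alleles if a.accession_id == "RedSun"]
        call = call_marker_genotype(idp, het)
        assert call.call == "Het"
        sizes = sorted(s for b in call.bands.values() for s in b)
        assert abs(sizes[1] - sizes[0]) == 14

    def test_band_set_is_union_of_allele_band_sets(self, pipeline_result, experiment):
        by_acc = {}
        for a in experiment.validation.alleles:
            by_acc.setdefault(a.accession_id, []).append(a)
        for marker in pipeline_result.markers:
            for acc_id, alleles in by_acc.items():
                both = call_marker_genotype(marker, alleles)
                for single in alleles:
                    solo = call_marker_genotype(marker, [single])
                    assert solo.bands[single.allele_id] == both.bands[single.allele_id]

    def test_chengwoo_ssr_call_is_rf_discordant_with_phenotype(
        self, pipeline_result, experiment
    ):
        ssr = next(m for m in pipeline_result.markers if m.marker_name == "SSR-P")
        cheng = [a for a in experiment.validation.alleles if a.accession_id == "Chengwoo"]
        call = call_marker_genotype(ssr, cheng)
        assert call.call == "Rf"
        assert predict_phenotype(call.call) == "red"  # phenotype on record is white

    def test_no_amplification_is_fail(self, pipeline_result):
        marker = pipeline_result.markers[0]
        scrambled = AlleleRecord("x_1", "x", None, "WsWf", _rand(3000))
        assert call_marker_genotype(marker, [scrambled]).call == "fail"

    def test_phenotype_rules(self):
        assert predict_phenotype("Het", "dominant") == "red"
        assert predict_phenotype("Het", "recessive") == "white"
        assert predict_phenotype("fail") is None
        with pytest.raises(ValueError):
            predict_phenotype("Rf", "codominant")


class TestConcordance:
    def test_default_panel_concordance(self, pipeline_result):
        rep = pipeline_result.concordance
        for name in ("PS-P", "ID-P", "WD/AD-P"):
            assert rep.fraction(name) == 1.0
        assert rep.fraction("SSR-P") < 1.0
        assert rep.discordant["SSR-P"] == ["Chengwoo"]
        df = rep.per_marker
        total = df[["concordant", "discordant", "uncallable", "segregating"]].sum(axis=1)
        assert (total == 10).all()  # panel size

    def test_unknown_phenotypes_are_uncallable(self, pipeline_result, experiment):
        alleles = [a for a in experiment.validation.alleles][:4]
        accs = [
            AccessionMeta(m.accession_id, m.line_name, "unknown", m.allele_ids, m.subtype)
            for m in experiment.validation.accessions[:2]
        ]
        calls, rep = genotype_panel(pipeline_result.markers[:1], alleles, accs)
        row = rep.per_marker.iloc[0]
        assert row["uncallable"] == 2 and row["concordant"] == 0
        assert np.isnan(row["fraction_concordant"])

    def test_segregating_bucket(self, pipeline_result, experiment):
        accs = [
            AccessionMeta(m.accession_id, m.line_name, "pink", m.allele_ids, m.subtype)
            for m in experiment.validation.accessions[:2]
        ]
        alleles = [
            a for a in experiment.validation.alleles
            if a.accession_id in {m.accession_id for m in accs}
        ]
        _, rep = genotype_panel(pipeline_result.markers[:1], alleles, accs)
        assert rep.per_marker.iloc[0]["segregating"] == 2

    def test_calls_frame_shape(self, pipeline_result):
        df = calls_to_frame(pipeline_result.calls)
        assert set(df.columns) == {"accession_id", "marker", "bands", "call", "note"}
        assert len(df) == len(pipeline_result.calls)
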