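import numpy as np
import pytest

from fleshmark.io_core import AlleleRecord, GeneFeature, GeneModel
from fleshmark.synthetic_panel import GeneratorConfig, simulate_experiment
from fleshmark.variant_analysis import (
    AlignParams,
    PanelAlignment,
    SSRLocus,
    Variant,
    align_pair,
    annotate_coding_effect,
    call_variants,
    canonical_rotation,
    classify_specificity,
    detect_ssr_loci,
    left_normalize,
    resolve_ssr_overlaps,
    summarize_matrix,
)

RNG = np.random.default_rng(1234)


def _random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _gotoh_score(a, b, p=AlignParams()):
    """Independent affine-gap DP (gap of length L costs open + L*extend)."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = p.gap_open + i * p.gap_extend
    for j in range(1, m + 1):
        Y[0][j] = p.gap_open + j * p.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + p.gap_open + p.gap_extend, X[i - 1][j] + p.gap_extend)
            Y[i][j] = max(M[i][j - 1] + p.gap_open + p.gap_extend, Y[i][j - 1] + p.gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


class TestAlignPair:
    def test_identity_has_no_edits(self):
        aln = align_pair("ACGT", "ACGT")
        assert aln.score == 8
        assert aln.counts().gaps == 0

    def test_single_substitution_column(self):
        aln = align_pair("ACGTACGT", "ACGAACGT")
        assert aln.counts().gaps == 0
        assert aln.counts().mismatches == 1

    @pytest.mark.parametrize("trial", range(4))
    def test_score_matches_independent_dp_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        ref = _random_seq(300, rng)
        ins = _random_seq(14, rng)
        q = ref[:150] + ins + ref[150:]
        q = q[:40] + ("A" if q[40] != "A" else "C") + q[41:]
        assert align_pair(ref, q).score == pytest.approx(_gotoh_score(ref, q))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestLeftNormalize:
    def test_deletion_in_homopolymer_shifts_to_run_start(self):
        ref = "GGGC" + "A" * 6 + "CGGG"
        # deleting any 2 As is equivalent; normal form starts at the first A
        for pos in range(5, 9):
            npos, nseq = left_normalize(ref, pos, "del", ref[pos - 1 : pos + 1])
            assert (npos, nseq) == (5, "AA")

    def test_insertion_in_repeat_shifts_left(self):
        ref = "GGC" + "TA" * 4 + "CGG"
        npos, nseq = left_normalize(ref, 8, "ins", "TA")
        assert npos == 4
        assert nseq in ("TA", "AT")  # rotated into the run's leftmost phase


# ---------------------------------------------------------------------------
# SSR detection
# ---------------------------------------------------------------------------


def _ssr_oracle(seq, min_unit=1, max_unit=6, min_repeats=4, min_length=8):
    """Array-based period scan, independent of the package's char-walk."""
    s = np.frombuffer(seq.encode(), np.uint8)
    cands = []
    for u in range(min_unit, max_unit + 1):
        eq = s[u:] == s[:-u]
        idx = np.flatnonzero(eq)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for a, b in zip(idx[starts], idx[ends]):
            start0 = a  # first matching comparison is at offset a (seq pos a+u vs a)
            total = (b - a + 1) + u
            reps = total // u
            unit = seq[start0 : start0 + u]
            if reps < min_repeats or reps * u < min_length:
                continue
            if set(unit) - set("ACGT"):
                continue
            if any(u % d == 0 and unit == unit[:d] * (u // d) for d in range(1, u)):
                continue
            cands.append(SSRLocus(canonical_rotation(unit), start0 + 1, reps))
    return resolve_ssr_overlaps(cands)


class TestSSRDetection:
    def test_tc_thirteen(self):
        seq = "AA" + "TC" * 13 + "GG"
        loci = detect_ssr_loci(seq)
        assert len(loci) == 1
        loc = loci[0]
        assert (loc.unit, loc.start, loc.repeats) == (canonical_rotation("TC"), 3, 13)

    def test_below_min_repeats_not_reported(self):
        assert detect_ssr_loci("AATCTCTCGG") == []  # (TC)3

    def test_homopolymer_and_primitivity(self):
        loci = detect_ssr_loci("GC" + "A" * 9 + "GC")
        assert len(loci) == 1
        assert (loci[0].unit, loci[0].repeats) == ("A", 9)

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_ssr_loci("ACGT", min_repeats=0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle_on_random_sequence(self, trial):
        rng = np.random.default_rng(42 + trial)
        seq = "".join(rng.choice(list("ACGT"), size=2000, p=[0.3, 0.2, 0.2, 0.3]))
        assert detect_ssr_loci(seq) == _ssr_oracle(seq)


# ---------------------------------------------------------------------------
# classification / annotation
# ---------------------------------------------------------------------------

INFO = {
    "rf1": ("Rf", "GsRf"),
    "rf2": ("Rf", "GsRf"),
    "rf3": ("Rf", "RsRf"),
    "rf4": ("Rf", "RsRf"),
    "ww1": ("Wf", "WsWf"),
    "ww2": ("Wf", "WsWf"),
    "rw1": ("Wf", "RsWf"),
    "rw2": ("Wf", "RsWf"),
}


class TestClassifySpecificity:
    @pytest.mark.parametrize(
        "states,expected",
        [
            (dict(rf1="A", rf2="A", rf3="A", rf4="A", ww1="G", ww2="G", rw1="G", rw2="G"),
             "Rf_vs_Wf"),
            (dict(rf1="A", rf2="G", rf3="A", rf4="A", ww1="G", ww2="G", rw1="G", rw2="G"),
             "nondiagnostic"),
            (dict(rf1="C", rf2="C", rf3="C", rf4="C", ww1="T", ww2="T", rw1="C", rw2="C"),
             "WsWf_specific"),
            (dict(rf1="C", rf2="C", rf3="C", rf4="C", ww1="C", ww2="C", rw1="A", rw2="A"),
             "RsWf_specific"),
            (dict(rf1="C", rf2="C", rf3="C", rf4="C", ww1="T", ww2="T", rw1="A", rw2="A"),
             "nondiagnostic"),
        ],
    )
    def test_definition_cases(self, states, expected):
        assert classify_specificity(states, INFO) == expected

    def test_missing_states_excluded_from_vote(self):
        states = dict(rf1="A", rf2=None, rf3="A", rf4="A",
                      ww1="G", ww2="G", rw1="G", rw2=None)
        assert classify_specificity(states, INFO) == "Rf_vs_Wf"


def _toy_model():
    # promoter 1..30, one exon covering CDS 41..52 (ATG at 41), strict off
    feats = (
        GeneFeature("promoter", 1, 1, 30),
        GeneFeature("exon", 1, 31, 60),
        GeneFeature("intron", 1, 61, 80),
        GeneFeature("exon", 2, 81, 100),
    )
    return GeneModel("ref", feats, tss_pos=31, atg_pos=41).validate(strict_structure=False)


class TestCodingEffect:
    def _variant(self, kind, gpos, states, length=1, ref_state=None):
        m = _toy_model()
        return Variant(
            kind=kind, position=gpos - 41 + 1 if gpos >= 41 else gpos - 41,
            genomic_pos=gpos, region=m.region_name(gpos),
            ref_state=ref_state, states=states, length=length,
        )

    def test_synonymous_third_position(self):
        m = _toy_model()
        ref = "T" * 40 + "ATGGAACTG" + "T" * 51
        v = self._variant("SNP", 46, {"a": "A", "b": "G"}, ref_state="A")
        assert annotate_coding_effect(v, m, ref) == "synonymous"  # GAA -> GAG (Glu)

    def test_nonsynonymous_first_position(self):
        m = _toy_model()
        ref = "T" * 40 + "ATGGAACTG" + "T" * 51
        v = self._variant("SNP", 44, {"a": "G", "b": "C"}, ref_state="G")
        assert annotate_coding_effect(v, m, ref) == "nonsynonymous"  # GAA -> CAA

    def test_intronic_indel_noncoding(self):
        m = _toy_model()
        ref = "A" * 100
        v = self._variant("InDel", 70, {"a": "ref", "b": "del:CAT"}, length=3)
        assert annotate_coding_effect(v, m, ref) == "noncoding"

    def test_exonic_two_nt_deletion_frameshift(self):
        m = _toy_model()
        ref = "A" * 100
        v = self._variant("InDel", 45, {"a": "ref", "b": "del:AA"}, length=2)
        assert annotate_coding_effect(v, m, ref) == "frameshift"

    def test_exonic_in_frame_insertion(self):
        m = _toy_model()
        ref = "A" * 100
        v = self._variant("InDel", 45, {"a": "ref", "b": "ins:CCC"}, length=3)
        assert annotate_coding_effect(v, m, ref) == "in_frame_indel"


# ---------------------------------------------------------------------------
# end-to-end calling
# ---------------------------------------------------------------------------


def _panel_from(seqs):
    subtype = {"r": "GsRf", "w": "WsWf"}
    return [
        AlleleRecord(aid, aid.split("_")[0], None, subtype[aid[0]], s)
        for aid, s in seqs.items()
    ]


class TestCallVariants:
    def test_identical_panel_yields_no_variants(self):
        seq = _random_seq(500)
        panel = _panel_from({"r1_1": seq, "r1_2": seq, "w1_1": seq, "w1_2": seq})
        feats = (GeneFeature("promoter", 1, 1, 100), GeneFeature("exon", 1, 101, 500))
        model = GeneModel("r1_1", feats, 101, 131).validate(strict_structure=False)
        assert call_variants(panel, model) == []

    def test_fourteen_nt_promoter_insertion_called_at_minus_35(self, experiment):
        pa = PanelAlignment(
            experiment.discovery.alleles, reference_id=experiment.reference_id
        )
        variants = call_variants(pa, experiment.model)
        hits = [v for v in variants if v.kind == "InDel" and v.position == -35]
        assert len(hits) == 1
        v = hits[0]
        assert v.length == 14
        assert v.region == "promoter"
        assert v.specificity == "Rf_vs_Wf"
        wf_states = {s for aid, s in v.states.items() if aid.startswith(("WsWf", "RsWf"))}
        assert len(wf_states) == 1 and next(iter(wf_states)).startswith("ins:")

    def test_n_bases_are_missing_states_not_variants(self):
        seq = _random_seq(400)
        qn = seq[:200] + "N" + seq[201:]
        panel = _panel_from({"r1_1": seq, "r1_2": seq, "w1_1": qn, "w1_2": seq})
        feats = (GeneFeature("promoter", 1, 1, 100), GeneFeature("exon", 1, 101, 400))
        model = GeneModel("r1_1", feats, 101, 131).validate(strict_structure=False)
        assert call_variants(panel, model) == []

    @pytest.mark.parametrize("seed", [3, 12])
    def test_recovery_equals_truth_set(self, seed):
        exp = simulate_experiment(GeneratorConfig(seed=seed))
        pa = PanelAlignment(exp.discovery.alleles, reference_id=exp.reference_id)
        called = {
            (v.kind, v.position, v.region, v.specificity)
            for v in call_variants(pa, exp.model)
        }
        truth = {
            (r.kind, r.position, r.region, r.specificity)
            for r in exp.discovery.truth.itertuples(index=False)
        }
        assert called == truth


class TestMatrix:
    def test_empty_variant_list_gives_zero_matrix(self):
        m = summarize_matrix([])
        assert (m.to_numpy() == 0).all()

    def test_total_row_equals_column_sums(self, discovery_variants):
        m = summarize_matrix(discovery_variants)
        assert (
            m.loc["Total"] == m.loc[["Promoter", "Exon", "Intron"]].sum(axis=0)
        ).all()

    def test_nondiagnostic_excluded(self, discovery_variants):
        m = summarize_matrix(discovery_variants)
        n_classified = int(m.loc["Total"].sum())
        assert n_classified <= len(discovery_variants)
        assert n_classified == sum(
            1 for v in discovery_variants if v.specificity != "nondiagnostic"
        )
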