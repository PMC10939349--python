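import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from archannot.consensus import (
    Agreement,
    AnnotationSource,
    Tier,
    annotate_all,
    classify_pf_likelihood,
    classify_tr_significance,
    labels_agree,
    pf_coverage,
    reconcile,
    tr_admissible,
)
from archannot.model import (
    DFPrediction,
    EvidenceBundle,
    KOAnnotation,
    PFKind,
    PFMatch,
    TRHit,
    ValidationError,
)
from ladder_oracle import oracle_reconcile


def _pf(e_value, label="alpha beta", kind=PFKind.TEMPLATE_3D,
        segment=100, qlen=200, identity=50.0):
    return PFMatch(kind, e_value, identity, segment, qlen, label)


def _tr(tm, label="gamma delta", confidence=0.8, e_value=1e-4,
        coverage=0.6, identity=0.4):
    return TRHit("tmpl1A", confidence, e_value, coverage, identity, tm, label)


class TestTierClassifiers:
    @pytest.mark.parametrize("e,tier", [
        (1e-7, Tier.CERTAIN),
        (1e-6, Tier.PROBABLE),   # boundary falls to the weaker tier
        (0.005, Tier.PROBABLE),
        (0.01, Tier.POSSIBLE),
        (0.05, Tier.POSSIBLE),
        (0.1, Tier.LONG_SHOT),
        (5.0, Tier.LONG_SHOT),
        (10.0, Tier.NONE),
        (0.0, Tier.CERTAIN),
    ])
    def test_pf_bands(self, e, tier):
        assert classify_pf_likelihood(e) == tier

    @pytest.mark.parametrize("tm,tier", [
        (0.75, Tier.VERY_HIGH),
        (0.7, Tier.HIGH),        # strict >
        (0.55, Tier.HIGH),
        (0.45, Tier.MEDIUM),
        (0.35, Tier.LOW),
        (0.30, Tier.NONE),
        (0.0, Tier.NONE),
        (1.0, Tier.VERY_HIGH),
    ])
    def test_tr_bands(self, tm, tier):
        assert classify_tr_significance(tm) == tier

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            classify_pf_likelihood(-1e-9)
        with pytest.raises(ValidationError):
            classify_tr_significance(1.01)

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_pf_tier_monotone_in_evalue(self, e):
        """Lowering an E-value never lowers the tier rank."""
        assert classify_pf_likelihood(e / 2) >= classify_pf_likelihood(e)

    @given(st.floats(min_value=0, max_value=1, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_tr_tier_monotone_in_tm(self, tm):
        assert classify_tr_significance(min(1.0, tm * 1.5)) >= \
            classify_tr_significance(tm)


class TestAdmissibilityAndCoverage:
    @pytest.mark.parametrize("conf,e,cov,ok", [
        (0.7, 1e-4, 0.5, True),
        (0.6, 1e-4, 0.5, False),   # strict >
        (0.7, 0.001, 0.5, False),  # strict <
        (0.7, 1e-4, 0.3, False),   # strict >
    ])
    def test_tr_admissibility_thresholds(self, conf, e, cov, ok):
        assert tr_admissible(_tr(0.8, confidence=conf, e_value=e,
                                 coverage=cov)) is ok

    @pytest.mark.parametrize("segment,qlen,expected", [
        (50, 100, 0.5), (0, 100, 0.0), (100, 100, 1.0),
    ])
    def test_pf_coverage_ratio(self, segment, qlen, expected):
        assert pf_coverage(segment, qlen) == expected

    def test_zero_query_length_rejected(self):
        with pytest.raises(ValidationError):
            pf_coverage(0, 0)


class TestReconcileLadder:
    def test_matching_labels_give_consensus_at_max_rank(self):
        bundle = EvidenceBundle("s", pf_matches=[_pf(1e-8, "protein X")],
                                tr_hits=[_tr(0.75, "protein X")])
        ann = reconcile(bundle)
        assert ann.source == AnnotationSource.CONSENSUS
        assert ann.final_label == "protein X"
        assert ann.tier == Tier.CERTAIN  # rank 4

    def test_very_high_tr_beats_probable_pf(self):
        bundle = EvidenceBundle("s", pf_matches=[_pf(1e-4, "hydrolase")],
                                tr_hits=[_tr(0.75, "kinase")])
        ann = reconcile(bundle)
        assert ann.source == AnnotationSource.TR
        assert ann.final_label == "kinase"

    def test_equal_rank_higher_coverage_wins(self):
        # both rank 4; TR coverage 0.8 vs PF coverage 0.6
        bundle = EvidenceBundle(
            "s",
            pf_matches=[_pf(1e-8, "hydrolase", segment=120, qlen=200)],
            tr_hits=[_tr(0.75, "kinase", coverage=0.8)],
        )
        assert reconcile(bundle).final_label == "kinase"
        bundle = EvidenceBundle(
            "s",
            pf_matches=[_pf(1e-8, "hydrolase", segment=180, qlen=200)],
            tr_hits=[_tr(0.75, "kinase", coverage=0.8)],
        )
        assert reconcile(bundle).final_label == "hydrolase"

    def test_admissible_tr_beats_long_shot(self):
        bundle = EvidenceBundle("s", pf_matches=[_pf(0.5, "hydrolase")],
                                tr_hits=[_tr(0.35, "kinase")])
        assert reconcile(bundle).source == AnnotationSource.TR

    def test_tr_priority_without_3d_hits(self):
        bundle = EvidenceBundle(
            "s",
            pf_matches=[_pf(1e-9, "hydrolase", kind=PFKind.SEQUENCE_VS_PDB)],
            tr_hits=[_tr(0.45, "kinase")],
        )
        assert reconcile(bundle).source == AnnotationSource.TR

    def test_lone_pf_assigns_only_at_certain(self):
        certain = EvidenceBundle("s", pf_matches=[_pf(1e-8, "protein X")])
        assert reconcile(certain).source == AnnotationSource.PF
        probable = EvidenceBundle("s", pf_matches=[_pf(1e-4, "protein X")])
        ann = reconcile(probable)
        assert ann.source == AnnotationSource.NONE
        assert ann.final_label == "unannotated"

    def test_inadmissible_tr_counts_as_absent(self):
        bundle = EvidenceBundle("s", tr_hits=[_tr(0.9, confidence=0.5)])
        assert reconcile(bundle).source == AnnotationSource.NONE

    def test_empty_bundle_unannotated(self):
        ann = reconcile(EvidenceBundle("s"))
        assert (ann.final_label, ann.source, ann.tier) == \
            ("unannotated", AnnotationSource.NONE, Tier.NONE)

    def test_best_pf_prefers_3d_at_equal_evalue(self):
        seq = _pf(1e-8, "seq label", kind=PFKind.SEQUENCE_VS_PDB)
        tpl = _pf(1e-8, "template label", kind=PFKind.TEMPLATE_3D)
        bundle = EvidenceBundle("s", pf_matches=[seq, tpl])
        assert reconcile(bundle).final_label == "template label"


class TestDFAndAgreement:
    def test_df_supports_only_above_gate_with_shared_token(self):
        bundle = EvidenceBundle(
            "s", pf_matches=[_pf(1e-8, "glycosyltransferase family protein")],
            df_predictions=[DFPrediction("GO:1", 0.8,
                                         "glycosyltransferase activity")])
        assert reconcile(bundle).df_supported is True
        bundle.df_predictions = [DFPrediction("GO:1", 0.7,
                                              "glycosyltransferase activity")]
        assert reconcile(bundle).df_supported is False  # strict > 0.7
        bundle.df_predictions = [DFPrediction("GO:1", 0.9, "protease activity")]
        assert reconcile(bundle).df_supported is False

    @pytest.mark.parametrize("structure,seq_ko,expected", [
        (True, True, Agreement.CONSISTENT),
        (True, False, Agreement.STRUCTURE_ONLY),
        (False, True, Agreement.SEQUENCE_ONLY),
        (False, False, Agreement.UNANNOTATED),
    ])
    def test_agreement_categories(self, structure, seq_ko, expected):
        bundle = EvidenceBundle("s")
        if structure:
            bundle.pf_matches = [_pf(1e-8, "recombinase protein")]
        if seq_ko:
            bundle.sequence_ko = KOAnnotation(
                "s", frozenset({"K06400"}),
                labels={"K06400": "site-specific recombinase"})
        assert reconcile(bundle).agreement == expected

    def test_disparate_when_labels_share_no_token(self):
        bundle = EvidenceBundle(
            "s", pf_matches=[_pf(1e-8, "pilus assembly protein")],
            sequence_ko=KOAnnotation("s", frozenset({"K00001"}),
                                     labels={"K00001": "alcohol dehydrogenase"}))
        assert reconcile(bundle).agreement == Agreement.DISPARATE

    def test_token_matching_ignores_short_words(self):
        assert labels_agree("ABC transporter", "ABC hydrolase") is False
        assert labels_agree("Type IV pilus", "pilus assembly") is True
        assert labels_agree("Protein X", "protein x", exact=True) is True


class TestOracleEquivalence:
    """The ladder must agree with an independent table-driven interpreter
    on the full enumeration of presence/label/tier combinations."""

    PF_EVALUES = {"certain": 1e-8, "probable": 1e-4, "possible": 0.05,
                  "long_shot": 0.5, "none": 50.0}
    TR_TMS = {"very_high": 0.8, "high": 0.6, "medium": 0.45,
              "low": 0.35, "none": 0.2}
    LABELS = {"A": "alpha factor", "B": "beta factor"}

    def _cases(self):
        for pf_state in (None, "A", "B"):
            for tr_state in (None, "A", "B"):
                for pf_tier, e in self.PF_EVALUES.items():
                    for tr_tier, tm in self.TR_TMS.items():
                        pf = None
                        if pf_state:
                            pf = {"kind": "template_3d", "e_value": e,
                                  "percent_identity": 40.0,
                                  "longest_fitted_segment": 100,
                                  "query_length": 200,
                                  "function_label": self.LABELS[pf_state]}
                        tr = None
                        if tr_state:
                            tr = {"template_id": "t", "confidence": 0.8,
                                  "e_value": 1e-4, "coverage": 0.6,
                                  "identity": 0.3, "tm_score": tm,
                                  "function_label": self.LABELS[tr_state]}
                        yield pf, tr

    def test_reconcile_matches_rule_interpreter_everywhere(self):
        n = 0
        for pf, tr in self._cases():
            bundle = EvidenceBundle("s")
            if pf:
                bundle.pf_matches = [PFMatch(
                    PFKind(pf["kind"]), pf["e_value"], pf["percent_identity"],
                    pf["longest_fitted_segment"], pf["query_length"],
                    pf["function_label"])]
            if tr:
                bundle.tr_hits = [TRHit(
                    tr["template_id"], tr["confidence"], tr["e_value"],
                    tr["coverage"], tr["identity"], tr["tm_score"],
                    tr["function_label"])]
            got = reconcile(bundle)
            want_label, want_source, want_rank = oracle_reconcile(pf, tr)
            assert (got.final_label, got.source.value, got.tier.value) == \
                (want_label, want_source, want_rank), (pf, tr)
            n += 1
        assert n == 3 * 3 * 5 * 5


class TestDeterminismAndTotality:
    def _random_bundle(self, rng) -> EvidenceBundle:
        bundle = EvidenceBundle(f"s{rng.integers(1e6)}")
        for _ in range(rng.integers(0, 3)):
            qlen = int(rng.integers(50, 400))
            bundle.pf_matches.append(PFMatch(
                PFKind.TEMPLATE_3D if rng.random() < 0.5
                else PFKind.SEQUENCE_VS_PDB,
                float(rng.uniform(0, 20)), float(rng.uniform(0, 100)),
                int(rng.integers(0, qlen + 1)), qlen,
                f"label {rng.integers(10)}"))
        for _ in range(rng.integers(0, 3)):
            bundle.tr_hits.append(TRHit(
                "t", float(rng.uniform(0, 1)), float(rng.uniform(0, 0.01)),
                float(rng.uniform(0, 1)), float(rng.uniform(0, 1)),
                float(rng.uniform(0, 1)), f"label {rng.integers(10)}"))
        return bundle

    def test_total_and_stable_on_random_bundles(self):
        rng = np.random.default_rng(123)
        for _ in range(2000):
            bundle = self._random_bundle(rng)
            first = reconcile(bundle)
            second = reconcile(bundle)
            assert first == second

    def test_annotate_all_one_row_per_subject_and_rerun_identical(self):
        rng = np.random.default_rng(5)
        bundles = []
        labels = {}
        for i in range(73):
            b = self._random_bundle(rng)
            b.subject_id = f"SC{i:03d}"
            bundles.append(b)
            labels[b.subject_id] = (f"u{i + 1}" if i < 28 else f"h{i - 27}")
        table = annotate_all(bundles, labels)
        assert len(table) == 73
        assert table.equals(annotate_all(bundles, labels))

    def test_missing_bundle_warns_and_yields_unannotated_row(self):
        with pytest.warns(UserWarning, match="sX"):
            table = annotate_all([], {"sX": "u1"})
        assert table.iloc[0]["final_label"] == "unannotated"
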