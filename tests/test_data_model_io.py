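import json

import pandas as pd
import pytest

from archannot import io as aio
from archannot.model import (
    Domain,
    FormatError,
    GeneFeature,
    KOAnnotation,
    MAGRecord,
    PFKind,
    PFMatch,
    ProteinCluster,
    TRHit,
    ValidationError,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestMagMetadata:
    HEADER = "mag_id\tdomain\ttaxonomy\tenvironment\tcatalog\n"

    def test_well_formed_rows_parse(self, tmp_path):
        p = _write(tmp_path / "m.tsv", self.HEADER +
                   "m1\tarchaea\ttax\thuman gut\tgem\n"
                   "m2\tbacteria\ttax\tsoil\tuhgg\n"
                   "m3\tarchaea\ttax\tmarine\tgem\n")
        recs = aio.read_mag_metadata(p)
        assert len(recs) == 3
        assert recs[0].domain == Domain.ARCHAEA

    def test_environment_is_normalized(self, tmp_path):
        p = _write(tmp_path / "m.tsv", self.HEADER +
                   "m1\tarchaea\ttax\t Human Gut \tgem\n")
        assert aio.read_mag_metadata(p)[0].environment == "human gut"

    def test_missing_column_is_format_error(self, tmp_path):
        p = _write(tmp_path / "m.tsv",
                   "mag_id\ttaxonomy\tenvironment\tcatalog\nm1\tt\tgut\tc\n")
        with pytest.raises(FormatError, match="domain"):
            aio.read_mag_metadata(p)

    def test_duplicate_mag_id_rejected(self, tmp_path):
        p = _write(tmp_path / "m.tsv", self.HEADER +
                   "m1\tarchaea\tt\tgut\tc\nm1\tarchaea\tt\tgut\tc\n")
        with pytest.raises(ValidationError, match="m1"):
            aio.read_mag_metadata(p)

    def test_unknown_domain_rejected(self, tmp_path):
        p = _write(tmp_path / "m.tsv", self.HEADER +
                   "m1\teukaryota\tt\tgut\tc\n")
        with pytest.raises(FormatError, match="domain"):
            aio.read_mag_metadata(p)


class TestClusterTable:
    def test_memberships_grouped(self, tmp_path):
        p = _write(tmp_path / "c.tsv",
                   "cluster_id\tmember_id\nc1\tp1\nc1\tp2\nc2\tp3\n")
        assert aio.read_cluster_table(p) == {"c1": ["p1", "p2"], "c2": ["p3"]}

    def test_member_in_two_clusters_violates_partition(self, tmp_path):
        p = _write(tmp_path / "c.tsv",
                   "cluster_id\tmember_id\nc1\tp1\nc2\tp1\n")
        with pytest.raises(ValidationError, match="p1"):
            aio.read_cluster_table(p)

    def test_duplicate_within_cluster_collapsed(self, tmp_path, caplog):
        p = _write(tmp_path / "c.tsv",
                   "cluster_id\tmember_id\nc1\tp1\nc1\tp1\n")
        with caplog.at_level("WARNING"):
            clusters = aio.read_cluster_table(p)
        assert clusters == {"c1": ["p1"]}
        assert any("collapsed" in r.message for r in caplog.records)

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = _write(tmp_path / "c.tsv", "")
        assert aio.read_cluster_table(p) == {}


class TestEvidenceBundles:
    def test_tr_hit_roundtrips(self, tmp_path):
        entry = {
            "subject_id": "s1",
            "tr_hits": [{"template_id": "t", "confidence": 0.8,
                         "e_value": 1e-4, "coverage": 0.5, "identity": 0.4,
                         "tm_score": 0.75, "function_label": "x"}],
        }
        p = _write(tmp_path / "e.json", json.dumps([entry]))
        bundles = aio.read_evidence_bundles(p)
        assert bundles[0].tr_hits[0].tm_score == 0.75

    @pytest.mark.parametrize("field,value", [
        ("tm_score", 1.5), ("tm_score", -0.1), ("confidence", 2.0),
    ])
    def test_out_of_range_score_names_subject(self, tmp_path, field, value):
        hit = {"template_id": "t", "confidence": 0.8, "e_value": 1e-4,
               "coverage": 0.5, "identity": 0.4, "tm_score": 0.75,
               "function_label": "x"}
        hit[field] = value
        p = _write(tmp_path / "e.json",
                   json.dumps([{"subject_id": "sX", "tr_hits": [hit]}]))
        with pytest.raises(ValidationError, match="sX"):
            aio.read_evidence_bundles(p)

    def test_negative_pf_evalue_rejected(self, tmp_path):
        m = {"kind": "template_3d", "e_value": -1, "percent_identity": 50,
             "longest_fitted_segment": 10, "query_length": 20,
             "function_label": "x"}
        p = _write(tmp_path / "e.json",
                   json.dumps([{"subject_id": "sY", "pf_matches": [m]}]))
        with pytest.raises(ValidationError, match="sY"):
            aio.read_evidence_bundles(p)

    def test_empty_slots_accepted(self, tmp_path):
        p = _write(tmp_path / "e.json", json.dumps([{"subject_id": "s1"}]))
        b = aio.read_evidence_bundles(p)[0]
        assert b.pf_matches == [] and b.tr_hits == [] and b.df_predictions == []
        assert b.sequence_ko is None


class TestGenesAndCoverage:
    GFF = ("##gff-version 3\n"
           "ctg1\tprodigal\tCDS\t100\t400\t.\t+\t0\tID=g1;partial=00\n"
           "ctg1\tprodigal\tCDS\t500\t900\t.\t-\t0\tID=g2;partial=00\n")

    def test_gff_coords_are_one_based_inclusive(self, tmp_path):
        p = _write(tmp_path / "g.gff3", self.GFF)
        genes = aio.read_gene_features(p)
        assert [(g.gene_id, g.start, g.end) for g in genes] == [
            ("g1", 100, 400), ("g2", 500, 900)]

    def test_ko_sidecar_attaches(self, tmp_path):
        gff = _write(tmp_path / "g.gff3", self.GFF)
        ko = _write(tmp_path / "k.tsv", "gene_id\tko_id\ng1\tK06400\n")
        genes = aio.read_gene_features(gff, ko)
        assert genes[0].ko_ids == frozenset({"K06400"})
        assert genes[1].ko_ids == frozenset()

    def test_coverage_row_parses(self, tmp_path):
        p = _write(tmp_path / "c.tsv",
                   "gene_id\tsample_id\tmean_coverage\ng1\ts1\t3.5\n")
        rec = aio.read_coverage(p)[0]
        assert (rec.gene_id, rec.sample_id, rec.mean_coverage) == ("g1", "s1", 3.5)

    def test_negative_coverage_rejected(self, tmp_path):
        p = _write(tmp_path / "c.tsv",
                   "gene_id\tsample_id\tmean_coverage\ng1\ts1\t-1\n")
        with pytest.raises(ValidationError, match="g1"):
            aio.read_coverage(p)


class TestWriters:
    def test_result_table_roundtrip(self, tmp_path):
        df = pd.DataFrame({"label": ["u1", "h2"], "value": [2.825846, 0.5],
                           "flag": [True, False]})
        aio.write_table(df, tmp_path / "t.tsv")
        back = aio.read_table(tmp_path / "t.tsv")
        assert list(back["label"]) == ["u1", "h2"]
        assert back["value"].tolist() == pytest.approx([2.82585, 0.5])

    def test_writer_is_byte_deterministic(self, tmp_path):
        df = pd.DataFrame({"a": [1.234567891, 3.0], "b": ["x", "y"]})
        aio.write_table(df, tmp_path / "1.tsv")
        aio.write_table(df.copy(), tmp_path / "2.tsv")
        assert (tmp_path / "1.tsv").read_bytes() == (tmp_path / "2.tsv").read_bytes()

    def test_write_results_emits_named_tables(self, tmp_path):
        out = aio.write_results(
            {"occurrence": pd.DataFrame({"ko": ["K00001"], "v": [1.0]})},
            tmp_path / "res",
        )
        assert [p.name for p in out] == ["occurrence.tsv"]


class TestTypeInvariants:
    def test_cluster_representative_must_be_member(self):
        with pytest.raises(ValidationError, match="representative"):
            ProteinCluster("c1", ["p1"], Domain.ARCHAEA, "p2")

    def test_gene_end_before_start_rejected(self):
        from archannot.model import Strand
        with pytest.raises(ValidationError, match="g1"):
            GeneFeature("ctg", "g1", 100, 50, Strand.PLUS)

    def test_malformed_ko_id_rejected(self):
        with pytest.raises(ValidationError, match="KO"):
            KOAnnotation("s1", frozenset({"X123"}))

    def test_pf_segment_longer_than_query_rejected(self):
        with pytest.raises(ValidationError):
            PFMatch(PFKind.TEMPLATE_3D, 1e-8, 50.0, 300, 200, "x")

    def test_tr_score_ranges_enforced(self):
        with pytest.raises(ValidationError):
            TRHit("t", 0.8, 1e-4, 0.5, 0.4, 1.2, "x")
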