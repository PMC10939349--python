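"""Readers and writers for every external format the pipeline touches.

Formats are deliberately plain: TSV for tabular data, GFF3 (Prodigal
dialect) for gene coordinates, FASTA for protein sequences, and a
documented JSON schema for parsed structure-annotation evidence.  All
writers are deterministic — fixed column order, floats at 6 significant
digits — so reruns produce byte-identical output.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import (
    CoverageRecord,
    DFPrediction,
    Domain,
    EvidenceBundle,
    FormatError,
    GeneFeature,
    InputBundle,
    KOAnnotation,
    MAGRecord,
    PFKind,
    PFMatch,
    ProteinCluster,
    ProteinRecord,
    Strand,
    SuperCluster,
    TRHit,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: canonical file names inside an input bundle directory
BUNDLE_FILES = {
    "mags": "mags.tsv",
    "proteins": "proteins.faa",
    "clusters": "clusters_mm2.tsv",
    "superclusters": "superclusters.tsv",
    "ko": "ko.tsv",
    "evidence": "evidence.json",
    "coverage": "coverage.tsv",
    "genes": "genes.gff3",
    "gene_ko": "gene_ko.tsv",
}


def _read_tsv(path: PathLike, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=required)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_mag_metadata(path: PathLike) -> list[MAGRecord]:
    """Read MAG metadata from a TSV with columns
    mag_id, domain, taxonomy, environment, catalog.

    Environment labels are normalized (lowercased, trimmed).  Unknown
    domains and duplicate MAG ids are rejected.
    """
    df = _read_tsv(path, ["mag_id", "domain", "taxonomy", "environment", "catalog"])
    records: list[MAGRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.mag_id in seen:
            raise ValidationError(f"{path}: duplicate mag_id {row.mag_id!r}")
        seen.add(row.mag_id)
        try:
            domain = Domain(row.domain.strip().lower())
        except ValueError:
            raise FormatError(
                f"{path}: MAG {row.mag_id!r} has unknown domain {row.domain!r}"
            ) from None
        records.append(
            MAGRecord(
                mag_id=row.mag_id,
                domain=domain,
                taxonomy=row.taxonomy,
                environment=row.environment.strip().lower(),
                catalog=row.catalog,
            )
        )
    return records


def read_proteins_fasta(path: PathLike, mag_of: Mapping[str, str] | None = None
                        ) -> dict[str, ProteinRecord]:
    """Read protein sequences; MAG provenance comes from the FASTA header
    (``>protein_id mag=MAG_ID``) or an explicit protein→MAG mapping."""
    proteins: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteins:
            raise ValidationError(f"{path}: duplicate protein_id {rec.id!r}")
        mag_id = ""
        for token in rec.description.split()[1:]:
            if token.startswith("mag="):
                mag_id = token[4:]
        if mag_of is not None:
            mag_id = mag_of.get(rec.id, mag_id)
        proteins[rec.id] = ProteinRecord(
            protein_id=rec.id, mag_id=mag_id, sequence=str(rec.seq)
        )
    return proteins


def read_cluster_table(path: PathLike, level: str = "mm2") -> dict[str, list[str]]:
    """Read a two-column (cluster_id, member_id) membership table.

    Members are protein ids at level ``mm2`` and level-1 cluster ids at
    level ``sourmash``.  Clustering is a partition, so a member listed
    under two clusters is a validation error; duplicates within one
    cluster are collapsed with a logged warning.
    """
    if level not in ("mm2", "sourmash"):
        raise ValueError(f"unknown cluster level {level!r}")
    df = _read_tsv(path, ["cluster_id", "member_id"])
    clusters: dict[str, list[str]] = {}
    owner: dict[str, str] = {}
    for row in df.itertuples(index=False):
        cid, mid = row.cluster_id, row.member_id
        if mid in owner and owner[mid] != cid:
            raise ValidationError(
                f"{path}: member {mid!r} appears in clusters "
                f"{owner[mid]!r} and {cid!r} at level {level}"
            )
        members = clusters.setdefault(cid, [])
        if mid in members:
            logger.warning("%s: duplicate member %r in cluster %r collapsed",
                           path, mid, cid)
            continue
        owner[mid] = cid
        members.append(mid)
    return clusters


def build_clusters(membership: Mapping[str, list[str]],
                   proteins: Mapping[str, ProteinRecord],
                   mags: Mapping[str, MAGRecord]) -> dict[str, ProteinCluster]:
    """Turn raw level-1 membership into typed clusters.

    The domain is inferred from the members' MAGs and must be
    homogeneous.  The representative is the longest member sequence,
    ties broken lexicographically by protein id; without sequences the
    lexicographically smallest id is used.
    """
    clusters: dict[str, ProteinCluster] = {}
    for cid, members in membership.items():
        domains = set()
        for pid in members:
            if pid not in proteins:
                raise ValidationError(
                    f"cluster {cid!r}: unknown protein {pid!r}"
                )
            mag_id = proteins[pid].mag_id
            if mag_id not in mags:
                raise ValidationError(
                    f"cluster {cid!r}: protein {pid!r} references unknown "
                    f"MAG {mag_id!r}"
                )
            domains.add(mags[mag_id].domain)
        if len(domains) != 1:
            raise ValidationError(
                f"cluster {cid!r}: members span domains "
                f"{sorted(d.value for d in domains)}"
            )
        rep = min(
            members,
            key=lambda p: (-(len(proteins[p].sequence or "")), p),
        )
        clusters[cid] = ProteinCluster(
            cluster_id=cid,
            member_ids=list(members),
            domain=domains.pop(),
            representative_id=rep,
        )
    return clusters


def build_superclusters(membership: Mapping[str, list[str]]
                        ) -> dict[str, SuperCluster]:
    return {
        sid: SuperCluster(supercluster_id=sid, member_cluster_ids=list(members))
        for sid, members in membership.items()
    }


def read_ko_table(path: PathLike) -> dict[str, KOAnnotation]:
    """Read KO assignments from a TSV with columns subject_id, ko_ids
    (comma-separated), source and an optional ko_names column
    (semicolon-separated, aligned with ko_ids)."""
    df = _read_tsv(path, ["subject_id", "ko_ids", "source"])
    out: dict[str, KOAnnotation] = {}
    for row in df.itertuples(index=False):
        ko_ids = frozenset(k for k in row.ko_ids.split(",") if k)
        labels: dict[str, str] = {}
        if "ko_names" in df.columns:
            names = [n for n in getattr(row, "ko_names").split(";") if n]
            labels = dict(zip(sorted(ko_ids), names))
        if row.subject_id in out:
            raise ValidationError(f"{path}: duplicate subject {row.subject_id!r}")
        out[row.subject_id] = KOAnnotation(
            subject_id=row.subject_id, ko_ids=ko_ids,
            source=row.source, labels=labels,
        )
    return out


def _parse_evidence_entry(entry: dict) -> EvidenceBundle:
    sid = entry.get("subject_id")
    if not sid:
        raise FormatError("evidence entry without subject_id")
    try:
        seq_ko = None
        if entry.get("sequence_ko"):
            raw = entry["sequence_ko"]
            seq_ko = KOAnnotation(
                subject_id=sid,
                ko_ids=frozenset(raw.get("ko_ids", [])),
                source=raw.get("source", ""),
                labels=raw.get("labels", {}),
            )
        pf = [
            PFMatch(
                kind=PFKind(m["kind"]),
                e_value=float(m["e_value"]),
                percent_identity=float(m["percent_identity"]),
                longest_fitted_segment=int(m["longest_fitted_segment"]),
                query_length=int(m["query_length"]),
                function_label=m["function_label"],
                subject_id=sid,
            )
            for m in entry.get("pf_matches", [])
        ]
        tr = [
            TRHit(
                template_id=h["template_id"],
                confidence=float(h["confidence"]),
                e_value=float(h["e_value"]),
                coverage=float(h["coverage"]),
                identity=float(h["identity"]),
                tm_score=float(h["tm_score"]),
                function_label=h["function_label"],
                subject_id=sid,
            )
            for h in entry.get("tr_hits", [])
        ]
        df_preds = [
            DFPrediction(
                term_id=p["term_id"],
                score=float(p["score"]),
                term_name=p["term_name"],
                subject_id=sid,
            )
            for p in entry.get("df_predictions", [])
        ]
    except KeyError as exc:
        raise FormatError(f"evidence for {sid!r}: missing field {exc}") from None
    return EvidenceBundle(
        subject_id=sid, sequence_ko=seq_ko,
        pf_matches=pf, tr_hits=tr, df_predictions=df_preds,
    )


def read_evidence_bundles(path: PathLike) -> list[EvidenceBundle]:
    """Read parsed structure/sequence evidence from the JSON schema.

    Every numeric field is range-checked against its type invariant;
    violations raise a :class:`ValidationError` identifying the subject.
    """
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise FormatError(f"{path}: expected a JSON array of bundles")
    return [_parse_evidence_entry(e) for e in data]


def read_gene_features(gff_path: PathLike,
                       ko_sidecar: Optional[PathLike] = None
                       ) -> list[GeneFeature]:
    """Read gene coordinates from GFF3 (Prodigal dialect, ID attribute =
    gene id); KO assignments come from a sidecar TSV gene_id→ko_id."""
    ko_of: dict[str, set[str]] = {}
    if ko_sidecar is not None:
        df = _read_tsv(ko_sidecar, ["gene_id", "ko_id"])
        for row in df.itertuples(index=False):
            ko_of.setdefault(row.gene_id, set()).add(row.ko_id)
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    for f in db.all_features():
        gene_id = f.attributes.get("ID", [f.id])[0]
        if f.end < f.start:
            raise ValidationError(
                f"{gff_path}: gene {gene_id!r}: end {f.end} < start {f.start}"
            )
        features.append(
            GeneFeature(
                contig_id=f.seqid,
                gene_id=gene_id,
                start=f.start,
                end=f.end,
                strand=Strand(f.strand if f.strand in ("+", "-") else "+"),
                ko_ids=frozenset(ko_of.get(gene_id, ())),
            )
        )
    return features


def read_coverage(path: PathLike) -> list[CoverageRecord]:
    """Read per-gene mean coverage (TSV: gene_id, sample_id, mean_coverage)."""
    df = _read_tsv(path, ["gene_id", "sample_id", "mean_coverage"])
    return [
        CoverageRecord(row.gene_id, row.sample_id, float(row.mean_coverage))
        for row in df.itertuples(index=False)
    ]


def _format_value(v: object) -> str:
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    """Write a result table as TSV, deterministically.

    Column order is taken from the frame; floats are rendered at 6
    significant digits so the same inputs always give identical bytes.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(df.columns))
        for row in df.itertuples(index=False):
            writer.writerow([_format_value(v) for v in row])


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=["NA"])


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: PathLike) -> list[Path]:
    """Write each named table as ``<name>.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        write_table(tables[name], path)
        written.append(path)
    return written


def load_bundle(directory: PathLike) -> InputBundle:
    """Load a complete input bundle from a directory of canonical files.

    Optional files (evidence, coverage, genes) are skipped silently when
    absent, so partial bundles support metric-only or synteny-only runs.
    """
    d = Path(directory)
    mags = {m.mag_id: m for m in read_mag_metadata(d / BUNDLE_FILES["mags"])}
    proteins = read_proteins_fasta(d / BUNDLE_FILES["proteins"])
    membership = read_cluster_table(d / BUNDLE_FILES["clusters"], level="mm2")
    clusters = build_clusters(membership, proteins, mags)
    sc_membership = read_cluster_table(
        d / BUNDLE_FILES["superclusters"], level="sourmash"
    )
    superclusters = build_superclusters(sc_membership)
    ko = read_ko_table(d / BUNDLE_FILES["ko"])
    evidence: dict[str, EvidenceBundle] = {}
    ev_path = d / BUNDLE_FILES["evidence"]
    if ev_path.exists():
        evidence = {b.subject_id: b for b in read_evidence_bundles(ev_path)}
    coverage: list[CoverageRecord] = []
    cov_path = d / BUNDLE_FILES["coverage"]
    if cov_path.exists():
        coverage = read_coverage(cov_path)
    genes: list[GeneFeature] = []
    gff_path = d / BUNDLE_FILES["genes"]
    if gff_path.exists():
        sidecar = d / BUNDLE_FILES["gene_ko"]
        genes = read_gene_features(gff_path, sidecar if sidecar.exists() else None)
    return InputBundle(
        mags=mags, proteins=proteins, clusters=clusters,
        superclusters=superclusters, ko=ko, evidence=evidence,
        coverage=coverage, genes=genes,
    )


def validate_bundle(directory: PathLike) -> list[str]:
    """Load a bundle and report problems instead of raising.

    Returns a list of human-readable messages; empty means the bundle
    passed every reader-level check.
    """
    problems: list[str] = []
    try:
        bundle = load_bundle(directory)
    except (ValidationError, FormatError, FileNotFoundError) as exc:
        return [str(exc)]
    for sc in bundle.superclusters.values():
        for cid in sc.member_cluster_ids:
            if cid not in bundle.clusters:
                problems.append(
                    f"supercluster {sc.supercluster_id!r}: unknown member "
                    f"cluster {cid!r}"
                )
    for sid in bundle.evidence:
        if sid not in bundle.superclusters and sid not in bundle.clusters:
            problems.append(f"evidence for unknown subject {sid!r}")
    return problems
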