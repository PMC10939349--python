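"""Domain types shared by every stage of the pipeline.

All readers produce these types and all downstream modules consume only
them, so format quirks never leak past the I/O layer.  Coordinates are
1-based inclusive throughout (the Prodigal/GFF3 convention); any
half-open arithmetic happens inside computations, never in stored
records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence


class ValidationError(ValueError):
    """A record violates a type invariant (names the offending record)."""


class FormatError(ValueError):
    """An input file does not match its documented layout."""


class Domain(str, Enum):
    ARCHAEA = "archaea"
    BACTERIA = "bacteria"


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


class PFKind(str, Enum):
    """Which section of a structure-annotation report a match came from."""

    SEQUENCE_VS_PDB = "sequence_vs_pdb"
    TEMPLATE_3D = "template_3d"


@dataclass(frozen=True)
class MAGRecord:
    """One metagenome-assembled genome with provenance metadata.

    ``environment`` is a free label from an open vocabulary, compared by
    exact string equality after lowercasing and trimming (done by the
    reader); ``catalog`` names the source collection.
    """

    mag_id: str
    domain: Domain
    taxonomy: str
    environment: str
    catalog: str = ""

    def __post_init__(self) -> None:
        if not self.mag_id:
            raise ValidationError("MAGRecord with empty mag_id")
        if not self.environment:
            raise ValidationError(f"MAG {self.mag_id!r}: empty environment")


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein with its MAG of origin.

    Sequence and coordinates are optional so metric-only runs can skip
    FASTA/GFF ingestion entirely.
    """

    protein_id: str
    mag_id: str
    sequence: Optional[str] = None
    contig_id: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[Strand] = None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None:
            if not (1 <= self.start <= self.end):
                raise ValidationError(
                    f"protein {self.protein_id!r}: invalid coordinates "
                    f"[{self.start}, {self.end}]"
                )


@dataclass
class ProteinCluster:
    """A level-1 (greedy sequence-identity) protein cluster.

    Level-1 clusters are domain-homogeneous: archaea and bacteria are
    clustered separately upstream, so a mixed-domain cluster is
    malformed input.
    """

    cluster_id: str
    member_ids: list[str]
    domain: Domain
    representative_id: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValidationError(f"cluster {self.cluster_id!r}: no members")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValidationError(
                f"cluster {self.cluster_id!r}: duplicate member ids"
            )
        if self.representative_id not in self.member_ids:
            raise ValidationError(
                f"cluster {self.cluster_id!r}: representative "
                f"{self.representative_id!r} is not a member"
            )

    @property
    def size(self) -> int:
        return len(self.member_ids)


class Group(str, Enum):
    """Final category of an archaeal supercluster."""

    UNIQUE = "unique"
    HOMOLOGOUS = "homologous"
    UNASSIGNED = "unassigned"


@dataclass
class SuperCluster:
    """A level-2 (MinHash sketch) grouping of level-1 clusters."""

    supercluster_id: str
    member_cluster_ids: list[str]
    group: Group = Group.UNASSIGNED
    label: str = ""

    def __post_init__(self) -> None:
        if not self.member_cluster_ids:
            raise ValidationError(
                f"supercluster {self.supercluster_id!r}: no member clusters"
            )


_KO_PATTERN = re.compile(r"^K\d{5}$")


def is_ko_id(token: str) -> bool:
    """True for a well-formed KEGG ortholog identifier (K + 5 digits)."""
    return bool(_KO_PATTERN.match(token))


@dataclass
class KOAnnotation:
    """KEGG-ortholog assignment for a protein or cluster.

    ``labels`` optionally carries human-readable KO names, used when
    comparing sequence-based calls against structure-based ones.
    """

    subject_id: str
    ko_ids: frozenset[str]
    source: str = ""
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = sorted(k for k in self.ko_ids if not is_ko_id(k))
        if bad:
            raise ValidationError(
                f"KO annotation for {self.subject_id!r}: malformed KO ids {bad}"
            )

    def label_text(self) -> str:
        """Concatenated KO names (falling back to the ids themselves)."""
        if self.labels:
            return " ".join(self.labels.get(k, k) for k in sorted(self.ko_ids))
        return " ".join(sorted(self.ko_ids))


def _check_range(subject: str, name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValidationError(
            f"{subject}: {name}={value!r} outside [{lo}, {hi}]"
        )


@dataclass(frozen=True)
class PFMatch:
    """One structure-annotation match (PDB sequence search or 3D template).

    ``longest_fitted_segment``/``query_length`` are residue counts; their
    ratio is the match coverage used in the reconciliation tie-breaks.
    """

    kind: PFKind
    e_value: float
    percent_identity: float
    longest_fitted_segment: int
    query_length: int
    function_label: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        who = f"PF match for {self.subject_id or '<unknown>'}"
        if self.e_value < 0:
            raise ValidationError(f"{who}: negative e_value {self.e_value!r}")
        _check_range(who, "percent_identity", self.percent_identity, 0.0, 100.0)
        if self.query_length <= 0:
            raise ValidationError(f"{who}: query_length must be positive")
        if not (0 <= self.longest_fitted_segment <= self.query_length):
            raise ValidationError(
                f"{who}: longest_fitted_segment {self.longest_fitted_segment} "
                f"exceeds query_length {self.query_length}"
            )


@dataclass(frozen=True)
class TRHit:
    """One template hit from de-novo structure prediction."""

    template_id: str
    confidence: float
    e_value: float
    coverage: float
    identity: float
    tm_score: float
    function_label: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        who = f"TR hit for {self.subject_id or '<unknown>'}"
        if self.e_value < 0:
            raise ValidationError(f"{who}: negative e_value {self.e_value!r}")
        for name in ("confidence", "coverage", "identity", "tm_score"):
            _check_range(who, name, getattr(self, name), 0.0, 1.0)


@dataclass(frozen=True)
class DFPrediction:
    """A GO/EC-style term prediction with a certainty score in [0, 1]."""

    term_id: str
    score: float
    term_name: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        _check_range(
            f"DF prediction for {self.subject_id or '<unknown>'}",
            "score", self.score, 0.0, 1.0,
        )


@dataclass
class EvidenceBundle:
    """Everything known about one subject before reconciliation.

    Any of the four slots may be empty; the reconciliation ladder is a
    total function over valid bundles.
    """

    subject_id: str
    sequence_ko: Optional[KOAnnotation] = None
    pf_matches: list[PFMatch] = field(default_factory=list)
    tr_hits: list[TRHit] = field(default_factory=list)
    df_predictions: list[DFPrediction] = field(default_factory=list)


@dataclass(frozen=True)
class CoverageRecord:
    """Mean read coverage of one gene in one sample."""

    gene_id: str
    sample_id: str
    mean_coverage: float

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise ValidationError(
                f"coverage for gene {self.gene_id!r}, sample "
                f"{self.sample_id!r}: negative mean_coverage"
            )


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a contig with its KO assignments (may be empty)."""

    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: Strand
    ko_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: end {self.end} < start {self.start}"
            )

    def overlaps(self, start: int, end: int) -> bool:
        """1-bp-or-more overlap with the closed interval [start, end]."""
        return self.start <= end and self.end >= start


@dataclass
class InputBundle:
    """A fully loaded input set, the unit the pipeline operates on."""

    mags: dict[str, MAGRecord]
    proteins: dict[str, ProteinRecord]
    clusters: dict[str, ProteinCluster]
    superclusters: dict[str, SuperCluster]
    ko: dict[str, KOAnnotation]
    evidence: dict[str, EvidenceBundle] = field(default_factory=dict)
    coverage: list[CoverageRecord] = field(default_factory=list)
    genes: list[GeneFeature] = field(default_factory=list)

    def clusters_of_domain(self, domain: Domain) -> list[ProteinCluster]:
        return [c for c in self.clusters.values() if c.domain == domain]

    def superclusters_of_domain(self, domain: Domain) -> list[SuperCluster]:
        out = []
        for sc in self.superclusters.values():
            doms = {self.clusters[c].domain for c in sc.member_cluster_ids
                    if c in self.clusters}
            if doms == {domain}:
                out.append(sc)
        return out
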