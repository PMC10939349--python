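"""Cluster-level inclusion/exclusion funnel for gut-specific proteins.

Three gates are applied in a fixed order: environment exclusivity
(every member protein comes from a MAG sampled in the target
environment), a minimum cluster size (2 for archaea, 10 for bacteria by
default), and annotation completeness (KEGG orthologs for every member,
or for the representative, depending on mode).  The size and annotation
gates commute; only the intermediate funnel counts depend on the order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .model import (
    Domain,
    InputBundle,
    KOAnnotation,
    MAGRecord,
    ProteinCluster,
    ProteinRecord,
    ValidationError,
)

DEFAULT_MIN_SIZE = {Domain.ARCHAEA: 2, Domain.BACTERIA: 10}


class AnnotationMode(str, Enum):
    ALL_MEMBERS = "all_members"
    REPRESENTATIVE = "representative"


@dataclass
class SelectionConfig:
    target_env: str = "human gut"
    min_size_archaea: int = 2
    min_size_bacteria: int = 10
    annotation_mode: AnnotationMode = AnnotationMode.ALL_MEMBERS

    def min_size(self, domain: Domain) -> int:
        return (self.min_size_archaea if domain == Domain.ARCHAEA
                else self.min_size_bacteria)


@dataclass
class SelectionReport:
    """Funnel counts at each selection stage, per domain.

    Counts are non-increasing along input → environment → size →
    annotation; ``retained`` holds the surviving cluster ids.
    """

    input_clusters: dict[Domain, int] = field(default_factory=dict)
    after_environment: dict[Domain, int] = field(default_factory=dict)
    after_size: dict[Domain, int] = field(default_factory=dict)
    after_annotation: dict[Domain, int] = field(default_factory=dict)
    retained: dict[Domain, list[str]] = field(default_factory=dict)

    def stages(self, domain: Domain) -> list[int]:
        return [
            self.input_clusters.get(domain, 0),
            self.after_environment.get(domain, 0),
            self.after_size.get(domain, 0),
            self.after_annotation.get(domain, 0),
        ]

    def to_dict(self) -> dict:
        return {
            d.value: {
                "input": self.input_clusters.get(d, 0),
                "after_environment": self.after_environment.get(d, 0),
                "after_size": self.after_size.get(d, 0),
                "after_annotation": self.after_annotation.get(d, 0),
                "retained": sorted(self.retained.get(d, [])),
            }
            for d in Domain
        }


def filter_by_environment(clusters: Iterable[ProteinCluster],
                          proteins: Mapping[str, ProteinRecord],
                          mags: Mapping[str, MAGRecord],
                          target_env: str) -> list[ProteinCluster]:
    """Keep clusters whose members all come from the target environment.

    Equivalently: at least one member sampled there and none sampled
    anywhere else.  The target label is normalized the same way MAG
    environments are (lowercased, trimmed).
    """
    target = target_env.strip().lower()
    kept = []
    for cluster in clusters:
        envs = set()
        for pid in cluster.member_ids:
            protein = proteins.get(pid)
            if protein is None:
                raise ValidationError(
                    f"cluster {cluster.cluster_id!r}: unknown protein {pid!r}"
                )
            mag = mags.get(protein.mag_id)
            if mag is None:
                raise ValidationError(
                    f"cluster {cluster.cluster_id!r}: protein {pid!r} "
                    f"references unknown MAG {protein.mag_id!r}"
                )
            envs.add(mag.environment)
        if envs == {target}:
            kept.append(cluster)
    return kept


def filter_by_min_size(clusters: Iterable[ProteinCluster],
                       min_size: int) -> list[ProteinCluster]:
    """Keep clusters with at least ``min_size`` member proteins."""
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    return [c for c in clusters if c.size >= min_size]


def _has_ko(subject_id: str, ko_table: Mapping[str, KOAnnotation]) -> bool:
    ann = ko_table.get(subject_id)
    return ann is not None and bool(ann.ko_ids)


def filter_fully_annotated(clusters: Iterable[ProteinCluster],
                           ko_table: Mapping[str, KOAnnotation],
                           mode: AnnotationMode = AnnotationMode.ALL_MEMBERS
                           ) -> list[ProteinCluster]:
    """Keep clusters with complete KEGG annotation.

    ``all_members`` requires every member protein to carry at least one
    KO (the strictest reading of "complete"); ``representative``
    requires only the representative, which suits cluster-level
    annotation tables.
    """
    mode = AnnotationMode(mode)
    kept = []
    for cluster in clusters:
        if mode == AnnotationMode.ALL_MEMBERS:
            ok = all(_has_ko(pid, ko_table) for pid in cluster.member_ids)
        else:
            ok = _has_ko(cluster.representative_id, ko_table)
        if ok:
            kept.append(cluster)
    return kept


def run_selection(bundle: InputBundle,
                  config: SelectionConfig | None = None) -> SelectionReport:
    """Run the full funnel (environment → size → annotation) per domain."""
    config = config or SelectionConfig()
    report = SelectionReport()
    for domain in Domain:
        clusters = bundle.clusters_of_domain(domain)
        report.input_clusters[domain] = len(clusters)
        clusters = filter_by_environment(
            clusters, bundle.proteins, bundle.mags, config.target_env
        )
        report.after_environment[domain] = len(clusters)
        clusters = filter_by_min_size(clusters, config.min_size(domain))
        report.after_size[domain] = len(clusters)
        clusters = filter_fully_annotated(
            clusters, bundle.ko, config.annotation_mode
        )
        report.after_annotation[domain] = len(clusters)
        report.retained[domain] = [c.cluster_id for c in clusters]
    return report
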