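"""Unique/homologous partition of archaeal superclusters by KO sharing.

An archaeal supercluster is *homologous* (label prefix ``h``) when its
KEGG-ortholog set intersects the bacterial KO universe, and *unique*
(prefix ``u``) otherwise.  KO identity is the sole homology criterion;
no sequence comparison is involved.  By default the bacterial universe
is global — the union of KOs over all retained bacterial clusters — with
a narrower within-supercluster mode available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .model import (
    Domain,
    Group,
    KOAnnotation,
    ProteinCluster,
    SuperCluster,
    ValidationError,
)
from .selection import AnnotationMode


def cluster_ko_sets(clusters: Iterable[ProteinCluster],
                    ko_table: Mapping[str, KOAnnotation],
                    mode: AnnotationMode = AnnotationMode.ALL_MEMBERS
                    ) -> dict[str, frozenset[str]]:
    """KO set per level-1 cluster.

    Cluster-level annotations (keyed by cluster id) take precedence;
    otherwise member-level KOs are used — the union over members in
    ``all_members`` mode, or the representative's KOs alone.
    """
    mode = AnnotationMode(mode)
    out: dict[str, frozenset[str]] = {}
    for cluster in clusters:
        direct = ko_table.get(cluster.cluster_id)
        if direct is not None:
            out[cluster.cluster_id] = frozenset(direct.ko_ids)
            continue
        if mode == AnnotationMode.REPRESENTATIVE:
            ann = ko_table.get(cluster.representative_id)
            kos = frozenset(ann.ko_ids) if ann else frozenset()
        else:
            kos: frozenset[str] = frozenset()
            for pid in cluster.member_ids:
                ann = ko_table.get(pid)
                if ann:
                    kos |= ann.ko_ids
        out[cluster.cluster_id] = kos
    return out


def supercluster_ko(sc: SuperCluster,
                    ko_by_cluster: Mapping[str, frozenset[str]]) -> frozenset[str]:
    kos: frozenset[str] = frozenset()
    for cid in sc.member_cluster_ids:
        kos |= ko_by_cluster.get(cid, frozenset())
    return kos


def collect_ko_universe(clusters: Iterable[ProteinCluster],
                        ko_table: Mapping[str, KOAnnotation],
                        domain: Optional[Domain] = None,
                        mode: AnnotationMode = AnnotationMode.ALL_MEMBERS
                        ) -> frozenset[str]:
    """Union of KOs over all (optionally domain-filtered) clusters."""
    selected = [c for c in clusters if domain is None or c.domain == domain]
    universe: frozenset[str] = frozenset()
    for kos in cluster_ko_sets(selected, ko_table, mode).values():
        universe |= kos
    return universe


@dataclass
class PartitionResult:
    """Outcome of the u/h split.

    ``venn`` is (archaea-only KOs, shared KOs, bacteria-only KOs) over
    the two domains' KO universes; archaea-only + shared equals the size
    of the archaeal universe.
    """

    unique_ids: list[str]
    homologous_ids: list[str]
    venn: tuple[int, int, int]
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def group_of(self) -> dict[str, Group]:
        out = {sid: Group.UNIQUE for sid in self.unique_ids}
        out.update({sid: Group.HOMOLOGOUS for sid in self.homologous_ids})
        return out


def partition_by_ko(arch_superclusters: Iterable[SuperCluster],
                    ko_by_cluster: Mapping[str, frozenset[str]],
                    bacterial_ko_universe: frozenset[str]) -> PartitionResult:
    """Split archaeal superclusters by KO overlap with bacteria.

    A supercluster with any KO in the bacterial universe is homologous,
    otherwise unique.  A supercluster without KOs means the annotation
    gate upstream was violated and is rejected.
    """
    unique: list[str] = []
    homologous: list[str] = []
    arch_universe: frozenset[str] = frozenset()
    for sc in sorted(arch_superclusters, key=lambda s: s.supercluster_id):
        kos = supercluster_ko(sc, ko_by_cluster)
        if not kos:
            raise ValidationError(
                f"supercluster {sc.supercluster_id!r} has no KOs; the "
                f"annotation gate should have removed it"
            )
        arch_universe |= kos
        if kos & bacterial_ko_universe:
            homologous.append(sc.supercluster_id)
            sc.group = Group.HOMOLOGOUS
        else:
            unique.append(sc.supercluster_id)
            sc.group = Group.UNIQUE
    shared = arch_universe & bacterial_ko_universe
    venn = (
        len(arch_universe - bacterial_ko_universe),
        len(shared),
        len(bacterial_ko_universe - arch_universe),
    )
    return PartitionResult(unique_ids=unique, homologous_ids=homologous, venn=venn)


def assign_labels(result: PartitionResult,
                  order: str = "by_id",
                  sizes: Optional[Mapping[str, int]] = None) -> dict[str, str]:
    """Assign stable u1…/h1… labels to the partitioned superclusters.

    ``by_id`` orders lexicographically by supercluster id; the
    alternative ``by_occurrence_desc`` orders by descending member
    protein count (``sizes``), ties broken by id.  Indices are 1-based
    and gap-free within each prefix.
    """
    if order not in ("by_id", "by_occurrence_desc"):
        raise ValueError(f"unknown label order {order!r}")
    if order == "by_occurrence_desc" and sizes is None:
        raise ValueError("by_occurrence_desc requires a sizes mapping")

    def ordered(ids: list[str]) -> list[str]:
        if order == "by_id":
            return sorted(ids)
        return sorted(ids, key=lambda sid: (-sizes[sid], sid))

    labels: dict[str, str] = {}
    for prefix, ids in (("u", result.unique_ids), ("h", result.homologous_ids)):
        for i, sid in enumerate(ordered(list(ids)), start=1):
            labels[sid] = f"{prefix}{i}"
    result.labels = labels
    return labels
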