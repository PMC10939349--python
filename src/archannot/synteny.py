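"""Gene-neighborhood extraction and HGT-context screening.

A synteny window spans 10 kb up- and downstream of a target gene's
boundaries (truncated at coordinate 1, never crossing a contig).  Any
gene overlapping the window by at least one base pair, on either strand,
belongs to the window.  The HGT-context screen then asks whether the
flanks carry the canonical mobilization motifs seen around horizontally
transferred sporulation genes: a site-specific DNA recombinase (K06400)
upstream, or Type IV pilus assembly proteins (K02662, K02664)
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import GeneFeature, Strand, ValidationError

DEFAULT_WINDOW = 10_000
DEFAULT_UPSTREAM_KOS = frozenset({"K06400"})
DEFAULT_DOWNSTREAM_KOS = frozenset({"K02662", "K02664"})


@dataclass
class SyntenyWindow:
    """A target gene with its overlapping neighborhood.

    ``flank_genes`` holds (gene, signed offset) pairs sorted by start;
    the offset is negative for genes entirely upstream of the target
    start, positive for genes entirely downstream of the target end, and
    zero for the target and anything overlapping it.
    """

    target: GeneFeature
    window_start: int
    window_end: int
    flank_genes: list[tuple[GeneFeature, int]] = field(default_factory=list)

    @property
    def target_gene_id(self) -> str:
        return self.target.gene_id

    @property
    def contig_id(self) -> str:
        return self.target.contig_id


@dataclass
class HGTContextFlags:
    """Outcome of the flank motif screen for one target."""

    target_gene_id: str
    upstream_recombinase: bool
    downstream_pilus: bool
    matches: list[tuple[str, str, int]] = field(default_factory=list)
    # matches: (gene_id, ko_id, signed offset)


def _signed_offset(gene: GeneFeature, target: GeneFeature) -> int:
    if gene.end < target.start:
        return gene.end - target.start
    if gene.start > target.end:
        return gene.start - target.end
    return 0


def extract_flank_window(features: Sequence[GeneFeature],
                         target_gene_id: str,
                         window: int = DEFAULT_WINDOW) -> SyntenyWindow:
    """Collect every gene overlapping the +/- ``window`` bp neighborhood.

    Membership is decided by >= 1 bp overlap with the closed interval
    [max(1, target.start - window), target.end + window] on the target's
    contig; the target itself is always included with offset 0.
    """
    target = next((f for f in features if f.gene_id == target_gene_id), None)
    if target is None:
        raise ValidationError(f"unknown target gene {target_gene_id!r}")
    window_start = max(1, target.start - window)
    window_end = target.end + window
    flank = [
        (f, _signed_offset(f, target))
        for f in features
        if f.contig_id == target.contig_id and f.overlaps(window_start, window_end)
    ]
    flank.sort(key=lambda pair: (pair[0].start, pair[0].end, pair[0].gene_id))
    return SyntenyWindow(target=target, window_start=window_start,
                         window_end=window_end, flank_genes=flank)


def flag_hgt_context(window: SyntenyWindow,
                     upstream_kos: frozenset[str] = DEFAULT_UPSTREAM_KOS,
                     downstream_kos: frozenset[str] = DEFAULT_DOWNSTREAM_KOS,
                     strand_relative: bool = False) -> HGTContextFlags:
    """Screen a window for mobilization-motif KOs on each side.

    A flag is raised only by a flank gene lying strictly on the stated
    side: the upstream motif requires the gene to end before the target
    starts, the downstream motif requires it to start after the target
    ends.  Sides follow contig coordinates; with ``strand_relative`` the
    sides are swapped for minus-strand targets.
    """
    target = window.target
    swap = strand_relative and target.strand == Strand.MINUS
    up_kos, down_kos = (
        (downstream_kos, upstream_kos) if swap else (upstream_kos, downstream_kos)
    )
    upstream_hit = downstream_hit = False
    matches: list[tuple[str, str, int]] = []
    for gene, offset in window.flank_genes:
        if gene.gene_id == target.gene_id:
            continue
        before = gene.end < target.start
        after = gene.start > target.end
        for ko in sorted(gene.ko_ids):
            if ko in up_kos and before:
                matches.append((gene.gene_id, ko, offset))
                if swap:
                    downstream_hit = True
                else:
                    upstream_hit = True
            elif ko in down_kos and after:
                matches.append((gene.gene_id, ko, offset))
                if swap:
                    upstream_hit = True
                else:
                    downstream_hit = True
    return HGTContextFlags(
        target_gene_id=target.gene_id,
        upstream_recombinase=upstream_hit,
        downstream_pilus=downstream_hit,
        matches=matches,
    )


def synteny_table(windows: Iterable[SyntenyWindow],
                  upstream_kos: frozenset[str] = DEFAULT_UPSTREAM_KOS,
                  downstream_kos: frozenset[str] = DEFAULT_DOWNSTREAM_KOS
                  ) -> pd.DataFrame:
    """Flatten windows into a plot-ready table, one row per flank gene.

    Deterministically ordered by (target, start, gene id); ``motif``
    marks genes whose KO belongs to either screened set.
    """
    motif_kos = upstream_kos | downstream_kos
    rows = []
    for w in sorted(windows, key=lambda w: w.target_gene_id):
        for gene, offset in w.flank_genes:
            rows.append({
                "target_gene_id": w.target_gene_id,
                "gene_id": gene.gene_id,
                "contig_id": gene.contig_id,
                "start": gene.start,
                "end": gene.end,
                "strand": gene.strand.value,
                "offset": offset,
                "ko_ids": ",".join(sorted(gene.ko_ids)),
                "is_target": gene.gene_id == w.target_gene_id,
                "motif": bool(gene.ko_ids & motif_kos),
            })
    return pd.DataFrame(rows, columns=["target_gene_id", "gene_id", "contig_id",
                                       "start", "end", "strand", "offset",
                                       "ko_ids", "is_target", "motif"])
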