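"""Reconciliation of sequence- and structure-based function annotations.

Two structure-annotation routes feed the ladder: matches from a
structure-vs-PDB annotation report ("PF" evidence — a sequence search
against existing PDB entries plus 3D functional-template searches,
scored by E-value) and template hits from de-novo structure prediction
("TR" evidence, scored by TM-score and gated by admissibility
thresholds).  Both E-values and TM-scores map onto one four-rung
confidence ladder:

    ====================  ==============  ==================  =========
    PF likelihood         PF E-value      TR significance     TM-score
    ====================  ==============  ==================  =========
    certain match         < 1e-6          very high           > 0.7
    probable match        < 0.01          high                > 0.5
    possible match        < 0.1           medium              > 0.4
    long shot             < 10            low                 > 0.3
    ====================  ==============  ==================  =========

All thresholds are strict, so a value sitting exactly on a boundary
falls to the weaker tier.  Only *certain* PF matches may set a final
label; a deep-learning term predictor ("DF" evidence) is auxiliary and
can only corroborate a call (``df_supported``), never make one.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import (
    DFPrediction,
    EvidenceBundle,
    PFKind,
    PFMatch,
    TRHit,
    ValidationError,
)

UNANNOTATED = "unannotated"

#: DF certainty gate for corroboration
DF_SCORE_THRESHOLD = 0.7
#: minimum token length for label agreement
MIN_TOKEN_LENGTH = 4


class Tier(IntEnum):
    """Confidence rung shared by the PF and TR scales (rank 4..0).

    The PF names (certain/probable/possible/long_shot) are canonical;
    the TR names (very_high/high/medium/low) are aliases at the same
    rank, which is what makes cross-scale comparison well defined.
    """

    NONE = 0
    LONG_SHOT = 1
    LOW = 1
    POSSIBLE = 2
    MEDIUM = 2
    PROBABLE = 3
    HIGH = 3
    CERTAIN = 4
    VERY_HIGH = 4


PF_TIER_NAMES = {4: "certain", 3: "probable", 2: "possible", 1: "long_shot", 0: "none"}
TR_TIER_NAMES = {4: "very_high", 3: "high", 2: "medium", 1: "low", 0: "none"}


class AnnotationSource(str, Enum):
    CONSENSUS = "consensus"
    TR = "TR"
    PF = "PF"
    NONE = "none"


class Agreement(str, Enum):
    """Relation between the structure-based call and the sequence KO."""

    CONSISTENT = "consistent"
    DISPARATE = "disparate"
    STRUCTURE_ONLY = "structure_only"
    SEQUENCE_ONLY = "sequence_only"
    UNANNOTATED = "unannotated"


@dataclass
class ConsensusAnnotation:
    """Final function call for one subject, with full provenance."""

    subject_id: str
    final_label: str
    source: AnnotationSource
    tier: Tier
    df_supported: bool
    agreement: Agreement

    def __post_init__(self) -> None:
        if (self.source == AnnotationSource.NONE) != (self.final_label == UNANNOTATED):
            raise ValidationError(
                f"{self.subject_id}: source {self.source.value!r} inconsistent "
                f"with final_label {self.final_label!r}"
            )


def classify_pf_likelihood(e_value: float) -> Tier:
    """Map a structure-match E-value onto the likelihood ladder.

    Bands are strict: e < 1e-6 certain; e < 0.01 probable; e < 0.1
    possible; e < 10 long shot; anything at or above 10 carries no
    likelihood at all.  A value exactly on a boundary (e.g. 1e-6) falls
    to the weaker tier.
    """
    if e_value < 0:
        raise ValidationError(f"negative e_value {e_value!r}")
    if e_value < 1e-6:
        return Tier.CERTAIN
    if e_value < 0.01:
        return Tier.PROBABLE
    if e_value < 0.1:
        return Tier.POSSIBLE
    if e_value < 10.0:
        return Tier.LONG_SHOT
    return Tier.NONE


def classify_tr_significance(tm_score: float) -> Tier:
    """Map a template TM-score onto the significance ladder (strict >)."""
    if not (0.0 <= tm_score <= 1.0):
        raise ValidationError(f"tm_score {tm_score!r} outside [0, 1]")
    if tm_score > 0.7:
        return Tier.VERY_HIGH
    if tm_score > 0.5:
        return Tier.HIGH
    if tm_score > 0.4:
        return Tier.MEDIUM
    if tm_score > 0.3:
        return Tier.LOW
    return Tier.NONE


def tr_admissible(hit: TRHit) -> bool:
    """A template hit is usable iff confidence > 0.6, E-value < 0.001
    and coverage > 0.3 — all three strictly."""
    return hit.confidence > 0.6 and hit.e_value < 0.001 and hit.coverage > 0.3


def pf_coverage(longest_fitted_segment: int, query_length: int) -> float:
    """Coverage of a PF match: longest fitted segment over query length."""
    if query_length <= 0:
        raise ValidationError(f"query_length must be positive, got {query_length}")
    if not (0 <= longest_fitted_segment <= query_length):
        raise ValidationError(
            f"longest_fitted_segment {longest_fitted_segment} outside "
            f"[0, {query_length}]"
        )
    return longest_fitted_segment / query_length


def _tokens(label: str) -> set[str]:
    return {
        t.lower()
        for t in re.findall(r"[A-Za-z0-9]+", label)
        if len(t) >= MIN_TOKEN_LENGTH
    }


def labels_agree(a: str, b: str, exact: bool = False) -> bool:
    """Case-insensitive label agreement.

    Default mode is token overlap (shared word of >= 4 characters),
    because the annotation sources word the same function differently;
    ``exact`` switches to whole-string equality.
    """
    if exact:
        return a.strip().lower() == b.strip().lower()
    return bool(_tokens(a) & _tokens(b))


def best_pf_match(matches: Iterable[PFMatch]) -> Optional[PFMatch]:
    """Lowest-E-value match from the merged candidate pool.

    Sequence-vs-PDB and 3D-template matches compete in one pool; at
    equal E-value the 3D template is preferred, then the label breaks
    the tie so the choice never depends on input order.
    """
    matches = list(matches)
    if not matches:
        return None
    return min(
        matches,
        key=lambda m: (m.e_value, m.kind != PFKind.TEMPLATE_3D, m.function_label),
    )


def best_tr_hit(hits: Iterable[TRHit]) -> Optional[TRHit]:
    """Admissible hit of highest TM-score (then coverage, identity, id)."""
    admissible = [h for h in hits if tr_admissible(h)]
    if not admissible:
        return None
    return max(
        admissible,
        key=lambda h: (h.tm_score, h.coverage, h.identity, h.template_id),
    )


def _df_supported(predictions: Iterable[DFPrediction], final_label: str,
                  exact: bool = False) -> bool:
    if final_label == UNANNOTATED:
        return False
    return any(
        p.score > DF_SCORE_THRESHOLD and labels_agree(p.term_name, final_label, exact)
        for p in predictions
    )


def reconcile(bundle: EvidenceBundle, exact_labels: bool = False) -> ConsensusAnnotation:
    """Apply the priority ladder to one evidence bundle.

    The ladder, in order:

    1. Pick the best PF match (lowest E-value, 3D template preferred at
       ties) and the best admissible TR hit (highest TM-score).  PF can
       assign a function only at the *certain* tier.
    2. Both present with matching labels → consensus; the final tier is
       the higher of the two ranks.
    3. Both present with differing labels → the higher rank wins, with
       three published overrides: an admissible TR hit always beats a PF
       *long shot*; if the PF report has no 3D functional hits at all,
       TR wins; a PF match below *certain* can never take the label, so
       TR wins those conflicts too.  At equal rank the higher coverage
       wins, then the higher identity, then TR (a fixed final tie-break
       so the outcome never depends on input order).
    4. Exactly one present → that source; a lone PF match below
       *certain* leaves the subject unannotated.
    5. ``df_supported`` is set when any DF prediction above the 0.7
       certainty gate shares a label token with the final call.
    6. ``agreement`` relates the structure call to the sequence KO label
       by the same token test.
    """
    pf = best_pf_match(bundle.pf_matches)
    tr = best_tr_hit(bundle.tr_hits)
    pf_tier = classify_pf_likelihood(pf.e_value) if pf else Tier.NONE
    tr_tier = classify_tr_significance(tr.tm_score) if tr else Tier.NONE
    pf_eligible = pf is not None and pf_tier == Tier.CERTAIN
    has_3d = any(m.kind == PFKind.TEMPLATE_3D for m in bundle.pf_matches)

    final_label = UNANNOTATED
    source = AnnotationSource.NONE
    tier = Tier.NONE

    if pf is not None and tr is not None:
        if labels_agree(pf.function_label, tr.function_label, exact_labels):
            final_label = tr.function_label
            source = AnnotationSource.CONSENSUS
            tier = Tier(max(pf_tier, tr_tier))
        else:
            winner = _resolve_conflict(pf, tr, pf_tier, tr_tier,
                                       pf_eligible, has_3d)
            if winner == "pf":
                final_label, source, tier = pf.function_label, AnnotationSource.PF, pf_tier
            else:
                final_label, source, tier = tr.function_label, AnnotationSource.TR, tr_tier
    elif tr is not None:
        final_label, source, tier = tr.function_label, AnnotationSource.TR, tr_tier
    elif pf is not None and pf_eligible:
        final_label, source, tier = pf.function_label, AnnotationSource.PF, pf_tier

    df_ok = _df_supported(bundle.df_predictions, final_label, exact_labels)

    seq_ko = bundle.sequence_ko
    if final_label != UNANNOTATED:
        if seq_ko is not None and seq_ko.ko_ids:
            agreement = (
                Agreement.CONSISTENT
                if labels_agree(final_label, seq_ko.label_text(), exact_labels)
                else Agreement.DISPARATE
            )
        else:
            agreement = Agreement.STRUCTURE_ONLY
    else:
        if seq_ko is not None and seq_ko.ko_ids:
            agreement = Agreement.SEQUENCE_ONLY
        else:
            agreement = Agreement.UNANNOTATED

    return ConsensusAnnotation(
        subject_id=bundle.subject_id,
        final_label=final_label,
        source=source,
        tier=tier,
        df_supported=df_ok,
        agreement=agreement,
    )


def _resolve_conflict(pf: PFMatch, tr: TRHit, pf_tier: Tier, tr_tier: Tier,
                      pf_eligible: bool, has_3d: bool) -> str:
    """Decide a differing-labels conflict; returns "pf" or "tr"."""
    if not has_3d:
        return "tr"  # no 3D functional hits: TR has priority
    if pf_tier == Tier.LONG_SHOT:
        return "tr"  # an admissible template beats a long shot
    if pf_tier > tr_tier:
        # rank favours PF, but only a certain match may assign
        return "pf" if pf_eligible else "tr"
    if tr_tier > pf_tier:
        return "tr"
    # equal rank: coverage, then identity, then TR
    pf_cov = pf_coverage(pf.longest_fitted_segment, pf.query_length)
    if tr.coverage != pf_cov:
        return "tr" if tr.coverage > pf_cov else "pf"
    pf_ident = pf.percent_identity / 100.0
    if tr.identity != pf_ident:
        return "tr" if tr.identity > pf_ident else "pf"
    return "tr"


def annotate_all(bundles: Iterable[EvidenceBundle],
                 labels: Optional[Mapping[str, str]] = None,
                 exact_labels: bool = False) -> pd.DataFrame:
    """Reconcile every bundle into one table of final annotations.

    ``labels`` maps subject ids to their assigned group labels
    (u1…/h1…); rows are ordered by group letter then label index, with
    unlabeled subjects last.  A subject present in ``labels`` but
    missing a bundle gets a warning and an unannotated row.
    """
    labels = dict(labels or {})
    by_subject = {b.subject_id: b for b in bundles}
    for sid in labels:
        if sid not in by_subject:
            warnings.warn(f"no evidence bundle for subject {sid!r}; "
                          f"recording as unannotated", stacklevel=2)
            by_subject[sid] = EvidenceBundle(subject_id=sid)

    def sort_key(sid: str):
        label = labels.get(sid, "")
        m = re.fullmatch(r"([a-z]+)(\d+)", label)
        if m:
            return (0, m.group(1), int(m.group(2)), sid)
        return (1, "", 0, sid)

    rows = []
    for sid in sorted(by_subject, key=sort_key):
        ann = reconcile(by_subject[sid], exact_labels)
        rows.append({
            "subject_id": sid,
            "label": labels.get(sid, ""),
            "final_label": ann.final_label,
            "source": ann.source.value,
            "tier": ann.tier.value,
            "tier_name": PF_TIER_NAMES[ann.tier.value]
            if ann.source in (AnnotationSource.PF, AnnotationSource.NONE)
            else TR_TIER_NAMES[ann.tier.value],
            "df_supported": ann.df_supported,
            "agreement": ann.agreement.value,
        })
    return pd.DataFrame(
        rows,
        columns=["subject_id", "label", "final_label", "source", "tier",
                 "tier_name", "df_supported", "agreement"],
    )
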