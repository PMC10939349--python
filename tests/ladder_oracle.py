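"""Table-driven rule interpreter for the annotation priority ladder.

This is a deliberately independent re-statement of the published
reconciliation rules, used only as a test oracle.  Each rule is a
(predicate, outcome) pair tried in order; the first matching rule wins.
It never imports from the consensus module it checks.
"""

from __future__ import annotations

from typing import Callable, Optional


def _band_pf(e: float) -> str:
    for band, bound in (("certain", 1e-6), ("probable", 0.01),
                        ("possible", 0.1), ("long_shot", 10.0)):
        if e < bound:
            return band
    return "none"


def _band_tr(tm: float) -> str:
    for band, bound in (("very_high", 0.7), ("high", 0.5),
                        ("medium", 0.4), ("low", 0.3)):
        if tm > bound:
            return band
    return "none"


RANK = {"certain": 4, "very_high": 4, "probable": 3, "high": 3,
        "possible": 2, "medium": 2, "long_shot": 1, "low": 1, "none": 0}


def _tokens(label: str) -> set[str]:
    import re
    return {t.lower() for t in re.findall(r"[A-Za-z0-9]+", label) if len(t) >= 4}


def _same_label(a: str, b: str) -> bool:
    return bool(_tokens(a) & _tokens(b))


def _ctx(pf: Optional[dict], tr: Optional[dict]) -> dict:
    """Precompute every fact a rule may consult."""
    tr_admissible = tr is not None and (
        tr["confidence"] > 0.6 and tr["e_value"] < 0.001 and tr["coverage"] > 0.3
    )
    ctx = {
        "pf": pf,
        "tr": tr if tr_admissible else None,
        "pf_band": _band_pf(pf["e_value"]) if pf else "none",
        "tr_band": _band_tr(tr["tm_score"]) if tr_admissible else "none",
    }
    ctx["pf_certain"] = ctx["pf_band"] == "certain"
    ctx["pf_has_3d"] = pf is not None and pf["kind"] == "template_3d"
    if pf and ctx["tr"]:
        ctx["labels_match"] = _same_label(pf["function_label"],
                                          tr["function_label"])
        ctx["pf_cov"] = pf["longest_fitted_segment"] / pf["query_length"]
        ctx["tr_cov"] = tr["coverage"]
        ctx["pf_ident"] = pf["percent_identity"] / 100.0
        ctx["tr_ident"] = tr["identity"]
    return ctx


# the ladder as an ordered decision table: (predicate, outcome)
# outcome: "consensus", "pf", "tr", "unannotated"
RULES: list[tuple[Callable[[dict], bool], str]] = [
    (lambda c: c["pf"] is None and c["tr"] is None, "unannotated"),
    (lambda c: c["pf"] is None, "tr"),
    (lambda c: c["tr"] is None and c["pf_certain"], "pf"),
    (lambda c: c["tr"] is None, "unannotated"),
    (lambda c: c["labels_match"], "consensus"),
    (lambda c: not c["pf_has_3d"], "tr"),
    (lambda c: c["pf_band"] == "long_shot", "tr"),
    (lambda c: RANK[c["pf_band"]] > RANK[c["tr_band"]] and c["pf_certain"], "pf"),
    (lambda c: RANK[c["pf_band"]] > RANK[c["tr_band"]], "tr"),
    (lambda c: RANK[c["tr_band"]] > RANK[c["pf_band"]], "tr"),
    (lambda c: c["tr_cov"] > c["pf_cov"], "tr"),
    (lambda c: c["tr_cov"] < c["pf_cov"], "pf"),
    (lambda c: c["tr_ident"] > c["pf_ident"], "tr"),
    (lambda c: c["tr_ident"] < c["pf_ident"], "pf"),
    (lambda c: True, "tr"),
]


def oracle_reconcile(pf: Optional[dict], tr: Optional[dict]) -> tuple[str, str, int]:
    """Returns (final_label, source, tier_rank) per the decision table.

    ``pf``/``tr`` are plain dicts with the raw report fields; a TR hit
    failing the admissibility thresholds counts as absent.
    """
    ctx = _ctx(pf, tr)
    for predicate, outcome in RULES:
        if predicate(ctx):
            break
    if outcome == "unannotated":
        return "unannotated", "none", 0
    if outcome == "consensus":
        return (ctx["tr"]["function_label"], "consensus",
                max(RANK[ctx["pf_band"]], RANK[ctx["tr_band"]]))
    if outcome == "pf":
        return ctx["pf"]["function_label"], "PF", RANK[ctx["pf_band"]]
    return ctx["tr"]["function_label"], "TR", RANK[ctx["tr_band"]]
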