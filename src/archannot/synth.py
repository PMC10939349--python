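"""Synthetic input bundles with planted ground truth.

The generator emulates the structure of real MAG catalogs — multi-
environment MAG provenance, domain-separated level-1 clusters, level-2
superclusters, cross-domain KO overlap, structure-annotation evidence
spanning every confidence tier, and gene neighborhoods with planted
flank motifs — and writes a truth manifest alongside the bundle.  Every
truth entry is re-derived from the generated records by straight-line
code in this module, independently of the pipeline modules it is later
used to test.

One global seed drives one named pseudo-random stream per file type, so
adding a new file type never perturbs existing fixtures, and the same
config + seed always produce byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml

PathLike = Union[str, Path]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: fixed per-file-type stream ids (never renumber; append only)
_STREAMS = {
    "mags": 1,
    "clusters": 2,
    "sequences": 3,
    "ko": 4,
    "evidence": 5,
    "coverage": 6,
    "synteny": 7,
}

PF_TIERS = ("certain", "probable", "possible", "long_shot", "none")
TR_TIERS = ("very_high", "high", "medium", "low", "none")

#: open E-value intervals strictly inside each likelihood band, so a
#: drawn value can never sit on a classification boundary
PF_EVALUE_INTERVALS = {
    "certain": (1e-12, 1e-7),
    "probable": (2e-6, 9e-3),
    "possible": (1.2e-2, 9e-2),
    "long_shot": (1.2e-1, 9.0),
}
TR_TM_INTERVALS = {
    "very_high": (0.705, 0.99),
    "high": (0.505, 0.695),
    "medium": (0.405, 0.495),
    "low": (0.305, 0.395),
}

FUNCTION_LABELS = (
    "site-specific DNA recombinase",
    "Type IV pilus assembly protein PilC",
    "polypeptide N-acetylgalactosaminyltransferase",
    "dolichyl-phosphate-mannose protein mannosyltransferase",
    "Type II restriction endonuclease BglII",
    "Type I restriction-modification enzyme specificity subunit",
    "intimin/invasin-like protein",
    "propanediol utilization protein PduA",
    "transthyretin-like protein",
    "2-aminoethylphosphonate aminotransferase",
    "cold-shock domain protein Unr",
    "stage V sporulation protein AD",
    "stage V sporulation protein AE",
    "phosphoenolpyruvate-dependent PTS system IIA component",
    "adhesin-like surface protein",
    "glycosyltransferase family 4 protein",
    "methyl-coenzyme M reductase subunit alpha",
    "tetrahydromethanopterin S-methyltransferase",
    "formate dehydrogenase subunit beta",
    "archaeal flagellin FlaB",
    "S-layer glycoprotein",
    "ABC transporter substrate-binding protein",
    "ferredoxin oxidoreductase",
    "novobiocin biosynthesis protein NovC",
    "LytR-Cps2A-Psr family protein",
    "78 kDa glucose-regulated protein",
    "mitochondrial import receptor subunit TOM40",
    "endophilin-A membrane curvature protein",
    "universal stress protein UspA",
    "CRISPR-associated endonuclease Cas9",
)

ARCHAEAL_TAXA = (
    "d__Archaea;p__Methanobacteriota;c__Methanobacteria;o__Methanobacteriales;"
    "f__Methanobacteriaceae;g__Methanobrevibacter;s__Methanobrevibacter smithii",
    "d__Archaea;p__Methanobacteriota;c__Methanobacteria;o__Methanobacteriales;"
    "f__Methanobacteriaceae;g__Methanobrevibacter;s__Methanobrevibacter intestini",
    "d__Archaea;p__Thermoplasmatota;c__Thermoplasmata;o__Methanomassiliicoccales;"
    "f__Methanomethylophilaceae;g__UBA71;s__UBA71 sp.",
)
BACTERIAL_TAXA = (
    "d__Bacteria;p__Bacillota_A;c__Clostridia;o__Oscillospirales;"
    "f__Ruminococcaceae;g__Faecalibacterium;s__Faecalibacterium prausnitzii",
    "d__Bacteria;p__Bacillota_A;c__Clostridia;o__Clostridiales;"
    "f__Clostridiaceae;g__Clostridium;s__Clostridium sp. CAG-302",
    "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
    "f__Bacteroidaceae;g__Bacteroides;s__Bacteroides uniformis",
)


class GeneratorConfigError(ValueError):
    """The generator configuration is internally inconsistent."""


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic bundle, all deterministic under ``seed``.

    Tier mixtures are probabilities over the PF likelihood tiers and the
    TR significance tiers (``none`` meaning no evidence of that kind);
    ``agreement_probability`` is the chance that PF and TR evidence for
    a subject carry the same function label.  Flank plants are
    (ko, side, distance) triples placed relative to the fixture's target
    gene; a distance beyond 10 kb deliberately lands outside any correct
    window.
    """

    seed: int = 0
    n_archaeal_mags: int = 12
    n_bacterial_mags: int = 24
    environments: tuple[tuple[str, float], ...] = (
        ("human gut", 0.7), ("soil", 0.2), ("marine", 0.1),
    )
    gut_label: str = "human gut"
    n_archaeal_clusters: int = 30
    n_bacterial_clusters: int = 40
    archaeal_cluster_size: tuple[int, int] = (1, 6)
    bacterial_cluster_size: tuple[int, int] = (8, 14)
    ko_universe_size: int = 120
    shared_ko_fraction: float = 0.3
    fraction_gut_exclusive: float = 0.4
    fraction_fully_annotated: float = 0.85
    pf_tier_mixture: tuple[float, float, float, float, float] = (
        0.35, 0.20, 0.15, 0.10, 0.20,
    )
    tr_tier_mixture: tuple[float, float, float, float, float] = (
        0.35, 0.20, 0.15, 0.10, 0.20,
    )
    agreement_probability: float = 0.7
    n_samples: int = 6
    flank_plants: tuple[tuple[str, str, int], ...] = (
        ("K06400", "upstream", 4000),
        ("K02662", "downstream", 2000),
        ("K02664", "downstream", 12000),
    )
    n_background_genes: int = 20

    def validate(self) -> None:
        for name, mixture in (("pf_tier_mixture", self.pf_tier_mixture),
                              ("tr_tier_mixture", self.tr_tier_mixture)):
            if len(mixture) != 5 or any(not (0 <= p <= 1) for p in mixture):
                raise GeneratorConfigError(f"{name}: need 5 probabilities in [0,1]")
            if abs(sum(mixture) - 1.0) > 1e-9:
                raise GeneratorConfigError(f"{name}: probabilities must sum to 1")
        env_p = [p for _, p in self.environments]
        if any(not (0 <= p <= 1) for p in env_p) or abs(sum(env_p) - 1) > 1e-9:
            raise GeneratorConfigError("environment probabilities must sum to 1")
        if self.gut_label not in {label for label, _ in self.environments}:
            raise GeneratorConfigError(
                f"gut_label {self.gut_label!r} not among environment labels"
            )
        for frac_name in ("shared_ko_fraction", "fraction_gut_exclusive",
                          "fraction_fully_annotated", "agreement_probability"):
            v = getattr(self, frac_name)
            if not (0.0 <= v <= 1.0):
                raise GeneratorConfigError(f"{frac_name} must be in [0,1], got {v}")
        for side in {s for _, s, _ in self.flank_plants}:
            if side not in ("upstream", "downstream"):
                raise GeneratorConfigError(f"unknown flank side {side!r}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    @classmethod
    def from_yaml(cls, path: PathLike) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("environments", "flank_plants"):
            if key in raw:
                raw[key] = tuple(tuple(item) for item in raw[key])
        for key in ("archaeal_cluster_size", "bacterial_cluster_size",
                    "pf_tier_mixture", "tr_tier_mixture"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthManifest:
    """Planted ground truth accompanying a generated bundle."""

    gut_exclusive_cluster_ids: list[str]
    group_by_supercluster: dict[str, str]
    expected_final_label: dict[str, str]
    planted_flank_hits: dict[str, dict[str, bool]]
    evidence_tiers: dict[str, dict[str, str]]

    def to_json(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: PathLike) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


# ---------------------------------------------------------------------------
# independent straight-line re-derivation of the reconciliation rules
# (duplicated on purpose: the manifest must not be produced by the code
# it is used to verify)

def _band_of_evalue(e: float) -> str:
    if e < 1e-6:
        return "certain"
    if e < 0.01:
        return "probable"
    if e < 0.1:
        return "possible"
    if e < 10.0:
        return "long_shot"
    return "none"


def _band_of_tm(tm: float) -> str:
    if tm > 0.7:
        return "very_high"
    if tm > 0.5:
        return "high"
    if tm > 0.4:
        return "medium"
    if tm > 0.3:
        return "low"
    return "none"


_RANK = {"certain": 4, "very_high": 4, "probable": 3, "high": 3,
         "possible": 2, "medium": 2, "long_shot": 1, "low": 1, "none": 0}


def _share_token(a: str, b: str) -> bool:
    import re
    ta = {t.lower() for t in re.findall(r"[A-Za-z0-9]+", a) if len(t) >= 4}
    tb = {t.lower() for t in re.findall(r"[A-Za-z0-9]+", b) if len(t) >= 4}
    return bool(ta & tb)


def _expected_label(pf: Optional[dict], tr: Optional[dict]) -> str:
    """What the published priority rules say the final call must be.

    The generator emits at most one PF match and one admissible TR hit
    per subject, so the rules apply directly, without best-of selection.
    """
    pf_band = _band_of_evalue(pf["e_value"]) if pf else "none"
    tr_ok = tr is not None and (
        tr["confidence"] > 0.6 and tr["e_value"] < 0.001 and tr["coverage"] > 0.3
    )
    if pf and tr_ok:
        if _share_token(pf["function_label"], tr["function_label"]):
            return tr["function_label"]
        if pf["kind"] != "template_3d":
            return tr["function_label"]
        if pf_band == "long_shot":
            return tr["function_label"]
        tr_band = _band_of_tm(tr["tm_score"])
        if _RANK[pf_band] > _RANK[tr_band]:
            return pf["function_label"] if pf_band == "certain" else tr["function_label"]
        if _RANK[tr_band] > _RANK[pf_band]:
            return tr["function_label"]
        pf_cov = pf["longest_fitted_segment"] / pf["query_length"]
        if tr["coverage"] != pf_cov:
            return tr["function_label"] if tr["coverage"] > pf_cov else pf["function_label"]
        pf_ident = pf["percent_identity"] / 100.0
        if tr["identity"] != pf_ident:
            return tr["function_label"] if tr["identity"] > pf_ident else pf["function_label"]
        return tr["function_label"]
    if tr_ok:
        return tr["function_label"]
    if pf and pf_band == "certain":
        return pf["function_label"]
    return "unannotated"


# ---------------------------------------------------------------------------
# generation


def _random_sequence(rng: np.random.Generator) -> str:
    length = int(rng.integers(80, 601))
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _sample_environments(cfg: GeneratorConfig, rng: np.random.Generator,
                         n: int, force_mix: bool) -> list[str]:
    labels = [label for label, _ in cfg.environments]
    probs = [p for _, p in cfg.environments]
    envs = list(rng.choice(labels, size=n, p=probs))
    non_gut = [label for label in labels if label != cfg.gut_label]
    if force_mix and n >= 2:
        # guarantee both a gut and (when the vocabulary allows) a non-gut
        # MAG exist, so exclusive and non-exclusive clusters are plantable
        envs[0] = cfg.gut_label
        if non_gut and cfg.fraction_gut_exclusive < 1.0:
            envs[1] = non_gut[0]
    return envs


def _generate_mags(cfg: GeneratorConfig) -> list[dict]:
    rng = cfg.rng("mags")
    mags = []
    arch_envs = _sample_environments(cfg, rng, cfg.n_archaeal_mags, True)
    for i, env in enumerate(arch_envs, start=1):
        mags.append({
            "mag_id": f"MAG_A{i:04d}", "domain": "archaea",
            "taxonomy": ARCHAEAL_TAXA[int(rng.integers(len(ARCHAEAL_TAXA)))],
            "environment": env, "catalog": "synthetic-gem",
        })
    bact_envs = _sample_environments(cfg, rng, cfg.n_bacterial_mags, True)
    for i, env in enumerate(bact_envs, start=1):
        mags.append({
            "mag_id": f"MAG_B{i:04d}", "domain": "bacteria",
            "taxonomy": BACTERIAL_TAXA[int(rng.integers(len(BACTERIAL_TAXA)))],
            "environment": env, "catalog": "synthetic-uhgg",
        })
    return mags


def _generate_clusters(cfg: GeneratorConfig, mags: list[dict]) -> tuple[
        list[dict], dict[str, list[str]], dict[str, list[str]]]:
    """Returns (proteins, mm2 membership, supercluster membership)."""
    rng = cfg.rng("clusters")
    arch_gut = [m["mag_id"] for m in mags
                if m["domain"] == "archaea" and m["environment"] == cfg.gut_label]
    arch_nongut = [m["mag_id"] for m in mags
                   if m["domain"] == "archaea" and m["environment"] != cfg.gut_label]
    arch_all = arch_gut + arch_nongut
    bact_all = [m["mag_id"] for m in mags if m["domain"] == "bacteria"]

    proteins: list[dict] = []
    membership: dict[str, list[str]] = {}
    counter = 0

    def new_protein(mag_id: str) -> str:
        nonlocal counter
        counter += 1
        pid = f"P{counter:06d}"
        proteins.append({"protein_id": pid, "mag_id": mag_id})
        return pid

    arch_cluster_ids = []
    lo, hi = cfg.archaeal_cluster_size
    for i in range(1, cfg.n_archaeal_clusters + 1):
        cid = f"CA{i:04d}"
        arch_cluster_ids.append(cid)
        size = int(rng.integers(lo, hi + 1))
        exclusive = bool(rng.random() < cfg.fraction_gut_exclusive) and bool(arch_gut)
        if exclusive:
            mag_choices = [arch_gut[int(rng.integers(len(arch_gut)))]
                           for _ in range(size)]
        else:
            mag_choices = [arch_all[int(rng.integers(len(arch_all)))]
                           for _ in range(size)]
            if arch_nongut:
                # force at least one out-of-environment member
                mag_choices[0] = arch_nongut[int(rng.integers(len(arch_nongut)))]
        membership[cid] = [new_protein(m) for m in mag_choices]

    bact_cluster_ids = []
    lo, hi = cfg.bacterial_cluster_size
    for i in range(1, cfg.n_bacterial_clusters + 1):
        cid = f"CB{i:04d}"
        bact_cluster_ids.append(cid)
        size = int(rng.integers(lo, hi + 1))
        membership[cid] = [
            new_protein(bact_all[int(rng.integers(len(bact_all)))])
            for _ in range(size)
        ]

    sc_membership: dict[str, list[str]] = {}

    def group_into_superclusters(cluster_ids: list[str], prefix: str) -> None:
        ids = list(cluster_ids)
        rng.shuffle(ids)
        k = 0
        while ids:
            k += 1
            take = int(rng.integers(1, min(3, len(ids)) + 1))
            sc_membership[f"{prefix}{k:04d}"] = sorted(ids[:take])
            ids = ids[take:]

    group_into_superclusters(arch_cluster_ids, "SCA")
    group_into_superclusters(bact_cluster_ids, "SCB")
    return proteins, membership, sc_membership


def _generate_ko(cfg: GeneratorConfig, membership: Mapping[str, list[str]],
                 sc_membership: Mapping[str, list[str]]) -> tuple[
        dict[str, list[str]], dict[str, str], dict[str, str]]:
    """Assign KOs per level-1 cluster and propagate to members.

    Returns (ko per protein, KO display name per KO id, sampled pool per
    archaeal supercluster: "shared" or "archaea_only").
    """
    rng = cfg.rng("ko")
    universe = [f"K{i:05d}" for i in rng.permutation(
        np.arange(1, cfg.ko_universe_size + 1))]
    n_shared = int(round(cfg.shared_ko_fraction * cfg.ko_universe_size))
    shared = universe[:n_shared]
    rest = universe[n_shared:]
    arch_only = rest[: len(rest) // 2]
    bact_only = rest[len(rest) // 2:]

    ko_names = {
        ko: FUNCTION_LABELS[int(rng.integers(len(FUNCTION_LABELS)))]
        for ko in universe
    }

    cluster_kos: dict[str, list[str]] = {}
    pool_choice: dict[str, str] = {}
    for sid in sorted(k for k in sc_membership if k.startswith("SCA")):
        use_shared = bool(rng.random() < 0.5) and bool(shared)
        pool = shared if use_shared else (arch_only or shared)
        pool_choice[sid] = "shared" if pool is shared else "archaea_only"
        for cid in sc_membership[sid]:
            n_kos = int(rng.integers(1, 3))
            cluster_kos[cid] = sorted(
                {pool[int(rng.integers(len(pool)))] for _ in range(n_kos)}
            )
    bact_pool = shared + bact_only
    for sid in sorted(k for k in sc_membership if k.startswith("SCB")):
        for cid in sc_membership[sid]:
            n_kos = int(rng.integers(1, 4))
            cluster_kos[cid] = sorted(
                {bact_pool[int(rng.integers(len(bact_pool)))] for _ in range(n_kos)}
            )

    protein_ko: dict[str, list[str]] = {}
    for cid in sorted(membership):
        members = membership[cid]
        kos = cluster_kos.get(cid, [])
        drop_index = -1
        if len(members) > 1 and rng.random() > cfg.fraction_fully_annotated:
            drop_index = int(rng.integers(len(members)))
        for j, pid in enumerate(members):
            if j != drop_index:
                protein_ko[pid] = list(kos)
    return protein_ko, ko_names, pool_choice


def generate_evidence(cfg: GeneratorConfig, subjects: Sequence[str],
                      subject_kos: Mapping[str, Sequence[str]],
                      ko_names: Mapping[str, str]) -> tuple[list[dict], dict, dict]:
    """Draw tiered PF/TR/DF evidence for each subject.

    Returns (bundle entries, expected final label per subject, sampled
    tier per subject).  Expected labels come from the straight-line
    rule re-derivation above, applied to the drawn values.
    """
    rng = cfg.rng("evidence")
    entries: list[dict] = []
    expected: dict[str, str] = {}
    tiers: dict[str, dict[str, str]] = {}
    labels = list(FUNCTION_LABELS)
    for sid in subjects:
        pf_tier = str(rng.choice(PF_TIERS, p=cfg.pf_tier_mixture))
        tr_tier = str(rng.choice(TR_TIERS, p=cfg.tr_tier_mixture))
        kos = sorted(subject_kos.get(sid, []))

        # function labels: one "true" label; with agreement_probability the
        # two structure routes say the same thing, and with prob 0.3 the
        # true label is the subject's own KO name so sequence/structure
        # agreement occurs too
        if kos and rng.random() < 0.3:
            true_label = ko_names[kos[0]]
        else:
            true_label = labels[int(rng.integers(len(labels)))]
        if rng.random() < cfg.agreement_probability:
            other_label = true_label
        else:
            other_label = labels[int(rng.integers(len(labels)))]
            while _share_token(other_label, true_label):
                other_label = labels[int(rng.integers(len(labels)))]

        pf = None
        if pf_tier != "none":
            lo, hi = PF_EVALUE_INTERVALS[pf_tier]
            e_value = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            qlen = int(rng.integers(100, 500))
            pf = {
                "kind": "template_3d" if rng.random() < 0.8 else "sequence_vs_pdb",
                "e_value": e_value,
                "percent_identity": float(np.round(rng.uniform(10, 95), 3)),
                "longest_fitted_segment": int(rng.integers(30, qlen + 1)),
                "query_length": qlen,
                "function_label": true_label,
            }
        tr = None
        if tr_tier != "none":
            lo, hi = TR_TM_INTERVALS[tr_tier]
            tr = {
                "template_id": f"tmpl{int(rng.integers(1000, 9999))}A",
                "confidence": float(np.round(rng.uniform(0.62, 0.95), 3)),
                "e_value": float(np.exp(rng.uniform(np.log(1e-8), np.log(8e-4)))),
                "coverage": float(np.round(rng.uniform(0.32, 0.95), 3)),
                "identity": float(np.round(rng.uniform(0.05, 0.9), 3)),
                "tm_score": float(np.round(rng.uniform(lo, hi), 4)),
                "function_label": other_label,
            }

        final = _expected_label(pf, tr)

        df_preds = []
        n_df = int(rng.integers(0, 3))
        for _ in range(n_df):
            if final != "unannotated" and rng.random() < 0.5:
                term_name = final
            else:
                term_name = labels[int(rng.integers(len(labels)))]
            df_preds.append({
                "term_id": f"GO:{int(rng.integers(1000000, 9999999)):07d}",
                "score": float(np.round(rng.uniform(0.4, 0.95), 3)),
                "term_name": term_name,
            })

        entry: dict = {"subject_id": sid, "pf_matches": [], "tr_hits": [],
                       "df_predictions": df_preds}
        if kos:
            entry["sequence_ko"] = {
                "ko_ids": kos,
                "labels": {k: ko_names[k] for k in kos},
                "source": "mantis",
            }
        if pf:
            entry["pf_matches"].append(pf)
        if tr:
            entry["tr_hits"].append(tr)
        entries.append(entry)
        expected[sid] = final
        tiers[sid] = {"pf": pf_tier, "tr": tr_tier}
    return entries, expected, tiers


def generate_synteny_fixture(cfg: GeneratorConfig, out_dir: PathLike,
                             ko_names: Optional[Mapping[str, str]] = None
                             ) -> dict[str, dict[str, bool]]:
    """Write a GFF3 + KO sidecar with planted flank motifs.

    One target gene sits mid-contig; each configured plant places a gene
    with the given KO at the signed distance from the target boundary.
    Returns the independently derived truth flags for the target.
    """
    rng = cfg.rng("synteny")
    out_dir = Path(out_dir)
    contig = "ctg_hgt0001"
    target_id = "tgt_spoVA"
    target_start, target_end = 15_001, 15_900
    gene_len = 600

    genes: list[tuple[str, int, int, str, list[str]]] = []
    genes.append((target_id, target_start, target_end, "+", ["K06398"]))

    motif_kos = {ko for ko, _, _ in cfg.flank_plants} | {"K06400", "K02662", "K02664"}
    plant_rows = []
    for idx, (ko, side, distance) in enumerate(cfg.flank_plants, start=1):
        if side == "upstream":
            end = target_start - distance
            start = end - (gene_len - 1)
        else:
            start = target_end + distance
            end = start + (gene_len - 1)
        if start < 1:
            raise GeneratorConfigError(
                f"flank plant {ko} at distance {distance} would start at "
                f"coordinate {start} (< 1)"
            )
        gid = f"plant_{ko}_{side}_{distance}"
        genes.append((gid, start, end, "-" if side == "upstream" else "+", [ko]))
        plant_rows.append((ko, side, distance))

    background_pool = [f"K{int(i):05d}" for i in rng.integers(10000, 20000,
                                                              size=200)]
    background_pool = [k for k in background_pool if k not in motif_kos]
    position = 1000
    for i in range(1, cfg.n_background_genes + 1):
        start = position + int(rng.integers(0, 400))
        end = start + int(rng.integers(300, 1200))
        strand = "+" if rng.random() < 0.5 else "-"
        ko = background_pool[int(rng.integers(len(background_pool)))]
        genes.append((f"bg{i:04d}", start, end, strand, [ko]))
        position = end + 200

    genes.sort(key=lambda g: (g[1], g[2], g[0]))
    gff_lines = ["##gff-version 3"]
    ko_lines = ["gene_id\tko_id"]
    for gid, start, end, strand, kos in genes:
        gff_lines.append(
            f"{contig}\tsynthetic\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
            f"ID={gid};partial=00"
        )
        for ko in kos:
            ko_lines.append(f"{gid}\t{ko}")
    (out_dir / "genes.gff3").write_text("\n".join(gff_lines) + "\n")
    (out_dir / "gene_ko.tsv").write_text("\n".join(ko_lines) + "\n")

    # truth: a motif counts only when its gene stays inside the 10-kb
    # window, i.e. plant distance <= 10 000 (derived arithmetically)
    upstream_hit = any(
        ko in {"K06400"} and side == "upstream" and distance <= 10_000
        for ko, side, distance in plant_rows
    )
    downstream_hit = any(
        ko in {"K02662", "K02664"} and side == "downstream" and distance <= 10_000
        for ko, side, distance in plant_rows
    )
    return {
        target_id: {
            "upstream_recombinase": upstream_hit,
            "downstream_pilus": downstream_hit,
        }
    }


def _derive_gut_exclusive(membership: Mapping[str, list[str]],
                          protein_mag: Mapping[str, str],
                          mag_env: Mapping[str, str],
                          gut_label: str) -> list[str]:
    """Gut exclusivity re-derived record by record from the raw tables."""
    out = []
    for cid in sorted(membership):
        envs = {mag_env[protein_mag[pid]] for pid in membership[cid]}
        if envs == {gut_label}:
            out.append(cid)
    return out


def _derive_groups(sc_membership: Mapping[str, list[str]],
                   protein_ko: Mapping[str, list[str]],
                   membership: Mapping[str, list[str]]) -> dict[str, str]:
    """u/h groups re-derived from first principles: an archaeal
    supercluster is homologous iff any of its KOs appears on any
    bacterial protein."""
    bacterial_kos: set[str] = set()
    for cid, members in membership.items():
        if cid.startswith("CB"):
            for pid in members:
                bacterial_kos.update(protein_ko.get(pid, []))
    groups: dict[str, str] = {}
    for sid in sorted(k for k in sc_membership if k.startswith("SCA")):
        kos: set[str] = set()
        for cid in sc_membership[sid]:
            for pid in membership[cid]:
                kos.update(protein_ko.get(pid, []))
        groups[sid] = "homologous" if kos & bacterial_kos else "unique"
    return groups


def generate_dataset(config: GeneratorConfig, out_dir: PathLike) -> TruthManifest:
    """Write a complete input bundle plus its truth manifest.

    Deterministic given the seed: running twice with the same config
    yields byte-identical files.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    mags = _generate_mags(config)
    proteins, membership, sc_membership = _generate_clusters(config, mags)
    protein_ko, ko_names, _ = _generate_ko(config, membership, sc_membership)

    seq_rng = config.rng("sequences")
    sequences = {p["protein_id"]: _random_sequence(seq_rng) for p in proteins}

    # --- mags.tsv
    lines = ["mag_id\tdomain\ttaxonomy\tenvironment\tcatalog"]
    for m in mags:
        lines.append("\t".join([m["mag_id"], m["domain"], m["taxonomy"],
                                m["environment"], m["catalog"]]))
    (out_dir / "mags.tsv").write_text("\n".join(lines) + "\n")

    # --- proteins.faa
    fasta = []
    for p in proteins:
        fasta.append(f">{p['protein_id']} mag={p['mag_id']}")
        fasta.append(sequences[p["protein_id"]])
    (out_dir / "proteins.faa").write_text("\n".join(fasta) + "\n")

    # --- clusters_mm2.tsv / superclusters.tsv
    lines = ["cluster_id\tmember_id"]
    for cid in sorted(membership):
        for pid in membership[cid]:
            lines.append(f"{cid}\t{pid}")
    (out_dir / "clusters_mm2.tsv").write_text("\n".join(lines) + "\n")
    lines = ["cluster_id\tmember_id"]
    for sid in sorted(sc_membership):
        for cid in sc_membership[sid]:
            lines.append(f"{sid}\t{cid}")
    (out_dir / "superclusters.tsv").write_text("\n".join(lines) + "\n")

    # --- ko.tsv (protein-level, with display names)
    lines = ["subject_id\tko_ids\tsource\tko_names"]
    for pid in sorted(protein_ko):
        kos = sorted(protein_ko[pid])
        names = ";".join(ko_names[k] for k in kos)
        lines.append(f"{pid}\t{','.join(kos)}\tmantis\t{names}")
    (out_dir / "ko.tsv").write_text("\n".join(lines) + "\n")

    # --- evidence.json + expected final labels
    subjects = sorted(k for k in sc_membership if k.startswith("SCA"))
    subject_kos = {
        sid: sorted({
            ko
            for cid in sc_membership[sid]
            for pid in membership[cid]
            for ko in protein_ko.get(pid, [])
        })
        for sid in subjects
    }
    entries, expected, tiers = generate_evidence(
        config, subjects, subject_kos, ko_names
    )
    with open(out_dir / "evidence.json", "w") as fh:
        json.dump(entries, fh, indent=1, sort_keys=True)
        fh.write("\n")

    # --- coverage.tsv over archaeal gut-exclusive member genes
    gut_exclusive = _derive_gut_exclusive(
        membership,
        {p["protein_id"]: p["mag_id"] for p in proteins},
        {m["mag_id"]: m["environment"] for m in mags},
        config.gut_label,
    )
    cov_rng = config.rng("coverage")
    lines = ["gene_id\tsample_id\tmean_coverage"]
    arch_exclusive = [c for c in gut_exclusive if c.startswith("CA")]
    for cid in arch_exclusive:
        for pid in membership[cid]:
            for s in range(1, config.n_samples + 1):
                if cov_rng.random() < 0.1:
                    continue  # gene not covered in this sample
                value = float(np.round(cov_rng.lognormal(1.0, 1.0), 4))
                lines.append(f"{pid}\tS{s:02d}\t{value:.6g}")
    (out_dir / "coverage.tsv").write_text("\n".join(lines) + "\n")

    # --- synteny fixture
    planted = generate_synteny_fixture(config, out_dir, ko_names)

    manifest = TruthManifest(
        gut_exclusive_cluster_ids=gut_exclusive,
        group_by_supercluster=_derive_groups(sc_membership, protein_ko, membership),
        expected_final_label=expected,
        planted_flank_hits=planted,
        evidence_tiers=tiers,
    )
    manifest.to_json(out_dir / "truth_manifest.json")
    return manifest
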