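# Methods

## Scope and data model

The pipeline operates downstream of the heavy bioinformatics tools.
Gene prediction, clustering, KO assignment, structure prediction and
structure annotation are treated as *inputs*: level-1 cluster
membership (greedy sequence clustering at ~90% identity/coverage),
level-2 supercluster membership (MinHash sketch grouping), KO tables,
and parsed structure-evidence records in a documented JSON schema. The
schema — per subject: an optional sequence KO, a list of PDB
structure-match records (`kind`, `e_value`, `percent_identity`,
`longest_fitted_segment`, `query_length`, `function_label`), a list of
template hits (`confidence`, `e_value`, `coverage`, `identity`,
`tm_score`, `function_label`) and a list of term predictions
(`term_id`, `score`, `term_name`) — replaces vendor-native report
parsing deliberately: it keeps the decision logic testable and
independent of tool versions.

Coordinates are 1-based inclusive everywhere (Prodigal/GFF3
convention). Environment labels form an open vocabulary compared by
exact equality after lowercasing and trimming; no fuzzy matching, so a
mislabeled environment is a data problem, never a silent recall issue.
Cluster representatives default to the longest member sequence, ties
broken lexicographically by protein id (the representative rule is not
fixed by the upstream tools' conventions; this one is deterministic
without extra inputs).

## Selection funnel

Gates run environment → size → annotation. Environment exclusivity is
the binding constraint: a cluster is retained iff it has at least one
member from the target environment and none from any other —
equivalently, all members are from the target environment. Size
defaults are ≥ 2 members for archaeal clusters and ≥ 10 for bacterial
ones. "Complete annotation" defaults to every member carrying at least
one KO (`all_members`), the strictest defensible reading; a
`representative` mode supports cluster-level KO tables. The size and
annotation gates commute (asserted by test), so the order only affects
intermediate funnel counts, which are reported per stage and per
domain. Level-1 clusters whose members span both domains are rejected
as malformed input, since the domains are clustered separately
upstream.

## Unique/homologous partition

KO identity is the sole homology criterion. By default the bacterial
KO universe is **global** — the union over all retained bacterial
clusters — rather than restricted to bacteria co-occurring in the same
supercluster; the narrower reading is available by passing a restricted
universe. Labels are u1…/h1… with 1-based gap-free indices; default
ordering is lexicographic by supercluster id (reproducible without any
occurrence data), with a descending-occurrence alternative.

## Consensus annotation ladder

E-values and TM-scores map onto one four-rung confidence scale. All
thresholds are strict as printed, so boundary values fall to the weaker
tier: an E-value of exactly 1e-6 is *probable*, a TM-score of exactly
0.3 carries no significance. The best PF match is chosen from a merged
pool of PDB-sequence-search and 3D-template matches by lowest E-value,
with the 3D template preferred at an exact tie and the label as a final
tie-break, so the choice never depends on input order. The best TR hit
is the admissible hit (confidence > 0.6, E-value < 0.001, coverage
> 0.3) of highest TM-score.

Conflicts between differing labels resolve in this order: no 3D
functional hits on the PF side → TR wins; PF at *long shot* → an
admissible TR hit wins; otherwise higher rank wins, except that a PF
match below *certain* can never take the label (the certain-only
assignment rule dominates the rank comparison), so those conflicts go
to TR as well; equal ranks are broken by coverage (TR's `coverage` vs
PF's longest-fitted-segment/query-length), then identity (TR identity
vs PF percent identity / 100), then TR — a fixed final tie-break chosen
so equal-everything cases are order-independent.

Label agreement — between the two structure routes, against term
predictions, and against the sequence KO's name — is case-insensitive
token overlap with tokens of ≥ 4 characters, because the sources word
the same function differently ("glycosyltransferase activity" vs
"glycosyltransferase family 4 protein"); exact-match mode is available
(`exact_labels=True`). Term predictions can only set the
`df_supported` flag (score strictly above 0.7 plus a shared token);
they never assign the final label. The agreement field classifies each
subject as consistent / disparate / structure_only / sequence_only /
unannotated relative to its sequence KO.

## Metrics

Relative occurrence is `n_select / n_total × 1e6`; the constant only
rescales for readability, and the measure is invariant under
proportional scaling of both counts (property-tested). The published
diagnostic formulas define specificity as `N_seq / (N_seq + N_str)`,
i.e. exactly `1 − sensitivity`, which forces both likelihood ratios to
1 for any positive counts. They are implemented as printed; the result
carries a `degenerate` flag and NaN (reported as undefined) where a
denominator vanishes, rather than pretending the ratios are
informative. Percentages are rounded half-away-from-zero (matching the
published style of 13/28 → 46%); note one published percentage
(11/45 printed as 25%) is not reproducible by any standard rounding —
100·11/45 = 24.4 — and the package reports 24.

Expression roll-up averages member genes first, then samples: per
cluster and sample, the mean over member genes with coverage data; the
overall mean is then the mean over samples. Genes without coverage in a
sample are missing, not zero — zeros would silently deflate means — and
a cluster with no covered genes keeps a missing overall mean and is
excluded from the high-expression percentile pool. The high-expression
flag defaults to the 75th percentile of cluster overall means
(numpy's linear interpolation); the threshold is a configurable
stand-in, since "relatively high expression" has no published number.

## Synteny and HGT context

Windows span `max(1, start − 10 000)` to `end + 10 000` on the target's
contig (never crossing contigs), and membership is ≥ 1 bp overlap —
partially overlapping neighbors are visible in synteny plots, so
containment would under-report; a containment mode is not provided but
the window length is a parameter. Offsets are signed from gene
boundaries: negative when the flank gene ends before the target starts,
positive when it starts after the target ends, zero for overlaps.
Motif sides are strict — the upstream flag requires `end < target.start`
— and defined on contig coordinates by default, with a strand-relative
mode that swaps sides for minus-strand targets. Default motif sets are
K06400 (site-specific DNA recombinase) upstream and K02662/K02664
(Type IV pilus assembly) downstream.

## Synthetic data generator

The generator emulates the *structure* of a real catalog survey, not
its biology: MAGs with environments drawn from a configurable mixture
(default 70% human gut / 20% soil / 10% marine over 12 archaeal and 24
bacterial MAGs), 30 archaeal clusters of 1–6 members and 40 bacterial
clusters of 8–14 members grouped into 1–3-cluster superclusters, a
120-KO universe with a 30% shared pool, evidence tiers drawn from
mixtures spanning every rung (defaults put 35% mass on the top tier and
20% on absence, for each route), an agreement probability of 0.7
between the two structure routes' labels, and a flank fixture planting
K06400 at 4 kb upstream, K02662 at 2 kb downstream and K02664 at 12 kb
downstream (the last deliberately outside any correct window). These
defaults give a few hundred proteins per bundle — large enough that
every pipeline branch is exercised, small enough that a hundred bundles
run in seconds.

Evidence values are drawn strictly inside open tier intervals (e.g. a
*certain* E-value from (1e-12, 1e-7)) so no generated value ever sits on
a classification boundary. Sequences are uniform random amino-acid
strings of length 80–600: clustering execution is out of scope, so no
attempt is made at clustering-realistic similarity. One global seed
drives a named pseudo-random stream per file type, so adding a file
type never perturbs existing fixtures, and a bundle is byte-identical
across reruns of the same config.

Every manifest entry is **re-derived independently** by straight-line
code in the generator module — gut exclusivity by scanning the raw
tables, groups by direct set intersection, expected final labels by a
second, inline statement of the reconciliation rules, flank flags by
distance arithmetic — never by calling the pipeline modules the
manifest is later used to test.

What passing on synthetic bundles does **not** show: robustness to the
messiness of real catalogs (inconsistent environment metadata,
chimeric MAGs, partial genes, tool-version drift in report formats) or
to label vocabularies beyond the generator's; the token-overlap
agreement rule in particular is a pragmatic stand-in for semantic
comparison and is evaluated only against the generator's vocabulary.

## Numerical and formatting choices

Writers emit fixed column orders with floats at 6 significant digits,
so identical inputs give identical bytes. Percent rounding uses decimal
half-away-from-zero (Python's built-in `round` is banker's rounding and
would print 12.5% as 12%). Validation errors always name the offending
record.

## Known limitations

- KO-set homology is binary; a single shared housekeeping KO makes a
  supercluster "homologous".
- The ladder compares at most the single best match per route; ensemble
  signals across multiple weaker matches are ignored by design.
- The expression percentile threshold and the member-then-sample
  averaging order are package choices, not published rules.
- HGT context flags are circumstantial screening, not transfer
  inference (no best-match or phylogenetic-incongruence testing).
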