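# Methods

This note documents the models, rules and numerical choices behind
`genetrends`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## Corpus model and filtering

An abstract record is a publication identifier with title, abstract text,
calendar year, journal, keywords and an ordered author list; each author
carries raw affiliation strings, preserved verbatim (the resolver needs
the original comma structure). Text fields are whitespace-normalized on
read (runs collapsed, ends trimmed) so downstream string matching is
stable across input formats.

The completeness filter keeps exactly the records with a non-empty
abstract, non-empty title, at least one author and a journal name, and
reports how many records lacked each field (a record missing several
fields is counted under each reason). Records missing only their *year*
are retained: the year matters only to year-indexed analyses, which skip
such records themselves and report the count. This keeps the two filters
orthogonal — a corpus can be complete but partially undated.

MEDLINE years come from the article date's `Year` element; when only a
free-text `MedlineDate` exists (e.g. "1998 Dec-1999 Jan"), the first
4-digit token in [1800, 2100] is used. This is deterministic and matches
the convention that a season-spanning issue belongs to its opening year.

## Gene recognition

Recognition is dictionary-based: a lexicon maps canonical symbols to
synonym sets (each symbol is a synonym of itself; protein names are
simply listed as synonyms of their gene, keeping the matcher single-pass).
A synonym claimed by two or more symbols is ambiguous, dropped at build
time and reported — an unsupervised matcher cannot adjudicate it.

Matching runs over the title+abstract concatenation (joined by a newline,
which is itself a token boundary) and is:

* **token-boundary respecting** — a match must be flanked by
  non-alphanumeric characters; hyphens count as boundaries, so "anti-PTEN"
  matches but "BRCA12" does not match BRCA1;
* **case-policy dependent** — synonyms of ≤ 3 characters match
  case-sensitively (short acronyms such as "BC" are too ambiguous to fold),
  longer ones case-insensitively;
* **longest-leftmost, non-overlapping** — candidates are selected greedily
  by position, preferring longer matches at equal start; remaining ties go
  to the lexicographically smaller symbol (unreachable for a valid lexicon,
  but fixed for determinism).

The matcher is a pure function of text and lexicon; a brute-force oracle
(try every synonym at every offset, same greedy rule) is part of the test
suite. Gene *counting* downstream is per-abstract presence: a gene
mentioned five times in one abstract counts once, both titles and
abstracts contribute.

## Country resolution

Affiliations are split on commas into trimmed sub-addresses. Resolution
starts from the rightmost sub-address (which usually carries the country)
and escalates: while the current query matches zero or ≥ 2 distinct
countries, the next sub-address to the left is prepended. Matching against
the gazetteer is case-insensitive, word-boundary-respecting substring
containment of an alias or keyword hint — "AB Canada" resolves through its
"Canada" token without a geocoder. A key equal to the *entire* query takes
priority over containment matches: this is what allows a longer, more
specific query to shrink an ambiguous candidate set, since containment
alone can only ever add candidates as the query grows. "Exactly one
country" means one distinct canonical name — several aliases of the same
country agreeing is a resolution, not an ambiguity.

Failures are statuses (`unresolved`, `ambiguous`), never exceptions. A
record's country set is the union over all affiliations of all authors;
this is the definition a collaboration count needs (a paper collaborates
internationally iff that union has ≥ 2 elements). A cache maps resolved
query strings to their country; it is a pure accelerator and tests verify
it cannot change any result.

Records with an empty country set are kept in a reserved `(unresolved)`
row of the count matrix so record totals stay checkable; that row is
excluded from effort, rankings and transactions.

## Count metrics

`effort(X, Y)` = abstracts from country X mentioning gene Y / papers from
X. Effort rows do *not* sum to 1: an abstract mentioning several genes
contributes to each, so a row sums to the mean number of distinct genes
per paper of that country. Multi-country papers count fully toward each
country (no fractional attribution), so the sum of per-country paper
counts exceeds the record count exactly when multi-country papers exist.
Rankings are descending by count with lexicographic tie-breaks.

## Itemset mining

Transactions are binary presence sets: one transaction per country (or
year) holding every gene that appears in at least one of its abstracts,
with no minimum mention count. Support is reported in percent, rounded
half-even to two decimals (48.43 = 77/159).

`mine_frequent` is an Eclat-style depth-first search over vertical
tid-sets with anti-monotone pruning; it enumerates *all* frequent itemsets
and is therefore exponential on dense databases — it exists for small
inputs and as the oracle-checked reference. `mine_closed` is an LCM-style
closure search (each candidate is closed against the intersection of its
supporting transactions; tid-set deduplication visits each closed set
once) and stays small even when transactions are near-identical, which is
the regime country/year transactions actually occupy. The closed
collection determines all supports; a closed set is maximal iff no closed
proper superset is frequent. The shipped pipeline mines closed sets; the
threshold comparison uses the exact fraction (count·100/n ≥ threshold
within 1e-9), not the rounded percentage.

Reported rankings order by descending support, then smaller cardinality,
then lexicographic items — ties in support are common and need a fixed
order.

## Network analysis

The co-occurrence graph connects two genes with weight equal to the number
of abstracts mentioning both; singleton genes remain as isolated nodes. The
analysis sequence is: giant component (most nodes; ties by edge count then
smallest member), pruning (drop edges with weight < 10, then isolated
nodes — weight 10 itself survives), then measurement. Stage summaries
report counts and two-decimal percentages of the full network, always
recomputed from the counts.

Betweenness and closeness are computed on the *unweighted* skeleton of the
pruned graph — co-occurrence weights are similarities, not path costs, and
shortest-path centralities over raw counts would invert their meaning.
Closeness uses the harmonic variant (mean reciprocal distance, normalized
by n−1), which is well-defined on disconnected graphs and coincides with
classic closeness on connected ones up to ordering. Community detection
*does* use the weights (co-occurrence strength is the natural affinity):
greedy multilevel (Louvain) modularity maximization with a fixed seed;
community labels are contiguous integers assigned by descending community
size then smallest member, so labels are reproducible.

## Clustering

**Hierarchical.** Countries are clustered on their gene-count rows with
complete linkage, implemented directly (Lance–Williams max-update) with a
deterministic tie-break: among equal-height merges the lexicographically
smallest cluster-id pair merges first. Complete linkage guarantees
monotone heights. The default metric is cosine distance — raw publication
volume differs by orders of magnitude between countries and would dominate
Euclidean distances; the metric is configurable, and a user-supplied
callable is checked for symmetry.

**Fuzzy c-means.** Alternating updates

    u_ik = 1 / Σ_j (‖x_k − v_i‖ / ‖x_k − v_j‖)^(2/(m−1))
    v_i  = Σ_k u_ik^m x_k / Σ_k u_ik^m

with fuzzifier m = 2, tolerance 1e−5 on the maximum center shift,
maximum 300 iterations, and initial centers drawn as distinct data points
with a seeded generator. A point coincident with a center receives crisp
membership (the limit convention). The objective J = Σ u^m d² is recorded
every sweep and asserted non-increasing. FCM runs in the full feature
space; PCA is used only for 2-D visualization coordinates (top-2 axes of
column-centered data, each axis signed so its largest-magnitude loading is
positive).

**Validity indices.** PC = (1/n)ΣΣu², CE = −(1/n)ΣΣu·ln u,
PI = Σ_i [Σ_k u_ik^m‖x_k−v_i‖²]/(n_i Σ_j‖v_j−v_i‖²) with n_i = Σ_k u_ik,
XBI = ΣΣu^m‖x_k−v_i‖²/(n·min_{i≠j}‖v_i−v_j‖²). Hard partitions give
PC = 1 and CE = 0; uniform partitions give PC = 1/c and CE = ln c; XBI is
reported as NaN when two centers coincide. Index tables over a c-range are
reported for inspection — PC/CE/PI/XBI all drift monotonically with c on
many data sets, so the package does not auto-select c; an optional
heuristic (`suggest_c`, the largest relative PI drop) is provided but
never applied implicitly.

**Fuzzy area.** The "fuzzy area" of a partition is quantified as the
entities whose largest membership falls below a threshold τ; τ = 0.6 is
the shipped default and is configurable, since no standard quantitative
definition exists. Mined itemsets are cross-matched by the fraction of
their genes in the fuzzy area.

## Synthetic corpus: what it emulates, and what it does not

The generator's defaults define the standard test conditions: 2,000
records, 3 planted communities of 15 genes, intra-block inclusion
p_in = 0.6, cross-block leakage p_out = 0.02, 8 countries with weights
0.30/0.15/0.12/0.10/0.09/0.09/0.08/0.07, years 2000–2019 uniform, two
countries per record with probability 0.1, one 3-gene itemset planted into
80 % of year transactions, seed 42.

Each record samples a home community uniformly; every home-block gene
enters with p_in and every other block gene with p_out (an empty draw is
replaced by one random home gene, so records are never gene-free). Each
of the record's countries force-includes its signature gene with a boost
probability (0.35 by default); the generator guarantees arg-max-effort
recovery of the signature for boosts ≥ 0.2, since the background inclusion
probability of any community gene is ≈ p_in/3 + 2p_out/3 ≈ 0.21. The
truncated-Poisson genes-per-abstract distribution (λ = 2, minimum 1)
governs only the no-communities mode; the two sampling mechanisms are
alternatives, not a composition. Itemset planting is stratified: exactly
round(f · n_years) year transactions receive the itemset, injected into
one random record of the year, so realized support equals the target up
to rounding. Planted itemsets use dedicated symbols outside the community
blocks — community genes saturate year/country transactions (a year's
union of ~100 records contains essentially every block gene), so only
dedicated symbols have interpretable planted support.

Affiliations are rendered as comma-delimited text from templates (country
names, aliases such as "USA" or "AB Canada", and city-only templates that
resolve through gazetteer hints) and re-parsed by the resolver — the
generator never passes countries as structured data. `expected_support`
is the analytic oracle for transaction support: inclusion–exclusion over
the itemset with records-per-transaction fixed at expectation and country
marginalized; Monte-Carlo tests cross-check it to ±0.1.

What the generator does *not* emulate: realistic gene-count marginals
(thousands of genes, heavy-tailed mention frequencies), noisy or
abbreviated affiliation strings beyond its templates, synonym ambiguity in
running text, non-uniform year volumes, or any actual gene–disease
biology. Passing recovery tests therefore demonstrates that the pipeline's
machinery is correct under its stated model, not that its output on a real
corpus is biologically valid.

## Problem sizes and numerical conventions

The shipped test and acceptance workloads use the 2,000-record default
corpus (≈ 45 community genes, 56-node pruned network, 20 year
transactions), small enough for the whole suite to run in well under a
minute while leaving every planted effect far above its recovery
threshold. Oracle-equivalence suites run at the scales where exhaustive
enumeration is exact: ≤ 12 items for the miner, ≤ 12 nodes for
centralities, ≤ 200-character texts for the matcher, ≤ 8 rows for the
from-scratch agglomeration check.

Percentages (support, network stage shares) are rounded half-even to two
decimals via decimal arithmetic; all random procedures (generation, FCM
initialization, Louvain) take explicit seeds, and the pipeline fans a
single run seed out to stages by fixed offsets. Degenerate inputs are
handled by convention rather than error where a limit exists: identical
FCM points give uniform memberships, rank-deficient PCA warns and zeros
the second axis, edgeless networks get singleton communities with
modularity 0.

## Known limitations

* The dictionary matcher has no acronym disambiguation or ML fallback;
  recall is bounded by the lexicon.
* Country resolution depends entirely on gazetteer coverage; institution
  names that imply a country absent from the gazetteer stay unresolved.
* `mine_frequent` is intentionally exponential; use `mine_closed` beyond
  toy databases.
* Effort and counts attribute multi-country papers fully to each country;
  no fractional or first-author weighting is offered.
* Optimal cluster count selection is left to inspection of the index
  tables, by design.
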