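# Methods

## The operon model

Prokaryotic genes that function together are frequently co-transcribed
in operons. `operonscan` approximates an operon, relative to one target
gene, as the maximal contiguous gene chain satisfying four rules:

* **window** — at most `max_genes_each_side` (default 15) genes are
  added on each side of the target; the limit is positional, so genes
  without a protein product occupy window slots;
* **gap** — the intergenic distance across every junction between
  consecutive chain members is at most `max_intergenic_bp` (default
  300 bp). The distance is `next.start − prev.end − 1` on 1-based
  inclusive coordinates: 0 for abutting genes, negative for overlaps.
  300 bp is deliberately permissive — unrelated neighbors picked up by
  a loose threshold wash out as noise in aggregate profiles, while a
  tight threshold silently truncates real operons;
* **overlap** — overlapping genes may overlap by at most
  `max_overlap_bp` (default 50 bp), far above the 1–4 bp typical of
  *E. coli* operons, again to err on the side of inclusion. An
  oversized overlap breaks the chain exactly like an oversized gap;
  skipping past it would yield a non-contiguous "operon";
* **strand** — by default a strand flip breaks the chain
  (`require_same_strand`, exposed as `--ignore-strand`). Known
  counter-examples exist (maturase genes encoded antisense just outside
  an operon), which is why it is a flag rather than a hard rule.

The gap rule is *chainwise*: it constrains consecutive junctions, not
each member's distance to the target. Extension stops at the first
failing gene on each side (distance rules are evaluated before the
strand rule when both fail) and the stop reason is recorded
(`gap_exceeded`, `overlap_exceeded`, `strand_change`, `gene_limit`,
`contig_end`). Under these rules the set of valid windows containing
the target is an interval lattice with a unique maximum, so the greedy
chain walk equals exhaustive window enumeration; the test suite and the
acceptance script verify this equivalence against an independent
brute-force oracle on randomized contigs that concentrate junction gaps
around the thresholds.

A size-1 operon is the "no neighbor" case and stays in every
denominator downstream.

## Functional categorization

Each gene receives exactly one category from a 14-name vocabulary via
prioritized case-insensitive regular expressions over its annotation
text (NCBI-style product strings and/or ortholog-database descriptions),
with per-accession overrides taking precedence over all rules — the
override path exists because some proteins (notably the CooJ nickel
chaperone) are not recoverable from text annotations and must be
supplied as curated accession lists. Priorities are
specific-before-generic: cooC/cooT/cooJ before generic regulators,
ferredoxin before the generic FeS category, hydrogenase-maturation
machinery before hydrogenase, ABC transporters before generic
transporters; ties break by rule-file order, making assignment a total,
deterministic function. Unmatched or unannotated genes fall through to
`other`.

The shipped rule set is data (`src/operonscan/data/default_rules.tsv`),
not code, and is a best-effort reconstruction of public product-name
conventions — users with different annotation pipelines are expected to
edit it. One non-obvious pattern choice: `(?<!de)hydrogenase`, because
"dehydrogenase" contains "hydrogenase" as a substring and the target
family's own product string would otherwise be mis-binned.

`regulation` is split into `transcription_regulation` and
`other_regulation`; `merge_regulation` collapses them (union semantics
at the target level) for coarse reporting.

An operon's category set contains the categories present among
non-target members, minus `other` and minus the target's own category.
Presence is per-target: three ferredoxins in one operon count once.

## Co-occurrence statistics

The counting unit is the genome assembly — the only linkage that is
always available — which underestimates organism-level co-occurrence
when an organism's genes are split across assemblies. For labels X, Y:

    P(X|Y) = N_XY / N_Y

with presence thresholded at ≥ 1 copy. Columns with N_Y = 0 are
*missing*, never 0 (the ratio is undefined, and emitting 0 would
fabricate certainty). Because both orientations derive from one
symmetric N_XY table, the integer identity
P(X|Y)·N_Y = N_XY = P(Y|X)·N_X is exact, and the matrix is asymmetric
whenever marginals differ — a small clade conditioned on shows high
co-occurrence with a large clade but not conversely. The cross-family
matrix is computed over the union of the two families' assembly
universes; only N_Y conditions each column.

Copy numbers feed a separate isoform-frequency distribution
(assemblies with exactly k copies per label) and the multi-isoform
fraction (assemblies with > 1 family member).

## Curation filters

Targets shorter than 400 aa are removed ("below" is strict: 400 is
kept), exact duplicate sequences collapse to their first occurrence,
and a target is analyzed only if its accession is found among the CDS
of its *stated* assembly — an accession found only in a different
assembly is flagged in a mismatch report, not silently relinked.
Identity clustering at sub-100 % thresholds is an upstream concern and
is not re-implemented. Accession version suffixes (`.1`) are stripped
at a single normalization point before any lookup, because public
tables mix versioned and unversioned forms.

## Profiles and reporting

A clade profile reports, per category, the fraction of the clade's
targets whose operon contains that category; the denominator is all
targets of the clade, including no-neighbor targets, so
`proportion ≤ 1 − no_neighbor_fraction` for every category. The
reporting cutoff is strictly greater than 10 % by default (a category
at exactly 0.100 is excluded); the uncut table is always written
alongside.

## The synthetic-data generator

The generator emulates a multi-assembly survey: per assembly it draws
independent per-label presence (defaults approximating the marginal
clade frequencies of a large CODH/HCP survey: A 0.13, B 0.14, C 0.18,
D 0.26, E 0.45, F 0.26; HCP I 0.35, II 0.30, III 0.25), a copy number
given presence (A/E/F: 1–3 copies with mean ≈ 1.4; B/C/D and HCP
essentially single-copy), and per target an operon whose category
content follows the clade-specific neighbor model (defaults mirror the
distinct clade regimes: maturase- and one-carbon-rich A/E/F with
one-carbon 0.93 and CooC 0.62 for clade A, ABC-transporter-dominated B
at 0.64, redox-partner-rich C, sparse D). Operon size given ≥ 1
neighbor follows a truncated geometric over 2–16 (small operons
dominate); slots not taken by emitted categories are filled with
`other` genes. Within-operon junction gaps are uniform on [−50, 300] bp,
flanking gaps uniform on (300, 3000] bp, gene lengths uniform on
300–3000 bp.

Each target's true operon is constructed to satisfy the chain rule at
every internal junction while the first flanking junction on each side
violates it — by an oversized gap or, with probability 0.3, by a strand
flip at small gap — so ground-truth membership, size, category set and
boundary reasons are exact by construction, and `call_all_operons` on
simulated data must reproduce them identically ("pipeline closure").
Neighbor products are drawn from the default rules' own language,
separating rule-engine gaps from parsing errors; an `annotation_noise`
fraction replaces products with "hypothetical protein" to exercise the
`other` path (ground truth records the post-noise category). Config and
seed fully determine every output byte.

What the generator does **not** emulate: sequence content, annotation
vocabulary drift between real databases, pseudogenes/accession-less
CDS, assembly fragmentation mid-operon, and non-independent clade
presence (phylogenetic autocorrelation). Passing closure and recovery
tests therefore demonstrates correctness of the *computation*, not
robustness to real-world annotation heterogeneity — the rule file is
the adjustable surface for the latter.

## Numerical and design choices

* Exact binomial (Clopper–Pearson) 95 % intervals are used for all
  statistical-recovery checks, via `scipy.stats.binomtest`.
* Identical coordinates tie-break gene ordering by accession, for
  determinism.
* Targets are keyed by (assembly, accession): identical proteins share
  one accession across assemblies.
* All randomness flows from a single seed; the run manifest's
  `generated_at` timestamp is the only field that differs between
  otherwise byte-identical runs.
* Problem sizes in the test suite and acceptance script (≈ 10²–10³
  assemblies, 10³ oracle contigs) were chosen so that binomial CIs are
  a few percentage points wide — large enough that parameter-recovery
  checks are meaningful, small enough to run in seconds.

## Known limitations

* Operon calling is purely distance/strand-based; no promoter,
  terminator or expression evidence is used.
* One category per gene: bifunctional products take the
  highest-priority match.
* Conditional probabilities are descriptive; no significance testing or
  phylogenetic correction is applied.
* GFF3 ingestion keeps only CDS features and assumes attribute text
  free of encoded commas in `product`.
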