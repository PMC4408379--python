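# Methods

## Curation model

The database builder consumes Swiss-Prot flat-file entries and keeps a
protein iff it is **reviewed** and carries at least one PTM annotation,
where an annotation is either

- a KW line keyword matching a keyword-level vocabulary term
  (case-insensitive exact match), or
- a feature with key in the configured set (default `MOD_RES`, `LIPID`,
  `CROSSLNK`) whose description normalizes to a non-empty term.

CC comment lines are parsed and retained verbatim but never mined for PTM
content: keyword and feature-table annotations are the curated,
controlled-vocabulary signal, while comments are free text.  `CARBOHYD`
and `DISULFID` features are excluded by default — glycosylation and
disulfide bonds surface through their keywords instead — but the FT key
set is a build parameter.

Each protein is tagged by annotation source (`KW-only`, `FT-only`,
`Both`), which yields the Venn partition statistic; per-FT-key composition
counts a protein once per key it carries, with percentages over the sum of
per-key counts (a composition of annotation classes, not a partition of
proteins — a protein with both `MOD_RES` and `LIPID` features contributes
to both numerators and twice to the denominator).  Reporting conventions:
percentages print with 2 decimals; Venn summaries round to the nearest
integer percent.

Organism keying uses the first OS name truncated at the first `(` (which
introduces common names), whitespace-normalized.  Swiss-Prot gives no
canonical species key in the DAT record itself, and this rule maps
"Homo sapiens (Human)" and "Homo sapiens" to the same partition.

## Vocabulary and DAG

The vocabulary is two label lists (KW level, FT level) plus FT→KW edges;
the DAG adds the literal root "PTM".  Exactly three levels; an FT term may
have several KW parents.  The XML exchange schema is flat:

```xml
<ptmdag root="PTM">
  <term id="d-valine" label="D-valine" level="FT">
    <parent ref="d-amino-acid"/>
  </term>
  ...
</ptmdag>
```

Flat `term` elements with `parent` references represent multi-parent nodes
without duplication; term ids are stable slugs of labels.  KW terms omit
parent elements (root is implicit).  Parsing validates the 3-level
structure, so dangling references, self-references and any cycle are
rejected.

Feature-description normalization strips the trailing period, truncates at
the first `;` (agent clauses such as `"; by PKA"` name the kinase, not the
modification), and removes the parenthesized qualifiers `(By similarity)`,
`(Probable)`, `(Potential)`; the presence of a qualifier classifies the
annotation as *putative*, otherwise *experimental*.  Internal parentheses
(e.g. `N6-(pyridoxal phosphate)lysine`) are part of the chemical name and
are preserved.  The operation is idempotent.  Cleaned descriptions that
match no FT-level vocabulary term are *not* dropped: they become ad-hoc FT
terms under a synthetic "Uncategorized" KW parent, so rare modifications
still count and surface in frequency tables.

The shipped default vocabulary (16 KW + 24 FT terms) covers the common
Swiss-Prot PTM keywords and frequent modified residues; its KW→FT edge set
is illustrative and real analyses should load a fuller vocabulary file
(TSV: `level`, `label`, `parent_labels` pipe-separated).
*Nucleotide-binding* is included although it is a binding property rather
than a covalent modification, for continuity with established PTM keyword
dictionaries; drop it from the vocabulary file if that reading is not
wanted.

## Enrichment statistics

The background population for organism *o* is the PTM-annotated proteins
of *o* in the database (size N).  This is deliberately **not** the whole
proteome: the database only stores PTM-annotated proteins, and P-values
must be read as "enriched relative to PTM-annotated proteins", which is
more conservative for ubiquitous terms than a whole-proteome background.

For each *testable* term (K ≥ 1 carriers in the background) the raw
P-value is the exact hypergeometric upper tail, computed by summing
log-binomial terms from a cached log-factorial table and exponentiating
around the largest term.  Structurally zero terms (x < n−(N−K)) are
excluded from the sum.  Properties enforced by tests: agreement with
exhaustive subset enumeration to 1e−12 for all N ≤ 12, agreement with
exact rational arithmetic to 1e−10 relative for N ≤ 60, monotone
non-increase in m, and agreement with `scipy.stats.hypergeom.sf` at
realistic N (scipy is a cross-check only; the log-space path is the
implementation).  Underflowing probabilities are floored at the smallest
positive double (5e−324) rather than reported as 0.

Multiplicity is corrected across T = number of testable terms — not the
full vocabulary, since terms absent from the background are vacuous tests
that would only inflate the correction; T is therefore organism-dependent
and is recorded in the export footer.  Bonferroni returns both adjusted
P-values (min(1, pT)) and the modified significance level α/T; the two
comparisons are decision-equivalent.  Benjamini–Hochberg uses the step-up
rule with cumulative-minimum monotonicity.  The default is α = 0.05 with
Bonferroni, the more conservative choice.

Enrichment output lists only terms the query actually hits (m ≥ 1; a
missed term has P = 1 by construction), ordered by ascending P then label;
the per-term statistics of *all* testable terms are retained on the result
object because two-list matching needs them.  Matching takes the **union**
of terms significant in either list — the union loses no information, and
the `significant_in` column recovers the intersection view.  Frequency
analysis lists every background term, including list misses, and performs
no testing.

## Synthetic data

The generator emits flat-file-writable records with per-term independent
Bernoulli annotation: each keyword-level term and each feature-level term
has a fixed per-protein probability; sampled FT terms become `MOD_RES` /
`LIPID` / `CROSSLNK` features (key chosen by the term's chemistry) whose
description carries `(By similarity)` with a configurable putative
fraction (default 0.3).  Accessions follow the UniProt grammar (letter +
five alphanumerics).  A seed fixes the entire stream; regeneration is
byte-identical.

The default study condition (`example_spec`) is 2000 proteins and 20 terms
— 8 keyword-level and 12 feature-level — with prevalences spanning 2–50%,
the range spanned by common PTM categories in curated proteomes
(phosphorylation keywords near the top, rare residue modifications at the
bottom).

Planted lists oversample a target term's carriers so the expected list
prevalence is min(1, f·p): the carrier quota is round(min(1, f·p)·n),
drawn without replacement, the rest uniform from non-carriers, the whole
list shuffled by seed.  The null case f = 1 is implemented as a genuinely
uniform draw from the background, since quota sampling would fix the
carrier count and distort calibration.

What the generator does **not** emulate: PTM co-occurrence structure
(phosphosites cluster on the same proteins in reality; here terms are
independent), sequence content (SQ blocks are omitted), organism-specific
annotation density, and keyword/feature redundancy beyond what the
vocabulary edges encode.  Calibration and recovery results on synthetic
data therefore validate the statistical machinery, not the biological
fidelity of any particular vocabulary.

## Numerical and design choices

- Log-factorial table grows geometrically and is shared across calls;
  each tail evaluation is a vectorized O(min(K,n) − m) sum.
- Ties in every ordering are broken by term label; exports of identical
  results are byte-identical (the database archive is likewise bit-stable,
  with fixed zip timestamps).
- P-values print in scientific notation with 4 significant digits.
- Fuzzy feature positions (`?`, `<1`, `>100`) parse with unknown markers
  and still count for term extraction — the curation counts terms, not
  coordinates.
- Flat-file input decodes per line as UTF-8 with a Latin-1 fallback
  (older releases mix encodings).
- The statistical property checks in the test suite use a 2000-protein
  background, 10,000 null draws and 100 planting replicates — large enough
  for 3-SE binomial bounds to be meaningful at the tested rates.

## Known limitations

- The published full-release curation statistics (hundreds of thousands of
  entries) require the corresponding Swiss-Prot download and are out of
  scope; consistency of the published counts under this package's rounding
  conventions is checked instead.  One published composition cell (the
  LIPID percentage) computes to 11.51 from its own published counts where
  11.53 was printed; this package reports the value computed from counts.
- One organism partition per protein: the first OS name defines the
  partition; further organism names are retained on the record but create
  no partitions and are not consulted by identifier resolution.
- No mid-P variant, two-sided Fisher test, or permutation null; the upper
  tail is the hypothesis of over-representation only.
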