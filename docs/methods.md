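# Methods

## Model of the task

`varlit` treats variant-mention extraction as a union of rule families rather
than a single recognizer. Each family is a deterministic pattern set over
Unicode text with 0-based half-open code-point offsets (the convention of
BRAT-style standoff annotation). The package's central structural claim —
that families with complementary coverage combine into higher recall with
little precision cost — is exercised end to end: recognizers, canonical key
normalization, span- and key-level merging, gene linking, and the two
evaluation regimes (span agreement with gold annotation; recovery of curated
triples).

## Recognizer families and their configuration

* `PROTEIN_POINT`: point substitutions in one-letter (`V600E`, `M23A`),
  three-letter (`Ala140Thr`) and `p.`-prefixed forms, with `X` accepted as
  the mutated residue (`p.Arg226X`).
  * `require_mutated_residue` (default on) suppresses residue-position tokens
    with no substitution target such as `A1796`; these tokens are a
    documented confusion source for point-mutation recognizers.
  * `allow_parenthesized` (default on) controls whether a mention immediately
    enclosed in parentheses is returned.
* `HGVS_STRICT`: a strict grammar over `c.`/`p.` forms — substitutions,
  deletions, insertions, duplications, deletion-insertions, underscore
  ranges, intron-offset coordinates (`423-6`), and underspecified `c.?`/`p.?`
  accepted with unresolved parts. Non-standard nomenclature (`del exon 3`,
  `codon 41: A←G`, `G:C to A:T transition`) is outside the grammar by design
  and is kept in the fixture catalog as a known gap.
* `DNA_EXTENDED`: DNA forms real documents contain but strict HGVS excludes:
  range substitutions (`c.1852_1853AA>GC`), hyphenated ranges
  (`c.597-598delGA`), bare-position deletions (`1705delAG`), and — only with
  `whitespace_tolerant` on — sloppy typography (`C1668 C > T`,
  `c.3927_3931del AAAGA`). Whitespace tolerance defaults off: the default
  ("faithful") configuration must reproduce the documented misses of
  formulaic recognizers, while `RecognizerConfig.extended()` turns it on. A
  separate `verbose_forms` toggle (off everywhere by default) recognizes
  "1799T to A"-style prose; it is an explicitly speculative extension.
* `RSID`: lowercase `rs` + digits at token boundaries, case-sensitive per
  dbSNP convention to avoid acronym collisions.

Within a family, overlapping candidate matches resolve to the longest match,
ties to the smaller start; output is sorted by (start, end) and deterministic.

## Normalization

Protein substitutions normalize to single-letter `wild + position + mutated`
keys via an explicit 20-residue three-to-one table; the stop/"any" residue is
written `X` (database style), accepting `Ter` and `*` on input. DNA
substitutions normalize to `c.<pos><wild>><mutated>` with bases uppercased
and restricted to ACGT. Range canonicalization removes internal whitespace
and replaces a hyphen joining an *increasing* pair of coordinates with an
underscore; a decreasing pair (`c.423-6del…`) is an intron offset and the
hyphen is preserved. This increasing/decreasing rule resolves the range/offset
ambiguity without transcript data and is idempotent. Codon indices convert to
the three candidate nucleotide positions {3k−2, 3k−1, 3k}; codon-derived
mentions carry candidate positions (and candidate keys) rather than one
asserted key, and extrinsic matching accepts any candidate. Exon/intron-only
mentions are dropped before key emission, and legacy IVS notation yields a
key-less UNKNOWN record, because no coding position is derivable from either.
Genome-level variants are never emitted. Sequence validation against
reference sequences is deliberately not performed. rsID expansion is a pure
table lookup injected by the caller (no network access); absent accessions
yield an empty result with a logged warning.

Variant typing assigns exactly one of SUBSTITUTION, DELETION, INSERTION,
DUPLICATION, DELETION_INSERTION, FRAMESHIFT, UNKNOWN by anchored full-string
grammar matching. Everything outside the grammar — including `c.?`/`p.?`,
non-standard frameshifts (`L280FfsX4`) and protein range substitutions
(`p.H776_C777>QS`) — types as UNKNOWN; the grammar does not guess.

## Ensemble combination

Span-level merging groups mentions into connected components of the pairwise
character-overlap graph, transitively closed (a chain A∩B, B∩C with A∩C empty
forms one component — the package's documented reading of "the same span of
text"). `longest`/`shortest` keep one representative *member* span per
component (never the hull); ties break by smaller start, then
lexicographically smaller extractor id, for determinism. `union` keeps all
distinct spans. Key-level combination is a plain per-document set union, so
combined coverage is monotonically at least any single recognizer's.

## Gene dictionary and linking

The dictionary filters (symbol, synonym) rows by: case-insensitive suffixes
"disease", "syndrome", "susceptibility" (phenotype names masquerading as gene
synonyms), a compact stopword list, and case-insensitive deduplication.
h-prefixed synonyms are added only for the configured symbols (default MSH2,
MSH6, PMS2 — the mismatch-repair genes commonly written hMSH2 etc.); MLH1 is
deliberately not prefixed by default. Tagging splits text and synonyms on
non-alphanumeric characters and matches token sequences case-insensitively,
in order, on consecutive tokens, keeping only the longest match at each
position; returned spans never overlap. Linking emits the full cross product
of a document's tagged genes and normalized keys; gene-free documents emit
gene-empty triples so gene-relaxed evaluation remains possible.

## Evaluation

Span matching is a *maximum* one-to-one bipartite matching (Hopcroft–Karp via
networkx, cross-checked in tests against a brute-force enumeration oracle)
under exact (identical spans) or partial (any character overlap)
compatibility. A maximum matching makes the TP count well-defined and
order-independent; greedy matching would not. Precision, recall and F1 follow
the standard formulas; F1 is computed from unrounded precision/recall and all
ratios are rounded half-up to 4 decimals for reporting only. The character
overlap column is the mean character-level Jaccard over matched pairs
(exactly 100.00 in exact mode); Jaccard is this package's choice where the
column is otherwise underdefined. Coverage evaluation matches reference rows
by PMID and by *either* the DNA or the protein key (curated rows carry both
levels), with the gene required unless relaxed; both strict and gene-relaxed
counts are always reported. The common-set filter keeps documents with at
least one extracted variant and one reference row. Overlap matrices report
|matched_i ∩ matched_j| / |matched_i| with a unit diagonal by convention.

## Synthetic corpus generator

The generator emulates the study conditions for this kind of pipeline:
documents mixing templated narrative sentences, tab-separated table blocks
(default fraction 0.3 — much curated variant content lives in tables), and
distractor tokens chosen to map onto documented confusions (`A1796`,
`exon 10`, `somatic mutation`, `APC+`, banned-suffix phrases). Planted
mentions are drawn from a weighted mix over the surface-form families
(defaults: strict substitutions 0.20, one-letter protein 0.20, three-letter
protein 0.10, strict deletions 0.10, hyphen ranges 0.10, and 0.05 each for
insertions, duplications, delins, whitespace-corrupted, rsIDs and verbose
known-gap forms) at a mean of 3 mentions per document. A matched synthetic
reference database curates each planted key with probability
`curation_rate` (default 0.9); each curated row is, with probability
`phantom_rate` (default 0.1), replaced by a phantom variant never planted in
the text — emulating variants curated from supplementary material the text
pipeline never sees — so a perfect extractor recovers 1 − phantom_rate of
the reference in expectation. Randomness is a single root seed with
per-document substreams keyed by (seed, document index), giving byte-identical
output for a fixed spec.

What the generator does **not** emulate: natural-language variety beyond
templates, PDF/Word layout artifacts, coreference, and the realistic surface-
form distribution of any particular journal. Passing the synthetic suite
shows the machinery is correct and the ensemble properties hold structurally;
it does not certify recall figures on real corpora.

## Problem sizes and numerical choices

The test suite and the acceptance script use 500-document synthetic corpora
for ensemble and parameter-recovery measurements (roughly 1,400–1,500 gold
mentions), 1,000 random instances of at most 8 spans per side for
matcher-oracle equivalence, and 3-standard-error binomial bands for the
stochastic phantom-rate recovery check — sizes chosen so every property is
measured with comfortable statistical margin while the whole suite runs in
seconds. Degenerate inputs are handled explicitly: zero-count score reports
are flagged, empty reference sets and empty dictionaries are errors, empty
text yields empty extraction.

## Known limitations

* The strict grammar accepts intron-offset coordinates syntactically but no
  transcript model is attached; offset positions are never resolved to
  genomic coordinates.
* The hyphen range/offset rule mis-reads a genuinely decreasing typo'd range
  as an offset; without sequence data this is irreducible.
* Verbose prose forms are out of coverage by default; enabling
  `verbose_forms` recognizes one narrow pattern only.
* Gene tagging is dictionary-bound: unseen synonyms and cross-species
  ambiguity are out of scope (human genes are comparatively unambiguous,
  which is why a dictionary is adequate here).
* The mentions TSV round-trips spans and families but not full parses;
  normalization from a TSV re-parses surfaces.
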