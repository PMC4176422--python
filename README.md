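# varlit

Rule-based mining of genetic-variant mentions from the biomedical literature:
complementary recognizer families, normalization to canonical HGVS-like keys,
ensemble merging, gene–variant linking, and both span-level and
curated-database evaluation.

## The problem

Curated variant databases (the shape of COSMIC or InSiGHT exports) record
triples *{article PMID, gene, variant}* that human curators extract from
papers, tables and supplementary files. Automatic variant-mention extractors
help, but no single formulaic recognizer covers the full range of surface
forms authors actually write: strict HGVS (`c.1668C>T`, `p.Lys618Ala`),
unprefixed point mutations (`V600E`, `M23A`), hyphenated ranges
(`c.597-598delGA`), range substitutions (`c.1852_1853AA>GC`), whitespace-
corrupted typography (`C1668 C > T`), dbSNP accessions (`rs123456`), and
verbose prose ("1799T to A", "del exon 3") that no pattern-based tool
recovers. Because coverage is complementary, merging several recognizers
raises recall substantially with little precision cost. `varlit` implements
this whole stack as a single testable package, with a seeded synthetic-corpus
generator so every stage can be exercised without downloading corpora or
databases.

## What it computes

* **Recognizer families** (`varlit.extractors`): `PROTEIN_POINT` (regex point
  mutations), `HGVS_STRICT` (a strict HGVS-style grammar, including
  intron-offset positions and underspecified `c.?`/`p.?`), `DNA_EXTENDED`
  (DNA forms beyond strict HGVS), `RSID` (dbSNP accessions). A
  `RecognizerConfig` toggles parenthesized context, whitespace tolerance and
  three-letter residues; the default configuration deliberately reproduces
  the documented coverage gaps of formulaic recognizers.
* **Normalization** (`varlit.normalize`): protein substitutions to
  single-letter *wild + position + mutated* keys (Ala140Thr → `A140T`, stop
  written `X`); DNA substitutions to `c.<pos><wild>><mut>`; hyphen ranges to
  underscore ranges with intron offsets preserved; codon indices to the three
  candidate nucleotide positions {3k−2, 3k−1, 3k}; exon/intron-only mentions
  removed; offline rsID→variant expansion.
* **Ensemble** (`varlit.ensemble`): span-level merge by overlap components
  (keep the longest or shortest member, or the union of distinct spans) and
  key-level set union.
* **Gene linking** (`varlit.genelink`): a filtered synonym dictionary
  (phenotype-suffix and stopword filtering, configurable h-prefix synonyms
  such as hMSH2), ConceptMapper-style longest-match tagging, and
  co-occurrence linking into curation triples.
* **Evaluation** (`varlit.evaluate`): maximum one-to-one span matching under
  exact or partial (any-overlap) compatibility; precision/recall/F1 and mean
  character Jaccard; triple coverage with strict and gene-relaxed matching;
  common-set filtering; per-tool overlap matrices; variant-type breakdowns
  (SUBSTITUTION … FRAMESHIFT, UNKNOWN).
* **Synthetic corpus** (`varlit.synth`): seeded documents with planted
  surface forms, table blocks, distractors, gold standoff offsets and a
  matched synthetic reference database with a controlled phantom rate — plus
  the frozen catalog of real-world fixture strings with their documented
  outcomes.

## Worked example

```python
from varlit import (RecognizerConfig, extract_all, normalize_mention,
                    build_gene_dictionary, tag_genes, link_by_cooccurrence,
                    evaluate_coverage, ReferenceRow)

text = ("Screening of MLH1 mutation carriers revealed the substitution "
        "Ala140Thr and a deletion c.597-598delGA in two families.")
mentions = [m for fam in extract_all(text, RecognizerConfig(), doc_id="pmid1").values()
            for m in fam]
print("mentions:", [(m.span.surface, m.family.value) for m in mentions])
keys = sorted({nv.key for m in mentions for nv in normalize_mention(m) if nv.key})
print("keys:", keys)

gdict = build_gene_dictionary([("MLH1", "MLH1"), ("MSH2", "MSH2")])
genes = {g.gene for g in tag_genes(text, gdict, doc_id="pmid1")}
triples = link_by_cooccurrence(genes, keys, "pmid1")
print("triples:", sorted((t.doc_id, t.gene, t.variant_key) for t in triples))

ref = [ReferenceRow(pmid="pmid1", gene="MLH1", dna_key="c.597_598delGA"),
       ReferenceRow(pmid="pmid1", gene="MLH1", protein_key="A140T"),
       ReferenceRow(pmid="pmid1", gene="MLH1", dna_key="IVS17(+5)G>C")]
print("coverage:", evaluate_coverage(triples, ref).to_dict())
```

This prints:

```
mentions: [('c.597-598delGA', 'DNA_EXTENDED'), ('c.597-598delGA', 'HGVS_STRICT'), ('Ala140Thr', 'PROTEIN_POINT')]
keys: ['A140T', 'c.597_598delGA']
triples: [('pmid1', 'MLH1', 'A140T'), ('pmid1', 'MLH1', 'c.597_598delGA')]
coverage: {'data_set': 'all', 'total': 3, 'matched': 2, 'recall': 0.6667, 'matched_no_gene': 2, 'recall_no_gene': 0.6667}
```

The hyphen range is found by two families, normalizes once to
`c.597_598delGA`, and both curated rows carried in recognizable nomenclature
are recovered; the legacy `IVS17(+5)G>C` row is not — no coding position can
be derived from IVS notation, so it counts against recall, which is exactly
the behaviour the coverage evaluation is designed to expose.

A CLI wraps the same pipeline (`varlit extract | merge | link | eval-span |
eval-coverage | simulate | fixtures`); run `varlit --help`.

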