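# Methods

## Task and model

`chemtag` locates chemical entity mentions in abstracts (title + body,
character offsets kept per section) and assigns each mention one of six
nomenclature classes: SYSTEMATIC (IUPAC-style names), TRIVIAL (common and
trade names), FAMILY (compound families), FORMULA (molecular formulas),
ABBREVIATION (short forms), IDENTIFIER (registry numbers).  MULTIPLE and
NO CLASS annotations are accepted on input but are never trained on,
predicted, or (by default) scored.

Three tagger families are combined in five run architectures:

1. CRF for SYSTEMATIC; gazetteers for TRIVIAL/FAMILY/ABBREVIATION; regexes
   for FORMULA/IDENTIFIER.
2. As run 1, but TRIVIAL moves to its own CRF.
3. One CRF per class (six models).
4. Per-class CRFs for all classes except IDENTIFIER (regex).
5. A single joint CRF labelling all six classes at once.

Per-class CRFs are trained on the full corpus with all other classes'
tokens relabelled O.  Dictionary terms and tagger regexes double as CRF
features, so a run's pattern resources also inform its sequence models.

### The chain CRF

Sequences are space-tokenized; trailing punctuation (`.,;:?!)]}'"`) is
stripped from a token's *core* before feature extraction (a closing bracket
that matches an opener inside the token is kept, protecting forms like
`(S)-ibuprofen`).  Labels follow the IOB scheme.  The model scores a label
sequence as

    s(y | x) = Σ_t w_emit(f(x,t), y_t) + Σ_t w_trans(y_{t-2}, y_{t-1}, y_t)

Emission weights are tied to the current label; second-order label
dependence lives entirely in the transition table over label triples (a
begin-of-sequence pseudo-label pads the history).  Decoding expands each
state to a (previous label, label) pair and runs first-order Viterbi over
the expanded space; the test-suite verifies this against brute-force
enumeration of all label sequences on small instances.  Transitions that
would break IOB validity carry -inf score in both training and decoding,
so decoded output is IOB-valid by construction.

Training maximises the L2-penalised conditional log-likelihood with
L-BFGS.  The objective is convex and optimisation starts at the origin, so
training is deterministic; the `random_seed` field exists for API
stability.  Defaults: penalty `c2 = 1.0` (applied as `c2/2 · ‖w‖²`),
`max_iterations = 200`, convergence tolerance `1e-4` interpreted as the
projected-gradient threshold (`gtol`) of L-BFGS-B, label order 2, feature
context window (offset conjunction) 1.  Unknown features at decode time
contribute zero.  Mention confidence is the minimum posterior marginal of
the mention's token labels, from the same forward-backward pass.

### Features

Per token core: word identity (lower-cased), length class (Short < 5,
Medium 5–15 inclusive, Large > 15), word-shape pattern and its
run-collapsed variant (`NaCl → AaAa`, `3-MCPD → 0-AAAA / 0-A`), prefixes
and suffixes of length 2–4, membership in the name-segment and stop-word
lists, per-class dictionary membership (multi-word terms mark every
covered token), and regex predicates: has-dash, all-caps, has-digit,
greek-letter (names and Unicode), strict roman numerals I–XX, formula
morphology (case-sensitive element-symbol sequences with counts, ≥ 2
symbols or a digit, optional charge/hydrate), identifier morphology
(registry prefix + separator + digits, CAS-like digit triples), and
systematic morphology (digit/dash plus a known name segment plus a
functional suffix).  With offset conjunction 1, each token also carries
its neighbours' features under `-1:`/`+1:` prefixes.

### Dictionary and regex taggers

The gazetteer tagger emits leftmost-longest, non-overlapping,
token-boundary-aligned matches on token cores.  TRIVIAL and FAMILY match
case-insensitively; ABBREVIATION matches case-sensitively, since short
forms are case-bearing ("DNA" is not "dna").  The regex taggers match
single token cores in full; a versioned stop list suppresses English words
and acronyms that happen to parse as element sequences ("In", "IN", "OF",
"HIV").  Spans end at the core, so sentence punctuation never enters a
mention.

### Post-processing and merging

Clean-up order is fixed: full-surface false-positive filters, then
action-word detagging, then bracket balancing.  Detagging strips one
trailing suffix from a configurable list ("-based", "-regulated",
"-induced", "-treated", "-dependent", "-mediated", "-containing",
"-derived") per pass; detagging can expose a bracket imbalance, which is
why balancing runs last.  Balancing compares per-pair bracket counts,
trims a single stray trailing closer or leading opener, and drops the
mention if it is still unbalanced.  Overlaps between taggers are resolved
greedily: longer span first, then tagger priority (default CRF >
dictionary > regex — the CRF carries contextual evidence), then leftmost.
The merged output is always sorted and non-overlapping (asserted on every
call), and merging is idempotent on its own output.

### Evaluation

CDI scores unique (document, surface) pairs, case-sensitively; CEM scores
exact (document, section, start, end) spans, class-blind.  Micro-averaged
precision/recall/F come from corpus-wide TP/FP/FN; macro mode averages
per-document scores.  Percentages are kept at full precision internally
and rounded half-up to two decimals only for reporting.  Ranked average
precision uses the per-document definition (each retrieved gold item
contributes its precision-at-rank, unretrieved gold contribute zero) with
documents pooled in proportion to their gold counts; pooled-ranking
variants would differ and this choice is a documented assumption.  The
ensemble union merge cleans each input prediction set individually, unions
the sets, and keeps the maximum confidence per item; surface-based
clean-up applies to CDI inputs (CEM prediction files carry no surfaces, so
for CEM only the union applies unless documents are supplied).

## Synthetic corpus

The generator emulates the corpus format exactly: one document per
abstracts line, gold annotations with per-section character offsets.
Entities are spliced into template sentences at recorded offsets, so every
gold mention satisfies the surface/offset invariant by construction.
Class closure is designed in: TRIVIAL/FAMILY/ABBREVIATION surfaces are
drawn verbatim from the packaged gazetteers (pairwise disjoint and
disjoint from the stop-word list), SYSTEMATIC names come from a locant /
multiplier / segment / suffix grammar that always fires the systematic
morphology feature, and FORMULA/IDENTIFIER draws always match their regex
sets and never collide with the regex stop list or (case-folded) the
stop-word list.

Defaults, chosen once as the study conditions: 2–4 body sentences per
document plus a one-sentence title (70% of titles carry an entity), an
85% chance that a body sentence carries entities, uniform class mixture,
and `inconsistency_rate = 0` (each gold annotation is independently
deleted with this probability to emulate incompletely annotated corpora).
80% of entity-bearing sentences use weakly informative contexts ("was
treated with X"); 20% are context-free so a sequence model must rely on
token-shape features rather than memorised templates.

Deliberate simplifications relative to real abstracts: tokens — including
sentence-final punctuation — are single-space separated, so entity spans
always align with space-token boundaries; vocabulary and syntax are
templated; class frequencies do not follow any real corpus.  Passing the
recovery test therefore shows that the pipeline learns and reproduces
separable structure end-to-end (featurization, training, decoding, span
reconstruction, merging, scoring), not that it reaches any particular
accuracy on real literature, where boundary mismatches, unseen vocabulary
and annotation inconsistency dominate the error budget.  The
intra-token-boundary path (annotations ending inside a hyphenated token
are expanded to token boundaries with a warning) is exercised by unit
tests rather than by the generator.

## Study sizes

The held-out recovery study trains run 5 on 300 generated documents
(~1 100 gold mentions) and tags 100 held-out documents from the same
distribution; exact-span CEM micro-F reaches 100% at these sizes (the
acceptance threshold is 90%).  Contract tests that only count model files
or check architecture wiring use 15–25 documents and a reduced iteration
cap, since fit quality is irrelevant there.

## Known limitations

* No fuzzy dictionary matching; gazetteer misses inflected or hyphenated
  variants unless post-processing detags them.
* The formula/identifier regex inventories are curated supersets of a few
  canonical pattern families, not a full grammar of chemical formulas;
  SMILES strings are matched only insofar as they look like element
  sequences.
* Per-class CRFs and the joint CRF share one feature extractor; no
  class-specific feature selection is done.
* The order-2 transition table is dense ((m+1)²·m parameters); this is
  fine for 13 labels but would not scale to large label sets.
* The shipped word lists are versioned artifacts sized for testing
  (hundreds of terms, not thousands); production use should drop in larger
  gazetteers via the resource-directory mechanism.
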