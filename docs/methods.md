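# Methods

## The rule model

A site rule binds together: a *trigger* (the accession of a protein-family
signature that an InterProScan scan must have assigned to the target), an
optional *taxonomic scope* (sets of included and excluded taxon names,
matched case-insensitively against the target organism's lineage, exclusion
taking precedence), and one or more *feature groups*. Each group names a
site-specific profile HMM (SRHMM), an e-value gate, and a list of feature
templates: 1-based inclusive positions on the curated template protein,
each with the set of amino acids the aligned target residue must belong to,
a feature key from the 16-type controlled vocabulary, a description and an
evidence tag. Keywords and comments attach at the rule level and are
propagated once per (protein, rule) pair when at least one feature fired —
the weakest gating that never attaches global annotation without local
evidence; it is deliberate that a residue mismatch suppresses them.

Conditions are evaluated strictly in order (trigger → scope → SRHMM gate →
residue identity), and a failure at any stage yields a typed rejection
record rather than silence. The stages are therefore independently
observable in tests and exportable for curation feedback.

### Range features

For range features (DISULFID, NP_BIND, ZN_FING, CHAIN, …) residue
conditions are checked at the two endpoints only; both endpoints must map
through profile match states, interior indels are tolerated, and the
annotation spans the mapped endpoints. If the endpoints map out of order
the feature is rejected as unmapped rather than emitted inverted.

### Rule flat-file dialect

Rules are stored in a line-oriented dialect of the UniRule flat format:
`ID`, `TR`, `TPL`, `KW`, `CC` header lines, a `Scope … end scope` block
with `include:`/`exclude:` lines, and `Case n … end case` blocks holding
`SRHMM`, an optional `Evalue` (default 1e-4 when absent) and `FT` lines
(`key from to condition "description" evidence`, with `.` for an empty
field and residue groups joined by `-` for range endpoints). Records end
with `//`. Unknown line types warn and are preserved verbatim so richer
rule files degrade gracefully. Serialization is canonical (sorted scope
taxa, groups in id order, alphabetized residue groups, `repr` floats), so
parse∘serialize is the identity and serialize∘parse∘serialize is a
fixpoint. Coordinates in files are 1-based inclusive (the UniProt feature
convention); all internal computation is 0-based half-open and converts at
the boundary.

## The profile HMM core

The SRHMM is a Plan7-style protein profile: per-node match and insert
emissions, the seven Plan7 transitions plus begin/end, and a 20-letter
background. The implementation is deliberately self-contained — simple
background-mixture pseudocounts, no sequence weighting, no entropy
weighting — because what matters here is that the alignment and scoring
semantics are exactly specified and oracle-testable, not bit-parity with
any external toolchain. The test suite nevertheless verifies that the
HMMER3-ASCII files we write are parsed with matching dimensions and
emissions by the standard toolchain's reader.

**Construction.** Alignment columns whose gap fraction is strictly below
0.5 become match states. Emissions are `(counts + w·background)/(n + w)`
with pseudocount weight `w = 1` by default; transitions are counted from
each row's observed state path with the same mixture scheme (uniform prior
within a transition group). Plan7 forbids I↔D transitions, so per-row paths
are doctored first: each adjacent D+I pair merges into a match state, as
the standard toolchain does. A transition group that was never observed
under zero pseudocount weight falls back deterministically to the
"continue" move (→M). Site blocks are cut from the source alignment as
windows of `flank` columns (default 10) around each annotated column,
merged where they overlap, with a column-provenance map retained so rule
positions can be traced back.

**Alignment.** Scoring is glocal: global across the profile — every node
must be traversed by a match or delete state — and local along the
sequence, with flanking residues free. A rule's SRHMM is a concatenated
conserved region; allowing a partial traversal would let targets match half
a site. The Viterbi recursion runs in log₂ space (probability zero is −∞,
never an underflowed float); ties prefer match over delete over insert and
the leftmost placement, so paths are deterministic. Ambiguity codes
(B, Z, X, U, O, J) score at background (log-odds 0) and never satisfy a
residue condition. Template-to-target position mapping goes through the
profile: the match node aligned to the template position is looked up in
the target's path; a template position on an insert state (curation drift)
or a target delete at that node yields "unmapped", never a guess.

**E-values.** Per profile, `n` i.i.d. background sequences (default 200,
length max(30, 2·M)) are scored and a Gumbel distribution is fitted to the
bit scores by maximum likelihood (scipy); the tail gives
`E = Z·exp(−λ(S−τ))`, clamped to [0, Z], with Z = 1 (per-sequence
e-value). The prediction gate defaults to 1e-4. Calibration parameters
persist in the profile file as a `STATS LOCAL VITERBI τ λ` line. The tail
approximation `exp(−λ(S−τ))` overstates the true Gumbel exceedance near τ
(at S = τ it reads 1.0 where the exact value is 1−e⁻¹); at the gate's
operating point, ten and more orders of magnitude below 1, the
approximation error is negligible next to calibration variance, and the
acceptance check confirms fitted-vs-empirical agreement within a factor of
two at the 95th percentile.

One deliberate openness: it is not specified here whether a production
UniRule engine gates on a full-sequence or best-domain score, nor its exact
alignment mode; this implementation fixes glocal Viterbi per feature group
and documents that choice rather than guessing another system's internals.

## Input handling

Targets arrive as InterProScan 5.x XML. Protein-centric files yield one
target per `protein` element; nucleotide-centric files yield one target per
ORF, carrying the source transcript id and ORF coordinates so annotations
can be traced back to contigs. Parsing ignores namespace prefixes and
attribute order. Sequences may be embedded in the XML or supplied as a side
FASTA (the FASTA wins, with a warning). Organism lineage comes per run
(`--organism`, a name or `;`-separated lineage, most general first) or per
sequence via a two-column TSV that wins on conflict; no taxonomy database
is bundled, and a bare name is treated as a single-element lineage. Scoped
rules skip targets with no lineage at all (configurable).

## Output formats

The same annotation list renders to a 9-column TSV (tab/newline escaped
descriptions), a tool-defined XML (schema in `src/pirsite/data/
predictions.xsd`) and GFF3 (feature keys mapped to Sequence Ontology-style
terms through a shipped table, unmapped keys falling back to
`sequence_feature`; attribute values percent-encoded; KW/CC as comment
lines). All three ship with read-back parsers and are
information-equivalent on the feature records; all coordinates everywhere
are 1-based inclusive.

## The synthetic-family generator

The generator emulates what curation starts from: a template with
experimentally known sites, and family members that diverged from it.
A member is the template with i.i.d. substitutions at non-site positions
(rate 0.05 by default, uniform over the 19 alternatives — no
exchangeability matrix, which is the simplest model that still stresses
position mapping), and indels started at rate 0.02 per position with
geometric(0.5) lengths capped at 3; deletions never remove a planted site.
A designated fraction of members ("negatives") instead carry a random
disallowed residue at the site, emulating the Glu-for-His near-misses that
motivate residue checking. Default family size is 8 members on a
120-residue template with one planted METAL histidine. The generator emits
the true alignment (so profile construction is testable separately from
alignment inference), the rule file, the calibrated SRHMM, InterProScan
XML with the planted family signature, reference annotations in member
coordinates, and a ground-truth table of exactly which (member, site) pairs
must be annotated or why not. Everything is a pure function of the spec
seed; the same spec is byte-identical. `perturb_lineages` reassigns a
seeded fraction of members to an out-of-scope lineage to exercise the
scope gate.

What the generator does **not** emulate: realistic evolutionary rate
variation, domain rearrangement, alignment-inference error (the true MSA is
used to build the SRHMM), InterProScan false triggers, and families where
the conserved flank around a site is itself variable. Passing the
planted-site checks therefore demonstrates the engine's correctness —
condition ordering, coordinate mapping through indels, residue gating — not
field accuracy on real proteomes, which depends on rule curation quality.

## Problem sizes and numerics

The shipped tests and the acceptance script use desk-scale sizes chosen to
exercise every code path: 20 family specs spanning indel rates 0–0.05 and
negative fractions 0–50% (8 members each), exhaustive Viterbi-vs-
enumeration checks on all profiles up to 4 nodes over a 3-letter alphabet
against all sequences up to length 6, 200-rule round trips, 200-sequence
calibrations checked against 1000 fresh scores. Emission and transition
rows must sum to 1 within 1e-9 in memory and 1e-4 after a file round trip
(5-decimal negative-log encoding); backgrounds are renormalized before
sampling to absorb that rounding.

## Known limitations

- Recall of the residue condition is bounded by the SRHMM alignment: a
  target whose site region diverges enough to misalign is rejected as
  unmapped rather than recovered.
- The e-value calibration is per-profile and simulation-based; very short
  profiles (a handful of nodes) give coarse tails, and profiles whose
  score distribution is degenerate (e.g. background-equal emissions)
  refuse to calibrate.
- The `.uru` dialect is self-contained and round-trip safe but is not a
  byte-level implementation of the full official UniRule grammar (protein
  names, gene names and catalytic-activity annotation are out of scope;
  site rules predict functional-site annotation only).
- Nucleotide-centric input relies on InterProScan's ORF calls; no ORF
  prediction is performed here.
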