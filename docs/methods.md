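# Methods

## Model

A base editor is modeled by five matching-relevant properties: deamination
chemistry (C>T for CBEs, A>G for ABEs, stated on the protospacer strand), a
PAM as an IUPAC pattern, the side of the protospacer the PAM occupies
(3′ for type II Cas, 5′ for type V/Cas12a), the gRNA/protospacer length
(20 nt default, 21 nt for the Sa constructs), and inclusive
distance-from-PAM activity windows. Construct families that share all five
properties (e.g. BE1…BE4-Gam) are a single registry entry; member names
resolve through aliases, and placements deduplicate accordingly. Editor
properties that do not affect matching — efficiency, protein size,
delivery — are deliberately not modeled.

### Distance convention

The protospacer base adjacent to the PAM is distance 1. For a 3′ PAM,
distance *d* maps to 5′-counted protospacer position `grna_length − d + 1`;
this makes the canonical 13–17 window of a 20-nt-spacer CBE coincide with
protospacer positions 4–8. For a 5′ PAM (Cas12a), distances count from the
PAM *into* the protospacer, so distance *d* is protospacer position *d*.
Some circularly-permuted constructs are reported to edit upstream of the
protospacer; this is carried as a free-text note, not as editable positions.

### Placement search

For an SNV embedded in a variant-bearing sequence, every editor, both
strands and every protospacer start are tested; a placement is emitted when
(i) the PAM matches on the protospacer strand, (ii) the SNV lies in the
major or a minor window, and (iii) protospacer and PAM fit inside the given
sequence (truncated flanks skip candidates, they are never padded). The
criteria are purely positional — an editor is never pre-filtered by the
SNV's substitution type, which is exactly what lets a CBE rescue an
ABE-looking transversion through a bystander. Results are ordered by
registry order, then + before −, then 5′→3′ start.

### Edit simulation

Editing is deterministic and all-or-nothing within the major window: every
source base converts simultaneously (the TC-context editor eA3A converts a
C only when the 5′-adjacent base on the protospacer strand is T; at the
sequence edge the context is unknown and treated as unsatisfied). Partial
edit outcomes are not enumerated: the scenario definitions presuppose
co-editing of window targets, and enumerating subsets would misrepresent
the efficient-window regime the classification is about. Source bases in
minor windows are *not* converted — editing there is an order of magnitude
weaker — but set a flag so users see that minor editing may occur. A
placement whose SNV is reachable only through a minor window is reported
with `minor_window_match=True` rather than dropped.

### Classification

The reference sequence is the input with the variant base swapped for the
reference base. Decision order: edited DNA == reference DNA → precise;
otherwise, if the full in-frame translation of the edited sequence equals
the reference translation, the scenario is sub-typed by the SNV base after
editing (reference base → multiple bases synonymous; a third base →
on-target synonymous; still the variant base → bystander synonymous);
anything else is no correction. Protein comparison spans the entire provided
sequence, so a window edit that changes a *neighboring* codon's amino acid
disqualifies the result — the main subtlety of window-based correction.
The whole input is treated as coding in the given frame with the standard
nuclear code; mitochondrial records are excluded upstream precisely because
their code differs. Outcomes that change nothing (no source base in the
major window) are dropped before reporting: under a literal reading of the
decision table a no-op on a silent variant would count as a "bystander
correction", which is not a correction.

### Codon-level recoverability bound

`recoverable_substitution_table()` enumerates, for each of the 61 sense
codons and each of its six single-base transversions, whether any single
chemistry applied to all of its source bases within some contiguous codon
interval restores the reference amino acid. The interval is not required to
contain the SNV: the bound describes what *some* window geometry could do,
and for the L>F class the rescuing edit (TTT→CTT) indeed lies two positions
away from the SNV. The enumeration yields exactly five recoverable
transversion-derived substitutions — I>M, L>F, R>G, R>W, R>\* — and none for
serine. PAM and window constraints can only shrink this set, which the test
suite asserts against cohort observations.

A geometric consequence worth spelling out: the L>F rescue needs codon
position 1 edited while positions 2 and 3 (the SNV) stay intact. A
contiguous major window containing the SNV would co-edit position 2
(TTT→CCC/CCT, Pro), so the only placements that report this rescue put the
SNV in a minor window with the bystander in the major window (e.g. the
ABE 7.10\* minus-strand geometry: distances 17/18/19 for codon positions
1/2/3). These matches carry the minor-window flag, and cohort statistics —
which count major-window corrections only, matching the efficient-editing
framing — tally them separately (`n_minor_only`).

## Cohort analysis

`apply_exclusion_filters` drops insertions/deletions/multi-nucleotide
variants, mitochondrial records, and rows whose sequence/position/frame are
unusable, counting each reason. `summarize` then classifies each record as
transition or transversion and counts: repairable transitions (≥1
major-window correction), transitions fixable only synonymously, repairable
transversions, and a (reference AA, variant AA) → (occurrences, repairable)
matrix over transversion records. Column names of the input table are
remappable via a small header-mapping config, since supplementary variant
tables in circulation differ in schema; reproduction of any published
cohort's absolute numbers therefore requires that table with usable
sequences and frames — the package itself builds and tests entirely from
synthetic cohorts.

## Synthetic data

The fixture generator plants one mutation class per record in a random
sense-codon CDS (default 120 nt, frame 0, 20 records):

* **precise**: a transition SNV as the only source base in the planted
  editor's major window (pool defaults: the BE3 family and ABE 7.10),
  with a concrete PAM instance at the right offset;
* **multiple_bases_synonymous**: the ACTCTA segment with an NGG at SNV
  distance 16, so the 13–17 window covers both cytosines and nothing else;
* **on_target_synonymous**: AGG→TGG (R>W) with a minus-strand NGG putting
  the variant T at ABE 7.10 distance 15;
* **bystander_synonymous**: TTA→TTT (L>F) in the ABE 7.10\* minus-strand
  geometry described above (inherently a minor-window match);
* **unrepairable**: GCC→GAC (A>D), a substitution outside the codon-level
  recoverable set — hence guaranteed uncorrectable regardless of what PAMs
  the random flanks happen to contain.

Ground truth is "the planted correction exists". Incidental additional
corrections from random flanks are allowed and do occur (e.g. a chance
narrow-window PAM can add a precise correction to a multiple-bases record);
uniqueness is not a goal and the tests tolerate extras while requiring the
planted class. The default class mix (35% precise, 15% + 15% + 10%
synonymous classes, 25% unrepairable) reflects that transitions dominate
pathogenic SNV collections and most feasible corrections are precise; it is
a test-bed composition, not an epidemiological model. The generator does
not emulate human genome context, mutation-rate structure, or intron/exon
boundaries — passing tests demonstrate the correctness of the search,
simulation and classification machinery, not population-level rates on
real data.

## Numerical and interface choices

* Coordinates are 0-based half-open internally, 1-based inclusive at every
  file/CLI surface.
* Input normalization: lowercase is upcased, U→T; ambiguity codes are
  rejected in target sequences (the method needs concrete alleles) and
  allowed in PAM patterns.
* Determinism: there is no unseeded randomness anywhere in the match,
  batch or cohort paths; repeated runs are byte-identical. Fixture
  generation is reproducible from its seed.
* Problem sizes in the test and acceptance runs (60-nt random records, 500
  placement-oracle fixtures, 200–300-record synthetic cohorts) were chosen
  as the smallest sizes that exercise every editor's geometry on both
  strands with comfortable statistical coverage.

## Known limitations

* Editing efficiency is not modeled; all major-window placements are
  treated as equally feasible, and results are not ranked.
* Off-target placement assessment is out of scope.
* One editor family row in the source repository assigns the NGA and
  NNNRRT PAMs to Sa(KKH)-ABE and VQR-ABE in an order that looks swapped
  relative to the construct names; the registry transcribes the rows as
  published rather than "fixing" them, so either assignment is reachable
  by name.
* Sequences are assumed fully coding in the provided frame; users must
  trim non-coding flanks. Only the standard nuclear genetic code is
  supported.
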