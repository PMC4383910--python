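# Methods

## The island signature and what is being computed

A tyrosine-integrase-mediated integration event at a tDNA splits the gene at
a crossover point inside it. The island's attP carries enough of the tDNA to
regenerate a functional gene on one side, leaving the displaced portion of
the original gene duplicated at the island's other end. On the finished
chromosome this reads, 5′→3′ in gene orientation: intact tDNA — island —
displaced tDNA fragment (for the common 3′-fragment case; 5′ fragments lie
upstream). The package's convention places the island interval so that it
*excludes* the intact gene and *includes* the displaced fragment: excising
the interval and re-joining the flanks leaves exactly one intact tDNA. The
interval is half-open, 0-based internally, 1-based inclusive on disk.

On circular replicons both arcs connect a gene to a hit, so the shorter arc
is taken; intervals crossing the origin are represented with start > end and
all interval arithmetic is topology-aware. This convention is only
unambiguous while an island spans less than half the replicon — for a
plasmid smaller than twice the island length the arc choice would flip. The
synthetic plans used for validation size circular replicons so that every
planted candidate, including the over-long length-filter decoy, stays below
the half-circle mark.

## Fragment search

Each tDNA (gene-oriented sequence) is aligned against its own replicon with
the gene's locus masked, which removes the trivial self-hit without
suppressing nearby fragments. Seeds are exact shared words of length 7 on
either strand; seed positions cluster into windows (merge gap ≤ query
length, margin query length + 8), and each window is scored by an exact
affine-gap local alignment (Gotoh) over the full query. Scoring is match +2,
mismatch −3, and a k-residue gap costs `gap_open + k·gap_extend` with
defaults 0 and 2.5, so every cell value is a multiple of 0.5 and float
comparisons in traceback are exact. Bases other than ACGT never match.

The word size and gap costs are fixed search parameters of the method; the
match/+2 mismatch/−3 pair is the standard megablast-style nucleotide scoring
this gap model is used with. Because no E-value machinery is attached, hit
significance is controlled by two floors, both config-exposed: minimum score
20 (about ten matched bases) and minimum aligned length 10 nt — att overlaps
of interest run from ~10 to ~250 bp. Redundant hits (subject overlap > 50 %
of the shorter) keep the higher score, ties to the leftmost; output order is
deterministic (subject coordinate).

`local_align_oracle` is an independent reference path for testing: an exact
local dynamic program (via Bio.Align.PairwiseAligner) under the same gap
model. The seeded search's best score equals the oracle on planted-copy
instances (500-instance suite) and never exceeds it; keeping the two routes
separate is what makes the check meaningful.

One window reports only its best local alignment. Two distinct fragments
closer than one query length would fall into one window and the weaker would
be lost; real tandem arrays space fragments by kilobases, so this is a
non-issue at intended scales.

## Filters

Seven predicates, each pure in (candidate, context); the accepted set is
therefore identical under any evaluation order, and the cascade order only
attributes rejections. In cascade order:

1. **integrase** — ≥1 bp overlap between the island interval and an
   *admitted* integrase ORF (the ORF interval, not the domain projection).
   Admission excludes Xer subfamilies (XerC/D/S/D-like) and integron
   integrases; an E-value at or below 1.2e−24 against the integron profile
   marks a call integron-like (smaller E-value = stronger match to the
   integron model, and the boundary value itself is excluded).
2. **cds** — the fragment hit *or the gene* overlapping a non-integrase
   Pfam-domain DNA projection rejects the candidate; integrase-domain
   overlaps are exempt because some integrases extend across attP. The gene
   is checked as well as the fragment because the rationale — real tDNAs and
   their split fragments do not overlap conserved coding regions — applies
   to both ends.
3. **tdna** — rejection requires the hit to fall *within* (be fully
   contained in) another full-length tDNA; mere overlap does not reject,
   since hits legitimately abut gene ends.
4. **length** — 2 000 ≤ length ≤ 200 000 bp, inclusive.
5. **internal** — the fragment must touch a gene end: query start exactly 0
   (5′), or query end within 3 nt of the gene end (3′). The 3 nt concession
   covers islands whose fragment carries a small deletion just upstream of
   the discriminator; such hits are flagged `damaged`. No analogous 5′
   slack exists.
6. **configuration** — 3′ fragments must lie downstream, 5′ fragments
   upstream, in gene orientation. Internal-sided candidates pass through
   this filter: their rejection belongs to the internal filter, which keeps
   every rejection attributable to exactly one filter without changing the
   accepted set (an internal candidate can never survive the conjunction).
7. **orientation** — fragment and gene on the same strand. Since candidate
   geometry gives opposite-orientation hits no other disadvantage, this
   late filter doubles as a false-positive meter for the whole candidate
   population.

## att subsite

The crossover is the fragment's proximal query boundary (query start for 3′
fragments, query end for 5′). Crossovers in the fractional window
[0.30, 0.60) of gene length are called A (anticodon arm); at or past 0.60, J
(T-loop and T/acceptor junction merged, as the two are hard to distinguish).
Crossovers before 0.30 would sit in the acceptor stem — biologically
unexpected — and are called J with a warning. The window is config-exposed
(`subsite_a_window`); the exact published boundary is not available, so
these are declared approximations chosen from tRNA architecture (the
anticodon loop sits mid-gene, the T loop in the 3′ third). tmRNA targets get
NA.

## Resolution and naming

Surviving candidates sharing a tDNA are ordered by fragment distance
(nearest first). They form a tandem array when all share side, direction and
strand and every inter-fragment segment both ends at its own fragment and
contains its own admitted integrase; members then get `(k of n)` indices and
the segments partition the span. Otherwise one winner is kept: highest
fragment score, then shortest island, then leftmost — strongest att evidence
first, deterministic thereafter.

Names are `<Nickname><serial>_<kbp><letter>`: first letter of the genus
(skipping a leading *Candidatus*), first two letters of the species, a
strain serial, island length in kbp rounded half away from zero (49 591 →
50), and the one-letter amino-acid code of the target isotype. tmRNA targets
use `Z`, which collides with no isotype letter here and is
config-overridable. Serials index strains within a run (input order) since
no global strain registry exists; name collisions (e.g. equal-length tandem
members) get `.2`, `.3` suffixes so GFF3 IDs stay unique.

## Synthetic genomes

The generator is the package's primary validation surface: it emulates the
island signature with exact, machine-checkable truth.

* **Templates.** Planted tDNAs use fixed synthetic 76-nt sequences, one per
  plant, chosen so that any two templates — and each template and its own
  reverse complement — share no 7-mer. Planted genes therefore cannot
  cross-seed each other.
* **Plants.** A canonical island block is: intact gene; island body
  (random padding, a stop-free 200-codon ORF emitted as a PF00589-labelled
  integrase call with its domain projection); and the template's portion
  from the crossover to the gene end at the island's distal edge (shortened
  by 3 nt for damaged plants; placed upstream as a 5′ prefix for
  five-prime plants; reverse-complemented for the orientation decoy).
  Tandem arrays chain member blocks, each with its own ORF and fragment.
  Minus-strand plants are built forward and mirrored. Each of the nine
  decoy classes perturbs exactly one property, mapping one-to-one onto a
  filter (the excluded-integrase decoy labels its only integrase Xer or
  integron and so fails the integrase filter through the admission path).
* **Fragment pinning.** Every planted fragment is flanked by a 12-base run
  of N. N matches nothing under the search scoring, so no alignment can
  creep across a fragment boundary (any path through the run is strictly
  score-decreasing) and no seed word can straddle one. Planted hits are
  therefore recovered at exactly their designed coordinates — which is what
  makes exact-endpoint truth tables possible under a cheap-gap scoring
  scheme whose local alignments otherwise wander a few bases at the
  boundary.
* **Background cleaning.** Background is i.i.d. ACGT at configurable GC.
  After assembly, any background word matching a planted gene's 7-mer
  vocabulary (either strand) is mutated away by a deterministic kernel that
  prefers replacements creating no new collisions; planted bases are
  immutable. Every remaining seed in the replicon thus points at a planted
  feature.
* **Verification.** As a final invariant check, the generator re-runs the
  fragment search and requires that every designed fragment is recovered at
  exactly its planted interval and every other hit is fully contained in an
  annotated tDNA (host-gene cross-hits, which the tDNA filter removes). A
  rare chance alignment elsewhere triggers regeneration from the next RNG
  substream; feature coordinates depend only on the plan, so truth intervals
  never move. Generation is deterministic per seed.

What the generator does *not* emulate: codon usage, composition bias,
phage-like gene content, realistic tRNA secondary structure, sequencing
error, or fuzzy att boundaries in real genomes (real BLAST hits at att sites
can extend or fall short by a few bases, so real crossover positions — and
hence A/J calls near the window boundary — carry uncertainty the synthetic
suite deliberately removes). Passing the suite shows the algorithm's logic
and coordinate handling are exact, not that real-genome annotation inputs
(tRNA callers, HMM scans) are error-free; those tools are consumed as file
adapters, not run.

## Validation conditions and problem sizes

The standard property suite plants, per seed: three canonical islands
(4–5 kb; one damaged, one with a 5′ upstream fragment), a depth-3 tandem
array (3 kb members), and one decoy per class (4 kb, except 1.5 kb short
and 201 kb long decoys) — on one strand and topology per seed, alternating
across 50 seeds, with circular replicons padded to 520 kb and rotated. The
length-bounds run plants six otherwise-canonical islands of 1.5, 2, 50, 200,
201 and 611 kb on a ~1.08 Mb replicon (the 611 kb plant mirrors a known
over-long symbiosis island lost to the length filter). The oracle
equivalence suite uses 500 random instances, queries 40–120 nt against
subjects up to ~2.3 kb.

## Numerical and degenerate-input choices

* All alignment scores are multiples of 0.5 (match 2, mismatch 3, gap 2.5);
  traceback compares floats exactly, with a fixed preference order
  (diagonal, then subject-gap, then query-gap) and first-maximum tie-break
  for the best cell, so output is deterministic.
* Translation uses the prokaryotic table's stops (TAA/TAG/TGA); codons
  containing N count as sense codons, conservative toward keeping ORFs
  intact. ORFs are stop-to-stop maximal runs, minimum 50 aa by default
  (integrase domains run ~170 aa); sequence ends bound runs on linear
  replicons, circular frames continue across the origin with full-circle
  stop-free runs capped just below one turn.
* Queries shorter than the word size, empty candidate lists, zero islands,
  and empty feature files all produce valid empty outputs rather than
  errors; malformed inputs (duplicate FASTA ids, unknown replicon
  references, out-of-bounds or isotype-less features, negative E-values)
  fail fast before any output is written.
* tRNA genes outside 60–120 nt warn but are not rejected.

## File dialects

These dialects are this package's own (the on-disk formats of the original
pipeline's intermediates were never published):

* **FASTA** headers may carry `topology=`, `genus=`, `species=`, `strain=`
  tags after the record id.
* **Features** (GFF3, 1-based inclusive): types `tRNA`/`tmRNA` (attributes
  `isotype`, required, one-letter code or `tmRNA`; `anticodon` optional),
  `integrase_CDS` (attributes `subfamily` ∈ {generic, XerC, XerD, XerS,
  XerD-like}, `integron_evalue`, `domain_start`/`domain_end`), and
  `protein_match` (attributes `accession`, `is_integrase`). A feature
  wrapping a circular origin is two lines sharing one ID; reading merges
  them, so feature I/O round-trips exactly. An equivalent TSV table
  (`replicon_id, feature_type, id, start, end, strand, attributes`) is
  accepted.
* **Islands** are written as `genomic_island` GFF3 lines carrying name,
  target, isotype, subsite, side, damage, tandem index, integrase count,
  length and fragment score/identities, plus a per-island FASTA and a
  summary TSV mirroring the database's statistics table.

## Known limitations

* The arc-choice ambiguity for islands larger than half a circular replicon
  (above).
* Significance floors replace BLAST E-values; on very large or repetitive
  real replicons the fixed score floor of 20 will pass more chance hits
  than an E-value cutoff would (the filter cascade absorbs most of them —
  by design, the orientation filter measures exactly this background).
* Serial numbers in names are run-local, not registry-stable.
* Two-piece tmRNAs and islands using host Xer recombinases at dif sites are
  out of scope: the former are an annotation-input concern, the latter are
  explicitly excluded by the integrase admission rules.
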