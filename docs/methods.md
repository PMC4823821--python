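# Methods

This note documents the models and procedures implemented in rbpkit, the
choices made where the design was open, and what the synthetic fixtures
do and do not demonstrate.

## Motif records and distinctness

A record ties one binding motif (IUPAC string, 4–12 nt, RNA alphabet) to
an RNA-binding protein (RBP), the experiment that identified the motif
(SELEX, RNAcompete, EMSA, X-ray, NMR, …), the organism, and provenance
(gene id, PubMed id, protein domain). Source literature is inconsistent
in gene nomenclature — the same human protein is CUGBP1 in one resource
and CELF1 in another — so ingestion renames records to official gene
names through a user-supplied per-organism synonym table (a live
nomenclature lookup would make the toolkit untestable offline). The
motif alphabet is unified to RNA at ingestion: uppercase, T→U.

A motif is a *distinct entry* when it binds a different RBP, or was
identified with a different experimental approach, or in a different
organism. Deduplication therefore keys on the quadruple
(motif, gene_name, experiment, organism) — gene id is deliberately not
part of the key — keeping the first occurrence and preserving input
order. Queries combine criteria conjunctively (AND), matching the
search-form idiom the record schema comes from; synonym queries match
the synonym list, and experiment strings are not canonicalised (no
authority exists for equating, say, "SELEX" and "in vitro selection").

## Position probability matrices and the quality score

A PPM holds P(nucleotide | position) over {A, C, G, U}, one row per
motif position. Two constructions:

* **From winner sequences** — the aligned, equal-length outputs of a
  selection experiment. Entries are raw empirical frequencies with *no
  pseudocounts*: the score below must be a pure product of observed
  frequencies, and an unobserved letter has probability exactly 0.
  Ragged winner sets must be aligned upstream; ambiguity codes are
  rejected in winners.
* **From an IUPAC consensus**, used when winners are not annotated:
  position i spreads probability uniformly over the letter's member set
  (R → A/G at 0.5 each, N → 0.25 each).

The quality score of motif m of length l under matrix M is

    S = ∏_{i=1..l} P(m_i | M),

the probability of observing the motif under the matrix, in [0, 1]. A
matrix built from a single winner sequence scores that motif exactly
1.0 — the single-sequence-experiment rule (EMSA, UV cross-linking).
When the stored motif itself contains ambiguity codes, P(m_i | M) is
taken as the *sum* of column probabilities over the letter's members.
This rule is a package choice (no published definition exists for the
case); it is the unique linear extension under which an IUPAC-derived
matrix scores its own consensus as 1.0, keeping the single-experiment
rule consistent. Summed over all 4^l concrete motifs, S forms a
probability distribution — a normalisation invariant the tests check to
1e-9 up to l = 8.

## Exact scanning with a BWT/FM-index

Scanning is perfect-match only: a hit requires the motif to equal the
k-mer at the reported position. The index is a classical FM-index built
in-package: the multi-FASTA entries are concatenated with sentinel
separators (so matches cannot span entries), the suffix array is built
by prefix doubling (O(n log² n), vectorised), and queries use backward
search over the BWT with per-character cumulative occurrence tables.
Locate resolves suffix-array rows through a text-position-sampled
suffix array (every 8th position) by LF-stepping — at most 7 extra
steps per hit. Construction is deterministic; inverting the BWT must
reproduce the input text exactly, and a fuzz suite holds locate equal
to a naive sliding-window oracle on a thousand seeded cases.

Conventions: offsets are 1-based (first nucleotide = position 1);
overlapping occurrences are all reported, because the enrichment
statistic normalises by the number of possible start positions, which
counts overlapping placements; N in an input sequence matches nothing,
and a query pattern containing N returns no hits (exact matching is
defined on concrete letters only). Ambiguous motifs are expanded to
their concrete strings (cap 4096 expansions) before querying, keeping
the index a pure exact-match structure. Input is capped at 20,000 nt
per file (total over entries, configurable); motifs outside 4–12 nt are
skipped with a warning. Reverse-strand scanning is deliberately absent:
the targets are single-stranded RNA.

## Genomic-functional-context enrichment

Short motifs occur by chance in almost any sequence, so each hit is
scored against three background populations from the organism of
interest — the genomic functional contexts (GFCs): all exons ±250 nt of
flank, all introns, all coding sequences. For a motif of length l_m
found t times in an entry of length l_s:

    Obs = t / (l_s − l_m + 1)
    Exp = c_m / Σ_i max(0, len(s_i) − l_m + 1)
    OR  = log₂(Obs / Exp)

with c_m the motif's overlapping occurrence count across the background
sequences (counted through the same FM-index as the scanner, so overlap
conventions agree; ambiguous motifs sum their expansions). l_s is the
length of the multi-FASTA entry containing the hit, not the file total.
OR > 0 means the motif is denser in the input than in the context.

Degenerate cases are explicit, not smoothed: a motif absent from a
background (Exp = 0) gets the sentinel `"undefined"` — the formula is
undefined there and any pseudocount would change every other score —
and a context with no background table for the hit's organism gets
`"unavailable"`. Backgrounds are user-supplied FASTA per context and
organism; deriving them from genome annotation is content, not method,
and is out of scope. Scoring a FASTA against itself as all three
contexts yields OR = 0 identically (numerator and denominator coincide)
— a self-consistency identity the tests enforce.

## Binding sites from protein–RNA complexes

Solved complexes encode binding preferences geometrically. The pipeline:

1. **Parse** (PDB format, via gemmi for coordinates and resolution;
   EXPDTA and the HEADER id code read directly). NMR ensembles reduce
   to the first MODEL. Chains classify deterministically from residue
   names: standard amino acids → protein, A/C/G/U → rna. Modified
   nucleotides fall outside the RNA residue set — they cannot appear in
   a concrete motif — and therefore break contiguity.
2. **Eligibility**: NMR and EM structures qualify outright; X-ray
   requires a recorded resolution strictly better than 3.9 Å. An X-ray
   entry without a resolution record, or an unrecognised method, is
   ineligible with a warning.
3. **Contacts**: a nucleotide is contacted when any of its N/O atoms
   lies within 3.0 Å of a protein N/O atom (hydrogen bond) or any atom
   pair lies within 3.9 Å (van der Waals). Cutoffs are inclusive —
   "cut-off 3.0 Å" is read as the boundary of acceptance — and the
   hydrogen-bond test is purely distance-based: donor/acceptor angular
   criteria used by full H-bond assignment programs are not reproduced,
   a documented simplification. Detection is vectorised all-pairs
   (structures of interest are small); a brute-force oracle must agree
   exactly on every fixture.
4. **Sites**: maximal runs of consecutive residue numbers in one RNA
   chain where every nucleotide has ≥1 contact of either kind; runs of
   ≥4 qualify, read 5′→3′ by residue number. Insertion codes and TER
   chain breaks interrupt runs (contiguity = consecutive numbering
   within one subchain). vdW-only contacts suffice — the criterion is
   interaction with *any* atom of the protein.
5. **Validation**: extracted motifs align ungapped against reference
   motifs for the same RBP — the shorter slides along the longer with
   full overlap, a position mismatches when the two letters' IUPAC
   member sets are disjoint, and pairs are classified by their minimum
   mismatch count (0 / 1 / 2 / >2), smallest offset winning ties.

## Synthetic fixtures

All inputs are generated, seeded and byte-deterministic:

* `gen_planted_fasta` — i.i.d. background with motifs inserted at
  recorded offsets (non-overlapping placements); the truth table lists
  planted copies, and tests reconcile against a naive search because
  chance occurrences in random background are possible and legitimate.
* `gen_background_pair` — a scan/context FASTA pair with an *exact*
  planted density ratio ρ: equal position counts, single-letter filler
  chosen so no chance occurrence can arise (verified by naive count),
  so OR = log₂ ρ holds in closed form from the truth counts. Defaults:
  motif UGCAUG (the RBFOX recognition element — a realistic 6-mer),
  ρ = 10, 400 start positions per side.
* `gen_toy_structure` — a glycine chain facing an RNA strand, one
  glycine per nucleotide at 10 Å spacing so contacts stay pairwise; the
  nucleotide's O2′ sits at the requested distance from the glycine N
  (polar probe) and its C1′ from the CA (carbon probe). Planted
  distances are single-axis, so boundary distances like 3.0/3.9 Å are
  exact in floating point. Truth (contact kinds, qualifying runs) is
  computed analytically from the requested distances.

What passing these fixtures shows: the rules — formulas, cutoffs,
thresholds, dedup and alignment semantics — are implemented exactly.
What it does not show: behaviour on real data. The generators have no
genome annotation, no base-composition structure, no real molecular
geometry (no bond networks, no angular H-bond criteria), and no
nomenclature noise beyond the synonym table supplied.

## Numerical choices and limitations

* PPM columns must sum to 1 within 1e-9; no pseudocounts anywhere.
* Quality scores clamp at 1.0 against summed-column float drift.
* Contact comparisons are plain IEEE-754 `<=` on Euclidean distance.
* Scan problem sizes: the fuzz equivalence suite uses sequences up to
  2 kb and 1000 (sequence, pattern) cases; the index itself is exercised
  up to the 20,000-nt cap.
* Out of scope by design: PWM-threshold or mismatch-tolerant scanning,
  reverse-strand scanning, enrichment p-values, mmCIF input, de novo
  motif discovery, and populating a motif database from external
  resources.
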