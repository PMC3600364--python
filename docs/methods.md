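# Methods

## Problem setting

Two transcript collections from closely related taxa are compared for
insertion/deletion length variation by electronic PCR: primer pairs
designed on collection A are virtually amplified on collection B, and
product-size differences are interpreted as InDels. In allotetraploids the
same pair can amplify orthologs (between species) and homoeologs (A/D
subgenome copies within a species), so one locus may legitimately show
several distinct deltas.

## Cleaning cascade

Stages run in a fixed order — quality trim, vector mask + excision,
terminal polyA/polyT removal, length filter — because each stage's
artifacts would otherwise corrupt the next (vector hits can hide inside
low-quality tails; polyA can be part of a vector junction).

* **Quality trimming** is the Mott construction: base *i* scores
  `c − 10^(−q_i/10)` with cutoff `c = 0.01` (Phred Q20) and the retained
  window maximizes the score sum. Ties break leftmost start, then longest;
  a window is kept only if its score is strictly positive. Records without
  quality strings skip this stage rather than failing, since public EST
  sets frequently lack QUAL files.
* **Vector masking** emulates cross_match-style screening with the two
  published knobs (`minmatch 20`, `minscore 20`): an exact shared word of
  ≥ minmatch seeds a local alignment (+1 match, −2 mismatch, −3 gap open,
  −1 gap extend, via Biopython's `PairwiseAligner`) and any hit scoring
  ≥ minscore is masked with `X` on either vector strand. The exact scoring
  scheme of the original screener is not published; the contract here is
  that any hit passing both thresholds on clean constructions is masked.
  Local alignment may extend a hit through a base or two of coincidentally
  matching flank — tests allow for that. Masked spans are then *excised*
  and the longest clean fragment kept, because downstream primer design
  cannot use `X` bases.
* **polyA/polyT** removal takes a terminal run of ≥ 8 identical letters
  ending within 50 bp of the terminus (run + distal junk removed,
  iterated to a fixed point). The windowed rule mirrors common
  EST-trimmer behaviour; the underlying protocol names only the step, not
  its parameters.
* **Length filter**: records shorter than 100 bp are rejected; exactly
  100 bp is kept (the protocol states "less than 100 bp were excluded").
  The cascade is idempotent: cleaning a cleaned record changes nothing.

## Segmentation and primer design

Transcripts are cut into ~300 bp segments whose union covers the whole
sequence; adjacent segments overlap by ≥ 60 bp (config knob — the
protocol does not state the overlap) and random mode jitters segment
lengths ±20% deterministically per seed. Within each segment all primer
placements are enumerated: hard bounds length 18–20 (opt 20), GC
0.45–0.65 (opt 0.50), Tm 57–62 °C (opt 58 °C), product 100–250 bp,
non-overlapping primer sites. Tm is nearest-neighbor with the SantaLucia
(1998) unified parameter table, 50 mM monovalent salt (entropy correction
`0.368·(N−1)·ln[Na+]`), 50 nM primer and no complement strand — the same
vectorized code path serves scalar calls and whole-segment screening, with
values rounded to 10⁻⁴ °C so both agree bit-for-bit; the test suite
cross-checks it against an independently hand-coded table and against
Biopython's implementation to within 0.5 °C. Since a window and its
reverse complement form the same duplex, one screening pass supplies both
forward and reverse candidates.

Pairs are ranked by the summed penalty
`|len−20| + 10·|GC−0.50| + |Tm−58|` (unit weights; only the ordering
matters and weights are configurable) with deterministic tie-break
(penalty, fwd_start, rev_end, fwd_len, rev_len), and up to `n_best = 2`
pairs with distinct amplicon intervals are kept per segment — a
"nested/staggered pairs" reading that favors coverage without a
combinatorial placement model. Regions no amplicon covers are reported as
gaps, never silently dropped.

## Virtual PCR

Primer sites are substitution-only (Hamming) matches on either strand —
gapped site matching would conflate primer-site InDels with the
amplicon-size InDels being measured. Defaults: ≤ 2 mismatches per primer
("fewer than 3 mismatching bases"; a per-pair total budget is also
available), one exactly matching 3′ base (polymerase extension needs a
paired terminus; kept minimal), `N` always mismatches. Amplicons are
0-based half-open on the target plus strand from the forward site start to
the reverse site end, in both template orientations, with
`len(fwd)+len(rev) ≤ size ≤ expected+500` (the cap comfortably exceeds
the largest simulated InDel and is configurable). The scanner is an
early-abandoning numba kernel; tests hold it equal to a brute-force
every-offset scan. Scans are cached per unique primer and run against a
single N-spacer-concatenated target index, discarding boundary-crossing
windows.

## Calling, collapse, markers

Each amplicon with `observed ≠ expected` yields a call with signed
`delta = observed − expected` (positive = net insertion in the target).
Calls collapse into loci per query (or per query cluster when an
assembly-derived mapping is supplied): overlap-connected components of
amplicon intervals. A locus keeps the delta set across targets, the
support count, and — for evaluation — the tightest contributing interval
per delta. Binning uses max |delta| per locus into 1 / 2–4 / 5–10 / >10 bp
classes; markers are exactly the loci with max |delta| ≥ 5 bp (inclusive).

Band-pattern classification works on per-species pooled product-size sets
(bands within `size_tolerance` merge; 0 for in silico sizes): all empty →
failure; equal sets → monomorphic (type 3); one band per species,
different → orthologous polymorphism (type 1); otherwise (some species
with ≥2 bands) → homoeologous polymorphism (type 2). When only one
species amplifies — a case the verbal typology does not cover — the call
follows that species' band count.

## Simulator

`simulate_tetraploid_pair` draws per gene an i.i.d. ACGT ancestor of
400–900 bp (EST scale), keeps it as the species-A A-subgenome copy,
derives the D-subgenome homoeolog by 3% i.i.d. substitutions, and derives
species-B orthologs of both copies by 1% substitutions plus Poisson(1)
planted InDels per transcript. InDel sizes follow the four size classes
with mass 0.49 / 0.347 / 0.085 / 0.078 (within-class uniform; the >10 bp
class truncated-geometric, max 168 bp). InDels avoid the outer 30 bp and
never overlap each other, so every event's query position and size are
exact. Raw query variants add polyA tails (p=0.5, 10–30 nt), a 5′
fragment of a synthetic vector (p=0.2, 30–80 nt), and Phred strings
(body ≈ Q50 ± 4 with a linear 3′ decay to ≈ Q8 over 60 nt).

The substitution model is uniform (Jukes–Cantor-like): adequate for
exercising mismatch budgets, with no transition bias, rate heterogeneity,
codon structure or splice isoforms. Homoeologs are colinear by
construction (substitutions only), so homoeologous deltas all stem from
planted InDels — real paralog structure is messier. Passing tests
therefore demonstrate the engine's arithmetic and search are exact under
substitution-type divergence at realistic rates; they do not certify
behaviour on assembly chimeras, splice variation or sequencing error
beyond quality decay.

## Truth-side evaluation

`detectable_events` marks a planted InDel recoverable iff some designed
pair on its query copy contains it strictly between primer sites, both
sites are InDel-free on the target with ≤ 2 substitutions each and an
intact 3′ anchor, and the net size change inside the amplicon is nonzero.
This is computed from coordinates and direct string comparison only — the
PCR engine is never invoked, keeping the oracle independent.

A locus delta is *explained* when, for some target copy of the gene, it
equals the net signed size of a contiguous run of that copy's planted
events inside the delta's amplicon interval (±10 bp slack). The
contiguous-run form matters: an amplicon containing two InDels correctly
reports their sum, and an InDel tolerated inside a primer site shifts the
product while sitting at the interval edge. Precision is the fraction of
loci with every delta explained; recall the fraction of (detectable)
events inside at least one explained delta; exactness the fraction of
explained deltas among truth-linked loci.

## Problem sizes and determinism

The default study scenario is 200 genes (400 query and 400 target
records, ~260 kb per collection) — large enough that recall/precision
estimates rest on ~200 detectable events, while a full simulate + discover
+ evaluate cycle stays under a minute on one CPU. All randomness flows
from explicit seeds (per-record design seeds derive from a stable string
hash, so results are independent of collection order and process hash
randomization); reruns are byte-identical.

## Known limitations

* No primer thermodynamic screening beyond Tm (no hairpin/dimer checks)
  and no amplification-efficiency model — a practical wet-lab marker
  panel would filter further.
* Substitution-only site matching means an InDel inside a primer site
  usually kills the amplicon rather than shifting it, matching e-PCR
  convention but underestimating tolerant polymerases.
* The redundancy rule (same query/cluster + interval overlap) does not
  deduplicate loci across unclustered paralogous queries; supply a
  cluster mapping for assembled unigene sets.
* Reported headline counts scale with the simulated input and are not
  comparable to full-database EST screens.
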