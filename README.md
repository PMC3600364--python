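# estindel

InDel marker discovery between two transcript (EST) collections by
*in silico* PCR.

Insertion/deletion differences between related genomes make cheap,
codominant PCR markers: a primer pair flanking an InDel yields products of
different sizes that separate on a gel. `estindel` finds such loci purely
computationally, for settings like the two cultivated allotetraploid
cottons (*Gossypium barbadense* vs. *G. hirsutum*) where large EST
collections exist for both species but genome sequence is scarce. Because
the species are allotetraploid, a primer pair can amplify both orthologous
copies (between species) and homoeologous copies (A vs. D subgenome within
a species); the tool models and classifies both.

## Method

1. **Cleaning** — ESTs are quality-trimmed with the Mott algorithm at a
   Q20 cutoff (each base scores `0.01 − 10^(−q/10)`; the retained window
   maximizes the score sum), masked against a vector library
   (exact ≥20 bp seed + local alignment score ≥20, `+1/−2/−3/−1`
   match/mismatch/open/extend), stripped of terminal polyA/polyT runs, and
   dropped if shorter than 100 bp.
2. **Segmentation & primer design** — each query transcript is cut into
   ~300 bp segments (randomly jittered, covering the whole sequence) and
   every feasible primer pair is enumerated per segment under hard bounds:
   length 18–20 nt (optimum 20), GC 45–65% (optimum 50%), nearest-neighbor
   Tm 57–62 °C (optimum 58 °C, SantaLucia 1998 unified parameters at 50 mM
   Na⁺ / 50 nM primer), product 100–250 bp. Pairs are ranked by
   `|len−20| + 10·|GC−0.50| + |Tm−58|` summed over both primers.
3. **Virtual PCR** — primer sites are located on the target collection by
   substitution-only (Hamming) matching on both strands with fewer than 3
   mismatches per primer (≤2) and an exactly matching 3′ terminus;
   correctly oriented site pairs within a product-size cap become
   amplicons.
4. **InDel calling and collapse** — an amplicon whose size differs from the
   expected query product yields a call with signed
   `delta = observed − expected`; calls on the same query region collapse
   into unique loci carrying the set of deltas seen across target copies.
   Loci are binned by size (1 / 2–4 / 5–10 / >10 bp) and loci with
   max |delta| ≥ 5 bp are exported as markers.
5. **Band-pattern typing** — per-species product-size sets classify as
   orthologous polymorphism (type 1: one distinct band per species),
   homoeologous polymorphism (type 2: multiple bands, differing sets),
   monomorphism (type 3), or amplification failure.

A built-in simulator generates tetraploid-style EST pairs (ancestor →
A/D homoeologs → species-B orthologs with planted, fully recorded InDels,
plus polyA/vector/quality artifacts) so the whole pipeline is testable
against exact ground truth without any downloads.

## Worked example

```sh
estindel simulate --out-dir demo --seed 3 --n-genes 20
estindel run --query demo/query.fasta --target demo/target.fasta \
             --seed 3 --out-dir demo_out
estindel evaluate --loci demo_out/loci.tsv --truth demo/truth.tsv \
                  --primers demo_out/primers.tsv \
                  --query demo/query.fasta --target demo/target.fasta
```

The `run` step prints its stage counts:

```json
{
  "query_in": 40, "query_cleaned": 40, "primer_pairs": 208,
  "amplicons": 362, "calls": 53, "loci": 31, "markers": 9
}
```

40 records because each of the 20 genes contributes an A- and a
D-subgenome copy; 208 designed pairs produced 362 virtual products on the
other species, 53 of them with a size different from the expected product;
these collapse to 31 unique InDel loci of which 9 reach the ≥5 bp marker
cutoff. Scoring against the planted truth:

```json
{"recall": 1.0, "precision": 1.0, "exactness": 1.0,
 "n_truth": 22, "n_recovered": 22, "n_loci": 31, "n_correct_loci": 31}
```

every planted InDel inside an amplifiable region was recovered, every
called delta equals the planted net size, and `demo_out/markers.tsv` holds
gel-ready rows such as

```text
marker_id  query_id  fwd_seq               rev_seq               expected  observed  max|delta|
IND00013   g0008_D   CCGTTCAACACTCGCACTGG  TCCGGAAGGTGTTCAACCGT  246       245,253   7
```

(the two observed sizes on `IND00013` come from the two homoeologous
target copies — a type 2 pattern).

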