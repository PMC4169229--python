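# paraprimer

Paralog-aware PCR primer design and FST-based insertion-site mapping.

Most plant genes belong to multigene families, and insertional-mutant
collections locate their T-DNA insertions from short flanking sequence
tags (FSTs). When an FST falls in a *paralogous region* — one of several
near-identical copies of a segment scattered through the genome — the
best database hit is not necessarily the true insertion locus, and a
primer designed naively against one copy will amplify the others too.
`paraprimer` implements the full desk-side workflow for that problem:

* **FST mapping (1-to-N).** Each FST is searched against the genome with
  an internal seed-and-extend local aligner. Predictions are
  categorised by e-value *E*: the single best hit gives the category-0
  prediction if *E* < 10⁻³ (category 2 otherwise); further hits with
  *E* < 10⁻³ become category-1 predictions, at most 3 per FST region and
  never more than a factor 10¹⁰ worse than the region's best hit.
  Distinct regions of one FST (< 30 bp query overlap) are evaluated
  independently, so "composite" FSTs carrying flanks of two insertions
  yield predictions for both; predicted sites closer than 1000 bp are
  one insertion.
* **Paralog groups.** A line's category-0/1 predictions are clustered
  bottom-up: two groups merge when every cross pair either derives from
  the same FST region or has > 79% global-alignment identity between
  the 400 bp flanks next to the predicted sites.
* **Primer design.** Around a target position two zones (default
  300–800 bp away on each side) are probed against the genome
  (cutoff 10⁻⁵). A zone with a ≥ 100 bp hit-free segment uses the
  *standard method*: overlapping ≥ 80 bp windows, melting temperature
  stepped by 0.4 °C up to ± 1.2 °C, first primer whose 3'-terminal
  12-mer occurs exactly once in the genome wins (falling back to
  ≥ 110 bp windows over the whole zone, then to the fewest-hits
  candidate). A fully paralogous zone uses the *paralog method*: the
  zone and its counterparts (hits ≥ 50 bp, elongated to zone length)
  are multiply aligned in ~220 bp windows; alignment columns with the
  most mismatches to the zone become primer 3' ends, because a
  3'-terminal mismatch is what blocks extension on the wrong copy.

Candidate primers are scored in points:

| criterion                                        | points |
|--------------------------------------------------|:------:|
| GC clamp: 1–3 G/C among the last 5 bases          | 8      |
| no homopolymer run longer than 5                  | 4      |
| GC content between 40% and 60%                    | 2      |
| last 5 bases' reverse complement absent (hairpin) | 1      |
| each discriminating mismatch                      | 1 each |

A candidate needs **≥ 15 points** — a primer without discriminating
mismatches must therefore satisfy all four criteria. Melting
temperature uses the classic GC/length formula
`Tm = 81.5 − 11.6 + 0.41·%GC − 600/length`, and 3'-end uniqueness is
ranked with a precomputed genome-wide index of 12-mer occurrence counts
(a perfect 12 bp 3' match is enough to misprime).

## Worked example

Everything runs on synthetic genomes with known truth — no external
data needed:

```
paraprimer simulate --n-chrom 1 --chrom-len 40000 --n-families 1 \
    --members-per-family 2 --divergence 0.03 --n-lines 2 \
    --fst-len 150 --seed 7 --out-prefix demo
paraprimer index --genome demo.genome.fa --out demo.idx
paraprimer predict --genome demo.genome.fa --fsts demo.fsts.fa \
    --index demo.idx --out demo.pred.tsv
```

`demo.pred.tsv` (line0002's insertion sits in a two-copy family, so one
FST yields two predictions — the true locus and its paralog):

```
line	fst	region	chrom	position1	category	evalue	score
line0001	fst00001	0	chr1	28606	0	2.277e-77	150
line0002	fst00002	0	chr1	9593	0	2.277e-77	150
line0002	fst00002	0	chr1	34141	1	4.964e-69	135
```

Category 0 is the best hit (exact, score 150 = FST length); the
category-1 prediction at 34,141 is the homologous position in the
second family copy (~3% diverged, hence the lower score). `paraprimer
group` clusters the two into one paralog group. Designing inside the
family member forces the paralog method:

```
paraprimer design --genome demo.genome.fa --index demo.idx \
    --position chr1:9790 --min-dist 100 --max-dist 350 --out demo.tsv
```

```
pair	role	method	sequence	chrom	start1	end1	strand	tm	gc	points	end12_hits	product_size
1	forward	paralog	CAGGCCAGAGTTCAAGTGAAA	chr1	9601	9621	+	60.85	47.6	16	1	498
1	reverse	paralog	CCATTGGTTCGACGTAGACT	chr1	10079	10098	-	60.40	50.0	16	1	498
```

Both primers were placed on discriminating mismatch columns (16 points
= all four criteria + 1 mismatch point), their 3'-terminal 12-mers are
unique in the genome (`end12_hits` = 1), and the 498 bp amplimer spans
the target, so the pair genotypes the wild-type allele directly; adding
`--border-primer` lists the two junction assays as well. A sequenced
amplicon can be adjudicated between candidate paralogs with
`paraprimer confirm` (each covered SNP shifts the alignment score by 3
under the +1/−2 scoring).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the primer quality-score constants from scratch: it
constructs primers with controlled criterion outcomes, runs them
through the package's flagging and scoring, reports the retention-
boundary total and the score difference attributable to each criterion,
and smoke-runs a full synthetic design beforehand so the numbers come
from a working pipeline.
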