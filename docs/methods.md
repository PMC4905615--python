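# Methods

## Model and assumptions

The analysis treats SHM as a point-substitution process on the IMGT-gapped
V-region frame: insertions and deletions are out of scope, and every
comparison is positional within that frame (1-based; '.' occupies a position
but never matches a base).  A mutation in a rearranged sequence is *shared*
(SH) with a germline allele when the introduced nucleotide equals that
allele's base at the same gapped position; it is *non-SH* when no germline in
the (filtered) reference carries the introduced base there.  SH is always
relative to a concrete TowG allele — the scan emits one record per
(mutation, sharing allele) pair, so a single mutation may yield many SH
records and every mutation is either represented by ≥1 SH record or exactly
one non-SH entry.

The reference hierarchy is alleles → genes → subgroups (1–7) → clans, with
the clan a deterministic function of the subgroup (I: 1/5/7, II: 2/4/6,
III: 3).  Clan is therefore computed, never read from metadata.  Orphon and
5'-partial alleles are dropped from the reference before scanning (both
flags default to on).  Comparisons between sequences of different coverage
are restricted to positions where both carry bases; pairwise identity and
dissimilarity exclude gaps and N from both numerator and denominator.

## Scoring and aggregation

For voter *i* and candidate gene *k*:

* `SH_ik` — arithmetic mean of the SH counts of gene *k*'s alleles (alleles
  with no SH contribute 0).  Averaging prevents many-allele genes from
  dominating.
* `M_i` — the voter's total mutation count (from the sBm/sAm comparison,
  optionally restricted to one V region).  `M_i = 0` marks a non-voter;
  a voter whose mutations are all non-SH still votes, contributing zeros
  after homogenization.
* `maxSH_k` — mean dissimilarity between the sBm allele and gene *k*'s
  alleles over compared positions; in conserved mode, only positions where
  all alleles of the sBm gene agree are counted.
* `selSc_k` — the number of candidate genes whose `SH_ik` equals gene *k*'s
  (self-inclusive, hence ≥1).

`score_ik = SH_ik² / (M_i · maxSH_k · selSc_k)`.

SH means and tie tests use exact `Fraction` arithmetic so selectivity never
depends on float rounding; scores are converted to float only after the
formula is evaluated.  Candidates with `SH_ik = 0` are omitted (they return
as explicit zeros during homogenization); candidates with `maxSH_k = 0`
(indistinguishable from the sBm over compared positions) are dropped with a
log line rather than dividing by zero.  Other alleles of the sBm gene count
as TowGs at the allele level, but the gene-level candidate set excludes the
sBm gene itself by default (`exclude_sbm_gene=True`): the question is
movement towards *other* genes.  The flag is exposed for exploration.

Lists are homogenized to the union gene set (lexicographic order), min-max
scaled to [0, 1] per list — an all-zero list stays zero, a non-zero constant
list becomes all ones — and aggregated as the per-gene arithmetic mean
across voters.  Ranked output breaks mean-score ties lexicographically by
gene name so every table is byte-stable.

Summaries: `pct_of_total` rescales consensus means to percentages of their
sum.  The clan summary averages (default, `clan_mode=avg`) or sums
(`clan_mode=sum`) the consensus means within each clan over the union genes
and rescales the three values to sum to 100; the two modes are provided
because either reading is defensible and they differ when clans contribute
different numbers of union genes.  The functionality summary repeats the
whole scoring at allele level (allele SH count, allele dissimilarity,
selectivity over alleles), aggregates, then averages aggregated allele
scores within each functionality class (F/P/ORF) and rescales.  Subset
clustering uses Euclidean distance and average linkage on the 3-component
clan vectors (neither choice is canonical; both are config options), with a
Newick export.

## Annotation choices

* **Hotspots** — configurable IUPAC motif set defaulting to the canonical
  AID/pol-η motifs RGYW, WRCY, WA, TW, matched on the *ungapped* sBm
  context; a position is a hotspot when any window matching a motif covers
  it.  Covering-window semantics (rather than anchoring on the mutated base)
  is deliberately permissive and documented here because motif definitions
  vary across the literature.
* **Transition** — A↔G or C↔T; **replacement** — the sBm and sAm codon
  translations differ; codons not fully covered by bases yield
  "undetermined" (None).
* **Amino-acid properties** — IMGT classes for hydropathy (3), volume (5),
  chemical (7), polarity (used as the "physicochemical" property) and
  charge; stop codons get chemical class `stop` and all other properties
  `undetermined`.
* **Datasets** — SHPD is fixed at 34 named columns (identifiers, SH
  counts, position/codon/region, hotspot/transition/replacement flags, the
  sBm/sAm codons and amino acids, and 5 properties × 3 steps).  nonSHPD
  replaces the TowG-specific fields with `new_property_functionality`: the
  set of functionality classes of germlines whose amino acid at that codon
  shares the sAm amino acid's chemical class — an interpretation, flagged as
  such.  GSHD has 8 columns: patient id, subset, sAm id, sBm,
  identity(sBm, sAm) (the reported GI%), TowG, identity(TowG, sBm)
  (recomputed over compared positions), and the SH count per
  (sequence, TowG) pair.

## Filters

Quality rejection reasons are attributed by first match in a fixed order —
unresolved germline, unproductive, ambiguity ('N' in the analyzed frame),
incomplete CDR1+upstream — so the report is deterministic and reconciles:
rejections + kept = input.  "Incomplete CDR1 and upstream" is operationalized
as any position in FR1∪CDR1 (IMGT nt 1–114) where the patient sequence lacks
a base although the sBm germline carries one; germline gap columns are
ignored.  Region delimitations default to the IMGT nucleotide spans
FR1 1–78, CDR1 79–114, FR2 115–165, CDR2 166–195, FR3 196–312 and are
configurable.  Selection filters (stereotyped subset, sBm gene, germline
identity range) combine as a conjunction and are idempotent.

## Synthetic data

The generator emulates the pipeline's two inputs with known ground truth.
Reference: subgroups 1..n (first three cover all clans), each gene descended
from a random ancestor, extra alleles diverging at 2 positions (giving every
multi-allele gene conserved and non-conserved columns), an optional
'...'-gapped codon per gene, functionality drawn per allele.  Defaults —
3 subgroups × 4 genes × 2 alleles, 120-nt frame, pseudogene fraction 0.13
and ORF fraction 0.04 (close to the human IGHV repertoire's proportions),
30 sequences with Poisson(6) mutations, bias 0.8 — are the package's
standing study conditions and are also what the recovery sweep in
`scripts/acceptance.py` uses.

Cohort: each sequence starts from an sBm allele of a non-target gene.  With
probability `bias_p` a mutation copies the target allele's base at a
position where sBm and target differ (guaranteed SH toward the target);
otherwise it introduces a base present in no germline at that column
(guaranteed non-SH; a saturated column is re-drawn).  The truth manifest
records every planted mutation, so the scan's SH-toward-target and non-SH
counts reconcile with the manifest exactly — there are no incidental
sharings toward the target by construction, which is what makes the
reconciliation exact.

What the generator does **not** emulate: realistic SHM targeting (hotspot
preference, strand bias, selection against stop codons), clonal lineage
structure, sequencing error, and realistic germline similarity structure
(real IGHV genes within a subgroup are far more similar than random
ancestors).  Passing tests therefore demonstrate the correctness of the
bookkeeping and arithmetic on known ground truth, not biological fidelity of
the movement profiles on real repertoires.

## Numerical and engineering choices

Problem sizes in the test suite and the acceptance script (references of
~24 alleles, cohorts of 8–30 sequences, 50-replicate sweeps) are chosen so a
full run completes in seconds while still exercising every code path; all
randomness is seeded (NumPy `default_rng`) and hypothesis runs derandomized.
Intermediate artifacts are plain TSV/JSON/Newick; every pipeline stage can
resume from them, and the run manifest hashes each output so reruns can be
verified byte for byte.

## Known limitations

* Only substitutions on the V-region frame; no indels, no CDR3/junction, no
  light chains.
* One sequence per patient is the expected case; duplicate patient IDs are
  tolerated and each row votes independently.
* The GSHD/nonSHPD schema details and the hotspot window rule are documented
  interpretations (see above), not community standards.
* Real-cohort subset profiles require proprietary clinical data and are out
  of scope; all shipped numbers are computed on synthetic cohorts.
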