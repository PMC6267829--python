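# Methods

This note documents the models behind each `polyorigin` stage, the
parameters that matter, what the synthetic-data generators emulate (and do
not), and the numerical choices a maintainer would want spelled out.  It
states no empirical result beyond what the test suite and the demo run
themselves compute.

## K-mer attribution (`polyorigin.kmers`)

**Model.**  A k-mer long enough to be effectively unique in a genome acts
as a barcode for its subgenome of origin.  K-mers are *canonical* (the
lexicographic minimum of a window and its reverse complement) so both
strands count once; k must be odd, which guarantees no k-mer equals its
own reverse complement.  Windows containing non-ACGT symbols are skipped.
For k ≤ 31 k-mers are 2-bit packed into `uint64` and all counting and set
arithmetic is vectorized with numpy; 31 < k ≤ 63 falls back to a string
engine with identical semantics (intended for small inputs only).

**Genome sizing.**  `G = Σ_{d ≥ cutoff} d·n_d / argmax_{d ≥ cutoff} n_d`,
where `n_d` is the number of distinct k-mers seen `d` times.  The error
cutoff defaults to the spectrum's first local minimum — the first depth
where counts stop strictly decreasing, i.e. the valley between the
low-depth error peak and the coverage peak — falling back to depth 5 when
the histogram is monotone.  Modal-depth ties break toward the lower depth
for determinism.  In the exactness limit (every k-mer unique, uniform
error-free coverage) the estimator returns the genome length exactly; with
uniform random read starts the only distortion is the ±(k−1) edge effect,
well under the 2% the tests allow.  Note the estimator counts genome
*content*: for a tetraploid, near-identical homeologous regions collapse
into double-depth k-mers, which biases the hybrid's size estimate low and
single-copy content high; the sizing tests therefore use haploid genomes.

**Attribution.**  Two distinct depth filters are used, mirroring standard
practice: sizing uses the spectrum valley, while cross-species set
comparisons keep k-mers seen between `d_min = 5` and `d_max = 250` times
(inclusive), suppressing sequencing errors and collapsed repeats.  Sets
are compared as *distinct* k-mers, not multiplicity-weighted.  With
hybrid set H, paternal set P and maternal-lineage set M (the union over
candidate maternal species, since extant relatives jointly proxy the
donor): `S_p = H∩P−M`, `S_m = H∩M−P`, and
`f_p = 100·|S_p|/(|S_p|+|S_m|)`.  K-mers in both or neither lineage are
reported but excluded from the denominator.

**Known bias.**  The exclusion of shared k-mers is not neutral when the
parents overlap substantially.  A 31-mer is identical in both parents iff
no substitution hit it on either lineage edge; at per-branch divergence
`d` that probability is `(1−d)^62`.  With subgenome fractions 40/60 the
expected estimate is `(40 − 40s)/(100 − 80s)` with `s = (1−d)^62`: at
`d = 0.02`, `s ≈ 0.286` and the estimator converges to ≈37% for a true
40% — a fixed ≈3-point bias that more seeds or coverage cannot remove.
The bias vanishes for symmetric (50/50) splits and becomes negligible
(<0.5 points) once shared k-mers are under ~5% of the hybrid set, the
regime real highly-repetitive plant genomes are in.  The acceptance suite
asserts the ±2-point recovery bound at the stated divergence and is
expected to surface this bias rather than hide it.

**Arithmetic reports.**  `expected_contribution_from_sizes` gives the
null expectation `100·G_a/(G_a+G_b)` (one decimal);
`downsizing_report(f_p, G_h, G_a, G_b)` converts an attribution fraction
into Gb contributions (`f_p/100·G_h` and the remainder) and per-parent
downsizing (`G_parent − contribution`, negative values labelled
upsizing; two decimals); `whole_genome_reduction_percent` is
`100·(G_a+G_b−G_h)/(G_a+G_b)` (one decimal).

## Plastid maternity (`polyorigin.plastid`)

Chloroplasts are maternally inherited, so the hybrid's plastid SNPs
(called against a shared reference) co-occur with the maternal lineage's.
SNP identity is the full `(chrom, pos, ref, alt)` tuple — a position
shared with a different allele is not shared ancestry.  Positions are
1-based; multiallelic records are decomposed; indels are skipped with a
warning.  SNP calling itself (mapping, pileup) is out of scope; inputs
are pre-called sets in VCF or 4-column TSV.

The lineage call maximizes hybrid-shared, side-private SNP counts:
paternal side = SNPs in hybrid ∩ paternal and no maternal candidate;
maternal side = SNPs in hybrid ∩ (any maternal candidate) − paternal.
Within a winning maternal clade, the closest species is the candidate
with the larger strictly-pairwise hybrid sharing count.  Side ties return
"ambiguous", a within-clade tie returns the maternal lineage with no tip,
and all-zero evidence returns "uninformative".  A handful of
hybrid∩paternal SNPs (homoplasy or mapping noise) are simply outvoted; no
significance test is applied because none is established for this design.

## Homeolog phylogeny (`polyorigin.phylogeny`)

Per ortholog group: (1) **composition filter** — exact match to the
polyploidy expectation (diploids 1 copy, tetraploid 2, outgroup 1; extra
or missing genes drop the group); (2) **terminal trimming** — remove
leading/trailing columns outside the first/last column that is gap-free
across all sequences (no gap-free column anywhere drops the group);
(3) **gap filter** — drop if any sequence's gap fraction strictly exceeds
τ = 0.05; (4) **p-distances** — mismatches over comparable columns,
where a column is comparable for a pair iff both carry canonical
residues (gaps and ambiguity codes excluded); (5) **neighbor joining** —
standard Saitou–Nei agglomeration on the Q-criterion, exact Q ties broken
by lexicographic order of each node's smallest descendant leaf label,
negative branch lengths clamped to zero, returning an unrooted binary
tree; (6) **assignment** — root at the outgroup; the homeolog sister to
the paternal diploid is the paternal-subgenome copy, and the remaining
focal homeolog is assigned by its sister group: one maternal tip, the
other, or the clade of both (= their common ancestor).  Anything else is
a "conflict", counted but excluded from the informative tally.

No tree method is canonical for this task; NJ on p-distances was chosen
for determinism and speed, and `PhyloTree.from_newick` lets externally
built (e.g. maximum-likelihood) trees be substituted into the same
assignment step.  On additive distance matrices NJ provably recovers the
generating topology; the tests verify agreement with a brute-force
least-squares minimum-evolution search over all 4–5-taxon topologies and
with an independent NJ implementation.

## Co-expression screen (`polyorigin.coexpression`)

Expression (genes × samples, FPKM ≥ 0) and a metabolite profile are
matched on shared (tissue, condition) labels, averaging replicates per
label first — concentrations are typically reported as per-condition
means, and per-plant pairing across assays is unavailable.  Pearson r is
the default (Spearman intentionally omitted: the screen follows the
magnitude-based practice it models), computed per gene, optionally on
`log10(x+1)`-transformed expression; constant genes have undefined r and
are excluded with a warning.  `screen` ranks genes with `r ≥ r_min`
(default 0.9) descending, ties broken by gene id.  No multiple-testing
correction is applied — the screen selects by magnitude, not
significance — but `n` is carried in the output for downstream use.

## Synthetic data (`polyorigin.simdata`)

What the generators emulate, and the defaults of the stated world:

- **Genomes**: a uniform-random ancestor (default 100 kb) evolved down
  independent lineage edges at `divergence_per_branch = 0.02`
  substitutions/site; Jukes–Cantor-like uniform replacement with a
  different base; **no indels in genomes**, so k-mer ground truth is
  exact.  `hybridize` concatenates two parents and removes exactly
  `round(fraction·len)` bases per designated subgenome as randomly
  placed non-overlapping blocks (default 1 kb), mimicking segmental
  loss while preserving local k-mer structure; a per-base origin map is
  returned.
- **Reads**: `ceil(coverage·L/read_length)` single-end, forward-strand
  reads (canonicalization makes strand irrelevant downstream), uniform
  starts, per-base substitution errors, constant placeholder qualities
  'I' (qualities are never consumed).  Defaults: 30×, 100 bp, error 0.
- **Plastid SNPs**: planted directly by exclusive-region counts at unique
  positions (sampled without replacement; all biallelic).  The default
  template is the study system's four-species Venn
  (336 paternal-private / 8 hybrid+paternal / 303 hybrid+both-tips /
  7 hybrid+tip1 / 17 hybrid+tip2 / 11 tip1+tip2, donor = tip2) — a clean
  lineage tree cannot produce hybrid-with-single-tip sharing on both
  tips, so the homoplasy regions are explicit extras.  A `"tree"` mode
  generates the clean three-branch alternative.
- **Ortholog families**: peptide alphabet (20 residues), default 300
  columns, per-branch substitution count `round(0.03·L)`.  Site draws
  are **without replacement across the whole gene tree**, so every site
  mutates at most once, p-distances are exactly additive, and NJ
  recovery of the planted topology is guaranteed — this is what
  "noise-free" means here, and what a green recovery test does and does
  not establish: it validates the pipeline's bookkeeping end-to-end, not
  robustness to homoplasy or alignment error.  The default topology mix
  (0.42, 0.36, 0.22) follows the proportions reported for the study
  system.  Configurable fractions of groups receive terminal gap runs
  (trimming exercise), >5% interior gaps in one sequence (planted gap
  -filter drops) or a duplicated diploid gene (planted composition
  drops).
- **Expression**: 12 samples (4 tissues × 3 growth conditions),
  log-normal background FPKM, and planted genes
  `c + a·m + ε` with `σ_ε = a·s_m·√(1/r² − 1)` so the population r given
  the metabolite profile equals `planted_correlation` (default 0.95;
  ±1 is the zero-noise limit, giving exact affine genes).  The positive
  shift keeps FPKM ≥ 0 and, being affine, preserves r.

Every generator is a pure function of (config, seed); identical inputs
give byte-identical outputs.  The generators do **not** emulate realistic
Illumina error profiles, PCR duplicates, structural variation beyond
block deletion, codon-aware evolution, or alignment uncertainty.

## Pipeline and reproducibility (`polyorigin.pipeline`, `io`, `cli`)

Readers/writers use Biopython (FASTA/FASTQ), pysam (VCF) and pandas
(TSV); VCF output is a minimal in-package v4.2 emitter with contig
headers.  Coordinates are 1-based in VCF and 0-based half-open
internally, converted only at the I/O boundary.  `run_all` chains
simulate → k-mer attribution → plastid maternity → homeolog tally →
co-expression screen; any stage failure aborts with the stage name.  The
JSON summary embeds the config echo, a config hash and the seed; JSON is
written with sorted keys so reruns are byte-identical.  Logging goes to
stderr, machine output to files/stdout.

## Known limitations

- The exclusive-k-mer attribution bias quantified above: accurate only
  when parental k-mer overlap is small or the split is near-symmetric.
- In-memory k-mer counting only; not intended for >1 Gb read sets
  (no disk-based counting or sketches).
- The homeolog stage takes ortholog groups and alignments as input;
  clustering and alignment themselves are out of scope, as are
  maximum-likelihood trees and Ka/Ks estimation.
- The maternity call is a vote, not a test; very small SNP sets can
  return calls with weak evidence (the counts are always reported).
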