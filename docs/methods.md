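# Methods

## Model

A sequenced isolate contains *n* replicons sorted by descending length;
the longest chromosome is the reference with copy number π₁ = 1, and
every other replicon (plasmid or secondary chromosome) gets a copy
number relative to it. Reads are assumed to be drawn multinomially with
per-replicon probability proportional to DNA mass π_k·L_k, so the
probability that a given read originates from replicon *k* is
π_k·L_k / Σ π·L. Under this model the maximum-likelihood copy number
from unambiguous reads is the coverage ratio
π_j = (R_j/L_j)/(R_1/L_1). We compute it as (R_j·L_1)/(R_1·L_j) in a
single expression, which is exact in floating point for integer counts
and lengths.

Reads compatible with several replicons (multireads) carry incomplete
origin labels. PIRA treats the origin of each multiread as the missing
data of an EM problem. With M_jk the number of distinct candidate
locations of multiread *j* on replicon *k*:

* E-step: responsibility L_jk = M_jk·π_k / Σ_k' M_jk'·π_k'. Length does
  not appear here: conditional on the read's sequence, each of the M_jk
  sites is a single position whose sampling probability scales with
  copy number only.
* M-step: π_k ← (R_k + Σ_j L_jk)/L_k, renormalized to π₁ = 1.

The observed-data log-likelihood (up to constants) is
Σ_k R_k·log(π_k·L_k/S) + Σ_j log(Σ_k M_jk·π_k/S) with S = Σ π·L; the
M-step above maximizes the corresponding Q-function exactly, so the
likelihood is non-decreasing along the iteration. The implementation
asserts this per step in the tests and the trace records π and the
log-likelihood at every iteration.

Convergence is declared when ‖π_new − π_old‖₁ < tol. The threshold
value 10⁻⁶ is standard; we chose the L1 norm because π₁ is pinned, so
the norm directly bounds the worst per-replicon change. A ceiling of
1000 iterations guards against pathological inputs; hitting it sets
`converged=False` on the trace and warns — never silently.

## Pseudoalignment

The index stores every canonical k-mer (lexicographic minimum of the
k-mer and its reverse complement, packed 2 bits/base into uint64, hence
k ≤ 31 and odd; default k = 31) of every replicon, with a color bitmask
over replicons (≤ 64 replicons, ample for prokaryotic genomes) and the
full occurrence list (replicon, position, strand). k-mers containing N
are neither indexed nor queried.

A read is assigned the **intersection** of the color sets of its k-mers
that hit the index — the standard pseudoalignment rule. Two guards
modify it:

* **minimum hit fraction** (default 0.4): a read counts as mapped only
  if at least this fraction of its valid k-mers hit the index. A read
  with one or two sequencing errors keeps ≥ ~48% of its 31-mers intact
  at 150 bp and passes; a heavily erroneous read retains only a stray
  intact k-mer and is dropped, which is the intended behaviour — error
  filtering by failure to pseudoalign. At a 10% substitution rate over
  99% of 150 bp reads are unmapped under this rule (tested), versus
  only ~60% under a bare any-hit rule.
* **τ fallback** (default 0.8): if the color intersection is empty
  (chimeric or junction artifacts), the read is assigned the union of
  colors supported by ≥ τ of its hit k-mers; if no color reaches τ the
  read is unmapped.

Classification is vectorized by concatenating batches of reads with
N-separators (whose windows are invalid by construction) and reducing
per-read segments with `reduceat`; the batch path is tested for exact
equality with the one-read reference path.

## Multiread location counting

PIRA needs the number of *distinct locations* each true multiread could
come from, per replicon — a repeat present twice on the chromosome and
once on a plasmid must weigh 2:1 at equal copy number. Instead of full
alignment we use seed-and-cluster on the k-mer occurrence positions
already in the index: every k-mer hit implies a candidate read start
(position − read offset, orientation-corrected); implied starts on one
replicon are clustered greedily, two locations being distinct when
their starts differ by at least the read length; a cluster supported by
≥ τ_loc (default 0.5) of the read's k-mers counts as one location. For
error-free and low-error short reads this recovers exactly the
occurrence counts of the read's source element (tested against
simulator truth). Counts may differ from a full aligner's on highly
degenerate repeats; location counts, not alignments, are the only
quantity the EM consumes. Multireads with exactly one total location
are promoted to unireads; zero-location multireads are reclassified
unmapped; read totals are conserved through every stage (asserted).

## Filters

Three rules, all with strict inequalities at the boundary:

* plasmids shorter than 1000 bp are removed (unplaced-contig artifacts);
  a 1000 bp plasmid stays;
* a genome whose plasmid exceeds its longest chromosome is rejected
  outright (likely misannotation);
* plasmid estimates backed by fewer than 10,000 mapped reads are
  dropped; exactly 10,000 stays; chromosomes are never dropped. Mapped
  reads = unireads + promoted reads + the replicon's expected multiread
  allocation rounded half-even. We apply this filter after the EM (the
  allocation is only known then) and report both counts.

Paired-end mates are counted as independent reads throughout; no
read-quality filtering is done (erroneous reads fail to pseudoalign
instead).

## Simulator

The simulator generates i.i.d.-uniform random replicon backbones,
splices shared elements (one random sequence per element, inserted
verbatim at uniform non-overlapping points into every carrier, keeping
the configured final lengths), and samples reads with per-replicon
probability ∝ copy number × length, uniform start and strand, and
i.i.d. substitutions. One RNG seeded from the config determines
everything; identical seeds give byte-identical output.

What it deliberately does not model: indels, position- or
quality-dependent error profiles, GC/coverage bias, insert-size
structure, replication-gradient (origin-to-terminus) coverage slopes,
and k-mer-sharing from convergent evolution rather than planted
elements. Tests passing on this generator therefore demonstrate
correctness of the estimator under the proportional-mass model and
robustness to uniform substitution errors and shared repeats — not
robustness to real-library artifacts such as biased coverage, which
would bias any coverage-ratio method.

### Recovery experiment conditions

The recovery suite uses copy numbers {0.5, 1, 2, 5, 20, 100} with one
2 kb element shared chromosome↔plasmid at 30× chromosome depth
(150 bp reads, 50 kb chromosome). Plasmid lengths are 30 kb (π ≤ 1),
10 kb (π = 2, 5), 5 kb (π = 20) and 3 kb (π = 100): sized so the
plasmid collects ≥ ~2000 reads even at the lowest copy number — keeping
binomial sampling error well inside the 5% acceptance band — while
high-copy plasmids stay small enough that replicate read totals remain
around 10⁴–10⁵. 40 replicates cycle over the six copy numbers.

## Segmented regression and downstream statistics

The scaling analysis fits log₁₀ PCN against log₁₀ plasmid length
(normalized by the genome's longest chromosome, or raw — both
supported) with the continuous broken-line model
y = a + b₁x + b₂·max(0, x−c), slopes b₁ and b₁+b₂. The breakpoint c is
estimated by profiling RSS over a 513-point grid of interior
x-quantiles (1%–99%, clipped so ≥ 3 distinct x remain on each side) and
refining the best cell by bounded golden-section search. This is
deterministic and derivative-free; an iterative-linearization fitter
could differ in ill-conditioned cases. Exactly collinear data collapse
both slopes to the common slope and the fit is flagged
`breakpoint_supported=False`.

Model comparison uses the Gaussian AIC form n·ln(RSS/n) + 2p with
p = 3/4/5 parameters (including σ) for linear/quadratic/segmented;
only ΔAIC and the resulting ranking are meaningful, and the ranking is
convention-invariant. Adjusted R² uses 4 mean-structure parameters for
the segmented model (a, b₁, b₂, c).

K-means (K = 2, 25 restarts, fixed seed) clusters log₁₀ plasmid length
— on the raw scale the small-plasmid mode is invisible to squared-error
clustering. The tests verify it against the exact 1-D sorted-split
optimum, which is enumerable. The intragenomic census computes Pearson
correlation of (length, PCN) within each genome holding ≥ 2 (and ≥ 3)
plasmids; zero-variance genomes are excluded and counted. DNA-content
scaling reuses the segmented machinery on
log₁₀(PCN × length / chromosome length); algebraically its slopes are
1 + the PCN-fit slopes, which the tests confirm numerically, and an
exact inverse (slope −1) law would give flat content.

## Numerical and design notes

* Replicon ordering is a pure function of (length desc, id asc);
  permuting FASTA input never changes the reference choice.
* Roles come from a metadata table when supplied, else from a
  case-insensitive "plasmid" substring in the FASTA description;
  overridable because annotation conventions vary.
* Coordinates are 0-based half-open internally.
* All stochastic components take explicit seeds/RNGs; the test suite is
  fully derandomized.
* Degenerate inputs: empty read streams yield zero-count summaries;
  zero reference coverage, genomes without a chromosome, replicons
  shorter than k, and degenerate regression predictors all raise with
  explicit messages rather than propagating NaNs.

## Limitations

* Copy numbers are relative to the longest chromosome; absolute
  plasmids-per-cell would require an external calibration.
* One genome at a time; the index is not designed for metagenomes.
* No within-replicon binning: copy-number variation along a replicon is
  averaged out.
* The location counter is a k-mer heuristic, not an aligner; divergent
  (mutated) element copies below ~97% identity at k = 31 lose shared
  k-mers and may under-count.
* At most 64 replicons per genome (color bitmask width).
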