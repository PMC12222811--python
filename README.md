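# pcnkit

Plasmid copy number (PCN) estimation from short-read sequencing data, and
the downstream statistics of how copy number scales with plasmid length.

## The problem

Bacteria and archaea carry plasmids at anywhere from a fraction of a copy
to thousands of copies per chromosome, and copy number is invisible in an
assembly: it has to be inferred from sequencing coverage. Because the
amount of sequencing data drawn from each replicon (chromosome or
plasmid) is proportional to its DNA mass, the copy number of replicon
*j* relative to the longest chromosome (replicon 1, copy number 1 by
definition) is the coverage ratio

```
π_j = (R_j / L_j) / (R_1 / L_1)
```

with `R_j` reads mapped to replicon *j* and `L_j` its length — read
length cancels. The complication is **multireads**: reads from mobile
elements (transposons, insertion sequences) present on both a chromosome
and a plasmid that pseudoalign to several replicons at once. Discarding
them biases plasmid estimates down, badly so for small plasmids
dominated by shared sequence.

`pcnkit` resolves multireads with **PIRA** (probabilistic iterative read
assignment), an expectation–maximization algorithm for multinomial read
counts. With `M_jk` the number of distinct locations multiread *j*
matches on replicon *k*:

* **E-step** — allocate multiread *j* to replicon *k* with probability
  `L_jk = M_jk π_k / Σ_k' M_jk' π_k'`;
* **M-step** — `π_k ← (R_k + Σ_j L_jk) / L_k`, renormalized so `π_1 = 1`;

iterated until the L1 change in π falls below 10⁻⁶. The observed-data
log-likelihood is non-decreasing at every step (the EM guarantee), and
the fixed point is verified in the test suite against an independent
damped fixed-point solver.

The toolkit contains:

* a **colored k-mer index** and pseudoaligner (canonical 31-mers,
  per-k-mer replicon color sets) that classifies reads as uniread /
  multiread / unmapped — erroneous reads simply fail to pseudoalign and
  drop out;
* a **multiread locator** that counts distinct candidate alignment
  locations per replicon by clustering k-mer hit positions, promotes
  multireads with a single genomic location to unireads, and builds the
  match matrix **M**;
* the **PIRA EM** behind a statsmodels-style
  `PlasmidCopyNumberModel.fit() -> PCNResults` interface;
* a **read simulator** with planted shared elements and full ground
  truth, used by every test;
* the **scaling-law analysis**: segmented (broken-line) log–log
  regression of PCN on normalized plasmid length with breakpoint
  estimation, AIC comparison against linear/quadratic models, K = 2
  size clustering, the per-genome length–PCN correlation census, and
  plasmid DNA-content scaling.

## Worked example

```python
import pcnkit as pk

cfg = pk.SimConfig(
    chromosome_length=50_000,
    plasmids=[(10_000, 3.0)],                     # 10 kb plasmid, 3 copies
    shared_elements=[pk.simulate.SharedElement(2_000, carriers=(0, 1))],
    read_length=150, total_reads=20_000, seed=42,
)
genome, truth = pk.simulate_genome(cfg)
reads, truth = pk.simulate_reads(genome, truth, cfg)

res = pk.PlasmidCopyNumberModel(genome, reads).fit(min_reads=0)
print(res.summary())
```

```
Plasmid copy number estimates (PIRA)
========================================================================
genome: sim   replicons: 2   reads: 20000
unireads: 18056   multireads (true): 1944   unmapped: 0
EM iterations: 7   converged: True
------------------------------------------------------------------------
replicon_id       role  length_bp  mapped_reads  pcn_direct  pcn_pira  kept
 chromosome chromosome      50000         12397      1.0000    1.0000  True
  plasmid_1    plasmid      10000          7603      2.5745    3.0664  True
========================================================================
```

The 2 kb element shared by chromosome and plasmid makes ~10% of reads
ambiguous. The direct (uniread-only) estimate of 2.57 understates the
true copy number 3; the EM reallocates the 1944 multireads and lands at
3.07 (the residual ~2% is binomial sampling noise). `mapped_reads`
includes each replicon's share of the probabilistically assigned
multireads; plasmids with fewer than 10,000 mapped reads are flagged
`kept=False` by default (here the filter is disabled for the small
example).

The same pipeline is available from the shell:

```bash
pcn simulate --config sim.yaml --out-prefix sim
pcn estimate --fasta sim.fa --reads sim_R1.fq --out pcn.tsv
pcn analyze  --table pcn_all.tsv --out-dir results/
```

`pcn analyze` takes a table of per-plasmid records (`genome_id,
replicon_id, length_bp, chromosome_length_bp, pcn`) and emits the
segmented-regression fits (normalized and raw length scales), the AIC
model-comparison tables, plasmid size clusters, the intragenomic
correlation census, DNA-content scaling, and log–log scatter plots.

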