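# panmeth

Allele-specific DNA methylation analysis on a haplotype sequence graph,
for parent–progeny trios of clonally propagated plants.

## The problem

Comparing whole-genome bisulfite data *between* genomes is usually done
by mapping every sample onto one linear reference. That approach is
biased: cytosines private to a non-reference genome are invisible, and
C>T substitutions in the sample are read as unmethylated cytosines —
exactly the substitution class that methylated cytosines accumulate.
A variation graph that embeds all haplotypes as paths removes the single
reference: every haplotype keeps its own coordinates, and homologous
regions are found by walking shared nodes.

`panmeth` implements that graph-based workflow for a hybrid trio: two
diploid parents (CF, haplotypes CF1/CF2; SB, haplotypes SB1/SB2) and a
progeny CS that carries one haplotype inherited from each parent (CSCF,
CSSB), each cultivar observed through three clones used as biological
replicates. It covers:

- **graphio** — GFA v1 I/O, chopping nodes to ≤ 200 bp, projecting
  positions between paths through shared single-copy nodes, and pairwise
  bubble deconstruction into SNP/INDEL/MNP/other variants (indels ≥ 50 bp
  flagged as structural variants).
- **methio** — bismark-style CX cytosine reports, the coverage ≥ 10
  filter, and uniting clones on the sites common to all of them
  (strands kept separate; a site is "methylated" at level ≥ 20%).
- **panmeth (nodes)** — projecting united profiles onto chopped nodes and
  classifying nodes as core / dispensable / private and all / intra /
  inter, by presence or by shared methylation status.
- **dma** — 200 bp windows tiled on the CS haplotypes, projected onto the
  other haplotypes (kept when every projection is 150–250 bp with ≥ 3
  cytosines), an overdispersion-corrected binomial likelihood-ratio test
  per window (clones are the samples, 3 vs 3), Benjamini–Hochberg
  q-values, calls at q < 0.01 with context differentials of 20 points
  (CG, CHG) and 10 points (CHH), inherited-DMR sets (iCF/iSB), the
  intra-cultivar concordance measure, and a window/coverage/differential
  parameter sweep.
- **refbias** — quantifying and correcting single-reference bias by
  porting a sample's own calls through homologous 200 bp chunks;
  regions grouped into corrected / original / low delta / high delta at
  the 75% level and 20-point delta thresholds, with Fisher tests for
  C>T (G>A) enrichment per group.
- **genemeth (genes)** — 100-bin metagene profiles, gbM/teM gene
  classification from mean exonic context levels, DMR annotation against
  the gene/repeat space, SV proximity (maxgap 1 kb), and reciprocal
  allelic-pair detection (≥ 50% projected overlap, both directions).
- **synthetic_trio (simulate)** — a generator producing the whole data
  bundle (graph, clone methylomes, annotations, variants) with complete
  ground truth, used to validate every step.

## The statistic

For one window and one context, each clone *i* contributes methylated
and total counts (mᵢ, nᵢ) pooled over the cytosines in the cultivar's
projected intervals. With group proportions p̂ₐ = Σmₐ/Σnₐ and
p̂ᵦ likewise, the methylation differential is 100·(p̂ₐ − p̂ᵦ) and the
test statistic is the binomial deviance

D = 2·[ℓ(p̂ₐ, p̂ᵦ) − ℓ(p̂₀)],  φ = (1/(N−2))·Σᵢ (mᵢ − nᵢp̂)² / (nᵢp̂(1−p̂))

where ℓ is the binomial log-likelihood, p̂₀ the pooled null proportion
and φ the Pearson overdispersion under the fitted group proportions.
When φ > 1, D is scaled to D/φ (McCullagh–Nelder); p-values come from
χ²₁, and q-values from Benjamini–Hochberg per comparison × context.

## Worked example

```python
from panmeth import dma
from panmeth.config import TrioConfig
from panmeth.graph import chop_nodes
from panmeth.methio import united_profiles
from panmeth.simulate import simulate_trio

cfg = TrioConfig(chrom_length=50_000, seed=1)
truth, methylomes = simulate_trio(cfg)
profiles = united_profiles(methylomes)            # coverage >= 10, 3 clones united
graph, _ = chop_nodes(truth.graphs["chr1"], 200)
windows, drops = dma.build_windows(graph, profiles)
print(f"retained {len(windows)} comparable windows (dropped: {dict(drops)})")
called = dma.adjust_and_call(
    dma.run_comparison(windows, profiles, "CFvSB", chrom="chr1")
)
print(called.groupby("context")["call"].value_counts().unstack(fill_value=0))
```

prints

```
retained 471 comparable windows (dropped: {'unprojectable': 16, 'length': 3, 'duplicate': 9})
call     hyper  hypo   ns
context
CG          12    16  443
CHG          7     8  456
CHH          0     0  471
```

471 of the 499 tiled 200 bp windows survive projection onto all six
haplotypes; with the default generator (independent per-site states per
haplotype) the CF-vs-SB comparison finds a few dozen CG/CHG windows
whose chance methylation differences clear the 20-point differential at
q < 0.01, and none in the sparsely methylated CHH context. The
strongest window here (`CSSB:33600-33800`, CG) has a differential of
33.7 points at q ≈ 2.6·10⁻¹²³.

There is also a small CLI for file-based runs:

```bash
panmeth simulate --config cfg.yaml --outdir trio/ --seed 5
panmeth classify-nodes --dir trio/ --mode methylation
panmeth dma --dir trio/ --comparison CFvSB
```

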