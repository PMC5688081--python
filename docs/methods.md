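# Methods

This note records the models, estimators, numerical conventions and design
choices behind `sweepscan`, and what the synthetic benchmarks do and do not
demonstrate.

## Statistics

### Haploid Weir F_ST

The two-population variance-component estimator is evaluated per SNP in its
haploid form: each individual contributes one allele, so there is no
heterozygosity (within-individual) term. With `r = 2` populations, `n_i`
non-missing calls, alt frequencies `p_i`, `n_T = n_1 + n_2` and weighted mean
`p̄`:

    MSP = Σ n_i (p_i − p̄)² / (r − 1)
    MSG = Σ n_i p_i (1 − p_i) / (n_T − r)
    n_c = (n_T − Σ n_i²/n_T) / (r − 1)
    θ   = (MSP − MSG) / (MSP + (n_c − 1) MSG)

θ is undefined (NaN, excluded downstream) when either population has < 2
non-missing calls or the site is monomorphic in both. Negative θ is kept:
clamping would bias ranks. The three pairwise comparisons are run
separately; no single three-population estimator is fitted, because the
composite score needs the pairs individually (one of them negated).
`multilocus_theta` aggregates by ratio of sums, the standard multi-locus
combination.

Permutation p-values shuffle the pooled samples' population labels and
report `#{θ_perm ≥ θ_obs} / n_perm` (no pseudocount; an `add_one` option
exists). By default one shuffle per iteration is shared across SNPs, which
preserves cross-SNP correlation under the null and is cheap; per-SNP
independent shuffles are available. Because θ takes finitely many values at
fixed counts, ties make the deterministic ratio conservative
(sub-uniform under the null); a `tie_break="randomized"` option implements
the standard randomized p-value `(#{>} + U·(#{=}+1))/(n_perm+1)`, exactly
Uniform(0,1) under exchangeability, and is what the calibration test uses.
Exhaustive enumeration over all label assignments is available for pooled
samples ≤ 20.

### EHH, iES and Rsb

Site-EHH at marker x flanking a core SNP is the probability that two
chromosomes sampled without replacement are identical over the closed
interval [core..x]: `EHH_S = Σ_h C(n_h,2)/C(n,2)`. The profile starts at 1
at the core (zero-width interval) and is extended one marker at a time on
each side until it first drops below `decay_threshold` (default 0.05, the
stopping marker included) or the scaffold ends; the truncation reason is
recorded per side. Profiles are monotone non-increasing by construction
(group refinement).

iES is the trapezoid integral of the profile against genetic position —
Morgans when a map is present (the simulator always emits one), bp
otherwise; the unit is recorded in the result. `ln(iES_num/iES_den)` is
computed as a difference of logs (so swapping populations negates it
exactly), median-centred over all finite SNPs genome-wide (not
per-scaffold), divided by the SD (MAD × 1.4826 by option), and
exponentiated into Rsb. If every ln-ratio is identical the spread is zero
and standardized values are defined as 0 (Rsb ≡ 1) with a warning. Sites
with zero iES (no flanking marker on either side) are undefined.

Whether the "median deviation" standardization in the statistic's usual
formulation divides by the SD or only median-centres is ambiguous; SD
scaling is the default here because the downstream composite expects an
approximately normal score, and the MAD alternative is one flag away.

### Composite selection score

Per constituent: fractional ranks `rank/(n+1)` ascending with ties
averaged; NaNs are dropped from ranking and propagate to the SNP's score.
z = Φ⁻¹(rank); z̄ is the mean over the m constituents; under independence
z̄ ~ N(0, 1/m), so the one-sided upper-tail p is `1 − Φ(z̄·√m)` and
CSS = −log10 p. An empirical-null option takes p from the upper-tail
fraction of the z̄ distribution itself. The score is invariant under any
strictly monotone transform of each constituent.

The F_ST composite uses m = 3 constituents
(θ_focal,admixed, θ_outgroup,admixed, −θ_focal,outgroup): high scores mean
the focal population moved away from its admixed source *toward* the
outgroup profile. The Rsb composite uses the focal population's two
standardized contrasts with equal weight (m = 2). Outliers are SNPs whose
CSS strictly exceeds the empirical 99th percentile (linear interpolation);
the final "selection allele" set is the intersection of the two metrics'
outlier sets, with per-SNP provenance.

### Haplotype blocks

Blocks are maximal four-gamete-consistent runs: scanning left to right per
scaffold, a block extends to the next SNP unless some pair (block SNP, next
SNP) shows all four gametes {00,01,10,11} across the pooled samples, under
the infinite-sites reading of a recombination witness. This deterministic,
haploid-native partition replaces likelihood-based block models; published
block counts from such models are therefore not comparable targets. Pairs
are evaluated over samples non-missing at both sites, which lets the
partition run on unimputed data and bootstrap the imputation below.
Spectra label haplotypes by descending pooled frequency, ties broken
lexicographically, so identifiers are stable across populations and runs.

### Missing-call rescue

Within each block, candidate haplotypes are the distinct strings of samples
with complete calls in the block, ordered by descending pooled frequency
then lexicographically. Each missing call takes the allele of the candidate
nearest in Hamming distance over the sample's observed sites (ties go to
the lower-index, i.e. more frequent, candidate). If a block has no complete
haplotype, the nearest other sample over mutually observed sites donates
per missing site; a sample with nothing observed in the block falls back to
per-site majority (logged). Observed calls are never altered, and the
operation is a no-op on complete matrices.

### Median-joining networks (ε = 0)

For binary haplotypes the quasi-median of three sequences is exactly their
per-site majority vector, so candidate Steiner vertices are majority
vectors of triples connected in the minimum-spanning network (the union of
all MSTs under Hamming distance; an edge of weight w belongs to some MST
iff its endpoints are disconnected using only edges of smaller weight).
A candidate is added only if it strictly reduces the total spanning length;
inferred vertices whose removal no longer increases the length are deleted
(this removes all degree-≤2 medians, by the triangle inequality); the loop
runs to a fixpoint and terminates because (length, vertex count) strictly
decreases lexicographically. Tie-breaking is lexicographic throughout, so
the network is deterministic. Only ε = 0 (the simplest network) is
supported. NEXUS export carries the observed haplotypes as a
standard-datatype character matrix plus a PopArt-style TRAITS block of
per-population counts, so the network is re-derivable from the file.

### csd diploid-male likelihood

An allele is the ordered call tuple over the designated non-synonymous
sites (annotation is an input; the package does not predict effects). For
a focal population,

    P(d) = Σ_{i=1..k} C(h_i, 2) / Σ_{i=1..K} C(h_i, 2)

with the numerator over the focal population's own counts and the
denominator over all K alleles with counts pooled across populations. The
pooled denominator is the default because it makes P(d) comparable across
populations; the literal within-population denominator is implemented
behind a flag but collapses to 1 for any focal population (every focal pair
appears in both sums), which is exactly the consistency check that
motivates the pooled reading.

## The synthetic-data generator

Discrete-generation haploid Wright–Fisher with two-parent reproduction and
a Poisson number of crossovers per offspring (mean = map length in
Morgans, positions uniform in bp; a uniform genetic map is emitted so iES
integrates over Morgans). Mutation flips alleles at a Poisson number of
random (individual, site) cells per generation. Demography: ancestral deme
→ split into African-like (A) and European-like (E) lineages → single
admixture pulse forming AHB (each parent drawn from E with probability
`admix_prop_E`, else A) → gAHB founded by `founder_size` haplotypes sampled
without replacement from AHB, growing by doubling up to the A-deme size,
with multiplicative viability selection (fitness `(1+s)` per favoured
allele) for `generations_post_invasion` generations. Selected loci are
drawn uniformly among sites whose AHB *minor* allele lies in the standing
window [0.05, 0.5] at founding, preferring sites where that allele is the
E-deme majority allele — the favoured allele is that standing allele, so
the planted sweeps both start from intermediate frequency and pull the
island population toward the outgroup profile, matching the scenario the
scan is designed for. An optional negative-frequency-dependent mode
(`csd_balancing`) down-weights carriers of common csd alleles to emulate
balancing selection.

Defaults (units: haploid individuals, generations, Morgans/bp): ancestral
and A demes 2,000; E deme 500 (a managed-apiary-sized outgroup);
`t_split`/`t_admix`/`t_invasion` = 150/165/205 with 12 post-invasion
generations; founder 300; admixture proportion 0.3; 2,000 SNPs on a 1 Mb
scaffold at 2.2 × 10⁻⁷ M/bp (22 cM/Mb, honeybee-scale recombination);
mutation 10⁻⁸. These are desk-scale stand-ins chosen once for qualitative
realism rather than demographic inference: deme sizes far below real
effective sizes are unavoidable in a forward simulator, but two failure
modes bound them from below. Very small demes leave so little haplotype
diversity that EHH never decays below threshold and iES stops being a
local statistic; and a severe founder bottleneck (tens of haplotypes)
inflates the focal population's background iES genome-wide until even a
completed sweep cannot exceed its own genome's background. The defaults sit
safely on the realistic side of both regimes. Ancestral variation is
initialised at linkage equilibrium with per-site frequencies ~U(0.05,
0.95) (options: fixed frequency, or a finite set of founder haplotypes);
LD therefore exists only where history put it — admixture tracts, the
founder bottleneck, drift and sweeps — which is the property the scan
exploits.

What the generator does *not* emulate: sequencing/calling error, the
16-chromosome karyotype (one scaffold suffices for the statistics),
variable recombination and mutation rates, colony structure and haplodiploid
mating (drones are treated as an unstructured haploid sample), and realistic
site-frequency spectra from mutation-drift equilibrium. Passing benchmarks
on these data show the estimators and their calibration behave as designed
under a known truth; they do not certify power on real genomes, where SNP
density, LD scale and demographic noise differ.

## Benchmarks and their honest limits

`evaluate.recovery_benchmark` plants five standing-variation sweeps
(s = 0.1, 12 generations) in the default scenario, scans 30/30/30 samples ×
2,000 SNPs, and scores a planted locus as recovered when some SNP within
±10 scanned positions lands in the F_ST ∩ Rsb outlier intersection.
`evaluate.null_outlier_rates` confirms each composite flags ≈1% of SNPs
when s = 0.

Twelve generations at s = 0.1 move a standing allele's odds by 1.1¹² ≈ 3.1
— a frequency displacement of ~0.2–0.3 — and spread the rise over several
haplotype backgrounds. With 30 samples per population, that puts selected
SNPs around the 90th–99th percentile of each composite, not reliably above
the 99th of both simultaneously: the intersection is a deliberately
conservative call set, and at this selection strength and timescale its
per-locus recovery probability is low (roughly 0.1–0.2). The recovery
benchmark reports this honestly; sweeps with s ≳ 0.3 are recovered readily
(see `examples/fst_permutation.py`, where a planted locus tops the θ
ranking). Statistically, brief weak selection on standing variation is
near the detection floor of haplotype-decay methods — which is precisely
why the scan triangulates rather than trusting any single statistic.

## Numerical conventions and degenerate inputs

- Missing calls use the sentinel −1; all per-site frequencies use
  non-missing denominators.
- MAF filtering is strict (`maf < threshold` drops), pooled across all
  samples; sites with no non-missing calls are dropped and logged.
- BED is 0-based half-open; VCF, GFF3 and the internal positions are
  1-based (gene BED input is converted on read).
- Quantile thresholds use linear interpolation; outlier calls are strict
  (`>`), so an all-ties score vector flags nothing.
- Permutation counts compare θ with exact float equality: identical counts
  reproduce θ bitwise, so no tolerance is needed.
- Monte-Carlo zero p-values are reported as `<1/n_perm` in CLI output and
  kept as 0.0 in arrays.
- Single-SNP scaffolds yield singleton blocks and zero iES (undefined Rsb),
  both handled and logged rather than raised.
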