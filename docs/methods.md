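# Methods

This note documents the models behind `parapop`, the defaults that matter,
the numerical conventions, and what the synthetic-data generator does and
does not emulate.

## The duplicated-gene setting

The package targets a pair of paralogues on a shared alignment frame: a
functional gene "A" sampled as n phased haplotypes from one population, and
a pseudogene "B" whose polymorphism may only be available as an external
frequency table. Non-allelic gene conversion between the copies acts like a
local homogenizing force; its suppression in a subregion lets fixed
differences between the copies accumulate there while each copy evolves
divergently. The analysis therefore revolves around (i) classifying sites by
coexistence across the pair, (ii) region-resolved diversity and
site-frequency-spectrum statistics, (iii) simulation-based significance
under realistic demography, and (iv) tree-topology diagnostics of concerted
evolution.

Coordinates are 1-based within the analysis frame; intervals are closed.
Columns containing gaps or N are excluded from nucleotide statistics
(complete deletion per column). Segregating sites below a configurable
minor-allele-frequency threshold can be excluded (the external pseudogene
table in the motivating setting was filtered at MAF < 0.01). Tri-allelic
sites count as polymorphic for classification; SFS statistics use the two
most frequent alleles.

## Site classification

With both paralogues on one frame, a position is

- `SHARED` if polymorphic in both copies,
- `SPECIFIC_A` / `SPECIFIC_B` if polymorphic in exactly one,
- `FIXED` if monomorphic in both but for different consensus bases,
- invariant otherwise.

B-side sites below the MAF threshold are demoted to monomorphic before
classification. The classification is symmetric under exchanging the two
copies (with the SPECIFIC labels swapped), and by construction
`SHARED + SPECIFIC_A = S_A` per region — an accounting identity the pipeline
surfaces end-to-end. Region contrasts of (fixed, shared, specific) counts
use Pearson's χ² without continuity correction and asymptotic p-values
(df = (r−1)(c−1)); this is deliberately the plain asymptotic test so that
published contingency p-values are exactly reproducible from printed counts.
The χ² power helper uses the standard noncentral formulation,
power = P(χ²_nc(df, λ = n·w²) > χ²_crit(df, α)); no attempt is made to mimic
any particular GUI tool's effect-size convention. Positional uniformity is
tested with a continuous one-sample KS against Uniform(0, L) plus a χ² over
300-bp bins (the window width), the terminal short bin's expectation scaled
by its length; the binning choice is ours and is configurable.

## Diversity and coding statistics

π is computed from site allele counts, Σ 2·Σ_{a<b}c_a c_b / (n(n−1)), divided
by the effective length analyzed; it equals brute-force pairwise comparison
weighted by haplotype multiplicities (a tested invariant). HHe uses Nei's
unbiased estimator with his sampling variance. Coding statistics follow
NG86 pathway counting: per-codon synonymous site fractions (mutations to
stop codons count as nonsynonymous — a documented convention), pathway
averaging that excludes stop-traversing paths when any stop-free path
exists, uncorrected within-sample π_A/π_S, and Ka/Ks versus an outgroup CDS
with Jukes–Cantor correction applied to the NG86 proportions (raw
proportions are emitted alongside, since cited tool chains differ on this
point). The McDonald–Kreitman table classifies in-sample segregating sites
and sample-vs-outgroup fixed differences as synonymous/nonsynonymous in the
consensus codon context and uses the two-sided Fisher exact test; the
neutrality index (Pn/Ps)/(Dn/Ds) is flagged undefined on zero margins.

## Neutrality statistics

All statistics are on the per-gene (total) scale, matching the magnitudes
printed by DnaSP/DH-style software.

- **Tajima's D** with the standard a₁…e₂ constants.
- **Fu's Fs**: S′ = P(K ≥ k_obs | θ = θ_π) under the Ewens sampling formula,
  computed as Σ_j |s(n,j)| θ^j / (θ)_n with exact-integer unsigned Stirling
  numbers of the first kind converted to logs; Fs = ln(S′/(1−S′)). k = 1
  gives S′ = 1 exactly and Fs = +∞ (flagged).
- **Fay & Wu's H** from the unfolded SFS, H = θ_π − θ_H; the identity
  H = 2(θ_π − θ_L) is enforced as a tested invariant. Polarization uses an
  outgroup aligned to the frame; sites whose outgroup base matches neither
  allele (or is a gap) are flagged unpolarizable and excluded from unfolded
  statistics while remaining available to folded ones.
- **Normalized H (nH)**: (θ_π − θ_L)/√Var with the published variance using
  θ̂ = S/a₁ and θ̂² = S(S−1)/(a₁² + a₂).
- **Ewens–Watterson**: observed homozygosity F = Σp̂ᵢ² against Monte-Carlo
  draws from the Ewens distribution conditional on (n, k): θ is solved from
  E[K | θ, n] = k by bisection and Chinese-restaurant samples are
  rejection-filtered to K = k. The lower tail (too-even haplotype
  frequencies) is the headline p-value; the upper tail is also emitted.
  The one-tailed conventions here are our documented choices.

## Coalescent simulator and rejection probabilities

Time runs backwards in generations. A demography is a contiguous epoch list;
within an epoch N(t) is constant or exponential, and waiting times are drawn
by inverting the cumulative pair-coalescence intensity ∫dt/(2N(t)), which is
closed-form in both cases — the simulator is exact, with no time
discretization. The packaged `european_default` model is: exponential decline
(looking backwards) from N_e = 10,000 at present to 1,861 at 840 generations
(21 kya at 25 y/generation), constant 1,861 to 2,040 generations (51 kya),
constant 10,000 before that. The bottleneck size and dates follow the
demographic literature for Europeans; present-day size, ancestral size and
generation time are not part of that specification and are exposed as
explicit parameters with the stated defaults.

The null for observed data conditions on S (the ms `-s` / mlcoalsim
convention): exactly S infinite-sites mutations are placed on the genealogy
with probability proportional to branch length. A θ mode (Poisson mutations)
exists for calibration. Rejection probabilities are one-tailed add-one
Monte-Carlo estimates, p = (1 + #{replicates ≤ observed})/(R + 1), lower
tail for D, Fs, H and nH. Conversion masking drops segregating sites inside
supplied tracts (defaults 624–634 and 3080–3186), recomputes all statistics,
and re-simulates the null at the reduced S.

Two calibration facts are worth stating because they are easy to
misremember. First, D and nH have intrinsically non-zero neutral
expectations (their variance estimates correlate with their numerators); at
n = 64 the neutral means are ≈ −0.11 and ≈ +0.08 respectively, reproduced
independently by msprime in the test suite. Second, fixed-S conditioning
adds a further small ratio bias (E[θ_π | S] < S/a₁), shifting the mean of H
to ≈ +0.3 at S = 44 even though H is exactly unbiased in θ mode. The test
suite asserts the true properties (θ-mode unbiasedness of S, θ_π and H;
agreement with msprime within Monte-Carlo error; 5% self-scored rejection
rate). Note also that in the packaged bottleneck+expansion model the
1,200-generation bottleneck dominates the post-glacial expansion at this
locus scale and shifts mean D positive relative to the constant-size null;
a growth-only demography shifts it negative (both are asserted as
qualitative properties).

No recombination is simulated within the locus by default (the motivating
region has a low crossover rate), and the null contains no non-allelic
conversion: available ms-lineage machinery models only allelic conversion,
so paralogue conversion is handled generatively by the synthetic module and
by tract masking, not mechanistically in the null.

## Sliding windows

Windows are nucleotide windows on the alignment frame (default 300-bp width,
30-bp step, partial final window dropped; a 3,357-bp frame gives 102 windows,
the last at 3031–3330). Windows report S, π, per-window D and H (computed
from the window's sites on the per-gene scale), and site-class counts.
Windows with no segregating sites report π = 0 but D and H as missing —
written as empty TSV fields, not zeros, to avoid spurious dips in plots.

## Trees and the BootScan-style signal

Distances are JC69, d = −(3/4)·ln(1 − 4p/3), over columns gap-free in every
sequence; p ≥ 0.75 is flagged saturated and set to a large sentinel.
Neighbor joining is the standard Saitou–Nei Q-criterion; a negative branch
in a joined sibling pair is clamped to zero with the deficit moved to its
sibling. NJ is exactly consistent on additive matrices (tested by
reconstructing path lengths). Bootstrap support resamples columns with
replacement and reports the percentage of replicate NJ trees containing each
original bipartition. The BootScan-style scan slides the window spec along
the frame and reports, per window, the percentage of bootstrap NJ trees in
which a designated sequence pair forms a cherry (a two-tip clade against all
other taxa) — pair monophyly is our generalization of the query-grouping
criterion of the original tool. Robinson–Foulds distances count bipartitions
present in exactly one tree, normalized by 2(t−3); the random baseline draws
uniform labeled topologies by sequential addition and reports the mean and
normal-approximation 95% CI half-width against a reference tree. NJ replaces
likelihood-based tree inference throughout: the downstream use is topology
comparison, for which the distance route is sufficient, and ML inference is
out of scope.

## MaxChi conversion scan

For an aligned pair, comparable (gap-free) positions form a match/mismatch
sequence. A window of 2k such positions slides along it; at each placement
the two halves are contrasted in a 2×2 match/mismatch χ². The maximizing
placement is the breakpoint candidate, its significance assessed by
permuting the match/mismatch sequence (destroying spatial structure while
preserving divergence) and comparing the observed maximum against the
permutation maxima, Bonferroni-multiplied by the number of reported
candidates (one per pair). The minimum conversion tract is the closed span
of the implicated segregating sites. The masking pipeline accepts externally
supplied tracts, so downstream reruns never depend on detection; only the
MaxChi-style scan is implemented (no GENECONV/3Seq/RDP-style detectors, no
donor/acceptor directionality).

## Synthetic-data generator

The generator plants structure directly rather than simulating two-locus
conversion mechanistically — the acceptance surface is exact recovery and
statistic behavior, not mechanistic realism; mechanistic neutral nulls come
from the coalescent module. Defaults emulate the motivating study's
conditions: a 3,357-bp frame split into a 282-bp intron-2-like subregion
(positions 624–905), a 1,488-bp coding block (906–2393) and 1,587 bp of
remaining non-coding sequence (exact exon boundaries are not reproduced —
the subregion lengths are, and the region map is an input); n = 64
haplotypes collapsing to 33 distinct variants; per-region class targets
(fixed, shared, specific-A) of (17, 1, 11) / (5, 3, 18) / (5, 6, 5);
a four-site conversion-tract landmark inside 624–634 and a six-site landmark
at 3080 and 3102–3186; four nonsynonymous coding sites arranged so the 33
variants encode exactly 6 proteins. Pseudogene-side specific-site targets
(2/8/5) and its sample size (n_B = 50, 15 distinct variants) are not printed
anywhere in the motivating material and are our realistic choices; so is the
outgroup divergence (12 synonymous + 4 nonsynonymous coding changes plus 30
non-coding changes), set to yield Ka/Ks and π_A/π_S comfortably below one as
in typical purifying-selection coding regions.

Haplotype multiplicities come from a deterministic skewed partition
(surplus halved repeatedly, then singletons), giving HHe ≈ 0.92 at the
defaults. Derived-allele counts are drawn from the neutral P(i) ∝ 1/i law —
or, in `sweep_skewed` mode, from a mixture with 80% of its mass within 8
copies of fixation, applied to the designated region — and realized greedily
as unions of whole haplotype classes (so a drawn target is approximated from
below by achievable class sums). The outgroup carries the ancestral allele
at every planted site, making polarization exact. A retry-on-subseed loop
enforces the hard constraints (distinct-variant count, protein count,
placement capacity) exactly; generation is deterministic given the seed.

What passing tests on this generator do show: the classifier, the SFS
machinery, polarization, masking, windows and the pipeline plumbing are
exact on data with known truth, and the statistics respond in the right
direction to planted high-frequency-derived excess. What they do not show:
robustness to homoplasy, alignment error, unphased or missing data,
recombination within the gene, or mechanistic conversion dynamics — real
data have all of these.

## Numerical conventions and edge cases

- Undefined statistics (S = 0, k = 1, zero denominators, unpolarizable
  regions) are NaN/flags, never silent zeros.
- Stirling numbers are exact integers before taking logs; Fs is computed
  entirely in log space and clipped at the S′ ∈ {0, 1} boundaries to ±∞
  flags.
- All Monte-Carlo machinery takes explicit seeds or Generator objects;
  the pipeline derives every stage from one seed, and equal seeds give
  byte-identical outputs.
- Ties in haplotype-spectrum ordering break lexicographically; consensus
  ties break alphabetically.
- Problem sizes used by the packaged checks: 10,000 replicates for the
  fixed-S calibration, 3,000 for demographic contrasts and pairwise-TMRCA
  checks, 100 seeds for generator-ordering properties, 1,000-and-under
  bootstrap/permutation counts in examples.
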