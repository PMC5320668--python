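# Methods

This note documents the statistical model, the inference procedure, the
synthetic-data generator, and the numerical and design choices behind
`epichain`.

## Observation model

Bisulfite treatment converts unmethylated cytosines to uracil (read as T
after PCR) and leaves methylated cytosines intact; conversion acts on
each strand's own cytosines. Reads are always considered in
forward-mapped orientation, so a read originating from the reverse
strand shows the complement of the converted reverse-strand base. Six
per-position epigenotypes {A, C, G, T, meC, meG} describe a fragment,
meG standing for a G whose complementary reverse-strand C is methylated.

Two error channels connect the epigenotype to the observed base. The
conversion channel has two rates: `alpha_fail`, the probability that an
unmethylated C escapes conversion (the configuration exposes the success
rate α, default 0.95, so `alpha_fail = 1 − α = 0.05`), and `beta`, the
probability that a methylated C is converted anyway (default 0.05). Both
defaults are deliberately conservative. The sequencing channel miscalls
a base with probability ε, uniformly over the other three bases; ε comes
from the Phred quality as `10^(−q/10)`, clamped to `[1e-6, 0.75]` — the
upper clamp keeps a quality-0 base from degenerating the emission
distribution, the lower keeps log-likelihoods finite. An observed N is
likelihood-neutral (probability 1 under every state).

With error-free reads from both strands, each of the six epigenotypes
produces a distinct (forward-read, reverse-read) base pair, so the state
is identifiable; from one strand alone, T (and several other bases) is
ambiguous — e.g. a forward-strand T can be a genomic T or a converted C.
This asymmetry is why strand assignments are estimated jointly with
everything else, and why the genotype prior is needed to break ties.

## Haplotype chains and feasibility

A haplotype chain is a set of reads plus one epigenotype sequence over
the union span of its reads. Chains must have positive read depth
throughout their range; depth is counted over read-*unit* spans, i.e. a
mate pair contributes its whole fragment interval including the
unsequenced insert. (Counting only sequenced bases would make a lone
paired unit with a positive insert gap infeasible, contradicting the
requirement that the all-singleton structure is always feasible.)

A chain is feasible if it can be built by adding one read at a time such
that each addition overlaps the existing chain by at least K₀ bp and the
overlap contains at least K₁ CpGs, K₂ isolated CpGs and K₃ isolated
GpCs. Overlap base pairs and site counts use the union of the mates'
*sequenced* intervals intersected with the chain range — a CpG-free
overlap carries no epigenetic evidence, however long the insert. A CpG
counts once per dinucleotide whose C lies in the overlap; a GpC is
counted at its G (5') position. Per-mode defaults: single-end WGBS
40/1/0/0, paired WGBS 50/2/0/0, NOMe 40/0/0/2.

Isolated sites use the standard nomenclature H = not G, D = not C: a CpG
is isolated in an HCGD context, a GpC in a DGCH context. N in the
flanking context, or a window edge, makes a site non-isolated.

## Posterior and priors

The posterior is `Λ(B,G,R) = π₀(B) · π₁(G|B) · L(B,G,R)` with the
likelihood a product of per-base emissions. `π₀(B) ∝ ∏ᵢ √L_{bᵢ}
(Σ_{j∈I_{bᵢ}} l_j)²` — a product over *reads*, each contributing its own
chain's factor — favors few, thick chains (the exponent on total read
length outweighs the one on chain length). `π₁(G|B)` weights every
position of every chain by q if the nucleotide projection of its state
(meC → C, meG → G) is the reference base or a known variant allele, and
1 − q otherwise; q defaults to 0.9999 and q = 0.5 disables reference
guidance. Without a variant file only the reference allele is "known";
an N reference base constrains nothing. The strand prior is uniform and
drops out. Normalization constants are ignored throughout; all
computation is in log space with exact zeros represented as −∞-like
large negative numbers.

## Optimal epigenotype chain (constrained Viterbi)

Given a chain's reads and strands, the optimal G maximizes the sum of
per-position emission scores plus the π₁ term, subject to strand
compatibility: meC must be followed by meG (a methylated CpG); in NOMe
mode meG followed by meC (a methylated GpC) is also permitted, and
pairing is *enforced* only at positions belonging to isolated CpG/GpC
dinucleotides — elsewhere lone methylated states are allowed, since
non-isolated sites cannot distinguish endogenous from enzymatic
methylation. These constraints are first-order, so the maximizer is
found exactly by a Viterbi pass over an 8-state expansion (each
methylated state split into pairs-right/paired-left variants),
implemented as a numba kernel. Positions covered only by an insert gap
are scored by the prior alone. Ties resolve deterministically by state
order.

## Optimization

Coordinate ascent starts from the all-singleton structure (each read its
own chain, strand chosen to maximize its own score, ties to forward).
Each pass sweeps reads in genomic order; for each read unit (a mate pair
moves as one unit) the candidate destinations are: stay, become a
singleton on either strand, join any feasible overlapping chain on
either strand, or re-attach to a remainder segment of its own chain.
Detaching a read may split its chain at a coverage gap; the detach is
allowed only if every resulting segment passes a feasibility re-check
(exact build-order search for segments of ≤ 10 reads, otherwise assumed).
The best strictly-improving move is applied (tolerance 1e-7); ties keep
the current assignment.

Single-read moves alone stall in two characteristic local optima, so two
further proposal types run after each sweep, both accepted only on exact
posterior improvement and both restricted to feasible results:

* **Chain merges** (pairwise, and whole overlap-clusters at once).
  Pairwise merges heal junctions that single-read moves cannot cross;
  cluster fusions escape "parallel thin chain" states — with many
  low-depth chains over the same interval, every pairwise merge is
  individually downhill (each thin chain has overfit the conversion
  noise of its few reads) while fusing them all gains large π₀ weight.
  Feasibility of a merged set uses the exact order search up to 10 reads
  and a greedy any-order build closure above that.
* **Chimera splits.** A chain that absorbed reads of two epi-alleles on
  its two sides is stable under read moves (each read agrees with its
  local states). The proposal cuts a chain at midpoints between
  adjacent methylation sites whose inferred state differs, partitions
  reads by span midpoint, and fuses each half with its best overlapping
  chain.

Every accepted move strictly increases Λ over a finite configuration
space, so the algorithm terminates; a pass limit (default 50) guards the
rare non-converged case with a warning. Because every structure visited
is feasible and scored identically to the exhaustive oracle,
`fit`'s final posterior can never exceed `brute_force_fit`'s.

`brute_force_fit` enumerates all set partitions of ≤ 6 reads, discards
infeasible blocks (no build order exists), optimizes strands per block
independently (the posterior factorizes over chains) and takes the exact
maximum. It exists purely as an independent check on small instances.

## Noise filtering and calls

The depth fraction of a chain is its total read bp divided by the read
bp of all chains whose ranges overlap it (itself included), with each
overlapping chain contributing only the base pairs that fall inside the
chain's range. The published description ("total base pairs overlapping
the chain") is ambiguous between this and counting overlapping chains'
full read lengths; the restricted reading is used because it compares
like with like (a true fraction of local coverage) and because the
full-length variant systematically under-scores island-spanning chains
whose flanks are crowded with short noise chains. A chain is kept iff
`a ≤ length + b·depth_fraction`; defaults a = 10000, b = 28500 (paired
WGBS; also reused for paired NOMe), a = 5000, b = 20000 (single WGBS).
Filtering is post-inference and never re-runs the fit.

Per position and chain, `l(x)` sums member reads' log emissions under
state x. The fit-ratios are `F = 2(max_{x∉{g,ḡ}} l − max_{x∈{g,ḡ}} l)`
for the inferred g, and `F_R`/`F_A` likewise for the reference /
alternative nucleotide y with its methylated partner when y ∈ {C, G}.
A chain contributes to the combined genotype at a position when
`F ≤ −15` or `|F_R − F_A| ≥ 15`; the combined genotype is the set of
nucleotide projections of the contributing chains (homozygous,
unordered heterozygous pair, or no-call; more than two alleles are
reported with all alleles listed). The methylation level at a CpG is
the fraction of covering reads (sequenced, non-N base) whose chain is
methylated there; zero informative coverage is a no-call.

In NOMe mode, each isolated GpC of a kept chain is accessible iff its
pair is methylated (M.CviPI only reaches open chromatin). The site
table reports both a chain-consensus and a read-consensus fraction;
inaccessible intervals are maximal runs of inaccessible isolated GpCs
within one chain, with end points at the midpoints toward the flanking
accessible sites (or the outermost run sites when no accessible flank
exists) — a deliberate convention, since only "approximate lengths" are
defined for such footprints.

## Simulator

The generator emulates the generative process the model inverts:
reference construction with controlled CpG/GpC placement (accidental
CGs are scrubbed so the realized CpG set is exactly the planted one;
planted sites get A/T flanks and are therefore isolated), 1–3
epi-alleles with per-CpG methylation, per-GpC accessibility and SNV
overrides, uniform fragment placement, uniform strand choice, categorical
sampling from the conversion table, and uniform-over-three sequencing
errors at the Phred-derived rate. Paired fragments are two mates of one
fragment on the same strand; the default fragment span is 2.5× the read
length (a typical WGBS insert). One seeded generator drives everything;
identical configs give bit-identical output. `empirical_conversion_rates`
closes the loop with method-of-moments estimates of `alpha_fail` and
`beta` from the truth records.

Benchmark scenarios fix the study conditions once:

* `asm_scenario`: 3 kb window, 30 CpGs as a central island at 28 bp
  spacing, paired 100 bp reads on 250 bp fragments, depth 20, α = 0.95,
  β = 0.05, Phred 30; two epi-alleles (fully methylated / unmethylated,
  frequency ½ each, one distinguishing SNV in the island) or one. The
  island geometry mirrors the regions where allele-specific methylation
  is studied — imprinted differentially methylated regions are CpG
  islands — and matters: at genome-average CpG density (~1/100 bp) the
  K₁ = 2 feasibility rule is marginal for 200 bp of sequenced footprint,
  and chains genuinely fragment, exactly as described for low-density
  regions in the field.
* `nome_scenario`: 1.5 kb window, isolated GpCs every 15 bp, one
  epi-allele accessible everywhere except a central 147 bp protected
  block, paired reads at depth 30.

What the simulator does *not* model — PCR duplicates, chimeric
fragments, mapping errors, context-dependent conversion rates,
position-dependent quality profiles, CpH methylation — bounds what
passing tests show: they validate the inference given the model's own
generative assumptions, not robustness to artifacts real libraries add.

## Problem sizes and numerics

The test and acceptance workloads use windows of 80 bp–4 kb and tens to
hundreds of read units per window, sizes at which the full pipeline runs
in well under a second to a few seconds per window; exhaustive oracles
are restricted to ≤ 6 reads / ≤ 120 bp (partition enumeration) and
L ≤ 6 (6^L state enumeration). Score matrices are cached per chain and
candidate moves are scored by a fused kernel without materializing the
merged matrix. Strict-improvement tolerance is 1e-7 on log-posteriors of
magnitude 10²–10⁴; oracle-equality comparisons use 1e-6.

## Known limitations

Windowed operation only; chains are never merged across windows.
Uncertainty beyond the fit-ratios (e.g. posterior over B) is not
quantified. The optimizer is deterministic ascent: global optimality is
checked only on small instances, and on adversarial data the final state
can be suboptimal (the pass limit warning marks non-convergence). The
conversion rates are global per run, not position- or context-dependent.
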