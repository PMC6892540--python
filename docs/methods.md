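# Methods

This note records the models, conventions and design choices behind
`chronograft`, in the order the pipeline uses them.

## The backbone-and-patch model

A complete timetree over `S` species is assembled from (i) a posterior
sample of dated backbone trees over a small set of representative tips
(one per patch clade, plus out-group and free lineages), and (ii) for each
patch clade, a posterior sample of ultrametric trees in *relative* time
(clock rate fixed, root depth normalized to 1) containing the in-group
species and one out-group tip. The two levels are glued at the single node
they share — the out-group/in-group split. For posterior index `i`:

1. locate, in backbone sample `i`, the MRCA of the patch's representative
   tip and its out-group counterpart; its age is the patch's *root time*
   `T` (Ma);
2. in patch sample `i`, the ratio `ρ = crown age / root age ∈ (0, 1]` is
   the relative scale of the stem edge; the absolute in-group crown age is
   `T·ρ`;
3. the out-group and any placeholder taxa are pruned from the patch, whose
   branch lengths are divided by the in-group crown height and multiplied
   by `T·ρ`;
4. the representative's pendant edge is cut at age `T·ρ` and the rescaled
   in-group crown is bound there, replacing the representative.

Anchor ages are always measured on the unmodified backbone sample, so
grafting order is immaterial, backbone node ages are conserved exactly,
and topological variation across backbone samples is honoured because the
anchor node is re-located per sample. Patches estimated with a distant
out-group are instead anchored to a named backbone node whose age is taken
as the crown age directly (`rescale_mode="crown"`); with `ρ = 1` the two
modes coincide. A guard raises an error (rather than clamping) if an
absolute crown age exceeds the representative's pendant edge span, since
`ρ ≤ 1` makes that impossible for a correctly specified plan.

Assumptions: both levels are clock trees (ultrametric within a relative
tolerance of 1e-6); patch in-groups are disjoint; sample `i` of every set
is treated as one joint draw (index pairing). After assembly, tip depths
are renormalized to their mean — a float-drift correction bounded by the
ultrametricity tolerance that never alters topology.

## Calibration and clock priors

Fossil node calibrations are either uniform on `[min, max]` or
offset-exponential with a soft maximum: `offset = min` and
`mean = (max − min)/(−ln 0.05)`, the unique exponential scale putting 95%
of the prior mass below the maximum. The printed form of that formula,
`(−ln[0.05]/[max − min])^(−1)`, is algebraically identical; the package
stores the scale in Ma. The birth–death clock-rate prior for a backbone of
expected root-to-tip depth `D` Ma is lognormal with `mean = ln(1/D)` and
`sd = e^(1/D)` — one expected substitution per site across the tree depth.
The sd expression is reproduced as specified (its value is ≈ 1.003 for
`D = 318`); no reinterpretation is attempted. Diversified-sampling runs
carry `ρ = n_sampled/n_total`, reported to 3 significant figures.

## Constraint generation for DNA-missing species

Within a patch, every internal node of the guide topology becomes a hard
constraint (including poorly supported nodes — the guide is enforced in
full). Every DNA-missing species receives one partial constraint whose
in-set is the least inclusive guide clade spanning the sampled members of
its target rank (genus for type 2, family for type 3, order for type 4)
plus the species itself; the out-set is the rest of the patch in-group.
A wholly unsampled genus is routed to an explicitly assigned family-level
clade. Two conventions the constraint language does not dictate: the patch
out-group representative is excluded from all out-sets (its position is
already fixed by the in-group hard constraint), and constraint names are
deterministic (`c_<target>_<ordinal>`) so emitted files are reproducible
byte for byte. Missing species whose rank target has no sampled member
visible in the guide are a hard error listing the species — placing them
would require a configured sibling-clade target.

## Posterior summaries

Burn-in/combining retains the **last** `retain_per_run` samples per run
after discarding `floor(burnin_frac·n)` leading samples; this makes the
retained count deterministic when `burnin_frac·n` is fractional (e.g.
3,333 samples at 25% burn-in retain exactly 2,500). The MCC tree is the
posterior *sample* maximizing the sum of log clade frequencies over its
non-trivial clades, reported with its own node heights — annotating
averaged heights onto a consensus can produce negative branches. Ties
break to the lowest sample index. HPD intervals use the shortest
contiguous window of the sorted samples containing `⌈mass·N⌉` points.
Note a finite-sample property verified empirically during development:
the shortest-window estimator is slightly anticonservative (coverage
≈ 0.93 at `N` in the hundreds for a nominal 0.95), which is why the
coverage acceptance band is two-sided and the calibration test uses
posterior sets of several hundred samples. Node-age summaries for a clade
are computed only over samples that recover that clade, with the recovery
fraction reported; a never-recovered clade is an explicit no-data result.
Both HPD and symmetric percentile intervals are provided since either
convention appears in published node-age tables.

## Tip-level speciation rates

`TipDR_i = 1/Σ_j l_j (1/2)^(j−1)` over the `N_i` edges from tip `i` to the
root, pendant edge first. Computed for all tips in one preorder pass via
`A(child) = l(child) + A(parent)/2`. The statistic assumes a fully
bifurcating tree (polytomies and unary nodes on the path are a hard
error) and should be computed on extant-complete trees; fossil tips must
be pruned first. Per-species summaries across a credible set use the
harmonic mean — the natural average for a rate whose reciprocal (the
equal-splits measure) is the additive quantity — and an empirical 95% CI
from the 2.5/97.5 percentiles across samples. Clade-versus-background
comparisons use the two-sided Mann–Whitney U on per-species harmonic
means; skewness is the adjusted Fisher–Pearson estimator. Cross-study
comparisons match species by exact binomial and report the Spearman rank
correlation plus the fraction of one study's top 1% recovered in the
other's top 1%.

## Fossil cross-checks

Occurrence tables follow Paleobiology Database export semantics: rows
flagged as ichnotaxa or with uncertain genus assignments are excluded,
then genus-level maxima are taken and the oldest genus per clade is the
"fossil stem maximum". A zombie-lineage flag fires when a molecular
crown-age interval lies strictly below a fossil-implied crown minimum;
the magnitude is reported conservatively from the HPD upper bound, with a
mean-anchored magnitude alongside when a posterior mean is supplied,
because published statements of such conflicts anchor on either.

## Synthetic data: what it emulates and what it does not

`simulate_bd_tree` draws a forward birth–death process from a crown of two
lineages, conditioned on survival, stopping one exponential holding time
after the extant count first reaches `n` (the memoryless stopping that
gives the pure-birth expected crown age `Σ_{k=2..n} 1/(kλ)`, which the
test suite checks against 1,000 replicates). For `μ > 0` this simple
conditioning is an approximation to sampling among all histories with `n`
survivors; the package uses it as a test-data generator, not as an
inference tool. Default study conditions: λ = 0.25/Ma, μ = 0.1/Ma
(mammal-like net diversification with moderate turnover), 64 tips, four
patches, ~30% of species DNA-missing, credible sets of 100 samples, 5%
age jitter.

`decompose_scenario` inverts the graft exactly: patches are disjoint
clades (smallest-first greedy selection), the backbone is the true tree
pruned to representatives plus free tips, and each patch tree is the true
crown subtree plus an out-group tip at the true stem-node age, normalized
to unit root depth. With zero jitter, grafting reproduces the true tree to
1e-6 — the pipeline's master oracle.

Pseudo-posteriors emulate posterior *spread*, not MCMC: node ages are
re-expressed as parent-relative ratios `r ∈ (0, 1)`, each perturbed as
`r^exp(σe)` (order-preserving for any displacement, no truncation), the
root age multiplicatively. Each set draws one run-level anchor
displacement per node plus independent per-sample displacements of the
same scale, so the generating truth deviates from the set's centre
exactly like one more sample and 95% HPD coverage of true crown ages is
close to nominal (the acceptance band 95% ± 3% absorbs the shortest-window
estimator's finite-sample narrowness). Topological uncertainty,
autocorrelation, and between-run disagreement are *not* emulated, so
passing tests say nothing about convergence diagnostics on real chains.

Taxonomies are built by cutting the true tree at genus/family/order age
thresholds; the DNA-sampling gap is seeded to include one wholly
unsampled genus and family when the budget allows, so all four sampling
types occur. Desk-scale imputation attaches each missing species within
its placement clade, choosing the edge with probability proportional to
edge length and the height uniformly along it — the constant-rate
birth-process expectation for where an unobserved lineage attaches, and a
deliberate stand-in for the engine's constrained joint estimation. Its
unbiasedness is itself a tested property (imputed and sampled species'
median tip rates indistinguishable at n = 200 samples, with wider CIs for
imputed species). Occurrence tables Poisson-sample fossils along branches;
alignments are structural gap-pattern fixtures with no substitution model,
sufficient for the QC and concatenation logic they exercise.

## Numerical conventions and degenerate inputs

* Ultrametricity: relative tolerance 1e-6 on tip-depth spread; zero-depth
  trees are ultrametric by definition.
* Sequence-length rule: strictly greater than 200 ungapped bases; ties in
  length break by input order, making the filter deterministic and
  idempotent.
* Stop-codon screen: codons read in alignment coordinates from the frame
  offset; codons containing gaps or ambiguities are skipped; a stop in the
  final complete codon is terminal, not internal.
* Singleton patch in-groups have no crown: the graft degenerates to
  relabeling the representative tip, flagged on the patch scale record.
* Pruning keeps the original root even if it becomes unary, so retained
  tips keep their root-to-tip depths; assembled trees are always binary
  because the pipeline's backbones retain tips on both sides of the root.
* Problem sizes in the test suite (48–64-tip trees, 200–400-sample
  pseudo-posteriors, 200-seed calibration sweeps, 1,000-replicate
  simulator checks) were chosen as the smallest scales at which the
  statistical checks have useful power.

## Known limitations

* The graft engine requires identical tip sets across samples within each
  tree set; reconciling heterogeneous posteriors is out of scope.
* Negative constraints exist in the data model but no rule generates them
  automatically.
* `max_stem_age` trusts the occurrence table's clade assignments; no
  cladistic placement of fossils is attempted.
* The MrBayes-dialect emitters cover the constraint/calibration/prior
  statements the pipeline needs, not the full command language.
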