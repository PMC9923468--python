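# Methods

## The inference problem

A survey collects up to ~10 colonies of a broadcast-spawning coral from each
of a few dozen patch reefs, with reefs grouped into regions by oceanography
(separations of 1–14 km within regions, 40–55 km between). Each colony
contributes a consensus whole mitochondrial genome (~18.5 kb) assembled from
short reads; uncalled positions appear as `N`, and the multiple alignment may
contain gaps. Because the mitogenome is a single non-recombining locus,
identical sequences mark recent maternal kinship, and the spatial arrangement
of identical (or nearly identical) genomes carries information about larval
dispersal at scales conventional F-statistics cannot resolve.

The package asks two separable questions of such data:

* **Regional structure** — do divergent mitochondrial clades occur at
  different frequencies in different regions? (AMOVA Φ statistics,
  per-haplogroup chi-square homogeneity.)
* **Local retention** — do highly similar genomes co-occur on the *same
  reef* more often than random placement predicts? (co-occurrence statistic
  with a constrained permutation null.)

## Distances and identity

All sequence comparisons use **pairwise deletion**: a site contributes to a
pair only when both members carry a called base (A/C/G/T). `N` and `-` are
both "not called". The distance d_ij is the raw count of differing jointly
called sites; the jointly called count C_ij is kept alongside so fractions
can be reported. No substitution-model correction is applied — within-survey
divergence is far below 1%, where multiple hits are negligible. Pairwise
deletion is essential rather than cosmetic: with ~50 uncalled bases per
genome, complete-case deletion would make "identical genomes" unobservable.
The cost is that d need not satisfy the triangle inequality and identity
(d = 0) need not be transitive; both are documented behaviours, and
non-transitive identity components are logged when they occur.

IUPAC ambiguity codes other than N are rejected at parse time: haploid
consensus calls should not contain them, and silently remapping them would
hide upstream assembly problems.

## Haplogroups

1. **Identity clustering.** Build the graph on colonies with an edge where
   d = 0 and take connected components. Components with ≥ 2 members are
   candidate groups; size-1 components are provisional singletons.
   Components are the defined resolution of non-transitive identity (kept
   whole, logged).
2. **Labels.** Groups are numbered 1..G by decreasing core size, ties broken
   by the lexicographically smallest member id — assignments are invariant
   to input order, labels included.
3. **Consensus.** Per-column majority base over core members (ties broken in
   A<C<G<T order; `N` where no member is called). The clustering step never
   needs a consensus, but folding does.
4. **Folding.** A singleton at distance 1 from exactly one group consensus
   becomes a `folded` member of that group; at distance 1 from several, it
   goes to the group with the largest core (ties to the lowest label) and
   the ambiguity is logged. Distance-1 is measured to the consensus
   regardless of whether the variant allele occurs elsewhere in the dataset;
   the stricter "allele unique in dataset" reading is computed and logged
   but not enforced, because enforcing it would silently drop legitimate
   recurrent variants. Everything else is `ungrouped`.
5. **Strict mode.** The same analysis restricted to exactly identical
   genomes: only core members of multi-member groups keep labels; folded
   colonies and singletons become ungrouped (they still occupy reef slots in
   permutation tests but contribute no pairs).

## AMOVA and Φ statistics

Sums of squares use the haplotypic convention for sequence data: the squared
inter-individual distance is the difference count itself, δ²_ij = d_ij
(`squared=True` switches to d², for sensitivity checks). For a colony set S,
SS(S) = (1/|S|) Σ_{i<j∈S} δ²_ij, partitioned into within-reef, among-reef-
within-region and among-region strata. Variance components σ²_c (within
reefs), σ²_b (among reefs within regions), σ²_a (among regions) solve the
expected-mean-square equations of the unbalanced three-level nested design
with the standard coefficients

    n1 = (N − Σ_g Σ_{p∈g} n_p²/N_g) / (P − G)
    n2 = (Σ_g Σ_{p∈g} n_p²/N_g − Σ_p n_p²/N) / (G − 1)
    n3 = (N − Σ_g N_g²/N) / (G − 1)

(N colonies, P reefs, G regions, n_p colonies on reef p, N_g in region g).
Φ_RT = σ²_a/σ²_T, Φ_PR = σ²_b/(σ²_b+σ²_c), Φ_ST = (σ²_a+σ²_b)/σ²_T are
computed from the **raw** component estimates, which may be negative;
percent-of-total columns truncate negatives at zero so percentages sum
to 100. Degenerate designs degrade rather than fail: one reef per region
fixes σ²_b = 0 (Φ_PR undefined, Φ_ST = Φ_RT); a single region drops the
regional stratum (Φ_RT not applicable); an all-identical dataset reports
zero components with Φ flagged undefined instead of NaN.

Permutation p-values (one-tailed, (1 + #{Φ* ≥ Φ_obs})/(B + 1)): whole reefs
among regions for Φ_RT (reef counts per region preserved), colonies among
reefs within their region for Φ_PR, colonies among all reefs for Φ_ST.

Per-haplogroup regional homogeneity uses a chi-square of observed regional
counts against expectations proportional to regional sampling totals, with
Benjamini–Hochberg correction across groups (Bonferroni available); rows
with any expected cell below 5 are flagged, since small groups make the
asymptotic p conservative at best.

## The co-occurrence test

Observed statistic (default "pairs"): Σ over (group g, reef r) of
C(k_gr, 2), where k_gr counts labelled members of g on r. An "instances"
reading, Σ max(k_gr − 1, 0), ships behind a flag. A second statistic counts
**rare** groups (2–10 members inclusive, configurable) having at least one
same-reef pair — rare groups are where chance co-location is least likely,
so this is the most sensitive summary.

The null holds fixed everything except geography: group memberships, the
group-size spectrum and the number of colonies per reef are preserved while
the reef-label multiset is permuted uniformly over colonies. Ungrouped
colonies keep occupying slots. p = (1 + #{null ≥ observed})/(B + 1), B =
1000 by default. Conditionally on the labels, this test is exact whenever
colony-to-reef assignment is exchangeable.

That conditional-exactness caveat matters for calibration. The permutation
null is exchangeability across *all* reefs; a process that concentrates
certain haplotypes in certain regions violates it even with zero natal-reef
retention, and the test will (correctly) reject — it detects spatial
structure of any scale, while Φ_RT and the chi-square isolate the regional
part. The type-I calibration test therefore simulates the exchangeable null
(retention 0 **and** no regional frequency weighting); under the default
generator with regional clade weighting the rejection rate at retention 0 is
elevated by design, not by error.

## Synthetic surveys

Scale defaults reproduce the study design the generator emulates: 7 regions
holding (6,6,6,6,5,5,5) reefs, 5–10 colonies per reef (~290 expected),
L = 18,482 bases.

* **Founders.** 31 haplotypes on a two-level genealogy: a root sequence,
  2–6 private mutations per founder on globally disjoint sites (so founder
  distances are sums of private counts, ≥ 4, and can never collide with the
  single-base folding rule), and a 5-founder divergent clade carrying a
  shared block of ~0.2% · L mutations — matching the observed inter-clade
  divergence that dates to ~2 Myr at 0.1%/Myr.
* **Frequencies.** One symmetric Dirichlet(α = 0.3) draw over founders gives
  the long-tailed size spectrum (largest class ≈ 55 of ~290 on average, a
  distributional property checked over 50 seeds). Divergent-clade
  frequencies are multiplied by 3 in the first 2 regions and renormalised,
  emulating a minority clade commoner in some regions — this induces
  Φ_RT > 0 in expectation; setting the weight to 1 removes it.
* **Retention.** Reefs fill sequentially; each colony copies the (possibly
  mutated) haplotype of a uniformly chosen earlier colony on the same reef
  with probability ρ, otherwise draws a founder from the regional spectrum.
  Default ρ = 0.2, the natal-reef recruitment fraction used by stepping-stone
  adaptation models for corals. This is the minimal mechanism that produces
  excess same-reef identity without regional haplotype clustering; it is not
  a larval-transport matrix.
* **Mutation.** With probability 0.11 per colonization (≈ the observed
  folded fraction, 31/284) the transmitted haplotype gains one uniform
  single-base change, creating the folded-variant class and, when copied
  onward, occasionally new derived cores.
* **Missing data.** i.i.d. per site per colony at 0.00265 (≈ 49 N's per
  genome). Clustered missingness (e.g. low-coverage windows) is out of
  scope.

Ground truth records each colony's founder lineage; recovery is scored as
pair-level precision/recall of co-membership. With mutation and missingness
off, identity clustering recovers the founder classes exactly.

What the generator does **not** emulate: within-reef spatial positions,
temporally structured sampling, coverage-dependent missingness, selection,
and oceanographically realistic transport. Passing tests therefore show the
statistics behave correctly under the stated mechanism, not that real reef
systems satisfy that mechanism.

## Rate arithmetic

Rates are **pairwise** divergence accumulation in percent per Myr:
divergence_time = pct / rate, and the expected wait between mutations
anywhere on an L-base genome is 1/(L · rate_per_site_per_year) with
rate_per_site_per_year = (rate/100)/10⁶ — e.g. 18,642 bases at 0.1%/Myr
wait ≈ 53,600 years. The per-lineage convention (half the pairwise rate per
lineage) is available via `per_lineage=True`.

## Numerical and testing choices

* Distances are computed over polymorphic columns only (monomorphic columns
  cannot contribute mismatches), with jointly-called counts from a sparse
  uncalled-overlap product — exact, and fast enough that hundreds of
  simulated datasets run in minutes on one CPU.
* Permutation p-values always use the +1 correction, so p ∈ (0, 1].
* AMOVA components are validated against an independent brute-force
  expected-mean-square solve (explicit pair loops, 3×3 linear solve) to
  1e-10 on small designs; permutation nulls against exhaustive enumeration
  of all reef relabellings for ≤ 8 colonies.
* Simulation problem sizes in the test suite: type-I calibration uses 200
  datasets at B = 200; retention monotonicity 200 datasets per ρ ∈
  {0, 0.25, 0.5}; spectrum checks 50 seeds. These sizes give comfortable
  margins on the assertions while keeping the full suite to a few minutes.
* All randomness flows through `numpy.random.Generator`; the CLI splits one
  top-level seed into per-stage seeds via `SeedSequence` and records them in
  the run manifest.

## Known limitations

* Identity under pairwise deletion can merge genuinely distinct genomes when
  missingness is heavy; components and logs surface this, but the resolution
  is the graph component, not a probabilistic genotype model.
* The AMOVA permutation tests treat reefs/regions as fixed strata; very
  small designs have few distinct permutations and correspondingly coarse
  p-values (a warning fires below B = 99).
* Reef-pair regressions treat pairs as independent observations, as is
  conventional; the Mantel-style permutation option is the honest
  alternative when that worries you.
* The co-occurrence test conflates all spatial scales of non-exchangeability;
  interpret it jointly with Φ_RT and the per-group chi-square, which isolate
  the regional component.
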