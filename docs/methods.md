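# Methods

`endosyncom` models a plate-based screening campaign for culturable plant
endophytes: how a host secondary metabolite (a triterpenoid mixture) shifts
each strain's growth, how strains affect one another in co-culture, which
plant-growth-promotion traits (PGPT) they carry, and what defined synthetic
communities (SynComs) assembled from them do to the host plant in pots.
Because raw assay tables for such campaigns are rarely deposited, the package
pairs every analysis stage with a synthetic-data generator that plants known
ground truth, so each stage is testable end to end.

## Reference panel

The default catalog is a 53-strain panel from a *Schisandra sphenanthera*
endophyte collection: 27 bacteria (7 Firmicutes, 5 Bacteroidetes,
4 Actinobacteria, 11 Proteobacteria) and 26 fungi (17 Ascomycota,
7 Basidiomycota, 2 Zygomycota), carried as genus + isolate code.  Two notes
on the source records: one isolate code was printed twice (both a
*Brevibacterium* and a *Rhizobium* as SLB15), so the *Rhizobium* isolate is
carried under the unused code SLB16; and the prose arithmetic accompanying
the screen implies slightly different per-phylum multiplicities (8 Firmicutes
/ 3 Actinobacteria; 15 Ascomycota / 6 Basidiomycota) than the printed strain
table.  The catalog follows the printed table.  The reference promoted
shares per phylum (4/5 Bacteroidetes, 5/7 Firmicutes, 0/4 Actinobacteria,
4/11 Proteobacteria; 8/17 Ascomycota, 3/7 Basidiomycota, 0/2 Zygomycota)
reproduce the screen's headline totals either way: 13 promoted / 14
inhibited bacteria (TPB/TNB) and 11 promoted / 15 inhibited fungi (TPF/TNF).

## Dose–response model and classification

Growth is logistic, `N(t) = K·f0 / (f0 + (1 − f0)·e^{−rt})`, with
strain-specific rate `r` (bacteria 0.15–0.35 h⁻¹, fungi 0.5–0.9 d⁻¹),
carrying capacity `K` (bacteria 0.8–1.4 OD600, fungi 0.5–1.5 g), and the
inoculum standardized at `f0 = 1%` of capacity — the assay's strain-specific
dilution step justifies scaling the inoculum with the strain.  The compound
acts multiplicatively on capacity only.  Both choices serve one identity:
every time point is exactly proportional to `K`, so a planted capacity
factor *f* yields an endpoint log2 fold change of exactly log2 *f* in the
noise-free limit, which the null-pipeline and round-trip tests exploit.

Concentrations default to 0 (solvent control), 20, 50, 100 and 250 µM with
five replicates.  Endpoints are OD600 at 48 h (bacteria) and fresh mass at
day 12 (fungi); earlier time points are carried but not scored.  log2FC is
referenced to the mean solvent-control endpoint; an `initial` baseline
(each culture's own t₀ value) is available since endpoint-vs-inoculum is the
other defensible reading of a "relative to initial value" convention.

Classification: mean log2FC over the 100/250 µM decision concentrations,
one-sample t test against zero at α = 0.05 (no multiplicity correction),
sign of the significant mean decides promoted vs inhibited; an inconclusive
test falls back to the sign of the grand mean over all concentrations, and
an exactly zero grand mean is labelled inhibited (conservative).  With zero
replicate variance the t statistic degenerates; any nonzero mean is then
decisive.  Planted effect factors place promoted strains at 1.45–1.70 and
inhibited strains at 0.45–0.68 at the decision concentrations (half the
inhibited strains get a slight low-dose boost, a shape seen in real panels),
±15% per-strain jitter — far enough from 1.0 that label recovery at the
simulated 5% noise is essentially complete.

## Interaction indices

Three geometries, all scored as percent fold change of a target's growth
under an actor relative to mono-culture control (II < 0 inhibition,
II > 0 facilitation):

* bacterium→bacterium V-shape:
  `II = [(D25-EA/D10-EA)/(D25-CA/D10-CA) − 1]·100`, with colony diameters
  read 25 and 10 mm from the V on experiment and control plates;
* fungus→fungus dual culture: `II = (S-EA/S-CA − 1)·100` on colony areas;
* bacterium→fungus streak: the same form on fungal colony diameters.

Replicate IIs are averaged per ordered pair (mean of per-replicate IIs, not
II of mean measurements, three replicates by default); self-pairs are kept
in raw tables but excluded from aggregation.  Image analysis is out of
scope — areas and diameters arrive as numbers.

Generator convention for the V-shape: the planted effect lands on the near
(10 mm) experimental colony as `D10-EA = D10-CA/(1 + e)`.  Multiplying the
near colony *by* (1 + e) would give `II = −e/(1+e)·100` under the
ratio-of-ratios formula; dividing keeps the biological intent (the closer
colony shows the neighbour's effect) while making the index recover exactly
`e·100` at zero noise, which the recovery tests require.  Planted effects
are drawn at |e| ∈ [0.05, 0.6] with facilitation more likely within
kingdoms (p = 0.55–0.75) than from bacteria onto fungi (p = 0.25–0.35),
and promoted targets slightly favoured — the community-dominance pattern
the received-effect comparison is designed to detect.

## Trait quantification

Linear standard curves (ordinary least squares, R² reported) back the
Salkowski IAA assay (535 nm, default latent slope 0.012 L/mg), Mo–Sb
phosphate (720 nm, 0.006), and the four plant-metabolite assays.  Linearity
is assumed because all cited colorimetric chemistries are linear in their
working ranges.  Inverse prediction is `(A − intercept)/slope`, floored at
zero, flagged when outside the standard range.  Replicate absorbances are
averaged before a single inverse prediction: flooring each replicate
separately would bias blank-level readings upward.  DPPH scavenging is
`(A_ctrl − A_sample)/A_ctrl·100`; siderophore output stays in
blank-referenced CAS absorbance units (the assay has no canonical standard
analyte; reported mg/L values for siderophores in comparable screens are
unit-ambiguous), with an optional user curve for conversion.

Ability counting uses detection-limit cutoffs, all overridable: IAA
> 5 mg/L and phosphate > 10 mg/L (blank + 3·SD at a typical 0.02 absorbance
noise, i.e. 3 × 0.02/slope), siderophore > 0.05 absorbance units (same 3·SD
rule), DPPH > 50% (the common half-scavenging criterion).  A strictly-zero
IAA cutoff would let any noise promote a true non-producer half the time.
Planted trait levels are kept away from the cutoffs (producers at ≥ 2× the
cutoff, non-producers at zero) so planted ability counts are unambiguous at
the simulated noise.

## SynComs and pot evaluation

Membership is rule-based: CK = ∅, AB = all bacteria, AF = all fungi,
ABF = AB ∪ AF, TPB&TPF = all promoted, TNB&TNF = all inhibited; the last two
partition ABF.  Pot arms have 3 pots × 3 plants; growth phenotypes are
direct measurements, chlorophyll comes from A645/A663 with Arnon-type
coefficients (20.2, 8.02 — config defaults, since the assay convention
varies) and the 0.2 g / 8 mL extraction, metabolites from assay absorbances
through their curves and the 1 g / 50 mL extraction bookkeeping.  Percent
changes are emitted against both CK and ABF for every arm; AB/AF/ABF are
interpreted against CK, the class-restricted communities against ABF.
Letters come from one-way ANOVA plus Duncan's multiple range test (Fisher's
LSD available).

Planted pot effects default to the reference campaign's reported percent
changes (e.g. +115.00% root length for ABF vs CK, +203.98% for TPB&TPF vs
ABF, −42.18% chlorophyll for AF — the fungus-only arm's wilt proxy,
+240.54% total triterpenoid for TPB&TPF vs CK); vs-ABF contrasts are
composed onto the CK scale multiplicatively.  Dry-weight and most
chlorophyll effects are not reported numerically anywhere and are set to
plausible values consistent with the reported ordering (e.g. ABF +60%,
TPB&TPF +90% vs ABF on dry weight).

## Noise model and numerical choices

Plate and phenotype measurements get multiplicative log-normal noise
(`×e^{N(0,σ)}`, keeping everything strictly positive): σ = 0.05 for growth
and plate assays, σ = 0.1 for pot phenotypes.  Absorbances get additive
Gaussian noise truncated at zero, σ = 0.02.  All generators take explicit
seeds (default 42) and are byte-deterministic given seed and parameters;
the orchestrator derives child seeds from one master seed.

Rank tests: unpaired contrasts use the rank-sum (Mann–Whitney) form even
where a screening write-up would say "Wilcoxon signed rank" — signed-rank is
undefined for unpaired, unequal groups.  The exact two-sided p enumerates
all C(n, n₁) group assignments (midranks for ties) for combined n ≤ 12;
larger samples use the tie-corrected normal approximation.  Groups of one
yield p = NA with a warning.  Duncan's test uses studentized-range critical
values at protection levels `1 − (1−α)^{p−1}` with step-down shielding and
the harmonic mean group size; the compact letter display assigns letters to
maximal cliques of the nonsignificance relation, ordered by descending
mean.  All-identical groups short-circuit to p = 1 / a single shared
letter; zero within-group variance everywhere falls back to letters by
exact mean ordering, with a warning.  Two-sided tests throughout, no
multiplicity correction.

## What the generator does and does not emulate

It emulates endpoint-level consequences of the planted truth: capacity-
scaled logistic growth, distance-dependent neighbour effects collapsed to
one multiplicative factor, linear colorimetry, and arm-level phenotype
shifts.  It does not emulate spatial colony morphology, growth-rate (as
opposed to capacity) effects, compound degradation over time, non-linear or
saturating standard curves, inter-plate batch effects, pathogen dynamics
beyond the planted negative chlorophyll effect for the fungus-only arm, or
microbe–microbe interactions inside pots (arm effects are planted directly,
not composed from pairwise IIs).  Passing recovery tests therefore show the
*scoring pipeline* is correct and well-conditioned at realistic noise — not
that real campaigns are free of the unmodelled effects.

A note on panel bookkeeping: a full directed screen over this panel is
27·26 + 26·25 + 27·26 = 2054 ordered pairs; reported totals for comparable
campaigns differ because panel subsets vary, so panel sizes stay parameters
throughout.

## Problem sizes

Default simulations are sized like the campaign they emulate (53 strains,
5 concentrations × 5 replicates, ~2000 directed pairs × 3 replicates,
6 arms × 9 plants), which keeps a full pipeline run and the whole test
suite in the tens of seconds on one core; the rank-test power check uses
1000 simulated panels of n = 25/25.

## Known limitations

Percent-change recovery for very large planted arm effects is limited by
sampling noise, not by the estimator: at σ = 0.1 and nine plants per arm a
contrast of fraction f carries a standard error of roughly
(1 + f)·4.7 points, ~14 points for the largest vs-ABF contrast — so
individual large contrasts scatter by tens of points while the panel-mean
absolute recovery error stays near 5 points.  The exact rank-sum
enumerator is O(C(n, n₁)) and deliberately capped at combined n = 12.
Duncan letters use the harmonic-mean group size for unbalanced designs, the
standard approximation.  The siderophore unit question above means CAS
results are comparable within a campaign but not across laboratories
without a shared standard.
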