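# Methods

This note documents the models, rules, parameters, and design choices
behind `nephrotriage`, in the order the pipeline applies them.

## Scope and data model

The pipeline operates downstream of alignment and annotation: its inputs
are per-patient small-variant calls (VCF v4.x with GT/AD/DP, plus
population allele frequency and molecular consequence in configurable
INFO keys), pedigree relations (6-column PED), a gene-panel registry
(TSV: gene, inheritance mode, chromosome, category, version), patient
metadata (TSV), and optionally per-exon depth matrices for CNV calling.
Consequences and population frequencies are *inputs*; the package never
computes annotations. All coordinates are 1-based, fully closed, as in
VCF. Multi-allelic records are decomposed into one record per alternate
allele per sample. An absent population-frequency annotation is read as
0 — a novel variant must pass the rarity filter.

Genotype mapping follows allele count with a sex-chromosome rule: any
haploid call, and any alt-carrying male genotype on X/Y, is
*hemizygous*. Samples that are hom-ref at a site still produce records,
because parental reference genotypes (and their depths) are the evidence
de novo detection relies on.

## Panels and escalation

One panel per clinical macro-category; a gene with dual inheritance is
entered once per mode and every mode is evaluated. The *kidneyome* is
defined as the exact union of the subpanels and is derived, never
persisted. Escalation to the kidneyome is a boolean function of three
clinician-supplied flags: it happens iff the subpanel result is negative
and the phenotype is unclear or overlapping. Filtering is a single pass:
the escalated analysis re-restricts the same filtered call set, since
the thresholds are panel-independent. The bundled
`data/panels_demo.tsv` registry is a demonstration list of genes named
in the kidney-disease literature; production panels (>400 genes, curated
yearly from OMIM/PanelApp/ClinGen/Malacards and the literature) are an
external input and out of scope.

## Filtering cascade

Order: panel restriction → consequence filter → quality/frequency
filter. Every input call receives a trace and a failed call carries
exactly one first-failing filter.

| Parameter | Default | Meaning |
|---|---|---|
| `max_pop_af` | 0.01 | population frequency must be strictly below 1% |
| `min_vaf` | 0.2 | in-patient alternate-read fraction, inclusive |
| `min_depth` | 20 reads | site coverage, inclusive |
| retained consequences | missense, nonsense, frameshift, splicing, inframe indel, CNV | synonymous/intronic retained only within splice regions |

Boundary semantics are the literal clinical wording: "less than 1%" is
strict; "at least 0.2 / 20 reads" are inclusive. Homozygous calls get no
VAF exemption. CNV records skip the VAF/depth clauses (a per-site allele
fraction is meaningless for a depth-based event) but still obey panel
membership and, when an AF is available, rarity. No QUAL/GQ filtering is
applied; the clinical rule set does not state any.

## ACMG engine

Evidence arrives pre-bucketed by strength (PVS, PS, PM, PP; BA, BS, BP)
— the 28-criterion catalog is a curation activity, not re-derived here.
The combining rules are the original 2015 ACMG/AMP standard (Richards et
al.), read strictly: a lone PVS1, or a lone BS, maps to VUS.
Pathogenic-side and benign-side rules are evaluated independently; if
both fire, the evidence conflicts and the class is C3. The engine is
total and, by construction (all rule predicates are `>=` comparisons),
monotone: adding a pathogenic-direction code never moves the class
toward benign. The intermediate C3/C4 class exists only as a manual
override modeling geneticist curation; it is handled with C4 weight by
the report rules but tallied as its own class.

## Segregation

Penetrance is assumed complete. Consequences of that assumption, chosen
deliberately because the clinical workflow states no penetrance model:
an unaffected carrier parent under AD yields *confirmed transmission*,
never refutation; only structurally impossible configurations refute
(compound het phased cis, AR homozygote with a well-covered hom-ref
parent, an X-linked variant carried by the unaffected father). Parental
mosaicism and parental VAF thresholds are not modeled. De novo calls
require both parents hom-ref with depth ≥ `min_parent_depth`
(default 20, mirroring the proband coverage rule); a missing or
under-covered parent makes the call *unavailable*, not negative — but a
carrier parent settles inheritance even when the other parent lacks
data. Compound-het phase comes from exclusive parental carriage: one
variant per parent is trans, both from the same parent is cis, anything
else (shared carriage, missing data) is unknown. Status semantics:
*pending* = parents exist but data are absent or indeterminate;
*unavailable* = no parents at all. Extended pedigrees beyond the trio
are out of scope.

## Report classification

Per gene group, in order: refuted segregation sinks the group; a single
het in a recessive gene is inconclusive regardless of class; C4/C5
(including curated C3/C4) with full phenotype fit and a satisfied
inheritance model is conclusive, with partial fit uncertain; C3 with
full fit is conclusive only when segregation is confirmed, uncertain
while pending/unavailable, and inconclusive when off-phenotype. Two
rules are under-specified by the clinical criteria and were fixed here:
a C3 with *partial* fit can at most be uncertain (conclusive VUS calls
require full compatibility), and a C4/C5 with *no* phenotype fit is
suppressed — logged, not reported, with no invented outcome (incidental
finding policy). The patient outcome is the best group outcome
(conclusive > uncertain > inconclusive); reasons of best-outcome groups
are primary, the rest secondary; variants are reported only from
best-outcome, reportable groups. An empty candidate set is inconclusive
with reason `no_variants`.

## CNV baseline caller

Per-exon mean depths, one column per sample. Normalization divides each
column by its own median autosomal depth. The test sample's normalized
depth is divided by the mean of the applicable baseline columns —
same-sex columns only on X/Y, which keeps a normal male X at ratio 1.0
and requires ≥ 2 baseline samples per sex. Ratio thresholds, exposed in
`CnvThresholds` because the clinical description names the baseline
strategy but no numbers, use conventional cut-offs: het deletion ≤ 0.7,
hom deletion ≤ 0.1, duplication ≥ 1.3. Consecutive same-state regions of
one gene are merged into one call (per-region merging; whether the
laboratory merged per exon or per gene is unstated). No segmentation
HMM/CBS, no GC correction, no array-CGH parsing. Calls convert to
`cnv_del`/`cnv_dup` variant records and flow through the standard
triage.

## Statistics and rounding

Diagnostic = conclusive; uncertain is not a diagnosis. All percentages
are 100·a/b rounded half-up to one decimal, and every denominator stays
explicit so each stored percentage recomputes from its two counts.
Report-category shares are expressed over variant-positive patients;
negative exomes are tracked separately. Known inconsistencies in the
source figures this package mirrors are documented rather than
reproduced: the overall conclusive rate 71/191 is 37.2% under half-up
(printed once as 37.1%), the positive-family-history yield 28/47 is
59.6% (printed once as 59.5%), and the nonsense share 14/96 is 14.6% (a
printed "145.6%" is an evident typo). The pipeline always reports the
arithmetic values.

## Synthetic cohorts

The generator emits summary-level data only (genotype, AD/DP, VAF,
annotations) — no reads. Every patient plan fixes an intended outcome
and the variants are engineered so the *pipeline* reaches it: causative
variants pass all filters and carry evidence profiles that compute to
the intended class (C5 ⇐ PVS1+PS, C4 ⇐ PS+PM, C3 ⇐ PM+PP; C3/C4 cases
compute to C3 and carry a manual override), trio genotypes realize the
intended segregation (de novo, carrier parents, trans/cis), and each
decoy is constructed to fail exactly one named filter (common variant,
low VAF, low depth, synonymous, intronic, off-panel gene). The
ground-truth ledger records all of it; exact pipeline-vs-ledger
agreement on noise-free cohorts is the contract, and any disagreement is
a bug on one side. Randomness flows from a single seeded generator, so
equal configs give byte-identical cohorts.

What the generator does not emulate — and therefore what passing tests
do not show about real data: sequencing noise in VAF/depth, annotation
errors, incomplete penetrance, mosaicism, multi-allelic sites beyond the
reader tests, pseudogene interference (relevant to PKD1 in practice),
and phenotype misclassification. The generator validates feasibility
before emission (for example a compound het requested against a panel
with no recessive gene raises immediately).

### The deterministic study fixture

`build_study_fixture()` encodes one 191-patient cohort whose engineered
marginals match a published single-institution pediatric series:
category sizes 34/39/62/22/20/14; 154 variant-positive and 37 negative
exomes; report split 71/22/61; per-category diagnoses 7/29/15/10/9/1;
family history positive in 47 patients of whom 28 diagnosed; 96 reported
variants in 32 genes across the conclusive reports (53 missense, 15
frameshift, 14 nonsense, 9 splicing, 5 CNVs — the CNVs planted in CAKUT
and glomerulopathy genes, the two in recessive genes as homozygous
deletions so the inheritance model is satisfied); leading classes
17 C5 / 34 C4 / 16 C3 / 4 C3/C4. The joint distribution of family
history × category × diagnosis is under-determined by the published
marginals; the fixture fixes one deterministic completion consistent
with all of them (ciliopathies 22 FH-positive, nephrolithiasis 12,
diagnosed FH-positive 1/16/2/8/1/0 per category). Eight patients are
consanguineous, assigned to recessive-homozygous cases. All marginals
are re-verified at build time; a mismatch is a build error. The fixture
is small enough that the whole build-classify-summarize cycle runs in
about a second on one CPU; the randomized suites (1,000-call filter
oracle, exhaustive MOI and ACMG grids, 2,000 random report bundles)
complete in seconds.

## Known limitations

Beyond the generator gaps above: no BAM/CRAM handling; no automated
evidence gathering for ACMG codes; no re-analysis/periodic
re-classification workflow; no statistical testing across strata; no
sample-swap QC for validation aliquots; prenatal cases and cost analysis
out of scope.
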