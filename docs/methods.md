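# Methods

## Segregation model

A gene with *c* copies on the male-specific region of chromosome Y
(MSY) that is absent from the alignment reference produces, at each site
where the Y-borne copy differs from the source locus, an expected
alternate-read fraction of *c*/(*c*+2) in a male for an autosomal source
(two autosomal copies plus *c* Y copies) and *c*/(*c*+1) for an X-linked
source (one X in a male). Females carry no Y, so their expected
alternate fraction is zero. The detection filter operationalizes this:

* every female sample: allele frequency ≤ `female_max_af` (default 0,
  i.e. exactly invariant);
* every male-class sample: allele frequency within
  [`male_af_lower`, `male_af_upper`] (defaults 0.001–0.999, the
  "0.1–99.9 %" window read as inclusive fractions);
* every sample: read depth ≥ `min_depth` (default 1). Sites with zero
  depth in any sample are excluded from candidacy rather than imputed
  as reference-homozygous — absence of evidence is not evidence of the
  reference allele. Under very low coverage this exclusion rule can
  drop true marker sites; the per-gene SNV counts should be read with
  that in mind.

Leave-one-out filtering repeats the procedure with one male at a time
held to the female rule; a gene whose sites all land under one strain is
reported as lacking the copy in that strain (the biological reading:
the duplication never happened, or was lost, on that strain's Y).

Per-gene summaries average allele frequency per site over male strains
and then over sites, with the SEM taken across sites (undefined for
single-site genes). Genes with a strain-level absence fail the all-male
filter at every site, so summaries are computed over the union of
all-male and leave-one-out candidate sites, and strains lacking the
gene are excluded from the per-site average — their structural zero is
not a draw from the read-sampling distribution. Partial absences
(individual sites missing in individual strains) stay in the average,
matching how sporadic dropouts behave in real panels.

## Sex inference

A sample is female only if zero reads contain a Y-marker probe (Sry
coding sequence) on either strand; a single marker read reclassifies it
as male-class. This deliberately has no minimum-count threshold: a
contaminated female library behaves as a diluted male and its variants
can then contribute to detection rather than vetoing it. BLAST-style
matching (100 % identity, E-value threshold) is replaced by exact
substring matching of probes ≥ 24 nt and their reverse complements —
for full-identity hits of that length the criteria coincide, and exact
matching is deterministic and dependency-free. The same replacement is
used for marker-expression counting and MSY probe placement.

## Clustering, probes, placement, classification

Marker SNVs are chained into clusters by transitive single-linkage with
an inter-site gap ≤ `max_gap` (default 20 bases); a three-SNV run at
18-base spacings is one cluster. The pairwise reading (each consecutive
pair ≤ 20) gives the same clusters for gap-bounded chains; transitive
linkage was chosen because it is order-independent and matches the
"single read covers multiple variants" use of the clusters. Clusters
need two or more SNVs; singletons are discarded.

Probes embed the alternate alleles and place the cluster either
centered (`middle`, default, with `flank` = 12 bases each side) or with
the outermost SNV on the probe boundary (`ends`); either way an exact
probe match necessarily covers every identifying SNV. Placement on MSY
contigs is exact substring search on both strands.

Mechanism classification compares the locus content against two
templates built from the source gene with the detected alternate
alleles applied: the spliced exon concatenation (retroposed) and the
intron-bearing genomic sequence (transposed). A proper subset of exons
present calls a partial transposition; a source annotated as MSY-native
short-circuits to `msy_duplication`. Intronless source genes cannot
discriminate retro- from transposition; the tie breaks to retroposed
with a warning. Because the detected variant set can miss a site (a
sampling zero in one sample removes the site from candidacy), template
matching in the pipeline tolerates a small edit distance
(`template_max_mismatches`, default 3, via edlib's infix alignment);
the spliced and genomic templates differ by whole introns (≥ 60 bases),
so the tolerance cannot confuse them.

Pseudogene assessment reads the coding sequence back off the located
MSY locus itself — not off the expected template — so disruptions
present only in the Y copy (e.g. a premature stop) are seen. An ORF
whose length is a multiple of three is translated in frame 0; otherwise
the three frames are scanned and the cleanest kept. Premature stop plus
marker expression below `rpm_threshold` (default 0.01 RPM, far above
any plausibly real transcript at billions of reads) calls a pseudogene;
an intact ORF with expression at or above threshold calls a functional
copy; anything else is indeterminate. Partial transpositions are
reported indeterminate: their ORF cannot be reconstructed without
knowing the retained exon subset.

## Expression quantification and distinguishability

Marker hits are counted per read (a read containing a probe twice
counts once), normalized as RPM = hits / total reads × 10⁶. The
Y-fraction of a gene pair is y/(y + homolog), 0.5 meaning equal
transcript contribution. A copy in a multi-copy family is reported
"nd" (not determined) if no window of at most the read length contains
a variant combination unique to it — the exhaustive window enumeration
over the shared coordinate frame is exact, not heuristic.

## Phenotype statistics

Mann-Whitney U, two-sided; exact enumeration when the smaller group has
at most eight observations and the data are tie-free, otherwise the
normal approximation with mid-ranks and tie-corrected variance.
Bonferroni adjustment multiplies by the family size *m*, which may
exceed the number of computed p-values (defaults to it otherwise) —
per-consomic families of 131 and 223 phenotypes are the motivating
case. Significance is adjusted *P* < 0.05. Sex-difference
classification is row-level over the comparison table: both parents /
background-parent only / donor-parent only / neither; the packaged
consomic table keeps duplicated rows as distinct rows, since the
published class counts are row-level. The per-chromosome contribution
metric is (significant / measured) / size, per Mb or per ten genes,
with the MSY fold reported against both the mean and the maximum of
the other chromosomes; chromosomes with no measured phenotypes are
skipped with a warning.

## SNV density

Density is SNVs per Mb per strain per chromosome. The MSY fold is,
per strain, MSY density divided by the unweighted mean of the other
chromosomes' densities (matching the per-chromosome box-plot framing);
a length-weighted genome-wide denominator is available via
`aggregate="genome_wide"`. Whether a real analysis would use mean or
median of the other chromosomes is not fixed by convention; mean is the
default here and the alternative is a one-line change.

## Synthetic data: what it emulates, and what it does not

The generator produces a panel with the statistical structure the
analysis assumes: constant per-site depth with Binomial(coverage, *p*)
alternate reads at marker sites in males (*p* from the copy-number
model), zero alternates in females, strain-private homozygous
background SNVs at a Poisson per-Mb rate with a configurable MSY
multiplier, BAC-like MSY contigs carrying the inserted copies
(spliced / intron-bearing / exon-subset, with a plantable premature
stop), Sry-paralog read sets with configurable copy weights, and
Normal phenotypes with strain and sex effects. One top-level seed
drives deterministic per-stage substreams keyed by stage name, so a
fixed seed reproduces byte-identical outputs and stages can be rerun
independently.

Deliberate simplifications: constant (not Poisson) depth keeps
closed-form Binomial oracle SDs; no sequencing error, indels, mapping
ambiguity, GC bias, or linked variants; background SNVs are
strain-private and homozygous; female samples carry no autosomal
variation of their own. Contaminated females receive a trace fraction
of Y-marker reads (default 0.1 % of the read set, floored at one read
so small synthetic read sets still witness the contamination) but no
alternate counts in the variant table unless
`contaminated_variant_fraction` is set; the demo sets 0.5, modelling a
heavily contaminated library whose diluted allele fractions still pass
the male window. Passing tests therefore demonstrate correctness of
the statistical logic under the stated model, not robustness to
alignment artifacts or error modes absent from the generator.

Default study conditions: a 23-genome panel (16 males, 2 contaminated
females, 5 pure females — 18 male-class in total), coverage 30 (40 in
the demo), MSY rate multiplier 2.0, and a ten-gene duplication panel
mirroring the canonical mechanism mix (seven retroposed, one
multi-copy transposed, one partial, one MSY-native; one strain-level
absence; one stop-disrupted silent pseudogene; two expressed functional
copies). Chromosome lengths are scaled down to 1–2 Mb with a 400/Mb
background rate so a full run takes seconds; the recovery tests use
7 male strains, 200 genes × 30 SNVs at coverage 50, and 100+ random
instances per oracle check — sizes chosen so the sampling noise of each
assertion is well below its tolerance.

## Numerical and design notes

* Coordinates are 1-based inclusive throughout (VCF convention);
  probe/ORF offsets within sequences are 0-based.
* Allele frequency at zero depth is missing (NaN / None), never 0.
* The AF windows are inclusive at both ends; a male at exactly 100 %
  (a fixed strain difference, not a duplication signal) fails.
* `run-all` uses declared-male samples for the density stage:
  strain genome libraries are of known sex, and contaminated female
  libraries are not strains.
* VCF reading is backed by pysam and restricted to the v4.2 subset the
  method needs (biallelic split of multi-allelic records, per-sample
  AD); the writer emits that subset as plain text. Parse errors are
  reported with file and CHROM:POS context rather than raw line
  numbers.
* The exact Mann-Whitney branch and its size-8 cutoff follow the
  standard practice for tie-free small samples; the brute-force
  enumeration and counting-recurrence oracles in the test suite are
  independent of the implementation path.

## Known limitations

* Copy-number estimation by inverting the expected-AF model is not
  attempted; multi-copy genes report all probe hits instead.
* No genotype likelihoods: the filters consume raw allelic depths, so
  depth-dependent miscalls upstream propagate.
* Distinguishability assumes error-free reads over the variant window.
* The phenotype module tests location shifts only (Mann-Whitney); no
  mixed models, repeated measures, or time-series structure.
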