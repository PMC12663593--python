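# Methods

## Enzyme model and in silico digestion

A Type IIB enzyme is specified by an IUPAC recognition pattern and two
flank lengths; the excised tag length is `left + |pattern| + right`. The
built-in BcgI definition is CGANNNNNNTGC with 10 nt flanks (32 bp tags),
following the REBASE geometry for this enzyme; other Type IIB enzymes can
be registered with the same record. Digestion scans the forward strand
for the pattern and for its reverse complement (a minus-strand
recognition event), emits the full tag window for every hit, skips
windows that fall off the sequence end or contain any N (no partial or
ambiguous tags — downstream matching is exact and iso-length), and
collapses a locus that matches in both orientations to a single site.
Tags are identified by their canonical form, the lexicographic minimum of
the sequence and its reverse complement, making identity strand-free.

IUPAC matching treats an uncalled N in the *subject* as matching only an
N in the *pattern*: a concrete pattern base cannot claim an uncalled
position. Since N-containing windows are discarded anyway, this choice
only matters for callers using `iupac_match` directly.

Coordinates are 0-based half-open internally and printed 1-based in the
`digest` command's TSV output. Digestion preserves multiplicity (two
identical loci yield two tags); deduplication happens at database
construction.

## Marker database

A species' tag set is the **union** of the distinct canonical tags of its
genomes (pangenome-sensitive; `--combine intersection` restricts to the
core instead). The database maps each tag to its carrier set; tags with
exactly one carrier are *specific markers*. Per-species statistics record
the genome count, total distinct tags (`M_total`, the expected
genome-wide count) and specific marker count (`M`).

Subsetting to a candidate species set recomputes specificity within the
subset, so a tag shared only with excluded species becomes specific to
its remaining carrier — the mechanism behind the dynamic second pass.
Correctness here requires the shared-tag map, so in-memory databases keep
it by default; `save_db(..., keep_shared=False)` (CLI `--no-keep-shared`)
writes a specific-markers-only file for scale, at the cost of disabling
two-pass profiling on reload.

Serialization is plain TSV with `#`-prefixed headers (enzyme definition,
version, counts) plus a `.stats.tsv` sidecar, gzip-transparent, and
round-trips exactly. `db_stats` reports *both* the mean distinct tags per
genome and the mean specific markers per species, because the two
denominators genuinely differ in multi-genome species collections.

## Profiling

**Read → tag.** A read exactly one tag long is used as-is (if N-free);
longer reads are scanned with a sliding window and accepted only when
exactly one distinct candidate window carries the recognition pattern at
its expected offset in either orientation. Shorter reads, N-containing
windows and ambiguous multi-candidate reads are rejected. This is the
whole of read QC: with exact iso-length matching, any base error already
removes the read from consideration, so no quality-score filtering is
layered on top.

**Classification.** Host exclusion is exact matching against the host
genome's own canonical tag set and takes precedence over microbial
assignment. A tag specific to species *s* increments that species' read
count S and marker set t; a tag in the database with multiple carriers is
counted as a shared-tag read (supporting no single species); anything
else is unassigned. Host + species + shared + unassigned reads always sum
to the sample total.

**G-score.** G = √(S·t) with S = reads on specific markers and
t = distinct specific markers detected. The published formula names S
"coverage" and t "marker specificity" without defining them; counts are
the only reading consistent with a √(S·t) threshold of 5, and they are
what is implemented. Species with G < g_min (default 5) are discarded;
the boundary G = g_min is retained.

**Two passes.** Pass 1 against the full database yields candidates; pass
2 re-classifies against the candidate-subset database. Decontamination is
applied to pass-2 counts, before the final G filter (the published order
is unstated; subtracting first is conservative, since contamination
support should not help a species clear the filter).

**Decontamination.** The default `per_taxon_scaled` mode subtracts, for
each taxon, its negative-control read count scaled by the depth ratio
T/N, flooring at zero and dropping emptied taxa. The published global
formula D = T·(T/N) is preserved verbatim as `literal_global` (D spread
proportionally over control taxa), but note it exceeds T whenever T > N,
which is why it is not the default.

**Abundance.** Coverage c_i = reads_i / M_i, with M_i the species' marker
count in the pass-2 database; abundances are coverages normalized to sum
to one. Dividing by M corrects for genome size and restriction-site
density: a large genome yields more markers and proportionally more
reads at equal cell abundance.

## Evaluation metrics

* **PR curve / AUPR** over distinct predicted-abundance thresholds
  (descending); a taxon is called when its abundance ≥ threshold.
  Precision where nothing is called is 1 by convention. AUPR is the
  average-precision step sum Σ P_k (R_k − R_{k−1}), which matches
  exhaustive enumeration exactly and involves no interpolation choice.
* **L2 similarity** = 1 − Euclidean distance between profiles zero-filled
  over the taxon union (identical profiles → 1; disjoint normalized
  profiles → 1 − √2).
* **Pearson (union)**: correlation of the zero-filled vectors; constant
  vectors (e.g. a perfectly even truth) have no defined correlation and
  return NaN with a warning.
* **Shannon index** in bits (log base 2, the common amplicon-pipeline
  convention; a `base` argument is provided). **Bray–Curtis** on
  zero-filled union vectors.
* **Rarefaction**: count vectors are subsampled without replacement
  (multivariate hypergeometric); read lists are subsampled by index
  permutation. Three replicates per depth by default; depths exceeding
  the sample size are skipped. Shannon-index similarity between a
  subsample and the full profile is the ratio min/max of the two indices
  (1 when equal); profile similarity is 1 − Bray–Curtis. The *saturating
  depth* is the smallest ladder depth at which both similarities are
  within 1 point of the full-depth value — the depth beyond which
  further sequencing changes the indices by ≤1%.

## Synthetic data

Generated genomes are i.i.d. background sequence at a chosen GC content
with Poisson(1 per kb by default) concrete recognition-pattern instances
planted in non-overlapping tag windows. Flank bases are i.i.d. random, so
two species share a given tag with probability ≈ 4⁻²⁰; in practice ≥99%
of database tags are species-specific, which the tests check. The host
genome is built identically but 10× the microbial genome length,
reproducing the host/microbe site-density asymmetry qualitatively (no
attempt is made to match the real ~150× gene-density ratio or human
sequence composition).

Reads are drawn tag-by-tag: a species is chosen with probability
proportional to abundance × its distinct tag count (DNA-mass-proportional
digestion of an equal-size-normalized mix — deliberately the same model
that the M-normalized abundance estimator inverts, so recovery tests are
self-consistent), a tag uniformly within the species, random orientation,
constant qualities, and substitution-only per-base error (2bRAD reads are
short and indel-poor; an erroneous tag almost surely matches nothing and
is counted as signal loss, not misassignment). Host reads are drawn the
same way from the host tag set. All generators are deterministic under an
integer seed.

The mock scenario mirrors a standards-based benchmarking design: 20
species mixed evenly (ground truth 0.05 each) across 18 synthetic genus
labels, spiked with 90% or 99% host reads, with two replicate runs
available by varying the seed.

What passing these tests does **not** show: robustness to real pangenome
diversity (conspecific genomes here are single sequences), to shared tags
between closely related real species, to GC- or PCR-bias, or to realistic
quality-score error profiles. The synthetic generator makes markers
nearly always species-specific; real databases have far lower specific
fractions, which the two-pass design exists to mitigate.

## Benchmark problem sizes

The packaged benchmarks run at desk scale, chosen so every species keeps
hundreds of reads: the mock fidelity run uses 100,000 reads at 90% host
(500 microbial reads per species) with 0.5% per-base error, and 1,000,000
reads for the 99% spike; the rarefaction benchmark uses 50 species with
log-uniform abundances (100× max/min span), 200,000 reads, the depth
ladder 1k/5k/10k/25k/50k/100k/150k and 3 replicates per depth; parameter
recovery uses 10-species log-uniform communities at 10,000 noiseless
reads over 10 seeds. 100 kb genomes at 1 site/kb give ≈100 markers per
species.

## Numerical and edge-case choices

Abundances sum to 1 within 1e-9 whenever any species is retained; an
empty candidate set yields a valid empty profile. Decontamination floors
at zero and drops emptied taxa; `off` is the identity. G uses exact
integer S·t under `sqrt`. Ties in PR thresholds are handled by the
≥-threshold rule (tied taxa enter together). `rarefy` errors on negative
depth or depth exceeding the total; the rarefaction driver skips
out-of-range depths instead, matching subsampling protocols that stop
when a sample runs out of data.

## Known limitations

Exact matching only (no mismatch tolerance — a deliberate property of
iso-length tags, but it makes per-read error the dominant loss channel);
no strain-level resolution; taxonomy strings are carried opaquely with no
tree reconciliation; the literal decontamination formula is kept only for
fidelity and is not recommended; host exclusion requires the host tag
set and silently does nothing without one.
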