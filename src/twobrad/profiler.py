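"""Two-pass read classification and abundance estimation.

Pipeline
--------
1. Each read is reduced to its canonical tag (exact, iso-length matching;
   reads longer than the tag carry it at an enzyme-defined offset).
2. Pass 1: reads are classified against the full marker database.  Host
   reads — those matching the host genome's own tag set — are removed
   first.  Candidate species are those whose confidence score
   G = sqrt(S × t) clears the threshold, where S is the number of reads on
   the species' specific markers and t the number of distinct specific
   markers hit.
3. Pass 2: a dynamic, sample-specific database is rebuilt over the
   candidates only, which promotes formerly shared tags to specific
   markers and increases per-candidate marker counts; reads are
   re-classified against it.
4. Negative-control counts are subtracted (scaled by the sample/control
   depth ratio T/N), the G filter is re-applied, and relative abundances
   are computed as marker coverage c = reads / M normalized across
   retained species — M being the species' marker count in the pass-2
   database, which corrects for genome size and marker density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Union

from twobrad.enzyme import EnzymeSpec, canonicalize, iupac_match, reverse_complement
from twobrad.tagdb import TagDB, subset_db

__all__ = [
    "REJECT",
    "ReadSet",
    "SpeciesHit",
    "SampleProfile",
    "ProfileConfig",
    "ClassificationResult",
    "extract_read_tag",
    "classify_reads",
    "g_score",
    "filter_candidates",
    "decontaminate",
    "estimate_abundance",
    "profile_sample",
    "host_fraction",
]


class _Reject:
    """Sentinel for a read that yields no usable tag."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "REJECT"


REJECT = _Reject()


@dataclass
class ReadSet:
    """A collection of reads belonging to one sample (or control)."""

    sample_id: str
    reads: Sequence[str]

    @property
    def total_reads(self) -> int:
        return len(self.reads)


@dataclass
class SpeciesHit:
    """Per-species hit statistics accumulated during classification."""

    species_id: str
    reads_assigned: int          # S: reads matching the species' markers
    markers_detected: int        # t: distinct markers with >= 1 read
    markers_total: int           # M: markers available in the DB pass used
    taxonomy: str = ""
    reads_after_decontam: int = -1   # set by decontaminate(); -1 = not applied
    relative_abundance: float = 0.0

    def __post_init__(self) -> None:
        if self.reads_after_decontam < 0:
            self.reads_after_decontam = self.reads_assigned

    @property
    def g_score(self) -> float:
        return g_score(self.reads_assigned, self.markers_detected)

    @property
    def coverage(self) -> float:
        """Marker coverage c = reads / M (post-decontamination reads)."""
        if self.markers_total == 0:
            return 0.0
        return self.reads_after_decontam / self.markers_total


@dataclass
class ProfileConfig:
    """Tunable parameters of the profiling pipeline."""

    g_min: float = 5.0
    decontam_mode: str = "per_taxon_scaled"  # per_taxon_scaled|literal_global|off
    two_pass: bool = True
    host_exclusion: bool = True
    min_read_length: Optional[int] = None  # defaults to enzyme tag length

    def __post_init__(self) -> None:
        if self.g_min < 0:
            raise ValueError("g_min must be >= 0")
        if self.decontam_mode not in ("per_taxon_scaled", "literal_global", "off"):
            raise ValueError(f"unknown decontam_mode {self.decontam_mode!r}")


@dataclass
class SampleProfile:
    """Final per-sample result: retained species plus read accounting."""

    sample_id: str
    hits: List[SpeciesHit]
    total_reads: int
    host_reads: int
    unassigned_reads: int
    shared_tag_reads: int
    params: ProfileConfig = field(default_factory=ProfileConfig)

    def abundances(self) -> Dict[str, float]:
        return {h.species_id: h.relative_abundance for h in self.hits}


@dataclass
class ClassificationResult:
    """Raw tallies from one classification pass."""

    species_reads: Dict[str, int]               # S per species
    species_markers: Dict[str, Set[str]]        # distinct markers hit
    host_reads: int
    shared_tag_reads: int
    unassigned_reads: int
    total_reads: int


def extract_read_tag(read: str, enzyme: EnzymeSpec) -> Union[str, _Reject]:
    """Reduce a read to its canonical tag, or ``REJECT``.

    A read exactly one tag long is taken as the tag (if N-free).  A longer
    read (e.g. with adapter remnants) is scanned with a sliding window: a
    window qualifies when the enzyme's recognition pattern sits at its
    expected offset in either orientation.  The read is rejected unless
    exactly one distinct candidate tag emerges.
    """
    tlen = enzyme.tag_length
    n = len(read)
    if n < tlen:
        return REJECT
    if n == tlen:
        if "N" in read:
            return REJECT
        return canonicalize(read)
    pattern = enzyme.recognition_pattern
    rc_pattern = reverse_complement(pattern)
    plen = len(pattern)
    candidates: Set[str] = set()
    for start in range(n - tlen + 1):
        window = read[start:start + tlen]
        fwd = window[enzyme.left_flank:enzyme.left_flank + plen]
        rev = window[enzyme.right_flank:enzyme.right_flank + plen]
        try:
            hit = iupac_match(pattern, fwd) or iupac_match(rc_pattern, rev)
        except ValueError:
            return REJECT
        if hit:
            if "N" in window:
                return REJECT
            candidates.add(canonicalize(window))
    if len(candidates) != 1:
        return REJECT
    return candidates.pop()


def classify_reads(readset: ReadSet, db: TagDB,
                   host_tags: Optional[FrozenSet[str]] = None,
                   ) -> ClassificationResult:
    """Assign every read to host / a species / shared / unassigned.

    Host matching takes precedence over microbial matching; a tag present
    in the database but carried by more than one species counts as a
    shared-tag read and supports no single species.  Counts conserve the
    total read number exactly.
    """
    host_tags = host_tags or frozenset()
    specific = db.specific_tag_map
    all_tags = db.tag_to_species
    species_reads: Dict[str, int] = {}
    species_markers: Dict[str, Set[str]] = {}
    n_host = n_shared = n_unassigned = 0
    for read in readset.reads:
        tag = extract_read_tag(read, db.enzyme)
        if tag is REJECT:
            n_unassigned += 1
            continue
        if tag in host_tags:
            n_host += 1
            continue
        sp = specific.get(tag)
        if sp is not None:
            species_reads[sp] = species_reads.get(sp, 0) + 1
            species_markers.setdefault(sp, set()).add(tag)
        elif tag in all_tags:
            n_shared += 1
        else:
            n_unassigned += 1
    return ClassificationResult(
        species_reads=species_reads,
        species_markers=species_markers,
        host_reads=n_host,
        shared_tag_reads=n_shared,
        unassigned_reads=n_unassigned,
        total_reads=readset.total_reads,
    )


def g_score(reads: int, markers: int) -> float:
    """Confidence score G = sqrt(S × t).

    S is read support on a species' specific markers and t the number of
    distinct markers detected; the geometric combination penalizes species
    supported by many reads on a single marker (a classic contamination or
    mismapping signature) as much as ones with thin read support.
    """
    if reads < 0 or markers < 0:
        raise ValueError("read and marker counts must be non-negative")
    return math.sqrt(reads * markers)


def filter_candidates(hits: Iterable[SpeciesHit], g_min: float) -> List[SpeciesHit]:
    """Retain hits with G >= ``g_min`` (strictly below the threshold is
    discarded; the boundary is kept).  Input order preserved."""
    return [h for h in hits if h.g_score >= g_min]


def decontaminate(sample_counts: Dict[str, int],
                  control_counts: Optional[Dict[str, int]],
                  total_reads: int, control_total: int,
                  mode: str = "per_taxon_scaled") -> Dict[str, int]:
    """Subtract negative-control background from per-taxon read counts.

    ``per_taxon_scaled`` (default): for each taxon i seen in the control,
    the expected contaminant reads in the sample are
    D_i = control_i × (T / N) — the control count scaled by the
    sample-to-control sequencing-depth ratio — and max(0, S_i − D_i)
    (floored) reads survive.  ``literal_global`` computes the global
    quantity D = T × (T / N) and removes it proportionally to control
    composition.  ``off`` is the identity.  Taxa reduced to zero reads are
    dropped.
    """
    if mode == "off":
        return dict(sample_counts)
    if control_counts is None:
        raise ValueError(f"decontam mode {mode!r} requires a negative control")
    if control_total <= 0:
        raise ValueError("control read total N must be > 0 for decontamination")
    scale = total_reads / control_total
    adjusted: Dict[str, int] = {}
    if mode == "per_taxon_scaled":
        for taxon, count in sample_counts.items():
            d = control_counts.get(taxon, 0) * scale
            kept = int(math.floor(max(0.0, count - d)))
            if kept > 0:
                adjusted[taxon] = kept
        return adjusted
    if mode == "literal_global":
        d_total = total_reads * scale
        control_sum = sum(control_counts.values())
        for taxon, count in sample_counts.items():
            if control_sum > 0 and taxon in control_counts:
                share = control_counts[taxon] / control_sum
                kept = int(math.floor(max(0.0, count - d_total * share)))
            else:
                kept = count
            if kept > 0:
                adjusted[taxon] = kept
        return adjusted
    raise ValueError(f"unknown decontamination mode {mode!r}")


def estimate_abundance(hits: List[SpeciesHit]) -> List[SpeciesHit]:
    """Set relative abundances from marker coverage.

    Coverage c_i = reads_i / M_i normalizes read counts by each species'
    marker complement, correcting for genome size and restriction-site
    density; abundances are coverages renormalized to sum to 1.
    """
    for h in hits:
        if h.markers_total == 0:
            raise ValueError(
                f"{h.species_id}: retained hit with zero markers in DB"
            )
    coverages = [h.reads_after_decontam / h.markers_total for h in hits]
    total = sum(coverages)
    out = []
    for h, c in zip(hits, coverages):
        out.append(replace(h, relative_abundance=(c / total if total > 0 else 0.0)))
    return out


def _hits_from_classification(result: ClassificationResult, db: TagDB,
                              ) -> List[SpeciesHit]:
    marker_totals = {sp: st.specific_tag_count
                     for sp, st in db.species_stats.items()}
    hits = []
    for sp in sorted(result.species_reads):
        hits.append(SpeciesHit(
            species_id=sp,
            reads_assigned=result.species_reads[sp],
            markers_detected=len(result.species_markers.get(sp, ())),
            markers_total=marker_totals.get(sp, 0),
            taxonomy=db.species_stats[sp].taxonomy,
        ))
    return hits


def profile_sample(readset: ReadSet, db: TagDB,
                   host_tags: Optional[FrozenSet[str]] = None,
                   control: Optional[ReadSet] = None,
                   config: Optional[ProfileConfig] = None) -> SampleProfile:
    """Run the full profiling pipeline on one sample.

    Deterministic for fixed inputs.  The profile's read accounting
    (host + species + shared + unassigned = T) refers to the pass-1
    classification against the full database.
    """
    config = config or ProfileConfig()
    host = host_tags if (config.host_exclusion and host_tags) else frozenset()

    pass1 = classify_reads(readset, db, host)
    hits1 = _hits_from_classification(pass1, db)
    candidates = [h.species_id for h in filter_candidates(hits1, config.g_min)]

    if not candidates:
        return SampleProfile(
            sample_id=readset.sample_id, hits=[],
            total_reads=pass1.total_reads, host_reads=pass1.host_reads,
            unassigned_reads=pass1.unassigned_reads,
            shared_tag_reads=pass1.shared_tag_reads, params=config,
        )

    if config.two_pass:
        db2 = subset_db(db, candidates)
        pass2 = classify_reads(readset, db2, host)
        hits2 = _hits_from_classification(pass2, db2)
    else:
        db2 = db
        hits2 = [h for h in hits1 if h.species_id in set(candidates)]

    if config.decontam_mode != "off" and control is not None:
        ctrl_pass = classify_reads(control, db2, host)
        counts = {h.species_id: h.reads_assigned for h in hits2}
        adjusted = decontaminate(
            counts, ctrl_pass.species_reads,
            readset.total_reads, control.total_reads,
            mode=config.decontam_mode,
        )
        kept = []
        for h in hits2:
            if h.species_id in adjusted:
                kept.append(replace(h, reads_after_decontam=adjusted[h.species_id]))
        hits2 = kept

    retained = filter_candidates(hits2, config.g_min)
    retained = estimate_abundance(retained)
    return SampleProfile(
        sample_id=readset.sample_id, hits=retained,
        total_reads=pass1.total_reads, host_reads=pass1.host_reads,
        unassigned_reads=pass1.unassigned_reads,
        shared_tag_reads=pass1.shared_tag_reads, params=config,
    )


def host_fraction(profile_or_host_reads, total_reads: Optional[int] = None) -> float:
    """Fraction of reads attributed to the host genome."""
    if isinstance(profile_or_host_reads, SampleProfile):
        host = profile_or_host_reads.host_reads
        total = profile_or_host_reads.total_reads
    else:
        host = int(profile_or_host_reads)
        total = total_reads
    if not total or total <= 0:
        raise ValueError("total read count must be > 0")
    return host / total
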