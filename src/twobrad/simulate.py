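"""Synthetic genomes, mock communities and host-rich read sets.

The generator reproduces the statistical structure the profiler relies
on, without any downloads:

* microbial genomes: i.i.d. background sequence at a chosen GC content
  with concrete instances of the enzyme's recognition pattern planted at
  Poisson-spaced, non-overlapping tag windows (~1 site/kb by default);
  flank bases are i.i.d. random, so tags collide between species with
  probability ~4^-20 per pair — negligible and quantifiable;
* a host genome built the same way but much longer, standing in for the
  host fraction of a high-host-content (HoC) sample such as saliva or
  tumor tissue, where host DNA can exceed 90-99% of reads;
* read sets: iso-length reads drawn tag-by-tag, species chosen with
  probability proportional to abundance × tag count (DNA-mass-
  proportional digestion of an equal-size-normalized mix), random
  orientation, optional per-base substitution error;
* negative controls carrying reagent-contaminant species only.

Everything is deterministic under an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from twobrad.enzyme import BCGI, IUPAC, EnzymeSpec, extract_tags, reverse_complement
from twobrad.profiler import ReadSet
from twobrad.tagdb import GenomeRecord

__all__ = [
    "SimGenomeSpec",
    "CommunitySpec",
    "synth_genome",
    "synth_host_genome",
    "simulate_reads",
    "simulate_negative_control",
    "mock_scenario",
    "log_uniform_abundances",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimGenomeSpec:
    """Parameters of one synthetic genome."""

    species_id: str
    length: int = 100_000
    gc_fraction: float = 0.5
    site_density: float = 1.0  # recognition sites per kb
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.site_density <= 0:
            raise ValueError("site_density must be positive")


@dataclass
class CommunitySpec:
    """A community to simulate: composition, depth, host spike, error."""

    abundances: Dict[str, float]
    n_reads: int
    host_fraction: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1, got {total}")
        if any(a < 0 for a in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        if not (0.0 <= self.host_fraction < 1.0):
            raise ValueError("host_fraction must be in [0, 1)")
        if not (0.0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must be in [0, 0.25)")


def _random_background(rng: np.random.Generator, length: int,
                       gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    return rng.choice(_BASES, size=length, p=probs)


def _concrete_pattern(rng: np.random.Generator, pattern: str) -> str:
    """Sample a concrete A/C/G/T instance of an IUPAC pattern."""
    out = []
    for c in pattern:
        choices = IUPAC[c].replace("N", "") if c == "N" else IUPAC[c]
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def synth_genome(spec: SimGenomeSpec, enzyme: EnzymeSpec = BCGI) -> Tuple[str, str]:
    """Generate one synthetic genome: ``(species_id, sequence)``.

    The number of planted sites is Poisson(site_density × length/1000),
    with at least one site; window starts are drawn uniformly among
    non-overlapping placements.  Digesting the result recovers at least
    the planted sites (spurious background matches can add more).
    """
    tlen = enzyme.tag_length
    if spec.length < tlen:
        raise ValueError(f"genome length {spec.length} < tag length {tlen}")
    rng = np.random.default_rng(spec.seed)
    seq = _random_background(rng, spec.length, spec.gc_fraction)
    n_sites = max(1, int(rng.poisson(spec.site_density * spec.length / 1000.0)))
    max_slots = spec.length // tlen
    if n_sites > max_slots:
        raise ValueError(
            f"cannot place {n_sites} non-overlapping {tlen} nt windows in "
            f"{spec.length} nt"
        )
    # non-overlapping placement on a tag-length grid, then jitter within
    # the leftover slack so starts are not lattice-aligned
    slots = rng.choice(max_slots, size=n_sites, replace=False)
    slack = spec.length - max_slots * tlen
    offset = int(rng.integers(slack + 1)) if slack > 0 else 0
    for slot in np.sort(slots):
        start = int(slot) * tlen + offset
        site = _concrete_pattern(rng, enzyme.recognition_pattern)
        pos = start + enzyme.left_flank
        seq[pos:pos + len(site)] = np.frombuffer(site.encode(), dtype="S1")
    return spec.species_id, seq.tobytes().decode()


def synth_host_genome(length: int, enzyme: EnzymeSpec = BCGI,
                      seed: int = 0, site_density: float = 1.0,
                      ) -> Tuple[str, frozenset]:
    """Synthetic host genome and its canonical tag set for host exclusion.

    Returns ``(sequence, host_tags)``; the tag set is obtained by
    digesting the emitted sequence with the same enzyme, exactly as a
    real pipeline precomputes host-derived motifs from the host assembly.
    """
    if length < enzyme.tag_length:
        raise ValueError(f"host length {length} < tag length {enzyme.tag_length}")
    _, seq = synth_genome(
        SimGenomeSpec("host", length=length, site_density=site_density,
                      seed=seed),
        enzyme,
    )
    return seq, frozenset(extract_tags(seq, enzyme))


def _mutate(rng: np.random.Generator, read: str, error_rate: float) -> str:
    if error_rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        alternatives = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([alternatives[rng.integers(3)]])
    return arr.tobytes().decode()


def simulate_reads(community: CommunitySpec, genomes: Dict[str, str],
                   enzyme: EnzymeSpec = BCGI,
                   host_tags: Optional[Sequence[str]] = None,
                   sample_id: str = "sim",
                   ) -> Tuple[ReadSet, Dict[str, float]]:
    """Simulate a read set from a community over synthetic genomes.

    Microbial reads: a species is chosen with probability proportional to
    abundance × its distinct tag count (a species contributing more DNA
    yields proportionally more fragments of every one of its sites), a
    tag is drawn uniformly from the species' tags, emitted in random
    orientation, and per-base substitution noise is applied.  Host reads
    (``host_fraction`` of the total) are drawn identically from
    ``host_tags``.  Reads are exactly one tag long; deterministic under
    the community seed.

    Returns the read set and the ground-truth profile (the input
    abundances).
    """
    rng = np.random.default_rng(community.seed)
    species = sorted(community.abundances)
    tag_lists: Dict[str, List[str]] = {}
    for sp in species:
        if sp not in genomes:
            raise KeyError(f"no genome supplied for species {sp}")
        tags = sorted(set(extract_tags(genomes[sp], enzyme)))
        if not tags:
            raise ValueError(f"species {sp} has no digestible tags")
        tag_lists[sp] = tags

    n_host = int(round(community.n_reads * community.host_fraction))
    n_microbial = community.n_reads - n_host
    if n_host > 0 and not host_tags:
        raise ValueError("host_fraction > 0 requires host_tags")

    weights = np.array(
        [community.abundances[sp] * len(tag_lists[sp]) for sp in species])
    reads: List[str] = []
    if n_microbial > 0 and weights.sum() > 0:
        counts = rng.multinomial(n_microbial, weights / weights.sum())
        for sp, count in zip(species, counts):
            tags = tag_lists[sp]
            picks = rng.integers(len(tags), size=count)
            flips = rng.random(count) < 0.5
            for idx, flip in zip(picks, flips):
                read = tags[idx]
                if flip:
                    read = reverse_complement(read)
                reads.append(_mutate(rng, read, community.error_rate))
    if n_host > 0:
        host_list = sorted(host_tags)
        picks = rng.integers(len(host_list), size=n_host)
        flips = rng.random(n_host) < 0.5
        for idx, flip in zip(picks, flips):
            read = host_list[idx]
            if flip:
                read = reverse_complement(read)
            reads.append(_mutate(rng, read, community.error_rate))
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    return ReadSet(sample_id, reads), dict(community.abundances)


def simulate_negative_control(contaminants: Dict[str, float],
                              n_control_reads: int,
                              genomes: Dict[str, str],
                              enzyme: EnzymeSpec = BCGI,
                              seed: int = 0,
                              sample_id: str = "control") -> ReadSet:
    """Reagent-contamination negative control: reads drawn only from the
    contaminant species' tags."""
    if n_control_reads == 0:
        return ReadSet(sample_id, [])
    if not contaminants:
        raise ValueError("contaminant set is empty but reads were requested")
    total = sum(contaminants.values())
    spec = CommunitySpec(
        abundances={k: v / total for k, v in contaminants.items()},
        n_reads=n_control_reads, seed=seed,
    )
    readset, _ = simulate_reads(spec, genomes, enzyme, sample_id=sample_id)
    return readset


def log_uniform_abundances(species: Sequence[str], seed: int,
                           span: float = 100.0) -> Dict[str, float]:
    """Log-uniform community composition over ``species`` with the given
    max/min abundance ratio ``span``."""
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.uniform(0.0, np.log(span), size=len(species)))
    raw /= raw.sum()
    return dict(zip(species, raw.tolist()))


@dataclass
class MockScenario:
    """Everything needed to run build-db -> profile -> evaluate offline."""

    genomes: Dict[str, str]
    manifest: List[GenomeRecord]
    host_sequence: str
    host_tags: frozenset
    readset: ReadSet
    truth: Dict[str, float]


def _toy_taxonomy(species_id: str, genus: str) -> str:
    return (f"d__Bacteria;p__SimPhylum;c__SimClass;o__SimOrder;"
            f"f__SimFamily;g__{genus};s__{species_id}")


def mock_scenario(n_species: int = 20, host_pct: float = 0.90,
                  n_reads: int = 100_000, seed: int = 0,
                  error_rate: float = 0.0,
                  genome_length: int = 100_000,
                  host_genome_length: Optional[int] = None,
                  enzyme: EnzymeSpec = BCGI,
                  abundances: Optional[Dict[str, float]] = None,
                  ) -> MockScenario:
    """Even mock community with host spike-in, fully synthetic.

    Defaults mirror a standards-based benchmarking design: ``n_species``
    evenly mixed microbial species (ground truth 1/n each) whose reads
    are diluted with ``host_pct`` host-genome reads — the regime of
    high-host samples such as saliva (≈90%) or tissue (≈99%).  The host
    genome defaults to 10× the microbial genome length, qualitatively
    reproducing the host/microbe restriction-site density asymmetry.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    species = [f"sp{idx + 1:03d}" for idx in range(n_species)]
    genomes: Dict[str, str] = {}
    manifest: List[GenomeRecord] = []
    for idx, sp in enumerate(species):
        gseed = int(rng.integers(2**31 - 1))
        _, seq = synth_genome(
            SimGenomeSpec(sp, length=genome_length, seed=gseed), enzyme)
        genomes[sp] = seq
        genus = f"Genus{(idx % max(1, n_species - 2)) + 1:02d}"
        manifest.append(GenomeRecord(
            genome_id=f"{sp}.g1", species_id=sp,
            taxonomy=_toy_taxonomy(sp, genus), fasta_path=""))
    if host_genome_length is None:
        host_genome_length = 10 * genome_length
    host_seq, host_tags = synth_host_genome(
        host_genome_length, enzyme, seed=int(rng.integers(2**31 - 1)))
    if abundances is None:
        abundances = {sp: 1.0 / n_species for sp in species}
    community = CommunitySpec(
        abundances=abundances, n_reads=n_reads, host_fraction=host_pct,
        error_rate=error_rate, seed=int(rng.integers(2**31 - 1)),
    )
    readset, truth = simulate_reads(
        community, genomes, enzyme, host_tags=host_tags,
        sample_id=f"mock{int(host_pct * 100)}")
    return MockScenario(
        genomes=genomes, manifest=manifest, host_sequence=host_seq,
        host_tags=host_tags, readset=readset, truth=truth,
    )
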