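"""Species-specific marker database over a taxonomically labeled genome set.

The database maps each canonical tag produced by in silico digestion to
the set of species whose genomes carry it.  Tags carried by exactly one
species are that species' *specific markers*: the currency of read
classification.  Restricting the species universe to a candidate subset
(the dynamic, sample-specific second pass) can only promote tags from
shared to specific, so per-species marker counts are monotone
non-decreasing under subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set

from twobrad import io as tbio
from twobrad.enzyme import ENZYMES, EnzymeSpec, extract_tags

__all__ = [
    "GenomeRecord",
    "SpeciesTagStats",
    "TagDB",
    "build_tag_db",
    "build_tag_db_from_sequences",
    "read_manifest",
    "species_specific_tags",
    "subset_db",
    "save_db",
    "load_db",
    "db_stats",
]

_RANKS = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass(frozen=True)
class GenomeRecord:
    """One row of a genome manifest: a genome with its species label."""

    genome_id: str
    species_id: str
    taxonomy: str  # 7-rank lineage string d__;p__;c__;o__;f__;g__;s__
    fasta_path: str

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError(f"genome {self.genome_id}: empty species_id")
        ranks = self.taxonomy.split(";")
        if len(ranks) != 7:
            raise ValueError(
                f"genome {self.genome_id}: taxonomy must have 7 ranks, "
                f"got {len(ranks)}: {self.taxonomy!r}"
            )


@dataclass
class SpeciesTagStats:
    """Per-species marker statistics.

    ``total_unique_tags`` is the species' expected genome-wide distinct tag
    count (union over its genomes); ``specific_tag_count`` is the number of
    those tags unique to this species within the database universe.
    """

    species_id: str
    genome_count: int
    total_unique_tags: int
    specific_tag_count: int
    taxonomy: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.specific_tag_count <= self.total_unique_tags):
            raise ValueError(
                f"{self.species_id}: specific count {self.specific_tag_count} "
                f"outside [0, {self.total_unique_tags}]"
            )
        if self.genome_count < 1:
            raise ValueError(f"{self.species_id}: genome_count must be >= 1")


@dataclass
class TagDB:
    """Canonical tag -> species mapping with per-species statistics."""

    enzyme: EnzymeSpec
    tag_to_species: Dict[str, frozenset]
    species_stats: Dict[str, SpeciesTagStats]
    universe: List[str]
    db_version: str = "1"
    keep_shared: bool = True

    def __post_init__(self) -> None:
        self._specific: Optional[Dict[str, str]] = None

    @property
    def specific_tag_map(self) -> Dict[str, str]:
        """Map of species-specific tag -> owning species (cached)."""
        if self._specific is None:
            self._specific = {
                tag: next(iter(spp))
                for tag, spp in self.tag_to_species.items()
                if len(spp) == 1
            }
        return self._specific

    def __eq__(self, other) -> bool:
        if not isinstance(other, TagDB):
            return NotImplemented
        return (
            self.enzyme == other.enzyme
            and self.tag_to_species == other.tag_to_species
            and self.species_stats == other.species_stats
            and sorted(self.universe) == sorted(other.universe)
            and self.db_version == other.db_version
        )


def read_manifest(path: str | Path) -> List[GenomeRecord]:
    """Parse a genome manifest TSV (genome_id, species_id, taxonomy, fasta_path)."""
    records = []
    with tbio.open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        required = ["genome_id", "species_id", "taxonomy", "fasta_path"]
        if [c for c in required if c not in header]:
            raise ValueError(f"manifest {path} must have columns {required}")
        idx = {c: header.index(c) for c in required}
        for line in handle:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            records.append(GenomeRecord(
                fields[idx["genome_id"]], fields[idx["species_id"]],
                fields[idx["taxonomy"]], fields[idx["fasta_path"]],
            ))
    return records


def _species_tag_sets(manifest: Iterable[GenomeRecord], enzyme: EnzymeSpec,
                      mode: str) -> tuple[Dict[str, Set[str]], Dict[str, int],
                                          Dict[str, str], List[int]]:
    """Digest every genome; combine conspecific tag sets by union or
    intersection.  Returns (species sets, genome counts, taxonomy,
    per-genome distinct tag counts)."""
    species_tags: Dict[str, Set[str]] = {}
    genome_counts: Dict[str, int] = {}
    taxonomy: Dict[str, str] = {}
    per_genome: List[int] = []
    seen_ids: Set[str] = set()
    for rec in manifest:
        if rec.genome_id in seen_ids:
            raise ValueError(f"duplicate genome_id in manifest: {rec.genome_id}")
        seen_ids.add(rec.genome_id)
        try:
            contigs = list(tbio.read_fasta(rec.fasta_path))
        except (OSError, ValueError) as exc:
            raise OSError(
                f"cannot read FASTA for genome {rec.genome_id}: "
                f"{rec.fasta_path} ({exc})"
            ) from exc
        tags: Set[str] = set()
        for _, seq in contigs:
            tags.update(extract_tags(seq, enzyme))
        per_genome.append(len(tags))
        genome_counts[rec.species_id] = genome_counts.get(rec.species_id, 0) + 1
        taxonomy.setdefault(rec.species_id, rec.taxonomy)
        if rec.species_id not in species_tags:
            species_tags[rec.species_id] = tags
        elif mode == "union":
            species_tags[rec.species_id] |= tags
        else:
            species_tags[rec.species_id] &= tags
    return species_tags, genome_counts, taxonomy, per_genome


def build_tag_db(manifest: Iterable[GenomeRecord], enzyme: EnzymeSpec,
                 combine: str = "union", db_version: str = "1") -> TagDB:
    """Build the marker database from a genome manifest.

    Parameters
    ----------
    combine : {"union", "intersection"}
        How conspecific genomes' tag sets are merged.  ``union`` is the
        default (pangenome-sensitive: a marker present in any genome of
        the species counts); ``intersection`` restricts to the core.
    """
    manifest = list(manifest)
    if not manifest:
        raise ValueError("manifest is empty")
    if combine not in ("union", "intersection"):
        raise ValueError(f"combine must be union|intersection, got {combine!r}")
    species_tags, genome_counts, taxonomy, per_genome = _species_tag_sets(
        manifest, enzyme, combine)

    tag_to_species: Dict[str, set] = {}
    for sp, tags in species_tags.items():
        for tag in tags:
            tag_to_species.setdefault(tag, set()).add(sp)
    frozen = {tag: frozenset(spp) for tag, spp in tag_to_species.items()}

    stats = {}
    specific_counts = {sp: 0 for sp in species_tags}
    for tag, spp in frozen.items():
        if len(spp) == 1:
            (sp,) = spp
            specific_counts[sp] += 1
    for sp, tags in species_tags.items():
        stats[sp] = SpeciesTagStats(
            species_id=sp,
            genome_count=genome_counts[sp],
            total_unique_tags=len(tags),
            specific_tag_count=specific_counts[sp],
            taxonomy=taxonomy[sp],
        )
    db = TagDB(
        enzyme=enzyme,
        tag_to_species=frozen,
        species_stats=stats,
        universe=sorted(species_tags),
        db_version=db_version,
    )
    db._per_genome_tag_counts = per_genome  # retained for db_stats
    return db


def build_tag_db_from_sequences(sequences: Dict[str, str], enzyme: EnzymeSpec,
                                taxonomy: Optional[Dict[str, str]] = None,
                                db_version: str = "1") -> TagDB:
    """Build a database from in-memory ``{species_id: sequence}`` genomes
    (one genome per species), bypassing FASTA files.  Used by simulation
    workflows; semantics identical to :func:`build_tag_db`."""
    if not sequences:
        raise ValueError("no sequences supplied")
    taxonomy = taxonomy or {}
    species_tags = {sp: set(extract_tags(seq, enzyme))
                    for sp, seq in sequences.items()}
    tag_to_species: Dict[str, set] = {}
    for sp, tags in species_tags.items():
        for tag in tags:
            tag_to_species.setdefault(tag, set()).add(sp)
    frozen = {tag: frozenset(spp) for tag, spp in tag_to_species.items()}
    specific_counts = {sp: 0 for sp in species_tags}
    for spp in frozen.values():
        if len(spp) == 1:
            specific_counts[next(iter(spp))] += 1
    stats = {
        sp: SpeciesTagStats(
            species_id=sp, genome_count=1, total_unique_tags=len(tags),
            specific_tag_count=specific_counts[sp],
            taxonomy=taxonomy.get(sp, ";".join(_RANKS)),
        )
        for sp, tags in species_tags.items()
    }
    db = TagDB(enzyme=enzyme, tag_to_species=frozen, species_stats=stats,
               universe=sorted(species_tags), db_version=db_version)
    db._per_genome_tag_counts = [len(t) for t in species_tags.values()]
    return db


def species_specific_tags(db: TagDB) -> Dict[str, Set[str]]:
    """Species -> set of tags unique to it.  Sets are pairwise disjoint."""
    out: Dict[str, Set[str]] = {sp: set() for sp in db.universe}
    for tag, sp in db.specific_tag_map.items():
        out[sp].add(tag)
    return out


def subset_db(db: TagDB, candidates: Iterable[str]) -> TagDB:
    """Dynamic, sample-specific database restricted to ``candidates``.

    Tag specificity is recomputed *within* the subset: a tag shared only
    with excluded species becomes specific to its remaining carrier, so
    every candidate's marker count can only grow.
    """
    candidates = set(candidates)
    unknown = candidates - set(db.universe)
    if unknown:
        raise KeyError(f"species not in database universe: {sorted(unknown)}")
    if not candidates:
        raise ValueError("candidate set is empty")
    if not db.keep_shared and candidates != set(db.universe):
        raise ValueError(
            "database was stored without shared tags; cannot recompute "
            "subset specificity (rebuild with keep_shared=True)"
        )
    new_map: Dict[str, frozenset] = {}
    specific_counts = {sp: 0 for sp in candidates}
    total_counts = {sp: 0 for sp in candidates}
    for tag, spp in db.tag_to_species.items():
        kept = spp & candidates
        if not kept:
            continue
        new_map[tag] = frozenset(kept)
        for sp in kept:
            total_counts[sp] += 1
        if len(kept) == 1:
            (sp,) = kept
            specific_counts[sp] += 1
    stats = {}
    for sp in candidates:
        old = db.species_stats[sp]
        stats[sp] = SpeciesTagStats(
            species_id=sp,
            genome_count=old.genome_count,
            total_unique_tags=total_counts[sp],
            specific_tag_count=specific_counts[sp],
            taxonomy=old.taxonomy,
        )
    return TagDB(
        enzyme=db.enzyme,
        tag_to_species=new_map,
        species_stats=stats,
        universe=sorted(candidates),
        db_version=db.db_version,
        keep_shared=db.keep_shared,
    )


# ---------------------------------------------------------------------------
# serialization: plain-text, gzip-transparent; a tags file plus a stats
# sidecar (<path>.stats.tsv) so both are auditable with standard tools.

def _stats_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.name + ".stats.tsv")


def save_db(db: TagDB, path: str | Path, keep_shared: Optional[bool] = None) -> None:
    """Write the database to ``path`` (+ a ``.stats.tsv`` sidecar).

    ``keep_shared=False`` stores only species-specific tags — a smaller
    file, but the dynamic second pass is then unavailable on reload.
    """
    if keep_shared is None:
        keep_shared = db.keep_shared
    enz = db.enzyme
    with tbio.open_text(path, "wt") as handle:
        handle.write(f"#enzyme\t{enz.name}\t{enz.recognition_pattern}"
                     f"\t{enz.left_flank}\t{enz.right_flank}\n")
        handle.write(f"#db_version\t{db.db_version}\n")
        handle.write(f"#keep_shared\t{int(keep_shared)}\n")
        handle.write(f"#species\t{len(db.universe)}\n")
        n_tags = sum(1 for spp in db.tag_to_species.values()
                     if keep_shared or len(spp) == 1)
        handle.write(f"#tags\t{n_tags}\n")
        handle.write("tag\tspecies_ids\n")
        for tag in sorted(db.tag_to_species):
            spp = db.tag_to_species[tag]
            if not keep_shared and len(spp) > 1:
                continue
            handle.write(f"{tag}\t{','.join(sorted(spp))}\n")
    with tbio.open_text(_stats_path(path), "wt") as handle:
        handle.write("species_id\tgenome_count\ttotal_unique_tags"
                     "\tspecific_tag_count\ttaxonomy\n")
        for sp in db.universe:
            st = db.species_stats[sp]
            handle.write(f"{sp}\t{st.genome_count}\t{st.total_unique_tags}"
                         f"\t{st.specific_tag_count}\t{st.taxonomy}\n")


def load_db(path: str | Path, enzyme: Optional[EnzymeSpec] = None) -> TagDB:
    """Load a database written by :func:`save_db`.

    Raises ``ValueError`` (with a line number) on malformed content, and
    when ``enzyme`` is given but does not match the stored definition.
    """
    headers: Dict[str, List[str]] = {}
    tag_to_species: Dict[str, frozenset] = {}
    with tbio.open_text(path) as handle:
        lineno = 0
        body_header_seen = False
        for line in handle:
            lineno += 1
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split("\t")
                headers[fields[0]] = fields[1:]
                continue
            if not body_header_seen:
                if line.split("\t") != ["tag", "species_ids"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'tag<TAB>species_ids' "
                        f"header, got {line!r}"
                    )
                body_header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed tag line {line!r}")
            tag_to_species[parts[0]] = frozenset(parts[1].split(","))
    for key in ("enzyme", "db_version", "tags", "species"):
        if key not in headers:
            raise ValueError(f"{path}: missing #{key} header")
    name, pattern, left, right = headers["enzyme"]
    stored_enzyme = EnzymeSpec(name, pattern, int(left), int(right))
    if enzyme is not None and enzyme != stored_enzyme:
        raise ValueError(
            f"enzyme mismatch: file has {stored_enzyme.name} "
            f"({stored_enzyme.recognition_pattern}), requested {enzyme.name}"
        )
    if len(tag_to_species) != int(headers["tags"][0]):
        raise ValueError(
            f"{path}: truncated — header declares {headers['tags'][0]} tags, "
            f"found {len(tag_to_species)}"
        )
    stats: Dict[str, SpeciesTagStats] = {}
    spath = _stats_path(path)
    with tbio.open_text(spath) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["species_id", "genome_count", "total_unique_tags",
                    "specific_tag_count", "taxonomy"]
        if header != expected:
            raise ValueError(f"{spath}:1: bad stats header {header!r}")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(f"{spath}:{lineno}: malformed stats line")
            stats[parts[0]] = SpeciesTagStats(
                species_id=parts[0], genome_count=int(parts[1]),
                total_unique_tags=int(parts[2]),
                specific_tag_count=int(parts[3]), taxonomy=parts[4],
            )
    if len(stats) != int(headers["species"][0]):
        raise ValueError(
            f"{spath}: truncated — expected {headers['species'][0]} species"
        )
    keep_shared = bool(int(headers.get("keep_shared", ["1"])[0]))
    return TagDB(
        enzyme=stored_enzyme,
        tag_to_species=tag_to_species,
        species_stats=stats,
        universe=sorted(stats),
        db_version=headers["db_version"][0],
        keep_shared=keep_shared,
    )


def db_stats(db: TagDB) -> Dict[str, float]:
    """Summary statistics of a database.

    Reports both the mean distinct tags per *genome* and the mean
    specific markers per *species*, since the two denominators differ
    whenever species have multiple genomes.
    """
    n_species = len(db.universe)
    n_genomes = sum(st.genome_count for st in db.species_stats.values())
    distinct = len(db.tag_to_species)
    per_genome = getattr(db, "_per_genome_tag_counts", None)
    if per_genome:
        mean_per_genome = sum(per_genome) / len(per_genome)
    elif n_genomes:
        # after a load round-trip the per-genome digests are gone; fall
        # back to species totals spread over genome counts
        mean_per_genome = sum(
            st.total_unique_tags for st in db.species_stats.values()
        ) / n_genomes
    else:
        mean_per_genome = 0.0
    mean_specific = (
        sum(st.specific_tag_count for st in db.species_stats.values()) / n_species
        if n_species else 0.0
    )
    return {
        "genome_count": n_genomes,
        "species_count": n_species,
        "distinct_tag_count": distinct,
        "mean_tags_per_genome": mean_per_genome,
        "mean_specific_tags_per_species": mean_specific,
    }
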