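"""Standard-format I/O: FASTA/FASTQ (gzip transparent) and profile TSVs."""

from __future__ import annotations

import gzip
import io
import warnings
from pathlib import Path
from typing import IO, Dict, Iterator, List, Tuple

import pandas as pd
from Bio import SeqIO

__all__ = [
    "open_text",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_profile_tsv",
    "write_profile_tsv",
    "read_abundance_tsv",
    "write_abundance_tsv",
]

PROFILE_COLUMNS = [
    "sample_id", "species_id", "taxonomy", "reads_assigned",
    "markers_detected", "markers_total", "g_score", "coverage",
    "reads_after_decontam", "relative_abundance",
]


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open ``path`` for text I/O, transparently handling ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> Iterator[Tuple[str, str]]:
    """Yield ``(record_id, uppercased_sequence)`` from a FASTA file."""
    with open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id, str(rec.seq).upper()


def write_fasta(records: Iterator[Tuple[str, str]], path: str | Path) -> None:
    with open_text(path, "wt") as handle:
        for rec_id, seq in records:
            handle.write(f">{rec_id}\n")
            for i in range(0, len(seq), 80):
                handle.write(seq[i:i + 80] + "\n")


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield uppercased read sequences from a FASTQ file.

    Records are validated (4-line structure, sequence/quality length
    agreement) by the underlying parser; a malformed record raises
    ``ValueError`` carrying the record index.
    """
    with open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
            try:
                yield str(rec.seq).upper()
            except ValueError as exc:  # pragma: no cover - parser detail
                raise ValueError(f"malformed FASTQ record {i}: {exc}") from exc


def write_fastq(reads: Iterator[str], path: str | Path,
                sample_id: str = "sample", quality_char: str = "I") -> None:
    with open_text(path, "wt") as handle:
        for i, read in enumerate(reads):
            handle.write(f"@{sample_id}.{i}\n{read}\n+\n{quality_char * len(read)}\n")


def write_profile_tsv(profile, path: str | Path) -> None:
    """Serialize a :class:`~twobrad.profiler.SampleProfile` as TSV.

    Header comment lines record the run configuration and the read
    accounting (total, host, shared, unassigned) so the file is
    self-describing.
    """
    cfg = profile.params
    lines = [
        f"#sample_id\t{profile.sample_id}",
        f"#total_reads\t{profile.total_reads}",
        f"#host_reads\t{profile.host_reads}",
        f"#shared_tag_reads\t{profile.shared_tag_reads}",
        f"#unassigned_reads\t{profile.unassigned_reads}",
        f"#g_min\t{cfg.g_min}",
        f"#decontam_mode\t{cfg.decontam_mode}",
        f"#two_pass\t{cfg.two_pass}",
        f"#host_exclusion\t{cfg.host_exclusion}",
    ]
    with open_text(path, "wt") as handle:
        handle.write("\n".join(lines) + "\n")
        handle.write("\t".join(PROFILE_COLUMNS) + "\n")
        for h in profile.hits:
            handle.write("\t".join(str(v) for v in (
                profile.sample_id, h.species_id, h.taxonomy, h.reads_assigned,
                h.markers_detected, h.markers_total,
                f"{h.g_score:.6f}", f"{h.coverage:.6g}",
                h.reads_after_decontam, f"{h.relative_abundance:.10g}",
            )) + "\n")


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    """Read a profile TSV into a DataFrame; header comments become attrs."""
    meta: Dict[str, str] = {}
    with open_text(path) as handle:
        pos = handle.tell()
        line = handle.readline()
        while line.startswith("#"):
            key, _, val = line[1:].rstrip("\n").partition("\t")
            meta[key] = val
            pos = handle.tell()
            line = handle.readline()
        handle.seek(pos)
        df = pd.read_csv(handle, sep="\t")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile file {path} missing columns: {missing}")
    df.attrs.update(meta)
    return df


def write_abundance_tsv(abundances: Dict[str, float], path: str | Path) -> None:
    """Write a two-column ``taxon<TAB>relative_abundance`` table."""
    with open_text(path, "wt") as handle:
        handle.write("taxon_id\trelative_abundance\n")
        for taxon, a in abundances.items():
            handle.write(f"{taxon}\t{a:.10g}\n")


def read_abundance_tsv(path: str | Path) -> Dict[str, float]:
    """Read a taxon->abundance table (either the two-column format or a
    full profile TSV, from which the abundance column is taken).

    Warns when a table declared as relative abundances does not sum to 1
    within 1e-6; values are returned as stored, not renormalized.
    """
    df = None
    with open_text(path) as handle:
        head = handle.readline()
        handle.seek(0)
        if head.startswith("#") or "species_id" in head:
            pass  # full profile
        else:
            df = pd.read_csv(handle, sep="\t")
    if df is not None and "taxon_id" in df.columns:
        result = dict(zip(df["taxon_id"], df["relative_abundance"].astype(float)))
    else:
        prof = read_profile_tsv(path)
        result = dict(zip(prof["species_id"],
                          prof["relative_abundance"].astype(float)))
    total = sum(result.values())
    if result and abs(total - 1.0) > 1e-6:
        warnings.warn(
            f"abundances in {path} sum to {total:.6g}, not 1", stacklevel=2
        )
    return result
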