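"""Type IIB restriction enzyme models and in silico digestion.

A Type IIB enzyme binds a (usually degenerate) recognition sequence and
cleaves both upstream and downstream of it, excising a fragment of fixed
length.  For BcgI the recognition sequence is CGANNNNNNTGC (12 nt) and the
excised tag is 32 bp: 10 nt flank + site + 10 nt flank.  Because the enzyme
cuts double-stranded DNA, a tag has no intrinsic orientation; tags are
identified by their canonical form, the lexicographic minimum of the
sequence and its reverse complement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, List

__all__ = [
    "IUPAC",
    "EnzymeSpec",
    "TagSite",
    "BCGI",
    "ENZYMES",
    "reverse_complement",
    "canonicalize",
    "iupac_match",
    "find_recognition_sites",
    "extract_tags",
]

#: IUPAC nucleotide codes -> set of matched bases.  A concrete pattern base
#: does not match an ambiguous 'N' in the subject; only pattern 'N' does.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(tag: str) -> str:
    """Canonical (strand-independent) form of a tag.

    Returns the lexicographic minimum of ``tag`` and its reverse
    complement, so that the two strands of one restriction fragment map to
    a single identifier.  Idempotent.

    Raises
    ------
    ValueError
        If ``tag`` contains characters outside A/C/G/T.
    """
    if not tag or any(b not in "ACGT" for b in tag):
        raise ValueError(f"tag must be non-empty and contain only A/C/G/T: {tag!r}")
    rc = tag.translate(_COMPLEMENT)[::-1]
    return tag if tag <= rc else rc


@dataclass(frozen=True)
class EnzymeSpec:
    """Definition of a Type IIB restriction enzyme.

    Parameters
    ----------
    name : str
        Enzyme name, e.g. ``"BcgI"``.
    recognition_pattern : str
        IUPAC recognition sequence on the forward strand.
    left_flank, right_flank : int
        Number of excised bases upstream/downstream of the recognition
        site (relative to a forward-strand match).
    """

    name: str
    recognition_pattern: str
    left_flank: int
    right_flank: int

    def __post_init__(self) -> None:
        bad = [c for c in self.recognition_pattern if c not in IUPAC]
        if bad:
            raise ValueError(
                f"recognition pattern contains non-IUPAC characters: {bad}"
            )
        if self.left_flank < 0 or self.right_flank < 0:
            raise ValueError("flank lengths must be non-negative")

    @property
    def tag_length(self) -> int:
        """Length of the excised tag: left flank + site + right flank."""
        return self.left_flank + len(self.recognition_pattern) + self.right_flank

    def _regexes(self) -> tuple[re.Pattern, re.Pattern]:
        return (_pattern_regex(self.recognition_pattern),
                _pattern_regex(reverse_complement(self.recognition_pattern)))


#: BcgI: CGANNNNNNTGC with 10 nt flanks on each side -> 32 bp tags
#: (10 + 12 + 10), following the REBASE geometry for this enzyme.
BCGI = EnzymeSpec("BcgI", "CGANNNNNNTGC", 10, 10)

#: Registry of built-in Type IIB enzymes; extendable by callers.
ENZYMES = {"BcgI": BCGI}


@dataclass(frozen=True)
class TagSite:
    """A digested tag located on a reference sequence.

    ``start`` is the 0-based position of the tag window on the forward
    strand; ``strand`` records the orientation of the recognition match.
    """

    contig_id: str
    start: int
    strand: str  # '+' or '-'
    tag: str
    canonical_tag: str


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for c in pattern:
        bases = IUPAC[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def iupac_match(pattern: str, window: str) -> bool:
    """True iff every base of ``window`` is in the IUPAC set of the
    corresponding ``pattern`` character.

    An ambiguous 'N' in the window matches nothing except pattern 'N'
    (an uncalled base cannot be claimed by a concrete pattern base).

    Raises
    ------
    ValueError
        On length mismatch or a non-IUPAC pattern character.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    for pc, wc in zip(pattern, window):
        try:
            allowed = IUPAC[pc]
        except KeyError:
            raise ValueError(f"invalid IUPAC code in pattern: {pc!r}") from None
        if wc not in allowed:
            return False
    return True


def find_recognition_sites(seq: str, enzyme: EnzymeSpec,
                           contig_id: str = "") -> List[TagSite]:
    """Locate all tags excised from ``seq`` by ``enzyme``.

    Both orientations of the recognition pattern are scanned on the
    forward strand.  A site is emitted only when the full tag window fits
    within the sequence and contains no N (no partial tags).  A locus
    matching in both orientations yields a single site: duplicates on
    (contig, start, canonical tag) are collapsed.
    """
    seq = seq.upper()
    plen = len(enzyme.recognition_pattern)
    tlen = enzyme.tag_length
    fwd_re, rev_re = enzyme._regexes()
    sites: List[TagSite] = []
    seen = set()
    # (regex, strand, offset of window start relative to recognition start)
    for regex, strand, upstream in (
        (fwd_re, "+", enzyme.left_flank),
        (rev_re, "-", enzyme.right_flank),
    ):
        for m in regex.finditer(seq):
            start = m.start() - upstream
            if start < 0 or start + tlen > len(seq):
                continue
            tag = seq[start:start + tlen]
            if "N" in tag:
                continue
            canon = canonicalize(tag)
            key = (contig_id, start, canon)
            if key in seen:
                continue
            seen.add(key)
            sites.append(TagSite(contig_id, start, strand, tag, canon))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def extract_tags(seq: str, enzyme: EnzymeSpec) -> List[str]:
    """Canonical tags excised from ``seq``, multiplicities preserved.

    Deduplication (for database construction) is the caller's concern;
    digestion itself reports every distinct locus.
    """
    return [s.canonical_tag for s in find_recognition_sites(seq, enzyme)]


def digest_fasta(records: Iterator[tuple[str, str]],
                 enzyme: EnzymeSpec) -> Iterator[TagSite]:
    """Digest an ``(id, sequence)`` iterator contig by contig."""
    for contig_id, seq in records:
        yield from find_recognition_sites(seq, enzyme, contig_id=contig_id)
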