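"""AU-rich element (ARE) scanning of 3'UTR sequences.

The ARE is operationalised as the literal heptamer ``TATTTAT``
(``UAUUUAU`` on the RNA strand), the destabilising element recognised
by ZFP36-family RNA-binding proteins.  Sequences are case-folded and
transliterated U->T before scanning, so DNA and RNA inputs are
equivalent.  Matches are reported as 0-based half-open intervals on the
sense strand; overlapping occurrences are all reported, and ``N`` (or
any other ambiguity code) never matches in literal mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

DEFAULT_MOTIF = "TATTTAT"

_ALLOWED_CHARS = frozenset("ACGTUN")

# IUPAC nucleotide codes, used only when degenerate matching is requested.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,U,N}."""


def normalize_sequence(sequence: str, gene_id: str | None = None) -> str:
    """Case-fold a nucleotide string and map U to T, validating the alphabet.

    Parameters
    ----------
    sequence
        Nucleotide string over ``{A, C, G, T, U, N}``, case-insensitive.
    gene_id
        Optional identifier used in error messages.

    Returns
    -------
    str
        Upper-case DNA-alphabet string (U replaced by T).

    Raises
    ------
    SequenceValidationError
        If any character falls outside the allowed alphabet; the message
        names the offending gene (when given) and 0-based position.
    """
    upper = sequence.upper()
    for pos, char in enumerate(upper):
        if char not in _ALLOWED_CHARS:
            where = f" in gene {gene_id!r}" if gene_id else ""
            raise SequenceValidationError(
                f"illegal character {char!r} at position {pos}{where}; "
                "allowed alphabet is A/C/G/T/U/N (case-insensitive)"
            )
    return upper.replace("U", "T")


@dataclass(frozen=True)
class UTRRecord:
    """A single 3'UTR sequence.

    ``sequence`` preserves the input exactly as read (for echo-back);
    ``normalized`` is the upper-case DNA-alphabet form used for scanning.
    """

    gene_id: str
    sequence: str
    normalized: str = field(repr=False, default="")

    def __post_init__(self) -> None:
        if not self.normalized:
            object.__setattr__(
                self, "normalized", normalize_sequence(self.sequence, self.gene_id)
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AREHit:
    """One motif occurrence within a UTR, in 0-based half-open coordinates."""

    gene_id: str
    start: int
    end: int
    matched_text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid hit interval [{self.start}, {self.end})")


def read_utr_fasta(path: str | Path) -> list[UTRRecord]:
    """Read 3'UTR sequences from a FASTA file.

    The first whitespace-delimited token of each header is the gene id.
    Records are returned in file order.  Duplicate gene ids and illegal
    sequence characters are errors.
    """
    path = Path(path)
    with open(path) as handle:
        # Reject files whose first non-blank content is not a header line;
        # Bio.SeqIO silently returns nothing for such files.
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:40]!r}"
                    )
                break

    records: list[UTRRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        gene_id = entry.id
        if gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        records.append(UTRRecord(gene_id=gene_id, sequence=str(entry.seq)))
    return records


def _degenerate_pattern(motif: str) -> re.Pattern[str]:
    parts = []
    for char in motif:
        bases = _IUPAC.get(char)
        if bases is None:
            raise ValueError(f"motif character {char!r} is not an IUPAC code")
        parts.append(f"[{bases}]" if len(bases) > 1 else bases)
    # Lookahead so overlapping occurrences are all found.
    return re.compile("(?=(" + "".join(parts) + "))")


def find_are_sites(
    sequence: str,
    motif: str = DEFAULT_MOTIF,
    *,
    degenerate: bool = False,
) -> list[tuple[int, int]]:
    """Locate every occurrence of the motif in a sequence.

    Both strings are normalised (case-folded, U==T) before matching, so
    ``UAUUUAU`` finds ``TATTTAT`` sites and vice versa.  All occurrences
    are returned, including overlapping ones, sorted by start.  Only the
    sense strand is scanned.  In the default literal mode ``N`` never
    matches; with ``degenerate=True`` the motif may contain IUPAC
    ambiguity codes (the sequence side must still be concrete bases).

    Parameters
    ----------
    sequence
        Nucleotide string (DNA or RNA alphabet, case-insensitive).
    motif
        Non-empty motif; default is the ARE heptamer.
    degenerate
        Interpret IUPAC codes in the motif.  Off by default: the screen
        uses the literal heptamer.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = normalize_sequence(sequence)
    # The motif is not forced through sequence validation: in literal mode
    # an ambiguity code in the motif simply never matches a validated
    # sequence, and in degenerate mode IUPAC codes are expanded.
    pat = motif.upper().replace("U", "T")
    if degenerate:
        return [(m.start(), m.start() + len(pat)) for m in _degenerate_pattern(pat).finditer(seq)]
    hits: list[tuple[int, int]] = []
    start = seq.find(pat)
    while start != -1:
        hits.append((start, start + len(pat)))
        start = seq.find(pat, start + 1)
    return hits


def scan_utr_set(
    records: Iterable[UTRRecord],
    motif: str = DEFAULT_MOTIF,
    *,
    degenerate: bool = False,
) -> tuple[dict[str, list[AREHit]], set[str]]:
    """Scan a collection of UTRs and report per-gene hits and ARE status.

    Returns
    -------
    (hits, are_positive)
        ``hits`` maps gene_id to its list of :class:`AREHit` (genes with
        zero hits are absent); ``are_positive`` is the set of gene ids
        with at least one hit.
    """
    hits: dict[str, list[AREHit]] = {}
    positive: set[str] = set()
    for rec in records:
        sites = find_are_sites(rec.normalized, motif, degenerate=degenerate)
        if sites:
            hits[rec.gene_id] = [
                AREHit(rec.gene_id, s, e, rec.sequence[s:e]) for s, e in sites
            ]
            positive.add(rec.gene_id)
    return hits, positive


def write_hits_bed(
    hits: Mapping[str, Sequence[AREHit]],
    path: str | Path,
    motif: str = DEFAULT_MOTIF,
) -> None:
    """Write hits as BED6 lines (gene id as the chrom surrogate).

    Coordinates are 0-based half-open; name is the motif, score 0,
    strand ``+``.
    """
    with open(path, "w") as out:
        for gene_id in hits:
            for hit in hits[gene_id]:
                out.write(f"{gene_id}\t{hit.start}\t{hit.end}\t{motif}\t0\t+\n")


def read_hits_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Re-parse a BED file written by :func:`write_hits_bed`."""
    out: list[tuple[str, int, int]] = []
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out
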