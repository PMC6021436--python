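"""Sequence and coordinate primitives, plus readers/writers for the formats the toolkit touches.

The toolkit works in two coordinate conventions:

* **Internal**: 0-based, half-open intervals on the supplied sequence. All
  arithmetic is done here.
* **Reporting**: the promoter-biology convention where the transcription
  start site (TSS) is position +1, the first base upstream is −1, and there
  is no position 0. :meth:`PromoterRecord.signed_position` converts.

Sequences are normalized on ingest: lowercase is uppercased, ``U`` becomes
``T`` (with a warning), and any IUPAC ambiguity code other than ``N`` is
rejected with the offending record and offset named.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FORWARD = "forward"
REVERSE = "reverse"


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def normalize_bases(raw: str, record_id: str = "") -> str:
    """Uppercase, convert U->T (warning), reject non-{ACGTN} characters.

    The offending record id and 0-based offset are reported so users can
    locate bad bases in large FASTA files.
    """
    bases = raw.upper()
    if "U" in bases:
        warnings.warn(
            f"record {record_id!r}: RNA-style 'U' bases converted to 'T'",
            stacklevel=2,
        )
        bases = bases.replace("U", "T")
    for offset, ch in enumerate(bases):
        if ch not in VALID_BASES:
            raise SequenceAlphabetError(
                f"record {record_id!r}: invalid base {ch!r} at offset {offset} "
                "(only A/C/G/T/N accepted; other ambiguity codes are rejected)"
            )
    if not bases:
        raise SequenceAlphabetError(f"record {record_id!r}: empty sequence")
    return bases


@dataclass(frozen=True)
class NucSequence:
    """A validated DNA sequence with an identifier.

    ``bases`` is guaranteed non-empty and restricted to {A,C,G,T,N} after
    construction; pass raw user input through :func:`normalize_bases` (or the
    readers in this module, which do it for you).
    """

    bases: str
    id: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise SequenceAlphabetError(f"record {self.id!r}: empty sequence")
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise SequenceAlphabetError(
                f"record {self.id!r}: invalid bases {sorted(bad)} "
                "(normalize input with normalize_bases first)"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @classmethod
    def from_raw(cls, raw: str, id: str = "") -> "NucSequence":
        return cls(normalize_bases(raw, id), id)


def reverse_complement(seq):
    """Watson-Crick reverse complement; N maps to N. Accepts str or NucSequence."""
    if isinstance(seq, NucSequence):
        return NucSequence(seq.bases.translate(_COMPLEMENT)[::-1], seq.id)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter sequence anchored by its TSS.

    ``tss_index`` is the 0-based offset of the +1 base of the transcript.
    ``gene_strand`` says which way the gene reads relative to the stored
    sequence: ``forward`` genes have their upstream region at lower
    coordinates, ``reverse`` genes at higher coordinates.
    """

    seq: NucSequence
    tss_index: int
    gene_strand: str = FORWARD

    def __post_init__(self) -> None:
        if not 0 <= self.tss_index < len(self.seq):
            raise ValueError(
                f"tss_index {self.tss_index} outside sequence of length {len(self.seq)}"
            )
        if self.gene_strand not in (FORWARD, REVERSE):
            raise ValueError(f"gene_strand must be 'forward' or 'reverse'")

    def upstream_distance(self, index: int) -> int:
        """Bases upstream of the TSS for a 0-based sequence index.

        Positive upstream of the +1 base, 0 at the TSS itself, negative
        downstream (inside the transcript).
        """
        if self.gene_strand == FORWARD:
            return self.tss_index - index
        return index - self.tss_index

    def signed_position(self, index: int) -> int:
        """Reporting-convention position: TSS = +1, first upstream base = −1."""
        d = self.upstream_distance(index)
        return -d if d >= 1 else 1 - d


def read_fasta(path) -> list[NucSequence]:
    """Read a FASTA file into a list of normalized NucSequence records.

    Raises on an empty file and on any base outside {A,C,G,T,N}.
    """
    records = [
        NucSequence(normalize_bases(str(rec.seq), rec.id), rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[NucSequence], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s.bases), id=s.id or f"seq{i}", description="") for i, s in enumerate(seqs)),
        str(path),
        "fasta",
    )


def read_tss_table(path) -> dict[str, tuple[int, str]]:
    """Read the side-car TSS annotation: record id, 1-based TSS, gene strand.

    Returns ``{record_id: (tss_index_0based, gene_strand)}``. The strand
    column accepts forward/reverse or +/−.
    """
    strand_alias = {"forward": FORWARD, "+": FORWARD, "reverse": REVERSE, "-": REVERSE}
    table: dict[str, tuple[int, str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
        rec_id, tss_1based, strand = fields[0], int(fields[1]), fields[2].lower()
        if tss_1based < 1:
            raise ValueError(f"{path}:{lineno}: TSS position is 1-based, got {tss_1based}")
        if strand not in strand_alias:
            raise ValueError(f"{path}:{lineno}: unknown strand {fields[2]!r}")
        table[rec_id] = (tss_1based - 1, strand_alias[strand])
    if not table:
        raise ValueError(f"{path}: no TSS annotations found")
    return table


def write_tss_table(table: dict[str, tuple[int, str]], path) -> None:
    lines = [f"{rid}\t{tss0 + 1}\t{strand}" for rid, (tss0, strand) in table.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def promoters_from_files(fasta_path, tss_path) -> list[PromoterRecord]:
    """Join a FASTA file with its TSS annotation table into PromoterRecords."""
    table = read_tss_table(tss_path)
    promoters = []
    for seq in read_fasta(fasta_path):
        if seq.id not in table:
            raise KeyError(f"no TSS annotation for record {seq.id!r}")
        tss, strand = table[seq.id]
        promoters.append(PromoterRecord(seq, tss, strand))
    return promoters


def write_sites_bed(sites: Sequence, promoter: PromoterRecord, path) -> None:
    """Write target sites as BED6: protospacer+PAM interval, label, scaled score, strand.

    Scores are scaled from [0, 1] to the BED convention [0, 1000]. An empty
    site list yields an empty file.
    """
    lines = []
    for site in sites:
        iv = site.interval
        if iv.end > len(promoter.seq):
            raise ValueError(
                f"site interval [{iv.start}, {iv.end}) outside sequence "
                f"of length {len(promoter.seq)}"
            )
        score = int(round(1000 * (site.window_score or 0.0)))
        lines.append(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{site.label}\t{score}\t{iv.strand}")
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_bed6(path) -> list[tuple[GenomicInterval, str, int]]:
    """Parse a BED6 file back into (interval, name, score) tuples."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        seq_id, start, end, name, score, strand = line.split("\t")[:6]
        out.append((GenomicInterval(seq_id, int(start), int(end), strand), name, int(score)))
    return out
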