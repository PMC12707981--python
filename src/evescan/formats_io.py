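"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (plain or gzip, detected by magic bytes), BLAST/DIAMOND-style
tabular hits (14-column dialect, configurable), NCBI taxdump (``nodes.dmp`` /
``names.dmp``), BED6, and the run summary TSV.

Internal coordinates are canonical 0-based half-open with an explicit strand;
the tabular dialect (1-based inclusive, orientation-encoded strand) is
converted at the parse boundary only.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from evescan.loci import CandidateLocus

__all__ = [
    "SequenceRecord",
    "Hit",
    "TaxonomyDB",
    "DEFAULT_HIT_COLUMNS",
    "SUMMARY_COLUMNS",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "parse_tabular_hits",
    "write_tabular_hits",
    "load_taxdump",
    "write_bed",
    "write_summary",
]

DNA_ALPHABET = frozenset("ACGTUNRYSWKMBDHV-")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBJOUXZ*-")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` is the full header line (without ``>``).
    """

    id: str
    description: str
    seq: str
    moltype: str = "dna"  # "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SequenceRecord {self.id!r}: empty sequence")
        if self.moltype not in ("dna", "protein"):
            raise ValueError(f"unknown moltype {self.moltype!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Hit:
    """One row of tabular search output.

    ``qstart``/``qend`` and ``sstart``/``send`` keep the source dialect
    (1-based inclusive, minus strand encoded as ``sstart > send``);
    ``canon_start``/``canon_end`` are 0-based half-open on the subject with
    ``canon_start < canon_end`` and the orientation carried by ``strand``.
    """

    qseqid: str
    sseqid: str
    pident: float
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    stitle: str = ""
    staxids: tuple[int, ...] = ()
    strand: str = "+"
    canon_start: int = 0
    canon_end: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.qseqid}/{self.sseqid}: negative evalue")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @classmethod
    def from_dialect(cls, **fields) -> "Hit":
        """Build a Hit from raw dialect fields, deriving strand and canonical
        subject coordinates from the ``sstart``/``send`` orientation."""
        sstart, send = fields["sstart"], fields["send"]
        fields.setdefault("strand", "-" if sstart > send else "+")
        fields.setdefault("canon_start", min(sstart, send) - 1)
        fields.setdefault("canon_end", max(sstart, send))
        return cls(**fields)


DEFAULT_HIT_COLUMNS: tuple[str, ...] = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "stitle", "staxids",
)

_INT_COLS = {"length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"}
_FLOAT_COLS = {"pident", "evalue", "bitscore"}
_COLUMN_TO_FIELD = {"length": "aln_len"}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain or gzipped text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, moltype: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file (plain or gzip) into :class:`SequenceRecord` objects.

    Sequences are uppercased; wrapped lines and CRLF endings are handled.
    Characters outside the IUPAC alphabet for ``moltype`` raise
    :class:`FormatError` naming the record and 1-based position.
    """
    alphabet = DNA_ALPHABET if moltype == "dna" else PROTEIN_ALPHABET
    records: list[SequenceRecord] = []
    rec_id = ""
    description = ""
    parts: list[str] = []

    def flush() -> None:
        if not rec_id:
            return
        seq = "".join(parts).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec_id!r} has no sequence")
        for pos, ch in enumerate(seq, start=1):
            if ch not in alphabet:
                raise FormatError(
                    f"{path}: record {rec_id!r} has illegal {moltype} "
                    f"character {ch!r} at position {pos}"
                )
        records.append(SequenceRecord(rec_id, description, seq, moltype))

    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: empty FASTA header")
                rec_id = header.split()[0]
                description = header
                parts = []
            elif line.strip():
                if not rec_id:
                    raise FormatError(f"{path}: sequence data before first header")
                parts.append(line.strip())
        flush()

    if not records:
        raise FormatError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular hits
# ---------------------------------------------------------------------------

def parse_tabular_hits(path: str | Path,
                       columns: Sequence[str] = DEFAULT_HIT_COLUMNS) -> list[Hit]:
    """Parse a BLAST/DIAMOND outfmt-6-style TSV into :class:`Hit` records.

    ``staxids`` is split on ``;``; strand and canonical coordinates are derived
    from the subject coordinate orientation. No filtering is applied here.
    """
    columns = tuple(columns)
    n_required = len(columns)
    # stitle / staxids may be absent from the tail of the column spec
    optional_tail = 0
    for col in reversed(columns):
        if col in ("stitle", "staxids"):
            optional_tail += 1
        else:
            break

    hits: list[Hit] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not (n_required - optional_tail <= len(parts) <= n_required):
                raise FormatError(
                    f"{path}:{lineno}: expected {n_required} tab-separated "
                    f"columns, got {len(parts)}"
                )
            fields: dict = {"stitle": "", "staxids": ()}
            for col, value in zip(columns, parts):
                name = _COLUMN_TO_FIELD.get(col, col)
                try:
                    if col in _INT_COLS:
                        fields[name] = int(value)
                    elif col in _FLOAT_COLS:
                        fields[name] = float(value)
                    elif col == "staxids":
                        fields[name] = tuple(
                            int(t) for t in value.split(";") if t.strip()
                        )
                    else:
                        fields[name] = value
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: unparseable value {value!r} "
                        f"for field {col!r}"
                    ) from exc
            hits.append(Hit.from_dialect(**fields))
    return hits


def write_tabular_hits(hits: Iterable[Hit], path: str | Path,
                       columns: Sequence[str] = DEFAULT_HIT_COLUMNS) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            parts = []
            for col in columns:
                name = _COLUMN_TO_FIELD.get(col, col)
                value = getattr(hit, name)
                if col == "staxids":
                    parts.append(";".join(str(t) for t in value))
                else:
                    parts.append(str(value))
            fh.write("\t".join(parts) + "\n")


# ---------------------------------------------------------------------------
# NCBI taxdump
# ---------------------------------------------------------------------------

class TaxonomyDB:
    """taxid → parent/rank/name mapping supporting lineage queries."""

    ROOT = 1

    def __init__(self, parents: dict[int, int], ranks: dict[int, str],
                 names: dict[int, str]):
        self.parents = parents
        self.ranks = ranks
        self.names = names
        self._validate()

    def _validate(self) -> None:
        orphans = sorted(
            t for t, p in self.parents.items()
            if p not in self.parents and t != self.ROOT
        )
        if orphans:
            raise FormatError(f"taxdump: orphan taxids (parent absent): {orphans}")
        for taxid in self.parents:
            seen = set()
            node = taxid
            while node != self.ROOT:
                if node in seen:
                    raise FormatError(f"taxdump: cycle involving taxid {node}")
                seen.add(node)
                node = self.parents[node]

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parents

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from ``taxid`` up to and including the root."""
        if taxid not in self.parents:
            raise KeyError(f"unknown taxid {taxid}")
        out = [taxid]
        while out[-1] != self.ROOT:
            out.append(self.parents[out[-1]])
        return out

    def name(self, taxid: int) -> str:
        return self.names.get(taxid, "")

    def rank(self, taxid: int) -> str:
        return self.ranks.get(taxid, "no rank")

    def rank_name(self, taxid: int, rank: str) -> str | None:
        """Scientific name of the ancestor (or self) at ``rank``, or None."""
        if taxid not in self.parents:
            return None
        for node in self.lineage(taxid):
            if self.ranks.get(node) == rank:
                return self.names.get(node)
        return None

    def superkingdom(self, taxid: int) -> str | None:
        # NCBI renamed the rank to "domain" in 2024; accept either spelling.
        return self.rank_name(taxid, "superkingdom") or self.rank_name(taxid, "domain")

    def kingdom(self, taxid: int) -> str | None:
        return self.rank_name(taxid, "kingdom")

    def family(self, taxid: int) -> str | None:
        return self.rank_name(taxid, "family")

    def is_viral(self, taxid: int) -> bool:
        return (self.superkingdom(taxid) or "").lower() == "viruses"

    def is_eukaryotic(self, taxid: int) -> bool:
        return (self.superkingdom(taxid) or "").lower() == "eukaryota"


def load_taxdump(nodes_path: str | Path, names_path: str | Path) -> TaxonomyDB:
    """Load ``nodes.dmp`` + ``names.dmp`` (NCBI dmp dialect, ``\\t|\\t``
    delimited). Only names of class "scientific name" are kept."""
    parents: dict[int, int] = {}
    ranks: dict[int, str] = {}
    with _open_text(nodes_path) as fh:
        for raw in fh:
            line = raw.rstrip("\r\n").rstrip("|").rstrip("\t")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t|\t")]
            if len(parts) < 3:
                raise FormatError(f"{nodes_path}: malformed row {raw!r}")
            taxid, parent, rank = int(parts[0]), int(parts[1]), parts[2]
            parents[taxid] = parent
            ranks[taxid] = rank

    names: dict[int, str] = {}
    with _open_text(names_path) as fh:
        for raw in fh:
            line = raw.rstrip("\r\n").rstrip("|").rstrip("\t")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t|\t")]
            if len(parts) < 4:
                raise FormatError(f"{names_path}: malformed row {raw!r}")
            taxid, name, _unique, name_class = int(parts[0]), parts[1], parts[2], parts[3]
            if name_class == "scientific name":
                names[taxid] = name

    return TaxonomyDB(parents, ranks, names)


# ---------------------------------------------------------------------------
# BED / summary writers
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS: tuple[str, ...] = (
    "locus_id", "contig", "start", "end", "strand", "category",
    "best_forward_hit", "best_rvdb_hit", "best_nr_hit",
    "n_stops", "n_insertions", "n_deletions", "n_frameshifts",
    "pident", "protein_coverage", "n_orfs",
)


def _sorted_loci(loci: Sequence["CandidateLocus"]) -> list["CandidateLocus"]:
    for locus in loci:
        if locus.canon_start >= locus.canon_end:
            raise ValueError(
                f"locus {locus.locus_id}: start {locus.canon_start} >= end "
                f"{locus.canon_end}"
            )
    return sorted(loci, key=lambda l: (l.contig, l.canon_start, l.canon_end))


def _best_hit_id(hits: Sequence[Hit]) -> str:
    if not hits:
        return "."
    best = max(hits, key=lambda h: (h.bitscore, -h.evalue, h.sseqid))
    return best.sseqid


def write_bed(loci: Sequence["CandidateLocus"], path: str | Path) -> None:
    """BED6: chrom, start, end, name, score (best forward bitscore), strand.

    0-based half-open, rows sorted by (contig, start, end). A 'both'-strand
    locus is written with BED's '.' strand.
    """
    with open(path, "w") as fh:
        for locus in _sorted_loci(loci):
            best = max(h.bitscore for h in locus.forward_hits)
            strand = locus.strand if locus.strand in ("+", "-") else "."
            fh.write(
                f"{locus.contig}\t{locus.canon_start}\t{locus.canon_end}\t"
                f"{locus.locus_id}\t{best:g}\t{strand}\n"
            )


def write_summary(loci: Sequence["CandidateLocus"], path: str | Path) -> None:
    """One TSV row per locus with coordinates, category, best hits per table,
    reconstruction counts and ORF count. Header always written."""
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for locus in _sorted_loci(loci):
            rec = locus.reconstruction
            row = [
                locus.locus_id, locus.contig,
                str(locus.canon_start), str(locus.canon_end), locus.strand,
                locus.category or ".",
                _best_hit_id(locus.forward_hits),
                _best_hit_id(locus.rvdb_hits),
                _best_hit_id(locus.nr_hits),
                str(rec.n_stops) if rec else ".",
                str(rec.n_insertions) if rec else ".",
                str(rec.n_deletions) if rec else ".",
                str(rec.n_frameshifts) if rec else ".",
                f"{rec.pident:.2f}" if rec else ".",
                f"{rec.protein_coverage:.4f}" if rec else ".",
                str(len(locus.orfs)),
            ]
            fh.write("\t".join(row) + "\n")
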