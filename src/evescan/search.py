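"""Forward and reciprocal hit production.

Three engines emit the same :class:`~evescan.formats_io.Hit` records:

* ``external`` — invoke a DIAMOND binary on the PATH;
* ``precomputed`` — ingest an existing tabular file (see
  :func:`evescan.formats_io.parse_tabular_hits`);
* ``builtin`` — a test/desk-scale six-frame translated Smith–Waterman
  aligner (O(m*n) per frame; the CLI warns above a size guard).

E-values from the builtin aligner use fixed published Karlin–Altschul
parameters and are approximate; they exist so the same filtering code paths
run without an external binary.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq

from evescan._align import (
    LocalAlignment,
    bitscore_from_raw,
    evalue_from_bitscore,
    smith_waterman,
)
from evescan.chunking import hit_sort_key
from evescan.formats_io import (
    DEFAULT_HIT_COLUMNS,
    Hit,
    SequenceRecord,
    parse_tabular_hits,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SearchParams",
    "EngineUnavailableError",
    "ExternalSearchError",
    "sixframe_search",
    "builtin_search",
    "protein_search",
    "filter_and_rank",
    "run_external_search",
]

SIZE_GUARD_BP = 5_000_000


@dataclass(frozen=True)
class SearchParams:
    evalue_max: float = 1e-5
    per_query_top_hits: int = 10
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_raw_score: int = 50

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.per_query_top_hits < 1:
            raise ValueError("per_query_top_hits must be >= 1")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")


class EngineUnavailableError(RuntimeError):
    """The requested external search binary is not available."""


class ExternalSearchError(RuntimeError):
    """The external search binary ran but failed."""


# ---------------------------------------------------------------------------
# Builtin six-frame translated aligner
# ---------------------------------------------------------------------------

def _revcomp(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def _frames(dna: str) -> list[tuple[str, int, str]]:
    """The six conceptual translations as (strand, frame_offset, peptide)."""
    out = []
    rc = _revcomp(dna)
    for strand, template in (("+", dna), ("-", rc)):
        for f in range(3):
            usable = (len(template) - f) // 3 * 3
            if usable >= 3:
                pep = str(Seq(template[f:f + usable]).translate())
                out.append((strand, f, pep))
    return out


def _all_local_alignments(protein: str, peptide: str, params: SearchParams,
                          offset: int = 0) -> list[tuple[LocalAlignment, int]]:
    """All disjoint (on the subject) local alignments with raw score >=
    min_raw_score, found greedily best-first; returns (alignment, aa offset of
    the subject slice)."""
    if len(peptide) == 0:
        return []
    aln = smith_waterman(protein, peptide, params.matrix,
                         params.gap_open, params.gap_extend)
    if aln is None or aln.score < params.min_raw_score:
        return []
    found = [(aln, offset)]
    found += _all_local_alignments(protein, peptide[:aln.b_start], params, offset)
    found += _all_local_alignments(protein, peptide[aln.b_end:], params,
                                   offset + aln.b_end)
    return found


def sixframe_search(protein: SequenceRecord, dna: SequenceRecord,
                    params: SearchParams = SearchParams()) -> list[Hit]:
    """Search one protein against all six conceptual translations of one DNA
    sequence; alignments with raw score >= ``min_raw_score`` become Hits.

    Nucleotide coordinates are mapped back from frame-local peptide
    coordinates (frame offset f on '+': nt = f + 3*aa; '-' frames mirrored
    through the reverse complement). Stops in the translations score the
    matrix minimum, so in-frame stops do not truncate a frame.
    """
    if not protein.seq:
        raise ValueError("empty protein query")
    if len(dna.seq) < 3:
        raise ValueError("dna subject shorter than one codon")

    L = len(dna.seq)
    m, n = len(protein.seq), L
    hits: list[Hit] = []
    for strand, f, peptide in _frames(dna.seq):
        for aln, aa_off in _all_local_alignments(protein.seq, peptide, params):
            # frame-local aa interval -> template nt interval
            t_start = f + 3 * (aa_off + aln.b_start)
            t_end = f + 3 * (aa_off + aln.b_end)
            if strand == "+":
                fwd_start, fwd_end = t_start, t_end
                sstart, send = fwd_start + 1, fwd_end
            else:
                fwd_start, fwd_end = L - t_end, L - t_start
                sstart, send = fwd_end, fwd_start + 1
            bitscore = bitscore_from_raw(aln.score, params.matrix)
            evalue = evalue_from_bitscore(bitscore, m, n)
            hits.append(Hit.from_dialect(
                qseqid=protein.id,
                sseqid=dna.id,
                pident=round(aln.pident, 1),
                aln_len=aln.n_cols,
                mismatch=aln.n_mismatch,
                gapopen=aln.n_gapopen,
                qstart=aln.a_start + 1,
                qend=aln.a_end,
                sstart=sstart,
                send=send,
                evalue=evalue,
                bitscore=round(bitscore, 1),
                stitle=protein.description,
            ))
    hits.sort(key=hit_sort_key)
    return hits


def builtin_search(proteins: Sequence[SequenceRecord],
                   subjects: Sequence[SequenceRecord],
                   params: SearchParams = SearchParams()) -> list[Hit]:
    """All-vs-all six-frame search (every protein against every DNA subject),
    filtered and ranked per query."""
    hits: list[Hit] = []
    for dna in subjects:
        for prot in proteins:
            hits.extend(sixframe_search(prot, dna, params))
    return filter_and_rank(hits, params)


def protein_search(queries: Sequence[SequenceRecord],
                   subjects: Sequence[SequenceRecord],
                   params: SearchParams = SearchParams(),
                   taxid_map: dict[str, tuple[int, ...]] | None = None) -> list[Hit]:
    """Protein-vs-protein local search (builtin reciprocal engine). Subject
    taxids are attached from ``taxid_map`` (subject id -> taxids) if given."""
    taxid_map = taxid_map or {}
    hits: list[Hit] = []
    for query in queries:
        for subj in subjects:
            aln = smith_waterman(query.seq, subj.seq, params.matrix,
                                 params.gap_open, params.gap_extend)
            if aln is None or aln.score < params.min_raw_score:
                continue
            bitscore = bitscore_from_raw(aln.score, params.matrix)
            evalue = evalue_from_bitscore(bitscore, len(query.seq), len(subj.seq))
            hits.append(Hit.from_dialect(
                qseqid=query.id,
                sseqid=subj.id,
                pident=round(aln.pident, 1),
                aln_len=aln.n_cols,
                mismatch=aln.n_mismatch,
                gapopen=aln.n_gapopen,
                qstart=aln.a_start + 1,
                qend=aln.a_end,
                sstart=aln.b_start + 1,
                send=aln.b_end,
                evalue=evalue,
                bitscore=round(bitscore, 1),
                stitle=subj.description,
                staxids=tuple(taxid_map.get(subj.id, ())),
            ))
    return filter_and_rank(hits, params)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_and_rank(hits: Sequence[Hit],
                    params: SearchParams = SearchParams()) -> list[Hit]:
    """Drop hits with evalue > ``evalue_max``; per query keep the top
    ``per_query_top_hits`` by descending bitscore (ties: ascending evalue,
    then lexicographic sseqid, qseqid)."""
    by_query: dict[str, list[Hit]] = {}
    for hit in hits:
        if hit.evalue > params.evalue_max:
            continue
        by_query.setdefault(hit.qseqid, []).append(hit)
    out: list[Hit] = []
    for query_hits in by_query.values():
        query_hits.sort(key=hit_sort_key)
        out.extend(query_hits[:params.per_query_top_hits])
    return out


# ---------------------------------------------------------------------------
# External engine
# ---------------------------------------------------------------------------

def run_external_search(query_db: str | Path, subject_fasta: str | Path,
                        params: SearchParams = SearchParams(),
                        mode: str = "forward",
                        binary: str = "diamond") -> list[Hit]:
    """Run an external DIAMOND-compatible binary and parse its tabular output.

    ``mode='forward'`` runs a translated search of the DNA in
    ``subject_fasta`` against the protein db (``blastx``);
    ``mode='reciprocal'`` runs candidate peptides against the protein db
    (``blastp``). The full argument vector is logged; the e-value filter and
    per-query ranking are applied to the parsed hits.
    """
    if mode not in ("forward", "reciprocal"):
        raise ValueError(f"unknown mode {mode!r}")
    exe = shutil.which(binary)
    if exe is None:
        raise EngineUnavailableError(
            f"search binary {binary!r} not found on PATH; use engine "
            f"'precomputed' with --hits, or the 'builtin' aligner"
        )
    subcommand = "blastx" if mode == "forward" else "blastp"
    with tempfile.TemporaryDirectory() as tmp:
        out_path = Path(tmp) / "hits.tsv"
        argv = [
            exe, subcommand,
            "--query", str(subject_fasta),
            "--db", str(query_db),
            "--out", str(out_path),
            "--outfmt", "6", *DEFAULT_HIT_COLUMNS,
            "--evalue", str(params.evalue_max),
            "--max-target-seqs", str(params.per_query_top_hits),
        ]
        logger.info("external search argv: %s", argv)
        proc = subprocess.run(argv, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalSearchError(
                f"{binary} exited with status {proc.returncode}:\n{proc.stderr}"
            )
        hits = parse_tabular_hits(out_path)
    return filter_and_rank(hits, params)
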