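"""Fixed-size genome chunking and hit coordinate remapping.

Genomes are split into non-overlapping chunks (default 50 kb) so each chunk
can be searched independently with a per-chunk cap on reported hits (default
1000). Chunk-local hit coordinates are remapped back to contig coordinates;
hits split across a chunk boundary are rejoined downstream by interval
merging.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

from evescan.formats_io import Hit, SequenceRecord

__all__ = [
    "Chunk",
    "ChunkParams",
    "chunk_genome",
    "chunks_to_records",
    "parse_chunk_id",
    "remap_hit",
    "unmap_hit",
    "cap_hits_per_chunk",
    "hit_sort_key",
]


@dataclass(frozen=True)
class Chunk:
    """A contiguous slice of a contig. ``chunk_id`` encodes ``{contig}:{offset}``
    with the LAST ':' as separator so contig names containing ':' survive."""

    contig: str
    offset: int
    seq: str

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("chunk offset must be >= 0")
        if not self.seq:
            raise ValueError("chunk must be non-empty")

    @property
    def chunk_id(self) -> str:
        return f"{self.contig}:{self.offset}"

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ChunkParams:
    chunk_size: int = 50_000
    per_chunk_top_hits: int = 1000

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if self.per_chunk_top_hits < 1:
            raise ValueError("per_chunk_top_hits must be >= 1")


def parse_chunk_id(chunk_id: str) -> tuple[str, int]:
    """Invert the ``{contig}:{offset}`` grammar (split on the last ':')."""
    contig, _, offset = chunk_id.rpartition(":")
    if not contig:
        raise ValueError(f"malformed chunk_id {chunk_id!r}")
    return contig, int(offset)


def chunk_genome(records: Sequence[SequenceRecord],
                 params: ChunkParams = ChunkParams()) -> list[Chunk]:
    """Tile each contig with chunks of ``chunk_size``; the final chunk of a
    contig may be shorter. Order: input record order, ascending offset."""
    chunks: list[Chunk] = []
    for rec in records:
        for offset in range(0, len(rec.seq), params.chunk_size):
            chunks.append(Chunk(rec.id, offset, rec.seq[offset:offset + params.chunk_size]))
    return chunks


def chunks_to_records(chunks: Iterable[Chunk]) -> list[SequenceRecord]:
    """Chunks as FASTA-writable records (id = chunk_id), for external tools."""
    return [SequenceRecord(c.chunk_id, c.chunk_id, c.seq, "dna") for c in chunks]


def remap_hit(hit: Hit, chunk: Chunk) -> Hit:
    """Remap a chunk-local hit to contig coordinates.

    Canonical interval becomes ``[offset + min(sstart, send) - 1,
    offset + max(sstart, send))``; the dialect ``sstart``/``send`` are shifted
    by the chunk offset (orientation preserved) and ``sseqid`` is replaced by
    the contig name.
    """
    if hit.sseqid != chunk.chunk_id:
        raise ValueError(
            f"hit subject {hit.sseqid!r} does not match chunk {chunk.chunk_id!r}"
        )
    lo, hi = min(hit.sstart, hit.send), max(hit.sstart, hit.send)
    if lo < 1 or hi > chunk.length:
        raise ValueError(
            f"hit coordinates [{lo},{hi}] outside chunk {chunk.chunk_id} "
            f"of length {chunk.length}"
        )
    return dataclasses.replace(
        hit,
        sseqid=chunk.contig,
        sstart=hit.sstart + chunk.offset,
        send=hit.send + chunk.offset,
        canon_start=chunk.offset + lo - 1,
        canon_end=chunk.offset + hi,
    )


def unmap_hit(hit: Hit, chunk: Chunk) -> Hit:
    """Inverse of :func:`remap_hit`: contig coordinates back to chunk-local."""
    if hit.sseqid != chunk.contig:
        raise ValueError(f"hit subject {hit.sseqid!r} is not contig {chunk.contig!r}")
    sstart = hit.sstart - chunk.offset
    send = hit.send - chunk.offset
    lo, hi = min(sstart, send), max(sstart, send)
    if lo < 1 or hi > chunk.length:
        raise ValueError("hit does not lie within this chunk")
    return dataclasses.replace(
        hit,
        sseqid=chunk.chunk_id,
        sstart=sstart,
        send=send,
        canon_start=lo - 1,
        canon_end=hi,
    )


def hit_sort_key(hit: Hit):
    """Deterministic ranking: descending bitscore, then ascending evalue,
    then lexicographic sseqid, qseqid."""
    return (-hit.bitscore, hit.evalue, hit.sseqid, hit.qseqid)


def cap_hits_per_chunk(hits: Sequence[Hit],
                       params: ChunkParams = ChunkParams()) -> list[Hit]:
    """Per chunk (``sseqid``), keep the top ``per_chunk_top_hits`` hits under
    :func:`hit_sort_key`. Output is grouped by first appearance of each chunk,
    ranked within each group."""
    by_chunk: dict[str, list[Hit]] = {}
    for hit in hits:
        by_chunk.setdefault(hit.sseqid, []).append(hit)
    out: list[Hit] = []
    for chunk_hits in by_chunk.values():
        chunk_hits.sort(key=hit_sort_key)
        out.extend(chunk_hits[:params.per_chunk_top_hits])
    return out
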