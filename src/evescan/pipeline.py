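"""End-to-end orchestration with a validated config and resumable stages.

Stage order: chunk -> forward search -> filter/cap -> remap -> merge ->
extract -> ORFs -> reciprocal search -> reconstruct -> classify -> outputs.
Each stage persists its outputs under the output directory with fixed
filenames, so a run can be stopped after any stage and resumed; the
expensive forward-search stage is reloaded from its persisted table on
resume, while cheap downstream stages are recomputed deterministically.

With engine 'builtin' or 'precomputed' no network access ever occurs.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import shutil
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

import evescan
from evescan.chunking import (
    Chunk,
    ChunkParams,
    cap_hits_per_chunk,
    chunk_genome,
    chunks_to_records,
    remap_hit,
)
from evescan.classify import RuleSet, write_classification
from evescan.formats_io import (
    Hit,
    SequenceRecord,
    load_taxdump,
    parse_tabular_hits,
    read_fasta,
    write_bed,
    write_fasta,
    write_summary,
    write_tabular_hits,
)
from evescan.loci import CandidateLocus, MergeParams, extract_locus_sequence, find_orfs
from evescan.reconstruct import (
    ReconstructParams,
    quantify_changes,
    reconstruct_locus,
)
from evescan.search import (
    SearchParams,
    builtin_search,
    filter_and_rank,
    protein_search,
    run_external_search,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline",
           "STAGES"]

STAGES = ("chunk", "search", "remap", "merge", "orfs", "reciprocal",
          "reconstruct", "classify", "summary")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    # mandatory
    query_fasta: str = ""
    genome_list: list[str] = field(default_factory=list)
    taxdump: str = ""
    # defaults mirroring the original pipeline where it prints them
    output_dir: str = "evescan_out"
    chunk_size: int = 50_000
    per_chunk_top_hits: int = 1000
    evalue_max: float = 1e-5
    per_query_top_hits: int = 10
    min_raw_score: int = 50
    merge_distance: int = 1000
    flank: int = 0
    min_orf_aa: int = 50
    orf_mode: str = "stop_to_stop"
    engine: str = "builtin"  # builtin | precomputed | external
    forward_hits: str | None = None  # for engine=precomputed
    reciprocal_mode: str = "precomputed"  # precomputed | builtin
    rvdb_hits: str | None = None
    nr_hits: str | None = None
    rvdb_db: str | None = None
    nr_db: str | None = None
    taxid_map: str | None = None  # subject id -> taxids TSV, builtin reciprocal
    seed: int = 0

    def validate(self) -> None:
        if not self.query_fasta:
            raise ConfigError("mandatory key missing: query_fasta")
        if not self.genome_list:
            raise ConfigError("mandatory key missing: genome_list")
        if not self.taxdump:
            raise ConfigError("mandatory key missing: taxdump")
        if self.chunk_size < 1:
            raise ConfigError("chunk_size must be >= 1")
        if self.evalue_max <= 0:
            raise ConfigError("evalue_max must be > 0")
        if self.engine not in ("builtin", "precomputed", "external"):
            raise ConfigError(f"unknown engine {self.engine!r}")
        if self.engine == "precomputed" and not self.forward_hits:
            raise ConfigError("engine 'precomputed' requires forward_hits")
        if self.engine == "external" and shutil.which("diamond") is None:
            raise ConfigError(
                "engine 'external' requires a 'diamond' binary on PATH; "
                "use engine 'builtin' or 'precomputed'"
            )
        if self.reciprocal_mode not in ("precomputed", "builtin"):
            raise ConfigError(f"unknown reciprocal_mode {self.reciprocal_mode!r}")
        if self.reciprocal_mode == "precomputed" and not (self.rvdb_hits and self.nr_hits):
            raise ConfigError(
                "reciprocal_mode 'precomputed' requires rvdb_hits and nr_hits"
            )
        if self.reciprocal_mode == "builtin" and not (self.rvdb_db and self.nr_db):
            raise ConfigError("reciprocal_mode 'builtin' requires rvdb_db and nr_db")
        if self.orf_mode not in ("stop_to_stop", "atg_to_stop"):
            raise ConfigError(f"unknown orf_mode {self.orf_mode!r}")

    def search_params(self) -> SearchParams:
        return SearchParams(evalue_max=self.evalue_max,
                            per_query_top_hits=self.per_query_top_hits,
                            min_raw_score=self.min_raw_score)

    def chunk_params(self) -> ChunkParams:
        return ChunkParams(chunk_size=self.chunk_size,
                           per_chunk_top_hits=self.per_chunk_top_hits)

    def merge_params(self) -> MergeParams:
        return MergeParams(merge_distance=self.merge_distance, flank=self.flank)


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load and validate a YAML config file (or dict). Unknown keys are
    rejected with a suggestion; defaults are filled; the resolved config is
    echoed to the log."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{source}: config must be a YAML mapping")
    for key in raw:
        if key not in _FIELD_NAMES:
            close = difflib.get_close_matches(key, _FIELD_NAMES, n=1)
            hint = f" (did you mean {close[0]!r}?)" if close else ""
            raise ConfigError(f"unknown config key {key!r}{hint}")
    config = PipelineConfig(**raw)
    config.validate()
    logger.info("resolved config: %s", dataclasses.asdict(config))
    return config


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _load_taxid_map(path: str | Path) -> dict[str, tuple[int, ...]]:
    out: dict[str, tuple[int, ...]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            seqid, taxids = line.rstrip("\n").split("\t")
            out[seqid] = tuple(int(t) for t in taxids.split(";") if t)
    return out


def _qseqid_interval(qseqid: str) -> tuple[str, int, int] | None:
    """Parse '{contig}:{start}-{end}' (possibly with an '|orf...' suffix)."""
    base = qseqid.split("|")[0]
    contig, _, span = base.rpartition(":")
    if not contig or "-" not in span:
        return None
    try:
        start_s, end_s = span.rsplit("-", 1)
        return contig, int(start_s), int(end_s)
    except ValueError:
        return None


def assign_hits_to_loci(hits: Sequence[Hit], loci: Sequence[CandidateLocus],
                        table: str) -> None:
    """Attach reciprocal hits to loci by query id: exact locus_id match, else
    maximal genomic overlap of the parsed query interval."""
    by_id = {locus.locus_id: locus for locus in loci}
    for hit in hits:
        target = by_id.get(hit.qseqid.split("|")[0])
        if target is None:
            parsed = _qseqid_interval(hit.qseqid)
            if parsed is not None:
                contig, start, end = parsed
                best_overlap = 0
                for locus in loci:
                    if locus.contig != contig:
                        continue
                    overlap = min(end, locus.canon_end) - max(start, locus.canon_start)
                    if overlap > best_overlap:
                        best_overlap = overlap
                        target = locus
        if target is None:
            logger.warning("reciprocal hit query %r matches no locus", hit.qseqid)
            continue
        (target.rvdb_hits if table == "rvdb" else target.nr_hits).append(hit)


def run_pipeline(config: PipelineConfig, stop_after: str | None = None,
                 resume: bool = False) -> Path:
    """Execute the pipeline; returns the output directory.

    ``stop_after`` halts after the named stage (see :data:`STAGES`);
    ``resume`` reuses the persisted forward-search table if present.
    """
    config.validate()
    if stop_after is not None and stop_after not in STAGES:
        raise ConfigError(f"unknown stage {stop_after!r}; stages: {STAGES}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    counts: dict[str, int] = {}
    timings: dict[str, float] = {}
    state_path = outdir / "state.json"
    done: list[str] = []
    if resume and state_path.exists():
        done = json.loads(state_path.read_text()).get("stages_done", [])

    def mark(stage: str, t_start: float) -> bool:
        """Record stage completion; return True when the run should stop."""
        timings[stage] = round(time.time() - t_start, 3)
        if stage not in done:
            done.append(stage)
        state_path.write_text(json.dumps({"stages_done": done}, indent=1))
        return stop_after == stage

    search_params = config.search_params()

    # --- chunk ------------------------------------------------------------
    t = time.time()
    proteins = read_fasta(config.query_fasta, moltype="protein")
    genome: list[SequenceRecord] = []
    for path in config.genome_list:
        genome.extend(read_fasta(path, moltype="dna"))
    chunks = chunk_genome(genome, config.chunk_params())
    chunk_by_id: dict[str, Chunk] = {c.chunk_id: c for c in chunks}
    write_fasta(chunks_to_records(chunks), outdir / "chunks.fna")
    counts["chunks"] = len(chunks)
    counts["queries"] = len(proteins)
    logger.info("chunk: %d contigs -> %d chunks", len(genome), len(chunks))
    if mark("chunk", t):
        return outdir

    # --- forward search ---------------------------------------------------
    t = time.time()
    raw_path = outdir / "forward_hits_raw.tsv"
    if resume and "search" in done and raw_path.exists():
        hits = parse_tabular_hits(raw_path)
        logger.info("search: reloaded %d persisted hits", len(hits))
    elif config.engine == "builtin":
        hits = builtin_search(proteins, chunks_to_records(chunks), search_params)
    elif config.engine == "precomputed":
        hits = filter_and_rank(parse_tabular_hits(config.forward_hits),
                               search_params)
    else:  # external
        hits = run_external_search(config.query_fasta, outdir / "chunks.fna",
                                   search_params, mode="forward")
    write_tabular_hits(hits, raw_path)
    counts["forward_hits"] = len(hits)
    logger.info("search: %d forward hits pass e-value/rank", len(hits))
    if mark("search", t):
        return outdir

    # --- per-chunk cap + remap -------------------------------------------
    t = time.time()
    hits = cap_hits_per_chunk(hits, config.chunk_params())
    counts["forward_hits_capped"] = len(hits)
    remapped: list[Hit] = []
    for hit in hits:
        chunk = chunk_by_id.get(hit.sseqid)
        remapped.append(remap_hit(hit, chunk) if chunk is not None else hit)
    write_tabular_hits(remapped, outdir / "forward_hits.tsv")
    logger.info("remap: %d hits on contig coordinates", len(remapped))
    if mark("remap", t):
        return outdir

    # --- merge + extract --------------------------------------------------
    t = time.time()
    from evescan.loci import merge_hits_to_loci  # local import avoids cycle confusion

    loci = merge_hits_to_loci(remapped, config.merge_params())
    for locus in loci:
        extract_locus_sequence(genome, locus, config.merge_params())
    write_bed(loci, outdir / "loci.bed")
    write_fasta(
        [SequenceRecord(l.locus_id, f"{l.locus_id} strand={l.strand}", l.seq, "dna")
         for l in loci],
        outdir / "candidate_cdna.fna",
    )
    counts["loci"] = len(loci)
    logger.info("merge: %d candidate loci", len(loci))
    if mark("merge", t):
        return outdir

    # --- ORFs -------------------------------------------------------------
    t = time.time()
    orf_records: list[SequenceRecord] = []
    for locus in loci:
        locus.orfs = find_orfs(locus.seq, config.min_orf_aa, config.orf_mode)
        for i, orf in enumerate(locus.orfs, start=1):
            orf_id = f"{locus.locus_id}|orf{i}|frame{orf.frame:+d}"
            orf_records.append(SequenceRecord(orf_id, orf_id, orf.peptide, "protein"))
    if orf_records:
        write_fasta(orf_records, outdir / "candidate_peptides.faa")
    else:
        (outdir / "candidate_peptides.faa").write_text("")
    counts["orfs"] = len(orf_records)
    if mark("orfs", t):
        return outdir

    # --- reciprocal search ------------------------------------------------
    t = time.time()
    reciprocal_db: dict[str, SequenceRecord] = {}
    if config.reciprocal_mode == "precomputed":
        rvdb = parse_tabular_hits(config.rvdb_hits)
        nr = parse_tabular_hits(config.nr_hits)
    else:  # builtin protein-protein search of ORF peptides vs the two dbs
        taxmap = _load_taxid_map(config.taxid_map) if config.taxid_map else {}
        rvdb_db = read_fasta(config.rvdb_db, moltype="protein")
        nr_db = read_fasta(config.nr_db, moltype="protein")
        reciprocal_db = {rec.id: rec for rec in (*rvdb_db, *nr_db)}
        rvdb = protein_search(orf_records, rvdb_db, search_params, taxmap)
        nr = protein_search(orf_records, nr_db, search_params, taxmap)
    rvdb = filter_and_rank(rvdb, search_params)
    nr = filter_and_rank(nr, search_params)
    assign_hits_to_loci(rvdb, loci, "rvdb")
    assign_hits_to_loci(nr, loci, "nr")
    write_tabular_hits(rvdb, outdir / "rvdb_hits.tsv")
    write_tabular_hits(nr, outdir / "nr_hits.tsv")
    counts["rvdb_hits"] = len(rvdb)
    counts["nr_hits"] = len(nr)
    if mark("reciprocal", t):
        return outdir

    # --- reconstruct ------------------------------------------------------
    t = time.time()
    protein_by_id = {p.id: p for p in proteins}
    recon_params = ReconstructParams()
    recon_rows: list[str] = []
    recon_peptides: list[SequenceRecord] = []
    for locus in loci:
        reference = _best_reference(locus, protein_by_id, reciprocal_db)
        if reference is None:
            continue
        alignment = reconstruct_locus(reference, locus.seq, recon_params,
                                      locus.locus_id)
        report = quantify_changes(alignment, reference.seq, recon_params)
        locus.reconstruction = report
        recon_rows.append("\t".join([
            locus.locus_id, reference.id, str(alignment.raw_score),
            alignment.strand, str(report.n_stops), str(report.n_insertions),
            str(report.n_deletions), str(report.n_frameshifts),
            f"{report.pident:.2f}", f"{report.protein_coverage:.4f}",
            str(report.intact),
        ]))
        if alignment.reconstructed_peptide:
            recon_peptides.append(SequenceRecord(
                f"{locus.locus_id}|{reference.id}",
                f"{locus.locus_id}|{reference.id} reconstructed",
                alignment.reconstructed_peptide, "protein"))
    header = ("locus_id\treference\traw_score\tstrand\tn_stops\tn_insertions"
              "\tn_deletions\tn_frameshifts\tpident\tprotein_coverage\tintact\n")
    (outdir / "reconstruction.tsv").write_text(
        header + "".join(row + "\n" for row in recon_rows))
    if recon_peptides:
        write_fasta(recon_peptides, outdir / "reconstructed_peptides.faa")
    counts["reconstructed"] = len(recon_rows)
    if mark("reconstruct", t):
        return outdir

    # --- classify ---------------------------------------------------------
    t = time.time()
    taxdump_dir = Path(config.taxdump)
    taxdb = load_taxdump(taxdump_dir / "nodes.dmp", taxdump_dir / "names.dmp")
    write_classification(loci, taxdb, outdir / "classification.tsv", RuleSet())
    counts["classified"] = len(loci)
    if mark("classify", t):
        return outdir

    # --- summary + manifest ----------------------------------------------
    t = time.time()
    write_summary(loci, outdir / "summary.tsv")
    manifest = {
        "config": dataclasses.asdict(config),
        "input_checksums": {
            "query_fasta": _sha256(config.query_fasta),
            **{f"genome_{i}": _sha256(p) for i, p in enumerate(config.genome_list)},
        },
        "counts": counts,
        "timings": timings,
        "total_seconds": round(time.time() - t0, 3),
        "versions": {
            "evescan": evescan.__version__,
            "python": sys.version.split()[0],
        },
    }
    mark("summary", t)
    # written last, atomically-ish: temp then rename
    tmp = outdir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    tmp.rename(outdir / "manifest.json")
    return outdir


def _best_reference(locus: CandidateLocus,
                    protein_by_id: dict[str, SequenceRecord],
                    reciprocal_db: dict[str, SequenceRecord]) -> SequenceRecord | None:
    """Closest related protein: the highest-bitscore hit across the forward
    and reciprocal tables whose sequence is available (forward queries
    always are; reciprocal subjects only with a builtin reciprocal db).
    Ties: lower e-value, then lexicographic subject id."""
    candidates: list[tuple[float, float, str, SequenceRecord]] = []
    for hit in locus.forward_hits:
        ref = protein_by_id.get(hit.qseqid)
        if ref is not None:
            candidates.append((-hit.bitscore, hit.evalue, hit.qseqid, ref))
    for hit in (*locus.rvdb_hits, *locus.nr_hits):
        ref = reciprocal_db.get(hit.sseqid)
        if ref is not None:
            candidates.append((-hit.bitscore, hit.evalue, hit.sseqid, ref))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[:3])
    return candidates[0][3]
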