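"""Synthetic fixtures: every input the pipeline needs, generated offline.

Provides toy viral proteins, host genomes with planted degraded inserts and
ground-truth records, mock reciprocal hit tables engineered to force each
classification rule, and a mock taxdump. Everything is deterministic under a
seed (numpy Generator; no locale or float formatting dependence).

Back-translation uses uniform random synonymous codons (no codon-usage
table); the background genome is i.i.d. uniform ACGT by default to minimize
accidental homology with planted inserts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.Data.CodonTable import standard_dna_table

from evescan.formats_io import Hit, SequenceRecord, write_tabular_hits

__all__ = [
    "PlantSpec",
    "PlantedLocus",
    "TruthSet",
    "SCENARIO_CATEGORY",
    "generate_proteins",
    "generate_genome",
    "back_translate",
    "degrade_insert",
    "plant_eves",
    "random_plant_specs",
    "write_mock_taxdump",
    "mock_reciprocal_tables",
]

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = ("TAA", "TGA", "TAG")

# aa -> synonymous codons, from the standard table
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

def generate_proteins(n: int, length_range: tuple[int, int] = (50, 60),
                      seed: int = 0) -> list[SequenceRecord]:
    """``n`` uniform-composition proteins with ids ``vp1..vpn``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    records = []
    for i in range(1, n + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(AA_LETTERS[k] for k in rng.integers(0, 20, size=length))
        records.append(SequenceRecord(f"vp{i}", f"vp{i} synthetic viral protein",
                                      seq, "protein"))
    return records


def generate_genome(n_contigs: int = 1, contig_length: int = 100_000,
                    seed: int = 0, gc: float = 0.5) -> list[SequenceRecord]:
    """Random background contigs ``contig1..contigN`` with the given GC."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for i in range(1, n_contigs + 1):
        draws = rng.choice(4, size=contig_length, p=p)
        seq = "".join("ACGT"[k] for k in draws)
        records.append(SequenceRecord(f"contig{i}", f"contig{i} synthetic background",
                                      seq, "dna"))
    return records


def back_translate(protein_seq: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform synonymous codon choice."""
    codons = []
    for aa in protein_seq:
        options = _CODONS_BY_AA[aa]
        codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# Planting degraded inserts
# ---------------------------------------------------------------------------

@dataclass
class PlantSpec:
    """Degradation plan for one planted insert.

    ``indel_events`` are whole-codon events ``(codon_index, n_codons, kind)``
    with kind 'ins' or 'del'. Stop and frameshift positions are drawn by the
    generator within the interior of the insert, pairwise separated so events
    never overlap.
    """

    protein_id: str
    target_contig: str
    insert_position: int
    strand: str = "+"
    n_planted_stops: int = 0
    n_planted_frameshifts: int = 0
    indel_events: list[tuple[int, int, str]] = field(default_factory=list)
    substitution_rate: float = 0.0
    # codons kept event-free at each end of the insert, and the minimum codon
    # distance between events; generous margins keep every alignment segment
    # long enough to stay reportable
    event_margin: int = 5
    event_separation: int = 8


@dataclass
class PlantedLocus:
    """Ground truth for one planted insert, in final genome coordinates."""

    spec: PlantSpec
    contig: str
    start: int
    end: int
    insert_seq: str
    expected_category: str | None = None

    @property
    def locus_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


@dataclass
class TruthSet:
    plants: list[PlantedLocus]
    seed: int

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in sorted(self.plants, key=lambda x: (x.contig, x.start)):
                fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.spec.protein_id}\t0\t"
                         f"{p.spec.strand}\n")

    def write_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "plants": [
                {
                    "contig": p.contig, "start": p.start, "end": p.end,
                    "expected_category": p.expected_category,
                    "spec": asdict(p.spec),
                }
                for p in self.plants
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _draw_event_positions(n_codons: int, n_events: int,
                          rng: np.random.Generator,
                          taken: set[int], margin: int,
                          separation: int) -> list[int]:
    candidates = [
        c for c in range(margin, n_codons - margin)
        if all(abs(c - t) >= separation for t in taken)
    ]
    positions: list[int] = []
    for _ in range(n_events):
        if not candidates:
            raise ValueError("insert too short for the requested events")
        pos = int(rng.choice(np.array(candidates)))
        positions.append(pos)
        taken.add(pos)
        candidates = [c for c in candidates if abs(c - pos) >= separation]
    return positions


def _draw_all_events(n_codons: int, spec: "PlantSpec",
                     rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Draw stop and frameshift codon positions jointly; the greedy sampler
    can corner itself even when a valid packing exists, so retry with fresh
    draws (deterministic under the generator state) before giving up."""
    last_error: ValueError | None = None
    for _ in range(200):
        taken = {p for pos, length, _ in spec.indel_events
                 for p in range(pos, pos + length)}
        try:
            stops = _draw_event_positions(
                n_codons, spec.n_planted_stops, rng, taken,
                spec.event_margin, spec.event_separation)
            shifts = _draw_event_positions(
                n_codons, spec.n_planted_frameshifts, rng, taken,
                spec.event_margin, spec.event_separation)
            return stops, shifts
        except ValueError as exc:
            last_error = exc
    raise ValueError(
        f"could not place {spec.n_planted_stops} stops + "
        f"{spec.n_planted_frameshifts} frameshifts in {n_codons} codons "
        f"(margin {spec.event_margin}, separation {spec.event_separation})"
    ) from last_error


def degrade_insert(protein_seq: str, spec: PlantSpec,
                   rng: np.random.Generator) -> str:
    """Back-translate ``protein_seq`` and apply the planted degradation.

    Order: substitutions (stop-free, away from event codons), stop overwrites
    (TAA/TGA/TAG), whole-codon indels, then 1-2 nt frameshift indels. Events
    occupy pairwise-separated interior codons, so planted counts are
    unambiguous.
    """
    codons = [back_translate(aa, rng) for aa in protein_seq]
    n_codons = len(codons)

    stop_positions, shift_positions = _draw_all_events(n_codons, spec, rng)
    taken: set[int] = set(stop_positions) | set(shift_positions) | {
        pos for pos, length, _ in spec.indel_events
        for pos in range(pos, pos + length)}

    # substitutions: one random nt change per selected codon, never creating
    # a stop, never touching an event codon, and keeping the terminal codons
    # exact so local alignments reach the insert boundaries
    for c in range(2, n_codons - 2):
        if c in taken or rng.random() >= spec.substitution_rate:
            continue
        for _ in range(10):  # resample cap
            pos = int(rng.integers(0, 3))
            base = "ACGT"[int(rng.integers(0, 4))]
            mutated = codons[c][:pos] + base + codons[c][pos + 1:]
            if mutated != codons[c] and mutated not in STOP_CODONS:
                codons[c] = mutated
                break

    for c in stop_positions:
        codons[c] = STOP_CODONS[int(rng.integers(0, 3))]

    # whole-codon indels and frameshifts, applied right-to-left so earlier
    # indices stay valid
    edits: list[tuple[int, str, object]] = []
    for pos, length, kind in spec.indel_events:
        edits.append((pos, kind, length))
    for pos in shift_positions:
        edits.append((pos, "shift", None))
    for pos, kind, arg in sorted(edits, reverse=True):
        if kind == "ins":
            extra = [back_translate(AA_LETTERS[int(rng.integers(0, 20))], rng)
                     for _ in range(arg)]
            codons[pos:pos] = extra
        elif kind == "del":
            del codons[pos:pos + arg]
        else:  # frameshift: delete or insert 1-2 nt inside codon `pos`
            n_nt = int(rng.integers(1, 3))
            if rng.random() < 0.5:
                codons[pos] = codons[pos][:3 - n_nt]
            else:
                extra_nt = "".join("ACGT"[int(rng.integers(0, 4))]
                                   for _ in range(n_nt))
                codons[pos] = codons[pos] + extra_nt
    return "".join(codons)


def plant_eves(genome: Sequence[SequenceRecord],
               proteins: Sequence[SequenceRecord],
               specs: Sequence[PlantSpec], seed: int = 0
               ) -> tuple[list[SequenceRecord], TruthSet]:
    """Insert degraded back-translations into the genome per ``specs``.

    ``insert_position`` refers to the original contig coordinates; truth
    intervals are recorded in final coordinates, accounting for upstream
    length changes. Overlapping planted intervals raise.
    """
    prot_by_id = {p.id: p for p in proteins}
    contig_seqs = {rec.id: rec.seq for rec in genome}
    rng = np.random.default_rng(seed)

    by_contig: dict[str, list[PlantSpec]] = {}
    for spec in specs:
        if spec.target_contig not in contig_seqs:
            raise KeyError(f"unknown contig {spec.target_contig!r}")
        if spec.protein_id not in prot_by_id:
            raise KeyError(f"unknown protein {spec.protein_id!r}")
        by_contig.setdefault(spec.target_contig, []).append(spec)

    plants: list[PlantedLocus] = []
    new_records: list[SequenceRecord] = []
    for rec in genome:
        contig_specs = sorted(by_contig.get(rec.id, []),
                              key=lambda s: s.insert_position)
        for a, b in zip(contig_specs, contig_specs[1:]):
            if a.insert_position == b.insert_position:
                raise ValueError(
                    f"overlapping planted intervals on {rec.id} at "
                    f"{a.insert_position}"
                )
        parts: list[str] = []
        cursor = 0
        shift = 0
        for spec in contig_specs:
            insert = degrade_insert(prot_by_id[spec.protein_id].seq, spec, rng)
            if spec.strand == "-":
                insert = str(Seq(insert).reverse_complement())
            parts.append(rec.seq[cursor:spec.insert_position])
            start = spec.insert_position + shift
            parts.append(insert)
            plants.append(PlantedLocus(
                spec=spec, contig=rec.id,
                start=start, end=start + len(insert),
                insert_seq=insert,
            ))
            shift += len(insert)
            cursor = spec.insert_position
        parts.append(rec.seq[cursor:])
        new_records.append(SequenceRecord(rec.id, rec.description,
                                          "".join(parts), "dna"))
    return new_records, TruthSet(plants=plants, seed=seed)


def random_plant_specs(proteins: Sequence[SequenceRecord],
                       genome: Sequence[SequenceRecord],
                       seed: int = 0,
                       min_spacing: int = 3000,
                       max_stops: int = 2,
                       max_frameshifts: int = 1,
                       substitution_rate: float = 0.02) -> list[PlantSpec]:
    """One spec per protein, round-robin over contigs, insert positions spaced
    more than ``min_spacing`` apart so merged loci stay distinct."""
    rng = np.random.default_rng(seed)
    specs: list[PlantSpec] = []
    per_contig_cursor = {rec.id: 1000 for rec in genome}
    contigs = [rec.id for rec in genome]
    for idx, prot in enumerate(proteins):
        contig = contigs[idx % len(contigs)]
        pos = per_contig_cursor[contig] + int(rng.integers(0, 500))
        per_contig_cursor[contig] = pos + min_spacing
        contig_len = len(next(r.seq for r in genome if r.id == contig))
        if pos >= contig_len - 1000:
            raise ValueError("genome too small for the requested plant count")
        specs.append(PlantSpec(
            protein_id=prot.id,
            target_contig=contig,
            insert_position=pos,
            strand="+" if rng.random() < 0.5 else "-",
            n_planted_stops=int(rng.integers(0, max_stops + 1)),
            n_planted_frameshifts=int(rng.integers(0, max_frameshifts + 1)),
            substitution_rate=substitution_rate,
            # events in the central third so every flanking segment is long
            # enough to pass the reporting floor and e-value filter
            event_margin=max(8, len(prot.seq) // 3),
            event_separation=6,
        ))
    return specs


# ---------------------------------------------------------------------------
# Mock taxonomy
# ---------------------------------------------------------------------------

# name -> (taxid, parent taxid, rank)
MOCK_TAXA: dict[str, tuple[int, int, str]] = {
    "root": (1, 1, "no rank"),
    "Viruses": (10239, 1, "superkingdom"),
    "Eukaryota": (2759, 1, "superkingdom"),
    # viral kingdoms
    "Orthornavirae": (2732396, 10239, "kingdom"),
    "Pararnavirae": (2732397, 10239, "kingdom"),
    "Bamfordvirae": (2732005, 10239, "kingdom"),
    "Heunggongvirae": (2732416, 10239, "kingdom"),
    "Shotokuvirae": (2732092, 10239, "kingdom"),
    # viral families
    "Retroviridae": (11632, 2732397, "family"),
    "Caulimoviridae": (186534, 2732397, "family"),
    "Bornaviridae": (178830, 2732396, "family"),
    "Filoviridae": (11266, 2732396, "family"),
    "Paramyxoviridae": (11158, 2732396, "family"),
    "Circoviridae": (39724, 2732092, "family"),
    "Parvoviridae": (19065, 2732092, "family"),
    "Poxviridae": (10240, 2732005, "family"),
    "Baculoviridae": (10442, 2732416, "family"),
    "Polyomaviridae": (151341, 2732092, "family"),
    # viral species
    "Human immunodeficiency virus 1": (11676, 11632, "species"),
    "Cauliflower mosaic virus": (10641, 186534, "species"),
    "Porcine circovirus 1": (133704, 39724, "species"),
    "Borna disease virus": (12455, 178830, "species"),
    "Zaire ebolavirus": (186538, 11266, "species"),
    "Vaccinia virus": (10245, 10240, "species"),
    "Autographa californica nucleopolyhedrovirus": (46015, 10442, "species"),
    # eukaryotes
    "Metazoa": (33208, 2759, "kingdom"),
    "Hominidae": (9604, 33208, "family"),
    "Homo sapiens": (9606, 9604, "species"),
    "Culicidae": (7157, 33208, "family"),
    "Aedes aegypti": (7159, 7157, "species"),
}

TAXID = {name: taxid for name, (taxid, _, _) in MOCK_TAXA.items()}


def write_mock_taxdump(outdir: str | Path) -> tuple[Path, Path]:
    """Write nodes.dmp/names.dmp for the ~30-node mock taxonomy."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes_path = outdir / "nodes.dmp"
    names_path = outdir / "names.dmp"
    with open(nodes_path, "w") as nodes, open(names_path, "w") as names:
        for name, (taxid, parent, rank) in MOCK_TAXA.items():
            nodes.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
            names.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    return nodes_path, names_path


# ---------------------------------------------------------------------------
# Mock reciprocal tables
# ---------------------------------------------------------------------------

SCENARIO_CATEGORY = {
    "retro": "likely-retro",
    "host": "likely-host-protein",
    "bamford": "bamford-related",
    "transposon": "likely-transposon",
    "eve": "likely-eve",
    "uncertain": "uncertain",
}

# per scenario: (rvdb rows, nr rows) as lists of (title, taxon name or None)
_SCENARIO_HITS: dict[str, tuple[list, list]] = {
    "retro": (
        [("gag polyprotein", "Human immunodeficiency virus 1")] * 3
        + [("reverse transcriptase", "Human immunodeficiency virus 1")] * 2,
        [("gag polyprotein", "Human immunodeficiency virus 1")] * 5,
    ),
    "host": (
        [("capsid protein", "Porcine circovirus 1")],
        [("hypothetical protein", "Homo sapiens")] * 10,
    ),
    "bamford": (
        [("major capsid protein", "Vaccinia virus")] * 5,
        [("major capsid protein", "Vaccinia virus")] * 5,
    ),
    "transposon": (
        [("transposase", "Aedes aegypti")] * 5,
        [("transposase", "Aedes aegypti")] * 5,
    ),
    "eve": (
        [("capsid protein", "Porcine circovirus 1")] * 5,
        [("replication-associated protein", "Porcine circovirus 1")] * 5,
    ),
    "uncertain": (
        [("occlusion-derived virus envelope protein EC27",
          "Autographa californica nucleopolyhedrovirus")] * 3
        + [("unannotated protein", None)] * 2,
        [("occlusion-derived virus envelope protein EC27",
          "Autographa californica nucleopolyhedrovirus")] * 2
        + [("hypothetical protein", "Homo sapiens")] * 3,
    ),
}


def _scenario_rows(locus_id: str, rows: list, db_tag: str) -> list[Hit]:
    hits = []
    for i, (title, taxon) in enumerate(rows):
        hits.append(Hit.from_dialect(
            qseqid=locus_id,
            sseqid=f"{db_tag}_subj_{i + 1}",
            pident=90.0 - i,
            aln_len=50,
            mismatch=5,
            gapopen=0,
            qstart=1,
            qend=50,
            sstart=1,
            send=50,
            evalue=1e-30 * (10.0 ** i),
            bitscore=200.0 - 5 * i,
            stitle=title,
            staxids=(TAXID[taxon],) if taxon else (999_999,),
        ))
    return hits


def mock_reciprocal_tables(truth: TruthSet, scenario, seed: int = 0,
                           outdir: str | Path = ".") -> tuple[Path, Path, Path]:
    """Emit rvdb_hits.tsv, nr_hits.tsv and a mock taxdump engineered so that
    each planted locus classifies into its scenario's category.

    ``scenario`` is a single scenario name applied to every planted locus, or
    a list with one scenario per plant (in ``truth.plants`` order). Also sets
    ``expected_category`` on the truth records.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(scenario, str):
        scenarios = [scenario] * len(truth.plants)
    else:
        scenarios = list(scenario)
    if len(scenarios) != len(truth.plants):
        raise ValueError("need one scenario per planted locus")

    rvdb_hits: list[Hit] = []
    nr_hits: list[Hit] = []
    for plant, name in zip(truth.plants, scenarios):
        if name not in _SCENARIO_HITS:
            raise ValueError(f"unknown scenario {name!r}")
        rvdb_rows, nr_rows = _SCENARIO_HITS[name]
        rvdb_hits.extend(_scenario_rows(plant.locus_id, rvdb_rows, "rvdb"))
        nr_hits.extend(_scenario_rows(plant.locus_id, nr_rows, "nr"))
        plant.expected_category = SCENARIO_CATEGORY[name]

    rvdb_path = outdir / "rvdb_hits.tsv"
    nr_path = outdir / "nr_hits.tsv"
    write_tabular_hits(rvdb_hits, rvdb_path)
    write_tabular_hits(nr_hits, nr_path)
    taxdump_dir = outdir / "taxdump"
    write_mock_taxdump(taxdump_dir)
    return rvdb_path, nr_path, taxdump_dir
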