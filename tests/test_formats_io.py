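import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evescan.formats_io import (
    DEFAULT_HIT_COLUMNS,
    FormatError,
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
from evescan.loci import CandidateLocus


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestReadFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_text(">a desc\nACGT\n")
        records = read_fasta(path)
        assert len(records) == 1
        assert records[0].id == "a"
        assert records[0].description == "a desc"
        assert records[0].seq == "ACGT"

    def test_line_wrap_concatenation(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_text(">a\nAC\nGT\n>b\nTTTT\n")
        records = read_fasta(path)
        assert [r.id for r in records] == ["a", "b"]
        assert records[0].seq == "ACGT"

    def test_crlf_and_lowercase(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_bytes(b">a\r\nacgt\r\nACGT\r\n")
        assert read_fasta(path)[0].seq == "ACGTACGT"

    def test_gzip_by_magic_bytes(self, tmp_path):
        # extension deliberately misleading
        path = tmp_path / "a.fa"
        path.write_bytes(gzip.compress(b">a\nACGT\n"))
        assert read_fasta(path)[0].seq == "ACGT"

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_text("")
        with pytest.raises(FormatError, match="no records"):
            read_fasta(path)

    def test_illegal_character_names_record_and_position(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_text(">ok\nACGT\n>bad\nAC1T\n")
        with pytest.raises(FormatError, match=r"'bad'.*position 3"):
            read_fasta(path)

    def test_protein_moltype(self, tmp_path):
        path = tmp_path / "a.faa"
        path.write_text(">p\nMKWVR\n")
        rec = read_fasta(path, moltype="protein")[0]
        assert rec.moltype == "protein"


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_fasta_round_trip_100_records(tmp_path_factory, data):
    n = data.draw(st.integers(1, 100))
    seed = data.draw(st.integers(0, 2**31))
    rng = np.random.default_rng(seed)
    records = [
        SequenceRecord(
            f"r{i}", f"r{i}",
            "".join("ACGTN"[k] for k in rng.integers(0, 5, size=rng.integers(1, 200))),
            "dna",
        )
        for i in range(n)
    ]
    path = tmp_path_factory.mktemp("fa") / "rt.fa"
    write_fasta(records, path)
    back = read_fasta(path)
    assert [r.id for r in back] == [r.id for r in records]
    assert [r.seq for r in back] == [r.seq for r in records]


# ---------------------------------------------------------------------------
# Tabular hits
# ---------------------------------------------------------------------------

class TestParseTabularHits:
    def test_minus_strand_example(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text(
            "q1\ts1\t45.0\t100\t50\t2\t1\t100\t500\t201\t1e-20\t120.5\t"
            "gag polyprotein\t11632\n"
        )
        (hit,) = parse_tabular_hits(path)
        assert hit.strand == "-"
        assert hit.evalue == 1e-20
        assert hit.staxids == (11632,)
        assert hit.canon_start == 200 and hit.canon_end == 500
        assert hit.stitle == "gag polyprotein"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("")
        assert parse_tabular_hits(path) == []

    def test_multi_taxids_split_on_semicolon(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("q\ts\t90.0\t10\t1\t0\t1\t10\t1\t30\t1e-9\t50.0\tx\t1;2;3\n")
        assert parse_tabular_hits(path)[0].staxids == (1, 2, 3)

    def test_optional_tail_columns_absent(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("q\ts\t90.0\t10\t1\t0\t1\t10\t1\t30\t1e-9\t50.0\n")
        hit = parse_tabular_hits(path)[0]
        assert hit.stitle == "" and hit.staxids == ()

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("q\ts\t90.0\n")
        with pytest.raises(FormatError, match=":1:"):
            parse_tabular_hits(path)

    def test_unparseable_numeric_names_field(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("q\ts\tnope\t10\t1\t0\t1\t10\t1\t30\t1e-9\t50.0\tx\t1\n")
        with pytest.raises(FormatError, match="pident"):
            parse_tabular_hits(path)


def _random_hits(rng, n):
    hits = []
    for i in range(n):
        sstart = int(rng.integers(1, 10_000))
        send = int(rng.integers(1, 10_000))
        if sstart == send:
            send += 1
        hits.append(Hit.from_dialect(
            qseqid=f"q{rng.integers(0, 50)}",
            sseqid=f"s{rng.integers(0, 50)}",
            pident=float(np.round(rng.uniform(0, 100), 2)),
            aln_len=int(rng.integers(1, 500)),
            mismatch=int(rng.integers(0, 100)),
            gapopen=int(rng.integers(0, 10)),
            qstart=int(rng.integers(1, 100)),
            qend=int(rng.integers(1, 100)),
            sstart=sstart,
            send=send,
            evalue=float(10.0 ** -rng.integers(0, 50)),
            bitscore=float(np.round(rng.uniform(20, 500), 1)),
            stitle=f"title {i}" if rng.random() < 0.7 else "",
            staxids=tuple(int(t) for t in rng.integers(1, 10_000, size=rng.integers(0, 4))),
        ))
    return hits


def test_tabular_round_trip_10000_hits(tmp_path):
    rng = np.random.default_rng(7)
    hits = _random_hits(rng, 10_000)
    path = tmp_path / "rt.tsv"
    write_tabular_hits(hits, path)
    assert parse_tabular_hits(path) == hits


# ---------------------------------------------------------------------------
# Taxdump
# ---------------------------------------------------------------------------

class TestTaxdump:
    def test_mock_lineages(self, taxdb):
        assert taxdb.superkingdom(11676) == "Viruses"
        assert taxdb.family(11676) == "Retroviridae"
        assert taxdb.kingdom(10245) == "Bamfordvirae"
        assert taxdb.is_eukaryotic(9606)
        assert not taxdb.is_viral(9606)

    def test_synonym_class_ignored(self, tmp_path):
        (tmp_path / "nodes.dmp").write_text(
            "1\t|\t1\t|\tno rank\t|\n2\t|\t1\t|\tspecies\t|\n")
        (tmp_path / "names.dmp").write_text(
            "2\t|\tGood name\t|\t\t|\tscientific name\t|\n"
            "2\t|\tBad name\t|\t\t|\tsynonym\t|\n")
        db = load_taxdump(tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        assert db.name(2) == "Good name"

    def test_orphan_taxid_errors(self, tmp_path):
        (tmp_path / "nodes.dmp").write_text(
            "1\t|\t1\t|\tno rank\t|\n5\t|\t99\t|\tspecies\t|\n")
        (tmp_path / "names.dmp").write_text("1\t|\troot\t|\t\t|\tscientific name\t|\n")
        with pytest.raises(FormatError, match=r"orphan.*\[5\]"):
            load_taxdump(tmp_path / "nodes.dmp", tmp_path / "names.dmp")

    def test_cycle_errors(self, tmp_path):
        (tmp_path / "nodes.dmp").write_text(
            "1\t|\t1\t|\tno rank\t|\n2\t|\t3\t|\tgenus\t|\n3\t|\t2\t|\tfamily\t|\n")
        (tmp_path / "names.dmp").write_text("1\t|\troot\t|\t\t|\tscientific name\t|\n")
        with pytest.raises(FormatError, match="cycle"):
            load_taxdump(tmp_path / "nodes.dmp", tmp_path / "names.dmp")

    def test_random_tree_lineages_terminate(self, tmp_path):
        # random tree of 500 taxids with known max depth
        rng = np.random.default_rng(11)
        nodes = ["1\t|\t1\t|\tno rank\t|"]
        names = ["1\t|\troot\t|\t\t|\tscientific name\t|"]
        depth = {1: 0}
        for taxid in range(2, 502):
            parent = int(rng.choice(list(depth)))
            depth[taxid] = depth[parent] + 1
            nodes.append(f"{taxid}\t|\t{parent}\t|\tclade\t|")
            names.append(f"{taxid}\t|\tnode {taxid}\t|\t\t|\tscientific name\t|")
        (tmp_path / "nodes.dmp").write_text("\n".join(nodes) + "\n")
        (tmp_path / "names.dmp").write_text("\n".join(names) + "\n")
        db = load_taxdump(tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        for taxid, d in depth.items():
            lineage = db.lineage(taxid)
            assert lineage[-1] == 1
            assert len(lineage) == d + 1


# ---------------------------------------------------------------------------
# BED / summary writers
# ---------------------------------------------------------------------------

def _locus(contig, start, end, strand="+", bitscore=77.0):
    hit = Hit.from_dialect(
        qseqid="q", sseqid=contig, pident=90.0, aln_len=10, mismatch=0,
        gapopen=0, qstart=1, qend=10, sstart=start + 1, send=end,
        evalue=1e-10, bitscore=bitscore)
    return CandidateLocus(
        locus_id=f"{contig}:{start}-{end}", contig=contig,
        canon_start=start, canon_end=end, strand=strand, forward_hits=[hit])


class TestWriters:
    def test_bed_coordinate_convention(self, tmp_path):
        path = tmp_path / "l.bed"
        write_bed([_locus("c1", 100, 250)], path)
        line = path.read_text().rstrip("\n")
        assert line == "c1\t100\t250\tc1:100-250\t77\t+"

    def test_zero_loci(self, tmp_path):
        write_bed([], tmp_path / "l.bed")
        write_summary([], tmp_path / "s.tsv")
        assert (tmp_path / "l.bed").read_text() == ""
        summary = (tmp_path / "s.tsv").read_text().splitlines()
        assert len(summary) == 1 and summary[0].startswith("locus_id\t")

    def test_rows_sorted_by_contig_start_end(self, tmp_path):
        loci = [_locus("c2", 5, 10), _locus("c1", 50, 80), _locus("c1", 5, 10)]
        write_bed(loci, tmp_path / "l.bed")
        firsts = [l.split("\t")[:2] for l in (tmp_path / "l.bed").read_text().splitlines()]
        assert firsts == [["c1", "5"], ["c1", "50"], ["c2", "5"]]

    def test_invalid_interval_errors(self, tmp_path):
        locus = _locus("c1", 10, 20)
        locus.canon_end = 10
        with pytest.raises(ValueError, match="start"):
            write_bed([locus], tmp_path / "l.bed")

    def test_summary_reparses_to_category_counts(self, tmp_path):
        loci = [_locus("c1", 0, 30), _locus("c1", 5000, 5030), _locus("c2", 7, 40)]
        for locus, cat in zip(loci, ["likely-eve", "likely-eve", "uncertain"]):
            locus.category = cat
        path = tmp_path / "s.tsv"
        write_summary(loci, path)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        idx = header.index("category")
        counts = {}
        for line in lines[1:]:
            cat = line.split("\t")[idx]
            counts[cat] = counts.get(cat, 0) + 1
        assert counts == {"likely-eve": 2, "uncertain": 1}
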