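"""Classifier tests, including a dual-implementation oracle of the six rules.

The oracle below is an independent transcription of the decision tree used
by ``classify_locus`` (first rule that fires wins, strict inequalities,
case-insensitive matching, word boundaries on short keywords).
"""

import itertools
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evescan.classify import (
    CATEGORIES,
    EvidenceProfile,
    RuleSet,
    build_evidence,
    classify_locus,
    classify_locus_detailed,
)
from evescan.formats_io import Hit
from evescan.loci import CandidateLocus
from evescan.simulate import TAXID

# ---------------------------------------------------------------------------
# Independent oracle
# ---------------------------------------------------------------------------

_RETRO_RE = re.compile(
    r"\bgag\b|\bpol\b|\benv\b|\bpro\b|\bpro[-]?pol\b|\brt[-]?in\b|reverse|protease")
_TRANSPOSON_RE = re.compile(r"\bpol\b|\bgag\b|transpos|group specific antigen")


def rule_oracle(p: EvidenceProfile) -> str:
    if any("retro" in f or "caulimo" in f for f in p.rvdb_families):
        if any(_RETRO_RE.search(t) for t in p.all_titles):
            return "likely-retro"
    host_kw = ("ubiquitin", "zinc", "nynrin", "kinase")
    if (p.n_rvdb == 0
            or (p.n_nr > 0 and p.n_rvdb / p.n_nr < 0.30)
            or any(k in t for t in p.all_titles for k in host_kw)):
        return "likely-host-protein"
    if any("bamford" in k for k in p.rvdb_kingdoms):
        return "bamford-related"
    if (p.frac_rvdb_euk is not None and p.frac_rvdb_euk > 0.80
            and _TRANSPOSON_RE.search(p.best_rvdb_title)):
        return "likely-transposon"
    bad_fam = ("baculo", "poly", "fabace", "allohe")
    if (p.frac_rvdb_viral is not None and p.frac_rvdb_viral > 0.60
            and not any(b in f for f in p.rvdb_families for b in bad_fam)):
        return "likely-eve"
    if p.frac_nr_viral is not None and p.frac_nr_viral > 0.50:
        return "likely-eve"
    return "uncertain"


FRACTIONS = (0.0, 0.25, 0.31, 0.55, 0.65, 0.85, 1.0)
FAMILY_SETS = (frozenset(), frozenset({"retroviridae"}),
               frozenset({"baculoviridae"}), frozenset({"circoviridae"}))
KINGDOM_SETS = (frozenset(), frozenset({"bamfordvirae"}), frozenset({"metazoa"}))
TITLE_SETS = (frozenset(), frozenset({"gag polyprotein"}),
              frozenset({"ubiquitin ligase"}), frozenset({"transposase"}),
              frozenset({"hypothetical protein"}))


def profile_grid():
    """Exhaustive discretized grid of consistent evidence profiles."""
    profiles = []
    for n_rvdb, n_nr in itertools.product((0, 5), (0, 10)):
        nr_fracs = FRACTIONS if n_nr else (None,)
        if n_rvdb == 0:
            for fnr, titles in itertools.product(nr_fracs, TITLE_SETS):
                profiles.append(EvidenceProfile(
                    n_rvdb=0, n_nr=n_nr, frac_nr_viral=fnr, all_titles=titles))
            continue
        for fv, fe, fnr, fams, kds, titles in itertools.product(
                FRACTIONS, FRACTIONS, nr_fracs, FAMILY_SETS, KINGDOM_SETS,
                TITLE_SETS):
            best = next(iter(titles)) if titles else ""
            profiles.append(EvidenceProfile(
                n_rvdb=n_rvdb, n_nr=n_nr, frac_rvdb_viral=fv,
                frac_rvdb_euk=fe, frac_nr_viral=fnr, rvdb_families=fams,
                rvdb_kingdoms=kds, best_rvdb_title=best, all_titles=titles))
    return profiles


def test_truth_table_grid_matches_oracle():
    profiles = profile_grid()
    assert len(profiles) > 10_000
    for profile in profiles:
        assert classify_locus(profile) == rule_oracle(profile)


# ---------------------------------------------------------------------------
# Per-rule examples
# ---------------------------------------------------------------------------

class TestRules:
    def test_rule1_retro(self):
        p = EvidenceProfile(n_rvdb=3, n_nr=3,
                            rvdb_families=frozenset({"retroviridae"}),
                            all_titles=frozenset({"gag-pol polyprotein"}))
        assert classify_locus_detailed(p) == ("likely-retro", 1)

    def test_rule2_ratio(self):
        p = EvidenceProfile(n_rvdb=2, n_nr=10,
                            all_titles=frozenset({"some protein"}))
        assert classify_locus_detailed(p) == ("likely-host-protein", 2)

    def test_rule2_host_keyword(self):
        p = EvidenceProfile(n_rvdb=5, n_nr=5,
                            all_titles=frozenset({"zinc finger protein"}))
        assert classify_locus_detailed(p) == ("likely-host-protein", 2)

    def test_rule3_bamford(self):
        p = EvidenceProfile(n_rvdb=2, n_nr=2,
                            rvdb_kingdoms=frozenset({"bamfordvirae"}))
        assert classify_locus_detailed(p) == ("bamford-related", 3)

    def test_rule4_transposon(self):
        p = EvidenceProfile(n_rvdb=10, n_nr=10, frac_rvdb_euk=0.9,
                            best_rvdb_title="transposase")
        assert classify_locus_detailed(p) == ("likely-transposon", 4)

    def test_rule5_eve(self):
        p = EvidenceProfile(n_rvdb=10, n_nr=10, frac_rvdb_viral=0.7,
                            rvdb_families=frozenset({"circoviridae"}),
                            frac_nr_viral=0.2)
        assert classify_locus_detailed(p) == ("likely-eve", 5)

    def test_rule5_excluded_family_blocks_first_clause(self):
        p = EvidenceProfile(n_rvdb=10, n_nr=10, frac_rvdb_viral=0.9,
                            rvdb_families=frozenset({"polyomaviridae"}),
                            frac_nr_viral=0.2)
        assert classify_locus(p) == "uncertain"

    def test_all_empty_profile_is_host(self):
        # n_rvdb == 0 fires rule 2 before anything else
        assert classify_locus_detailed(EvidenceProfile()) == ("likely-host-protein", 2)

    def test_bamford_with_zero_rvdb_is_host(self):
        # strict rule order: rule 2 wins over rule 3
        p = EvidenceProfile(n_rvdb=0, n_nr=5,
                            rvdb_kingdoms=frozenset({"bamfordvirae"}))
        assert classify_locus(p) == "likely-host-protein"

    def test_word_boundary_pol_does_not_match_polymerase(self):
        p = EvidenceProfile(n_rvdb=5, n_nr=5, frac_rvdb_euk=1.0,
                            best_rvdb_title="dna polymerase")
        assert classify_locus(p) == "uncertain"

    def test_substring_mode_matches_polymerase(self):
        p = EvidenceProfile(n_rvdb=5, n_nr=5, frac_rvdb_euk=1.0,
                            best_rvdb_title="dna polymerase")
        rules = RuleSet(substring_keywords=True)
        assert classify_locus(p, rules) == "likely-transposon"


class TestBoundaries:
    """Fractions exactly at a printed threshold do NOT fire."""

    def test_ratio_exactly_030(self):
        p = EvidenceProfile(n_rvdb=3, n_nr=10)  # 3/10 == 0.30
        category, rule = classify_locus_detailed(p)
        assert (category, rule) != ("likely-host-protein", 2)

    def test_euk_exactly_080(self):
        p = EvidenceProfile(n_rvdb=5, n_nr=5, frac_rvdb_euk=4 / 5,
                            best_rvdb_title="transposase")
        assert classify_locus(p) != "likely-transposon"

    def test_viral_exactly_060(self):
        p = EvidenceProfile(n_rvdb=5, n_nr=5, frac_rvdb_viral=3 / 5)
        assert classify_locus(p) != "likely-eve"

    def test_nr_viral_exactly_050(self):
        p = EvidenceProfile(n_rvdb=5, n_nr=10, frac_nr_viral=5 / 10)
        assert classify_locus(p) != "likely-eve"


# ---------------------------------------------------------------------------
# build_evidence
# ---------------------------------------------------------------------------

def _recip_hit(sseqid, title, taxids, bitscore=100.0, evalue=1e-20):
    return Hit.from_dialect(
        qseqid="locus", sseqid=sseqid, pident=80.0, aln_len=40, mismatch=5,
        gapopen=0, qstart=1, qend=40, sstart=1, send=40,
        evalue=evalue, bitscore=bitscore, stitle=title, staxids=taxids)


def _locus(rvdb_hits, nr_hits):
    anchor = _recip_hit("fwd", "forward", ())
    anchor.sseqid = "c"
    locus = CandidateLocus("c:0-100", "c", 0, 100, "+", [anchor])
    locus.rvdb_hits = rvdb_hits
    locus.nr_hits = nr_hits
    return locus


class TestBuildEvidence:
    def test_all_viral_fraction_one(self, taxdb):
        hits = [_recip_hit(f"s{i}", "capsid", (TAXID["Porcine circovirus 1"],))
                for i in range(3)]
        profile = build_evidence(_locus(hits, []), taxdb)
        assert profile.frac_rvdb_viral == 1.0
        assert profile.n_nr == 0 and profile.frac_nr_viral is None

    def test_empty_rvdb_fractions_undefined(self, taxdb):
        profile = build_evidence(_locus([], [_recip_hit("s", "x", (9606,))]), taxdb)
        assert profile.n_rvdb == 0
        assert profile.frac_rvdb_viral is None
        assert profile.frac_rvdb_euk is None

    def test_hand_tally_12_hit_fixture(self, taxdb):
        hiv = TAXID["Human immunodeficiency virus 1"]
        circo = TAXID["Porcine circovirus 1"]
        homo = TAXID["Homo sapiens"]
        aedes = TAXID["Aedes aegypti"]
        rvdb = [
            _recip_hit("r1", "gag polyprotein", (hiv,), bitscore=250.0),
            _recip_hit("r2", "capsid protein", (circo,), bitscore=200.0),
            _recip_hit("r3", "hypothetical protein", (homo,), bitscore=150.0),
            _recip_hit("r4", "unknown", (999_999,), bitscore=140.0),
            _recip_hit("r5", "mixed subject", (hiv, homo), bitscore=130.0),
            _recip_hit("r6", "transposase", (aedes,), bitscore=120.0),
        ]
        nr = [
            _recip_hit("n1", "gag polyprotein", (hiv,)),
            _recip_hit("n2", "kinase", (homo,)),
            _recip_hit("n3", "kinase", (homo,)),
            _recip_hit("n4", "no taxid", ()),
            _recip_hit("n5", "capsid protein", (circo,)),
            _recip_hit("n6", "hypothetical protein", (homo,)),
        ]
        profile = build_evidence(_locus(rvdb, nr), taxdb)
        assert profile.n_rvdb == 6 and profile.n_nr == 6
        # viral rvdb: r1, r2, r5 (any-taxid reading) = 3/6
        assert profile.frac_rvdb_viral == pytest.approx(3 / 6)
        # eukaryotic rvdb: r3, r5, r6 = 3/6
        assert profile.frac_rvdb_euk == pytest.approx(3 / 6)
        # viral nr: n1, n5 = 2/6
        assert profile.frac_nr_viral == pytest.approx(2 / 6)
        assert profile.rvdb_families == {
            "retroviridae", "circoviridae", "hominidae", "culicidae"}
        assert profile.best_rvdb_title == "gag polyprotein"
        assert "kinase" in profile.all_titles

    def test_order_independence(self, taxdb):
        hiv = TAXID["Human immunodeficiency virus 1"]
        rvdb = [_recip_hit(f"s{i}", f"title {i}", (hiv,), bitscore=100.0 + i)
                for i in range(5)]
        p1 = build_evidence(_locus(list(rvdb), []), taxdb)
        p2 = build_evidence(_locus(list(reversed(rvdb)), []), taxdb)
        assert p1 == p2


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

fraction_or_none = st.one_of(
    st.none(), st.floats(min_value=0.0, max_value=1.0, allow_nan=False))


@st.composite
def profiles(draw):
    n_rvdb = draw(st.integers(0, 20))
    n_nr = draw(st.integers(0, 20))
    def frac(n):
        return draw(fraction_or_none) if n > 0 else None
    return EvidenceProfile(
        n_rvdb=n_rvdb, n_nr=n_nr,
        frac_rvdb_viral=frac(n_rvdb), frac_rvdb_euk=frac(n_rvdb),
        frac_nr_viral=frac(n_nr),
        rvdb_families=frozenset(draw(st.sets(st.sampled_from(
            ["retroviridae", "baculoviridae", "circoviridae", "polyomaviridae"])))),
        rvdb_kingdoms=frozenset(draw(st.sets(st.sampled_from(
            ["bamfordvirae", "orthornavirae", "metazoa"])))),
        best_rvdb_title=draw(st.sampled_from(
            ["", "gag polyprotein", "transposase", "hypothetical protein"])),
        all_titles=frozenset(draw(st.sets(st.sampled_from(
            ["gag polyprotein", "ubiquitin ligase", "transposase",
             "hypothetical protein", "reverse transcriptase"])))),
    )


@settings(max_examples=300, deadline=None)
@given(profiles())
def test_partition_exactly_one_category(profile):
    category, rule = classify_locus_detailed(profile)
    assert category in CATEGORIES
    assert 1 <= rule <= 6
    assert classify_locus(profile) == rule_oracle(profile)


def test_eve_monotonicity_under_added_viral_hit():
    # strengthening the viral fraction of a likely-eve profile can only yield
    # likely-eve or an earlier rule, never uncertain
    base = EvidenceProfile(n_rvdb=5, n_nr=5, frac_rvdb_viral=0.8,
                           frac_rvdb_euk=0.2, frac_nr_viral=0.2,
                           rvdb_families=frozenset({"circoviridae"}))
    assert classify_locus(base) == "likely-eve"
    stronger = EvidenceProfile(
        n_rvdb=6, n_nr=5, frac_rvdb_viral=5 / 6 + 1 / 6 * 0.8,
        frac_rvdb_euk=0.2 * 5 / 6, frac_nr_viral=0.2,
        rvdb_families=frozenset({"circoviridae"}))
    category, rule = classify_locus_detailed(stronger)
    assert category != "uncertain"
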