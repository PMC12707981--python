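"""Reciprocal-evidence aggregation and the six-category decision tree.

A locus's reciprocal hits against a viral database (RVDB-style) and a broad
protein database (nr-style) are condensed into an :class:`EvidenceProfile`;
six rules are then evaluated strictly in order and the first that fires wins:

1. likely-retro        2. likely-host-protein   3. bamford-related
4. likely-transposon   5. likely-eve            6. uncertain

All string predicates are case-insensitive substring matches on lowercased
titles, family and kingdom names — except the short keywords (gag, pol, env,
pro, rt-in), which are matched with word boundaries by default because as
bare substrings they fire on words like "polymerase" and "protein". Set
``RuleSet.substring_keywords=True`` for literal substring behaviour.

Threshold comparisons are strict inequalities: a fraction exactly at a
threshold does not fire its rule.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from evescan.chunking import hit_sort_key
from evescan.formats_io import Hit, TaxonomyDB
from evescan.loci import CandidateLocus

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "EvidenceProfile",
    "RuleSet",
    "build_evidence",
    "classify_locus",
    "classify_locus_detailed",
    "write_classification",
]

CATEGORIES = (
    "likely-retro",
    "likely-host-protein",
    "bamford-related",
    "likely-transposon",
    "likely-eve",
    "uncertain",
)


@dataclass(frozen=True)
class EvidenceProfile:
    """Aggregated reciprocal evidence for one locus.

    Fractions are None when their denominator is zero (never coerced to 0).
    """

    n_rvdb: int = 0
    n_nr: int = 0
    frac_rvdb_viral: float | None = None
    frac_rvdb_euk: float | None = None
    frac_nr_viral: float | None = None
    rvdb_families: frozenset[str] = frozenset()
    rvdb_kingdoms: frozenset[str] = frozenset()
    best_rvdb_title: str = ""
    all_titles: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RuleSet:
    retro_family_substrings: tuple[str, ...] = ("retro", "caulimo")
    retro_short_keywords: tuple[str, ...] = ("gag", "pol", "env", "pro", r"pro[-]?pol", r"rt[-]?in")
    retro_long_keywords: tuple[str, ...] = ("reverse", "protease")
    host_title_substrings: tuple[str, ...] = ("ubiquitin", "zinc", "nynrin", "kinase")
    rvdb_vs_nr_min_ratio: float = 0.30
    bamford_kingdom_substring: str = "bamford"
    transposon_euk_frac: float = 0.80
    transposon_short_keywords: tuple[str, ...] = ("pol", "gag")
    transposon_long_keywords: tuple[str, ...] = ("transpos", "group specific antigen")
    eve_rvdb_viral_frac: float = 0.60
    eve_excluded_family_substrings: tuple[str, ...] = ("baculo", "poly", "fabace", "allohe")
    eve_nr_viral_frac: float = 0.50
    substring_keywords: bool = False  # True = literal substring matching for short keywords

    def retro_title_pattern(self) -> re.Pattern:
        if self.substring_keywords:
            parts = list(self.retro_short_keywords) + list(self.retro_long_keywords)
        else:
            parts = [rf"\b(?:{kw})\b" for kw in self.retro_short_keywords]
            parts += list(self.retro_long_keywords)
        return re.compile("|".join(parts))

    def transposon_title_pattern(self) -> re.Pattern:
        if self.substring_keywords:
            parts = list(self.transposon_short_keywords) + list(self.transposon_long_keywords)
        else:
            parts = [rf"\b(?:{kw})\b" for kw in self.transposon_short_keywords]
            parts += list(self.transposon_long_keywords)
        return re.compile("|".join(parts))


def _hit_predicates(hits: Sequence[Hit], taxdb: TaxonomyDB):
    """Per-hit (is_viral, is_euk, families, kingdoms) under the 'any taxid
    satisfies' reading; unresolvable taxids satisfy no predicate but the hit
    still counts in denominators."""
    out = []
    for hit in hits:
        viral = euk = False
        families: set[str] = set()
        kingdoms: set[str] = set()
        for taxid in hit.staxids:
            if taxid not in taxdb:
                logger.debug("unresolvable taxid %d on hit %s", taxid, hit.sseqid)
                continue
            viral = viral or taxdb.is_viral(taxid)
            euk = euk or taxdb.is_eukaryotic(taxid)
            fam = taxdb.family(taxid)
            if fam:
                families.add(fam.lower())
            kd = taxdb.kingdom(taxid)
            if kd:
                kingdoms.add(kd.lower())
        out.append((viral, euk, families, kingdoms))
    return out


def build_evidence(locus: CandidateLocus, taxdb: TaxonomyDB) -> EvidenceProfile:
    """Condense a locus's (already filtered/ranked) reciprocal hit lists into
    an :class:`EvidenceProfile`. Counts are over hits, not unique subjects."""
    rvdb_preds = _hit_predicates(locus.rvdb_hits, taxdb)
    nr_preds = _hit_predicates(locus.nr_hits, taxdb)
    n_rvdb, n_nr = len(locus.rvdb_hits), len(locus.nr_hits)

    families: set[str] = set()
    kingdoms: set[str] = set()
    for _, _, fams, kds in rvdb_preds:
        families |= fams
        kingdoms |= kds

    best_title = ""
    if locus.rvdb_hits:
        best = min(locus.rvdb_hits, key=hit_sort_key)
        best_title = best.stitle.lower()

    titles = frozenset(
        h.stitle.lower() for h in (*locus.rvdb_hits, *locus.nr_hits) if h.stitle
    )
    return EvidenceProfile(
        n_rvdb=n_rvdb,
        n_nr=n_nr,
        frac_rvdb_viral=(sum(v for v, _, _, _ in rvdb_preds) / n_rvdb) if n_rvdb else None,
        frac_rvdb_euk=(sum(e for _, e, _, _ in rvdb_preds) / n_rvdb) if n_rvdb else None,
        frac_nr_viral=(sum(v for v, _, _, _ in nr_preds) / n_nr) if n_nr else None,
        rvdb_families=frozenset(families),
        rvdb_kingdoms=frozenset(kingdoms),
        best_rvdb_title=best_title,
        all_titles=titles,
    )


def classify_locus_detailed(profile: EvidenceProfile,
                            rules: RuleSet = RuleSet()) -> tuple[str, int]:
    """Evaluate the six rules strictly in order; return (category, fired rule
    index 1-6)."""
    # 1. likely-retro
    retro_family = any(
        sub in fam for fam in profile.rvdb_families
        for sub in rules.retro_family_substrings
    )
    if retro_family:
        pattern = rules.retro_title_pattern()
        if any(pattern.search(t) for t in profile.all_titles):
            return "likely-retro", 1

    # 2. likely-host-protein
    if profile.n_rvdb == 0:
        return "likely-host-protein", 2
    if profile.n_nr > 0 and (profile.n_rvdb / profile.n_nr) < rules.rvdb_vs_nr_min_ratio:
        return "likely-host-protein", 2
    if any(kw in t for t in profile.all_titles for kw in rules.host_title_substrings):
        return "likely-host-protein", 2

    # 3. bamford-related
    if any(rules.bamford_kingdom_substring in kd for kd in profile.rvdb_kingdoms):
        return "bamford-related", 3

    # 4. likely-transposon
    if (profile.frac_rvdb_euk is not None
            and profile.frac_rvdb_euk > rules.transposon_euk_frac
            and rules.transposon_title_pattern().search(profile.best_rvdb_title)):
        return "likely-transposon", 4

    # 5. likely-eve
    excluded_family = any(
        sub in fam for fam in profile.rvdb_families
        for sub in rules.eve_excluded_family_substrings
    )
    if (profile.frac_rvdb_viral is not None
            and profile.frac_rvdb_viral > rules.eve_rvdb_viral_frac
            and not excluded_family):
        return "likely-eve", 5
    if (profile.frac_nr_viral is not None
            and profile.frac_nr_viral > rules.eve_nr_viral_frac):
        return "likely-eve", 5

    return "uncertain", 6


def classify_locus(profile: EvidenceProfile, rules: RuleSet = RuleSet()) -> str:
    category, rule = classify_locus_detailed(profile, rules)
    logger.debug("profile classified %s (rule %d)", category, rule)
    return category


CLASSIFICATION_COLUMNS = (
    "locus_id", "category", "fired_rule", "n_rvdb", "n_nr",
    "frac_rvdb_viral", "frac_rvdb_euk", "frac_nr_viral",
    "rvdb_families", "rvdb_kingdoms", "best_rvdb_title",
)


def write_classification(loci: Sequence[CandidateLocus], taxdb: TaxonomyDB,
                         path: str | Path,
                         rules: RuleSet = RuleSet()) -> None:
    """Classify every locus (setting ``locus.category``) and write the
    per-locus classification TSV."""
    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.4f}"

    with open(path, "w") as fh:
        fh.write("\t".join(CLASSIFICATION_COLUMNS) + "\n")
        for locus in sorted(loci, key=lambda l: (l.contig, l.canon_start)):
            profile = build_evidence(locus, taxdb)
            category, rule = classify_locus_detailed(profile, rules)
            locus.category = category
            fh.write("\t".join([
                locus.locus_id, category, str(rule),
                str(profile.n_rvdb), str(profile.n_nr),
                fmt(profile.frac_rvdb_viral), fmt(profile.frac_rvdb_euk),
                fmt(profile.frac_nr_viral),
                ";".join(sorted(profile.rvdb_families)) or ".",
                ";".join(sorted(profile.rvdb_kingdoms)) or ".",
                profile.best_rvdb_title or ".",
            ]) + "\n")
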