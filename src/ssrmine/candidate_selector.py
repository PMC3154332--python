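"""Marker-selection filters for profiled microsatellite loci.

Candidates for primer design are retained when they (i) carry enough
flanking sequence on both sides for primer placement, (ii) have a minimum
read depth across the repeat and its flanks, (iii) come from an annotated
contig, (iv) come from a contig mapped to a reference genome, and — to
avoid typing the same gene twice — at most one locus is kept per isogroup
(the set of splice-variant contigs of one gene).  Optionally only loci
classified variable in silico are kept.  Every failed rule is recorded so a
locus's exclusion is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .assembly_profiler import InSilicoProfile

__all__ = [
    "AnnotationRecord",
    "SelectionRules",
    "CandidateLocus",
    "match_annotation",
    "select_candidates",
]

RULE_FLANK = "flank"
RULE_COVERAGE = "coverage"
RULE_ANNOTATED = "annotated"
RULE_MAPPED = "mapped"
RULE_VARIABLE = "variable"
RULE_ISOGROUP = "isogroup"


@dataclass(frozen=True)
class AnnotationRecord:
    contig_id: str
    isogroup_id: str | None = None
    go_terms: str = ""
    annotated: bool = False
    mapped: bool = False


@dataclass(frozen=True)
class SelectionRules:
    """Thresholds for candidate selection; defaults follow the study design."""

    min_flank_bp: int = 30
    min_region_coverage: int = 2
    require_annotated: bool = True
    require_mapped: bool = True
    one_per_isogroup: bool = True
    require_variable: bool = False


@dataclass
class CandidateLocus:
    locus_id: str
    contig_id: str
    profile: InSilicoProfile
    flank_left_bp: int
    flank_right_bp: int
    min_coverage_region: int
    annotated: bool
    mapped: bool
    isogroup_id: str | None
    category_tags: list[str] = field(default_factory=list)
    filter_failures: list[str] = field(default_factory=list)
    selected: bool = False


def match_annotation(
    annotations: Iterable[AnnotationRecord],
    patterns: Sequence[str],
) -> dict[str, list[str]]:
    """Tag each contig with every pattern found in its GO term text.

    Matching is case-insensitive substring search (so a pattern ``immun``
    hits "immune response" and "immunoglobulin" alike).  Contigs without a
    matching term are absent from the result.
    """
    tags: dict[str, list[str]] = {}
    lowered = [(p, p.lower()) for p in patterns]
    for rec in annotations:
        text = rec.go_terms.lower()
        hits = [p for p, pl in lowered if pl in text]
        if hits:
            tags[rec.contig_id] = hits
    return tags


def _contig_of(profile: InSilicoProfile) -> str:
    # locus ids are "<contig>:<start1>-<end1>:<motif>"
    return profile.locus_id.rsplit(":", 2)[0]


def select_candidates(
    profiles: Sequence[InSilicoProfile],
    annotations: Mapping[str, AnnotationRecord],
    region_meta: Mapping[str, Mapping[str, int]],
    rules: SelectionRules = SelectionRules(),
    patterns: Sequence[str] = (),
) -> list[CandidateLocus]:
    """Apply the selection rules; returns one CandidateLocus per profile.

    ``region_meta`` supplies per-locus ``flank_left_bp``, ``flank_right_bp``
    and ``min_region_coverage`` (from :func:`~ssrmine.assembly_profiler.profile_alignments`).
    When several passing loci share an isogroup, the representative kept is
    the one with the most in silico alleles, ties broken by spanning depth,
    then by locus id — a fixed, deterministic choice.
    """
    ann_records = list(annotations.values())
    tag_map = match_annotation(ann_records, patterns) if patterns else {}

    candidates: list[CandidateLocus] = []
    for prof in sorted(profiles, key=lambda p: p.locus_id):
        contig = _contig_of(prof)
        ann = annotations.get(contig)
        meta = region_meta.get(prof.locus_id, {})
        cand = CandidateLocus(
            locus_id=prof.locus_id,
            contig_id=contig,
            profile=prof,
            flank_left_bp=int(meta.get("flank_left_bp", 0)),
            flank_right_bp=int(meta.get("flank_right_bp", 0)),
            min_coverage_region=int(meta.get("min_region_coverage", 0)),
            annotated=bool(ann.annotated) if ann else False,
            mapped=bool(ann.mapped) if ann else False,
            isogroup_id=ann.isogroup_id if ann else None,
            category_tags=list(tag_map.get(contig, [])),
        )
        fails = cand.filter_failures
        if min(cand.flank_left_bp, cand.flank_right_bp) < rules.min_flank_bp:
            fails.append(RULE_FLANK)
        if cand.min_coverage_region < rules.min_region_coverage:
            fails.append(RULE_COVERAGE)
        if rules.require_annotated and not cand.annotated:
            fails.append(RULE_ANNOTATED)
        if rules.require_mapped and not cand.mapped:
            fails.append(RULE_MAPPED)
        if rules.require_variable and not prof.is_variable:
            fails.append(RULE_VARIABLE)
        candidates.append(cand)

    if rules.one_per_isogroup:
        by_group: dict[str, list[CandidateLocus]] = {}
        for cand in candidates:
            if cand.filter_failures or cand.isogroup_id is None:
                continue
            by_group.setdefault(cand.isogroup_id, []).append(cand)
        for group in by_group.values():
            group.sort(
                key=lambda c: (
                    -c.profile.n_alleles_insilico,
                    -c.profile.depth_spanning,
                    c.locus_id,
                )
            )
            for loser in group[1:]:
                loser.filter_failures.append(RULE_ISOGROUP)

    for cand in candidates:
        cand.selected = not cand.filter_failures
    return candidates


def primer_design_windows(
    candidates: Sequence[CandidateLocus],
    loci_coords: Mapping[str, tuple[int, int]],
    flank: int = 30,
) -> list[tuple[str, int, int, str]]:
    """BED-style (contig, start, end, locus_id) windows around selected tracts.

    0-based half-open, clipped at the contig start; intended as input to an
    external primer-design step targeting 100-250 bp products.
    """
    out = []
    for cand in candidates:
        if not cand.selected:
            continue
        start, end = loci_coords[cand.locus_id]
        out.append((cand.contig_id, max(0, start - flank), end + flank, cand.locus_id))
    return out
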