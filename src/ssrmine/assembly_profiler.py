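"""Read-level repeat-unit counting and allele profiling from contig alignments.

Given a repeat locus on a contig and the reads aligned to that contig, each
spanning read (one whose alignment covers the full tract plus ``anchor_len``
exact-matching flanking bases on both sides) contributes a repeat-unit count.
The histogram of unit counts over spanning reads is the locus's in silico
allele profile: each distinct unit count is one motif length variant,
inferred to be a different allele, and reads whose count differs from the
modal (consensus) count are the off-consensus reads.  Reads carrying a
substitution or partial motif copy inside the tract, or a mismatch in an
anchor, are tallied as ``irregular`` and excluded from the histogram — a
single base substitution must not fabricate a length allele.

Alleles here are read-level length classes from pooled sequencing, never
diploid genotype calls: the individual of origin of each read is unknown.

Primer-binding regions can additionally be screened for SNPs (per-column
base counts over aligned reads, alignment gaps excluded from depth), the
diagnostic used to explain null alleles at loci with homozygote excess.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

from .repeat_scanner import RepeatLocus

__all__ = [
    "ReadObservation",
    "InSilicoProfile",
    "PrimerSiteReport",
    "SnpCall",
    "count_units",
    "build_profile",
    "screen_primer_sites",
    "profile_alignments",
    "region_depths",
]

COUNTED = "counted"
NON_SPANNING = "non_spanning"
IRREGULAR = "irregular"

DEFAULT_ANCHOR_LEN = 5


@dataclass(frozen=True)
class ReadObservation:
    """Outcome of unit counting for one read at one locus."""

    read_id: str
    locus_id: str
    spans: bool
    unit_count: int | None
    status: str  # counted | non_spanning | irregular

    def __post_init__(self) -> None:
        if (self.status == COUNTED) != (self.unit_count is not None):
            raise ValueError("unit_count must be present iff status == counted")


@dataclass
class InSilicoProfile:
    """Per-locus allele histogram and variability classification."""

    locus_id: str
    depth_spanning: int
    allele_histogram: dict[int, int]
    n_alleles_insilico: int
    consensus_units: int | None
    n_off_consensus_reads: int
    min_units_observed: int | None
    is_variable: bool
    n_irregular: int = 0
    n_non_spanning: int = 0
    low_coverage: bool = False


@dataclass(frozen=True)
class SnpCall:
    position: int  # 0-based contig coordinate
    major_base: str
    minor_base: str
    minor_count: int
    depth: int

    @property
    def maf(self) -> float:
        return self.minor_count / self.depth


@dataclass
class PrimerSiteReport:
    locus_id: str
    region_start: int
    region_end: int
    min_depth: int
    snps: list[SnpCall] = field(default_factory=list)


def _tract_segment_and_anchors(
    aln: pysam.AlignedSegment,
    start: int,
    end: int,
    anchor_len: int,
) -> tuple[str, str, str] | None:
    """Split the read into (left anchor, tract segment, right anchor) strings.

    The tract segment collects read bases aligned to reference positions in
    [start, end) plus inserted bases whose insertion point lies in
    (start-1, end) — i.e. anywhere from just inside the left tract boundary
    to the right boundary, so a slipped-in extra motif copy is always
    assigned to the tract regardless of indel placement.  Anchor strings
    collect bases aligned within the flanking windows; an insertion strictly
    inside an anchor window is appended to that anchor (and will fail the
    exact-match test).  Returns None if any anchor position or tract
    position the read should cover is absent in a way already excluded by
    the span test (should not happen for spanning reads).
    """
    left: list[str] = []
    tract: list[str] = []
    right: list[str] = []
    seq = aln.query_sequence
    if seq is None:
        return None
    last_ref = None
    for qpos, rpos in aln.get_aligned_pairs():
        if rpos is not None:
            if qpos is not None:  # aligned base (deletions have qpos None)
                base = seq[qpos]
                if start - anchor_len <= rpos < start:
                    left.append(base)
                elif start <= rpos < end:
                    tract.append(base)
                elif end <= rpos < end + anchor_len:
                    right.append(base)
            last_ref = rpos
        elif qpos is not None:  # insertion relative to the reference
            base = seq[qpos]
            if last_ref is None:
                continue  # leading soft-clip/insertion outside alignment
            if start - 1 <= last_ref < end:
                tract.append(base)
            elif start - anchor_len <= last_ref < start - 1:
                left.append(base)
            elif end <= last_ref < end + anchor_len - 1:
                right.append(base)
    return "".join(left), "".join(tract), "".join(right)


def count_units(
    aln: pysam.AlignedSegment,
    locus: RepeatLocus,
    contig_seq: str,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> ReadObservation:
    """Count perfect motif copies carried by one aligned read at ``locus``.

    The motif phase used for counting is the contig's own tract rotation
    (``contig_seq[start:start+p]``), which may differ from the canonical
    motif naming the locus.

    Raises
    ------
    ValueError
        If the alignment is on a different contig, or the locus coordinates
        fall outside the contig sequence.
    """
    if aln.reference_name != locus.contig_id:
        raise ValueError(
            f"read {aln.query_name} aligned to {aln.reference_name}, "
            f"not {locus.contig_id}"
        )
    if locus.end > len(contig_seq) or locus.start < 0:
        raise ValueError(f"locus {locus.locus_id} outside contig bounds")
    start, end = locus.start, locus.end
    p = locus.motif_size
    phase_motif = contig_seq[start : start + p].upper()
    window_lo = start - anchor_len
    window_hi = end + anchor_len
    if aln.is_unmapped or window_lo < 0 or window_hi > len(contig_seq):
        # not enough contig flank to anchor -> no read can be counted
        return ReadObservation(aln.query_name, locus.locus_id, False, None, NON_SPANNING)
    if aln.reference_start > window_lo or aln.reference_end < window_hi:
        return ReadObservation(aln.query_name, locus.locus_id, False, None, NON_SPANNING)

    parts = _tract_segment_and_anchors(aln, start, end, anchor_len)
    if parts is None:
        return ReadObservation(aln.query_name, locus.locus_id, False, None, NON_SPANNING)
    left, tract, right = parts
    exp_left = contig_seq[window_lo:start].upper()
    exp_right = contig_seq[end:window_hi].upper()
    if left.upper() != exp_left or right.upper() != exp_right:
        return ReadObservation(aln.query_name, locus.locus_id, True, None, IRREGULAR)
    tract = tract.upper()
    k, rem = divmod(len(tract), p)
    if rem != 0 or tract != phase_motif * k:
        return ReadObservation(aln.query_name, locus.locus_id, True, None, IRREGULAR)
    return ReadObservation(aln.query_name, locus.locus_id, True, k, COUNTED)


def build_profile(
    locus: RepeatLocus,
    observations: Iterable[ReadObservation],
    min_minor_reads: int = 1,
) -> InSilicoProfile:
    """Summarise read observations into an allele histogram and variability call.

    ``min_minor_reads`` is the smallest number of reads a non-consensus
    length class needs before the locus is called variable.  The default of
    1 counts even a single off-consensus read as evidence of a second
    allele; raising it discounts rare classes more likely to be slippage
    sequencing errors.
    """
    obs = [o for o in observations if o.locus_id == locus.locus_id]
    hist = Counter(o.unit_count for o in obs if o.status == COUNTED)
    n_irregular = sum(o.status == IRREGULAR for o in obs)
    n_non_spanning = sum(o.status == NON_SPANNING for o in obs)
    depth = sum(hist.values())
    if depth == 0:
        return InSilicoProfile(
            locus_id=locus.locus_id,
            depth_spanning=0,
            allele_histogram={},
            n_alleles_insilico=0,
            consensus_units=None,
            n_off_consensus_reads=0,
            min_units_observed=None,
            is_variable=False,
            n_irregular=n_irregular,
            n_non_spanning=n_non_spanning,
            low_coverage=True,
        )
    top = max(hist.values())
    modal = sorted(u for u, c in hist.items() if c == top)
    # tie-break: prefer the contig-consensus unit count, then the smaller
    consensus = (
        locus.unit_count_consensus
        if locus.unit_count_consensus in modal
        else modal[0]
    )
    off = depth - hist[consensus]
    variable = any(
        c >= min_minor_reads for u, c in hist.items() if u != consensus
    )
    return InSilicoProfile(
        locus_id=locus.locus_id,
        depth_spanning=depth,
        allele_histogram=dict(sorted(hist.items())),
        n_alleles_insilico=len(hist),
        consensus_units=consensus,
        n_off_consensus_reads=off,
        min_units_observed=min(hist),
        is_variable=variable,
        n_irregular=n_irregular,
        n_non_spanning=n_non_spanning,
    )


def _column_counts(
    alignments: Iterable[pysam.AlignedSegment],
    contig_id: str,
    start: int,
    end: int,
) -> list[Counter]:
    """Per-reference-column base counts over [start, end).

    Only aligned (match/mismatch) read bases count toward depth; deletions,
    pads and inserted bases do not occupy a reference column.
    """
    cols: list[Counter] = [Counter() for _ in range(end - start)]
    for aln in alignments:
        if aln.is_unmapped or aln.reference_name != contig_id:
            continue
        if aln.reference_end <= start or aln.reference_start >= end:
            continue
        seq = aln.query_sequence
        if seq is None:
            continue
        for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
            if start <= rpos < end:
                base = seq[qpos].upper()
                if base in "ACGT":
                    cols[rpos - start][base] += 1
    return cols


def screen_primer_sites(
    alignments: Sequence[pysam.AlignedSegment],
    contig_id: str,
    regions: Iterable[tuple[int, int]],
    locus_id: str = "",
    snp_min_minor_reads: int = 2,
) -> list[PrimerSiteReport]:
    """Screen candidate primer-binding regions for SNPs and low coverage.

    A column is a SNP when at least two distinct bases each reach
    ``snp_min_minor_reads`` supporting reads; the reported minor allele
    frequency is minor count / column depth, hence always in (0, 0.5].
    ``min_depth`` is the minimum column depth over the region (0 if any
    column is uncovered) — low primer-site coverage limits the power to
    exclude a null allele even when no SNP is seen.
    """
    reports = []
    for (rstart, rend) in regions:
        cols = _column_counts(alignments, contig_id, rstart, rend)
        snps: list[SnpCall] = []
        min_depth = None
        for offset, counts in enumerate(cols):
            depth = sum(counts.values())
            min_depth = depth if min_depth is None else min(min_depth, depth)
            ranked = counts.most_common()
            if len(ranked) >= 2:
                (major, _), (minor, minor_n) = ranked[0], ranked[1]
                if minor_n >= snp_min_minor_reads and ranked[0][1] >= snp_min_minor_reads:
                    snps.append(
                        SnpCall(rstart + offset, major, minor, minor_n, depth)
                    )
        reports.append(
            PrimerSiteReport(
                locus_id=locus_id,
                region_start=rstart,
                region_end=rend,
                min_depth=min_depth or 0,
                snps=snps,
            )
        )
    return reports


def region_depths(
    alignments: Sequence[pysam.AlignedSegment],
    contig_id: str,
    start: int,
    end: int,
) -> list[int]:
    """Aligned-base depth per column over [start, end) (clipped to >= 0)."""
    return [sum(c.values()) for c in _column_counts(alignments, contig_id, start, end)]


def profile_alignments(
    sam_path: str,
    contigs: dict[str, str],
    loci: Sequence[RepeatLocus],
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    min_minor_reads: int = 1,
    flank_window: int = 30,
) -> tuple[list[InSilicoProfile], dict[str, dict]]:
    """Profile every locus from a SAM/BAM file.

    Returns the profiles plus, per locus, region metadata used downstream by
    candidate selection: flank lengths available on the contig and the
    minimum aligned-read depth over the tract extended by ``flank_window``
    bases each side (clipped at the contig ends).
    """
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        segments = [aln for aln in fh if not aln.is_unmapped]
    return profile_segments(
        segments, contigs, loci, anchor_len, min_minor_reads, flank_window
    )


def profile_segments(
    segments: Iterable[pysam.AlignedSegment],
    contigs: dict[str, str],
    loci: Sequence[RepeatLocus],
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    min_minor_reads: int = 1,
    flank_window: int = 30,
) -> tuple[list[InSilicoProfile], dict[str, dict]]:
    """In-memory counterpart of :func:`profile_alignments`."""
    by_contig: dict[str, list[pysam.AlignedSegment]] = {}
    for aln in segments:
        if aln.is_unmapped:
            continue
        by_contig.setdefault(aln.reference_name, []).append(aln)

    profiles: list[InSilicoProfile] = []
    meta: dict[str, dict] = {}
    for locus in loci:
        seq = contigs[locus.contig_id]
        alns = by_contig.get(locus.contig_id, [])
        obs = []
        for aln in alns:
            if aln.reference_end <= locus.start or aln.reference_start >= locus.end:
                continue
            obs.append(count_units(aln, locus, seq, anchor_len))
        profiles.append(build_profile(locus, obs, min_minor_reads))
        lo = max(0, locus.start - flank_window)
        hi = min(len(seq), locus.end + flank_window)
        depths = region_depths(alns, locus.contig_id, lo, hi)
        meta[locus.locus_id] = {
            "flank_left_bp": locus.start,
            "flank_right_bp": len(seq) - locus.end,
            "min_region_coverage": min(depths) if depths else 0,
        }
    return profiles, meta
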