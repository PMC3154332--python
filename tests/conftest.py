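"""Shared fixtures: hand-built alignments and small simulated datasets."""

from __future__ import annotations

import pysam
import pytest


def make_segments(
    contigs: dict[str, str],
    reads: list[tuple[str, str, int, str, str]],
) -> list[pysam.AlignedSegment]:
    """Build in-memory alignments from (name, contig, pos0, cigar, seq) tuples."""
    order = {cid: i for i, cid in enumerate(contigs)}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": cid, "LN": len(seq)} for cid, seq in contigs.items()],
        }
    )
    out = []
    for name, contig, pos, cigar, seq in reads:
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.query_sequence = seq
        a.flag = 0
        a.reference_id = order[contig]
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigarstring = cigar
        out.append(a)
    return out


def write_sam_file(path, contigs, reads) -> str:
    """Write the same hand-built alignments to a SAM file; returns the path."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cid, "LN": len(seq)} for cid, seq in contigs.items()],
    }
    segments = make_segments(contigs, sorted(reads, key=lambda r: (r[1], r[2])))
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for seg in segments:
            fh.write(seg)
    return str(path)


@pytest.fixture
def ttg_locus_dataset():
    """A trinucleotide (TTG)x6 locus with spanning 6- and 7-unit reads.

    Mirrors the classic screenshot of a polymorphic repeat viewed in an
    assembly browser: most reads carry the consensus six units, a minority
    carry seven (3 bp insertion), one read has a substitution inside the
    tract and one stops short of spanning it.
    """
    left = "GATCCTGAAGCTTACGGATCATTCGAACCT"   # 30 bp
    right = "CCGTAAGTGATCCTTAGAACGGTCATAGCA"   # 30 bp
    tract = "TTG" * 6
    contig = left + tract + right
    start, end = len(left), len(left) + len(tract)

    def spanning(units: int) -> tuple[int, str, str]:
        # reads start 20 bp into the left flank and end 10 bp into the right
        seq = left[10:] + "TTG" * units + right[:10]
        if units == 6:
            cigar = "48M"  # consensus length, pure match
        elif units > 6:
            cigar = f"38M{(units - 6) * 3}I10M"  # extra copies inserted at tract end
        else:
            cigar = f"{20 + units * 3}M{(6 - units) * 3}D10M"
        return 10, cigar, seq

    reads = []
    for i in range(10):
        pos, cigar, seq = spanning(6)
        reads.append((f"six{i}", "isotig1", pos, cigar, seq))
    for i in range(4):
        pos, cigar, seq = spanning(7)
        reads.append((f"seven{i}", "isotig1", pos, cigar, seq))
    # substitution inside the tract: TTG TTG TAG TTG TTG TTG
    bad = left[10:] + "TTGTTGTAGTTGTTGTTG" + right[:10]
    reads.append(("subst", "isotig1", 10, "48M", bad))
    # alignment ends inside the tract
    reads.append(("short", "isotig1", 10, "26M", left[10:] + "TTGTTG"))
    return {"contig": contig, "start": start, "end": end, "reads": reads}
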