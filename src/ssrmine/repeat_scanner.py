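"""Detection of perfect short tandem repeats (microsatellites) in contig sequences.

A microsatellite is reported as a maximal perfect tract: a run of whole
copies of a 2-4 bp motif that cannot be extended by another full copy on
either side.  Each tract is reported exactly once, at its smallest period,
under the lexicographically minimal rotation of its motif (so (CA)n and
(AC)n name the same locus).  Partial trailing copies do not count toward
the unit number.  Tracts are broken by any non-ACGT character.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "RepeatLocus",
    "PeriodicMotifError",
    "canonicalize_motif",
    "scan_contig",
    "scan_fasta",
]

_ACGT = frozenset("ACGT")

#: unit-count threshold applied to di-, tri- and tetranucleotide motifs
DEFAULT_MIN_UNITS: Mapping[int, int] = {2: 5, 3: 5, 4: 5}
DEFAULT_MOTIF_SIZES = (2, 3, 4)


class PeriodicMotifError(ValueError):
    """Raised when a motif is a whole-number repetition of a shorter motif."""


@dataclass(frozen=True)
class RepeatLocus:
    """A maximal perfect tandem repeat on one contig.

    Coordinates are 0-based half-open on the given strand; ``motif`` is the
    canonical (minimal-rotation) motif while the tract itself may start at
    any rotation of it.  ``end - start == len(motif) * unit_count_consensus``.
    """

    locus_id: str
    contig_id: str
    motif: str
    start: int
    end: int
    unit_count_consensus: int

    @property
    def motif_size(self) -> int:
        return len(self.motif)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.unit_count_consensus:
            raise ValueError(
                f"{self.locus_id}: span {self.end - self.start} != "
                f"{len(self.motif)} x {self.unit_count_consensus}"
            )


def _is_periodic(motif: str) -> bool:
    """True if motif is a whole-number repetition of a strictly shorter string."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return True
    return False


def canonicalize_motif(motif: str) -> str:
    """Return the lexicographically minimal rotation of ``motif``.

    Raises
    ------
    ValueError
        If the motif contains a non-ACGT character or has length outside 2-4.
    PeriodicMotifError
        If the motif is itself periodic (e.g. ``ATAT`` = ``AT`` twice), in
        which case the repeat should be described at the shorter period.
    """
    motif = motif.upper()
    if not 2 <= len(motif) <= 4:
        raise ValueError(f"motif length must be 2-4, got {motif!r}")
    if not set(motif) <= _ACGT:
        raise ValueError(f"motif contains non-ACGT characters: {motif!r}")
    if _is_periodic(motif):
        raise PeriodicMotifError(f"motif {motif!r} is periodic")
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def scan_contig(
    sequence: str,
    contig_id: str = "contig",
    min_units: Mapping[int, int] | None = None,
    motif_sizes: Iterable[int] = DEFAULT_MOTIF_SIZES,
) -> list[RepeatLocus]:
    """Find every maximal perfect di/tri/tetranucleotide tract in ``sequence``.

    For each period p, maximal p-periodic runs are located by comparing each
    base with the base p positions downstream; a run yields one locus anchored
    at the run start, with unit count = floor(run length / p).  Runs whose
    motif is periodic (reducible to a smaller p) are skipped — they are
    reported at the smaller period instead.  Loci are returned sorted by
    start, then motif size.
    """
    if min_units is None:
        min_units = DEFAULT_MIN_UNITS
    seq = sequence.upper()
    n = len(seq)
    loci: list[RepeatLocus] = []
    for p in sorted(motif_sizes):
        threshold = min_units.get(p, 5)
        i = 0
        # b[x] := seq[x] == seq[x+p], both ACGT; a maximal True stretch
        # [i, j) corresponds to the tract occupying [i, j + p).
        while i + p < n:
            if seq[i] in _ACGT and seq[i] == seq[i + p]:
                j = i
                while j + p < n and seq[j] in _ACGT and seq[j] == seq[j + p]:
                    j += 1
                tract_len = j - i + p
                units = tract_len // p
                motif_here = seq[i : i + p]
                if units >= threshold and not _is_periodic(motif_here):
                    canon = canonicalize_motif(motif_here)
                    start, end = i, i + units * p
                    loci.append(
                        RepeatLocus(
                            locus_id=f"{contig_id}:{start + 1}-{end}:{canon}",
                            contig_id=contig_id,
                            motif=canon,
                            start=start,
                            end=end,
                            unit_count_consensus=units,
                        )
                    )
                i = j + 1
            else:
                i += 1
    loci.sort(key=lambda l: (l.start, l.motif_size))
    return loci


def scan_fasta(
    records: Iterable[tuple[str, str]],
    min_units: Mapping[int, int] | None = None,
    motif_sizes: Iterable[int] = DEFAULT_MOTIF_SIZES,
) -> list[RepeatLocus]:
    """Scan an iterable of (contig_id, sequence) pairs; see :func:`scan_contig`."""
    out: list[RepeatLocus] = []
    for contig_id, seq in records:
        out.extend(scan_contig(seq, contig_id, min_units, motif_sizes))
    return out
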