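"""Synthetic pooled-individual sequencing data with repeat-slippage errors.

Emulates the study design behind in silico microsatellite mining: cDNA
from a panel of diploid individuals is pooled and sequenced, reads are
assembled against per-gene consensus contigs, and repeat loci show a
mixture of genuine allelic length variants and slippage sequencing errors.
Each simulated contig carries one microsatellite; every individual draws
two alleles (repeat-unit counts) from the locus's frequency spectrum;
reads are sampled uniformly from random haplotypes with approximately the
configured mean depth and read length.  Two error processes operate:
per-base substitutions, and whole-unit slippage in which a read's repeat
tract gains or loses one full motif copy — the process that makes rare
length variants ambiguous between sequencing error and genuine rare
alleles.

Alignments are emitted as coordinate-sorted SAM with analytically
constructed CIGAR strings (length differences between a read's tract and
the consensus appear as whole-copy insertions or deletions at the right
edge of the matched copies; insertions that would hang off an alignment
edge are soft-clipped), together with a truth table recording every
read's individual of origin, haplotype and error events.  Identical seeds
give byte-identical FASTA/SAM/truth outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from .popgen_stats import LocusRecord, CATEGORY_IMMUNE, CATEGORY_GROWTH, CATEGORY_INSILICO
from .assembly_profiler import InSilicoProfile

__all__ = [
    "LocusSpec",
    "SimulationConfig",
    "SimRead",
    "SimLocus",
    "SimulationResult",
    "simulate",
    "write_sam",
    "write_fasta",
    "make_locus_record_fixture",
    "PcrModel",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class LocusSpec:
    """Explicit description of one simulated locus."""

    motif: str
    allele_freqs: dict[int, float]  # repeat-unit count -> population frequency
    consensus_units: int | None = None  # defaults to the modal allele


@dataclass
class SimulationConfig:
    """Study-condition defaults: 12 pooled individuals, ~19x depth, 286 bp reads."""

    n_individuals: int = 12
    n_loci: int = 20
    motifs: Sequence[str] = ("AC", "AG", "ATG", "TTG", "AAGG", "ACAG")
    unit_count_range: tuple[int, int] = (6, 12)
    max_extra_alleles: int = 2  # a locus carries 1..(1+this) distinct alleles
    flank_len: int = 150
    mean_depth: float = 19.0
    read_length_mean: int = 286
    read_length_sd: float = 30.0
    min_read_length: int = 60
    substitution_rate: float = 0.005
    slippage_rate: float = 0.01  # per read spanning a tract
    seed: int = 1
    loci: Sequence[LocusSpec] | None = None  # overrides random locus generation

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "slippage_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class SimRead:
    read_id: str
    contig_id: str
    pos: int  # 0-based leftmost reference coordinate
    cigar: list[tuple[int, int]]  # pysam (op, length) tuples
    seq: str
    individual: int
    haplotype: int
    allele_units: int
    slip_delta: int
    n_subs: int


@dataclass
class SimLocus:
    locus_id: str
    contig_id: str
    motif: str  # phase motif as embedded in the contig
    start: int
    end: int
    consensus_units: int
    allele_freqs: dict[int, float]
    genotypes: list[tuple[int, int]]  # per individual, unit counts
    category: str = CATEGORY_GROWTH

    @property
    def realized_alleles(self) -> set[int]:
        return set(a for g in self.genotypes for a in g)


@dataclass
class SimulationResult:
    config: SimulationConfig
    contigs: dict[str, str]
    loci: list[SimLocus]
    reads: list[SimRead]


# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _draw_locus_specs(cfg: SimulationConfig, rng: np.random.Generator) -> list[LocusSpec]:
    specs = []
    lo, hi = cfg.unit_count_range
    for _ in range(cfg.n_loci):
        motif = str(cfg.motifs[rng.integers(0, len(cfg.motifs))])
        consensus = int(rng.integers(lo, hi + 1))
        n_alleles = 1 + int(rng.integers(0, cfg.max_extra_alleles + 1))
        units = [consensus]
        step = 1
        while len(units) < n_alleles:
            cand = consensus + step if step % 2 else consensus - step // 2
            if cand >= 3 and cand not in units:
                units.append(cand)
            step += 1
        freqs = rng.dirichlet(np.ones(len(units)) * 2.0)
        specs.append(
            LocusSpec(
                motif=motif,
                allele_freqs={u: float(f) for u, f in zip(units, freqs)},
                consensus_units=consensus,
            )
        )
    return specs


def _build_cigar(
    rs: int,
    read_len_left: int,
    tract_content_len: int,
    has_right: bool,
    right_len: int,
    ref_tract_start: int,
    ref_tract_len: int,
) -> tuple[int, list[tuple[str, int]]]:
    """Compose (pos, cigar ops) for a read from its three segments.

    ``rs`` is the read's start on the haplotype (= reference coordinate when
    the read starts in the left flank).  Tract content is aligned to the
    reference tract left-anchored when the read enters from the left,
    right-anchored when it enters from the right; surplus read copies
    become an insertion (or a soft clip at an alignment edge) and missing
    copies a deletion (only when the alignment continues past the tract).
    """
    ops: list[tuple[str, int]] = []
    cp = ref_tract_len
    if read_len_left > 0:
        pos = rs
        ops.append(("M", read_len_left))
        if tract_content_len > 0:
            m = min(tract_content_len, cp)
            ops.append(("M", m))
            if tract_content_len > cp:
                if has_right:
                    ops.append(("I", tract_content_len - cp))
                else:
                    ops.append(("S", tract_content_len - cp))
            elif cp > tract_content_len and has_right:
                ops.append(("D", cp - tract_content_len))
    elif tract_content_len > 0:
        if has_right:
            if tract_content_len >= cp:
                pos = ref_tract_start
                if tract_content_len > cp:
                    ops.append(("S", tract_content_len - cp))
                ops.append(("M", cp))
            else:
                pos = ref_tract_start + cp - tract_content_len
                ops.append(("M", tract_content_len))
        else:  # read entirely within the tract
            pos = ref_tract_start
            m = min(tract_content_len, cp)
            ops.append(("M", m))
            if tract_content_len > cp:
                ops.append(("S", tract_content_len - cp))
    else:  # no left-flank and no tract content: caller handles right-flank reads
        raise AssertionError("right-flank-only reads are positioned by the caller")
    if has_right and right_len > 0:
        ops.append(("M", right_len))
    return pos, ops


_OP_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[str, int]] = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return [(_OP_CODE[op], ln) for op, ln in merged]


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate contigs, genotypes and aligned reads under ``config``.

    Raises
    ------
    ValueError
        If a locus's longest allele plus flanking anchors cannot fit within
        the configured read length (no read could ever span it).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    specs = list(cfg.loci) if cfg.loci is not None else _draw_locus_specs(cfg, rng)

    contigs: dict[str, str] = {}
    loci: list[SimLocus] = []
    reads: list[SimRead] = []
    categories = (CATEGORY_IMMUNE, CATEGORY_GROWTH, CATEGORY_INSILICO)
    read_no = 0

    for i, spec in enumerate(specs):
        contig_id = f"contig{i + 1:04d}"
        locus_id = f"sim{i + 1:04d}"
        p = len(spec.motif)
        freqs = dict(spec.allele_freqs)
        if abs(sum(freqs.values()) - 1.0) > 1e-6:
            raise ValueError(f"{locus_id}: allele frequencies must sum to 1")
        units_all = sorted(freqs)
        consensus = (
            spec.consensus_units
            if spec.consensus_units is not None
            else max(freqs, key=lambda u: (freqs[u], -u))
        )
        max_tract = max(units_all) * p
        if max_tract + 2 * 10 > cfg.read_length_mean:
            raise ValueError(
                f"{locus_id}: longest allele tract ({max_tract} bp) plus anchors "
                f"cannot fit in reads of ~{cfg.read_length_mean} bp"
            )

        left = _random_seq(rng, cfg.flank_len)
        right = _random_seq(rng, cfg.flank_len)
        # keep the tract maximal: the flanks must not extend its periodicity
        while left[-1] == spec.motif[-1]:
            left = left[:-1] + _random_seq(rng, 1)
        while right[0] == spec.motif[0]:
            right = _random_seq(rng, 1) + right[1:]
        start = len(left)
        end = start + consensus * p
        contig = left + spec.motif * consensus + right
        contigs[contig_id] = contig

        unit_arr = np.array(units_all)
        prob_arr = np.array([freqs[u] for u in units_all])
        prob_arr = prob_arr / prob_arr.sum()
        draws = rng.choice(unit_arr, size=(cfg.n_individuals, 2), p=prob_arr)
        genotypes = [tuple(int(x) for x in row) for row in draws]
        locus = SimLocus(
            locus_id=locus_id,
            contig_id=contig_id,
            motif=spec.motif,
            start=start,
            end=end,
            consensus_units=consensus,
            allele_freqs=freqs,
            genotypes=genotypes,
            category=categories[i % 3],
        )
        loci.append(locus)

        # haplotype sequences per (individual, haplotype)
        hap_seqs: dict[int, str] = {
            u: left + spec.motif * u + right for u in units_all
        }
        n_reads = max(1, round(cfg.mean_depth * len(contig) / cfg.read_length_mean))
        for _ in range(n_reads):
            ind = int(rng.integers(0, cfg.n_individuals))
            hap = int(rng.integers(0, 2))
            a_units = genotypes[ind][hap]
            hap_seq = hap_seqs[a_units]
            hap_len = len(hap_seq)
            ts, te = start, start + a_units * p
            length = int(
                np.clip(
                    round(rng.normal(cfg.read_length_mean, cfg.read_length_sd)),
                    cfg.min_read_length,
                    hap_len,
                )
            )
            rs = int(rng.integers(0, hap_len - length + 1))
            re_ = rs + length

            spans_fully = rs < ts and re_ > te
            slip = 0
            if spans_fully and cfg.slippage_rate > 0 and rng.random() < cfg.slippage_rate:
                slip = 1 if rng.random() < 0.5 else -1
                if a_units + slip < 1:
                    slip = 1
            eff_units = a_units + slip

            left_part = hap_seq[rs:min(re_, ts)]
            if spans_fully and slip != 0:
                tract_part = spec.motif * eff_units
            else:
                tract_part = hap_seq[max(rs, ts):min(re_, te)]
            right_part = hap_seq[max(rs, te):re_]
            seq = left_part + tract_part + right_part

            if rs >= te:  # entirely within the right flank
                pos = rs - (a_units - consensus) * p
                ops = [("M", len(seq))]
            else:
                pos, ops = _build_cigar(
                    rs=rs,
                    read_len_left=len(left_part),
                    tract_content_len=len(tract_part),
                    has_right=len(right_part) > 0,
                    right_len=len(right_part),
                    ref_tract_start=start,
                    ref_tract_len=consensus * p,
                )
            cigar = _merge_ops(ops)

            n_subs = 0
            if cfg.substitution_rate > 0:
                mask = rng.random(len(seq)) < cfg.substitution_rate
                if mask.any():
                    chars = list(seq)
                    for j in np.flatnonzero(mask):
                        old = chars[j]
                        choices = [b for b in "ACGT" if b != old]
                        chars[j] = choices[int(rng.integers(0, 3))]
                        n_subs += 1
                    seq = "".join(chars)

            read_no += 1
            reads.append(
                SimRead(
                    read_id=f"r{read_no:07d}",
                    contig_id=contig_id,
                    pos=pos,
                    cigar=cigar,
                    seq=seq,
                    individual=ind,
                    haplotype=hap,
                    allele_units=a_units,
                    slip_delta=slip,
                    n_subs=n_subs,
                )
            )

    return SimulationResult(config=cfg, contigs=contigs, loci=loci, reads=reads)


# ---------------------------------------------------------------------------
# output writers


def write_fasta(contigs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(result: SimulationResult, path: str) -> None:
    """Write coordinate-sorted SAM with @SQ lines for every contig."""
    order = {cid: i for i, cid in enumerate(result.contigs)}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": cid, "LN": len(seq)} for cid, seq in result.contigs.items()
        ],
    }
    reads = sorted(result.reads, key=lambda r: (order[r.contig_id], r.pos, r.read_id))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.flag = 0
            a.reference_id = order[r.contig_id]
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigar = r.cigar
            out.write(a)


def as_aligned_segments(result: SimulationResult) -> list[pysam.AlignedSegment]:
    """Simulated reads as in-memory pysam segments (no file round-trip)."""
    order = {cid: i for i, cid in enumerate(result.contigs)}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": cid, "LN": len(seq)} for cid, seq in result.contigs.items()],
        }
    )
    segments = []
    for r in sorted(result.reads, key=lambda r: (order[r.contig_id], r.pos, r.read_id)):
        a = pysam.AlignedSegment(header)
        a.query_name = r.read_id
        a.query_sequence = r.seq
        a.flag = 0
        a.reference_id = order[r.contig_id]
        a.reference_start = r.pos
        a.mapping_quality = 60
        a.cigar = r.cigar
        segments.append(a)
    return segments


def truth_frames(result: SimulationResult):
    """Truth tables as pandas DataFrames (loci, genotypes, reads)."""
    import pandas as pd

    loci = pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "contig_id": l.contig_id,
                "motif": l.motif,
                "start_1based": l.start + 1,
                "end_1based": l.end,
                "consensus_units": l.consensus_units,
                "allele_freqs": ";".join(
                    f"{u}:{f:.6g}" for u, f in sorted(l.allele_freqs.items())
                ),
                "realized_alleles": ";".join(map(str, sorted(l.realized_alleles))),
                "category": l.category,
            }
            for l in result.loci
        ]
    )
    genos = pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "individual": f"ind{i + 1:02d}",
                "allele1_units": g[0],
                "allele2_units": g[1],
            }
            for l in result.loci
            for i, g in enumerate(l.genotypes)
        ]
    )
    reads = pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "contig_id": r.contig_id,
                "pos_1based": r.pos + 1,
                "individual": f"ind{r.individual + 1:02d}",
                "haplotype": r.haplotype,
                "allele_units": r.allele_units,
                "slip_delta": r.slip_delta,
                "n_subs": r.n_subs,
            }
            for r in result.reads
        ]
    )
    return loci, genos, reads


# ---------------------------------------------------------------------------
# wet-lab outcome model


@dataclass(frozen=True)
class PcrModel:
    """Stochastic PCR outcome: amplification and polymorphism detection."""

    amplify_prob: float = 0.76
    polymorphic_given_variable: float = 1.0
    genotyping_panel_size: int = 24


def make_locus_record_fixture(
    result: SimulationResult,
    profiles: Sequence[InSilicoProfile],
    pcr_model: PcrModel = PcrModel(),
    seed: int = 1,
) -> list[LocusRecord]:
    """Join simulation truth and profiles into a validation-dataset table.

    Each locus amplifies with ``amplify_prob``; an amplified locus whose
    population truly carries >= 2 alleles is scored polymorphic with
    ``polymorphic_given_variable``, with the observed allele number drawn
    by genotyping a fresh panel of individuals from the locus's allele
    frequency spectrum.  Loci without a profile are skipped.
    """
    rng = np.random.default_rng(seed)
    records: list[LocusRecord] = []
    for locus in result.loci:
        contig_profiles = [
            p for p in profiles if p.locus_id.startswith(locus.contig_id + ":")
        ]
        if not contig_profiles:
            continue
        prof = max(contig_profiles, key=lambda p: p.depth_spanning)
        amplified = bool(rng.random() < pcr_model.amplify_prob)
        polymorphic: bool | None = None
        n_obs: int | None = None
        if amplified:
            units = sorted(locus.allele_freqs)
            probs = np.array([locus.allele_freqs[u] for u in units])
            probs = probs / probs.sum()
            panel = rng.choice(
                np.array(units), size=(pcr_model.genotyping_panel_size, 2), p=probs
            )
            observed = set(int(x) for x in panel.ravel())
            truly_variable = len(locus.allele_freqs) >= 2
            detect = truly_variable and rng.random() < pcr_model.polymorphic_given_variable
            polymorphic = bool(detect and len(observed) >= 2)
            n_obs = len(observed) if polymorphic else 1
        records.append(
            LocusRecord(
                locus_id=locus.locus_id,
                category=locus.category,
                motif_size=len(locus.motif),
                min_units=prof.min_units_observed,
                n_alleles_insilico=prof.n_alleles_insilico,
                n_off_consensus=prof.n_off_consensus_reads,
                is_variable_insilico=prof.is_variable,
                amplified=amplified,
                polymorphic_pcr=polymorphic,
                n_alleles_observed=n_obs,
            )
        )
    return records
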