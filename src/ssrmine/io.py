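"""Shared readers and writers: FASTA, TSV interchange tables, config.

All TSV outputs are tab-separated UTF-8 with '.' decimals, a leading
comment line recording the tool version and the parameters of the run,
then a header line.  Coordinates in TSVs are 1-based inclusive; BED output
is 0-based half-open.  Files are written atomically (temp file + rename).
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__
from .assembly_profiler import InSilicoProfile
from .candidate_selector import AnnotationRecord, CandidateLocus
from .repeat_scanner import RepeatLocus

__all__ = [
    "read_fasta",
    "atomic_write_text",
    "write_tsv",
    "read_tsv",
    "loci_to_frame",
    "frame_to_loci",
    "profiles_to_frame",
    "frame_to_profiles",
    "read_annotations",
    "candidates_to_frame",
    "records_to_frame",
    "frame_to_records",
]


def read_fasta(path: str) -> dict[str, str]:
    """Read a (multi-)FASTA into {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def atomic_write_text(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _param_comment(params: Mapping[str, object] | None) -> str:
    items = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    return f"# ssrmine v{__version__} {items}".rstrip()


def write_tsv(df: pd.DataFrame, path: str, params: Mapping[str, object] | None = None) -> None:
    body = df.to_csv(sep="\t", index=False, na_rep="NA")
    atomic_write_text(path, _param_comment(params) + "\n" + body)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


# ---------------------------------------------------------------------------
# repeat loci


def loci_to_frame(loci: Sequence[RepeatLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "contig_id": l.contig_id,
                "motif": l.motif,
                "motif_size": l.motif_size,
                "start_1based": l.start + 1,
                "end_1based": l.end,
                "unit_count": l.unit_count_consensus,
            }
            for l in loci
        ],
        columns=[
            "locus_id", "contig_id", "motif", "motif_size",
            "start_1based", "end_1based", "unit_count",
        ],
    )


def frame_to_loci(df: pd.DataFrame) -> list[RepeatLocus]:
    return [
        RepeatLocus(
            locus_id=str(r["locus_id"]),
            contig_id=str(r["contig_id"]),
            motif=str(r["motif"]),
            start=int(r["start_1based"]) - 1,
            end=int(r["end_1based"]),
            unit_count_consensus=int(r["unit_count"]),
        )
        for r in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# profiles


def _hist_to_str(hist: Mapping[int, int]) -> str:
    return ";".join(f"{u}:{c}" for u, c in sorted(hist.items()))


def _str_to_hist(text: str) -> dict[int, int]:
    if not text or pd.isna(text):
        return {}
    out = {}
    for part in str(text).split(";"):
        u, c = part.split(":")
        out[int(u)] = int(c)
    return out


def profiles_to_frame(
    profiles: Sequence[InSilicoProfile],
    meta: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "locus_id": p.locus_id,
            "depth_spanning": p.depth_spanning,
            "n_alleles_insilico": p.n_alleles_insilico,
            "consensus_units": p.consensus_units,
            "n_off_consensus": p.n_off_consensus_reads,
            "min_units": p.min_units_observed,
            "is_variable": int(p.is_variable),
            "n_irregular": p.n_irregular,
            "n_non_spanning": p.n_non_spanning,
            "histogram": _hist_to_str(p.allele_histogram),
        }
        if meta and p.locus_id in meta:
            row.update(meta[p.locus_id])
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> tuple[list[InSilicoProfile], dict[str, dict]]:
    profiles = []
    meta: dict[str, dict] = {}
    for r in df.to_dict("records"):
        hist = _str_to_hist(r.get("histogram", ""))
        profiles.append(
            InSilicoProfile(
                locus_id=str(r["locus_id"]),
                depth_spanning=int(r["depth_spanning"]),
                allele_histogram=hist,
                n_alleles_insilico=int(r["n_alleles_insilico"]),
                consensus_units=None if pd.isna(r["consensus_units"]) else int(r["consensus_units"]),
                n_off_consensus_reads=int(r["n_off_consensus"]),
                min_units_observed=None if pd.isna(r["min_units"]) else int(r["min_units"]),
                is_variable=bool(int(r["is_variable"])),
                n_irregular=int(r.get("n_irregular", 0)),
                n_non_spanning=int(r.get("n_non_spanning", 0)),
                low_coverage=int(r["depth_spanning"]) == 0,
            )
        )
        m = {}
        for key in ("flank_left_bp", "flank_right_bp", "min_region_coverage"):
            if key in r and not pd.isna(r[key]):
                m[key] = int(r[key])
        if m:
            meta[str(r["locus_id"])] = m
    return profiles, meta


# ---------------------------------------------------------------------------
# annotations, candidates, locus records


def read_annotations(path: str) -> dict[str, AnnotationRecord]:
    """Annotation TSV: contig_id, isogroup_id, go_terms, annotated, mapped."""
    df = read_tsv(path)
    out = {}
    for r in df.to_dict("records"):
        cid = str(r["contig_id"])
        out[cid] = AnnotationRecord(
            contig_id=cid,
            isogroup_id=None if pd.isna(r.get("isogroup_id")) else str(r["isogroup_id"]),
            go_terms="" if pd.isna(r.get("go_terms")) else str(r["go_terms"]),
            annotated=bool(int(r.get("annotated", 0))),
            mapped=bool(int(r.get("mapped", 0))),
        )
    return out


def candidates_to_frame(candidates: Sequence[CandidateLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "contig_id": c.contig_id,
                "isogroup_id": c.isogroup_id,
                "n_alleles_insilico": c.profile.n_alleles_insilico,
                "depth_spanning": c.profile.depth_spanning,
                "is_variable": int(c.profile.is_variable),
                "flank_left_bp": c.flank_left_bp,
                "flank_right_bp": c.flank_right_bp,
                "min_coverage_region": c.min_coverage_region,
                "annotated": int(c.annotated),
                "mapped": int(c.mapped),
                "category_tags": ";".join(c.category_tags),
                "filter_failures": ";".join(c.filter_failures),
                "selected": int(c.selected),
            }
            for c in candidates
        ]
    )


def records_to_frame(records) -> pd.DataFrame:
    from .popgen_stats import LocusRecord  # noqa: F401

    def enc(v):
        if v is None:
            return pd.NA
        if isinstance(v, bool):
            return int(v)
        return v

    return pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "category": r.category,
                "motif_size": enc(r.motif_size),
                "min_units": enc(r.min_units),
                "n_alleles_insilico": enc(r.n_alleles_insilico),
                "n_off_consensus": enc(r.n_off_consensus),
                "is_variable_insilico": enc(r.is_variable_insilico),
                "amplified": enc(r.amplified),
                "polymorphic_pcr": enc(r.polymorphic_pcr),
                "n_alleles_observed": enc(r.n_alleles_observed),
                "ho": enc(r.ho),
                "he": enc(r.he),
                "null_freq": enc(r.null_freq),
                "hwe_p": enc(r.hwe_p),
            }
            for r in records
        ]
    )


def frame_to_records(df: pd.DataFrame):
    from .popgen_stats import LocusRecord

    def dec(r, key, cast):
        v = r.get(key)
        if v is None or pd.isna(v):
            return None
        return cast(v)

    return [
        LocusRecord(
            locus_id=str(r["locus_id"]),
            category=str(r["category"]),
            motif_size=dec(r, "motif_size", int),
            min_units=dec(r, "min_units", int),
            n_alleles_insilico=dec(r, "n_alleles_insilico", int),
            n_off_consensus=dec(r, "n_off_consensus", int),
            is_variable_insilico=dec(r, "is_variable_insilico", lambda v: bool(int(v))),
            amplified=bool(dec(r, "amplified", lambda v: bool(int(v))) or False),
            polymorphic_pcr=dec(r, "polymorphic_pcr", lambda v: bool(int(v))),
            n_alleles_observed=dec(r, "n_alleles_observed", int),
            ho=dec(r, "ho", float),
            he=dec(r, "he", float),
            null_freq=dec(r, "null_freq", float),
            hwe_p=dec(r, "hwe_p", float),
        )
        for r in df.to_dict("records")
    ]


def read_genotype_table(path: str):
    """Genotype TSV (individual, locus, allele1, allele2) -> GenotypeTable."""
    from .popgen_stats import GenotypeTable

    return GenotypeTable.from_frame(read_tsv(path))
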