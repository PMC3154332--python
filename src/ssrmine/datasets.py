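"""Packaged reference data from the Antarctic fur seal validation study.

Fifty primer pairs were evaluated: Agt1-Agt13 targeted microsatellites in
immune-related transcripts (13 pairs), Agt14-Agt40 growth-related ones
(27 pairs) and Agt41-Agt50 loci picked for appearing highly variable in
silico (10 pairs).  ``fur_seal_table1`` transcribes the polymorphism
characteristics of the 21 loci that amplified scoreable polymorphic
products (allele number, Ho, He, null-allele frequency, HWE P), and
``fur_seal_table2`` the 2x2 concordance counts between in silico and PCR
polymorphism over the 38 interpretable loci.
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

from .popgen_stats import (
    CATEGORY_GROWTH,
    CATEGORY_IMMUNE,
    CATEGORY_INSILICO,
    ConcordanceTable,
    LocusRecord,
)

__all__ = [
    "ARM_SIZES",
    "locus_category",
    "fur_seal_table1",
    "fur_seal_table1_records",
    "fur_seal_table2",
]

#: number of primer pairs designed per selection arm
ARM_SIZES = {CATEGORY_IMMUNE: 13, CATEGORY_GROWTH: 27, CATEGORY_INSILICO: 10}


def locus_category(locus_id: str) -> str:
    """Selection arm of a locus from its index: Agt1-13 immune, 14-40 growth, 41-50 in silico."""
    m = re.fullmatch(r"Agt(\d+)", locus_id)
    if not m:
        raise ValueError(f"unrecognised locus id {locus_id!r}")
    idx = int(m.group(1))
    if 1 <= idx <= 13:
        return CATEGORY_IMMUNE
    if 14 <= idx <= 40:
        return CATEGORY_GROWTH
    if 41 <= idx <= 50:
        return CATEGORY_INSILICO
    raise ValueError(f"locus index {idx} outside 1-50")


def _read(name: str) -> pd.DataFrame:
    with resources.files("ssrmine.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def fur_seal_table1() -> pd.DataFrame:
    """Polymorphism characteristics of the 21 scoreable polymorphic loci."""
    df = _read("fur_seal_table1.tsv")
    df["category"] = df["locus"].map(locus_category)
    return df


def fur_seal_table1_records() -> list[LocusRecord]:
    """Polymorphism-table rows as LocusRecord objects (all amplified and polymorphic)."""
    return [
        LocusRecord(
            locus_id=row.locus,
            category=row.category,
            amplified=True,
            polymorphic_pcr=True,
            n_alleles_observed=int(row.n_alleles),
            ho=float(row.ho),
            he=float(row.he),
            null_freq=float(row.null_freq),
            hwe_p=None if pd.isna(row.hwe_p) else float(row.hwe_p),
        )
        for row in fur_seal_table1().itertuples(index=False)
    ]


def conversion_rates() -> dict[str, float]:
    """Percent of designed primer pairs per arm yielding scoreable polymorphic loci.

    Numerator: loci present in the packaged polymorphism table; denominator:
    the number of primer pairs designed for that arm (13 immune, 27 growth,
    10 picked for in silico variability).
    """
    from collections import Counter

    counts = Counter(locus_category(l) for l in fur_seal_table1()["locus"])
    return {cat: 100.0 * counts[cat] / n for cat, n in ARM_SIZES.items()}


def fur_seal_table2() -> ConcordanceTable:
    """Concordance counts between in silico and PCR polymorphism (38 loci)."""
    df = _read("fur_seal_table2.tsv")
    cells = {
        (row["insilico"], row["pcr"]): int(row["count"])
        for row in df.to_dict("records")
    }
    return ConcordanceTable(
        insilico_poly_pcr_poly=cells[("polymorphic", "polymorphic")],
        insilico_poly_pcr_mono=cells[("polymorphic", "monomorphic")],
        insilico_mono_pcr_poly=cells[("monomorphic", "polymorphic")],
        insilico_mono_pcr_mono=cells[("monomorphic", "monomorphic")],
    )
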