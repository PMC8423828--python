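"""Derived-allele filtering and trinucleotide mutation-spectrum classification.

Derived-allele observations (pre-polarized against an outgroup reference)
are filtered — biallelic only, not derived in the outgroup panel, outside
repeat and archaic-introgression masks — then counted dosage-aware
(homozygous derived = 2, heterozygous = 1) into the 96 strand-collapsed
trinucleotide context types and 9 reported types: the six base changes with
the ancestral allele collapsed to a pyrimidine, with C>T subdivided into
CpG>TpG (3' G context), the TCC>TTC signature, and the remainder C>T'.

Fraction reporting convention: all nine fractions share one denominator,
the total over the six base types (the three C>T subtypes are not added to
the denominator since they duplicate C>T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .intervals import IntervalSet, merge_intervals

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = {"C", "T"}

BASE6_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CT_SUBTYPES = ("CpG>TpG", "TCC>TTC", "C>T'")
TYPES9 = BASE6_TYPES + CT_SUBTYPES

#: The 96 strand-collapsed context types, as "XAY>XDY" strings.
CONTEXT_TYPES96 = tuple(
    f"{c5}{anc}{c3}>{c5}{der}{c3}"
    for anc in "CT"
    for der in BASES
    if der != anc
    for c5, c3 in product(BASES, repeat=2)
)


class VariantRecord(NamedTuple):
    """One derived-allele observation with its reference-strand context."""

    chrom: str
    pos: int  # 1-based
    ancestral: str
    derived: str
    ctx5: str
    ctx3: str
    dosage: int  # 1 het, 2 hom derived
    individual: str


class AmbiguousBaseError(ValueError):
    """Record carries a base outside {A, C, G, T}."""


def classify_mutation(record: VariantRecord) -> tuple[str, str]:
    """Strand-collapsed (96-type, 9-type) classification of one record.

    If the ancestral allele is a purine the alleles are complemented and the
    flanking context reverse-complemented, so every mutation is read off the
    strand on which the ancestral base is a pyrimidine.  CpG>TpG (post-
    collapse 3' G) takes precedence over TCC>TTC; the contexts cannot in fact
    conflict (TCC has 3' C).
    """
    anc, der, c5, c3 = record.ancestral, record.derived, record.ctx5, record.ctx3
    for b in (anc, der, c5, c3):
        if b not in COMPLEMENT:
            raise AmbiguousBaseError(f"ambiguous base {b!r} at {record.chrom}:{record.pos}")
    if anc == der:
        raise ValueError(f"ancestral == derived at {record.chrom}:{record.pos}")
    if anc not in PYRIMIDINES:
        anc, der = COMPLEMENT[anc], COMPLEMENT[der]
        c5, c3 = COMPLEMENT[c3], COMPLEMENT[c5]
    type96 = f"{c5}{anc}{c3}>{c5}{der}{c3}"
    base = f"{anc}>{der}"
    if base != "C>T":
        return type96, base
    if c3 == "G":
        return type96, "CpG>TpG"
    if c5 == "T" and c3 == "C":
        return type96, "TCC>TTC"
    return type96, "C>T'"


@dataclass
class SpectrumCounts:
    """Dosage-weighted mutation-type counts for one individual."""

    individual: str
    counts96: dict[str, int] = field(default_factory=dict)
    counts9: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts96 = {t: int(self.counts96.get(t, 0)) for t in CONTEXT_TYPES96}
        self.counts9 = {t: int(self.counts9.get(t, 0)) for t in TYPES9}

    @property
    def denominator(self) -> int:
        """Total over the six base types (C>T subtypes excluded: duplicates)."""
        return sum(self.counts9[t] for t in BASE6_TYPES)

    def validate(self) -> None:
        subs = sum(self.counts9[t] for t in CT_SUBTYPES)
        if subs != self.counts9["C>T"]:
            raise ValueError("C>T subtypes do not sum to the C>T count")


def count_spectrum(records: Iterable[VariantRecord], individual: str = "") -> SpectrumCounts:
    """Accumulate dosage-weighted 96- and 9-type counts over records.

    Records with ambiguous bases are skipped and tallied in ``n_skipped``.
    C>T records increment both "C>T" and their subtype.
    """
    out = SpectrumCounts(individual=individual)
    for rec in records:
        try:
            t96, t9 = classify_mutation(rec)
        except AmbiguousBaseError:
            out.n_skipped += 1
            continue
        out.counts96[t96] += rec.dosage
        if t9 in CT_SUBTYPES:
            out.counts9["C>T"] += rec.dosage
        out.counts9[t9] += rec.dosage
    return out


def spectrum_fractions(counts: SpectrumCounts) -> dict[str, float]:
    """The nine reported fractions, all over the six-base-type denominator."""
    denom = counts.denominator
    if denom == 0:
        raise ValueError("zero denominator: no classified mutations")
    return {t: counts.counts9[t] / denom for t in TYPES9}


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_outgroup: int
    n_multiallelic: int
    n_masked: int
    n_kept: int


def filter_variants(
    records: Sequence[VariantRecord],
    outgroup_derived_sites: Iterable[tuple[str, int]] | None = None,
    masks: Sequence[IntervalSet] | IntervalSet | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the derived-allele call filters.

    Drops, in order: records whose derived allele segregates in the outgroup
    panel (site list of (chrom, 1-based pos)); records at multi-allelic
    positions (more than one distinct derived allele observed across the
    dataset); records inside any mask interval (repeats, archaic
    introgression evidence).  Returns the retained records and per-rule drop
    counts.
    """
    outgroup = set(outgroup_derived_sites or ())
    if masks is None:
        mask_set = None
    elif isinstance(masks, IntervalSet):
        mask_set = masks if masks.is_merged() else merge_intervals(masks)
    else:
        mask_set = merge_intervals(*masks) if masks else None

    alleles: dict[tuple[str, int], set[str]] = {}
    for rec in records:
        alleles.setdefault((rec.chrom, rec.pos), set()).add(rec.derived)

    kept: list[VariantRecord] = []
    n_out = n_multi = n_masked = 0
    for rec in records:
        if (rec.chrom, rec.pos) in outgroup:
            n_out += 1
            continue
        if len(alleles[(rec.chrom, rec.pos)]) > 1:
            n_multi += 1
            continue
        if mask_set is not None and mask_set.contains_position(rec.chrom, rec.pos - 1):
            n_masked += 1
            continue
        kept.append(rec)
    report = FilterReport(
        n_input=len(records), n_outgroup=n_out, n_multiallelic=n_multi,
        n_masked=n_masked, n_kept=len(kept),
    )
    return kept, report


# -- tabular I/O ------------------------------------------------------------

VARIANT_COLUMNS = ["chrom", "pos", "ancestral", "derived", "ctx5", "ctx3", "dosage", "individual"]


def records_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame.from_records(list(records), columns=VARIANT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[VariantRecord]:
    return [
        VariantRecord(str(r.chrom), int(r.pos), r.ancestral, r.derived,
                      r.ctx5, r.ctx3, int(r.dosage), str(r.individual))
        for r in df.itertuples(index=False)
    ]


def read_variants_tsv(path) -> list[VariantRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_variants_tsv(records: Iterable[VariantRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_variants_vcf(records: Iterable[VariantRecord], path) -> None:
    """Minimal VCF 4.2 with the ancestral allele in the AA info tag.

    REF is taken as the ancestral allele (records are pre-polarized);
    the genotype encodes dosage (1 -> 0/1, 2 -> 1/1).
    """
    rows = sorted(records, key=lambda r: (r.chrom, r.pos, r.individual))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = sorted({r.individual for r in rows})
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        by_site: dict[tuple[str, int, str, str], dict[str, int]] = {}
        for r in rows:
            by_site.setdefault((r.chrom, r.pos, r.ancestral, r.derived), {})[r.individual] = r.dosage
        for (chrom, pos, anc, der), dosages in sorted(by_site.items()):
            gts = ["0/1" if dosages.get(s) == 1 else "1/1" if dosages.get(s) == 2 else "0/0"
                   for s in samples]
            fh.write(f"{chrom}\t{pos}\t.\t{anc}\t{der}\t.\tPASS\tAA={anc}\tGT\t" + "\t".join(gts) + "\n")


def spectrum_table(counts_by_chrom: Mapping[str, SpectrumCounts], individual: str) -> pd.DataFrame:
    """Per-chromosome 96-type count table (long format) for one individual."""
    rows = []
    for chrom, counts in sorted(counts_by_chrom.items()):
        for t, n in counts.counts96.items():
            rows.append((individual, chrom, t, n))
    return pd.DataFrame(rows, columns=["individual", "chrom", "type96", "count"])
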