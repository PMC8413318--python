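"""On-disk formats for the pipeline.

Phased genotypes travel as VCF v4.x (phase taken from the GT separator:
``|`` phased, ``/`` unphased); repeat-length genotypes and all result
tables travel as UTF-8 TSV with a header row and ``NA`` for missing
values.  Variants are matched by rsID throughout; positions are carried
as metadata only.

Parsers are strict: malformed cells raise :class:`VcfFormatError` /
:class:`RepeatTableError` with the offending location instead of
silently coercing.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "VariantSite",
    "GenotypeEntry",
    "PhasedGenotypeMatrix",
    "AlleleKind",
    "RepeatAllele",
    "EXPANDED",
    "RepeatGenotypeTable",
    "VcfFormatError",
    "MissingSiteError",
    "RepeatTableError",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_repeat_table",
    "write_repeat_table",
    "write_assignment_table",
]

EXPANDED_TOKEN = "EXP"
NA_TOKEN = "NA"


class VcfFormatError(ValueError):
    """Raised for malformed or unusable VCF content."""


class MissingSiteError(VcfFormatError):
    """Raised when required rsIDs are absent from a VCF."""

    def __init__(self, missing: Sequence[str]):
        self.missing = tuple(missing)
        super().__init__(
            "required variant(s) missing from VCF: " + ", ".join(self.missing)
        )


class RepeatTableError(ValueError):
    """Raised for malformed repeat-length tables."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant identified by rsID; position is metadata."""

    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.pos <= 0:
            raise ValueError(f"{self.rsid}: pos must be positive, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")


@dataclass(frozen=True)
class GenotypeEntry:
    """One diploid genotype: ordered allele pair plus phase flag.

    Alleles are strings (``None`` = missing).  Haplotype-resolved use of
    the pair requires ``phased`` to be true.
    """

    allele1: str | None
    allele2: str | None
    phased: bool

    @property
    def is_missing(self) -> bool:
        return self.allele1 is None or self.allele2 is None


@dataclass
class PhasedGenotypeMatrix:
    """Samples x sites genotype matrix restricted to a tag-SNP panel."""

    samples: list[str]
    sites: list[VariantSite]
    # entries[i][j] is the genotype of samples[i] at sites[j]
    entries: list[list[GenotypeEntry]]

    def __post_init__(self) -> None:
        rsids = [s.rsid for s in self.sites]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsIDs in site panel")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        if len(self.entries) != len(self.samples):
            raise ValueError("entries/sample length mismatch")
        for row in self.entries:
            if len(row) != len(self.sites):
                raise ValueError("entries/site length mismatch")
        self._site_index = {s.rsid: j for j, s in enumerate(self.sites)}
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        for i, row in enumerate(self.entries):
            for j, e in enumerate(row):
                site = self.sites[j]
                for a in (e.allele1, e.allele2):
                    if a is not None and a not in (site.ref, site.alt):
                        raise ValueError(
                            f"sample {self.samples[i]}, site {site.rsid}: "
                            f"allele {a!r} not in {{ref={site.ref}, alt={site.alt}}}"
                        )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site(self, rsid: str) -> VariantSite:
        return self.sites[self._site_index[rsid]]

    def entry(self, sample: str, rsid: str) -> GenotypeEntry:
        return self.entries[self._sample_index[sample]][self._site_index[rsid]]

    def haplotype_alleles(
        self, sample: str
    ) -> tuple[dict[str, str | None], dict[str, str | None]]:
        """Per-haplotype rsid->allele maps for one sample.

        Unphased or missing entries contribute ``None`` on both
        haplotypes: haplotype extraction requires phase.
        """
        row = self.entries[self._sample_index[sample]]
        hap1: dict[str, str | None] = {}
        hap2: dict[str, str | None] = {}
        for site, e in zip(self.sites, row):
            if e.phased and not e.is_missing:
                hap1[site.rsid] = e.allele1
                hap2[site.rsid] = e.allele2
            else:
                hap1[site.rsid] = None
                hap2[site.rsid] = None
        return hap1, hap2


class AlleleKind(enum.Enum):
    MEASURED = "MEASURED"
    EXPANDED = "EXPANDED"


@dataclass(frozen=True)
class RepeatAllele:
    """A repeat-length measurement in repeat units.

    ``EXPANDED`` marks an allele beyond the pathological threshold whose
    exact length is unknown (repeat-primed PCR carrier call).
    """

    kind: AlleleKind
    length: int | None = None

    def __post_init__(self) -> None:
        if self.kind is AlleleKind.MEASURED:
            if self.length is None or self.length < 1:
                raise ValueError(f"MEASURED allele needs length >= 1, got {self.length}")
        elif self.length is not None:
            raise ValueError("EXPANDED allele carries no length")

    @property
    def is_expanded(self) -> bool:
        return self.kind is AlleleKind.EXPANDED

    def sort_key(self) -> float:
        return float("inf") if self.is_expanded else float(self.length)  # type: ignore[arg-type]

    def __str__(self) -> str:
        return EXPANDED_TOKEN if self.is_expanded else str(self.length)

    @classmethod
    def measured(cls, length: int) -> "RepeatAllele":
        return cls(AlleleKind.MEASURED, length)


EXPANDED = RepeatAllele(AlleleKind.EXPANDED)


def _infer_band_count(a: RepeatAllele, b: RepeatAllele) -> int:
    # Fragment analysis shows one band for equal-length alleles and for
    # expanded alleles (which do not amplify a sized product).
    if a.is_expanded or b.is_expanded:
        return 1
    return 1 if a.length == b.length else 2


@dataclass
class RepeatGenotypeTable:
    """Per-sample unordered pairs of repeat alleles with band counts."""

    pairs: dict[str, tuple[RepeatAllele, RepeatAllele]]
    band_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, (a, b) in self.pairs.items():
            bc = self.band_counts.get(sample)
            if bc is None:
                self.band_counts[sample] = _infer_band_count(a, b)
            elif bc == 1 and not (a.is_expanded or b.is_expanded or a.length == b.length):
                raise RepeatTableError(
                    f"sample {sample}: band_count=1 but alleles "
                    f"{a}/{b} are distinct measured lengths"
                )

    def __contains__(self, sample: str) -> bool:
        return sample in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def pair(self, sample: str) -> tuple[RepeatAllele, RepeatAllele]:
        return self.pairs[sample]


# --------------------------------------------------------------------------
# VCF I/O


_GT_RE = re.compile(r"^(\.|\d+)([/|](\.|\d+))*$")


def _prescan_genotype_fields(path: str | Path) -> None:
    """Validate GT syntax line by line so errors carry a line number.

    Only applicable to plain-text VCF, which is the supported dialect.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                continue  # site-only line, no genotypes
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise VcfFormatError(f"line {lineno}: FORMAT lacks GT")
            gt_idx = fmt.index("GT")
            for col, cell in enumerate(fields[9:], start=10):
                parts = cell.split(":")
                if gt_idx >= len(parts) or not _GT_RE.match(parts[gt_idx]):
                    bad = parts[gt_idx] if gt_idx < len(parts) else cell
                    raise VcfFormatError(
                        f"line {lineno}, column {col}: malformed GT field {bad!r}"
                    )


def read_phased_vcf(
    path: str | Path, required_rsids: Sequence[str]
) -> PhasedGenotypeMatrix:
    """Read a VCF restricted to ``required_rsids`` (in that order).

    Raises :class:`MissingSiteError` listing any absent rsIDs and
    :class:`VcfFormatError` (with line number) on malformed GT fields.
    Sample order of the VCF is preserved.
    """
    required = list(required_rsids)
    if len(set(required)) != len(required):
        raise ValueError("required_rsids contains duplicates")
    _prescan_genotype_fields(path)
    found: dict[str, tuple[VariantSite, list[GenotypeEntry]]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.id not in required or rec.id in found:
                continue
            alts = rec.alts or ()
            if len(alts) != 1:
                raise VcfFormatError(
                    f"site {rec.id}: expected exactly one ALT allele, got {len(alts)}"
                )
            site = VariantSite(rec.id, str(rec.contig), rec.pos, rec.ref, alts[0])
            col: list[GenotypeEntry] = []
            for s in samples:
                sd = rec.samples[s]
                idx = sd["GT"]
                if idx is None or len(idx) != 2:
                    raise VcfFormatError(
                        f"site {rec.id}, sample {s}: genotype is not diploid"
                    )
                alleles = tuple(
                    None if i is None else rec.alleles[i] for i in idx
                )
                col.append(GenotypeEntry(alleles[0], alleles[1], bool(sd.phased)))
            found[rec.id] = (site, col)
    missing = [r for r in required if r not in found]
    if missing:
        raise MissingSiteError(missing)
    sites = [found[r][0] for r in required]
    entries = [
        [found[r][1][i] for r in required] for i in range(len(samples))
    ]
    return PhasedGenotypeMatrix(samples=samples, sites=sites, entries=entries)


def write_phased_vcf(matrix: PhasedGenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as plain-text VCF v4.x with ``|``-separated phased GT."""
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, site in enumerate(matrix.sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref, site.alt),
                id=site.rsid,
            )
            allele_index = {site.ref: 0, site.alt: 1, None: None}
            for i, sample in enumerate(matrix.samples):
                e = matrix.entries[i][j]
                rec.samples[sample]["GT"] = (
                    allele_index[e.allele1],
                    allele_index[e.allele2],
                )
                rec.samples[sample].phased = e.phased and not e.is_missing
            out.write(rec)


# --------------------------------------------------------------------------
# Repeat-length tables


def _parse_repeat_token(token: str, sample: str, column: str) -> RepeatAllele:
    if token == EXPANDED_TOKEN:
        return EXPANDED
    try:
        length = int(token)
    except ValueError:
        raise RepeatTableError(
            f"sample {sample}, column {column}: {token!r} is neither a "
            f"positive integer nor {EXPANDED_TOKEN!r}"
        ) from None
    if length < 1:
        raise RepeatTableError(
            f"sample {sample}, column {column}: repeat length must be >= 1, got {length}"
        )
    return RepeatAllele.measured(length)


def read_repeat_table(path: str | Path) -> RepeatGenotypeTable:
    """Read a TSV with columns sample_id, allele1, allele2[, band_count]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"sample_id", "allele1", "allele2"}
    if not needed.issubset(df.columns):
        raise RepeatTableError(
            f"repeat table must have columns {sorted(needed)}, got {list(df.columns)}"
        )
    pairs: dict[str, tuple[RepeatAllele, RepeatAllele]] = {}
    band_counts: dict[str, int] = {}
    for row in df.itertuples(index=False):
        sample = str(row.sample_id)
        if sample in pairs:
            raise RepeatTableError(f"duplicate sample {sample}")
        a = _parse_repeat_token(str(row.allele1), sample, "allele1")
        b = _parse_repeat_token(str(row.allele2), sample, "allele2")
        pairs[sample] = (a, b)
        if "band_count" in df.columns and not pd.isna(getattr(row, "band_count")):
            band_counts[sample] = int(getattr(row, "band_count"))
    return RepeatGenotypeTable(pairs=pairs, band_counts=band_counts)


def write_repeat_table(table: RepeatGenotypeTable, path: str | Path) -> None:
    rows = []
    for sample, (a, b) in table.pairs.items():
        rows.append(
            {
                "sample_id": sample,
                "allele1": str(a),
                "allele2": str(b),
                "band_count": table.band_counts[sample],
            }
        )
    pd.DataFrame(rows, columns=["sample_id", "allele1", "allele2", "band_count"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# Assignment tables

ASSIGNMENT_COLUMNS = ["sample", "haplotype", "class", "length", "posterior"]


def write_assignment_table(results: Iterable, path: str | Path) -> None:
    """Serialize phasing results: one row per haplotype.

    ``results`` is an iterable of objects with ``sample`` and a pair of
    assignments carrying ``hap_class``, ``allele`` (``None`` when
    unassigned) and ``posterior``.
    """
    rows = []
    for res in results:
        for k, assignment in enumerate(res.assignments, start=1):
            allele = assignment.allele
            rows.append(
                {
                    "sample": res.sample,
                    "haplotype": k,
                    "class": assignment.hap_class.name,
                    "length": NA_TOKEN if allele is None else str(allele),
                    "posterior": f"{assignment.posterior:.6g}",
                }
            )
    pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_assignment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assignment table missing columns: {missing}")
    return df
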