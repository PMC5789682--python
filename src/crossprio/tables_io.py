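"""Readers, writers and canonical in-memory containers for every external
table the cross-species prioritization pipeline touches.

All tabular inputs are tab-delimited UTF-8 text with a header line; lines
starting with ``#`` are comments.  Variant tables can alternatively be read
from a VCF (v4.x) subset carrying gene-symbol and allele-frequency INFO
annotations.  Gene symbols are canonicalized on ingest: human symbols are
uppercased, mouse symbols are title-cased (``SOX9`` vs ``Sox9``); species
are only ever compared through an explicit :class:`OrthologMap`, never by
case-folding.

Readers never silently drop rows: every input row either becomes a record,
raises a :class:`RowError` naming its index, or is logged as a warning
(duplicate gene-set symbols, empty files).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "RowError",
    "Zygosity",
    "VariantRecord",
    "PatientRecord",
    "ExpressionMatrix",
    "GeneSet",
    "OrthologMap",
    "canonical_symbol",
    "read_variant_table",
    "write_variant_table",
    "read_patient_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_set",
    "write_gene_set",
    "read_ortholog_map",
    "write_ortholog_map",
]


class SchemaError(ValueError):
    """A table is missing a mandatory column or is structurally malformed."""


class RowError(ValueError):
    """A single input row could not be interpreted; the message names the row."""


class Zygosity(str, Enum):
    HET = "het"
    HOM = "hom"
    CMPD_HET = "cmpd_het"


#: raw zygosity tokens accepted on input (case/spacing-insensitive)
_ZYGOSITY_TOKENS = {
    "het": Zygosity.HET,
    "heterozygous": Zygosity.HET,
    "hom": Zygosity.HOM,
    "homozygous": Zygosity.HOM,
    "cmpdhet": Zygosity.CMPD_HET,
    "compoundhet": Zygosity.CMPD_HET,
    "compoundheterozygous": Zygosity.CMPD_HET,
}


def canonical_symbol(symbol: str, species: str) -> str:
    """Canonicalize a gene symbol to the species' case convention.

    Human symbols are fully uppercased; mouse symbols get an initial capital
    with the remainder lowercased (the standard nomenclature difference
    between ``SOX9`` and ``Sox9``).
    """
    s = str(symbol).strip()
    if not s:
        raise ValueError("empty gene symbol")
    if species == "human":
        return s.upper()
    if species == "mouse":
        return s[:1].upper() + s[1:].lower()
    raise ValueError(f"unknown species {species!r} (expected 'human' or 'mouse')")


def _parse_zygosity(token: str) -> Zygosity:
    key = re.sub(r"[^a-z]", "", str(token).lower())
    if key not in _ZYGOSITY_TOKENS:
        raise ValueError(f"unknown zygosity token {token!r}")
    return _ZYGOSITY_TOKENS[key]


@dataclass(frozen=True)
class VariantRecord:
    """One patient-variant observation from an exome cohort.

    ``maf_percent`` is the population minor allele frequency on a 0-100
    percent scale (``0.1`` means 0.1 %).  ``math.nan`` encodes a missing
    frequency; downstream filtering treats missing as 0 (rare until proven
    common).  HGVS strings are preserved verbatim beyond a prefix check.
    ``predictions`` maps predictor name (e.g. ``sift``) to a raw or
    harmonized call; harmonization lives in :mod:`crossprio.variants`.
    """

    patient_id: str
    gene: str
    zygosity: Zygosity
    hgvs_c: str = ""
    hgvs_p: str = ""
    maf_percent: float = math.nan
    predictions: Mapping[str, str] = field(default_factory=dict)
    conservation: float | None = None
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.gene:
            raise ValueError("gene must be non-empty")
        if not math.isnan(self.maf_percent) and not 0.0 <= self.maf_percent <= 100.0:
            raise ValueError(f"maf_percent {self.maf_percent} outside [0, 100]")
        if self.hgvs_c and not self.hgvs_c.startswith("c."):
            raise ValueError(f"hgvs_c {self.hgvs_c!r} lacks the 'c.' prefix")
        if self.hgvs_p and not self.hgvs_p.startswith("p."):
            raise ValueError(f"hgvs_p {self.hgvs_p!r} lacks the 'p.' prefix")
        if self.conservation is not None and self.conservation < 0:
            raise ValueError("conservation score must be non-negative")


@dataclass(frozen=True)
class PatientRecord:
    """One cohort member: 46,XY karyotype, phenotype category 1-4."""

    patient_id: str
    category: int
    karyotype: str = "46,XY"
    dsd_category: str = ""
    clinical_notes: str = ""

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.category not in (1, 2, 3, 4):
            raise ValueError(f"category must be 1-4, got {self.category}")


# ---------------------------------------------------------------------------
# variant tables


_VARIANT_ALIASES = {
    "patient": "patient_id",
    "patientid": "patient_id",
    "case": "patient_id",
    "caseid": "patient_id",
    "dsdcaseid": "patient_id",
    "gene": "gene",
    "genesymbol": "gene",
    "zygosity": "zygosity",
    "hgvsc": "hgvs_c",
    "hgvsp": "hgvs_p",
    "maf": "maf_percent",
    "mafpercent": "maf_percent",
    "mafgnomad": "maf_percent",
    "mafgnomadpercent": "maf_percent",
    "conservation": "conservation",
    "sift": "sift",
    "polyphen": "polyphen",
}

_VARIANT_REQUIRED = ("patient_id", "gene", "zygosity", "hgvs_c", "hgvs_p", "maf_percent")


def _normalize_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False, **kwargs)


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    *,
    species: str = "human",
    vcf_gene_key: str = "GENE",
    vcf_af_key: str = "AF",
    vcf_af_scale: str = "fraction",
) -> list[VariantRecord]:
    """Read a per-patient variant table.

    ``dialect`` is ``"tsv"`` (header-named columns, Table-2-style aliases
    accepted) or ``"vcf_subset"`` (a VCF whose INFO field carries a gene
    symbol under ``vcf_gene_key`` and an allele frequency under
    ``vcf_af_key``; one record is emitted per carrier sample per ALT
    allele).  MAF values are normalized to the percent scale;
    ``vcf_af_scale`` says whether the VCF annotation is a 0-1 ``fraction``
    or already a ``percent``.
    """
    if dialect == "tsv":
        return _read_variant_tsv(path, species=species)
    if dialect == "vcf_subset":
        return _read_variant_vcf(
            path, species=species, gene_key=vcf_gene_key, af_key=vcf_af_key, af_scale=vcf_af_scale
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variant_tsv(path: str | Path, species: str) -> list[VariantRecord]:
    df = _read_tsv(path)
    colmap: dict[str, str] = {}
    for col in df.columns:
        canon = _VARIANT_ALIASES.get(_normalize_header(col))
        if canon is not None and canon not in colmap:
            colmap[canon] = col
    for required in _VARIANT_REQUIRED:
        if required not in colmap:
            raise SchemaError(f"missing mandatory column: {required}")
    predictors = [p for p in ("sift", "polyphen") if p in colmap]
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        maf_raw = str(row[colmap["maf_percent"]]).strip()
        if maf_raw == "":
            maf = math.nan
            logger.warning("%s row %d: missing MAF, treated as unknown (rare)", path, i)
        else:
            try:
                maf = float(maf_raw)
            except ValueError:
                raise RowError(f"row {i}: non-numeric MAF {maf_raw!r}") from None
        try:
            zyg = _parse_zygosity(row[colmap["zygosity"]])
        except ValueError as exc:
            raise RowError(f"row {i}: {exc}") from None
        predictions = {
            p: str(row[colmap[p]]).strip() for p in predictors if str(row[colmap[p]]).strip()
        }
        conservation = None
        if "conservation" in colmap and str(row[colmap["conservation"]]).strip():
            conservation = float(row[colmap["conservation"]])
        try:
            records.append(
                VariantRecord(
                    patient_id=str(row[colmap["patient_id"]]).strip(),
                    gene=canonical_symbol(row[colmap["gene"]], species),
                    zygosity=zyg,
                    hgvs_c=str(row[colmap["hgvs_c"]]).strip(),
                    hgvs_p=str(row[colmap["hgvs_p"]]).strip(),
                    maf_percent=maf,
                    predictions=predictions,
                    conservation=conservation,
                )
            )
        except ValueError as exc:
            raise RowError(f"row {i}: {exc}") from None
    return records


def _read_variant_vcf(
    path: str | Path, species: str, gene_key: str, af_key: str, af_scale: str
) -> list[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise SchemaError("VCF has no sample columns; per-patient genotypes are required")
    records: list[VariantRecord] = []
    for idx, var in enumerate(vcf):
        gene = var.INFO.get(gene_key)
        af = var.INFO.get(af_key)
        if gene is None:
            raise RowError(f"VCF record {idx}: missing INFO/{gene_key} gene symbol")
        if af is None:
            raise RowError(f"VCF record {idx}: missing INFO/{af_key} allele frequency")
        afs = af if isinstance(af, (tuple, list)) else [af] * len(var.ALT)
        # multi-allelic records are split: one logical variant per ALT allele
        for j, alt in enumerate(var.ALT):
            maf = float(afs[j]) * (100.0 if af_scale == "fraction" else 1.0)
            meta = {"chrom": var.CHROM, "pos": str(var.POS), "ref": var.REF, "alt": alt}
            for sample, gt_type in zip(samples, var.gt_types):
                if gt_type == 1:
                    zyg = Zygosity.HET
                elif gt_type == 3:
                    zyg = Zygosity.HOM
                else:
                    continue
                records.append(
                    VariantRecord(
                        patient_id=sample,
                        gene=canonical_symbol(gene, species),
                        zygosity=zyg,
                        maf_percent=maf,
                        meta=meta,
                    )
                )
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as canonical TSV (round-trips through the TSV reader)."""
    records = list(records)
    predictors = sorted({p for r in records for p in r.predictions})
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "gene": r.gene,
            "zygosity": r.zygosity.value,
            "hgvs_c": r.hgvs_c,
            "hgvs_p": r.hgvs_p,
            "maf_percent": r.maf_percent,
        }
        for p in predictors:
            row[p] = r.predictions.get(p, "")
        if r.conservation is not None:
            row["conservation"] = r.conservation
        rows.append(row)
    columns = ["patient_id", "gene", "zygosity", "hgvs_c", "hgvs_p", "maf_percent", *predictors]
    if any("conservation" in row for row in rows):
        columns.append("conservation")
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read the cohort description table (one row per patient)."""
    df = _read_tsv(path)
    cols = {_normalize_header(c): c for c in df.columns}
    if "patientid" not in cols:
        raise SchemaError("missing mandatory column: patient_id")
    if "category" not in cols:
        raise SchemaError("missing mandatory column: category")
    records = []
    for i, row in df.iterrows():
        def get(key: str, default: str = "") -> str:
            if key not in cols:
                return default
            val = row[cols[key]]
            return default if (isinstance(val, float) and math.isnan(val)) else str(val)

        try:
            category = int(str(row[cols["category"]]).strip())
        except ValueError:
            raise RowError(f"row {i}: non-integer category {row[cols['category']]!r}") from None
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row[cols["patientid"]]).strip(),
                    category=category,
                    karyotype=get("karyotype", "46,XY"),
                    dsd_category=get("dsdcategory"),
                    clinical_notes=get("clinicalfeatures") or get("clinicalnotes"),
                )
            )
        except ValueError as exc:
            raise RowError(f"row {i}: {exc}") from None
    return records


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with group labels and a unit.

    ``values`` is a DataFrame indexed by canonical gene symbol with one
    column per sample; ``groups`` maps every sample to its group label.
    ``unit`` is ``"FPKM"`` (non-negative reals) or ``"counts"``
    (non-negative integers).
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    unit: str
    species: str = "mouse"

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "counts"):
            raise ValueError(f"unit must be 'FPKM' or 'counts', got {self.unit!r}")
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            g, s = np.argwhere(np.asarray(self.values.values) < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.unit == "counts":
            if arr.size and not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValueError(
                    f"counts unit requires integer values; offending value "
                    f"{arr[tuple(bad)]} at gene {self.values.index[bad[0]]!r}"
                )
            self.values = self.values.astype(np.int64)
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols after canonicalization: {dupes}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def read_expression_matrix(
    path: str | Path,
    unit: str,
    *,
    groups: Mapping[str, str] | None = None,
    species: str = "mouse",
    duplicate_policy: str = "error",
) -> ExpressionMatrix:
    """Read a genes x samples TSV.

    The first column holds gene symbols.  Group labels come either from the
    ``groups`` mapping or from a ``sample|group`` suffix in the header.
    ``duplicate_policy`` for repeated gene rows is ``"error"`` (default),
    ``"sum"`` or ``"first"``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, float_precision="round_trip")
    if df.isna().to_numpy().any():
        raise SchemaError(f"{path}: ragged rows or missing values in expression matrix")
    parsed_groups: dict[str, str] = {}
    rename: dict[str, str] = {}
    for col in df.columns:
        if "|" in str(col):
            sample, grp = str(col).split("|", 1)
            rename[col] = sample
            parsed_groups[sample] = grp
    df = df.rename(columns=rename)
    if groups is None:
        if len(parsed_groups) != len(df.columns):
            raise SchemaError(
                "group labels required: pass groups= or use 'sample|group' headers"
            )
        groups = parsed_groups
    df.index = [canonical_symbol(g, species) for g in df.index]
    df.index.name = "gene"
    if df.index.duplicated().any():
        if duplicate_policy == "sum":
            df = df.groupby(level=0, sort=False).sum()
        elif duplicate_policy == "first":
            df = df[~df.index.duplicated(keep="first")]
        # "error" falls through to ExpressionMatrix validation
    return ExpressionMatrix(values=df, groups=dict(groups), unit=unit, species=species)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write as canonical TSV with ``sample|group`` column headers."""
    out = matrix.values.copy()
    out.columns = [f"{s}|{matrix.groups[s]}" for s in out.columns]
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets and ortholog maps


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols for one species."""

    name: str
    species: str
    symbols: frozenset[str]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


def read_gene_set(path: str | Path, species: str, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; duplicates are logged, not fatal."""
    symbols: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.append(canonical_symbol(line, species))
    if not symbols:
        logger.warning("%s: empty gene set", path)
    n_dupes = len(symbols) - len(set(symbols))
    if n_dupes:
        logger.warning("%s: %d duplicate symbol(s) removed", path, n_dupes)
    return GeneSet(name=name or Path(path).stem, species=species, symbols=frozenset(symbols))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in sorted(gene_set.symbols)), encoding="utf-8")


class OrthologMap:
    """A partial, possibly one-to-many human-mouse gene-symbol relation.

    Lookups on unmapped symbols return an empty tuple; callers are expected
    to report unmapped genes explicitly rather than drop them.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]], provenance: str = "") -> None:
        seen: set[tuple[str, str]] = set()
        ordered: list[tuple[str, str]] = []
        for human, mouse in pairs:
            pair = (canonical_symbol(human, "human"), canonical_symbol(mouse, "mouse"))
            if pair in seen:
                logger.warning("duplicate ortholog pair %s dropped", pair)
                continue
            seen.add(pair)
            ordered.append(pair)
        self.pairs: tuple[tuple[str, str], ...] = tuple(ordered)
        self.provenance = provenance
        self._h2m: dict[str, tuple[str, ...]] = {}
        self._m2h: dict[str, tuple[str, ...]] = {}
        for human, mouse in self.pairs:
            self._h2m[human] = self._h2m.get(human, ()) + (mouse,)
            self._m2h[mouse] = self._m2h.get(mouse, ()) + (human,)

    def mouse_for(self, human_symbol: str) -> tuple[str, ...]:
        return self._h2m.get(canonical_symbol(human_symbol, "human"), ())

    def human_for(self, mouse_symbol: str) -> tuple[str, ...]:
        return self._m2h.get(canonical_symbol(mouse_symbol, "mouse"), ())

    def is_mapped_human(self, human_symbol: str) -> bool:
        return bool(self.mouse_for(human_symbol))

    def __len__(self) -> int:
        return len(self.pairs)


def read_ortholog_map(path: str | Path, provenance: str | None = None) -> OrthologMap:
    """Read a two-column (human TAB mouse) symbol map."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise RowError(f"row {i}: expected two tab-separated symbols, got {line!r}")
            pairs.append((fields[0], fields[1]))
    if not pairs:
        logger.warning("%s: empty ortholog map", path)
    return OrthologMap(pairs, provenance=provenance or str(path))


def write_ortholog_map(ortholog_map: OrthologMap, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{h}\t{m}\n" for h, m in ortholog_map.pairs), encoding="utf-8"
    )
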