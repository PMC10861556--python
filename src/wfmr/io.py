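"""Tabular and VCF input/output for SNP panels, dosages and phenotypes.

File conventions
----------------
All tabular files are tab-separated UTF-8 with a mandatory header row; lines
starting with ``#`` are ignored on read.  Writers prepend a single schema
comment of the form ``# wfmr <kind> schema v<n>`` so files are
self-describing.  Floating point values round-trip to better than 1e-12.

A *panel* lists birth-weight-associated variants with their effect allele
(oriented to be birth-weight increasing; harmonisation against a reference is
out of scope and input is assumed pre-harmonised), effect-allele frequency,
an effect class describing whether the variant acts through the maternal
genome, the fetal genome, or both, and per-allele weights on birth weight for
each genome.

A *dosage matrix* stores, per individual and variant, the expected count of
the effect allele in [0, 2] (integer for hard genotype calls, fractional for
imputed data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EFFECT_CLASSES",
    "SNPPanel",
    "DosageMatrix",
    "PhenotypeTable",
    "read_panel",
    "write_panel",
    "read_dosages",
    "read_dosages_vcf",
    "write_dosages",
    "read_phenotypes",
    "write_phenotypes",
    "write_table",
]

#: Variant effect classes: maternal-only, fetal-only, shared with
#: directionally concordant effects, shared with opposing effects, and
#: birth-weight associated but unclassified.
EFFECT_CLASSES = ("M_ONLY", "F_ONLY", "SHARED_CONC", "SHARED_OPP", "UNCLASSIFIED")

PANEL_COLUMNS = ("variant_id", "effect_allele", "eaf", "effect_class", "w_maternal", "w_fetal")
_SCHEMA_VERSION = 1
_ALLELES = frozenset("ACGT")


def _schema_comment(kind: str) -> str:
    return f"# wfmr {kind} schema v{_SCHEMA_VERSION}\n"


@dataclass
class SNPPanel:
    """Validated table of panel variants.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``variant_id, effect_allele, eaf, effect_class, w_maternal,
        w_fetal``.  Validated on construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PANEL_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"panel is missing required columns: {missing}")
        if len(t) == 0:
            raise ValidationError("panel contains no variants")
        t = t.loc[:, list(PANEL_COLUMNS)].reset_index(drop=True)
        dup = t["variant_id"][t["variant_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate variant_id: {sorted(dup.unique())}")
        bad_allele = t.loc[~t["effect_allele"].isin(_ALLELES), "variant_id"]
        if len(bad_allele):
            raise ValidationError(f"effect_allele must be one of A/C/G/T; offending variants: {list(bad_allele)}")
        eaf = pd.to_numeric(t["eaf"], errors="coerce")
        if eaf.isna().any() or (eaf <= 0).any() or (eaf >= 1).any():
            bad = t.loc[eaf.isna() | (eaf <= 0) | (eaf >= 1), "variant_id"]
            raise ValidationError(f"eaf must lie strictly in (0, 1); offending variants: {list(bad)}")
        bad_class = t.loc[~t["effect_class"].isin(EFFECT_CLASSES), "variant_id"]
        if len(bad_class):
            raise ValidationError(f"unknown effect_class for variants: {list(bad_class)}")
        for col in ("w_maternal", "w_fetal"):
            t[col] = pd.to_numeric(t[col], errors="raise").astype(float)
        t["eaf"] = eaf.astype(float)
        m_only = t["effect_class"] == "M_ONLY"
        if (t.loc[m_only, "w_fetal"] != 0).any():
            bad = t.loc[m_only & (t["w_fetal"] != 0), "variant_id"]
            raise ValidationError(f"M_ONLY variants must have w_fetal = 0: {list(bad)}")
        f_only = t["effect_class"] == "F_ONLY"
        if (t.loc[f_only, "w_maternal"] != 0).any():
            bad = t.loc[f_only & (t["w_maternal"] != 0), "variant_id"]
            raise ValidationError(f"F_ONLY variants must have w_maternal = 0: {list(bad)}")
        self.table = t

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])

    def class_counts(self) -> dict[str, int]:
        counts = self.table["effect_class"].value_counts()
        return {c: int(counts.get(c, 0)) for c in EFFECT_CLASSES}

    def subset(self, classes: Iterable[str]) -> "SNPPanel":
        """Panel restricted to the given effect classes (may be empty -> error)."""
        classes = list(classes)
        unknown = set(classes) - set(EFFECT_CLASSES)
        if unknown:
            raise ValidationError(f"unknown effect classes: {sorted(unknown)}")
        sub = self.table[self.table["effect_class"].isin(classes)]
        if len(sub) == 0:
            raise ValidationError(f"panel subset for classes {classes} is empty")
        return SNPPanel(sub.copy())

    def restrict(self, variant_ids: Iterable[str]) -> "SNPPanel":
        keep = self.table[self.table["variant_id"].isin(set(variant_ids))]
        return SNPPanel(keep.copy())


@dataclass
class DosageMatrix:
    """Effect-allele dosages, individuals x variants.

    ``matrix`` is indexed by ``individual_id`` with one column per
    ``variant_id``; entries lie in [0, 2] with no missing values (missingness
    is resolved at read time).
    """

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.matrix
        if m.index.duplicated().any():
            dup = m.index[m.index.duplicated()]
            raise ValidationError(f"duplicate individual_id in dosages: {sorted(set(dup))}")
        vals = m.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("dosage matrix contains unresolved missing values")
        if (vals < 0).any() or (vals > 2).any():
            rows = m.index[np.where((vals < 0) | (vals > 2))[0]]
            raise ValidationError(f"dosages outside [0, 2] for individuals: {sorted(set(rows))[:5]}")
        self.matrix = m.astype(float)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_individuals(self) -> int:
        return len(self.matrix)


@dataclass
class PhenotypeTable:
    """Per-individual phenotypes: birth weight, binary endpoints, covariates.

    A thin wrapper over a DataFrame indexed by ``individual_id``.  Binary
    endpoint columns must contain only {0, 1} (NaN allowed for individuals
    without follow-up, e.g. parents in a children-only endpoint).
    """

    table: pd.DataFrame
    endpoints: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.table.index.name != "individual_id":
            if "individual_id" in self.table.columns:
                self.table = self.table.set_index("individual_id")
            else:
                raise FormatError("phenotype table needs an individual_id column or index")
        for ep in self.endpoints:
            if ep not in self.table.columns:
                raise ValidationError(f"declared endpoint column missing: {ep}")
            vals = self.table[ep].dropna()
            if not vals.isin([0, 1]).all():
                raise ValidationError(f"endpoint column {ep!r} must be binary 0/1")

    def with_column(self, name: str, values: pd.Series, endpoint: bool = False) -> "PhenotypeTable":
        t = self.table.copy()
        t[name] = values
        eps = self.endpoints + ((name,) if endpoint and name not in self.endpoints else ())
        return PhenotypeTable(t, eps)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype={"variant_id": str, "individual_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: file has no data rows") from exc


def read_panel(path: str | Path) -> SNPPanel:
    """Read a SNP panel TSV and validate it.

    Raises
    ------
    FormatError
        If a required column is absent.
    ValidationError
        On duplicate variant ids, out-of-range allele frequencies, or
        class/weight inconsistencies.
    """
    df = _read_tsv(path)
    return SNPPanel(df)


def write_panel(panel: SNPPanel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_schema_comment("snp-panel"))
        panel.table.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_dosages(
    path: str | Path,
    panel: SNPPanel,
    on_missing: Literal["drop_variant", "fail"] = "drop_variant",
) -> DosageMatrix:
    """Read a wide dosage TSV (individual_id + one column per variant).

    Panel variants absent from the file are dropped with a logged count
    (``on_missing="drop_variant"``) or raise (``on_missing="fail"``).
    Missing entries within a retained variant are mean-imputed from the
    cohort, with the imputation count logged.
    """
    df = _read_tsv(path)
    if "individual_id" not in df.columns:
        raise FormatError("dosage file must have an individual_id column")
    df = df.set_index("individual_id")
    absent = [v for v in panel.variant_ids if v not in df.columns]
    if absent:
        if on_missing == "fail":
            raise ValidationError(f"panel variants absent from dosage file: {absent}")
        logger.info("dropped %d panel variants absent from dosage file: %s", len(absent), absent)
    keep = [v for v in panel.variant_ids if v in df.columns]
    if not keep:
        raise ValidationError("no panel variants present in dosage file")
    mat = df.loc[:, keep].apply(pd.to_numeric, errors="coerce")
    # distinguish unparseable/missing cells from genuine values before imputing
    n_missing = int(mat.isna().sum().sum())
    if n_missing:
        logger.info("mean-imputed %d missing dosage entries", n_missing)
        mat = mat.fillna(mat.mean(axis=0))
    return DosageMatrix(mat)


def read_dosages_vcf(
    path: str | Path,
    panel: SNPPanel,
    field: Literal["GT", "DS"] = "GT",
    on_missing: Literal["drop_variant", "fail"] = "drop_variant",
) -> DosageMatrix:
    """Read effect-allele dosages from a VCF 4.x file.

    Only biallelic SNVs are used.  Genotypes (``GT``) are converted to 0/1/2
    counts of the panel's effect allele; ``DS`` dosages are taken as ALT
    counts and flipped to ``2 - DS`` when the effect allele is REF.  Variants
    are matched on the VCF ID field.  Missing genotypes are mean-imputed.
    """
    from cyvcf2 import VCF  # deferred: optional heavy import

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = {v: (ea,) for v, ea in zip(panel.variant_ids, panel.table["effect_allele"])}
    columns: dict[str, np.ndarray] = {}
    for rec in vcf:
        vid = rec.ID
        if vid not in wanted or vid in columns:
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue  # biallelic SNVs only
        effect_allele = wanted[vid][0]
        if field == "DS":
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
            alt_count = ds
        else:
            gts = np.asarray(rec.genotypes, dtype=float)[:, :2]
            gts[gts < 0] = np.nan  # missing calls
            alt_count = gts.sum(axis=1)
        if effect_allele == rec.ALT[0]:
            columns[vid] = alt_count
        elif effect_allele == rec.REF:
            columns[vid] = 2.0 - alt_count
        # other alleles: leave variant absent; handled by on_missing below
    vcf.close()
    absent = [v for v in panel.variant_ids if v not in columns]
    if absent:
        if on_missing == "fail":
            raise ValidationError(f"panel variants absent from VCF: {absent}")
        logger.info("dropped %d panel variants absent from VCF: %s", len(absent), absent)
    keep = [v for v in panel.variant_ids if v in columns]
    if not keep:
        raise ValidationError("no panel variants present in VCF")
    mat = pd.DataFrame({v: columns[v] for v in keep}, index=pd.Index(samples, name="individual_id"))
    n_missing = int(mat.isna().sum().sum())
    if n_missing:
        logger.info("mean-imputed %d missing VCF genotypes", n_missing)
        mat = mat.fillna(mat.mean(axis=0))
    return DosageMatrix(mat)


def write_dosages(dosages: DosageMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_schema_comment("dosage-matrix"))
        dosages.matrix.to_csv(fh, sep="\t", index=True, index_label="individual_id", float_format="%.17g")


def read_phenotypes(path: str | Path, endpoints: Iterable[str] = ()) -> PhenotypeTable:
    df = _read_tsv(path)
    return PhenotypeTable(df, tuple(endpoints))


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_schema_comment("phenotypes"))
        pheno.table.to_csv(fh, sep="\t", index=True, index_label="individual_id", float_format="%.17g")


def write_table(df: pd.DataFrame, path: str | Path, kind: str = "table", index: bool = False) -> None:
    """Generic result-table writer with the standard schema comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_schema_comment(kind))
        df.to_csv(fh, sep="\t", index=index, float_format="%.17g")
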