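"""Readers, writers, and typed in-memory containers for every external table.

All tables are TSV with ``.`` as decimal separator.  The protein table follows
a configurable *dialect*; the default matches MaxQuant ``proteinGroups.txt``
conventions (``Reverse`` / ``Potential contaminant`` flags marked ``+``,
``Unique peptides``, per-sample ``Intensity <sample>`` columns).  Readers only
parse and validate; scientific decisions (which zeros become missing values,
normalization) live in :mod:`adipoproteo.preprocess`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinTableDialect",
    "IntensityMatrix",
    "SampleMetadata",
    "SignatureSet",
    "MetaboliteTable",
    "read_protein_table",
    "write_protein_table",
    "read_gmt",
    "write_gmt",
    "read_metadata",
    "write_metadata",
    "read_metabolites",
    "write_metabolites",
    "write_results",
    "read_results",
    "metadata_frame",
]

RECORD_COLUMNS = ["accession", "gene", "n_unique_peptides", "is_reverse", "is_contaminant"]

#: string tokens treated as missing cells on input
NA_TOKENS = ("", "NA", "NaN", "nan")


@dataclass(frozen=True)
class ProteinTableDialect:
    """Column naming of a protein quantification table.

    Defaults follow MaxQuant ``proteinGroups.txt``.  The identification
    software behind the data is configurable because label-free tables from
    other tools use the same shape with different headers.
    """

    accession: str = "Protein IDs"
    gene: str = "Gene names"
    unique_peptides: str = "Unique peptides"
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    intensity_prefix: str = "Intensity "
    flag_true: str = "+"


@dataclass
class IntensityMatrix:
    """Proteins x samples abundance table with protein metadata.

    ``values`` is a float DataFrame indexed by accession with one column per
    sample; ``NaN`` encodes missing.  ``records`` carries per-protein metadata
    aligned row-by-row with ``values``.  Pre-normalization all present values
    must be finite and non-negative; after :func:`~adipoproteo.preprocess.apply_vsn`
    the ``normalized`` flag is set and values may be any real number.
    """

    records: pd.DataFrame
    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if list(self.records.columns) != RECORD_COLUMNS:
            missing = set(RECORD_COLUMNS) - set(self.records.columns)
            raise ValidationError(f"records table lacks columns: {sorted(missing)}")
        if len(self.records) != self.values.shape[0]:
            raise ValidationError(
                f"records ({len(self.records)}) and values ({self.values.shape[0]}) row counts differ"
            )
        acc = self.records["accession"]
        if acc.duplicated().any():
            dups = acc[acc.duplicated()].tolist()[:5]
            raise ValidationError(f"duplicate accessions: {dups}")
        if (acc == "").any():
            raise ValidationError("empty accession")
        if (self.records["n_unique_peptides"] < 0).any():
            raise ValidationError("negative unique-peptide count")
        if not (self.values.index == acc.to_numpy()).all():
            raise ValidationError("values index does not match record accessions")
        vals = self.values.to_numpy()
        present = ~np.isnan(vals)
        if np.isinf(vals[present]).any():
            raise ValidationError("non-finite intensity")
        if not self.normalized and (vals[present] < 0).any():
            raise ValidationError("negative intensity in un-normalized matrix")

    # -- convenience ------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the value is missing."""
        return self.values.isna()

    def gene_symbols(self) -> pd.Series:
        """Gene symbol per protein, falling back to the accession when empty."""
        genes = self.records["gene"].astype(str)
        fallback = genes.isin(("", "nan"))
        out = genes.mask(fallback, self.records["accession"].astype(str))
        out.index = self.values.index
        return out

    def select_records(self, keep: np.ndarray) -> "IntensityMatrix":
        """Row subset by boolean mask, preserving order."""
        return IntensityMatrix(
            records=self.records.loc[keep].reset_index(drop=True),
            values=self.values.loc[np.asarray(keep)],
            normalized=self.normalized,
        )

    def drop_samples(self, samples: Iterable[str]) -> "IntensityMatrix":
        drop = set(samples)
        keep = [s for s in self.samples if s not in drop]
        return IntensityMatrix(self.records.copy(), self.values[keep].copy(), self.normalized)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.records.copy(), self.values.copy(), self.normalized)


GROUP_LEVELS = ("patient", "control")
SEX_LEVELS = ("female", "male")


@dataclass(frozen=True)
class SampleMetadata:
    """Clinical covariates for one sample.

    ``presurgery_weightloss_pct`` is the percent body-weight lost on the
    presurgery very-low-calorie diet; it is 0 for controls, who do not diet.
    """

    sample_id: str
    group: str
    sex: str
    presurgery_weightloss_pct: float
    sleep_apnea: bool
    lipid_med: bool
    bp_med: bool
    age: float
    t2dm: bool | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_LEVELS:
            raise ValidationError(f"unknown group level {self.group!r} for sample {self.sample_id!r}")
        if self.sex not in SEX_LEVELS:
            raise ValidationError(f"unknown sex level {self.sex!r} for sample {self.sample_id!r}")
        if not np.isfinite(self.presurgery_weightloss_pct):
            raise ValidationError(f"non-finite weight loss for sample {self.sample_id!r}")


def metadata_frame(meta: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Tabular view of a metadata list, indexed by sample_id."""
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in metadata")
    df = pd.DataFrame(
        {
            "group": [m.group for m in meta],
            "sex": [m.sex for m in meta],
            "presurgery_weightloss_pct": [m.presurgery_weightloss_pct for m in meta],
            "sleep_apnea": [m.sleep_apnea for m in meta],
            "lipid_med": [m.lipid_med for m in meta],
            "bp_med": [m.bp_med for m in meta],
            "age": [m.age for m in meta],
            "t2dm": [m.t2dm for m in meta],
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return df


@dataclass(frozen=True)
class SignatureSet:
    """Named gene list used as a GSEA target set."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("signature set with empty name")
        if not self.genes:
            raise ValidationError(f"signature set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class MetaboliteTable:
    """Samples x measures table of serum metabolic measures (NaN = missing)."""

    values: pd.DataFrame  # index: sample_id, columns: measure names

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if np.isinf(vals[present]).any():
            raise ValidationError("non-finite metabolite measure")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate sample_id in metabolite table")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def measures(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# protein table


def read_protein_table(
    path: str | Path, dialect: ProteinTableDialect | None = None
) -> IntensityMatrix:
    """Parse a proteinGroups-style TSV into an :class:`IntensityMatrix`.

    Zeros are preserved as zeros — the decision which of them denote missing
    values belongs to :func:`adipoproteo.preprocess.zeros_to_missing`.  Empty
    and ``NA`` cells are read as missing immediately.  Row order is preserved.
    """
    dialect = dialect or ProteinTableDialect()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (dialect.accession, dialect.unique_peptides, dialect.reverse, dialect.contaminant):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    sample_cols = [c for c in df.columns if c.startswith(dialect.intensity_prefix)]
    if not sample_cols:
        raise FormatError(
            f"{path}: no sample columns with prefix {dialect.intensity_prefix!r}"
        )
    samples = [c[len(dialect.intensity_prefix):] for c in sample_cols]

    records = pd.DataFrame(
        {
            "accession": df[dialect.accession].astype(str),
            "gene": df[dialect.gene].astype(str) if dialect.gene in df.columns else "",
            "n_unique_peptides": pd.to_numeric(df[dialect.unique_peptides]).astype(int),
            "is_reverse": df[dialect.reverse].astype(str) == dialect.flag_true,
            "is_contaminant": df[dialect.contaminant].astype(str) == dialect.flag_true,
        }
    )
    raw = df[sample_cols].replace(list(NA_TOKENS), np.nan)
    try:
        vals = raw.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric intensity cell ({exc})") from exc
    present = ~np.isnan(vals)
    if (vals[present] < 0).any():
        raise ValidationError(f"{path}: negative intensity value")
    values = pd.DataFrame(vals, index=pd.Index(records["accession"], name="accession"),
                          columns=samples)
    return IntensityMatrix(records=records, values=values, normalized=False)


def write_protein_table(
    path: str | Path, m: IntensityMatrix, dialect: ProteinTableDialect | None = None
) -> None:
    """Write an un-normalized matrix back to the proteinGroups dialect."""
    dialect = dialect or ProteinTableDialect()
    out = pd.DataFrame(
        {
            dialect.accession: m.records["accession"],
            dialect.gene: m.records["gene"],
            dialect.unique_peptides: m.records["n_unique_peptides"],
            dialect.reverse: np.where(m.records["is_reverse"], dialect.flag_true, ""),
            dialect.contaminant: np.where(m.records["is_contaminant"], dialect.flag_true, ""),
        }
    )
    for s in m.samples:
        out[dialect.intensity_prefix + s] = m.values[s].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[SignatureSet]:
    """Read GMT gene sets: ``name TAB description TAB gene...`` per line.

    Duplicate genes within a line are deduplicated with a logged warning;
    lines with fewer than three fields are a format error.
    """
    sets: list[SignatureSet] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            uniq = frozenset(genes)
            if len(uniq) < len(genes):
                logger.warning(
                    "%s:%d: %d duplicate genes in set %r deduplicated",
                    path, lineno, len(genes) - len(uniq), name,
                )
            sets.append(SignatureSet(name=name, genes=uniq))
    return sets


def write_gmt(path: str | Path, sets: Sequence[SignatureSet]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# sample metadata

_BOOL_TOKENS = {
    "1": True, "0": False, "yes": True, "no": False, "true": True, "false": False,
}


def _parse_bool(token: str, column: str) -> bool:
    try:
        return _BOOL_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValidationError(f"cannot parse boolean {token!r} in column {column!r}") from None


def read_metadata(path: str | Path, casefold_levels: bool = True) -> list[SampleMetadata]:
    """Read the sample metadata TSV into typed records.

    With ``casefold_levels`` (default) the categorical columns ``group`` and
    ``sex`` are lower-cased before validation, so ``PATIENT`` parses to
    ``patient``; unknown levels raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "group", "sex", "presurgery_weightloss_pct",
                "sleep_apnea", "lipid_med", "bp_med", "age"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns: {sorted(missing)}")
    meta = []
    for _, row in df.iterrows():
        group = row["group"].strip()
        sex = row["sex"].strip()
        if casefold_levels:
            group, sex = group.lower(), sex.lower()
        t2dm = None
        if "t2dm" in df.columns and row["t2dm"].strip() != "":
            t2dm = _parse_bool(row["t2dm"], "t2dm")
        meta.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                group=group,
                sex=sex,
                presurgery_weightloss_pct=float(row["presurgery_weightloss_pct"]),
                sleep_apnea=_parse_bool(row["sleep_apnea"], "sleep_apnea"),
                lipid_med=_parse_bool(row["lipid_med"], "lipid_med"),
                bp_med=_parse_bool(row["bp_med"], "bp_med"),
                age=float(row["age"]),
                t2dm=t2dm,
            )
        )
    metadata_frame(meta)  # validates sample_id uniqueness
    return meta


def write_metadata(path: str | Path, meta: Sequence[SampleMetadata]) -> None:
    df = metadata_frame(meta).reset_index()
    df["sleep_apnea"] = df["sleep_apnea"].astype(int)
    df["lipid_med"] = df["lipid_med"].astype(int)
    df["bp_med"] = df["bp_med"].astype(int)
    df["t2dm"] = df["t2dm"].map(lambda v: "" if v is None else str(int(v)))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# metabolite table


def read_metabolites(path: str | Path) -> MetaboliteTable:
    """Read the serum metabolite TSV (``sample_id`` + one column per measure)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    df = df.replace(list(NA_TOKENS), np.nan)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric metabolite cell ({exc})") from exc
    return MetaboliteTable(values=df)


def write_metabolites(path: str | Path, tbl: MetaboliteTable) -> None:
    tbl.values.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# generic results tables


def write_results(path: str | Path, table: pd.DataFrame) -> None:
    """Write a results table as TSV at full float precision (round-trip safe)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
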