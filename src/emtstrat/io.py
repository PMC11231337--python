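"""Readers, writers and validated containers for expression, clinical and gene-set data.

Expression matrices are genes x samples on the log2 scale (log2(x + 1) of a
normalized abundance).  Gene sets travel in the GMT dialect: one set per line,
tab-separated ``name<TAB>description<TAB>gene...``.  An EMT signature is a pair
of GMT entries ``<name>_EPI`` / ``<name>_MES`` holding the epithelial and
mesenchymal arms.

The package bundles placeholder signatures whose arm sizes mirror the published
tumor-tissue (145 epithelial + 170 mesenchymal) and cell-line (170 + 48) EMT
signatures; the gene lists themselves are synthetic stand-ins (see the file
names), since only their sizes, not their symbols, are needed by the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "ExpressionMatrix",
    "EMTSignature",
    "ImmuneSignature",
    "read_expression",
    "write_expression",
    "load_gmt",
    "write_gmt",
    "load_emt_signature",
    "resolve_genes",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "tumor_tissue_signature",
    "cell_line_signature",
    "immune_signatures",
    "RESPONSE_LEVELS",
]

RESPONSE_LEVELS = ("CR", "PR", "SD", "PD", "NA")


class ValidationError(ValueError):
    """Input data violates a schema or invariant."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Validated log2-scale gene-by-sample expression matrix.

    Wraps a :class:`pandas.DataFrame` whose index holds gene symbols and whose
    columns hold sample identifiers.  Construction enforces uniqueness of both
    identifier sets, finiteness of every value, and a minimum 2 x 2 shape.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValidationError(f"need at least 2 genes and 2 samples, got {df.shape}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_values(self, sample_id: str) -> pd.Series:
        if sample_id not in self.data.columns:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.data[sample_id]


@dataclass(frozen=True)
class ImmuneSignature:
    """A named flat gene set (CTL, Treg, M1, M2 or user-defined)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")


@dataclass(frozen=True)
class EMTSignature:
    """Disjoint epithelial and mesenchymal gene lists under one name."""

    name: str
    epithelial: tuple[str, ...]
    mesenchymal: tuple[str, ...]

    def __post_init__(self) -> None:
        for arm_name, arm in (("epithelial", self.epithelial), ("mesenchymal", self.mesenchymal)):
            if not arm:
                raise ValidationError(f"{self.name}: {arm_name} arm is empty")
            if len(set(arm)) != len(arm):
                raise ValidationError(f"{self.name}: duplicate genes in {arm_name} arm")
        shared = set(self.epithelial) & set(self.mesenchymal)
        if shared:
            raise ValidationError(f"{self.name}: arms overlap on {sorted(shared)[:5]}")

    @property
    def size(self) -> int:
        return len(self.epithelial) + len(self.mesenchymal)


def read_expression(path: str | Path, delimiter: str = "\t", linear: bool = False) -> ExpressionMatrix:
    """Read a genes-as-rows expression table (first column gene ids, header samples).

    ``linear=True`` applies log2(x + 1) to the body, for inputs on the linear
    scale; the default assumes the file is already log2 transformed.
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0)
    body = raw.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & raw.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"malformed numeric cell {raw.iloc[gi, si]!r} at gene {raw.index[gi]!r},"
            f" sample {raw.columns[si]!r}"
        )
    if linear:
        if (body.to_numpy() < 0).any():
            raise ValidationError("linear-scale input must be non-negative")
        body = np.log2(body + 1.0)
    body.index = body.index.astype(str)
    body.columns = body.columns.astype(str)
    body.index.name = "gene"
    return ExpressionMatrix(body)


def write_expression(matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep=delimiter)


def load_gmt(path: str | Path) -> dict[str, ImmuneSignature]:
    """Parse a GMT file into an ordered mapping of name -> gene set.

    Duplicate genes within a line are dropped (first occurrence kept) with a
    warning; trailing empty fields are ignored; a line with fewer than three
    fields is a format error.
    """
    sigs: dict[str, ImmuneSignature] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, description = parts[0], parts[1]
            genes: list[str] = []
            seen: set[str] = set()
            dup = False
            for g in parts[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    dup = True
                    continue
                seen.add(g)
                genes.append(g)
            if dup:
                warnings.warn(f"{path}:{lineno}: duplicate genes in set {name!r} dropped")
            if name in sigs:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sigs[name] = ImmuneSignature(name=name, genes=tuple(genes), description=description)
    return sigs


def write_gmt(signatures: Mapping[str, ImmuneSignature] | Iterable[ImmuneSignature],
              path: str | Path) -> None:
    if isinstance(signatures, Mapping):
        signatures = signatures.values()
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.description or "na", *sig.genes]) + "\n")


def load_emt_signature(path: str | Path, name: str) -> EMTSignature:
    """Assemble an EMT signature from paired GMT entries ``<name>_EPI`` / ``<name>_MES``.

    Genes appearing in both arms are removed from both, with a warning, so the
    arms are always disjoint.
    """
    sigs = load_gmt(path)
    missing = [k for k in (f"{name}_EPI", f"{name}_MES") if k not in sigs]
    if missing:
        raise ValidationError(f"{path}: missing GMT entries {missing} for signature {name!r}")
    epi = list(sigs[f"{name}_EPI"].genes)
    mes = list(sigs[f"{name}_MES"].genes)
    shared = set(epi) & set(mes)
    if shared:
        warnings.warn(
            f"signature {name!r}: {len(shared)} gene(s) in both arms removed: {sorted(shared)[:5]}"
        )
        epi = [g for g in epi if g not in shared]
        mes = [g for g in mes if g not in shared]
    return EMTSignature(name=name, epithelial=tuple(epi), mesenchymal=tuple(mes))


def resolve_genes(sig_genes: Sequence[str], matrix: ExpressionMatrix) -> tuple[list[str], list[str]]:
    """Split signature genes into (present, missing) against the matrix rows.

    Matching is case-sensitive exact symbol match; order is preserved.
    """
    rows = set(matrix.gene_ids)
    present = [g for g in sig_genes if g in rows]
    missing = [g for g in sig_genes if g not in rows]
    return present, missing


# --- cohort metadata -------------------------------------------------------

_HSCORE_RANGE = (0, 300)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical metadata table and return a normalized copy.

    Required column: ``sample_id`` (unique).  Optional columns follow the
    cohort schema: ``pdl1_expr``, ``pdl1_tps`` (0-100), ``response`` in
    {CR, PR, SD, PD, NA}, ``pfs_time``/``os_time`` (non-negative),
    ``pfs_event``/``os_event`` (0/1) and integer ``hscore_*`` columns in
    [0, 300].
    """
    if "sample_id" not in df.columns:
        raise ValidationError("cohort table must have a 'sample_id' column")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    if "response" in df.columns:
        df["response"] = df["response"].fillna("NA").astype(str)
        bad = sorted(set(df["response"]) - set(RESPONSE_LEVELS))
        if bad:
            raise ValidationError(f"unknown response labels: {bad}")
    for col in ("pfs_time", "os_time"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValidationError(f"{col} contains negative times")
    for col in ("pfs_event", "os_event"):
        if col in df.columns:
            vals = set(df[col].dropna().unique())
            if not vals <= {0, 1}:
                raise ValidationError(f"{col} must be 0/1, got {sorted(vals)[:5]}")
    if "pdl1_tps" in df.columns:
        tps = df["pdl1_tps"].dropna()
        if ((tps < 0) | (tps > 100)).any():
            raise ValidationError("pdl1_tps outside [0, 100]")
    lo, hi = _HSCORE_RANGE
    for col in df.columns:
        if col.startswith("hscore_"):
            hs = df[col].dropna()
            if ((hs < lo) | (hs > hi)).any():
                raise ValidationError(f"{col} outside [{lo}, {hi}]")
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df).to_csv(path, index=False)


# --- bundled gene sets -----------------------------------------------------

def _data_path(filename: str):
    return resources.files("emtstrat") / "data" / filename


def tumor_tissue_signature() -> EMTSignature:
    """Bundled tumor-tissue EMT signature: 145 epithelial + 170 mesenchymal genes.

    Synthetic placeholder gene lists sized to the published tumor-tissue
    signature; suitable for pipeline wiring and size-dependent checks.
    """
    with resources.as_file(_data_path("emt_signatures.synthetic.gmt")) as p:
        return load_emt_signature(p, "tumor_tissue")


def cell_line_signature() -> EMTSignature:
    """Bundled cell-line EMT signature: 170 epithelial + 48 mesenchymal genes."""
    with resources.as_file(_data_path("emt_signatures.synthetic.gmt")) as p:
        return load_emt_signature(p, "cell_line")


def immune_signatures() -> dict[str, ImmuneSignature]:
    """Bundled CTL / Treg / M1 / M2 signatures (20 genes each, placeholders)."""
    with resources.as_file(_data_path("immune_signatures.synthetic.gmt")) as p:
        return load_gmt(p)
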