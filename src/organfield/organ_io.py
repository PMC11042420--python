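"""Readers, writers and the in-memory data model for whole-organ tables.

The variant table is a MAF-like TSV in two dialects: ``long`` (one row per
(mutation, field) observation) and ``wide`` (one VAF column per field).
Field annotations are a TSV of grid coordinates and histology codes; the
96-motif signature matrix is a CSV with motif labels such as ``A[C>A]A``.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConflictError, SchemaError, ValidationError

# ---------------------------------------------------------------------------
# enums and canonical orders
# ---------------------------------------------------------------------------

HISTOLOGY_CODES = ("NU", "LGIN", "HGIN", "UC")

#: merged grouping used throughout downstream comparisons
HISTOLOGY_TO_GROUP = {"NU": "NU_LGIN", "LGIN": "NU_LGIN", "HGIN": "HGIN", "UC": "UC"}
GROUPS = ("NU_LGIN", "HGIN", "UC")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def canonical_motifs() -> list[str]:
    """96 motif labels: substitution class major, then 5' base, then 3' base."""
    out = []
    for sub in SUBSTITUTION_CLASSES:
        for five in _BASES:
            for three in _BASES:
                out.append(f"{five}[{sub}]{three}")
    return out


CANONICAL_MOTIFS = tuple(canonical_motifs())
MOTIF_INDEX = {m: i for i, m in enumerate(CANONICAL_MOTIFS)}


class VariantType(str, enum.Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


class CodingEffect(str, enum.Enum):
    SILENT = "silent"
    NON_SILENT = "non_silent"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldInfo:
    """One 1x2 cm mucosal well of the mapping grid."""

    field_id: str
    row: int
    col: int
    histology: str

    def __post_init__(self) -> None:
        if self.histology not in HISTOLOGY_CODES:
            raise ValidationError(
                f"unknown histology code {self.histology!r} for field "
                f"{self.field_id!r}; expected one of {HISTOLOGY_CODES}"
            )
        if self.row < 0 or self.col < 0:
            raise ValidationError(
                f"grid indices must be non-negative for field {self.field_id!r}"
            )

    @property
    def group(self) -> str:
        return HISTOLOGY_TO_GROUP[self.histology]


@dataclass
class OrganMap:
    """Ordered collection of mapped mucosal fields."""

    fields: list[FieldInfo]

    def __post_init__(self) -> None:
        ids = [f.field_id for f in self.fields]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate field_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.fields)

    @property
    def field_ids(self) -> list[str]:
        return [f.field_id for f in self.fields]

    @property
    def groups(self) -> list[str]:
        return [f.group for f in self.fields]

    def fields_in_group(self, group: str) -> list[str]:
        return [f.field_id for f in self.fields if f.group == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "field_id": self.field_ids,
                "row": [f.row for f in self.fields],
                "col": [f.col for f in self.fields],
                "histology": [f.histology for f in self.fields],
                "group": self.groups,
            }
        )


@dataclass(frozen=True)
class MutationRecord:
    """One genomic variant with its annotations (field-independent part)."""

    mutation_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str = VariantType.SNV.value
    coding_effect: str = CodingEffect.NON_SILENT.value
    context: str | None = None
    is_cosmic_driver: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.mutation_id}: pos must be >= 1")
        if self.variant_type not in (v.value for v in VariantType):
            raise ValidationError(
                f"{self.mutation_id}: unknown variant_type {self.variant_type!r}"
            )
        if self.coding_effect not in (c.value for c in CodingEffect):
            raise ValidationError(
                f"{self.mutation_id}: unknown coding_effect {self.coding_effect!r}"
            )
        if self.variant_type == VariantType.SNV.value:
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValidationError(
                    f"{self.mutation_id}: SNV ref/alt must be single bases"
                )
            if self.ref == self.alt:
                raise ValidationError(f"{self.mutation_id}: SNV ref equals alt")
            if self.ref not in _BASES or self.alt not in _BASES:
                raise ValidationError(
                    f"{self.mutation_id}: SNV ref/alt must be A/C/G/T"
                )
            if self.context is not None:
                ctx = self.context
                if len(ctx) != 3 or any(b not in _BASES for b in ctx):
                    raise ValidationError(
                        f"{self.mutation_id}: context must be a 3-mer over ACGT"
                    )
                if ctx[1] != self.ref:
                    raise ValidationError(
                        f"{self.mutation_id}: context middle base {ctx[1]!r} "
                        f"does not match ref {self.ref!r}"
                    )

    @property
    def is_snv(self) -> bool:
        return self.variant_type == VariantType.SNV.value


@dataclass
class VafMatrix:
    """Mutations x fields VAF matrix with an explicit observed mask.

    ``values`` holds 0.0 where the mask is False; classification treats
    masked-missing and observed-zero entries identically (absent).
    """

    values: np.ndarray
    mask: np.ndarray  # True where the entry was observed
    mutation_ids: list[str]
    field_ids: list[str]
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.mutation_ids), len(self.field_ids)):
            raise ValidationError(
                f"VAF matrix shape {self.values.shape} does not match "
                f"{len(self.mutation_ids)} mutations x {len(self.field_ids)} fields"
            )
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask shape does not match values")
        if len(set(self.mutation_ids)) != len(self.mutation_ids):
            raise ValidationError("duplicate mutation_ids in VafMatrix")
        if len(set(self.field_ids)) != len(self.field_ids):
            raise ValidationError("duplicate field_ids in VafMatrix")
        bad = (self.values < 0) | (self.values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"VAF out of [0, 1] for mutation {self.mutation_ids[i]!r} "
                f"in field {self.field_ids[j]!r}: {self.values[i, j]}"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
            if self.depth.shape != self.values.shape:
                raise ValidationError("depth shape does not match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, mutation_id: str) -> np.ndarray:
        return self.values[self.mutation_ids.index(mutation_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.mutation_ids, columns=self.field_ids
        )


# ---------------------------------------------------------------------------
# mutation table IO
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "mutation_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_type",
    "coding_effect",
    "context",
]
_LONG_COLUMNS = _META_COLUMNS + ["field_id", "vaf", "depth"]
_MANDATORY_LONG = [
    "mutation_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "field_id",
    "vaf",
]


def _record_from_row(row: Mapping, driver_genes: set[str]) -> MutationRecord:
    ctx = row.get("context")
    if ctx is not None and (pd.isna(ctx) or ctx == ""):
        ctx = None
    return MutationRecord(
        mutation_id=str(row["mutation_id"]),
        gene=str(row["gene"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        variant_type=str(row.get("variant_type", "SNV")),
        coding_effect=str(row.get("coding_effect", "non_silent")),
        context=None if ctx is None else str(ctx),
        is_cosmic_driver=str(row["gene"]) in driver_genes,
    )


def read_mutation_table(
    path,
    dialect: str = "long",
    driver_genes: Iterable[str] = (),
    field_ids: Sequence[str] | None = None,
) -> tuple[list[MutationRecord], VafMatrix]:
    """Parse a MAF-like variant table in the long or wide dialect.

    Parameters
    ----------
    path:
        TSV file path.
    dialect:
        ``"long"``: one row per (mutation, field); missing pairs are simply
        absent rows. ``"wide"``: metadata columns followed by one VAF column
        per field (empty cell = missing).
    driver_genes:
        Optional gene symbols used to set ``is_cosmic_driver``.
    field_ids:
        Optional explicit field ordering for the output matrix (long dialect);
        defaults to order of first appearance.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    driver_set = set(driver_genes)
    if dialect == "long":
        return _parse_long(df, driver_set, field_ids)
    return _parse_wide(df, driver_set)


def _validate_vaf(raw: str, where: str) -> float:
    try:
        v = float(raw)
    except ValueError as exc:
        raise ValidationError(f"malformed VAF {raw!r} at {where}") from exc
    if not (0.0 <= v <= 1.0):
        raise ValidationError(f"VAF {v} outside [0, 1] at {where}")
    return v


def _check_columns(df: pd.DataFrame, mandatory: Sequence[str], known: Sequence[str]) -> None:
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"unknown column(s): {unknown}")


def _collect_records(df: pd.DataFrame, driver_set: set[str]) -> list[MutationRecord]:
    """One record per mutation_id; conflicting duplicate annotations rejected."""
    records: dict[str, MutationRecord] = {}
    for idx, row in df.iterrows():
        rec = _record_from_row(row, driver_set)
        prev = records.get(rec.mutation_id)
        if prev is None:
            records[rec.mutation_id] = rec
        elif prev != rec:
            raise ConflictError(
                f"mutation_id {rec.mutation_id!r} has conflicting annotations "
                f"(row {idx + 2})"
            )
    return list(records.values())


def _parse_long(
    df: pd.DataFrame, driver_set: set[str], field_ids: Sequence[str] | None
) -> tuple[list[MutationRecord], VafMatrix]:
    _check_columns(df, _MANDATORY_LONG, _LONG_COLUMNS)
    records = _collect_records(df, driver_set)
    mut_ids = [r.mutation_id for r in records]
    mut_index = {m: i for i, m in enumerate(mut_ids)}
    if field_ids is None:
        fids: list[str] = []
        for f in df["field_id"]:
            if f not in fids:
                fids.append(f)
    else:
        fids = list(field_ids)
        extra = set(df["field_id"]) - set(fids)
        if extra:
            raise ValidationError(f"field_id(s) not in the declared set: {sorted(extra)}")
    fid_index = {f: j for j, f in enumerate(fids)}

    values = np.zeros((len(mut_ids), len(fids)))
    mask = np.zeros_like(values, dtype=bool)
    have_depth = "depth" in df.columns
    depth = np.zeros_like(values) if have_depth else None
    for idx, row in df.iterrows():
        where = f"row {idx + 2}"  # 1-based, counting the header line
        i = mut_index[row["mutation_id"]]
        j = fid_index[row["field_id"]]
        if mask[i, j]:
            raise ConflictError(
                f"duplicate (mutation, field) pair "
                f"({row['mutation_id']!r}, {row['field_id']!r}) at {where}"
            )
        values[i, j] = _validate_vaf(row["vaf"], where)
        mask[i, j] = True
        if have_depth:
            depth[i, j] = float(row["depth"]) if row["depth"] != "" else 0.0
    vafs = VafMatrix(values, mask, mut_ids, fids, depth=depth)
    return records, vafs


def _parse_wide(
    df: pd.DataFrame, driver_set: set[str]
) -> tuple[list[MutationRecord], VafMatrix]:
    meta_present = [c for c in _META_COLUMNS if c in df.columns]
    missing = [c for c in _MANDATORY_LONG if c not in df.columns and c not in ("field_id", "vaf")]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    fids = [c for c in df.columns if c not in _META_COLUMNS]
    if not fids:
        raise SchemaError("wide dialect requires at least one field column")
    if df["mutation_id"].duplicated().any():
        dup = df.loc[df["mutation_id"].duplicated(), "mutation_id"].iloc[0]
        raise ConflictError(f"duplicate mutation_id {dup!r} in wide table")
    records = _collect_records(df[meta_present], driver_set)
    mut_ids = [r.mutation_id for r in records]
    values = np.zeros((len(mut_ids), len(fids)))
    mask = np.zeros_like(values, dtype=bool)
    for i, (idx, row) in enumerate(df.iterrows()):
        for j, f in enumerate(fids):
            raw = row[f]
            if raw == "":
                continue
            values[i, j] = _validate_vaf(raw, f"row {idx + 2}, column {f!r}")
            mask[i, j] = True
    return records, VafMatrix(values, mask, mut_ids, fids)


def write_mutation_table(
    records: Sequence[MutationRecord],
    vafs: VafMatrix,
    path,
    dialect: str = "long",
) -> None:
    """Inverse of :func:`read_mutation_table` (round-trips on valid data)."""
    rec_by_id = {r.mutation_id: r for r in records}
    rows = []
    if dialect == "long":
        for i, m in enumerate(vafs.mutation_ids):
            r = rec_by_id[m]
            for j, f in enumerate(vafs.field_ids):
                if not vafs.mask[i, j]:
                    continue
                row = {
                    "mutation_id": r.mutation_id,
                    "gene": r.gene,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "ref": r.ref,
                    "alt": r.alt,
                    "variant_type": r.variant_type,
                    "coding_effect": r.coding_effect,
                    "context": r.context or "",
                    "field_id": f,
                    "vaf": repr(float(vafs.values[i, j])),
                }
                if vafs.depth is not None:
                    row["depth"] = repr(float(vafs.depth[i, j]))
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif dialect == "wide":
        for i, m in enumerate(vafs.mutation_ids):
            r = rec_by_id[m]
            row = {
                "mutation_id": r.mutation_id,
                "gene": r.gene,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "variant_type": r.variant_type,
                "coding_effect": r.coding_effect,
                "context": r.context or "",
            }
            for j, f in enumerate(vafs.field_ids):
                row[f] = repr(float(vafs.values[i, j])) if vafs.mask[i, j] else ""
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# field annotations
# ---------------------------------------------------------------------------


def read_field_annotations(path) -> OrganMap:
    """TSV with columns field_id, row, col, histology -> :class:`OrganMap`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_columns(df, ["field_id", "row", "col", "histology"],
                   ["field_id", "row", "col", "histology"])
    if df["field_id"].duplicated().any():
        dup = df.loc[df["field_id"].duplicated(), "field_id"].iloc[0]
        raise ValidationError(f"duplicate field_id {dup!r}")
    fields = [
        FieldInfo(
            field_id=str(r["field_id"]),
            row=int(r["row"]),
            col=int(r["col"]),
            histology=str(r["histology"]),
        )
        for _, r in df.iterrows()
    ]
    return OrganMap(fields)


def write_field_annotations(organ_map: OrganMap, path) -> None:
    organ_map.to_frame().drop(columns=["group"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signature matrix IO
# ---------------------------------------------------------------------------


def read_signature_matrix(path):
    """CSV of 96 motif rows x K signature columns -> ``SignatureMatrix``.

    The first column must hold motif labels in the ``A[C>A]A`` style; rows
    may appear in any order and are normalized to the canonical order.
    Columns must sum to 1 within 1e-6 (then renormalized exactly).
    """
    from .signatures import SignatureMatrix  # local import avoids a cycle

    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != 96:
        raise SchemaError(f"signature matrix must have 96 motif rows, got {df.shape[0]}")
    if df.shape[1] < 1:
        raise SchemaError("signature matrix must have at least one signature column")
    unknown = [m for m in df.index if m not in MOTIF_INDEX]
    if unknown:
        raise SchemaError(f"unknown motif label(s): {unknown[:5]}")
    if df.index.duplicated().any():
        raise SchemaError("duplicate motif labels")
    df = df.loc[list(CANONICAL_MOTIFS)]
    W = df.to_numpy(dtype=float)
    if (W < 0).any():
        raise ValidationError("signature matrix has negative entries")
    sums = W.sum(axis=0)
    off = np.abs(sums - 1.0)
    if (off > 1e-6).any():
        k = int(np.argmax(off))
        raise ValidationError(
            f"signature column {df.columns[k]!r} sums to {sums[k]:.8f}, not 1"
        )
    W = W / sums
    return SignatureMatrix(W=W, labels=list(df.columns))


def write_signature_matrix(sig, path) -> None:
    pd.DataFrame(sig.W, index=list(CANONICAL_MOTIFS), columns=sig.labels).to_csv(path)


# ---------------------------------------------------------------------------
# misc helpers
# ---------------------------------------------------------------------------


def extract_context(sequences: Mapping[str, str], chrom: str, pos: int) -> str:
    """3-mer centered on ``pos`` (1-based) from user-supplied sequences."""
    seq = sequences[chrom]
    if pos < 2 or pos > len(seq) - 1:
        raise ValidationError(f"position {pos} too close to the end of {chrom!r}")
    return seq[pos - 2 : pos + 1].upper()


def records_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
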