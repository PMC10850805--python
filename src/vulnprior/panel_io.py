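"""Tabular I/O and the canonical in-memory data model.

One reader/writer pair per format the pipeline touches:

* screen matrices (cell line x gene CSV, gene labels ``SYMBOL (ENTREZ)``)
* one-symbol-per-line gene lists with ``#`` comments
* cell-line annotation tables
* flat mutation tables
* long-format drug-response tables and dose-viability points
* per-tumour tables and GISTIC call matrices

Writers emit a ``<path>.meta.json`` sidecar with row/column counts and a
SHA-256 content hash for provenance.  Missing values are never imputed.
Cell-line identifiers are opaque strings; the only normalization applied
anywhere is whitespace trimming.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    EmptySetError,
    FormatError,
    RangeError,
    SchemaError,
)

logger = logging.getLogger(__name__)

ROLES = ("effect", "probability", "expression", "copy_number")

GISTIC_CODES = (-2, -1, 0, 1, 2)

HPV_STATES = ("negative", "positive", "unknown")


# ---------------------------------------------------------------------------
# gene identity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneId:
    """A gene identified by HUGO-style symbol and optional Entrez id.

    Equality is on (symbol, entrez) when both sides carry an Entrez id and
    falls back to symbol-only when either side lacks one — DepMap, GDSC and
    TCGA exports disagree on identifier completeness, so joins degrade
    gracefully.  The hash is symbol-only to keep fallback equality usable
    in sets and dict keys.
    """

    symbol: str
    entrez: int | None = None

    def __post_init__(self) -> None:
        if not self.symbol or any(c.isspace() for c in self.symbol):
            raise FormatError(f"invalid gene symbol {self.symbol!r}")
        if self.entrez is not None and self.entrez <= 0:
            raise FormatError(f"entrez id must be positive, got {self.entrez}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneId):
            return NotImplemented
        if self.symbol != other.symbol:
            return False
        if self.entrez is None or other.entrez is None:
            return True
        return self.entrez == other.entrez

    def __hash__(self) -> int:
        return hash(self.symbol)

    @property
    def label(self) -> str:
        """The DepMap column convention: ``SYMBOL (ENTREZ)``."""
        return self.symbol if self.entrez is None else f"{self.symbol} ({self.entrez})"


def parse_gene_label(label: str) -> GeneId:
    """Parse ``"SYMBOL (ENTREZ)"`` or plain ``"SYMBOL"`` into a :class:`GeneId`."""
    text = label.strip()
    if not text:
        raise FormatError(f"empty gene label {label!r}")
    symbol, entrez = text, None
    if text.endswith(")") and "(" in text:
        head, _, tail = text.rpartition("(")
        inner = tail[:-1].strip()
        if inner.isdigit():
            symbol, entrez = head.strip(), int(inner)
    if not symbol:
        raise FormatError(f"gene label {label!r} has an empty symbol")
    return GeneId(symbol, entrez)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

PROVENANCES = ("druggable", "common_essential", "core_fitness", "prioritized", "custom")


@dataclass(frozen=True)
class GeneSet:
    """Named, provenance-tagged set of gene identifiers."""

    name: str
    provenance: str
    members: frozenset[GeneId]

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ConfigError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: object) -> bool:
        if isinstance(item, str):
            return item in self.symbols
        return item in self.members

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(g.symbol for g in self.members)

    @classmethod
    def from_symbols(
        cls, symbols: Iterable[str], name: str = "set", provenance: str = "custom"
    ) -> "GeneSet":
        return cls(name, provenance, frozenset(GeneId(s) for s in symbols))


def read_gene_set(
    path: str | Path,
    name: str | None = None,
    provenance: str = "custom",
    allow_empty: bool = False,
) -> GeneSet:
    """Read a one-symbol-per-line gene list (``SYMBOL`` or ``SYMBOL (ENTREZ)``).

    Lines starting with ``#`` are comments.  Duplicates are dropped and the
    duplicate count is logged for the audit trail.
    """
    path = Path(path)
    members: list[GeneId] = []
    seen: set[str] = set()
    n_dup = 0
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        gid = parse_gene_label(line)
        if gid.symbol in seen:
            n_dup += 1
            continue
        seen.add(gid.symbol)
        members.append(gid)
    if n_dup:
        logger.warning("gene set %s: dropped %d duplicate entries", path, n_dup)
    if not members and not allow_empty:
        raise EmptySetError(f"gene set file {path} is empty")
    return GeneSet(name or path.stem, provenance, frozenset(members))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    path = Path(path)
    lines = sorted(g.label for g in gene_set.members)
    text = "\n".join([f"# {gene_set.name} ({gene_set.provenance})"] + lines) + "\n"
    path.write_text(text)
    _write_sidecar(path, n_rows=len(lines), n_cols=1)


# ---------------------------------------------------------------------------
# screen matrices
# ---------------------------------------------------------------------------


@dataclass
class ScreenMatrix:
    """Cell-line x gene numeric matrix with a role tag.

    ``data`` is indexed by line id with gene symbols as columns; ``genes``
    carries the full :class:`GeneId` list (same order as the columns).
    """

    role: str
    data: pd.DataFrame
    genes: list[GeneId] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"unknown matrix role {self.role!r}; expected one of {ROLES}")
        if not self.genes:
            self.genes = [GeneId(str(c)) for c in self.data.columns]
        self.validate()

    # -- contracts ---------------------------------------------------------

    def validate(self) -> None:
        dup_lines = self.data.index[self.data.index.duplicated()].tolist()
        if dup_lines:
            raise SchemaError(f"duplicate line ids: {sorted(set(map(str, dup_lines)))}")
        dup_genes = self.data.columns[self.data.columns.duplicated()].tolist()
        if dup_genes:
            raise SchemaError(f"duplicate gene ids: {sorted(set(map(str, dup_genes)))}")
        if len(self.genes) != self.data.shape[1]:
            raise SchemaError(
                f"gene list length {len(self.genes)} != column count {self.data.shape[1]}"
            )
        vals = self.data.to_numpy(dtype=float)
        if self.role == "probability":
            bad = np.argwhere((vals < 0) | (vals > 1))
            if bad.size:
                r, c = bad[0]
                raise RangeError(
                    f"probability value {vals[r, c]} outside [0, 1] at "
                    f"(line {self.data.index[r]!r}, gene {self.data.columns[c]!r})"
                )
        elif self.role == "expression":
            bad = np.argwhere(vals < 0)
            if bad.size:
                r, c = bad[0]
                raise RangeError(
                    f"expression value {vals[r, c]} below 0 at "
                    f"(line {self.data.index[r]!r}, gene {self.data.columns[c]!r})"
                )

    # -- convenience -------------------------------------------------------

    @property
    def line_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def symbols(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def column(self, symbol: str) -> pd.Series:
        return self.data[symbol]

    def subset_lines(self, line_ids: Sequence[str]) -> "ScreenMatrix":
        missing = [l for l in line_ids if l not in self.data.index]
        if missing:
            raise SchemaError(f"line ids absent from matrix: {missing[:5]}")
        return ScreenMatrix(self.role, self.data.loc[list(line_ids)].copy(), list(self.genes))


def read_matrix(path: str | Path, role: str, sep: str = ",") -> ScreenMatrix:
    """Read a line x gene CSV into a validated :class:`ScreenMatrix`.

    First column = line id, header = gene labels; blank cells become NaN.
    Duplicate line or gene ids raise a :class:`SchemaError` naming them
    (pandas would silently mangle duplicate headers, so the header row is
    checked verbatim first).
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(sep)
    labels = [h.strip().strip('"') for h in header[1:]]
    dup = sorted({l for l in labels if labels.count(l) > 1})
    if dup:
        raise SchemaError(f"{path}: duplicate gene ids in header: {dup}")
    # round_trip parsing: the default C float parser can be off by one ulp,
    # which would break the write->read bit-identity contract
    df = pd.read_csv(path, index_col=0, sep=sep, float_precision="round_trip")
    df.index = df.index.map(lambda x: str(x).strip())
    genes = [parse_gene_label(str(c)) for c in df.columns]
    df.columns = [g.symbol for g in genes]
    dup_sym = sorted({s for s in df.columns if list(df.columns).count(s) > 1})
    if dup_sym:
        raise SchemaError(f"{path}: duplicate gene symbols after parsing: {dup_sym}")
    df = df.astype(float)
    try:
        return ScreenMatrix(role, df, genes)
    except (RangeError, SchemaError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_matrix(matrix: ScreenMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a matrix with ``SYMBOL (ENTREZ)`` headers plus a provenance sidecar.

    Values round-trip bit-identically through :func:`read_matrix` (pandas
    emits shortest-repr floats) and the missingness mask is preserved as
    blank cells.
    """
    path = Path(path)
    out = matrix.data.copy()
    out.columns = [g.label for g in matrix.genes]
    out.index.name = "line_id"
    out.to_csv(path, sep=sep)
    _write_sidecar(path, n_rows=out.shape[0], n_cols=out.shape[1])


def _write_sidecar(path: Path, n_rows: int, n_cols: int) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    meta = {"path": path.name, "n_rows": n_rows, "n_cols": n_cols, "sha256": digest}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1) + "\n")


def content_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# sample annotations and panel subsetting
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("line_id", "lineage", "subtype", "hpv_status")


def read_annotations(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a cell-line (or tumour) annotation table; line_id must be unique."""
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("unknown")
    missing = [c for c in ("line_id",) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df["line_id"] = df["line_id"].str.strip()
    dup = df.loc[df["line_id"].duplicated(), "line_id"].tolist()
    if dup:
        raise SchemaError(f"{path}: duplicate line ids: {sorted(set(dup))}")
    return df


def subset_panel(
    annot: pd.DataFrame, rules: Sequence[Mapping[str, object]] | None
) -> list[str]:
    """Select line ids whose annotation matches any rule clause.

    ``rules`` is a list of clauses; a clause maps annotation fields to an
    allowed value (or collection of values).  A line matches a clause when
    every field constraint holds (conjunction), and is selected when it
    matches any clause (disjunction).  An empty/None rule set selects every
    line.  Input order is preserved.
    """
    if not rules:
        return annot["line_id"].tolist()
    mask = np.zeros(len(annot), dtype=bool)
    for clause in rules:
        clause_mask = np.ones(len(annot), dtype=bool)
        for fld, allowed in clause.items():
            if fld not in annot.columns:
                raise ConfigError(
                    f"rule references unknown annotation field {fld!r}; "
                    f"available: {list(annot.columns)}"
                )
            values = (
                {str(allowed)}
                if isinstance(allowed, (str, int, float))
                else {str(v) for v in allowed}
            )
            clause_mask &= annot[fld].astype(str).isin(values).to_numpy()
        mask |= clause_mask
    return annot.loc[mask, "line_id"].tolist()


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = ("line_id", "gene", "variant_class", "is_hotspot", "is_damaging")


def read_mutations(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a flat mutation table (one row per variant call).

    Multiple rows per (line, gene) are allowed.  Flag columns are parsed to
    booleans; at least one of the two flag columns must be present.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"line_id", "gene"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if "is_hotspot" not in df.columns and "is_damaging" not in df.columns:
        raise SchemaError(f"{path}: needs at least one of is_hotspot/is_damaging")
    for col in ("is_hotspot", "is_damaging"):
        if col in df.columns:
            df[col] = df[col].map(_parse_bool)
        else:
            df[col] = False
    if "variant_class" not in df.columns:
        df["variant_class"] = "unknown"
    df["line_id"] = df["line_id"].astype(str).str.strip()
    df["gene"] = df["gene"].astype(str).str.strip()
    return df


def _parse_bool(x: object) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, float)) and not isinstance(x, bool):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"true", "t", "1", "yes"}:
        return True
    if s in {"false", "f", "0", "no", "", "nan"}:
        return False
    raise FormatError(f"cannot parse boolean flag {x!r}")


# ---------------------------------------------------------------------------
# drug response
# ---------------------------------------------------------------------------

RESPONSE_METRICS = ("ln_ic50", "auc")


def read_drug_response(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a long-format drug-response table.

    Columns: drug_id, drug_name, target_genes (semicolon-separated symbols),
    line_id, metric, value.  AUC values must lie in [0, 1].
    """
    df = pd.read_csv(path, sep=sep)
    required = {"drug_id", "line_id", "metric", "value"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad_metric = sorted(set(df["metric"]) - set(RESPONSE_METRICS))
    if bad_metric:
        raise SchemaError(f"{path}: unknown response metrics {bad_metric}")
    auc = df.loc[df["metric"] == "auc", "value"]
    out_of_range = auc[(auc < 0) | (auc > 1)]
    if len(out_of_range):
        raise RangeError(f"{path}: AUC values outside [0, 1] at rows {out_of_range.index.tolist()[:5]}")
    if "drug_name" not in df.columns:
        df["drug_name"] = df["drug_id"]
    if "target_genes" not in df.columns:
        df["target_genes"] = ""
    df["line_id"] = df["line_id"].astype(str).str.strip()
    return df


def read_dose_curves(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read dose-viability points: drug_id, line_id, concentration, viability.

    Concentrations must be strictly increasing within each (drug, line) curve.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"drug_id", "line_id", "concentration", "viability"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df["line_id"] = df["line_id"].astype(str).str.strip()
    for (drug, line), grp in df.groupby(["drug_id", "line_id"]):
        conc = grp["concentration"].to_numpy()
        if not np.all(np.diff(conc) > 0):
            raise SchemaError(
                f"{path}: concentrations not strictly increasing for drug {drug}, line {line}"
            )
    return df


# ---------------------------------------------------------------------------
# tumour tables
# ---------------------------------------------------------------------------


def read_tumours(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a per-tumour table: tumour_id, hpv_status, os_months, os_event."""
    df = pd.read_csv(path, sep=sep)
    required = {"tumour_id", "hpv_status"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df["tumour_id"] = df["tumour_id"].astype(str).str.strip()
    dup = df.loc[df["tumour_id"].duplicated(), "tumour_id"].tolist()
    if dup:
        raise SchemaError(f"{path}: duplicate tumour ids: {sorted(set(dup))[:5]}")
    bad_hpv = sorted(set(df["hpv_status"]) - set(HPV_STATES))
    if bad_hpv:
        raise SchemaError(f"{path}: unknown hpv_status values {bad_hpv}")
    if "os_months" in df.columns:
        if (df["os_months"].dropna() < 0).any():
            raise RangeError(f"{path}: negative os_months")
    return df


def read_gistic(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a tumour x gene GISTIC call matrix (integer codes in -2..2)."""
    df = pd.read_csv(path, index_col=0, sep=sep)
    df.index = df.index.map(lambda x: str(x).strip())
    vals = df.to_numpy()
    bad = np.argwhere(~np.isin(vals, GISTIC_CODES))
    if bad.size:
        r, c = bad[0]
        raise RangeError(
            f"{path}: GISTIC code {vals[r, c]} outside {{-2..2}} at "
            f"(tumour {df.index[r]!r}, gene {df.columns[c]!r})"
        )
    return df.astype(int)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a generic CSV table with a provenance sidecar."""
    path = Path(path)
    df.to_csv(path, index=index)
    _write_sidecar(path, n_rows=df.shape[0], n_cols=df.shape[1])
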