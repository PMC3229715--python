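"""Containers and tab-delimited I/O for Ct-value pipelines.

All tables are plain TSV.  A Ct matrix is stored assays x samples with
``NaN`` marking missing (undetermined) wells; on disk a missing cell is an
empty field or ``NA``.  Readers validate strictly and reject rather than
coerce: duplicate identifiers, non-numeric Ct values, ragged rows, unknown
group labels and out-of-range p-values are all errors that name the
offending row or column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

logger = logging.getLogger(__name__)

#: Pipeline stages in the only order transitions are allowed.
STAGES = ("raw", "filtered", "normalized", "imputed", "shrunk")

GROUPS = ("PGRN+", "PGRN-")
TISSUES = ("cortex", "cerebellum")
SUBTYPES = ("type1", "type2", "type3", "n/a")

#: Ct values above this are accepted on read but flagged; the instrument
#: range ends at 40 cycles.
CT_SOFT_MAX = 40.0

MISSING_TOKENS = ("", "NA")


@dataclass
class CtMatrix:
    """Assays x samples matrix of Ct values with an explicit missing mask.

    Parameters
    ----------
    data
        DataFrame indexed by assay id with sample ids as columns; ``NaN``
        encodes a missing Ct.
    stage
        Processing stage tag, one of :data:`STAGES`.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise DataError(f"unknown stage tag {self.stage!r}; expected one of {STAGES}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate assay id(s): {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample id(s): {dups}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            raise DataError("non-finite Ct value present")

    @property
    def assay_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_assays(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def advance(self, data: pd.DataFrame, stage: str) -> "CtMatrix":
        """Return a new matrix at the next pipeline stage.

        Enforces that ``stage`` comes after the current tag in pipeline
        order; jumping backwards is a programming error.
        """
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise DataError(
                f"stage transition {self.stage!r} -> {stage!r} violates pipeline order"
            )
        return CtMatrix(data, stage=stage)

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.data.copy(), stage=self.stage)


@dataclass
class GroupDesign:
    """Sample sheet: per-sample group, tissue and pathology subtype."""

    table: pd.DataFrame  # index sample_id; columns group, tissue, subtype

    def __post_init__(self) -> None:
        required = {"group", "tissue", "subtype"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParseError(f"sample sheet missing column(s): {sorted(missing)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample id(s) in sample sheet: {dups}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ParseError(
                f"unknown group value(s) {sorted(bad)}; allowed values: {list(GROUPS)}"
            )
        bad = set(self.table["tissue"]) - set(TISSUES)
        if bad:
            raise ParseError(
                f"unknown tissue value(s) {sorted(bad)}; allowed values: {list(TISSUES)}"
            )
        bad = set(self.table["subtype"]) - set(SUBTYPES)
        if bad:
            raise ParseError(
                f"unknown subtype value(s) {sorted(bad)}; allowed values: {list(SUBTYPES)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "group"])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def group_sizes(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()

    def check_covers(self, sample_ids: Iterable[str]) -> None:
        """Raise if any sample id lacks a label."""
        unlabelled = [s for s in sample_ids if s not in self.table.index]
        if unlabelled:
            raise DataError(f"sample(s) present in matrix but not in sample sheet: {unlabelled}")

    def subset(self, sample_ids: Iterable[str]) -> "GroupDesign":
        ids = [s for s in sample_ids]
        self.check_covers(ids)
        return GroupDesign(self.table.loc[ids])


@dataclass
class QpcrWellTable:
    """Duplicate-well qPCR Ct table with a designated endogenous control."""

    wells: pd.DataFrame  # columns: assay_id, sample_id, well_replicate, ct
    control_assay_id: str = "RNU48"

    def __post_init__(self) -> None:
        required = {"assay_id", "sample_id", "well_replicate", "ct"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ParseError(f"well table missing column(s): {sorted(missing)}")
        reps = set(self.wells["well_replicate"].astype(int))
        if not reps <= {1, 2}:
            raise ParseError(f"well_replicate must be 1 or 2, found {sorted(reps - {1, 2})}")
        counts = self.wells.groupby(["assay_id", "sample_id"]).size()
        if (counts > 2).any():
            bad = counts[counts > 2].index.tolist()
            raise ParseError(f">2 wells for assay x sample pair(s): {bad}")
        if self.control_assay_id not in set(self.wells["assay_id"]):
            raise DataError(f"control assay {self.control_assay_id!r} absent from well table")
        control_samples = set(
            self.wells.loc[self.wells["assay_id"] == self.control_assay_id, "sample_id"]
        )
        all_samples = set(self.wells["sample_id"])
        if control_samples != all_samples:
            raise DataError(
                "control assay missing for sample(s): "
                f"{sorted(all_samples - control_samples)}"
            )

    @property
    def assay_ids(self) -> list[str]:
        return sorted(set(self.wells["assay_id"]))

    @property
    def sample_ids(self) -> list[str]:
        return sorted(set(self.wells["sample_id"]))


#: miRNA id -> set of predicted target gene symbols (upper-cased on ingest).
TargetMap = dict


@dataclass
class MrnaDeTable:
    """Per-probeset mRNA differential-expression calls for one tissue."""

    table: pd.DataFrame  # columns: probeset_id, gene_symbol, direction, p_value

    def __post_init__(self) -> None:
        required = {"probeset_id", "gene_symbol", "direction", "p_value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParseError(f"DE table missing column(s): {sorted(missing)}")
        if self.table["probeset_id"].duplicated().any():
            dups = self.table.loc[self.table["probeset_id"].duplicated(), "probeset_id"].tolist()
            raise ParseError(f"duplicate probeset id(s): {dups}")
        p = self.table["p_value"].astype(float)
        bad = self.table.loc[(p < 0) | (p > 1) | p.isna(), "probeset_id"].tolist()
        if bad:
            raise ParseError(f"p-value outside [0, 1] for probeset(s): {bad}")
        direc = set(self.table["direction"])
        if not direc <= {"up", "down"}:
            raise ParseError(
                f"direction must be 'up' or 'down', found {sorted(direc - {'up', 'down'})}"
            )
        self.table = self.table.assign(
            gene_symbol=self.table["gene_symbol"].astype(str).str.upper(),
            p_value=p,
        )


# ---------------------------------------------------------------------------
# Readers / writers


def _read_tsv_strict(path: str | Path) -> list[list[str]]:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: file is empty")
    rows = [line.split("\t") for line in text.splitlines()]
    return rows


def read_ct_table(path: str | Path, stage: str = "raw") -> CtMatrix:
    """Read a Ct matrix: header row of sample ids, first column assay ids.

    Missing cells are encoded as an empty field or ``NA``.
    """
    path = Path(path)
    rows = _read_tsv_strict(path)
    header = rows[0]
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample id(s) in header: {dups}")
    width = len(header)
    assay_ids: list[str] = []
    values: list[list[float]] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {lineno}: expected {width} fields, found {len(row)}"
            )
        assay = row[0]
        if assay in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate assay id {assay!r}")
        seen.add(assay)
        parsed: list[float] = []
        for col, cell in zip(sample_ids, row[1:]):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                parsed.append(np.nan)
                continue
            try:
                ct = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}, sample {col!r}: non-numeric Ct {cell!r}"
                ) from None
            if not np.isfinite(ct):
                raise ParseError(f"{path}: line {lineno}, sample {col!r}: non-finite Ct")
            if ct > CT_SOFT_MAX:
                warnings.warn(
                    f"{path}: assay {assay!r}, sample {col!r}: Ct {ct} exceeds the "
                    f"instrument range ({CT_SOFT_MAX} cycles)",
                    stacklevel=2,
                )
            parsed.append(ct)
        assay_ids.append(assay)
        values.append(parsed)
    data = pd.DataFrame(values, index=assay_ids, columns=sample_ids, dtype=float)
    return CtMatrix(data, stage=stage)


def write_ct_table(matrix: CtMatrix, path: str | Path) -> None:
    """Write a Ct matrix as TSV; missing cells are written as ``NA``.

    Uses ``repr`` precision so a write/read round trip is value-exact.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("assay_id\t" + "\t".join(str(s) for s in matrix.sample_ids) + "\n")
        for assay, row in matrix.data.iterrows():
            cells = ["NA" if pd.isna(v) else repr(float(v)) for v in row]
            fh.write(str(assay) + "\t" + "\t".join(cells) + "\n")


def read_sample_sheet(path: str | Path) -> GroupDesign:
    """Read a TSV sample sheet with columns sample_id, group, tissue, subtype."""
    path = Path(path)
    rows = _read_tsv_strict(path)
    header = [h.strip() for h in rows[0]]
    expected = ["sample_id", "group", "tissue", "subtype"]
    if header[: len(expected)] != expected:
        raise ParseError(f"{path}: expected header {expected}, found {header}")
    records = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) < len(expected):
            raise ParseError(f"{path}: line {lineno}: expected {len(expected)} fields")
        records.append([c.strip() for c in row[: len(expected)]])
    if not records:
        raise ParseError(f"{path}: no samples in sample sheet")
    table = pd.DataFrame(records, columns=expected).set_index("sample_id")
    return GroupDesign(table)


def write_sample_sheet(design: GroupDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample_id")


def read_well_table(path: str | Path, control_assay_id: str = "RNU48") -> QpcrWellTable:
    """Read a duplicate-well qPCR table: assay_id, sample_id, well_replicate, ct."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"assay_id": str, "sample_id": str})
    if df.empty:
        raise ParseError(f"{path}: empty well table")
    if "ct" in df.columns:
        df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    return QpcrWellTable(df, control_assay_id=control_assay_id)


def write_well_table(wells: QpcrWellTable, path: str | Path) -> None:
    wells.wells.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_target_lists(path_or_dir: str | Path) -> TargetMap:
    """Read predicted-target lists as two-column TSV (mirna_id, gene_symbol).

    Accepts a single file or a directory of ``*.tsv`` files.  Gene symbols
    are upper-cased; duplicate (mirna, gene) rows collapse to one
    membership.  A header line of exactly ``mirna_id<TAB>gene_symbol`` is
    skipped if present.
    """
    path = Path(path_or_dir)
    files = sorted(path.glob("*.tsv")) if path.is_dir() else [path]
    if not files:
        raise ParseError(f"{path}: no target-list TSV files found")
    targets: TargetMap = {}
    for fp in files:
        for lineno, row in enumerate(_read_tsv_strict(fp), start=1):
            if lineno == 1 and [c.strip() for c in row[:2]] == ["mirna_id", "gene_symbol"]:
                continue
            if len(row) < 2:
                raise ParseError(f"{fp}: line {lineno}: expected 2 fields")
            mirna, gene = row[0].strip(), row[1].strip().upper()
            if not gene:
                raise ParseError(f"{fp}: line {lineno}: empty gene symbol")
            targets.setdefault(mirna, set()).add(gene)
    return targets


def write_target_lists(targets: Mapping[str, set], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("mirna_id\tgene_symbol\n")
        for mirna in sorted(targets):
            for gene in sorted(targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def read_mrna_de_table(path: str | Path) -> MrnaDeTable:
    """Read a four-column mRNA DE table: probeset_id, gene_symbol, direction, p_value."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"probeset_id": str, "gene_symbol": str})
    if df.empty:
        raise ParseError(f"{path}: empty DE table")
    return MrnaDeTable(df)


def write_mrna_de_table(table: MrnaDeTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)
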