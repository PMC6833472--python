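"""Domain types and text-format I/O.

The pipeline works on three plain-text formats:

* a gene x sample count matrix (TSV, first column gene IDs, header row
  sample IDs),
* a sample sheet (TSV with columns ``sample``, ``condition``,
  ``replicate``),
* gene-set annotations in GMT (one term per line: ID, description, then
  member genes, tab-separated).

Gene and sample identifiers are opaque, case-sensitive strings; no
symbol/ID mapping is performed. Sample <-> column reconciliation is by
identifier, never by column position, so a reordered count file can not
silently mislabel conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

SAMPLE_SHEET_COLUMNS = ("sample", "condition", "replicate")


@dataclass(frozen=True)
class CountDataset:
    """Integer expression counts with per-sample condition metadata.

    Parameters
    ----------
    counts
        Genes x samples matrix of non-negative integers. The index holds
        gene identifiers, the columns sample identifiers; both unique.
    sample_meta
        One row per sample (index = sample identifier) with columns
        ``condition`` and ``replicate``, in the same order as the count
        matrix columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if not self.counts.columns.is_unique:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            loc = _first_noninteger(self.counts)
            raise FormatError(
                f"non-integer count at gene {loc[0]!r}, sample {loc[1]!r}"
            )
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        missing = {"condition", "replicate"} - set(self.sample_meta.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if list(self.sample_meta.index) != list(self.counts.columns):
            raise FormatError("sample_meta rows must match count columns in order")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        return list(dict.fromkeys(self.sample_meta["condition"]))

    def condition_samples(self, condition: str) -> list[str]:
        """Sample identifiers belonging to one condition."""
        mask = self.sample_meta["condition"] == condition
        if not mask.any():
            raise DesignError(f"condition {condition!r} has no samples")
        return list(self.sample_meta.index[mask])

    def equals(self, other: "CountDataset") -> bool:
        return self.counts.equals(other.counts) and self.sample_meta.equals(
            other.sample_meta
        )


@dataclass(frozen=True)
class ExperimentDesign:
    """The fixed reference condition and the ordered contrast conditions.

    All fold changes and calls are computed against ``reference_condition``;
    a gene's co-expression path is the tuple of its calls over
    ``path_conditions`` in this order.
    """

    reference_condition: str
    path_conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        conds = tuple(self.path_conditions)
        object.__setattr__(self, "path_conditions", conds)
        if len(conds) == 0:
            raise DesignError("path_conditions must have at least one entry")
        if len(set(conds)) != len(conds):
            raise DesignError("path_conditions contains duplicates")
        if self.reference_condition in conds:
            raise DesignError(
                f"reference condition {self.reference_condition!r} can not "
                "also be a path condition"
            )

    @property
    def conditions(self) -> tuple[str, ...]:
        return (self.reference_condition,) + self.path_conditions


@dataclass(frozen=True)
class GeneSetCollection:
    """Flat gene-set annotations: term ID -> (name, member genes)."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if len(genes) == 0:
                raise FormatError(f"term {term_id!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def name_of(self, term_id: str) -> str:
        return self.terms[term_id][0]


def _first_noninteger(counts: pd.DataFrame) -> tuple[str, str]:
    for sample in counts.columns:
        col = counts[sample]
        if np.issubdtype(col.dtype, np.integer):
            continue
        for gene, value in col.items():
            try:
                ok = float(value) == int(float(value))
            except (TypeError, ValueError):
                ok = False
            if not ok:
                return str(gene), str(sample)
    return str(counts.index[0]), str(counts.columns[0])


def read_counts(counts_path, sample_sheet_path) -> CountDataset:
    """Read a count matrix and sample sheet, reconciling by identifier.

    The returned dataset's columns follow the sample sheet order, whatever
    the column order of the count file. Any sample present in only one of
    the two files is a :class:`FormatError` naming that sample.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"sample": str})
    missing_cols = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing_cols:
        raise FormatError(
            f"sample sheet {sample_sheet_path} missing columns: "
            f"{sorted(missing_cols)}"
        )
    if sheet["sample"].duplicated().any():
        dup = sheet.loc[sheet["sample"].duplicated(), "sample"].iloc[0]
        raise FormatError(f"duplicate sample {dup!r} in sample sheet")

    file_samples = set(counts.columns)
    sheet_samples = set(sheet["sample"])
    only_file = sorted(file_samples - sheet_samples)
    if only_file:
        raise FormatError(
            f"sample {only_file[0]!r} in count file but not in sample sheet"
        )
    only_sheet = sorted(sheet_samples - file_samples)
    if only_sheet:
        raise FormatError(
            f"sample {only_sheet[0]!r} in sample sheet but not in count file"
        )

    counts = counts.loc[:, list(sheet["sample"])]
    for sample in counts.columns:
        if not np.issubdtype(counts[sample].dtype, np.integer):
            gene, samp = _first_noninteger(counts)
            raise FormatError(
                f"non-integer count at gene {gene!r}, sample {samp!r}"
            )
    meta = sheet.set_index("sample")[["condition", "replicate"]]
    return CountDataset(counts=counts, sample_meta=meta)


def write_counts(ds: CountDataset, counts_path, sample_sheet_path) -> None:
    """Write a dataset back to the count-matrix + sample-sheet dialect."""
    out = ds.counts.copy()
    out.index.name = "gene"
    out.to_csv(counts_path, sep="\t")
    sheet = ds.sample_meta.reset_index(names="sample")
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one term per line, >= 3 tab-separated fields.

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields is a :class:`FormatError` carrying its line number.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, found {len(fields)}"
                )
            term_id, name = fields[0], fields[1]
            if term_id in terms:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate term {term_id!r}"
                )
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(
                    f"{path}: line {lineno}: term {term_id!r} has no genes"
                )
            terms[term_id] = (name, genes)
    return GeneSetCollection(terms=terms)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id in sets:
            name = sets.name_of(term_id)
            genes = sorted(sets.genes_of(term_id))
            fh.write("\t".join([term_id, name, *genes]) + "\n")


def write_table(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV, floats at 6 significant digits."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
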