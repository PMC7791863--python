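"""OTU count-table data model and TSV I/O.

The table is the product of an upstream 16S pipeline (read QC, chimera
removal, 97%-identity OTU clustering); this module only represents and
transforms the resulting integer count matrix. Internal orientation is
fixed as samples x OTUs; files may store either orientation and declare
it on read. TSV (tab-delimited, UTF-8, header row) is the canonical
on-disk format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

Orientation = Literal["otus_as_rows", "samples_as_rows"]

TAXONOMY_COLUMN = "taxonomy"


@dataclass
class OtuTable:
    """Integer OTU count matrix with sample/OTU identifiers.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (rows of ``counts``).
    otu_ids : list of str
        Unique OTU identifiers (columns of ``counts``).
    counts : ndarray of int, shape (n_samples, n_otus)
        Non-negative read counts.
    taxonomy : dict, optional
        Map otu_id -> semicolon-delimited ranked lineage string.
    group : dict, optional
        Map sample_id -> group label (e.g. diet treatment).
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None
    group: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            len(self.otu_ids),
        ):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.otu_ids)} OTUs)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise ValueError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.otu_ids, "OTU id")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.otu_ids)
            if unknown:
                raise ValueError(f"taxonomy refers to unknown OTU ids: {sorted(unknown)[:5]}")
        if self.group is not None:
            unknown = set(self.group) - set(self.sample_ids)
            if unknown:
                raise ValueError(f"group map refers to unknown sample ids: {sorted(unknown)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample total counts (sequencing depth)."""
        return self.counts.sum(axis=1)

    def samples_in_group(self, label: str) -> list[str]:
        if self.group is None:
            raise ValueError("table has no group labels")
        return [s for s in self.sample_ids if self.group.get(s) == label]

    def subset_samples(self, sample_ids: list[str]) -> "OtuTable":
        """Return a new table restricted to the given samples (in the given order)."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        group = None
        if self.group is not None:
            group = {s: self.group[s] for s in sample_ids if s in self.group}
        return OtuTable(
            sample_ids=list(sample_ids),
            otu_ids=list(self.otu_ids),
            counts=self.counts[idx, :].copy(),
            taxonomy=dict(self.taxonomy) if self.taxonomy else None,
            group=group,
        )

    def summary(self) -> dict:
        """JSON-serializable summary: identifiers, depths, group labels."""
        return {
            "sample_ids": list(self.sample_ids),
            "otu_ids": list(self.otu_ids),
            "depths": [int(d) for d in self.depths],
            "group": dict(self.group) if self.group else None,
        }


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} {i!r}")
        seen.add(i)


def read_otu_table(
    path: str | Path,
    orientation: Orientation = "otus_as_rows",
) -> OtuTable:
    """Read a TSV OTU table into samples x OTUs orientation.

    The first column holds row identifiers; an optional final column named
    ``taxonomy`` (only meaningful with ``otus_as_rows``) holds lineage
    strings. Cells must be non-negative integers.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(lines) == 1:
        raise ValueError(f"{path}: no data rows")
    ncol = len(header)
    has_tax = header[-1] == TAXONOMY_COLUMN
    col_ids = header[1 : ncol - 1] if has_tax else header[1:]
    row_ids: list[str] = []
    taxonomy: dict[str, str] = {}
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(fields)} fields, expected {ncol})"
            )
        row_ids.append(fields[0])
        vals = fields[1 : ncol - 1] if has_tax else fields[1:]
        row: list[int] = []
        for j, v in enumerate(vals):
            try:
                x = float(v)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric count {v!r} at row {fields[0]!r}, "
                    f"column {col_ids[j]!r}"
                ) from None
            if x < 0 or x != int(x):
                raise ValueError(
                    f"{path}: invalid count {v!r} (must be a non-negative "
                    f"integer) at row {fields[0]!r}, column {col_ids[j]!r}"
                )
            row.append(int(x))
        rows.append(row)
        if has_tax:
            taxonomy[fields[0]] = fields[-1]
    counts = np.array(rows, dtype=np.int64)
    if orientation == "otus_as_rows":
        return OtuTable(
            sample_ids=col_ids,
            otu_ids=row_ids,
            counts=counts.T.copy(),
            taxonomy=taxonomy or None,
        )
    elif orientation == "samples_as_rows":
        if has_tax:
            raise ValueError("taxonomy column is only supported with otus_as_rows")
        return OtuTable(sample_ids=row_ids, otu_ids=col_ids, counts=counts)
    raise ValueError(f"unknown orientation {orientation!r}")


def write_otu_table(
    table: OtuTable,
    path: str | Path,
    orientation: Orientation = "otus_as_rows",
) -> Path:
    """Write a table as TSV; round-trips exactly through :func:`read_otu_table`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if orientation == "otus_as_rows":
            header = ["otu_id"] + list(table.sample_ids)
            if table.taxonomy:
                header.append(TAXONOMY_COLUMN)
            fh.write("\t".join(header) + "\n")
            for j, otu in enumerate(table.otu_ids):
                row = [otu] + [str(int(c)) for c in table.counts[:, j]]
                if table.taxonomy:
                    row.append(table.taxonomy.get(otu, ""))
                fh.write("\t".join(row) + "\n")
        elif orientation == "samples_as_rows":
            fh.write("\t".join(["sample_id"] + list(table.otu_ids)) + "\n")
            for i, s in enumerate(table.sample_ids):
                fh.write("\t".join([s] + [str(int(c)) for c in table.counts[i]]) + "\n")
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
    return path


def write_group_labels(table: OtuTable, path: str | Path) -> Path:
    """Write sample -> group labels as a two-column TSV."""
    if table.group is None:
        raise ValueError("table has no group labels")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\n")
        for s in table.sample_ids:
            fh.write(f"{s}\t{table.group.get(s, '')}\n")
    return path


def read_group_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id/group TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (sample_id, group)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def to_relative_abundance(table: OtuTable) -> np.ndarray:
    """Per-sample relative abundances; each row sums to 1.

    Raises if any sample has zero total counts.
    """
    depths = table.depths
    zero = np.nonzero(depths == 0)[0]
    if zero.size:
        raise ValueError(f"zero-sum sample {table.sample_ids[zero[0]]!r}")
    return table.counts / depths[:, None]


def group_mean_abundance(table: OtuTable, group_label: str) -> np.ndarray:
    """Arithmetic mean of per-sample relative abundances over one group.

    Each sample contributes equally regardless of depth; the result sums
    to 1. This is the per-sample normalisation of pooled group profiles.
    """
    samples = table.samples_in_group(group_label)
    if not samples:
        available = sorted(set((table.group or {}).values()))
        raise ValueError(f"unknown group {group_label!r}; available: {available}")
    sub = table.subset_samples(samples)
    return to_relative_abundance(sub).mean(axis=0)


def export_summary_json(table: OtuTable, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(table.summary(), indent=2) + "\n", encoding="utf-8")
    return path
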