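"""Readers and writers for the tabular artifacts of the pipeline.

Count matrices follow the HTSeq-count orientation: genes as rows, samples
as columns. Missing counts are not allowed — a dropped sample is expressed
by omitting its column. ``"NA"`` is the single sentinel for untested or
undefined statistics in every output table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio

DEFAULT_PARTS = ("BS", "CE", "DI", "OB", "OT", "TE")

#: HTSeq-count appends special counter rows; they are rejected on read if
#: they match one of these prefixes.
SPECIAL_ROW_PREFIXES = ("__",)


class QlseqIOError(ValueError):
    """Raised when an input file violates a structural invariant."""


# ---------------------------------------------------------------------------
# CountMatrix


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample library sizes."""

    counts: pd.DataFrame
    lib_sizes: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] == 0 or c.shape[1] == 0:
            raise QlseqIOError("empty count matrix")
        dup_g = c.index[c.index.duplicated()].unique().tolist()
        if dup_g:
            raise QlseqIOError(f"duplicate gene ids: {dup_g}")
        dup_s = c.columns[c.columns.duplicated()].unique().tolist()
        if dup_s:
            raise QlseqIOError(f"duplicate sample ids: {dup_s}")
        arr = c.to_numpy()
        bad = ~np.isfinite(arr) | (arr < 0) | (arr != np.floor(arr))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise QlseqIOError(
                f"count matrix entry at gene {c.index[i]!r}, sample "
                f"{c.columns[j]!r} is not a non-negative integer: {arr[i, j]!r}"
            )
        self.counts = c.astype(np.int64)
        self.counts.index.name = None
        self.counts.columns.name = None
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0)
        else:
            self.lib_sizes = pd.Series(self.lib_sizes, copy=True).reindex(c.columns)
            if self.lib_sizes.isna().any():
                raise QlseqIOError("lib_sizes missing for some samples")
        if (self.lib_sizes <= 0).any():
            bad_s = self.lib_sizes.index[self.lib_sizes <= 0].tolist()
            raise QlseqIOError(f"non-positive library size for samples: {bad_s}")
        self.lib_sizes = self.lib_sizes.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        sub = self.counts.loc[mask_or_ids] if not isinstance(
            mask_or_ids, (np.ndarray, pd.Series, list)
        ) or not _is_bool_mask(mask_or_ids) else self.counts.loc[np.asarray(mask_or_ids)]
        return CountMatrix(sub, self.lib_sizes.copy())

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.lib_sizes[list(sample_ids)])


def _is_bool_mask(x) -> bool:
    a = np.asarray(x)
    return a.dtype == bool


def read_count_matrix(path, format: str = "tsv", transpose: bool = False) -> CountMatrix:
    """Read a count matrix (genes x samples) from TSV or MatrixMarket.

    MatrixMarket input expects sibling label files ``<path>.rows`` and
    ``<path>.cols`` (one id per line). ``transpose`` flips a
    samples-as-rows file into the native orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx":
        m = spio.mmread(path)
        mat = np.asarray(m.todense() if hasattr(m, "todense") else m)
        rows = Path(f"{path}.rows").read_text().split()
        cols = Path(f"{path}.cols").read_text().split()
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        raise ValueError(f"unknown count format {format!r}")
    if transpose:
        df = df.T
    special = [g for g in df.index if str(g).startswith(SPECIAL_ROW_PREFIXES)]
    if special:
        raise QlseqIOError(
            f"count matrix contains special counter rows {special}; strip them upstream"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# SampleTable


@dataclass
class SampleTable:
    """Per-sample factors: individual, species, brain part.

    Factor levels are recorded in first-appearance order. Individuals must
    be nested in species (each individual belongs to exactly one species).
    """

    table: pd.DataFrame
    parts: tuple = DEFAULT_PARTS

    def __post_init__(self) -> None:
        required = ["sample_id", "individual", "species", "brain_part"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise QlseqIOError(f"sample table missing columns: {missing}")
        unknown = [c for c in self.table.columns if c not in required]
        if unknown:
            raise QlseqIOError(f"sample table has unknown columns: {unknown}")
        t = self.table.astype(str)
        dup = t.sample_id[t.sample_id.duplicated()].tolist()
        if dup:
            raise QlseqIOError(f"duplicate sample ids: {dup}")
        bad_parts = sorted(set(t.brain_part) - set(self.parts))
        if bad_parts:
            raise QlseqIOError(
                f"unknown brain_part levels {bad_parts}; configured levels are {list(self.parts)}"
            )
        nesting = t.groupby("individual")["species"].nunique()
        broken = nesting.index[nesting > 1].tolist()
        if broken:
            raise QlseqIOError(
                f"individual nested in species violated for: {broken}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.sample_id)

    @property
    def individuals(self) -> list[str]:
        return list(dict.fromkeys(self.table.individual))

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.table.species))

    @property
    def brain_parts(self) -> list[str]:
        return [p for p in self.parts if p in set(self.table.brain_part)]

    def species_of_individual(self) -> dict[str, str]:
        return dict(zip(self.table.individual, self.table.species))

    def aligned_to(self, sample_ids) -> "SampleTable":
        t = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(t, self.parts)


def read_sample_table(path, parts: tuple = DEFAULT_PARTS) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(df, parts)


def write_sample_table(st: SampleTable, path) -> None:
    st.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> frozenset:
        return self.sets[set_id]

    def restricted_to(self, universe, min_size: int = 1) -> "GeneSetCollection":
        uni = set(universe)
        kept = {
            sid: frozenset(g for g in genes if g in uni)
            for sid, genes in self.sets.items()
        }
        kept = {sid: g for sid, g in kept.items() if len(g) >= min_size}
        return GeneSetCollection(
            kept, {sid: self.descriptions.get(sid, "") for sid in kept}
        )


def read_gene_sets(path, format: str = "two_column_tsv") -> GeneSetCollection:
    """Read a gene -> set mapping as two-column TSV or GMT."""
    import warnings

    path = Path(path)
    sets: dict[str, set] = {}
    desc: dict[str, str] = {}
    if format == "two_column_tsv":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise QlseqIOError(f"{path}:{lineno}: expected 'gene<TAB>set', got {line!r}")
            gene, sid = fields
            sets.setdefault(sid, set()).add(gene)
    elif format == "gmt":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise QlseqIOError(f"{path}:{lineno}: malformed GMT record")
            sid, d, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                warnings.warn(f"{path}:{lineno}: empty gene set {sid!r} dropped")
                continue
            sets.setdefault(sid, set()).update(genes)
            desc[sid] = d
    else:
        raise ValueError(f"unknown gene-set format {format!r}")
    return GeneSetCollection({k: frozenset(v) for k, v in sets.items()}, desc)


def write_gene_sets_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, genes in gsc.sets.items():
            d = gsc.descriptions.get(sid, "")
            fh.write("\t".join([sid, d, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Result tables and manifests

NA = "NA"
_FLOAT_FMT = "%.6g"


def write_results_table(rows: pd.DataFrame, path) -> None:
    """Write a result table as TSV with a fixed column order and ``NA``
    for missing statistics; floats at 6 significant digits."""
    rows = pd.DataFrame(rows)
    rows.to_csv(path, sep="\t", index=False, na_rep=NA, float_format=_FLOAT_FMT)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
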