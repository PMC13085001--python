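"""Readers and writers for the external formats the pipeline touches.

Formats: TSV count/metadata/DE tables, MatrixMarket count triplets with
row/column sidecar files, Ensembl-dialect GTF for gene lengths, and GMT
gene-set collections.  All readers validate strictly and raise
:class:`ValidationError` rather than silently coercing malformed input;
every writer's output is re-readable to an equal in-memory value.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CountMatrix",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "gene_lengths_from_gtf",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_gmt",
    "write_gmt",
    "read_de_table",
    "write_de_table",
]

META_COLUMNS = ("cohort", "condition", "treatment")
DE_REQUIRED = ("gene_id", "log2fc", "pvalue", "padj")
DE_COLUMNS = ("gene_id", "base_mean", "log2fc", "se", "pvalue", "padj")


class ValidationError(ValueError):
    """Malformed or inconsistent external input."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample metadata.

    Parameters
    ----------
    counts
        Genes x samples integer DataFrame; index = gene ids, columns =
        sample ids.
    sample_meta
        DataFrame indexed by sample id with at least ``cohort``,
        ``condition`` and ``treatment`` columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene_id(s): {dups[:5]}")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(values != np.floor(values))
                raise ValidationError(
                    f"non-integer count at gene {self.counts.index[bad[0][0]]!r}"
                    if len(bad)
                    else "non-finite counts"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts are not allowed")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"sample(s) missing from metadata: {missing}")
        absent = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if absent:
            raise ValidationError(f"metadata missing required column(s): {absent}")
        # keep metadata aligned to the count columns; canonical axis names
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        self.sample_meta.index.name = "sample_id"

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.counts[sample_ids], self.sample_meta.loc[sample_ids])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.sample_meta)

    def groups(self, column: str = "condition") -> dict[str, list[str]]:
        """Map group label -> sample ids, per a metadata column."""
        out: dict[str, list[str]] = {}
        for sid, label in self.sample_meta[column].items():
            out.setdefault(str(label), []).append(sid)
        return out

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.sample_meta.equals(
            other.sample_meta
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> member ids, plus descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# count matrices


def _read_meta(meta_path: str) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata table must have a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    return meta.set_index("sample_id")


def read_counts(path: str, meta_path: str) -> CountMatrix:
    """Read a count matrix (TSV, or MatrixMarket with sidecars) plus metadata.

    A TSV has gene ids in the first column and one column per sample.  A
    MatrixMarket file ``X.mtx`` needs sidecars ``X.mtx.rows`` and
    ``X.mtx.cols`` holding one gene/sample id per line.
    """
    meta = _read_meta(meta_path)
    if str(path).endswith(".mtx"):
        counts = _read_mtx(path)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
    return CountMatrix(counts, meta)


def _read_mtx(path: str) -> pd.DataFrame:
    from scipy.io import mmread

    rows_path, cols_path = f"{path}.rows", f"{path}.cols"
    for p in (rows_path, cols_path):
        if not os.path.exists(p):
            raise ValidationError(f"MatrixMarket sidecar missing: {p}")
    mat = mmread(path)
    genes = [line.strip() for line in open(rows_path, encoding="utf-8") if line.strip()]
    samples = [line.strip() for line in open(cols_path, encoding="utf-8") if line.strip()]
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    if dense.shape != (len(genes), len(samples)):
        raise ValidationError(
            f"matrix shape {dense.shape} does not match sidecars "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    if np.any(dense != np.floor(dense)):
        raise ValidationError("non-integer entries in MatrixMarket counts")
    return pd.DataFrame(dense.astype(np.int64), index=genes, columns=samples)


def write_counts(cm: CountMatrix, path: str, meta_path: str) -> None:
    """Write counts + metadata as TSV (UTF-8, header line)."""
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", encoding="utf-8")
    meta = cm.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t", encoding="utf-8")


def write_counts_mtx(cm: CountMatrix, path: str) -> None:
    """Write counts as MatrixMarket with .rows/.cols sidecars."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(path, coo_matrix(cm.counts.to_numpy()))
    # mmwrite may append .mtx; normalise
    actual = path if os.path.exists(path) else f"{path}.mtx"
    base = actual
    with open(f"{base}.rows", "w", encoding="utf-8") as fh:
        fh.write("\n".join(map(str, cm.counts.index)) + "\n")
    with open(f"{base}.cols", "w", encoding="utf-8") as fh:
        fh.write("\n".join(map(str, cm.counts.columns)) + "\n")


# ---------------------------------------------------------------------------
# gene annotation


def gene_lengths_from_gtf(
    path: str,
    feature: str = "gene",
    length_mode: str = "span",
    strip_versions: bool = False,
) -> pd.Series:
    """Extract per-gene lengths (bp) from an Ensembl-dialect GTF.

    ``length_mode='span'`` (default) is the genomic span of the gene
    feature, ``end - start + 1`` in the GTF's 1-based inclusive
    coordinates.  ``length_mode='exonic'`` is the length of the union of
    the gene's exon intervals instead.  ``strip_versions`` drops a
    trailing ``.N`` from gene ids.
    """
    import gffutils

    if length_mode not in ("span", "exonic"):
        raise ValueError("length_mode must be 'span' or 'exonic'")
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    lengths: dict[str, int] = {}
    conflicts: list[str] = []
    for feat in db.features_of_type(feature):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        if strip_versions:
            gid = gid.rsplit(".", 1)[0]
        if length_mode == "span":
            length = feat.end - feat.start + 1
        else:
            ivals = sorted(
                (e.start, e.end)
                for e in db.children(feat, featuretype="exon")
            )
            length = _union_length(ivals) if ivals else feat.end - feat.start + 1
        if gid in lengths and lengths[gid] != length:
            conflicts.append(gid)
        lengths[gid] = length
    if conflicts:
        raise ValidationError(
            f"duplicated gene_id(s) with conflicting spans: {sorted(set(conflicts))}"
        )
    if not lengths:
        import warnings

        warnings.warn(f"no {feature!r} features found in {path}", stacklevel=2)
    out = pd.Series(lengths, name="length_bp", dtype=np.int64)
    out.index.name = "gene_id"
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by 1-based inclusive intervals (assumed sorted)."""
    total, cur_start, cur_end = 0, None, None
    for s, e in intervals:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def read_gene_lengths(path: str) -> pd.Series:
    """Read a two-column gene_id / length_bp TSV."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "length_bp"):
        if col not in table.columns:
            raise ValidationError(f"gene annotation table missing column {col!r}")
    if table["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in annotation table")
    lengths = table.set_index("gene_id")["length_bp"].astype(np.int64)
    if (lengths < 1).any():
        raise ValidationError("gene lengths must be >= 1 bp")
    return lengths


def write_gene_lengths(lengths: pd.Series, path: str) -> None:
    out = lengths.rename("length_bp").to_frame()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    """Write GMT with members in sorted order (stable bytes for fixed input)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# DE tables


def read_de_table(path: str) -> pd.DataFrame:
    """Read an externally produced differential-expression table.

    Required columns: gene_id, log2fc, pvalue, padj; base_mean and se are
    optional.  p-values outside [0, 1] are rejected.
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in DE_REQUIRED if c not in table.columns]
    if missing:
        raise ValidationError(f"DE table missing column(s): {missing}")
    if table["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in DE table")
    for col in ("pvalue", "padj"):
        vals = table[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValidationError(f"{col} outside [0, 1] in DE table")
    return table.reset_index(drop=True)


def write_de_table(de: pd.DataFrame, path: str) -> None:
    cols = [c for c in DE_COLUMNS if c in de.columns]
    cols += [c for c in de.columns if c not in cols]
    de.loc[:, cols].to_csv(path, sep="\t", index=False, encoding="utf-8")
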