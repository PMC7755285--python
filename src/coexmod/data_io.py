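"""Expression-matrix and annotation I/O plus the pre-network gene filter.

Expression matrices are plain TSV/CSV with gene ids in the first column
(genes in rows by default).  Sample metadata — gestational stage in days and
replicate number — comes from a sidecar sample sheet (TSV with columns
``sample_id``, ``stage_day``, ``replicate``) or, failing that, is parsed from
sample ids of the form ``d45_r1`` / ``45d_1`` / ``D115R3``.  Gene-set
annotation uses the Broad GMT dialect (term, description, member genes).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

__all__ = [
    "ExpressionMatrix",
    "AnnotationSet",
    "Term",
    "FilterRecord",
    "read_expression",
    "read_sample_sheet",
    "filter_genes",
    "log_transform",
    "read_gmt",
    "write_results",
]

_SAMPLE_ID_RE = re.compile(r"(?:d\s*)?(\d+)\s*d?[\s._-]*r?(?:ep)?[\s._-]*(\d+)", re.IGNORECASE)


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of nonnegative abundances (FPKM or log scale).

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns; ``sample_meta`` is indexed by sample id with integer columns
    ``stage_day`` and ``replicate`` (nullable when unknown).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        for name, ids in (("gene", idx), ("sample", cols)):
            dup = ids[ids.duplicated()]
            if len(dup):
                raise ValueError(f"duplicate {name} id: {dup[0]!r}")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")
        if not self.sample_meta.index.equals(cols):
            self.sample_meta = self.sample_meta.reindex(cols)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    namespace: str  # BP | CC | MF | pathway
    genes: frozenset[str]


@dataclass
class AnnotationSet:
    """Local stand-in for GO/KEGG-style annotation: term id → gene set."""

    terms: dict[str, Term] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, t in self.terms.items():
            if not t.genes:
                raise ValueError(f"term {tid!r} has an empty gene set")

    def restrict(self, universe: set[str]) -> "AnnotationSet":
        """Intersect every term with *universe*, dropping emptied terms."""
        kept = {}
        for tid, t in self.terms.items():
            g = t.genes & universe
            if g:
                kept[tid] = Term(t.term_id, t.name, t.namespace, frozenset(g))
        return AnnotationSet(kept)

    def update(self, other: "AnnotationSet") -> None:
        self.terms.update(other.terms)


@dataclass(frozen=True)
class FilterRecord:
    n_input: int
    n_kept: int
    n_dropped: int
    min_value: float
    min_fraction: float
    min_mad: float


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "stage_day", "replicate"} - set(meta.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {sorted(missing)}")
    return meta.set_index("sample_id")[["stage_day", "replicate"]].astype(int)


def _meta_from_ids(sample_ids: list[str]) -> pd.DataFrame:
    days, reps = [], []
    for sid in sample_ids:
        m = _SAMPLE_ID_RE.search(sid)
        if m:
            days.append(int(m.group(1)))
            reps.append(int(m.group(2)))
        else:
            days.append(pd.NA)
            reps.append(pd.NA)
    return pd.DataFrame(
        {"stage_day": days, "replicate": reps},
        index=pd.Index(sample_ids, name="sample_id"),
        dtype="Int64",
    )


def read_expression(
    path: str | os.PathLike,
    delimiter: str | None = None,
    genes_in_rows: bool = True,
    sample_sheet: str | os.PathLike | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table; ids are preserved verbatim.

    ``delimiter=None`` infers tab vs comma from the extension (.csv → comma).
    """
    if delimiter is None:
        delimiter = "," if str(path).lower().endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if not genes_in_rows:
        raw = raw.T
    try:
        values = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {cell!r} at row {i + 1} "
                        f"(gene {raw.index[i]!r}), column {j + 1} ({col!r})"
                    ) from None
        raise
    if sample_sheet is not None:
        meta = read_sample_sheet(sample_sheet).reindex(values.columns)
    else:
        meta = _meta_from_ids(list(values.columns))
    return ExpressionMatrix(values, meta)


def filter_genes(
    x: ExpressionMatrix,
    min_value: float = 1.0,
    min_fraction: float = 0.5,
    min_mad: float = 0.0,
) -> tuple[ExpressionMatrix, FilterRecord]:
    """Drop low-quality genes before network construction.

    A gene is kept when its abundance is ≥ ``min_value`` in at least
    ``min_fraction`` of the samples *and* its median absolute deviation
    across samples exceeds ``min_mad``.  Gene order is preserved.  Returns
    the filtered matrix together with a :class:`FilterRecord` of counts.
    """
    if min(min_value, min_fraction, min_mad) < 0:
        raise ValueError("filter thresholds must be nonnegative")
    v = x.values.to_numpy(dtype=float)
    frac_expressed = (v >= min_value).mean(axis=1)
    mad = median_abs_deviation(v, axis=1)
    keep = (frac_expressed >= min_fraction) & (mad > min_mad)
    record = FilterRecord(
        n_input=len(keep),
        n_kept=int(keep.sum()),
        n_dropped=int((~keep).sum()),
        min_value=min_value,
        min_fraction=min_fraction,
        min_mad=min_mad,
    )
    if record.n_kept == 0:
        raise ValueError(
            "gene filter removed every gene; relax min_value/min_fraction/min_mad"
        )
    return ExpressionMatrix(x.values.loc[keep], x.sample_meta.copy()), record


def log_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Return log2(value + 1); sample metadata is unchanged."""
    v = x.values.to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("log_transform requires nonnegative values")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(v + 1.0), index=x.values.index, columns=x.values.columns),
        x.sample_meta.copy(),
    )


def read_gmt(path: str | os.PathLike, namespace: str = "BP") -> AnnotationSet:
    """Read a GMT file: ``term_id TAB description TAB gene TAB gene ...``.

    Duplicate genes within a term are collapsed (set semantics); every
    term is tagged with *namespace* (BP, CC, MF or pathway).
    """
    terms: dict[str, Term] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno}: expected "
                    f"term, description and ≥1 gene, got {len(parts)} field(s)"
                )
            tid, desc = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"{path}: malformed GMT line {lineno}: no genes")
            if tid in terms:
                raise ValueError(f"{path}: duplicate term id {tid!r} at line {lineno}")
            terms[tid] = Term(tid, desc, namespace, genes)
    return AnnotationSet(terms)


def write_results(
    partition,
    eigengenes,
    stats: pd.DataFrame | None,
    hubs,
    enrichment: pd.DataFrame | None,
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write the pipeline result tables as TSV with deterministic row order.

    Layouts mirror the conventional supplementary-table shapes: per-gene
    module assignment, sample × module eigengene matrix, per-gene
    connectivity/kME/p table, hub list, and the enrichment table.  Genes are
    ordered lexicographically, modules by descending size.  Returns a map of
    logical name → written path.
    """
    out_dir = str(out_dir)
    try:
        os.makedirs(out_dir, exist_ok=True)
        probe = os.path.join(out_dir, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as e:
        raise OSError(f"output directory {out_dir!r} is not writable: {e}") from e

    written: dict[str, str] = {}

    if partition is not None:
        rows = sorted(partition.assignment.items())
        df = pd.DataFrame(rows, columns=["gene_id", "module"])
        df["color"] = [partition.colors.get(m, m) for m in df["module"]]
        p = os.path.join(out_dir, "module_assignment.tsv")
        df.to_csv(p, sep="\t", index=False)
        written["module_assignment"] = p

    if eigengenes is not None:
        p = os.path.join(out_dir, "module_eigengenes.tsv")
        eigengenes.values.to_csv(p, sep="\t", index_label="sample_id", float_format="%.15g")
        written["module_eigengenes"] = p

    if stats is not None:
        p = os.path.join(out_dir, "gene_stats.tsv")
        stats.sort_index().to_csv(p, sep="\t", index_label="gene_id", float_format="%.17g")
        written["gene_stats"] = p

    if hubs is not None:
        p = os.path.join(out_dir, "hubs.tsv")
        with open(p, "w") as fh:
            fh.write("gene_id\tmodule\tin_k_set\tin_kme_set\n")
            for g in sorted(hubs.set_k | hubs.set_kme):
                fh.write(
                    f"{g}\t{hubs.module}\t{int(g in hubs.set_k)}\t{int(g in hubs.set_kme)}\n"
                )
        written["hubs"] = p

    if enrichment is not None:
        p = os.path.join(out_dir, "enrichment.tsv")
        enrichment.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written["enrichment"] = p

    return written
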