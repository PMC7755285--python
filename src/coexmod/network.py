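"""Weighted co-expression network construction.

Pearson correlation → soft-threshold adjacency (|r|^β unsigned, or
((1+r)/2)^β signed) → whole-network connectivity, scale-free topology fit,
automatic power selection, and the topological overlap matrix (TOM):

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),   l_ij = Σ_u a_iu a_uj

Correlation and the l_ij product are computed in gene blocks so that large
networks (~20k genes) stay within a few GiB of memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "TOMMatrix",
    "ScaleFreeFit",
    "correlation_matrix",
    "soft_adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom_similarity",
]

DEFAULT_BLOCK_SIZE = 2000


@dataclass
class _GeneSquare:
    gene_ids: list[str]
    values: np.ndarray  # genes × genes, symmetric, unit diagonal

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with gene id list")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


class CorrelationMatrix(_GeneSquare):
    pass


@dataclass
class AdjacencyMatrix(_GeneSquare):
    power: int = 1
    network_type: str = "unsigned"


class TOMMatrix(_GeneSquare):
    pass


@dataclass(frozen=True)
class ScaleFreeFit:
    """Goodness of the scale-free topology fit at one soft power."""

    power: int
    r_squared: float
    slope: float
    mean_connectivity: float


def correlation_matrix(x: ExpressionMatrix, block_size: int = DEFAULT_BLOCK_SIZE) -> CorrelationMatrix:
    """Exact Pearson correlation between all gene pairs across samples."""
    v = x.values.to_numpy(dtype=float)
    n_genes, n_samples = v.shape
    if n_samples < 3:
        raise ValueError("correlation needs ≥ 3 samples")
    sd = v.std(axis=1)
    bad = np.where(sd == 0)[0]
    if len(bad):
        raise ValueError(
            f"zero-variance gene {x.gene_ids[bad[0]]!r}; run filter_genes first"
        )
    z = (v - v.mean(axis=1, keepdims=True)) / (sd[:, None] * np.sqrt(n_samples))
    out = np.empty((n_genes, n_genes))
    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        out[start:stop] = z[start:stop] @ z.T
    np.clip(out, -1.0, 1.0, out=out)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return CorrelationMatrix(x.gene_ids, out)


def soft_adjacency(c: CorrelationMatrix, power: int, network_type: str = "unsigned") -> AdjacencyMatrix:
    """Raise similarity to the soft-threshold power β; diagonal forced to 1."""
    if power < 1:
        raise ValueError(f"soft power must be ≥ 1, got {power}")
    if network_type == "unsigned":
        a = np.abs(c.values) ** power
    elif network_type == "signed":
        a = ((1.0 + c.values) / 2.0) ** power
    else:
        raise ValueError(f"network_type must be 'unsigned' or 'signed', got {network_type!r}")
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(c.gene_ids, a, power=power, network_type=network_type)


def connectivity(a: AdjacencyMatrix) -> pd.Series:
    """Whole-network connectivity k_i = Σ_{j≠i} a_ij (diagonal excluded)."""
    k = a.values.sum(axis=1) - np.diag(a.values)
    return pd.Series(k, index=a.gene_ids, name="connectivity")


def scale_free_fit(k: np.ndarray | pd.Series, power: int = 0, n_bins: int = 10) -> ScaleFreeFit:
    """Fit log10(freq) ~ log10(k) over equal-width connectivity bins.

    R² is the coefficient of determination of the regression over nonempty
    bins; a scale-free degree distribution gives a straight line with
    negative slope.
    """
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    if edges[0] == edges[-1]:
        raise ValueError("connectivity is constant; scale-free fit undefined")
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    nonempty = counts > 0
    if nonempty.sum() < 2:
        raise ValueError("fewer than 2 nonempty connectivity bins")
    bin_mean_k = np.array([k[idx == b].mean() for b in range(n_bins) if nonempty[b]])
    freq = counts[nonempty] / counts.sum()
    if np.any(bin_mean_k <= 0):
        # guard log of zero-connectivity bin
        keep = bin_mean_k > 0
        if keep.sum() < 2:
            raise ValueError("fewer than 2 usable bins with positive connectivity")
        bin_mean_k, freq = bin_mean_k[keep], freq[keep]
    lx, ly = np.log10(bin_mean_k), np.log10(freq)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ScaleFreeFit(
        power=power,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        slope=float(slope),
        mean_connectivity=float(k.mean()),
    )


def pick_soft_threshold(
    x: ExpressionMatrix,
    candidate_powers: list[int] | None = None,
    r2_cut: float = 0.8,
    network_type: str = "unsigned",
    n_bins: int = 10,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> tuple[int, pd.DataFrame]:
    """Sweep candidate powers and pick the soft threshold.

    Returns the smallest power whose scale-free R² (with negative slope)
    exceeds ``r2_cut``.  If none qualifies, falls back to the first plateau
    power (R² gain over the previous power < 0.01) and flags it in the
    returned table (column ``plateau_fallback``).

    Powers that shrink the network below the connectedness floor
    (mean connectivity < ln(n genes)) are ineligible for automatic
    selection: a nearly edgeless adjacency produces artifactually
    scale-free-looking degree histograms while being useless for module
    detection.  The full fit table reports them with ``eligible=False``.
    """
    if candidate_powers is None:
        candidate_powers = list(range(1, 21))
    if not candidate_powers:
        raise ValueError("candidate_powers is empty")
    c = correlation_matrix(x, block_size=block_size)
    rows = []
    for p in candidate_powers:
        a = soft_adjacency(c, p, network_type)
        k = connectivity(a).to_numpy()
        try:
            fit = scale_free_fit(k, power=p, n_bins=n_bins)
        except ValueError:
            fit = ScaleFreeFit(p, np.nan, np.nan, float(k.mean()))
        rows.append(fit)
    table = pd.DataFrame(
        {
            "power": [f.power for f in rows],
            "r_squared": [f.r_squared for f in rows],
            "slope": [f.slope for f in rows],
            "mean_connectivity": [f.mean_connectivity for f in rows],
        }
    )
    table["plateau_fallback"] = False
    n_genes = len(c.gene_ids)
    table["eligible"] = table["mean_connectivity"] >= np.log(n_genes)
    if not table["eligible"].any():
        table["eligible"] = True
    ok = table["eligible"] & (table["r_squared"] > r2_cut) & (table["slope"] < 0)
    if ok.any():
        chosen = int(table.loc[ok, "power"].iloc[0])
        return chosen, table
    gain = table["r_squared"].diff()
    plateau = table["eligible"] & (gain < 0.01) & (table["slope"] < 0)
    if plateau.any():
        pos = int(plateau.idxmax())
    else:
        pos = int(table.index[table["eligible"]][-1])
    table.loc[pos, "plateau_fallback"] = True
    return int(table.loc[pos, "power"]), table


def tom_similarity(a: AdjacencyMatrix, block_size: int = DEFAULT_BLOCK_SIZE) -> TOMMatrix:
    """Topological overlap of an adjacency matrix (unit diagonal)."""
    a0 = a.values.copy()
    np.fill_diagonal(a0, 0.0)
    n = a0.shape[0]
    k = a0.sum(axis=1)
    tom = np.empty_like(a0)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = a0[start:stop]
        l_block = block @ a0  # l_ij including u = i or j terms, which are 0
        denom = np.minimum(k[start:stop, None], k[None, :]) + 1.0 - block
        tom[start:stop] = (l_block + block) / denom
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    return TOMMatrix(a.gene_ids, tom)
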