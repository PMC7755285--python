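"""Synthetic expression data with planted co-expression modules.

Emulates a staged developmental RNA-seq design — by default 7 ordered
gestational stages × 3 replicates, mirroring fetal skin sampling at
45–135 days — with a known module structure so that every downstream stage
(network, module detection, hub screening, enrichment intersection) can be
tested quantitatively against ground truth.

Each module m has a smooth stage-indexed profile; module gene g with drawn
membership r_g is generated on a latent (log-like) scale as

    latent_g = r_g · profile_m + sqrt(1 − r_g²) · ε,   ε ~ N(0, 1) iid,

so the population correlation between gene and profile equals r_g exactly.
Background genes are pure noise.  The latent scale is mapped to a
nonnegative FPKM-like scale by ``2**(loc + scale·latent) − 1`` (clipped at
zero), chosen so that the pipeline's default ``log2(x+1)`` transform is an
approximate inverse.

The designated target module's profile increases strictly over stages, so
its two largest stage means fall in the last two stages — the late-peaking
("mature-stage") module that target-module selection must recover.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "simulate_profiles",
    "simulate_expression",
    "write_fixture_bundle",
]

# Gestational sampling days of the emulated 7-stage design.
DEFAULT_STAGE_DAYS = (45, 55, 65, 75, 95, 115, 135)

# FPKM mapping: fpkm = 2**(_FPKM_LOC + _FPKM_SCALE * latent) - 1.  loc = 4
# keeps the latent N(0,1) range almost entirely above zero after exp2.
_FPKM_LOC = 4.0
_FPKM_SCALE = 1.0


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic dataset; generation is a pure function
    of this object (the seed is part of it)."""

    n_stages: int = 7
    n_reps: int = 3
    module_sizes: tuple[int, ...] = (200, 200, 200, 200, 200)
    kme_range: tuple[float, float] = (0.6, 0.95)
    n_background: int = 500
    target_module_index: int = 0
    noise_sd: float = 0.15  # replicate jitter on the shared profiles
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_stages < 1 or self.n_reps < 1:
            raise ValueError("n_stages and n_reps must be ≥ 1")
        if not self.module_sizes or min(self.module_sizes) < 1:
            raise ValueError("module sizes must all be ≥ 1")
        lo, hi = self.kme_range
        if not (0 < lo <= hi < 1):
            raise ValueError("kme_range must satisfy 0 < low ≤ high < 1")
        if not (0 <= self.target_module_index < len(self.module_sizes)):
            raise ValueError("target_module_index out of range")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return self.n_stages * self.n_reps

    def stage_days(self) -> list[int]:
        if self.n_stages == len(DEFAULT_STAGE_DAYS):
            return list(DEFAULT_STAGE_DAYS)
        return [45 + 15 * i for i in range(self.n_stages)]

    def sample_ids(self) -> list[str]:
        return [
            f"d{day}_r{r + 1}"
            for day in self.stage_days()
            for r in range(self.n_reps)
        ]


@dataclass
class GroundTruth:
    """Planted structure of one generated dataset.

    ``table`` has one row per gene: ``module`` (0-based module index, −1 for
    background), ``kme_param`` (the drawn mixture weight r_g) and
    ``true_kme`` (the realized latent-scale correlation between the gene and
    its module profile in this particular dataset — the operative ground
    truth for hub recovery; NaN for background genes).
    """

    table: pd.DataFrame
    true_profiles: pd.DataFrame  # stages × modules (stage-level shapes)
    target_module_index: int

    def module_genes(self, module: int) -> list[str]:
        return list(self.table.index[self.table["module"] == module])

    def hub_genes(self, module: int, kme_min: float = 0.9) -> list[str]:
        t = self.table
        mask = (t["module"] == module) & (t["true_kme"] >= kme_min)
        return list(t.index[mask])


def _stage_shapes(n_stages: int, n_modules: int, target: int) -> np.ndarray:
    """Mutually near-orthogonal smooth shapes over stage index.

    Columns of a QR-orthogonalized polynomial basis (degrees 1..n_modules) —
    discrete orthogonal polynomials, hence pairwise uncorrelated over the
    stage grid.  The linear (strictly increasing) shape goes to the target
    module.
    """
    if n_stages < 2:
        raise ValueError("profiles need ≥ 2 stages (one stage has zero variance)")
    if n_modules > n_stages - 1:
        raise ValueError(
            f"at most {n_stages - 1} mutually orthogonal module profiles exist "
            f"for {n_stages} stages; got {n_modules} modules"
        )
    t = np.linspace(-1.0, 1.0, n_stages)
    vander = np.column_stack([t**d for d in range(1, n_modules + 1)])
    vander -= vander.mean(axis=0)
    q, _ = np.linalg.qr(vander)
    # orient each shape so its last-stage value is positive; the first
    # (linear) column is then strictly increasing
    q *= np.where(q[-1] > 0, 1.0, -1.0)
    others = [j for j in range(n_modules) if j != 0]
    cols = []
    k = 0
    for m in range(n_modules):
        if m == target:
            cols.append(0)
        else:
            cols.append(others[k])
            k += 1
    return q[:, cols]


def simulate_profiles(design: SyntheticDesign, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Samples × modules matrix of shared module profiles.

    Stage shapes are replicated within stage with N(0, noise_sd) replicate
    jitter, then standardized to zero mean, unit variance across samples.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    shapes = _stage_shapes(design.n_stages, design.n_modules, design.target_module_index)
    per_sample = np.repeat(shapes, design.n_reps, axis=0)
    per_sample = per_sample + rng.normal(0.0, design.noise_sd, size=per_sample.shape)
    per_sample -= per_sample.mean(axis=0)
    sd = per_sample.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate profile with zero variance")
    per_sample /= sd
    return pd.DataFrame(
        per_sample,
        index=pd.Index(design.sample_ids(), name="sample_id"),
        columns=[f"module_{m}" for m in range(design.n_modules)],
    )


def _gene_ids(design: SyntheticDesign) -> tuple[list[str], np.ndarray]:
    ids, labels = [], []
    for m, size in enumerate(design.module_sizes):
        for i in range(size):
            ids.append(f"M{m}_G{i:04d}")
            labels.append(m)
    for i in range(design.n_background):
        ids.append(f"BG_G{i:04d}")
        labels.append(-1)
    return ids, np.asarray(labels)


def simulate_expression(design: SyntheticDesign) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate one dataset plus its ground truth (pure function of design)."""
    rng = np.random.default_rng(design.seed)
    profiles = simulate_profiles(design, rng)
    prof = profiles.to_numpy()
    n_samples = design.n_samples
    gene_ids, labels = _gene_ids(design)
    n_genes = len(gene_ids)

    lo, hi = design.kme_range
    kme_param = np.full(n_genes, np.nan)
    module_mask = labels >= 0
    kme_param[module_mask] = rng.uniform(lo, hi, size=module_mask.sum())

    latent = np.empty((n_genes, n_samples))
    eps = rng.standard_normal((n_genes, n_samples))
    for g in range(n_genes):
        m = labels[g]
        if m < 0:
            latent[g] = eps[g]
        else:
            r = kme_param[g]
            latent[g] = r * prof[:, m] + np.sqrt(1.0 - r * r) * eps[g]

    # realized latent-scale correlation with the own-module profile
    true_kme = np.full(n_genes, np.nan)
    zprof = (prof - prof.mean(axis=0)) / prof.std(axis=0)
    for m in range(design.n_modules):
        rows = np.where(labels == m)[0]
        z = latent[rows] - latent[rows].mean(axis=1, keepdims=True)
        z /= z.std(axis=1, keepdims=True)
        true_kme[rows] = z @ zprof[:, m] / n_samples

    fpkm = np.maximum(np.exp2(_FPKM_LOC + _FPKM_SCALE * latent) - 1.0, 0.0)
    values = pd.DataFrame(
        fpkm, index=pd.Index(gene_ids, name="gene_id"), columns=design.sample_ids()
    )
    meta = pd.DataFrame(
        {
            "stage_day": np.repeat(design.stage_days(), design.n_reps),
            "replicate": list(range(1, design.n_reps + 1)) * design.n_stages,
        },
        index=pd.Index(design.sample_ids(), name="sample_id"),
    )
    truth = GroundTruth(
        table=pd.DataFrame(
            {"module": labels, "kme_param": kme_param, "true_kme": true_kme},
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        true_profiles=pd.DataFrame(
            _stage_shapes(design.n_stages, design.n_modules, design.target_module_index),
            index=pd.Index(design.stage_days(), name="stage_day"),
            columns=[f"module_{m}" for m in range(design.n_modules)],
        ),
        target_module_index=design.target_module_index,
    )
    return ExpressionMatrix(values, meta), truth


def _write_gmt(path: str, terms: list[tuple[str, str, list[str]]]) -> None:
    with open(path, "w") as fh:
        for tid, desc, genes in terms:
            fh.write("\t".join([tid, desc, *genes]) + "\n")


def write_fixture_bundle(design: SyntheticDesign, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a complete text fixture: expression TSV, sample sheet, ground
    truth, and synthetic annotation GMTs.

    ``modules.gmt`` holds one term per planted module containing that
    module's hub genes (true_kme ≥ 0.9).  ``go_terms.gmt`` (3 terms) and
    ``pathways.gmt`` (3 terms) partition the *target* module's hubs so that
    exactly one gene — the highest-kME hub — belongs to every term, giving
    the enrichment-intersection stage a known unique nominee.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    x, truth = simulate_expression(design)

    paths = {
        "expression": os.path.join(out_dir, "expression.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "ground_truth": os.path.join(out_dir, "ground_truth.tsv"),
        "modules_gmt": os.path.join(out_dir, "modules.gmt"),
        "go_gmt": os.path.join(out_dir, "go_terms.gmt"),
        "pathway_gmt": os.path.join(out_dir, "pathways.gmt"),
    }
    x.to_tsv(paths["expression"])
    x.sample_meta.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    truth.table.to_csv(paths["ground_truth"], sep="\t", index_label="gene_id", float_format="%.15g")

    module_terms = []
    for m in range(design.n_modules):
        hubs = truth.hub_genes(m)
        if not hubs:  # degenerate designs: fall back to the top-kME gene
            t = truth.table[truth.table["module"] == m]
            hubs = [t["true_kme"].idxmax()]
        module_terms.append((f"MOD{m}", f"planted module {m} hub genes", sorted(hubs)))
    _write_gmt(paths["modules_gmt"], module_terms)

    tm = truth.target_module_index
    target_hubs = truth.hub_genes(tm)
    if not target_hubs:
        t = truth.table[truth.table["module"] == tm]
        target_hubs = [t["true_kme"].idxmax()]
    nominee = truth.table.loc[target_hubs, "true_kme"].idxmax()
    rest = sorted(g for g in target_hubs if g != nominee)

    def split_terms(prefix: str, desc: str) -> list[tuple[str, str, list[str]]]:
        # three disjoint slices of the non-nominee hubs; nominee in all three
        terms = []
        for i in range(3):
            members = [nominee] + rest[i::3]
            terms.append((f"{prefix}{i}", f"{desc} {i}", members))
        return terms

    _write_gmt(paths["go_gmt"], split_terms("GO_TARGET", "synthetic GO term"))
    _write_gmt(paths["pathway_gmt"], split_terms("PATHWAY", "synthetic pathway"))
    return paths
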