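"""Target-module selection, kME statistics and dual-threshold hub screening.

The target module is the one whose eigengene is on average highest over a
designated sample set (here: the late, mature developmental stages).  For
every gene, module membership kME is the Pearson correlation with each
module eigengene; its two-sided p-value comes from the exact Student-t
transform t = r·sqrt(n−2)/sqrt(1−r²) with n−2 degrees of freedom.  Hubs are
the intersection of a connectivity cut (k ≥ k_min) and a membership cut
(kME ≥ kme_min) inside the target module; both thresholds are inclusive and
kME is used signed, so only genes positively associated with the module
eigengene qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import ExpressionMatrix
from .modules import ModuleEigengenes

__all__ = [
    "GeneModuleStats",
    "HubScreenResult",
    "select_target_module",
    "kme_with_p",
    "screen_hubs",
    "spearman_concordance",
    "SPEARMAN_BANDS",
]

SPEARMAN_BANDS = (
    (0.8, "extremely strong"),
    (0.6, "strong"),
    (0.4, "medium"),
    (0.2, "weak"),
    (0.0, "none"),
)


@dataclass
class GeneModuleStats:
    """Per-gene network statistics.

    ``kme``/``p_value`` are genes × modules frames; ``connectivity`` is the
    whole-network connectivity k_i and ``module`` the assigned label (both
    optional until the pipeline attaches them).
    """

    kme: pd.DataFrame
    p_value: pd.DataFrame
    connectivity: pd.Series | None = None
    module: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.kme.index)
        if self.module is not None:
            out["module"] = self.module
        if self.connectivity is not None:
            out["connectivity"] = self.connectivity
        for m in self.kme.columns:
            out[f"kME_{m}"] = self.kme[m]
            out[f"p_{m}"] = self.p_value[m]
        return out


@dataclass
class HubScreenResult:
    module: str
    k_threshold: float
    kme_threshold: float
    set_k: set[str] = field(default_factory=set)
    set_kme: set[str] = field(default_factory=set)

    @property
    def hubs(self) -> set[str]:
        return self.set_k & self.set_kme

    def venn_counts(self) -> dict[str, int]:
        both = len(self.hubs)
        return {
            "k_only": len(self.set_k) - both,
            "kme_only": len(self.set_kme) - both,
            "both": both,
        }


def select_target_module(
    me: ModuleEigengenes, target_samples: set[str] | list[str]
) -> tuple[str, pd.DataFrame]:
    """Module whose eigengene has the highest mean over the target samples.

    Returns the winning label together with the full ranking table
    (module, mean eigengene over targets), highest first.
    """
    targets = list(target_samples)
    if not targets:
        raise ValueError("target_samples is empty")
    unknown = set(targets) - set(me.sample_ids)
    if unknown:
        raise ValueError(f"unknown sample id(s): {sorted(unknown)}")
    means = me.values.loc[targets].mean(axis=0).sort_values(ascending=False)
    table = means.rename("mean_me_on_targets").to_frame()
    table.index.name = "module"
    return str(means.index[0]), table.reset_index()


def kme_with_p(x: ExpressionMatrix, me: ModuleEigengenes) -> GeneModuleStats:
    """kME (gene–eigengene Pearson r) and its two-sided Student-t p-value."""
    n = len(x.sample_ids)
    if n < 3:
        raise ValueError("kME p-values need ≥ 3 samples")
    v = x.values.to_numpy(dtype=float)
    sd = v.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene; filter first")
    zg = (v - v.mean(axis=1, keepdims=True)) / (sd[:, None] * np.sqrt(n))
    e = me.values.to_numpy(dtype=float)
    ze = (e - e.mean(axis=0)) / (e.std(axis=0) * np.sqrt(n))
    r = np.clip(zg @ ze, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), df=n - 2))
    idx = pd.Index(x.gene_ids, name="gene_id")
    cols = me.module_labels
    return GeneModuleStats(
        kme=pd.DataFrame(r, index=idx, columns=cols),
        p_value=pd.DataFrame(p, index=idx, columns=cols),
    )


def screen_hubs(
    stats: GeneModuleStats,
    module: str,
    k_min: float = 900.0,
    kme_min: float = 0.9,
    k_quantile: float | None = None,
) -> HubScreenResult:
    """Dual-threshold hub screen inside one module.

    ``set_k``: module genes with whole-network connectivity ≥ ``k_min``;
    ``set_kme``: module genes with kME to the module eigengene ≥ ``kme_min``
    (signed).  Hubs are the intersection.  When ``k_quantile`` is given,
    ``k_min`` is replaced by that quantile of the module's own connectivity
    distribution (useful when the absolute scale of k differs from the
    network the default was calibrated on).
    """
    if module not in stats.kme.columns:
        raise ValueError(f"unknown module {module!r}")
    if stats.connectivity is None or stats.module is None:
        raise ValueError("stats must carry connectivity and module assignment")
    in_module = stats.module[stats.module == module].index
    k = stats.connectivity.loc[in_module]
    if k_quantile is not None:
        k_min = float(np.quantile(k.to_numpy(), k_quantile))
    kme = stats.kme.loc[in_module, module]
    return HubScreenResult(
        module=module,
        k_threshold=float(k_min),
        kme_threshold=float(kme_min),
        set_k=set(k.index[k >= k_min]),
        set_kme=set(kme.index[kme >= kme_min]),
    )


def spearman_concordance(series_a, series_b) -> tuple[float, str]:
    """Spearman rank correlation (average ranks for ties) plus the
    qualitative band of |Rs|: >0.8 extremely strong, >0.6 strong,
    >0.4 medium, >0.2 weak, otherwise none."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-d series of length ≥ 3")
    rho = float(sps.spearmanr(a, b).statistic)
    mag = abs(rho)
    band = "none"
    for cut, name in SPEARMAN_BANDS:
        if mag > cut or (cut == 0.0 and mag >= 0.0):
            band = name
            break
    return rho, band
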