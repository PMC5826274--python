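"""Permutation module-preservation statistics between two expression datasets.

Given a reference partition (e.g. juvenile Area X modules) and a test
dataset (the adjacent striatopallidum, or adult tissue), each module is
scored by how well its coexpression survives in the test data:

* density statistics (computed in the test data): mean within-module
  adjacency, module-eigengene variance explained, mean kME;
* connectivity statistics (computed across the two datasets): correlation
  of within-module kIN, of kME, and of the vectorized within-module
  correlation matrices.

The null emulates a permutation of module labels in the test data: the
reference-side module is held fixed while the test-side gene set is
replaced by a random same-size set drawn (without replacement) from the
genes common to both datasets.  Per statistic
Z = (observed - null mean) / null SD; Zdensity and
Zconnectivity are the medians of their statistic groups, and

    Zsummary = (Zdensity + Zconnectivity) / 2.

By the usual convention Zsummary < 2 is no evidence of preservation and
Zsummary > 10 is strong preservation; both thresholds are conventions, not
estimates.  ``median_rank`` complements Zsummary with a size-insensitive
ordering of modules by observed preservation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import pick_soft_threshold
from .synthdata import GREY

__all__ = [
    "CommonGeneView",
    "intersect_networks",
    "module_preservation",
    "ModulePreservation",
    "PreservationResults",
    "LOW_PRESERVATION_Z",
    "HIGH_PRESERVATION_Z",
]

LOW_PRESERVATION_Z = 2.0
HIGH_PRESERVATION_Z = 10.0

DENSITY_STATS = ("mean_adjacency", "var_explained", "mean_kme")
CONNECTIVITY_STATS = ("cor_kin", "cor_kme", "cor_cor")


@dataclass
class CommonGeneView:
    """Sorted intersection of two datasets' gene sets with index maps."""

    genes: pd.Index
    idx_ref: np.ndarray
    idx_test: np.ndarray
    n_dropped_ref: int
    n_dropped_test: int


def intersect_networks(expr_ref: pd.DataFrame, expr_test: pd.DataFrame) -> CommonGeneView:
    """Deterministic sorted gene intersection between two expression matrices."""
    common = expr_ref.index.intersection(expr_test.index).sort_values()
    if len(common) == 0:
        raise ValueError("no genes shared between the two datasets")
    return CommonGeneView(
        genes=common,
        idx_ref=expr_ref.index.get_indexer(common),
        idx_test=expr_test.index.get_indexer(common),
        n_dropped_ref=expr_ref.shape[0] - len(common),
        n_dropped_test=expr_test.shape[0] - len(common),
    )


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=1)
    sd[sd == 0] = np.nan
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def _me(z_block: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigengene (first right singular vector) of a standardized gene block
    and the proportion of variance it explains."""
    _, s, vt = np.linalg.svd(z_block, full_matrices=False)
    me = vt[0]
    if np.dot(me, z_block.mean(axis=0)) < 0:
        me = -me
    return me, float(s[0] ** 2 / np.sum(s**2))


def _cor(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _ref_side(
    idx: np.ndarray, corr_ref: np.ndarray, z_ref: np.ndarray, beta_ref: float
) -> dict[str, np.ndarray]:
    """Reference-dataset quantities of the (fixed) module gene set."""
    c_r = corr_ref[np.ix_(idx, idx)]
    a_r = ((1.0 + c_r) / 2.0) ** beta_ref
    me_r, _ = _me(z_ref[idx])
    kme_r = (z_ref[idx] @ me_r) / (
        np.linalg.norm(z_ref[idx], axis=1) * np.linalg.norm(me_r)
    )
    iu = np.triu_indices(idx.size, k=1)
    return {
        "kin": a_r.sum(axis=1) - np.diag(a_r),
        "kme": kme_r,
        "corvec": c_r[iu],
    }


def _test_side_stats(
    idx: np.ndarray,
    ref: dict[str, np.ndarray],
    corr_test: np.ndarray,
    z_test: np.ndarray,
    beta_test: float,
) -> dict[str, float]:
    """All six statistics pairing the fixed reference-side module with a
    test-side gene set (the true module for the observed value; a random
    same-size set, emulating a test-label permutation, for the null)."""
    c_t = corr_test[np.ix_(idx, idx)]
    a_t = ((1.0 + c_t) / 2.0) ** beta_test
    n = idx.size
    off = ~np.eye(n, dtype=bool)
    me_t, ve_t = _me(z_test[idx])
    kme_t = (z_test[idx] @ me_t) / (
        np.linalg.norm(z_test[idx], axis=1) * np.linalg.norm(me_t)
    )
    kin_t = a_t.sum(axis=1) - np.diag(a_t)
    iu = np.triu_indices(n, k=1)
    return {
        "mean_adjacency": float(a_t[off].mean()),
        "var_explained": ve_t,
        "mean_kme": float(kme_t.mean()),
        "cor_kin": _cor(ref["kin"], kin_t),
        "cor_kme": _cor(ref["kme"], kme_t),
        "cor_cor": _cor(ref["corvec"], c_t[iu]),
    }


def module_preservation(
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    labels_ref: pd.Series,
    beta_test: float | str = "auto",
    beta_ref: float | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation Zdensity/Zconnectivity/Zsummary per reference module.

    Statistics are computed only over genes present in both datasets; the
    null draws ``n_perm`` same-size random gene sets from that common
    universe.  ``beta_test`` "auto" selects the test dataset's own soft
    threshold by scale-free fit.
    """
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    view = intersect_networks(expr_ref, expr_test)
    genes = view.genes
    xr = expr_ref.loc[genes].to_numpy(dtype=float)
    xt = expr_test.loc[genes].to_numpy(dtype=float)
    z_ref = _standardize_rows(xr)
    z_test = _standardize_rows(xt)
    ok = ~np.isnan(z_ref).any(axis=1) & ~np.isnan(z_test).any(axis=1)
    genes, z_ref, z_test = genes[ok], z_ref[ok], z_test[ok]

    if beta_test == "auto":
        scan = pick_soft_threshold(expr_test.loc[genes])
        beta_test = scan.selected if scan.selected is not None else 12.0
    beta_test = float(beta_test)
    beta_ref = beta_test if beta_ref is None else float(beta_ref)

    ns = z_ref.shape[1]
    corr_ref = (z_ref @ z_ref.T) / (ns - 1)
    nt = z_test.shape[1]
    corr_test = (z_test @ z_test.T) / (nt - 1)
    np.clip(corr_ref, -1, 1, out=corr_ref)
    np.clip(corr_test, -1, 1, out=corr_test)

    lab = labels_ref.reindex(genes)
    modules = [m for m in lab.dropna().unique() if m != GREY]
    rng = np.random.default_rng(seed)
    n_genes = len(genes)
    all_stats = DENSITY_STATS + CONNECTIVITY_STATS

    rows = []
    for m in sorted(modules):
        idx = np.flatnonzero((lab == m).to_numpy())
        if idx.size < 3:
            warnings.warn(f"module {m!r} has fewer than 3 common genes; skipped")
            continue
        ref = _ref_side(idx, corr_ref, z_ref, beta_ref)
        obs = _test_side_stats(idx, ref, corr_test, z_test, beta_test)
        null = {s: np.empty(n_perm) for s in all_stats}
        for p in range(n_perm):
            ridx = rng.choice(n_genes, idx.size, replace=False)
            st = _test_side_stats(ridx, ref, corr_test, z_test, beta_test)
            for s in all_stats:
                null[s][p] = st[s]
        row = {"module": m, "size": int(idx.size)}
        zs = {}
        degenerate = []
        for s in all_stats:
            mu = float(np.nanmean(null[s]))
            sd = float(np.nanstd(null[s], ddof=1))
            row[f"obs_{s}"] = obs[s]
            if sd == 0 or np.isnan(sd) or np.isnan(obs[s]):
                zs[s] = 0.0
                degenerate.append(s)
            else:
                zs[s] = (obs[s] - mu) / sd
            row[f"z_{s}"] = zs[s]
        row["Zdensity"] = float(np.median([zs[s] for s in DENSITY_STATS]))
        row["Zconnectivity"] = float(np.median([zs[s] for s in CONNECTIVITY_STATS]))
        row["Zsummary"] = (row["Zdensity"] + row["Zconnectivity"]) / 2.0
        row["degenerate_stats"] = ",".join(degenerate)
        rows.append(row)

    table = pd.DataFrame(rows)
    if len(table):
        ranks = pd.DataFrame(
            {s: table[f"obs_{s}"].rank(ascending=False) for s in all_stats}
        )
        table["median_rank"] = ranks.median(axis=1)
        table.attrs["n_perm"] = n_perm
        table.attrs["seed"] = seed
        table.attrs["beta_test"] = beta_test
        table.attrs["beta_ref"] = beta_ref
    return table


class ModulePreservation:
    """Model object: does a reference partition persist in a test dataset?"""

    def __init__(
        self,
        expr_ref: pd.DataFrame,
        expr_test: pd.DataFrame,
        labels_ref: pd.Series,
        beta_test: float | str = "auto",
        beta_ref: float | None = None,
        n_perm: int = 200,
        seed: int = 0,
    ) -> None:
        self.expr_ref = expr_ref
        self.expr_test = expr_test
        self.labels_ref = labels_ref
        self.beta_test = beta_test
        self.beta_ref = beta_ref
        self.n_perm = n_perm
        self.seed = seed

    def fit(self) -> "PreservationResults":
        table = module_preservation(
            self.expr_ref,
            self.expr_test,
            self.labels_ref,
            beta_test=self.beta_test,
            beta_ref=self.beta_ref,
            n_perm=self.n_perm,
            seed=self.seed,
        )
        return PreservationResults(self, table)


class PreservationResults:
    """Per-module preservation Z statistics and ranks."""

    def __init__(self, model: ModulePreservation, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def zsummary(self) -> pd.Series:
        return self.table.set_index("module")["Zsummary"]

    def preserved(self, threshold: float = HIGH_PRESERVATION_Z) -> list[str]:
        return self.table.loc[self.table["Zsummary"] > threshold, "module"].tolist()

    def not_preserved(self, threshold: float = LOW_PRESERVATION_Z) -> list[str]:
        return self.table.loc[self.table["Zsummary"] < threshold, "module"].tolist()

    def summary(self) -> pd.DataFrame:
        cols = ["module", "size", "Zdensity", "Zconnectivity", "Zsummary", "median_rank"]
        return self.table[cols].sort_values("Zsummary", ascending=False).reset_index(drop=True)

    def plot(self, module_trait_rho: pd.Series | None = None, ax=None):
        """Zsummary per module, optionally against a module-trait correlation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        x = (
            module_trait_rho.reindex(t["module"]).to_numpy()
            if module_trait_rho is not None
            else np.arange(len(t))
        )
        ax.scatter(x, t["Zsummary"], s=t["size"] / 2)
        for xi, yi, m in zip(x, t["Zsummary"], t["module"]):
            ax.annotate(m, (xi, yi), fontsize=7)
        ax.axhline(LOW_PRESERVATION_Z, ls="--", c="grey")
        ax.axhline(HIGH_PRESERVATION_Z, ls="--", c="grey")
        ax.set_ylabel("Zsummary")
        ax.set_xlabel("ME-trait correlation" if module_trait_rho is not None else "module")
        return ax
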