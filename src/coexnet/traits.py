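"""Behavioural metrics and gene/module-trait correlation statistics.

Four per-animal traits are used throughout: ``motifs`` (number of motifs
sung in the two hours before sacrifice), ``tutor_similarity`` (percentage
acoustic match to the tutor), ``variability_induction`` (the
(NS - UD)/(NS + UD) effect size on the Wiener-entropy coefficient of
variation), and ``motif_identity`` (similarity x accuracy / 100 of a
motif's self-comparison batch; higher means less variable song).

Module-trait association is the Pearson correlation between a module
eigengene and a trait, with two-sided p-values from the Fisher z transform
(z = atanh(rho) * sqrt(n - 3)) and Benjamini-Hochberg correction over the
full modules x traits family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "effect_size",
    "motif_identity",
    "gene_significance",
    "module_trait_correlation",
    "fdr_adjust",
    "ModuleTraitAnalysis",
    "ModuleTraitResults",
    "TRAIT_COLUMNS",
]

TRAIT_COLUMNS = ("motifs", "tutor_similarity", "variability_induction", "motif_identity")


def effect_size(ns, ud):
    """(NS - UD) / (NS + UD) contrast of a feature between non-singing and
    undirected-singing conditions.

    Negative values indicate the feature (e.g. an acoustic CV) increased
    after undirected singing.  Antisymmetric in its arguments and bounded in
    (-1, 1) for positive inputs.
    """
    ns = np.asarray(ns, dtype=float)
    ud = np.asarray(ud, dtype=float)
    denom = ns + ud
    if np.any(denom == 0):
        raise ValueError("NS + UD must be nonzero")
    out = (ns - ud) / denom
    return out.item() if out.ndim == 0 else out


def motif_identity(similarity_pct, accuracy_pct):
    """Motif self-identity: similarity% x accuracy% / 100.

    Both inputs must lie in [0, 100]; higher identity means lower vocal
    variability.
    """
    sim = np.asarray(similarity_pct, dtype=float)
    acc = np.asarray(accuracy_pct, dtype=float)
    if np.any((sim < 0) | (sim > 100)) or np.any((acc < 0) | (acc > 100)):
        raise ValueError("similarity and accuracy must lie in [0, 100]")
    out = sim * acc / 100.0
    return out.item() if out.ndim == 0 else out


def gene_significance(expr: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Signed Pearson correlation of every gene with every trait
    (pairwise-complete over samples).

    Constant traits yield NaN columns with a warning.
    """
    common = expr.columns.intersection(traits.index)
    if len(common) < 4:
        raise ValueError("need at least 4 paired samples")
    x = expr[common].to_numpy(dtype=float)
    out = {}
    for trait in traits.columns:
        t = traits.loc[common, trait].to_numpy(dtype=float)
        valid = ~np.isnan(t)
        tv = t[valid]
        if tv.size < 4 or np.std(tv) == 0:
            warnings.warn(f"trait {trait!r} is constant or too sparse; gene significance is NaN")
            out[trait] = np.full(x.shape[0], np.nan)
            continue
        xv = x[:, valid]
        mask = np.isnan(xv)
        if mask.any():
            vals = np.empty(x.shape[0])
            for i in range(x.shape[0]):
                ok = ~mask[i]
                vals[i] = (
                    np.corrcoef(xv[i, ok], tv[ok])[0, 1] if ok.sum() >= 4 else np.nan
                )
            out[trait] = vals
        else:
            xc = xv - xv.mean(axis=1, keepdims=True)
            tc = tv - tv.mean()
            denom = np.sqrt((xc**2).sum(axis=1) * (tc**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                out[trait] = (xc @ tc) / denom
    return pd.DataFrame(out, index=expr.index)


def _fisher_p(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        z = np.arctanh(rho) * np.sqrt(n - 3)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.where(np.abs(rho) >= 1.0, 0.0, p)


def _student_p(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, p)


def module_trait_correlation(
    mes: pd.DataFrame,
    traits: pd.DataFrame,
    method: str = "fisher",
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Module-eigengene vs trait Pearson correlations with p and FDR q.

    ``method`` "fisher" uses the Fisher z-transform normal approximation;
    "student" the exact-t form.  q-values are Benjamini-Hochberg over
    ``n_comparisons`` hypotheses (default: modules x traits).  Returns a
    long-format table: module, trait, rho, p, q, pass (q <= alpha).
    """
    common = mes.index.intersection(traits.index)
    n = len(common)
    if n < 4:
        raise ValueError("need at least 4 samples")
    pfun = {"fisher": _fisher_p, "student": _student_p}[method]
    rows = []
    for m in mes.columns:
        me = mes.loc[common, m].to_numpy(dtype=float)
        for trait in traits.columns:
            t = traits.loc[common, trait].to_numpy(dtype=float)
            valid = ~np.isnan(t) & ~np.isnan(me)
            if valid.sum() < 4 or np.std(t[valid]) == 0:
                rho, p = np.nan, np.nan
            else:
                rho = float(np.corrcoef(me[valid], t[valid])[0, 1])
                p = float(pfun(np.array(rho), valid.sum()))
            rows.append({"module": m, "trait": trait, "rho": rho, "p": p})
    table = pd.DataFrame(rows)
    m_total = n_comparisons if n_comparisons is not None else len(table)
    pvals = table["p"].to_numpy()
    ok = ~np.isnan(pvals)
    q = np.full_like(pvals, np.nan)
    if ok.any():
        q[ok] = fdr_adjust(pvals[ok], m=m_total)
    table["q"] = q
    table["pass"] = table["q"] <= alpha
    return table


def fdr_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment over exactly ``m`` hypotheses.

    When fewer p-values are supplied than ``m``, the family is padded with
    p = 1 (mirroring an adjustment run with the comparison count fixed at
    traits x modules); ``m`` smaller than the number supplied is an error.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError("m must be >= the number of supplied p-values")
    padded = np.concatenate([p, np.ones(m - k)])
    _, q, _, _ = multipletests(padded, method="fdr_bh")
    return q[:k]


class ModuleTraitAnalysis:
    """Model object linking module eigengenes to behavioural traits."""

    def __init__(self, mes: pd.DataFrame, traits: pd.DataFrame, alpha: float = 0.05):
        self.mes = mes
        self.traits = traits
        self.alpha = alpha

    def fit(self, method: str = "fisher") -> "ModuleTraitResults":
        table = module_trait_correlation(
            self.mes, self.traits, method=method, alpha=self.alpha
        )
        return ModuleTraitResults(self, table)


class ModuleTraitResults:
    """Long-format module x trait correlation table with pivot helpers."""

    def __init__(self, model: ModuleTraitAnalysis, table: pd.DataFrame):
        self.model = model
        self.table = table

    def pivot(self, value: str = "rho") -> pd.DataFrame:
        return self.table.pivot(index="module", columns="trait", values=value)

    def significant(self, use_fdr: bool = False) -> pd.DataFrame:
        col = "q" if use_fdr else "p"
        return self.table[self.table[col] <= self.model.alpha]

    def summary(self) -> pd.DataFrame:
        out = self.table.copy()
        out["rho"] = out["rho"].round(3)
        return out.sort_values(["trait", "p"]).reset_index(drop=True)

    def plot_heatmap(self, ax=None):
        """Module x trait correlation heatmap annotated with uncorrected p."""
        import matplotlib.pyplot as plt

        rho = self.pivot("rho")
        p = self.pivot("p")
        if ax is None:
            _, ax = plt.subplots(figsize=(1.5 * rho.shape[1] + 2, 0.4 * rho.shape[0] + 2))
        im = ax.imshow(rho.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
        ax.set_xticks(range(rho.shape[1]), rho.columns, rotation=45, ha="right")
        ax.set_yticks(range(rho.shape[0]), rho.index)
        for i in range(rho.shape[0]):
            for j in range(rho.shape[1]):
                if p.iloc[i, j] <= self.model.alpha:
                    ax.text(
                        j, i, f"{rho.iloc[i, j]:.2f}\n({p.iloc[i, j]:.3g})",
                        ha="center", va="center", fontsize=7,
                    )
        ax.figure.colorbar(im, ax=ax, label="Pearson rho")
        return ax
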