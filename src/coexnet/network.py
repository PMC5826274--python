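"""Signed weighted coexpression network construction and module detection.

The construction chain is the classical one for weighted coexpression
analysis:

1. adjacency        a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta   (signed)
2. topological overlap
                    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
                    with  l_ij = sum_{u != i,j} a_iu * a_uj
3. average-linkage hierarchical clustering on 1 - w with a dynamic-height
   tree cut (deep-split granularity knob, minimum module size, small
   branches to the reserved "grey" label)
4. module eigengenes (first principal component of the standardized module
   block) and membership (kME) pruning rules
5. iteration: grey genes are removed and the network rebuilt until no gene
   lands in grey.

Connectivity sums exclude the self-adjacency term (a_ii), which keeps the
isolated perfectly-connected pair at topological overlap exactly 1.

The model-style entry point is :class:`CoexpressionNetwork`; ``fit()``
returns a :class:`CoexpressionNetworkResults` carrying the partition,
eigengenes, connectivities, and a per-module ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .synthdata import GREY, MODULE_COLORS

__all__ = [
    "adjacency",
    "connectivity",
    "tom",
    "pick_soft_threshold",
    "cluster_and_cut",
    "module_eigengene",
    "apply_membership_rules",
    "build_network",
    "SoftThresholdScan",
    "Network",
    "ModuleSet",
    "CoexpressionNetwork",
    "CoexpressionNetworkResults",
]

DEFAULT_POWERS = tuple(range(1, 11)) + (12, 14, 16, 18, 20)


def _pearson_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlations, pairwise-complete when NaNs present."""
    x = expr.to_numpy(dtype=float)
    if np.isnan(x).any():
        return np.asarray(expr.T.corr(method="pearson"))
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = expr.index[sd == 0][:5].tolist()
        raise ValueError(f"zero-variance gene(s) reached the network stage: {bad}")
    return np.corrcoef(x)


def adjacency(
    expr: pd.DataFrame, beta: float, sign_mode: str = "signed"
) -> "Network":
    """Correlation-derived adjacency matrix at soft-threshold power ``beta``.

    signed: a = ((1 + cor) / 2) ** beta; unsigned: a = |cor| ** beta.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if expr.shape[1] < 4:
        raise ValueError("adjacency needs at least 4 samples")
    corr = _pearson_matrix(expr)
    A = _adjacency_from_corr(corr, beta, sign_mode)
    return Network(gene_ids=expr.index.copy(), adjacency=A, power=float(beta), sign_mode=sign_mode)


def _adjacency_from_corr(corr: np.ndarray, beta: float, sign_mode: str) -> np.ndarray:
    if sign_mode == "signed":
        A = ((1.0 + corr) / 2.0) ** beta
    elif sign_mode == "unsigned":
        A = np.abs(corr) ** beta
    else:
        raise ValueError(f"unknown sign_mode: {sign_mode!r}")
    A = np.clip(A, 0.0, 1.0)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A


def connectivity(
    A: np.ndarray, labels: pd.Series | None = None, gene_ids: pd.Index | None = None
) -> pd.DataFrame:
    """Whole-network (kTotal) and, given a partition, within-module (kIN)
    connectivity.  The self-term a_ii is excluded from every sum."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if gene_ids is None:
        gene_ids = labels.index if labels is not None else pd.RangeIndex(n)
    k_total = A.sum(axis=1) - np.diag(A)
    out = pd.DataFrame({"kTotal": k_total}, index=gene_ids)
    if labels is not None:
        lab = labels.reindex(gene_ids).to_numpy()
        k_in = np.zeros(n)
        for m in pd.unique(lab):
            idx = np.flatnonzero(lab == m)
            block = A[np.ix_(idx, idx)]
            k_in[idx] = block.sum(axis=1) - np.diag(block)
        out["kIN"] = k_in
    return out


def tom(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency matrix.

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), with the shared-
    neighbour sum l_ij = sum_{u != i,j} a_iu a_uj and k the self-excluded
    connectivity; the diagonal is set to 1 by convention.
    """
    A = np.asarray(A, dtype=float)
    a = A.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a  # a_ii = 0 removes the u = i and u = j terms
    num = L + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, num / denom, 0.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return w


@dataclass
class SoftThresholdScan:
    """Scale-free-fit scan over candidate soft-threshold powers."""

    table: pd.DataFrame  # power, r2_signed, slope, mean_k, median_k, max_k
    selected: float | None
    fit_cut: float
    sign_mode: str


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of log10(frequency) ~ log10(mean connectivity) over
    equal-width bins of k.  Returns (signed_r2, slope); NaNs when degenerate."""
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        return np.nan, np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size and members.mean() > 0:
            freqs.append(members.size / k.size)
            means.append(members.mean())
    if len(freqs) < 3:
        return np.nan, np.nan
    fit = linregress(np.log10(means), np.log10(freqs))
    r2 = fit.rvalue**2
    return -np.sign(fit.slope) * r2, fit.slope


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=DEFAULT_POWERS,
    fit_cut: float = 0.8,
    sign_mode: str = "signed",
) -> SoftThresholdScan:
    """Scan candidate powers and select the smallest with signed scale-free
    fit R^2 >= ``fit_cut`` (selected is None when no power qualifies)."""
    powers = list(candidate_powers)
    if len(powers) < 2:
        raise ValueError("need at least 2 candidate powers")
    corr = _pearson_matrix(expr)
    rows = []
    for beta in powers:
        A = _adjacency_from_corr(corr, beta, sign_mode)
        k = A.sum(axis=1) - 1.0
        r2, slope = scale_free_fit(k)
        rows.append(
            {
                "power": beta,
                "r2_signed": r2,
                "slope": slope,
                "mean_k": k.mean(),
                "median_k": float(np.median(k)),
                "max_k": k.max(),
            }
        )
    table = pd.DataFrame(rows)
    qualifying = table.loc[table["r2_signed"] >= fit_cut, "power"]
    selected = float(qualifying.iloc[0]) if len(qualifying) else None
    return SoftThresholdScan(table=table, selected=selected, fit_cut=fit_cut, sign_mode=sign_mode)


_N_CUT_CANDIDATES = 60


def cluster_and_cut(
    tomm: np.ndarray,
    gene_ids: pd.Index,
    min_module_size: int = 100,
    deep_split: int = 2,
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a dynamic-height cut.

    Candidate cut heights are scanned over the merge-height range; the cut
    retained is one that maximizes the number of branches reaching
    ``min_module_size``, with ``deep_split`` (0..4) choosing among tied
    cuts from the highest (coarsest partition) to the lowest (finest).
    Branches below the minimum size go to the grey label; module labels are
    arbitrary colours assigned largest-first.
    """
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    n = len(gene_ids)
    if n < min_module_size:
        return pd.Series(GREY, index=gene_ids, name="module")
    diss = 1.0 - np.asarray(tomm, dtype=float)
    np.fill_diagonal(diss, 0.0)
    Z = sch.linkage(squareform(diss, checks=False), method="average")
    heights = Z[:, 2]
    hi, lo = float(heights.max()), float(np.quantile(heights, 0.25))
    candidates = np.linspace(hi - 1e-9 * max(1.0, abs(hi)), lo, _N_CUT_CANDIDATES)
    best: list[tuple[float, np.ndarray]] = []
    best_count = -1
    for cut in candidates:
        flat = sch.fcluster(Z, t=cut, criterion="distance")
        sizes = np.bincount(flat)
        count = int((sizes >= min_module_size).sum())
        if count > best_count:
            best_count = count
            best = [(cut, flat)]
        elif count == best_count:
            best.append((cut, flat))
    # Tied cuts are ordered high to low; deep_split indexes into them.
    pick = int(round(deep_split / 4 * (len(best) - 1)))
    _, labels = best[pick]
    out = np.full(n, GREY, dtype=object)
    kept = [c for c, s in pd.Series(labels).value_counts().items() if s >= min_module_size]
    for rank, c in enumerate(kept):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank:03d}"
        out[labels == c] = color
    return pd.Series(out, index=gene_ids, name="module")


def module_eigengene(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's standardized expression.

    Returns (eigengenes: samples x modules scaled to unit variance and
    sign-aligned with the module's mean expression profile, variance
    explained per module).
    """
    modules = [m for m in labels.unique() if m != GREY]
    mes = {}
    var_explained = {}
    x = expr.to_numpy(dtype=float)
    lab = labels.reindex(expr.index).to_numpy()
    for m in modules:
        block = x[lab == m]
        sd = block.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise ValueError(f"module {m!r} contains constant gene(s)")
        zs = (block - block.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(zs, full_matrices=False)
        me = vt[0]
        me = me / me.std(ddof=1)
        mean_profile = zs.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        mes[m] = me
        var_explained[m] = float(s[0] ** 2 / np.sum(s**2))
    me_df = pd.DataFrame(mes, index=expr.columns)
    return me_df, pd.Series(var_explained, name="var_explained")


def module_membership(expr: pd.DataFrame, mes: pd.DataFrame) -> pd.DataFrame:
    """kME: Pearson correlation of every gene with every module eigengene."""
    x = expr.to_numpy(dtype=float)
    zs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1)[:, None]
    me = mes.to_numpy(dtype=float)
    zme = (me - me.mean(axis=0)) / me.std(axis=0, ddof=1)
    n = x.shape[1]
    kme = zs @ zme / (n - 1)
    return pd.DataFrame(kme, index=expr.index, columns=mes.columns)


def apply_membership_rules(
    expr: pd.DataFrame,
    labels: pd.Series,
    mes: pd.DataFrame,
    kme_keep: float = 0.3,
    core_kme: float = 0.5,
    min_module_size: int = 100,
) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Membership pruning: weak members to grey, weak-cored modules disbanded.

    A gene stays in its module only with kME >= ``kme_keep`` against the
    module eigengene; a module survives only if at least
    ceil(min_module_size / 3) members reach kME >= ``core_kme``.  Eigengenes
    are recomputed after reassignment.  Returns (labels, eigengenes,
    variance explained).
    """
    kme = module_membership(expr, mes)
    new_labels = labels.copy()
    core_needed = math.ceil(min_module_size / 3)
    for m in [m for m in labels.unique() if m != GREY]:
        members = labels.index[labels == m]
        own = kme.loc[members, m]
        weak = own.index[own < kme_keep]
        new_labels.loc[weak] = GREY
        strong_core = int((own >= core_kme).sum())
        if strong_core < core_needed:
            new_labels.loc[members] = GREY
    if (new_labels != GREY).any():
        mes2, ve = module_eigengene(expr, new_labels)
    else:
        mes2 = pd.DataFrame(index=expr.columns)
        ve = pd.Series(dtype=float, name="var_explained")
    return new_labels, mes2, ve


@dataclass
class Network:
    """Adjacency (and optionally TOM) with the parameters that produced it."""

    gene_ids: pd.Index
    adjacency: np.ndarray
    power: float
    sign_mode: str
    tom: np.ndarray | None = None

    def edge_list(self, min_weight: float = 0.0, use_tom: bool = True) -> pd.DataFrame:
        """Upper-triangle edge list (gene_i, gene_j, weight) for export."""
        W = self.tom if (use_tom and self.tom is not None) else self.adjacency
        iu, ju = np.triu_indices(len(self.gene_ids), k=1)
        w = W[iu, ju]
        keep = w >= min_weight
        return pd.DataFrame(
            {
                "gene_i": self.gene_ids.to_numpy()[iu[keep]],
                "gene_j": self.gene_ids.to_numpy()[ju[keep]],
                "weight": w[keep],
            }
        )


@dataclass
class ModuleSet:
    """A gene partition with its eigengenes and connectivity statistics."""

    labels: pd.Series
    eigengenes: pd.DataFrame
    var_explained: pd.Series
    kme: pd.DataFrame
    k: pd.DataFrame  # kTotal, kIN
    params: dict = field(default_factory=dict)

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def module_genes(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    def own_kme(self) -> pd.Series:
        """Each gene's kME against its own module eigengene (NaN for grey)."""
        out = pd.Series(np.nan, index=self.labels.index, name="kME_own")
        for m in self.module_names:
            genes = self.module_genes(m)
            out.loc[genes] = self.kme.loc[genes, m]
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"module": self.labels})
        df = df.join(self.k)
        df["kME_own"] = self.own_kme()
        return df


def build_network(
    expr: pd.DataFrame,
    beta: float | None = None,
    sign_mode: str = "signed",
    min_module_size: int = 100,
    deep_split: int = 2,
    kme_keep: float = 0.3,
    core_kme: float = 0.5,
    fit_cut: float = 0.8,
    candidate_powers=DEFAULT_POWERS,
    max_iter: int = 10,
) -> tuple[Network, ModuleSet, dict]:
    """Iterative network construction until no gene is assigned to grey.

    Each round: adjacency -> TOM -> cluster-and-cut -> eigengenes ->
    membership rules; grey genes are dropped and the network rebuilt.  The
    final network retains only assigned genes.  When ``beta`` is None the
    soft threshold is chosen once, on the full expression matrix (fallback:
    largest candidate when no power reaches the fit cut).
    """
    info: dict = {"grey_per_iteration": [], "converged": False, "scan": None}
    scan = None
    if beta is None:
        scan = pick_soft_threshold(expr, candidate_powers, fit_cut=fit_cut, sign_mode=sign_mode)
        beta = scan.selected if scan.selected is not None else float(max(candidate_powers))
        info["scan"] = scan
    current = expr
    net = None
    labels = pd.Series(GREY, index=expr.index, name="module")
    mes = pd.DataFrame(index=expr.columns)
    ve = pd.Series(dtype=float)
    for _ in range(max_iter):
        if current.shape[0] < min_module_size:
            labels = pd.Series(GREY, index=current.index, name="module")
            break
        net = adjacency(current, beta, sign_mode)
        net.tom = tom(net.adjacency)
        labels = cluster_and_cut(net.tom, current.index, min_module_size, deep_split)
        if (labels == GREY).all():
            break
        mes, ve = module_eigengene(current, labels)
        labels, mes, ve = apply_membership_rules(
            current, labels, mes, kme_keep, core_kme, min_module_size
        )
        n_grey = int((labels == GREY).sum())
        info["grey_per_iteration"].append(n_grey)
        if n_grey == 0:
            info["converged"] = True
            break
        current = current.loc[labels != GREY]
    else:
        warnings.warn("grey-removal iteration did not converge; returning current state")

    assigned = labels.index[labels != GREY]
    if len(assigned) == 0:
        empty = Network(
            gene_ids=pd.Index([], name=expr.index.name),
            adjacency=np.empty((0, 0)),
            power=float(beta),
            sign_mode=sign_mode,
        )
        modules = ModuleSet(
            labels=labels,
            eigengenes=pd.DataFrame(index=expr.columns),
            var_explained=pd.Series(dtype=float),
            kme=pd.DataFrame(index=labels.index),
            k=pd.DataFrame(columns=["kTotal", "kIN"]),
        )
        return empty, modules, info

    final_expr = expr.loc[assigned]
    net = adjacency(final_expr, beta, sign_mode)
    net.tom = tom(net.adjacency)
    final_labels = labels.loc[assigned]
    mes, ve = module_eigengene(final_expr, final_labels)
    kme = module_membership(final_expr, mes)
    k = connectivity(net.adjacency, labels=final_labels, gene_ids=final_expr.index)
    modules = ModuleSet(
        labels=final_labels,
        eigengenes=mes,
        var_explained=ve,
        kme=kme,
        k=k,
        params={
            "beta": float(beta),
            "sign_mode": sign_mode,
            "min_module_size": min_module_size,
            "deep_split": deep_split,
            "kme_keep": kme_keep,
            "core_kme": core_kme,
        },
    )
    return net, modules, info


class CoexpressionNetwork:
    """Model object for a signed weighted coexpression network.

    Parameters
    ----------
    expr : DataFrame
        Preprocessed log-scale expression, genes x samples; every gene must
        have nonzero variance.
    power : "auto" or number
        Soft-threshold power; "auto" selects the smallest candidate whose
        signed scale-free fit reaches ``fit_cut``.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        power: float | str = "auto",
        sign_mode: str = "signed",
        min_module_size: int = 100,
        deep_split: int = 2,
        kme_keep: float = 0.3,
        core_kme: float = 0.5,
        fit_cut: float = 0.8,
        candidate_powers=DEFAULT_POWERS,
        max_iter: int = 10,
    ) -> None:
        if expr.index.has_duplicates or expr.columns.has_duplicates:
            raise ValueError("duplicate gene or sample identifiers")
        self.expr = expr
        self.power = None if power == "auto" else float(power)
        self.sign_mode = sign_mode
        self.min_module_size = min_module_size
        self.deep_split = deep_split
        self.kme_keep = kme_keep
        self.core_kme = core_kme
        self.fit_cut = fit_cut
        self.candidate_powers = candidate_powers
        self.max_iter = max_iter

    @classmethod
    def from_dataframe(cls, expr: pd.DataFrame, **kwargs) -> "CoexpressionNetwork":
        return cls(expr, **kwargs)

    def fit(self) -> "CoexpressionNetworkResults":
        net, modules, info = build_network(
            self.expr,
            beta=self.power,
            sign_mode=self.sign_mode,
            min_module_size=self.min_module_size,
            deep_split=self.deep_split,
            kme_keep=self.kme_keep,
            core_kme=self.core_kme,
            fit_cut=self.fit_cut,
            candidate_powers=self.candidate_powers,
            max_iter=self.max_iter,
        )
        return CoexpressionNetworkResults(self, net, modules, info)


class CoexpressionNetworkResults:
    """Fitted coexpression network: partition, eigengenes, connectivities."""

    def __init__(self, model: CoexpressionNetwork, network: Network, modules: ModuleSet, info: dict):
        self.model = model
        self.network = network
        self.modules = modules
        self.scan: SoftThresholdScan | None = info.get("scan")
        self.grey_per_iteration: list[int] = info.get("grey_per_iteration", [])
        self.converged: bool = info.get("converged", False)

    @property
    def labels(self) -> pd.Series:
        return self.modules.labels

    @property
    def eigengenes(self) -> pd.DataFrame:
        return self.modules.eigengenes

    @property
    def power(self) -> float:
        return self.network.power

    def expression(self) -> pd.DataFrame:
        """Expression restricted to the genes retained in the final network."""
        return self.model.expr.loc[self.network.gene_ids]

    def summary(self) -> pd.DataFrame:
        """Per-module table: size, variance explained, mean kME/kIN/kTotal."""
        rows = []
        for m in self.modules.module_names:
            genes = self.modules.module_genes(m)
            rows.append(
                {
                    "module": m,
                    "size": len(genes),
                    "var_explained": self.modules.var_explained.get(m, np.nan),
                    "mean_kME": float(self.modules.kme.loc[genes, m].mean()),
                    "mean_kIN": float(self.modules.k.loc[genes, "kIN"].mean()),
                    "mean_kTotal": float(self.modules.k.loc[genes, "kTotal"].mean()),
                }
            )
        return pd.DataFrame(rows).sort_values("size", ascending=False).reset_index(drop=True)

    def correlate_traits(self, traits: pd.DataFrame, method: str = "fisher"):
        from .traits import ModuleTraitAnalysis

        return ModuleTraitAnalysis(self.eigengenes, traits).fit(method=method)

    def gene_table(self) -> pd.DataFrame:
        return self.modules.to_frame()
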