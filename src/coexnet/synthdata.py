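"""Synthetic expression, trait, annotation, interaction, and promoter generators.

Every generator plants known structure and returns it alongside the data, so
each downstream stage of the pipeline has a parameter-recovery oracle.  The
generative model mirrors the module-eigengene view of a coexpression network:
each module is summarised by a latent per-sample eigengene ``E_m`` (i.i.d.
standard normal across samples) and a module gene ``i`` is

    x_i = mu_i + r_i * E_m + sqrt(1 - r_i^2) * noise_sd * eps,   eps ~ N(0, 1)

so that with ``noise_sd = 1`` the expected gene-eigengene correlation (the
gene's module membership, kME) equals its planted loading ``r_i``.
Background genes are independent noise around their own baselines.

All randomness flows through one :func:`numpy.random.default_rng` stream
derived from the config seed; identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "MODULE_COLORS",
    "TRAIT_NAMES",
    "generate_expression",
    "generate_traits",
    "generate_counts",
    "generate_condition2",
    "generate_annotations",
    "generate_interactions",
    "generate_promoters",
    "default_pwm_counts",
    "study_replica_config",
]

#: WGCNA-style arbitrary module colour labels, assigned largest-first.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

#: Behavioural trait columns, fixed order.
TRAIT_NAMES = ("motifs", "tutor_similarity", "variability_induction", "motif_identity")

#: Unassigned-gene label.
GREY = "grey"

# Study-scale defaults: 19 samples, 21 planted modules between 100 and 2000
# genes (7461 module genes), ~6200 background genes, four behavioural traits
# each coupled to one module.
_DEFAULT_MODULE_SIZES = (
    1986, 800, 600, 500, 440, 390, 345, 305, 275, 245, 216, 196, 176, 156,
    146, 136, 126, 116, 106, 101, 100,
)
assert sum(_DEFAULT_MODULE_SIZES) == 7461


def _default_trait_couplings() -> dict[str, tuple[str, float]]:
    return {
        "motifs": ("blue", 0.85),
        "tutor_similarity": ("green", 0.8),
        "variability_induction": ("purple", -0.8),
        "motif_identity": ("darkred", 0.7),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for the synthetic datasets.

    Defaults emulate the sequencing design the generators stand in for:
    19 samples, ~13.7k genes of which 7461 fall into 21 modules of 100-2000
    genes, four behavioural traits linearly coupled to chosen module
    eigengenes, and a second condition (brain-region / age analogue) in which
    a designated subset of modules keeps its coexpression and the rest are
    scrambled.
    """

    n_samples: int = 19
    module_sizes: tuple[int, ...] = _DEFAULT_MODULE_SIZES
    n_background_genes: int = 6204
    kme_targets: tuple[float, ...] | float = 0.8
    trait_couplings: Mapping[str, tuple[str, float]] = field(
        default_factory=_default_trait_couplings
    )
    preserved_modules: tuple[str, ...] | None = None  # None => all but "green"
    noise_sd: float = 1.0
    kme_spread: float = 0.10
    baseline_mean: float = 4.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4 (correlations undefined below)")
        if len(self.module_sizes) == 0 or sum(self.module_sizes) == 0:
            raise ValueError("module sizes must sum to > 0")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("every module size must be >= 1")
        targets = self.kme_targets_per_module()
        if any(not 0.0 <= t <= 1.0 for t in targets):
            raise ValueError("kME targets must lie in [0, 1]")
        labels = set(self.module_labels())
        for trait, (module, rho) in self.trait_couplings.items():
            if abs(rho) > 1.0:
                raise ValueError(f"trait coupling |rho| > 1 for {trait!r}")
            if module not in labels:
                raise ValueError(f"trait {trait!r} coupled to unknown module {module!r}")
        for m in self.preserved_module_labels():
            if m not in labels:
                raise ValueError(f"unknown module label in preserved_modules: {m!r}")

    def module_labels(self) -> tuple[str, ...]:
        if len(self.module_sizes) > len(MODULE_COLORS):
            return tuple(f"module{i:03d}" for i in range(len(self.module_sizes)))
        return MODULE_COLORS[: len(self.module_sizes)]

    def kme_targets_per_module(self) -> tuple[float, ...]:
        if isinstance(self.kme_targets, (int, float)):
            return (float(self.kme_targets),) * len(self.module_sizes)
        if len(self.kme_targets) != len(self.module_sizes):
            raise ValueError("kme_targets length must match module_sizes")
        return tuple(float(t) for t in self.kme_targets)

    def preserved_module_labels(self) -> tuple[str, ...]:
        if self.preserved_modules is not None:
            return tuple(self.preserved_modules)
        return tuple(m for m in self.module_labels() if m != "green")


@dataclass
class GroundTruth:
    """Planted structure returned next to every synthetic dataset."""

    labels: pd.Series  # gene -> module label ("grey" = background)
    eigengenes: pd.DataFrame  # samples x modules, the latent standardized E_m
    loadings: pd.Series  # gene -> planted loading r_i (0 for background)
    baselines: pd.Series  # gene -> mean log2 expression mu_i
    trait_couplings: dict[str, tuple[str, float]]
    preserved_modules: tuple[str, ...]
    motif_offsets: pd.DataFrame | None = None  # seq_id, offset (0-based), strand

    def module_genes(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_expression(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a gene x sample log2-scale expression matrix with planted modules.

    Returns the matrix and the :class:`GroundTruth` holding the planted
    partition, latent eigengenes, and per-gene loadings.
    """
    rng = _rng(config.seed)
    labels_list = config.module_labels()
    targets = config.kme_targets_per_module()
    n_module_genes = sum(config.module_sizes)
    n_genes = n_module_genes + config.n_background_genes
    gene_ids = pd.Index([f"G{i:06d}" for i in range(n_genes)], name="gene_id")
    sample_ids = pd.Index([f"S{j:02d}" for j in range(config.n_samples)], name="sample_id")

    # Latent standardized eigengenes, one per module.
    E = rng.standard_normal((config.n_samples, len(labels_list)))
    E = (E - E.mean(axis=0)) / E.std(axis=0, ddof=1)
    eigengenes = pd.DataFrame(E, index=sample_ids, columns=list(labels_list))

    labels = np.full(n_genes, GREY, dtype=object)
    loadings = np.zeros(n_genes)
    baselines = config.baseline_mean + config.baseline_sd * rng.standard_normal(n_genes)
    values = np.empty((n_genes, config.n_samples))

    start = 0
    for m, (label, size, target) in enumerate(zip(labels_list, config.module_sizes, targets)):
        stop = start + size
        labels[start:stop] = label
        r = np.clip(rng.normal(target, config.kme_spread, size), 0.05, 0.98)
        loadings[start:stop] = r
        eps = rng.standard_normal((size, config.n_samples))
        values[start:stop] = (
            baselines[start:stop, None]
            + r[:, None] * E[:, m]
            + np.sqrt(1.0 - r[:, None] ** 2) * config.noise_sd * eps
        )
        start = stop
    # Background: independent noise around baseline.
    n_bg = config.n_background_genes
    if n_bg:
        values[start:] = baselines[start:, None] + config.noise_sd * rng.standard_normal(
            (n_bg, config.n_samples)
        )

    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    truth = GroundTruth(
        labels=pd.Series(labels, index=gene_ids, name="module"),
        eigengenes=eigengenes,
        loadings=pd.Series(loadings, index=gene_ids, name="loading"),
        baselines=pd.Series(baselines, index=gene_ids, name="baseline"),
        trait_couplings=dict(config.trait_couplings),
        preserved_modules=config.preserved_module_labels(),
    )
    return expr, truth


def generate_traits(truth: GroundTruth, config: SynthConfig, seed=None) -> pd.DataFrame:
    """Behavioural trait table linearly coupled to planted module eigengenes.

    Each trait t coupled to module m at target rho is rho*E_m + sqrt(1-rho^2)*eps
    mapped affinely onto a plausible behavioural scale (clipped at natural
    bounds; the affine map leaves the Pearson correlation untouched).
    """
    rng = _rng(config.seed + 1 if seed is None else seed)
    samples = truth.eigengenes.index
    n = len(samples)
    scales = {
        # trait -> (location, scale, lo, hi)
        "motifs": (150.0, 60.0, 0.0, np.inf),
        "tutor_similarity": (65.0, 15.0, 0.0, 100.0),
        "variability_induction": (-0.05, 0.08, -0.99, 0.99),
        "motif_identity": (60.0, 12.0, 0.0, 100.0),
    }
    cols = {}
    for trait, (module, rho) in config.trait_couplings.items():
        z = rho * truth.eigengenes[module].to_numpy() + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        loc, scale, lo, hi = scales.get(trait, (0.0, 1.0, -np.inf, np.inf))
        x = np.clip(loc + scale * z, lo, hi)
        if trait == "motifs":
            x = np.round(x)
        cols[trait] = x
    return pd.DataFrame(cols, index=samples)


def generate_counts(
    expr: pd.DataFrame,
    gene_lengths: pd.Series | np.ndarray,
    library_sizes: pd.Series | np.ndarray | float,
    seed: int = 0,
    dispersion: float = 0.05,
    input_scale: str = "log2",
) -> pd.DataFrame:
    """Negative-binomial read counts whose expected TPM recovers ``expr``.

    ``expr`` is interpreted per ``input_scale``: "log2" (abundance = 2**x,
    the generator's native scale) or "abundance" (linear, zeros allowed).
    Expected reads for gene i in sample s are proportional to
    abundance_is * length_i, so that length-normalised rates — and hence
    TPM — recover the relative abundances.  ``dispersion`` is the NB
    inverse-size parameter; 0 gives the Poisson limit.
    """
    rng = _rng(seed)
    lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.shape[0] != expr.shape[0]:
        raise ValueError("gene_lengths length must match number of genes")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if input_scale == "log2":
        abundance = np.exp2(expr.to_numpy(dtype=float))
    elif input_scale == "abundance":
        abundance = expr.to_numpy(dtype=float)
        if np.any(abundance < 0):
            raise ValueError("abundances must be non-negative")
    else:
        raise ValueError(f"unknown input_scale: {input_scale!r}")

    libs = np.broadcast_to(np.asarray(library_sizes, dtype=float), (expr.shape[1],))
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")

    frag_weight = abundance * lengths[:, None]
    share = frag_weight / frag_weight.sum(axis=0, keepdims=True)
    mu = share * libs[None, :]

    if dispersion > 0:
        # NB as gamma-Poisson: lambda ~ Gamma(shape=1/disp, scale=mu*disp)
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu * dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    counts[abundance == 0] = 0
    return pd.DataFrame(counts, index=expr.index, columns=expr.columns)


def generate_condition2(
    expr: pd.DataFrame,
    truth: GroundTruth,
    config: SynthConfig,
    seed=None,
    preservation_strengths: Mapping[str, float] | None = None,
    n_samples: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Second-condition expression with per-module preservation control.

    Preserved modules are regenerated from the same gene loadings onto a
    freshly drawn latent eigengene (fresh noise, fresh sample effects).
    Scrambled modules have each gene's loading reassigned to its own
    independent latent factor, destroying within-module coexpression while
    keeping every gene's marginal mean and variance.  A module's
    preservation ``strength`` interpolates: the shared-latent loading is
    r*strength-weighted via  c = r*(s*E' + sqrt(1-s^2)*u_gene) + resid.
    """
    rng = _rng(config.seed + 2 if seed is None else seed)
    labels_list = config.module_labels()
    strengths = {m: 0.0 for m in labels_list}
    for m in truth.preserved_modules:
        strengths[m] = 1.0
    if preservation_strengths:
        for m, s in preservation_strengths.items():
            if m not in strengths:
                raise ValueError(f"unknown module label: {m!r}")
            if not 0.0 <= s <= 1.0:
                raise ValueError("preservation strength must lie in [0, 1]")
            strengths[m] = float(s)

    n = expr.shape[1] if n_samples is None else int(n_samples)
    sample_ids = pd.Index([f"T{j:02d}" for j in range(n)], name="sample_id")
    E2 = rng.standard_normal((n, len(labels_list)))
    E2 = (E2 - E2.mean(axis=0)) / E2.std(axis=0, ddof=1)
    eigengenes2 = pd.DataFrame(E2, index=sample_ids, columns=list(labels_list))

    values = np.empty((expr.shape[0], n))
    lab = truth.labels.to_numpy()
    r_all = truth.loadings.to_numpy()
    mu_all = truth.baselines.to_numpy()
    for m, label in enumerate(labels_list):
        idx = np.flatnonzero(lab == label)
        if idx.size == 0:
            continue
        s = strengths[label]
        r = r_all[idx]
        shared = s * E2[:, m]
        private = np.sqrt(1.0 - s**2) * rng.standard_normal((idx.size, n))
        eps = rng.standard_normal((idx.size, n))
        values[idx] = (
            mu_all[idx, None]
            + r[:, None] * (shared[None, :] + private)
            + np.sqrt(1.0 - r[:, None] ** 2) * config.noise_sd * eps
        )
    bg = np.flatnonzero(lab == GREY)
    if bg.size:
        values[bg] = mu_all[bg, None] + config.noise_sd * rng.standard_normal((bg.size, n))

    expr2 = pd.DataFrame(values, index=expr.index, columns=sample_ids)
    truth2 = GroundTruth(
        labels=truth.labels.copy(),
        eigengenes=eigengenes2,
        loadings=truth.loadings.copy(),
        baselines=truth.baselines.copy(),
        trait_couplings=dict(truth.trait_couplings),
        preserved_modules=tuple(m for m, s in strengths.items() if s == 1.0),
    )
    return expr2, truth2


def generate_annotations(
    truth: GroundTruth,
    n_terms: int,
    seed: int = 0,
    enriched_fraction: float = 0.5,
    genes_per_term: tuple[int, int] = (10, 50),
) -> pd.DataFrame:
    """Term -> gene annotation table with module-enriched terms.

    Roughly ``enriched_fraction`` of terms draw 80% of their genes from one
    planted module and carry small p-values (10^-U(2,6)); the rest draw
    random genes with p ~ U(0.05, 1).  Categories cycle through
    disease/GO/pathway tags.
    """
    rng = _rng(seed)
    genes = truth.labels.index.to_numpy()
    modules = [m for m in truth.labels.unique() if m != GREY]
    categories = ("disease", "go_bp", "go_mf", "pathway")
    rows = []
    for t in range(n_terms):
        size = int(rng.integers(genes_per_term[0], genes_per_term[1] + 1))
        enriched = modules and rng.random() < enriched_fraction
        if enriched:
            module = modules[rng.integers(len(modules))]
            pool = truth.module_genes(module).to_numpy()
            n_in = min(max(1, int(round(0.8 * size))), pool.size)
            inside = rng.choice(pool, n_in, replace=False)
            outside = rng.choice(genes, size - n_in, replace=False)
            term_genes = np.unique(np.concatenate([inside, outside]))
            p = 10.0 ** (-rng.uniform(2, 6))
        else:
            module = ""
            term_genes = rng.choice(genes, size, replace=False)
            p = rng.uniform(0.05, 1.0)
        rows.append(
            {
                "term_id": f"TERM{t:04d}",
                "category": categories[t % len(categories)],
                "p_value": p,
                "gene_ids": ",".join(sorted(term_genes)),
                "enriched_module": module,
            }
        )
    return pd.DataFrame(rows)


def generate_interactions(
    truth: GroundTruth,
    seed: int = 0,
    n_edges: int = 500,
    high_conf_fraction: float = 0.3,
) -> pd.DataFrame:
    """Confidence-scored gene-pair interaction table.

    A designated ``high_conf_fraction`` of edges carry confidence >= 0.9 (the
    high-confidence flag) and preferentially span pairs of distinct planted
    modules; the remainder are uniform below 0.9.
    """
    rng = _rng(seed)
    genes = truth.labels.index.to_numpy()
    module_genes = genes[truth.labels.to_numpy() != GREY]
    pool = module_genes if module_genes.size >= 2 else genes
    seen: set[tuple[str, str]] = set()
    rows = []
    n_high = int(round(n_edges * high_conf_fraction))
    while len(rows) < n_edges:
        high = len(rows) < n_high
        src = pool if high else genes
        a, b = rng.choice(src, 2, replace=False)
        key = (a, b) if a < b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        conf = rng.uniform(0.9, 1.0) if high else rng.uniform(0.0, 0.9)
        rows.append(
            {
                "gene_i": key[0],
                "gene_j": key[1],
                "confidence": conf,
                "high_confidence": conf >= 0.9,
            }
        )
    return pd.DataFrame(rows)


def generate_promoters(
    pwm,
    n: int,
    motif_rate: float,
    seed: int = 0,
    length: int = 1000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Uniform-background promoter sequences with motif instances planted.

    Each promoter independently receives one motif instance with probability
    ``motif_rate``; the instance is sampled column-wise from the PWM's base
    probabilities and written at a uniform random offset, which is recorded
    (0-based, forward strand).  Returns (id -> sequence, offsets table with
    seq_id/offset/strand/instance).
    """
    from .motifscan import PWM  # local import to avoid a cycle

    if not isinstance(pwm, PWM):
        raise TypeError("pwm must be a coexnet.motifscan.PWM")
    L = pwm.length
    if L > length:
        raise ValueError("motif longer than promoter")
    rng = _rng(seed)
    bases = np.array(list("ACGT"))
    probs = pwm.probabilities  # 4 x L
    seqs: dict[str, str] = {}
    rows = []
    for i in range(n):
        seq_id = f"promoter{i:04d}"
        seq = rng.choice(bases, length)
        if rng.random() < motif_rate:
            offset = int(rng.integers(0, length - L + 1))
            instance = np.array(
                [bases[rng.choice(4, p=probs[:, j])] for j in range(L)]
            )
            seq[offset : offset + L] = instance
            rows.append(
                {
                    "seq_id": seq_id,
                    "offset": offset,
                    "strand": "+",
                    "instance": "".join(instance),
                }
            )
        seqs[seq_id] = "".join(seq)
    offsets = pd.DataFrame(rows, columns=["seq_id", "offset", "strand", "instance"])
    return seqs, offsets


def study_replica_config(
    seed: int = 0,
    scale: int = 5,
    min_module_size: int = 60,
    n_samples: int = 19,
    scrambled_module: str = "green",
) -> SynthConfig:
    """Desk-scale replica of the study design for preservation analyses.

    The 21 planted module sizes follow the full design's size distribution
    divided by ``scale`` with a ``min_module_size`` floor, the background
    fraction matches the full design, and both conditions have the study's
    19 samples.  All modules except ``scrambled_module`` (by default the
    green learning-module analogue) are preserved in condition 2.
    """
    sizes = tuple(max(min_module_size, round(s / scale)) for s in _DEFAULT_MODULE_SIZES)
    n_bg = round(sum(sizes) * 6204 / 7461)
    labels = MODULE_COLORS[: len(sizes)]
    if scrambled_module not in labels:
        raise ValueError(f"unknown module label: {scrambled_module!r}")
    return SynthConfig(
        n_samples=n_samples,
        module_sizes=sizes,
        n_background_genes=n_bg,
        kme_targets=0.8,
        trait_couplings={
            "motifs": ("blue", 0.85),
            "tutor_similarity": ("green", 0.8),
            "variability_induction": ("purple", -0.8),
            "motif_identity": ("darkred", 0.7),
        },
        preserved_modules=tuple(m for m in labels if m != scrambled_module),
        seed=seed,
    )


def default_pwm_counts() -> pd.DataFrame:
    """A synthetic forkhead-like binding-motif count matrix.

    Constructed (not derived from any database) 12-column matrix whose
    consensus, TGTTTACTTTAC, resembles a forkhead-family core with a
    partial second half-site; used by the demo pipeline and tests as a
    stand-in motif.
    """
    counts = np.array(
        [
            #  T   G   T   T   T   A   C   T   T   T   A   C
            [2, 1, 1, 0, 2, 18, 1, 2, 1, 2, 15, 2],  # A
            [1, 2, 0, 1, 0, 1, 16, 2, 1, 0, 2, 14],  # C
            [2, 16, 1, 1, 1, 0, 1, 1, 2, 1, 2, 2],  # G
            [15, 1, 18, 18, 17, 1, 2, 15, 16, 17, 1, 2],  # T
        ],
        dtype=float,
    )
    return pd.DataFrame(counts, index=list("ACGT"))
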