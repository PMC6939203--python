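"""Synthetic data with planted structure for end-to-end pipeline testing.

The generator emulates the statistical shape of a sorted-mTEC single-cell
experiment: five FACS sort conditions (TSPAN8+/-, GP2+/-, unselected)
across several mice, sparse tissue-restricted-gene expression (each cell
detects only a few percent of genes), planted cell subpopulations, planted
gene co-expression modules, genomic coordinates for every gene, and
multi-channel microscopy images whose marker-positive cells are placed by
an even, random, or clustered point process inside a medullary mask.

Everything planted is recorded in :class:`SyntheticTruth`, so downstream
stages (QC, cell clustering, gene-module discovery, co-expression
reproducibility, spatial classification) can be scored against known ground
truth.

The generative model for counts is hierarchical: each cell belongs to a
cell cluster; each cluster switches a subset of the gene modules "on"; genes
of on-modules are detected with ``active_detect_prob``, all other genes with
``baseline_detect_prob``; a detected entry draws its UMI count as
``1 + NegBin(mean_umi_per_gene - 1, dispersion)`` so that the realised
detection probability equals the configured one exactly. Sorted conditions
are coupled to marker modules: the TSPAN8+ (GP2+) sort forces its marker
module on, mirroring sorted subpopulations preferring particular satellite
clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CONDITIONS, CountMatrix
from .spatial import sample_points

#: Sorted condition -> index of the planted module it prefers.
MARKER_MODULES = {"TSPAN8+": 1, "GP2+": 2}

CHROMOSOME_LENGTH_BP = 100_000_000


@dataclass
class SimConfig:
    """Parameters of the synthetic count generator.

    Defaults describe the study conditions used throughout the test-suite:
    2,000 genes, 600 cells in each of the five sort conditions (3,000 cells
    total) from 4 mice, 8 cell clusters, 5 gene modules of 80-120 genes,
    baseline detection probability 0.02 per gene per cell versus 0.25 for
    genes of an active module, and mildly overdispersed UMI counts.
    """

    n_genes: int = 2000
    n_cells_per_condition: dict = field(
        default_factory=lambda: {c: 600 for c in CONDITIONS}
    )
    n_mice: int = 4
    n_cell_clusters: int = 8
    n_modules: int = 5
    module_size_range: tuple = (80, 120)
    frac_trg: float = 0.3
    baseline_detect_prob: float = 0.02
    active_detect_prob: float = 0.25
    mean_umi_per_gene: float = 2.0
    dispersion: float = 1.0
    depth_sigma: float = 0.7
    n_chromosomes: int = 19
    condition_depth_multiplier: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_genes, self.n_mice, self.n_cell_clusters,
            self.n_modules, self.n_chromosomes,
        ] + list(self.n_cells_per_condition.values())
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        for p in (self.baseline_detect_prob, self.active_detect_prob, self.frac_trg):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.active_detect_prob < self.baseline_detect_prob:
            raise ValueError(
                "active_detect_prob must be >= baseline_detect_prob "
                "(equality yields a structureless null dataset)"
            )
        if self.mean_umi_per_gene < 1.0 or self.dispersion <= 0:
            raise ValueError("mean_umi_per_gene must be >= 1 and dispersion > 0")
        lo, hi = self.module_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid module_size_range")

    @property
    def n_cells(self) -> int:
        return sum(self.n_cells_per_condition.values())


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a synthetic dataset."""

    gene_module_labels: np.ndarray | None = None  # 1..M, -1 = noise
    cell_cluster_labels: np.ndarray | None = None
    condition_labels: np.ndarray | None = None
    mouse_ids: np.ndarray | None = None
    cluster_module_activity: np.ndarray | None = None  # clusters x modules, bool
    marker_modules: dict = field(default_factory=dict)
    depth_factors: np.ndarray | None = None
    point_process_kind: str | None = None
    true_centroids: np.ndarray | None = None
    mask: np.ndarray | None = None

    def write_json(self, path: str | Path) -> None:
        payload = {}
        for key, val in asdict(self).items():
            if val is None:
                continue
            payload[key] = val.tolist() if isinstance(val, np.ndarray) else val
        Path(path).write_text(json.dumps(payload))


def _plant_modules(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    total = int(sizes.sum())
    if total > config.n_genes:
        raise ValueError(
            f"module sizes sum to {total} but only {config.n_genes} genes are "
            f"available (deficit {total - config.n_genes})"
        )
    labels = np.full(config.n_genes, -1, dtype=int)
    order = rng.permutation(config.n_genes)
    start = 0
    for m, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = m
        start += size
    return labels


def _cluster_activity(
    config: SimConfig, rng: np.random.Generator, on_clusters_per_module: int = 2
) -> np.ndarray:
    """Boolean clusters x modules activity matrix.

    Each module is switched on in a small number of cell clusters
    (default 2), emulating context-specific co-expression programmes that
    prefer particular satellite subpopulations; clusters with no active
    module mimic immature subpopulations with little tissue-restricted
    expression. Rows are resampled until all cluster profiles are distinct
    (when combinatorially possible).
    """
    K, M = config.n_cell_clusters, config.n_modules
    k_on = min(on_clusters_per_module, K)
    act = np.zeros((K, M), dtype=bool)
    for _ in range(5000):
        act[:] = False
        for m in range(M):
            act[rng.choice(K, size=k_on, replace=False), m] = True
        if len({tuple(r) for r in act}) == K:
            return act
    return act  # distinct rows infeasible for this K, M; accept last draw


def _gene_metadata(
    config: SimConfig, rng: np.random.Generator, module_labels: np.ndarray
) -> pd.DataFrame:
    n = config.n_genes
    is_trg = rng.random(n) < config.frac_trg
    trg_cats = rng.choice(
        ["AIRE-dependent", "AIRE-enhanced", "AIRE-independent TRG"], size=n
    )
    other_cats = rng.choice(
        ["housekeeping", "other", "unclassified"], size=n, p=[0.25, 0.5, 0.25]
    )
    return pd.DataFrame(
        {
            "gene_id": [f"gene_{i:05d}" for i in range(n)],
            "chromosome": rng.integers(1, config.n_chromosomes + 1, size=n),
            "position_bp": rng.integers(1, CHROMOSOME_LENGTH_BP + 1, size=n),
            "category": np.where(is_trg, trg_cats, other_cats),
            "module_truth": module_labels,
        }
    )


def _detection_probs(
    config: SimConfig,
    module_labels: np.ndarray,
    activity: np.ndarray,
    clusters: np.ndarray,
    conditions: np.ndarray,
) -> np.ndarray:
    """Dense genes x cells detection probability matrix."""
    n_genes, n_cells = config.n_genes, len(clusters)
    # per (cluster, module) -> per (cluster, gene) activity
    gene_active = np.zeros((config.n_cell_clusters, n_genes), dtype=bool)
    in_module = module_labels > 0
    gene_active[:, in_module] = activity[:, module_labels[in_module] - 1]
    probs = np.where(
        gene_active[clusters],  # cells x genes
        config.active_detect_prob,
        config.baseline_detect_prob,
    ).T
    # sorted positive conditions force their marker module on
    for cond, module in MARKER_MODULES.items():
        if module > config.n_modules:
            continue
        cell_sel = conditions == cond
        gene_sel = module_labels == module
        if cell_sel.any() and gene_sel.any():
            probs[np.ix_(gene_sel, cell_sel)] = config.active_detect_prob
    return probs


def _draw_counts(
    probs: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> sp.csr_matrix:
    detected = rng.random(probs.shape) < probs
    genes, cells = np.nonzero(detected)
    mu = config.mean_umi_per_gene - 1.0
    if mu > 0:
        theta = config.dispersion
        extra = rng.negative_binomial(theta, theta / (theta + mu), size=len(genes))
    else:
        extra = np.zeros(len(genes), dtype=int)
    values = 1 + extra
    return sp.csr_matrix(
        (values.astype(float), (genes, cells)), shape=probs.shape
    )


def _cell_layout(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    conditions = np.repeat(
        list(config.n_cells_per_condition),
        list(config.n_cells_per_condition.values()),
    )
    n_cells = len(conditions)
    if config.n_mice > n_cells:
        raise ValueError(
            f"n_mice={config.n_mice} exceeds the {n_cells} available cells"
        )
    clusters = rng.integers(0, config.n_cell_clusters, size=n_cells)
    mice = rng.integers(0, config.n_mice, size=n_cells)
    # guarantee every mouse contributes at least one cell
    for m in range(config.n_mice):
        if not (mice == m).any():
            mice[rng.integers(0, n_cells)] = m
    return conditions, clusters, mice


def generate_counts(
    config: SimConfig,
    mouse_detect_jitter: float = 0.0,
    permute_modules_per_mouse: bool = False,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate a sparse count matrix with planted modules and clusters.

    Parameters
    ----------
    config
        Study-condition parameters; ``config.seed`` drives all randomness
        (identical config => bit-identical output).
    mouse_detect_jitter
        Multiplicative per-mouse jitter on detection probabilities
        (0.1 => factors uniform in [0.9, 1.1]).
    permute_modules_per_mouse
        When True, each mouse receives an independently permuted gene ->
        module assignment — a negative control that destroys cross-mouse
        co-expression reproducibility while preserving marginals.
    """
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["genes", "activity", "cells", "counts", "mito"], root.spawn(5)
        )
    }
    module_labels = _plant_modules(config, streams["genes"])
    activity = _cluster_activity(config, streams["activity"])
    gene_meta = _gene_metadata(config, streams["genes"], module_labels)
    conditions, clusters, mice = _cell_layout(config, streams["cells"])
    n_cells = len(conditions)

    if permute_modules_per_mouse:
        probs = np.empty((config.n_genes, n_cells))
        for m in range(config.n_mice):
            perm = streams["cells"].permutation(config.n_genes)
            sel = mice == m
            p_m = _detection_probs(
                config, module_labels[perm], activity, clusters[sel], conditions[sel]
            )
            probs[:, sel] = p_m
    else:
        probs = _detection_probs(config, module_labels, activity, clusters, conditions)

    if mouse_detect_jitter:
        factors = streams["cells"].uniform(
            1.0 - mouse_detect_jitter, 1.0 + mouse_detect_jitter, size=config.n_mice
        )
        probs = np.clip(probs * factors[mice][None, :], 0.0, 1.0)
    for cond, mult in config.condition_depth_multiplier.items():
        probs[:, conditions == cond] = np.clip(
            probs[:, conditions == cond] * mult, 0.0, 1.0
        )
    # per-cell library-size variability: UMI libraries are log-normally
    # dispersed in depth, which the MAD quality filters presuppose
    if config.depth_sigma > 0:
        depth = np.exp(
            streams["cells"].normal(0.0, config.depth_sigma, size=n_cells)
            - config.depth_sigma ** 2 / 2.0
        )
        probs = np.clip(probs * depth[None, :], 0.0, 0.95)
    else:
        depth = np.ones(n_cells)

    counts = _draw_counts(probs, config, streams["counts"])
    mito = np.clip(streams["mito"].normal(0.05, 0.01, size=n_cells), 0.0, 1.0)
    cell_meta = pd.DataFrame(
        {
            "cell_id": [f"cell_{i:05d}" for i in range(n_cells)],
            "mouse_id": [f"mouse_{m}" for m in mice],
            "condition": conditions,
            "batch": [f"batch_{m}" for m in mice],  # one 10x run per mouse
            "mito_fraction": mito,
        }
    )
    truth = SyntheticTruth(
        gene_module_labels=module_labels,
        cell_cluster_labels=clusters,
        condition_labels=np.asarray(conditions),
        mouse_ids=cell_meta["mouse_id"].to_numpy(),
        cluster_module_activity=activity,
        marker_modules={c: m for c, m in MARKER_MODULES.items() if m <= config.n_modules},
        depth_factors=depth,
    )
    return CountMatrix(counts, gene_meta, cell_meta), truth


def generate_mouse_panel(
    config: SimConfig,
    mouse_detect_jitter: float = 0.1,
    permute_modules_per_mouse: bool = False,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Multi-mouse panel sharing one module structure (or not, as control).

    All mice share the planted module structure; per-mouse detection rates
    receive a ±10% multiplicative jitter by default. With
    ``permute_modules_per_mouse=True`` the gene->module map is reshuffled
    independently for every mouse (negative control).
    """
    if config.n_mice < 2:
        raise ValueError("a mouse panel needs n_mice >= 2")
    return generate_counts(
        config,
        mouse_detect_jitter=mouse_detect_jitter,
        permute_modules_per_mouse=permute_modules_per_mouse,
    )


# ---------------------------------------------------------------------------
# Synthetic microscopy images
# ---------------------------------------------------------------------------

@dataclass
class MaskSpec:
    """Elliptical-blob parameters of the synthetic medullary mask."""

    n_blobs: int = 2
    min_axis_frac: float = 0.18
    max_axis_frac: float = 0.32


def _render_mask(
    width: int, height: int, spec: MaskSpec, rng: np.random.Generator
) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    mask = np.zeros((height, width), dtype=bool)
    for _ in range(spec.n_blobs):
        cx = rng.uniform(0.3 * width, 0.7 * width)
        cy = rng.uniform(0.3 * height, 0.7 * height)
        ax = rng.uniform(spec.min_axis_frac, spec.max_axis_frac) * width
        ay = rng.uniform(spec.min_axis_frac, spec.max_axis_frac) * height
        theta = rng.uniform(0, np.pi)
        xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        mask |= (xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0
    return mask


def _render_spots(
    shape: tuple[int, int], points: np.ndarray, spot_radius: float
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros(shape, dtype=float)
    s2 = 2.0 * spot_radius ** 2
    for x, y in points:
        win = int(np.ceil(4 * spot_radius))
        x0, x1 = max(0, int(x) - win), min(w, int(x) + win + 1)
        y0, y1 = max(0, int(y) - win), min(h, int(y) + win + 1)
        sub = np.exp(
            -((xx[y0:y1, x0:x1] - x) ** 2 + (yy[y0:y1, x0:x1] - y) ** 2) / s2
        )
        img[y0:y1, x0:x1] += sub
    return img


def generate_image(
    width: int = 512,
    height: int = 512,
    kind: str = "random",
    n_points: int = 50,
    mask_spec: MaskSpec | None = None,
    spot_radius: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    **process_kwargs,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Two-channel synthetic immunofluorescence image.

    Channel 0 is a smooth medulla-defining signal (union of elliptical
    blobs, lightly blurred); channel 1 contains Gaussian spots of width
    ``spot_radius`` centred on points sampled inside the mask by the stated
    point process, plus optional Gaussian noise. The truth records the
    process kind, the exact centroids, and the binary mask.

    Returns ``(image, truth)`` with ``image`` of shape (2, height, width).
    """
    from skimage.filters import gaussian  # local import keeps module load light

    rng = np.random.default_rng(seed)
    mask = _render_mask(width, height, mask_spec or MaskSpec(), rng)
    # keep spots comfortably inside: sample from the eroded mask
    from skimage.morphology import disk, erosion

    inner = erosion(mask, disk(int(np.ceil(spot_radius))))
    if not inner.any():
        inner = mask
    points = sample_points(inner, n_points, kind, rng, **process_kwargs)
    structure = gaussian(mask.astype(float), sigma=max(width, height) / 100.0,
                         preserve_range=True)
    marker = _render_spots((height, width), points, spot_radius)
    if noise_sd > 0:
        structure = structure + rng.normal(0.0, noise_sd, structure.shape)
        marker = marker + rng.normal(0.0, noise_sd, marker.shape)
    image = np.stack([structure, marker])
    truth = SyntheticTruth(
        point_process_kind=kind, true_centroids=points, mask=mask
    )
    return image, truth


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a (channels, height, width) image stack as TIFF."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF image stack written by :func:`write_image`."""
    import tifffile

    return np.asarray(tifffile.imread(str(path)))


def expected_detection_fraction(
    config: SimConfig, truth: SyntheticTruth
) -> np.ndarray:
    """Per-cell expected fraction of genes detected, from the planted truth."""
    labels = truth.gene_module_labels
    activity = truth.cluster_module_activity
    in_module = labels > 0
    n_active = np.zeros(config.n_cell_clusters)
    module_sizes = np.bincount(labels[in_module], minlength=config.n_modules + 1)[1:]
    for k in range(config.n_cell_clusters):
        n_active[k] = module_sizes[activity[k]].sum()
    n_act_cell = n_active[truth.cell_cluster_labels].astype(float)
    # sorted positive conditions force their marker module on
    for cond, module in truth.marker_modules.items():
        off = ~activity[truth.cell_cluster_labels, module - 1]
        sel = (truth.condition_labels == cond) & off
        n_act_cell[sel] += module_sizes[module - 1]
    frac = (
        n_act_cell * config.active_detect_prob
        + (config.n_genes - n_act_cell) * config.baseline_detect_prob
    ) / config.n_genes
    if truth.depth_factors is not None:
        frac = np.minimum(frac * truth.depth_factors, 0.95)
    return frac
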