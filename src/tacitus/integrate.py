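"""Combine selections into one dataset with cross-platform normalization.

Five methods are exposed:

* ``none`` — merge only, values untouched;
* ``sims`` — per-dataset per-gene mean-centering;
* ``genestd`` — per-dataset per-gene z-scoring (mean 0, sd 1);
* ``combat`` — parametric empirical-Bayes location/scale batch adjustment;
* ``xpn`` — pairwise block normalization: genes and samples are clustered,
  a block-linear model is fitted per platform, and block parameters are
  replaced by their sample-size-weighted cross-platform averages.

Merging intersects gene sets (ordered as the first input), concatenates
sample columns, and disambiguates duplicate sample ids by appending a
numeric suffix. Count-scale inputs are transformed to log2-CPM (+0.5
offset) before any Gaussian-scale method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from tacitus import io_formats
from tacitus.types import ExpressionMatrix, SampleMetadata, TacitusError

logger = logging.getLogger(__name__)

METHODS = ("none", "sims", "genestd", "combat", "xpn")

_EPS = 1e-12


@dataclass
class IntegratedDataset:
    """Combined matrix + merged metadata + per-sample batch ordinals."""

    matrix: ExpressionMatrix
    metadata: SampleMetadata
    batch_labels: dict[str, int]
    method: str

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise TacitusError(f"unknown method {self.method!r}; expected one of {METHODS}")
        missing = [s for s in self.matrix.sample_ids if s not in self.batch_labels]
        if missing:
            raise TacitusError(f"batch labels missing for samples: {missing}")


# ---------------------------------------------------------------------------
# merging


def _dedup_sample_ids(id_lists: list[list[str]]) -> list[list[str]]:
    """First occurrence unchanged; k-th duplicate gets suffix ``_k``."""
    counts: dict[str, int] = {}
    out: list[list[str]] = []
    for ids in id_lists:
        renamed = []
        for sid in ids:
            k = counts.get(sid, 0)
            counts[sid] = k + 1
            renamed.append(sid if k == 0 else f"{sid}_{k}")
        out.append(renamed)
    return out


def merge_metadata(metadatas: list[SampleMetadata]) -> SampleMetadata:
    """Union attributes in first-seen order; add a ``batch`` attribute.

    Duplicate sample ids across inputs are disambiguated with a numeric
    suffix; missing attribute values are empty strings.
    """
    if not metadatas:
        raise TacitusError("empty metadata list")
    attributes: list[str] = []
    seen: set[str] = set()
    for md in metadatas:
        for attr in md.attributes:
            if attr not in seen:
                seen.add(attr)
                attributes.append(attr)
    if "batch" not in seen:
        attributes = attributes + ["batch"]
    renamed = _dedup_sample_ids([md.sample_ids for md in metadatas])
    sample_ids: list[str] = []
    table: dict[str, dict[str, str]] = {}
    for batch, (md, new_ids) in enumerate(zip(metadatas, renamed)):
        for old_id, new_id in zip(md.sample_ids, new_ids):
            sample_ids.append(new_id)
            row = {a: md.table[old_id].get(a, "") for a in attributes}
            row["batch"] = str(batch)
            table[new_id] = row
    return SampleMetadata(sample_ids, attributes, table)


def merge_matrices(
    matrices: list[ExpressionMatrix],
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Row-intersect and column-concatenate the inputs.

    Rows are the intersection of probe/gene id sets, ordered as in the first
    input; columns are the inputs concatenated in order with duplicate
    sample ids disambiguated. Returns the merged matrix and per-sample
    batch ordinals.
    """
    if not matrices:
        raise TacitusError("empty matrix list")
    common = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        common &= set(m.probe_ids)
    if not common:
        counts = [f"input {i}: {m.n_probes} ids" for i, m in enumerate(matrices)]
        raise TacitusError("empty probe id intersection (" + "; ".join(counts) + ")")
    rows = [p for p in matrices[0].probe_ids if p in common]

    blocks = []
    for m in matrices:
        idx = {p: r for r, p in enumerate(m.probe_ids)}
        blocks.append(m.values[[idx[p] for p in rows], :])
    values = np.concatenate(blocks, axis=1)

    renamed = _dedup_sample_ids([m.sample_ids for m in matrices])
    sample_ids = [sid for ids in renamed for sid in ids]
    batch_labels = {
        sid: batch for batch, ids in enumerate(renamed) for sid in ids
    }
    merged = ExpressionMatrix(rows, sample_ids, values, scale=matrices[0].scale)
    return merged, batch_labels


def _default_metadata(matrices: list[ExpressionMatrix]) -> list[SampleMetadata]:
    return [
        SampleMetadata(m.sample_ids, [], {s: {} for s in m.sample_ids}) for m in matrices
    ]


def _assemble(
    matrix: ExpressionMatrix,
    metadatas: list[SampleMetadata] | None,
    matrices: list[ExpressionMatrix],
    batch_labels: dict[str, int],
    method: str,
) -> IntegratedDataset:
    mds = metadatas if metadatas is not None else _default_metadata(matrices)
    merged_md = merge_metadata(mds)
    merged_md = merged_md.subset(matrix.sample_ids)
    return IntegratedDataset(matrix, merged_md, batch_labels, method)


# ---------------------------------------------------------------------------
# simple per-dataset transforms


def mean_center_integration(
    matrices: list[ExpressionMatrix],
    metadatas: list[SampleMetadata] | None = None,
) -> IntegratedDataset:
    """Subtract each gene's within-dataset mean, then merge."""
    centered = []
    for m in matrices:
        vals = m.values - m.values.mean(axis=1, keepdims=True)
        centered.append(ExpressionMatrix(m.probe_ids, m.sample_ids, vals, scale=m.scale))
    merged, batches = merge_matrices(centered)
    return _assemble(merged, metadatas, matrices, batches, "sims")


def gene_standardize_integration(
    matrices: list[ExpressionMatrix],
    metadatas: list[SampleMetadata] | None = None,
) -> IntegratedDataset:
    """Z-score each gene within each dataset (sd divisor n-1), then merge.

    Rows with sd below 1e-12 become all zeros.
    """
    standardized = []
    for m in matrices:
        if m.n_samples < 2:
            raise TacitusError(
                "gene standardization requires >=2 samples per dataset, "
                f"got {m.n_samples}"
            )
        mean = m.values.mean(axis=1, keepdims=True)
        sd = m.values.std(axis=1, ddof=1, keepdims=True)
        vals = np.where(sd < _EPS, 0.0, (m.values - mean) / np.where(sd < _EPS, 1.0, sd))
        standardized.append(
            ExpressionMatrix(m.probe_ids, m.sample_ids, vals, scale="standardized")
        )
    merged, batches = merge_matrices(standardized)
    return _assemble(merged, metadatas, matrices, batches, "genestd")


# ---------------------------------------------------------------------------
# empirical-Bayes batch adjustment


def combat_adjust(
    values: np.ndarray,
    batches: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> np.ndarray:
    """Parametric empirical-Bayes location/scale batch-effect removal.

    Per gene the grand mean and pooled variance are estimated and the data
    standardized; per batch-and-gene location and scale estimates are shrunk
    toward across-gene priors (normal for location, inverse-gamma for scale,
    both fitted by method of moments) via the standard fixed-point
    iteration; the standardized data are adjusted and the gene scale and
    location restored. Deterministic.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_total = values.shape
    if n_genes < 2:
        raise TacitusError("batch adjustment requires >=2 genes")
    batch_ids = list(dict.fromkeys(batches.tolist()))
    if len(batch_ids) < 2:
        raise TacitusError("batch adjustment requires >=2 batches")
    batch_cols = [np.flatnonzero(batches == b) for b in batch_ids]
    sizes = np.array([len(c) for c in batch_cols])
    for b, size in zip(batch_ids, sizes):
        if size < 2:
            raise TacitusError(f"batch {b!r} has {size} sample(s); >=2 required")

    # per-batch gene means; grand mean is their size-weighted average
    batch_means = np.stack([values[:, c].mean(axis=1) for c in batch_cols], axis=1)
    grand = batch_means @ (sizes / n_total)
    # pooled variance of residuals around the own-batch mean, divisor N
    resid = values.copy()
    for j, cols in enumerate(batch_cols):
        resid[:, cols] -= batch_means[:, [j]]
    pooled_var = (resid**2).sum(axis=1) / n_total
    pooled_sd = np.sqrt(np.maximum(pooled_var, _EPS))
    z = (values - grand[:, None]) / pooled_sd[:, None]

    adjusted = np.empty_like(z)
    for j, cols in enumerate(batch_cols):
        n_b = sizes[j]
        zb = z[:, cols]
        gamma_hat = zb.mean(axis=1)
        delta_hat = ((zb - gamma_hat[:, None]) ** 2).mean(axis=1)  # divisor n_b

        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)

        if tau2 < _EPS and s2 < _EPS:
            gamma_star = np.full(n_genes, gamma_bar)
            delta_star = delta_hat.copy()
        elif s2 < _EPS:
            delta_star = delta_hat.copy()
            gamma_star = (n_b * tau2 * gamma_hat + delta_star * gamma_bar) / (
                n_b * tau2 + delta_star
            )
        else:
            lam = (m * m + 2.0 * s2) / s2
            theta = (m**3 + m * s2) / s2
            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            converged = False
            for _ in range(max_iter):
                if tau2 < _EPS:
                    g_new = np.full(n_genes, gamma_bar)
                else:
                    g_new = (n_b * tau2 * gamma_hat + delta_star * gamma_bar) / (
                        n_b * tau2 + delta_star
                    )
                sum_sq = ((zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (theta + 0.5 * sum_sq) / (n_b / 2.0 + lam - 1.0)
                change = max(
                    np.max(np.abs(g_new - gamma_star) / np.maximum(np.abs(gamma_star), _EPS)),
                    np.max(np.abs(d_new - delta_star) / np.maximum(np.abs(delta_star), _EPS)),
                )
                gamma_star, delta_star = g_new, d_new
                if change < tol:
                    converged = True
                    break
            if not converged:
                logger.warning(
                    "batch %r: EB iteration did not converge in %d steps", batch_ids[j], max_iter
                )
        delta_star = np.maximum(delta_star, _EPS)
        adjusted[:, cols] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    return adjusted * pooled_sd[:, None] + grand[:, None]


def combat_integration(
    matrix: ExpressionMatrix,
    batch_labels: dict[str, int],
    metadata: SampleMetadata | None = None,
) -> IntegratedDataset:
    """Apply :func:`combat_adjust` to an already-merged matrix."""
    batches = np.array([batch_labels[s] for s in matrix.sample_ids])
    adjusted = combat_adjust(matrix.values, batches)
    out = ExpressionMatrix(matrix.probe_ids, matrix.sample_ids, adjusted, scale=matrix.scale)
    if metadata is None:
        metadata = merge_metadata(
            [SampleMetadata(matrix.sample_ids, [], {s: {} for s in matrix.sample_ids})]
        )
        for sid in metadata.sample_ids:
            metadata.table[sid]["batch"] = str(batch_labels[sid])
    return IntegratedDataset(out, metadata, dict(batch_labels), "combat")


# ---------------------------------------------------------------------------
# block normalization (pairwise)


def _row_standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd < _EPS, 1.0, sd)
    return (values - mean) / sd


def _kmeans_labels(points: np.ndarray, k: int, seed: int) -> np.ndarray:
    if k <= 1 or len(points) <= k:
        if len(points) <= k:
            return np.arange(len(points))
        return np.zeros(len(points), dtype=int)
    km = KMeans(n_clusters=k, n_init=1, random_state=seed)
    return km.fit_predict(points)


def _fit_block_model(
    x: np.ndarray,
    gene_cluster: np.ndarray,
    sample_cluster: np.ndarray,
    n_gene_clusters: int,
    n_sample_clusters: int,
    n_iter: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit of x_gs = A[α(g), β(s)]·b_g + c_g + σ_g·ε_gs.

    Returns (A, b, c, sigma, eps)."""
    n_genes, n_samples = x.shape
    b = np.ones(n_genes)
    c = x.mean(axis=1)
    sigma = np.maximum(x.std(axis=1, ddof=1), _EPS)
    A = np.zeros((n_gene_clusters, n_sample_clusters))

    gene_groups = [np.flatnonzero(gene_cluster == k) for k in range(n_gene_clusters)]
    sample_groups = [np.flatnonzero(sample_cluster == l) for l in range(n_sample_clusters)]

    for _ in range(n_iter):
        w = 1.0 / np.maximum(sigma**2, _EPS)
        # block update of A given (b, c)
        for k, gg in enumerate(gene_groups):
            if len(gg) == 0:
                continue
            wk = w[gg] * b[gg]
            denom_per_gene = w[gg] * b[gg] ** 2
            for l, ss in enumerate(sample_groups):
                if len(ss) == 0:
                    A[k, l] = 0.0
                    continue
                resid = x[np.ix_(gg, ss)] - c[gg][:, None]
                num = (wk[:, None] * resid).sum()
                den = denom_per_gene.sum() * len(ss)
                A[k, l] = num / den if den > _EPS else 0.0
        # per-gene regression of x on the block profile
        a = A[gene_cluster][:, sample_cluster]  # genes x samples
        a_mean = a.mean(axis=1)
        x_mean = x.mean(axis=1)
        a_centered = a - a_mean[:, None]
        var_a = (a_centered**2).mean(axis=1)
        cov_ax = (a_centered * (x - x_mean[:, None])).mean(axis=1)
        b = np.where(var_a > _EPS, cov_ax / np.maximum(var_a, _EPS), 1.0)
        c = x_mean - b * a_mean
        fitted = a * b[:, None] + c[:, None]
        res = x - fitted
        if n_samples > 2:
            sigma = np.maximum(np.sqrt((res**2).sum(axis=1) / (n_samples - 2)), _EPS)
        else:
            sigma = np.maximum(res.std(axis=1, ddof=0), _EPS)

    a = A[gene_cluster][:, sample_cluster]
    fitted = a * b[:, None] + c[:, None]
    eps = (x - fitted) / sigma[:, None]
    return A, b, c, sigma, eps


def xpn_integration(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    metadatas: list[SampleMetadata] | None = None,
    n_gene_clusters: int = 25,
    n_sample_clusters: int = 5,
    n_repeats: int = 30,
    seed: int = 0,
) -> IntegratedDataset:
    """Pairwise block normalization of two platforms.

    Per repeat: genes are clustered on the combined row-standardized data
    and samples of both platforms jointly; a block-linear model is fitted
    per platform; block parameters are replaced by sample-size-weighted
    cross-platform averages and the data reconstructed. The final output is
    the mean over repeats. Deterministic given ``seed``.
    """
    merged, batch_labels = merge_matrices([matrix_a, matrix_b])
    n_a = matrix_a.n_samples
    n_b = matrix_b.n_samples
    if n_a < 2 or n_b < 2:
        raise TacitusError("xpn requires >=2 samples in each platform")
    n_genes = merged.n_probes
    n_total = n_a + n_b

    k = n_gene_clusters
    l = n_sample_clusters
    max_k = max(1, n_genes // 2)
    max_l = max(1, min(n_a, n_b) // 2)
    if k > max_k:
        logger.warning("clamping gene clusters %d -> %d (few genes)", k, max_k)
        k = max_k
    if l > max_l:
        logger.warning("clamping sample clusters %d -> %d (few samples)", l, max_l)
        l = max_l

    cols_a = np.arange(n_a)
    cols_b = np.arange(n_a, n_total)
    x_a = merged.values[:, cols_a]
    x_b = merged.values[:, cols_b]
    z = np.concatenate([_row_standardize(x_a), _row_standardize(x_b)], axis=1)

    rng = np.random.default_rng(seed)
    acc = np.zeros_like(merged.values)
    for _ in range(n_repeats):
        gene_cluster = _kmeans_labels(z, k, int(rng.integers(2**31)))
        sample_cluster = _kmeans_labels(z.T, l, int(rng.integers(2**31)))
        sc_a = sample_cluster[cols_a]
        sc_b = sample_cluster[cols_b]

        A_a, b_a, c_a, s_a, e_a = _fit_block_model(x_a, gene_cluster, sc_a, k, l)
        A_b, b_b, c_b, s_b, e_b = _fit_block_model(x_b, gene_cluster, sc_b, k, l)

        b_avg = (n_a * b_a + n_b * b_b) / n_total
        c_avg = (n_a * c_a + n_b * c_b) / n_total
        s_avg = (n_a * s_a + n_b * s_b) / n_total
        # block averages weighted by the per-platform occupancy of each
        # joint sample cluster; an empty side contributes zero weight
        counts_a = np.bincount(sc_a, minlength=l).astype(float)
        counts_b = np.bincount(sc_b, minlength=l).astype(float)
        denom = np.maximum(counts_a + counts_b, 1.0)
        A_avg = (A_a * counts_a[None, :] + A_b * counts_b[None, :]) / denom[None, :]

        prof_a = A_avg[gene_cluster][:, sc_a]
        prof_b = A_avg[gene_cluster][:, sc_b]
        rec_a = prof_a * b_avg[:, None] + c_avg[:, None] + s_avg[:, None] * e_a
        rec_b = prof_b * b_avg[:, None] + c_avg[:, None] + s_avg[:, None] * e_b
        acc[:, cols_a] += rec_a
        acc[:, cols_b] += rec_b
    acc /= n_repeats

    out = ExpressionMatrix(merged.probe_ids, merged.sample_ids, acc, scale=merged.scale)
    return _assemble(out, metadatas, [matrix_a, matrix_b], batch_labels, "xpn")


# ---------------------------------------------------------------------------
# dispatch + output


def log2_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Transform count-scale data to log2 counts-per-million (+0.5 offset)."""
    if matrix.scale != "linear_count":
        return matrix
    lib = matrix.values.sum(axis=0)
    vals = np.log2((matrix.values + 0.5) / (lib + 1.0) * 1e6)
    return ExpressionMatrix(matrix.probe_ids, matrix.sample_ids, vals, scale="log2_cpm")


def integrate(
    selections: list[tuple[ExpressionMatrix, SampleMetadata]],
    method: str = "none",
    seed: int = 0,
    xpn_gene_clusters: int = 25,
    xpn_sample_clusters: int = 5,
    xpn_repeats: int = 30,
) -> IntegratedDataset:
    """Merge selections and apply the chosen integration method.

    Method ``none`` merges with values bit-unchanged; the Gaussian-scale
    methods first convert count-scale inputs to log2-CPM.
    """
    if method not in METHODS:
        raise TacitusError(f"unknown method {method!r}; expected one of {METHODS}")
    if not selections:
        raise TacitusError("no selections to integrate")
    matrices = [m for m, _ in selections]
    metadatas = [md for _, md in selections]
    if method != "none":
        if len(selections) < 2:
            raise TacitusError(f"method {method!r} requires >=2 selections")
        matrices = [log2_cpm(m) for m in matrices]
    if method == "xpn" and len(matrices) != 2:
        raise TacitusError("xpn is pairwise: exactly 2 selections required")

    if method == "none":
        merged, batches = merge_matrices(matrices)
        return _assemble(merged, metadatas, matrices, batches, "none")
    if method == "sims":
        return mean_center_integration(matrices, metadatas)
    if method == "genestd":
        return gene_standardize_integration(matrices, metadatas)
    if method == "combat":
        merged, batches = merge_matrices(matrices)
        md = merge_metadata(metadatas).subset(merged.sample_ids)
        batch_arr = np.array([batches[s] for s in merged.sample_ids])
        adjusted = combat_adjust(merged.values, batch_arr)
        out = ExpressionMatrix(merged.probe_ids, merged.sample_ids, adjusted, scale=merged.scale)
        return IntegratedDataset(out, md, batches, "combat")
    return xpn_integration(
        matrices[0],
        matrices[1],
        metadatas,
        n_gene_clusters=xpn_gene_clusters,
        n_sample_clusters=xpn_sample_clusters,
        n_repeats=xpn_repeats,
        seed=seed,
    )


def write_integrated(
    dataset: IntegratedDataset,
    out_dir: str | Path,
    dialect: str = "tsv",
    delimiter: str | None = None,
) -> tuple[Path, Path]:
    """Write the combined matrix and merged metadata into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if dialect == "tsv" else "csv"
    matrix_path = out_dir / f"matrix.{ext}"
    metadata_path = out_dir / f"metadata.{ext}"
    io_formats.write_table(dataset.matrix, matrix_path, dialect=dialect, delimiter=delimiter)
    io_formats.write_metadata(dataset.metadata, metadata_path, dialect=dialect, delimiter=delimiter)
    return matrix_path, metadata_path
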