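"""Synthetic differential-expression benchmark.

Simulates microarray-like (Gaussian log-intensity) and NGS-like
(negative-binomial count) two-condition datasets with known DEG truth,
randomly partitions them, integrates the halves with a chosen method,
calls DEGs with an empirical-Bayes moderated t-test, and scores the
ranking by ROC/AUC against the simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.metrics import roc_curve

from tacitus import integrate as integ
from tacitus.types import ExpressionMatrix, SampleMetadata, TacitusError

BENCHMARK_METHODS = ("baseline", "none", "sims", "genestd", "combat", "xpn")

#: p-value thresholds for the secondary (partial) ROC sweep.
SWEEP_THRESHOLDS = tuple(np.round(np.arange(0.001, 0.0501, 0.001), 4))


@dataclass
class SimulatedDataset:
    """Expression matrix + condition labels + ground-truth DEG set."""

    matrix: ExpressionMatrix
    condition: dict[str, str]
    truth: dict[str, str]  # gene id -> "up" | "down"

    def __post_init__(self) -> None:
        probe_set = set(self.matrix.probe_ids)
        bad = [g for g in self.truth if g not in probe_set]
        if bad:
            raise TacitusError(f"truth genes absent from matrix: {bad[:5]}")
        labels = set(self.condition.values())
        if labels - {"case", "control"}:
            raise TacitusError(f"unknown condition labels: {labels}")
        if "case" not in labels or "control" not in labels:
            raise TacitusError("both conditions must be non-empty")

    @property
    def truth_ids(self) -> set[str]:
        return set(self.truth)


@dataclass
class DEGResult:
    """Per-gene moderated t statistics."""

    gene_ids: list[str]
    t: np.ndarray
    p: np.ndarray
    lfc_sign: np.ndarray
    prior_df: float
    prior_var: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.gene_ids, "t": self.t, "p": self.p, "sign": self.lfc_sign}
        )


@dataclass
class ROCResult:
    """Full-ranking ROC curve plus a p-threshold sweep for reporting."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    threshold_curve: list[tuple[float, float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# simulators


def _truth_split(n_genes: int, frac_de: float, rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Pick round(frac_de*n_genes) DE gene indexes, half up / half down."""
    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    n_up = n_de // 2
    up = sorted(de_idx[:n_up].tolist())
    down = sorted(de_idx[n_up:].tolist())
    return up, down


def _sample_names(n_per_group: int) -> tuple[list[str], dict[str, str]]:
    cases = [f"case_{i + 1}" for i in range(n_per_group)]
    controls = [f"ctrl_{i + 1}" for i in range(n_per_group)]
    condition = {s: "case" for s in cases}
    condition.update({s: "control" for s in controls})
    return cases + controls, condition


def simulate_microarray(
    n_genes: int = 10000,
    n_per_group: int = 7,
    frac_de: float = 0.1,
    lfc_sd: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SimulatedDataset:
    """Gaussian log-intensity simulator.

    Gene baselines are Normal(7, 1.5); DE genes receive a group-mean offset
    of magnitude |Normal(0, lfc_sd)| clamped at >= 0.5, signed by direction;
    per-sample noise is Normal(0, noise_sd).
    """
    if not 0.0 <= frac_de <= 1.0:
        raise TacitusError("frac_de must be in [0, 1]")
    if min(n_genes, n_per_group) < 1 or min(lfc_sd, noise_sd) <= 0:
        raise TacitusError("simulation parameters must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i + 1}" for i in range(n_genes)]
    sample_ids, condition = _sample_names(n_per_group)

    baseline = rng.normal(7.0, 1.5, size=n_genes)
    up, down = _truth_split(n_genes, frac_de, rng)
    offset = np.zeros(n_genes)
    for idx, sign in ((up, 1.0), (down, -1.0)):
        mags = np.maximum(np.abs(rng.normal(0.0, lfc_sd, size=len(idx))), 0.5)
        offset[idx] = sign * mags

    means = np.tile(baseline[:, None], (1, 2 * n_per_group))
    means[:, :n_per_group] += offset[:, None]  # cases shifted
    values = means + rng.normal(0.0, noise_sd, size=means.shape)

    matrix = ExpressionMatrix(gene_ids, sample_ids, values, scale="log2_intensity")
    truth = {gene_ids[i]: "up" for i in up}
    truth.update({gene_ids[i]: "down" for i in down})
    return SimulatedDataset(matrix, condition, truth)


def simulate_counts(
    n_genes: int = 12500,
    n_per_group: int = 7,
    frac_de: float = 0.1,
    effect: float = 1.5,
    seed: int = 0,
    dispersion: float | None = None,
) -> SimulatedDataset:
    """Negative-binomial count simulator.

    Per-gene means are log-normal with median ~100; per-gene dispersions are
    Gamma-distributed around 0.2 (a fixed ``dispersion`` can be forced for
    moment checks). DE genes have their case-group mean multiplied or
    divided by ``effect``.
    """
    if effect <= 1.0:
        raise TacitusError("effect must be > 1")
    if not 0.0 <= frac_de <= 1.0:
        raise TacitusError("frac_de must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i + 1}" for i in range(n_genes)]
    sample_ids, condition = _sample_names(n_per_group)

    mu = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    if dispersion is not None:
        phi = np.full(n_genes, float(dispersion))
    else:
        phi = rng.gamma(shape=4.0, scale=0.05, size=n_genes)  # mean 0.2
    phi = np.maximum(phi, 1e-8)

    up, down = _truth_split(n_genes, frac_de, rng)
    case_mu = mu.copy()
    case_mu[up] *= effect
    case_mu[down] /= effect

    n_samples = 2 * n_per_group
    means = np.tile(mu[:, None], (1, n_samples))
    means[:, :n_per_group] = case_mu[:, None]
    # gamma-Poisson mixture: counts ~ NB(mean=m, var=m + phi m^2)
    lam = rng.gamma(shape=(1.0 / phi)[:, None], scale=means * phi[:, None])
    values = rng.poisson(lam).astype(float)

    matrix = ExpressionMatrix(gene_ids, sample_ids, values, scale="linear_count")
    truth = {gene_ids[i]: "up" for i in up}
    truth.update({gene_ids[i]: "down" for i in down})
    return SimulatedDataset(matrix, condition, truth)


def random_partition(
    dataset: SimulatedDataset, seed: int = 0
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Split the samples into two stratified halves (floor(n/2) / ceil(n/2)).

    Both halves keep every gene, the truth set, and at least one sample of
    each condition.
    """
    sample_ids = dataset.matrix.sample_ids
    if len(sample_ids) < 4:
        raise TacitusError("partition requires >=4 samples")
    rng = np.random.default_rng(seed)
    half_a: list[str] = []
    half_b: list[str] = []
    for i, label in enumerate(("case", "control")):
        group = [s for s in sample_ids if dataset.condition[s] == label]
        if len(group) < 2:
            raise TacitusError(f"condition {label!r} has {len(group)} sample(s); >=2 required")
        group = [group[j] for j in rng.permutation(len(group))]
        # alternate rounding across conditions so the overall split is n//2 vs n-n//2
        cut = (len(group) + i) // 2
        half_a.extend(group[:cut])
        half_b.extend(group[cut:])

    def _subset(ids: list[str]) -> SimulatedDataset:
        ordered = [s for s in sample_ids if s in set(ids)]
        return SimulatedDataset(
            matrix=dataset.matrix.subset_samples(ordered),
            condition={s: dataset.condition[s] for s in ordered},
            truth=dict(dataset.truth),
        )

    return _subset(half_a), _subset(half_b)


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on the trigamma function
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (prior df d0, prior variance s0^2) on log sample variances."""
    ok = s2 > 0
    if ok.sum() < 2:
        return 1e6, float(np.median(s2)) if len(s2) else 1.0
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        d0 = min(d0, 1e6)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = 1e6
        s0_2 = float(np.exp(e_mean))
    return d0, s0_2


def moderated_t_test(
    matrix: ExpressionMatrix,
    condition: dict[str, str],
    prior_df: float | None = None,
) -> DEGResult:
    """Two-group moderated t-test with empirical-Bayes variance shrinkage.

    Count-scale matrices are converted to log2-CPM first. Per gene the
    pooled residual variance (n-2 df) is shrunk toward a prior variance
    estimated across genes; ``prior_df=0`` recovers the ordinary pooled
    two-sample t-test.
    """
    matrix = integ.log2_cpm(matrix)
    # canonical (sorted) group order so results are invariant to column order
    cases = sorted(s for s in matrix.sample_ids if condition.get(s) == "case")
    controls = sorted(s for s in matrix.sample_ids if condition.get(s) == "control")
    n1, n2 = len(cases), len(controls)
    if n1 < 2 or n2 < 2:
        raise TacitusError(f"both groups need >=2 samples (got {n1} cases, {n2} controls)")
    idx = {s: j for j, s in enumerate(matrix.sample_ids)}
    x1 = matrix.values[:, [idx[s] for s in cases]]
    x2 = matrix.values[:, [idx[s] for s in controls]]

    diff = x1.mean(axis=1) - x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df

    if prior_df is None:
        d0, s0_2 = _fit_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        s0_2 = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    d0 = min(d0, 1e6)

    if d0 > 0:
        s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        s2_tilde = s2.copy()
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))

    t = np.zeros_like(diff)
    nonzero = se > 0
    t[nonzero] = diff[nonzero] / se[nonzero]
    # zero moderated variance with zero difference: no evidence, t = 0
    total_df = min(d0 + df, 1e6)
    p = 2.0 * stats.t.sf(np.abs(t), df=total_df)
    p = np.clip(p, 0.0, 1.0)
    return DEGResult(
        gene_ids=list(matrix.probe_ids),
        t=t,
        p=p,
        lfc_sign=np.sign(diff),
        prior_df=d0,
        prior_var=s0_2,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(result: DEGResult, truth: set[str]) -> ROCResult:
    """ROC over the full p-value ranking against the truth set.

    Genes are scored by -p (ascending p first); ties follow the midrank
    convention. A secondary partial curve at the fixed p-value thresholds in
    :data:`SWEEP_THRESHOLDS` is attached for reporting.
    """
    if not truth:
        raise TacitusError("empty truth set")
    gene_set = set(result.gene_ids)
    pos = truth & gene_set
    if not pos:
        raise TacitusError("truth set does not overlap the result genes")
    if len(pos) == len(gene_set):
        raise TacitusError("degenerate truth: every gene is a true DEG")

    y_true = np.array([1 if g in pos else 0 for g in result.gene_ids])
    score = -result.p
    fpr, tpr, _ = roc_curve(y_true, score, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))

    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    sweep = []
    for thr in SWEEP_THRESHOLDS:
        called = result.p < thr
        tp = int((called & (y_true == 1)).sum())
        fp = int((called & (y_true == 0)).sum())
        sweep.append((float(thr), fp / n_neg, tp / n_pos))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, threshold_curve=sweep)


# ---------------------------------------------------------------------------
# benchmark driver


def _metadata_for(half: SimulatedDataset) -> SampleMetadata:
    ids = half.matrix.sample_ids
    return SampleMetadata(
        ids, ["condition"], {s: {"condition": half.condition[s]} for s in ids}
    )


def _simulate(kind: str, seed: int, sim_params: dict | None) -> SimulatedDataset:
    params = dict(sim_params or {})
    if kind == "microarray":
        return simulate_microarray(seed=seed, **params)
    if kind == "ngs":
        return simulate_counts(seed=seed, **params)
    raise TacitusError(f"unknown kind {kind!r}; expected 'microarray' or 'ngs'")


def run_benchmark(
    kind: str,
    methods: list[str],
    n_replicates: int = 10,
    seed: int = 0,
    sim_params: dict | None = None,
    xpn_repeats: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, partition, integrate, DEG-call and score per method.

    ``baseline`` scores the moderated-t ranking on the unsplit matrix; every
    other method partitions the samples, integrates the two halves and
    scores the integrated matrix. Returns (per-replicate table, per-method
    mean AUC summary); deterministic given ``seed``.
    """
    unknown = [m for m in methods if m not in BENCHMARK_METHODS]
    if unknown:
        raise TacitusError(f"unknown methods {unknown}; expected subset of {BENCHMARK_METHODS}")
    records = []
    for rep in range(n_replicates):
        sim_seed = seed + 1000 * rep
        dataset = _simulate(kind, sim_seed, sim_params)
        truth = dataset.truth_ids
        halves = None
        for method in methods:
            if method == "baseline":
                deg = moderated_t_test(dataset.matrix, dataset.condition)
            else:
                if halves is None:
                    halves = random_partition(dataset, seed=sim_seed + 1)
                a, b = halves
                result = integ.integrate(
                    [(a.matrix, _metadata_for(a)), (b.matrix, _metadata_for(b))],
                    method=method,
                    seed=sim_seed + 2,
                    xpn_repeats=xpn_repeats,
                )
                deg = moderated_t_test(result.matrix, dataset.condition)
            auc = roc_auc(deg, truth).auc
            records.append({"method": method, "replicate": rep, "auc": auc})
    table = pd.DataFrame.from_records(records, columns=["method", "replicate", "auc"])
    summary = (
        table.groupby("method", sort=False)["auc"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_auc", "std": "sd_auc", "count": "n_replicates"})
    )
    return table, summary
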