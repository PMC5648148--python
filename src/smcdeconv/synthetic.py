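"""Self-contained synthetic benchmarks mimicking mixed-tissue microarrays.

Datasets follow the simulation design used to test blind deconvolution:
positive RMA-scale signature intensities, per-sample mixing proportions drawn
column-wise from a Dirichlet distribution, additive zero-mean Gaussian noise,
and pure-sample technical replicates for deriving ground-truth signatures and
marker genes.

The signature generator plants differential expression explicitly: baseline
intensities are log-normal (log-mean 6, log-sd 1, i.e. roughly 10-10^4 on the
linear scale); a ``de_fraction`` of genes has one randomly chosen cell type
multiplied by ``fold_factor`` (> 2), while every other gene is identical
across types, so the fold-change-rule DE labels are exact by construction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluate import de_truth_labels
from .model import ExpressionMatrix

__all__ = [
    "SimulationTruth",
    "simulate_proportions",
    "simulate_signatures",
    "simulate_mixture",
    "simulate_pure_replicates",
    "simulate_dataset",
    "make_benchmark",
]

# Study-condition defaults: 500 genes, 3 cell types, flat Dirichlet mixing,
# noise sd at 5% of the mean mixed intensity, 3 technical replicates per
# pure type, 30% of genes with a 5-fold planted expression difference.
DEFAULT_I = 500
DEFAULT_K = 3
DEFAULT_DIRICHLET_ALPHA = 1.0
DEFAULT_NOISE_FRACTION = 0.05
DEFAULT_DE_FRACTION = 0.3
DEFAULT_FOLD_FACTOR = 5.0
DEFAULT_N_REP = 3
DEFAULT_J_GRID = (10, 15, 20, 25, 30, 35, 40)
DEFAULT_N_RUNS = 25


@dataclass
class SimulationTruth:
    """A generated dataset together with everything needed to score it."""

    X_true: np.ndarray
    M_true: np.ndarray
    noise_sd: float
    Y: ExpressionMatrix
    Y_pure: ExpressionMatrix
    pure_labels: tuple[str, ...]
    de_labels: dict[tuple[int, int], np.ndarray]
    seed: int


def simulate_proportions(
    K: int, J: int, alpha_dirichlet: float | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """K x J proportion matrix; each column an independent Dirichlet draw."""
    if K < 1 or J < 1:
        raise ValueError("K and J must be >= 1")
    alpha = np.broadcast_to(np.asarray(alpha_dirichlet, dtype=float), (K,))
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentration must be positive")
    return rng.dirichlet(alpha, size=J).T


def simulate_signatures(
    I: int,
    K: int,
    rng: np.random.Generator,
    *,
    log_mean: float = 6.0,
    log_sd: float = 1.0,
    de_fraction: float = DEFAULT_DE_FRACTION,
    fold_factor: float = DEFAULT_FOLD_FACTOR,
) -> np.ndarray:
    """I x K positive signature matrix with planted differential expression.

    Non-DE genes have the same intensity in every cell type (fold change 1);
    each DE gene has exactly one type upregulated by ``fold_factor``, so its
    true fold change against every other type is exactly ``fold_factor``.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if fold_factor <= 2.0:
        raise ValueError("fold_factor must exceed the DE-rule threshold of 2")
    base = rng.lognormal(mean=log_mean, sigma=log_sd, size=I)
    X = np.tile(base[:, None], (1, K)).astype(float)
    n_de = int(round(de_fraction * I))
    de_genes = rng.choice(I, size=n_de, replace=False)
    up_types = rng.integers(0, K, size=n_de)
    X[de_genes, up_types] *= fold_factor
    return X


def simulate_mixture(
    X_true: np.ndarray,
    M_true: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    gene_ids=None,
    sample_ids=None,
) -> ExpressionMatrix:
    """Y = X_true M_true + E with i.i.d. Normal(0, noise_sd^2) noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    mean = np.asarray(X_true, float) @ np.asarray(M_true, float)
    Y = mean + noise_sd * rng.standard_normal(mean.shape)
    return ExpressionMatrix.from_values(Y, gene_ids=gene_ids, sample_ids=sample_ids)


def simulate_pure_replicates(
    X_true: np.ndarray,
    n_rep: int,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    gene_ids=None,
    type_names: tuple[str, ...] | None = None,
) -> tuple[ExpressionMatrix, tuple[str, ...]]:
    """Pure-sample replicate matrix: n_rep noisy copies of each signature column.

    Returns the K*n_rep-column matrix and the per-column cell-type labels.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    X_true = np.asarray(X_true, float)
    I, K = X_true.shape
    if type_names is None:
        type_names = tuple(f"type{k}" for k in range(K))
    cols, labels, ids = [], [], []
    for k in range(K):
        for r in range(n_rep):
            cols.append(X_true[:, k] + noise_sd * rng.standard_normal(I))
            labels.append(type_names[k])
            ids.append(f"{type_names[k]}_rep{r}")
    mat = ExpressionMatrix.from_values(
        np.column_stack(cols), gene_ids=gene_ids, sample_ids=ids
    )
    return mat, tuple(labels)


def simulate_dataset(
    I: int = DEFAULT_I,
    K: int = DEFAULT_K,
    J: int = 10,
    *,
    seed: int = 0,
    alpha_dirichlet: float = DEFAULT_DIRICHLET_ALPHA,
    noise_fraction: float | None = DEFAULT_NOISE_FRACTION,
    noise_sd: float | None = None,
    de_fraction: float = DEFAULT_DE_FRACTION,
    fold_factor: float = DEFAULT_FOLD_FACTOR,
    n_rep: int = DEFAULT_N_REP,
) -> SimulationTruth:
    """Generate one complete benchmark dataset.

    The noise standard deviation is either given absolutely (``noise_sd``) or
    as a fraction of the mean mixed intensity (``noise_fraction``, default 5%).
    """
    rng = np.random.default_rng(seed)
    X_true = simulate_signatures(
        I, K, rng, de_fraction=de_fraction, fold_factor=fold_factor
    )
    M_true = simulate_proportions(K, J, alpha_dirichlet, rng)
    if noise_sd is None:
        if noise_fraction is None:
            raise ValueError("give either noise_sd or noise_fraction")
        noise_sd = float(noise_fraction) * float((X_true @ M_true).mean())
    Y = simulate_mixture(X_true, M_true, noise_sd, rng)
    Y_pure, labels = simulate_pure_replicates(X_true, n_rep, noise_sd, rng)
    de_labels = {
        (r, u): de_truth_labels(X_true, (r, u))
        for r, u in itertools.permutations(range(K), 2)
    }
    return SimulationTruth(
        X_true=X_true,
        M_true=M_true,
        noise_sd=float(noise_sd),
        Y=Y,
        Y_pure=Y_pure,
        pure_labels=labels,
        de_labels=de_labels,
        seed=seed,
    )


def make_benchmark(
    out_dir: str | Path,
    *,
    I: int = DEFAULT_I,
    K: int = DEFAULT_K,
    J_grid: tuple[int, ...] = DEFAULT_J_GRID,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
    **dataset_kwargs,
) -> dict:
    """Write a deterministic bundle of datasets across sample sizes to disk.

    Every (J, run) cell gets its own sub-seed derived from ``seed``; a
    manifest (JSON) records parameters and file paths.  Returns the manifest.
    """
    from .io import write_matrix  # local import: io depends on model only

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for J in J_grid:
        for run in range(n_runs):
            sub_seed = int(
                np.random.SeedSequence([seed, J, run]).generate_state(1)[0] % (2**31)
            )
            sim = simulate_dataset(I=I, K=K, J=J, seed=sub_seed, **dataset_kwargs)
            tag = f"J{J}_run{run}"
            paths = {
                "Y": f"{tag}_Y.tsv",
                "Y_pure": f"{tag}_Ypure.tsv",
                "X_true": f"{tag}_Xtrue.tsv",
                "M_true": f"{tag}_Mtrue.tsv",
            }
            write_matrix(sim.Y, out_dir / paths["Y"])
            write_matrix(sim.Y_pure, out_dir / paths["Y_pure"])
            write_matrix(
                ExpressionMatrix.from_values(
                    sim.X_true, sample_ids=[f"type{k}" for k in range(K)]
                ),
                out_dir / paths["X_true"],
            )
            write_matrix(
                ExpressionMatrix.from_values(
                    sim.M_true,
                    gene_ids=[f"type{k}" for k in range(K)],
                    sample_ids=list(sim.Y.sample_ids),
                ),
                out_dir / paths["M_true"],
            )
            entries.append(
                {"J": J, "run": run, "seed": sub_seed,
                 "noise_sd": sim.noise_sd,
                 "pure_labels": list(sim.pure_labels),
                 "files": paths}
            )
    manifest = {
        "seed": seed, "I": I, "K": K, "J_grid": list(J_grid),
        "n_runs": n_runs, "params": {k: v for k, v in dataset_kwargs.items()},
        "datasets": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
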