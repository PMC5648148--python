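"""Point estimates, proportion rescaling, marker genes and cell-type mapping.

The final weighted particle set is collapsed to weighted posterior means
(theta_hat = sum_n w_n theta_n) with weighted standard deviations as spreads.
Because the decomposition is blind, the estimated cell-type columns carry an
arbitrary permutation (label switching); it is resolved by scoring estimated
columns against marker genes derived from pure-sample signatures.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import ExpressionMatrix
from .sampler import ParticleSystem

__all__ = [
    "DeconvolutionResult",
    "MarkerSet",
    "posterior_estimate",
    "finalize_result",
    "rescale_proportions",
    "ground_truth_signatures",
    "select_markers",
    "map_cell_types",
]


@dataclass
class DeconvolutionResult:
    """Posterior point estimates with spreads.

    ``M_hat`` columns are nonnegative and sum to one.  ``X_raw``/``M_raw``
    keep the unclamped weighted means; ``mapping`` records the cell-type
    permutation applied (identity if unmapped); ``n_clamped`` how many
    negative proportion entries were clamped before rescaling.
    """

    X_hat: np.ndarray
    M_hat: np.ndarray
    lambda_hat: float
    X_sd: np.ndarray
    M_sd: np.ndarray
    lambda_sd: float
    mapping: tuple[int, ...]
    X_raw: np.ndarray
    M_raw: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if np.any(self.M_hat < 0):
            raise ValueError("M_hat entries must be nonnegative")
        if not np.allclose(self.M_hat.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("M_hat columns must sum to 1")


@dataclass
class MarkerSet:
    """Marker gene ids per cell type with their selection scores."""

    markers: dict[int, list[str]]
    scores: dict[int, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for k, genes in self.markers.items():
            overlap = seen.intersection(genes)
            if overlap:
                raise ValueError(f"marker genes shared across types: {sorted(overlap)}")
            seen.update(genes)

    @property
    def n_types(self) -> int:
        return len(self.markers)


def posterior_estimate(system: ParticleSystem) -> tuple[
    np.ndarray, np.ndarray, float, np.ndarray, np.ndarray, float
]:
    """Weighted posterior means and standard deviations of X, M and lambda.

    Returns ``(X_hat, M_hat_raw, lambda_hat, X_sd, M_sd, lambda_sd)`` prior to
    any clamping, rescaling or cell-type mapping.
    """
    w = system.norm_weights
    X_hat = np.einsum("n,nik->ik", w, system.X)
    M_hat = np.einsum("n,nkj->kj", w, system.M)
    lam_hat = float(w @ system.lam)
    X_var = np.einsum("n,nik->ik", w, (system.X - X_hat[None]) ** 2)
    M_var = np.einsum("n,nkj->kj", w, (system.M - M_hat[None]) ** 2)
    lam_var = float(w @ (system.lam - lam_hat) ** 2)
    return X_hat, M_hat, lam_hat, np.sqrt(X_var), np.sqrt(M_var), np.sqrt(lam_var)


def finalize_result(
    system: ParticleSystem,
    markers: MarkerSet | None = None,
    gene_ids: tuple[str, ...] | None = None,
) -> DeconvolutionResult:
    """Full estimate pipeline: weighted means, clamp/rescale, optional mapping."""
    X_hat, M_raw, lam_hat, X_sd, M_sd, lam_sd = posterior_estimate(system)
    M_hat, n_clamped = rescale_proportions(M_raw)
    K = X_hat.shape[1]
    mapping: tuple[int, ...] = tuple(range(K))
    X_out = X_hat
    if markers is not None:
        if gene_ids is None:
            raise ValueError("gene_ids are required for marker-based mapping")
        X_out, M_hat, mapping = map_cell_types(X_hat, M_hat, markers, tuple(gene_ids))
        X_sd = X_sd[:, mapping]
        M_sd = M_sd[mapping, :]
    return DeconvolutionResult(
        X_hat=X_out,
        M_hat=M_hat,
        lambda_hat=lam_hat,
        X_sd=X_sd,
        M_sd=M_sd,
        lambda_sd=lam_sd,
        mapping=mapping,
        X_raw=X_hat,
        M_raw=M_raw,
        n_clamped=n_clamped,
    )


def rescale_proportions(M_raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Clamp negative entries to zero, then rescale each column to sum to 1.

    Returns the simplex-column matrix and the number of clamped entries.
    Raises if any column has no positive mass.
    """
    M_raw = np.asarray(M_raw, dtype=float)
    clamped = np.clip(M_raw, 0.0, None)
    n_clamped = int(np.sum(M_raw < 0))
    col_sums = clamped.sum(axis=0)
    dead = np.where(col_sums <= 0)[0]
    if dead.size:
        raise ValueError(
            f"proportion column(s) {dead.tolist()} have no positive entries"
        )
    return clamped / col_sums, n_clamped


def ground_truth_signatures(
    Y_pure: ExpressionMatrix, labels: list[str] | tuple[str, ...]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-type mean profiles from pure-sample replicates.

    ``labels`` names the cell type of each column of ``Y_pure``; signature
    ``x_ik`` is the mean of gene i over the replicates of type k.  Returns
    the I x K matrix and the type names in first-appearance order.
    """
    if len(labels) != Y_pure.n_samples:
        raise ValueError(
            f"{len(labels)} labels for {Y_pure.n_samples} pure samples"
        )
    types: list[str] = []
    for lab in labels:
        if lab not in types:
            types.append(lab)
    cols = {t: [j for j, lab in enumerate(labels) if lab == t] for t in types}
    X = np.column_stack(
        [Y_pure.values[:, cols[t]].mean(axis=1) for t in types]
    )
    return X, tuple(types)


def select_markers(
    X_true: np.ndarray,
    gene_ids: tuple[str, ...] | list[str],
    fold_margin: float = 5.0,
    floor: float | None = None,
    n_max: int = 50,
) -> MarkerSet:
    """Pick genes expressed predominantly in one cell type.

    Gene i is a candidate marker for type k iff
    ``x_ik >= fold_margin * max_{k' != k} x_ik'`` and ``x_ik >= floor``
    (default floor: the median of X_true).  The top ``n_max`` candidates per
    type by dominance ratio are retained; the unique-argmax condition makes
    marker lists disjoint by construction.
    """
    if fold_margin <= 1.0:
        raise ValueError("fold_margin must exceed 1")
    X_true = np.asarray(X_true, dtype=float)
    I, K = X_true.shape
    if len(gene_ids) != I:
        raise ValueError("gene id count does not match X_true rows")
    if floor is None:
        floor = float(np.median(X_true))
    markers: dict[int, list[str]] = {k: [] for k in range(K)}
    scores: dict[int, list[float]] = {k: [] for k in range(K)}
    for k in range(K):
        own = X_true[:, k]
        others = np.delete(X_true, k, axis=1)
        rival = others.max(axis=1) if K > 1 else np.zeros(I)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(rival > 0, own / rival, np.inf)
        cand = np.where((own >= fold_margin * rival) & (own >= floor))[0]
        order = cand[np.argsort(-ratio[cand])][:n_max]
        markers[k] = [gene_ids[i] for i in order]
        scores[k] = [float(ratio[i]) for i in order]
        if not len(order):
            warnings.warn(f"no marker genes found for cell type {k}", UserWarning,
                          stacklevel=2)
    return MarkerSet(markers=markers, scores=scores)


def _marker_score_matrix(
    X_hat: np.ndarray, gene_ids: tuple[str, ...], markers: MarkerSet
) -> np.ndarray:
    """score[c, k]: mean row-normalized X_hat over type-k markers, column c."""
    idx = {g: i for i, g in enumerate(gene_ids)}
    K = X_hat.shape[1]
    row_max = np.abs(X_hat).max(axis=1)
    row_max[row_max == 0] = 1.0
    Xn = X_hat / row_max[:, None]
    score = np.zeros((K, K))
    for k, genes in markers.markers.items():
        if not genes:
            continue
        rows = [idx[g] for g in genes]
        score[:, k] = Xn[rows].mean(axis=0)
    return score


def map_cell_types(
    X_hat: np.ndarray,
    M_hat: np.ndarray,
    markers: MarkerSet,
    gene_ids: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Resolve label switching by matching estimated columns to marker sets.

    Finds the permutation ``perm`` maximizing the total marker score, where
    ``perm[k]`` is the estimated column assigned to true type k; exhaustive
    search for K <= 8, greedy beyond.  Returns the permuted X_hat (columns)
    and M_hat (rows) and the permutation applied.
    """
    K = X_hat.shape[1]
    if not any(markers.markers.get(k) for k in range(K)):
        raise ValueError("markers are empty for every cell type")
    score = _marker_score_matrix(X_hat, gene_ids, markers)
    if np.allclose(score, score.flat[0]):
        warnings.warn("all marker scores tied; keeping lowest-index assignment",
                      UserWarning, stacklevel=2)
    if K <= 8:
        best, best_total = None, -np.inf
        for perm in itertools.permutations(range(K)):
            total = sum(score[perm[k], k] for k in range(K))
            if total > best_total + 1e-15:
                best, best_total = perm, total
        perm = best
    else:
        perm_l: list[int] = []
        taken: set[int] = set()
        for k in range(K):
            order = np.argsort(-score[:, k])
            choice = next(int(c) for c in order if int(c) not in taken)
            perm_l.append(choice)
            taken.add(choice)
        perm = tuple(perm_l)
    perm = tuple(int(c) for c in perm)
    return X_hat[:, perm], M_hat[perm, :], perm
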