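"""Alpha/beta diversity of immune-cell compositions and NMDS embedding.

Alpha diversity uses the Gini-Simpson index 1 - sum(p_i^2): the probability
that two cells drawn at random from a sample belong to different types.
Beta diversity defaults to the Bray-Curtis dissimilarity, which for
simplex-normalized rows reduces to 1 - sum(min(u_i, v_i)).  Samples are
embedded with non-metric multidimensional scaling (NMDS): Kruskal stress-1
is minimized by alternating isotonic regression of the embedded distances
against the rank order of input dissimilarities with SMACOF (Guttman
transform) coordinate updates, over several seeded random restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
from sklearn.isotonic import IsotonicRegression

from .deconvolution import CompositionTable

logger = logging.getLogger(__name__)


class DiversityError(ValueError):
    pass


class DegenerateDistanceError(DiversityError):
    """All pairwise dissimilarities are zero; no embedding is informative."""


def alpha_simpson(p, variant: str = "gini") -> float:
    """Simpson diversity of one composition row.

    ``gini`` returns 1 - sum(p^2) in [0, 1); ``inverse`` returns 1/sum(p^2).
    The row must lie on the probability simplex (sum 1 within 1e-6).
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise DiversityError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise DiversityError(f"composition row sums to {p.sum():.8f}, not 1")
    ss = float(np.sum(p**2))
    if variant == "gini":
        return 1.0 - ss
    if variant == "inverse":
        return 1.0 / ss
    raise DiversityError(f"unknown Simpson variant {variant!r}")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample dissimilarities with a zero diagonal."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.data.to_numpy(dtype=float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise DiversityError("distance matrix is not symmetric")
        if not np.all(np.diag(v) == 0):
            raise DiversityError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise DiversityError("distances must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def beta_braycurtis(composition: CompositionTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between composition rows."""
    if composition.data.shape[0] < 2:
        raise DiversityError("beta diversity needs at least 2 samples")
    X = composition.values
    D = ssd.squareform(ssd.pdist(X, metric="braycurtis"))
    np.fill_diagonal(D, 0.0)
    df = pd.DataFrame(D, index=composition.sample_ids, columns=composition.sample_ids)
    return DistanceMatrix(data=df)


def beta_distance(composition: CompositionTable, metric: str = "braycurtis") -> DistanceMatrix:
    """Beta diversity under a chosen dissimilarity (braycurtis, euclidean, jensenshannon)."""
    if metric == "braycurtis":
        return beta_braycurtis(composition)
    if metric not in {"euclidean", "jensenshannon"}:
        raise DiversityError(f"unknown beta metric {metric!r}")
    if composition.data.shape[0] < 2:
        raise DiversityError("beta diversity needs at least 2 samples")
    D = ssd.squareform(ssd.pdist(composition.values, metric=metric))
    np.fill_diagonal(D, 0.0)
    df = pd.DataFrame(D, index=composition.sample_ids, columns=composition.sample_ids)
    return DistanceMatrix(data=df)


@dataclass
class NMDSResult:
    sample_ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_restarts_used: int
    seed: int
    stress_history: list[float] = field(default_factory=list, repr=False)

    @property
    def frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _guttman_update(X: np.ndarray, dhat_sq: np.ndarray) -> np.ndarray:
    # dhat_sq: full square matrix of disparities
    n = X.shape[0]
    d = ssd.squareform(ssd.pdist(X))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat_sq / np.where(d > 0, d, 1.0), 0.0)
    B = -ratio
    np.fill_diagonal(B, 0.0)
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ X) / n


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
    tol: float = 1e-7,
) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Each restart starts from a seeded random configuration and alternates
    (a) isotonic regression of the current embedded Euclidean distances on
    the rank order of the input dissimilarities (weak monotonicity: ties in
    the input collapse to a common fitted value) with (b) a Guttman
    transform toward the fitted disparities.  A restart stops when stress
    improves by less than ``tol`` or would increase; the best restart wins.
    """
    if k not in (2, 3):
        raise DiversityError("k must be 2 or 3")
    delta_sq = d.values
    n = delta_sq.shape[0]
    if n < k + 1:
        raise DiversityError(f"NMDS with k={k} needs at least {k + 1} samples, got {n}")
    delta = ssd.squareform(delta_sq, checks=False)
    if np.all(delta == 0):
        raise DegenerateDistanceError("all pairwise distances are zero")

    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    rng = np.random.default_rng(seed)
    scale = float(np.max(delta))

    best: Optional[tuple[float, np.ndarray, list[float]]] = None
    for _ in range(n_restarts):
        X = rng.normal(scale=scale, size=(n, k))
        dists = ssd.pdist(X)
        dhat = iso.fit(delta[order], dists[order]).predict(delta)
        stress = _stress1(dists, dhat)
        history = [stress]
        for _ in range(max_iter):
            X_new = _guttman_update(X, ssd.squareform(dhat, checks=False))
            dists_new = ssd.pdist(X_new)
            dhat_new = iso.fit(delta[order], dists_new[order]).predict(delta)
            stress_new = _stress1(dists_new, dhat_new)
            if stress_new > stress:  # keep the monotone prefix
                break
            X, dists, dhat = X_new, dists_new, dhat_new
            improved = stress - stress_new
            stress = stress_new
            history.append(stress)
            if improved < tol:
                break
        if best is None or stress < best[0]:
            best = (stress, X, history)

    stress, X, history = best
    X = X - X.mean(axis=0, keepdims=True)
    logger.info("NMDS: stress=%.6g over %d restarts (seed=%d)", stress, n_restarts, seed)
    return NMDSResult(
        sample_ids=d.sample_ids,
        coordinates=X,
        stress=stress,
        n_restarts_used=n_restarts,
        seed=seed,
        stress_history=history,
    )


@dataclass
class DiversityReport:
    alpha: pd.Series
    beta: Optional[DistanceMatrix]
    nmds_result: Optional[NMDSResult]
    notices: list[str] = field(default_factory=list)


def diversity_report(
    composition: CompositionTable,
    groups: Optional[Mapping[str, str]] = None,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    metric: str = "braycurtis",
    simpson_variant: str = "gini",
    out_dir=None,
) -> DiversityReport:
    """Per-sample Simpson alpha, Bray-Curtis beta matrix, NMDS embedding, plots.

    With fewer than 2 samples the beta/NMDS stages are skipped with a
    logged notice; a degenerate (all-identical) cohort skips NMDS only.
    Static plots (stacked bars, dendrogram, alpha scatter, NMDS scatter)
    are written to ``out_dir`` when given.
    """
    samples = composition.sample_ids
    if groups is not None:
        unknown = [s for s in groups if s not in samples]
        if unknown:
            raise DiversityError(f"group map references unknown samples: {unknown}")
    notices: list[str] = []
    alpha = pd.Series(
        [alpha_simpson(composition.data.loc[s], variant=simpson_variant) for s in samples],
        index=samples,
        name="simpson",
    )
    beta = None
    embedding = None
    if len(samples) < 2:
        notices.append("single sample: beta diversity and NMDS skipped")
        logger.info(notices[-1])
    else:
        beta = beta_distance(composition, metric=metric)
        try:
            embedding = nmds(beta, k=k, n_restarts=n_restarts, seed=seed)
        except DegenerateDistanceError:
            notices.append("all samples identical: NMDS degenerate, skipped")
            logger.info(notices[-1])
        except DiversityError as exc:
            notices.append(f"NMDS skipped: {exc}")
            logger.info(notices[-1])
    if out_dir is not None:
        _write_plots(composition, alpha, beta, embedding, groups, Path(out_dir))
    return DiversityReport(alpha=alpha, beta=beta, nmds_result=embedding, notices=notices)


def _write_plots(composition, alpha, beta, embedding, groups, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import scipy.cluster.hierarchy as sch

    out_dir.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(8, 4))
    composition.data.plot(kind="bar", stacked=True, ax=ax, legend=False, width=0.9)
    ax.set_ylabel("proportion")
    ax.set_title("Immune-cell composition")
    fig.tight_layout()
    fig.savefig(out_dir / "composition_stacked_bar.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.scatter(range(len(alpha)), alpha.values)
    ax.set_xticks(range(len(alpha)))
    ax.set_xticklabels(alpha.index, rotation=90, fontsize=6)
    ax.set_ylabel("Gini-Simpson")
    ax.set_title("Alpha diversity")
    fig.tight_layout()
    fig.savefig(out_dir / "alpha_diversity.png", dpi=120)
    plt.close(fig)

    if beta is not None and len(beta.sample_ids) >= 2:
        from .deconvolution import hierarchical_cluster

        result = hierarchical_cluster(composition)
        fig, ax = plt.subplots(figsize=(7, 3.5))
        sch.dendrogram(result.linkage_matrix, labels=result.sample_ids, ax=ax)
        ax.set_title("Hierarchical clustering of samples")
        fig.tight_layout()
        fig.savefig(out_dir / "dendrogram.png", dpi=120)
        plt.close(fig)

    if embedding is not None:
        fig, ax = plt.subplots(figsize=(5, 5))
        coords = embedding.frame
        if groups:
            labels = [groups.get(s, "ungrouped") for s in coords.index]
            for g in sorted(set(labels)):
                idx = [i for i, lab in enumerate(labels) if lab == g]
                ax.scatter(coords.iloc[idx, 0], coords.iloc[idx, 1], label=g)
            ax.legend(fontsize=7)
        else:
            ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1])
        ax.set_xlabel("NMDS1")
        ax.set_ylabel("NMDS2")
        ax.set_title(f"NMDS (stress={embedding.stress:.4f})")
        fig.tight_layout()
        fig.savefig(out_dir / "nmds.png", dpi=120)
        plt.close(fig)
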