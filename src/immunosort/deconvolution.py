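"""Signature-matrix construction and constrained deconvolution.

The mixing model is linear: a bulk profile is modelled as a non-negative
combination of per-cell-type reference columns, m = S w with w >= 0.  The
default solver is non-negative least squares on per-gene scaled linear
values, followed by renormalization of w onto the probability simplex.
A nu-SVR solver is exposed behind the same interface for comparison with
support-vector-based deconvolution tools.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.optimize
import scipy.spatial.distance as ssd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

SIMPLEX_TOL = 1e-9
COND_WARN = 1e6


class DeconvolutionError(ValueError):
    pass


@dataclass
class SignatureMatrix:
    """Signature genes x cell types reference basis (linear scale).

    Invariants: no all-zero gene row or cell-type column, at least two
    cell types, and at least as many genes as cell types.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.data.to_numpy(dtype=float)
        if (v < 0).any():
            raise DeconvolutionError("signature values must be non-negative")
        if self.data.shape[1] < 2:
            raise DeconvolutionError("signature needs at least 2 cell types")
        if self.data.shape[0] < self.data.shape[1]:
            raise DeconvolutionError("signature needs at least as many genes as cell types")
        if (v.sum(axis=1) == 0).any():
            raise DeconvolutionError("signature contains an all-zero gene row")
        if (v.sum(axis=0) == 0).any():
            raise DeconvolutionError("signature contains an all-zero cell-type column")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def celltype_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.data.to_numpy(dtype=float)))


@dataclass
class CompositionTable:
    """Samples x cell types relative proportions; each row on the simplex."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.data.to_numpy(dtype=float)
        if v.size:
            if (v < -SIMPLEX_TOL).any() or (v > 1 + SIMPLEX_TOL).any():
                raise DeconvolutionError("composition entries must lie in [0, 1]")
            bad = np.abs(v.sum(axis=1) - 1.0) > SIMPLEX_TOL
            if bad.any():
                offenders = list(self.data.index[bad])
                raise DeconvolutionError(f"composition rows not summing to 1: {offenders}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def celltype_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class SignatureBuildReport:
    excluded_types: dict[str, float]
    chosen_g: int
    condition_number: float
    condition_warning: bool
    candidate_conditions: dict[int, float] = field(default_factory=dict)


def _mean_pairwise_pearson(profiles: np.ndarray) -> float:
    # profiles: genes x replicates, log scale
    if profiles.shape[1] < 2:
        return 1.0
    c = np.corrcoef(profiles.T)
    iu = np.triu_indices_from(c, k=1)
    return float(np.nanmean(c[iu]))


def build_signature(
    reference: ExpressionMatrix,
    labels,
    g_min: int = 5,
    g_max: int = 50,
    consistency_threshold: float = 0.5,
) -> tuple[SignatureMatrix, SignatureBuildReport]:
    """Build a signature matrix from labeled linear-scale reference profiles.

    Steps: (a) drop cell types whose replicate profiles have mean pairwise
    Pearson correlation (on log2(x+1) values) below ``consistency_threshold``;
    (b) rank candidate markers per surviving type by fold change of the
    type's mean over the highest other-type mean; (c) sweep G over
    [g_min, g_max], take the union of the top-G markers per type, and keep
    the G whose per-type-mean matrix has the smallest 2-norm condition
    number (ties -> smaller G).
    """
    labels = pd.Series(list(labels), index=reference.sample_ids)
    if reference.unit == "LOG2":
        raise DeconvolutionError("reference must be on a linear scale (TPM/FPKM)")
    expr = reference.data
    logexpr = np.log2(expr + 1.0)

    excluded: dict[str, float] = {}
    surviving: list[str] = []
    for ct in pd.unique(labels):
        cols = labels.index[labels == ct]
        if len(cols) < 2:
            warnings.warn(f"cell type {ct!r} has a single reference profile; consistency unchecked")
            surviving.append(ct)
            continue
        r = _mean_pairwise_pearson(logexpr[cols].to_numpy())
        if r < consistency_threshold:
            excluded[ct] = r
        else:
            surviving.append(ct)
    if excluded:
        logger.info("excluded low-consistency cell types: %s", excluded)
    if len(surviving) < 2:
        raise DeconvolutionError(
            f"fewer than 2 cell types survive the consistency filter (excluded: {excluded})"
        )

    means = pd.DataFrame(
        {ct: expr[labels.index[labels == ct]].mean(axis=1) for ct in surviving}
    )
    eps = 1e-9
    ranked: dict[str, list[str]] = {}
    for ct in surviving:
        others = means.drop(columns=[ct]).max(axis=1)
        fc = (means[ct] + eps) / (others + eps)
        ranked[ct] = list(fc.sort_values(ascending=False, kind="stable").index)

    max_available = min(len(v) for v in ranked.values())
    if g_min > max_available:
        raise DeconvolutionError(f"g_min={g_min} exceeds available markers ({max_available})")
    g_max = min(g_max, max_available)

    conds: dict[int, float] = {}
    best_g, best_cond = None, np.inf
    for g in range(g_min, g_max + 1):
        genes: list[str] = []
        seen = set()
        for ct in surviving:
            for gene in ranked[ct][:g]:
                if gene not in seen:
                    seen.add(gene)
                    genes.append(gene)
        cand = means.loc[genes]
        if cand.shape[0] < cand.shape[1]:
            continue
        conds[g] = float(np.linalg.cond(cand.to_numpy()))
        if conds[g] < best_cond - 1e-12:
            best_cond, best_g = conds[g], g
    if best_g is None:
        raise DeconvolutionError("no G in range yields at least as many genes as cell types")

    genes = []
    seen = set()
    for ct in surviving:
        for gene in ranked[ct][:best_g]:
            if gene not in seen:
                seen.add(gene)
                genes.append(gene)
    sig_df = means.loc[genes]
    keep = sig_df.sum(axis=1) > 0
    sig_df = sig_df.loc[keep]
    warn = best_cond > COND_WARN
    if warn:
        warnings.warn(
            f"signature is near-singular (condition number {best_cond:.3g}); "
            "deconvolution results will be unstable"
        )
    report = SignatureBuildReport(
        excluded_types=excluded,
        chosen_g=best_g,
        condition_number=best_cond,
        condition_warning=warn,
        candidate_conditions=conds,
    )
    return SignatureMatrix(data=sig_df), report


def _gene_scale(sig_values: np.ndarray) -> np.ndarray:
    # per-gene root-mean-square across cell types; equalizes the leverage of
    # high- and low-expressed signature genes without centering (centering
    # would make the columns linearly dependent and break identifiability)
    s = np.sqrt(np.mean(sig_values**2, axis=1))
    s[s <= 0] = 1.0
    return s


def _solve_nnls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    w, _ = scipy.optimize.nnls(A, b)
    return w


def _solve_svr(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    # nu-SVR with linear kernel on sd-scaled columns; the fitted intercept is
    # folded back into weight space (its least-squares preimage under A) so
    # that small proportions are not absorbed by the constant term, then the
    # coefficients are clipped to >= 0 and later renormalized
    from sklearn.svm import NuSVR

    col_sd = A.std(axis=0)
    col_sd[col_sd <= 0] = 1.0
    As = A / col_sd
    best = None
    for nu in (0.25, 0.5, 0.75):
        model = NuSVR(nu=nu, C=1.0, kernel="linear")
        model.fit(As, b)
        beta = model.coef_.ravel() / col_sd
        c = float(np.asarray(model.intercept_).ravel()[0])
        delta, *_ = np.linalg.lstsq(A, np.full(len(b), c), rcond=None)
        w = np.clip(beta + delta, 0.0, None)
        resid = np.linalg.norm(A @ w - b)
        if best is None or resid < best[0]:
            best = (resid, w)
    return best[1]


def deconvolve(
    mixture: ExpressionMatrix,
    signature: SignatureMatrix,
    min_overlap_frac: float = 0.5,
    solver: str = "nnls",
) -> CompositionTable:
    """Estimate per-sample cell-type proportions from bulk mixtures.

    The mixture is matched to the signature by gene symbol.  LOG2 input is
    back-transformed (2**x - 1) to linear scale first.  Per sample, solves
    for non-negative weights minimizing || S w - m || over the overlapping
    genes after per-gene scaling, then renormalizes w to sum to one.
    """
    if solver not in {"nnls", "svr"}:
        raise DeconvolutionError(f"unknown solver {solver!r}")
    mix = mixture.data
    if mixture.unit == "LOG2":
        mix = np.power(2.0, mix) - 1.0

    sig_genes = signature.data.index
    overlap = [g for g in sig_genes if g in mix.index]
    frac = len(overlap) / len(sig_genes)
    if frac < min_overlap_frac:
        raise DeconvolutionError(
            f"gene overlap {frac:.3f} below required {min_overlap_frac} "
            f"({len(overlap)}/{len(sig_genes)} signature genes found)"
        )

    S = signature.data.loc[overlap].to_numpy(dtype=float)
    scale = _gene_scale(S)
    A = S / scale[:, None]
    solve = _solve_nnls if solver == "nnls" else _solve_svr

    rows = []
    for sample in mix.columns:
        b_raw = mix.loc[overlap, sample].to_numpy(dtype=float)
        if not np.any(b_raw > 0):
            raise DeconvolutionError(f"sample {sample!r} is all zero over the signature genes")
        b = b_raw / scale
        w = solve(A, b)
        total = w.sum()
        if total <= 0:
            raise DeconvolutionError(
                f"solver returned an all-zero weight vector for sample {sample!r}"
            )
        resid = float(np.linalg.norm(A @ w - b))
        logger.info(
            "sample %s: overlap=%d/%d residual=%.4g", sample, len(overlap), len(sig_genes), resid
        )
        rows.append(w / total)

    comp = pd.DataFrame(rows, index=list(mix.columns), columns=signature.celltype_ids)
    return CompositionTable(data=comp)


@dataclass
class ClusterResult:
    """Agglomerative merge sequence over samples (scipy linkage encoding)."""

    sample_ids: list[str]
    linkage_matrix: np.ndarray
    method: str
    metric: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def hierarchical_cluster(
    composition: CompositionTable,
    linkage: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Cluster samples by immune composition (deterministic merge order).

    Samples are sorted lexicographically before linkage so that distance
    ties resolve by sample name.
    """
    if linkage not in {"average", "complete", "ward"}:
        raise DeconvolutionError(f"unknown linkage {linkage!r}")
    if metric not in {"euclidean", "braycurtis"}:
        raise DeconvolutionError(f"unknown metric {metric!r}")
    if linkage == "ward" and metric != "euclidean":
        raise DeconvolutionError("ward linkage requires the euclidean metric")
    if composition.data.shape[0] < 2:
        raise DeconvolutionError("clustering needs at least 2 samples")
    ordered = sorted(composition.sample_ids)
    X = composition.data.loc[ordered].to_numpy(dtype=float)
    D = ssd.pdist(X, metric=metric)
    Z = sch.linkage(D, method=linkage)
    return ClusterResult(sample_ids=ordered, linkage_matrix=Z, method=linkage, metric=metric)
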