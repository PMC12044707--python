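"""Synthetic reference profiles, bulk mixtures, and single-cell cohorts.

Every stage of the pipeline is testable without external downloads: the
generator emits TPM-like data (each profile rescaled to a fixed total)
with disjoint marker blocks per cell type, shared background genes,
mitochondrial (``MT-``) and housekeeping genes, multiplicative log-normal
expression noise and Bernoulli dropout.  T-cell subtypes carry CD4 /
CD8A / CD8B expression consistent with their identity so that marker
gating can recover them.  All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .deconvolution import CompositionTable, SignatureMatrix
from .io import ExpressionMatrix, SingleCellDataset

# 21-type immune panel used as the default deconvolution output space
DEFAULT_PANEL: tuple[str, ...] = (
    "B_naive", "B_memory", "Plasma",
    "CD4_T", "CD8_T", "T_gamma_delta", "T_reg",
    "NK", "NKT",
    "Monocyte", "Macrophage_M1", "Macrophage_M2",
    "Dendritic_myeloid", "Dendritic_plasmacytoid",
    "Mast", "Neutrophil", "Eosinophil", "Basophil",
    "MDSC", "ILC", "Progenitor",
)

GATING_GENES = ("CD4", "CD8A", "CD8B")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_celltypes: int = 21
    n_genes: int = 600
    markers_per_type: int = 10
    n_patients: int = 10
    cells_per_patient: Union[int, tuple[int, int]] = 500
    dirichlet_alpha: Union[float, Sequence[float]] = 1.0
    lognormal_sigma: float = 0.2
    dropout_rate: float = 0.3
    mito_gene_count: int = 10
    housekeeping_gene_count: int = 10
    seed: int = 0
    # generator knobs beyond the core study conditions
    replicates_per_type: int = 3
    marker_fold: float = 50.0
    marker_overlap: int = 0
    total_per_cell: float = 1e4
    merge_t_labels: bool = True

    def __post_init__(self) -> None:
        if self.n_celltypes < 2:
            raise SimulationError("need at least 2 cell types")
        if self.markers_per_type * self.n_celltypes > self.n_genes:
            raise SimulationError("markers_per_type x n_celltypes must not exceed n_genes")
        if not (0 <= self.dropout_rate < 1):
            raise SimulationError("dropout_rate must be in [0, 1)")
        if self.lognormal_sigma < 0:
            raise SimulationError("lognormal_sigma must be >= 0")
        alphas = np.atleast_1d(np.asarray(self.dirichlet_alpha, dtype=float))
        if (alphas <= 0).any():
            raise SimulationError("dirichlet_alpha must be positive")
        if alphas.size not in (1, self.n_celltypes):
            raise SimulationError("dirichlet_alpha must be scalar or length n_celltypes")
        if self.marker_overlap < 0 or self.marker_overlap >= self.markers_per_type:
            if self.marker_overlap != 0:
                raise SimulationError("marker_overlap must be in [0, markers_per_type)")

    @property
    def celltype_names(self) -> list[str]:
        if self.n_celltypes <= len(DEFAULT_PANEL):
            return list(DEFAULT_PANEL[: self.n_celltypes])
        extra = [f"Type_{i}" for i in range(len(DEFAULT_PANEL), self.n_celltypes)]
        return list(DEFAULT_PANEL) + extra

    def alpha_vector(self) -> np.ndarray:
        a = np.atleast_1d(np.asarray(self.dirichlet_alpha, dtype=float))
        if a.size == 1:
            return np.full(self.n_celltypes, float(a[0]))
        return a.copy()


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(cfg.seed), stream)))


def _gene_names(cfg: SimulationConfig, types: list[str]) -> tuple[list[str], dict]:
    """Deterministic gene naming: marker blocks, mito, housekeeping, background."""
    names: list[str] = []
    marker_of_type: dict[str, list[str]] = {}
    for k, ct in enumerate(types):
        block = [f"{ct.upper()}_MARK{j}" for j in range(cfg.markers_per_type)]
        if ct == "CD4_T" and cfg.markers_per_type >= 1:
            block[0] = "CD4"
        if ct == "CD8_T":
            if cfg.markers_per_type >= 1:
                block[0] = "CD8A"
            if cfg.markers_per_type >= 2:
                block[1] = "CD8B"
        marker_of_type[ct] = block
        names.extend(block)
    n_special = cfg.mito_gene_count + cfg.housekeeping_gene_count
    n_marker = len(names)
    if n_marker + n_special > cfg.n_genes:
        raise SimulationError("not enough genes for markers plus mito/housekeeping genes")
    mito = [f"MT-SIM{i}" for i in range(cfg.mito_gene_count)]
    hk = [f"HK{i}" for i in range(cfg.housekeeping_gene_count)]
    n_bg = cfg.n_genes - n_marker - n_special
    bg = [f"BG{i}" for i in range(n_bg)]
    names = names + mito + hk + bg
    meta = {"markers": marker_of_type, "mito": mito, "housekeeping": hk, "background": bg}
    return names, meta


def _base_profiles(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Per-type base expression (types x genes), shared by reference and cells."""
    types = cfg.celltype_names
    genes, meta = _gene_names(cfg, types)
    rng = _rng(cfg, 17)
    n_bg_like = cfg.mito_gene_count + cfg.housekeeping_gene_count + len(meta["background"])
    background = rng.lognormal(mean=np.log(5.0), sigma=1.0, size=cfg.n_genes)
    base = pd.DataFrame(
        np.tile(background, (len(types), 1)), index=types, columns=genes
    )
    # markers: high in the owning type, zero elsewhere (disjoint blocks)
    all_markers = [g for ms in meta["markers"].values() for g in ms]
    base.loc[:, all_markers] = 0.0
    bg_scale = float(np.median(background))
    for ct in types:
        lift = cfg.marker_fold * bg_scale * rng.uniform(0.5, 1.5, size=cfg.markers_per_type)
        base.loc[ct, meta["markers"][ct]] = lift
    # optional marker sharing between adjacent types, for stress tests
    if cfg.marker_overlap > 0:
        for i, ct in enumerate(types):
            nxt = types[(i + 1) % len(types)]
            shared = meta["markers"][ct][: cfg.marker_overlap]
            base.loc[nxt, shared] = base.loc[ct, shared].to_numpy() * 0.5
    # housekeeping genes: uniformly high; mito: moderate
    base.loc[:, meta["housekeeping"]] = 20.0 * bg_scale
    base.loc[:, meta["mito"]] = 4.0 * bg_scale
    del n_bg_like
    return base, meta


def true_signature(cfg: SimulationConfig) -> SignatureMatrix:
    """The generating per-type profiles restricted to marker genes (genes x types)."""
    base, meta = _base_profiles(cfg)
    markers = [g for ms in meta["markers"].values() for g in ms]
    sig = base[markers].T
    return SignatureMatrix(data=sig)


def simulate_reference(cfg: SimulationConfig) -> tuple[ExpressionMatrix, list[str]]:
    """Replicate reference profiles per cell type with log-normal replicate noise.

    Returns a genes x (types * replicates) matrix plus the cell-type label of
    each column, TPM-like (each profile rescaled to ``cfg.total_per_cell``).
    """
    base, _ = _base_profiles(cfg)
    rng = _rng(cfg, 23)
    cols = {}
    labels: list[str] = []
    for ct in base.index:
        for r in range(cfg.replicates_per_type):
            noise = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=base.shape[1])
            profile = base.loc[ct].to_numpy() * noise
            profile = profile / profile.sum() * cfg.total_per_cell
            cols[f"{ct}_rep{r}"] = profile
            labels.append(ct)
    df = pd.DataFrame(cols, index=base.columns)
    return ExpressionMatrix(data=df, unit="TPM"), labels


def simulate_bulk(
    signature: SignatureMatrix,
    n_samples: int,
    dirichlet_alpha: Union[float, Sequence[float]] = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, CompositionTable]:
    """Bulk mixtures S @ w with known simplex weights and log-normal noise."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 31)))
    K = len(signature.celltype_ids)
    alpha = np.atleast_1d(np.asarray(dirichlet_alpha, dtype=float))
    if alpha.size == 1:
        alpha = np.full(K, float(alpha[0]))
    W = rng.dirichlet(alpha, size=n_samples)  # samples x types
    S = signature.data.to_numpy(dtype=float)
    M = S @ W.T  # genes x samples
    if noise_sigma > 0:
        M = M * rng.lognormal(mean=0.0, sigma=noise_sigma, size=M.shape)
    samples = [f"sample{i}" for i in range(n_samples)]
    mix = ExpressionMatrix(
        data=pd.DataFrame(M, index=signature.gene_ids, columns=samples), unit="TPM"
    )
    truth = CompositionTable(
        data=pd.DataFrame(W, index=samples, columns=signature.celltype_ids)
    )
    return mix, truth


def simulate_cells(cfg: SimulationConfig) -> SingleCellDataset:
    """Annotated single-cell cohort with known per-patient composition.

    Per patient a true composition is drawn from Dirichlet(alpha); each
    cell samples its type from it, takes the type base profile times cell
    level log-normal noise, suffers Bernoulli dropout, and is rescaled to
    a fixed TPM-like total.  UMI totals are derived from pre-rescaling
    sums.  The drawn compositions are attached as ``true_composition``.
    """
    base, meta = _base_profiles(cfg)
    rng = _rng(cfg, 47)
    types = list(base.index)
    alpha = cfg.alpha_vector()

    rows = []
    cell_ids: list[str] = []
    patients: list[str] = []
    labels: list[str] = []
    umis: list[int] = []
    truth_rows = []
    patient_names = [f"P{i:02d}" for i in range(cfg.n_patients)]
    for pname in patient_names:
        comp = rng.dirichlet(alpha)
        truth_rows.append(comp)
        if isinstance(cfg.cells_per_patient, tuple):
            lo, hi = cfg.cells_per_patient
            n_cells = int(rng.integers(lo, hi + 1))
        else:
            n_cells = int(cfg.cells_per_patient)
        type_idx = rng.choice(len(types), size=n_cells, p=comp)
        for j, ti in enumerate(type_idx):
            ct = types[ti]
            expr = base.loc[ct].to_numpy(dtype=float).copy()
            if cfg.lognormal_sigma > 0:
                expr = expr * rng.lognormal(0.0, cfg.lognormal_sigma, size=expr.size)
            if cfg.dropout_rate > 0:
                keep = rng.random(expr.size) >= cfg.dropout_rate
                expr = expr * keep
            raw_total = expr.sum()
            if raw_total <= 0:  # pathological full dropout; keep a housekeeping count
                expr[base.columns.get_loc(meta["housekeeping"][0])] = 1.0
                raw_total = 1.0
            umis.append(int(round(raw_total)))
            expr = expr / raw_total * cfg.total_per_cell
            rows.append(expr)
            cell_ids.append(f"{pname}_c{j:04d}")
            patients.append(pname)
            if cfg.merge_t_labels and ct in ("CD4_T", "CD8_T"):
                labels.append("T cell")
            else:
                labels.append(ct)

    matrix = pd.DataFrame(np.asarray(rows), index=cell_ids, columns=base.columns)
    obs = pd.DataFrame(
        {"patient": patients, "cell_type": labels, "umi_total": umis}, index=cell_ids
    )
    truth = pd.DataFrame(truth_rows, index=patient_names, columns=types)
    return SingleCellDataset(matrix=matrix, obs=obs, unit="TPM", true_composition=truth)


def inject_qc_failures(
    d: SingleCellDataset,
    cfg,
    fractions: Mapping[str, float],
    seed: int = 0,
) -> tuple[SingleCellDataset, dict[str, list[str]]]:
    """Plant cells that each violate exactly one QC rule of ``cfg`` (a QCConfig).

    Recognized rules: ``low_genes``, ``high_genes``, ``high_umi``,
    ``high_mito``.  Planted cells are disjoint across rules; the mapping of
    rule -> planted cell ids is returned for assertions.
    """
    valid = {"low_genes", "high_genes", "high_umi", "high_mito"}
    unknown = set(fractions) - valid
    if unknown:
        raise SimulationError(f"unknown QC rules: {sorted(unknown)}")
    if sum(fractions.values()) >= 1:
        raise SimulationError("rule fractions must sum to < 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 59)))
    matrix = d.matrix.copy()
    obs = d.obs.copy()
    n = matrix.shape[0]
    perm = list(np.asarray(d.cell_ids)[rng.permutation(n)])
    planted: dict[str, list[str]] = {}
    cursor = 0
    genes = list(matrix.columns)
    mito_mask = np.array([g.upper().startswith(cfg.mito_prefix.upper()) for g in genes])
    hk = [g for g in getattr(cfg, "housekeeping_genes", []) if g in matrix.columns]

    for rule, frac in fractions.items():
        count = int(round(frac * n))
        chosen = perm[cursor: cursor + count]
        cursor += count
        planted[rule] = chosen
        for cid in chosen:
            row = matrix.loc[cid].to_numpy(dtype=float)
            if rule == "low_genes":
                if cfg.min_genes <= len(hk):
                    raise SimulationError(
                        "cannot plant low_genes: min_genes must exceed the housekeeping list"
                    )
                # keep housekeeping plus a few non-mito genes, total < min_genes
                keep = list(hk)
                for gi, g in enumerate(genes):
                    if len(keep) >= cfg.min_genes - 1:
                        break
                    if g not in keep and not mito_mask[gi] and row[gi] > 0:
                        keep.append(g)
                new = np.zeros_like(row)
                for g in keep:
                    loc = matrix.columns.get_loc(g)
                    new[loc] = row[loc] if row[loc] > 0 else 1.0
                matrix.loc[cid] = new
            elif rule == "high_genes":
                if cfg.max_genes is None:
                    raise SimulationError("cfg has no max_genes rule to violate")
                nonmito = np.where(~mito_mask)[0]
                if cfg.max_genes + 1 > len(nonmito):
                    raise SimulationError(
                        f"cannot express {cfg.max_genes + 1} non-mito genes; only {len(nonmito)}"
                    )
                new = row.copy()
                zero_nonmito = [i for i in nonmito if new[i] <= 0]
                need = cfg.max_genes + 1 - int((new > 0).sum())
                for i in zero_nonmito[: max(need, 0)]:
                    new[i] = 0.5
                matrix.loc[cid] = new
            elif rule == "high_umi":
                if cfg.max_umis is None:
                    raise SimulationError("cfg has no max_umis rule to violate")
                obs.loc[cid, "umi_total"] = int(cfg.max_umis * 1.5) + 1
            elif rule == "high_mito":
                if not mito_mask.any():
                    raise SimulationError("dataset has no mitochondrial genes to inflate")
                target = min(0.95, cfg.max_mito_frac * 1.5 + 0.05)
                nonmito_total = row[~mito_mask].sum()
                mito_total = nonmito_total * target / (1.0 - target)
                new = row.copy()
                new[mito_mask] = mito_total / mito_mask.sum()
                matrix.loc[cid] = new
    out = SingleCellDataset(
        matrix=matrix, obs=obs, unit=d.unit, true_composition=d.true_composition
    )
    return out, planted
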