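"""Pseudo-bulk benchmarking of deconvolution against single-cell ground truth.

The protocol: filter low-quality cells, split annotated T cells into CD4/CD8
subsets by marker gating, compute each patient's true immune composition by
counting labels, average each patient's cells into a pseudo-bulk profile,
deconvolve it, restrict truth and prediction to the shared cell types with
each row rescaled to sum to one, and score agreement with Pearson's r and
RMSE, pooled and per cell type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .deconvolution import CompositionTable, SignatureMatrix, deconvolve
from .io import ExpressionMatrix, SingleCellDataset, write_composition

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


@dataclass
class QCConfig:
    """Cell-level quality-control thresholds.

    ``min_genes``/``max_genes`` bound the number of expressed (value > 0)
    genes per cell; ``max_umis`` caps the per-cell UMI total; a cell's
    mitochondrial fraction (genes whose symbol starts with ``mito_prefix``
    over the cell total) must not exceed ``max_mito_frac``; when
    ``housekeeping_genes`` is non-empty, the mean log2(x+1) over that list
    must reach ``min_housekeeping_expr``.
    """

    min_genes: int = 0
    max_genes: Optional[int] = None
    max_umis: Optional[int] = None
    max_mito_frac: float = 1.0
    housekeeping_genes: tuple[str, ...] = ()
    min_housekeeping_expr: float = 0.0
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes < 0:
            raise ValidationError("min_genes must be >= 0")
        if self.max_genes is not None and self.max_genes <= self.min_genes:
            raise ValidationError("max_genes must exceed min_genes")
        if not (0 <= self.max_mito_frac <= 1):
            raise ValidationError("max_mito_frac must be in [0, 1]")


@dataclass
class ValidationPreset:
    qc: QCConfig
    immune_types: tuple[str, ...]
    min_immune_frac: float = 0.0
    min_immune_cells: int = 50
    gate_t_subsets: bool = True


# Per-dataset profiles: melanoma and HNSCC Smart-seq2 cohorts keep cells with
# many expressed genes plus a housekeeping check; the NSCLC droplet cohort
# uses the four-rule filter and the >20% immune-content patient cutoff.
PRESETS: dict[str, ValidationPreset] = {
    "melanoma": ValidationPreset(
        qc=QCConfig(min_genes=1700, housekeeping_genes=(), min_housekeeping_expr=0.0),
        immune_types=("B", "CD4_T", "CD8_T", "NK", "Macrophage"),
        min_immune_frac=0.0,
        min_immune_cells=50,
        gate_t_subsets=True,
    ),
    "hnscc": ValidationPreset(
        qc=QCConfig(min_genes=2000),
        immune_types=("B", "CD4_T", "CD8_T", "Macrophage", "Dendritic", "Mast"),
        min_immune_frac=0.0,
        min_immune_cells=50,
        gate_t_subsets=True,
    ),
    "nsclc": ValidationPreset(
        qc=QCConfig(min_genes=200, max_genes=5000, max_umis=30000, max_mito_frac=0.30),
        immune_types=("T cell", "B", "Mast", "Neutrophil"),
        min_immune_frac=0.20,
        min_immune_cells=50,
        gate_t_subsets=False,
    ),
    "smoke": ValidationPreset(
        qc=QCConfig(min_genes=10),
        immune_types=("B_naive", "CD4_T", "CD8_T", "NK", "Macrophage_M1"),
        min_immune_frac=0.0,
        min_immune_cells=10,
        gate_t_subsets=True,
    ),
}


def read_preset_file(path) -> dict[str, str]:
    """Parse a key=value preset file (one pair per line, # comments)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"malformed preset line: {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_kept: int
    n_removed_by_rule: dict[str, int]
    per_patient_kept: dict[str, int]

    def frame(self) -> pd.DataFrame:
        rows = [("cells_in", self.n_cells_in), ("cells_kept", self.n_cells_kept)]
        rows += [(f"removed_{k}", v) for k, v in self.n_removed_by_rule.items()]
        return pd.DataFrame(rows, columns=["metric", "count"]).set_index("metric")


def _rule_violations(d: SingleCellDataset, cfg: QCConfig) -> dict[str, np.ndarray]:
    """Boolean violation mask per rule (a cell may violate several)."""
    X = d.matrix.to_numpy(dtype=float)
    expressed = (X > 0).sum(axis=1)
    out: dict[str, np.ndarray] = {}
    out["min_genes"] = expressed < cfg.min_genes
    if cfg.max_genes is not None:
        out["max_genes"] = expressed > cfg.max_genes
    if cfg.max_umis is not None:
        if "umi_total" not in d.obs.columns or d.obs["umi_total"].isna().any():
            raise ValidationError("max_umis rule requires per-cell umi_total annotations")
        out["max_umis"] = d.obs["umi_total"].to_numpy(dtype=float) > cfg.max_umis
    mito_cols = [g for g in d.gene_ids if g.upper().startswith(cfg.mito_prefix.upper())]
    if cfg.max_mito_frac < 1.0:
        totals = X.sum(axis=1)
        mito = d.matrix[mito_cols].to_numpy(dtype=float).sum(axis=1) if mito_cols else np.zeros(len(totals))
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.where(totals > 0, totals, 1.0), 0.0)
        out["max_mito"] = frac > cfg.max_mito_frac
    if cfg.housekeeping_genes:
        known = [g for g in cfg.housekeeping_genes if g in d.matrix.columns]
        unknown = [g for g in cfg.housekeeping_genes if g not in d.matrix.columns]
        if unknown:
            warnings.warn(f"housekeeping genes absent from the matrix: {unknown}")
        if known:
            hk = np.log2(d.matrix[known].to_numpy(dtype=float) + 1.0).mean(axis=1)
            out["housekeeping"] = hk < cfg.min_housekeeping_expr
    return out


def qc_filter(d: SingleCellDataset, cfg: QCConfig) -> tuple[SingleCellDataset, QCReport]:
    """Remove low-quality cells; count each cell under every rule it violates."""
    violations = _rule_violations(d, cfg)
    any_bad = np.zeros(d.n_cells, dtype=bool)
    removed_by_rule = {}
    for rule, mask in violations.items():
        removed_by_rule[rule] = int(mask.sum())
        any_bad |= mask
    keep_ids = list(np.asarray(d.cell_ids)[~any_bad])
    if not keep_ids:
        raise ValidationError("quality control removed every cell")
    kept = d.subset_cells(keep_ids)
    per_patient = kept.obs["patient"].value_counts().to_dict()
    report = QCReport(
        n_cells_in=d.n_cells,
        n_cells_kept=len(keep_ids),
        n_removed_by_rule=removed_by_rule,
        per_patient_kept={str(k): int(v) for k, v in per_patient.items()},
    )
    logger.info("QC kept %d/%d cells; removals by rule: %s",
                report.n_cells_kept, report.n_cells_in, removed_by_rule)
    return kept, report


def gate_t_cells(
    d: SingleCellDataset,
    expr_threshold: float = 0.0,
    t_cell_label: str = "T cell",
) -> SingleCellDataset:
    """Split annotated T cells into CD4_T / CD8_T / unassigned by marker gating.

    CD4 > threshold with CD8A and CD8B at or below threshold -> CD4_T;
    CD8A and CD8B > threshold with CD4 at or below threshold -> CD8_T;
    every other T cell -> 'unassigned' (excluded from ground truth).
    """
    for g in ("CD4", "CD8A", "CD8B"):
        if g not in d.matrix.columns:
            raise ValidationError(f"gating gene {g} absent from the expression matrix")
    if "cell_type" not in d.obs.columns:
        raise ValidationError("dataset has no cell_type annotations to gate")
    is_t = d.obs["cell_type"] == t_cell_label
    if not is_t.any():
        raise ValidationError(f"no cells labeled {t_cell_label!r} to gate")
    cd4 = d.matrix["CD4"].to_numpy(dtype=float)
    cd8a = d.matrix["CD8A"].to_numpy(dtype=float)
    cd8b = d.matrix["CD8B"].to_numpy(dtype=float)
    thr = expr_threshold
    is_cd4 = (cd4 > thr) & (cd8a <= thr) & (cd8b <= thr)
    is_cd8 = (cd8a > thr) & (cd8b > thr) & (cd4 <= thr)
    new_labels = d.obs["cell_type"].copy()
    tmask = is_t.to_numpy()
    new_labels[tmask & is_cd4] = "CD4_T"
    new_labels[tmask & is_cd8] = "CD8_T"
    new_labels[tmask & ~is_cd4 & ~is_cd8] = "unassigned"
    obs = d.obs.copy()
    obs["cell_type"] = new_labels
    n_cd4 = int((tmask & is_cd4).sum())
    n_cd8 = int((tmask & is_cd8).sum())
    logger.info("gated %d T cells: %d CD4_T, %d CD8_T, %d unassigned",
                int(tmask.sum()), n_cd4, n_cd8, int(tmask.sum()) - n_cd4 - n_cd8)
    return SingleCellDataset(matrix=d.matrix, obs=obs, unit=d.unit,
                             true_composition=d.true_composition)


def ground_truth_composition(
    d: SingleCellDataset,
    immune_types: Sequence[str],
    min_immune_frac: float = 0.0,
    min_immune_cells: int = 50,
) -> tuple[CompositionTable, list[str]]:
    """Per-patient immune composition by counting annotated labels.

    Proportions are taken among each patient's immune-type cells.  Patients
    whose immune fraction (immune cells over all cells) is below
    ``min_immune_frac`` or whose immune-cell count is below
    ``min_immune_cells`` are excluded and listed.
    """
    immune_types = list(immune_types)
    if not immune_types:
        raise ValidationError("immune_types must be non-empty")
    if "cell_type" not in d.obs.columns:
        raise ValidationError("dataset has no cell_type annotations")
    observed = set(d.obs["cell_type"].unique())
    missing = [t for t in immune_types if t not in observed]
    if missing:
        warnings.warn(f"immune types never observed in the data: {missing}")
    rows = {}
    excluded: list[str] = []
    for patient, obs_p in d.obs.groupby("patient", sort=True):
        counts = obs_p["cell_type"].value_counts()
        immune_counts = np.array([counts.get(t, 0) for t in immune_types], dtype=float)
        n_immune = immune_counts.sum()
        frac = n_immune / len(obs_p)
        if frac < min_immune_frac or n_immune < min_immune_cells:
            excluded.append(str(patient))
            continue
        rows[str(patient)] = immune_counts / n_immune
    if not rows:
        raise ValidationError("every patient was excluded by the immune-content filter")
    if excluded:
        logger.info("excluded patients (immune content below threshold): %s", excluded)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = immune_types
    return CompositionTable(data=table), excluded


def make_pseudobulk(d: SingleCellDataset) -> ExpressionMatrix:
    """Average each patient's cells (all types) into one bulk-like profile."""
    if d.n_cells == 0:
        raise ValidationError("no cells to average")
    means = d.matrix.groupby(d.obs["patient"], sort=True).mean()
    return ExpressionMatrix(data=means.T, unit=d.unit)


def rescale_shared(
    truth: CompositionTable, pred: CompositionTable
) -> tuple[CompositionTable, CompositionTable]:
    """Restrict both tables to their shared cell types and renormalize rows to 1."""
    shared = [t for t in truth.celltype_ids if t in pred.celltype_ids]
    if not shared:
        raise ValidationError("truth and prediction share no cell types")
    if set(truth.sample_ids) != set(pred.sample_ids):
        only_t = sorted(set(truth.sample_ids) - set(pred.sample_ids))
        only_p = sorted(set(pred.sample_ids) - set(truth.sample_ids))
        raise ValidationError(f"sample mismatch: truth-only {only_t}, prediction-only {only_p}")
    out = []
    for table in (truth, pred):
        sub = table.data.loc[truth.sample_ids, shared]
        sums = sub.sum(axis=1)
        zero = sums[sums <= 0]
        if len(zero):
            raise ValidationError(
                f"zero shared-type mass for samples {list(zero.index)}; cannot rescale"
            )
        out.append(CompositionTable(data=sub.div(sums, axis=0)))
    return out[0], out[1]


@dataclass
class EvaluationReport:
    per_celltype: pd.DataFrame  # index cell type; columns pearson_r, rmse, n_samples, r_defined
    pooled_r: float
    pooled_rmse: float
    n_points: int
    shared_celltypes: list[str]
    pooled_r_defined: bool = True

    def frame(self) -> pd.DataFrame:
        pooled = pd.DataFrame(
            {"pearson_r": [self.pooled_r], "rmse": [self.pooled_rmse],
             "n_samples": [self.n_points], "r_defined": [self.pooled_r_defined]},
            index=["POOLED"],
        )
        return pd.concat([self.per_celltype, pooled])


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), False
    r = scipy.stats.pearsonr(x, y).statistic
    return float(r), True


def evaluate(truth: CompositionTable, pred: CompositionTable) -> EvaluationReport:
    """Pearson r and RMSE between aligned truth and prediction tables.

    Pooled statistics run over every (sample, cell type) pair; per-type
    statistics run across samples.  A correlation against a constant
    vector is reported as undefined (NaN with a flag), not as zero.
    """
    if list(truth.celltype_ids) != list(pred.celltype_ids):
        raise ValidationError("cell-type panels differ; run rescale_shared first")
    if set(truth.sample_ids) != set(pred.sample_ids):
        raise ValidationError("sample sets differ between truth and prediction")
    P = pred.data.loc[truth.sample_ids]
    T = truth.data
    diffs = (P.to_numpy() - T.to_numpy()).ravel()
    pooled_rmse = float(np.sqrt(np.mean(diffs**2)))
    pooled_r, pooled_def = _safe_pearson(T.to_numpy().ravel(), P.to_numpy().ravel())
    rows = []
    for ct in truth.celltype_ids:
        r, defined = _safe_pearson(T[ct].to_numpy(), P[ct].to_numpy())
        rmse = float(np.sqrt(np.mean((T[ct].to_numpy() - P[ct].to_numpy()) ** 2)))
        rows.append((ct, r, rmse, len(T), defined))
    per_ct = pd.DataFrame(
        rows, columns=["cell_type", "pearson_r", "rmse", "n_samples", "r_defined"]
    ).set_index("cell_type")
    return EvaluationReport(
        per_celltype=per_ct,
        pooled_r=pooled_r,
        pooled_rmse=pooled_rmse,
        n_points=int(T.size),
        shared_celltypes=list(truth.celltype_ids),
        pooled_r_defined=pooled_def,
    )


@dataclass
class ValidationResult:
    qc_report: QCReport
    excluded_patients: list[str]
    truth: CompositionTable
    truth_raw: CompositionTable
    pseudobulk: ExpressionMatrix
    prediction: CompositionTable
    prediction_raw: CompositionTable
    report: EvaluationReport


def run_validation(
    d: SingleCellDataset,
    cfg: QCConfig,
    signature: SignatureMatrix,
    immune_types: Sequence[str],
    min_immune_frac: float = 0.0,
    min_immune_cells: int = 50,
    gate_t_subsets: bool = True,
    gate_threshold: float = 0.0,
    solver: str = "nnls",
    min_overlap_frac: float = 0.5,
    out_dir=None,
) -> ValidationResult:
    """Full protocol: QC -> gating -> truth -> pseudo-bulk -> deconvolve -> score."""
    kept, qc_report = qc_filter(d, cfg)
    if gate_t_subsets:
        kept = gate_t_cells(kept, expr_threshold=gate_threshold)
    truth_raw, excluded = ground_truth_composition(
        kept, immune_types, min_immune_frac=min_immune_frac, min_immune_cells=min_immune_cells
    )
    qualified = kept.subset_cells(
        [c for c in kept.cell_ids if str(kept.obs.loc[c, "patient"]) in truth_raw.sample_ids]
    )
    if len(truth_raw.sample_ids) < 2:
        raise ValidationError(
            "fewer than 2 qualified patients; Pearson correlation is undefined"
        )
    pseudobulk = make_pseudobulk(qualified)
    pred_raw = deconvolve(pseudobulk, signature, min_overlap_frac=min_overlap_frac, solver=solver)
    truth_s, pred_s = rescale_shared(truth_raw, pred_raw)
    report = evaluate(truth_s, pred_s)
    result = ValidationResult(
        qc_report=qc_report,
        excluded_patients=excluded,
        truth=truth_s,
        truth_raw=truth_raw,
        pseudobulk=pseudobulk,
        prediction=pred_s,
        prediction_raw=pred_raw,
        report=report,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        qc_report.frame().to_csv(out / "qc_report.csv")
        write_composition(truth_raw, out / "truth_raw.csv")
        write_composition(truth_s, out / "truth_rescaled.csv")
        write_composition(pred_raw, out / "prediction_raw.csv")
        write_composition(pred_s, out / "prediction_rescaled.csv")
        pseudobulk.data.to_csv(out / "pseudobulk.csv", float_format="%.17g")
        report.frame().to_csv(out / "evaluation.csv")
        pd.Series(excluded, name="excluded_patient").to_csv(out / "excluded_patients.csv", index=False)
    return result
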