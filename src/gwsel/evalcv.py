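"""k-fold cross-validation and the prediction-ability statistic.

Prediction ability is the Pearson correlation between genomic estimated
breeding values (GEBVs) and the observed phenotypes of the validation fold.
Folds partition the plants; for every training fit the validation phenotypes
are masked (set to NaN) and all data-dependent statistics — allele
frequencies for centering, kernel bandwidth medians, variance components —
are computed from the training fold only, so no information leaks from the
validation set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MarkerMatrix, PhenotypeTable
from .wgr import METHOD_CODES, WGRSpec, make_model

logger = logging.getLogger("gwsel")


@dataclass
class CVPlan:
    """Balanced fold assignments: one array of fold labels per repeat."""

    plant_ids: list
    n_folds: int
    n_repeats: int
    seed: int
    assignments: np.ndarray = field(default=None)   # (n_repeats, n_plants)

    def folds(self, repeat: int):
        for f in range(self.n_folds):
            yield f, self.assignments[repeat] == f


def make_folds(plant_ids, n_folds: int = 5, n_repeats: int = 1,
               seed: int = 0) -> CVPlan:
    """Random balanced partition of plants into folds, per repeat."""
    plant_ids = list(plant_ids)
    n = len(plant_ids)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds {n} plants")
    rng = np.random.default_rng(seed)
    assignments = np.empty((n_repeats, n), dtype=np.int64)
    base = np.arange(n) % n_folds          # sizes differ by <= 1
    for r in range(n_repeats):
        labels = base.copy()
        rng.shuffle(labels)
        assignments[r] = labels
    return CVPlan(plant_ids, n_folds, n_repeats, seed, assignments)


def prediction_ability(gebv, y_observed) -> float:
    """Sample Pearson correlation of GEBV with observed phenotype.

    Returns NaN (with a warning) when either side has zero variance; callers
    exclude such folds from their averages rather than zero-imputing them.
    """
    gebv = np.asarray(gebv, dtype=float)
    y = np.asarray(y_observed, dtype=float)
    if gebv.shape != y.shape or gebv.ndim != 1:
        raise ValueError("gebv and phenotype vectors must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(gebv) == 0 or np.std(y) == 0:
        logger.warning("zero variance in GEBV or phenotype: ability undefined")
        return np.nan
    return float(np.corrcoef(gebv, y)[0, 1])


@dataclass
class CVResult:
    """Per-fold prediction abilities plus per-method summaries."""

    records: pd.DataFrame        # method, trait, repeat, fold, r, h2_hat, n_val
    trait: str = "trait"

    def summary(self) -> pd.DataFrame:
        rows = []
        for method, grp in self.records.groupby("method", sort=False):
            r = grp["r"].dropna()
            rows.append({
                "method": method,
                "code": METHOD_CODES.get(method, method),
                "trait": self.trait,
                "ability_mean": r.mean(),
                "ability_se": r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else np.nan,
                "n_folds_used": len(r),
                "n_folds_failed": int(grp["r"].isna().sum()),
                "h2_hat_mean": grp["h2_hat"].mean(),
            })
        return pd.DataFrame(rows)


def cross_validate(geno: MarkerMatrix, y, methods, plan: CVPlan,
                   trait: str = "trait") -> CVResult:
    """Run k-fold CV for each method and score prediction ability.

    ``y`` is the plant-level (entry-mean) phenotype vector aligned with
    ``geno.plant_ids``; ``methods`` is a list of :class:`WGRSpec` (or method
    name strings).  Fold failures are recorded (NaN ability) and the run
    continues.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != geno.n_plants:
        raise ValueError("phenotype length does not match genotype rows")
    if list(plan.plant_ids) != list(geno.plant_ids):
        raise ValueError("CV plan was built for different plants")
    specs = [m if isinstance(m, WGRSpec) else WGRSpec(method=m) for m in methods]
    rows = []
    for spec in specs:
        for rep in range(plan.n_repeats):
            for fold, val_mask in plan.folds(rep):
                y_masked = y.copy()
                y_masked[val_mask] = np.nan
                try:
                    model = make_model(spec).fit(geno, y_masked)
                    gebv_val = np.asarray(model.gebv_)[val_mask] \
                        if hasattr(model, "gebv_") and len(model.gebv_) == len(y) \
                        else model.predict_gebv(geno.select_plants(val_mask))
                    r = prediction_ability(gebv_val, y[val_mask])
                    h2 = getattr(model, "h2_", np.nan)
                except Exception as exc:  # noqa: BLE001 - fold robustness contract
                    logger.warning("fold failed (%s rep %d fold %d): %s",
                                   spec.method, rep, fold, exc)
                    r, h2 = np.nan, np.nan
                rows.append((spec.method, trait, rep, fold, r, h2,
                             int(val_mask.sum())))
    records = pd.DataFrame(
        rows, columns=["method", "trait", "repeat", "fold", "r", "h2_hat", "n_val"]
    )
    return CVResult(records, trait)


def adjusted_means(pheno: PhenotypeTable, trait: str, experiment: str = None,
                   plant_ids=None) -> pd.Series:
    """Block-adjusted plant means: the validation phenotype of the CV loop.

    Fits ordinary least squares y ~ block + plant (both as factors, sum-coded
    blocks) and returns intercept + plant effect, i.e. the plant mean freed
    of block shifts.  With a single block per plant this reduces to the raw
    value; with complete blocks it equals the arithmetic plant mean.
    """
    df = pheno.data
    if experiment is not None:
        df = df[df["experiment"] == experiment]
    df = df[df["trait"] == trait]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    plants = pd.unique(df["plant_id"])
    blocks = pd.unique(df["block"])
    p_idx = {p: i for i, p in enumerate(plants)}
    b_idx = {b: i for i, b in enumerate(blocks)}
    n = len(df)
    # sum-coded blocks (effects sum to zero) + full plant dummies
    B = np.zeros((n, len(blocks) - 1))
    for i, b in enumerate(df["block"]):
        j = b_idx[b]
        if j < len(blocks) - 1:
            B[i, j] = 1.0
        else:
            B[i, :] = -1.0
    P = np.zeros((n, len(plants)))
    P[np.arange(n), [p_idx[p] for p in df["plant_id"]]] = 1.0
    Xd = np.hstack([B, P])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coef, *_ = np.linalg.lstsq(Xd, df["value"].to_numpy(float), rcond=None)
    means = pd.Series(coef[len(blocks) - 1:], index=plants)
    if plant_ids is not None:
        means = means.reindex([str(p) for p in plant_ids])
    return means
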