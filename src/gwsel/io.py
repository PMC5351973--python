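"""Genotype/phenotype containers, on-disk formats, QC and config plumbing.

The canonical interchange format for genotypes is a tab-delimited matrix
(rows = plants, header = marker ids) with an optional ``#marker_type`` comment
line carrying the codominant/dominant flag per marker.  Phenotypes travel as a
long-format CSV with columns ``plant_id, experiment, family, block, trait,
value``.  VCF (v4.2, biallelic, unphased GT) is supported as a read dialect.

Genotype coding
---------------
Codominant (SNP-style) markers are coded as the ALT-allele dose {0, 1, 2};
dominant (DArT-style presence/absence) markers as {0, 1}.  For all
dose-based computations (relationship matrices, regressions) dominant calls
are expanded to dose equivalents {0, 2} — see :meth:`MarkerMatrix.doses`.
Missing values are NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gwsel")

CODOMINANT = "codominant"
DOMINANT = "dominant"

PHENO_COLUMNS = ["plant_id", "experiment", "family", "block", "trait", "value"]


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


class ParseError(ValueError):
    """Raised when an on-disk file cannot be parsed."""


@dataclass
class MarkerMatrix:
    """n plants x m markers of small-integer genotype codes (NaN = missing).

    Parameters
    ----------
    values : ndarray of shape (n, m), float
        Codominant entries in {0, 1, 2, NaN}; dominant entries in {0, 1, NaN}.
    plant_ids, marker_ids : sequences of unique str
    marker_type : ndarray of shape (m,), str
        Per-marker flag, ``"codominant"`` or ``"dominant"``.
    """

    values: np.ndarray
    plant_ids: list
    marker_ids: list
    marker_type: np.ndarray = None
    # True after mean imputation: entries may be fractional within range
    imputed: bool = False
    # set by the simulator: latent allele doses behind dominant calls
    true_doses: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be a 2-D matrix")
        n, m = self.values.shape
        self.plant_ids = [str(p) for p in self.plant_ids]
        self.marker_ids = [str(mk) for mk in self.marker_ids]
        if len(self.plant_ids) != n or len(self.marker_ids) != m:
            raise ValidationError(
                f"id lengths ({len(self.plant_ids)}, {len(self.marker_ids)}) "
                f"inconsistent with matrix shape {self.values.shape}"
            )
        if len(set(self.plant_ids)) != n:
            raise ValidationError("duplicate plant ids")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("duplicate marker ids")
        if self.marker_type is None:
            self.marker_type = np.array([CODOMINANT] * m)
        self.marker_type = np.asarray(self.marker_type, dtype=object)
        if self.marker_type.shape != (m,):
            raise ValidationError("marker_type length inconsistent with matrix")
        bad = set(self.marker_type) - {CODOMINANT, DOMINANT}
        if bad:
            raise ValidationError(f"unknown marker types: {bad}")
        self._check_codes()

    def _check_codes(self):
        vals = self.values
        codom = self.marker_type == CODOMINANT
        with np.errstate(invalid="ignore"):
            if self.imputed:
                # imputed matrices carry fractional mean doses within range
                ok_codom = np.isnan(vals[:, codom]) | (
                    (vals[:, codom] >= 0) & (vals[:, codom] <= 2))
                ok_dom = np.isnan(vals[:, ~codom]) | (
                    (vals[:, ~codom] >= 0) & (vals[:, ~codom] <= 1))
            else:
                ok_codom = np.isnan(vals[:, codom]) | np.isin(
                    vals[:, codom], (0.0, 1.0, 2.0))
                ok_dom = np.isnan(vals[:, ~codom]) | np.isin(
                    vals[:, ~codom], (0.0, 1.0))
        if not ok_codom.all():
            raise ValidationError("codominant entries must be in {0,1,2,NaN}")
        if not ok_dom.all():
            raise ValidationError("dominant entries must be in {0,1,NaN}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_plants(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def doses(self) -> np.ndarray:
        """Allele-dose view: dominant {0,1} calls expanded to {0,2}."""
        d = self.values.copy()
        dom = self.marker_type == DOMINANT
        d[:, dom] = d[:, dom] * 2.0
        return d

    def allele_freqs(self) -> np.ndarray:
        """Observed ALT-allele frequency per marker (dose scale, NaN-aware)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.doses(), axis=0) / 2.0

    def select_markers(self, index) -> "MarkerMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return MarkerMatrix(
            self.values[:, index],
            self.plant_ids,
            [self.marker_ids[i] for i in index],
            self.marker_type[index],
            imputed=self.imputed,
            true_doses=None if self.true_doses is None else self.true_doses[:, index],
        )

    def select_plants(self, index) -> "MarkerMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return MarkerMatrix(
            self.values[index, :],
            [self.plant_ids[i] for i in index],
            self.marker_ids,
            self.marker_type,
            imputed=self.imputed,
            true_doses=None if self.true_doses is None else self.true_doses[index, :],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.plant_ids, columns=self.marker_ids)


@dataclass
class PhenotypeTable:
    """Plant-level phenotype records (long format).

    Columns: plant_id, experiment ({germplasm, diallel}), family, block,
    trait, value.  Each (experiment, plant, trait, block) appears at most
    once and all values are finite.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.data).copy()
        missing = set(PHENO_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
        df = df[PHENO_COLUMNS]
        df["value"] = df["value"].astype(float)
        if not np.isfinite(df["value"]).all():
            raise ValidationError("phenotype values must be finite")
        dup = df.duplicated(subset=["experiment", "plant_id", "trait", "block"])
        if dup.any():
            raise ValidationError(
                f"{int(dup.sum())} duplicate (experiment, plant, trait, block) records"
            )
        self.data = df.reset_index(drop=True)

    @property
    def traits(self) -> list:
        return sorted(self.data["trait"].unique())

    def subset(self, experiment=None, trait=None) -> "PhenotypeTable":
        df = self.data
        if experiment is not None:
            df = df[df["experiment"] == experiment]
        if trait is not None:
            df = df[df["trait"] == trait]
        return PhenotypeTable(df.reset_index(drop=True))

    def plant_means(self, trait: str, plant_ids=None) -> pd.Series:
        """Per-plant mean value across blocks for one trait.

        This is the entry-mean phenotype y_i = mean_k y_ik used as the
        response of the whole-genome regressions.
        """
        df = self.data[self.data["trait"] == trait]
        means = df.groupby("plant_id")["value"].mean()
        if plant_ids is not None:
            means = means.reindex([str(p) for p in plant_ids])
        return means


# ---------------------------------------------------------------------------
# Delimited genotype matrix
# ---------------------------------------------------------------------------

def write_genotypes(geno: MarkerMatrix, path) -> None:
    """Write the tab-delimited genotype matrix (with marker-type comment)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#marker_type\t" + "\t".join(geno.marker_type) + "\n")
        fh.write("plant_id\t" + "\t".join(geno.marker_ids) + "\n")
        for i, pid in enumerate(geno.plant_ids):
            row = [
                "NA" if np.isnan(v) else str(int(v)) for v in geno.values[i]
            ]
            fh.write(pid + "\t" + "\t".join(row) + "\n")


def _read_delimited(path) -> MarkerMatrix:
    path = Path(path)
    marker_type = None
    header = None
    plant_ids, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if line.startswith("#marker_type"):
                marker_type = parts[1:]
                continue
            if header is None:
                header = parts[1:]
                continue
            if len(parts) != len(header) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)+1} fields, got {len(parts)}"
                )
            plant_ids.append(parts[0])
            try:
                rows.append(
                    [np.nan if v in ("NA", "", "nan", ".") else float(v) for v in parts[1:]]
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if header is None:
        raise ParseError(f"{path}: no header line found")
    return MarkerMatrix(np.array(rows, dtype=float), plant_ids, header, marker_type)


def _read_vcf(path) -> MarkerMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading VCF requires cyvcf2 (install the 'vcf' extra)"
        ) from exc
    vcf = VCF(str(path))
    plant_ids = list(vcf.samples)
    marker_ids, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multiallelic record %s:%s", var.CHROM, var.POS
            )
            continue
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012=False maps 3->unknown)
        doses = np.array(
            [gt[0] + gt[1] if gt[0] >= 0 and gt[1] >= 0 else np.nan
             for gt in (g[:2] for g in var.genotypes)],
            dtype=float,
        )
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        cols.append(doses)
    values = np.column_stack(cols) if cols else np.empty((len(plant_ids), 0))
    return MarkerMatrix(values, plant_ids, marker_ids)


def read_genotypes(path, format: str = "delimited") -> MarkerMatrix:
    """Read a genotype matrix from disk.

    ``format`` is ``"delimited"`` (canonical TSV layout) or ``"vcf"``
    (biallelic records mapped to ALT-allele dose 0/1/2; multiallelic records
    are skipped with a warning; ``./.`` becomes missing).
    """
    if format == "delimited":
        return _read_delimited(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ConfigError(f"unknown genotype format: {format!r}")


def write_vcf(geno: MarkerMatrix, path) -> None:
    """Write codominant markers as a minimal VCF v4.2 (unphased diploid GT).

    Dominant presence/absence markers have no faithful GT representation and
    are skipped with a warning; use the delimited format to carry them.
    """
    path = Path(path)
    dom = geno.marker_type == DOMINANT
    if dom.any():
        logger.warning("write_vcf: skipping %d dominant markers", int(dom.sum()))
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.plant_ids) + "\n")
        pos = 0
        for j in np.flatnonzero(~dom):
            pos += 1
            calls = [
                "./." if np.isnan(v) else gt_map[v] for v in geno.values[:, j]
            ]
            fh.write(f"1\t{pos}\t{geno.marker_ids[j]}\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# QC: imputation and filtering
# ---------------------------------------------------------------------------

class EmptyPanelError(ValueError):
    """All markers removed by QC."""


def impute_and_filter(
    geno: MarkerMatrix, maf_min: float = 0.0, max_missing: float = 1.0
) -> MarkerMatrix:
    """Drop low-MAF / high-missingness markers and mean-impute the rest.

    Markers with minor-allele frequency strictly below ``maf_min`` or
    missing-call rate strictly above ``max_missing`` are removed; surviving
    missing entries are replaced by the marker mean (in the marker's own
    coding).  The default thresholds keep every marker, mirroring an
    analysis that uses the full panel.  Idempotent.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ConfigError("maf_min must be in [0, 0.5]")
    if not 0.0 <= max_missing <= 1.0:
        raise ConfigError("max_missing must be in [0, 1]")
    p = geno.allele_freqs()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1.0 - p)
    miss = np.mean(np.isnan(geno.values), axis=0)
    keep = (np.nan_to_num(maf, nan=0.0) >= maf_min) & (miss <= max_missing)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "QC removed %d/%d markers (maf<%g or missing>%g)",
            n_drop, geno.n_markers, maf_min, max_missing,
        )
    if not keep.any():
        raise EmptyPanelError("QC removed all markers")
    out = geno.select_markers(keep)
    vals = out.values
    if np.isnan(vals).any():
        col_mean = np.nanmean(vals, axis=0)
        idx = np.where(np.isnan(vals))
        vals[idx] = col_mean[idx[1]]
    return MarkerMatrix(vals, out.plant_ids, out.marker_ids, out.marker_type,
                        imputed=True)


# ---------------------------------------------------------------------------
# Config + logging plumbing
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a flat YAML key/value run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError("config file must contain a mapping")
    return cfg


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING if verbosity <= 0 else (
        logging.INFO if verbosity == 1 else logging.DEBUG
    )
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=True,
    )
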