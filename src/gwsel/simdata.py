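"""Synthetic half-sib / diallel populations with known genetic architecture.

The generator emulates a small perennial-crop genomic-selection trial: a
germplasm bank of half-sib founder genotypes evaluated in a randomized
complete block design, plus a diallel of full-sib families obtained by
crossing contrasting founders.  Markers are unlinked biallelic loci (a mix of
codominant SNP-style and dominant DArT-style presence/absence calls); a
configurable subset of markers act as additive QTL, and — in the diallel —
full-sib families carry an extra dominance/family deviation.  Every output is
a pure function of (config, seed), and the true genetic values are returned
alongside the phenotypes so downstream estimators can be checked against
ground truth.

Default dimensions are the study conditions: 36 genotyped founders, 3 diallel
families x 14 progeny (78 plants), 1,248 markers, target narrow-sense
heritabilities 0.27 (grain yield, GY) and 0.35 (100-seed weight, W100S),
2 blocks in the germplasm trial and 5 in the diallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CODOMINANT, DOMINANT, ConfigError, MarkerMatrix, PhenotypeTable


@dataclass
class SimConfig:
    """Dimensions and genetic architecture of a simulated trial."""

    n_founders: int = 36
    n_halfsib_plants: int = 36          # genotyped plants from the germplasm bank
    diallel_families: int = 3
    progeny_per_family: int = 14
    n_markers: int = 1248
    n_qtl: int = 100
    maf_range: tuple = (0.05, 0.5)
    target_h2: float = 0.3
    dominance_ratio: float = 0.25       # sigma_f^2 / sigma_a^2 in the diallel
    block_count: int = 2
    block_sd: float = 0.0               # SD of fixed block effects, trait units
    seed: int = 0
    dominant_fraction: float = 0.5      # share of dominant (DArT-style) markers
    missing_rate: float = 0.0
    mean: float = 0.0                   # trait grand mean
    genetic_sd: float = 1.0             # SD of true additive values

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must be within (0, 0.5]")
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ConfigError("target_h2 must be in [0, 1]")
        if self.n_qtl > self.n_markers:
            raise ConfigError("n_qtl cannot exceed n_markers")
        if self.dominance_ratio < 0:
            raise ConfigError("dominance_ratio must be nonnegative")
        if not 0.0 <= self.dominant_fraction <= 1.0:
            raise ConfigError("dominant_fraction must be in [0, 1]")


@dataclass
class TrueGeneticValues:
    """Ground-truth genetic values behind a simulated phenotype."""

    plant_ids: list
    additive: np.ndarray                 # a_i, trait units
    dominance: np.ndarray                # f_i (family deviation; zeros if none)
    qtl_indices: np.ndarray              # column indices of causal markers
    qtl_effects: np.ndarray              # trait units per allele dose

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"plant_id": self.plant_ids, "additive": self.additive,
             "dominance": self.dominance}
        )


def _observe(true_doses: np.ndarray, marker_type: np.ndarray,
             rng: np.random.Generator, missing_rate: float) -> np.ndarray:
    """Map latent allele doses {0,1,2} to observed calls per marker type."""
    obs = true_doses.astype(float).copy()
    dom = marker_type == DOMINANT
    # dominant scoring: presence of >=1 copy of the marker allele
    obs[:, dom] = (obs[:, dom] >= 1).astype(float)
    if missing_rate > 0:
        mask = rng.random(obs.shape) < missing_rate
        obs[mask] = np.nan
    return obs


def sim_founder_genotypes(cfg: SimConfig) -> MarkerMatrix:
    """Unrelated founder genotypes: HWE draws at frequencies ~ U(maf_range)."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    p = rng.uniform(lo, hi, size=cfg.n_markers)
    doses = rng.binomial(2, p, size=(cfg.n_founders, cfg.n_markers)).astype(float)
    n_dom = int(round(cfg.dominant_fraction * cfg.n_markers))
    marker_type = np.array([DOMINANT] * n_dom + [CODOMINANT] * (cfg.n_markers - n_dom))
    rng.shuffle(marker_type)
    obs = _observe(doses, marker_type, rng, cfg.missing_rate)
    geno = MarkerMatrix(
        obs,
        [f"F{i+1:03d}" for i in range(cfg.n_founders)],
        [f"M{j+1:05d}" for j in range(cfg.n_markers)],
        marker_type,
    )
    geno.true_doses = doses
    return geno


def sim_diallel_progeny(
    founders: MarkerMatrix,
    parent_pairs: list,
    progeny_per_family: int,
    seed: int = 0,
    missing_rate: float = 0.0,
):
    """Mendelian full-sib progeny of the given parent pairs (no linkage).

    Returns ``(progeny: MarkerMatrix, pedigree: DataFrame)``; the pedigree has
    one row per progeny with columns plant_id, family, mother, father.
    """
    rng = np.random.default_rng(seed)
    idx = {p: i for i, p in enumerate(founders.plant_ids)}
    for pair in parent_pairs:
        for p in pair:
            if str(p) not in idx:
                raise KeyError(f"unknown parent id: {p}")
    parental = founders.true_doses if founders.true_doses is not None else founders.values
    if np.isnan(parental).any():
        raise ValueError("parent genotypes must not contain missing values")
    rows, ped = [], []
    for k, (mother, father) in enumerate(parent_pairs, start=1):
        dm = parental[idx[str(mother)]]
        df_ = parental[idx[str(father)]]
        for j in range(progeny_per_family):
            # gamete allele ~ Bernoulli(dose/2) per unlinked marker
            g1 = rng.random(founders.n_markers) < dm / 2.0
            g2 = rng.random(founders.n_markers) < df_ / 2.0
            rows.append((g1.astype(float) + g2.astype(float)))
            ped.append((f"D{k}_{j+1:02d}", f"FAM{k}", str(mother), str(father)))
    doses = np.array(rows)
    obs = _observe(doses, founders.marker_type, rng, missing_rate)
    progeny = MarkerMatrix(
        obs, [r[0] for r in ped], founders.marker_ids, founders.marker_type
    )
    progeny.true_doses = doses
    pedigree = pd.DataFrame(ped, columns=["plant_id", "family", "mother", "father"])
    return progeny, pedigree


def _draw_qtl(geno: MarkerMatrix, cfg: SimConfig, rng) -> TrueGeneticValues:
    doses = geno.true_doses if geno.true_doses is not None else geno.doses()
    qtl = np.sort(rng.choice(geno.n_markers, size=cfg.n_qtl, replace=False))
    effects = rng.standard_normal(cfg.n_qtl)
    a = doses[:, qtl] @ effects
    a = a - a.mean()
    sd = a.std(ddof=1)
    if cfg.n_qtl > 0 and sd > 0 and cfg.genetic_sd > 0:
        scale = cfg.genetic_sd / sd
        a *= scale
        effects = effects * scale
    else:
        a = np.zeros_like(a)
        effects = np.zeros_like(effects)
    return TrueGeneticValues(list(geno.plant_ids), a, np.zeros_like(a), qtl, effects)


def sim_phenotypes(
    geno: MarkerMatrix,
    cfg: SimConfig,
    design: str = "germplasm",
    trait: str = "trait",
    family_of: dict = None,
    seed_offset: int = 1,
):
    """Simulate block-replicated phenotypes with a known architecture.

    Additive values come from ``cfg.n_qtl`` markers with normal effects,
    rescaled so the realized additive SD equals ``cfg.genetic_sd``.  The
    residual SD is chosen so that the plant-level narrow-sense heritability
    sigma_a^2 / (sigma_a^2 + sigma_f^2 + sigma_e^2) equals ``cfg.target_h2``
    exactly on the realized additive variance.  Fixed block effects (SD
    ``cfg.block_sd``) shift whole blocks; in the diallel design each full-sib
    family additionally carries a dominance/family deviation with variance
    ``cfg.dominance_ratio * sigma_a^2``.

    Returns ``(PhenotypeTable, TrueGeneticValues)``.
    """
    if design not in ("germplasm", "diallel"):
        raise ConfigError(f"unknown design: {design!r}")
    rng = np.random.default_rng((cfg.seed, seed_offset))
    truth = _draw_qtl(geno, cfg, rng)
    var_a = float(np.var(truth.additive, ddof=1)) if cfg.n_qtl else 0.0

    fam_labels = None
    if design == "diallel":
        if family_of is None:
            raise ConfigError("diallel design requires family_of mapping")
        fam_labels = np.array([family_of[p] for p in geno.plant_ids])
        fams = pd.unique(fam_labels)
        sigma_f = np.sqrt(cfg.dominance_ratio * var_a)
        # rescale the realized draws so the family variance is exact even
        # with very few families (mirrors the additive-value rescaling)
        draws = rng.standard_normal(len(fams))
        if len(fams) > 1 and sigma_f > 0 and draws.std(ddof=1) > 0:
            draws = (draws - draws.mean()) / draws.std(ddof=1) * sigma_f
        else:
            draws = np.zeros(len(fams))
        fam_dev = dict(zip(fams, draws))
        truth.dominance = np.array([fam_dev[f] for f in fam_labels])
    var_f = float(np.var(truth.dominance, ddof=1)) if design == "diallel" else 0.0

    h2 = cfg.target_h2
    genetic_scale = 1.0
    if h2 >= 1.0:
        sigma_e = 0.0
        if var_f > 0:
            raise ConfigError("target_h2=1 is incompatible with dominance variance")
    elif h2 <= 0.0:
        # pure-noise trait: the true genetic values are still reported, but
        # the phenotype carries none of them (residual at the genetic scale)
        genetic_scale = 0.0
        sigma_e = cfg.genetic_sd if cfg.genetic_sd > 0 else 1.0
    else:
        # h2 = va / (va + vf + ve)  =>  ve = va (1 - h2)/h2 - vf
        sigma_e2 = var_a * (1.0 - h2) / h2 - var_f
        if sigma_e2 < 0:
            raise ConfigError(
                "dominance_ratio too large for target_h2 (implied residual < 0)"
            )
        sigma_e = np.sqrt(sigma_e2)

    n_blocks = cfg.block_count
    block_eff = rng.standard_normal(n_blocks) * cfg.block_sd
    records = []
    for b in range(n_blocks):
        e = rng.standard_normal(geno.n_plants) * sigma_e
        y = (cfg.mean + block_eff[b]
             + genetic_scale * (truth.additive + truth.dominance) + e)
        for i, pid in enumerate(geno.plant_ids):
            records.append(
                (pid, design, fam_labels[i] if fam_labels is not None else "NA",
                 f"B{b+1}", trait, y[i])
            )
    pheno = PhenotypeTable(
        pd.DataFrame(records, columns=[
            "plant_id", "experiment", "family", "block", "trait", "value"])
    )
    return pheno, truth


def sim_germplasm_trial(n_genotypes: int, n_blocks: int, sigma2_a: float,
                        sigma2_e: float, mean: float = 50.0,
                        block_sd: float = 0.0, seed: int = 0,
                        trait: str = "trait"):
    """Plain randomized-complete-block trial with genotype-level effects.

    y_gb = mean + r_b + a_g + e_gb with a ~ N(0, sigma2_a) i.i.d. per
    genotype and e ~ N(0, sigma2_e) per record.  Returns
    ``(PhenotypeTable, a)`` — the design the variance-component recovery
    studies use.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, np.sqrt(sigma2_a), n_genotypes)
    blocks = rng.normal(0.0, block_sd, n_blocks)
    rows = []
    for b in range(n_blocks):
        e = rng.normal(0.0, np.sqrt(sigma2_e), n_genotypes)
        for g in range(n_genotypes):
            rows.append((f"P{g+1:04d}", "germplasm", "NA", f"B{b+1}", trait,
                         mean + blocks[b] + a[g] + e[g]))
    pheno = PhenotypeTable(pd.DataFrame(rows, columns=[
        "plant_id", "experiment", "family", "block", "trait", "value"]))
    return pheno, a


def sim_halfsib_trial(n_families: int, n_blocks: int, sigma2_a: float,
                      sigma2_e: float, plants_per_plot: int = 5,
                      mean: float = 50.0, block_sd: float = 0.0,
                      seed: int = 0, trait: str = "trait"):
    """Half-sib family trial recorded at the plot-mean level.

    Each record is the mean of ``plants_per_plot`` half-sibs in one block:
    y_fb = mean + r_b + f_f + w_fb, with the family effect
    f ~ N(0, sigma2_a / 4) (half-sibs share a quarter of the additive
    variance) and the plot-mean deviation
    w ~ N(0, (3/4 sigma2_a + sigma2_e) / plants_per_plot) — the
    within-family additive variance plus the plant residual, shrunk by the
    plot average.  Combined with the Falconer conversion
    sigma_a^2 = 4 sigma_f^2 this is the setting in which a small residual
    drives the reported heritability above 1.
    """
    rng = np.random.default_rng(seed)
    fam = rng.normal(0.0, np.sqrt(sigma2_a / 4.0), n_families)
    blocks = rng.normal(0.0, block_sd, n_blocks)
    w_sd = np.sqrt((0.75 * sigma2_a + sigma2_e) / plants_per_plot)
    rows = []
    for b in range(n_blocks):
        w = rng.normal(0.0, w_sd, n_families)
        for f in range(n_families):
            rows.append((f"HS{f+1:04d}", "germplasm", f"HS{f+1:04d}",
                         f"B{b+1}", trait,
                         mean + blocks[b] + fam[f] + w[f]))
    pheno = PhenotypeTable(pd.DataFrame(rows, columns=[
        "plant_id", "experiment", "family", "block", "trait", "value"]))
    return pheno, fam


@dataclass
class StudyDataset:
    """Bundle returned by :func:`make_study_like_dataset`."""

    geno: MarkerMatrix
    pheno: PhenotypeTable
    truth: dict                         # trait -> TrueGeneticValues
    pedigree: pd.DataFrame
    family_of: dict

    @property
    def traits(self):
        return sorted(self.truth)


# trait architecture: (target h2, grand mean, additive SD) — scales chosen to
# give realistic genetic/residual coefficients of variation for a seed crop
STUDY_TRAITS = {
    "GY": dict(target_h2=0.27, mean=740.0, genetic_sd=97.0),
    "W100S": dict(target_h2=0.35, mean=62.0, genetic_sd=3.4),
}


def make_study_like_dataset(seed: int = 0, cfg: SimConfig = None) -> StudyDataset:
    """78 plants x 1,248 markers, two traits, germplasm + diallel structure.

    36 half-sib founders from the germplasm bank (2 blocks) plus 3 full-sib
    families x 14 progeny from a complete diallel of 3 contrasting founders
    (5 blocks).  Traits: GY (target h2 0.27) and W100S (target h2 0.35).
    """
    if cfg is None:
        cfg = SimConfig(seed=seed)
    else:
        cfg = replace(cfg, seed=seed)
    founders = sim_founder_genotypes(cfg)
    parents = founders.plant_ids[: 3]
    pairs = [(parents[0], parents[1]), (parents[0], parents[2]),
             (parents[1], parents[2])][: cfg.diallel_families]
    progeny, pedigree = sim_diallel_progeny(
        founders, pairs, cfg.progeny_per_family, seed=cfg.seed + 1,
        missing_rate=cfg.missing_rate,
    )
    geno = MarkerMatrix(
        np.vstack([founders.values, progeny.values]),
        founders.plant_ids + progeny.plant_ids,
        founders.marker_ids,
        founders.marker_type,
    )
    td_f = founders.true_doses if founders.true_doses is not None else founders.values
    geno.true_doses = np.vstack([td_f, progeny.true_doses])
    family_of = dict(zip(pedigree["plant_id"], pedigree["family"]))

    frames, truth = [], {}
    for t, (trait, arch) in enumerate(STUDY_TRAITS.items()):
        tcfg = replace(cfg, **arch)
        germ = replace(tcfg, block_count=2)
        founders_view = geno.select_plants(range(cfg.n_founders))
        ph_g, tr_g = sim_phenotypes(
            founders_view, germ, design="germplasm", trait=trait,
            seed_offset=10 + t,
        )
        dia = replace(tcfg, block_count=5)
        progeny_view = geno.select_plants(
            range(cfg.n_founders, geno.n_plants)
        )
        ph_d, tr_d = sim_phenotypes(
            progeny_view, dia, design="diallel", trait=trait,
            family_of=family_of, seed_offset=20 + t,
        )
        frames += [ph_g.data, ph_d.data]
        truth[trait] = TrueGeneticValues(
            geno.plant_ids,
            np.concatenate([tr_g.additive, tr_d.additive]),
            np.concatenate([tr_g.dominance, tr_d.dominance]),
            tr_g.qtl_indices, tr_g.qtl_effects,
        )
    pheno = PhenotypeTable(pd.concat(frames, ignore_index=True))
    return StudyDataset(geno, pheno, truth, pedigree, family_of)
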