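"""Seeded synthetic cohorts with the structure the analysis assumes.

The generator emulates the shape of a pan-cancer study: a gene x sample
log2(FPKM+1)-like expression matrix containing the packaged regulator
catalog, per-sample clinical annotations with four survival endpoints,
a MAF-like mutation table, immune/molecular score tables, and a cell-line
panel with per-drug IC50 values.

Every tumor sample carries a latent activation level a ~ Uniform(0, 1)
(normal tissue has a = 0) which drives all planted couplings:

* positive-regulator genes are shifted by +delta * a and negative
  regulators by -kappa * delta * a (log2 units);
* survival times are exponential with log-hazard hazard_beta * a and
  independent exponential censoring calibrated to the requested rate;
* planted immune-cell fractions and the immune/stromal/ESTIMATE scores
  increase with a, tumor purity decreases;
* per-drug IC50 decreases with a (higher activation = more sensitive);
* immune subtype labels C1-C6 come from thresholding a, with label noise.

The latent activation is stored for recovery tests only and is never an
input to any analysis stage.  All randomness flows from a single seed
through ``numpy.random.SeedSequence`` spawning, so each block of the
cohort is reproducible independently and two runs with the same config
are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pyroppi.catalog import DirectionalCatalog, GeneSet, catalog_to_gmt, packaged_prg_catalog

#: the 22 immune-cell fraction labels emitted in score tables
CELL_TYPES = (
    "B_cells_naive", "B_cells_memory", "Plasma_cells", "T_cells_CD8",
    "T_cells_CD4_naive", "T_cells_CD4_memory_resting",
    "T_cells_CD4_memory_activated", "T_cells_follicular_helper",
    "T_cells_regulatory_Tregs", "T_cells_gamma_delta", "NK_cells_resting",
    "NK_cells_activated", "Monocytes", "Macrophages_M0", "Macrophages_M1",
    "Macrophages_M2", "Dendritic_cells_resting", "Dendritic_cells_activated",
    "Mast_cells_resting", "Mast_cells_activated", "Eosinophils", "Neutrophils",
)

#: fractions planted to increase with activation
COUPLED_CELL_TYPES = ("T_cells_CD8", "Macrophages_M1", "T_cells_regulatory_Tregs")

DRUG_NAMES = ("cisplatin", "rapamycin", "gemcitabine", "paclitaxel",
              "docetaxel", "methotrexate", "sorafenib")

IMMUNE_SUBTYPES = ("C1", "C2", "C3", "C4", "C5", "C6")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; the defaults are the study conditions
    the package is tested under (see docs/methods.md for rationale)."""

    n_genes: int = 1500
    n_samples: int = 200
    n_strata: int = 4
    frac_normal: float = 0.15
    activation_effect: float = 1.5     # delta, log2-units shift on positives
    negative_effect_ratio: float = 1.0  # kappa; negatives shift by -kappa*delta*a
    hazard_beta: float | tuple[float, ...] = 0.8  # per unit activation
    immune_coupling: float = 0.3
    drug_coupling: float = 1.0
    mutation_coupling: float = 0.0
    mutation_rate: float = 20.0        # mean mutation rows per tumor sample
    noise_sd: float = 1.0              # per-gene expression noise, log2 units
    score_noise_sd: float = 0.1
    drug_noise_sd: float = 0.5
    censor_rate: float = 0.3
    base_survival_days: float = 1000.0
    subtype_label_noise: float = 0.1
    n_cell_lines: int = 60
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("n_genes", "n_samples", "n_strata", "n_cell_lines"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.frac_normal < 1:
            raise ValueError("frac_normal must be in [0, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")

    def hazard_betas(self) -> np.ndarray:
        hb = np.atleast_1d(np.asarray(self.hazard_beta, dtype=float))
        if len(hb) == 1:
            hb = np.repeat(hb, self.n_strata)
        if len(hb) != self.n_strata:
            raise ValueError("hazard_beta must be scalar or length n_strata")
        return hb


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame          # gene x sample, log2(FPKM+1)-like
    clinical: pd.DataFrame            # CohortAnnotations columns
    mutations: pd.DataFrame           # sample, gene, variant_classification
    scores: pd.DataFrame              # per-sample annotation scores
    panel_expression: pd.DataFrame    # gene x cell line
    panel_drugs: pd.DataFrame         # drug x cell line IC50
    catalog: DirectionalCatalog
    true_activation: pd.Series        # recovery tests only
    config: SimulationConfig = field(repr=False, default=None)


def _gene_universe(n_genes: int, catalog: DirectionalCatalog) -> list[str]:
    members = sorted(catalog.all_members)
    if n_genes < len(members) + 2:
        raise ValueError(
            f"n_genes={n_genes} cannot accommodate the {len(members)} "
            "catalog genes plus background"
        )
    background = [f"gene_{i:05d}" for i in range(n_genes - len(members))]
    return members + background


def _expression_block(genes: list[str], sample_ids: list[str],
                      activation: np.ndarray, catalog: DirectionalCatalog,
                      cfg: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    gene_means = np.clip(rng.normal(4.0, 1.5, size=len(genes)), 0.0, None)
    values = gene_means[:, None] + rng.normal(0.0, cfg.noise_sd,
                                              size=(len(genes), len(sample_ids)))
    idx = pd.Index(genes, name="gene")
    pos = idx.isin(catalog.positive.members)
    neg = idx.isin(catalog.negative.members)
    delta = cfg.activation_effect
    values[pos, :] += delta * activation[None, :]
    values[neg, :] -= cfg.negative_effect_ratio * delta * activation[None, :]
    values = np.clip(values, 0.0, None)
    return pd.DataFrame(values, index=idx, columns=sample_ids)


def simulate_survival(activation: np.ndarray, beta: float, cfg: SimulationConfig,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with log-hazard beta * activation and
    independent exponential censoring at the configured marginal rate."""
    n = len(activation)
    scale = cfg.base_survival_days * np.exp(-beta * activation)
    event_t = rng.exponential(scale=scale)
    if cfg.censor_rate > 0:
        censor_scale = cfg.base_survival_days * (1 - cfg.censor_rate) / cfg.censor_rate
        censor_t = rng.exponential(scale=censor_scale, size=n)
    else:
        censor_t = np.full(n, np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return np.maximum(time, 0.5), event


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; bitwise deterministic per seed."""
    catalog = packaged_prg_catalog()
    genes = _gene_universe(config.n_genes, catalog)
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rng_design, rng_expr, rng_surv, rng_scores, rng_mut, rng_panel = (
        np.random.default_rng(s) for s in seeds
    )

    # --- design: strata, tissue, pairing, activation -----------------------
    strata_names = [f"CT{i + 1:02d}" for i in range(config.n_strata)]
    base = config.n_samples // config.n_strata
    sizes = [base + (1 if i < config.n_samples % config.n_strata else 0)
             for i in range(config.n_strata)]
    rows = []
    counter = 0
    for st, size in zip(strata_names, sizes):
        n_normal = int(round(config.frac_normal * size))
        n_tumor = size - n_normal
        for j in range(n_tumor):
            counter += 1
            pid = f"{st}-P{j + 1:04d}"
            rows.append({"sample": f"S{counter:05d}", "patient_id": pid,
                         "cancer_type": st, "tissue": "tumor"})
        for j in range(n_normal):  # normals pair with the first tumors
            counter += 1
            pid = f"{st}-P{j + 1:04d}"
            rows.append({"sample": f"S{counter:05d}", "patient_id": pid,
                         "cancer_type": st, "tissue": "normal"})
    design = pd.DataFrame(rows).set_index("sample")
    is_tumor = (design["tissue"] == "tumor").to_numpy()
    activation = np.where(is_tumor, rng_design.uniform(0, 1, size=len(design)), 0.0)
    true_activation = pd.Series(activation, index=design.index, name="activation")

    # --- expression --------------------------------------------------------
    expression = _expression_block(genes, list(design.index), activation,
                                   catalog, config, rng_expr)

    # --- clinical ----------------------------------------------------------
    clinical = design.copy()
    clinical["age"] = np.round(rng_design.normal(62, 11, size=len(design))).clip(18, 95)
    clinical["sex"] = rng_design.choice(["male", "female"], size=len(design))
    clinical["race"] = rng_design.choice(
        ["white", "black", "asian", "other"], size=len(design),
        p=[0.6, 0.2, 0.15, 0.05])
    clinical["grade"] = rng_design.choice(["G1", "G2", "G3", "G4"], size=len(design))
    clinical["stage"] = rng_design.choice(["I", "II", "III", "IV"], size=len(design))
    hbs = config.hazard_betas()
    beta_by_stratum = dict(zip(strata_names, hbs))
    for ep in ("os", "dss", "dfs", "pfs"):
        tcol = np.full(len(design), np.nan)
        ecol = np.full(len(design), np.nan)
        for st in strata_names:
            m = (design["cancer_type"] == st).to_numpy() & is_tumor
            t, e = simulate_survival(activation[m], beta_by_stratum[st],
                                     config, rng_surv)
            tcol[m], ecol[m] = t, e
        clinical[f"{ep}_time"] = np.round(tcol, 1)
        clinical[f"{ep}_event"] = ecol
    # immune subtype: threshold activation into six bins, then label noise
    bins = np.minimum((activation * len(IMMUNE_SUBTYPES)).astype(int),
                      len(IMMUNE_SUBTYPES) - 1)
    labels = np.array(IMMUNE_SUBTYPES)[bins].astype(object)
    flip = rng_design.uniform(size=len(design)) < config.subtype_label_noise
    labels[flip] = rng_design.choice(IMMUNE_SUBTYPES, size=int(flip.sum()))
    labels[~is_tumor] = None
    clinical["immune_subtype"] = labels

    # --- annotation scores --------------------------------------------------
    a = activation
    c, sn = config.immune_coupling, config.score_noise_sd
    scores = pd.DataFrame(index=design.index)
    scores["immune_score"] = c * a + rng_scores.normal(0, sn, len(a))
    scores["stromal_score"] = 0.5 * c * a + rng_scores.normal(0, sn, len(a))
    scores["estimate_score"] = scores["immune_score"] + scores["stromal_score"]
    scores["tumor_purity"] = np.clip(
        0.8 - 0.5 * c * a + rng_scores.normal(0, sn, len(a)), 0.0, 1.0)
    # base composition from normalized gamma draws (sums to 0.9), then an
    # additive activation coupling on the planted cell types, renormalized
    # so the fractions stay on the simplex (sum <= 1)
    raw = rng_scores.gamma(shape=2.0, scale=1.0, size=(len(a), len(CELL_TYPES)))
    fractions = 0.9 * raw / raw.sum(axis=1, keepdims=True)
    for ct in COUPLED_CELL_TYPES:
        fractions[:, CELL_TYPES.index(ct)] += c * a / len(COUPLED_CELL_TYPES)
    fractions /= np.maximum(fractions.sum(axis=1, keepdims=True), 1.0)
    for k, ct in enumerate(CELL_TYPES):
        scores[ct] = fractions[:, k]
    scores["msi"] = np.clip(0.4 - 0.3 * c * a + rng_scores.normal(0, sn, len(a)), 0, None)
    scores["rnass"] = np.clip(0.5 - 0.4 * c * a + rng_scores.normal(0, sn, len(a)), 0, 1)
    scores["dnass"] = np.clip(0.5 - 0.4 * c * a + rng_scores.normal(0, sn, len(a)), 0, 1)
    scores["hrd"] = np.clip(10 + rng_scores.normal(0, 20 * sn, len(a)), 0, None)
    scores["pathway_ifn"] = c * a + rng_scores.normal(0, sn, len(a))
    scores["pathway_pi3k"] = 0.5 * c * a + rng_scores.normal(0, sn, len(a))
    scores.loc[~is_tumor, :] = np.nan

    # --- mutations ----------------------------------------------------------
    rates = config.mutation_rate * np.exp(config.mutation_coupling * a)
    ns_classes = ("Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
                  "Frame_Shift_Ins", "Splice_Site")
    mut_rows = []
    tumor_ids = design.index[is_tumor]
    for sid, rate in zip(design.index, rates):
        if sid not in set(tumor_ids):
            continue
        k = rng_mut.poisson(rate)
        if k == 0:
            continue
        mut_genes = rng_mut.choice(genes, size=k)
        silent = rng_mut.uniform(size=k) < 0.3
        classes = np.where(silent, "Silent",
                           rng_mut.choice(ns_classes, size=k))
        for g, vc in zip(mut_genes, classes):
            mut_rows.append({"sample": sid, "gene": g,
                             "variant_classification": vc})
    mutations = pd.DataFrame(mut_rows,
                             columns=["sample", "gene", "variant_classification"])

    # --- cell-line panel ----------------------------------------------------
    line_ids = [f"CL{i + 1:03d}" for i in range(config.n_cell_lines)]
    a_line = rng_panel.uniform(0, 1, size=config.n_cell_lines)
    panel_expression = _expression_block(genes, line_ids, a_line, catalog,
                                         config, rng_panel)
    drug_base = rng_panel.normal(3.0, 0.5, size=len(DRUG_NAMES))
    ic50 = (drug_base[:, None]
            - config.drug_coupling * a_line[None, :]
            + rng_panel.normal(0, config.drug_noise_sd,
                               size=(len(DRUG_NAMES), config.n_cell_lines)))
    panel_drugs = pd.DataFrame(ic50, index=pd.Index(DRUG_NAMES, name="drug"),
                               columns=line_ids)

    return SyntheticCohort(
        expression=expression, clinical=clinical, mutations=mutations,
        scores=scores, panel_expression=panel_expression,
        panel_drugs=panel_drugs, catalog=catalog,
        true_activation=true_activation, config=config,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every cohort table in the dialects the analysis modules read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "mutations": outdir / "mutations.tsv",
        "scores": outdir / "scores.tsv",
        "panel_expression": outdir / "panel_expression.tsv",
        "panel_drugs": outdir / "panel_drugs.tsv",
        "catalog": outdir / "catalog.gmt",
        "activation": outdir / "true_activation.tsv",
    }
    fmt = "%.6g"
    cohort.expression.to_csv(paths["expression"], sep="\t", float_format=fmt)
    cohort.clinical.to_csv(paths["clinical"], sep="\t", float_format=fmt)
    cohort.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    cohort.scores.to_csv(paths["scores"], sep="\t", float_format=fmt)
    cohort.panel_expression.to_csv(paths["panel_expression"], sep="\t", float_format=fmt)
    cohort.panel_drugs.to_csv(paths["panel_drugs"], sep="\t", float_format=fmt)
    catalog_to_gmt(cohort.catalog, paths["catalog"])
    cohort.true_activation.to_csv(paths["activation"], sep="\t", float_format=fmt)
    return paths


def worked_fixture() -> SyntheticCohort:
    """A tiny literal cohort (10 genes, 8 samples) with hand-checkable values.

    Four tumor/normal pairs in one pseudo cancer type; a 2+2-gene
    directional catalog; a 10-row mutation table of which 6 rows are
    nonsynonymous.  Every value is a fixed literal so downstream oracle
    tests can enumerate expected results by hand.
    """
    genes = ["POSA", "POSB", "NEGA", "NEGB", "G1", "G2", "G3", "G4", "G5", "G6"]
    samples = ["P1T", "P1N", "P2T", "P2N", "P3T", "P3N", "P4T", "P4N"]
    values = np.array([
        # P1T P1N P2T P2N P3T P3N P4T P4N
        [9.0, 5.0, 8.0, 4.0, 9.5, 6.0, 7.0, 6.5],   # POSA (high in tumor)
        [8.5, 4.0, 9.0, 5.0, 8.0, 5.5, 7.5, 6.0],   # POSB
        [2.0, 6.0, 1.0, 7.0, 2.5, 6.5, 3.0, 5.0],   # NEGA (low in tumor)
        [1.5, 7.0, 2.0, 6.0, 1.0, 7.5, 2.5, 5.5],   # NEGB
        [5.0, 5.5, 4.0, 4.5, 5.0, 5.0, 4.5, 4.0],   # G1
        [3.0, 3.5, 3.0, 3.5, 3.0, 3.0, 3.5, 3.0],   # G2
        [6.0, 6.5, 6.0, 5.5, 6.5, 6.0, 6.0, 6.5],   # G3
        [4.0, 4.5, 5.0, 5.5, 4.0, 4.5, 5.0, 4.5],   # G4
        [7.0, 7.5, 7.0, 6.5, 7.0, 7.5, 6.5, 7.0],   # G5
        [0.5, 1.0, 0.5, 1.0, 0.5, 1.0, 0.5, 1.0],   # G6
    ])
    expression = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                              columns=samples)
    catalog = DirectionalCatalog(
        positive=GeneSet(name="fix_pos", members=frozenset({"POSA", "POSB"})),
        negative=GeneSet(name="fix_neg", members=frozenset({"NEGA", "NEGB"})),
    )
    clinical = pd.DataFrame({
        "patient_id": ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"],
        "cancer_type": ["FIXT"] * 8,
        "tissue": ["tumor", "normal"] * 4,
        "os_time": [400.0, np.nan, 250.0, np.nan, 800.0, np.nan, 150.0, np.nan],
        "os_event": [1.0, np.nan, 1.0, np.nan, 0.0, np.nan, 1.0, np.nan],
    }, index=pd.Index(samples, name="sample"))
    mutations = pd.DataFrame({
        "sample": ["P1T", "P1T", "P2T", "P2T", "P3T", "P3T",
                   "P1T", "P2T", "P3T", "P4T"],
        "gene": ["POSA", "G1", "POSA", "NEGA", "POSB", "G2",
                 "G3", "G4", "G5", "G6"],
        "variant_classification": [
            "Missense_Mutation", "Nonsense_Mutation", "Missense_Mutation",
            "Frame_Shift_Del", "Splice_Site", "Missense_Mutation",
            "Silent", "Silent", "Silent", "Silent"],
    })
    scores = pd.DataFrame({
        "immune_score": [0.5, np.nan, 0.3, np.nan, 0.7, np.nan, 0.2, np.nan],
        "tumor_purity": [0.6, np.nan, 0.8, np.nan, 0.5, np.nan, 0.9, np.nan],
    }, index=pd.Index(samples, name="sample"))
    return SyntheticCohort(
        expression=expression, clinical=clinical, mutations=mutations,
        scores=scores, panel_expression=expression.copy(),
        panel_drugs=pd.DataFrame(
            [[3.0, 2.5, 3.5, 2.0, 3.2, 2.8, 3.1, 2.6]],
            index=pd.Index(["drugA"], name="drug"), columns=samples),
        catalog=catalog,
        true_activation=pd.Series([1, 0, 1, 0, 1, 0, 1, 0],
                                  index=pd.Index(samples, name="sample"),
                                  dtype=float, name="activation"),
        config=None,
    )
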