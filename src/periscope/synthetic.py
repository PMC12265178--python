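"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure that the analysis of a
longitudinal buffy-coat RNA-seq cohort assumes:

* negative-binomial gene counts driven by latent immune-cell fractions
  with disjoint cell-type marker blocks,
* power-law (symmetric-Dirichlet) clonotype abundances with a
  controllable concentration (hence Shannon diversity),
* subtype-linked baseline composition differences (more B cells in HR+
  patients, more monocytes in TNBC),
* response-linked longitudinal effects (TNBC responders: effector
  T-cell fraction increase plus TCR clonal expansion at EarlyTreatment;
  HR+ responders: monocyte/chemotaxis decrease),
* exponential distant-recurrence-free survival with the hazard tied to
  the latent baseline immune score.

The gene sets handed downstream are exactly the marker blocks, so
enrichment, deconvolution, clustering and the response model are all
verifiable by parameter recovery against :class:`SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ClonotypeTable,
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    SampleTable,
)

__all__ = [
    "CELL_TYPES",
    "EFFECTOR_CELL_TYPE",
    "SUPERTYPE_MAP",
    "CHEMOTAXIS_SET",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_clonotype_table",
]

#: The 11 reference immune cell subtypes: four CD8 T-cell states, CD4 T,
#: B cells, two monocyte compartments, NK cells and two DC compartments.
CELL_TYPES = (
    "CD8_naive_cm",
    "CD8_early_activation",
    "CD8_GZMB_cytotoxic",
    "CD8_GZMK_cytotoxic",
    "CD4_T",
    "B_cell",
    "Monocyte_nonclassical",
    "Monocyte_classical",
    "NK",
    "cDC",
    "pDC",
)

#: The cytotoxic-effector block whose 19 markers play the role of the
#: 19-gene T-cell composite panel.
EFFECTOR_CELL_TYPE = "CD8_GZMB_cytotoxic"

#: Immune-cell supertypes used for cluster annotation.
SUPERTYPE_MAP: dict[str, tuple[str, ...]] = {
    "T cell": (
        "CD8_naive_cm",
        "CD8_early_activation",
        "CD8_GZMB_cytotoxic",
        "CD8_GZMK_cytotoxic",
        "CD4_T",
    ),
    "B cell": ("B_cell",),
    "Myeloid": ("Monocyte_nonclassical", "Monocyte_classical", "cDC", "pDC"),
    "NK": ("NK",),
}

#: Name of the emitted leukocyte-chemotaxis program gene set (the union
#: of the two monocyte marker blocks, so its score tracks monocyte
#: abundance by construction).
CHEMOTAXIS_SET = "LEUKOCYTE_CHEMOTAXIS"

_MONOCYTE_TYPES = ("Monocyte_nonclassical", "Monocyte_classical")

#: Arms that include an anti-PD-1 agent; response-linked effects are
#: ICI-specific, so simulated Chemo-only patients carry no predictive signal.
ICI_ARMS = ("ChemoPembro", "Dostar")


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Effect sizes operate on the latent Dirichlet cell fractions (additive
    shifts on the fraction scale) or on the log concentration of the
    clonotype distribution; the seed fully determines the output.
    """

    n_patients_per_cell: int = 8  # per (subtype x arm x response) cell
    n_genes: int = 400
    markers_per_celltype: int = 20
    effector_block_size: int = 19
    marker_fold: float = 12.0
    nb_dispersion: float = 0.1
    library_size_mean: float = 1e5
    timepoints: tuple[str, ...] = ("Baseline", "EarlyTreatment")
    arms: tuple[str, ...] = ("Chemo", "ChemoPembro")
    # effect sizes
    delta_tcell_tnbc_pcr: float = 0.10
    delta_chemotaxis_hr_pcr: float = -0.08
    delta_baseline_tcell_hr_pcr: float = 0.06
    subtype_baseline_shift: float = 0.6
    baseline_diversity_shift_pcr: float = 1.0
    clonal_expansion_tnbc_pcr: float = 1.5
    # clonotypes
    clones_per_sample: int = 150
    clone_power_alpha: float = 0.5
    clone_total_reads: int = 3000
    # survival
    survival_base_hazard: float = 5e-4
    survival_loghr_per_score_unit: float = -0.8
    censor_horizon: float = 1825.0
    batch_label: str = "batch1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_patients_per_cell",
            "n_genes",
            "markers_per_celltype",
            "effector_block_size",
            "clones_per_sample",
            "clone_total_reads",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.clone_power_alpha <= 0:
            raise ValueError("clone_power_alpha must be > 0")
        n_marker = self.markers_per_celltype * (len(CELL_TYPES) - 1) + self.effector_block_size
        if self.n_genes < n_marker:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than total marker genes {n_marker}"
            )
        for name in (
            "delta_tcell_tnbc_pcr",
            "delta_chemotaxis_hr_pcr",
            "delta_baseline_tcell_hr_pcr",
        ):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(
                    f"{name}={getattr(self, name)} is outside (-1, 1); fraction "
                    "shifts must keep the composition on the simplex"
                )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    fractions: pd.DataFrame  # sample x cell type, rows sum to 1
    gene_celltype: pd.Series  # gene -> cell type or "background"
    marker_blocks: dict[str, list[str]]
    profiles: pd.DataFrame  # cell type x gene expression profiles (rows sum to 1)
    patient_effects: pd.DataFrame  # per patient: immune score, true effects
    hazards: pd.Series  # per patient true hazard
    effector_panel: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("latent fractions must sum to 1 per sample")


def simulate_clonotype_table(
    n_clones: int, alpha: float, total_reads: int, seed: int | np.random.Generator
) -> ClonotypeTable:
    """Draw a clonotype table with symmetric-Dirichlet clone proportions.

    Expected Shannon diversity increases monotonically with ``alpha`` at
    fixed ``n_clones``; ``alpha -> inf`` approaches the uniform limit
    ``ln(n_clones)``.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if total_reads < n_clones:
        raise ValueError("total_reads must be >= n_clones (every clone observed)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_clones == 1:
        counts = np.array([total_reads])
    else:
        props = rng.dirichlet(np.full(n_clones, alpha))
        # guarantee each clone at least one read, distribute the rest
        extra = rng.multinomial(total_reads - n_clones, props)
        counts = extra + 1
    cdr3 = [f"CASS{_encode(i)}F" for i in range(n_clones)]
    return ClonotypeTable("synthetic", pd.DataFrame({"cdr3": cdr3, "count": counts}))


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _encode(i: int) -> str:
    out = []
    i += 1
    while i:
        i, r = divmod(i, len(_AA))
        out.append(_AA[r])
    return "".join(out)


def _marker_blocks(cfg: SimulationConfig) -> tuple[dict[str, list[str]], pd.Series]:
    """Assign disjoint marker blocks; remaining genes are background."""
    blocks: dict[str, list[str]] = {}
    assignment = {}
    g = 0
    for ct in CELL_TYPES:
        size = cfg.effector_block_size if ct == EFFECTOR_CELL_TYPE else cfg.markers_per_celltype
        genes = [f"G{g + j:04d}_{ct}" for j in range(size)]
        blocks[ct] = genes
        for gene in genes:
            assignment[gene] = ct
        g += size
    for j in range(g, cfg.n_genes):
        gene = f"G{j:04d}_bg"
        assignment[gene] = "background"
    return blocks, pd.Series(assignment, name="cell_type")


def _profiles(cfg: SimulationConfig, genes: list[str], blocks: Mapping[str, list[str]], rng) -> np.ndarray:
    """Per-cell-type expression profiles (cell type x gene), each row sums to 1.

    Every gene has a lognormal baseline expression shared across cell
    types; marker genes are elevated ``marker_fold``-fold in their own
    cell type only.
    """
    base = rng.lognormal(mean=0.0, sigma=0.6, size=len(genes))
    gene_idx = {g: i for i, g in enumerate(genes)}
    prof = np.tile(base, (len(CELL_TYPES), 1))
    for c, ct in enumerate(CELL_TYPES):
        for gene in blocks[ct]:
            prof[c, gene_idx[gene]] *= cfg.marker_fold
    prof /= prof.sum(axis=1, keepdims=True)
    return prof


def _base_alpha(cfg: SimulationConfig, subtype: str) -> np.ndarray:
    """Dirichlet concentration for the latent composition of one subtype."""
    alpha = np.full(len(CELL_TYPES), 6.0)
    shift = np.exp(cfg.subtype_baseline_shift)
    for c, ct in enumerate(CELL_TYPES):
        if subtype == "TNBC" and ct in _MONOCYTE_TYPES:
            alpha[c] *= shift
        if subtype == "HRpos" and ct == "B_cell":
            alpha[c] *= shift
    if (alpha <= 0).any():
        raise ValueError("effect sizes drove a Dirichlet parameter <= 0")
    return alpha


def _shift_fraction(frac: np.ndarray, idx: Sequence[int], delta: float) -> np.ndarray:
    """Additively shift the summed fraction of ``idx`` by ``delta``,
    rescaling the remaining components to keep the simplex constraint.

    Draws for which the full shift would leave (0, 1) are clamped to
    retain/move at most 90% of the available room, so extreme Dirichlet
    draws stay valid; with realistic effect sizes the clamp is a rare
    tail event and the mean shift stays at the configured delta.
    """
    frac = frac.copy()
    cur = frac[list(idx)].sum()
    new = float(np.clip(cur + delta, 0.1 * cur, cur + 0.9 * (1.0 - cur)))
    if cur <= 0 or cur >= 1:
        return frac
    frac[list(idx)] *= new / cur if cur > 0 else 0.0
    rest = [i for i in range(len(frac)) if i not in set(idx)]
    frac[rest] *= (1.0 - new) / (1.0 - cur)
    return frac


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleTable, dict[str, ClonotypeTable], GeneSetCollection, SyntheticTruth]:
    """Simulate a full longitudinal cohort.

    Returns the count matrix, sample metadata, per-sample clonotype
    tables, the marker-block gene sets (plus the chemotaxis program) and
    the :class:`SyntheticTruth` record.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    blocks, gene_celltype = _marker_blocks(cfg)
    genes = list(gene_celltype.index)
    profiles = _profiles(cfg, genes, blocks, rng)
    eff_idx = CELL_TYPES.index(EFFECTOR_CELL_TYPE)
    tcell_idx = [CELL_TYPES.index(ct) for ct in SUPERTYPE_MAP["T cell"]]
    mono_idx = [CELL_TYPES.index(ct) for ct in _MONOCYTE_TYPES]

    meta_rows = []
    frac_rows = {}
    clonotypes: dict[str, ClonotypeTable] = {}
    counts_cols = {}
    patient_rows = []
    hazards = {}

    p = 0
    for subtype in ("HRpos", "TNBC"):
        for arm in cfg.arms:
            for response in ("pCR", "RD"):
                for _ in range(cfg.n_patients_per_cell):
                    p += 1
                    pid = f"P{p:04d}"
                    base_frac = rng.dirichlet(_base_alpha(cfg, subtype))
                    is_ici = arm in ICI_ARMS
                    # HR+ ICI responders start with an elevated effector fraction
                    if (
                        subtype == "HRpos"
                        and response == "pCR"
                        and is_ici
                        and cfg.delta_baseline_tcell_hr_pcr
                    ):
                        base_frac = _shift_fraction(
                            base_frac, [eff_idx], cfg.delta_baseline_tcell_hr_pcr
                        )
                    # baseline clonotype concentration: ICI responders more diverse
                    log_alpha = np.log(cfg.clone_power_alpha)
                    if response == "pCR" and is_ici:
                        log_alpha += cfg.baseline_diversity_shift_pcr
                    drew_score = None
                    for tp in cfg.timepoints:
                        sid = f"{pid}_{tp}"
                        frac = base_frac
                        tp_log_alpha = log_alpha
                        if tp != "Baseline" and response == "pCR" and is_ici:
                            if subtype == "TNBC":
                                if cfg.delta_tcell_tnbc_pcr:
                                    frac = _shift_fraction(
                                        frac, [eff_idx], cfg.delta_tcell_tnbc_pcr
                                    )
                                tp_log_alpha -= cfg.clonal_expansion_tnbc_pcr
                            else:  # HRpos responders: monocyte/chemotaxis decrease
                                if cfg.delta_chemotaxis_hr_pcr:
                                    frac = _shift_fraction(
                                        frac, mono_idx, cfg.delta_chemotaxis_hr_pcr
                                    )
                        frac_rows[sid] = frac
                        lib = rng.poisson(cfg.library_size_mean)
                        mu = lib * frac @ profiles
                        r = 1.0 / cfg.nb_dispersion
                        counts_cols[sid] = rng.negative_binomial(r, r / (r + mu))
                        clon = simulate_clonotype_table(
                            cfg.clones_per_sample,
                            float(np.exp(tp_log_alpha)),
                            cfg.clone_total_reads,
                            rng,
                        )
                        clonotypes[sid] = ClonotypeTable(sid, clon.clones)
                        if tp == "Baseline":
                            drew_score = float(frac[list(tcell_idx)].sum())
                        meta_rows.append(
                            {
                                "sample_id": sid,
                                "patient_id": pid,
                                "timepoint": tp,
                                "arm": arm,
                                "clinical_subtype": subtype,
                                "response": response,
                                "batch": cfg.batch_label,
                            }
                        )
                    patient_rows.append(
                        {
                            "patient_id": pid,
                            "clinical_subtype": subtype,
                            "arm": arm,
                            "response": response,
                            "true_immune_score": drew_score,
                            "baseline_log_clone_alpha": log_alpha,
                        }
                    )

    pat = pd.DataFrame(patient_rows).set_index("patient_id")
    score_z = (pat["true_immune_score"] - pat["true_immune_score"].mean()) / pat[
        "true_immune_score"
    ].std(ddof=1)
    haz = cfg.survival_base_hazard * np.exp(cfg.survival_loghr_per_score_unit * score_z)
    times = rng.exponential(1.0 / haz.to_numpy())
    events = (times <= cfg.censor_horizon).astype(int)
    drfs_time = np.minimum(times, cfg.censor_horizon)
    drfs = pd.DataFrame(
        {"drfs_time": np.round(drfs_time, 1), "drfs_event": events}, index=pat.index
    )

    meta = pd.DataFrame(meta_rows)
    meta = meta.merge(drfs, left_on="patient_id", right_index=True, how="left")
    sample_table = SampleTable(meta)

    count_matrix = CountMatrix(
        genes, list(meta["sample_id"]), np.column_stack([counts_cols[s] for s in meta["sample_id"]])
    )

    sets = [GeneSet(ct, f"marker block for {ct}", blocks[ct]) for ct in CELL_TYPES]
    chemo_genes = [g for ct in _MONOCYTE_TYPES for g in blocks[ct]]
    sets.append(GeneSet(CHEMOTAXIS_SET, "monocyte-recruitment program", chemo_genes))
    collection = GeneSetCollection(sets)

    truth = SyntheticTruth(
        fractions=pd.DataFrame(frac_rows, index=list(CELL_TYPES)).T,
        gene_celltype=gene_celltype,
        marker_blocks={ct: list(blocks[ct]) for ct in CELL_TYPES},
        profiles=pd.DataFrame(profiles, index=list(CELL_TYPES), columns=genes),
        patient_effects=pat.reset_index(),
        hazards=pd.Series(haz, index=pat.index, name="hazard"),
        effector_panel=list(blocks[EFFECTOR_CELL_TYPE]),
        config=asdict(cfg),
    )
    return count_matrix, sample_table, clonotypes, collection, truth
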