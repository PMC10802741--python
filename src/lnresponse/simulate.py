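"""Synthetic data generators with known ground truth.

Every input the analysis consumes can be generated here: a longitudinal
bulk-expression cohort with patient random intercepts and planted per-drug
non-response signatures, a single-cell count matrix with planted gene
programs and low-quality cells, a cell-type signature basis with known
mixing fractions, and small signed receptor->effector signaling circuits.

All generators are pure functions of their configuration and seed: the same
seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "BulkSimConfig", "ScSimConfig", "GroundTruth",
    "generate_bulk_cohort", "generate_single_cell",
    "generate_signature_basis", "generate_circuits",
]


@dataclass
class BulkSimConfig:
    """Configuration for the longitudinal bulk-expression cohort.

    Expression is simulated on the log2 scale as
    ``baseline_g + u_p + covariate terms + planted shift + e``, with patient
    intercept ``u_p ~ N(0, patient_sd^2)`` and residual
    ``e ~ N(0, noise_sd^2)``. Planted up/down genes are shifted by
    ``+/- effect_size`` only in non-responder samples of the matching drug.
    """

    n_patients_per_arm: int = 15
    visits_per_patient: int = 3
    n_genes: int = 500
    n_up: int = 20
    n_down: int = 20
    effect_size: float = 1.0
    patient_sd: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    drugs: Tuple[str, ...] = ("MMF", "AZA")
    covariate_effects: Dict[str, float] = field(default_factory=lambda: {
        "sex": 0.2, "sledai": 0.03, "prednisone": 0.01, "dose": 0.0})
    # dose distributions (mean, SD) per response group; non-responders are
    # dosed higher, as physicians escalate in the face of poor response
    dose_responder: Tuple[float, float] = (1550.0, 900.0)
    dose_nonresponder: Tuple[float, float] = (2440.0, 975.0)
    prednisone_responder: Tuple[float, float] = (5.0, 7.2)
    prednisone_nonresponder: Tuple[float, float] = (10.4, 13.5)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients_per_arm", "visits_per_patient", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("planted gene counts must be >= 0")
        if self.patient_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        n_planted = (self.n_up + self.n_down) * len(self.drugs)
        if n_planted > self.n_genes:
            raise ValueError("planted gene sets do not fit into n_genes")


@dataclass
class ScSimConfig:
    """Configuration for the synthetic single-cell count matrix."""

    n_cells: int = 1000
    n_genes: int = 500
    n_clusters: int = 4
    program_gene_count: int = 30
    mito_gene_count: int = 10
    ribo_gene_count: int = 20
    fraction_low_quality: float = 0.05
    mean_counts: float = 20000.0
    program_fold: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.fraction_low_quality <= 1.0:
            raise ValueError("fraction_low_quality must lie in [0, 1]")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("dimensions must be >= 1")
        special = self.mito_gene_count + self.ribo_gene_count
        if self.program_gene_count > self.n_genes - special:
            raise ValueError("program_gene_count exceeds available genes")


@dataclass
class GroundTruth:
    """Planted truth accompanying each generated dataset."""

    planted_up: Dict[str, List[str]] = field(default_factory=dict)
    planted_down: Dict[str, List[str]] = field(default_factory=dict)
    response: Dict[str, str] = field(default_factory=dict)
    program_genes: List[str] = field(default_factory=list)
    program_cluster: Optional[str] = None
    cluster_labels: Optional[pd.Series] = None
    low_quality_cells: List[str] = field(default_factory=list)
    mixing_fractions: Optional[pd.DataFrame] = None
    circuits: list = field(default_factory=list)
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# bulk cohort

def _clinical_series(rng: np.random.Generator, responder: bool,
                     months: np.ndarray) -> Dict[str, np.ndarray]:
    """SLEDAI / PGA / UPCR trajectories consistent with the response label.

    Responders reach a sustained >=4-point SLEDAI drop (with stable PGA) and
    a sustained sub-500 mg/g UPCR from month 3 on; non-responders never do.
    """
    n = len(months)
    sledai0 = int(rng.integers(6, 13))
    pga0 = float(rng.uniform(1.0, 2.5))
    upcr0 = float(rng.uniform(600.0, 2500.0))
    sledai = np.empty(n)
    pga = np.empty(n)
    upcr = np.empty(n)
    sledai[0], pga[0], upcr[0] = sledai0, pga0, upcr0
    for i in range(1, n):
        if responder:
            drop = int(rng.integers(4, sledai0 + 1))
            sledai[i] = sledai0 - drop
            pga[i] = max(0.0, pga0 + rng.uniform(-0.5, 0.25))
            upcr[i] = rng.uniform(50.0, 450.0)
        else:
            sledai[i] = max(0, sledai0 - int(rng.integers(0, 4)))
            pga[i] = min(3.0, pga0 + rng.uniform(-0.1, 0.4))
            upcr[i] = rng.uniform(520.0, 3000.0)
    return {"sledai": sledai, "pga": pga, "upcr": upcr}


def generate_bulk_cohort(
    config: BulkSimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a longitudinal cohort of log2 expression plus clinical table.

    Returns ``(expr, cohort, truth)`` where ``expr`` is genes x samples and
    ``cohort`` has one row per sample (patient, visit, drug, response label,
    demographics, visit-level SLEDAI/PGA/UPCR and doses).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    truth = GroundTruth(seed=config.seed)
    cursor = 0
    for drug in config.drugs:
        truth.planted_up[drug] = genes[cursor:cursor + config.n_up]
        cursor += config.n_up
        truth.planted_down[drug] = genes[cursor:cursor + config.n_down]
        cursor += config.n_down

    months = 3.0 * np.arange(config.visits_per_patient)
    rows = []
    pid = 0
    for drug in config.drugs:
        for responder in (True, False):
            for _ in range(config.n_patients_per_arm):
                patient = f"P{pid:04d}"
                pid += 1
                label = "responder" if responder else "non-responder"
                truth.response[patient] = label
                sex = "F" if rng.random() < 0.9 else "M"
                race = rng.choice(["C", "AA", "O"], p=[0.45, 0.45, 0.10])
                age = float(rng.uniform(18, 60))
                clin = _clinical_series(rng, responder, months)
                dose_mu, dose_sd = (config.dose_responder if responder
                                    else config.dose_nonresponder)
                pred_mu, pred_sd = (config.prednisone_responder if responder
                                    else config.prednisone_nonresponder)
                for j, month in enumerate(months):
                    rows.append({
                        "sample_id": f"{patient}_V{j}",
                        "patient_id": patient,
                        "drug": drug,
                        "visit_month": month,
                        "response": label,
                        "sex": sex,
                        "race": race,
                        "age": age,
                        "sledai": clin["sledai"][j],
                        "pga": clin["pga"][j],
                        "upcr": clin["upcr"][j],
                        "prednisone_dose": max(0.0, rng.normal(pred_mu,
                                                               pred_sd)),
                        "drug_dose": max(0.0, rng.normal(dose_mu, dose_sd)),
                    })
    cohort = pd.DataFrame(rows).set_index("sample_id", drop=False)
    n_samples = len(cohort)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          config.n_genes)
    expr = np.tile(baseline[:, None], (1, n_samples))
    # per-gene patient intercepts: each gene's repeated measures share a
    # patient-specific level, independent across genes
    uniq_pat, pat_idx = np.unique(cohort["patient_id"], return_inverse=True)
    U = rng.normal(0.0, config.patient_sd,
                   (config.n_genes, uniq_pat.size))
    expr += U[:, pat_idx]

    ce = config.covariate_effects
    expr += ce.get("sex", 0.0) * (cohort["sex"] == "F").to_numpy(float)
    expr += ce.get("sledai", 0.0) * cohort["sledai"].to_numpy(float)
    expr += ce.get("prednisone", 0.0) * cohort["prednisone_dose"].to_numpy(float)
    expr += ce.get("dose", 0.0) * cohort["drug_dose"].to_numpy(float) / 1000.0

    gene_pos = {g: i for i, g in enumerate(genes)}
    for drug in config.drugs:
        target = ((cohort["drug"] == drug)
                  & (cohort["response"] == "non-responder")).to_numpy()
        for g in truth.planted_up[drug]:
            expr[gene_pos[g], target] += config.effect_size
        for g in truth.planted_down[drug]:
            expr[gene_pos[g], target] -= config.effect_size

    expr += rng.normal(0.0, config.noise_sd, expr.shape)
    expr_df = pd.DataFrame(expr, index=genes, columns=cohort.index.tolist())
    expr_df.index.name = "gene"
    return expr_df, cohort, truth


# ---------------------------------------------------------------------------
# single cell

def generate_single_cell(config: ScSimConfig) -> Tuple[ad.AnnData, GroundTruth]:
    """Simulate a cells x genes count matrix with planted structure.

    Mitochondrial ("MT-") and ribosomal ("RPS"/"RPL") genes are
    prefix-identifiable. A planted gene program is over-expressed in cluster
    ``cl0`` and planted low-quality cells carry a mitochondrial count share
    far above the 25% QC threshold, with tiny libraries.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    mito = [f"MT-{i}" for i in range(config.mito_gene_count)]
    ribo = [f"RPS{i}" if i % 2 == 0 else f"RPL{i}"
            for i in range(config.ribo_gene_count)]
    n_plain = config.n_genes - len(mito) - len(ribo)
    plain = [f"GENE{i:05d}" for i in range(n_plain)]
    genes = plain + mito + ribo
    program = plain[:config.program_gene_count]

    n_low = int(round(config.fraction_low_quality * config.n_cells))
    barcodes = [f"CELL{i:05d}" for i in range(config.n_cells)]
    low_quality = np.zeros(config.n_cells, bool)
    low_quality[rng.choice(config.n_cells, n_low, replace=False)] = True
    clusters = rng.integers(0, config.n_clusters, config.n_cells)

    # per-cluster expected expression: shared lognormal means, program genes
    # boosted in cluster 0, mild cluster-specific wobble elsewhere
    base = rng.lognormal(0.0, 0.15, len(plain))
    cluster_means = np.empty((config.n_clusters, len(genes)))
    for c in range(config.n_clusters):
        mean_plain = base * rng.lognormal(0.0, 0.08, len(plain))
        if c == 0:
            mean_plain[:config.program_gene_count] *= config.program_fold
        mean_plain /= mean_plain.sum()
        cluster_means[c, :len(plain)] = mean_plain

    counts = np.zeros((config.n_cells, len(genes)), dtype=np.int64)
    mito_share = np.where(low_quality, 0.45, 0.02)
    ribo_share = 0.04
    lib = rng.lognormal(np.log(config.mean_counts), 0.25, config.n_cells)
    lib[low_quality] = rng.uniform(120, 180, low_quality.sum())
    mito_w = rng.dirichlet(np.full(len(mito), 5.0))
    ribo_w = rng.dirichlet(np.full(len(ribo), 5.0))
    for i in range(config.n_cells):
        p = np.empty(len(genes))
        plain_share = 1.0 - mito_share[i] - ribo_share
        p[:len(plain)] = cluster_means[clusters[i], :len(plain)] * plain_share
        p[len(plain):len(plain) + len(mito)] = mito_w * mito_share[i]
        p[len(plain) + len(mito):] = ribo_w * ribo_share
        counts[i] = rng.poisson(lib[i] * p)

    adata = ad.AnnData(X=counts)
    adata.obs_names = barcodes
    adata.var_names = genes
    adata.obs["cluster"] = pd.Categorical([f"cl{c}" for c in clusters])
    adata.obs["major_type"] = pd.Categorical(
        [f"major{c // 2}" for c in clusters])
    adata.obs["is_low_quality"] = low_quality

    truth = GroundTruth(
        program_genes=list(program),
        program_cluster="cl0",
        cluster_labels=adata.obs["cluster"].astype(str).copy(),
        low_quality_cells=[b for b, lq in zip(barcodes, low_quality) if lq],
        seed=config.seed,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# signature basis and mixtures

def generate_signature_basis(
    n_cell_types: int,
    n_marker_genes: int,
    n_mixtures: int,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Build a non-negative marker basis plus mixtures with known fractions.

    Each cell type owns a block of high-expression marker genes; mixture
    sample ``j`` equals ``basis @ fractions_j`` plus optional Gaussian noise
    (``noise_sd`` is a fraction of the mean signal). Fractions sum to 1.
    """
    if n_cell_types < 2:
        raise ValueError("n_cell_types must be >= 2")
    if n_marker_genes < n_cell_types:
        raise ValueError("n_marker_genes must be >= n_cell_types")
    rng = np.random.default_rng(seed)

    genes = [f"M{i:04d}" for i in range(n_marker_genes)]
    types = [f"type{t}" for t in range(n_cell_types)]
    basis = rng.uniform(0.0, 1.0, (n_marker_genes, n_cell_types))
    block = n_marker_genes // n_cell_types
    for t in range(n_cell_types):
        lo = t * block
        hi = n_marker_genes if t == n_cell_types - 1 else lo + block
        basis[lo:hi, t] += rng.uniform(8.0, 12.0, hi - lo)
    basis_df = pd.DataFrame(basis, index=genes, columns=types)

    fractions = rng.dirichlet(np.ones(n_cell_types), n_mixtures)
    mixtures = basis @ fractions.T
    if noise_sd > 0:
        mixtures = mixtures + rng.normal(
            0.0, noise_sd * mixtures.mean(), mixtures.shape)
        mixtures = np.clip(mixtures, 0.0, None)
    sample_ids = [f"MIX{j:04d}" for j in range(n_mixtures)]
    mixtures_df = pd.DataFrame(mixtures, index=genes, columns=sample_ids)
    frac_df = pd.DataFrame(fractions, index=sample_ids, columns=types)
    truth = GroundTruth(mixing_fractions=frac_df, seed=seed)
    return basis_df, mixtures_df, truth


# ---------------------------------------------------------------------------
# circuits

def generate_circuits(
    n_circuits: int,
    nodes_per_circuit: int,
    inhibitor_fraction: float = 0.25,
    seed: int = 0,
    genes_per_node: int = 1,
    gene_pool: Optional[Sequence[str]] = None,
) -> list:
    """Generate acyclic signed receptor->effector circuits.

    Each circuit carries a chain backbone of activations (node 0 the
    receptor, the last node the effector), so every node lies on a
    receptor->effector path and every non-receptor node has at least one
    activating parent; extra shortcut edges are inhibitions with probability
    ``inhibitor_fraction``.
    """
    from .druggability import CircuitGraph

    if nodes_per_circuit < 2:
        raise ValueError("nodes_per_circuit must be >= 2")
    rng = np.random.default_rng(seed)
    pool = list(gene_pool) if gene_pool is not None else None
    circuits = []
    for c in range(n_circuits):
        nodes = []
        for i in range(nodes_per_circuit):
            if pool is not None:
                genes = tuple(rng.choice(pool, genes_per_node, replace=False))
            else:
                genes = tuple(f"C{c}N{i}g{k}" for k in range(genes_per_node))
            nodes.append((f"n{i}", genes))
        edges = [(f"n{i}", f"n{i+1}", 1) for i in range(nodes_per_circuit - 1)]
        # shortcut edges skipping at least one node, never into the receptor
        candidates = [(i, j) for i in range(nodes_per_circuit - 2)
                      for j in range(i + 2, nodes_per_circuit)]
        if candidates:
            n_extra = int(rng.integers(0, len(candidates) + 1))
            picked = rng.choice(len(candidates), n_extra, replace=False)
            for idx in sorted(picked):
                i, j = candidates[idx]
                sign = -1 if rng.random() < inhibitor_fraction else 1
                edges.append((f"n{i}", f"n{j}", sign))
        circuits.append(CircuitGraph.from_tables(f"circuit{c}", nodes, edges))
    return circuits
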