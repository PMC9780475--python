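"""Synthetic cohort generator with the structure the analysis assumes.

A latent two-state model stands in for TP53 functional status: each sample
is either TP53-active or TP53-inactive.  Active samples express the induced
signature genes higher; inactive samples express the repressed genes higher
(both by ``effect_delta`` within-gene standard deviations on the log scale).
Survival follows an exponential hazard that is ``hazard_ratio`` times larger
for inactive samples; inactive samples also carry passing TP53 variant
records more often.  Spatial maps emulate 1 mm^2 imaging ROIs with a tumor
core, a one-block boundary ring and stroma, with regulatory T cells (Tregs)
planted at higher density in the boundary ring of the low-score (inactive-
enriched) patient group, and CD47+PD1+ cells placed preferentially within
the neighbor margin of Tregs in that group.

This is a stand-in for the statistical shape of the real data, not a
biological model; defaults are the study conditions the property suites
assume (effect_delta = 2, hazard_ratio = 3, boundary_enrichment = 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signature import GeneSignature, load_signature

PHENOTYPES = (
    "cancer_1",
    "cancer_3",
    "fibroblast",
    "endothelial",
    "granulocyte",
    "Treg",
    "CD47_PD1",
    "other_immune",
)

# baseline phenotype mixing per region (tumor core, boundary ring, stroma)
_REGION_FREQS = {
    "tumor": {"cancer_1": 0.45, "cancer_3": 0.25, "fibroblast": 0.05, "endothelial": 0.05,
              "granulocyte": 0.05, "Treg": 0.03, "CD47_PD1": 0.02, "other_immune": 0.10},
    "boundary": {"cancer_1": 0.20, "cancer_3": 0.15, "fibroblast": 0.20, "endothelial": 0.05,
                 "granulocyte": 0.10, "Treg": 0.05, "CD47_PD1": 0.05, "other_immune": 0.20},
    "stroma": {"cancer_1": 0.02, "cancer_3": 0.02, "fibroblast": 0.50, "endothelial": 0.10,
               "granulocyte": 0.08, "Treg": 0.03, "CD47_PD1": 0.03, "other_immune": 0.22},
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    effect_delta is the shift (in within-gene SD units, log scale) applied
    to induced genes in active samples and repressed genes in inactive
    samples; hazard_ratio is the relative death hazard of inactive vs
    active samples.
    """

    n_samples: int = 200
    fraction_inactive: float = 0.5
    effect_delta: float = 2.0
    noise_sd: float = 1.0
    n_background_genes: int = 300
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.2
    seed: int = 0
    # variant stage
    p_mut_inactive: float = 0.7
    p_mut_active: float = 0.1
    # spatial stage
    n_rois_per_group: int = 50
    cells_per_roi: int = 600
    boundary_enrichment: float = 3.0
    roi_side: float = 1000.0
    cell_radius: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.fraction_inactive < 1:
            raise SimulationError("fraction_inactive must lie in (0, 1)")
        if self.effect_delta < 0:
            raise SimulationError("effect_delta must be >= 0")
        if self.hazard_ratio <= 0:
            raise SimulationError("hazard_ratio must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise SimulationError("censoring_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")


def _rng(cfg: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def simulate_expression(
    cfg: SimulationConfig, sig: GeneSignature | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a genes x samples expression matrix plus latent truth labels.

    Returns ``(expr, states)`` where ``states[j] = 1`` marks a TP53-active
    sample and 0 an inactive one.  Background genes are log-normal;
    signature genes receive the state-dependent shift.
    """
    if cfg.n_samples < 4:
        raise SimulationError("need at least 4 samples")
    sig = sig or load_signature()
    rng = _rng(cfg, 1)
    n_inactive = int(round(cfg.n_samples * cfg.fraction_inactive))
    states = np.ones(cfg.n_samples, dtype=int)
    states[:n_inactive] = 0
    rng.shuffle(states)

    genes = list(sig.genes) + [f"BG{i:04d}" for i in range(cfg.n_background_genes)]
    n_genes = len(genes)
    base = rng.normal(loc=5.0, scale=1.5, size=n_genes)  # per-gene log2 mean
    log_expr = base[:, None] + rng.normal(scale=cfg.noise_sd, size=(n_genes, cfg.n_samples))

    shift = cfg.effect_delta * cfg.noise_sd
    induced_idx = np.arange(len(sig.induced))
    repressed_idx = np.arange(len(sig.induced), len(sig.genes))
    active = states == 1
    log_expr[np.ix_(induced_idx, active)] += shift
    log_expr[np.ix_(repressed_idx, ~active)] += shift

    expr = pd.DataFrame(
        2.0 ** log_expr,
        index=pd.Index(genes, name="gene_id"),
        columns=[f"S{j:04d}" for j in range(cfg.n_samples)],
    )
    return expr, states


def simulate_survival(states: np.ndarray, cfg: SimulationConfig) -> pd.DataFrame:
    """Exponential survival with state-dependent hazard and random censoring.

    Hazard is ``baseline_hazard`` for active samples and
    ``baseline_hazard * hazard_ratio`` for inactive ones.  Censoring times
    are exponential with the rate solved per state so the marginal censoring
    probability is ``censoring_rate``.
    """
    if cfg.hazard_ratio <= 0:
        raise SimulationError("hazard_ratio must be positive")
    rng = _rng(cfg, 2)
    states = np.asarray(states)
    hazards = np.where(states == 1, cfg.baseline_hazard, cfg.baseline_hazard * cfg.hazard_ratio)
    death = rng.exponential(1.0 / hazards)
    if cfg.censoring_rate == 0:
        time, event = death, np.ones_like(states)
    else:
        # with C ~ Exp(c) independent of T ~ Exp(h): P(C < T) = c / (c + h)
        c_rate = hazards * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        censor = rng.exponential(1.0 / c_rate)
        time = np.minimum(death, censor)
        event = (death <= censor).astype(int)
    return pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index([f"S{j:04d}" for j in range(len(states))], name="sample_id"),
    )


def simulate_variants(states: np.ndarray, cfg: SimulationConfig) -> pd.DataFrame:
    """Variant records correlated with the latent state, straddling thresholds.

    Inactive samples carry a passing TP53 record with probability
    ``p_mut_inactive``; active samples with ``p_mut_active``.  Extra records
    are planted that fail exactly one screening criterion each (depth-only,
    VAF-only, quality-only), so filter behavior is exercised.
    """
    rng = _rng(cfg, 3)
    states = np.asarray(states)
    sample_ids = [f"S{j:04d}" for j in range(len(states))]
    rows = []

    def passing_record(sid: str) -> dict:
        depth = int(rng.integers(60, 200))
        return {
            "sample_id": sid, "gene": "TP53",
            "position": int(rng.choice([743, 817, 524, 733, 818])),
            "ref": "C", "alt": "T", "total_depth": depth,
            "variant_depth": int(depth * rng.uniform(0.2, 0.6)),
            "quality_q": float(rng.uniform(25, 60)),
        }

    for sid, state in zip(sample_ids, states):
        p = cfg.p_mut_active if state == 1 else cfg.p_mut_inactive
        if rng.random() < p:
            rows.append(passing_record(sid))
        # occasional passing record in an unrelated gene
        if rng.random() < 0.2:
            rec = passing_record(sid)
            rec["gene"] = "FGFR3"
            rows.append(rec)

    # threshold-straddling TP53 records, each failing a single criterion
    straddlers = rng.choice(sample_ids, size=3, replace=False)
    rows.append({"sample_id": straddlers[0], "gene": "TP53", "position": 743,
                 "ref": "G", "alt": "A", "total_depth": 30, "variant_depth": 15,
                 "quality_q": 40.0})                     # fails depth only (30 not > 30)
    rows.append({"sample_id": straddlers[1], "gene": "TP53", "position": 817,
                 "ref": "C", "alt": "T", "total_depth": 100, "variant_depth": 1,
                 "quality_q": 40.0})                     # fails VAF only (0.01 not > 0.01)
    rows.append({"sample_id": straddlers[2], "gene": "TP53", "position": 524,
                 "ref": "G", "alt": "A", "total_depth": 100, "variant_depth": 40,
                 "quality_q": 10.0})                     # fails quality only (10 not > 10)
    return pd.DataFrame(rows)


def _roi_mask(grid_k: int = 20, core_half: int = 5) -> pd.DataFrame:
    """One ROI mask: central square tumor core, one-block boundary ring, stroma."""
    labels = np.full((grid_k, grid_k), "stroma", dtype=object)
    c0, c1 = grid_k // 2 - core_half, grid_k // 2 + core_half
    labels[c0 - 1:c1 + 1, c0 - 1:c1 + 1] = "boundary"
    labels[c0:c1, c0:c1] = "tumor"
    return pd.DataFrame(
        {"block_index": np.arange(1, grid_k * grid_k + 1), "region": labels.ravel()}
    )


def simulate_spatial(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell spatial tables and region masks for both groups.

    Returns ``(cells, masks)``.  Each ROI uses the same core/ring/stroma
    mask; cells are placed uniformly within their region's blocks with
    region-specific phenotype frequencies.  In the low group, boundary Treg
    frequency is multiplied by ``boundary_enrichment`` and a matching share
    of CD47+PD1+ cells is re-placed within the 4 um neighbor margin of a
    Treg.
    """
    if cfg.cells_per_roi < len(PHENOTYPES):
        raise SimulationError("cells_per_roi smaller than the phenotype palette")
    rng = _rng(cfg, 4)
    grid_k = 20
    block_side = cfg.roi_side / grid_k
    mask_one = _roi_mask(grid_k)
    region_blocks = {
        r: mask_one.loc[mask_one["region"] == r, "block_index"].to_numpy()
        for r in ("tumor", "boundary", "stroma")
    }
    # cells split across regions proportionally to region area
    region_share = {r: len(b) / (grid_k * grid_k) for r, b in region_blocks.items()}

    cell_rows = []
    mask_rows = []
    for group in ("high", "low"):
        for r in range(cfg.n_rois_per_group):
            roi = f"{group}_roi{r:03d}"
            m = mask_one.copy()
            m.insert(0, "roi_id", roi)
            mask_rows.append(m)
            for region, blocks in region_blocks.items():
                n_cells = int(round(cfg.cells_per_roi * region_share[region]))
                freqs = dict(_REGION_FREQS[region])
                if region == "boundary" and group == "low":
                    freqs["Treg"] *= cfg.boundary_enrichment
                phenos = np.array(list(freqs))
                probs = np.array(list(freqs.values()))
                probs = probs / probs.sum()
                chosen = rng.choice(phenos, size=n_cells, p=probs)
                blk = rng.choice(blocks, size=n_cells)
                row, col = np.divmod(blk - 1, grid_k)
                x = (col + rng.random(n_cells)) * block_side
                y = (row + rng.random(n_cells)) * block_side
                df = pd.DataFrame(
                    {"roi_id": roi, "x": x, "y": y, "phenotype": chosen,
                     "radius": cfg.cell_radius, "patient_group": group}
                )
                if group == "low" and region == "boundary":
                    tregs = df.index[df["phenotype"] == "Treg"].to_numpy()
                    targets = df.index[df["phenotype"] == "CD47_PD1"].to_numpy()
                    if len(tregs) and len(targets):
                        # park CD47+PD1+ cells just inside the neighbor margin of a Treg
                        anchors = rng.choice(tregs, size=len(targets))
                        gap = 2 * cfg.cell_radius + 4.0
                        theta = rng.uniform(0, 2 * math.pi, size=len(targets))
                        rad = rng.uniform(0.2, 0.9, size=len(targets)) * gap
                        nx = df.loc[anchors, "x"].to_numpy() + rad * np.cos(theta)
                        ny = df.loc[anchors, "y"].to_numpy() + rad * np.sin(theta)
                        df.loc[targets, "x"] = np.clip(nx, 0, cfg.roi_side)
                        df.loc[targets, "y"] = np.clip(ny, 0, cfg.roi_side)
                cell_rows.append(df)
    cells = pd.concat(cell_rows, ignore_index=True)
    masks = pd.concat(mask_rows, ignore_index=True)
    return cells, masks


def simulate_cohort(cfg: SimulationConfig) -> dict:
    """Run every generator and bundle outputs with the truth labels."""
    expr, states = simulate_expression(cfg)
    return {
        "expression": expr,
        "states": states,
        "clinical": simulate_survival(states, cfg),
        "variants": simulate_variants(states, cfg),
    }
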