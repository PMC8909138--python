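"""Synthetic single-cell, bulk and survival data with known ground truth.

The generator emulates the inputs of the glioblastoma CSC comparison: a
TPM matrix of 1091 malignant cells with planted lipid-program (slow
cycling), cycling (G1S/G2M) and marker-high populations under a
controllable pairwise-overlap structure; bulk mixtures of known SCC/FCC
fractions with multiplicative log-normal noise; and survival times whose
hazard rises with the SCC fraction.  A deterministic fixture reproduces
the published seven-group overlap arithmetic exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, GeneSetCollection, UNIT_TPM, ValidationError
from .groups import CellGroup
from .survival import SurvivalRecord

MARKERS = ("CD133", "SOX2", "PTPRZ1", "ITGB8", "CD44")

#: the published pairwise shared-cell counts among the seven groups
PRINTED_OVERLAP: dict[tuple[str, str], int] = {
    ("CD44", "PTPRZ1"): 3,
    ("CD133", "SOX2"): 2,
    ("CD133", "ITGB8"): 1,
    ("ITGB8", "SOX2"): 1,
    ("ITGB8", "PTPRZ1"): 1,
    ("CD44", "ITGB8"): 1,
    ("CD133", "FCC"): 1,
    ("FCC", "ITGB8"): 1,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the analyzed dataset where it states them (1091 cells,
    populations of 22 = top 2%) and field-typical values elsewhere: Tirosh
    cell-cycle list sizes (43 G1S / 54 G2M genes), a 50-gene lipid
    program, +3 log2 planted program effects, log-normal(0, 1) baseline
    TPM renormalized to 1e6 per cell.  Marker genes use a tighter baseline
    spread (sdlog 0.5) and a +6 log2 boost in their high cells, emulating
    the bimodal on/off expression of canonical surface markers.
    """

    n_cells: int = 1091
    n_genes: int = 2000
    seed: int = 0
    n_scc: int = 22
    n_fcc: int = 22
    n_marker_high: int = 22
    n_lipid_genes: int = 50
    n_g1s_genes: int = 43
    n_g2m_genes: int = 54
    effect_log2: float = 3.0
    marker_effect_log2: float = 6.0
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 1.0
    marker_baseline_sdlog: float = 0.5
    tpm_total: float = 1e6
    overlap: dict[tuple[str, str], int] = field(default_factory=dict)
    # bulk mixtures
    n_bulk_samples: int = 50
    bulk_noise_sd: float = 0.2
    # survival
    baseline_hazard: float = 1.0 / 365.0
    hazard_coef: float = 1.5
    censor_rate: float = 0.2

    def population_sizes(self) -> dict[str, int]:
        sizes = {"SCC": self.n_scc, "FCC": self.n_fcc}
        sizes.update({m: self.n_marker_high for m in MARKERS})
        return sizes

    def validate(self) -> None:
        sizes = self.population_sizes()
        if sum(sizes.values()) > self.n_cells:
            raise ValidationError("planted populations exceed cell count")
        shared_per_pop: dict[str, int] = {p: 0 for p in sizes}
        for (a, b), k in self.overlap.items():
            if a not in sizes or b not in sizes:
                raise ValidationError(f"overlap names unknown population: {(a, b)}")
            if k < 0:
                raise ValidationError("negative overlap count")
            shared_per_pop[a] += k
            shared_per_pop[b] += k
        for p, s in shared_per_pop.items():
            if s > sizes[p]:
                raise ValidationError(f"population {p}: shared cells ({s}) exceed its size")
        needed = sum(sizes.values()) - sum(self.overlap.values())
        if needed > self.n_cells:
            raise ValidationError("overlap specification does not fit in n_cells")
        if min(self.n_lipid_genes, self.n_g1s_genes, self.n_g2m_genes) < 2:
            raise ValidationError("program gene lists need >= 2 genes")
        if self.n_lipid_genes + self.n_g1s_genes + self.n_g2m_genes + len(MARKERS) > self.n_genes:
            raise ValidationError("program genes exceed gene count")


def _gene_ids(cfg: SimConfig) -> tuple[list[str], dict[str, list[str]]]:
    programs = {
        "LIPID": [f"LIPID_{i:03d}" for i in range(cfg.n_lipid_genes)],
        "G1S": [f"G1S_{i:03d}" for i in range(cfg.n_g1s_genes)],
        "G2M": [f"G2M_{i:03d}" for i in range(cfg.n_g2m_genes)],
        "MARKER": list(MARKERS),
    }
    named = [g for genes in programs.values() for g in genes]
    filler = [f"GENE_{i:05d}" for i in range(cfg.n_genes - len(named))]
    return named + filler, programs


def _assign_cells(cfg: SimConfig) -> dict[str, list[int]]:
    """Allocate cell indices to populations, realizing the pairwise overlap
    spec with disjoint shared blocks (no cell in three populations)."""
    cfg.validate()
    members: dict[str, list[int]] = {p: [] for p in cfg.population_sizes()}
    cursor = 0
    for (a, b) in sorted(cfg.overlap):
        k = cfg.overlap[(a, b)]
        block = list(range(cursor, cursor + k))
        cursor += k
        members[a].extend(block)
        members[b].extend(block)
    for p, size in cfg.population_sizes().items():
        need = size - len(members[p])
        members[p].extend(range(cursor, cursor + need))
        cursor += need
    return members


def gene_sets(cfg: SimConfig) -> GeneSetCollection:
    """The planted program gene lists as a GMT-style collection."""
    _, programs = _gene_ids(cfg)
    return GeneSetCollection(
        [
            GeneSet("LIPID", frozenset(programs["LIPID"])),
            GeneSet("G1S", frozenset(programs["G1S"])),
            GeneSet("G2M", frozenset(programs["G2M"])),
        ]
    )


def simulate_cells(cfg: SimConfig) -> tuple[ExpressionMatrix, dict]:
    """Draw the single-cell TPM matrix and its ground truth.

    Baseline TPM is log-normal; planted cells get multiplicative 2^effect
    boosts on their program genes (lipid for SCC, G1S+G2M for FCC, the
    marker gene for marker-high cells); every cell is then renormalized to
    a constant TPM column sum.  Deterministic under the config seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, programs = _gene_ids(cfg)
    cell_ids = [f"cell_{i:04d}" for i in range(cfg.n_cells)]
    gene_index = {g: i for i, g in enumerate(genes)}

    x = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, size=(cfg.n_genes, cfg.n_cells))
    marker_rows = [gene_index[g] for g in MARKERS]
    x[marker_rows, :] = rng.lognormal(
        cfg.baseline_meanlog, cfg.marker_baseline_sdlog, size=(len(MARKERS), cfg.n_cells)
    )

    members = _assign_cells(cfg)
    boost = 2.0 ** cfg.effect_log2
    lipid_rows = [gene_index[g] for g in programs["LIPID"]]
    cycle_rows = [gene_index[g] for g in programs["G1S"] + programs["G2M"]]
    x[np.ix_(lipid_rows, members["SCC"])] *= boost
    x[np.ix_(cycle_rows, members["FCC"])] *= boost
    for m in MARKERS:
        x[gene_index[m], members[m]] *= 2.0 ** cfg.marker_effect_log2

    x *= cfg.tpm_total / x.sum(axis=0, keepdims=True)
    matrix = ExpressionMatrix(x, genes, cell_ids, UNIT_TPM)

    cell_labels = pd.Series([[] for _ in cell_ids], index=cell_ids, dtype=object)
    for p, idx in members.items():
        for i in idx:
            cell_labels.iloc[i].append(p)
    gene_labels = pd.Series("filler", index=genes)
    for prog, gs in programs.items():
        gene_labels.loc[gs] = prog
    truth = {
        "members": {p: [cell_ids[i] for i in idx] for p, idx in members.items()},
        "cell_labels": cell_labels,
        "gene_labels": gene_labels,
    }
    return matrix, truth


def printed_overlap_fixture() -> list[CellGroup]:
    """Seven 22-cell groups realizing the published overlap counts exactly.

    Pairwise: PTPRZ1/CD44 = 3, CD133/SOX2 = 2, one shared cell for each of
    CD133/ITGB8, SOX2/ITGB8, PTPRZ1/ITGB8, ITGB8/CD44, CD133/FCC and
    ITGB8/FCC; SCC disjoint from everything; no cell in three groups.
    Shared cells occupy disjoint blocks, which reproduces the published
    private counts (SCC 22, FCC 20, SOX2 19, CD133/PTPRZ1/CD44 18,
    ITGB8 17) by construction.
    """
    cfg = SimConfig(overlap=dict(PRINTED_OVERLAP))
    members = _assign_cells(cfg)
    kinds = {"SCC": "signature", "FCC": "cycle", **{m: "marker" for m in MARKERS}}
    sources = {"SCC": "ssgsea_LIPID", "FCC": "CCS", **{m: m for m in MARKERS}}
    groups = []
    for name in ("SCC", "FCC", *MARKERS):
        idx = sorted(members[name])
        cells = [f"cell_{i:04d}" for i in idx]
        # strictly positive, strictly decreasing stand-in ranking scores
        scores = np.linspace(2.0, 1.0, len(cells))
        groups.append(
            CellGroup(
                name,
                cells,
                scores,
                {"kind": kinds[name], "source": sources[name], "fraction": 0.02},
            )
        )
    return groups


def simulate_bulk(
    cfg: SimConfig,
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    genes: list[str],
    fractions: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Bulk mixtures f * profile_a + (1 - f) * profile_b with log-normal noise.

    ``fractions`` defaults to Uniform(0, 1) draws, one per sample; each
    gene of each sample is multiplied by exp(Normal(0, bulk_noise_sd)).
    Returns the bulk matrix and the true mixing fractions.
    """
    profile_a = np.asarray(profile_a, dtype=float)
    profile_b = np.asarray(profile_b, dtype=float)
    if profile_a.shape != profile_b.shape or profile_a.shape != (len(genes),):
        raise ValidationError("profiles must share the gene space")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if fractions is None:
        fractions = rng.uniform(0.0, 1.0, size=cfg.n_bulk_samples)
    fractions = np.asarray(fractions, dtype=float)
    samples = [f"bulk_{j:03d}" for j in range(len(fractions))]
    clean = np.outer(profile_a, fractions) + np.outer(profile_b, 1.0 - fractions)
    if cfg.bulk_noise_sd > 0:
        clean = clean * np.exp(rng.normal(0.0, cfg.bulk_noise_sd, size=clean.shape))
    bulk = ExpressionMatrix(clean, list(genes), samples, UNIT_TPM)
    return bulk, pd.Series(fractions, index=samples, name="scc_fraction")


def simulate_survival(
    fractions: pd.Series, cfg: SimConfig, seed: int | None = None
) -> list[SurvivalRecord]:
    """Exponential survival with hazard h0 * exp(beta * fraction).

    Censoring is non-informative: with probability ``censor_rate`` a
    subject is censored at a Uniform(0, t) fraction of its event time.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    records = []
    for sid, f in fractions.items():
        if not np.isfinite(f):
            raise ValidationError(f"non-finite fraction for {sid}")
        hazard = cfg.baseline_hazard * np.exp(cfg.hazard_coef * f)
        t = rng.exponential(1.0 / hazard)
        if rng.uniform() < cfg.censor_rate:
            records.append(SurvivalRecord(str(sid), t * rng.uniform(), 0))
        else:
            records.append(SurvivalRecord(str(sid), t, 1))
    return records
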