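"""Synthetic paired tumor/normal cohorts with planted immune lncRNAs.

The generator emulates the statistical structure the discovery pipeline
assumes: immune-pathway mRNAs co-vary through latent immune-activity factors,
a subset of lncRNAs rides those factors (tumor-only for the "tumor-specific"
plants, both cohorts for the shared plants), two latent tumor subtypes shift
immune activity, and survival depends on subtype through a proportional
hazard.  Every downstream stage can therefore be scored against ground truth.

Generative model (log2 scale), per sample:

* subtype ``u = +1`` (C1, immune-high) or ``-1`` (C2), balanced across tumors;
* global immune factor ``g = (subtype_shift / 2) * u + N(0, 1)`` in tumors and
  ``N(0, 1)`` in normals;
* per-pathway activity ``f_p = beta * g + gamma * u + eta * h_p`` with
  ``h_p ~ N(0, 1)`` i.i.d. and ``eta = sqrt(1 - beta^2 - gamma^2)`` (normals
  have no subtype term: ``f_p = beta * g + sqrt(1 - beta^2) * h_p``);
* pathway-member mRNA: ``baseline + factor_loading * f_p + N(0, noise_sd)``;
* marker mRNA (cell type c): ``baseline + marker_loading * g + N(0, noise_sd)``;
* planted lncRNA i (assigned pathway p(i), sign s_i alternating +/-):
  ``baseline + s_i * (lnc_pathway_loading * f_p(i) + lnc_global_loading * g)
  + N(0, lnc_noise_sd)`` -- in tumors only for tumor-specific plants, in both
  cohorts for shared plants;
* everything else is baseline + noise.

TPM is recovered as ``max(0, 2^x - 1)`` so the pipeline's ``log2(TPM + 1)``
inverts the construction.  Survival times are exponential with hazard
``baseline_hazard * hazard_ratio`` for C2 and uniform censoring on
``(0, censor_time_max)``.  All randomness flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_formats import (
    ENDPOINTS,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SurvivalTable,
)

__all__ = ["SimulationParams", "GroundTruth", "CohortBundle", "generate_cohort",
           "generate_worked_toy", "pairs_from_counts"]


@dataclass
class SimulationParams:
    n_tumor: int = 120
    n_normal: int = 40
    n_lnc: int = 300
    n_mrna: int = 2000
    n_pathways: int = 17
    pathway_size_range: tuple[int, int] = (20, 80)
    n_cell_types: int = 24
    marker_size_range: tuple[int, int] = (10, 40)
    n_tumor_specific_lnc: int = 20
    n_shared_lnc: int = 15
    factor_loading: float = 1.8
    marker_loading: float = 1.05
    noise_sd: float = 1.0
    subtype_shift: float = 2.0
    pathway_global_weight: float = 0.25   # beta
    pathway_subtype_weight: float = 0.7   # gamma
    lnc_pathway_loading: float = 2.0
    lnc_global_loading: float = 0.3
    lnc_noise_sd: float = 0.4
    zero_gene_fraction: float = 0.02
    hazard_ratio: float = 2.0
    baseline_hazard: float = 0.002        # events per day
    censor_time_max: float = 2000.0       # days
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_lnc", "n_mrna", "n_pathways",
                     "n_cell_types"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_tumor_specific_lnc + self.n_shared_lnc > self.n_lnc:
            raise ValueError("planted lncRNA counts exceed n_lnc")
        b2 = self.pathway_global_weight ** 2
        g2 = self.pathway_subtype_weight ** 2
        if b2 + g2 >= 1:
            raise ValueError(
                "pathway_global_weight^2 + pathway_subtype_weight^2 must be < 1"
            )
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard parameters must be positive")


@dataclass
class GroundTruth:
    """What was planted: the answer key for every downstream stage."""

    tumor_specific_lnc_ids: list[str]
    shared_lnc_ids: list[str]
    subtype_labels: pd.Series            # tumor sample -> C1/C2
    lnc_pathway: dict[str, str]          # planted lncRNA -> its pathway
    lnc_sign: dict[str, int]             # planted lncRNA -> +1/-1 loading sign
    biotype: dict[str, str]              # gene -> lncRNA / protein_coding
    params: SimulationParams

    def __post_init__(self) -> None:
        if set(self.tumor_specific_lnc_ids) & set(self.shared_lnc_ids):
            raise ValueError("tumor-specific and shared plant sets must be disjoint")
        if set(self.subtype_labels.unique()) - {"C1", "C2"}:
            raise ValueError("subtype labels must be C1/C2")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["subtype_labels"] = self.subtype_labels.to_dict()
        out["params"] = asdict(self.params)
        return out


class CohortBundle(NamedTuple):
    tumor: ExpressionMatrix
    normal: ExpressionMatrix
    pathways: GeneSetCollection
    markers: GeneSetCollection
    survival: SurvivalTable
    truth: GroundTruth


def _sample_disjoint_sets(
    pool: list[str], sizes: list[int], rng: np.random.Generator
) -> list[list[str]]:
    if sum(sizes) > len(pool):
        raise ValueError(
            f"cannot draw disjoint sets of total size {sum(sizes)} "
            f"from a pool of {len(pool)} genes"
        )
    chosen = rng.choice(len(pool), size=sum(sizes), replace=False)
    out, offset = [], 0
    for s in sizes:
        out.append([pool[i] for i in chosen[offset:offset + s]])
        offset += s
    return out


def generate_cohort(params: SimulationParams | None = None) -> CohortBundle:
    """Generate one paired tumor/normal cohort with planted ground truth.

    Returns expression matrices (TPM; lncRNAs and mRNAs stacked, split by the
    biotype map in the truth object), immune-pathway and immune-cell-marker
    gene sets, a three-endpoint survival table for the tumor samples, and the
    :class:`GroundTruth` answer key.  Identical params (incl. seed) give
    bitwise-identical outputs.
    """
    p = params or SimulationParams()
    rng = np.random.default_rng(p.seed)

    mrna_ids = [f"M{i:05d}" for i in range(p.n_mrna)]
    lnc_ids = [f"L{i:05d}" for i in range(p.n_lnc)]
    tumor_samples = [f"T{i:03d}" for i in range(p.n_tumor)]
    normal_samples = [f"N{i:03d}" for i in range(p.n_normal)]

    n_zero_mrna = int(p.zero_gene_fraction * p.n_mrna)
    n_zero_lnc = int(p.zero_gene_fraction * p.n_lnc)
    zero_mrna = set(mrna_ids[p.n_mrna - n_zero_mrna:])
    zero_lnc = set(lnc_ids[p.n_lnc - n_zero_lnc:])
    live_mrna = [g for g in mrna_ids if g not in zero_mrna]
    live_lnc = [g for g in lnc_ids if g not in zero_lnc]

    # --- gene sets -------------------------------------------------------
    lo, hi = p.pathway_size_range
    pathway_sizes = rng.integers(lo, hi + 1, size=p.n_pathways).tolist()
    mlo, mhi = p.marker_size_range
    marker_sizes = rng.integers(mlo, mhi + 1, size=p.n_cell_types).tolist()
    all_sets = _sample_disjoint_sets(live_mrna, pathway_sizes + marker_sizes, rng)
    pathway_members = all_sets[: p.n_pathways]
    marker_members = all_sets[p.n_pathways:]
    pathway_names = [f"PW{i:02d}" for i in range(p.n_pathways)]
    cell_names = [f"CELL{i:02d}" for i in range(p.n_cell_types)]
    pathways = GeneSetCollection({
        name: GeneSet(name, "immune pathway", frozenset(genes))
        for name, genes in zip(pathway_names, pathway_members)
    })
    markers = GeneSetCollection({
        name: GeneSet(name, "immune cell markers", frozenset(genes))
        for name, genes in zip(cell_names, marker_members)
    })

    # --- latent structure -------------------------------------------------
    n_c1 = p.n_tumor // 2
    u = np.full(p.n_tumor, -1.0)
    c1_idx = rng.choice(p.n_tumor, size=n_c1, replace=False)
    u[c1_idx] = 1.0
    subtype = pd.Series(
        np.where(u > 0, "C1", "C2"), index=tumor_samples, name="subtype"
    )

    beta = p.pathway_global_weight
    gamma = p.pathway_subtype_weight
    eta_t = np.sqrt(1.0 - beta**2 - gamma**2)
    eta_n = np.sqrt(1.0 - beta**2)

    g_t = 0.5 * p.subtype_shift * u + rng.normal(size=p.n_tumor)
    g_n = rng.normal(size=p.n_normal)
    h_t = rng.normal(size=(p.n_pathways, p.n_tumor))
    h_n = rng.normal(size=(p.n_pathways, p.n_normal))
    f_t = beta * g_t + gamma * u + eta_t * h_t
    f_n = beta * g_n + eta_n * h_n

    # --- planted lncRNAs --------------------------------------------------
    planted = rng.choice(
        live_lnc, size=p.n_tumor_specific_lnc + p.n_shared_lnc, replace=False
    ).tolist()
    ts_lnc = planted[: p.n_tumor_specific_lnc]
    shared_lnc = planted[p.n_tumor_specific_lnc:]
    lnc_pathway = {
        l: pathway_names[i % p.n_pathways] for i, l in enumerate(planted)
    }
    # majority positive: immune-activating lncRNAs dominate, so the panel's
    # mean expression tracks immune activity and the C1-is-immune-high naming
    # convention stays well defined; a third load negatively (suppressive)
    lnc_sign = {l: (-1 if i % 3 == 2 else 1) for i, l in enumerate(planted)}
    pw_index = {name: i for i, name in enumerate(pathway_names)}

    # --- expression -------------------------------------------------------
    mrna_base = rng.uniform(2.0, 8.0, size=p.n_mrna)
    lnc_base = rng.uniform(1.0, 5.0, size=p.n_lnc)

    mrna_row = {g: i for i, g in enumerate(mrna_ids)}
    lnc_row = {g: i for i, g in enumerate(lnc_ids)}

    def _expr(n_samples, f, g, tumor: bool) -> np.ndarray:
        x = np.empty((p.n_mrna + p.n_lnc, n_samples))
        x[: p.n_mrna] = mrna_base[:, None] + rng.normal(
            scale=p.noise_sd, size=(p.n_mrna, n_samples)
        )
        for pw_i, genes in enumerate(pathway_members):
            rows = [mrna_row[gene] for gene in genes]
            x[rows] += p.factor_loading * f[pw_i]
        for genes in marker_members:
            rows = [mrna_row[gene] for gene in genes]
            x[rows] += p.marker_loading * g
        x[p.n_mrna:] = lnc_base[:, None] + rng.normal(
            scale=p.noise_sd, size=(p.n_lnc, n_samples)
        )
        loaded = planted if tumor else shared_lnc
        for l in loaded:
            row = p.n_mrna + lnc_row[l]
            signal = lnc_sign[l] * (
                p.lnc_pathway_loading * f[pw_index[lnc_pathway[l]]]
                + p.lnc_global_loading * g
            )
            x[row] = (
                lnc_base[lnc_row[l]]
                + signal
                + rng.normal(scale=p.lnc_noise_sd, size=n_samples)
            )
        return x

    x_t = _expr(p.n_tumor, f_t, g_t, tumor=True)
    x_n = _expr(p.n_normal, f_n, g_n, tumor=False)

    gene_order = mrna_ids + lnc_ids
    zero_rows = [gene_order.index(g) for g in sorted(zero_mrna | zero_lnc)]

    def _to_tpm(x: np.ndarray) -> np.ndarray:
        tpm = np.maximum(0.0, np.exp2(x) - 1.0)
        tpm[zero_rows] = 0.0
        return tpm

    tumor = ExpressionMatrix(
        pd.DataFrame(_to_tpm(x_t), index=gene_order, columns=tumor_samples)
    )
    normal = ExpressionMatrix(
        pd.DataFrame(_to_tpm(x_n), index=gene_order, columns=normal_samples)
    )

    # --- survival ---------------------------------------------------------
    hazard = p.baseline_hazard * np.where(u > 0, 1.0, p.hazard_ratio)
    rows = []
    for endpoint in ENDPOINTS:
        t_event = rng.exponential(1.0 / hazard)
        t_censor = rng.uniform(1e-6, p.censor_time_max, size=p.n_tumor)
        time = np.minimum(t_event, t_censor)
        event = (t_event <= t_censor).astype(int)
        rows.append(pd.DataFrame({
            "sample_id": tumor_samples,
            "time": np.maximum(time, 1e-6),
            "event": event,
            "endpoint": endpoint,
        }))
    survival = SurvivalTable(pd.concat(rows, ignore_index=True))

    biotype = {g: "protein_coding" for g in mrna_ids}
    biotype.update({g: "lncRNA" for g in lnc_ids})
    truth = GroundTruth(
        tumor_specific_lnc_ids=ts_lnc,
        shared_lnc_ids=shared_lnc,
        subtype_labels=subtype,
        lnc_pathway=lnc_pathway,
        lnc_sign=lnc_sign,
        biotype=biotype,
        params=p,
    )
    return CohortBundle(tumor, normal, pathways, markers, survival, truth)


def pairs_from_counts(
    tumor_pairs: int,
    normal_pairs: int,
    shared_pairs: int,
    tumor_lncrnas: int,
    normal_lncrnas: int,
    shared_lncrnas: int,
) -> tuple[set, set]:
    """Construct synthetic (lncRNA, pathway) pair sets with given cardinalities.

    Builds the smallest labelled structure realising a reported overlap
    configuration -- total significant pairs and lncRNAs per cohort together
    with the shared counts -- so that summary statistics computed from whole
    pair sets can be exercised against published totals.  Raises if the
    requested counts are mutually inconsistent.
    """
    if shared_pairs < shared_lncrnas:
        raise ValueError("need at least one shared pair per shared lncRNA")
    t_only_lnc = tumor_lncrnas - shared_lncrnas
    n_only_lnc = normal_lncrnas - shared_lncrnas
    if t_only_lnc < 0 or n_only_lnc < 0:
        raise ValueError("shared lncRNAs exceed a cohort total")
    if tumor_pairs - shared_pairs < t_only_lnc:
        raise ValueError("not enough tumor-only pairs to cover tumor-only lncRNAs")
    if normal_pairs - shared_pairs < n_only_lnc:
        raise ValueError("not enough normal-only pairs to cover normal-only lncRNAs")

    shared_ids = [f"LS{i:05d}" for i in range(shared_lncrnas)]
    t_ids = [f"LT{i:05d}" for i in range(t_only_lnc)]
    n_ids = [f"LN{i:05d}" for i in range(n_only_lnc)]

    def _round_robin(ids: list[str], n_pairs: int, tag: str) -> set:
        # every lncRNA gets pair j -> pathway f"{tag}{j}"; cycling over the id
        # list yields n_pairs distinct (lnc, pathway) tuples
        out = set()
        for j in range(n_pairs):
            lnc = ids[j % len(ids)]
            out.add((lnc, f"{tag}{j // len(ids):05d}"))
        return out

    shared = _round_robin(shared_ids, shared_pairs, "PS")
    tumor = shared | _round_robin(t_ids, tumor_pairs - shared_pairs, "PT")
    normal = shared | _round_robin(n_ids, normal_pairs - shared_pairs, "PN")
    assert len(tumor) == tumor_pairs and len(normal) == normal_pairs
    assert len({l for l, _ in tumor}) == tumor_lncrnas
    assert len({l for l, _ in normal}) == normal_lncrnas
    return tumor, normal


def generate_worked_toy() -> CohortBundle:
    """A fixed micro-cohort small enough to check by hand.

    8 tumor + 4 normal samples, 6 lncRNAs, 30 mRNAs, 2 pathways, 3 cell
    types.  lncRNA ``L00000`` is an exact copy of pathway gene ``M00000`` in
    the tumor cohort, so their Pearson correlation is exactly 1.  The survival
    table carries at least one event and one censored row per endpoint.
    """
    params = SimulationParams(
        n_tumor=8, n_normal=4, n_lnc=6, n_mrna=30,
        n_pathways=2, pathway_size_range=(5, 8),
        n_cell_types=3, marker_size_range=(3, 5),
        n_tumor_specific_lnc=2, n_shared_lnc=1,
        zero_gene_fraction=0.0,
        seed=20240401,
    )
    bundle = generate_cohort(params)
    tumor = bundle.tumor.values.copy()
    tumor.loc["L00000"] = tumor.loc["M00000"]
    surv = bundle.survival.data.copy()
    # pin one event and one censored row per endpoint so KM curves always
    # have both behaviours to estimate
    for endpoint in ENDPOINTS:
        idx = surv.index[surv["endpoint"] == endpoint]
        surv.loc[idx[0], "event"] = 1
        surv.loc[idx[1], "event"] = 0
    return CohortBundle(
        ExpressionMatrix(tumor),
        bundle.normal,
        bundle.pathways,
        bundle.markers,
        SurvivalTable(surv),
        bundle.truth,
    )
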