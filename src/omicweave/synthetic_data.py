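"""Coupled multi-omics simulator with planted structure.

Generates CNV segments, promoter methylation probes, expression (FPKM and
counts), mutations, clinical covariates and survival endpoints for a
configurable number of planted subtypes, such that:

* designated copy-number driver genes have expression positively coupled
  to their copy number at a target correlation;
* designated methylation driver genes have expression negatively coupled
  to their promoter methylation;
* one designated subtype carries an elevated gain/loss burden;
* each subtype carries a multiplicative hazard on survival and an enriched
  mutation rate in a designated gene set.

The generator is a pure function of its config (all randomness flows from
``cfg.seed``), so regeneration from the echoed truth is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .omics_io import (
    AnnotationSet,
    ClinicalTable,
    GeneAnnotation,
    GeneMatrix,
    MutationTable,
    ProbeManifest,
    SegmentTable,
)

GENERATOR_VERSION = "1"

_GENE_LEN = 2000
_GENE_SPACING = 10000
_N_CHROMS = 5
_PROBE_OFFSETS = (1500, 500, -100)  # upstream distances; negative = downstream
_REGION_CYCLE = ("Island", "N_Shore", "S_Shore")


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 300
    n_genes: int = 2000
    n_subtypes: int = 3
    mixing: tuple[float, ...] | None = None  # default: equal proportions
    cnv_driver_frac: float = 0.05
    met_driver_frac: float = 0.05
    informative_frac: float = 0.10
    cis_rho: float = 0.6
    segment_len_mean: int = 8
    cnv_noise_sd: float = 0.15
    beta_noise: float = 50.0  # beta-distribution concentration
    expr_noise_sd: float = 1.0
    subtype_shift: float = 2.0  # informative-gene shift in noise-SD units
    nb_dispersion: float = 0.1
    hazard_ratios: tuple[float, ...] = (1.0, 2.5, 0.8)
    baseline_hazard: float = 1e-3  # per day
    censor_rate: float = 8e-4  # per day
    mut_rate_base: float = 0.02
    mut_enriched_per_subtype: int = 20
    mut_enriched_rate: float = 0.35
    missing_frac: float = 0.05
    dropout_gene_frac: float = 0.02
    burden_subtype: int = 1  # index of the high-CNV-burden subtype
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cnv_driver_frac", "met_driver_frac", "informative_frac",
            "missing_frac", "dropout_gene_frac",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.cis_rho > 0.95:
            raise ValueError("cis_rho > 0.95 is infeasible under the noise model")
        if self.mixing is not None:
            if len(self.mixing) != self.n_subtypes:
                raise ValueError("mixing length must equal n_subtypes")
            if abs(sum(self.mixing) - 1.0) > 1e-9:
                raise ValueError("mixing must sum to 1")
        if len(self.hazard_ratios) < self.n_subtypes:
            raise ValueError("need a hazard ratio per subtype")
        if any(h <= 0 for h in self.hazard_ratios):
            raise ValueError("hazard ratios must be positive")

    def proportions(self) -> np.ndarray:
        if self.mixing is not None:
            return np.asarray(self.mixing, dtype=float)
        return np.full(self.n_subtypes, 1.0 / self.n_subtypes)


@dataclass
class SimTruth:
    labels: pd.Series  # sample -> "S1".."Sk"
    cnv_driver_ids: list[str]
    met_driver_ids: list[str]
    informative_ids: list[str]
    enriched_mutation_genes: dict[str, list[str]]
    config: SimConfig
    version: str = GENERATOR_VERSION


@dataclass
class SimData:
    segments: SegmentTable
    probe_beta: pd.DataFrame  # probes x samples, may contain NA
    manifest: ProbeManifest
    expr_fpkm: GeneMatrix
    expr_count: GeneMatrix
    mutations: MutationTable
    clinical: ClinicalTable
    annotation: AnnotationSet
    truth: SimTruth
    # internal gene-level matrices, handy as oracles in tests
    gene_cnv: GeneMatrix = None
    gene_met: GeneMatrix = None


def _build_annotation(cfg: SimConfig, rng: np.random.Generator) -> AnnotationSet:
    genes = []
    per_chrom = int(np.ceil(cfg.n_genes / _N_CHROMS))
    for i in range(cfg.n_genes):
        chrom_idx = i // per_chrom
        within = i - chrom_idx * per_chrom
        start = 10_000 + within * _GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        gene_type = "protein_coding" if rng.random() < 0.85 else "lincRNA"
        genes.append(
            GeneAnnotation(
                gene_id=f"G{i:05d}",
                symbol=f"SYM{i:05d}",
                chrom=f"chr{chrom_idx + 1}",
                strand=strand,
                gene_start=start,
                gene_end=start + _GENE_LEN - 1,
                gene_type=gene_type,
            )
        )
    return AnnotationSet(genes)


def _blocks(cfg: SimConfig) -> list[list[int]]:
    """Contiguous gene index blocks (CNV segment units), never crossing a
    chromosome boundary."""
    per_chrom = int(np.ceil(cfg.n_genes / _N_CHROMS))
    blocks: list[list[int]] = []
    L = max(1, cfg.segment_len_mean)
    for c in range(_N_CHROMS):
        lo = c * per_chrom
        hi = min((c + 1) * per_chrom, cfg.n_genes)
        i = lo
        while i < hi:
            blocks.append(list(range(i, min(i + L, hi))))
            i += L
    return blocks


def simulate(cfg: SimConfig) -> SimData:
    """Generate the full coupled dataset; see the module docstring."""
    rng = np.random.default_rng(cfg.seed)
    n, g, k = cfg.n_samples, cfg.n_genes, cfg.n_subtypes
    samples = [f"SAMP{i:04d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(g)]
    subtype_names = [f"S{i + 1}" for i in range(k)]
    ann = _build_annotation(cfg, rng)

    labels_int = rng.choice(k, size=n, p=cfg.proportions())
    labels = pd.Series([subtype_names[i] for i in labels_int], index=samples)

    # -- gene role assignment on contiguous blocks -------------------------
    blocks = _blocks(cfg)
    n_cnv_driver = round(cfg.cnv_driver_frac * g)
    n_met_driver = round(cfg.met_driver_frac * g)
    n_informative = round(cfg.informative_frac * g)
    block_order = rng.permutation(len(blocks))
    cnv_var_blocks: list[int] = []
    burden_blocks: list[int] = []
    flat_blocks: list[int] = []
    acc = 0
    want_cnv_var = n_cnv_driver * 2  # driver genes plus CNV-varying decoys
    want_burden = max(1, len(blocks) // 10)
    for b in block_order:
        if acc < want_cnv_var:
            cnv_var_blocks.append(b)
            acc += len(blocks[b])
        elif len(burden_blocks) < want_burden:
            burden_blocks.append(b)
        else:
            flat_blocks.append(b)
    cnv_var_genes = [i for b in cnv_var_blocks for i in blocks[b]]
    flat_genes = [i for b in flat_blocks for i in blocks[b]]
    cnv_drivers = sorted(rng.choice(cnv_var_genes, size=min(n_cnv_driver, len(cnv_var_genes)), replace=False))
    pool = rng.permutation(flat_genes)
    met_drivers = sorted(pool[:n_met_driver])
    informative = sorted(pool[n_met_driver: n_met_driver + n_informative])

    # -- CNV: per-subtype block means + sample noise -----------------------
    block_base = np.zeros((len(blocks), k))
    for b in cnv_var_blocks:
        for s in range(k):
            if rng.random() < 0.6:
                block_base[b, s] = rng.choice([-1.0, 1.0]) * rng.uniform(0.35, 0.65)
    bsub = min(cfg.burden_subtype, k - 1)
    for b in burden_blocks:
        block_base[b, bsub] = rng.choice([-1.0, 1.0]) * rng.uniform(0.35, 0.7)
    block_vals = (
        block_base[:, labels_int]
        + rng.normal(scale=cfg.cnv_noise_sd, size=(len(blocks), n))
    )
    gene_block = np.empty(g, dtype=int)
    for bi, idxs in enumerate(blocks):
        gene_block[idxs] = bi
    cnv_gene = block_vals[gene_block]  # genes x samples

    seg_rows = []
    for bi, idxs in enumerate(blocks):
        first, last = ann.genes[idxs[0]], ann.genes[idxs[-1]]
        n_probes = 5 + int(rng.poisson(10 * len(idxs)))
        for j, samp in enumerate(samples):
            seg_rows.append(
                (samp, first.chrom, first.gene_start, last.gene_end, n_probes,
                 round(float(block_vals[bi, j]), 6))
            )
    segments = SegmentTable(
        pd.DataFrame(
            seg_rows,
            columns=["sample_id", "chrom", "start", "end", "n_probes", "value"],
        )
    )

    # -- methylation: gene-level means, then beta-noised probes ------------
    base_met = np.where(
        rng.random(g) < 0.6,
        rng.uniform(0.25, 0.6, size=g),
        np.where(rng.random(g) < 0.5, rng.uniform(0.8, 0.95, size=g),
                 rng.uniform(0.03, 0.15, size=g)),
    )
    met_delta = np.zeros((g, k))
    for i in met_drivers:
        met_delta[i] = rng.uniform(-0.28, 0.28, size=k)
    met_sd = np.where(np.isin(np.arange(g), met_drivers), 0.08, 0.03)
    met_gene = np.clip(
        base_met[:, None]
        + met_delta[np.arange(g)][:, labels_int]
        + rng.normal(scale=met_sd[:, None], size=(g, n)),
        0.01, 0.99,
    )

    probe_rows = []
    beta_rows = []
    conc = cfg.beta_noise
    for i, gene in enumerate(ann.genes):
        for pidx, off in enumerate(_PROBE_OFFSETS):
            pos = gene.tss - off if gene.strand == "+" else gene.tss + off
            probe_rows.append(
                (f"cg{i:05d}_{pidx}", gene.chrom, pos,
                 _REGION_CYCLE[(i + pidx) % 3], [gene.gene_id])
            )
            mu = met_gene[i]
            beta_rows.append(rng.beta(mu * conc, (1.0 - mu) * conc))
    manifest = ProbeManifest(
        pd.DataFrame(
            probe_rows, columns=["probe_id", "chrom", "pos", "region_class", "gene_ids"]
        )
    )
    beta = np.clip(np.vstack(beta_rows), 0.0, 1.0)
    if cfg.missing_frac > 0:
        mask = rng.random(beta.shape) < cfg.missing_frac
        # keep at least one observed value per probe
        all_gone = mask.all(axis=1)
        mask[all_gone, 0] = False
        beta = np.where(mask, np.nan, beta)
    probe_beta = pd.DataFrame(
        beta, index=[r[0] for r in probe_rows], columns=samples
    )

    # -- expression: baseline + planted couplings + subtype shifts ---------
    sigma_e = cfg.expr_noise_sd
    base_expr = rng.normal(loc=3.0, scale=1.0, size=g)
    log_expr = np.tile(base_expr[:, None], (1, n)).astype(float)
    shift = np.zeros((g, k))
    for i in informative:
        shift[i] = rng.normal(scale=cfg.subtype_shift * sigma_e / 2.0, size=k)
    log_expr += shift[np.arange(g)][:, labels_int]
    amp = cfg.cis_rho / np.sqrt(1.0 - cfg.cis_rho**2) * sigma_e
    for i in cnv_drivers:
        sd_c = cnv_gene[i].std()
        if sd_c > 0:
            log_expr[i] += (amp / sd_c) * (cnv_gene[i] - cnv_gene[i].mean())
    for i in met_drivers:
        sd_m = met_gene[i].std()
        if sd_m > 0:
            log_expr[i] -= (amp / sd_m) * (met_gene[i] - met_gene[i].mean())
    log_expr += rng.normal(scale=sigma_e, size=(g, n))
    fpkm = np.power(2.0, log_expr)

    # low-expression genes to exercise the zero-fraction filter
    special = set(cnv_drivers) | set(met_drivers) | set(informative)
    dropout_candidates = [i for i in range(g) if i not in special]
    n_drop = round(cfg.dropout_gene_frac * g)
    dropout_genes = sorted(
        rng.choice(dropout_candidates, size=min(n_drop, len(dropout_candidates)), replace=False)
    )
    for i in dropout_genes:
        zero_mask = rng.random(n) < 0.7
        fpkm[i, zero_mask] = 0.0
    fpkm = np.round(fpkm, 6)

    mean_counts = fpkm * 10.0
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, mean_counts / shape + 1e-12)
    counts = rng.poisson(lam).astype(float)

    expr_fpkm = GeneMatrix("EXPR_FPKM", pd.DataFrame(fpkm, index=gene_ids, columns=samples))
    expr_count = GeneMatrix("EXPR_COUNT", pd.DataFrame(counts, index=gene_ids, columns=samples))

    # -- mutations ---------------------------------------------------------
    enriched: dict[str, list[str]] = {}
    mut_pool = [i for i in range(g) if i not in special]
    rng.shuffle(mut_pool)
    pos0 = 0
    for s, name in enumerate(subtype_names):
        chosen = mut_pool[pos0: pos0 + cfg.mut_enriched_per_subtype]
        pos0 += cfg.mut_enriched_per_subtype
        enriched[name] = [gene_ids[i] for i in chosen]
    rate = np.full((g, n), cfg.mut_rate_base)
    for s, name in enumerate(subtype_names):
        cols = labels_int == s
        for gid in enriched[name]:
            rate[gene_ids.index(gid), cols] = cfg.mut_enriched_rate
    mutated = rng.random((g, n)) < rate
    silent = rng.random((g, n)) < cfg.mut_rate_base * 0.5
    intron = rng.random((g, n)) < cfg.mut_rate_base * 0.3
    recs = []
    for i, j in zip(*np.nonzero(mutated)):
        vc = "Missense_Mutation" if rng.random() < 0.8 else "Nonsense_Mutation"
        recs.append((samples[j], gene_ids[i], vc, False, False))
    for i, j in zip(*np.nonzero(silent)):
        recs.append((samples[j], gene_ids[i], "Silent", True, False))
    for i, j in zip(*np.nonzero(intron)):
        recs.append((samples[j], gene_ids[i], "Intron", False, True))
    mutations = MutationTable(
        pd.DataFrame(
            recs,
            columns=["sample_id", "gene_id", "variant_classification",
                     "is_silent", "is_intronic"],
        ).sort_values(["sample_id", "gene_id"], kind="stable").reset_index(drop=True)
    )

    # -- survival + clinical covariates ------------------------------------
    hr = np.asarray(cfg.hazard_ratios[:k])
    os_haz = cfg.baseline_hazard * hr[labels_int]
    t_os = rng.exponential(1.0 / os_haz)
    c_os = rng.exponential(1.0 / cfg.censor_rate, size=n)
    os_time = np.minimum(t_os, c_os)
    os_event = (t_os <= c_os).astype(int)
    pfs_haz = 1.4 * cfg.baseline_hazard * hr[labels_int]
    t_pfs = rng.exponential(1.0 / pfs_haz)
    c_pfs = rng.exponential(1.0 / cfg.censor_rate, size=n)
    pfs_time = np.minimum(t_pfs, c_pfs)
    pfs_event = (t_pfs <= c_pfs).astype(int)

    stage_p = np.array(
        [[0.6, 0.1, 0.22, 0.08], [0.35, 0.12, 0.38, 0.15], [0.7, 0.1, 0.16, 0.04]]
    )
    grade_p = np.array(
        [[0.1, 0.15, 0.7, 0.05], [0.02, 0.08, 0.82, 0.08], [0.45, 0.3, 0.24, 0.01]]
    )
    stages = np.array(["I", "II", "III", "IV"])
    grades = np.array(["G1", "G2", "G3", "G4"])
    stage = [stages[rng.choice(4, p=stage_p[labels_int[j] % 3])] for j in range(n)]
    grade = [grades[rng.choice(4, p=grade_p[labels_int[j] % 3])] for j in range(n)]
    age = np.clip(rng.normal(63 + 3 * (labels_int == bsub), 10), 31, 90)
    bmi = np.clip(rng.normal(32 - 1.5 * (labels_int == bsub), 7), 17, 60)
    new_event = np.where(
        pfs_event == 1,
        np.where(rng.random(n) < 0.5, "Locoregional Recurrence", "Distant Metastasis"),
        "Primary",
    )
    immune = rng.normal(size=n) - 0.8 * (labels_int == bsub)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": np.round(os_time, 2),
                "os_event": os_event,
                "pfs_time": np.round(pfs_time, 2),
                "pfs_event": pfs_event,
                "stage": stage,
                "grade": grade,
                "age": np.round(age, 1),
                "bmi": np.round(bmi, 1),
                "new_event_type": new_event,
                "immune_score": np.round(immune, 4),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )

    truth = SimTruth(
        labels=labels,
        cnv_driver_ids=[gene_ids[i] for i in cnv_drivers],
        met_driver_ids=[gene_ids[i] for i in met_drivers],
        informative_ids=[gene_ids[i] for i in informative],
        enriched_mutation_genes=enriched,
        config=cfg,
    )
    return SimData(
        segments=segments,
        probe_beta=probe_beta,
        manifest=manifest,
        expr_fpkm=expr_fpkm,
        expr_count=expr_count,
        mutations=mutations,
        clinical=clinical,
        annotation=ann,
        truth=truth,
        gene_cnv=GeneMatrix("CNV", pd.DataFrame(cnv_gene, index=gene_ids, columns=samples)),
        gene_met=GeneMatrix("MET_BETA", pd.DataFrame(met_gene, index=gene_ids, columns=samples)),
    )


def regenerate(truth: SimTruth) -> SimData:
    """Re-run the generator from the echoed config; byte-identical output."""
    if truth.version != GENERATOR_VERSION:
        raise ValueError(
            f"generator version mismatch: truth has {truth.version!r}, "
            f"current is {GENERATOR_VERSION!r}"
        )
    return simulate(truth.config)


def truth_to_json(truth: SimTruth) -> str:
    payload = {
        "version": truth.version,
        "config": asdict(truth.config),
        "labels": truth.labels.to_dict(),
        "cnv_driver_ids": truth.cnv_driver_ids,
        "met_driver_ids": truth.met_driver_ids,
        "informative_ids": truth.informative_ids,
        "enriched_mutation_genes": truth.enriched_mutation_genes,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
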