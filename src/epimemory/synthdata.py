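"""Miniature synthetic cohorts with planted ground truth.

The generator emits a cord-blood cohort with a paired postnatal subset and
an expression subset, mirroring the structure the analysis stages assume:

* gestational age (GA) spanning 23-41 weeks with prenatal covariates that
  depend on GA in known directions;
* CpGs with true GA effects in both directions on the logit-beta scale;
* "memory" CpGs whose cord and postnatal methylation share a subject-level
  component tuned to a target cross-sample correlation;
* GA-dependent cell composition (the confounder cell-fraction adjustment
  must neutralize), driven by a reference profile matrix;
* expression probes linked to CpGs with signed effects, placed within the
  cis window on a toy genome.

Randomness: every operation draws from ``numpy.random.default_rng``
(PCG64) seeded with ``(design.seed, stage_offset)``, so each stage has its
own deterministic stream and results are reproducible across platforms.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from epimemory.datamodel import (
    CELL_TYPES,
    CHROM_STATES,
    ISLAND_RELATIONS,
    ValidationError,
    validate_manifest,
    validate_sample_sheet,
)

_STAGE_COHORT = 0
_STAGE_METH = 1
_STAGE_EXPR = 2

_GA_LO, _GA_HI = 23.0, 41.0
_GA_MID = 32.0

# background chromatin-state frequencies (Quies-heavy, like blood segmentations)
_STATE_BASE = {
    "Quies": 0.30, "TxWk": 0.10, "Tx": 0.05, "TssA": 0.05, "PromU": 0.04,
    "ReprPC": 0.05, "PromBiv": 0.03, "Het": 0.04, "EnhW1": 0.04, "EnhW2": 0.03,
    "EnhA1": 0.03, "EnhA2": 0.02, "EnhAF": 0.02, "EnhAc": 0.02, "DNase": 0.03,
    "TxReg": 0.02, "Tx5": 0.02, "Tx3": 0.02, "TxEnh5": 0.02, "TxEnh3": 0.02,
    "TxEnhW": 0.02, "PromD1": 0.01, "PromD2": 0.01, "ZNF_Rpts": 0.005,
}

_ISLAND_BASE = {"Island": 0.25, "Shore": 0.25, "Shelf": 0.15, "OpenSea": 0.35}

_GENE_REGION_PROBS = {
    "TSS200": 0.20, "TSS1500": 0.20, "UTR5": 0.10, "FirstExon": 0.10,
    "Body": 0.30, "UTR3": 0.10,
}


@dataclasses.dataclass
class SimDesign:
    """Knobs of the generative model; defaults emulate the cohort scale."""

    n_cord: int = 110
    n_paired_postnatal: int = 47
    n_expr: int = 55
    n_cpgs: int = 5000
    n_expr_probes: int = 800
    frac_ga_cpgs: float = 0.10
    ga_effect_logit_per_week: float = 0.02
    frac_memory: float = 0.30
    memory_icc: float = 0.85
    nonmemory_icc: float = 0.20
    frac_discordant_promoter: float = 0.35
    frac_linked: float = 0.50
    cell_ga_slopes: tuple[float, ...] = (0.01, 0.0, 0.0, 0.0, 0.01, 0.0, -0.05)
    cell_frac_noise_sd: float = 0.35
    noise_sd_logit: float = 0.30
    covariate_effect_scale: float = 1.0
    memory_state_enrichment: float = 6.0
    ga_shore_enrichment: float = 1.0
    frac_near_miss: float = 0.05
    linked_max_offset_bp: int = 200_000
    expr_link_scale: float = 1.0
    expr_noise_sd: float = 0.5
    expr_baseline: float = 8.0
    ref_mu_sd: float = 1.0
    ref_delta_sd: float = 0.4
    n_batches: int = 2
    igr_frac: float = 0.25
    cpgs_per_chrom: int = 1000
    n_planted_top_gene_cpgs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_ga_cpgs", "frac_memory", "frac_discordant_promoter",
                     "frac_linked", "frac_near_miss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]; got {v}")
        if self.n_paired_postnatal > self.n_cord:
            raise ValidationError("n_paired_postnatal cannot exceed n_cord")
        if self.n_expr > self.n_cord:
            raise ValidationError("n_expr cannot exceed n_cord")
        if len(self.cell_ga_slopes) != len(CELL_TYPES):
            raise ValidationError("cell_ga_slopes must have one entry per cell type")

    def ga_effect_for_tratio(self, t: float) -> float:
        """Logit-scale GA effect whose OLS t-ratio is ~``t`` at ``n_cord``.

        Uses SE(slope) ~ sigma / (sd(GA) * sqrt(n)); sd(GA) comes from the
        uniform draw over the GA range.
        """
        sd_ga = (_GA_HI - _GA_LO) / np.sqrt(12.0)
        return t * self.noise_sd_logit / (sd_ga * np.sqrt(self.n_cord))


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator decided, used as the oracle in tests.

    ``cpg`` carries per-CpG flags and genomic placement; ``expr`` per
    expression-probe placement and link backrefs; ``cell_fractions`` the
    true per-sample mixing weights; ``reference`` the CpG x cell-type
    methylation profile matrix (beta scale).
    """

    cpg: pd.DataFrame
    expr: pd.DataFrame
    cell_fractions: pd.DataFrame
    reference: pd.DataFrame


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_categorical(rng, labels, probs, n, odds_boost=None, boost_labels=()):
    p = np.asarray(probs, dtype=float)
    if odds_boost is not None and odds_boost != 1.0:
        p = p.copy()
        for lab in boost_labels:
            p[labels.index(lab)] *= odds_boost
    p = p / p.sum()
    return rng.choice(labels, size=n, p=p)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(design: SimDesign) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the sample sheet and all static ground truth (flags, genome,
    cell fractions, reference profiles)."""
    rng = np.random.default_rng([design.seed, _STAGE_COHORT])
    s = design.covariate_effect_scale

    n = design.n_cord
    subjects = [f"S{i:04d}" for i in range(n)]
    ga = rng.uniform(_GA_LO, _GA_HI, size=n)

    def logistic_binary(slope_per_week, base_logit):
        p = _invlogit(base_logit + s * slope_per_week * (ga - _GA_MID))
        return (rng.uniform(size=n) < p).astype(int)

    # directions: male, cesarean, higher BMI, smoking before, CAM, iPROM
    # all push toward earlier GA
    sex = np.where(logistic_binary(-0.10, 0.0) == 1, "male", "female")
    cesarean = logistic_binary(-0.15, 1.2)
    smoke_before = logistic_binary(-0.20, -2.6)
    cam = logistic_binary(-0.25, -1.4)
    iprom = logistic_binary(-0.15, -2.2)
    parity_gt0 = (rng.uniform(size=n) < 0.40).astype(int)
    art = (rng.uniform(size=n) < 0.23).astype(int)
    gdm = (rng.uniform(size=n) < 0.05).astype(int)
    preeclampsia = (rng.uniform(size=n) < 0.18).astype(int)
    previa = (rng.uniform(size=n) < 0.09).astype(int)

    maternal_age = rng.normal(34.0, 4.7, size=n)
    maternal_bmi = np.clip(rng.normal(21.0, 3.0, size=n) - s * 0.12 * (ga - _GA_MID), 14, 45)
    paternal_age = rng.normal(36.0, 5.0, size=n)
    paternal_bmi = np.clip(rng.normal(23.0, 3.0, size=n), 15, 45)

    bw_sd = (s * 0.10 * (ga - ga.mean()) - s * 0.9 * preeclampsia
             + rng.normal(0.0, 1.2, size=n))

    batch = np.array([f"b{i % design.n_batches}" for i in range(n)])
    rng.shuffle(batch)

    cord = pd.DataFrame({
        "sample_id": [f"C{i:04d}" for i in range(n)],
        "subject_id": subjects,
        "tissue": "cord",
        "ga_weeks": np.round(ga, 2),
        "bw_sd_score": np.round(bw_sd, 3),
        "sex": sex,
        "batch": batch,
        "maternal_age": np.round(maternal_age, 1),
        "maternal_bmi": np.round(maternal_bmi, 1),
        "paternal_age": np.round(paternal_age, 1),
        "paternal_bmi": np.round(paternal_bmi, 1),
        "parity_gt0": parity_gt0, "cesarean": cesarean, "art": art,
        "smoke_before": smoke_before, "gdm": gdm, "cam": cam,
        "iprom": iprom, "preeclampsia": preeclampsia, "previa": previa,
        "postmenstrual_age_at_draw": np.round(ga, 2),
        "interval_weeks": np.nan,
    })

    paired_idx = np.sort(rng.choice(n, size=design.n_paired_postnatal, replace=False))
    interval = np.round(rng.uniform(2.0, 18.1, size=design.n_paired_postnatal), 1)
    post = cord.iloc[paired_idx].copy().reset_index(drop=True)
    post["sample_id"] = [f"P{i:04d}" for i in paired_idx]
    post["tissue"] = "postnatal"
    post["interval_weeks"] = interval
    post["postmenstrual_age_at_draw"] = np.round(
        post["ga_weeks"].to_numpy() + interval, 2)

    sheet = validate_sample_sheet(pd.concat([cord, post], ignore_index=True))

    truth = _simulate_truth(design, sheet, rng)
    return sheet, truth


def _simulate_truth(design: SimDesign, sheet: pd.DataFrame, rng) -> GroundTruth:
    m = design.n_cpgs
    probe_ids = np.array([f"cg{i:06d}" for i in range(m)])

    # -- gene/block structure on a toy genome --------------------------------
    gene, region = np.empty(m, dtype=object), np.empty(m, dtype=object)
    block_id = np.empty(m, dtype=int)
    region_labels = list(_GENE_REGION_PROBS)
    region_probs = np.array([_GENE_REGION_PROBS[k] for k in region_labels])
    region_probs = region_probs / region_probs.sum()
    i = g = b = 0
    while i < m:
        k = min(int(rng.integers(2, 7)), m - i)
        if rng.uniform() < design.igr_frac:
            gene[i:i + k] = ""
            region[i:i + k] = "IGR"
        else:
            gene[i:i + k] = f"G{g:04d}"
            region[i:i + k] = rng.choice(region_labels, size=k, p=region_probs)
            g += 1
        block_id[i:i + k] = b
        b += 1
        i += k

    # -- GA-association flags, block-correlated so genes can collect >=2
    #    qualifying promoter CpGs -------------------------------------------
    n_blocks = b
    block_ga = rng.uniform(size=n_blocks) < design.frac_ga_cpgs
    block_dir = rng.choice([-1, 1], size=n_blocks)
    is_ga = block_ga[block_id]
    direction = np.where(is_ga, block_dir[block_id], 0)
    is_memory = is_ga & (rng.uniform(size=m) < design.frac_memory)

    # -- planted top gene: all-promoter, GA+, memory, discordant-linked ------
    if design.n_planted_top_gene_cpgs > 0:
        k = design.n_planted_top_gene_cpgs
        gene[:k] = "GTOP"
        region[:k] = "TSS200"
        block_id[:k] = block_id[0]
        is_ga[:k] = True
        direction[:k] = 1
        is_memory[:k] = True

    # -- positions: one chromosome per cpgs_per_chrom, strictly increasing ---
    chrom = np.array([f"chr{1 + i // design.cpgs_per_chrom}" for i in range(m)])
    pos = np.empty(m, dtype=int)
    cursor = 0
    for i in range(m):
        if i % design.cpgs_per_chrom == 0:
            cursor = 10_000
        cursor += int(rng.integers(500, 5000))
        pos[i] = cursor

    island = _draw_categorical(
        rng, list(_ISLAND_BASE), list(_ISLAND_BASE.values()), m)
    if design.ga_shore_enrichment != 1.0:
        redraw = _draw_categorical(
            rng, list(_ISLAND_BASE), list(_ISLAND_BASE.values()), int(is_ga.sum()),
            odds_boost=design.ga_shore_enrichment, boost_labels=("Shore",))
        island[is_ga] = redraw
    assert set(island) <= set(ISLAND_RELATIONS)

    state_labels = [lab for lab in CHROM_STATES]
    base_probs = [_STATE_BASE.get(lab, 0.005) for lab in state_labels]
    chromstate_T = _draw_categorical(rng, state_labels, base_probs, m)
    chromstate_B = _draw_categorical(rng, state_labels, base_probs, m)
    if design.memory_state_enrichment != 1.0 and is_memory.any():
        nmem = int(is_memory.sum())
        chromstate_T[is_memory] = _draw_categorical(
            rng, state_labels, base_probs, nmem,
            odds_boost=design.memory_state_enrichment,
            boost_labels=("ReprPC", "PromBiv"))
        chromstate_B[is_memory] = _draw_categorical(
            rng, state_labels, base_probs, nmem,
            odds_boost=design.memory_state_enrichment,
            boost_labels=("ReprPC", "PromBiv"))

    # -- expression probes and links -----------------------------------------
    promoter = np.isin(region, ("TSS200", "TSS1500", "UTR5", "FirstExon"))
    linkable = np.flatnonzero(is_ga & (gene != ""))
    n_links = min(int(round(design.frac_linked * len(linkable))),
                  design.n_expr_probes)
    link_order = rng.permutation(linkable)
    if design.n_planted_top_gene_cpgs > 0:
        planted = np.arange(design.n_planted_top_gene_cpgs)
        link_order = np.concatenate(
            [planted, link_order[~np.isin(link_order, planted)]])
        n_links = max(n_links, design.n_planted_top_gene_cpgs)
    linked_cpg_idx = np.sort(link_order[:n_links])

    linked_expr_probe = np.full(m, "", dtype=object)
    link_sign = np.zeros(m, dtype=int)
    expr_rows = []
    chrom_end = {c: pos[chrom == c].max() for c in np.unique(chrom)}
    for j, ci in enumerate(linked_cpg_idx):
        pid = f"ex{j:05d}"
        linked_expr_probe[ci] = pid
        if promoter[ci]:
            sgn = 1 if rng.uniform() < design.frac_discordant_promoter else -1
        else:
            sgn = int(rng.choice([-1, 1]))
        link_sign[ci] = sgn
        offset = int(rng.integers(-design.linked_max_offset_bp,
                                  design.linked_max_offset_bp + 1))
        ppos = max(1, pos[ci] + offset)
        if design.n_planted_top_gene_cpgs > 0 and ci < design.n_planted_top_gene_cpgs:
            sgn = 1  # planted top gene is all-discordant by construction
            link_sign[ci] = 1
        expr_rows.append((pid, chrom[ci], ppos, gene[ci] or f"G_EX{j}",
                          probe_ids[ci], sgn))

    # unlinked probes: a fraction placed just outside the window near a GA
    # CpG (near misses), the rest scattered
    n_unlinked = design.n_expr_probes - len(expr_rows)
    ga_idx = np.flatnonzero(is_ga) if is_ga.any() else np.arange(m)
    for j in range(n_unlinked):
        pid = f"ex{len(linked_cpg_idx) + j:05d}"
        if rng.uniform() < design.frac_near_miss:
            ci = int(rng.choice(ga_idx))
            off = int(rng.integers(250_001, 300_000)) * int(rng.choice([-1, 1]))
            ppos = max(1, pos[ci] + off)
            expr_rows.append((pid, chrom[ci], ppos, f"G_NM{j}", "", 0))
        else:
            c = rng.choice(list(chrom_end))
            ppos = int(rng.integers(1, chrom_end[c] + 500_000))
            expr_rows.append((pid, c, ppos, f"G_UN{j}", "", 0))

    expr = pd.DataFrame(
        expr_rows,
        columns=["expr_probe_id", "chrom", "pos", "gene", "linked_cpg", "link_sign"],
    )

    # -- cell fractions (simplex) and reference profiles ---------------------
    slopes = np.asarray(design.cell_ga_slopes, dtype=float)
    base_w = np.log(np.array([0.25, 0.12, 0.07, 0.12, 0.20, 0.10, 0.14]))
    pm_age = sheet["postmenstrual_age_at_draw"].to_numpy(dtype=float)
    logw = (base_w[None, :] + slopes[None, :] * (pm_age[:, None] - _GA_MID)
            + rng.normal(0.0, design.cell_frac_noise_sd, size=(len(sheet), 7)))
    w = np.exp(logw)
    w = w / w.sum(axis=1, keepdims=True)
    cell_fractions = pd.DataFrame(w, index=sheet["sample_id"], columns=CELL_TYPES)

    mu = np.clip(rng.normal(0.0, design.ref_mu_sd, size=m), -1.5, 1.5)
    delta = rng.normal(0.0, design.ref_delta_sd, size=(m, 7))
    reference = pd.DataFrame(_invlogit(mu[:, None] + delta),
                             index=probe_ids, columns=CELL_TYPES)

    cpg = pd.DataFrame({
        "probe_id": probe_ids, "chrom": chrom, "pos": pos,
        "gene": gene, "gene_region": region, "island_relation": island,
        "chromstate_T": chromstate_T, "chromstate_B": chromstate_B,
        "is_ga_assoc": is_ga, "direction": direction, "is_memory": is_memory,
        "linked_expr_probe": linked_expr_probe, "link_sign": link_sign,
    })
    return GroundTruth(cpg=cpg, expr=expr,
                       cell_fractions=cell_fractions, reference=reference)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    sheet: pd.DataFrame, truth: GroundTruth, design: SimDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Logit-normal betas for cord and paired postnatal samples.

    Per sample: ``beta = invlogit(logit(reference x fractions)
    + direction * effect * (GA - mean GA) + subject_intercept + noise)``.
    Memory CpGs share the subject intercept *and* the GA term between
    tissues; the intercept variance is tuned so the cross-sample cord-post
    correlation approximates the design ICC targets.
    """
    rng = np.random.default_rng([design.seed, _STAGE_METH])
    cpg = truth.cpg
    m = len(cpg)

    cord = sheet[sheet["tissue"] == "cord"].reset_index(drop=True)
    post = sheet[sheet["tissue"] == "postnatal"].reset_index(drop=True)
    ga_cord = cord["ga_weeks"].to_numpy(dtype=float)
    ga_mean = ga_cord.mean()
    ga_var = ga_cord.var()

    b = design.ga_effect_logit_per_week
    direction = cpg["direction"].to_numpy()
    is_ga = cpg["is_ga_assoc"].to_numpy()
    is_mem = cpg["is_memory"].to_numpy()
    sigma2 = design.noise_sd_logit ** 2

    # shared-variance targets per CpG
    tau2 = np.full(m, design.nonmemory_icc / (1 - design.nonmemory_icc) * sigma2)
    mem_shared = design.memory_icc / (1 - design.memory_icc) * sigma2
    ga_shared = (b * direction) ** 2 * ga_var  # GA term persists for memory CpGs
    tau2[is_mem] = np.maximum(mem_shared - ga_shared[is_mem], 1e-10)
    tau = np.sqrt(tau2)

    subjects = cord["subject_id"].to_numpy()
    u = rng.normal(size=(m, len(subjects))) * tau[:, None]  # CpG x subject
    subj_col = {s: i for i, s in enumerate(subjects)}

    ref = truth.reference.to_numpy()

    def matrix(rows: pd.DataFrame, with_ga_effect: np.ndarray) -> pd.DataFrame:
        w = truth.cell_fractions.loc[rows["sample_id"]].to_numpy()
        base = ref @ w.T                      # CpG x sample, beta scale
        base = np.clip(base, 1e-4, 1 - 1e-4)
        x = _logit(base)
        ga = rows["ga_weeks"].to_numpy(dtype=float)
        eff = (b * direction * with_ga_effect)[:, None] * (ga - ga_mean)[None, :]
        cols = [subj_col[s] for s in rows["subject_id"]]
        x = x + eff + u[:, cols]
        if design.noise_sd_logit > 0:
            x = x + rng.normal(0.0, design.noise_sd_logit, size=x.shape)
        beta = np.clip(_invlogit(x), 1e-6, 1 - 1e-6)
        return pd.DataFrame(beta, index=cpg["probe_id"].to_numpy(),
                            columns=rows["sample_id"].to_numpy())

    cord_beta = matrix(cord, is_ga.astype(float))
    post_beta = matrix(post, (is_ga & is_mem).astype(float))
    return cord_beta, post_beta


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    sheet: pd.DataFrame, truth: GroundTruth, design: SimDesign,
    cord_beta: pd.DataFrame,
) -> pd.DataFrame:
    """log2 expression for the first ``n_expr`` cord samples.

    Linked probes: ``baseline + link_sign * scale * centered logit
    methylation + noise``; unlinked probes are independent of methylation.
    """
    rng = np.random.default_rng([design.seed, _STAGE_EXPR])
    cord = sheet[sheet["tissue"] == "cord"].reset_index(drop=True)
    samples = cord["sample_id"].to_numpy()[: design.n_expr]

    expr = truth.expr
    n_probes = len(expr)
    baseline = rng.normal(design.expr_baseline, 1.5, size=n_probes)
    out = np.empty((n_probes, len(samples)))
    for i, row in enumerate(expr.itertuples(index=False)):
        noise = (rng.normal(0.0, design.expr_noise_sd, size=len(samples))
                 if design.expr_noise_sd > 0 else 0.0)
        if row.linked_cpg:
            if row.linked_cpg not in cord_beta.index:
                raise ValidationError(
                    f"linked CpG {row.linked_cpg!r} absent from methylation matrix")
            meth = _logit(cord_beta.loc[row.linked_cpg, samples].to_numpy())
            meth = meth - meth.mean()
            out[i] = baseline[i] + row.link_sign * design.expr_link_scale * meth + noise
        else:
            out[i] = baseline[i] + noise
    out = np.maximum(out, 0.0)
    return pd.DataFrame(out, index=expr["expr_probe_id"].to_numpy(), columns=samples)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def emit_manifests(
    truth: GroundTruth, design: SimDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project ground truth into the CpG and expression probe manifests."""
    manifest = truth.cpg[
        ["probe_id", "chrom", "pos", "gene", "gene_region",
         "island_relation", "chromstate_T", "chromstate_B"]
    ].copy()
    manifest["is_cpg"] = 1  # synthetic probes are all true CpGs
    expr_manifest = truth.expr[["expr_probe_id", "chrom", "pos", "gene"]].copy()
    return validate_manifest(manifest), expr_manifest


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimDataset:
    design: SimDesign
    sheet: pd.DataFrame
    truth: GroundTruth
    cord_beta: pd.DataFrame
    post_beta: pd.DataFrame
    expression: pd.DataFrame
    manifest: pd.DataFrame
    expr_manifest: pd.DataFrame


def simulate_dataset(design: SimDesign) -> SimDataset:
    """Run every generator stage and return the full bundle."""
    sheet, truth = simulate_cohort(design)
    cord_beta, post_beta = simulate_methylation(sheet, truth, design)
    expression = simulate_expression(sheet, truth, design, cord_beta)
    manifest, expr_manifest = emit_manifests(truth, design)
    return SimDataset(design, sheet, truth, cord_beta, post_beta,
                      expression, manifest, expr_manifest)


def write_dataset(data: SimDataset, outdir) -> None:
    from pathlib import Path

    from epimemory.datamodel import (
        write_beta_matrix, write_expression_matrix, write_sample_sheet,
        write_table,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sample_sheet(data.sheet, outdir / "sample_sheet.csv")
    write_beta_matrix(data.cord_beta, outdir / "beta_cord.tsv")
    write_beta_matrix(data.post_beta, outdir / "beta_postnatal.tsv")
    write_expression_matrix(data.expression, outdir / "expression.tsv")
    write_table(data.manifest, outdir / "cpg_manifest.tsv")
    write_table(data.expr_manifest, outdir / "expr_manifest.tsv")
    write_table(data.truth.cpg, outdir / "truth_cpg.tsv")
    write_table(data.truth.expr, outdir / "truth_expr.tsv")
    write_table(data.truth.cell_fractions.reset_index(), outdir / "truth_cell_fractions.tsv")
    write_table(data.truth.reference.reset_index(names="probe_id"),
                outdir / "reference_profiles.tsv")
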