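"""Synthetic paired tumor/normal cohorts with planted SCNA-dosage structure.

The generator emulates the statistical skeleton of a paired liver-cancer
cohort: segmented DNA copy number for tumors and matched normals, FPKM-like
expression for tumors and a smaller normal panel, overall survival driven by
one gene's expression, and planted subclass template signatures.

Structure of the default cohort (a desk-scale stand-in for a 376-tumor
SNP-array / 371-tumor RNA-seq cohort with 369 samples in common):

* a toy genome of 4 chromosomes x 500 genes;
* one recurrent arm-level deletion ("13q-like": carrier fraction 0.4, mean
  log2 shift -0.7) and one gain arm (0.3, +0.6);
* 100 dosage-coupled genes inside the deletion arm whose log2 expression
  follows their log2 copy ratio with slope ``beta``; with the default noise
  the theoretical dosage correlation is
  rho = beta * sd(c) / sqrt(beta^2 var(c) + sigma_e^2) ~ 0.70;
* exponential survival with hazard h0 * exp(gamma * z) on the driver gene's
  standardized log2 expression, uniform censoring;
* two planted subclass templates (50 signature genes each, mean log2 shift
  delta on assigned samples).

Copy-number noise is applied per segment (segments are random partitions of
each chromosome), so downstream segment-to-gene mapping is genuinely
exercised. One master seed fans out into named independent substreams per
component, so changing e.g. survival parameters does not perturb the
copy-number draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CohortDataset, assemble_cohort
from .preprocess import map_segments_to_genes

_SUBSTREAMS = ("baseline", "copy_number", "expression", "survival", "templates")


@dataclass(frozen=True)
class ChromosomeSpec:
    chromosome: str
    n_genes: int = 500
    gene_length: int = 10_000
    spacing: int = 60_000  # start-to-start distance between consecutive genes

    @property
    def length(self) -> int:
        return self.n_genes * self.spacing


@dataclass(frozen=True)
class ScnaEvent:
    """A recurrent arm-level event: carried independently by each tumor
    with probability ``pi``; carriers shift the region's segment log2 values
    by ``mu`` (negative for loss)."""
    name: str
    chromosome: str
    start: int
    end: int
    kind: str  # "gain" | "loss"
    pi: float
    mu: float


@dataclass(frozen=True)
class TemplateSpec:
    class_label: str
    genes: tuple[str, ...]
    directions: tuple[int, ...]
    delta: float = 1.5
    fraction: float = 0.25


@dataclass
class SimulationConfig:
    n_pt_dcn: int = 376
    n_pt_expression: int = 371
    n_intersection: int = 369
    n_nt_expression: int = 50
    genome: tuple[ChromosomeSpec, ...] = ()
    scna_events: tuple[ScnaEvent, ...] = ()
    sigma_c: float = 0.1          # per-segment log2 copy noise sd
    seg_drop_rate: float = 0.01   # chance a segment is absent (missing coverage)
    dosage_genes: tuple[str, ...] = ()
    beta: float = 1.7             # dosage slope: log2 expression per log2 copy ratio
    sigma_e: float = 0.62         # expression noise sd (log2)
    baseline_mean: float = 5.0    # per-gene log2 FPKM baseline distribution
    baseline_sd: float = 1.5
    expr_baseline_log2: np.ndarray | None = None  # explicit per-gene override
    h0: float = 0.02              # baseline hazard (events per month)
    driver_gene: str = ""
    gamma: float = -0.5           # log-hazard per sd of driver log2 expression
    censor_horizon: float = 120.0  # months
    templates: tuple[TemplateSpec, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        chroms = {c.chromosome: c for c in self.genome}
        for ev in self.scna_events:
            if ev.chromosome not in chroms:
                raise ValueError(f"event {ev.name!r} on unknown chromosome {ev.chromosome!r}")
            if not (0 <= ev.start < ev.end <= chroms[ev.chromosome].length):
                raise ValueError(f"event {ev.name!r} region outside the genome")
            if not 0 <= ev.pi <= 1:
                raise ValueError(f"event {ev.name!r}: pi must be in [0, 1]")
        if self.sigma_c <= 0 or self.sigma_e <= 0:
            raise ValueError("sigma_c and sigma_e must be positive")
        if self.h0 <= 0:
            raise ValueError("baseline hazard must be positive")
        if sum(t.fraction for t in self.templates) > 1 + 1e-12:
            raise ValueError("template class fractions must sum to <= 1")
        if self.n_intersection > min(self.n_pt_dcn, self.n_pt_expression):
            raise ValueError("intersection larger than a component cohort")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated cohort."""
    carriers: pd.DataFrame          # PT samples x events, bool
    dosage_genes: list[str]
    driver_gene: str
    subclass: pd.Series             # PT expression samples -> class label or "none"
    event_genes: dict[str, list[str]]
    beta: float
    gamma: float
    h0: float
    gene_log2_copy: pd.DataFrame | None = None  # genes x all PT samples


def _gene_id(chrom: str, i: int) -> str:
    return f"g{chrom}_{i:04d}"


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions described in the module docstring."""
    genome = tuple(ChromosomeSpec(c) for c in ("1", "8", "13", "17"))
    spacing = genome[0].spacing
    events = (
        ScnaEvent("del_13q", "13", 150 * spacing, 400 * spacing, "loss", 0.4, -0.7),
        ScnaEvent("gain_8q", "8", 150 * spacing, 400 * spacing, "gain", 0.3, +0.6),
    )
    dosage = tuple(_gene_id("13", i) for i in range(150, 250))
    templates = (
        TemplateSpec("S1", tuple(_gene_id("1", i) for i in range(100, 150)),
                     tuple(1 if i % 2 == 0 else -1 for i in range(50))),
        TemplateSpec("S2", tuple(_gene_id("17", i) for i in range(100, 150)),
                     tuple(1 if i % 2 == 0 else -1 for i in range(50))),
    )
    return SimulationConfig(
        genome=genome, scna_events=events, dosage_genes=dosage,
        driver_gene=_gene_id("13", 200), templates=templates, seed=seed,
    )


def make_annotation(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for spec in config.genome:
        for i in range(spec.n_genes):
            start = i * spec.spacing
            gid = _gene_id(spec.chromosome, i)
            rows.append((gid, spec.chromosome, start, start + spec.gene_length, gid, ""))
    ann = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "symbol", "tags"])
    return ann.set_index("gene_id")[["chromosome", "start", "end", "symbol", "tags"]]


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str], list[str]]:
    """(all PT, PT with DCN, PT with expression, NT expression) sample ids.

    The first ``n_intersection`` samples carry both assays; the remainder are
    split into expression-only then DCN-only samples.
    """
    n_total = (config.n_intersection
               + (config.n_pt_expression - config.n_intersection)
               + (config.n_pt_dcn - config.n_intersection))
    pt_all = [f"PT_{i:04d}" for i in range(n_total)]
    both = pt_all[: config.n_intersection]
    expr_only = pt_all[config.n_intersection: config.n_pt_expression]
    dcn_only = pt_all[config.n_pt_expression:]
    nt_expr = [f"NTE_{i:04d}" for i in range(config.n_nt_expression)]
    return pt_all, both + dcn_only, both + expr_only, nt_expr


def _segment_sample(rng, spec: ChromosomeSpec, sigma_c: float) -> tuple[np.ndarray, np.ndarray]:
    """Random partition of one chromosome into segments with N(0, sigma_c) log2 values."""
    n_breaks = int(rng.integers(2, 6))
    breaks = np.sort(rng.integers(1, spec.length, size=n_breaks))
    edges = np.unique(np.concatenate(([0], breaks, [spec.length])))
    log2 = rng.normal(0.0, sigma_c, size=len(edges) - 1)
    return edges, log2


def simulate_copy_number(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Simulate segmented copy number for all tumor samples and paired normals.

    Returns (segments for all PT samples, segments for paired NT samples,
    carrier indicator frame, PT -> NT pairing). Values are linear copy ratios;
    the carrier frame marks which tumor carries which recurrent event.
    """
    config.validate()
    pt_all, _, _, _ = _sample_ids(config)
    nt_ids = {s: f"{s}-N" for s in pt_all}

    carriers = pd.DataFrame(
        {ev.name: rng.random(len(pt_all)) < ev.pi for ev in config.scna_events},
        index=pt_all,
    )

    rows_pt, rows_nt = [], []
    for sample in pt_all:
        for spec in config.genome:
            # paired normal: noise-only segmentation of the same chromosome
            edges_n, log2_n = _segment_sample(rng, spec, config.sigma_c)
            for s0, s1, lv in zip(edges_n[:-1], edges_n[1:], log2_n):
                if rng.random() >= config.seg_drop_rate:
                    rows_nt.append((nt_ids[sample], spec.chromosome, s0, s1, 2.0 ** lv))

            edges, log2 = _segment_sample(rng, spec, config.sigma_c)
            # split segments at event boundaries, then shift carried regions
            ev_here = [ev for ev in config.scna_events
                       if ev.chromosome == spec.chromosome and carriers.at[sample, ev.name]]
            cut = np.unique(np.concatenate(
                [edges] + [np.array([ev.start, ev.end]) for ev in ev_here]
            )) if ev_here else edges
            vals = log2[np.searchsorted(edges, cut[:-1], side="right") - 1].copy()
            for ev in ev_here:
                inside = (cut[:-1] >= ev.start) & (cut[1:] <= ev.end)
                vals[inside] += ev.mu
            for s0, s1, lv in zip(cut[:-1], cut[1:], vals):
                if rng.random() >= config.seg_drop_rate:
                    rows_pt.append((sample, spec.chromosome, s0, s1, 2.0 ** lv))

    cols = ["sample", "chromosome", "start", "end", "value"]
    return (pd.DataFrame(rows_pt, columns=cols),
            pd.DataFrame(rows_nt, columns=cols),
            carriers, nt_ids)


def simulate_expression(
    config: SimulationConfig,
    gene_log2_copy: pd.DataFrame,
    baseline: pd.Series,
    rng: np.random.Generator,
    pt_samples: list[str],
    nt_samples: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM-like expression given per-gene log2 copy ratios of the tumors.

    Dosage genes follow ``baseline + beta * c + N(0, sigma_e)`` in log2;
    all other genes have slope 0. Normals are baseline + noise. Values are
    emitted on the linear scale (2**log2), hence nonnegative.
    """
    genes = gene_log2_copy.index
    beta_vec = pd.Series(0.0, index=genes)
    beta_vec.loc[list(config.dosage_genes)] = config.beta

    c = gene_log2_copy[pt_samples].fillna(0.0).to_numpy()
    log2_pt = (baseline.to_numpy()[:, None]
               + beta_vec.to_numpy()[:, None] * c
               + rng.normal(0.0, config.sigma_e, size=(len(genes), len(pt_samples))))
    log2_nt = (baseline.to_numpy()[:, None]
               + rng.normal(0.0, config.sigma_e, size=(len(genes), len(nt_samples))))
    expr_pt = pd.DataFrame(2.0 ** log2_pt, index=genes, columns=pt_samples)
    expr_nt = pd.DataFrame(2.0 ** log2_nt, index=genes, columns=nt_samples)
    return expr_pt, expr_nt


def plant_templates(
    config: SimulationConfig,
    expr_pt: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.Series:
    """Assign samples to subclasses and shift their signature genes in place.

    Each sample joins class k with probability ``fraction_k`` (remainder
    unassigned); for members, ``delta * direction`` is added to the log2
    expression of the class's signature genes. Returns the assignment.
    """
    samples = list(expr_pt.columns)
    labels = [t.class_label for t in config.templates]
    fracs = np.array([t.fraction for t in config.templates])
    probs = np.concatenate([fracs, [max(0.0, 1.0 - fracs.sum())]])
    draw = rng.choice(len(probs), size=len(samples), p=probs / probs.sum())
    assignment = pd.Series([labels[d] if d < len(labels) else "none" for d in draw],
                           index=samples, name="subclass")
    for t in config.templates:
        members = assignment.index[assignment == t.class_label]
        if len(members) == 0:
            continue
        shift = 2.0 ** (np.array(t.directions, dtype=float) * t.delta)
        expr_pt.loc[list(t.genes), members] = (
            expr_pt.loc[list(t.genes), members].to_numpy() * shift[:, None]
        )
    return assignment


def simulate_survival(
    config: SimulationConfig,
    expression_pt: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Overall survival with hazard h0 * exp(gamma * z), z the driver gene's
    standardized log2 expression; uniform censoring on (0, horizon)."""
    if config.driver_gene not in expression_pt.index:
        raise ValueError(f"driver gene {config.driver_gene!r} absent from expression")
    x = np.log2(expression_pt.loc[config.driver_gene].to_numpy() + 1e-12)
    z = (x - x.mean()) / x.std(ddof=1)
    rate = config.h0 * np.exp(config.gamma * z)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, config.censor_horizon, size=len(z))
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {"os_time": os_time, "os_event": os_event, "driver_z": z},
        index=pd.Index(expression_pt.columns, name="sample_id"),
    )


def simulate_cohort(config: SimulationConfig | None = None, seed: int | None = None
                    ) -> tuple[CohortDataset, GroundTruth]:
    """Generate a full cohort bundle; deterministic given ``config.seed``."""
    if config is None:
        config = default_config(seed=0 if seed is None else seed)
    elif seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rngs = _substreams(config.seed)
    annotation = make_annotation(config)

    if config.expr_baseline_log2 is not None:
        baseline = pd.Series(np.asarray(config.expr_baseline_log2, float), index=annotation.index)
    else:
        baseline = pd.Series(
            rngs["baseline"].normal(config.baseline_mean, config.baseline_sd, len(annotation)),
            index=annotation.index,
        )

    pt_all, pt_dcn, pt_expr, nt_expr = _sample_ids(config)
    seg_pt_all, seg_nt_all, carriers, nt_ids = simulate_copy_number(config, rngs["copy_number"])

    gene_log2_copy = np.log2(map_segments_to_genes(seg_pt_all, annotation))

    expr_pt, expr_nt = simulate_expression(
        config, gene_log2_copy, baseline, rngs["expression"], pt_expr, nt_expr)
    subclass = plant_templates(config, expr_pt, rngs["templates"])
    clinical = simulate_survival(config, expr_pt, rngs["survival"])

    seg_pt = seg_pt_all[seg_pt_all["sample"].isin(pt_dcn)].reset_index(drop=True)
    nt_keep = {nt_ids[s] for s in pt_dcn}
    seg_nt = seg_nt_all[seg_nt_all["sample"].isin(nt_keep)].reset_index(drop=True)
    pairing = {s: nt_ids[s] for s in pt_dcn}

    cohort = assemble_cohort(expr_pt, expr_nt, seg_pt, seg_nt, annotation, clinical, pairing)
    event_genes = {
        ev.name: annotation.index[
            (annotation["chromosome"] == ev.chromosome)
            & (annotation["start"] >= ev.start)
            & (annotation["end"] <= ev.end)
        ].tolist()
        for ev in config.scna_events
    }
    truth = GroundTruth(
        carriers=carriers, dosage_genes=list(config.dosage_genes),
        driver_gene=config.driver_gene, subclass=subclass,
        event_genes=event_genes, beta=config.beta, gamma=config.gamma,
        h0=config.h0, gene_log2_copy=gene_log2_copy,
    )
    return cohort, truth


def theoretical_dosage_correlation(config: SimulationConfig, event: ScnaEvent) -> float:
    """Closed-form DE-SCNA correlation of a dosage gene inside ``event``:
    rho = beta sd(c) / sqrt(beta^2 var(c) + sigma_e^2), with
    var(c) = mu^2 pi (1 - pi) + sigma_c^2."""
    var_c = event.mu ** 2 * event.pi * (1 - event.pi) + config.sigma_c ** 2
    return config.beta * np.sqrt(var_c) / np.sqrt(config.beta ** 2 * var_c + config.sigma_e ** 2)
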