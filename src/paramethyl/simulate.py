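"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the study design of a tomato paramutation
experiment: two wild-type and two *sulf* bisulfite methylomes at roughly
5x depth, genotype-structured small-RNA locus counts over three genotype
levels (wt, sulf/+, sulf), a four-class differential-expression pattern
matrix, and qPCR Cq tables.  Every generator takes an explicit seed and
returns planted ground truth alongside the data, so parameter-recovery
tests can score the analysis code against what was simulated.

Methylation noise model
-----------------------
Per-cytosine coverage is Poisson(mean_depth); methylated calls are
beta-binomial with mean level ``p`` and dispersion ``rho`` (``rho = 0``
degenerates to the binomial).  Sites are placed as independent
homogeneous Bernoulli processes per context and strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONTEXTS = ("CG", "CHG", "CHH")
GENOTYPES_3 = ("wt", "sulf/+", "sulf")

#: Per-strand cytosine densities (sites per bp) used as study conditions.
DEFAULT_CONTEXT_DENSITY: dict[str, float] = {"CG": 0.02, "CHG": 0.02, "CHH": 0.10}

#: Background methylation probabilities per context.
DEFAULT_BACKGROUND: dict[str, float] = {"CG": 0.30, "CHG": 0.20, "CHH": 0.05}

#: Whole-genome bisulfite depth of the emulated experiment (about 5x).
DEFAULT_MEAN_DEPTH = 5.0

#: Methylation probabilities at the promoter-proximal DMR overlapping the
#: transcriptional start site (hypermethylated in sulf, all contexts).
DMR1_LEVELS: dict[str, dict[str, float]] = {
    "CG": {"wt": 0.24, "sulf": 0.73},
    "CHG": {"wt": 0.04, "sulf": 0.62},
    "CHH": {"wt": 0.007, "sulf": 0.04},
}
DMR1_LENGTH = 727

#: Probabilities at the adjacent repeat-overlapping DMR (hypomethylated in
#: sulf in the non-CG contexts).
DMR2_LEVELS: dict[str, dict[str, float]] = {
    "CG": {"wt": 0.96, "sulf": 0.95},
    "CHG": {"wt": 0.93, "sulf": 0.78},
    "CHH": {"wt": 0.27, "sulf": 0.04},
}
DMR2_LENGTH = 600


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class PlantedRegion:
    """A planted methylation interval [start, end), 0-based half-open.

    ``levels`` maps context -> genotype -> methylation probability; contexts
    absent from the mapping keep the background level.
    """

    start: int
    end: int
    levels: Mapping[str, Mapping[str, float]]

    def level_for(self, context: str, genotype: str, background: float) -> float:
        ctx = self.levels.get(context)
        if ctx is None:
            return background
        return ctx.get(genotype, background)


@dataclass(frozen=True)
class MethylomeSimSpec:
    chrom_name: str = "2"
    chrom_length: int = 100_000
    context_density: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_DENSITY)
    )
    background_level: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND)
    )
    planted_regions: Sequence[PlantedRegion] = ()
    mean_depth: float = DEFAULT_MEAN_DEPTH
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length < 0:
            raise ValueError("chrom_length must be >= 0")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0 <= self.overdispersion < 1:
            raise ValueError("overdispersion rho must be in [0, 1)")
        for ctx, d in self.context_density.items():
            if ctx not in CONTEXTS or not 0 <= d <= 1:
                raise ValueError(f"bad context density {ctx}={d}")
        for ctx, p in self.background_level.items():
            if ctx not in CONTEXTS or not 0 <= p <= 1:
                raise ValueError(f"bad background level {ctx}={p}")
        for region in self.planted_regions:
            if not 0 <= region.start < region.end <= self.chrom_length:
                raise ValueError(
                    f"planted region [{region.start}, {region.end}) outside chromosome"
                )
            for ctx, by_geno in region.levels.items():
                for geno, p in by_geno.items():
                    if not 0 <= p <= 1:
                        raise ValueError(f"bad planted level {ctx}/{geno}={p}")


@dataclass(frozen=True)
class SrnaSimSpec:
    n_loci: int = 2000
    library_sizes: Mapping[str, float] = field(
        default_factory=lambda: {
            "wt1": 1.0, "wt2": 1.0, "het1": 1.0, "het2": 1.0, "sulf1": 1.0, "sulf2": 1.0,
        }
    )
    genotype_design: Mapping[str, str] = field(
        default_factory=lambda: {
            "wt1": "wt", "wt2": "wt",
            "het1": "sulf/+", "het2": "sulf/+",
            "sulf1": "sulf", "sulf2": "sulf",
        }
    )
    baseline_mean: float = 20.0
    effect_loci: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")
        if set(self.library_sizes) != set(self.genotype_design):
            raise ValueError("library_sizes and genotype_design must cover the same libraries")
        for lib, size in self.library_sizes.items():
            if size <= 0:
                raise ValueError(f"library size for {lib} must be > 0")
        for lib, geno in self.genotype_design.items():
            if geno not in GENOTYPES_3:
                raise ValueError(f"unknown genotype {geno!r} for library {lib}")


@dataclass(frozen=True)
class ExpressionAnnotationPlan:
    """Sequential gene layout with a designated S-locus boundary coordinate."""

    chrom: str = "2"
    gene_length: int = 2000
    spacing: int = 5000
    s_locus: int | None = None  # default: midpoint of the layout


@dataclass(frozen=True)
class ExpressionSimSpec:
    n_genes: int = 200
    class_assignment: Sequence[str] | None = None  # per-gene labels, default balanced
    class_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            # log2 offsets over (wt, sulf/+, sulf); signs follow the four
            # expression classes: I down in both mutants, II down in sulf
            # only, III up in both, IV up in sulf only.
            "I": (0.0, -2.0, -2.0),
            "II": (0.0, 0.0, -2.0),
            "III": (0.0, 2.0, 2.0),
            "IV": (0.0, 0.0, 2.0),
            "null": (0.0, 0.0, 0.0),
        }
    )
    noise_sd: float = 0.2
    annotation_plan: ExpressionAnnotationPlan = field(default_factory=ExpressionAnnotationPlan)
    seed: int = 0
    #: samples per genotype, mirroring the RNA-seq design (2 wt, 3 pairs)
    n_samples: Mapping[str, int] = field(
        default_factory=lambda: {"wt": 2, "sulf/+": 3, "sulf": 3}
    )

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.class_assignment is not None:
            if len(self.class_assignment) != self.n_genes:
                raise ValueError("class_assignment length must equal n_genes")
            unknown = set(self.class_assignment) - set(self.class_effects)
            if unknown:
                raise ValueError(f"classes without effects: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# methylome generator


def simulate_cytosine_sites(spec: MethylomeSimSpec) -> pd.DataFrame:
    """Place cytosine sites along the chromosome.

    Independent Bernoulli processes per context and strand; where two
    contexts collide on the same (position, strand) the priority CG > CHG
    > CHH keeps sites unique per strand.  Positions are 1-based.
    """
    rng = np.random.default_rng(spec.seed)
    length = spec.chrom_length
    frames = []
    for strand in ("+", "-"):
        taken = np.zeros(length, dtype=bool)
        for ctx in CONTEXTS:  # priority order
            density = spec.context_density.get(ctx, 0.0)
            if density <= 0 or length == 0:
                continue
            mask = rng.random(length) < density
            mask &= ~taken
            taken |= mask
            pos = np.flatnonzero(mask) + 1  # 1-based
            frames.append(pd.DataFrame({"pos": pos, "strand": strand, "context": ctx}))
    if not frames:
        return pd.DataFrame({"pos": pd.Series(dtype=np.int64),
                             "strand": pd.Series(dtype=str),
                             "context": pd.Series(dtype=str)})
    sites = pd.concat(frames, ignore_index=True)
    return sites.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray, rho: float) -> np.ndarray:
    """Beta-binomial draws with mean p and dispersion rho (rho=0 -> binomial)."""
    if rho == 0:
        return rng.binomial(n, p)
    out = np.zeros_like(n)
    interior = (p > 0) & (p < 1)
    a = p[interior] * (1 - rho) / rho
    b = (1 - p[interior]) * (1 - rho) / rho
    q = rng.beta(a, b)
    out[interior] = rng.binomial(n[interior], q)
    out[p >= 1] = n[p >= 1]
    return out


def site_levels(spec: MethylomeSimSpec, sites: pd.DataFrame, genotype: str) -> np.ndarray:
    """Planted-truth methylation probability for each site under a genotype."""
    levels = np.array(
        [spec.background_level.get(ctx, 0.0) for ctx in sites["context"]], dtype=float
    )
    pos0 = sites["pos"].to_numpy() - 1
    for region in spec.planted_regions:
        inside = (pos0 >= region.start) & (pos0 < region.end)
        if not inside.any():
            continue
        for ctx in CONTEXTS:
            sel = inside & (sites["context"].to_numpy() == ctx)
            if sel.any():
                bg = spec.background_level.get(ctx, 0.0)
                levels[sel] = region.level_for(ctx, genotype, bg)
    return levels


def simulate_cytosine_report(
    spec: MethylomeSimSpec, genotype: str, seed: int | None = None
) -> pd.DataFrame:
    """Simulate one sample's cytosine report for a genotype.

    Site placement is driven by ``spec.seed`` so every sample of the same
    spec shares the same cytosines (same genome); coverage and methylation
    draws are driven by ``seed``.  Returns a DataFrame in cytosine-report
    layout (chrom, pos, strand, meth, unmeth, context, trinucleotide).
    """
    sites = simulate_cytosine_sites(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_sites = len(sites)
    depth = rng.poisson(spec.mean_depth, size=n_sites)
    levels = site_levels(spec, sites, genotype)
    meth = _beta_binomial(rng, depth, levels, spec.overdispersion)
    return pd.DataFrame(
        {
            "chrom": spec.chrom_name,
            "pos": sites["pos"].to_numpy(),
            "strand": sites["strand"].to_numpy(),
            "meth": meth,
            "unmeth": depth - meth,
            "context": sites["context"].to_numpy(),
            "trinucleotide": "NNN",
        }
    )


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_methylome_experiment(
    spec: MethylomeSimSpec, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Two wild-type and two sulf cytosine reports over a shared genome."""
    seeds = replicate_seeds(spec.seed if seed is None else seed, 4)
    samples = {}
    for name, genotype, s in zip(
        ("wt1", "wt2", "sulf1", "sulf2"), ("wt", "wt", "sulf", "sulf"), seeds
    ):
        samples[name] = simulate_cytosine_report(spec, genotype, seed=s)
    return samples


# ---------------------------------------------------------------------------
# scenario builders


def null_methylome_spec(
    chrom_length: int = 24_000_000, seed: int = 0, mean_depth: float = DEFAULT_MEAN_DEPTH
) -> MethylomeSimSpec:
    """Genotype-identical background methylome (CG 30%) for null calibration."""
    return MethylomeSimSpec(
        chrom_name="null",
        chrom_length=chrom_length,
        context_density={"CG": DEFAULT_CONTEXT_DENSITY["CG"]},
        background_level={"CG": 0.30},
        mean_depth=mean_depth,
        seed=seed,
    )


def planted_dmr_spec(
    n_regions: int = 30,
    region_length: int = DMR1_LENGTH,
    levels: Mapping[str, Mapping[str, float]] | None = None,
    spacing: int = 10_000,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    seed: int = 0,
) -> MethylomeSimSpec:
    """Methylome with evenly spaced promoter-DMR-like planted regions.

    Background CG/CHG stay at the wild-type level of the planted region so
    the planted contrast, not a background step, is what gets recovered.
    """
    levels = dict(DMR1_LEVELS if levels is None else levels)
    background = {ctx: by_geno["wt"] for ctx, by_geno in levels.items()}
    regions = [
        PlantedRegion(start=spacing * (i + 1), end=spacing * (i + 1) + region_length, levels=levels)
        for i in range(n_regions)
    ]
    chrom_length = spacing * (n_regions + 1) + region_length + spacing
    return MethylomeSimSpec(
        chrom_name="2",
        chrom_length=chrom_length,
        context_density={"CG": DEFAULT_CONTEXT_DENSITY["CG"], "CHG": DEFAULT_CONTEXT_DENSITY["CHG"]},
        background_level=background,
        planted_regions=regions,
        mean_depth=mean_depth,
        seed=seed,
    )


def single_region_spec(
    region_length: int,
    levels: Mapping[str, Mapping[str, float]],
    mean_depth: float = 50.0,
    seed: int = 0,
    flank: int = 1000,
) -> MethylomeSimSpec:
    """One planted region with flanking background, for estimator recovery."""
    return MethylomeSimSpec(
        chrom_name="2",
        chrom_length=2 * flank + region_length,
        planted_regions=[PlantedRegion(flank, flank + region_length, levels)],
        mean_depth=mean_depth,
        overdispersion=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sRNA generator


def simulate_srna_counts(spec: SrnaSimSpec) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Poisson locus x library counts with genotype-structured effects.

    Returns (counts, genotype, truth): counts is a loci x libraries integer
    DataFrame, genotype maps library -> genotype label, and truth holds the
    planted per-genotype fold-change for every locus.
    """
    rng = np.random.default_rng(spec.seed)
    libraries = list(spec.genotype_design)
    loci = [f"locus_{i:05d}" for i in range(spec.n_loci)]
    fc = np.ones((spec.n_loci, len(libraries)))
    truth_rows = []
    locus_index = {name: i for i, name in enumerate(loci)}
    for locus, by_geno in spec.effect_loci.items():
        i = locus_index[locus]
        for j, lib in enumerate(libraries):
            fc[i, j] = by_geno.get(spec.genotype_design[lib], 1.0)
        truth_rows.append({"locus": locus, **{g: by_geno.get(g, 1.0) for g in GENOTYPES_3}})
    sizes = np.array([spec.library_sizes[lib] for lib in libraries])
    lam = spec.baseline_mean * sizes[None, :] * fc
    counts = pd.DataFrame(rng.poisson(lam), index=pd.Index(loci, name="locus"), columns=libraries)
    genotype = pd.Series({lib: spec.genotype_design[lib] for lib in libraries}, name="genotype")
    truth = pd.DataFrame(truth_rows, columns=["locus", *GENOTYPES_3])
    return counts, genotype, truth


# ---------------------------------------------------------------------------
# expression generator


def simulate_expression(
    spec: ExpressionSimSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Four-class log2 expression patterns plus DE table and annotation.

    Returns (values, genotype, de_table, annotation, truth_labels).  The
    value matrix is pattern + Gaussian noise on the log2 scale, the working
    currency of the downstream clustering (upstream count normalisation and
    DE calling are emulated, not recomputed).  The DE table's adjusted-p
    proxy is derived from the planted effect: exactly 1 for null genes, the
    two-sided normal tail of the planted wt-sulf contrast otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    if spec.class_assignment is None:
        classes = ["I", "II", "III", "IV", "null"]
        labels = [classes[i % len(classes)] for i in range(spec.n_genes)]
        labels = list(rng.permutation(labels))
    else:
        labels = list(spec.class_assignment)
    truth = pd.Series(labels, index=pd.Index(genes, name="gene"), name="class")

    sample_names, sample_geno = [], []
    for geno, short in (("wt", "wt"), ("sulf/+", "het"), ("sulf", "sulf")):
        for k in range(spec.n_samples[geno]):
            sample_names.append(f"{short}{k + 1}")
            sample_geno.append(geno)
    genotype = pd.Series(sample_geno, index=sample_names, name="genotype")

    geno_col = {g: i for i, g in enumerate(GENOTYPES_3)}
    pattern = np.array([spec.class_effects[lab] for lab in labels])  # genes x 3
    mean = pattern[:, [geno_col[g] for g in sample_geno]]
    values = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    values = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_names)

    # DE table: log2FC is the wt-over-sulf contrast of the sample means
    n_wt = sum(g == "wt" for g in sample_geno)
    n_sulf = sum(g == "sulf" for g in sample_geno)
    wt_mean = values.loc[:, genotype == "wt"].mean(axis=1)
    sulf_mean = values.loc[:, genotype == "sulf"].mean(axis=1)
    log2fc = wt_mean - sulf_mean
    planted_delta = pattern[:, geno_col["wt"]] - pattern[:, geno_col["sulf"]]
    if spec.noise_sd > 0:
        se = spec.noise_sd * np.sqrt(1 / n_wt + 1 / n_sulf)
        p_proxy = 2 * stats.norm.sf(np.abs(planted_delta) / se)
    else:
        p_proxy = np.where(planted_delta != 0, 0.0, 1.0)
    p_proxy = np.where(planted_delta == 0, 1.0, p_proxy)
    de_table = pd.DataFrame({"gene": genes, "log2fc": log2fc.to_numpy(), "padj": p_proxy})

    plan = spec.annotation_plan
    starts = np.arange(spec.n_genes) * plan.spacing
    annotation = pd.DataFrame(
        {
            "gene": genes,
            "chrom": plan.chrom,
            "start": starts,
            "end": starts + plan.gene_length,
            "strand": "+",
        }
    )
    return values, genotype, de_table, annotation, truth


def s_locus_boundary(spec: ExpressionSimSpec) -> int:
    """Designated S-locus coordinate for the candidate triage (default midpoint)."""
    plan = spec.annotation_plan
    if plan.s_locus is not None:
        return plan.s_locus
    return (spec.n_genes // 2) * plan.spacing


# ---------------------------------------------------------------------------
# qPCR generator (pipeline plumbing)


def simulate_qpcr_tables(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Small McrBC and relative-expression Cq tables for end-to-end runs.

    McrBC table: digested/undigested Cq pairs for a methylated (sulf-like)
    and an unmethylated (wt-like) sample.  Expression table: target and two
    housekeepers across genotypes with a strong target knock-down in sulf.
    """
    rng = np.random.default_rng(seed)

    def cq(base):
        return round(base + rng.normal(0, 0.05), 3)

    mcrbc_rows = []
    for sample, delta in (("wt", 0.05), ("sulf", 4.0), ("vigs_sector", 3.5)):
        undig = cq(24.0)
        mcrbc_rows.append({"sample": sample, "target": "promoter", "treatment": "undigested",
                           "replicate": 1, "cq": undig})
        mcrbc_rows.append({"sample": sample, "target": "promoter", "treatment": "digested",
                           "replicate": 1, "cq": round(undig + delta, 3)})
    mcrbc = pd.DataFrame(mcrbc_rows)

    expr_rows = []
    for sample, geno, shift in (("wt_a", "wt", 0.0), ("wt_b", "wt", 0.0),
                                ("sulf_a", "sulf", 4.7), ("sulf_b", "sulf", 4.7)):
        for rep in (1, 2, 3):
            expr_rows.append({"sample": sample, "target": "target", "replicate": rep,
                              "cq": cq(22.0 + shift)})
            expr_rows.append({"sample": sample, "target": "hk1", "replicate": rep, "cq": cq(20.0)})
            expr_rows.append({"sample": sample, "target": "hk2", "replicate": rep, "cq": cq(21.0)})
    expression = pd.DataFrame(expr_rows)
    return mcrbc, expression
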