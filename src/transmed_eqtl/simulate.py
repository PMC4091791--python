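"""Synthetic genotype-expression cohorts with planted ground truth.

The generator emulates the statistical structure an eQTL study rests
on: several hundred unrelated individuals; biallelic SNPs with MAF above
1% in Hardy-Weinberg proportions, optionally organized in LD blocks;
integer-copy CNVs, optionally with sex-imbalanced copy distributions;
and probe-level expression with additive cis effects, a polygenic term
filling the gap between cis variance and total heritability, and
mediated trans chains (SCT), reverse-causal chains (STC) or pleiotropic
independent effects (INDEP).  Expression noise is Gaussian - downstream
inference is rank-based or operates on standard-normalized data, so the
marginal family is immaterial while Gaussianity keeps the variance
budget exact in expectation.

Every quantity is a pure function of (config, seed); rerunning a
scenario reproduces it byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CNV, SNP, ExpressionMatrix, GenotypeTable, ProbeAnnotation

GENE_SPACING = 12_000_000  # bp between gene loci: cis windows stay disjoint
FIRST_TSS = 10_000_000
SNP_SPREAD = 400_000       # local SNPs placed within +-SNP_SPREAD of the TSS

MODELS = ("SCT", "STC", "INDEP")


@dataclass(frozen=True)
class GeneSpec:
    """One gene/probe: its cis genetic architecture and nuisance terms.

    ``cis_r2`` lists variance-explained targets for the first k of the
    gene's local SNPs; ``h2`` is total (narrow-sense) heritability, the
    excess over sum(cis_r2) realized as an unlinked polygenic score.
    """

    gene_id: str
    cis_r2: tuple[float, ...] = ()
    h2: float = 0.0
    chromosome: int | None = None
    sex_effect: float = 0.0  # additive mean shift for males
    multi_mapped: bool = False
    contains_common_snp: bool = False


@dataclass(frozen=True)
class TripletSpec:
    """A planted causal triplet anchored at the cis gene's first local SNP.

    SCT:   C = f(G) ; T = f(C)      (cis transcript mediates)
    STC:   T = f(G) ; C = f(T)      (trans transcript mediates)
    INDEP: C = f(G) ; T = f(G)      (independent pleiotropy)

    ``r2_genetic`` is the variance of the G-proximal transcript explained
    by G; ``strength`` the variance of the downstream transcript
    explained by its parent (mediator or G).
    """

    model: str
    cis_gene: str
    trans_gene: str
    r2_genetic: float
    strength: float


@dataclass(frozen=True)
class CnvSpec:
    cnv_id: str
    chromosome: int
    position: int
    freq: float                 # duplication allele frequency
    male_freq: float | None = None  # if set, males draw from this frequency


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int
    genes: tuple[GeneSpec, ...]
    triplets: tuple[TripletSpec, ...] = ()
    cnvs: tuple[CnvSpec, ...] = ()
    snps_per_gene: int = 4
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_r2: float = 0.0
    n_chromosomes: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0.01, 0.5]")
        if not (0.0 <= self.ld_r2 < 1.0):
            raise ValueError(f"target LD r^2 {self.ld_r2} unreachable (need [0, 1))")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids")
        for g in self.genes:
            if any(not (0 <= r < 1) for r in g.cis_r2):
                raise ValueError(f"{g.gene_id}: cis r2 targets must lie in [0, 1)")
            if sum(g.cis_r2) >= 1:
                raise ValueError(
                    f"{g.gene_id}: inconsistent variance budget, sum(cis_r2) >= 1"
                )
            if g.h2 and g.h2 < sum(g.cis_r2) - 1e-12:
                raise ValueError(f"{g.gene_id}: h2 below variance explained by variants")
            if len(g.cis_r2) > self.snps_per_gene:
                raise ValueError(f"{g.gene_id}: more cis targets than local SNPs")
        for t in self.triplets:
            if t.model not in MODELS:
                raise ValueError(f"unknown triplet model {t.model!r}")
            if not (0 < t.r2_genetic < 1 and 0 < t.strength < 1):
                raise ValueError("triplet variance targets must lie in (0, 1)")
            if t.cis_gene not in ids or t.trans_gene not in ids:
                raise ValueError("triplet references unknown gene")


@dataclass
class SimulationTruth:
    """Planted effects, for recovery tests against the pipeline's calls."""

    genes: pd.DataFrame      # gene_id, probe_id, variant_ids, betas, h2
    triplets: pd.DataFrame   # model, variant_id, cis/trans gene+probe, targets
    sex: np.ndarray          # 1 = male, 0 = female
    sex_imbalanced_cnvs: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def _layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene placement: round-robin over chromosomes unless
    a gene pins its chromosome, positions spaced so cis windows are
    disjoint and >5 Mb apart."""
    slots: dict[int, int] = {}
    rows = []
    for i, gene in enumerate(config.genes):
        chrom = gene.chromosome or (i % config.n_chromosomes) + 1
        slot = slots.get(chrom, 0)
        slots[chrom] = slot + 1
        tss = FIRST_TSS + slot * GENE_SPACING
        rows.append({"gene_id": gene.gene_id, "probe_id": f"probe_{gene.gene_id}",
                     "chromosome": chrom, "tss": tss})
    return pd.DataFrame(rows)


def make_annotation(config: SimulationConfig) -> ProbeAnnotation:
    lay = _layout(config)
    flags = {g.gene_id: g for g in config.genes}
    tab = pd.DataFrame({
        "probe_id": lay["probe_id"],
        "gene_id": lay["gene_id"],
        "chromosome": lay["chromosome"].astype(str),
        "tss": lay["tss"].astype(int),
        "contains_common_snp": [flags[g].contains_common_snp for g in lay["gene_id"]],
        "multi_mapped": [flags[g].multi_mapped for g in lay["gene_id"]],
    })
    return ProbeAnnotation(table=tab)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _ld_block_dosages(
    n_samples: int, freqs: np.ndarray, ld_r2: float, rng: np.random.Generator
) -> np.ndarray:
    """SNP dosages for one LD block via a shared latent haplotype pair.

    Each variant copies the block leader's haplotype alleles with
    probability sqrt(ld_r2) and redraws Bernoulli(f) otherwise, giving
    pairwise allelic correlation ~sqrt(r2) and dosage r^2 ~ld_r2 when
    frequencies match.
    """
    m = len(freqs)
    s = np.sqrt(ld_r2)
    lead = rng.random((2, n_samples)) < freqs[0]
    out = np.empty((m, n_samples))
    for j in range(m):
        if j == 0 and ld_r2 > 0:
            hap = lead
        else:
            copy = rng.random((2, n_samples)) < s
            fresh = rng.random((2, n_samples)) < freqs[j]
            hap = np.where(copy, lead, fresh) if ld_r2 > 0 else fresh
        out[j] = hap.sum(axis=0)
    return out


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeTable, np.ndarray]:
    """Generate the variant panel and the per-sample sex vector.

    SNP dosages are binomial(2, f) with f uniform in ``maf_range``
    (folded so f is always the minor allele), grouped in LD blocks of
    ``ld_block_size`` with target pairwise r^2 ``ld_r2``.  CNV dosages
    are integer copy numbers 2 + binomial(2, freq), with a separate
    duplication frequency for males when a CNV is sex-imbalanced.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sex = (rng.random(n) < 0.5).astype(int)  # 1 = male
    lay = _layout(config)

    meta_rows, dose_rows = [], []
    for (_, gene_row) in lay.iterrows():
        k = config.snps_per_gene
        positions = np.linspace(gene_row.tss - SNP_SPREAD,
                                gene_row.tss + SNP_SPREAD, k).astype(int)
        j = 0
        while j < k:
            block = min(config.ld_block_size, k - j)
            freqs = rng.uniform(*config.maf_range, size=block)
            if config.ld_r2 > 0:
                # matched frequencies within a block keep the target
                # pairwise r^2 reachable
                freqs[:] = freqs[0]
            doses = _ld_block_dosages(n, freqs, config.ld_r2, rng)
            for b in range(block):
                meta_rows.append((
                    f"snp_{gene_row.gene_id}_{j + b}", str(gene_row.chromosome),
                    int(positions[j + b]), SNP,
                ))
                dose_rows.append(doses[b])
            j += block
    for cnv in config.cnvs:
        f = np.full(n, cnv.freq)
        if cnv.male_freq is not None:
            f = np.where(sex == 1, cnv.male_freq, cnv.freq)
        copies = 2 + rng.binomial(2, f)
        meta_rows.append((cnv.cnv_id, str(cnv.chromosome), cnv.position, CNV))
        dose_rows.append(copies.astype(float))

    variants = pd.DataFrame(
        meta_rows, columns=["variant_id", "chromosome", "position", "variant_type"]
    )
    dosages = np.vstack(dose_rows)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    geno = GenotypeTable(variants=variants, dosages=dosages, sample_ids=sample_ids)
    geno.variants["maf"] = geno.computed_maf()
    return geno, sex


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def _mix(signal: np.ndarray, r2: float, rng: np.random.Generator) -> np.ndarray:
    """sqrt(r2) * standardized signal + sqrt(1 - r2) * N(0,1) noise."""
    return np.sqrt(r2) * _standardize(signal) + np.sqrt(1 - r2) * rng.standard_normal(len(signal))


def simulate_expression(
    geno: GenotypeTable, config: SimulationConfig, sex: np.ndarray
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Build the expression matrix and the planted-effect ground truth.

    Genes with a cis architecture are sums of scaled standardized
    dosages, an unlinked polygenic score topping variance up to h2, and
    Gaussian noise; triplet downstream genes are mixed from their
    mediator (SCT/STC) or drawn with an independent direct effect
    (INDEP); everything else is pure noise.  Realized variance fractions
    converge to the targets as n grows.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_samples
    lay = _layout(config).set_index("gene_id")
    constructed = {t.trans_gene for t in config.triplets if t.model in ("SCT", "INDEP")}
    constructed |= {t.cis_gene for t in config.triplets if t.model == "STC"}
    genetic_override = {t.trans_gene: t for t in config.triplets if t.model == "STC"}

    values: dict[str, np.ndarray] = {}
    truth_rows = []
    for gene in config.genes:
        gid = gene.gene_id
        if gid in constructed:
            continue  # built from its mediator below
        if gid in genetic_override:
            # STC: the trans transcript carries the genetic effect of the
            # variant located near the triplet's cis gene
            trip = genetic_override[gid]
            vid = f"snp_{trip.cis_gene}_0"
            y = _mix(geno.dosage_of(vid), trip.r2_genetic, rng)
            truth_rows.append({"gene_id": gid, "probe_id": f"probe_{gid}",
                               "variant_ids": vid,
                               "betas": f"{np.sqrt(trip.r2_genetic):.6g}",
                               "h2": trip.r2_genetic})
        else:
            vids = [f"snp_{gid}_{j}" for j in range(len(gene.cis_r2))]
            parts = np.zeros(n)
            for vid, r2 in zip(vids, gene.cis_r2):
                parts = parts + np.sqrt(r2) * _standardize(geno.dosage_of(vid))
            explained = sum(gene.cis_r2)
            poly_var = max(gene.h2 - explained, 0.0)
            y = (parts
                 + np.sqrt(poly_var) * rng.standard_normal(n)
                 + np.sqrt(max(1.0 - explained - poly_var, 0.0))
                 * rng.standard_normal(n))
            truth_rows.append({"gene_id": gid, "probe_id": f"probe_{gid}",
                               "variant_ids": ";".join(vids),
                               "betas": ";".join(f"{np.sqrt(r):.6g}" for r in gene.cis_r2),
                               "h2": gene.h2})
        if gene.sex_effect:
            y = y + gene.sex_effect * (np.asarray(sex) == 1)
        values[gid] = y

    triplet_rows = []
    for trip in config.triplets:
        vid = f"snp_{trip.cis_gene}_0"
        if trip.model == "SCT":
            mediator = values[trip.cis_gene]
            values[trip.trans_gene] = _mix(mediator, trip.strength, rng)
        elif trip.model == "STC":
            mediator = values[trip.trans_gene]  # carries the genetic effect
            values[trip.cis_gene] = _mix(mediator, trip.strength, rng)
        else:  # INDEP: direct trans effect with independent noise
            values[trip.trans_gene] = _mix(geno.dosage_of(vid), trip.strength, rng)
        triplet_rows.append({
            "model": trip.model, "variant_id": vid,
            "cis_gene": trip.cis_gene, "trans_gene": trip.trans_gene,
            "cis_probe": f"probe_{trip.cis_gene}",
            "trans_probe": f"probe_{trip.trans_gene}",
            "r2_genetic": trip.r2_genetic, "strength": trip.strength,
        })
        for gid in (trip.cis_gene, trip.trans_gene):
            if gid in constructed:
                spec = next(g for g in config.genes if g.gene_id == gid)
                if spec.sex_effect:
                    values[gid] = values[gid] + spec.sex_effect * (np.asarray(sex) == 1)

    order = [g.gene_id for g in config.genes]
    mat = np.vstack([values[g] for g in order])
    probe_ids = [f"probe_{g}" for g in order]
    expr = ExpressionMatrix(
        values=pd.DataFrame(mat, index=pd.Index(probe_ids, name="probe_id"),
                            columns=[f"S{i:05d}" for i in range(n)]),
        probe_to_gene=dict(zip(probe_ids, order)),
    )
    truth = SimulationTruth(
        genes=pd.DataFrame(truth_rows),
        triplets=pd.DataFrame(
            triplet_rows,
            columns=["model", "variant_id", "cis_gene", "trans_gene",
                     "cis_probe", "trans_probe", "r2_genetic", "strength"],
        ),
        sex=np.asarray(sex),
        sex_imbalanced_cnvs=[c.cnv_id for c in config.cnvs
                             if c.male_freq is not None],
    )
    return expr, truth


@dataclass
class SimulatedCohort:
    genotypes: GenotypeTable
    expression: ExpressionMatrix
    annotation: ProbeAnnotation
    truth: SimulationTruth
    sex: np.ndarray
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Genotypes, expression, annotation and truth in one call."""
    geno, sex = simulate_genotypes(config)
    expr, truth = simulate_expression(geno, config, sex)
    return SimulatedCohort(genotypes=geno, expression=expr,
                           annotation=make_annotation(config),
                           truth=truth, sex=sex, config=config)


# ---------------------------------------------------------------------------
# documented scenario presets
# ---------------------------------------------------------------------------

SCENARIOS = ("null", "cis_only", "multi_cis", "mediation", "sex_cnv_confound")


def make_scenario(name: str, n_samples: int | None = None,
                  seed: int | None = None) -> SimulationConfig:
    """A documented preset cohort configuration.

    null
        500 pure-noise genes, 2000 SNPs, n = 400: every association is a
        false positive; exercises FDR calibration.
    cis_only
        100 genes with a single cis variant explaining 10% of expression
        variance plus 50 noise genes, n = 800: cis discovery power.
    multi_cis
        50 genes with two uncorrelated cis variants (10% each, h2 = 0.3)
        plus 20 noise genes, n = 800: conditional-regression recovery.
    mediation
        12 planted triplets per model (SCT, STC, INDEP; genetic and
        mediated variance fractions 0.2) plus 20 noise genes, n = 800.
    sex_cnv_confound
        5 sex-imbalanced and 5 balanced CNVs plus 30 sex-differential
        probes on other chromosomes, n = 400: the CNV trans filter must
        remove exactly the confounded associations.

    ``n_samples`` and ``seed`` may be overridden; with defaults the same
    name always returns the identical config object.
    """
    if name == "null":
        genes = tuple(GeneSpec(f"g{i:04d}") for i in range(500))
        return SimulationConfig(n_samples=n_samples or 400, genes=genes,
                                snps_per_gene=4, seed=11 if seed is None else seed)
    if name == "cis_only":
        genes = tuple(GeneSpec(f"g{i:04d}", cis_r2=(0.1,), h2=0.1)
                      for i in range(100))
        genes += tuple(GeneSpec(f"null{i:04d}") for i in range(50))
        return SimulationConfig(n_samples=n_samples or 800, genes=genes,
                                snps_per_gene=5, seed=13 if seed is None else seed)
    if name == "multi_cis":
        genes = tuple(GeneSpec(f"g{i:04d}", cis_r2=(0.1, 0.1), h2=0.3)
                      for i in range(50))
        genes += tuple(GeneSpec(f"null{i:04d}") for i in range(20))
        return SimulationConfig(n_samples=n_samples or 800, genes=genes,
                                snps_per_gene=6, seed=17 if seed is None else seed)
    if name == "mediation":
        genes: tuple[GeneSpec, ...] = ()
        triplets: tuple[TripletSpec, ...] = ()
        half = 4  # chromosomes 1..4 carry cis genes, 5..8 trans genes
        for i, model in enumerate(m for m in MODELS for _ in range(12)):
            cg = GeneSpec(f"cis{i:03d}", cis_r2=(0.2,) if model != "STC" else (),
                          h2=0.2 if model != "STC" else 0.0,
                          chromosome=(i % half) + 1)
            tg = GeneSpec(f"trans{i:03d}", chromosome=half + (i % half) + 1)
            genes += (cg, tg)
            triplets += (TripletSpec(model=model, cis_gene=cg.gene_id,
                                     trans_gene=tg.gene_id,
                                     r2_genetic=0.2, strength=0.2),)
        genes += tuple(GeneSpec(f"null{i:04d}") for i in range(20))
        return SimulationConfig(n_samples=n_samples or 800, genes=genes,
                                triplets=triplets, snps_per_gene=3,
                                seed=19 if seed is None else seed)
    if name == "sex_cnv_confound":
        genes = tuple(GeneSpec(f"sexdiff{i:03d}", sex_effect=0.5,
                               chromosome=3 + (i % 6)) for i in range(30))
        genes += tuple(GeneSpec(f"null{i:04d}", chromosome=3 + (i % 6))
                       for i in range(30))
        cnvs = tuple(CnvSpec(f"cnv_imb{i}", chromosome=1 + (i % 2),
                             position=1_000_000 + i * 2_000_000,
                             freq=0.1, male_freq=0.4) for i in range(5))
        cnvs += tuple(CnvSpec(f"cnv_bal{i}", chromosome=1 + (i % 2),
                              position=1_500_000 + i * 2_000_000,
                              freq=0.2) for i in range(5))
        return SimulationConfig(n_samples=n_samples or 400, genes=genes,
                                cnvs=cnvs, snps_per_gene=2,
                                seed=23 if seed is None else seed)
    raise ValueError(f"unknown scenario {name!r}; options: {', '.join(SCENARIOS)}")


def write_truth(truth: SimulationTruth, genes_path: str, triplets_path: str) -> None:
    truth.genes.to_csv(genes_path, sep="\t", index=False)
    truth.triplets.to_csv(triplets_path, sep="\t", index=False)
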