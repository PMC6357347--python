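"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a two-group brain RNA-seq study (cases vs
cognitively normal controls at a 24/50 scale) at the exon-count level:
negative-binomial exon counts whose means factor into a per-sample size
factor, a per-gene expression level and a per-exon, per-condition
inclusion proportion ψ; genomic sequences with planted SRE hexamers;
biallelic SNP genotypes drawn under Hardy–Weinberg equilibrium at a
stated minor-allele frequency; and a quantitative endophenotype linear in
allele dosage plus age/sex/education covariates with Gaussian noise.

Every operation is deterministic under the configuration seed, and every
planted signal (affected exons, motif placements, causal SNP, phenotype
coefficients) is returned as a truth record so downstream stages can be
tested by exact set comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, Variant
from .sre import reverse_complement

CHROM = "chr1"

# rng stream tags so independently-called operations stay decoupled
_GEOMETRY, _COUNTS, _SEQUENCE, _GENOTYPE, _PHENOTYPE = range(5)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the emulated study: 24 cases vs 50 controls, exon
    inclusion dropping from ψ = 0.6 to 0.3 in affected exons, moderate
    negative-binomial dispersion (variance = μ + αμ²) and a modest
    negative per-allele phenotype effect.
    """

    n_cases: int = 24
    n_controls: int = 50
    genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 8)
    baseline_expression: float = 500.0  # mean reads per gene
    dispersion: float = 0.05  # NB alpha: var = mu + alpha*mu^2
    psi_control: float = 0.6  # inclusion of affected exons in controls
    psi_case: float = 0.3  # inclusion of affected exons in cases
    n_affected_genes: int = 0  # genes carrying one differentially used exon
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    planted_motifs: list[tuple[str, str, int]] = field(default_factory=list)
    # each: (hexamer on the gene strand, "gene:exon:i" or "gene:intron:i"
    # with 1-based region index, 0-based offset from the region's forward start)
    snp_specs: list = field(default_factory=list)
    pheno_beta: float = -0.1  # phenotype units per alt allele
    pheno_sigma: float = 0.2
    covariate_specs: dict = field(
        default_factory=lambda: {
            "age": (89.0, 7.0),
            "education": (14.5, 3.1),
            "p_male": 0.55,
            "braak_case": (4.4, 1.7),
            "braak_control": (2.76, 1.49),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.psi_control < 1 and 0 < self.psi_case < 1):
            raise ValueError("psi values must lie in (0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n_cases + self.n_controls < 4:
            raise ValueError("need at least 4 samples")


@dataclass
class SnpSpec:
    """One simulated SNP; unset placement fields get defaults."""

    maf: float
    id: str | None = None
    chrom: str = CHROM
    pos: int | None = None  # 1-based
    ref: str | None = None
    alt: str | None = None
    sre_overlap: bool = False


@dataclass
class CountSim:
    models: list[GeneModel]
    counts: pd.DataFrame  # exons × samples, int
    gene_of: pd.Series
    samples: pd.DataFrame  # indexed by sample_id
    size_factors: pd.Series
    truth: dict


def make_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Synthetic gene geometries on one chromosome.

    Exon lengths 80–200 bp, introns 150–400 bp, alternating strand, all
    bins fully coding (CDS length = bin length) so the frame and residue
    arithmetic downstream has a complete input path.
    """
    rng = np.random.default_rng([config.seed, _GEOMETRY])
    models = []
    cursor = 500
    lo, hi = config.exons_per_gene
    for g in range(config.genes):
        gene_id = f"g{g + 1:04d}"
        n_ex = int(rng.integers(lo, hi + 1))
        strand = "+" if g % 2 == 0 else "-"
        intervals = []
        pos = cursor
        for _ in range(n_ex):
            length = int(rng.integers(80, 201))
            intervals.append(GenomicInterval(CHROM, pos, pos + length, strand))
            pos += length + int(rng.integers(150, 401))
        exon_ids = [f"{gene_id}:E{i + 1:03d}" for i in range(n_ex)]
        models.append(
            GeneModel(
                gene_id=gene_id,
                intervals=intervals,
                exon_ids=exon_ids,
                cds_flags=[True] * n_ex,
            )
        )
        cursor = intervals[-1].end + 800
    return models


def simulate_samples(config: SimulationConfig) -> pd.DataFrame:
    """Case/control sample table with age, sex, education and Braak stage."""
    rng = np.random.default_rng([config.seed, _COUNTS, 1])
    cs = config.covariate_specs
    n = config.n_cases + config.n_controls
    cond = ["case"] * config.n_cases + ["control"] * config.n_controls
    age = rng.normal(*cs["age"], n).round(1)
    edu = np.clip(rng.normal(*cs["education"], n).round(0), 6, 21)
    sex = np.where(rng.random(n) < cs["p_male"], "M", "F")
    braak = np.concatenate(
        [
            rng.normal(*cs["braak_case"], config.n_cases),
            rng.normal(*cs["braak_control"], config.n_controls),
        ]
    )
    braak = np.clip(np.rint(braak), 0, 6).astype(int)
    return pd.DataFrame(
        {
            "condition": cond,
            "age": age,
            "sex": sex,
            "education": edu.astype(int),
            "braak": braak,
        },
        index=pd.Index([f"s{i + 1:03d}" for i in range(n)], name="sample_id"),
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with variance μ + αμ²; Poisson in the α → 0 limit."""
    if alpha < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_exon_counts(config: SimulationConfig) -> CountSim:
    """Two-group exon count matrix with planted differential usage.

    The count for exon e in sample s is NB with mean
    sf_s · μ_gene · ψ_{e, condition(s)} and dispersion α. Baseline
    inclusion per exon is drawn Uniform(0.4, 0.9), shared between
    conditions; in ``n_affected_genes`` genes one internal exon gets
    ψ_control / ψ_case from the config instead. Truth records the
    affected exon ids and their ψ values.
    """
    models = make_gene_models(config)
    samples = simulate_samples(config)
    rng = np.random.default_rng([config.seed, _COUNTS, 0])
    n = len(samples)
    is_case = (samples["condition"] == "case").to_numpy()
    sf = rng.uniform(*config.size_factor_range, n)

    affected: dict[str, tuple[float, float]] = {}
    if config.n_affected_genes > 0:
        if config.n_affected_genes > len(models):
            raise ValueError("more affected genes than genes")
        chosen = rng.choice(len(models), size=config.n_affected_genes, replace=False)
    else:
        chosen = np.array([], dtype=int)

    exon_ids, gene_ids, rows = [], [], []
    for gi, model in enumerate(models):
        n_ex = model.n_exons()
        mu_gene = config.baseline_expression * rng.lognormal(0.0, 0.4)
        psi_ctrl = rng.uniform(0.4, 0.9, n_ex)
        psi_case = psi_ctrl.copy()
        if gi in chosen:
            # internal exon, so an intron flanks it on both sides
            tgt = int(rng.integers(1, n_ex - 1)) if n_ex > 2 else 0
            psi_ctrl[tgt] = config.psi_control
            psi_case[tgt] = config.psi_case
            affected[model.exon_ids[tgt]] = (config.psi_control, config.psi_case)
        psi = np.where(is_case[None, :], psi_case[:, None], psi_ctrl[:, None])
        mean = sf[None, :] * mu_gene * psi
        rows.append(_nb_draw(rng, mean, config.dispersion))
        exon_ids.extend(model.exon_ids)
        gene_ids.extend([model.gene_id] * n_ex)

    counts = pd.DataFrame(
        np.vstack(rows), index=pd.Index(exon_ids, name="exon_id"), columns=samples.index
    )
    truth = {
        "affected_exons": affected,
        "size_factors": dict(zip(samples.index, sf)),
    }
    return CountSim(
        models=models,
        counts=counts,
        gene_of=pd.Series(gene_ids, index=counts.index, name="gene_id"),
        samples=samples,
        size_factors=pd.Series(sf, index=samples.index),
        truth=truth,
    )


def _resolve_region(model: GeneModel, kind: str, index: int) -> GenomicInterval:
    if kind == "exon":
        regions = model.intervals
    elif kind == "intron":
        regions = model.introns()
    else:
        raise ValueError(f"region kind must be exon or intron, got {kind!r}")
    if not 1 <= index <= len(regions):
        raise ValueError(f"{model.gene_id} has no {kind} #{index}")
    return regions[index - 1]


def simulate_sequences(
    config: SimulationConfig, models: list[GeneModel]
) -> tuple[dict[str, str], list[dict]]:
    """Background-uniform chromosome sequence with planted SRE hexamers.

    Each planted motif is given on its gene's strand and placed verbatim
    from the scanner's point of view (minus-strand genes receive the
    reverse complement on the forward strand). Returns the sequences and
    a truth record per planted motif with its forward-strand coordinates.
    """
    rng = np.random.default_rng([config.seed, _SEQUENCE])
    length = max(m.span.end for m in models) + 500
    seq = rng.choice(list("ACGT"), size=length)
    by_gene = {m.gene_id: m for m in models}
    truth = []
    for hexamer, region_str, offset in config.planted_motifs:
        hexamer = hexamer.upper()
        if len(hexamer) != 6 or set(hexamer) - set("ACGT"):
            raise ValueError(f"planted motif must be an ACGT hexamer: {hexamer!r}")
        gene_id, kind, idx = region_str.split(":")
        model = by_gene[gene_id]
        region = _resolve_region(model, kind, int(idx))
        if offset < 0 or offset + 6 > len(region):
            raise ValueError(
                f"offset {offset} outside {region_str} (length {len(region)})"
            )
        start = region.start + offset
        planted = hexamer if model.strand == "+" else reverse_complement(hexamer)
        seq[start : start + 6] = list(planted)
        truth.append(
            {
                "gene_id": gene_id,
                "region": region_str,
                "chrom": model.chrom,
                "start": start,
                "end": start + 6,
                "strand": model.strand,
                "hexamer": hexamer,
                "context": "exonic" if kind == "exon" else "intronic",
            }
        )
    return {CHROM: "".join(seq)}, truth


def simulate_genotypes(
    sample_ids,
    snp_specs: list[SnpSpec],
    seed: int,
    sequences: dict[str, str] | None = None,
) -> tuple[list[Variant], pd.DataFrame]:
    """Hardy–Weinberg genotypes: dosage ~ Binomial(2, maf) per sample.

    Placement defaults: SNP i at position 1000·(i+1) with ref taken from
    the sequence when given (A otherwise) and a deterministic non-ref alt.
    """
    rng = np.random.default_rng([seed, _GENOTYPE])
    sample_ids = list(sample_ids)
    variants, rows = [], []
    alt_for = {"A": "G", "C": "T", "G": "A", "T": "C"}
    for i, spec in enumerate(snp_specs):
        pos = spec.pos if spec.pos is not None else 1000 * (i + 1)
        ref = spec.ref
        if ref is None:
            ref = (
                sequences[spec.chrom][pos - 1].upper()
                if sequences is not None
                else "A"
            )
        alt = spec.alt or alt_for[ref]
        vid = spec.id or f"snp{i + 1:04d}"
        dosage = rng.binomial(2, spec.maf, len(sample_ids)).astype(float)
        emp_af = dosage.mean() / 2
        emp_maf = min(emp_af, 1 - emp_af)
        variants.append(
            Variant(vid, spec.chrom, pos, ref, alt, maf=emp_maf if emp_maf > 0 else None)
        )
        rows.append(pd.Series(dosage, index=sample_ids, name=vid))
    dosages = pd.DataFrame(rows) if rows else pd.DataFrame(columns=sample_ids)
    return variants, dosages


def simulate_phenotype(
    dosage: pd.Series,
    covariates: pd.DataFrame,
    pheno_beta: float,
    pheno_sigma: float,
    seed: int,
    gammas: dict[str, float] | None = None,
    intercept: float = 1.2,
) -> tuple[pd.Series, dict]:
    """Quantitative phenotype linear in dosage and covariates.

    y = intercept + β·dosage + Σ γ_c·covariate_c + ε, ε ~ N(0, σ²).
    ``sex`` columns are coded M=1/F=0. Returns the phenotype and the truth
    coefficients for recovery tests.
    """
    rng = np.random.default_rng([seed, _PHENOTYPE])
    if gammas is None:
        gammas = {"age": 0.005, "sex": -0.02, "education": -0.005}
    cov = covariates.copy()
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"] == "M").astype(float)
    y = pd.Series(intercept, index=dosage.index, dtype=float)
    y = y + pheno_beta * dosage.astype(float)
    for name, g in gammas.items():
        if name in cov.columns:
            y = y + g * cov[name].astype(float)
    y = y + rng.normal(0.0, pheno_sigma, len(y))
    truth = {"beta": pheno_beta, "gammas": dict(gammas), "intercept": intercept,
             "sigma": pheno_sigma}
    return y.rename("phenotype"), truth
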