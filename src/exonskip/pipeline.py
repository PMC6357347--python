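"""End-to-end orchestration: counts → skipping events → SRE/SNP calls →
impact annotation → phenotype association.

Stages run in a fixed order, each writing its output before the next
starts, so a rerun with identical inputs and seed is bit-identical. The
run manifest records inputs (with checksums), thresholds, the seed and
every stage output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import permutation_maxT
from .diffexon import adjust_bh, call_skipping_events, test_exon_usage
from .impact import annotate_impacts, read_domains_tsv
from .io_formats import (
    read_counts_tsv,
    read_fasta,
    read_gtf,
    read_motifs,
    read_table_tsv,
    read_vcf,
    write_bed_sites,
    write_counts_tsv,
    write_fasta,
    write_gtf,
    write_motifs,
    write_vcf,
)
from .sre import filter_candidate_snps, map_snps_to_sres, scan_sre_sites
from .simulate import (
    CHROM,
    SimulationConfig,
    SnpSpec,
    simulate_exon_counts,
    simulate_genotypes,
    simulate_phenotype,
    simulate_sequences,
)

logger = logging.getLogger(__name__)

SRE_CLASS_KEYS = ("ESE", "ESS", "ISE")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and run parameters for a full pipeline run."""

    counts: str
    samples: str
    gtf: str
    fasta: str
    motifs: dict[str, str]  # SRE class -> motif file
    vcf: str
    phenotype: str
    outdir: str
    domains: str | None = None
    fdr_max: float = 0.05
    fc_min: float = 1.5
    maf_min: float = 0.01
    intron_flank: int | str = "full"
    permutations: int = 1000
    covariates: tuple[str, ...] = ("age", "sex", "education")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fdr_max <= 0 or self.fc_min <= 0 or self.maf_min < 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _events_frame(events) -> pd.DataFrame:
    cols = [
        "exon_id", "gene_id", "p_value", "fdr", "fold_change", "direction",
        "mean_usage_case", "mean_usage_control",
    ]
    return pd.DataFrame([asdict(e) for e in events], columns=cols)


def _calls_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "variant_id": c.variant.id,
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "maf": c.variant.maf,
                "sre_class": c.site.sre_class,
                "hexamer": c.site.hexamer,
                "offset_in_motif": c.offset_in_motif,
                "context": c.site.context,
                "site_start": c.site.interval.start,
                "site_end": c.site.interval.end,
                "skipped_exon_id": c.skipped_exon_id,
                "effect_call": c.effect_call,
                "alt_creates_motif": (
                    f"{c.alt_creates_motif[0]}:{c.alt_creates_motif[1]}"
                    if c.alt_creates_motif
                    else ""
                ),
            }
        )
    cols = [
        "variant_id", "chrom", "pos", "ref", "alt", "maf", "sre_class", "hexamer",
        "offset_in_motif", "context", "site_start", "site_end", "skipped_exon_id",
        "effect_call", "alt_creates_motif",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to the outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "fdr_max": config.fdr_max,
            "fc_min": config.fc_min,
            "maf_min": config.maf_min,
        },
        "inputs": {},
        "outputs": {},
    }
    input_paths = {
        "counts": config.counts,
        "samples": config.samples,
        "gtf": config.gtf,
        "fasta": config.fasta,
        "vcf": config.vcf,
        "phenotype": config.phenotype,
        **{f"motifs_{k}": v for k, v in config.motifs.items()},
    }
    if config.domains:
        input_paths["domains"] = config.domains
    for name, path in input_paths.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {name!r} not found: {path}")
        manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def _stage(name):
        logger.info("stage: %s", name)

    # 1. differential exon usage
    _stage("diffexon")
    try:
        counts, gene_of = read_counts_tsv(config.counts)
        samples = read_table_tsv(config.samples)
        models = read_gtf(config.gtf)
    except Exception as exc:
        raise RuntimeError(f"stage diffexon failed reading inputs: {exc}") from exc
    results = test_exon_usage(counts, gene_of, samples)
    results["fdr"] = adjust_bh(results["p_value"])
    results_path = outdir / "exon_usage_tests.tsv"
    results.to_csv(results_path, sep="\t")
    events = call_skipping_events(results, config.fdr_max, config.fc_min)
    events_path = outdir / "skipping_events.tsv"
    _events_frame(events).to_csv(events_path, sep="\t", index=False)
    manifest["outputs"]["exon_usage_tests"] = str(results_path)
    manifest["outputs"]["skipping_events"] = str(events_path)

    # 2. SRE scan
    _stage("srescan")
    seqs = read_fasta(config.fasta)
    motif_sets = [read_motifs(path, klass) for klass, path in config.motifs.items()]
    sites = scan_sre_sites(seqs, models, motif_sets, config.intron_flank)
    sites_path = outdir / "sre_sites.bed"
    write_bed_sites(sites, sites_path)
    manifest["outputs"]["sre_sites"] = str(sites_path)

    # 3. splicing decision
    _stage("decide")
    variants, dosages = read_vcf(config.vcf)
    overlaps = map_snps_to_sres(variants, sites)
    from .sre import splicing_decision

    calls = splicing_decision(overlaps, events, models, motif_sets)
    calls = filter_candidate_snps(calls, config.maf_min)
    calls_path = outdir / "splicing_snp_calls.tsv"
    _calls_frame(calls).to_csv(calls_path, sep="\t", index=False)
    manifest["outputs"]["splicing_snp_calls"] = str(calls_path)

    # 4. impact annotation
    _stage("annotate")
    domains = read_domains_tsv(config.domains) if config.domains else []
    impacts = annotate_impacts([e.exon_id for e in events], models, domains)
    imp_rows = [
        {
            "exon_id": a.exon_id,
            "cds_length": a.cds_length,
            "frame_status": a.frame_status,
            "residue_start": a.residues_lost[0] if a.residues_lost else "",
            "residue_end": a.residues_lost[1] if a.residues_lost else "",
            "domains_overlapped": ",".join(a.domains_overlapped),
        }
        for a in impacts
    ]
    impact_path = outdir / "impact_annotations.tsv"
    pd.DataFrame(
        imp_rows,
        columns=[
            "exon_id", "cds_length", "frame_status", "residue_start",
            "residue_end", "domains_overlapped",
        ],
    ).to_csv(impact_path, sep="\t", index=False)
    manifest["outputs"]["impact_annotations"] = str(impact_path)

    # 5. association
    _stage("assoc")
    pheno = read_table_tsv(config.phenotype)
    assoc_path = outdir / "association.tsv"
    candidate_ids = sorted({c.variant.id for c in calls})
    if candidate_ids:
        cov = pheno[list(config.covariates)].copy()
        if "sex" in cov.columns and cov["sex"].dtype == object:
            cov["sex"] = (cov["sex"] == "M").astype(float)  # sex coded M=1, F=0
        fam = permutation_maxT(
            pheno["phenotype"],
            dosages.loc[candidate_ids],
            cov,
            n_permutations=config.permutations,
            seed=config.seed,
        )
        fam.to_csv(assoc_path, sep="\t", index_label="variant_id")
    else:
        pd.DataFrame(
            columns=["beta", "se", "t_statistic", "p_nominal", "p_perm_corrected", "n_used"]
        ).to_csv(assoc_path, sep="\t", index_label="variant_id")
    manifest["outputs"]["association"] = str(assoc_path)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = str(manifest_path)
    return manifest


@dataclass
class FixtureTruth:
    """Planted signals of a written synthetic input set."""

    affected_exons: list[str]
    causal_snp: str
    decoy_snps: list[str]
    planted_sites: list[dict]
    pheno_beta: float


def write_synthetic_inputs(
    outdir: str | Path,
    seed: int = 0,
    genes: int = 12,
    n_affected_genes: int = 2,
    n_pheno_samples: int = 500,
    pheno_beta: float = -0.1,
    permutations: int = 1000,
) -> tuple[PipelineConfig, FixtureTruth]:
    """Write a complete, self-consistent synthetic input set plus truth.

    Plants one ISE hexamer (CCTTCC) in the intron downstream of each
    affected exon, a causal SNP at the 5th motif base of the first
    planted site, a decoy SNP (no phenotype effect) in the second, a SNP
    in a planted site of an unaffected gene, and an intergenic SNP. The
    genotype/phenotype cohort is simulated separately from the RNA-seq
    cohort, as in a two-cohort imaging-genetics design.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(
        genes=genes,
        n_affected_genes=n_affected_genes,
        psi_control=0.6,
        psi_case=0.3,
        pheno_beta=pheno_beta,
        seed=seed,
    )
    sim = simulate_exon_counts(config)
    models = {m.gene_id: m for m in sim.models}
    affected = sorted(sim.truth["affected_exons"])

    # plant an ISE in the intron just downstream (genomic order) of each
    # affected exon, close to the exon so it anchors to it; plus one in an
    # unaffected gene as a negative control
    planted: list[tuple[str, str, int]] = []
    for exon_id in affected:
        gene_id = exon_id.split(":")[0]
        idx = models[gene_id].exon_index(exon_id)
        planted.append(("CCTTCC", f"{gene_id}:intron:{idx + 1}", 20))
    unaffected_gene = next(
        m.gene_id
        for m in sim.models
        if not any(e.startswith(m.gene_id + ":") for e in affected)
        and m.n_exons() >= 2
    )
    planted.append(("CCTTCC", f"{unaffected_gene}:intron:1", 20))
    config.planted_motifs = planted
    seqs, site_truth = simulate_sequences(config, sim.models)

    def _snp_at_motif_offset(site: dict, offset1: int) -> tuple[int, str]:
        """1-based genomic position and forward ref base of a motif offset."""
        if site["strand"] == "+":
            pos0 = site["start"] + offset1 - 1
        else:
            pos0 = site["end"] - offset1
        return pos0 + 1, seqs[site["chrom"]][pos0]

    linked_sites = site_truth[:-1]  # sites next to the affected exons
    specs = []
    if linked_sites:
        pos_causal, ref_causal = _snp_at_motif_offset(linked_sites[0], 5)
    else:  # null run: no skipping events, park the SNP between genes
        pos_causal = sim.models[-1].span.end + 100
        ref_causal = seqs[CHROM][pos_causal - 1]
    specs.append(SnpSpec(maf=0.3, id="rs_causal", pos=pos_causal, ref=ref_causal))
    if len(linked_sites) > 1:
        pos_decoy, ref_decoy = _snp_at_motif_offset(linked_sites[1], 3)
    else:
        pos_decoy = sim.models[-1].span.end + 150
        ref_decoy = seqs[CHROM][pos_decoy - 1]
    specs.append(SnpSpec(maf=0.2, id="rs_decoy_site", pos=pos_decoy, ref=ref_decoy))
    pos_neg, ref_neg = _snp_at_motif_offset(site_truth[-1], 2)
    specs.append(SnpSpec(maf=0.25, id="rs_unlinked_site", pos=pos_neg, ref=ref_neg))
    intergenic_pos = sim.models[-1].span.end + 200
    specs.append(
        SnpSpec(
            maf=0.2,
            id="rs_intergenic",
            pos=intergenic_pos,
            ref=seqs[CHROM][intergenic_pos - 1],
        )
    )

    pheno_ids = [f"p{i + 1:04d}" for i in range(n_pheno_samples)]
    variants, dosages = simulate_genotypes(pheno_ids, specs, seed, seqs)
    cov_rng_cfg = SimulationConfig(
        n_cases=n_pheno_samples, n_controls=4, seed=seed + 1
    )
    from .simulate import simulate_samples

    pheno_cov = simulate_samples(cov_rng_cfg).iloc[:n_pheno_samples]
    pheno_cov.index = pd.Index(pheno_ids, name="sample_id")
    phenotype, _ = simulate_phenotype(
        dosages.loc["rs_causal"], pheno_cov, pheno_beta, config.pheno_sigma, seed
    )

    # write everything in the formats the pipeline reads
    write_counts_tsv(sim.counts, sim.gene_of, outdir / "counts.tsv")
    sim.samples.to_csv(outdir / "samples.tsv", sep="\t")
    write_gtf(sim.models, outdir / "genes.gtf")
    write_fasta(seqs, outdir / "genome.fa")
    from .sre import MotifSet

    write_motifs(MotifSet("ISE", frozenset({"CCTTCC"})), outdir / "motifs_ise.txt")
    write_vcf(variants, dosages, outdir / "genotypes.vcf")
    ptab = pheno_cov.copy()
    ptab.insert(0, "phenotype", phenotype)
    ptab.drop(columns=["condition", "braak"]).to_csv(outdir / "phenotype.tsv", sep="\t")

    pipe_cfg = PipelineConfig(
        counts=str(outdir / "counts.tsv"),
        samples=str(outdir / "samples.tsv"),
        gtf=str(outdir / "genes.gtf"),
        fasta=str(outdir / "genome.fa"),
        motifs={"ISE": str(outdir / "motifs_ise.txt")},
        vcf=str(outdir / "genotypes.vcf"),
        phenotype=str(outdir / "phenotype.tsv"),
        outdir=str(outdir / "results"),
        permutations=permutations,
        seed=seed,
    )
    truth = FixtureTruth(
        affected_exons=affected,
        causal_snp="rs_causal",
        decoy_snps=["rs_decoy_site", "rs_unlinked_site", "rs_intergenic"],
        planted_sites=site_truth,
        pheno_beta=pheno_beta,
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=2)
    return pipe_cfg, truth
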