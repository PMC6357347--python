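"""Splicing-regulatory-element (SRE) scanning and the splicing decision model.

SREs are short cis-acting hexamer motifs that enhance or silence exon
recognition by the spliceosome. Four classes exist — exonic splicing
enhancers (ESE) and silencers (ESS), and their intronic counterparts ISE
and ISS — of which three (ESE, ESS, ISE) are handled here; ISS catalogs
are not part of the motif inputs.

The splicing decision model links a SNP inside a perfect-match SRE site
to an exon-skipping call: an exonic site is linked to the exon that embeds
it, an intronic site to the exons flanking its host intron. A SNP that
falls in such a site, when the linked exon is differentially skipped, is
predicted to act through loss of the element — loss of an enhancer
promotes skipping, loss of a silencer promotes inclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .intervals import GeneModel, GenomicInterval, Variant

logger = logging.getLogger(__name__)

SRE_CLASSES = ("ESE", "ESS", "ISE")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSet:
    """A class of hexameric SRE motifs."""

    sre_class: str
    hexamers: frozenset[str]

    def __post_init__(self) -> None:
        if self.sre_class not in SRE_CLASSES:
            raise ValueError(f"unknown SRE class {self.sre_class!r}")
        for h in self.hexamers:
            if len(h) != 6 or set(h) - set("ACGT"):
                raise ValueError(f"not an ACGT hexamer: {h!r}")

    @property
    def is_exonic(self) -> bool:
        return self.sre_class in ("ESE", "ESS")


@dataclass(frozen=True)
class SRESite:
    """A perfect hexamer match inside a gene, on the gene's strand.

    ``interval`` is always reported in forward-strand coordinates;
    ``hexamer`` is the motif as matched on the gene's strand.
    ``anchor_exon_id`` is the embedding exon for exonic sites and the
    nearest flanking exon for intronic sites; ``flanking_exon_ids`` lists
    both exons adjacent to the host intron (intronic sites only).
    """

    interval: GenomicInterval
    sre_class: str
    hexamer: str
    context: str  # "exonic" | "intronic"
    gene_id: str
    anchor_exon_id: str
    flanking_exon_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.interval) != 6:
            raise ValueError("SRE site interval must have length 6")
        if self.context not in ("exonic", "intronic"):
            raise ValueError(f"bad context {self.context!r}")
        exonic = self.sre_class in ("ESE", "ESS")
        if exonic != (self.context == "exonic"):
            raise ValueError(
                f"class {self.sre_class} inconsistent with context {self.context}"
            )


@dataclass(frozen=True)
class SplicingSNPCall:
    """A SNP predicted to disrupt an SRE linked to a skipped exon."""

    variant: Variant
    site: SRESite
    offset_in_motif: int  # 1-based within the hexamer, on the motif's strand
    skipped_exon_id: str
    effect_call: str  # enhancer_loss_promotes_skipping | silencer_loss_promotes_inclusion
    alt_creates_motif: tuple[str, str] | None = None  # (class, hexamer)


def _scan_region(
    seq: str,
    region: GenomicInterval,
    hexamers: frozenset[str],
    strand: str,
) -> list[tuple[int, str]]:
    """All (forward 0-based start, matched hexamer) in ``region``.

    Minus-strand genes are scanned on the reverse complement and match
    coordinates mapped back to the forward strand. Overlapping matches are
    all reported.
    """
    sub = seq[region.start : region.end]
    if strand == "-":
        sub = reverse_complement(sub)
    hits = []
    for i in range(len(sub) - 5):
        w = sub[i : i + 6].upper()
        if w in hexamers:
            if strand == "+":
                fwd = region.start + i
            else:
                fwd = region.end - i - 6
            hits.append((fwd, w))
    return hits


def scan_sre_sites(
    sequence: str | dict[str, str],
    models: list[GeneModel],
    motif_sets: list[MotifSet],
    intron_flank: int | str = "full",
) -> list[SRESite]:
    """Find every perfect SRE hexamer match in the intragenic regions.

    Exonic classes (ESE/ESS) are searched within exon bins; the intronic
    class (ISE) within each intron, restricted to ``intron_flank`` bases
    from either exon boundary unless ``intron_flank="full"``. Matching is
    exact and case-insensitive, with no ambiguity codes. Minus-strand
    genes are scanned on the reverse complement with coordinates reported
    on the forward strand.

    ``sequence`` is either the sequence of the single chromosome all
    models live on, or a mapping from chromosome name to sequence.
    """
    if intron_flank != "full" and (not isinstance(intron_flank, int) or intron_flank <= 0):
        raise ValueError("intron_flank must be a positive length or 'full'")
    sites: list[SRESite] = []
    for model in models:
        if isinstance(sequence, dict):
            try:
                chrom_seq = sequence[model.chrom]
            except KeyError:
                raise ValueError(f"no sequence for chromosome {model.chrom}")
        else:
            chrom_seq = sequence
        if len(chrom_seq) < model.span.end:
            raise ValueError(
                f"sequence shorter than the span of gene {model.gene_id}"
            )
        strand = model.strand
        for mset in motif_sets:
            if not mset.hexamers:
                continue
            if mset.is_exonic:
                for exon_id, iv in zip(model.exon_ids, model.intervals):
                    if len(iv) < 6:
                        continue
                    for fwd, hexamer in _scan_region(chrom_seq, iv, mset.hexamers, strand):
                        sites.append(
                            SRESite(
                                interval=GenomicInterval(model.chrom, fwd, fwd + 6, strand),
                                sre_class=mset.sre_class,
                                hexamer=hexamer,
                                context="exonic",
                                gene_id=model.gene_id,
                                anchor_exon_id=exon_id,
                            )
                        )
            else:
                for k, intron in enumerate(model.introns()):
                    regions = [intron]
                    if intron_flank != "full" and len(intron) > 2 * intron_flank:
                        regions = [
                            GenomicInterval(
                                model.chrom, intron.start, intron.start + intron_flank, strand
                            ),
                            GenomicInterval(
                                model.chrom, intron.end - intron_flank, intron.end, strand
                            ),
                        ]
                    upstream, downstream = model.exon_ids[k], model.exon_ids[k + 1]
                    seen: set[int] = set()
                    for region in regions:
                        if len(region) < 6:
                            continue
                        for fwd, hexamer in _scan_region(
                            chrom_seq, region, mset.hexamers, strand
                        ):
                            if fwd in seen:
                                continue  # flank windows may overlap in short introns
                            seen.add(fwd)
                            mid = fwd + 3
                            anchor = (
                                upstream
                                if mid - intron.start <= intron.end - mid
                                else downstream
                            )
                            sites.append(
                                SRESite(
                                    interval=GenomicInterval(
                                        model.chrom, fwd, fwd + 6, strand
                                    ),
                                    sre_class=mset.sre_class,
                                    hexamer=hexamer,
                                    context="intronic",
                                    gene_id=model.gene_id,
                                    anchor_exon_id=anchor,
                                    flanking_exon_ids=(upstream, downstream),
                                )
                            )
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.sre_class, s.hexamer))
    return sites


def motif_offset(site: SRESite, pos0: int) -> int:
    """1-based offset of a forward 0-based position within the motif.

    Counted on the motif's strand, so on minus-strand sites base 1 is the
    rightmost forward-strand base.
    """
    if not site.interval.contains(pos0):
        raise ValueError("position outside the SRE site")
    if site.interval.strand == "+":
        return pos0 - site.interval.start + 1
    return site.interval.end - pos0


def map_snps_to_sres(
    variants: list[Variant], sites: list[SRESite]
) -> list[tuple[Variant, SRESite, int]]:
    """Intersect SNPs with SRE sites.

    A SNP overlapping k sites yields k records; the offset is the SNP's
    1-based position within the matched hexamer on the motif's strand.
    """
    by_chrom: dict[str, list[SRESite]] = {}
    for s in sites:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    out = []
    for v in variants:
        for s in by_chrom.get(v.chrom, []):
            if s.interval.contains(v.pos0):
                out.append((v, s, motif_offset(s, v.pos0)))
    return out


def _site_base_forward(site: SRESite, pos0: int) -> str:
    """The reference base the motif implies at a forward-strand position."""
    off = motif_offset(site, pos0)
    base = site.hexamer[off - 1]
    if site.interval.strand == "-":
        base = reverse_complement(base)
    return base


def splicing_decision(
    snp_site_overlaps: list[tuple[Variant, SRESite, int]],
    skipping_events: list,
    models: list[GeneModel],
    motif_sets: list[MotifSet] | None = None,
) -> list[SplicingSNPCall]:
    """Apply the splicing decision model to SNP/SRE overlaps.

    An overlap is retained iff the site is exonic and its embedding exon
    is a called skipping event, or the site is intronic and either exon
    flanking the host intron is a called skipping event. The reference
    allele must equal the motif base at the SNP's offset (strand-aware);
    mismatches are dropped with a warning. If the alternate allele turns
    the window into a different perfect motif of any class, that is
    recorded in ``alt_creates_motif``.
    """
    skipped_ids = {getattr(e, "exon_id", e) for e in skipping_events}
    all_motifs = motif_sets or []
    calls = []
    for variant, site, offset in snp_site_overlaps:
        if site.context == "exonic":
            linked = [site.anchor_exon_id] if site.anchor_exon_id in skipped_ids else []
        else:
            linked = [e for e in site.flanking_exon_ids if e in skipped_ids]
        if not linked:
            continue
        expected_ref = _site_base_forward(site, variant.pos0)
        if variant.ref != expected_ref:
            logger.warning(
                "dropping %s at %s:%d: ref %s does not match motif base %s",
                variant.id, variant.chrom, variant.pos, variant.ref, expected_ref,
            )
            continue
        alt_motif = None
        alt_on_motif = (
            variant.alt if site.interval.strand == "+" else reverse_complement(variant.alt)
        )
        mutated = site.hexamer[: offset - 1] + alt_on_motif + site.hexamer[offset:]
        for mset in all_motifs:
            if mutated in mset.hexamers:
                alt_motif = (mset.sre_class, mutated)
                break
        effect = (
            "silencer_loss_promotes_inclusion"
            if site.sre_class == "ESS"
            else "enhancer_loss_promotes_skipping"
        )
        for exon_id in linked:
            calls.append(
                SplicingSNPCall(
                    variant=variant,
                    site=site,
                    offset_in_motif=offset,
                    skipped_exon_id=exon_id,
                    effect_call=effect,
                    alt_creates_motif=alt_motif,
                )
            )
    return calls


def filter_candidate_snps(
    calls: list[SplicingSNPCall], maf_min: float = 0.01
) -> list[SplicingSNPCall]:
    """Keep calls whose SNP has minor-allele frequency strictly above ``maf_min``."""
    return [c for c in calls if c.variant.maf is not None and c.variant.maf > maf_min]
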