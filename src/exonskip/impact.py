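"""Protein-level consequence annotation for skipped exons.

Skipping a coding exon whose CDS length is not a multiple of 3 shifts the
downstream reading frame, typically truncating the protein; an in-frame
exon removes a block of residues instead. Either way the residues encoded
by the exon are lost, so overlap of the exon's residue interval with
protein domain annotations flags domains that would be disrupted.

Each exon's frame effect is evaluated in isolation (single-exon skipping);
combinatorial multi-exon events are out of scope. Domain annotations are
supplied as a table (protein_id, domain_id, start/end residues, 1-based
inclusive) rather than fetched from a live database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .intervals import GeneModel


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein domain, 1-based inclusive residue coordinates."""

    domain_id: str
    protein_id: str
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if self.start_residue < 1 or self.end_residue < self.start_residue:
            raise ValueError(
                f"bad residue interval {self.start_residue}-{self.end_residue}"
            )


@dataclass(frozen=True)
class ImpactAnnotation:
    exon_id: str
    cds_length: int
    frame_status: str  # in_frame | out_of_frame | non_coding
    residues_lost: tuple[int, int] | None
    domains_overlapped: tuple[str, ...]


def frame_status(cds_length: int) -> str:
    """Classify an exon's reading-frame effect from its CDS length."""
    if cds_length < 0:
        raise ValueError("cds_length must be non-negative")
    if cds_length == 0:
        return "non_coding"
    return "in_frame" if cds_length % 3 == 0 else "out_of_frame"


def exon_to_residues(exon_id: str, model: GeneModel) -> tuple[int, int]:
    """Residue interval (1-based inclusive) encoded by a coding exon.

    The cumulative CDS length upstream of the exon in translation order
    (genomic order on +, reversed on −) gives first residue
    floor(offset/3) + 1 and last residue ceil((offset + cds_length)/3).
    Junction codons are shared, so adjacent exons may overlap by one
    residue.
    """
    idx = model.exon_index(exon_id)
    cds_len = model.cds_lengths[idx]
    if cds_len == 0:
        raise ValueError(f"exon {exon_id} is non-coding")
    order = range(len(model.intervals))
    if model.strand == "-":
        order = reversed(order)
    offset = 0
    for i in order:
        if i == idx:
            break
        offset += model.cds_lengths[i]
    first = offset // 3 + 1
    last = math.ceil((offset + cds_len) / 3)
    return first, last


def domains_lost(
    residues: tuple[int, int], annotations: list[DomainAnnotation]
) -> list[str]:
    """Domain ids whose residue interval overlaps the lost interval.

    Any overlap of the 1-based inclusive intervals counts as "encodes
    part of" the domain.
    """
    lo, hi = residues
    return [
        d.domain_id
        for d in annotations
        if d.start_residue <= hi and lo <= d.end_residue
    ]


def annotate_impacts(
    exon_ids: list[str],
    models: list[GeneModel],
    annotations: list[DomainAnnotation] | None = None,
) -> list[ImpactAnnotation]:
    """Annotate frame status, lost residues and overlapped domains per exon."""
    by_exon = {e: m for m in models for e in m.exon_ids}
    out = []
    for exon_id in exon_ids:
        model = by_exon.get(exon_id)
        if model is None:
            raise KeyError(f"exon {exon_id} not found in any gene model")
        idx = model.exon_index(exon_id)
        cds_len = model.cds_lengths[idx]
        status = frame_status(cds_len)
        if status == "non_coding":
            residues = None
            domains: tuple[str, ...] = ()
        else:
            residues = exon_to_residues(exon_id, model)
            domains = tuple(domains_lost(residues, annotations or []))
        out.append(
            ImpactAnnotation(
                exon_id=exon_id,
                cds_length=cds_len,
                frame_status=status,
                residues_lost=residues,
                domains_overlapped=domains,
            )
        )
    return out


def read_domains_tsv(path: str | Path) -> list[DomainAnnotation]:
    """Read domain annotations: protein_id, domain_id, start_residue, end_residue."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "domain_id", "start_residue", "end_residue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DomainAnnotation(
            domain_id=str(r.domain_id),
            protein_id=str(r.protein_id),
            start_residue=int(r.start_residue),
            end_residue=int(r.end_residue),
        )
        for r in df.itertuples()
    ]
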