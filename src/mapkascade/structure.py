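"""Transcript feature lengths, intron splice phases, and the
kinase-domain-restricted intron pattern.

Phase convention: the phase of an intron is the number of CDS bases
upstream of it (in transcript orientation) modulo 3, so an intron that
interrupts a codon after k bases has phase k mod 3.  Introns lying in
UTRs have no defined phase and are reported as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .models import GeneModel, Span, Transcript

UNDEFINED_PHASE = None


def _oriented(spans: list[Span], strand: str) -> list[Span]:
    return spans if strand == "+" else list(reversed(spans))


def transcript_features(
    gene: GeneModel, transcript_id: str
) -> tuple[int, int, int, int, int]:
    """(cdna_len, utr5_len, cds_len, utr3_len, intron_count), all in
    transcript orientation.  cdna = utr5 + cds + utr3 always holds."""
    t = gene.transcript(transcript_id)
    cdna_len = sum(e - s for s, e in t.exons)
    cds_len = sum(e - s for s, e in t.cds)
    if cds_len == 0:
        return cdna_len, 0, 0, cdna_len, t.intron_count
    cds_start = min(s for s, _ in t.cds)
    cds_end = max(e for _, e in t.cds)
    before = sum(max(0, min(e, cds_start) - s) for s, e in t.exons)
    after = sum(max(0, e - max(s, cds_end)) for s, e in t.exons)
    utr5, utr3 = (before, after) if gene.strand == "+" else (after, before)
    assert utr5 + cds_len + utr3 == cdna_len
    return cdna_len, utr5, cds_len, utr3, t.intron_count


def _cds_bases_upstream(t: Transcript, strand: str, genomic_pos: int) -> int:
    """CDS bases 5' of a genomic boundary position, transcript orientation."""
    if strand == "+":
        return sum(max(0, min(e, genomic_pos) - s) for s, e in t.cds)
    return sum(max(0, e - max(s, genomic_pos)) for s, e in t.cds)


def intron_phases(gene: GeneModel, transcript_id: str) -> list[Optional[int]]:
    """Splice-site phase per intron, 5'->3' in transcript orientation.

    Raises ValueError if the CDS is incomplete (length not divisible by 3).
    """
    t = gene.transcript(transcript_id)
    cds_len = sum(e - s for s, e in t.cds)
    if cds_len == 0 or cds_len % 3 != 0:
        raise ValueError(
            f"{transcript_id}: incomplete CDS (length {cds_len})")
    phases: list[Optional[int]] = []
    for intron_start, intron_end in _oriented(t.introns, gene.strand):
        boundary = intron_start if gene.strand == "+" else intron_end
        upstream = _cds_bases_upstream(t, gene.strand, boundary)
        if upstream == 0 or upstream == cds_len:
            phases.append(UNDEFINED_PHASE)  # UTR intron
        else:
            phases.append(upstream % 3)
    return phases


def domain_intron_pattern(
    gene: GeneModel, transcript_id: str, kinase_domain: Span
) -> tuple[int, list[int]]:
    """Count and phases of introns whose CDS position falls inside the
    kinase-domain codon range (protein coordinates, 0-based half-open)."""
    t = gene.transcript(transcript_id)
    cds_len = sum(e - s for s, e in t.cds)
    dom_start, dom_end = kinase_domain
    if not (0 <= dom_start < dom_end and dom_end * 3 <= cds_len):
        raise ValueError(
            f"{transcript_id}: domain span {kinase_domain} outside CDS "
            f"({cds_len // 3} codons)")
    phases = []
    for intron_start, intron_end in _oriented(t.introns, gene.strand):
        boundary = intron_start if gene.strand == "+" else intron_end
        upstream = _cds_bases_upstream(t, gene.strand, boundary)
        if dom_start * 3 < upstream < dom_end * 3:
            phases.append(upstream % 3)
    return len(phases), phases


@dataclass
class IsoformDiff:
    """Structural difference between two transcripts of one gene."""

    identical: bool
    extra_introns: int          # introns in t2 not in t1, minus converse
    extension: bool             # one isoform extends past the other's end
    end: Optional[str]          # "5prime" / "3prime" / "both" / None
    region: Optional[str]       # "inside" / "outside" the kinase domain


def isoform_structure_diff(
    gene: GeneModel, t1_id: str, t2_id: str,
    kinase_domain: Optional[Span] = None,
) -> IsoformDiff:
    """Classify how two splice isoforms differ: where the extra
    intron(s) sit (5' or 3' end; inside or outside the kinase domain of
    the reference isoform t1) and whether one isoform extends the other."""
    t1, t2 = gene.transcript(t1_id), gene.transcript(t2_id)
    introns1, introns2 = set(t1.introns), set(t2.introns)
    span1 = (min(s for s, _ in t1.exons), max(e for _, e in t1.exons))
    span2 = (min(s for s, _ in t2.exons), max(e for _, e in t2.exons))
    if introns1 == introns2 and span1 == span2:
        return IsoformDiff(True, 0, False, None, None)

    differing = sorted(introns1 ^ introns2)
    extension = span1 != span2
    end: Optional[str] = None
    if differing or extension:
        lo = min(span1[0], span2[0])
        hi = max(span1[1], span2[1])
        mid = (lo + hi) / 2
        points = [(s + e) / 2 for s, e in differing]
        if span1[0] != span2[0]:
            points.append(lo)
        if span1[1] != span2[1]:
            points.append(hi)
        sides = {"5prime" if (p < mid) == (gene.strand == "+") else "3prime"
                 for p in points}
        end = sides.pop() if len(sides) == 1 else "both"

    region: Optional[str] = None
    if kinase_domain is not None and differing:
        dom_genomic = _domain_genomic_intervals(t1, gene.strand, kinase_domain)
        inside = any(
            any(ds < (s + e) / 2 < de for ds, de in dom_genomic)
            for s, e in differing
        )
        region = "inside" if inside else "outside"
    return IsoformDiff(False, len(introns2) - len(introns1), extension, end, region)


def _domain_genomic_intervals(
    t: Transcript, strand: str, kinase_domain: Span
) -> list[Span]:
    """Genomic intervals covered by a protein-coordinate domain span."""
    cds_lo, cds_hi = kinase_domain[0] * 3, kinase_domain[1] * 3
    segs = _oriented(t.cds, strand)
    out: list[Span] = []
    offset = 0
    for s, e in segs:
        seg_len = e - s
        a = max(cds_lo, offset)
        b = min(cds_hi, offset + seg_len)
        if a < b:
            if strand == "+":
                out.append((s + (a - offset), s + (b - offset)))
            else:
                out.append((e - (b - offset), e - (a - offset)))
        offset += seg_len
    return out
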