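"""Core domain containers shared across the pipeline.

Coordinate convention: everything in memory is 0-based half-open
(Python slicing); GFF3 1-based closed coordinates are converted at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

Span = tuple[int, int]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample factor metadata.

    ``values``: DataFrame indexed by gene id, one column per sample.
    ``samples``: DataFrame indexed by sample id, one column per factor
    (condition, organ, temperature, time, zone, ...).  Every column of
    ``values`` must be described in ``samples``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_where(self, **factors) -> list[str]:
        """Sample ids whose metadata matches all given factor=value pairs."""
        mask = pd.Series(True, index=self.samples.index)
        for key, value in factors.items():
            mask &= self.samples[key] == value
        return [s for s in self.samples.index[mask] if s in self.values.columns]


@dataclass
class Transcript:
    """One mRNA: exon and CDS spans in genomic coordinates, sorted by start."""

    transcript_id: str
    exons: list[Span]
    cds: list[Span] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        for s, e in self.exons + self.cds:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty or inverted span ({s},{e})")
        for i in range(1, len(self.exons)):
            if self.exons[i][0] < self.exons[i - 1][1]:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS segment ({s},{e}) outside exon bounds"
                )

    @property
    def introns(self) -> list[Span]:
        """Gaps between consecutive exons, genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")

    def transcript(self, transcript_id: str) -> Transcript:
        try:
            return self.transcripts[transcript_id]
        except KeyError:
            raise KeyError(f"{self.gene_id}: no transcript {transcript_id!r}") from None


@dataclass
class ProteinRecord:
    """A protein with its kinase-domain span and classification metadata."""

    id: str
    sequence: str
    kinase_domain: Optional[Span] = None
    subfamily: str = "unclassified"
    mw_kda: Optional[float] = None
    pi: Optional[float] = None
    localization: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kinase_domain is not None:
            s, e = self.kinase_domain
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"{self.id}: kinase domain span {self.kinase_domain} "
                                 f"outside sequence of length {len(self.sequence)}")

    @property
    def n_ter_len(self) -> int:
        return self.kinase_domain[0] if self.kinase_domain else 0

    @property
    def c_ter_len(self) -> int:
        return len(self.sequence) - self.kinase_domain[1] if self.kinase_domain else 0


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    params: object = None

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")


@dataclass
class DuplicatePair:
    """One duplicated gene pair with divergence statistics (one table row)."""

    gene_a: str
    gene_b: str
    identity_pct: Optional[float] = None
    coverage_frac: Optional[float] = None
    ka: Optional[float] = None
    ks: Optional[float] = None
    ratio: Optional[float] = None
    t_myr: Optional[float] = None
    dup_type: Optional[str] = None  # "TD" or "CSD"
    expr_pcc: Optional[float] = None


@dataclass
class CircadianFit:
    gene_id: str
    condition: str
    best_r: Optional[float]
    best_period: Optional[float]
    best_phase: Optional[float]
    cycling: bool


@dataclass
class MotifHit:
    seq_id: str
    motif: str
    start: int
    strand: str
    matched: str


@dataclass(frozen=True)
class CascadeTriad:
    """A predicted MAPKKK-MKK-MPK pathway with shared localization."""

    mapkkk: str
    mkk: str
    mpk: str
    localization: str
    mr_kkk_mkk: float
    mr_mkk_mpk: float
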