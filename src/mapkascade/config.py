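"""Pipeline configuration: thresholds, motif dictionaries, seeds.

Defaults are the analysis constants used throughout: 70%/70%
identity/coverage for tandem-duplicate calls, mutual-rank cutoff 1500,
circadian correlation cutoff 0.8, q and adjusted-p cutoffs 0.01,
synonymous clock rate 6.1e-9 substitutions/site/year, and 2-kb
promoters.  The 50% / 1e-5 BLAST identity/e-value pair is retained only
as a constant for filtering a user-provided homology table; no BLAST
search is run here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: IUPAC consensi of the cis-acting elements scanned by default.  sp1,
#: G-box, ACE and 3-AF1 have no fixed consensus here and must be
#: supplied by the user if wanted.
DEFAULT_MOTIFS: dict[str, str] = {
    "HSE": "AAAAAATTTC",
    "TCA-element": "GAGAAGAATA",
    "ABRE": "CCGCGTAGGC",
    "motif-IIb": "CCGCCGCGC",
    "CGTCA-motif": "CGTCA",
    "TGACG-motif": "TGACG",
    "circadian": "CAANNNNATC",
}


@dataclass
class PipelineConfig:
    identity_pct: float = 70.0          # tandem-pair identity threshold (%)
    coverage_frac: float = 0.70         # aligned fraction of the longer gene
    max_intervening_genes: int = 1      # "tightly linked" adjacency slack
    blast_identity_pct: float = 50.0    # provided-database filter only
    blast_evalue: float = 1e-5
    mr_cutoff: float = 1500.0
    circadian_r_cutoff: float = 0.8
    q_cutoff: float = 0.01
    p_adj_cutoff: float = 0.01
    log2fc_cutoffs: dict = field(default_factory=lambda: {
        "development": 1.0, "virus": 1.0, "drought": 1.0, "heat": 0.5,
    })
    cv_low_pct: float = 20.0            # "stable expression" band
    cv_high_pct: float = 200.0          # "stage-specific" band
    clock_rate_lambda: float = 6.1e-9   # synonymous subs/site/year
    promoter_len_bp: int = 2000
    pseudocount: float = 1.0            # log2(x + 1) default transform
    motifs: dict = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_cutoff", "p_adj_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.coverage_frac <= 1.0:
            raise ValueError(f"coverage_frac must be in (0,1], got {self.coverage_frac}")
        if self.clock_rate_lambda <= 0:
            raise ValueError("clock_rate_lambda must be > 0")
        if self.promoter_len_bp <= 0:
            raise ValueError("promoter_len_bp must be > 0")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct must be in [0,100]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
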