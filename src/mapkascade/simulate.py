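"""Synthetic-data generators with the statistical structure the
analyses assume: a MAPKKK-like gene family with planted subfamily
signatures and gene structures, duplicate CDS pairs with controlled
synonymous divergence, expression matrices with planted differential
expression, factorial effects, cosine circadian signals and
co-expressed communities, and promoters with planted cis-elements.

Every generator is deterministic under a fixed seed.  Default
parameters mirror the study conditions: 73 genes split 24/43/6 over
MEKK/Raf/ZIK, heat treatments at 12/22/27 degC for 2/24 h, diurnal
series sampled every 4 h over 48 h, 2-kb promoters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import helmert

from . import io as mio
from .config import DEFAULT_MOTIFS
from .evolution import NUCS, STOP_CODONS, _STANDARD, _syn_fraction, translate_cds
from .models import ExpressionMatrix, GeneModel, Transcript
from .motifs import IUPAC
from .classify import SIGNATURES

_AA = sorted("ACDEFGHIKLMNPQRSTVWY")
_CODONS_FOR = {}
for codon, aa in _STANDARD.forward_table.items():
    if set(codon) <= set(NUCS):
        _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()

#: Intron-count ranges per subfamily (inclusive), as observed for the
#: three MAPKKK subfamilies.
INTRON_RANGE = {"MEKK": (0, 24), "Raf": (1, 16), "ZIK": (1, 8)}


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study; defaults mirror the study design."""

    n_genes: int = 73
    subfamily_mix: dict = field(default_factory=lambda: {
        "MEKK": 24 / 73, "Raf": 43 / 73, "ZIK": 6 / 73})
    duplicate_pairs: list = field(default_factory=lambda: [
        (0.6532, True), (0.3825, True), (0.1896, True)])  # (target Ks, tandem)
    temperature_levels: tuple = (12, 22, 27)
    time_levels: tuple = (2, 24)
    effect_log2: float = 2.0
    noise_sd: float = 0.5
    circadian_period_h: float = 24.0
    circadian_interval_h: float = 4.0
    circadian_duration_h: float = 48.0
    circadian_amplitude: float = 5.0
    circadian_noise_sd: float = 1.0
    triad_corr: float = 0.95
    promoter_len_bp: int = 2000
    promoter_insertions: dict = field(
        default_factory=lambda: {name: 1 for name in DEFAULT_MOTIFS})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if abs(sum(self.subfamily_mix.values()) - 1.0) > 1e-9:
            raise ValueError("subfamily proportions must sum to 1")
        if self.noise_sd < 0 or self.circadian_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        n_points = self.circadian_duration_h / self.circadian_interval_h
        if abs(n_points - round(n_points)) > 1e-9:
            raise ValueError("sampling interval must divide duration")


# ------------------------------------------------------------ gene family

def _sample_pattern(pattern: tuple[str, ...], rng) -> str:
    return "".join(
        rng.choice(_AA) if allowed == "x" else allowed[rng.integers(len(allowed))]
        for allowed in pattern
    )


def _gene_geometry(subfamily: str, dom_len: int, rng) -> tuple[int, int]:
    """(n_ter_len, c_ter_len) respecting the subfamily position rules."""
    if subfamily == "ZIK":
        return int(rng.integers(2, 36)), int(rng.integers(100, 400))
    if subfamily == "Raf":
        c_ter = int(rng.integers(0, 41))
        total = int(rng.integers(max(480, int((dom_len + c_ter) / 0.65)), 1200))
        return total - dom_len - c_ter, c_ter
    n_ter = int(rng.integers(0, 500))
    return n_ter, int(rng.integers(0, 400))


def simulate_gene_family(
    spec: Optional[SimulationSpec] = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[GeneModel], pd.DataFrame]:
    """Synthetic protein + CDS + gene-structure set.

    Each protein embeds exactly one planted subfamily signature at a
    position consistent with that subfamily's domain-position rule; the
    CDS back-translates the protein; gene models carry intron counts
    drawn from the subfamily's observed range.  Returns (proteins, cds,
    gene models, truth table).
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    subfamilies = sorted(spec.subfamily_mix)
    probs = np.array([spec.subfamily_mix[s] for s in subfamilies])
    proteins, cds_records, genes, truth = [], [], [], []
    genome_cursor: dict[str, int] = {}
    from .structure import intron_phases  # local import avoids cycle

    for idx in range(spec.n_genes):
        gene_id = f"SYN{idx + 1:03d}"
        subfamily = subfamilies[rng.choice(len(subfamilies), p=probs)]
        dom_len = int(rng.integers(240, 266))
        n_ter, c_ter = _gene_geometry(subfamily, dom_len, rng)
        length = n_ter + dom_len + c_ter
        seq = list(rng.choice(_AA, size=length))
        pattern = SIGNATURES[subfamily]
        sig = _sample_pattern(pattern, rng)
        sig_pos = n_ter + dom_len - len(sig) - int(rng.integers(10, 40))
        seq[sig_pos:sig_pos + len(sig)] = list(sig)
        protein = "".join(seq)
        cds = "".join(_CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))]
                      for aa in protein)

        chrom = f"chr{idx % 5 + 1}"
        n_introns_lo, n_introns_hi = INTRON_RANGE[subfamily]
        n_introns = int(rng.integers(n_introns_lo, n_introns_hi + 1))
        gene = _build_gene_model(gene_id, chrom, cds_len=len(cds),
                                 n_introns=n_introns, rng=rng,
                                 start=genome_cursor.get(chrom, 1000))
        genome_cursor[chrom] = max(
            e for t in gene.transcripts.values() for _, e in t.exons) + 5000

        tid = f"{gene_id}.1"
        phases = intron_phases(gene, tid)
        proteins.append((gene_id, protein))
        cds_records.append((gene_id, cds))
        genes.append(gene)
        truth.append({
            "gene_id": gene_id, "transcript_id": tid, "subfamily": subfamily,
            "dom_start": n_ter, "dom_end": n_ter + dom_len,
            "n_introns": n_introns,
            "phases": ",".join("U" if p is None else str(p) for p in phases),
        })
    return proteins, cds_records, genes, pd.DataFrame(truth)


def _build_gene_model(gene_id: str, chrom: str, cds_len: int,
                      n_introns: int, rng, start: int) -> GeneModel:
    """Gene model whose CDS has the requested intron count; UTRs are
    added (contiguous with the terminal exons) about half the time."""
    strand = "+" if rng.random() < 0.5 else "-"
    utr5 = int(rng.integers(50, 400)) if rng.random() < 0.5 else 0
    utr3 = int(rng.integers(50, 400)) if rng.random() < 0.5 else 0
    cuts = sorted(rng.choice(np.arange(3, cds_len - 2), size=n_introns,
                             replace=False)) if n_introns else []
    intron_lens = [int(rng.integers(60, 301)) for _ in cuts]

    # lay out in transcript orientation, then mirror for minus strand
    exons_t, cds_t = [], []
    pos = 0
    prev = 0
    boundaries = list(cuts) + [cds_len]
    first = True
    for cut, ilen in zip(boundaries, intron_lens + [0]):
        seg = cut - prev
        exon_start = pos - (utr5 if first else 0)
        cds_t.append((pos, pos + seg))
        exon_end = pos + seg + (utr3 if cut == cds_len else 0)
        exons_t.append((exon_start, exon_end))
        pos += seg + ilen
        prev = cut
        first = False
    # last exon holds the 3' UTR; first the 5' UTR (shift to 0-origin)
    shift = utr5
    exons_t = [(s + shift, e + shift) for s, e in exons_t]
    cds_t = [(s + shift, e + shift) for s, e in cds_t]
    total = exons_t[-1][1]
    if strand == "-":
        exons_t = [(total - e, total - s) for s, e in exons_t]
        cds_t = [(total - e, total - s) for s, e in cds_t]
    exons = sorted((s + start, e + start) for s, e in exons_t)
    cds = sorted((s + start, e + start) for s, e in cds_t)
    t = Transcript(f"{gene_id}.1", exons, cds)
    return GeneModel(gene_id, chrom, strand, {t.transcript_id: t})


# -------------------------------------------------------- duplicate pairs

def _neighbors(codon: str, synonymous: bool) -> list[str]:
    aa = _STANDARD.forward_table[codon]
    out = []
    for pos in range(3):
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            if (_STANDARD.forward_table[alt] == aa) == synonymous:
                out.append(alt)
    return sorted(out)


def simulate_duplicate_pair(
    ancestral_cds: str, target_ks: float, seed: int, target_ka: float = 0.0,
) -> tuple[str, str]:
    """Duplicate a CDS and apply Poisson numbers of synonymous (and,
    optionally, nonsynonymous) single-nucleotide substitutions so the
    NG86 estimate is near the target divergence.  Substitutions pick
    uniformly among same-class single-nucleotide codon neighbors,
    rejecting stops.  With ``target_ka`` 0 the NG86 Ka is exactly 0."""
    if target_ks < 0 or target_ka < 0:
        raise ValueError("target divergence must be >= 0")
    if len(ancestral_cds) % 3:
        raise ValueError("ancestral CDS length not divisible by 3")
    codons = [ancestral_cds[i:i + 3] for i in range(0, len(ancestral_cds), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("ancestral CDS contains a stop codon")
    rng = np.random.default_rng(seed)
    ancestral = list(codons)
    s_sites = sum(_syn_fraction(c) for c in codons)
    n_sites = 3 * len(codons) - s_sites
    for synonymous, n_events in (
        (True, rng.poisson(target_ks * s_sites)),
        (False, rng.poisson(target_ka * n_sites)),
    ):
        applied = 0
        while applied < n_events:
            i = int(rng.integers(len(codons)))
            options = _neighbors(codons[i], synonymous)
            if synonymous and target_ka == 0:
                # keep NG86 Ka at exactly 0: refuse multi-hit states whose
                # pathway average vs the ancestor counts a nonsynonymous
                # step (e.g. TTA -> TTG -> CTG read as TTA vs CTG)
                from .evolution import _pathway_diffs
                options = [c for c in options
                           if _pathway_diffs(ancestral[i], c)[1] == 0]
            if not options:
                continue
            codons[i] = options[rng.integers(len(options))]
            applied += 1
    return ancestral_cds, "".join(codons)


def random_cds(n_codons: int, seed: int) -> str:
    """Random stop-free CDS (uniform over sense codons)."""
    rng = np.random.default_rng(seed)
    sense = sorted(c for c in _STANDARD.forward_table if set(c) <= set(NUCS))
    return "".join(sense[rng.integers(len(sense))] for _ in range(n_codons))


# ------------------------------------------------------------- expression

def simulate_two_group(
    n_genes: int = 100,
    n_planted: int = 10,
    effect_log2: float = 2.0,
    n_reps: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
    pseudocount: float = 1.0,
    condition: str = "development",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-group design with the first ``n_planted`` genes shifted by
    exactly ``effect_log2`` on the log2(x + pseudocount) scale."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    base = rng.uniform(2.0, 50.0, size=n_genes)
    mean_b = base.copy()
    mean_b[:n_planted] = (base[:n_planted] + pseudocount) * 2.0 ** effect_log2 - pseudocount
    cols_a = [f"A_r{r + 1}" for r in range(n_reps)]
    cols_b = [f"B_r{r + 1}" for r in range(n_reps)]
    values = np.concatenate([
        base[:, None] + rng.normal(0, noise_sd, (n_genes, n_reps)),
        mean_b[:, None] + rng.normal(0, noise_sd, (n_genes, n_reps)),
    ], axis=1)
    if noise_sd > 0:
        values = np.clip(values, 0.0, None)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=cols_a + cols_b),
        samples=pd.DataFrame({
            "group": ["A"] * n_reps + ["B"] * n_reps,
            "condition": condition,
        }, index=cols_a + cols_b),
    )
    truth = pd.DataFrame({"gene": genes[:n_planted], "effect_log2": effect_log2})
    return matrix, truth


def simulate_factorial(
    n_genes: int = 60,
    n_planted_a: int = 5,
    n_planted_b: int = 5,
    n_planted_ab: int = 5,
    levels_a: Sequence = (12, 22, 27),
    levels_b: Sequence = (2, 24),
    n_reps: int = 3,
    effect: float = 4.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Balanced two-factor design (defaults: temperature x time) with
    disjoint gene sets carrying main effects and a pure interaction."""
    if n_planted_a + n_planted_b + n_planted_ab > n_genes:
        raise ValueError("planted gene sets exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    set_a = set(range(n_planted_a))
    set_b = set(range(n_planted_a, n_planted_a + n_planted_b))
    set_ab = set(range(n_planted_a + n_planted_b,
                       n_planted_a + n_planted_b + n_planted_ab))
    base = rng.uniform(5.0, 20.0, size=n_genes)
    cols, meta = [], []
    data = np.zeros((n_genes, len(levels_a) * len(levels_b) * n_reps))
    col = 0
    for ia, la in enumerate(levels_a):
        for ib, lb in enumerate(levels_b):
            for r in range(n_reps):
                name = f"T{la}_H{lb}_r{r + 1}"
                cols.append(name)
                meta.append({"sample": name, "temperature": la, "time_h": lb,
                             "condition": "heat"})
                shift = np.zeros(n_genes)
                shift[list(set_a)] += effect * ia
                shift[list(set_b)] += effect * ib
                # product of zero-sum contrasts: pure interaction with
                # exactly zero marginal main effects
                shift[list(set_ab)] += effect * (ia - (len(levels_a) - 1) / 2) \
                    * (ib - (len(levels_b) - 1) / 2)
                data[:, col] = base + shift + rng.normal(0, noise_sd, n_genes)
                col += 1
    matrix = ExpressionMatrix(
        values=pd.DataFrame(data, index=genes, columns=cols),
        samples=pd.DataFrame(meta).set_index("sample"),
    )
    truth = pd.DataFrame({
        "gene": genes,
        "effect_a": [i in set_a for i in range(n_genes)],
        "effect_b": [i in set_b for i in range(n_genes)],
        "effect_ab": [i in set_ab for i in range(n_genes)],
    }).set_index("gene")
    return matrix, truth


def make_circadian_assignments(
    n_genes: int = 73, n_any: int = 41, n_all: int = 7,
    conditions: Sequence[str] = ("LDHH", "LDHC", "LLHC"),
) -> dict[str, set[str]]:
    """Cycling-condition assignment with exactly ``n_all`` genes cycling
    in every condition and ``n_any`` cycling in at least one."""
    if not 0 <= n_all <= n_any <= n_genes:
        raise ValueError("need 0 <= n_all <= n_any <= n_genes")
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    out: dict[str, set[str]] = {}
    for i, gene in enumerate(genes):
        if i < n_all:
            out[gene] = set(conditions)
        elif i < n_any:
            out[gene] = {conditions[i % (len(conditions) - 1)]} \
                if len(conditions) > 1 else {conditions[0]}
        else:
            out[gene] = set()
    return out


def simulate_circadian(
    assignments: Mapping[str, set],
    conditions: Sequence[str] = ("LDHH", "LDHC", "LLHC"),
    period_h: float = 24.0,
    interval_h: float = 4.0,
    duration_h: float = 48.0,
    amplitude: float = 5.0,
    noise_sd: float = 1.0,
    baseline: float = 10.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Cosine time courses for genes assigned to cycle per condition;
    non-cycling series are baseline + noise."""
    rng = np.random.default_rng(seed)
    genes = list(assignments)
    times = np.arange(0.0, duration_h + 1e-9, interval_h)
    cols, meta = [], []
    for cond in conditions:
        for t in times:
            name = f"{cond}_t{int(t):02d}"
            cols.append(name)
            meta.append({"sample": name, "condition": cond, "time_h": t})
    data = np.zeros((len(genes), len(cols)))
    phases = {g: float(rng.integers(0, int(period_h))) for g in genes}
    col = 0
    for cond in conditions:
        for t in times:
            for gi, gene in enumerate(genes):
                if cond in assignments[gene]:
                    data[gi, col] = baseline + amplitude * np.cos(
                        2 * np.pi * (t - phases[gene]) / period_h)
                else:
                    data[gi, col] = baseline
            col += 1
    data += rng.normal(0, noise_sd, data.shape)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(data, index=genes, columns=cols),
        samples=pd.DataFrame(meta).set_index("sample"),
    )
    truth = pd.DataFrame({
        "gene": genes,
        **{cond: [cond in assignments[g] for g in genes] for cond in conditions},
    }).set_index("gene")
    return matrix, truth


def simulate_coexpression(
    memberships: Mapping[str, Sequence[str]],
    n_background: int = 50,
    n_samples: int = 40,
    rho: float = 0.95,
    seed: int = 0,
    background_prefix: str = "bg",
) -> ExpressionMatrix:
    """Latent-factor co-expression: each gene listed in ``memberships``
    loads its factors with total planted variance ``rho``; background
    genes are independent noise."""
    rng = np.random.default_rng(seed)
    factors = sorted({f for fs in memberships.values() for f in fs})
    z = {f: rng.normal(size=n_samples) for f in factors}
    rows, genes = [], []
    for gene in memberships:
        fs = memberships[gene]
        signal = np.sum([z[f] for f in fs], axis=0) / np.sqrt(len(fs))
        rows.append(np.sqrt(rho) * signal
                    + np.sqrt(1 - rho) * rng.normal(size=n_samples))
        genes.append(gene)
    for i in range(n_background):
        rows.append(rng.normal(size=n_samples))
        genes.append(f"{background_prefix}{i + 1:04d}")
    cols = [f"s{j + 1:03d}" for j in range(n_samples)]
    return ExpressionMatrix(
        values=pd.DataFrame(np.array(rows), index=genes, columns=cols),
        samples=pd.DataFrame({"condition": "pooled"}, index=cols),
    )


# Synthetic ten-cascade co-expression design.  The membership map wires
# shared MKK hubs so that exactly ten colocalized MAPKKK-MKK-MPK triads
# exist: one chloroplast triad and nine cytoplasmic ones.  Gene names
# follow the field's Brachypodium nomenclature purely as a synthetic
# stand-in; no real expression data is involved.
CASCADE_MEMBERSHIPS: dict[str, list[str]] = {
    "BdMAPKKK32": ["fA"], "BdMKK10-5": ["fA"], "BdMPK11": ["fA"],
    "BdMAPKKK25": ["fB"], "BdMKK3-3": ["fB"],
    "BdMKK6": ["fC"],
    "BdMAPKKK51": ["fB", "fC", "fD"],
    "BdMPK17": ["fB", "fC", "fD"],
    "BdMAPKKK68": ["fD"], "BdMAPKKK4": ["fD"], "BdMKK3-1": ["fD"],
    "BdMPK16": ["fD"],
}

CASCADE_FAMILIES: dict[str, str] = {
    **{g: "MAPKKK" for g in CASCADE_MEMBERSHIPS if g.startswith("BdMAPKKK")},
    **{g: "MKK" for g in CASCADE_MEMBERSHIPS if g.startswith("BdMKK")},
    **{g: "MPK" for g in CASCADE_MEMBERSHIPS if g.startswith("BdMPK")},
}

CASCADE_LOCALIZATIONS: dict[str, str] = {
    g: ("Chloroplast" if g in {"BdMAPKKK32", "BdMKK10-5", "BdMPK11"}
        else "Cytoplasm")
    for g in CASCADE_MEMBERSHIPS
}


def cascade_demo_matrix(
    n_background: int = 30, unique_weight: float = 0.3,
) -> tuple[ExpressionMatrix, dict[str, str], dict[str, str]]:
    """Deterministic co-expression fixture realizing the ten-cascade
    topology exactly.

    Gene vectors are built from orthonormal zero-mean (Helmert) basis
    vectors: one per latent factor plus one unique component per gene,
    so every pairwise Pearson correlation is an exact cosine
    (cross-community correlations are exactly zero) and the resulting
    mutual-rank network is seed-independent.  Background genes are named
    to sort before the pathway genes so zero-correlation rank ties
    resolve away from spurious edges.
    """
    planted = list(CASCADE_MEMBERSHIPS)
    factors = sorted({f for fs in CASCADE_MEMBERSHIPS.values() for f in fs})
    n_basis = len(factors) + len(planted) + n_background + 1
    n_samples = n_basis + 1
    basis = helmert(n_samples)  # (n_samples-1, n_samples), orthonormal rows
    z = {f: basis[i] for i, f in enumerate(factors)}
    # A weak common component separates the correlation tiers strictly:
    # pathway genes correlate more with every background gene than with
    # pathway genes of other communities, so cross-community ranks are
    # large by construction rather than by floating-point tie noise.
    common = basis[len(factors)]
    rows, genes = [], []
    for i, gene in enumerate(planted):
        fs = CASCADE_MEMBERSHIPS[gene]
        vec = np.sum([z[f] for f in fs], axis=0)
        vec = vec + unique_weight * basis[len(factors) + 1 + i] + 0.05 * common
        rows.append(vec)
        genes.append(gene)
    offset = len(factors) + 1 + len(planted)
    for i in range(n_background):
        rows.append(basis[offset + i] + (0.2 + 0.002 * i) * common)
        genes.append(f"Bd{i + 1:04d}")
    cols = [f"s{j + 1:03d}" for j in range(n_samples)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(np.array(rows) + 10.0, index=genes, columns=cols),
        samples=pd.DataFrame({"condition": "pooled"}, index=cols),
    )
    families = {**CASCADE_FAMILIES,
                **{g: "other" for g in genes if g not in CASCADE_FAMILIES}}
    locs = {**CASCADE_LOCALIZATIONS,
            **{g: "none" for g in genes if g not in CASCADE_LOCALIZATIONS}}
    return matrix, families, locs


# -------------------------------------------------------------- promoters

def simulate_promoters(
    n_seqs: int = 10,
    length: int = 2000,
    insertions: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    motifs: Optional[Mapping[str, str]] = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Uniform-ACGT backgrounds with each requested element inserted at
    recorded, non-overlapping positions and random strands."""
    motifs = dict(DEFAULT_MOTIFS if motifs is None else motifs)
    insertions = dict(insertions if insertions is not None else {})
    rng = np.random.default_rng(seed)
    from .motifs import reverse_complement_iupac
    records, truth = [], []
    for i in range(n_seqs):
        seq_id = f"prom{i + 1:03d}"
        seq = list(rng.choice(list("ACGT"), size=length))
        occupied: list[tuple[int, int]] = []
        for name, count in sorted(insertions.items()):
            consensus = motifs[name]
            for _ in range(count):
                instance = "".join(
                    sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))]
                    for c in consensus.upper())
                strand = "+" if rng.random() < 0.5 else "-"
                planted = instance if strand == "+" else \
                    reverse_complement_iupac(instance)
                for _attempt in range(1000):
                    start = int(rng.integers(0, length - len(planted) + 1))
                    span = (start, start + len(planted))
                    if all(span[1] <= s or span[0] >= e for s, e in occupied):
                        break
                else:  # pragma: no cover - essentially impossible at 2 kb
                    raise RuntimeError("could not place motif")
                occupied.append(span)
                seq[span[0]:span[1]] = list(planted)
                truth.append({"seq_id": seq_id, "motif": name, "start": start,
                              "strand": strand, "instance": instance})
        records.append((seq_id, "".join(seq)))
    return records, pd.DataFrame(
        truth, columns=["seq_id", "motif", "start", "strand", "instance"])


# ------------------------------------------------------------- full bundle

def simulate_all(spec: Optional[SimulationSpec] = None, outdir=None) -> dict:
    """Generate the full synthetic study; optionally write it to a
    directory (proteins.faa, cds.fna, genes.gff3, expr.tsv, samples.tsv,
    promoters.fna, truth/*.tsv)."""
    spec = spec or SimulationSpec()
    proteins, cds, genes, family_truth = simulate_gene_family(spec)
    assignments = make_circadian_assignments(
        min(spec.n_genes, 73), min(41, spec.n_genes), min(7, spec.n_genes))
    circ_matrix, circ_truth = simulate_circadian(
        assignments,
        period_h=spec.circadian_period_h, interval_h=spec.circadian_interval_h,
        duration_h=spec.circadian_duration_h, amplitude=spec.circadian_amplitude,
        noise_sd=spec.circadian_noise_sd, seed=spec.seed + 1)
    de_matrix, de_truth = simulate_two_group(
        n_genes=spec.n_genes, n_planted=max(1, spec.n_genes // 10),
        effect_log2=spec.effect_log2, noise_sd=spec.noise_sd, seed=spec.seed + 2)
    promoters, promoter_truth = simulate_promoters(
        n_seqs=min(spec.n_genes, 20), length=spec.promoter_len_bp,
        insertions=spec.promoter_insertions, seed=spec.seed + 3)
    pairs = []
    for i, (target_ks, tandem) in enumerate(spec.duplicate_pairs):
        ancestral = random_cds(300, seed=spec.seed + 10 + i)
        a, b = simulate_duplicate_pair(ancestral, target_ks, seed=spec.seed + 20 + i)
        pairs.append({"pair": i + 1, "target_ks": target_ks, "tandem": tandem,
                      "cds_a": a, "cds_b": b})
    bundle = {
        "proteins": proteins, "cds": cds, "genes": genes,
        "family_truth": family_truth,
        "circadian": (circ_matrix, circ_truth),
        "expression": (de_matrix, de_truth),
        "promoters": (promoters, promoter_truth),
        "duplicate_pairs": pd.DataFrame(pairs),
    }
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
        mio.write_fasta(proteins, outdir / "proteins.faa")
        mio.write_fasta(cds, outdir / "cds.fna")
        mio.write_gff3(genes, outdir / "genes.gff3")
        mio.write_expression_table(de_matrix, outdir / "expr.tsv",
                                   outdir / "samples.tsv")
        mio.write_expression_table(circ_matrix, outdir / "circadian_expr.tsv",
                                   outdir / "circadian_samples.tsv")
        mio.write_fasta(promoters, outdir / "promoters.fna")
        family_truth.to_csv(outdir / "truth" / "family.tsv", sep="\t", index=False)
        circ_truth.to_csv(outdir / "truth" / "circadian.tsv", sep="\t")
        de_truth.to_csv(outdir / "truth" / "expression.tsv", sep="\t", index=False)
        promoter_truth.to_csv(outdir / "truth" / "promoters.tsv", sep="\t",
                              index=False)
        bundle["duplicate_pairs"].to_csv(outdir / "truth" / "duplicates.tsv",
                                         sep="\t", index=False)
    return bundle
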