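"""Duplicate-pair evolution machinery: global protein alignment,
identity/coverage statistics, tandem-duplication classification,
protein-guided codon alignment, Nei-Gojobori (1986) Ka/Ks with
Jukes-Cantor correction, synonymous-clock dating, and neighbor-joining
trees.

The NG86 estimator counts synonymous and nonsynonymous sites per codon
as the fraction of one-nucleotide changes that preserve the encoded
amino acid (changes creating a stop codon count as nonsynonymous),
averages site totals over both sequences, averages difference counts
over all minimal mutational pathways for multi-hit codons (pathways
passing through a stop codon are excluded when any stop-free pathway
exists), and applies the Jukes-Cantor correction
d = -(3/4) ln(1 - 4p/3).

Divergence dating uses the synonymous molecular clock T = Ks / (2 * lambda)
with lambda in substitutions/site/year; the default rate is 6.1e-9.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .models import DuplicatePair, PairwiseAlignment

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_STANDARD.stop_codons)
NUCS = "ACGT"


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (no terminal stop expected)."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate())


# ------------------------------------------------------------ alignment

@dataclass
class AlignParams:
    """Scoring for global affine-gap alignment.  Either a named
    substitution matrix (protein) or match/mismatch scores (nucleotide)."""

    matrix: Optional[str] = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5


def global_align(seq_a: str, seq_b: str,
                 params: Optional[AlignParams] = None) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch global alignment with affine gaps."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    params = params or AlignParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if params.matrix:
        aligner.substitution_matrix = Align.substitution_matrices.load(params.matrix)
        alphabet = set(str(aligner.substitution_matrix.alphabet))
    else:
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
        alphabet = set(NUCS) | {"N"}
    bad = (set(seq_a) | set(seq_b)) - alphabet
    if bad:
        raise ValueError(f"invalid alignment alphabet characters: {sorted(bad)}")
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    return PairwiseAlignment(aligned_a=a, aligned_b=b, score=aln.score, params=params)


def pair_identity_coverage(alignment: PairwiseAlignment,
                           len_a: int, len_b: int) -> tuple[float, float]:
    """Identity (% matching columns, double-gap columns excluded) and
    coverage (columns aligning residue to residue over the longer
    sequence length)."""
    a, b = alignment.aligned_a, alignment.aligned_b
    cols = sum(1 for x, y in zip(a, b) if not (x == "-" and y == "-"))
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    paired = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    identity = 100.0 * matches / cols if cols else 0.0
    coverage = paired / max(len_a, len_b)
    return identity, coverage


# --------------------------------------------------- tandem duplication

def classify_tandem(
    pairs: pd.DataFrame,
    coords: pd.DataFrame,
    identity_pct: float = 70.0,
    coverage_frac: float = 0.70,
    max_intervening: int = 1,
) -> tuple[pd.DataFrame, int]:
    """Call tandem duplicates among candidate pairs.

    ``pairs`` needs columns gene_a, gene_b, identity_pct, coverage_frac;
    ``coords`` is indexed by gene id with columns chrom and order (the
    gene's ordinal position along its chromosome).  A pair is tandem iff
    both genes sit on one chromosome separated by at most
    ``max_intervening`` genes, with identity and coverage above the
    thresholds.  Tightly linked qualifying pairs are grouped into
    clusters and one duplication event is counted per cluster; the
    returned frame lists every qualifying pair with its cluster id.
    """
    unknown = ({*pairs["gene_a"], *pairs["gene_b"]}) - set(coords.index)
    if unknown:
        raise KeyError(f"unknown gene id(s): {sorted(unknown)}")
    kept = []
    for row in pairs.itertuples(index=False):
        ca, cb = coords.loc[row.gene_a], coords.loc[row.gene_b]
        if ca["chrom"] != cb["chrom"]:
            continue
        if abs(int(ca["order"]) - int(cb["order"])) - 1 > max_intervening:
            continue
        if row.identity_pct <= identity_pct or row.coverage_frac <= coverage_frac:
            continue
        kept.append((row.gene_a, row.gene_b, row.identity_pct, row.coverage_frac))

    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, *_ in kept:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        parent[find(a)] = find(b)
    roots = sorted({find(g) for g in parent})
    cluster_id = {root: i + 1 for i, root in enumerate(roots)}
    out = pd.DataFrame(kept, columns=["gene_a", "gene_b", "identity_pct",
                                      "coverage_frac"])
    out["cluster"] = [cluster_id[find(a)] for a in out["gene_a"]] if kept else []
    out["dup_type"] = "TD"
    return out, len(roots)


# ------------------------------------------------------ codon alignment

def codon_align(protein_alignment: PairwiseAlignment,
                cds_a: str, cds_b: str) -> tuple[str, str]:
    """Back-translate a protein alignment onto the CDS pair: every
    protein gap becomes a 3-base gap, so codon columns align
    residue-wise.  Raises ValueError (naming the position) when a CDS
    does not translate to its aligned protein."""
    out = []
    for aligned, cds, label in ((protein_alignment.aligned_a, cds_a, "a"),
                                (protein_alignment.aligned_b, cds_b, "b")):
        protein = aligned.replace("-", "")
        translated = translate_cds(cds)
        if translated != protein:
            diff = next((i for i, (x, y) in enumerate(zip(translated, protein))
                         if x != y), min(len(translated), len(protein)))
            raise ValueError(
                f"sequence {label}: CDS translation differs from aligned "
                f"protein at residue {diff}")
        codons = iter(cds[i:i + 3] for i in range(0, len(cds), 3))
        out.append("".join("---" if aa == "-" else next(codons) for aa in aligned))
    return out[0], out[1]


# ----------------------------------------------------------------- NG86

def _syn_fraction(codon: str) -> float:
    """Synonymous sites of a codon: per position, the fraction of the 3
    one-nucleotide changes that are synonymous (stops nonsynonymous)."""
    aa = _STANDARD.forward_table.get(codon)
    if aa is None:
        raise ValueError(f"stop or invalid codon {codon!r}")
    syn = 0.0
    for pos in range(3):
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if _STANDARD.forward_table.get(alt) == aa:
                syn += 1.0
    return syn / 3.0


def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous / nonsynonymous difference counts over all
    minimal mutational pathways between two codons."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(positions):
        current = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
            aa_from = _STANDARD.forward_table.get(current)
            aa_to = _STANDARD.forward_table.get(nxt)
            if aa_from is not None and aa_from == aa_to:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        results.append((sd, nd, through_stop))
    clean = [(s, n) for s, n, stop in results if not stop]
    use = clean if clean else [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(codon_aln_a: str, codon_aln_b: str
              ) -> tuple[float, float, Optional[float]]:
    """Nei-Gojobori (1986) (Ka, Ks, Ka/Ks) from an aligned codon pair.

    Gapped codon columns are skipped.  Returns ratio ``None`` when Ks is
    zero or either distance is saturated (p >= 3/4 gives NaN).
    """
    if len(codon_aln_a) != len(codon_aln_b):
        raise ValueError("aligned CDS lengths differ")
    if len(codon_aln_a) % 3:
        raise ValueError("aligned CDS length not divisible by 3")
    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(codon_aln_a), 3):
        ca, cb = codon_aln_a[i:i + 3], codon_aln_b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            if i + 3 == len(codon_aln_a):
                continue  # terminal stop tolerated
            raise ValueError(f"internal stop codon at nucleotide {i}")
        n_codons += 1
        s_sites_a += _syn_fraction(ca)
        s_sites_b += _syn_fraction(cb)
        d_s, d_n = _pathway_diffs(ca, cb)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise ValueError("no ungapped codon columns")
    s_sites = (s_sites_a + s_sites_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    return ka, ks, kaks_ratio(ka, ks)


def kaks_ratio(ka: float, ks: float) -> Optional[float]:
    """Ka/Ks; ``None`` (undefined) when Ks is 0 or either input is NaN."""
    if ka is None or ks is None or math.isnan(ka) or math.isnan(ks) or ks == 0:
        return None
    return ka / ks


def divergence_time(ks: float, lambda_rate: float = 6.1e-9) -> float:
    """Duplication age in million years under the synonymous clock
    T = Ks / (2 * lambda)."""
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    if lambda_rate <= 0:
        raise ValueError("lambda must be > 0")
    return ks / (2.0 * lambda_rate) / 1e6


def analyze_pair(gene_a: str, gene_b: str, protein_a: str, protein_b: str,
                 cds_a: str, cds_b: str,
                 lambda_rate: float = 6.1e-9,
                 params: Optional[AlignParams] = None) -> DuplicatePair:
    """Full per-pair workup: protein alignment -> identity/coverage ->
    codon alignment -> NG86 -> clock dating."""
    aln = global_align(protein_a, protein_b, params)
    identity, coverage = pair_identity_coverage(aln, len(protein_a), len(protein_b))
    ca, cb = codon_align(aln, cds_a, cds_b)
    ka, ks, ratio = ng86_kaks(ca, cb)
    t = divergence_time(ks, lambda_rate) if not math.isnan(ks) else math.nan
    return DuplicatePair(gene_a=gene_a, gene_b=gene_b, identity_pct=identity,
                         coverage_frac=coverage, ka=ka, ks=ks, ratio=ratio,
                         t_myr=t)


# -------------------------------------------------------- neighbor joining

def nj_tree(dist, labels: Sequence[str]) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string with branch
    lengths.  Ties in the Q criterion break on the lexicographically
    smallest label pair, so the output is deterministic."""
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / label size mismatch")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix not symmetric")
    if (d < 0).any() or not np.allclose(np.diag(d), 0):
        raise ValueError("distances must be non-negative with zero diagonal")

    if n == 2:
        half = d[0, 1] / 2.0
        return f"({labels[0]}:{half:.10g},{labels[1]}:{half:.10g});"

    nodes = [str(x) for x in labels]   # newick fragment per active node
    names = [str(x) for x in labels]   # tie-break keys
    dm = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        totals = dm.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dm[i, j] - totals[i] - totals[j]
                key = (q, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * dm[i, j] + (totals[i] - totals[j]) / (2.0 * (m - 2))
        vj = dm[i, j] - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        merged = f"({nodes[i]}:{vi:.10g},{nodes[j]}:{vj:.10g})"
        new_name = min(names[i], names[j])
        new_row = np.array([
            0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
            for k in range(m) if k not in (i, j)
        ])
        keep = [k for k in range(m) if k not in (i, j)]
        dm = dm[np.ix_(keep, keep)]
        dm = np.pad(dm, ((0, 1), (0, 1)))
        dm[-1, :-1] = new_row
        dm[:-1, -1] = new_row
        nodes = [nodes[k] for k in keep] + [merged]
        names = [names[k] for k in keep] + [new_name]

    # terminal trifurcation via the three-point formula
    a, b, c = dm[0, 1], dm[0, 2], dm[1, 2]
    va = max((a + b - c) / 2.0, 0.0)
    vb = max((a + c - b) / 2.0, 0.0)
    vc = max((b + c - a) / 2.0, 0.0)
    return (f"({nodes[0]}:{va:.10g},{nodes[1]}:{vb:.10g},"
            f"{nodes[2]}:{vc:.10g});")


def identity_distance_matrix(proteins: list[tuple[str, str]],
                             params: Optional[AlignParams] = None
                             ) -> tuple[np.ndarray, list[str]]:
    """1 - fractional identity from global alignments; default NJ input."""
    names = [name for name, _ in proteins]
    n = len(proteins)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(proteins[i][1], proteins[j][1], params)
            ident, _ = pair_identity_coverage(
                aln, len(proteins[i][1]), len(proteins[j][1]))
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return d, names
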