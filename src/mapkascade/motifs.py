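"""IUPAC degenerate-consensus scanning of promoter sequences.

Both strands are scanned; a minus-strand hit is reported at its
plus-strand start coordinate.  An 'N' in the *sequence* matches only
motif positions whose allowed set is all four bases, so ambiguous
sequence never creates specific-element hits.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .config import DEFAULT_MOTIFS
from .models import MotifHit

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement_iupac(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def _allowed_sets(motif: str) -> list[frozenset[str]]:
    try:
        return [IUPAC[c] for c in motif]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in motif {motif!r}") from None


def _matches(window: str, allowed: list[frozenset[str]]) -> bool:
    for base, ok in zip(window, allowed):
        if base == "N":
            if len(ok) != 4:
                return False
        elif base not in ok:
            return False
    return True


def scan_motifs(sequence: str, dictionary: Mapping[str, str],
                seq_id: str = "") -> list[MotifHit]:
    """All plus- and minus-strand matches of every motif, sorted by
    (start, strand, name).  Overlapping hits are all reported."""
    sequence = sequence.upper()
    hits: list[MotifHit] = []
    for name, consensus in dictionary.items():
        for strand, motif in (("+", consensus.upper()),
                              ("-", reverse_complement_iupac(consensus.upper()))):
            allowed = _allowed_sets(motif)
            k = len(motif)
            for start in range(len(sequence) - k + 1):
                window = sequence[start:start + k]
                if _matches(window, allowed):
                    hits.append(MotifHit(seq_id, name, start, strand, window))
    hits.sort(key=lambda h: (h.start, h.strand, h.motif))
    return hits


def scan_promoters(promoters: Iterable[tuple[str, str]],
                   dictionary: Mapping[str, str] | None = None) -> list[MotifHit]:
    dictionary = DEFAULT_MOTIFS if dictionary is None else dictionary
    hits: list[MotifHit] = []
    for seq_id, seq in promoters:
        hits.extend(scan_motifs(seq, dictionary, seq_id=seq_id))
    return hits


def element_profile(hits: Iterable[MotifHit], gene_ids: Iterable[str],
                    dictionary: Mapping[str, str] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x element hit-count table plus presence (count >= 1) flags."""
    dictionary = DEFAULT_MOTIFS if dictionary is None else dictionary
    counts = pd.DataFrame(0, index=list(gene_ids),
                          columns=list(dictionary), dtype=int)
    for hit in hits:
        if hit.seq_id in counts.index and hit.motif in counts.columns:
            counts.loc[hit.seq_id, hit.motif] += 1
    return counts, counts >= 1


def expected_chance_hits(motif: str, seq_len: int) -> float:
    """Closed-form expected number of chance hits of a motif in an
    i.i.d. uniform-ACGT sequence of the given length, both strands:
    2 * (L - k + 1) * prod(|allowed_i| / 4)."""
    allowed = _allowed_sets(motif.upper())
    p = 1.0
    for ok in allowed:
        p *= len(ok) / 4.0
    return 2.0 * max(0, seq_len - len(motif) + 1) * p


def extract_promoters(genome: Mapping[str, str], genes, length: int = 2000
                      ) -> list[tuple[str, str]]:
    """Strand-aware upstream regions (default 2 kb) from a genome dict
    and GeneModels, truncated at contig edges."""
    out = []
    for gene in genes:
        contig = genome[gene.chrom]
        spans = [s for t in gene.transcripts.values() for s in t.exons]
        if gene.strand == "+":
            tss = min(s for s, _ in spans)
            seq = contig[max(0, tss - length):tss]
        else:
            tss = max(e for _, e in spans)
            comp = str.maketrans("ACGTN", "TGCAN")
            seq = contig[tss:tss + length].upper().translate(comp)[::-1]
        out.append((gene.gene_id, seq.upper()))
    return out
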