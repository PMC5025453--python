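"""MAPKKK subfamily classification from kinase-domain signature motifs.

The three plant MAPKKK subfamilies carry degenerate signature motifs in
kinase subdomain VIII:

* ZIK:  ``GTPEFMAPE(L/V)(Y/F)``
* MEKK: ``G(T/S)Px(F/W)MAPEV``
* Raf:  ``GTxx(W/Y)MAPE``

The consensus alone is not sufficient: the Raf signature also occurs in
receptor-like serine/threonine kinases, so Raf assignment additionally
requires a C-terminal kinase domain with a long N-terminal regulatory
region, and ZIK assignment requires an N-terminal kinase domain.
"""

from __future__ import annotations

from typing import Iterable, Optional

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .models import ProteinRecord, Span

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

#: Signature patterns: one string per position; multi-letter strings are
#: alternations, "x" matches any residue.  Scan order is specificity
#: order (ZIK's 11-mer first) so that more specific motifs win.
SIGNATURES: dict[str, tuple[str, ...]] = {
    "ZIK": ("G", "T", "P", "E", "F", "M", "A", "P", "E", "LV", "YF"),
    "MEKK": ("G", "TS", "P", "x", "FW", "M", "A", "P", "E", "V"),
    "Raf": ("G", "T", "x", "x", "WY", "M", "A", "P", "E"),
}

#: Domain-position rules.  ZIK kinase domains sit at the N-terminus;
#: Raf domains sit C-terminally behind a long regulatory region.
ZIK_MAX_NTER = 60          # residues before the domain
RAF_MAX_CTER_FRAC = 0.20   # tail after the domain, fraction of length
RAF_MIN_NTER_FRAC = 0.30   # regulatory region, fraction of length


def _matches_at(sequence: str, pattern: tuple[str, ...], pos: int) -> bool:
    if pos + len(pattern) > len(sequence):
        return False
    for offset, allowed in enumerate(pattern):
        if allowed != "x" and sequence[pos + offset] not in allowed:
            return False
    return True


def scan_kinase_signature(
    sequence: str,
    signatures: Optional[dict[str, tuple[str, ...]]] = None,
) -> list[tuple[str, int]]:
    """All (subfamily, 0-based position) signature matches, sorted by position.

    Raises ValueError on residues outside the 20-letter amino-acid alphabet.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - AA20
    if bad:
        raise ValueError(f"invalid residues: {sorted(bad)}")
    signatures = signatures if signatures is not None else SIGNATURES
    hits = []
    for name, pattern in signatures.items():
        for pos in range(len(sequence) - len(pattern) + 1):
            if _matches_at(sequence, pattern, pos):
                hits.append((name, pos))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def classify_subfamily(
    record: ProteinRecord,
    hits: Iterable[tuple[str, int]],
    exclude: Optional[set[str]] = None,
) -> str:
    """Assign MEKK / Raf / ZIK / unclassified from signature hits and
    the position of the kinase domain within the protein.

    ``exclude`` optionally lists ids known to be receptor-like kinases
    that share the Raf consensus; those are never called Raf.
    """
    if record.kinase_domain is None:
        raise ValueError(f"{record.id}: kinase domain span required")
    families = {name for name, _ in hits}
    length = len(record.sequence)
    n_ter, c_ter = record.n_ter_len, record.c_ter_len
    # Most specific pattern first: the ZIK 11-mer, then the MEKK 10-mer,
    # then the 9-position Raf consensus (which MEKK instances can also
    # satisfy by chance, hence last).
    if "ZIK" in families and n_ter <= ZIK_MAX_NTER:
        return "ZIK"
    if "MEKK" in families:
        return "MEKK"
    if (
        "Raf" in families
        and (exclude is None or record.id not in exclude)
        and c_ter <= RAF_MAX_CTER_FRAC * length
        and n_ter >= RAF_MIN_NTER_FRAC * length
    ):
        return "Raf"
    return "unclassified"


def infer_domain_span(sequence: str, signature_pos: int,
                      upstream: int = 200, downstream: int = 60) -> Span:
    """Fallback kinase-domain span when no annotation is supplied: the
    maximal window around the signature hit (the signature sits in
    subdomain VIII, near the C-terminal end of the catalytic core).
    """
    return (max(0, signature_pos - upstream),
            min(len(sequence), signature_pos + downstream))


def protein_features(sequence: str) -> tuple[float, float]:
    """Theoretical molecular weight (kDa) and isoelectric point.

    MW is the sum of average residue masses plus one water; pI is the
    Henderson-Hasselbalch bisection root of the net-charge function with
    the Bjellqvist pK set (Bio.SeqUtils.ProtParam).
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - AA20
    if bad:
        raise ValueError(f"ambiguous or invalid residues: {sorted(bad)}")
    analysis = ProteinAnalysis(sequence)
    return analysis.molecular_weight() / 1000.0, analysis.isoelectric_point()


def classify_proteins(
    proteins: Iterable[tuple[str, str]],
    domains: Optional[dict[str, Span]] = None,
    localizations: Optional[dict[str, str]] = None,
    exclude: Optional[set[str]] = None,
) -> list[ProteinRecord]:
    """Classify a batch of proteins, inferring domain spans from the
    signature hit when no annotation is provided."""
    out = []
    for name, seq in proteins:
        hits = scan_kinase_signature(seq)
        span = (domains or {}).get(name)
        if span is None and hits:
            span = infer_domain_span(seq, hits[0][1])
        mw, pi = protein_features(seq)
        rec = ProteinRecord(
            id=name, sequence=seq, kinase_domain=span, mw_kda=mw, pi=pi,
            localization=(localizations or {}).get(name),
        )
        rec.subfamily = (
            classify_subfamily(rec, hits, exclude) if span else "unclassified"
        )
        out.append(rec)
    return out
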