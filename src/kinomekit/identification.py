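"""Kinome identification: from per-domain profile hits to the
typical / atypical / non-kinase partition of a proteome.

The contract is defined on the HMMER3 per-domain tabular output
(``--domtblout``): a protein is a *typical* kinase when at least one
kinase-domain hit passes the E-value cutoff (strict ``< 1.0`` on the
per-domain independent E-value) **and** covers at least 50% of the profile
model; *atypical* when a hit passes the E-value cutoff but none reaches the
coverage threshold; *non-kinase* otherwise.  Multi-isoform genes are first
reduced to their longest peptide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from collections import defaultdict
from pathlib import Path

from Bio import SeqIO

from .errors import IntegrityError, InvalidParameterError, UnassignedIsoformError

#: default isoform naming rule: everything before the last dot is the gene
DEFAULT_ISOFORM_PATTERN = re.compile(r"^(?P<gene>.+)\.[^.]+$")

#: grapevine 12X V2 convention, e.g. VIT_201s0011g03010.t01 -> VIT_201s0011g03010
VIT_ISOFORM_PATTERN = re.compile(r"^(?P<gene>VIT_\d+s\d+g\d+)")

TYPICAL = "typical"
ATYPICAL = "atypical"
NON_KINASE = "non_kinase"


@dataclass(frozen=True)
class DomainHit:
    """One profile-model alignment on one protein (one domtblout row)."""

    protein_id: str
    model_name: str
    evalue: float
    bit_score: float
    model_from: int
    model_to: int
    model_length: int
    protein_from: int
    protein_to: int

    def __post_init__(self):
        if not (1 <= self.model_from <= self.model_to <= self.model_length):
            raise InvalidParameterError(
                f"bad model span {self.model_from}-{self.model_to}/{self.model_length}"
            )
        if not (1 <= self.protein_from <= self.protein_to):
            raise InvalidParameterError("bad protein span")
        if self.evalue < 0:
            raise InvalidParameterError("evalue must be >= 0")

    @property
    def model_coverage(self) -> float:
        return (self.model_to - self.model_from + 1) / self.model_length


@dataclass
class KinaseAnnotation:
    """Per-gene verdict after isoform dedup and hit filtering."""

    gene_id: str
    representative_protein_id: str
    status: str
    n_kinase_domains: int
    best_hit: DomainHit | None = None


def parse_domain_hits(source):
    """Parse a HMMER3 ``--domtblout`` table.

    ``source`` may be a path, an open file or the table text itself.
    Returns ``(hits, errors)`` where ``errors`` is a list of
    ``(line_number, message)`` for malformed rows; parsing continues past
    them.  Comment lines (``#``) and blanks are skipped.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        text = Path(s).read_text() if ("\n" not in s and Path(s).is_file()) else s
    hits: list[DomainHit] = []
    errors: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 19:
            errors.append((lineno, f"expected >= 19 columns, got {len(fields)}"))
            continue
        try:
            hits.append(
                DomainHit(
                    protein_id=fields[0],
                    model_name=fields[3],
                    model_length=int(fields[5]),
                    evalue=float(fields[12]),  # per-domain independent E-value
                    bit_score=float(fields[13]),
                    model_from=int(fields[15]),
                    model_to=int(fields[16]),
                    protein_from=int(fields[17]),
                    protein_to=int(fields[18]),
                )
            )
        except (ValueError, InvalidParameterError) as exc:
            errors.append((lineno, str(exc)))
    return hits, errors


def gene_of_isoform(protein_id: str, id_pattern=DEFAULT_ISOFORM_PATTERN, mapping=None):
    """Gene id for a protein id, via mapping first, then the regex pattern."""
    if mapping and protein_id in mapping:
        return mapping[protein_id]
    m = id_pattern.match(protein_id)
    return m.group("gene") if m else None


def dedup_longest_isoform(records, id_pattern=DEFAULT_ISOFORM_PATTERN, mapping=None):
    """Keep only the longest peptide per gene.

    ``records`` is an iterable of Bio.SeqRecord.  Ties on length are broken
    by the lexicographically smallest protein id.  Ids that match neither
    the pattern nor the mapping raise :class:`UnassignedIsoformError` listing
    all offenders.
    """
    best: dict[str, object] = {}
    offenders = []
    for rec in records:
        gene = gene_of_isoform(rec.id, id_pattern, mapping)
        if gene is None:
            offenders.append(rec.id)
            continue
        cur = best.get(gene)
        if cur is None or (len(rec.seq), _neg_id(rec.id)) > (len(cur.seq), _neg_id(cur.id)):
            best[gene] = rec
    if offenders:
        raise UnassignedIsoformError(offenders)
    return best


class _neg_id(str):
    """Reverses lexicographic comparison, so max() prefers the smaller id."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def classify_hit_status(
    protein_id: str,
    hits,
    min_model_coverage: float = 0.5,
    max_evalue: float = 1.0,
    *,
    gene_id: str | None = None,
    overlap_fraction: float = 0.25,
) -> KinaseAnnotation:
    """Classify one protein from its domain hits.

    Coverage is ``(model_to - model_from + 1) / model_length``; the coverage
    boundary is inclusive (>= min_model_coverage) and the E-value cutoff is
    strict (< max_evalue).  ``n_kinase_domains`` counts qualifying hits after
    merging hits whose protein spans overlap by more than
    ``overlap_fraction`` of the shorter span (higher bit score wins) — hits
    from both kinase profiles on one locus therefore count once.
    """
    hits = [h for h in hits if h.protein_id == protein_id] if hits else []
    passing = [h for h in hits if h.evalue < max_evalue]
    qualifying = [h for h in passing if h.model_coverage >= min_model_coverage]
    if qualifying:
        status = TYPICAL
    elif passing:
        status = ATYPICAL
    else:
        status = NON_KINASE
    kept: list[DomainHit] = []
    for h in sorted(qualifying, key=lambda h: (-h.bit_score, h.evalue, h.protein_from)):
        if all(not _overlaps(h, k, overlap_fraction) for k in kept):
            kept.append(h)
    best = min(passing, key=lambda h: (h.evalue, -h.bit_score)) if passing else None
    return KinaseAnnotation(
        gene_id=gene_id or protein_id,
        representative_protein_id=protein_id,
        status=status,
        n_kinase_domains=len(kept),
        best_hit=best,
    )


def _overlaps(a: DomainHit, b: DomainHit, frac: float) -> bool:
    lo = max(a.protein_from, b.protein_from)
    hi = min(a.protein_to, b.protein_to)
    if hi < lo:
        return False
    shorter = min(a.protein_to - a.protein_from + 1, b.protein_to - b.protein_from + 1)
    return (hi - lo + 1) > frac * shorter


def annotate_kinome(
    proteins,
    hits,
    min_model_coverage: float = 0.5,
    max_evalue: float = 1.0,
    id_pattern=DEFAULT_ISOFORM_PATTERN,
    mapping=None,
):
    """Full identification pass: dedup isoforms, then classify each
    representative protein.  ``proteins`` is a FASTA path/handle/text or an
    iterable of SeqRecord; ``hits`` a list of :class:`DomainHit`.
    Returns a list of :class:`KinaseAnnotation`, one per gene, sorted by
    gene id.
    """
    records = _as_records(proteins)
    reps = dedup_longest_isoform(records, id_pattern, mapping)
    by_protein = defaultdict(list)
    for h in hits:
        by_protein[h.protein_id].append(h)
    out = []
    for gene in sorted(reps):
        rep = reps[gene]
        out.append(
            classify_hit_status(
                rep.id,
                by_protein.get(rep.id, []),
                min_model_coverage,
                max_evalue,
                gene_id=gene,
            )
        )
    return out


def _as_records(proteins):
    if hasattr(proteins, "read"):
        return list(SeqIO.parse(proteins, "fasta"))
    if isinstance(proteins, (str, Path)):
        s = str(proteins)
        if "\n" in s or s.startswith(">"):
            import io

            return list(SeqIO.parse(io.StringIO(s), "fasta"))
        return list(SeqIO.parse(s, "fasta"))
    return list(proteins)


def summarize_kinome(annotations):
    """Counts table over an annotation list.

    Returns ``{"typical": n, "atypical": n, "non_kinase": n,
    "multi_domain": {k: count of typical genes with k domains}}``.
    Duplicate gene ids raise :class:`IntegrityError`.
    """
    seen = set()
    counts = {TYPICAL: 0, ATYPICAL: 0, NON_KINASE: 0}
    histogram: dict[int, int] = {}
    for a in annotations:
        if a.gene_id in seen:
            raise IntegrityError(f"duplicate gene id {a.gene_id}")
        seen.add(a.gene_id)
        counts[a.status] += 1
        if a.status == TYPICAL:
            histogram[a.n_kinase_domains] = histogram.get(a.n_kinase_domains, 0) + 1
    return {**counts, "multi_domain": dict(sorted(histogram.items()))}


def annotation_table(annotations):
    """Annotation list as a tidy DataFrame (for TSV export)."""
    import pandas as pd

    rows = []
    for a in annotations:
        rows.append(
            {
                "gene_id": a.gene_id,
                "protein_id": a.representative_protein_id,
                "status": a.status,
                "n_domains": a.n_kinase_domains,
                "best_evalue": a.best_hit.evalue if a.best_hit else float("nan"),
                "best_coverage": a.best_hit.model_coverage if a.best_hit else float("nan"),
            }
        )
    return pd.DataFrame(rows)
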