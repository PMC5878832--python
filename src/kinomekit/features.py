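"""Per-gene structural and physicochemical features.

Gene structure (exon/intron counts, chromosomal position) comes from GFF3
via gffutils; protein properties are the isoelectric point, computed by
bisection on the Henderson–Hasselbalch net-charge function with the
Bjellqvist pKa set, and the molecular weight from average residue masses.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import pandas as pd
from Bio.SeqUtils import molecular_weight

from .errors import InvalidParameterError, InvalidSequenceError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Bjellqvist pKa values (as used by the ExPASy Compute pI tool).  The table
# is plain data and swappable; N-terminal pKa depends on the first residue.
BJELLQVIST_PKA = {
    "Cterm": 3.55,
    "Nterm": 7.5,
    "C": 9.0,
    "D": 4.05,
    "E": 4.45,
    "H": 5.98,
    "K": 10.0,
    "R": 12.0,
    "Y": 10.0,
}

BJELLQVIST_NTERM_PKA = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    exons: list  # 1-based closed [start, end] intervals, sorted by start
    start: int
    end: int
    ordinal_index: int = -1  # rank of gene start along its chromosome


@dataclass
class ProteinProperties:
    protein_id: str
    pI: float
    MW: float


def read_gene_models(gff_source, representative: dict | None = None):
    """Parse GFF3 into :class:`GeneModel` records.

    One representative transcript per gene: the one named in
    ``representative`` (gene id -> transcript id) when given — normally the
    transcript of the longest-isoform protein — otherwise the transcript
    with the greatest summed exon length (ties to the smaller id).
    Ordinal indices are assigned per chromosome by gene start.
    """
    data = str(gff_source)
    from_string = "\n" in data
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        chosen_exons = None
        if transcripts:
            want = (representative or {}).get(gene.id)

            def _key(t):
                exons = list(db.children(t, featuretype="exon"))
                return (sum(e.end - e.start + 1 for e in exons), _rev(t.id))

            if want is not None:
                pick = [t for t in transcripts if t.id == want]
                tr = pick[0] if pick else max(transcripts, key=_key)
            else:
                tr = max(transcripts, key=_key)
            chosen_exons = sorted(
                ([e.start, e.end] for e in db.children(tr, featuretype="exon")),
            )
        if not chosen_exons:
            chosen_exons = [[gene.start, gene.end]]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                exons=chosen_exons,
                start=gene.start,
                end=gene.end,
            )
        )
    assign_ordinals(models)
    return models


class _rev(str):
    def __lt__(self, other):
        return str.__gt__(self, other)


def assign_ordinals(models):
    """Rank genes along each chromosome by start (ties by gene id)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom_models in by_chrom.values():
        chrom_models.sort(key=lambda m: (m.start, m.gene_id))
        for i, m in enumerate(chrom_models):
            m.ordinal_index = i
    return models


def count_introns(model: GeneModel) -> int:
    """Intron count of the representative transcript: exons minus one."""
    if not model.exons:
        raise InvalidParameterError(f"gene {model.gene_id} has no exons")
    return len(model.exons) - 1


def chromosome_distribution(family_of: dict, models, chromosomes=None):
    """Counts of genes per chromosome and per (chromosome, family).

    ``family_of`` restricts the tally to the genes it names (e.g. the kinase
    set).  Genes whose chromosome label is outside ``chromosomes`` (when
    given) count as unplaced.  Returns
    ``(per_chromosome: Series, per_chromosome_family: DataFrame, n_unplaced)``.
    """
    placed = {}
    per_fam_rows = {}
    unplaced = 0
    model_of = {m.gene_id: m for m in models}
    for gene, family in family_of.items():
        m = model_of.get(gene)
        if m is None:
            unplaced += 1
            continue
        if chromosomes is not None and m.chromosome not in chromosomes:
            unplaced += 1
            continue
        placed[m.chromosome] = placed.get(m.chromosome, 0) + 1
        key = (m.chromosome, family)
        per_fam_rows[key] = per_fam_rows.get(key, 0) + 1
    per_chrom = pd.Series(placed, dtype=int).sort_index()
    per_fam = pd.DataFrame(
        [(c, f, n) for (c, f), n in sorted(per_fam_rows.items())],
        columns=["chromosome", "family", "count"],
    )
    return per_chrom, per_fam, unplaced


# ---------------------------------------------------------------------------
# Protein properties
# ---------------------------------------------------------------------------

def _residue_counts(sequence: str, on_ambiguous: str):
    counts: dict[str, int] = {}
    first = None
    for ch in sequence:
        if ch not in AMINO_ACIDS:
            if on_ambiguous == "skip":
                continue
            raise InvalidSequenceError(f"unexpected residue {ch!r}")
        if first is None:
            first = ch
        counts[ch] = counts.get(ch, 0) + 1
    if first is None:
        raise InvalidSequenceError("empty sequence")
    return counts, first


def net_charge(sequence_or_counts, pH: float, pka_table=None, nterm_residue=None):
    """Henderson–Hasselbalch net charge at a given pH.

    Positive contributions from the N-terminus, H, K and R; negative from
    the C-terminus, D, E, C and Y.  Strictly decreasing in pH.
    """
    table = dict(BJELLQVIST_PKA if pka_table is None else pka_table)
    if isinstance(sequence_or_counts, str):
        counts, first = _residue_counts(sequence_or_counts, "raise")
    else:
        counts, first = sequence_or_counts, nterm_residue
    nterm_pka = BJELLQVIST_NTERM_PKA.get(first, table["Nterm"]) if first else table["Nterm"]
    q = 1.0 / (1.0 + 10 ** (pH - nterm_pka))
    q -= 1.0 / (1.0 + 10 ** (table["Cterm"] - pH))
    for aa in _POSITIVE:
        q += counts.get(aa, 0) / (1.0 + 10 ** (pH - table[aa]))
    for aa in _NEGATIVE:
        q -= counts.get(aa, 0) / (1.0 + 10 ** (table[aa] - pH))
    return q


def compute_pI(sequence: str, pka_table=None, *, on_ambiguous: str = "raise",
               charge_tol: float = 1e-4, max_iter: int = 120) -> float:
    """Isoelectric point: the pH of zero net charge, by bisection on [0, 14].

    The net-charge function is strictly decreasing in pH so bisection always
    converges; iteration stops once the residual charge is below
    ``charge_tol`` (well inside 1e-3 pH of the root for any peptide).
    """
    counts, first = _residue_counts(sequence, on_ambiguous)
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        q = net_charge(counts, mid, pka_table, nterm_residue=first)
        if abs(q) <= charge_tol:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def compute_MW(sequence: str) -> float:
    """Molecular weight in daltons: average residue masses plus one water."""
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    if set(sequence) - AMINO_ACIDS:
        raise InvalidSequenceError(
            f"unexpected residues {sorted(set(sequence) - AMINO_ACIDS)}"
        )
    return molecular_weight(sequence, seq_type="protein", monoisotopic=False)


def feature_table(models, sequences: dict) -> pd.DataFrame:
    """Tidy per-gene table: chromosome, introns, pI, MW.

    ``sequences`` maps gene id -> representative protein sequence.
    """
    rows = []
    for m in models:
        seq = sequences.get(m.gene_id)
        rows.append(
            {
                "gene_id": m.gene_id,
                "chromosome": m.chromosome,
                "strand": m.strand,
                "introns": count_introns(m),
                "pI": compute_pI(seq) if seq else float("nan"),
                "MW": compute_MW(seq) if seq else float("nan"),
            }
        )
    return pd.DataFrame(rows)
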