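"""Synthetic-data generators with machine-readable ground truth.

Every input the pipeline consumes — protein FASTA, GFF3 gene models,
domain-hit tables, family score tables, aligned CDS pairs and expression
matrices — can be generated here with a known planted structure, so each
downstream stage is testable without external databases.

All generators take an explicit integer ``seed`` and hold no global state:
the same call with the same seed produces byte-identical output.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._codons import SENSE_CODONS, NUCLEOTIDES, AA_OF, is_stop
from .errors import InvalidParameterError, GenerationError

# A fixed kinase-flavoured sentinel peptide standing in for the catalytic
# domain profile.  Identification looks for profile hits, not for this string;
# ``synthetic_hit_table`` converts planted occurrences into a domain-hit table
# so the real filtering code path is exercised.
KINASE_SENTINEL = "HRDLKPENLLLDSKGQLKIADFGLARVMTPQGDVYSFGVVLWEILTGQRAFD"
SENTINEL_MODEL_NAME = "Pkinase"
SENTINEL_MODEL_LENGTH = len(KINASE_SENTINEL)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Family labels drawn on by default for planted kinase genes.
DEFAULT_FAMILIES = (
    "RLK-Pelle_DLSV",
    "RLK-Pelle_LRK10L-2",
    "RLK-Pelle_LRR-XI-1",
    "CAMK_CAMKL-CHK1",
    "CMGC_MAPK",
    "AGC_PDK1",
    "STE_STE11",
    "CK1_CK1",
    "TKL-Pl-4",
    "NEK",
)


def family_signature(family: str) -> str:
    """Deterministic 6-residue token unique to a family label.

    Planted into synthetic kinase proteins so that family assignment has a
    recoverable signal with positive margin by construction.
    """
    digest = hashlib.blake2b(family.encode(), digest_size=6).digest()
    return "".join(AMINO_ACIDS[b % 20] for b in digest)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    kinase_gene_ids: set = field(default_factory=set)
    family_of_gene: dict = field(default_factory=dict)
    #: arrays that satisfy the tandem rule by construction
    tandem_arrays: list = field(default_factory=list)
    #: planted arrays designed to violate the rule (negative controls)
    designed_negative_arrays: list = field(default_factory=list)
    collinear_blocks: list = field(default_factory=list)
    omega_of_pair: dict = field(default_factory=dict)
    planted_edges: set = field(default_factory=set)
    longest_isoform: dict = field(default_factory=dict)
    atypical_gene_ids: set = field(default_factory=set)
    effects: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["kinase_gene_ids"] = sorted(self.kinase_gene_ids)
        d["atypical_gene_ids"] = sorted(self.atypical_gene_ids)
        d["planted_edges"] = sorted(list(e) for e in self.planted_edges)
        d["omega_of_pair"] = {"|".join(k): v for k, v in self.omega_of_pair.items()}
        d["effects"] = {"|".join(k): v for k, v in self.effects.items()}
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["kinase_gene_ids"] = set(d["kinase_gene_ids"])
        d["atypical_gene_ids"] = set(d.get("atypical_gene_ids", []))
        d["planted_edges"] = {tuple(e) for e in d["planted_edges"]}
        d["omega_of_pair"] = {tuple(k.split("|")): v for k, v in d["omega_of_pair"].items()}
        d["effects"] = {tuple(k.split("|")): v for k, v in d["effects"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_proteome(
    n_genes: int,
    n_kinase_genes: int,
    isoforms_per_gene=1,
    seed: int = 0,
    *,
    gene_ids=None,
    family_of=None,
    families=DEFAULT_FAMILIES,
    atypical_fraction: float = 0.0,
    kinase_gene_ids=None,
):
    """Generate a protein FASTA with planted kinase-domain sentinels.

    Parameters
    ----------
    n_genes, n_kinase_genes:
        Total genes and how many of them carry a planted kinase domain.
    isoforms_per_gene:
        Either a constant count or a ``{count: probability}`` distribution.
    atypical_fraction:
        Fraction of kinase genes planted with a truncated (40%) domain so
        their model coverage falls below the typical threshold.
    gene_ids, family_of:
        Optional externally supplied gene ids and family labels (used when
        coordinating with :func:`gen_gene_models`).

    Returns ``(fasta_text, SyntheticTruth)``.
    """
    if n_genes <= 0:
        raise InvalidParameterError("n_genes must be positive")
    if not 0 <= n_kinase_genes <= n_genes:
        raise InvalidParameterError("need 0 <= n_kinase_genes <= n_genes")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    elif len(gene_ids) != n_genes:
        raise InvalidParameterError("gene_ids length must equal n_genes")

    if kinase_gene_ids is None:
        kin_idx = sorted(rng.choice(n_genes, size=n_kinase_genes, replace=False))
        kinase_ids = [gene_ids[i] for i in kin_idx]
    else:
        kinase_ids = sorted(kinase_gene_ids)
        if len(kinase_ids) != n_kinase_genes or not set(kinase_ids) <= set(gene_ids):
            raise InvalidParameterError("kinase_gene_ids inconsistent with gene_ids")
    n_atypical = int(round(atypical_fraction * n_kinase_genes))
    atypical = set(kinase_ids[:n_atypical])

    truth = SyntheticTruth()
    truth.kinase_gene_ids = set(kinase_ids)
    truth.atypical_gene_ids = atypical
    if family_of is None:
        fam_pool = list(families)
        truth.family_of_gene = {
            g: fam_pool[i % len(fam_pool)] for i, g in enumerate(kinase_ids)
        }
    else:
        truth.family_of_gene = {g: family_of[g] for g in kinase_ids if g in family_of}

    buf = io.StringIO()
    for g in gene_ids:
        if isinstance(isoforms_per_gene, int):
            n_iso = isoforms_per_gene
        else:
            counts = sorted(isoforms_per_gene)
            probs = np.array([isoforms_per_gene[c] for c in counts], dtype=float)
            n_iso = int(rng.choice(counts, p=probs / probs.sum()))
        n_iso = max(1, n_iso)
        base_len = int(rng.integers(150, 600))
        lengths = [base_len] + [
            max(60, base_len - int(rng.integers(10, base_len // 2 + 11)))
            for _ in range(n_iso - 1)
        ]
        order = list(rng.permutation(n_iso))
        longest_j = max(range(n_iso), key=lambda j: (lengths[order[j]], -j))
        for j in range(n_iso):
            length = lengths[order[j]]
            seq = _random_peptide(rng, length)
            if g in truth.kinase_gene_ids:
                domain = KINASE_SENTINEL
                if g in atypical:
                    domain = KINASE_SENTINEL[: int(0.4 * SENTINEL_MODEL_LENGTH)]
                token = family_signature(truth.family_of_gene.get(g, "NEK"))
                insert = domain + token
                pos = int(rng.integers(0, max(1, length - len(insert))))
                seq = seq[:pos] + insert + seq[pos + len(insert):]
                if len(seq) < length:
                    seq = seq + _random_peptide(rng, length - len(seq))
                seq = seq[: max(length, len(insert))]
            pid = f"{g}.{j + 1}"
            if j == longest_j:
                truth.longest_isoform[g] = pid
            buf.write(f">{pid}\n")
            for k in range(0, len(seq), 60):
                buf.write(seq[k : k + 60] + "\n")
    return buf.getvalue(), truth


def synthetic_hit_table(fasta_text: str) -> str:
    """Emit a HMMER3 per-domain table for planted sentinel occurrences.

    Scans each FASTA record for the full sentinel or a prefix of it (>= 10
    residues) and writes one domain row per occurrence, so that the real
    hit-table parser and coverage filter run unchanged on synthetic data.
    """
    lines = [
        "#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
        "#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------",
    ]
    pid = None
    chunks: list[str] = []

    def flush():
        if pid is None:
            return
        seq = "".join(chunks)
        span = None
        # longest planted prefix of the sentinel present in the sequence
        for k in range(SENTINEL_MODEL_LENGTH, 9, -1):
            pos = seq.find(KINASE_SENTINEL[:k])
            if pos >= 0:
                span = (pos + 1, pos + k, k)
                break
        if span is not None:
            ali_from, ali_to, k = span
            lines.append(
                f"{pid:<20s} -          {len(seq):>5d} {SENTINEL_MODEL_NAME:<20s} "
                f"PF00069.1  {SENTINEL_MODEL_LENGTH:>5d}   1.0e-30  120.0   0.0   1   1   1.0e-32   1.0e-30  118.0   0.0 "
                f"{1:>5d} {k:>5d} {ali_from:>5d} {ali_to:>5d} {max(1, ali_from - 2):>5d} {ali_to + 2:>5d} 0.95 synthetic"
            )

    for raw in fasta_text.splitlines():
        if raw.startswith(">"):
            flush()
            pid = raw[1:].split()[0]
            chunks = []
        elif raw.strip():
            chunks.append(raw.strip())
    flush()
    return "\n".join(lines) + "\n#\n# [ok]\n"


def family_score_table(truth: SyntheticTruth, seed: int = 0):
    """Per-(gene, family) bit-score/E-value rows for classification tests.

    The true family always receives the top bit score; every gene also gets
    one or two weak cross-family rows so argmax selection is non-trivial.
    Returns a pandas DataFrame with columns gene_id, family, bit_score, evalue.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    fams = sorted(set(truth.family_of_gene.values()))
    rows = []
    for g in sorted(truth.kinase_gene_ids):
        true_fam = truth.family_of_gene[g]
        rows.append((g, true_fam, 200.0 + rng.normal(0, 5), 1e-40))
        for other in rng.choice(fams, size=min(2, len(fams)), replace=False):
            if other != true_fam:
                rows.append((g, str(other), 30.0 + rng.normal(0, 3), 0.3))
    return pd.DataFrame(rows, columns=["gene_id", "family", "bit_score", "evalue"])


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

#: rule thresholds used to label planted arrays detectable / not detectable
TANDEM_MAX_INTERVENING = 5
TANDEM_MAX_GAP_BP = 100_000


@dataclass
class _Slot:
    gene_id: str
    family: str | None = None  # kinase family if kinase
    array_tag: int | None = None
    forced_start: int | None = None


def gen_gene_models(
    n_chromosomes: int,
    genes_per_chromosome: int,
    tandem_spec=(),
    collinear_spec=(),
    seed: int = 0,
    *,
    extra_kinase_genes: int = 0,
):
    """Lay out genes on chromosomes with planted tandem arrays and collinear
    anchor runs; emit GFF3 and the truth sidecar.

    ``tandem_spec`` is a list of ``(array_size, intervening_genes, span_bp)``
    tuples; ``span_bp`` is the start-to-start distance between adjacent array
    members.  Specs whose intervening count exceeds 5 or whose span exceeds
    100 kb are planted as designed negatives and recorded as such.

    ``collinear_spec`` is a list of ``(n_anchors, (chrom_i, chrom_j))`` with
    0-based chromosome indices.  Extra kinase genes (outside arrays) each get
    a unique synthetic family so no unplanned array can form.
    """
    if n_chromosomes <= 0 or genes_per_chromosome <= 0:
        raise InvalidParameterError("chromosome and gene counts must be positive")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()

    chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    slots = {c: [_Slot(gene_id="") for _ in range(genes_per_chromosome)] for c in chrom_names}
    used = {c: np.zeros(genes_per_chromosome, dtype=bool) for c in chrom_names}

    # ---- plant tandem arrays ----
    planted = []  # (chrom, member_slot_indices, family, span_bp, detectable)
    for i, (size, intervening, span_bp) in enumerate(tandem_spec):
        if size < 2:
            raise InvalidParameterError("tandem arrays need >= 2 members")
        chrom = chrom_names[i % n_chromosomes]
        run_len = size + (size - 1) * intervening
        if run_len > genes_per_chromosome:
            raise GenerationError(
                f"tandem spec {i}: run of {run_len} slots exceeds chromosome capacity"
            )
        # find a free contiguous run, deterministic left-to-right scan from a
        # seeded offset
        free = ~used[chrom]
        start = None
        offset = int(rng.integers(0, genes_per_chromosome - run_len + 1))
        for s in list(range(offset, genes_per_chromosome - run_len + 1)) + list(range(0, offset)):
            if free[s : s + run_len].all():
                start = s
                break
        if start is None:
            raise GenerationError(f"tandem spec {i}: no free run on {chrom}")
        used[chrom][start : start + run_len] = True
        family = f"RLK-Pelle_TANDEM-{i + 1:02d}"
        member_idx = [start + k * (intervening + 1) for k in range(size)]
        for j in member_idx:
            slots[chrom][j].family = family
            slots[chrom][j].array_tag = i
        detectable = intervening <= TANDEM_MAX_INTERVENING and span_bp <= TANDEM_MAX_GAP_BP
        planted.append((chrom, member_idx, family, span_bp, intervening, detectable))

    # ---- extra kinase genes with unique families ----
    flat_free = [
        (c, j) for c in chrom_names for j in range(genes_per_chromosome) if not used[c][j]
    ]
    if extra_kinase_genes > len(flat_free):
        raise GenerationError("not enough free slots for extra kinase genes")
    if extra_kinase_genes:
        pick = rng.choice(len(flat_free), size=extra_kinase_genes, replace=False)
        for k, p in enumerate(sorted(pick)):
            c, j = flat_free[p]
            slots[c][j].family = f"RLK-Pelle_SYN-{k + 1:02d}"
            used[c][j] = True

    # ---- assign ids and coordinates ----
    gff = io.StringIO()
    gff.write("##gff-version 3\n")
    counter = 0
    start_of = {}
    order_on = {c: [] for c in chrom_names}
    for c in chrom_names:
        cursor = int(rng.integers(5_000, 20_000))
        j = 0
        while j < genes_per_chromosome:
            slot = slots[c][j]
            if slot.array_tag is not None and _is_first_member(slots[c], j):
                # lay out the whole run with controlled spacing
                chrom_i, member_idx, family, span_bp, intervening, detectable = planted[
                    slot.array_tag
                ]
                size = len(member_idx)
                run_end_slot = member_idx[-1]
                base = cursor
                step = span_bp // (intervening + 1) if intervening else span_bp
                pos = base
                for jj in range(member_idx[0], run_end_slot + 1):
                    counter += 1
                    gid = f"G{counter:04d}"
                    slots[c][jj].gene_id = gid
                    slots[c][jj].forced_start = pos
                    rel = jj - member_idx[0]
                    # next start: members sit exactly span_bp apart
                    k_next = rel + 1
                    pos = base + (k_next // (intervening + 1)) * span_bp + (
                        k_next % (intervening + 1)
                    ) * step
                cursor = base + (size - 1) * span_bp + span_bp // 2 + int(
                    rng.integers(2_000, 8_000)
                )
                j = run_end_slot + 1
                continue
            counter += 1
            slot.gene_id = f"G{counter:04d}"
            slot.forced_start = cursor
            cursor += int(rng.integers(3_000, 9_000))
            j += 1
        # emit features in coordinate order
        for slot in slots[c]:
            start = slot.forced_start
            n_exons = int(rng.integers(1, 4))
            exon_lens = rng.integers(200, 500, size=n_exons)
            intron_lens = rng.integers(100, 400, size=max(0, n_exons - 1))
            gid = slot.gene_id
            tid = f"{gid}.1"
            # keep genes compact enough not to overlap the next slot
            end = start + int(exon_lens.sum() + intron_lens.sum()) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gff.write(f"{c}\tsynth\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n")
            gff.write(
                f"{c}\tsynth\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={tid};Parent={gid}\n"
            )
            pos = start
            for e in range(n_exons):
                e_end = pos + int(exon_lens[e]) - 1
                gff.write(
                    f"{c}\tsynth\texon\t{pos}\t{e_end}\t.\t{strand}\t.\t"
                    f"ID={tid}.exon{e + 1};Parent={tid}\n"
                )
                if e < n_exons - 1:
                    pos = e_end + 1 + int(intron_lens[e])
            start_of[gid] = start
            order_on[c].append(gid)
            if slot.family is not None:
                truth.kinase_gene_ids.add(gid)
                truth.family_of_gene[gid] = slot.family

    # ---- record planted arrays in truth ----
    for chrom, member_idx, family, span_bp, intervening, detectable in planted:
        members = [slots[chrom][j].gene_id for j in member_idx]
        if detectable:
            truth.tandem_arrays.append(members)
        else:
            truth.designed_negative_arrays.append(members)

    # ---- collinear anchor runs ----
    for n_anchors, (ia, ib) in collinear_spec:
        ca, cb = chrom_names[ia], chrom_names[ib]
        step = 2
        need = n_anchors * step
        if need > genes_per_chromosome:
            raise GenerationError("collinear spec does not fit on chromosome")
        offs_a = int(rng.integers(0, genes_per_chromosome - need + 1))
        offs_b = int(rng.integers(0, genes_per_chromosome - need + 1))
        block = [
            (order_on[ca][offs_a + k * step], order_on[cb][offs_b + k * step])
            for k in range(n_anchors)
        ]
        truth.collinear_blocks.append(block)

    return gff.getvalue(), truth


def _is_first_member(chrom_slots, j):
    slot = chrom_slots[j]
    if slot.array_tag is None:
        return False
    return j == min(
        k for k, s in enumerate(chrom_slots) if s.array_tag == slot.array_tag
    )


def anchors_with_noise(truth: SyntheticTruth, n_noise: int, gene_ids, seed: int = 0):
    """Planted collinear anchors plus random noise pairs, as a DataFrame.

    Noise pairs are drawn from genes outside the planted anchors, so noise
    cannot silently substitute for a planted homolog.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = [(a, b, 95.0) for block in truth.collinear_blocks for a, b in block]
    anchored = {g for block in truth.collinear_blocks for pair in block for g in pair}
    ids = sorted(set(gene_ids) - anchored)
    for _ in range(n_noise):
        a, b = rng.choice(len(ids), size=2, replace=False)
        rows.append((ids[int(a)], ids[int(b)], 60.0))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "similarity"])


# ---------------------------------------------------------------------------
# Codon-pair evolution
# ---------------------------------------------------------------------------

def evolve_codon_pair(n_codons: int, omega: float, expected_subs_per_codon: float, seed: int = 0):
    """Evolve one sequence from a random ancestor under a Nei–Gojobori-style
    substitution process with selection intensity ``omega``.

    Proposals are uniform single-nucleotide changes; changes creating a stop
    are rejected outright; synonymous and nonsynonymous proposals are accepted
    with relative probabilities 1 : omega (rescaled when omega > 1).  The
    accepted-substitution budget is ``round(n_codons * expected_subs_per_codon)``.

    Returns ``(ancestor, derived, omega)`` as DNA strings.
    """
    if n_codons < 1:
        raise InvalidParameterError("n_codons must be >= 1")
    if omega <= 0:
        raise InvalidParameterError("omega must be positive")
    if expected_subs_per_codon < 0:
        raise InvalidParameterError("expected_subs_per_codon must be >= 0")
    rng = np.random.default_rng(seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]
    ancestor = "".join(codons)
    target = int(round(n_codons * expected_subs_per_codon))
    p_syn, p_nonsyn = (1.0, omega) if omega <= 1 else (1.0 / omega, 1.0)
    accepted = 0
    guard = 0
    limit = 200 * max(target, 1) + 10_000
    while accepted < target:
        guard += 1
        if guard > limit:  # pragma: no cover - defensive
            raise GenerationError("substitution process failed to converge")
        ci = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        old = codons[ci]
        new_nt = NUCLEOTIDES[int(rng.integers(0, 4))]
        if new_nt == old[pos]:
            continue
        new = old[:pos] + new_nt + old[pos + 1 :]
        if is_stop(new):
            continue
        syn = AA_OF[new] == AA_OF[old]
        p = p_syn if syn else p_nonsyn
        if rng.random() < p:
            codons[ci] = new
            accepted += 1
    return ancestor, "".join(codons), float(omega)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gen_expression(
    families: dict,
    n_samples: int,
    planted_blocks=(),
    treatment_design=None,
    effect_spec=None,
    noise_sd: float = 0.3,
    seed: int = 0,
    *,
    base_log2: float = 8.0,
    family_sd: float = 1.0,
):
    """Generate a linear-scale expression TSV with planted family structure.

    Family latent series are standard normal per sample; planted family pairs
    share a latent mixed to the requested population correlation; condition
    effects are added on the log2 scale so a planted effect of ``e`` gives an
    expected fold change of ``2**e``.

    ``families`` maps family label -> list of member gene ids.
    ``planted_blocks`` is a list of ``((family_a, family_b), target_r)``.
    ``treatment_design`` maps sample id -> condition label; when omitted,
    samples are ``S01..Snn`` with condition ``"none"``.
    ``effect_spec`` maps ``(family, condition)`` -> log2 effect.

    Returns ``(tsv_text, SyntheticTruth)``.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if treatment_design is None:
        samples = [f"S{i + 1:02d}" for i in range(n_samples)]
        condition_of = {s: "none" for s in samples}
    else:
        samples = sorted(treatment_design)
        condition_of = dict(treatment_design)
        if n_samples != len(samples):
            raise InvalidParameterError("n_samples must match treatment_design size")
    effect_spec = dict(effect_spec or {})
    fam_names = sorted(families)
    for (fa, fb), r in planted_blocks:
        if fa not in families or fb not in families:
            raise InvalidParameterError(f"planted block references unknown family: {fa}/{fb}")
        if not -1.0 <= r <= 1.0:
            raise InvalidParameterError("target_r must lie in [-1, 1]")

    latent = {f: rng.standard_normal(n_samples) for f in fam_names}
    truth = SyntheticTruth()
    for (fa, fb), r in planted_blocks:
        e = rng.standard_normal(n_samples)
        latent[fb] = r * latent[fa] + np.sqrt(max(0.0, 1 - r * r)) * e
        key = tuple(sorted((fa, fb)))
        truth.planted_edges.add((key[0], key[1], 1 if r > 0 else -1))
    truth.effects = dict(effect_spec)
    truth.family_of_gene = {g: f for f, genes in families.items() for g in genes}
    truth.kinase_gene_ids = set(truth.family_of_gene)

    buf = io.StringIO()
    buf.write("gene_id\t" + "\t".join(samples) + "\n")
    for f in fam_names:
        z = latent[f]
        for g in families[f]:
            noise = rng.normal(0.0, noise_sd, size=n_samples)
            row = []
            for k, s in enumerate(samples):
                log2v = (
                    base_log2
                    + family_sd * z[k]
                    + effect_spec.get((f, condition_of[s]), 0.0)
                    + noise[k]
                )
                row.append(f"{2.0 ** log2v:.6f}")
            buf.write(g + "\t" + "\t".join(row) + "\n")
    return buf.getvalue(), truth


def design_tsv(treatment_design: dict) -> str:
    """Sample/condition/replicate sidecar for an expression matrix."""
    seen: dict[str, int] = {}
    lines = ["sample\tcondition\treplicate"]
    for s in sorted(treatment_design):
        cond = treatment_design[s]
        seen[cond] = seen.get(cond, 0) + 1
        lines.append(f"{s}\t{cond}\t{seen[cond]}")
    return "\n".join(lines) + "\n"
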