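"""Duplication detection and molecular evolution.

Tandem arrays follow the physical-proximity rule: two same-family kinase
genes on one chromosome are linked when at most five genes of any kind lie
between them and their starts are within 100 kb; arrays are maximal runs of
linked genes.  Segmental (collinear) blocks are found by dynamic-programming
chaining of homolog anchor pairs with strictly monotone gene ordinals on
both chromosomes.  Substitution rates use Nei–Gojobori (1986) counting with
the Jukes–Cantor multiple-hit correction; divergence times are T = Ks/(2λ)
with λ the synonymous rate per site per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import pandas as pd

from ._codons import AA_OF, NUCLEOTIDES, is_stop
from .errors import AlignmentError, InvalidParameterError, InvalidSequenceError

#: default synonymous substitution rate per site per year (grapevine)
DEFAULT_LAMBDA = 6.5e-9

PURIFYING = "purifying"
NEUTRAL = "neutral"
POSITIVE = "positive"
UNDEFINED = "undefined"


# ---------------------------------------------------------------------------
# Tandem arrays
# ---------------------------------------------------------------------------

@dataclass
class TandemArray:
    chromosome: str
    members: list  # gene ids sorted by start
    family: str
    span_bp: int


def detect_tandem_arrays(
    models,
    kinase_genes,
    family_of: dict,
    max_intervening: int = 5,
    max_gap_bp: int = 100_000,
):
    """Detect tandem arrays of same-family kinase genes.

    Both thresholds are inclusive: a pair separated by exactly
    ``max_intervening`` genes and exactly ``max_gap_bp`` apart is linked.
    Because the intervening-gene count and the start distance are both
    monotone along a chromosome, connectivity reduces to consecutive links
    within each (chromosome, family) run; arrays are those runs with >= 2
    members.  Kinase genes absent from the gene models are skipped and
    reported in the second return value.
    """
    model_of = {m.gene_id: m for m in models}
    missing = sorted(g for g in kinase_genes if g not in model_of)
    groups: dict[tuple, list] = {}
    for g in kinase_genes:
        m = model_of.get(g)
        if m is None:
            continue
        fam = family_of.get(g)
        if fam is None:
            continue
        groups.setdefault((m.chromosome, fam), []).append(m)
    arrays = []
    for (chrom, fam), ms in sorted(groups.items()):
        ms.sort(key=lambda m: (m.start, m.gene_id))
        run = [ms[0]]
        for prev, cur in zip(ms, ms[1:]):
            intervening = cur.ordinal_index - prev.ordinal_index - 1
            gap = cur.start - prev.start
            if intervening <= max_intervening and gap <= max_gap_bp:
                run.append(cur)
            else:
                if len(run) >= 2:
                    arrays.append(_make_array(chrom, fam, run))
                run = [cur]
        if len(run) >= 2:
            arrays.append(_make_array(chrom, fam, run))
    arrays.sort(key=lambda a: (a.chromosome, a.members[0]))
    return arrays, missing


def _make_array(chrom, fam, run):
    return TandemArray(
        chromosome=chrom,
        members=[m.gene_id for m in run],
        family=fam,
        span_bp=run[-1].start - run[0].start,
    )


# ---------------------------------------------------------------------------
# Collinear blocks
# ---------------------------------------------------------------------------

@dataclass
class CollinearBlock:
    chromosome_pair: tuple
    anchors: list  # ordered (gene_a, gene_b) pairs
    score: float
    orientation: int  # +1 same order, -1 inverted


def detect_collinear_blocks(anchor_pairs, models, min_anchors: int = 5,
                            max_gene_gap: int = 25):
    """Chain homolog anchor pairs into collinear blocks.

    ``anchor_pairs`` is an iterable of (gene_a, gene_b) (extra columns
    ignored).  Per chromosome pair, the best chain with strictly monotone
    ordinals on both chromosomes (either orientation) and per-step ordinal
    gaps <= ``max_gene_gap`` is extracted repeatedly until no chain of
    ``min_anchors`` anchors remains; an anchor is used in at most one block.
    """
    pos = {m.gene_id: (m.chromosome, m.ordinal_index) for m in models}
    by_pair: dict[tuple, list] = {}
    for pair in anchor_pairs:
        a, b = pair[0], pair[1]
        if a == b or a not in pos or b not in pos:
            continue
        (ca, oa), (cb, ob) = pos[a], pos[b]
        if (cb, b) < (ca, a):
            a, b, ca, cb, oa, ob = b, a, cb, ca, ob, oa
        by_pair.setdefault((ca, cb), []).append((oa, ob, a, b))
    blocks = []
    for cpair, anchors in sorted(by_pair.items()):
        remaining = sorted(set(anchors))
        while len(remaining) >= min_anchors:
            best_chain, best_orient = None, 0
            for orient in (1, -1):
                chain = _best_chain(remaining, orient, max_gene_gap)
                if best_chain is None or len(chain) > len(best_chain):
                    best_chain, best_orient = chain, orient
            if best_chain is None or len(best_chain) < min_anchors:
                break
            blocks.append(
                CollinearBlock(
                    chromosome_pair=cpair,
                    anchors=[(a, b) for _, _, a, b in best_chain],
                    score=float(len(best_chain)),
                    orientation=best_orient,
                )
            )
            used = set(best_chain)
            remaining = [x for x in remaining if x not in used]
    return blocks


def _best_chain(anchors, orient, max_gap):
    """Longest strictly-monotone chain under the gap constraint (O(n^2) DP)."""
    n = len(anchors)
    if n == 0:
        return []
    dp = [1] * n
    back = [-1] * n
    for i in range(n):
        oa_i, ob_i = anchors[i][0], anchors[i][1]
        for j in range(i):
            oa_j, ob_j = anchors[j][0], anchors[j][1]
            if not (0 < oa_i - oa_j <= max_gap):
                continue
            db = (ob_i - ob_j) * orient
            if not (0 < db <= max_gap):
                continue
            if dp[j] + 1 > dp[i]:
                dp[i] = dp[j] + 1
                back[i] = j
    i = max(range(n), key=lambda k: (dp[k], -anchors[k][0]))
    chain = []
    while i >= 0:
        chain.append(anchors[i])
        i = back[i]
    return chain[::-1]


# ---------------------------------------------------------------------------
# Nei–Gojobori substitution estimation
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_site_counts(codon: str):
    """Synonymous and nonsynonymous site counts (s, n) for a sense codon.

    For each position the synonymous fraction is the number of
    single-nucleotide changes that preserve the amino acid divided by the
    number of changes that do not create a stop; s is the sum over the three
    positions and n = 3 - s, so s + n = 3 per codon by construction.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(c not in NUCLEOTIDES for c in codon):
        raise InvalidSequenceError(f"not a codon: {codon!r}")
    if is_stop(codon):
        raise InvalidSequenceError(f"stop codon {codon} has no site counts")
    aa = AA_OF[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if is_stop(alt):
                continue
            non_stop += 1
            if AA_OF[alt] == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_pair_differences(codon_a: str, codon_b: str):
    """Synonymous/nonsynonymous difference counts (sd, nd) between codons.

    For multi-difference codons, step counts are averaged over all orderings
    of the differing positions whose intermediates are not stop codons; when
    every ordering passes through a stop, the average is taken over all
    orderings instead (so sd + nd always equals the number of differing
    positions).
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if is_stop(c):
            raise InvalidSequenceError(f"stop codon {c} in pair")
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    valid = []
    all_paths = []
    for order in permutations(diffs):
        cur = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                blocked = True
            if AA_OF.get(nxt, "*") == AA_OF[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not blocked:
            valid.append((sd, nd))
    paths = valid if valid else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float):
    """JC correction; None when the proportion is at or beyond saturation."""
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class SubstitutionEstimate:
    pair: tuple
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    mode: str
    T_mya: float | None
    lam: float = DEFAULT_LAMBDA
    n_codons_used: int = 0
    saturated: bool = False
    notes: list = field(default_factory=list)


def estimate_ka_ks(seq_a: str, seq_b: str, *, pair=("a", "b"),
                   lam: float = DEFAULT_LAMBDA, neutral_band: float = 0.0):
    """NG86 Ka/Ks for one aligned CDS pair.

    Sequences must be equal length and a multiple of three; codons with a
    gap or a stop in either sequence are excluded pairwise.  Site totals are
    the mean of the two sequences' sums; proportions are corrected with
    Jukes–Cantor.  Saturated proportions (>= 3/4) yield None for the
    corresponding rate.  A pair with Ks = 0 but Ka > 0 is reported with an
    infinite ratio (positive mode) rather than a division error; Ka = Ks = 0
    leaves the ratio undefined.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise AlignmentError("aligned sequences differ in length")
    if len(a) % 3:
        raise AlignmentError("alignment length is not a multiple of 3")
    sa = sb = sd = nd = 0.0
    used = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        if any(c not in NUCLEOTIDES for c in ca + cb):
            continue
        if is_stop(ca) or is_stop(cb):
            continue
        s1, _ = ng86_site_counts(ca)
        s2, _ = ng86_site_counts(cb)
        d_s, d_n = ng86_pair_differences(ca, cb)
        sa += s1
        sb += s2
        sd += d_s
        nd += d_n
        used += 1
    if used == 0:
        raise AlignmentError("no usable codons in alignment")
    S = (sa + sb) / 2.0
    N = 3.0 * used - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(ps)
    Ka = _jukes_cantor(pn)
    saturated = Ks is None or Ka is None
    if saturated:
        ratio = None
    elif Ks == 0.0:
        ratio = math.inf if Ka > 0 else None
    else:
        ratio = Ka / Ks
    mode = classify_selection(ratio, neutral_band)
    T = divergence_time(Ks, lam) if Ks is not None else None
    notes = ["saturated"] if saturated else []
    return SubstitutionEstimate(
        pair=tuple(pair), S_sites=S, N_sites=N, Sd=sd, Nd=nd, Ks=Ks, Ka=Ka,
        ratio=ratio, mode=mode, T_mya=T, lam=lam, n_codons_used=used,
        saturated=saturated, notes=notes,
    )


def classify_selection(ratio, neutral_band: float = 0.0) -> str:
    """Selection mode from Ka/Ks: < 1 purifying, = 1 neutral, > 1 positive.

    ``neutral_band`` widens the neutral class to ``|ratio - 1| <= band``.
    An undefined ratio gives ``undefined``.
    """
    if ratio is None:
        return UNDEFINED
    if ratio == math.inf:
        return POSITIVE
    if ratio < 1.0 - neutral_band:
        return PURIFYING
    if ratio > 1.0 + neutral_band:
        return POSITIVE
    return NEUTRAL


def divergence_time(Ks, lam: float = DEFAULT_LAMBDA):
    """Divergence time in MYA: T = Ks / (2 lambda), converted to 10^6 years."""
    if Ks is None:
        return None
    if Ks < 0:
        raise InvalidParameterError("Ks must be >= 0")
    if lam <= 0:
        raise InvalidParameterError("lambda must be positive")
    return Ks / (2.0 * lam) * 1e-6


def kaks_table(pairs: dict, *, lam: float = DEFAULT_LAMBDA) -> pd.DataFrame:
    """Ka/Ks/mode/T table for a mapping (id_a, id_b) -> (cds_a, cds_b)."""
    rows = []
    for pair, (a, b) in pairs.items():
        est = estimate_ka_ks(a, b, pair=pair, lam=lam)
        rows.append(
            {
                "gene_a": pair[0], "gene_b": pair[1], "Ka": est.Ka, "Ks": est.Ks,
                "ratio": est.ratio, "mode": est.mode, "T_mya": est.T_mya,
                "n_codons": est.n_codons_used, "saturated": est.saturated,
            }
        )
    return pd.DataFrame(rows)


def array_member_pairs(arrays):
    """All unordered within-array member pairs (the pair-level event table)."""
    pairs = []
    for arr in arrays:
        ms = arr.members
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                pairs.append((ms[i], ms[j]))
    return pairs


# ---------------------------------------------------------------------------
# GO tabulation
# ---------------------------------------------------------------------------

GO_CATEGORIES = ("biological_process", "cellular_component", "molecular_function")


def summarize_go(go_annotations: dict, go_metadata: dict, gene_subset):
    """Tabulate GO term and category proportions over a gene subset.

    ``go_annotations`` maps gene -> list of GO ids; ``go_metadata`` maps
    GO id -> (category, name).  Proportions are over term occurrences in the
    subset.  Returns ``(category_table, term_table, missing_ids)``.
    """
    occurrences = []
    missing = set()
    for gene in sorted(gene_subset):
        for go_id in go_annotations.get(gene, ()):
            meta = go_metadata.get(go_id)
            if meta is None:
                missing.add(go_id)
                continue
            occurrences.append((go_id, meta[0], meta[1]))
    if not occurrences:
        empty = pd.DataFrame(columns=["category", "count", "share_pct"])
        empty_t = pd.DataFrame(columns=["go_id", "category", "name", "count", "share_pct"])
        return empty, empty_t, sorted(missing)
    df = pd.DataFrame(occurrences, columns=["go_id", "category", "name"])
    total = len(df)
    cat = (
        df.groupby("category").size().rename("count").reset_index()
        .assign(share_pct=lambda d: (100.0 * d["count"] / total).round(2))
    )
    term = (
        df.groupby(["go_id", "category", "name"]).size().rename("count").reset_index()
        .assign(share_pct=lambda d: (100.0 * d["count"] / total).round(2))
        .sort_values(["count", "go_id"], ascending=[False, True], ignore_index=True)
    )
    return cat, term, sorted(missing)
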