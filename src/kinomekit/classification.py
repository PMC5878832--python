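"""Family and group assignment of typical kinases from per-family model
scores, with an explicit "unclassified" fallback, plus cross-species
catalogue comparison.

Each gene receives the family with the maximal bit score; ties go to the
lower E-value, then to the lexicographically smaller family name.  A gene
whose best hit fails the E-value threshold — or, optionally, whose winning
margin is small while its best E-value is poor — is reported as
``unclassified`` rather than forced into a family.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import CatalogueError

UNCLASSIFIED = "unclassified"

#: the 20 kinase groups used for rollups (the plant-specific group is
#: labelled Group-Pl)
KNOWN_GROUPS = (
    "AGC", "Aur", "BUB", "CAMK", "CK1", "CMGC", "IRE1", "NAK", "NEK", "PEK_GCN2",
    "RLK-Pelle", "SCY1", "STE", "TKL", "TLK", "TTK", "ULK", "WEE", "WNK",
    "Group-Pl",
)


@dataclass
class FamilyAssignment:
    gene_id: str
    family: str
    group: str
    score: float | None
    margin: float


def load_group_catalogue(path=None) -> dict:
    """family -> group mapping; the packaged catalogue by default."""
    if path is None:
        with resources.files("kinomekit.data").joinpath("family_groups.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["family"], df["group"]))


def infer_group(family: str, catalogue: dict | None = None) -> str:
    """Group for a family: catalogue lookup first, then longest-prefix match
    against the known group names (families are conventionally named
    ``<group>_<family>`` or ``<group>-<suffix>``)."""
    if family == UNCLASSIFIED:
        return UNCLASSIFIED
    if catalogue and family in catalogue:
        return catalogue[family]
    for g in sorted(KNOWN_GROUPS, key=len, reverse=True):
        if family == g or family.startswith(g + "_") or family.startswith(g + "-"):
            return g
    raise CatalogueError(f"family {family!r} not in catalogue and group not inferable")


def _norm_scores(score_table) -> pd.DataFrame:
    if isinstance(score_table, pd.DataFrame):
        return score_table
    rows = [
        (g, f, b, e) for (g, f), (b, e) in score_table.items()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "family", "bit_score", "evalue"])


def assign_family(
    score_table,
    min_evalue_for_assignment: float = 1e-5,
    *,
    catalogue: dict | None = None,
    margin_floor: float = 0.0,
    evalue_ceiling: float | None = None,
):
    """Assign each gene the argmax-bit-score family.

    ``score_table`` is a DataFrame (gene_id, family, bit_score, evalue) or a
    ``{(gene, family): (bit_score, evalue)}`` mapping.  A gene becomes
    ``unclassified`` when its best E-value is not below
    ``min_evalue_for_assignment``, or — when ``evalue_ceiling`` is set —
    when its margin (best minus second-best bit score) falls below
    ``margin_floor`` while its best E-value exceeds the ceiling.  The margin
    rule is the operational stand-in for a phylogenetic cross-check: genes
    with weak, ambiguous scores do not cluster reliably with any family.

    Row order of the table never affects the result.
    """
    df = _norm_scores(score_table)
    cat = catalogue if catalogue is not None else load_group_catalogue()
    out = []
    for gene, sub in df.groupby("gene_id", sort=True):
        sub = sub.sort_values(
            ["bit_score", "evalue", "family"], ascending=[False, True, True]
        )
        best = sub.iloc[0]
        margin = (
            float(best.bit_score - sub.iloc[1].bit_score) if len(sub) > 1 else 0.0
        )
        family = str(best.family)
        unclassified = best.evalue >= min_evalue_for_assignment
        if evalue_ceiling is not None and margin < margin_floor and best.evalue > evalue_ceiling:
            unclassified = True
        if unclassified:
            out.append(FamilyAssignment(str(gene), UNCLASSIFIED, UNCLASSIFIED,
                                        float(best.bit_score), margin))
        else:
            out.append(
                FamilyAssignment(str(gene), family, infer_group(family, cat),
                                 float(best.bit_score), margin)
            )
    return out


def share(count: int, total: int) -> float:
    """Percentage share reported to two decimals (e.g. 872/1168 -> 74.66)."""
    if total <= 0:
        raise CatalogueError("total must be positive")
    return round(100.0 * count / total, 2)


def rollup_groups(assignments, group_catalogue: dict | None = None):
    """Per-group and per-family count tables with percentage shares.

    ``assignments`` may be :class:`FamilyAssignment` objects or a mapping
    family -> count.  Shares are out of all classified + unclassified genes.
    Returns ``(group_table, family_table)`` DataFrames.
    """
    cat = group_catalogue if group_catalogue is not None else load_group_catalogue()
    if isinstance(assignments, dict):
        fam_counts = dict(assignments)
    else:
        fam_counts = {}
        for a in assignments:
            fam_counts[a.family] = fam_counts.get(a.family, 0) + 1
    total = sum(fam_counts.values())
    fam_rows = [
        {"family": f, "group": infer_group(f, cat), "count": c,
         "share_pct": share(c, total)}
        for f, c in sorted(fam_counts.items())
    ]
    family_table = pd.DataFrame(fam_rows)
    group_table = (
        family_table.groupby("group", as_index=False)["count"].sum()
        .assign(share_pct=lambda d: d["count"].map(lambda c: share(c, total)))
        .sort_values("count", ascending=False, ignore_index=True)
    )
    return group_table, family_table


def compare_kinomes(catalogue_a: dict, catalogue_b: dict) -> pd.DataFrame:
    """Compare two family-count catalogues sharing one family namespace.

    Families are partitioned into present-in-both / a-only / b-only; shared
    families get the expansion ratio ``count_a / count_b``.
    """
    fams = sorted(set(catalogue_a) | set(catalogue_b))
    rows = []
    for f in fams:
        ca, cb = catalogue_a.get(f, 0), catalogue_b.get(f, 0)
        if ca and cb:
            status, ratio = "both", ca / cb
        elif ca:
            status, ratio = "a_only", float("inf")
        else:
            status, ratio = "b_only", 0.0
        rows.append({"family": f, "count_a": ca, "count_b": cb,
                     "status": status, "ratio": ratio})
    return pd.DataFrame(rows)
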