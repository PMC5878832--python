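"""Family-level coexpression network from Pearson correlations.

Every unordered pair of included family profiles is tested once; pairs
whose two-sided p-value (from t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of
freedom) falls below alpha become signed edges.  No multiplicity correction
is applied by default, matching the raw 0.05 significance convention;
Benjamini–Hochberg is available behind a flag.  Families without any
significant partner stay out of the node count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError, InvalidParameterError


@dataclass(frozen=True)
class CoexpressionEdge:
    family_a: str
    family_b: str
    r: float
    p_value: float

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    degree: dict = field(default_factory=dict)
    max_degree_family: str | None = None


def pcc(x, y):
    """Pearson r and two-sided p after pairwise missing-value removal.

    Returns ``(nan, nan)`` for fewer than 3 complete pairs or a constant
    vector (no edge can be drawn from an undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _corr_pvalues(mat: np.ndarray):
    """All-pairs r and p for rows of ``mat`` (no missing values), vectorized."""
    n = mat.shape[1]
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    p[bad, :] = np.nan
    p[:, bad] = np.nan
    return r, p


def build_network(profiles, alpha: float = 0.05, *, design: dict | None = None,
                  condition_means: bool = True, bh_correct: bool = False):
    """Build the coexpression network from family expression profiles.

    ``profiles`` is a list of FamilyExpressionProfile (only those with
    ``included`` True are used) or a family x sample DataFrame.  With a
    ``design`` and ``condition_means`` (the default), each family vector is
    first averaged per condition so correlations are taken across the
    treatments rather than across raw replicates.  Edges are unordered
    pairs with p < alpha (strict); the sign is the sign of r.

    Returns ``(edges, summary)``.
    """
    if isinstance(profiles, pd.DataFrame):
        mat = profiles
    else:
        included = [p for p in profiles if p.included]
        mat = pd.DataFrame({p.family: p.vector for p in included}).T
    if mat.shape[0] < 2:
        return [], network_stats([])
    if design is not None and condition_means:
        conds = sorted(set(design.values()))
        mat = pd.DataFrame(
            {
                c: mat[[s for s in mat.columns if design.get(s) == c]].mean(axis=1)
                for c in conds
            }
        )
    if mat.shape[1] < 3:
        raise InvalidParameterError("need >= 3 points per profile for a p-value")
    fams = list(mat.index)
    values = mat.to_numpy(dtype=float)
    if np.isnan(values).any():
        # fall back to pairwise-complete correlations
        edges = []
        raw = []
        for i in range(len(fams)):
            for j in range(i + 1, len(fams)):
                r, p = pcc(values[i], values[j])
                raw.append((fams[i], fams[j], r, p))
    else:
        r, p = _corr_pvalues(values)
        raw = [
            (fams[i], fams[j], float(r[i, j]), float(p[i, j]))
            for i in range(len(fams))
            for j in range(i + 1, len(fams))
        ]
    pvals = np.array([x[3] for x in raw])
    if bh_correct:
        finite = np.isfinite(pvals)
        adj = np.full_like(pvals, np.nan)
        adj[finite] = stats.false_discovery_control(pvals[finite])
        pvals = adj
    edges = [
        CoexpressionEdge(*_ordered(a, b), r=r_, p_value=float(p_))
        for (a, b, r_, _), p_ in zip(raw, pvals)
        if np.isfinite(p_) and p_ < alpha
    ]
    return edges, network_stats(edges)


def _ordered(a, b):
    return (a, b) if a <= b else (b, a)


def network_stats(edges) -> NetworkSummary:
    """Degrees and sign partition; only families with degree >= 1 count as
    nodes.  The max-degree family breaks ties lexicographically."""
    seen = set()
    degree: dict[str, int] = {}
    n_pos = n_neg = 0
    for e in edges:
        key = _ordered(e.family_a, e.family_b)
        if key[0] == key[1]:
            raise IntegrityError(f"self-edge on {key[0]}")
        if key in seen:
            raise IntegrityError(f"duplicate edge {key}")
        seen.add(key)
        degree[key[0]] = degree.get(key[0], 0) + 1
        degree[key[1]] = degree.get(key[1], 0) + 1
        if e.r > 0:
            n_pos += 1
        else:
            n_neg += 1
    max_fam = None
    if degree:
        max_fam = min(degree, key=lambda f: (-degree[f], f))
    return NetworkSummary(
        n_nodes=len(degree),
        n_edges=len(edges),
        n_positive=n_pos,
        n_negative=n_neg,
        degree=dict(sorted(degree.items())),
        max_degree_family=max_fam,
    )


def edge_table(edges) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"family_a": e.family_a, "family_b": e.family_b, "r": e.r,
             "p_value": e.p_value, "sign": e.sign}
            for e in edges
        ],
        columns=["family_a", "family_b", "r", "p_value", "sign"],
    )


def to_graph(edges) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.family_a, e.family_b, r=e.r, p_value=e.p_value, sign=e.sign)
    return g


def write_graphml(edges, path):
    nx.write_graphml(to_graph(edges), path)


def write_sif(edges, path):
    """Simple interaction format: family_a <sign> family_b per line."""
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.family_a}\t{e.sign}\t{e.family_b}\n")
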