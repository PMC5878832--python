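"""Family-level expression aggregation and stress-response statistics.

Expression matrices are genes x samples DataFrames on a linear scale, with
a design mapping sample -> condition.  Family profiles are arithmetic means
over the members present in the matrix; a family enters downstream analyses
only when at least one third of its members are represented (exact rational
comparison, boundary inclusive).  Differential response is a log2 fold
change of arm means with a two-sided two-sample t-test on log-scale
replicate values; candidate genes are those induced more than two-fold at
p < 0.05 in at least three distinct stresses.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CatalogueError, InvalidParameterError, KinomekitError


@dataclass
class FamilyExpressionProfile:
    family: str
    vector: pd.Series  # per-sample mean over present members
    n_members_present: int
    n_members_total: int
    included: bool


@dataclass
class StressResponse:
    unit: str  # gene or family id
    condition: str
    log2fc: float | None
    p_value: float | None


def read_expression_tsv(source) -> pd.DataFrame:
    """Genes x samples matrix from TSV (first column = gene ids)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    return pd.read_csv(source, sep="\t", index_col=0)


def read_design_tsv(source) -> dict:
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t")
    return dict(zip(df["sample"], df["condition"]))


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    return Fraction(x).limit_denominator(10**6)


def family_profiles(matrix: pd.DataFrame, families: dict,
                    min_fraction=Fraction(1, 3)):
    """Average expression of each family's present members, per sample.

    Missing values are excluded per cell.  The inclusion flag compares the
    exact fraction present against ``min_fraction`` (>=, so 4 of 12 members
    passes a 1/3 rule).  A family with zero catalogued members raises
    :class:`CatalogueError`.
    """
    frac = _as_fraction(min_fraction)
    profiles = []
    present_idx = set(matrix.index)
    for family in sorted(families):
        members = list(families[family])
        if not members:
            raise CatalogueError(f"family {family} has no members")
        present = [g for g in members if g in present_idx]
        if present:
            vector = matrix.loc[present].mean(axis=0, skipna=True)
        else:
            vector = pd.Series(np.nan, index=matrix.columns)
        profiles.append(
            FamilyExpressionProfile(
                family=family,
                vector=vector,
                n_members_present=len(present),
                n_members_total=len(members),
                included=Fraction(len(present), len(members)) >= frac,
            )
        )
    return profiles


def profile_matrix(profiles, included_only: bool = True) -> pd.DataFrame:
    rows = [p for p in profiles if p.included or not included_only]
    return pd.DataFrame({p.family: p.vector for p in rows}).T


def normalize_profiles(matrix: pd.DataFrame, method: str = "zscore_by_row"):
    """Normalize a family x sample matrix.

    ``zscore_by_row`` standardizes each row to mean 0 / sd 1 (sample sd);
    constant rows become all-zero and are reported in the returned flag
    list.  ``log2`` takes log2 of positive values.  ``none`` returns the
    input unchanged.  Returns ``(matrix, flagged_rows)``.
    """
    flagged: list[str] = []
    if method == "none":
        return matrix, flagged
    if method == "log2":
        return np.log2(matrix.where(matrix > 0)), flagged
    if method != "zscore_by_row":
        raise InvalidParameterError(f"unknown normalization {method!r}")
    if matrix.shape[1] < 2:
        raise InvalidParameterError("z-scoring needs >= 2 samples")
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    out = matrix.sub(means, axis=0).div(sds.replace(0.0, np.nan), axis=0)
    const = sds == 0.0
    flagged = list(matrix.index[const])
    out.loc[const] = 0.0
    return out, flagged


def stress_response(matrix: pd.DataFrame, design: dict, condition: str,
                    control: str, families: dict | None = None):
    """Differential response of each unit (gene, or family when ``families``
    is given) in one condition versus control.

    log2fc is log2(mean treated / mean control) on the linear scale; the
    p-value is a two-sided two-sample t-test on log2 replicate values and is
    None with fewer than two replicates per arm.  Non-positive arm means
    leave log2fc as None.
    """
    treated_cols = [s for s, c in design.items() if c == condition and s in matrix.columns]
    control_cols = [s for s, c in design.items() if c == control and s in matrix.columns]
    if not treated_cols or not control_cols:
        raise InvalidParameterError(
            f"design has no samples for {condition!r} vs {control!r}"
        )
    if families is not None:
        profs = family_profiles(matrix, families)
        data = profile_matrix(profs, included_only=True)
    else:
        data = matrix
    out = []
    for unit, row in data.iterrows():
        t = row[treated_cols].astype(float).dropna()
        c = row[control_cols].astype(float).dropna()
        mt, mc = t.mean(), c.mean()
        if len(t) == 0 or len(c) == 0 or mt <= 0 or mc <= 0:
            out.append(StressResponse(str(unit), condition, None, None))
            continue
        log2fc = math.log2(mt / mc)
        p = None
        if len(t) >= 2 and len(c) >= 2 and (t > 0).all() and (c > 0).all():
            tt = stats.ttest_ind(np.log2(t), np.log2(c))
            p = float(tt.pvalue)
            if math.isnan(p):  # zero variance in both arms, identical means
                p = 1.0
        out.append(StressResponse(str(unit), condition, log2fc, p))
    return out


def select_candidates(responses, min_fold: float = 2.0, max_p: float = 0.05,
                      min_conditions: int = 3) -> dict:
    """Units induced more than ``min_fold`` (strict) at p < ``max_p``
    (strict) in at least ``min_conditions`` distinct conditions.

    Only up-regulation counts as induction.  Returns unit -> sorted list of
    supporting conditions, for qualifying units only.
    """
    support: dict[str, set] = {}
    log2_min = math.log2(min_fold)
    for r in responses:
        if r.log2fc is None or r.p_value is None:
            continue
        if r.log2fc > log2_min and r.p_value < max_p:
            support.setdefault(r.unit, set()).add(r.condition)
    return {
        u: sorted(conds)
        for u, conds in sorted(support.items())
        if len(conds) >= min_conditions
    }


def compute_fpkm(fragment_counts: dict, exon_model_length_bp: dict,
                 total_mapped_fragments: int) -> dict:
    """Fragments per kilobase of exon model per million mapped fragments."""
    if total_mapped_fragments <= 0:
        raise InvalidParameterError("total_mapped_fragments must be positive")
    out = {}
    for gene, count in fragment_counts.items():
        length = exon_model_length_bp.get(gene, 0)
        if length <= 0:
            raise InvalidParameterError(f"gene {gene} has non-positive exon length")
        out[gene] = count / (length / 1e3) / (total_mapped_fragments / 1e6)
    return out


def ddct_relative_expression(ct: dict, reference_gene: str, control_samples):
    """Relative expression by the delta-delta-Ct method.

    ``ct`` maps (gene, sample) -> cycle threshold.  Per sample,
    dCt = Ct_target - Ct_reference; ddCt subtracts the mean dCt over the
    control samples; fold change is 2**(-ddCt), so control samples average a
    fold change of 1 by construction.  A sample without a reference-gene Ct
    raises an error naming it.
    """
    control_samples = set(control_samples)
    samples_of: dict[str, list] = {}
    for gene, sample in ct:
        samples_of.setdefault(gene, []).append(sample)
    ref_ct = {}
    for sample in {s for ss in samples_of.values() for s in ss}:
        if (reference_gene, sample) not in ct:
            raise KinomekitError(f"reference gene not measured in sample {sample!r}")
        ref_ct[sample] = ct[(reference_gene, sample)]
    out = {}
    for gene, samples in samples_of.items():
        if gene == reference_gene:
            continue
        dct = {s: ct[(gene, s)] - ref_ct[s] for s in samples}
        ctrl = [dct[s] for s in samples if s in control_samples]
        if not ctrl:
            raise KinomekitError(f"gene {gene} has no control samples")
        base = sum(ctrl) / len(ctrl)
        for s in samples:
            out[(gene, s)] = 2.0 ** (-(dct[s] - base))
    return out
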