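import numpy as np
import pytest

from kinomekit.features import GeneModel, assign_ordinals


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_models(layout):
    """Build GeneModel list from (gene_id, chromosome, start) tuples.

    Each gene gets a single 1 kb exon; ordinals are assigned by start.
    """
    models = [
        GeneModel(
            gene_id=g, chromosome=c, strand="+",
            exons=[[s, s + 999]], start=s, end=s + 999,
        )
        for g, c, s in layout
    ]
    return assign_ordinals(models)


def random_genome(rng, max_genes=200, n_families=4):
    """Random gene layout with a random kinase subset sharing few families.

    Returns (models, kinase_genes, family_of).  Spacing straddles the 100 kb
    rule so tandem linkage is genuinely random.
    """
    n_chrom = int(rng.integers(1, 4))
    models = []
    counter = 0
    for c in range(n_chrom):
        n = int(rng.integers(5, max(6, max_genes // n_chrom + 1)))
        start = int(rng.integers(1, 10_000))
        for _ in range(n):
            counter += 1
            models.append((f"g{counter:04d}", f"chr{c + 1}", start))
            start += int(rng.integers(1_000, 120_000))
    models = make_models(models)
    gene_ids = [m.gene_id for m in models]
    n_kin = int(rng.integers(2, max(3, len(gene_ids) // 2)))
    kin = sorted(rng.choice(gene_ids, size=n_kin, replace=False))
    family_of = {g: f"FAM{int(rng.integers(0, n_families))}" for g in kin}
    return models, set(kin), family_of


def brute_force_tandem(models, kinase_genes, family_of,
                       max_intervening=5, max_gap_bp=100_000):
    """Independent oracle: all-pairs linkage + union-find components."""
    info = {m.gene_id: m for m in models}
    genes = [g for g in kinase_genes if g in info and g in family_of]
    parent = {g: g for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            ma, mb = info[a], info[b]
            if ma.chromosome != mb.chromosome or family_of[a] != family_of[b]:
                continue
            intervening = abs(ma.ordinal_index - mb.ordinal_index) - 1
            gap = abs(ma.start - mb.start)
            if intervening <= max_intervening and gap <= max_gap_bp:
                parent[find(a)] = find(b)
    comps = {}
    for g in genes:
        comps.setdefault(find(g), []).append(g)
    return sorted(
        sorted(members, key=lambda g: info[g].start)
        for members in comps.values()
        if len(members) >= 2
    )
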