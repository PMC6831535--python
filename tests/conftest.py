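"""Shared fixtures: hand-built checklists, matrices and random trees."""

import random

import pandas as pd
import pytest

from pteridiv import occurrences as occ
from pteridiv.checklist import TaxonTable
from pteridiv.phylodiv import parse_newick


def make_taxon(taxon_id, **overrides):
    """One checklist row with sensible defaults, overridable per field."""
    row = dict(
        taxon_id=taxon_id, name=f"Taxon {taxon_id}", rank="species",
        is_hybrid=False, lineage="fern", reproductive_mode="sexual",
        ploidy_class="diploid", phenology="evergreen", endemic=False,
        redlist="none", in_tree=True,
    )
    row.update(overrides)
    return row


def make_table(rows):
    return TaxonTable(pd.DataFrame(rows))


@pytest.fixture
def tiny_table():
    """Six natives spanning the trait levels, plus one hybrid."""
    return make_table([
        make_taxon("t1"),
        make_taxon("t2", reproductive_mode="apomictic",
                   ploidy_class="unknown", redlist="VU"),
        make_taxon("t3", reproductive_mode="both", phenology="seasonal_green"),
        make_taxon("t4", lineage="lycophyte", endemic=True, redlist="CR"),
        make_taxon("t5", ploidy_class="polyploid", rank="variety"),
        make_taxon("t6", reproductive_mode="unknown", in_tree=False),
        make_taxon("h1", is_hybrid=True, reproductive_mode="unknown",
                   ploidy_class="unknown", redlist="EN"),
    ])


def matrix_of(pairs, table):
    """Occurrence matrix from explicit (taxon_id, mesh_code) pairs."""
    df = pd.DataFrame(pairs, columns=["taxon_id", "mesh_code"])
    return occ.matrix_from_records(df, table)


def random_newick(rng: random.Random, n_tips: int, polytomy_prob=0.2):
    """Random rooted tree string: uniform joins, occasional 3-way merges,
    branch lengths uniform in (0.01, 1]."""
    parts = [f"s{i}" for i in range(n_tips)]
    parts = [f"{p}" for p in parts]
    while len(parts) > 1:
        take = 3 if (len(parts) >= 3 and rng.random() < polytomy_prob) else 2
        picks = rng.sample(range(len(parts)), take)
        children = ",".join(
            f"{parts[i]}:{rng.uniform(0.01, 1.0):.6f}" for i in picks)
        merged = f"({children})"
        for i in sorted(picks, reverse=True):
            parts.pop(i)
        parts.append(merged)
    return parts[0] + ";"


@pytest.fixture
def random_tree_factory():
    def factory(seed, n_tips, polytomy_prob=0.2):
        rng = random.Random(seed)
        return parse_newick(random_newick(rng, n_tips, polytomy_prob))
    return factory


def brute_force_pd(tree, tips, include_root_path=False):
    """Independent Faith's-PD oracle: mark edges on each tip-to-MRCA path
    (tip-to-root with *include_root_path*) and sum their lengths."""
    nodes = sorted({tree.tip_index[t] for t in tips if t in tree.tip_index})
    if len(nodes) < 2:
        return None

    def ancestors(v):
        out = []
        while v != tree.root:
            v = int(tree.parent[v])
            out.append(v)
        return out

    common = set(ancestors(nodes[0])) | {nodes[0]}
    for nd in nodes[1:]:
        common &= set(ancestors(nd)) | {nd}

    def depth(v):
        return len(ancestors(v))

    mrca = max(common, key=depth)
    stop = tree.root if include_root_path else mrca
    marked = set()
    for nd in nodes:
        v = nd
        while v != stop:
            marked.add(v)
            v = int(tree.parent[v])
    marked.discard(tree.root)
    return float(sum(tree.length[v] for v in marked))
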