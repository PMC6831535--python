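"""Faith's phylogenetic diversity (PD) over a rooted reference phylogeny.

Faith's PD of a taxon set is the total branch length of the minimal
subtree of the reference phylogeny connecting the set's tips.  Here the
reference tree is a rooted rbcL tree (a majority consensus, so polytomies
are allowed) whose branch lengths are expected substitutions per site.

Convention for "excluding the root": the pruned subtree is rooted at the
most recent common ancestor (MRCA) of the retained tips, and any residual
edge above that ancestor is discarded — the common unrooted-PD convention.
The alternative, retaining the full path from the MRCA up to the original
root, is available behind ``include_root_path=True`` so real data can
arbitrate between the two; the root's own edge length is never summed
under either convention.

Tips requested but absent from the tree (taxa without an rbcL sequence)
are dropped before computing and counted in the result.  PD is undefined —
a value, not an error — when fewer than two retained tips remain.

Implementation: one postorder pass counts, for every edge, how many of the
selected tips lie below it.  With ``k`` selected tips in the tree, the
edges of the MRCA-rooted spanning subtree are exactly those with a count
in ``[1, k)``; edges with count ``k`` form the MRCA-to-root path.  The
per-cell map version vectorises the same counts as a (cells x tips) @
(tips x edges) product in chunks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy
import numpy as np
import pandas as pd

from .errors import PhylogenyError
from .gridmaps import GridMap
from .occurrences import OccurrenceMatrix

__all__ = ["Phylogeny", "PDValue", "read_newick", "parse_newick",
           "faith_pd", "pd_map"]

logger = logging.getLogger(__name__)


class Phylogeny:
    """Rooted, branch-length tree over checklist taxa, in array form.

    ``parent[i]`` is the parent node of node *i* (-1 at the root);
    ``length[i]`` is the length of the edge above node *i* (NaN at the
    root, whose edge is never summed); ``postorder`` lists the node indices
    children-before-parents.  Tip names map one-to-one to checklist
    taxon_ids; no collapsing of subspecies or varieties to species.
    """

    def __init__(self, parent: np.ndarray, length: np.ndarray,
                 postorder: np.ndarray, tip_index: dict):
        self.parent = parent
        self.length = length
        self.postorder = postorder
        self.tip_index = tip_index          # taxon_id -> node index
        self.n_nodes = len(parent)
        (root,) = np.nonzero(parent < 0)
        self.root = int(root[0])

    @property
    def n_tips(self) -> int:
        return len(self.tip_index)

    @property
    def tip_labels(self) -> list:
        return list(self.tip_index)

    def total_length(self) -> float:
        """Sum of all non-root edge lengths."""
        mask = np.arange(self.n_nodes) != self.root
        return float(np.nansum(self.length[mask]))


@dataclass(frozen=True)
class PDValue:
    """Faith's PD of one taxon set.

    ``value`` is None when undefined (fewer than two tips of the set are in
    the tree); ``n_tips_used`` counts set members found in the tree and
    ``n_dropped`` those without a tip.
    """

    value: Optional[float]
    n_tips_used: int
    n_dropped: int = 0

    @property
    def defined(self) -> bool:
        return self.value is not None


def _from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    length = np.full(n, np.nan, dtype=float)
    tip_index: dict = {}
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise PhylogenyError(
                    "tree has an edge without a branch length; lengths are "
                    "required (no silent zero)"
                )
            length[i] = float(nd.edge.length)
            if length[i] < 0:
                raise PhylogenyError(
                    f"negative branch length {length[i]} in tree"
                )
        else:
            # Root: a length, if present, is carried but never summed.
            if nd.edge.length is not None:
                length[i] = float(nd.edge.length)
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else None
            if not label:
                raise PhylogenyError("tree has an unlabeled tip")
            if label in tip_index:
                raise PhylogenyError(f"duplicate tip label {label!r}")
            tip_index[label] = i
    # Preorder listing reversed is a valid postorder (children before
    # parents) for count accumulation.
    postorder = np.arange(n - 1, -1, -1, dtype=np.int64)
    return Phylogeny(parent, length, postorder, tip_index)


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick string with branch lengths."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise PhylogenyError(f"unparseable Newick: {exc}") from exc
    return _from_dendropy(tree)


def read_newick(path) -> Phylogeny:
    """Read a single rooted Newick tree file with branch lengths."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise PhylogenyError(f"unparseable Newick file {path}: {exc}") \
            from exc
    return _from_dendropy(tree)


def _tip_counts(tree: Phylogeny, tip_nodes: np.ndarray) -> np.ndarray:
    """Per-node count of selected tips at or below each node."""
    cnt = np.zeros(tree.n_nodes, dtype=np.int64)
    cnt[tip_nodes] = 1
    for v in tree.postorder:
        p = tree.parent[v]
        if p >= 0:
            cnt[p] += cnt[v]
    return cnt


def faith_pd(tree: Phylogeny, tips: Iterable[str], *,
             include_root_path: bool = False) -> PDValue:
    """Faith's PD of a taxon set on the reference tree.

    Set members without a tip are dropped (and counted in ``n_dropped``).
    Undefined when fewer than two retained tips remain.  With
    *include_root_path* the path from the retained tips' MRCA up to the
    original root is kept in the sum; by default it is excluded.
    """
    tips = list(dict.fromkeys(tips))  # de-duplicate, keep order
    present = [tree.tip_index[t] for t in tips if t in tree.tip_index]
    k = len(present)
    dropped = len(tips) - k
    if k < 2:
        return PDValue(None, k, dropped)
    cnt = _tip_counts(tree, np.asarray(present, dtype=np.int64))
    nonroot = np.arange(tree.n_nodes) != tree.root
    if include_root_path:
        used = nonroot & (cnt >= 1)
    else:
        used = nonroot & (cnt >= 1) & (cnt < k)
    return PDValue(float(np.sum(tree.length[used])), k, dropped)


def pd_map(m: OccurrenceMatrix, tree: Phylogeny, *,
           include_root_path: bool = False,
           chunk_cells: int = 2048) -> GridMap:
    """Per-cell Faith's PD over an occurrence matrix.

    The matrix should already be filtered to native, non-hybrid taxa (and
    to ferns only, for the fern-specific layer).  Cells with fewer than two
    in-tree taxa carry an undefined (NaN) value.  Taxa without an rbcL tip
    contribute to richness elsewhere but are dropped here; the total number
    of dropped presences is logged.
    """
    taxa = m.taxa
    in_tree = [t for t in taxa if t in tree.tip_index]
    dropped_taxa = len(taxa) - len(in_tree)
    if dropped_taxa:
        dropped_presences = int(
            m.presence.loc[[t for t in taxa if t not in tree.tip_index]]
            .to_numpy().sum())
        logger.info(
            "pd_map: %d taxa (%d presences) have no tree tip and are "
            "excluded from PD", dropped_taxa, dropped_presences)

    cells = m.presence.columns
    n_cells = len(cells)
    if not in_tree:
        return GridMap(pd.Series(np.nan, index=cells), name="pd")

    tip_nodes = np.asarray([tree.tip_index[t] for t in in_tree],
                           dtype=np.int64)
    # Incidence: below[j, e] = tip j lies at-or-below node e.  Built by one
    # postorder accumulation per tip-block, reused for every cell.
    n_nodes = tree.n_nodes
    below = np.zeros((len(in_tree), n_nodes), dtype=bool)
    below[np.arange(len(in_tree)), tip_nodes] = True
    for v in tree.postorder:
        p = tree.parent[v]
        if p >= 0:
            below[:, p] |= below[:, v]

    lengths = np.where(np.isnan(tree.length), 0.0, tree.length)
    lengths[tree.root] = 0.0
    presence = m.presence.loc[in_tree].to_numpy()  # tips x cells
    values = np.full(n_cells, np.nan)
    below_f = below.astype(np.float32)
    for start in range(0, n_cells, chunk_cells):
        stop = min(start + chunk_cells, n_cells)
        block = presence[:, start:stop].T.astype(np.float32)  # cells x tips
        counts = block @ below_f                              # cells x nodes
        k = block.sum(axis=1)                                 # tips per cell
        defined = k >= 2
        if not defined.any():
            continue
        cnt = counts[defined]
        kk = k[defined][:, None]
        if include_root_path:
            used = cnt >= 1
        else:
            used = (cnt >= 1) & (cnt < kk)
        values[start:stop][defined] = used @ lengths
    return GridMap(pd.Series(values, index=cells), name="pd",
                   provenance={"include_root_path": include_root_path,
                               "n_taxa_dropped": dropped_taxa})
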