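"""NJ/UPGMA tree building, column bootstrap, and species monophyly tests.

Trees are held as :class:`skbio.TreeNode` objects. Neighbor joining follows
Saitou & Nei with the Studier-Keppler Q-criterion and deterministic
tie-breaking (first minimal pair in creation order, leaves in label order);
negative branch lengths are clamped to zero with the deficit logged. UPGMA
is average-linkage agglomeration with node height equal to half the merge
distance, yielding a rooted ultrametric tree.

A species passes the monophyly test when its tips form one side of some
bipartition (unrooted trees) or exactly one clade (rooted trees). The
overall discrimination rate is the fraction of species that pass; singleton
species cannot fail and are counted as successes by default (an exclude
policy is available).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
from skbio import TreeNode

from .core_io import AlignedSequenceSet
from .distances import DistanceMatrix, distance_matrix

__all__ = [
    "MatrixError",
    "nj_tree",
    "upgma_tree",
    "bootstrap_support",
    "MonophylyReport",
    "monophyly_report",
    "tree_to_newick",
    "tree_from_newick",
    "write_monophyly_tsv",
]

logger = logging.getLogger(__name__)


class MatrixError(ValueError):
    """Distance matrix unusable for tree building (undefined entries)."""


def _check_defined(dm: DistanceMatrix) -> np.ndarray:
    bad = np.argwhere(np.isnan(dm.values))
    if len(bad):
        i, j = bad[0]
        raise MatrixError(
            f"undefined distance between {dm.labels[i]!r} and {dm.labels[j]!r}"
        )
    return dm.values.astype(float).copy()


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.debug("clamping negative branch length %.6g at %s", length, context)
        return 0.0
    return length


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    The returned :class:`TreeNode` has a trifurcating root representing the
    unrooted topology. Requires >= 3 labels and a fully defined matrix.
    Ties in the Q-criterion break to the first minimal pair in creation
    order, so results are platform-independent.
    """
    if len(dm) < 3:
        raise ValueError("neighbor joining requires at least 3 sequences")
    D = _check_defined(dm)
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    active = list(range(len(nodes)))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first minimal entry in row-major order == creation-order tie-break
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        vj = dij - vi
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clamp(vi, f"{child_i.name or 'node'}")
        child_j.length = _clamp(vj, f"{child_j.name or 'node'}")
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row
        D[:-1, -1] = new_row
        nodes.append(parent)
        new_index = len(nodes) - 1
        active = [k for k in active if k not in (i, j)] + [new_index]

    # resolve the final three nodes around a trifurcating root
    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, v in ((a, va), (b, vb), (c, vc)):
        nodes[idx].length = _clamp(v, f"{nodes[idx].name or 'node'}")
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def upgma_tree(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) agglomeration; returns a rooted ultrametric tree.

    Node height is half the merge distance; tip branch lengths therefore sum
    to equal root-to-tip distances. Requires >= 2 labels.
    """
    if len(dm) < 2:
        raise ValueError("UPGMA requires at least 2 sequences")
    D = _check_defined(dm)
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    heights = [0.0] * len(nodes)
    sizes = [1] * len(nodes)
    active = list(range(len(nodes)))

    while len(active) > 1:
        m = len(active)
        sub = D[np.ix_(active, active)]
        np.fill_diagonal(sub, np.inf)
        flat = int(np.argmin(sub))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        height = dij / 2.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, height - heights[i])
        child_j.length = max(0.0, height - heights[j])
        parent = TreeNode(children=[child_i, child_j])
        ni, nj = sizes[i], sizes[j]
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = (ni * D[i, k] + nj * D[j, k]) / (ni + nj)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row
        D[:-1, -1] = new_row
        nodes.append(parent)
        heights.append(height)
        sizes.append(ni + nj)
        new_index = len(nodes) - 1
        active = [k for k in active if k not in (i, j)] + [new_index]

    return nodes[active[0]]


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode, all_tips: frozenset[str]) -> set[frozenset[str]]:
    """Canonical non-trivial bipartitions (side not containing the first tip)."""
    ref = min(all_tips)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        if ref in side:
            side = all_tips - side
        out.add(side)
    return out


def bootstrap_support(
    aln: AlignedSequenceSet,
    method: Literal["nj", "upgma"] = "nj",
    replicates: int = 100,
    seed: int = 0,
) -> TreeNode:
    """Column bootstrap: resample alignment columns, rebuild, count bipartitions.

    The tree built from the original alignment has each internal edge
    annotated (``node.support``, also written as the internal node name)
    with the percentage of valid replicates whose tree contains the same
    bipartition. Replicates whose resampled distance matrix has undefined
    entries are skipped and counted. Reproducible given ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    build = nj_tree if method == "nj" else upgma_tree
    base_dm = distance_matrix(aln)
    tree = build(base_dm)
    all_tips = frozenset(aln.ids)
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    n_cols = aln.alignment_length
    valid = 0
    skipped = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = AlignedSequenceSet.from_records(
            (
                r.id,
                r.species,
                r.population,
                "".join(r.residues[c] for c in cols),
            )
            for r in aln.records
        )
        try:
            rep_tree = build(distance_matrix(resampled))
        except MatrixError:
            skipped += 1
            logger.warning("bootstrap replicate skipped: undefined distances")
            continue
        valid += 1
        for bp in _bipartitions(rep_tree, all_tips):
            counts[bp] = counts.get(bp, 0) + 1
    if skipped:
        logger.warning("%d/%d bootstrap replicates skipped", skipped, replicates)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        canon = all_tips - side if min(all_tips) in side else side
        support = 100.0 * counts.get(canon, 0) / max(valid, 1)
        node.support = support  # serialized as the internal-node label
    return tree


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------

@dataclass
class MonophylyReport:
    per_species: dict[str, bool]
    n_tips_per_species: dict[str, int]
    singleton_policy: Literal["count_as_success", "exclude"]
    n_species_counted: int
    n_monophyletic: int

    @property
    def discrimination_rate(self) -> float:
        if self.n_species_counted == 0:
            return float("nan")
        return self.n_monophyletic / self.n_species_counted


def monophyly_report(
    tree: TreeNode,
    species_map: Mapping[str, str],
    rooted: bool = False,
    singleton_policy: Literal["count_as_success", "exclude"] = "count_as_success",
) -> MonophylyReport:
    """Test, per species, whether its tips form an exclusive group.

    For unrooted trees a species passes when some edge's bipartition puts
    exactly its tips on one side; for rooted trees, when some clade equals
    its tip set. Singletons trivially pass and either count as successes
    (default) or are excluded from the rate.
    """
    tips = [t.name for t in tree.tips()]
    unmapped = [t for t in tips if t not in species_map]
    if unmapped:
        raise KeyError(f"tree tips missing from species map: {unmapped[:5]}")
    all_tips = frozenset(tips)
    clades: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clades.add(frozenset(t.name for t in node.tips()))

    species_tips: dict[str, set[str]] = {}
    for tip in tips:
        species_tips.setdefault(species_map[tip], set()).add(tip)

    per_species: dict[str, bool] = {}
    for sp, sp_tips in species_tips.items():
        s = frozenset(sp_tips)
        if len(s) == 1 or s == all_tips:
            per_species[sp] = True
        elif rooted:
            per_species[sp] = s in clades
        else:
            # any edge's bipartition counts, including a tip edge whose far
            # side is every other tip (complement of size 1)
            per_species[sp] = (
                s in clades
                or (all_tips - s) in clades
                or len(all_tips - s) == 1
            )

    counted = {
        sp: ok
        for sp, ok in per_species.items()
        if singleton_policy == "count_as_success" or len(species_tips[sp]) > 1
    }
    return MonophylyReport(
        per_species=per_species,
        n_tips_per_species={sp: len(t) for sp, t in species_tips.items()},
        singleton_policy=singleton_policy,
        n_species_counted=len(counted),
        n_monophyletic=sum(counted.values()),
    )


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def tree_to_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick (supports stored as internal-node labels)."""
    buf = StringIO()
    tree.write(buf)
    newick = buf.getvalue()
    if path is not None:
        Path(path).write_text(newick)
    return newick


def tree_from_newick(source: str | Path) -> TreeNode:
    """Read a Newick tree from a string or file path.

    Internal node labels that parse as numbers are also exposed as
    ``node.support``.
    """
    text = None
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and not source.lstrip().startswith("("):
        text = Path(source).read_text()
    else:
        text = source
    tree = TreeNode.read(StringIO(text))
    for node in tree.non_tips(include_self=False):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree


def write_monophyly_tsv(report: MonophylyReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn_tips\tmonophyletic\n")
        for sp, ok in sorted(report.per_species.items()):
            fh.write(f"{sp}\t{report.n_tips_per_species[sp]}\t{ok}\n")
        fh.write(
            f"#discrimination_rate\t{report.discrimination_rate:.4f}"
            f"\t({report.n_monophyletic}/{report.n_species_counted},"
            f" singletons={report.singleton_policy})\n"
        )
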