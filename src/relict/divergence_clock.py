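"""Species divergence from third codon positions, compared to TE copy ages.

Third codon positions of single-copy orthologs evolve nearly neutrally, so
their pairwise K80 distance is a usable molecular clock on the same scale
as TE copy-vs-consensus divergence (both computed by
:func:`relict.te_landscape.k2p`, deliberately shared). With each internal
tree node annotated by its median spanning-pair distance, the TE
divergence landscape can be split at a node's value: copies younger than
the split are lineage-specific insertions, older copies predate it.
No rate correction is applied — the comparison is a deliberate
apples-to-apples approximation on raw K80 distances.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .te_landscape import SaturationError, k2p

__all__ = [
    "SpeciesDistanceMatrix",
    "third_positions",
    "species_matrix",
    "annotate_nodes",
    "te_vs_node",
]


@dataclass(frozen=True)
class SpeciesDistanceMatrix:
    species: tuple[str, ...]
    matrix: pd.DataFrame      # symmetric, zero diagonal; median over genes
    per_gene: pd.DataFrame    # long table: gene, sp_a, sp_b, d


def third_positions(alignment: Mapping[str, str]) -> dict[str, str]:
    """Extract every third column of an in-frame codon alignment."""
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    (length,) = lengths or {0}
    if length % 3 != 0:
        raise ValueError(f"alignment length {length} not divisible by 3")
    return {name: seq[2::3] for name, seq in alignment.items()}


def species_matrix(
    gene_alignments: Mapping[str, Mapping[str, str]],
    shared_only: bool = True,
    mode: str = "median",
) -> SpeciesDistanceMatrix:
    """Median pairwise third-position K80 distance across genes.

    ``gene_alignments`` maps gene id -> {species: aligned CDS}. With
    ``shared_only`` genes missing any species are dropped entirely.
    ``mode='median'`` takes the median over per-gene distances;
    ``'concatenate'`` computes one distance on the concatenated
    third-position alignment. Gene/pair combinations that are saturated or
    have no comparable columns are skipped; a pair with no scorable gene
    at all is an error.
    """
    if mode not in ("median", "concatenate"):
        raise ValueError(f"unknown mode: {mode!r}")
    all_species = sorted({sp for aln in gene_alignments.values() for sp in aln})
    if len(all_species) < 2:
        raise ValueError("need at least 2 species")
    genes = dict(gene_alignments)
    if shared_only:
        genes = {g: a for g, a in genes.items() if set(a) >= set(all_species)}

    rows = []
    concat: dict[tuple[str, str], tuple[list[str], list[str]]] = {}
    for gene in sorted(genes):
        third = third_positions(genes[gene])
        present = sorted(third)
        for i, sa in enumerate(present):
            for sb in present[i + 1 :]:
                if mode == "concatenate":
                    pair = concat.setdefault((sa, sb), ([], []))
                    pair[0].append(third[sa])
                    pair[1].append(third[sb])
                    continue
                try:
                    d = k2p(third[sa], third[sb]).d
                except (SaturationError, ValueError):
                    continue
                rows.append({"gene": gene, "sp_a": sa, "sp_b": sb, "d": d})

    per_gene = pd.DataFrame(rows, columns=["gene", "sp_a", "sp_b", "d"])
    n = len(all_species)
    mat = np.zeros((n, n))
    for i, sa in enumerate(all_species):
        for j in range(i + 1, n):
            sb = all_species[j]
            if mode == "concatenate":
                chunks = concat.get((sa, sb))
                if not chunks:
                    raise ValueError(f"no genes scorable for pair ({sa}, {sb})")
                try:
                    d = k2p("".join(chunks[0]), "".join(chunks[1])).d
                except (SaturationError, ValueError) as exc:
                    raise ValueError(f"pair ({sa}, {sb}) unscorable: {exc}") from exc
            else:
                ds = per_gene[(per_gene.sp_a == sa) & (per_gene.sp_b == sb)]["d"]
                if ds.empty:
                    raise ValueError(f"no genes scorable for pair ({sa}, {sb})")
                d = float(ds.median())
            mat[i, j] = mat[j, i] = d
    matrix = pd.DataFrame(mat, index=all_species, columns=all_species)
    return SpeciesDistanceMatrix(tuple(all_species), matrix, per_gene)


def annotate_nodes(tree, matrix: SpeciesDistanceMatrix | pd.DataFrame) -> pd.DataFrame:
    """Annotate each internal node with its spanning-pair K80 divergence.

    A pair spans a node when the node is the pair's MRCA; the node's
    divergence is the median (min also reported) over those pairs. Nested
    nodes should have non-decreasing divergence toward the root; the
    ``monotone_ok`` column flags nodes whose divergence falls below that
    of any descendant internal node.
    """
    import dendropy

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    dm = matrix.matrix if isinstance(matrix, SpeciesDistanceMatrix) else matrix

    rows = []
    node_div: dict[int, float] = {}
    node_children_div: dict[int, list[float]] = {}
    counter = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        counter += 1
        node_id = node.label or f"node_{counter}"
        child_tip_sets = []
        for child in node.child_nodes():
            tips = [lf.taxon.label for lf in child.leaf_iter() if lf.taxon]
            child_tip_sets.append([t for t in tips if t in dm.index])
        pair_ds = []
        for a in range(len(child_tip_sets)):
            for b in range(a + 1, len(child_tip_sets)):
                for ta in child_tip_sets[a]:
                    for tb in child_tip_sets[b]:
                        pair_ds.append(float(dm.loc[ta, tb]))
        if not pair_ds:
            continue
        med = float(np.median(pair_ds))
        node_div[id(node)] = med
        desc = [
            node_div[id(c)] for c in node.preorder_iter()
            if id(c) in node_div and c is not node
        ]
        rows.append(
            {
                "node_id": node_id,
                "n_tips": sum(len(s) for s in child_tip_sets),
                "tips": ",".join(sorted(t for s in child_tip_sets for t in s)),
                "median_k2p": med,
                "min_k2p": float(min(pair_ds)),
                "n_pairs": len(pair_ds),
                "monotone_ok": all(med >= d - 1e-12 for d in desc),
            }
        )
    return pd.DataFrame(rows)


def te_vs_node(
    landscape: pd.DataFrame,
    node_divergence: float,
    overflow_bp: int = 0,
    unscorable_bp: int = 0,
) -> dict:
    """Partition TE bp at a node's divergence value.

    Copies less diverged than the node post-date the species split
    (lineage-specific); more diverged copies pre-date it (shared). The bin
    containing the node value is apportioned linearly. Fractions are over
    scorable, in-horizon bp only; the ``caveat`` flag is raised when >= 10%
    of total bp sits in the overflow/unscorable buckets, where the
    partition is unreliable.
    """
    if node_divergence < 0:
        raise ValueError("node divergence must be non-negative")
    if node_divergence >= 0.5:
        warnings.warn(
            "node divergence beyond the 50% TE detection horizon; "
            "pre/post-split fractions are not meaningful",
            stacklevel=2,
        )
    below = 0.0
    total = 0.0
    for row in landscape.itertuples(index=False):
        total += row.bp
        if row.bin_high <= node_divergence:
            below += row.bp
        elif row.bin_low < node_divergence:
            frac = (node_divergence - row.bin_low) / (row.bin_high - row.bin_low)
            below += row.bp * frac
    if total == 0:
        raise ValueError("empty landscape")
    post_split = below / total
    flagged = overflow_bp + unscorable_bp
    return {
        "post_split_fraction": post_split,
        "pre_split_fraction": 1.0 - post_split,
        "scored_bp": total,
        "flagged_bp": flagged,
        "caveat": flagged >= 0.1 * (total + flagged),
    }
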