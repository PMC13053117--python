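"""Phylogenetic correlation structure from a Newick tree.

The species random effect in the toxicity model is given a Brownian-motion
covariance: the expected covariance between two species is the depth of
their most recent common ancestor (shared root-to-MRCA path length), so the
correlation between tips *i* and *j* of an ultrametric tree is

    C[i, j] = depth(MRCA(i, j)) / total depth.

For non-ultrametric input the same quantity is normalised per pair by
``sqrt(depth_i * depth_j)``, which is the correlation implied by the BM
covariance matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloCorrelation",
    "read_newick",
    "write_newick",
    "prune_to",
    "correlation_matrix",
]


@dataclass
class PhyloCorrelation:
    """Ordered species list with the BM correlation matrix between them."""

    species: list[str]
    matrix: np.ndarray
    repaired: bool = field(default=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        s = len(self.species)
        if self.matrix.shape != (s, s):
            raise ValueError("matrix shape does not match species list")

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor, with a tiny jitter if C is singular."""
        try:
            return np.linalg.cholesky(self.matrix)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * np.eye(len(self.species))
            return np.linalg.cholesky(self.matrix + jitter)

    def reorder(self, species: list[str]) -> "PhyloCorrelation":
        """Return a copy with rows/columns ordered as ``species``."""
        missing = [s for s in species if s not in self.species]
        if missing:
            raise KeyError(f"species not in correlation matrix: {missing}")
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelation(list(species), self.matrix[np.ix_(idx, idx)], self.repaired)


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick tree from a path or a literal Newick string.

    Underscores in labels are preserved verbatim (no conversion to spaces).
    Raises ``ValueError`` on malformed input, including the parser's
    position information where available.
    """
    if "(" in source or ";" in source:
        data = source
    else:
        with open(source) as fh:
            data = fh.read()
    if ";" not in data:
        raise ValueError("malformed Newick: missing terminating ';'")
    try:
        tree = dendropy.Tree.get(
            data=data, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tip labels are not unique")
    return tree


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    """Serialise a tree to Newick; writes to ``path`` if given."""
    s = tree.as_string(schema="newick", unquoted_underscores=True,
                       suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s.strip()


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    # string round-trip: guarantees an independent taxon namespace
    return read_newick(write_newick(tree))


def prune_to(tree: dendropy.Tree, mapping: dict[str, str]) -> dendropy.Tree:
    """Induced subtree on the mapped tips, relabelled to species ids.

    ``mapping`` sends each study species id to a tip label of ``tree``
    (the "closest available tip" substitution is the caller's contract;
    nothing is guessed here).  Degree-2 internal nodes are suppressed and
    path lengths between retained tips are preserved.
    """
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unmapped = sorted(t for t in mapping.values() if t not in tip_labels)
    if unmapped:
        raise KeyError(f"mapped tips absent from tree: {unmapped}")
    tips = list(mapping.values())
    if len(tips) != len(set(tips)):
        dup = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"multiple species map to the same tip: {dup}")
    sub = _clone(tree).extract_tree_with_taxa_labels(set(tips))
    tip_to_species = {v: k for k, v in mapping.items()}
    for leaf in sub.leaf_node_iter():
        leaf.taxon.label = tip_to_species[leaf.taxon.label]
    return sub


def correlation_matrix(
    tree: dendropy.Tree, psd_tol: float = 1e-8
) -> PhyloCorrelation:
    """Brownian-motion correlation matrix between the tips of ``tree``.

    Shared depth of a pair is computed as ``(d_i + d_j - patristic_ij)/2``
    from root-to-tip and patristic distances.  Eigenvalues in
    ``(-psd_tol, 0)`` (numerical noise) are clipped and the matrix
    reconstructed; larger violations raise.
    """
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    species = [l.taxon.label for l in leaves]
    n = len(species)
    if n < 1:
        raise ValueError("tree has no tips")
    depth = np.array([l.distance_from_root() for l in leaves], dtype=float)
    if np.any(depth <= 0):
        raise ValueError("zero root-to-tip depth: tree has no usable branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {l.taxon.label: l.taxon for l in leaves}
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            dij = pdm.patristic_distance(taxa[species[i]], taxa[species[j]])
            shared = 0.5 * (depth[i] + depth[j] - dij)
            C[i, j] = C[j, i] = shared / np.sqrt(depth[i] * depth[j])
    C = np.clip(C, -1.0, 1.0)

    repaired = False
    w = np.linalg.eigvalsh(C)
    if w.min() < -psd_tol:
        raise ValueError(
            f"correlation matrix is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )
    if w.min() < 0:
        ew, ev = np.linalg.eigh(C)
        ew = np.clip(ew, 1e-10, None)
        C = ev @ np.diag(ew) @ ev.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        repaired = True
    return PhyloCorrelation(species, C, repaired)


def write_correlation(corr: PhyloCorrelation, path: str) -> None:
    """Write the matrix as TSV with a header row of species ids."""
    import pandas as pd

    pd.DataFrame(corr.matrix, index=corr.species, columns=corr.species).to_csv(
        path, sep="\t", index_label="species"
    )


def read_mapping(path: str) -> dict[str, str]:
    """Two-column delimited mapping table: species_id <tab> tip_label."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("mapping table needs two columns: species_id, tip_label")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
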