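"""Bootstrap consensus clustering of transmembrane-domain peptides.

Substrates of intramembrane proteases from the same family tend to carry
similar TMD sequences, so grouping MB-TFs by TMD similarity can hint at a
shared release mechanism.  The procedure: progressively align the TMD
peptides (BLOSUM62, affine gaps), resample alignment columns with
replacement, build a neighbor-joining tree per replicate from a
normalized substitution-matrix dissimilarity (gaps scored as maximal
mismatch), and summarise the replicates as a majority-rule consensus tree
whose internal-node supports are bipartition frequencies in percent.
High-support clades (e.g. support > 70 or > 90) are then read off as
candidate substrate groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import subprocess
import tempfile

import numpy as np
import biotite.sequence.align as balign
import dendropy
from Bio import SeqIO
from skbio import DistanceMatrix
from skbio.tree import nj

__all__ = [
    "TMDAlignment",
    "ConsensusTree",
    "align_tmds",
    "bootstrap_consensus",
    "clusters_above",
]

_GAP = "-"


@dataclass(frozen=True)
class TMDAlignment:
    """A gapped multiple alignment of TMD peptides (one row per protein)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    parameters: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def ungapped(self, protein_id: str) -> str:
        return self.rows[self.ids.index(protein_id)].replace(_GAP, "")


@dataclass
class ConsensusTree:
    """A majority-rule consensus tree with bootstrap supports.

    ``newick`` carries supports as internal-node labels in [0, 100].
    ``bipartition_freqs`` maps a normalized leaf-id frozenset (the side
    of the split not containing the alphabetically first leaf) to its
    replicate frequency in percent, for arbitrary support queries.
    """

    newick: str
    tree: dendropy.Tree
    leaf_ids: tuple[str, ...]
    replicates: int
    seed: int
    bipartition_freqs: dict[frozenset, float] = field(default_factory=dict)
    note: str = ""

    def support_of(self, leaf_set: Sequence[str]) -> float:
        """Bootstrap support (percent) of the bipartition separating
        ``leaf_set`` from the remaining leaves."""
        group = frozenset(leaf_set)
        anchor = min(self.leaf_ids)
        if anchor in group:
            group = frozenset(self.leaf_ids) - group
        return self.bipartition_freqs.get(group, 0.0)


def align_tmds(peptides: dict[str, str]) -> TMDAlignment:
    """Progressive global alignment of TMD peptides.

    Runs MAFFT (G-INS-1 strategy: global pairwise alignments, one
    progressive round, BLOSUM62, affine gaps), which handles the short
    and often mutually unrelated TMD peptides robustly.  Requires at
    least 3 peptides of >= 12 residues each; deterministic for a fixed
    input order (output keeps input order).
    """
    if len(peptides) < 3:
        raise ValueError("TMD alignment requires at least 3 peptides")
    short = [pid for pid, pep in peptides.items() if len(pep) < 12]
    if short:
        raise ValueError(f"TMD peptides shorter than 12 residues: {short}")
    ids = tuple(peptides.keys())
    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        for j, pid in enumerate(ids):
            fh.write(f">s{j}\n{peptides[pid]}\n")
        in_path = fh.name
    try:
        proc = subprocess.run(
            ["mafft", "--globalpair", "--maxiterate", "0", "--quiet", in_path],
            capture_output=True, text=True, check=True)
    except FileNotFoundError as exc:  # pragma: no cover
        raise RuntimeError("mafft executable not found on PATH") from exc
    finally:
        import os
        os.unlink(in_path)
    gapped = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(__import__("io").StringIO(proc.stdout),
                                     "fasta")}
    rows = tuple(gapped[f"s{j}"] for j in range(len(ids)))
    for pid, row in zip(ids, rows):
        if row.replace(_GAP, "") != peptides[pid].upper():
            raise RuntimeError(f"alignment row for {pid} does not ungap "
                               f"to its input peptide")
    return TMDAlignment(
        ids=ids, rows=rows,
        parameters={"program": "mafft --globalpair --maxiterate 0",
                    "matrix": "BLOSUM62", "gaps": "affine"},
    )


def _dissimilarity_table() -> np.ndarray:
    """Per-pair residue dissimilarity in [0, 1] from BLOSUM62.

    d(a, b) = 1 - (S(a,b) - Smin) / (max(S(a,a), S(b,b)) - Smin), so
    identical residues have distance 0 and dissimilar pairs approach 1.
    Indexed by ``ord(char) - ord('A')`` with the gap in slot 26; gap
    against a residue scores 1 (maximal mismatch), gap against gap 0
    (identical states).
    """
    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    alph = matrix.get_alphabet1()
    letters = [str(s) for s in alph]
    scores = matrix.score_matrix()
    smin = scores.min()
    table = np.ones((27, 27))
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            ai, bj = ord(a) - 65, ord(b) - 65
            if 0 <= ai < 26 and 0 <= bj < 26:
                denom = max(scores[i, i], scores[j, j]) - smin
                d = 1.0 - (scores[i, j] - smin) / denom
                table[ai, bj] = min(1.0, max(0.0, d))
    table[26, 26] = 0.0
    return table


_DISSIM = None


def _pairwise_distances(rows_idx: np.ndarray) -> np.ndarray:
    """Mean per-column dissimilarity between all row pairs.

    ``rows_idx`` is an (n_rows, n_cols) integer matrix of
    ``ord(char) - 65`` values, with gaps encoded as 26.
    """
    global _DISSIM
    if _DISSIM is None:
        _DISSIM = _dissimilarity_table()
    n = rows_idx.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        d = _DISSIM[rows_idx[i][None, :], rows_idx]
        dm[i, :] = d.mean(axis=1)
    dm = (dm + dm.T) / 2.0
    np.fill_diagonal(dm, 0.0)
    return dm


def _encode(alignment: TMDAlignment) -> np.ndarray:
    arr = np.frombuffer("".join(alignment.rows).encode(), dtype=np.uint8)
    arr = arr.reshape(len(alignment.rows), alignment.n_columns).astype(np.intp) - 65
    arr[arr < 0] = 26  # '-' and any other non-letter -> gap slot
    arr[arr > 25] = 26
    return arr


def _nj_newick(dm: np.ndarray, ids: Sequence[str]) -> str:
    skdm = DistanceMatrix(dm, ids=list(ids))
    return str(nj(skdm))


def bootstrap_consensus(alignment: TMDAlignment, replicates: int = 1000,
                        seed: int = 0) -> ConsensusTree:
    """Column-bootstrap neighbor-joining consensus of a TMD alignment.

    Per replicate, alignment columns are resampled with replacement, a
    neighbor-joining tree is built from normalized BLOSUM62 dissimilarity
    (gap = maximal mismatch), and the majority-rule (> 50%) consensus of
    all replicate trees is returned with supports in percent.
    Reproducible for a fixed seed (per-replicate RNG substreams are
    derived deterministically from it).
    """
    if replicates < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    ids = alignment.ids
    anchor = min(ids)
    encoded = _encode(alignment)
    n_cols = alignment.n_columns

    dm_full = _pairwise_distances(encoded)
    if np.allclose(dm_full, 0.0):
        # all rows identical: a star tree, with a note
        newick = "(" + ",".join(ids) + ");"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return ConsensusTree(
            newick=newick, tree=tree, leaf_ids=ids,
            replicates=replicates, seed=seed,
            note="all sequences identical; star tree",
        )

    streams = np.random.SeedSequence(seed).spawn(replicates)
    tns = dendropy.TaxonNamespace(list(ids))
    trees = dendropy.TreeList(taxon_namespace=tns)
    counts: dict[frozenset, int] = {}
    for ss in streams:
        rng = np.random.default_rng(ss)
        cols = rng.integers(0, n_cols, size=n_cols)
        dm = _pairwise_distances(encoded[:, cols])
        t = dendropy.Tree.get(data=_nj_newick(dm, ids), schema="newick",
                              taxon_namespace=tns)
        trees.append(t)
        seen = set()
        for edge in t.preorder_edge_iter():
            node = edge.head_node
            if node.is_leaf() or node.parent_node is None:
                continue
            leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
            group = frozenset(ids) - leaves if anchor in leaves else leaves
            if 1 < len(group) < len(ids) - 1:  # non-trivial splits only
                seen.add(group)
        for g in seen:
            counts[g] = counts.get(g, 0) + 1

    freqs = {g: 100.0 * c / replicates for g, c in counts.items()}
    consensus = trees.consensus(min_freq=0.5, support_as_percentages=True)
    for node in consensus.preorder_internal_node_iter():
        if node.parent_node is not None and node.support is not None:
            node.label = f"{node.support:g}"
    newick = consensus.as_string(schema="newick", suppress_rooting=True).strip()
    return ConsensusTree(
        newick=newick, tree=consensus, leaf_ids=ids,
        replicates=replicates, seed=seed, bipartition_freqs=freqs,
    )


def best_bipartition(tree: ConsensusTree) -> tuple[frozenset, float]:
    """The highest-supported non-trivial split of the leaf set.

    Ties are broken toward the most balanced split, then by lexicographic
    leaf ids.  Returns (one side of the split, support in percent); the
    other side is the complement.  Useful for reading a two-group
    structure off an unrooted consensus tree.
    """
    if not tree.bipartition_freqs:
        raise ValueError("tree has no recorded bipartitions (star tree?)")
    n = len(tree.leaf_ids)

    def sort_key(item):
        group, freq = item
        balance = abs(len(group) - n / 2)
        return (-freq, balance, tuple(sorted(group)))

    group, freq = min(tree.bipartition_freqs.items(), key=sort_key)
    return group, freq


def clusters_above(tree: ConsensusTree, threshold: float) -> list[frozenset]:
    """Maximal clades whose subtending bootstrap support exceeds
    ``threshold`` (leaf-id sets; descendants of a reported clade are not
    reported again)."""
    out: list[frozenset] = []

    def walk(node) -> None:
        support = getattr(node, "support", None)
        if (support is not None and support > threshold
                and node.parent_node is not None and not node.is_leaf()):
            out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
            return
        for child in node.child_nodes():
            walk(child)

    walk(tree.tree.seed_node)
    return out
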