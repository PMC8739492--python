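"""Distance phylogenetics for carrier-protein and KS classification.

Pipeline: pairwise proportion of differing sites (with pairwise deletion of
gap/ambiguous columns) → Jukes-Cantor correction → neighbour joining →
bootstrap supports (column resampling) → clade membership of a query
sequence among labeled references.

The Jukes-Cantor correction generalizes over the alphabet size k:

    d = -((k-1)/k) * ln(1 - (k/(k-1)) * p)

with k = 4 for nucleotides and k = 20 for amino acids (the alphabet is
auto-detected).  The correction diverges at p = (k-1)/k; saturated pairs
raise an error rather than being silently clamped.

Neighbour joining follows the standard Q-criterion agglomeration.  Ties in
the Q matrix are broken toward the lowest taxon-index pair, and negative
branch lengths are clamped to zero with a warning recorded on the result.
On additive distance matrices the generating topology and branch lengths
are recovered exactly.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .errors import PhyloError, SaturationError

NUCLEOTIDE_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_GAPS = frozenset("-.X?N")


# ---------------------------------------------------------------------------
# Alignment / distance containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """Equal-length sequence rows with unique taxon labels."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise PhyloError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise PhyloError("alignment rows differ in length")
        if len(self.labels) != len(self.rows):
            raise PhyloError("labels/rows mismatch")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def add(self, label: str, seq: str) -> "Alignment":
        if len(seq) != self.n_columns:
            raise PhyloError(
                f"sequence length {len(seq)} != alignment width {self.n_columns}")
        return Alignment(self.labels + (label,), self.rows + (seq,))

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return Alignment(self.labels, rows)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(tuple(labels), tuple(rows))

    def is_nucleotide(self) -> bool:
        residues = {ch for r in self.rows for ch in r} - _GAPS
        return residues <= set(NUCLEOTIDE_ALPHABET + "U")


@dataclass
class DistanceMatrix:
    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise PhyloError("distance matrix shape mismatch")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise PhyloError("matrix must be symmetric, non-negative, zero-diagonal")


# ---------------------------------------------------------------------------
# Jukes-Cantor
# ---------------------------------------------------------------------------

def jc_distance(p: float, alphabet_size: int = 4) -> float:
    """Jukes-Cantor corrected distance for an observed difference proportion.

    Undefined for p >= (k-1)/k (saturation): raises ``SaturationError``.
    """
    if p < 0:
        raise PhyloError("difference proportion must be non-negative")
    k = alphabet_size
    limit = (k - 1) / k
    if p >= limit:
        raise SaturationError(
            f"p={p:.4f} at or beyond the JC saturation limit {limit:.4f}")
    # log1p keeps d >= p down to the smallest representable proportions
    return -limit * math.log1p(-p / limit)


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Proportion of differing sites with pairwise deletion of gap columns."""
    pairs = [(x, y) for x, y in zip(a, b) if x not in _GAPS and y not in _GAPS]
    if not pairs:
        raise PhyloError("no comparable (gap-free) columns between sequences")
    diff = sum(1 for x, y in pairs if x != y)
    return diff / len(pairs), len(pairs)


def distance_matrix(aln: Alignment, alphabet_size: int | None = None) -> DistanceMatrix:
    """Pairwise JC-corrected distances over an alignment."""
    if alphabet_size is None:
        alphabet_size = 4 if aln.is_nucleotide() else 20
    n = aln.n_taxa
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, _ = p_distance(aln.rows[i], aln.rows[j])
            m[i, j] = m[j, i] = jc_distance(p, alphabet_size)
    return DistanceMatrix(aln.labels, m)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloResult:
    """An unrooted NJ tree (trifurcating root node), optional bootstrap
    supports keyed by canonical bipartition, and clamping warnings."""

    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def newick(self) -> str:
        tree = self.tree.copy()
        if self.supports:
            taxa = frozenset(t.name for t in tree.tips())
            for node in tree.non_tips():
                tips = frozenset(t.name for t in node.tips())
                key = _canonical_split(tips, taxa)
                if key in self.supports:
                    node.name = f"{self.supports[key]:.0f}"
        buf = _io.StringIO()
        tree.write(buf)
        return buf.getvalue().strip()


def nj_tree(D: DistanceMatrix) -> PhyloResult:
    """Standard neighbour joining with deterministic tie-breaking."""
    n = len(D.taxa)
    if n < 3:
        raise PhyloError("neighbour joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]
    d = {(i, j): float(D.matrix[i, j]) for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n
    warnings: list[str] = []

    def dist(i, j):
        return d[(i, j)] if i <= j else d[(j, i)]

    node_of = {i: nodes[i] for i in range(n)}
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best, best_q = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        dij = dist(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj, clamped = _clamp(li, lj)
        if clamped:
            warnings.append(f"negative branch length clamped at join ({i},{j})")
        parent = TreeNode()
        for child, length in ((node_of[i], li), (node_of[j], lj)):
            child.length = length
            parent.append(child)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            d[(min(k, u), max(k, u))] = max(
                0.0, (dist(i, k) + dist(j, k) - dij) / 2)
        node_of[u] = parent
        active = [k for k in active if k not in (i, j)] + [u]

    # Final trifurcation via the three-point formulas.
    a, b, c = active
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = dist(a, b) - la
    lc = dist(a, c) - la
    root = TreeNode()
    for node_id, length in ((a, la), (b, lb), (c, lc)):
        child = node_of[node_id]
        if length < 0:
            warnings.append("negative terminal branch length clamped")
            length = 0.0
        child.length = length
        root.append(child)
    return PhyloResult(tree=root, warnings=warnings)


def _clamp(li, lj):
    clamped = False
    if li < 0:
        lj += li  # preserve the pair distance
        li, clamped = 0.0, True
    if lj < 0:
        li += lj
        lj, clamped = 0.0, True
    return max(li, 0.0), max(lj, 0.0), clamped


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap
# ---------------------------------------------------------------------------

def _canonical_split(side: frozenset, taxa: frozenset) -> frozenset:
    """Canonical form of a bipartition: the side not containing the
    lexicographically smallest taxon."""
    anchor = min(taxa)
    return frozenset(taxa - side) if anchor in side else frozenset(side)


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions induced by the internal edges."""
    taxa = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            splits.add(_canonical_split(side, taxa))
    return splits


def bootstrap_support(aln: Alignment, reps: int = 100, seed: int = 0,
                      alphabet_size: int | None = None) -> PhyloResult:
    """NJ tree with bootstrap supports from ``reps`` column resamplings.

    Support is the percentage of replicate trees containing each internal
    bipartition of the full-data tree.  The same seed gives bitwise
    identical supports.
    """
    if reps < 1:
        raise PhyloError("bootstrap requires at least one replicate")
    if aln.n_columns < 2:
        raise PhyloError("bootstrap requires an alignment with >=2 columns")
    result = nj_tree(distance_matrix(aln, alphabet_size))
    target = tree_bipartitions(result.tree)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        rep = aln.resample_columns(rng)
        try:
            rep_tree = nj_tree(distance_matrix(rep, alphabet_size))
        except SaturationError:
            continue  # replicate discarded; documented behaviour
        rep_splits = tree_bipartitions(rep_tree.tree)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    result.supports = {s: 100.0 * c / reps for s, c in counts.items()}
    return result


# ---------------------------------------------------------------------------
# Clade classification
# ---------------------------------------------------------------------------

@dataclass
class CladeCall:
    label: str                  # ACP | PCP | ... | unclassified
    support: float | None
    group: frozenset
    diagnostics: str = ""


def classify_clade(query_label: str, query_seq: str, references: Alignment,
                   clade_labels: dict[str, str], reps: int = 100,
                   seed: int = 0) -> CladeCall:
    """Assign a query to the clade of its smallest enclosing labeled group.

    The query (pre-aligned to the reference width) joins the reference
    alignment; the smallest NJ bipartition side containing the query defines
    its group.  If that group's reference members carry one label, the query
    inherits it with the bootstrap support of the defining bipartition;
    mixed labels yield ``unclassified`` with diagnostics.
    """
    missing = set(references.labels) - set(clade_labels)
    if missing:
        raise PhyloError(f"unlabeled reference taxa: {sorted(missing)}")
    aln = references.add(query_label, query_seq)
    result = bootstrap_support(aln, reps=reps, seed=seed)
    taxa = frozenset(aln.labels)
    sides = []
    for node in result.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        for candidate in (side, taxa - side):
            if query_label in candidate and 2 <= len(candidate) < len(taxa):
                sides.append(candidate)
    if not sides:
        return CladeCall("unclassified", None, frozenset(),
                         "no internal edge separates the query")
    group = min(sides, key=lambda s: (len(s), sorted(s)))
    member_labels = {clade_labels[t] for t in group if t != query_label}
    support = result.supports.get(_canonical_split(group, taxa))
    if len(member_labels) == 1:
        return CladeCall(member_labels.pop(), support, group)
    return CladeCall("unclassified", support, group,
                     f"smallest enclosing group mixes labels {sorted(member_labels)}")
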