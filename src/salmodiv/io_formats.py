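"""Core phylogenetic containers and plain-text readers/writers.

Trees are :class:`dendropy.Tree` objects throughout the package; ages are
measured backwards from the present in Myr (present = 0, so a dated root sits
at the crown age).  Alignments are in-frame coding nucleotide matrices, trait
tables map species to a binary ecological state (0 = freshwater resident,
1 = anadromous), and :class:`BranchingTimes` holds the internode statistics
that the lineage-through-time machinery consumes.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Tree",
    "Alignment",
    "TraitTable",
    "BranchingTimes",
    "SeaLevelSeries",
    "TestResult",
    "read_newick",
    "write_newick",
    "read_fasta",
    "write_fasta",
    "node_ages",
    "is_ultrametric",
    "branching_times",
]

Tree = dendropy.Tree

DNA_ALPHABET = frozenset("ACGTN-")


# ---------------------------------------------------------------------------
# Trees


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted :class:`dendropy.Tree`.

    Branch lengths are required on all edges except (optionally) the root;
    internal node labels (e.g. support values) are preserved as node labels.
    Raises ``ValueError`` on syntax errors or duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise ValueError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError(
                f"missing branch length on edge above {_node_repr(node)}"
            )
        if not math.isfinite(node.edge.length) or node.edge.length < 0:
            raise ValueError(
                f"non-finite or negative branch length above {_node_repr(node)}"
            )
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to Newick with >= 9 significant digits on lengths.

    Single-tip trees are written as ``A:0.0;`` style strings (tip plus its
    root edge), which :func:`read_newick` accepts back.
    """
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
        unquoted_underscores=True,
    ).strip()


def _node_repr(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return repr(node.taxon.label)
    return f"internal node ({len(node.leaf_nodes())} tips)"


def node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Age of every node, measured backwards from the most distant tip.

    The deepest tip defines the present (age 0); for an ultrametric tree all
    tips have age ~0 and the root age equals the crown age.
    """
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    max_depth = max(depth[leaf] for leaf in tree.leaf_node_iter())
    return {node: max_depth - d for node, d in depth.items()}


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    """True iff all root-to-tip path lengths agree within ``tol`` (relative).

    ``tol`` is interpreted relative to the maximum root-to-tip path, so dated
    trees carrying rounding noise from external programs still qualify.
    """
    depths = []
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            depths.append(depth[node])
    dmax = max(depths)
    if dmax == 0.0:
        return True
    return (dmax - min(depths)) <= tol * dmax


# ---------------------------------------------------------------------------
# Branching times


@dataclass(frozen=True)
class BranchingTimes:
    """Sorted node ages of an ultrametric binary tree plus derived sums.

    ``times`` holds the n-1 branching (node) ages in Ma, descending, so
    ``times[0]`` is the root age.  ``g[k-2]`` is the duration during which the
    reconstructed tree had exactly k lineages (k = 2..n), ``T_i[i-2]`` the
    cumulative sum T_i = sum_{k=2}^{i} k*g_k and ``T = T_n`` the total.
    """

    times: np.ndarray
    n: int
    g: np.ndarray
    T_i: np.ndarray
    T: float

    @classmethod
    def from_times(cls, times: Iterable[float]) -> "BranchingTimes":
        x = np.sort(np.asarray(list(times), dtype=float))[::-1]
        if x.size < 2:
            raise ValueError("need at least 2 branching times (>= 3 tips)")
        if not np.all(np.isfinite(x)) or x[-1] < 0:
            raise ValueError("branching times must be finite and >= 0")
        n = x.size + 1
        bounds = np.concatenate([x, [0.0]])
        g = -np.diff(bounds)  # g_k for k = 2..n
        k = np.arange(2, n + 1, dtype=float)
        T_i = np.cumsum(k * g)
        return cls(times=x, n=n, g=g, T_i=T_i, T=float(T_i[-1]))


def branching_times(tree: dendropy.Tree, tol: float = 1e-6) -> BranchingTimes:
    """Extract branching times from an ultrametric binary tree (>= 3 tips)."""
    leaves = tree.leaf_nodes()
    if len(leaves) < 3:
        raise ValueError("branching_times requires >= 3 tips")
    if not is_ultrametric(tree, tol=tol):
        raise ValueError(f"tree is not ultrametric within relative tol {tol}")
    internal_ages = []
    ages = node_ages(tree)
    for node in tree.preorder_internal_node_iter():
        nchild = len(node.child_nodes())
        if nchild != 2:
            raise ValueError(
                f"polytomy ({nchild} children) at {_node_repr(node)}; "
                "branching-time statistics assume a binary tree"
            )
        internal_ages.append(ages[node])
    return BranchingTimes.from_times(internal_ages)


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class Alignment:
    """In-frame coding nucleotide alignment.

    ``offset`` is the 0-based column index of codon position 1; operations
    that need codon structure require ``(length - offset) % 3 == 0``.
    ``kept_positions`` records which codon positions the columns cycle over
    (``(1, 2, 3)`` for an intact frame).
    """

    sequences: dict[str, str]
    offset: int = 0
    kept_positions: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def codon_positions(self) -> np.ndarray:
        """Per-column codon position (1/2/3), cycling over kept_positions.

        Columns before ``offset`` are marked 0 (outside the frame).
        """
        pos = np.zeros(self.length, dtype=int)
        cycle = np.array(self.kept_positions, dtype=int)
        idx = np.arange(self.length - self.offset)
        pos[self.offset :] = cycle[idx % cycle.size]
        return pos

    def require_in_frame(self) -> None:
        if self.kept_positions != (1, 2, 3):
            raise ValueError("alignment columns are not a full codon frame")
        if (self.length - self.offset) % 3 != 0:
            raise ValueError(
                f"length {self.length} minus offset {self.offset} "
                "is not divisible by 3"
            )


def read_fasta(source: str) -> Alignment:
    """Read an equal-length FASTA into an :class:`Alignment` (upper-cased).

    ``source`` is FASTA text (anything containing a newline or '>') or a
    file path.
    """
    if "\n" in source or source.lstrip().startswith(">"):
        handle = io.StringIO(source)
    else:
        handle = open(source)
    try:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    except ValueError as exc:
        raise ValueError(f"invalid FASTA input: {exc}") from exc
    finally:
        handle.close()
    if not records:
        raise ValueError("empty FASTA input")
    return Alignment(records)


def write_fasta(aln: Alignment, path: str | None = None, width: int = 70) -> str:
    chunks = []
    for name, seq in aln.sequences.items():
        chunks.append(f">{name}")
        for i in range(0, len(seq), width):
            chunks.append(seq[i : i + width])
    text = "\n".join(chunks) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Trait tables


@dataclass(frozen=True)
class TraitTable:
    """Species -> binary ecological state (0 freshwater, 1 anadromous)."""

    states: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.states.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"trait states must be 0 or 1, got {bad}")

    def __getitem__(self, species: str) -> int:
        return self.states[species]

    def __len__(self) -> int:
        return len(self.states)

    def validate_against(self, tree: dendropy.Tree) -> None:
        missing = [
            leaf.taxon.label
            for leaf in tree.leaf_node_iter()
            if leaf.taxon.label not in self.states
        ]
        if missing:
            raise ValueError(f"tips without trait states: {missing}")

    @classmethod
    def read_tsv(cls, source: str) -> "TraitTable":
        """Read a two-column TSV with header columns ``species`` and ``state``."""
        buf = io.StringIO(source) if "\n" in source else source
        df = pd.read_csv(buf, sep="\t")
        return cls(dict(zip(df["species"].astype(str), df["state"].astype(int))))

    def to_tsv(self) -> str:
        lines = ["species\tstate"]
        lines += [f"{sp}\t{st}" for sp, st in self.states.items()]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Climate series


@dataclass(frozen=True)
class SeaLevelSeries:
    """Time series of (age Ma, value in metres), e.g. eustatic sea level."""

    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if ages.shape != values.shape or ages.ndim != 1:
            raise ValueError("ages and values must be 1-D arrays of equal size")
        if ages.size == 0:
            raise ValueError("empty series")
        if not np.all(np.isfinite(ages)) or np.any(ages < 0):
            raise ValueError("ages must be finite and >= 0")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.ages.size

    @classmethod
    def read_csv(cls, source: str) -> "SeaLevelSeries":
        """Read a CSV with columns ``age_ma`` and ``value``."""
        buf = io.StringIO(source) if "\n" in source else source
        df = pd.read_csv(buf)
        return cls(df["age_ma"].to_numpy(float), df["value"].to_numpy(float))

    def to_csv(self) -> str:
        df = pd.DataFrame({"age_ma": self.ages, "value": self.values})
        return df.to_csv(index=False)


# ---------------------------------------------------------------------------
# Shared statistics container


@dataclass(frozen=True)
class TestResult:
    """Outcome of a frequentist test (chi-square based throughout)."""

    statistic: float
    df: int
    pvalue: float
    method: str
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.pvalue}")
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
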