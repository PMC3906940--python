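"""Curation of whole-genome-duplication paralogue datasets.

After a WGD, duplicated loci only become phylogenetically usable once
diploidization resolution (DR) has fixed them as independently evolving
disomic loci.  A gene tree of the paralogue pair across species betrays when
that happened: if DR predates the first speciation, the tree splits into two
paralogous clades that each mirror the species tree; if DR happened
independently within lineages, the paralogue splits nest inside those
lineages; and a lineage that never resolved (ongoing tetrasomic inheritance
with gene conversion) shows a species' sequence variants clustering
together.  Only the first pattern supports treating the paralogues as
ancestrally resolved loci, so datasets are kept for downstream dating only
when they conform to it.

This module provides that topology classifier plus the machinery around it:
enumerating/sampling the 2^k ways of concatenating k paralogue-pair
alignments, building the orthologue supermatrix, codon-position filtering,
Tajima's relative-rate test, and a transition/transversion saturation scan
with closed-form Kimura two-parameter distances.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_formats import Alignment, TestResult

__all__ = [
    "TaxonMap",
    "TaxonEntry",
    "ClassificationResult",
    "ParalogPair",
    "ConcatenationSet",
    "SaturationScan",
    "TestResult",
    "classify_diploidization",
    "enumerate_concatenations",
    "sample_concatenations",
    "concat_orthologs",
    "codon_partition",
    "tajima_rrt",
    "saturation_scan",
]

logger = logging.getLogger(__name__)

OUTGROUP = "outgroup"


# ---------------------------------------------------------------------------
# Taxon bookkeeping


@dataclass(frozen=True)
class TaxonEntry:
    species: str
    subfamily: str  # e.g. Salmoninae / Thymallinae / Coregoninae / "outgroup"
    paralog: str | None = None


@dataclass(frozen=True)
class TaxonMap:
    """Tip label -> (species, subfamily, paralogue tag)."""

    entries: Mapping[str, TaxonEntry]

    def __post_init__(self) -> None:
        if not any(e.subfamily == OUTGROUP for e in self.entries.values()):
            raise ValueError("taxon map must flag at least one outgroup")

    def __getitem__(self, tip: str) -> TaxonEntry:
        return self.entries[tip]

    def is_outgroup(self, tip: str) -> bool:
        return self.entries[tip].subfamily == OUTGROUP

    @property
    def outgroup_tips(self) -> frozenset[str]:
        return frozenset(
            t for t, e in self.entries.items() if e.subfamily == OUTGROUP
        )

    @property
    def ingroup_subfamilies(self) -> frozenset[str]:
        return frozenset(
            e.subfamily for e in self.entries.values() if e.subfamily != OUTGROUP
        )

    @classmethod
    def from_subfamilies(
        cls,
        tips: Iterable[str],
        subfamily_of: Mapping[str, str],
        outgroups: Iterable[str] = (),
        sep: str = "|",
    ) -> "TaxonMap":
        """Build a map from tips like ``"Salmo|P1"`` plus a species table.

        ``subfamily_of`` maps species to subfamily; species listed in
        ``outgroups`` (or mapped to ``"outgroup"``) are flagged as such.
        """
        og = set(outgroups)
        entries = {}
        for tip in tips:
            species, _, tag = tip.partition(sep)
            paralog = tag or None
            if species in og:
                entries[tip] = TaxonEntry(species, OUTGROUP, paralog)
                continue
            try:
                entries[tip] = TaxonEntry(species, subfamily_of[species], paralog)
            except KeyError:
                raise ValueError(f"no subfamily for species {species!r}") from None
        return cls(entries)


# ---------------------------------------------------------------------------
# Diploidization-resolution classifier


SCENARIO_LABELS = (
    "resolved_ancestral",
    "lineage_specific",
    "unresolved_tetrasomic",
    "ambiguous",
)


@dataclass(frozen=True)
class Diagnostics:
    outgroup_ok: bool
    ingroup_monophyletic: bool
    two_clade_split: bool
    clade_subfamilies: tuple[frozenset[str], ...] | None
    paralog_split_support: float | None
    n_species: int
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class ClassificationResult:
    scenario: str
    keep: bool
    diagnostics: Diagnostics

    def __post_init__(self) -> None:
        if self.keep and self.scenario != "resolved_ancestral":
            raise ValueError("only resolved_ancestral datasets are kept")


def _node_support(node: dendropy.Node) -> float | None:
    label = node.label
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


def classify_diploidization(
    gene_tree: dendropy.Tree,
    taxon_map: TaxonMap,
    min_support: float | None = None,
) -> ClassificationResult:
    """Classify a WGD paralogue gene tree by its diploidization history.

    Decision sequence: (1) root on the outgroup and require the ingroup to be
    monophyletic; (2) test whether the ingroup's basal split separates two
    paralogous clades, i.e. both sides carry the full species set; (3) a
    valid paralogue split whose clades each contain every subfamily present
    is ``resolved_ancestral`` (kept); otherwise a species whose two
    paralogues are sister tips indicates ongoing tetrasomy
    (``unresolved_tetrasomic``), a duplicated-species-set split nested inside
    a lineage indicates ``lineage_specific`` resolution, and anything else is
    ``ambiguous``.  With ``min_support`` set, the paralogue-split node must
    carry a support annotation meeting it or the dataset is ``ambiguous``.

    The decision depends only on splits, so it is invariant to tip-order
    permutation and to rerooting along the outgroup branch.
    """
    tips = [leaf.taxon.label for leaf in gene_tree.leaf_node_iter()]
    unmapped = [t for t in tips if t not in taxon_map.entries]
    if unmapped:
        raise ValueError(f"unmapped tips: {unmapped}")
    og_tips = [t for t in tips if taxon_map.is_outgroup(t)]
    in_tips = [t for t in tips if not taxon_map.is_outgroup(t)]
    if not og_tips:
        raise ValueError("gene tree contains no outgroup tip")
    n_species = len({taxon_map[t].species for t in in_tips})
    if n_species < 2:
        raise ValueError("need >= 2 ingroup species to classify")

    tree = gene_tree.clone(depth=1)
    og_leaf = next(
        leaf
        for leaf in tree.leaf_node_iter()
        if taxon_map.is_outgroup(leaf.taxon.label)
    )
    edge = og_leaf.edge
    if edge.length and tree.seed_node is not og_leaf.parent_node:
        tree.reroot_at_edge(edge, length1=edge.length / 2.0, length2=edge.length / 2.0)

    # species set of every clade
    species_of: dict[dendropy.Node, frozenset[str]] = {}
    subfam_of: dict[dendropy.Node, frozenset[str]] = {}
    ingroup_node = None
    in_set = frozenset(in_tips)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            entry = taxon_map[node.taxon.label]
            is_og = entry.subfamily == OUTGROUP
            species_of[node] = frozenset() if is_og else frozenset([entry.species])
            subfam_of[node] = frozenset() if is_og else frozenset([entry.subfamily])
            node._tipset = frozenset([node.taxon.label])
        else:
            kids = node.child_nodes()
            species_of[node] = frozenset().union(*(species_of[k] for k in kids))
            subfam_of[node] = frozenset().union(*(subfam_of[k] for k in kids))
            node._tipset = frozenset().union(*(k._tipset for k in kids))
        if node._tipset == in_set and ingroup_node is None:
            ingroup_node = node

    def result(scenario: str, **kwargs) -> ClassificationResult:
        diag = Diagnostics(
            outgroup_ok=True,
            n_species=n_species,
            **{
                "ingroup_monophyletic": ingroup_node is not None,
                "two_clade_split": False,
                "clade_subfamilies": None,
                "paralog_split_support": None,
                **kwargs,
            },
        )
        return ClassificationResult(
            scenario=scenario, keep=scenario == "resolved_ancestral", diagnostics=diag
        )

    if ingroup_node is None:
        return result("ambiguous", notes=("ingroup not monophyletic",))

    all_species = species_of[ingroup_node]
    kids = ingroup_node.child_nodes()
    clade_subfams = tuple(subfam_of[k] for k in kids)

    if len(kids) == 2 and all(species_of[k] == all_species for k in kids):
        # basal paralogue split spanning the whole ingroup
        support = _node_support(ingroup_node)
        present = taxon_map.ingroup_subfamilies & subfam_of[ingroup_node]
        if not all(subfam_of[k] == present for k in kids):
            return result(
                "ambiguous",
                two_clade_split=True,
                clade_subfamilies=clade_subfams,
                paralog_split_support=support,
                notes=("a paralogous clade misses a subfamily",),
            )
        if min_support is not None:
            if support is None:
                return result(
                    "ambiguous",
                    two_clade_split=True,
                    clade_subfamilies=clade_subfams,
                    notes=("min_support requested but node unannotated",),
                )
            if support < min_support:
                return result(
                    "ambiguous",
                    two_clade_split=True,
                    clade_subfamilies=clade_subfams,
                    paralog_split_support=support,
                    notes=(f"support {support} below threshold {min_support}",),
                )
        return result(
            "resolved_ancestral",
            two_clade_split=True,
            clade_subfamilies=clade_subfams,
            paralog_split_support=support,
        )

    # Fig. 1d pattern: a species' paralogue variants cluster together
    for node in ingroup_node.postorder_internal_node_iter():
        ckids = node.child_nodes()
        if all(k.is_leaf() for k in ckids) and len(ckids) == 2:
            sp = {taxon_map[k.taxon.label].species for k in ckids}
            if len(sp) == 1:
                return result(
                    "unresolved_tetrasomic",
                    notes=(f"paralogue pair of {sp.pop()!r} are sister tips",),
                )

    # Fig. 1c pattern: a duplicated species set nested inside one lineage
    for node in ingroup_node.postorder_internal_node_iter():
        if node is ingroup_node:
            continue
        ckids = node.child_nodes()
        if len(ckids) == 2 and species_of[ckids[0]] == species_of[ckids[1]] != frozenset():
            return result(
                "lineage_specific",
                notes=(
                    "paralogue split nested within lineage "
                    f"{sorted(species_of[ckids[0]])}",
                ),
            )

    return result("ambiguous", notes=("no recognisable paralogue-split pattern",))


# ---------------------------------------------------------------------------
# Concatenation machinery


@dataclass(frozen=True)
class ParalogPair:
    """One WGD paralogue dataset: two same-taxon alignments (the two loci)."""

    name: str
    first: Alignment
    second: Alignment

    def __post_init__(self) -> None:
        if set(self.first.taxa) != set(self.second.taxa):
            raise ValueError(
                f"pair {self.name!r}: the two alignments must share a taxon set"
            )
        if self.first.length != self.second.length:
            raise ValueError(
                f"pair {self.name!r}: the two loci must be aligned to the "
                "same length"
            )

    @property
    def taxa(self) -> list[str]:
        return self.first.taxa

    @property
    def length(self) -> int:
        return self.first.length

    def member(self, which: int) -> Alignment:
        return self.first if which == 0 else self.second


class ConcatenationSet:
    """All 2^k ways of assigning k paralogue pairs to two super-rows.

    Each assignment is a length-k bit vector: bit i says which member of
    pair i feeds super-row "A" (the other feeds "B").  Swapping every bit
    relabels the rows globally, so assignments are distinct up to that swap
    in 2^(k-1) canonical forms (first bit fixed to 0).
    """

    def __init__(self, pairs: Sequence[ParalogPair]):
        if not pairs:
            raise ValueError("no paralogue pairs supplied")
        taxa = set(pairs[0].taxa)
        for p in pairs:
            if set(p.taxa) != taxa:
                raise ValueError(
                    f"pair {p.name!r} taxa differ from the first pair's"
                )
        self.pairs = list(pairs)
        self.taxa = sorted(taxa)

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def n_assignments(self) -> int:
        return 2**self.k

    @property
    def n_canonical(self) -> int:
        return 2 ** (self.k - 1)

    def assignment(self, index: int) -> tuple[int, ...]:
        if not (0 <= index < self.n_assignments):
            raise IndexError(index)
        return tuple((index >> i) & 1 for i in range(self.k))

    def iter_assignments(self, canonical: bool = False):
        top = self.n_canonical if canonical else self.n_assignments
        return (self.assignment(i) for i in range(top))

    def build(self, bits: Sequence[int]) -> Alignment:
        """Concatenated paralogue-mode matrix for one assignment.

        Rows are ``taxon|A`` / ``taxon|B``; columns are the pair blocks in
        order, so the length is the sum of the per-locus block lengths.
        """
        if len(bits) != self.k:
            raise ValueError(f"assignment needs {self.k} bits")
        rows: dict[str, list[str]] = {}
        for taxon in self.taxa:
            rows[f"{taxon}|A"] = []
            rows[f"{taxon}|B"] = []
        for pair, bit in zip(self.pairs, bits):
            a, b = pair.member(bit), pair.member(1 - bit)
            for taxon in self.taxa:
                rows[f"{taxon}|A"].append(a.sequences[taxon])
                rows[f"{taxon}|B"].append(b.sequences[taxon])
        return Alignment({name: "".join(parts) for name, parts in rows.items()})


def enumerate_concatenations(
    pairs: Sequence[ParalogPair | tuple[Alignment, Alignment]],
) -> ConcatenationSet:
    """Wrap paralogue pairs into a lazily enumerable set of concatenations."""
    wrapped = [
        p
        if isinstance(p, ParalogPair)
        else ParalogPair(f"pair{i + 1}", p[0], p[1])
        for i, p in enumerate(pairs)
    ]
    return ConcatenationSet(wrapped)


def sample_concatenations(
    cset: ConcatenationSet,
    n: int,
    seed: int | np.random.Generator | None = None,
    canonical: bool = False,
    as_alignments: bool = True,
):
    """Draw ``n`` distinct assignments uniformly without replacement."""
    total = cset.n_canonical if canonical else cset.n_assignments
    if n > total:
        raise ValueError(f"requested {n} samples from {total} assignments")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if total <= 2**24:
        indices = rng.choice(total, size=n, replace=False)
    else:  # avoid materialising the index range
        chosen: set[int] = set()
        while len(chosen) < n:
            chosen.add(int(rng.integers(total)))
        indices = np.fromiter(chosen, dtype=np.int64)
    bits = [cset.assignment(int(i)) for i in indices]
    if not as_alignments:
        return bits
    return [cset.build(b) for b in bits]


def concat_orthologs(
    pairs: Sequence[ParalogPair],
    taxon_map: TaxonMap,
    outgroup_policy: str = "duplicate",
) -> Alignment:
    """Orthologue supermatrix: one row per species over both paralogue blocks.

    Columns are ``[all first-locus blocks | all second-locus blocks]`` so each
    column block contains only orthologues; the total width is twice the sum
    of per-locus block lengths (e.g. 21,666 bp when the blocks sum to
    10,833 bp per paralogue).  Outgroup species carry a single sequence per
    gene, which is duplicated across the two blocks
    (``outgroup_policy="duplicate"``) or placed in the first block with the
    second gap-filled (``"single"``).  Missing salmonid sequences are
    gap-filled and logged, never silently dropped.
    """
    if outgroup_policy not in ("duplicate", "single"):
        raise ValueError(f"unknown outgroup_policy {outgroup_policy!r}")
    species: list[str] = []
    outgroups: list[str] = []
    for pair in pairs:
        for taxon in pair.taxa:
            entry = taxon_map[taxon] if taxon in taxon_map.entries else None
            if entry is None:
                raise ValueError(f"taxon {taxon!r} missing from the taxon map")
            target = outgroups if entry.subfamily == OUTGROUP else species
            if taxon not in target:
                target.append(taxon)
    rows: dict[str, list[str]] = {t: [] for t in species + outgroups}
    for which in (0, 1):
        for pair in pairs:
            block = pair.member(which)
            gap = "-" * block.length
            for taxon in species:
                seq = block.sequences.get(taxon)
                if seq is None:
                    logger.warning(
                        "gap-filling %s for missing taxon %s (block %d)",
                        pair.name, taxon, which + 1,
                    )
                    seq = gap
                rows[taxon].append(seq)
            for taxon in outgroups:
                seq = block.sequences.get(taxon)
                if seq is None:
                    other = pair.member(1 - which).sequences.get(taxon)
                    if outgroup_policy == "duplicate" and other is not None:
                        seq = other
                    elif outgroup_policy == "single" and which == 0 and other is not None:
                        seq = other
                    else:
                        seq = gap
                elif outgroup_policy == "single" and which == 1:
                    seq = gap
                rows[taxon].append(seq)
    return Alignment({t: "".join(parts) for t, parts in rows.items()})


def codon_partition(aln: Alignment, keep_positions: Iterable[int]) -> Alignment:
    """Filter alignment columns by codon position (subset of {1, 2, 3})."""
    keep = tuple(sorted(set(keep_positions)))
    if not keep or not set(keep) <= {1, 2, 3}:
        raise ValueError("keep_positions must be a non-empty subset of {1, 2, 3}")
    aln.require_in_frame()
    if keep == (1, 2, 3):
        return Alignment(dict(aln.sequences), offset=aln.offset)
    positions = aln.codon_positions()
    mask = np.isin(positions, keep)
    idx = np.flatnonzero(mask)
    out = {
        name: "".join(seq[i] for i in idx) for name, seq in aln.sequences.items()
    }
    return Alignment(out, offset=0, kept_positions=keep)


# ---------------------------------------------------------------------------
# Molecular-clock diagnostics


def tajima_rrt(
    aln: Alignment, taxon_a: str, taxon_b: str, outgroup: str
) -> TestResult:
    """Tajima's relative-rate test of clock-like behaviour for two taxa.

    Over sites where none of the three sequences has a gap or N, m1 counts
    sites where A alone differs (B agrees with the outgroup) and m2 the
    symmetric count for B; under equal rates m1 and m2 are exchangeable and
    chi2 = (m1-m2)^2/(m1+m2) with df 1.  m1 + m2 = 0 gives p = 1.
    """
    for taxon in (taxon_a, taxon_b, outgroup):
        if taxon not in aln.sequences:
            raise ValueError(f"taxon {taxon!r} not in alignment")
    a = np.frombuffer(aln.sequences[taxon_a].encode(), dtype="S1")
    b = np.frombuffer(aln.sequences[taxon_b].encode(), dtype="S1")
    o = np.frombuffer(aln.sequences[outgroup].encode(), dtype="S1")
    ok = np.ones(a.size, dtype=bool)
    for seq in (a, b, o):
        ok &= (seq != b"-") & (seq != b"N")
    m1 = int(np.sum(ok & (a != b) & (a != o) & (b == o)))
    m2 = int(np.sum(ok & (a != b) & (b != o) & (a == o)))
    if m1 + m2 == 0:
        stat, p = 0.0, 1.0
    else:
        stat = (m1 - m2) ** 2 / (m1 + m2)
        p = float(chi2.sf(stat, 1))
    return TestResult(
        statistic=float(stat),
        df=1,
        pvalue=p,
        method="tajima_rrt",
        details={"m1": m1, "m2": m2, "n_sites": int(ok.sum())},
    )


_TRANSITION_PAIRS = {frozenset(b"AG"), frozenset(b"CT")}
_VALID = frozenset(b"ACGT")


@dataclass(frozen=True)
class SaturationScan:
    """Pairwise divergence table plus the raw-differences-vs-distance slope."""

    table: pd.DataFrame
    slope: float
    intercept: float


def saturation_scan(aln: Alignment) -> SaturationScan:
    """Mutational-saturation diagnostics over every unordered sequence pair.

    For each pair, counts over shared ungapped sites: raw differences,
    transitions (A<->G, C<->T), transversions, and the Kimura two-parameter
    distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q)) with P and Q the transition
    and transversion proportions.  Pairs whose K2P argument is non-positive
    (saturation) are flagged undefined and excluded from the least-squares
    regression of raw differences on distance.
    """
    taxa = aln.taxa
    if len(taxa) < 2:
        raise ValueError("saturation scan needs >= 2 sequences")
    arrays = {
        t: np.frombuffer(aln.sequences[t].encode(), dtype="S1") for t in taxa
    }
    valid = {
        t: np.isin(arr, np.frombuffer(b"ACGT", dtype="S1"))
        for t, arr in arrays.items()
    }
    rows = []
    for t1, t2 in itertools.combinations(taxa, 2):
        a, b = arrays[t1], arrays[t2]
        ok = valid[t1] & valid[t2]
        n = int(ok.sum())
        diff_mask = ok & (a != b)
        diffs = int(diff_mask.sum())
        ts = 0
        for x, y in ((b"A", b"G"), (b"G", b"A"), (b"C", b"T"), (b"T", b"C")):
            ts += int(np.sum(diff_mask & (a == x) & (b == y)))
        tv = diffs - ts
        p_prop = ts / n if n else math.nan
        q_prop = tv / n if n else math.nan
        arg1 = 1.0 - 2.0 * p_prop - q_prop if n else math.nan
        arg2 = 1.0 - 2.0 * q_prop if n else math.nan
        defined = n > 0 and arg1 > 0 and arg2 > 0
        k2p = (
            -0.5 * math.log(arg1) - 0.25 * math.log(arg2) if defined else math.nan
        )
        rows.append(
            {
                "taxon1": t1,
                "taxon2": t2,
                "n_sites": n,
                "differences": diffs,
                "transitions": ts,
                "transversions": tv,
                "p_distance": diffs / n if n else math.nan,
                "P": p_prop,
                "Q": q_prop,
                "k2p": k2p,
                "ts_tv": (ts / tv) if tv else (math.inf if ts else math.nan),
                "k2p_defined": defined,
            }
        )
    table = pd.DataFrame(rows)
    usable = table[table["k2p_defined"]]
    if len(usable) >= 2 and usable["k2p"].nunique() > 1:
        slope, intercept = np.polyfit(usable["k2p"], usable["differences"], 1)
    else:
        slope, intercept = math.nan, math.nan
    return SaturationScan(table=table, slope=float(slope), intercept=float(intercept))
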