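"""Simulators for trees, traits, WGD gene trees, alignments and climate series.

Every analysis stage in this package can be exercised on data with known
generating parameters: birth–death and BiSSE trees conditioned on a number of
extant tips, gene trees under the competing diploidization-resolution
scenarios that follow a whole-genome duplication, HKY codon alignments with
per-position rate multipliers, and a sea-level-style time series with a known
piecewise-linear trend.  All simulators are bit-reproducible under a fixed
seed.

Tip-count conditioning uses forward (Gillespie) simulation: attempts in which
the clade dies out are rejected, and when the extant count first reaches n
the present is placed one full waiting time (to the next would-be event)
after that birth, so the complete n-lineage internode interval is observed.
Stopping exactly at the n-th birth would leave a zero-length final interval
and shift the null expectation of the gamma statistic upward by roughly
sqrt(3/(n-2)); the full-interval convention keeps the pure-birth gamma null
standard normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .io_formats import (
    Alignment,
    SeaLevelSeries,
    TraitTable,
    node_ages,
    read_newick,
)
from .bisse import BisseParams

__all__ = [
    "BisseParams",
    "WgdScenarioSpec",
    "HkyParams",
    "simulate_bd_tree",
    "simulate_bisse",
    "simulate_wgd_gene_tree",
    "simulate_alignment",
    "make_sealevel_fixture",
]


# ---------------------------------------------------------------------------
# Forward birth–death / BiSSE simulation


class _Lineage:
    __slots__ = ("parent", "t_birth", "t_end", "children", "alive", "state")

    def __init__(self, parent: int, t_birth: float, state: int):
        self.parent = parent
        self.t_birth = t_birth
        self.t_end: float | None = None
        self.children: tuple[int, int] | None = None
        self.alive = True
        self.state = state


def _prune_to_newick(records: list[_Lineage], t_present: float) -> str | None:
    """Reconstructed (extant-only) crown tree as Newick, or None if extinct."""
    n = len(records)
    rep: list[tuple[str, float] | None] = [None] * n
    tip_counter = 0
    # children always have larger indices than parents: walk backwards
    for i in range(n - 1, -1, -1):
        rec = records[i]
        if rec.children is None:
            if rec.alive:
                tip_counter += 1
                rep[i] = (f"t{tip_counter}", t_present)
            continue
        left, right = rec.children
        rl, rr = rep[left], rep[right]
        if rl is None and rr is None:
            rep[i] = None
        elif rl is None or rr is None:
            rep[i] = rl if rr is None else rr
        else:
            t_node = rec.t_end
            rep[i] = (
                f"({rl[0]}:{rl[1] - t_node:.12g},{rr[0]}:{rr[1] - t_node:.12g})",
                t_node,
            )
    if rep[0] is None:
        return None
    return rep[0][0] + ";"


def _tip_states_in_newick_order(records: list[_Lineage]) -> dict[str, int]:
    states: dict[str, int] = {}
    counter = 0
    for i in range(len(records) - 1, -1, -1):
        rec = records[i]
        if rec.children is None and rec.alive:
            counter += 1
            states[f"t{counter}"] = rec.state
    return states


def _forward_once(
    rng: np.random.Generator,
    lam: tuple[float, float],
    mu: tuple[float, float],
    q: tuple[float, float],
    n_tips: int,
    root_state: int,
    max_events: int,
) -> tuple[list[_Lineage], float] | None:
    records = [_Lineage(-1, 0.0, root_state)]
    active: list[list[int]] = [[], []]
    active[root_state].append(0)
    t = 0.0
    per_state = (
        lam[0] + mu[0] + q[0],
        lam[1] + mu[1] + q[1],
    )
    for _ in range(max_events):
        n0, n1 = len(active[0]), len(active[1])
        if n0 + n1 == 0:
            return None
        total = n0 * per_state[0] + n1 * per_state[1]
        if n0 + n1 == n_tips:
            # observe at the end of the complete n-lineage interval
            t_present = t + rng.exponential(1.0 / total)
            for s in (0, 1):
                for i in active[s]:
                    records[i].t_end = t_present
            return records, t_present
        t += rng.exponential(1.0 / total)
        if rng.random() < n0 * per_state[0] / total:
            state = 0
        else:
            state = 1
        pool = active[state]
        pos = int(rng.integers(len(pool)))
        i = pool[pos]
        u = rng.random() * per_state[state]
        if u < lam[state]:
            rec = records[i]
            rec.t_end = t
            rec.alive = False
            ca = len(records)
            records.append(_Lineage(i, t, state))
            records.append(_Lineage(i, t, state))
            rec.children = (ca, ca + 1)
            pool[pos] = pool[-1]
            pool.pop()
            pool.extend((ca, ca + 1))
        elif u < lam[state] + mu[state]:
            records[i].t_end = t
            records[i].alive = False
            pool[pos] = pool[-1]
            pool.pop()
        else:
            records[i].state = 1 - state
            pool[pos] = pool[-1]
            pool.pop()
            active[1 - state].append(i)
    return None  # event cap exceeded (near-critical runaway)


def _simulate_conditioned(
    rng: np.random.Generator,
    lam: tuple[float, float],
    mu: tuple[float, float],
    q: tuple[float, float],
    n_tips: int,
    root_state: int,
    max_attempts: int,
    max_events: int,
) -> tuple[dendropy.Tree, dict[str, int]]:
    for _ in range(max_attempts):
        out = _forward_once(rng, lam, mu, q, n_tips, root_state, max_events)
        if out is None:
            continue
        records, t_present = out
        newick = _prune_to_newick(records, t_present)
        if newick is None or newick.count(",") != n_tips - 1:
            continue  # pruning left fewer than n extant tips (cannot happen
            # when the count is exactly n, but guard against degenerate cases)
        tree = read_newick(newick)
        states = _tip_states_in_newick_order(records)
        return tree, states
    raise RuntimeError(
        f"failed to simulate a surviving {n_tips}-tip tree in "
        f"{max_attempts} attempts; the parameter regime may be degenerate "
        "(extinction-dominated or near-critical)"
    )


def simulate_bd_tree(
    birth: float,
    death: float,
    n_tips: int,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 1000,
) -> dendropy.Tree:
    """Ultrametric birth–death tree conditioned on ``n_tips`` extant tips.

    Rates are per lineage per Myr; extinct lineages are pruned so the
    returned tree is the reconstructed crown tree with tips at the present.
    Requires ``birth > death >= 0``.
    """
    if not (birth > death >= 0):
        raise ValueError(f"need birth > death >= 0, got {birth}, {death}")
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    max_events = 200 * n_tips + 10_000
    tree, _ = _simulate_conditioned(
        rng, (birth, birth), (death, death), (0.0, 0.0),
        n_tips, 0, max_attempts, max_events,
    )
    return tree


def simulate_bisse(
    params: BisseParams,
    n_tips: int,
    root_state: int = 0,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 1000,
) -> tuple[dendropy.Tree, TraitTable]:
    """Joint (tree, tip states) sample from the BiSSE forward process.

    The process starts from a single stem lineage in ``root_state`` and is
    conditioned on ``n_tips`` extant survivors; extinct lineages are pruned
    and the reconstructed crown tree is returned with a complete trait table.
    """
    if root_state not in (0, 1):
        raise ValueError("root_state must be 0 or 1")
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    max_events = 200 * n_tips + 10_000
    tree, states = _simulate_conditioned(
        rng,
        (params.lam0, params.lam1),
        (params.mu0, params.mu1),
        (params.q01, params.q10),
        n_tips,
        root_state,
        max_attempts,
        max_events,
    )
    return tree, TraitTable(states)


# ---------------------------------------------------------------------------
# WGD gene trees under the diploidization-resolution scenarios


SCENARIOS = (
    "a_species_only",
    "b_ancestral_DR",
    "c_lineage_specific_DR",
    "d_unresolved_tetrasomic",
)


@dataclass(frozen=True)
class WgdScenarioSpec:
    """Which diploidization-resolution history a simulated gene tree follows.

    ``wgd_depth`` (Ma) is the duplication age and must predate every ingroup
    divergence; ``dr_depths`` gives the diploidization-resolution age(s):
    a single age for the ancestral scenario (b), or a mapping keyed by
    lineage (a crown child of the ingroup, identified by its
    alphabetically-first tip label) for the lineage-specific scenarios (c/d),
    with ``None`` marking a lineage that never resolves (d).
    ``conversion_strength`` in [0, 1] sets how strongly concerted evolution
    homogenised an unresolved lineage's paralogue pair: the within-species
    pair coalesces at (1 - conversion_strength) times the species' stem age.
    ``outgroups`` flags the outgroup tips of the species tree (they must
    subtend the ingroup as successive outgroups with divergences older than
    ``wgd_depth``).
    """

    scenario: str
    wgd_depth: float
    outgroups: tuple[str, ...]
    dr_depths: float | Mapping[str, float | None] | None = None
    conversion_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (self.wgd_depth > 0 and math.isfinite(self.wgd_depth)):
            raise ValueError("wgd_depth must be positive and finite")
        if not (0.0 <= self.conversion_strength <= 1.0):
            raise ValueError("conversion_strength must lie in [0, 1]")
        if not self.outgroups:
            raise ValueError("at least one outgroup must be flagged")


def _render_subtree(node: dendropy.Node, ages, tip_fn) -> tuple[str, float]:
    """(newick without stem, node age); ``tip_fn(label, parent_age)`` returns
    the tip's rendered form and the age it sits at (0 for a plain tip, > 0
    when a species is replaced by a shallow paralogue cherry)."""
    if node.is_leaf():
        return tip_fn(node.taxon.label, None)
    parts = []
    my_age = ages[node]
    for child in node.child_nodes():
        if child.is_leaf():
            rep, child_age = tip_fn(child.taxon.label, my_age)
        else:
            rep, child_age = _render_subtree(child, ages, tip_fn)
        parts.append(f"{rep}:{my_age - child_age:.12g}")
    return "(" + ",".join(parts) + ")", my_age


def _peel_outgroups(
    tree: dendropy.Tree, outgroups: Sequence[str]
) -> tuple[dendropy.Node, list[tuple[str, float]]]:
    """Strip successive outgroup tips off the root; return (ingroup, ladder).

    The ladder lists (outgroup label, divergence age) from innermost to
    outermost.
    """
    ages = node_ages(tree)
    remaining = set(outgroups)
    node = tree.seed_node
    ladder: list[tuple[str, float]] = []
    while remaining:
        kids = node.child_nodes()
        og_kids = [
            k for k in kids if k.is_leaf() and k.taxon.label in remaining
        ]
        if len(kids) != 2 or len(og_kids) != 1:
            raise ValueError(
                "outgroups must subtend the ingroup as successive lone tips; "
                f"cannot peel {sorted(remaining)}"
            )
        og = og_kids[0]
        ladder.append((og.taxon.label, ages[node]))
        node = kids[0] if kids[1] is og else kids[1]
        remaining.discard(og.taxon.label)
    ingroup_tips = {leaf.taxon.label for leaf in node.leaf_iter()}
    if ingroup_tips & set(outgroups):
        raise ValueError("outgroup tips nested inside the ingroup")
    return node, ladder[::-1]  # outermost last -> reverse to innermost-first


def _lineage_key(node: dendropy.Node) -> str:
    return min(leaf.taxon.label for leaf in node.leaf_iter())


def simulate_wgd_gene_tree(
    species_tree: dendropy.Tree,
    spec: WgdScenarioSpec,
    seed: int | None = None,  # noqa: ARG001 - construction is deterministic
) -> dendropy.Tree:
    """Gene tree implied by a WGD plus a diploidization-resolution scenario.

    Tips are ``"Species|P1"`` / ``"Species|P2"`` for duplicated loci and bare
    species labels for outgroups (and for every tip under the no-WGD scenario
    a).  Scenario b places a single paralogue split at the ancestral DR age,
    mirroring the species tree in each paralogue clade; scenario c nests the
    paralogue splits within the crown lineages at their own DR ages;
    scenario d additionally lets one or more lineages stay tetrasomic, whose
    within-species paralogue pairs coalesce near the present according to
    ``conversion_strength``.  The construction is deterministic; ``seed`` is
    accepted for interface uniformity with the stochastic simulators.
    """
    ages = node_ages(species_tree)
    ingroup, ladder = _peel_outgroups(species_tree, spec.outgroups)
    crown_age = ages[ingroup]
    max_ingroup_age = max(ages[n] for n in ingroup.preorder_iter())
    if spec.wgd_depth <= max_ingroup_age:
        raise ValueError(
            f"wgd_depth {spec.wgd_depth} must predate the deepest ingroup "
            f"divergence ({max_ingroup_age})"
        )
    for _og, div_age in ladder:
        if div_age < spec.wgd_depth:
            raise ValueError(
                f"outgroup divergence at {div_age} Ma is younger than the "
                f"WGD at {spec.wgd_depth} Ma"
            )

    def plain_tip(label: str, _parent_age):
        return label, 0.0

    def paralog_tip(tag: str):
        def fn(label: str, _parent_age):
            return f"{label}|{tag}", 0.0

        return fn

    if spec.scenario == "a_species_only":
        core, core_age = _render_subtree(ingroup, ages, plain_tip)

    elif spec.scenario == "b_ancestral_DR":
        if not isinstance(spec.dr_depths, (int, float)):
            raise ValueError("scenario b needs a single numeric dr_depth")
        dr = float(spec.dr_depths)
        if not (crown_age < dr <= spec.wgd_depth):
            raise ValueError(
                f"ancestral DR age {dr} must lie in (crown {crown_age}, "
                f"wgd {spec.wgd_depth}]"
            )
        clades = []
        for tag in ("P1", "P2"):
            rep, sub_age = _render_subtree(ingroup, ages, paralog_tip(tag))
            clades.append(f"{rep}:{dr - sub_age:.12g}")
        core, core_age = "(" + ",".join(clades) + ")", dr

    elif spec.scenario in ("c_lineage_specific_DR", "d_unresolved_tetrasomic"):
        if ingroup.is_leaf() or not isinstance(spec.dr_depths, Mapping):
            raise ValueError(
                "scenarios c/d need a multi-species ingroup and a mapping "
                "of per-lineage DR ages"
            )
        lineages = ingroup.child_nodes()
        keys = {_lineage_key(n): n for n in lineages}
        if set(spec.dr_depths) != set(keys):
            raise ValueError(
                f"dr_depths keys {sorted(spec.dr_depths)} do not match crown "
                f"lineages {sorted(keys)}"
            )
        unresolved = [k for k, v in spec.dr_depths.items() if v is None]
        if spec.scenario == "c_lineage_specific_DR":
            if unresolved:
                raise ValueError("scenario c requires a DR age for every lineage")
        elif not unresolved:
            raise ValueError("scenario d needs >= 1 lineage with dr_depth None")

        parts = []
        for key, node in keys.items():
            dr = spec.dr_depths[key]
            node_age = ages[node] if not node.is_leaf() else 0.0
            if dr is not None:
                if not (node_age <= dr < crown_age):
                    raise ValueError(
                        f"lineage {key!r}: DR age {dr} must lie in "
                        f"[lineage crown {node_age}, ingroup crown {crown_age})"
                    )
                copies = []
                for tag in ("P1", "P2"):
                    if node.is_leaf():
                        rep, sub_age = f"{key}|{tag}", 0.0
                    else:
                        rep, sub_age = _render_subtree(node, ages, paralog_tip(tag))
                    copies.append(f"{rep}:{dr - sub_age:.12g}")
                parts.append(f"({','.join(copies)}):{crown_age - dr:.12g}")
            else:
                # tetrasomic lineage: species topology retained, each species'
                # paralogue pair homogenised towards the present by concerted
                # evolution; the pair coalesces at (1 - conversion_strength)
                # of the species' stem age
                def cherry(label: str, parent_age):
                    ref = parent_age if parent_age is not None else crown_age
                    h = (1.0 - spec.conversion_strength) * ref
                    return f"({label}|P1:{h:.12g},{label}|P2:{h:.12g})", h

                if node.is_leaf():
                    rep, node_age2 = cherry(key, crown_age)
                else:
                    rep, node_age2 = _render_subtree(node, ages, cherry)
                parts.append(f"{rep}:{crown_age - node_age2:.12g}")
        core, core_age = "(" + ",".join(parts) + ")", crown_age
    else:  # pragma: no cover
        raise AssertionError

    # climb the outgroup ladder, innermost first
    for og_label, div_age in ladder:
        core = f"({core}:{div_age - core_age:.12g},{og_label}:{div_age:.12g})"
        core_age = div_age
    return read_newick(core + ";")


# ---------------------------------------------------------------------------
# HKY sequence simulation


@dataclass(frozen=True)
class HkyParams:
    """HKY85 substitution model with per-codon-position rate multipliers."""

    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    position_rates: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if any(f < 0 for f in self.base_freqs):
            raise ValueError("base frequencies must be >= 0")
        if any(r <= 0 for r in self.position_rates):
            raise ValueError("position rate multipliers must be > 0")

    def rate_matrix(self) -> np.ndarray:
        """HKY Q matrix (order ACGT), scaled to one expected event per unit."""
        pi = np.asarray(self.base_freqs)
        q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = pi[j] * (self.kappa if (i, j) in transitions else 1.0)
                q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.dot(pi, np.diag(q))
        if scale <= 0:
            raise ValueError("degenerate rate matrix")
        return q / scale


_NUC = np.array(list("ACGT"))


def simulate_alignment(
    tree: dendropy.Tree,
    hky: HkyParams,
    n_codons: int,
    seed: int | np.random.Generator | None = None,
    clock_rate: float = 1.0,
) -> Alignment:
    """Evolve an in-frame codon alignment along a tree under HKY.

    ``clock_rate`` converts branch lengths (Myr) into substitutions per site
    at a position with rate multiplier 1, keeping time and divergence units
    separate.  Codon position p uses ``hky.position_rates[p-1]`` as a rate
    multiplier; sites are independent.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    q = hky.rate_matrix()
    pi = np.asarray(hky.base_freqs)

    seqs: dict[dendropy.Node, np.ndarray] = {}
    root_states = rng.choice(4, size=(3, n_codons), p=pi)
    seqs[tree.seed_node] = root_states
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_states = seqs[node.parent_node]
        blen = (node.edge.length or 0.0) * clock_rate
        child = np.empty_like(parent_states)
        for p in range(3):
            if blen * hky.position_rates[p] == 0.0:
                child[p] = parent_states[p]
                continue
            pmat = expm(q * blen * hky.position_rates[p])
            pmat = np.maximum(pmat, 0.0)
            pmat /= pmat.sum(axis=1, keepdims=True)
            cum = pmat.cumsum(axis=1)
            u = rng.random(n_codons)
            child[p] = (u[:, None] > cum[parent_states[p]]).sum(axis=1)
        seqs[node] = child

    out: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        states = seqs[leaf]
        arr = np.empty(3 * n_codons, dtype="U1")
        for p in range(3):
            arr[p::3] = _NUC[states[p]]
        out[leaf.taxon.label] = "".join(arr)
    return Alignment(out, offset=0)


# ---------------------------------------------------------------------------
# Sea-level fixture


DEFAULT_TREND = ((0.0, -20.0), (10.0, 25.0), (34.0, 55.0), (100.0, 85.0), (130.0, 70.0))


def make_sealevel_fixture(
    n_points: int = 1100,
    trend: Sequence[tuple[float, float]] = DEFAULT_TREND,
    noise_sd: float = 5.0,
    seed: int | np.random.Generator | None = None,
    age_max: float = 130.0,
) -> SeaLevelSeries:
    """Synthetic sea-level series: piecewise-linear trend + Gaussian noise.

    Ages are stratified-jittered over [0, age_max] so every 1-Myr bin is
    populated at the default density (1100 points over 130 Ma, emulating the
    resolution of published eustatic compilations).  ``trend`` is a list of
    (age Ma, metres) knots.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    knots = np.asarray(sorted(trend), dtype=float)
    ages = (np.arange(n_points) + rng.random(n_points)) / n_points * age_max
    values = np.interp(ages, knots[:, 0], knots[:, 1])
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_points)
    return SeaLevelSeries(ages=ages, values=values)
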