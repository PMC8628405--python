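"""Ground-truthed protein-sequence simulation along a known tree.

Sequences evolve site-independently under the 20-state equal-exchangeability
CTMC with uniform stationary frequencies (the 20-state analogue of
Jukes-Cantor): over a branch of length t expected substitutions/site, a site
differs from its parent with probability

    p_diff(t) = (19/20) * (1 - exp(-(20/19) * t))

and, conditional on differing, is uniform over the 19 other residues.  There
is no indel process, so the true alignment is exactly the leaf sequences.

Clade-diagnostic "planted" sites emulate the contrasts the downstream
classifiers read off real data (e.g. E vs an uncharged residue at the
counterion position, present vs absent RLBP1-critical residues): a planted
site is set to the clade's residue on the clade's stem branch and held
invariant in every descendant, so recovery tests have exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import dendropy
import numpy as np

from .align import AMINO_ACIDS, MSA, SubstitutionMatrix, nw_align, progressive_msa
from .errors import SimulationError
from .phylo import CladeMap, OUTGROUP_LABEL, bootstrap_clade_support, filter_columns
from .sites import (
    ROLE_COUNTERION,
    ROLE_RLBP1,
    CHARGED_COUNTERION,
    STATE_CHARGED,
    STATE_UNCHARGED,
    ReferenceScheme,
    SiteSpec,
    classify_counterion,
    map_sites,
    score_rlbp1,
)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def p_different(t: float) -> float:
    """Probability a site differs across a branch of length t (closed form)."""
    return (19.0 / 20.0) * (1.0 - math.exp(-(20.0 / 19.0) * t))


@dataclass
class SimConfig:
    """Generative model description.

    ``clades`` maps clade labels to leaf ids; ``outgroup`` leaves are kept
    separate.  ``constrained_sites`` maps a 1-based site index (root
    coordinates) to the residue planted per clade label ("outgroup" allowed).
    """

    newick: str
    root_seq_length: int
    clades: dict[str, list[str]] = field(default_factory=dict)
    outgroup: list[str] = field(default_factory=list)
    constrained_sites: dict[int, dict[str, str]] = field(default_factory=dict)
    seed: int | None = None

    def groups(self) -> dict[str, list[str]]:
        g = dict(self.clades)
        if self.outgroup:
            g[OUTGROUP_LABEL] = list(self.outgroup)
        return g


@dataclass
class SimResult:
    true_alignment: MSA
    root_seq: str
    true_clades: CladeMap | None
    planted_states: dict[str, dict[int, str]]
    tree: dendropy.Tree

    @property
    def leaf_seqs(self) -> list[tuple[str, str]]:
        """Leaf sequences; identical to the true alignment rows (no indels)."""
        return list(self.true_alignment.rows)


def _parse_tree(config: SimConfig) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=config.newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise SimulationError(f"tree: cannot parse newick ({exc})") from exc
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            raise SimulationError("tree: branch length missing on an edge")
        if edge.length < 0:
            raise SimulationError("tree: negative branch length")
    return tree


def _validate(config: SimConfig, tree: dendropy.Tree) -> None:
    if config.root_seq_length < 1:
        raise SimulationError("root_seq_length: must be >= 1")
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    groups = config.groups()
    for label, members in groups.items():
        unknown = sorted(set(members) - leaf_names)
        if unknown:
            raise SimulationError(
                f"clade_annotation: leaves {unknown} of {label!r} not in tree"
            )
    for pos, plants in config.constrained_sites.items():
        if not 1 <= pos <= config.root_seq_length:
            raise SimulationError(
                f"constrained_sites: position {pos} outside root coordinates"
            )
        for clade, res in plants.items():
            if clade not in groups:
                raise SimulationError(
                    f"constrained_sites: clade {clade!r} not annotated"
                )
            if res not in _AA_INDEX:
                raise SimulationError(
                    f"constrained_sites: {res!r} is not an amino acid"
                )


def simulate(config: SimConfig, seed: int | None = None) -> SimResult:
    """Evolve sequences along the config tree; reproducible from the seed."""
    if seed is None:
        seed = config.seed
    if seed is None:
        raise SimulationError("seed: required (none in config or argument)")
    tree = _parse_tree(config)
    _validate(config, tree)
    rng = np.random.default_rng(seed)
    L = config.root_seq_length

    # Stem node (MRCA) per annotated group carrying planted sites.
    stems: dict[int, list[str]] = {}
    groups = config.groups()
    plants_by_group: dict[str, dict[int, int]] = {}
    for gname, members in groups.items():
        plant = {
            pos - 1: _AA_INDEX[plants[gname]]
            for pos, plants in config.constrained_sites.items()
            if gname in plants
        }
        if not plant:
            continue
        plants_by_group[gname] = plant
        mrca = tree.mrca(taxon_labels=members)
        stems.setdefault(id(mrca), []).append(gname)

    root_codes = rng.integers(0, 20, size=L)
    leaf_rows: list[tuple[str, str]] = []

    def descend(node, codes: np.ndarray, frozen: np.ndarray) -> None:
        frozen = frozen.copy()
        codes = codes.copy()
        for gname in stems.get(id(node), ()):
            for pos0, code in plants_by_group[gname].items():
                codes[pos0] = code
                frozen[pos0] = True
        if node.is_leaf():
            leaf_rows.append(
                (node.taxon.label, "".join(AMINO_ACIDS[c] for c in codes))
            )
            return
        for child in node.child_nodes():
            t = child.edge.length
            p = p_different(t)
            hit = (rng.random(L) < p) & ~frozen
            child_codes = codes.copy()
            nhit = int(hit.sum())
            if nhit:
                jumps = rng.integers(1, 20, size=nhit)
                child_codes[hit] = (child_codes[hit] + jumps) % 20
            descend(child, child_codes, frozen)

    descend(tree.seed_node, root_codes, np.zeros(L, dtype=bool))

    clade_map = None
    if config.clades and config.outgroup:
        clade_map = CladeMap(
            clades={c: frozenset(m) for c, m in config.clades.items()},
            outgroup=frozenset(config.outgroup),
        )
    planted = {
        gname: {pos0 + 1: AMINO_ACIDS[code] for pos0, code in plant.items()}
        for gname, plant in plants_by_group.items()
    }
    return SimResult(
        true_alignment=MSA(rows=leaf_rows),
        root_seq="".join(AMINO_ACIDS[c] for c in root_codes),
        true_clades=clade_map,
        planted_states=planted,
        tree=tree,
    )


def random_additive_tree(
    n_taxa: int,
    rng: np.random.Generator,
    min_bl: float = 0.1,
    max_bl: float = 1.0,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Random binary tree with uniform branch lengths in [min_bl, max_bl].

    Grown by splitting a uniformly chosen edge for each added leaf; its
    patristic distance matrix is exactly additive, which makes it the
    canonical input for neighbor-joining consistency checks.
    """
    if n_taxa < 3:
        raise SimulationError("n_taxa: need >= 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    labels = [f"T{i + 1}" for i in range(n_taxa)]

    def new_leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=label)
        return node

    first, second = new_leaf(labels[0]), new_leaf(labels[1])
    tree.seed_node.add_child(first)
    tree.seed_node.add_child(second)
    for label in labels[2:]:
        candidates = [
            nd for nd in tree.preorder_node_iter() if nd.parent_node is not None
        ]
        target = candidates[rng.integers(0, len(candidates))]
        parent = target.parent_node
        splitter = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(splitter)
        splitter.add_child(target)
        splitter.add_child(new_leaf(label))
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(rng.uniform(min_bl, max_bl))
    tree.is_rooted = False
    return tree


def single_branch_mismatch(
    t: float, n_sites: int, seed: int
) -> tuple[float, float, float]:
    """Observed vs expected mismatch fraction across one branch of length t.

    Returns (observed, expected, binomial standard error); used to calibrate
    the substitution process against its closed form.
    """
    config = SimConfig(
        newick=f"(A:0.0,B:{t});", root_seq_length=n_sites, seed=seed
    )
    res = simulate(config)
    rows = dict(res.true_alignment.rows)
    a, b = rows["A"], rows["B"]
    observed = sum(x != y for x, y in zip(a, b)) / n_sites
    expected = p_different(t)
    se = math.sqrt(expected * (1.0 - expected) / n_sites)
    return observed, expected, se


# ---------------------------------------------------------------------------
# The reference recovery experiment


@dataclass
class RecoverySetup:
    """A simulation config plus the truth needed to grade the pipeline."""

    config: SimConfig
    query_of_clade: dict[str, str]  # clade label -> held-out query leaf
    counterion_pos: int
    counterion_expected: str
    rlbp1_sites: list[tuple[str, int, str]]  # (label, 1-based pos, expected)

    def scheme_from_root(self, root_seq: str) -> ReferenceScheme:
        """Reference scheme whose backbone is the simulation root with the
        expected residues imposed at the planted positions."""
        ref = list(root_seq)
        ref[self.counterion_pos - 1] = self.counterion_expected
        for _label, pos, res in self.rlbp1_sites:
            ref[pos - 1] = res
        sites = [
            SiteSpec(
                label=f"E{self.counterion_pos}",
                ref_position=self.counterion_pos,
                expected_residues=frozenset(self.counterion_expected),
                role=ROLE_COUNTERION,
            )
        ]
        sites += [
            SiteSpec(
                label=label,
                ref_position=pos,
                expected_residues=frozenset(res),
                role=ROLE_RLBP1,
            )
            for label, pos, res in self.rlbp1_sites
        ]
        return ReferenceScheme(
            scheme_id="simulated_truth",
            reference_seq="".join(ref),
            sites=tuple(sites),
        )

    def truth_for(self, clade: str, planted: dict[int, str]) -> tuple[str, int]:
        """(true counterion state, true rlbp1 score) for one clade."""
        counterion_res = planted[self.counterion_pos]
        state = (
            STATE_CHARGED if counterion_res in CHARGED_COUNTERION else STATE_UNCHARGED
        )
        score = sum(1 for _l, pos, res in self.rlbp1_sites if planted[pos] == res)
        return state, score


#: The study conditions of the recovery experiment: four clades of three
#: references plus one held-out query each, a two-leaf outgroup, 200 sites,
#: internal branches 0.3 and terminal branches 0.1 substitutions/site.
REFERENCE_N_SITES = 200
REFERENCE_INTERNAL_BL = 0.3
REFERENCE_TERMINAL_BL = 0.1
REFERENCE_COUNTERION_POS = 113
#: Planted counterion residues: clade A is the monostable-like contrast
#: (E = charged), the other clades carry uncharged residues.
REFERENCE_COUNTERION_PLANTS = {
    "cladeA": "E",
    "cladeB": "F",
    "cladeC": "Y",
    "cladeD": "S",
}
#: Ten RLBP1-style critical sites (labels echo the residue+position form).
REFERENCE_RLBP1_SITES = [
    ("W150", 150, "W"),
    ("Y151", 151, "Y"),
    ("F152", 152, "F"),
    ("C153", 153, "C"),
    ("M154", 154, "M"),
    ("Q155", 155, "Q"),
    ("M156", 156, "M"),
    ("V157", 157, "V"),
    ("M158", 158, "M"),
    ("W159", 159, "W"),
]
#: Number of critical residues planted intact per clade; the rest are planted
#: as L (never an expected residue above).
REFERENCE_RLBP1_INTACT = {"cladeA": 10, "cladeB": 8, "cladeC": 6, "cladeD": 3}


def reference_setup(
    internal_bl: float = REFERENCE_INTERNAL_BL,
    terminal_bl: float = REFERENCE_TERMINAL_BL,
    n_sites: int = REFERENCE_N_SITES,
) -> RecoverySetup:
    """Build the reference recovery configuration."""
    ib, tb = internal_bl, terminal_bl
    clade_leaves = {
        f"clade{X}": [f"{X}_r1", f"{X}_r2", f"{X}_r3", f"{X}_q"]
        for X in "ABCD"
    }

    def clade_nwk(X: str) -> str:
        leaves = ",".join(f"{leaf}:{tb}" for leaf in clade_leaves[f"clade{X}"])
        return f"({leaves}):{ib}"

    # Star of clade stems: exactly one internal branch per clade (plus the
    # outgroup stem), so the only internal branches are the stated ones and
    # query-to-root divergence stays at terminal + internal length.
    newick = (
        f"((OUT1:{tb},OUT2:{tb}):{ib},"
        f"{clade_nwk('A')},{clade_nwk('B')},{clade_nwk('C')},{clade_nwk('D')});"
    )
    constrained: dict[int, dict[str, str]] = {
        REFERENCE_COUNTERION_POS: dict(REFERENCE_COUNTERION_PLANTS)
    }
    for i, (label, pos, res) in enumerate(REFERENCE_RLBP1_SITES):
        constrained[pos] = {
            clade: (res if i < REFERENCE_RLBP1_INTACT[clade] else "L")
            for clade in clade_leaves
        }
    config = SimConfig(
        newick=newick,
        root_seq_length=n_sites,
        clades=clade_leaves,
        outgroup=["OUT1", "OUT2"],
        constrained_sites=constrained,
    )
    return RecoverySetup(
        config=config,
        query_of_clade={f"clade{X}": f"{X}_q" for X in "ABCD"},
        counterion_pos=REFERENCE_COUNTERION_POS,
        counterion_expected="E",
        rlbp1_sites=list(REFERENCE_RLBP1_SITES),
    )


def recovery_experiment(
    setup: RecoverySetup | None = None,
    n_trials: int = 50,
    seed: int | None = None,
    n_boot: int = 100,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    min_occupancy: float = 0.5,
) -> dict:
    """Run the full pipeline on simulated datasets and score it against truth.

    Per trial: simulate; for each clade's held-out query, (a) align the query
    to the planted-truth reference scheme, map sites, classify the counterion
    and score the ten critical sites; (b) build the progressive MSA of all
    leaves, occupancy-filter it, and bootstrap-assign the query to a clade
    using only the reference and outgroup rows plus that query.  Reports the
    fraction of correct clade assignments, correct counterion states, and
    exactly recovered conservation scores.
    """
    if setup is None:
        setup = reference_setup()
    if seed is None:
        raise SimulationError("seed: required")
    sm = SubstitutionMatrix.blosum62()
    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=n_trials)
    boot_seeds = rng.integers(0, 2**31 - 1, size=(n_trials, len(setup.query_of_clade)))

    n_clade_ok = n_counter_ok = n_rlbp_ok = n_total = 0
    refs_map = {
        clade: [m for m in members if m != setup.query_of_clade[clade]]
        for clade, members in setup.config.clades.items()
    }
    assign_map = CladeMap(
        clades={c: frozenset(m) for c, m in refs_map.items()},
        outgroup=frozenset(setup.config.outgroup),
    )
    for trial in range(n_trials):
        sim = simulate(setup.config, seed=int(trial_seeds[trial]))
        scheme = setup.scheme_from_root(sim.root_seq)
        rows = dict(sim.true_alignment.rows)

        msa = progressive_msa(
            sim.leaf_seqs, sm, gap_open=gap_open, gap_extend=gap_extend
        )
        filtered = filter_columns(msa, min_occupancy)

        for qi, (clade, query) in enumerate(sorted(setup.query_of_clade.items())):
            true_state, true_score = setup.truth_for(
                clade, {p: r for p, r in sim.planted_states[clade].items()}
            )
            aln = nw_align(
                rows[query], scheme.reference_seq, sm, gap_open, gap_extend,
                query_id=query, ref_id=scheme.scheme_id,
            )
            calls = map_sites(aln, scheme)
            state, _stability = classify_counterion(calls, scheme)
            score, _breakdown = score_rlbp1(calls, scheme)
            n_counter_ok += state == true_state
            n_rlbp_ok += score == true_score

            keep = sorted(
                set(assign_map.references) | set(assign_map.outgroup) | {query}
            )
            sub = filtered.subset(keep)
            assignment = bootstrap_clade_support(
                sub, assign_map, query, n_reps=n_boot,
                seed=int(boot_seeds[trial, qi]),
            )
            n_clade_ok += assignment.assigned == clade
            n_total += 1

    return {
        "clade_accuracy": n_clade_ok / n_total,
        "counterion_accuracy": n_counter_ok / n_total,
        "rlbp1_exact_rate": n_rlbp_ok / n_total,
        "n_trials": n_trials,
        "n_queries": n_total,
    }
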