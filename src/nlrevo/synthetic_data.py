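"""Gene-family simulator with known ground truth.

A gene family evolves along a dated species tree by a birth-death-transfer
process: each gene lineage duplicates at rate ``dup_rate``, dies at rate
``loss_rate`` and copies itself into a uniformly chosen contemporaneous other
species branch at rate ``transfer_rate`` (all per gene per unit branch
length); at every speciation each lineage enters both daughter branches.
Binary domain presence (TIR, RPW8, Rx_N, LRR) then evolves along the pruned
gene tree as independent two-state Markov chains from an NL root state
(NB-ARC + LRR only); NB-ARC itself is never lost.  A separate generator
plants a single recombination breakpoint into an otherwise i.i.d. pair of
parental sequences.

Everything is reproducible from the configuration seed, and the full event
log (duplications, losses, transfers with their surviving descendants) is
returned so that event-calling rules can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .tree_events import GeneTree, HGTEvent

__all__ = [
    "SimulationConfig",
    "SimEvent",
    "GeneFamilyTruth",
    "ladder_species_tree",
    "simulate_gene_family",
    "evolve_domain_states",
    "simulate_recombinant_alignment",
    "match_hgt_calls",
]

DOMAINS = ("TIR", "RPW8", "Rx_N", "LRR")

#: Default per-unit-length gain/loss rates for the binary domain states.
DEFAULT_GAIN_RATES = {"TIR": 0.3, "RPW8": 0.1, "Rx_N": 0.3, "LRR": 0.1}
DEFAULT_LOSS_RATES = {"TIR": 0.5, "RPW8": 0.5, "Rx_N": 0.5, "LRR": 0.1}


def ladder_species_tree(n_species: int = 10, depth: float = 1.0) -> GeneTree:
    """Ultrametric caterpillar species tree with evenly spaced split times.

    Leaves are ``s01 .. sNN``; the root splits at time 0 and tips sit at
    ``depth``.  The default shape echoes a ten-genome study design.
    """
    if n_species < 2:
        raise ValueError("need >= 2 species")
    names = [f"s{i + 1:02d}" for i in range(n_species)]
    t = [i * depth / (n_species - 1) for i in range(n_species - 1)]
    cur = (f"({names[-2]}:{depth - t[-1]:.10g},"
           f"{names[-1]}:{depth - t[-1]:.10g})")
    for i in range(n_species - 3, -1, -1):
        cur = (f"({names[i]}:{depth - t[i]:.10g},"
               f"{cur}:{t[i + 1] - t[i]:.10g})")
    from .io_formats import parse_newick

    return parse_newick(cur + ";")


@dataclass(frozen=True)
class SimulationConfig:
    species_tree: Optional[GeneTree] = None  # default: 10-leaf unit-depth ladder
    #: per-gene per-unit-length duplication rate; either one number or a
    #: mapping from species-tree branch label to a rate (key "default"
    #: covers unlisted branches)
    dup_rate: Union[float, Mapping[str, float]] = 0.3
    loss_rate: float = 0.1
    transfer_rate: float = 0.1
    domain_gain_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GAIN_RATES))
    domain_loss_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOSS_RATES))
    n_root_genes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        dup_vals = (self.dup_rate.values()
                    if isinstance(self.dup_rate, Mapping) else [self.dup_rate])
        if any(v < 0 for v in dup_vals):
            raise ValueError("dup_rate must be >= 0")
        for name, val in (("loss_rate", self.loss_rate),
                          ("transfer_rate", self.transfer_rate)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        for d in DOMAINS:
            if self.domain_gain_rates.get(d, 0.0) < 0 or \
                    self.domain_loss_rates.get(d, 0.0) < 0:
                raise ValueError(f"negative domain rate for {d}")
        if self.n_root_genes < 1:
            raise ValueError("n_root_genes must be >= 1")

    def resolved_species_tree(self) -> GeneTree:
        return self.species_tree if self.species_tree is not None \
            else ladder_species_tree()


@dataclass(frozen=True)
class SimEvent:
    """One entry of the simulator's truth log."""

    type: str                # duplication | loss | transfer
    branch: str              # species-tree branch label where it happened
    time: float
    donor_species: str = ""
    recipient_species: str = ""          # branch label; a species iff terminal
    terminal_branch: bool = False        # branch (donor branch for transfers)
    recipient_leaf_ids: frozenset[str] = frozenset()  # transfers only


@dataclass
class GeneFamilyTruth:
    gene_tree: Optional[GeneTree]
    species_map: dict[str, str]
    event_log: list[SimEvent]
    domain_states: dict[str, frozenset[str]]
    species: list[str]
    species_branch_paths: dict[str, tuple[str, ...]]

    def true_classes(self) -> dict[str, str]:
        """Class label implied by each extant gene's simulated domain set."""
        out = {}
        for gid, doms in self.domain_states.items():
            if "TIR" in doms:
                out[gid] = "TNL"
            elif "RPW8" in doms:
                out[gid] = "RNL"
            elif "Rx_N" in doms:
                out[gid] = "CNL"
            else:
                out[gid] = "NL"
        return out


class _GeneNode:
    __slots__ = ("start", "end", "kind", "branch", "children", "gene_id")

    def __init__(self, start: float, branch) -> None:
        self.start = start
        self.end: Optional[float] = None
        self.kind = "open"
        self.branch = branch
        self.children: list["_GeneNode"] = []
        self.gene_id: Optional[str] = None


class _SpBranch:
    """One species-tree branch, identified by its child-end node."""

    __slots__ = ("label", "start", "end", "children", "is_leaf", "path")

    def __init__(self, label, start, end, is_leaf):
        self.label = label
        self.start = start
        self.end = end
        self.children: list["_SpBranch"] = []
        self.is_leaf = is_leaf
        self.path: tuple[str, ...] = ()


def _species_branches(tree: GeneTree) -> tuple[_SpBranch, list[_SpBranch]]:
    """Flatten a dated species tree into branch records in preorder."""
    t = tree.tree
    anc = 0
    root_b: Optional[_SpBranch] = None
    branches: list[_SpBranch] = []
    by_node: dict[int, _SpBranch] = {}
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            start = 0.0
        else:
            length = node.edge.length
            if length is None:
                raise ValueError("species tree must have branch lengths")
            start = by_node[id(parent)].end
        end = start if parent is None else start + node.edge.length
        if node.is_leaf():
            label = node.taxon.label if node.taxon else (node.label or "")
        elif parent is None:
            label = "root"
        else:
            anc += 1
            label = f"anc{anc}"
        b = _SpBranch(label, start, end, node.is_leaf())
        by_node[id(node)] = b
        branches.append(b)
        if parent is None:
            root_b = b
        else:
            pb = by_node[id(parent)]
            pb.children.append(b)
            b.path = pb.path + (b.label,)
    assert root_b is not None
    return root_b, branches


def simulate_gene_family(cfg: SimulationConfig) -> GeneFamilyTruth:
    """Run the birth-death-transfer process and return tree, maps and log.

    The returned gene tree is pruned to lineages with extant descendants
    (unary nodes suppressed, branch lengths merged).  A family whose lineages
    all die returns an empty truth object rather than raising.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 11]))
    sp_tree = cfg.resolved_species_tree()
    root_b, branches = _species_branches(sp_tree)
    mu, tau = cfg.loss_rate, cfg.transfer_rate
    if isinstance(cfg.dup_rate, Mapping):
        dmap = dict(cfg.dup_rate)

        def lam_of(b: _SpBranch) -> float:
            return float(dmap.get(b.label, dmap.get("default", 0.0)))
    else:
        lam_const = float(cfg.dup_rate)

        def lam_of(b: _SpBranch) -> float:
            return lam_const
    eps = 1e-12

    # branch end events, parents before children at equal times
    order = sorted(range(len(branches)), key=lambda i: (branches[i].end, i))
    active: dict[int, _SpBranch] = {id(root_b): root_b}
    lineages: dict[int, list[_GeneNode]] = {
        id(root_b): [_GeneNode(root_b.start, root_b) for _ in range(cfg.n_root_genes)]
    }
    roots = list(lineages[id(root_b)])
    log: list[tuple] = []  # (SimEvent fields..., transferred node)
    extant: list[_GeneNode] = []

    t_cur = root_b.start
    for i in order:
        b_end = branches[i]
        t_next = b_end.end
        # Gillespie on (t_cur, t_next) over all open lineages
        if t_next > t_cur + eps:
            t = t_cur
            while True:
                pool = [g for lst in lineages.values() for g in lst]
                if not pool:
                    break
                rates = np.array([lam_of(g.branch) + mu + tau for g in pool])
                total = float(rates.sum())
                if total <= 0:
                    break
                t += rng.exponential(1.0 / total)
                if t >= t_next - eps:
                    break
                g = pool[int(rng.choice(len(pool), p=rates / total))]
                br = g.branch
                lam = lam_of(br)
                u = rng.random() * (lam + mu + tau)
                if u < lam:  # duplication
                    g.end, g.kind = t, "dup"
                    kids = [_GeneNode(t, br), _GeneNode(t, br)]
                    g.children = kids
                    lineages[id(br)].remove(g)
                    lineages[id(br)].extend(kids)
                    log.append(SimEvent("duplication", br.label, t,
                                        terminal_branch=br.is_leaf))
                elif u < lam + mu:  # loss
                    g.end, g.kind = t, "loss"
                    lineages[id(br)].remove(g)
                    log.append(SimEvent("loss", br.label, t,
                                        terminal_branch=br.is_leaf))
                else:  # transfer
                    recips = [bb for bb in active.values() if bb is not br]
                    if not recips:
                        continue
                    rb = recips[rng.integers(len(recips))]
                    g.end, g.kind = t, "transfer"
                    cont = _GeneNode(t, br)
                    moved = _GeneNode(t, rb)
                    g.children = [cont, moved]
                    lineages[id(br)].remove(g)
                    lineages[id(br)].append(cont)
                    lineages[id(rb)].append(moved)
                    log.append((SimEvent("transfer", br.label, t,
                                         donor_species=br.label,
                                         recipient_species=rb.label,
                                         terminal_branch=br.is_leaf),
                                moved))
        t_cur = max(t_cur, t_next)
        # branch b_end terminates now
        on_branch = lineages.pop(id(b_end), [])
        active.pop(id(b_end), None)
        if b_end.is_leaf:
            for g in on_branch:
                g.end, g.kind = t_next, "leaf"
                extant.append(g)
        else:
            for child in b_end.children:
                active[id(child)] = child
                lineages.setdefault(id(child), [])
            for g in on_branch:
                g.end, g.kind = t_next, "speciation"
                for child in b_end.children:
                    kid = _GeneNode(t_next, child)
                    g.children.append(kid)
                    lineages[id(child)].append(kid)

    # gene ids per species, in simulation order
    species = [b.label for b in branches if b.is_leaf]
    counters = {s: 0 for s in species}
    species_map: dict[str, str] = {}
    for g in extant:
        sp = g.branch.label
        counters[sp] += 1
        g.gene_id = f"{sp}.g{counters[sp]}"
        species_map[g.gene_id] = sp

    def extant_ids(node: _GeneNode) -> frozenset[str]:
        stack, out = [node], []
        while stack:
            nd = stack.pop()
            if nd.kind == "leaf":
                out.append(nd.gene_id)
            stack.extend(nd.children)
        return frozenset(out)

    event_log: list[SimEvent] = []
    for entry in log:
        if isinstance(entry, SimEvent):
            event_log.append(entry)
        else:
            ev, moved = entry
            event_log.append(replace(ev, recipient_leaf_ids=extant_ids(moved)))

    paths = {b.label: b.path for b in branches if b.is_leaf}
    truth = GeneFamilyTruth(None, species_map, event_log, {}, species, paths)
    if not extant:
        return truth

    # prune to extant lineages, suppressing unary nodes
    def prune(node: _GeneNode) -> Optional[tuple[float, object]]:
        """Return (subtending branch length, newick-fragment) or None."""
        stack_out: dict[int, Optional[tuple[float, str]]] = {}
        post: list[_GeneNode] = []
        stack = [node]
        while stack:
            nd = stack.pop()
            post.append(nd)
            stack.extend(nd.children)
        for nd in reversed(post):
            if nd.kind == "leaf":
                stack_out[id(nd)] = (nd.end - nd.start, nd.gene_id)
                continue
            kept = [stack_out[id(c)] for c in nd.children
                    if stack_out.get(id(c)) is not None]
            own = (nd.end - nd.start) if nd.end is not None else 0.0
            if not kept:
                stack_out[id(nd)] = None
            elif len(kept) == 1:
                ln, frag = kept[0]
                stack_out[id(nd)] = (own + ln, frag)
            else:
                inner = ",".join(f"{frag}:{ln:.10g}" for ln, frag in kept)
                stack_out[id(nd)] = (own, f"({inner})")
        return stack_out[id(node)]

    kept_roots = [r for r in (prune(r) for r in roots) if r is not None]
    if len(kept_roots) == 1:
        ln, frag = kept_roots[0]
        newick = frag if frag.startswith("(") else f"({frag}:{ln:.10g})"
        if not frag.startswith("("):
            newick = f"({frag}:{ln:.10g});"
        else:
            newick = frag + ";"
    else:
        inner = ",".join(f"{frag}:{ln:.10g}" for ln, frag in kept_roots)
        newick = f"({inner});"
    from .io_formats import parse_newick

    gt = parse_newick(newick).with_species(species_map)
    truth.gene_tree = gt
    truth.domain_states = evolve_domain_states(truth, cfg)
    return truth


def evolve_domain_states(truth: GeneFamilyTruth,
                         cfg: SimulationConfig) -> dict[str, frozenset[str]]:
    """Sample binary domain states along the gene tree.

    Root state is the plain NL architecture (NB-ARC + LRR).  Each domain
    gains/loses independently with its rates; the transition probability over
    a branch of length t is the standard two-state chain formula.  NB-ARC is
    always present.
    """
    if truth.gene_tree is None or len(truth.gene_tree) == 0:
        return {}
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 23]))
    gains = {d: float(cfg.domain_gain_rates.get(d, 0.0)) for d in DOMAINS}
    losses = {d: float(cfg.domain_loss_rates.get(d, 0.0)) for d in DOMAINS}
    root_state = {"TIR": False, "RPW8": False, "Rx_N": False, "LRR": True}

    def step(state: bool, g: float, l: float, t: float) -> bool:
        rate = g + l
        if rate == 0.0 or t <= 0.0:
            return state
        p_change_to_present = (g / rate) * (1.0 - np.exp(-rate * t))
        p_change_to_absent = (l / rate) * (1.0 - np.exp(-rate * t))
        u = rng.random()
        if state:
            return not (u < p_change_to_absent)
        return u < p_change_to_present

    t = truth.gene_tree.tree
    states: dict[int, dict[str, bool]] = {}
    out: dict[str, frozenset[str]] = {}
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            st = dict(root_state)
        else:
            ln = node.edge.length or 0.0
            st = {d: step(states[id(parent)][d], gains[d], losses[d], ln)
                  for d in DOMAINS}
        states[id(node)] = st
        if node.is_leaf():
            gid = node.taxon.label if node.taxon else node.label
            doms = {"NB-ARC"} | {d for d in DOMAINS if st[d]}
            out[gid] = frozenset(doms)
    return out


def simulate_recombinant_alignment(
    n_background: int = 2,
    length: int = 1000,
    divergence: float = 0.3,
    breakpoint_frac: float = 0.5,
    seed: int = 0,
):
    """Plant one recombination breakpoint into a simulated alignment.

    Parent A is uniform random DNA; parent B (and any further background
    sequences) differ from A independently at each site with probability
    ``divergence``; the recombinant C is A up to site ``k = round(
    breakpoint_frac * length)`` and B afterwards.  Returns the alignment and
    the true breakpoint k (1-based last site inherited from A).
    """
    from .recombination import Alignment

    if n_background < 2:
        raise ValueError("need at least the two parents")
    if not (0.0 < divergence < 1.0):
        raise ValueError("divergence must be in (0, 1)")
    if not (0.0 < breakpoint_frac < 1.0):
        raise ValueError("breakpoint_frac must be in (0, 1)")
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 37]))
    bases = np.array(list("ACGT"))
    a_idx = rng.integers(4, size=length)

    def mutate(idx: np.ndarray) -> np.ndarray:
        flip = rng.random(length) < divergence
        shift = rng.integers(1, 4, size=length)  # guaranteed different base
        out = idx.copy()
        out[flip] = (out[flip] + shift[flip]) % 4
        return out

    b_idx = mutate(a_idx)
    k = int(round(breakpoint_frac * length))
    c_idx = np.concatenate([a_idx[:k], b_idx[k:]])
    ids = ["A", "B"] + [f"bg{i}" for i in range(1, n_background - 1)] + ["C"]
    rows = [a_idx, b_idx] + [mutate(a_idx) for _ in range(n_background - 2)] \
        + [c_idx]
    aln = Alignment(tuple(ids),
                    tuple("".join(bases[r]) for r in rows))
    return aln, k


def match_hgt_calls(
    truth: Iterable[GeneFamilyTruth],
    calls: Iterable[Sequence[HGTEvent]],
    min_jaccard: float = 0.5,
) -> tuple[float, float, int]:
    """Score called transfers against truth logs: (precision, recall, matched).

    Per family, a call matches a true transfer when the called recipient
    species occurs among the transfer's surviving descendants and the Jaccard
    overlap between called clade and surviving descendant set is at least
    ``min_jaccard``; matching is greedy, best overlap first, one-to-one.
    Only true transfers with surviving descendants count toward recall.
    """
    n_calls = n_true = n_matched = 0
    for fam, fam_calls in zip(truth, calls):
        true_tr = [ev for ev in fam.event_log
                   if ev.type == "transfer" and ev.recipient_leaf_ids]
        n_true += len(true_tr)
        n_calls += len(fam_calls)
        pairs = []
        for ci, call in enumerate(fam_calls):
            for ti, ev in enumerate(true_tr):
                desc = ev.recipient_leaf_ids
                desc_species = {fam.species_map[g] for g in desc}
                if call.recipient_species not in desc_species:
                    continue
                inter = len(call.recipient_clade_leaf_ids & desc)
                union = len(call.recipient_clade_leaf_ids | desc)
                jac = inter / union if union else 0.0
                if jac >= min_jaccard:
                    pairs.append((jac, ci, ti))
        used_c: set[int] = set()
        used_t: set[int] = set()
        for jac, ci, ti in sorted(pairs, key=lambda p: -p[0]):
            if ci in used_c or ti in used_t:
                continue
            used_c.add(ci)
            used_t.add(ti)
            n_matched += 1
    precision = n_matched / n_calls if n_calls else 1.0
    recall = n_matched / n_true if n_true else 1.0
    return precision, recall, n_matched
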