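import numpy as np
import pytest

import dendropy

from nlrevo import (SimulationConfig, classify_architecture,
                    ladder_species_tree, simulate_gene_family,
                    simulate_recombinant_alignment)
from nlrevo.nlr_identify import DomainArchitecture
from .conftest import arch_from_flags


def test_null_rates_reproduce_species_tree_topology():
    cfg = SimulationConfig(dup_rate=0, loss_rate=0, transfer_rate=0, seed=4)
    truth = simulate_gene_family(cfg)
    assert truth.event_log == []
    assert sorted(truth.species_map.values()) == sorted(
        cfg.resolved_species_tree().leaf_ids)
    # one gene per species and gene tree congruent with the species tree
    sp = cfg.resolved_species_tree().tree.clone(depth=1)
    gene = truth.gene_tree.tree.clone(depth=1)
    for lf in gene.leaf_node_iter():
        lf.taxon.label = truth.species_map[lf.taxon.label]
    ns = dendropy.TaxonNamespace()
    sp.migrate_taxon_namespace(ns)
    gene.migrate_taxon_namespace(ns)
    sp.encode_bipartitions()
    gene.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(sp, gene) == 0


def test_seed_determinism_is_byte_exact():
    cfg = SimulationConfig(dup_rate=0.4, loss_rate=0.1, transfer_rate=0.15,
                           seed=99)
    a = simulate_gene_family(cfg)
    b = simulate_gene_family(cfg)
    assert a.gene_tree.as_newick() == b.gene_tree.as_newick()
    assert a.species_map == b.species_map
    assert a.event_log == b.event_log
    assert a.domain_states == b.domain_states


def test_transfer_log_is_consistent():
    hits = 0
    for seed in range(30):
        cfg = SimulationConfig(dup_rate=0.3, loss_rate=0.1, transfer_rate=0.3,
                               seed=seed)
        truth = simulate_gene_family(cfg)
        for ev in truth.event_log:
            if ev.type != "transfer":
                continue
            hits += 1
            assert ev.donor_species != ev.recipient_species
            for gid in ev.recipient_leaf_ids:
                assert gid in truth.species_map
    assert hits > 0


def test_extant_count_equals_one_plus_ancestral_duplications():
    # with no loss and no transfer, each species' copy number is explained
    # exactly by the duplications on its root-to-tip species path
    for seed in range(25):
        cfg = SimulationConfig(dup_rate=0.5, loss_rate=0, transfer_rate=0,
                               seed=300 + seed)
        truth = simulate_gene_family(cfg)
        counts = {s: 0 for s in truth.species}
        for sp in truth.species_map.values():
            counts[sp] += 1
        for s in truth.species:
            path = set(truth.species_branch_paths[s]) | {"root"}
            n_dup = sum(1 for e in truth.event_log
                        if e.type == "duplication" and e.branch in path)
            assert counts[s] == cfg.n_root_genes + n_dup


def test_all_extinct_family_returns_empty_truth():
    cfg = SimulationConfig(dup_rate=0.0, loss_rate=50.0, transfer_rate=0.0,
                           seed=8)
    truth = simulate_gene_family(cfg)
    assert truth.gene_tree is None
    assert truth.species_map == {} and truth.domain_states == {}


def test_zero_domain_rates_keep_everything_NL():
    cfg = SimulationConfig(dup_rate=0.3, loss_rate=0, transfer_rate=0,
                           domain_gain_rates={}, domain_loss_rates={}, seed=2)
    truth = simulate_gene_family(cfg)
    assert set(truth.true_classes().values()) == {"NL"}
    assert all(doms == {"NB-ARC", "LRR"}
               for doms in truth.domain_states.values())


def test_high_tir_gain_produces_tnls_and_partition_is_total():
    cfg = SimulationConfig(dup_rate=0.3, loss_rate=0, transfer_rate=0,
                           domain_gain_rates={"TIR": 5.0},
                           domain_loss_rates={}, seed=3)
    truth = simulate_gene_family(cfg)
    classes = truth.true_classes()
    assert len(classes) == len(truth.species_map)
    assert sum(1 for c in classes.values() if c == "TNL") > 0


def test_simulated_domain_states_reclassify_to_truth():
    cfg = SimulationConfig(dup_rate=0.3, loss_rate=0.05, transfer_rate=0.05,
                           seed=12)
    truth = simulate_gene_family(cfg)
    for gid, doms in truth.domain_states.items():
        arch = arch_from_flags(nbarc="NB-ARC" in doms, tir="TIR" in doms,
                               rpw8="RPW8" in doms, rxn="Rx_N" in doms,
                               lrr="LRR" in doms)
        assert classify_architecture(arch).value == truth.true_classes()[gid]


def test_ladder_species_tree_shape():
    t = ladder_species_tree(10, 1.0)
    assert len(t) == 10
    depths = {sum(nd.edge.length for nd in lf.ancestor_iter(inclusive=True)
                  if nd.edge.length)
              for lf in t.tree.leaf_node_iter()}
    assert all(abs(d - 1.0) < 1e-9 for d in depths)  # ultrametric


def test_recombinant_alignment_construction():
    aln, k = simulate_recombinant_alignment(2, 1000, 0.3, 0.25, seed=6)
    assert k == 250
    a, b, c = aln.row("A"), aln.row("B"), aln.row("C")
    assert c == a[:250] + b[250:]
    diff = sum(x != y for x, y in zip(a, b))
    # binomial(1000, 0.3) 99% band
    sd = np.sqrt(1000 * 0.3 * 0.7)
    assert abs(diff - 300) < 2.58 * sd
    again, _ = simulate_recombinant_alignment(2, 1000, 0.3, 0.25, seed=6)
    assert again == aln
    with_bg = simulate_recombinant_alignment(4, 100, 0.2, 0.5, seed=1)[0]
    assert set(with_bg.ids) == {"A", "B", "C", "bg1", "bg2"}


@pytest.mark.parametrize("kwargs", [
    dict(dup_rate=-0.1), dict(n_root_genes=0),
    dict(domain_gain_rates={"TIR": -1.0}),
])
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)
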