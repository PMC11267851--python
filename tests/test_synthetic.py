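import numpy as np
import pandas as pd
import pytest

from msm.synthetic import (
    LOHEvent,
    MixtureModel,
    NoiseModel,
    SyntheticGenome,
    expected_af,
    make_cluster_map,
    make_phased_variants,
    sample_id,
    simulate_counts,
    simulate_phased_reads,
    simulate_single_cell_counts,
    simulate_truth,
)
from msm.topology import TreeTopology

SMALL_GENOME = SyntheticGenome(chrom_lengths={"chr1": 50_000}, seed=3, n_at_hotspots=20)


def test_pregraft_only_truth_covers_all_tips():
    top = TreeTopology.from_newick("((B1,(B2,B3)),B4);")
    truth = simulate_truth(
        top, rate_l1=0, rate_l2=0, p_shared=0, n_pregraft_l1=5, n_pregraft_l2=0,
        n_organ_per_sample=0, seed=1, genome=SMALL_GENOME,
    )
    assert len(truth) == 5
    for m in truth.mutations:
        assert m.branch_set == {"B1", "B2", "B3", "B4"}
        assert m.origin_layer == "L1" and m.origin_node == "pre-graft"


def test_branch_set_equals_subtree_of_origin_node(topology, genome):
    truth = simulate_truth(topology, seed=4, genome=genome)
    for m in truth.mutations:
        if m.origin_node == "pre-graft":
            assert m.branch_set == set(topology.tips)
        elif m.origin_node.startswith("organ:"):
            assert len(m.branch_set) == 1
        else:
            assert m.branch_set == topology.subtree_tips(m.origin_node)


def test_positions_unique_per_chrom(topology, genome):
    truth = simulate_truth(topology, seed=5, genome=genome)
    df = truth.to_frame()
    assert not df.duplicated(["chrom", "pos"]).any()


def test_truth_rate_ratio_matches_request(topology):
    """Monte-Carlo: layer-specific truth counts follow the 2:1 rate ratio."""
    n1 = n2 = 0
    for seed in range(300):
        truth = simulate_truth(
            topology, rate_l1=2.0, rate_l2=1.0, p_shared=0, n_pregraft_l1=0,
            n_pregraft_l2=0, n_organ_per_sample=0, seed=seed, genome=SMALL_GENOME,
        )
        n1 += sum(m.origin_layer == "L1" for m in truth.mutations)
        n2 += sum(m.origin_layer == "L2" for m in truth.mutations)
    assert n1 / n2 == pytest.approx(2.0, rel=0.05)


def test_truth_determinism(topology, genome, tmp_path):
    a = simulate_truth(topology, seed=9, genome=genome)
    b = simulate_truth(topology, seed=9, genome=genome)
    assert a.mutations == b.mutations
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    a.write_tsv(pa)
    b.write_tsv(pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_truth_input_validation(topology, genome):
    with pytest.raises(ValueError):
        simulate_truth(topology, rate_l1=-1, genome=genome)
    with pytest.raises(ValueError):
        simulate_truth(topology, rate_l1=1, rate_l2=2, genome=genome)
    with pytest.raises(ValueError):
        simulate_truth(topology, p_shared=1.5, genome=genome)


def test_mixture_validation():
    MixtureModel()
    with pytest.raises(ValueError):
        MixtureModel(fractions={"leaf": {"L1": 0.6, "L2": 0.6}})


def test_noise_validation():
    with pytest.raises(ValueError):
        NoiseModel(error_rate=0.5)
    with pytest.raises(ValueError):
        NoiseModel(mean_depth=-10)


def test_expected_af_closed_forms(topology, genome):
    truth = simulate_truth(topology, seed=6, genome=genome)
    mix = MixtureModel()
    m_l1 = next(m for m in truth.mutations if m.origin_layer == "L1")
    m_l2 = next(m for m in truth.mutations if m.origin_layer == "L2")
    assert expected_af(m_l1, "leaf", mix) == pytest.approx(0.5 * 0.089)
    assert expected_af(m_l2, "L2-fruit", mix) == pytest.approx(0.49)
    assert expected_af(m_l1, "L1-fruit", mix) == pytest.approx(0.475)


def test_counts_match_expected_af(small_simulation):
    """Observed AFs at carrier sites track the mixture closed form."""
    truth = small_simulation["truth"]
    mix = small_simulation["mixture"]
    for tissue, layer in (("L1-fruit", "L1"), ("L2-fruit", "L2"), ("leaf", "L2")):
        muts = [
            m for m in truth.mutations
            if m.origin_layer == layer and not m.origin_node.startswith("organ")
        ]
        afs = []
        for m in muts:
            for b in m.branch_set:
                t = small_simulation["tables"][sample_id(b, tissue)]
                stats = t.site_stats()
                row = stats[(stats["chrom"] == m.chrom) & (stats["pos"] == m.pos)]
                if len(row):
                    afs.append(float(row["af"].iloc[0]))
        assert np.mean(afs) == pytest.approx(
            expected_af(muts[0], tissue, mix), abs=0.02
        )


def test_non_carrier_sites_have_error_level_alt(small_simulation):
    truth = small_simulation["truth"]
    m = next(
        m for m in truth.mutations
        if len(m.branch_set) == 1 and not m.origin_node.startswith("organ")
    )
    other_branch = next(b for b in "B1 B2 B3 B4 B5 B6 B7".split() if b not in m.branch_set)
    t = small_simulation["tables"][sample_id(other_branch, "L1-fruit")]
    stats = t.site_stats()
    row = stats[(stats["chrom"] == m.chrom) & (stats["pos"] == m.pos)]
    assert row.empty or row["af"].iloc[0] < 0.05


def test_zero_depth_emits_no_rows(topology, genome):
    truth = simulate_truth(topology, seed=7, genome=genome)
    tables = simulate_counts(
        truth, MixtureModel(), NoiseModel(mean_depth=0, seed=7),
        [("B1", "L1-fruit")], n_background=10,
    )
    assert tables[sample_id("B1", "L1-fruit")].empty


def test_counts_reject_unknown_tissue_or_branch(topology, genome):
    truth = simulate_truth(topology, seed=7, genome=genome)
    with pytest.raises(ValueError, match="tissue"):
        simulate_counts(truth, MixtureModel(), NoiseModel(), [("B1", "petal")])
    with pytest.raises(ValueError, match="tip"):
        simulate_counts(truth, MixtureModel(), NoiseModel(), [("B99", "leaf")])


def test_counts_determinism(topology, genome):
    truth = simulate_truth(topology, seed=8, genome=genome)
    args = (truth, MixtureModel(), NoiseModel(seed=8), [("B1", "L1-fruit")])
    t1 = simulate_counts(*args, n_background=50)
    t2 = simulate_counts(*args, n_background=50)
    sid = sample_id("B1", "L1-fruit")
    assert t1[sid].df.equals(t2[sid].df)


# -- phased reads ----------------------------------------------------------


def test_switch_reads_at_planted_event():
    genome = SyntheticGenome(chrom_lengths={"chr1": 30_000}, seed=2)
    phased = make_phased_variants(genome, spacing=500, end=30_000, seed=2)
    ev = LOHEvent(chrom="chr1", start=10_000, end=15_000, branch="B1", layer="L1")
    obs, _ = simulate_phased_reads(
        [ev], phased, NoiseModel(error_rate=0.0, seed=2),
        [("B1", "L1-fruit"), ("B1", "L2-fruit")], span_reads=30,
    )
    carrier = obs[obs["sample"] == "B1.L1-fruit"]
    switches = carrier[carrier["hap1"] != carrier["hap2"]]
    assert len(switches) >= 30  # all spanning reads at each boundary switch
    other = obs[obs["sample"] == "B1.L2-fruit"]
    assert (other["hap1"] == other["hap2"]).all()  # zero error rate


def test_event_af_shift_in_carrier_only():
    genome = SyntheticGenome(chrom_lengths={"chr1": 30_000}, seed=2)
    phased = make_phased_variants(genome, spacing=500, end=30_000, seed=2)
    ev = LOHEvent(chrom="chr1", start=10_000, end=15_000, branch="B1", layer="L1")
    _, tables = simulate_phased_reads(
        [ev], phased, NoiseModel(seed=3), [("B1", "L1-fruit"), ("B1", "L2-fruit")],
    )
    inside = phased[(phased["pos"] >= 10_000) & (phased["pos"] <= 15_000)]["pos"]

    def af_b(table, pos):
        df = table.df
        site = df[df["pos"] == pos]
        b = phased.set_index("pos").loc[pos, "allele_b"]
        hit = site[site["allele"] == b]
        return (hit["count"].iloc[0] if len(hit) else 0) / site["depth"].iloc[0]

    carrier_afs = [af_b(tables["B1.L1-fruit"], p) for p in inside]
    other_afs = [af_b(tables["B1.L2-fruit"], p) for p in inside]
    assert np.mean(carrier_afs) < 0.1  # retained haplotype A: alt collapses
    assert np.mean(other_afs) == pytest.approx(0.5, abs=0.05)


def test_no_event_means_no_switch_signal():
    """Binomial bound: at error 1e-3 no pair accumulates 10 switch reads."""
    genome = SyntheticGenome(chrom_lengths={"chr1": 30_000}, seed=2)
    phased = make_phased_variants(genome, spacing=500, end=30_000, seed=2)
    obs, _ = simulate_phased_reads(
        [], phased, NoiseModel(seed=4), [("B1", "L1-fruit"), ("B1", "L2-fruit")],
    )
    obs["switch"] = obs["hap1"] != obs["hap2"]
    per_pair = obs.groupby(["sample", "pos1"])["switch"].sum()
    assert (per_pair < 10).all()


def test_unobservable_event_warns():
    genome = SyntheticGenome(chrom_lengths={"chr1": 30_000}, seed=2)
    phased = make_phased_variants(genome, spacing=500, start=20_000, end=30_000, seed=2)
    ev = LOHEvent(chrom="chr1", start=1_000, end=2_000, branch="B1", layer="L1")
    with pytest.warns(UserWarning, match="unobservable"):
        simulate_phased_reads([ev], phased, NoiseModel(seed=5), [("B1", "L1-fruit")])


# -- single cell -----------------------------------------------------------


def _l2_truth():
    top = TreeTopology.default()
    return simulate_truth(
        top, rate_l1=0.5, rate_l2=0.5, p_shared=0, n_pregraft_l1=0,
        n_pregraft_l2=0, n_organ_per_sample=0, seed=13, genome=SMALL_GENOME,
    )


def test_mutant_reads_confined_to_origin_layer():
    truth = _l2_truth()
    cmap = make_cluster_map(truth.topology.tips, cells_per_branch=150, seed=13)
    sc = simulate_single_cell_counts(truth, cmap, expression_rate=0.5, seed=13)
    layer_of = cmap.set_index("barcode")["layer"]
    for m in truth.mutations:
        at = sc[(sc["chrom"] == m.chrom) & (sc["pos"] == m.pos)]
        mut = at[at["allele"] == (m.token or m.alt)]
        assert set(layer_of.loc[mut["barcode"]]) <= {m.origin_layer}


def test_zero_expression_rate_no_reads():
    truth = _l2_truth()
    cmap = make_cluster_map(truth.topology.tips, cells_per_branch=50, seed=1)
    sc = simulate_single_cell_counts(truth, cmap, expression_rate=0.0, seed=1)
    assert sc.empty


def test_invalid_cluster_layers_rejected():
    truth = _l2_truth()
    cmap = make_cluster_map(truth.topology.tips, cells_per_branch=10, seed=1)
    cmap.loc[0, "layer"] = "L9"
    with pytest.raises(ValueError, match="layer"):
        simulate_single_cell_counts(truth, cmap, seed=1)


def test_genome_triplet_and_hotspots():
    g = SMALL_GENOME
    chrom, pos = g.at_hotspots[0]
    run = g.slice(chrom, pos, pos + 9)
    assert run in ("ATATATATAT"[:10], "ATATATATAT")
    assert g.triplet("chr1", 1) is None  # contig edge
    trip = g.triplet("chr1", 100)
    assert len(trip) == 3 and trip[1] == g.base("chr1", 100)
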