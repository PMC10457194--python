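"""Synthetic-data generator: determinism, conservation and planted structure."""

import numpy as np
import pandas as pd
import pytest

from kappacascade.simdata import (CapacityError, SimConfig, simulate_counts,
                                  simulate_dataset, simulate_genome, simulate_tags,
                                  standard_design)


def test_empty_genome_case():
    cfg = SimConfig(n_genes=0, n_sites_shared=0, n_sites_relA_only=0,
                    n_sites_rel_only=0, class_counts={})
    genome, truth = simulate_genome(cfg)
    assert genome.genes == [] and truth.gene_table.empty


def test_genome_determinism_under_seed():
    cfg = SimConfig(seed=1)
    g1, t1 = simulate_genome(cfg)
    g2, t2 = simulate_genome(cfg)
    assert [vars(a) for a in g1.genes] == [vars(b) for b in g2.genes]
    pd.testing.assert_frame_equal(t1.site_table, t2.site_table)


def test_site_class_tallies():
    cfg = SimConfig(seed=7, n_sites_shared=50, n_sites_relA_only=25,
                    n_sites_rel_only=25)
    _, truth = simulate_genome(cfg)
    tallies = truth.site_table.site_class.value_counts()
    assert len(truth.site_table) == 100
    assert tallies["shared"] == 50
    assert tallies["relA_only"] == 25 and tallies["rel_only"] == 25


def test_indirect_genes_unlinked():
    _, truth = simulate_genome(SimConfig(seed=3))
    gt = truth.gene_table.set_index("gene_id")
    ind = gt[gt.gene_class == "indirect"]
    assert (ind.linked_sites.map(len) == 0).all()
    direct = gt[gt.gene_class.isin(["relA_selective", "rel_dependent",
                                    "redundant_direct", "rel_repressed"])]
    sites = set(truth.site_table.site_id)
    assert all(set(v) <= sites and len(v) == 1 for v in direct.linked_sites)


def test_capacity_errors():
    with pytest.raises(CapacityError):
        simulate_genome(SimConfig(n_genes=2000))  # territories too small
    with pytest.raises(CapacityError):
        simulate_genome(SimConfig(n_genes=50, class_counts={"null": 50},
                                  n_sites_shared=60, n_sites_relA_only=0,
                                  n_sites_rel_only=0))  # more sites than genes


def test_tag_totals_conserved_within_poisson_bounds():
    cfg = SimConfig(seed=5)
    _, truth = simulate_genome(cfg)
    genome, _ = simulate_genome(cfg)
    for factor, t in (("RelA", 1), ("Rel", 18), ("input", 0)):
        lib = simulate_tags(truth, genome, factor, t, 1, cfg)
        assert abs(lib.total_tags - cfg.chip_depth_tags) <= 3 * np.sqrt(cfg.chip_depth_tags)


def test_inactive_site_emits_no_extra_tags():
    """RelA tags at 18 h on a rel_only site stay at background density."""
    cfg = SimConfig(seed=9)
    genome, truth = simulate_genome(cfg)
    lib = simulate_tags(truth, genome, "RelA", 18, 1, cfg)
    rel_sites = truth.site_table[truth.site_table.site_class == "rel_only"]
    rate = cfg.chip_depth_tags / cfg.genome_length
    counts = [
        int(lib.counts_in(r.chrom, np.array([r.center - 100]), np.array([r.center + 100]))[0])
        for r in rel_sites.itertuples()
    ]
    expected_bg = rate * 200
    # mean over 25 windows ~ Poisson; allow 4 sigma
    assert np.mean(counts) < expected_bg + 4 * np.sqrt(expected_bg / len(counts))


def test_tag_determinism_and_unknown_factor():
    cfg = SimConfig(seed=2)
    genome, truth = simulate_genome(cfg)
    l1 = simulate_tags(truth, genome, "Rel", 18, 1, cfg)
    l2 = simulate_tags(truth, genome, "Rel", 18, 1, cfg)
    for c in l1.positions:
        for s in "+-":
            assert np.array_equal(l1.positions[c][s], l2.positions[c][s])
    with pytest.raises(ValueError, match="factor"):
        simulate_tags(truth, genome, "H3K4me3", 1, 1, cfg)


@pytest.mark.parametrize("dispersion,bound", [
    # near-Poisson: fold-change noise is shot noise only, well under 0.5
    (0.001, 0.5),
    # default biological dispersion: replicate-pair noise floor is
    # sqrt(2*alpha/n_rep)/ln2 ~ 0.32, so the 95% bound sits near 2 sigma
    (0.05, 1.0),
])
def test_counts_determinism_and_null_flatness(dispersion, bound):
    cfg = SimConfig(seed=4, dispersion=dispersion)
    _, truth = simulate_genome(cfg)
    design = standard_design(cfg)
    cm1 = simulate_counts(truth, design, cfg)
    cm2 = simulate_counts(truth, design, cfg)
    pd.testing.assert_frame_equal(cm1.counts, cm2.counts)

    from kappacascade.diffexpr import fold_changes, normalize
    fc = fold_changes(normalize(cm1))
    nulls = truth.gene_table.gene_id[truth.gene_table.gene_class == "null"]
    null_fc = fc.loc[nulls].abs().values
    assert np.quantile(null_fc, 0.95) < bound


def test_counts_missing_baseline_rejected():
    cfg = SimConfig(seed=4)
    _, truth = simulate_genome(cfg)
    design = [m for m in standard_design(cfg) if m.time_h != 0]
    with pytest.raises(ValueError, match="baseline"):
        simulate_counts(truth, design, cfg)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(enrichment_fold=1.0)
    with pytest.raises(ValueError):
        SimConfig(dispersion=0.0)
    with pytest.raises(ValueError):
        SimConfig(class_counts={"null": 10**6})
    with pytest.raises(ValueError):
        SimConfig(class_counts={"mystery": 1})


def test_fixture_roundtrip(tmp_path, small_dataset):
    from kappacascade.io import read_fixture, write_fixture
    write_fixture(small_dataset, tmp_path)
    back = read_fixture(tmp_path)
    pd.testing.assert_frame_equal(back.counts.counts, small_dataset.counts.counts)
    assert back.counts.samples == small_dataset.counts.samples
    assert len(back.genome.genes) == len(small_dataset.genome.genes)
    for a, b in zip(sorted(back.genome.genes, key=lambda g: g.gene_id),
                    sorted(small_dataset.genome.genes, key=lambda g: g.gene_id)):
        assert vars(a) == vars(b)
    for la, lb in zip(back.tags, small_dataset.tags):
        assert la.sample_id == lb.sample_id
        assert la.total_tags == lb.total_tags
        for c in lb.positions:
            for s in "+-":
                assert np.array_equal(la.positions[c][s], lb.positions[c][s])
    pd.testing.assert_frame_equal(back.truth.gene_table, small_dataset.truth.gene_table)
    # BED line counts equal emitted tag counts
    for lib in small_dataset.tags:
        n_lines = sum(1 for _ in open(tmp_path / "tags" / f"{lib.sample_id}.bed"))
        assert n_lines == lib.total_tags
    # GTF gene feature count equals configured gene number
    gtf = (tmp_path / "genes.gtf").read_text().splitlines()
    assert sum(1 for l in gtf if l.split("\t")[2] == "gene") == small_dataset.config.n_genes
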