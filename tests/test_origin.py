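"""Donor assignment, panel placement, imputation and k-means validation."""

import numpy as np
import pandas as pd
import pytest

from b73prov import origin as O
from b73prov.model import GenomicInterval, SITE_COLUMNS
from _util import make_matrix


def _panel(calls, names=None, positions=None, chrom="1"):
    calls = np.asarray(calls, dtype=np.int8)
    if names is None:
        names = [f"H{j + 1}" for j in range(calls.shape[1])]
    if positions is None:
        positions = [100 * (i + 1) for i in range(calls.shape[0])]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"},
        columns=SITE_COLUMNS,
    )
    return O.PanelMatrix(sites, list(names), calls)


REGION = GenomicInterval("1", 1, 10_000)


def test_nearest_haplotype_exact_match_and_tie():
    panel = _panel([[2, 0, 2], [2, 0, 0], [2, 0, 2], [0, 2, 2]])
    consensus = np.array([2, 2, 2, 0], dtype=np.int8)
    sites = panel.sites
    names, dist = O.nearest_haplotype(consensus, sites, panel, REGION)
    assert names == ["H1"]
    assert dist == 0.0
    # equidistant pair -> both reported, flagged as no single best match
    tie_panel = _panel([[2, 2], [0, 2], [2, 0], [0, 0]])
    names, dist = O.nearest_haplotype(
        np.array([2, 2, 2, 0], dtype=np.int8), sites, tie_panel, REGION
    )
    assert names == ["H1", "H2"]
    assert dist == pytest.approx(0.25)


def test_nearest_haplotype_requires_shared_sites():
    panel = _panel([[-1], [-1]])
    with pytest.raises(ValueError):
        O.nearest_haplotype(np.array([2, 0], dtype=np.int8), panel.sites, panel, REGION)


def test_nearest_haplotype_distance_zero_iff_identical():
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(30, 4)).astype(np.int8)
    panel = _panel(calls)
    for j in range(4):
        names, dist = O.nearest_haplotype(calls[:, j], panel.sites, panel, REGION)
        assert panel.haplotypes[j] in names
        assert dist == 0.0


def test_panel_tree_places_copy_at_zero_terminal_branch():
    rng = np.random.default_rng(1)
    calls = np.where(rng.random((40, 6)) < 0.3, 2, 0).astype(np.int8)
    panel = _panel(calls)
    query = calls[:, 2].copy()
    tree, terms = O.place_in_panel_tree(
        {"query": query}, panel.sites, panel, REGION
    )
    assert terms["query"] == pytest.approx(0.0, abs=1e-9)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    assert labels == set(panel.haplotypes) | {"query"}


def test_two_consensuses_from_same_donor_cluster_together():
    from b73prov import phylo

    rng = np.random.default_rng(2)
    calls = np.where(rng.random((60, 8)) < 0.4, 2, 0).astype(np.int8)
    panel = _panel(calls)
    donor = calls[:, 5]
    qa, qb = donor.copy(), donor.copy()
    qa[:2] = 2 - qa[:2]  # tiny independent perturbations
    qb[2:4] = 2 - qb[2:4]
    tree, _ = O.place_in_panel_tree(
        {"cladeA": qa, "cladeB": qb}, panel.sites, panel, REGION
    )
    assert phylo.has_split(tree, {"cladeA", "cladeB", "H6"})


def test_impute_identity_when_nothing_missing():
    m = make_matrix([[0, 1, 2], [2, 2, 2]])
    assert O.impute_missing(m) == m


def test_impute_fills_from_identical_neighbours():
    calls = np.full((6, 5), 2, dtype=np.int8)
    calls[3, 0] = -1
    m = make_matrix(calls)
    out = O.impute_missing(m, k=3)
    assert out.calls[3, 0] == 2


def test_impute_never_alters_observed_calls():
    rng = np.random.default_rng(3)
    calls = rng.integers(-1, 3, size=(50, 8)).astype(np.int8)
    calls[:, 0] = rng.integers(0, 3, 50)  # ensure no all-missing pair errors
    m = make_matrix(calls)
    out = O.impute_missing(m, k=3)
    observed = calls >= 0
    assert np.array_equal(out.calls[observed], calls[observed])
    assert (out.calls >= 0).all()


def test_kmeans_separates_constructed_groups_deterministically():
    rng = np.random.default_rng(4)
    n_sites = 40
    carrier_hap = np.full(n_sites, 2, dtype=np.int8)
    ref_hap = np.zeros(n_sites, dtype=np.int8)
    cols = []
    for j in range(6):  # samples: 3 carriers, 3 reference
        base = carrier_hap if j < 3 else ref_hap
        noisy = base.copy()
        flip = rng.random(n_sites) < 0.05
        noisy[flip] = 2 - noisy[flip]
        cols.append(noisy)
    m = make_matrix(np.column_stack(cols))
    panel = _panel(np.column_stack([carrier_hap, ref_hap]), names=["donor", "refpanel"])
    part = O.kmeans_validation(m, panel, REGION, seed=9)
    cluster_with_donor = part[0] if "donor" in part[0] else part[1]
    assert cluster_with_donor == frozenset({"s1", "s2", "s3", "donor"})
    again = O.kmeans_validation(m, panel, REGION, seed=9)
    assert set(part) == set(again)


def test_kmeans_rejects_degenerate_input():
    m = make_matrix(np.zeros((5, 3), dtype=np.int8))
    panel = _panel(np.zeros((5, 2), dtype=np.int8))
    with pytest.raises(ValueError, match="distinct"):
        O.kmeans_validation(m, panel, REGION, seed=0)
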