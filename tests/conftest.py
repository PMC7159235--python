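import json

import pytest

from enloft import genomic_io as gio
from enloft.curation import LabelSet
from enloft.features import (
    compute_enhancer_features,
    impute_missing,
    prune_correlated_features,
)
from enloft.meganet import build_meganet, extract_tissue_subnetwork
from enloft.synthetic_fixtures import FixtureSpec, generate_universe


def load_manifest(bundle):
    return dict(bundle.manifest)


def build_matrix(bundle, prune_threshold=0.9):
    """Standard network -> features -> prune -> impute path for a bundle."""
    with open(bundle.paths["tissue_map"]) as fh:
        tissue_map = json.load(fh)
    table = gio.read_enhancer_network(bundle.paths["network"], tissue_map)
    interactions, _ = gio.read_gene_interactions(bundle.paths["interactions"])
    net = build_meganet(table.edges, interactions)
    subs = [extract_tissue_subnetwork(net, t) for t in sorted(net.tissues)]
    gis = gio.read_scalar_table(bundle.paths["gis"])
    cons = gio.read_scalar_table(bundle.paths["conservation"])
    matrix = compute_enhancer_features(net, subs, gis, cons)
    matrix = prune_correlated_features(matrix, threshold=prune_threshold)
    return impute_missing(matrix, policy="median"), net, table


def labels_from_manifest(bundle):
    return LabelSet.from_calls(
        bundle.ids_of("tolerant"), bundle.ids_of("low")
    )


@pytest.fixture(scope="session")
def signal_universe(tmp_path_factory):
    """Default synthetic universe with realistic class signal."""
    out = tmp_path_factory.mktemp("signal_universe")
    return generate_universe(FixtureSpec(seed=11), out)


@pytest.fixture(scope="session")
def signal_matrix(signal_universe):
    matrix, _, _ = build_matrix(signal_universe)
    return matrix


@pytest.fixture(scope="session")
def signal_labels(signal_universe):
    return labels_from_manifest(signal_universe)


@pytest.fixture(scope="session")
def noise_universe(tmp_path_factory):
    """Signal-free universe: class-conditional distributions identical."""
    out = tmp_path_factory.mktemp("noise_universe")
    return generate_universe(FixtureSpec(seed=13, signal_strength=0.0), out)


@pytest.fixture(scope="session")
def noise_matrix(noise_universe):
    matrix, _, _ = build_matrix(noise_universe)
    return matrix


@pytest.fixture(scope="session")
def noise_labels(noise_universe):
    return labels_from_manifest(noise_universe)
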