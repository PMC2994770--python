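import dendropy
import numpy as np
import pandas as pd
import pytest

from mitolocus.alignment_io import TaxonomyTable, make_alignment
from mitolocus.synthetic_data import SimulationConfig, TruthBundle, simulate_locus


@pytest.fixture
def tiny_alignment():
    return make_alignment(
        [
            ("s1", "ACGTACGTACGT"),
            ("s2", "ACGTACGTACGA"),
            ("s3", "ACGTACGTACGT"),
        ]
    )


@pytest.fixture
def bear_taxonomy():
    """Taxonomy with conspecific subspecies samples (black bear style)."""
    rows = [
        ("U1", "Ursus thibetanus ussuricus", "Ursus thibetanus"),
        ("U2", "Ursus thibetanus formosanus", "Ursus thibetanus"),
        ("U3", "", "Ursus thibetanus"),
        ("H1", "", "Homo sapiens"),
        ("B1", "", "Bos taurus"),
    ]
    df = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "subspecies": ssp,
                "species": sp,
                "genus": sp.split()[0],
                "family": "Fam_" + sp.split()[0],
                "order": "Ord_" + sp.split()[0],
                "superorder": "Sup_" + sp.split()[0],
            }
            for sid, ssp, sp in rows
        ]
    )
    return TaxonomyTable(df)


@pytest.fixture(scope="session")
def separated_locus():
    """A well-separated simulated locus: clean barcoding gap, 48 samples."""
    config = SimulationConfig(
        seq_length=1500,
        inter_depth=0.08,
        intra_depth=0.003,
        seed=11,
    )
    bundle, alignment = simulate_locus(config)
    return config, bundle, alignment


def two_leaf_bundle(total_path: float, config: SimulationConfig) -> TruthBundle:
    """Minimal truth bundle: two leaves at tree distance ``total_path``."""
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = dendropy.Node()
    for sid in ("x", "y"):
        leaf = dendropy.Node(taxon=ns.new_taxon(label=sid))
        root.add_child(leaf)
        leaf.edge.length = total_path / 2.0
    tree.seed_node = root
    taxonomy = TaxonomyTable(
        pd.DataFrame(
            [
                {
                    "sample_id": sid,
                    "subspecies": "",
                    "species": f"sp_{sid}",
                    "genus": "g",
                    "family": "f",
                    "order": "o",
                    "superorder": "so",
                }
                for sid in ("x", "y")
            ]
        )
    )
    ids = ["x", "y"]
    mat = pd.DataFrame(
        np.array([[0.0, total_path], [total_path, 0.0]]), index=ids, columns=ids
    )
    return TruthBundle(taxonomy, tree, mat, config)
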