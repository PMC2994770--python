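"""Neighbor-Joining trees and taxonomy congruence for both loci.

Builds the NJ tree from the K2P matrix of each locus, writes it as
Newick, and scores congruence with the simulated taxonomy at every rank
under both accounting variants.  Also scores the true generating tree as
a sanity ceiling.  Outputs under results/congruence/.
"""

import json
from pathlib import Path

import pandas as pd

from mitolocus.alignment_io import read_alignment, read_newick, read_taxonomy, write_newick
from mitolocus.distances import complete_deletion, pairwise_matrix
from mitolocus.phylogeny import congruence, nj_tree

SIM = Path("results/sim")
OUT = Path("results/congruence")

RANKS = ("superorder", "order", "family", "genus")
VARIANTS = ("per_sample", "species_collapsed")


def score(tree, taxonomy, label, rows):
    overall = {}
    for rank in RANKS:
        for variant in VARIANTS:
            report = congruence(tree, taxonomy, rank, variant)
            rows.extend(
                {**r, "tree": label} for r in report.as_rows()
            )
            overall[f"{rank}/{variant}"] = report.overall_percent
    return overall


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    taxonomy = read_taxonomy(SIM / "taxonomy.tsv")
    rows: list[dict] = []
    summary = {}
    for name in ("cytb_like", "coi_like"):
        alignment = read_alignment(SIM / f"{name}.fasta")
        clean, _ = complete_deletion(alignment)
        tree = nj_tree(pairwise_matrix(clean, "k2p"))
        write_newick(tree, OUT / f"{name}_nj.nwk")
        summary[f"{name}_nj"] = score(tree, taxonomy, f"{name}_nj", rows)
        true_tree = read_newick(SIM / f"{name}_true_tree.nwk")
        summary[f"{name}_true"] = score(true_tree, taxonomy, f"{name}_true", rows)
        so = summary[f"{name}_nj"]["superorder/per_sample"]
        fam = summary[f"{name}_nj"]["family/per_sample"]
        print(f"{name}: NJ congruence {so:.2f}% at superorder, {fam:.2f}% at family")
    pd.DataFrame(rows).to_csv(OUT / "per_group.tsv", sep="\t", index=False)
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
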