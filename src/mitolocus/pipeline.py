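"""End-to-end orchestration: conservation -> distances -> discrimination
-> NJ tree -> congruence for one or more loci, with a consolidated
side-by-side report.

Each locus is either an (alignment, taxonomy) pair read from disk or a
simulation configuration.  The report is a plain nested dict (JSON-ready)
in which every number is traceable to one module operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import conservation, discrimination, distances, phylogeny
from .alignment_io import Alignment, TaxonomyTable
from .discrimination import DEFAULT_THRESHOLDS
from .errors import MitolocusError
from .synthetic_data import SimulationConfig, simulate_locus

logger = logging.getLogger("mitolocus")

__all__ = ["LocusInput", "analyse_locus", "run_locus_comparison"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class LocusInput:
    name: str
    alignment: Alignment | None = None
    taxonomy: TaxonomyTable | None = None
    simulation: SimulationConfig | None = None

    def realise(self) -> tuple[Alignment, TaxonomyTable]:
        if self.simulation is not None:
            bundle, alignment = simulate_locus(self.simulation)
            return alignment, bundle.taxonomy
        if self.alignment is None or self.taxonomy is None:
            raise MitolocusError(
                f"locus {self.name!r}: need alignment+taxonomy or a simulation config"
            )
        return self.alignment, self.taxonomy


def analyse_locus(
    name: str,
    alignment: Alignment,
    taxonomy: TaxonomyTable,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    window_sizes: tuple[int, ...] = conservation.DEFAULT_WINDOW_SIZES,
    bootstrap_replicates: int = 200,
    seed: int = 0,
    deduplicate: bool = True,
) -> dict:
    """Run the full single-locus analysis and return the report dict."""
    logger.info("[%s] %d sequences x %d bp", name, alignment.n_sequences, alignment.length)
    report: dict = {"locus": name, "schema_version": REPORT_SCHEMA_VERSION, "seed": seed}

    # conservation on the raw alignment (heteroplasmy rule wants ambiguities)
    track = conservation.conservation_track(alignment, window_sizes)
    counts = conservation.variability_counts(alignment)
    report["conservation"] = {
        "mean_rs_percent": conservation.mean_conservation_percent(track.rs_values),
        "total_variable_sites": counts.total_variable_sites,
        "singleton_variable_sites": counts.singleton_variable_sites,
        "window_mean_percent": {
            x: 100.0 * float(frac.mean()) for x, frac in track.window_fractions.items()
        },
    }

    if deduplicate:
        records = discrimination.deduplicate_sequences(alignment.records)
        if len(records) < alignment.n_sequences:
            logger.info(
                "[%s] removed %d duplicate sequences",
                name,
                alignment.n_sequences - len(records),
            )
        alignment = Alignment(records)

    clean, kept_sites = distances.complete_deletion(alignment)
    logger.info("[%s] complete deletion kept %d sites", name, clean.length)
    mask = distances.codon_mask_from_columns(kept_sites)

    report["distances"] = {}
    for metric in ("p", "k2p"):
        per_subset = {}
        for subset in ("all", "pos1", "pos2", "pos3"):
            mat = distances.pairwise_matrix(
                clean, metric, subset, scale_x100=True, mask=mask
            )
            per_subset[subset] = mat.summary()
        per_subset["all"]["bootstrap_se"] = (
            distances.bootstrap_se(
                clean, metric, "all", replicates=bootstrap_replicates, seed=seed
            ).se
            * 100.0
        )
        report["distances"][metric] = per_subset
    try:
        codon_clean, _ = distances.complete_deletion_codons(alignment)
        ds, dn = _mean_ds_dn(codon_clean)
        report["distances"]["ng"] = {"mean_ds_x100": ds * 100, "mean_dn_x100": dn * 100}
    except MitolocusError as exc:
        report["distances"]["ng"] = {"error": str(exc)}

    k2p = distances.pairwise_matrix(clean, "k2p", "all", scale_x100=True)
    pairs = discrimination.label_pairs(k2p, taxonomy)
    report["n_pairs"] = len(pairs)
    report["thresholds"] = {}
    for t in thresholds:
        table = discrimination.contingency(pairs, t)
        m = discrimination.metrics(table)
        report["thresholds"][str(t)] = {**table.as_dict(), **m.as_dict()}
    both_classes = any(p.same_species for p in pairs) and any(
        not p.same_species for p in pairs
    )
    if both_classes:
        gap = discrimination.gap_scan(pairs, thresholds)
        report["barcoding_gap"] = {
            "max_intra": gap.max_intra,
            "min_inter": gap.min_inter,
            "gap_interval": list(gap.gap_interval) if gap.gap_interval else None,
        }
        curve = discrimination.roc(pairs)
        report["roc"] = {"auc": curve.auc, "auc_se": curve.auc_se}
    else:
        logger.warning("[%s] one pair class absent; gap/ROC skipped", name)
        report["barcoding_gap"] = None
        report["roc"] = None

    if clean.n_sequences >= 3:
        tree = phylogeny.nj_tree(distances.pairwise_matrix(clean, "k2p", "all"))
        report["congruence"] = {}
        for rank in ("superorder", "order", "family", "genus"):
            report["congruence"][rank] = {}
            for variant in ("per_sample", "species_collapsed"):
                rep = phylogeny.congruence(tree, taxonomy, rank, variant)
                report["congruence"][rank][variant] = rep.overall_percent
    else:
        logger.warning("[%s] <3 sequences; congruence skipped", name)
        report["congruence"] = None
    return report


def _mean_ds_dn(alignment: Alignment) -> tuple[float, float]:
    seqs = alignment.sequences
    ds_vals, dn_vals = [], []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ds, dn = distances.ng_distance(seqs[i], seqs[j], lenient=True)
            ds_vals.append(ds)
            dn_vals.append(dn)
    return float(np.mean(ds_vals)), float(np.mean(dn_vals))


def run_locus_comparison(
    loci: list[LocusInput],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    bootstrap_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Apply the identical pipeline to >=2 loci and pair up the reports."""
    if len(loci) < 2:
        raise MitolocusError("need at least 2 loci to compare")
    reports = {}
    for locus in loci:
        alignment, taxonomy = locus.realise()
        reports[locus.name] = analyse_locus(
            locus.name,
            alignment,
            taxonomy,
            thresholds=thresholds,
            bootstrap_replicates=bootstrap_replicates,
            seed=seed,
        )
    return {"schema_version": REPORT_SCHEMA_VERSION, "loci": reports}
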