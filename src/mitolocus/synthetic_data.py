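"""Synthetic taxonomies, species trees and alignments with known truth.

The generator emulates the statistical structure a mitochondrial
barcoding analysis assumes:

- a balanced ranked taxonomy (superorder / order / family / species /
  sample) realised as an ultrametric species tree whose rank-boundary
  depths are ordered superorder > order > family > species > sample;
- a clean barcoding gap: intraspecific divergences far below the
  smallest interspecific divergence;
- codon-position rate heterogeneity (3rd > 1st > 2nd), imposed as
  branch-length multipliers per position class;
- rare heteroplasmic positions encoded as IUPAC ambiguity codes.

Sequence evolution follows the Kimura 2-parameter process sampled from
its exact transition probabilities per branch, so a branch of length d
has expected K2P distance exactly d — true distances are additive on the
tree by construction, making parameter-recovery tests exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .alignment_io import (
    AMBIGUITY_FOR_PAIR,
    BASES,
    Alignment,
    TaxonomyTable,
)
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "TruthBundle",
    "simulate_taxonomy",
    "evolve_alignment",
    "inject_heteroplasmy",
    "simulate_locus",
]

#: Depth of each rank-boundary node (height above the tips) as a multiple
#: of inter_depth / 2: the family node splits species within a family, so
#: two congeners sit at tree distance inter_depth, and splits deepen
#: toward the root.
_RANK_DEPTH_SCALE = {
    "family": 1.0,
    "order": 1.6,
    "superorder": 2.2,
    "root": 2.8,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated locus.

    Defaults mirror a mammalian mitochondrial protein-coding gene:
    interspecific K2P (x100) divergences in the ~20-30 band with
    intraspecific divergences well below 1.5 (the barcoding gap), a
    strong transition bias, and 3rd > 1st > 2nd codon-position rates.
    """

    n_superorders: int = 2
    orders_per_superorder: int = 2
    families_per_order: int = 2
    species_per_family: int = 3
    samples_per_species: int = 2
    seq_length: int = 1200  # bp, divisible by 3
    kappa: float = 8.0  # transition/transversion rate ratio
    inter_depth: float = 0.12  # substitutions/site between congeners
    intra_depth: float = 0.003  # substitutions/site within species
    pos_rate_multipliers: tuple[float, float, float] = (0.7, 0.2, 2.1)
    heteroplasmy_rate: float = 0.0
    third_position_transitions_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intra_depth >= self.inter_depth:
            raise ConfigError("intra_depth must be below inter_depth")
        if self.seq_length < 300 or self.seq_length % 3:
            raise ConfigError("seq_length must be >= 300 and divisible by 3")
        if any(m < 0 for m in self.pos_rate_multipliers) or all(
            m == 0 for m in self.pos_rate_multipliers
        ):
            raise ConfigError("pos_rate_multipliers must be non-negative, not all 0")
        if self.kappa <= 0:
            raise ConfigError("kappa must be positive")

    @property
    def n_species(self) -> int:
        return (
            self.n_superorders
            * self.orders_per_superorder
            * self.families_per_order
            * self.species_per_family
        )

    @property
    def n_samples(self) -> int:
        return self.n_species * self.samples_per_species


@dataclass
class TruthBundle:
    """Ground truth for one simulation: taxonomy, true tree, distances."""

    taxonomy: TaxonomyTable
    tree: dendropy.Tree
    true_distances: pd.DataFrame  # square, indexed by sample id
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore


def _rng_stream(seed: int, stream: str) -> np.random.Generator:
    """Independent generator per named operation, all derived from one seed."""
    tag = zlib.crc32(stream.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def simulate_taxonomy(config: SimulationConfig) -> TruthBundle:
    """Balanced ranked taxonomy and the matching ultrametric species tree."""
    rows = []
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    half_inter = config.inter_depth / 2.0
    depth = {k: v * half_inter for k, v in _RANK_DEPTH_SCALE.items()}
    depth["species"] = config.intra_depth / 2.0  # within-species MRCA

    root = dendropy.Node()
    sample_idx = 0
    for so in range(config.n_superorders):
        so_name = f"Superorder{so + 1}"
        so_node = dendropy.Node()
        root.add_child(so_node)
        so_node.edge.length = depth["root"] - depth["superorder"]
        for o in range(config.orders_per_superorder):
            o_name = f"{so_name}_Order{o + 1}"
            o_node = dendropy.Node()
            so_node.add_child(o_node)
            o_node.edge.length = depth["superorder"] - depth["order"]
            for f in range(config.families_per_order):
                f_name = f"{o_name}_Family{f + 1}"
                f_node = dendropy.Node()
                o_node.add_child(f_node)
                f_node.edge.length = depth["order"] - depth["family"]
                for s in range(config.species_per_family):
                    sp_name = f"{f_name}_Species{s + 1}"
                    sp_node = dendropy.Node()
                    f_node.add_child(sp_node)
                    sp_node.edge.length = depth["family"] - depth["species"]
                    for k in range(config.samples_per_species):
                        sample_idx += 1
                        sid = f"S{sample_idx:04d}"
                        leaf = dendropy.Node(taxon=taxon_ns.new_taxon(label=sid))
                        sp_node.add_child(leaf)
                        leaf.edge.length = depth["species"]
                        rows.append(
                            {
                                "sample_id": sid,
                                "subspecies": "",
                                "species": sp_name,
                                "genus": f_name + "_G1",
                                "family": f_name,
                                "order": o_name,
                                "superorder": so_name,
                            }
                        )
    tree.seed_node = root
    tree.is_rooted = False
    taxonomy = TaxonomyTable(pd.DataFrame(rows))

    pdm = tree.phylogenetic_distance_matrix()
    ids = [r["sample_id"] for r in rows]
    taxa = {t.label: t for t in taxon_ns}
    mat = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            dist = pdm.distance(taxa[a], taxa[ids[j]])
            mat[i, j] = mat[j, i] = dist
    true_d = pd.DataFrame(mat, index=ids, columns=ids)
    return TruthBundle(taxonomy, tree, true_d, config)


def _k2p_step_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """(P_same, P_transition, P_each_transversion) after distance d."""
    if d <= 0:
        return 1.0, 0.0, 0.0
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e1 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return 1.0 - p_ts - 2.0 * p_tv_each, p_ts, p_tv_each


_STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})


def _random_root(length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random coding sequence with no in-frame stop codons."""
    seq = rng.integers(0, 4, size=length)
    for i in range(0, length, 3):
        while "".join(BASES[x] for x in seq[i : i + 3]) in _STOP_CODONS:
            seq[i : i + 3] = rng.integers(0, 4, size=3)
    return seq


def _evolve_along(
    seq: np.ndarray,
    length_by_site: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch of K2P evolution; per-site branch lengths allow
    codon-position rate multipliers."""
    out = seq.copy()
    # sites share only a few distinct rates, so group them
    for d in np.unique(length_by_site):
        idx = np.flatnonzero(length_by_site == d)
        if d <= 0 or idx.size == 0:
            continue
        p_same, p_ts, p_tv = _k2p_step_probs(float(d), kappa)
        u = rng.random(idx.size)
        ts_mask = u < p_ts
        tv1_mask = (u >= p_ts) & (u < p_ts + p_tv)
        tv2_mask = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
        # base encoding: A=0 C=1 G=2 T=3; transition partner and the two
        # transversion partners per base
        ts_map = np.array([2, 3, 0, 1])
        tv1_map = np.array([1, 0, 1, 0])
        tv2_map = np.array([3, 2, 3, 2])
        cur = out[idx]
        new = cur.copy()
        new[ts_mask] = ts_map[cur[ts_mask]]
        new[tv1_mask] = tv1_map[cur[tv1_mask]]
        new[tv2_mask] = tv2_map[cur[tv2_mask]]
        out[idx] = new
    return out


def evolve_alignment(bundle: TruthBundle, config: SimulationConfig) -> Alignment:
    """Evolve sequences along the true tree under the K2P process.

    Branch lengths are interpreted as expected substitutions/site for a
    position of multiplier 1; per-codon-position multipliers scale them.
    With ``third_position_transitions_only`` set, change is confined to
    third positions at a very high transition bias, creating dS >> dN
    structure without a full codon model.
    """
    rng = _rng_stream(config.seed, "evolve")
    length = config.seq_length
    multipliers = np.array(config.pos_rate_multipliers, dtype=float)
    kappa = config.kappa
    if config.third_position_transitions_only:
        multipliers = np.array([0.0, 0.0, float(multipliers.sum())])
        kappa = 1000.0
    site_mult = np.tile(multipliers, length // 3)

    root_seq = _random_root(length, rng)
    seqs: dict[str, np.ndarray] = {}

    def _recurse(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_seq = _evolve_along(seq, bl * site_mult, kappa, rng)
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                _recurse(child, child_seq)

    _recurse(bundle.tree.seed_node, root_seq)
    lookup = np.array(list("ACGT"))
    records = [
        (sid, "".join(lookup[seqs[sid]]))
        for sid in bundle.taxonomy.sample_ids
    ]
    return Alignment(records)


def inject_heteroplasmy(
    alignment: Alignment, rate: float, seed: int
) -> tuple[Alignment, int]:
    """Replace random cells with two-base IUPAC codes (heteroplasmy).

    Each (sequence, site) cell is hit independently with probability
    ``rate``; the base is joined with one random alternative base.
    Returns the modified alignment and the number of injections.
    """
    if not 0.0 <= rate <= 0.01:
        raise ConfigError("heteroplasmy rate must be in [0, 0.01]")
    if rate == 0.0:
        return alignment, 0
    rng = _rng_stream(seed, "heteroplasmy")
    n_injected = 0
    records = []
    for sid, seq in alignment.records:
        chars = list(seq)
        hits = np.flatnonzero(rng.random(len(chars)) < rate)
        for i in hits:
            base = chars[i]
            if base not in BASES:
                continue
            alt = BASES[rng.integers(0, 4)]
            while alt == base:
                alt = BASES[rng.integers(0, 4)]
            chars[i] = AMBIGUITY_FOR_PAIR[frozenset((base, alt))]
            n_injected += 1
        records.append((sid, "".join(chars)))
    return Alignment(records), n_injected


def simulate_locus(config: SimulationConfig) -> tuple[TruthBundle, Alignment]:
    """Convenience: taxonomy + tree + evolved alignment (+ heteroplasmy)."""
    bundle = simulate_taxonomy(config)
    alignment = evolve_alignment(bundle, config)
    if config.heteroplasmy_rate > 0:
        alignment, _ = inject_heteroplasmy(
            alignment, config.heteroplasmy_rate, config.seed
        )
    return bundle, alignment
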