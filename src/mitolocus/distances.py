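"""Pairwise distance suite: p-distance, Kimura 2-parameter distance,
codon-position partitions, Nei–Gojobori dS/dN under the vertebrate
mitochondrial code, and bootstrap standard errors.

All distances are computed on a complete-deletion alignment (every column
with a gap or ambiguity in any sequence removed for all sequences, the
convention of the common tree packages).  Distances are stored unscaled
(substitutions/site); the conventional x100 presentation is a formatting
flag applied at report time.

K2P distinguishes transitions (A<->G, C<->T) from transversions.  With P
and Q the observed transition and transversion proportions,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

which is undefined (saturated) when 1-2P-Q <= 0 or 1-2Q <= 0; saturated
pairs raise :class:`SaturationError` and are excluded from summaries.

The Nei–Gojobori method counts synonymous (S) and non-synonymous (N) sites
per codon as the fraction of the three single-base alternatives at each
position that preserve the amino acid, and counts synonymous/non-synonymous
differences between two codons by averaging over all orderings of the
single-base steps between them, excluding pathways through stop codons.
dS and dN here are the p-distance flavour (no Jukes–Cantor correction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .alignment_io import BASES, GAP, Alignment, CodonMask, codon_mask
from .errors import (
    AlignmentError,
    InputError,
    SaturationError,
    UndefinedDistanceError,
)

__all__ = [
    "DistanceMatrix",
    "CodonProfile",
    "BootstrapSE",
    "complete_deletion",
    "complete_deletion_codons",
    "codon_mask_from_columns",
    "p_distance",
    "k2p_distance",
    "ng_site_counts",
    "ng_differences",
    "ng_distance",
    "pairwise_matrix",
    "bootstrap_se",
    "VERTEBRATE_MITO_TABLE",
]

#: NCBI translation table 2 (AGA/AGG/TAA/TAG stop, ATA Met, TGA Trp).
VERTEBRATE_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

_STOPS = frozenset(VERTEBRATE_MITO_TABLE.stop_codons)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with metric metadata.

    ``saturated`` marks pairs where the distance transform is undefined;
    those entries hold NaN and are excluded from summaries.
    """

    sample_ids: list[str]
    values: np.ndarray
    metric: str  # one of {"p", "k2p", "ds", "dn"}
    position_subset: str = "all"  # {"all", "pos1", "pos2", "pos3"}
    scale_x100: bool = False
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match ids")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def scaled(self) -> np.ndarray:
        """Values on the reporting scale (x100 if flagged)."""
        return self.values * 100.0 if self.scale_x100 else self.values

    def pair_value(self, id1: str, id2: str) -> float:
        i, j = self.sample_ids.index(id1), self.sample_ids.index(id2)
        return float(self.scaled()[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values (unordered pairs), saturated pairs dropped."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.scaled()[iu]
        return vals[~self.saturated[iu]]

    def n_saturated_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(self.saturated[iu].sum())

    def summary(self) -> dict[str, float]:
        vals = self.condensed()
        if vals.size == 0:
            raise UndefinedDistanceError("no finite pairwise values")
        return {
            "mean": float(vals.mean()),
            "max": float(vals.max()),
            "min": float(vals.min()),
            "n_pairs": int(vals.size),
            "n_saturated_excluded": self.n_saturated_pairs(),
        }


def complete_deletion(alignment: Alignment) -> tuple[Alignment, list[int]]:
    """Drop every column containing a gap or ambiguity in any sequence.

    Returns the filtered alignment together with the kept original
    1-based column indices, so codon masks can be re-derived.
    """
    if alignment.n_sequences < 2:
        raise AlignmentError("need at least 2 sequences")
    good = set(BASES)
    keep = [
        site
        for site, col in enumerate(alignment.columns(), start=1)
        if all(sym in good for sym in col)
    ]
    if not keep:
        raise AlignmentError("complete deletion removed every column")
    recs = [
        (sid, "".join(seq[i - 1] for i in keep)) for sid, seq in alignment.records
    ]
    return Alignment(recs), keep


def complete_deletion_codons(
    alignment: Alignment, frame_offset: int = 0
) -> tuple[Alignment, list[int]]:
    """Codon-wise complete deletion: drop every whole in-frame codon whose
    three columns contain a gap or ambiguity in any sequence (preserves the
    reading frame for dS/dN).  Returns the filtered alignment and the kept
    1-based codon indices.
    """
    if alignment.n_sequences < 2:
        raise AlignmentError("need at least 2 sequences")
    good = set(BASES)
    mask = codon_mask(alignment.length, frame_offset)
    cols = list(alignment.columns())
    keep_codons = []
    keep_sites: list[int] = []
    for c in range(mask.n_codons):
        start = frame_offset + 3 * c + 1
        sites = (start, start + 1, start + 2)
        if all(all(sym in good for sym in cols[s - 1]) for s in sites):
            keep_codons.append(c + 1)
            keep_sites.extend(sites)
    if not keep_sites:
        raise AlignmentError("codon-wise complete deletion removed every codon")
    recs = [
        (sid, "".join(seq[i - 1] for i in keep_sites))
        for sid, seq in alignment.records
    ]
    return Alignment(recs), keep_codons


def codon_mask_from_columns(
    kept_columns: list[int], frame_offset: int = 0
) -> CodonMask:
    """Re-derive codon-position sets after column deletion.

    ``kept_columns`` are the original 1-based columns surviving
    :func:`complete_deletion`; each keeps the codon position it had in the
    original frame, indexed by its new position in the filtered alignment.
    """
    sets: list[set[int]] = [set(), set(), set()]
    for new_idx, orig in enumerate(kept_columns, start=1):
        if orig <= frame_offset:
            continue
        sets[(orig - 1 - frame_offset) % 3].add(new_idx)
    return CodonMask(frame_offset, tuple(frozenset(s) for s in sets))


def _subset_indices(length: int, subset: str, mask: CodonMask | None) -> np.ndarray:
    if subset == "all":
        return np.arange(length)
    if subset not in ("pos1", "pos2", "pos3"):
        raise InputError(f"unknown position subset {subset!r}")
    if mask is None:
        mask = codon_mask(length)
    sites = sorted(mask.positions(int(subset[-1])))
    return np.array(sites, dtype=int) - 1


def p_distance(s1: str, s2: str, sites: np.ndarray | None = None) -> float:
    """Proportion of differing sites over the given site subset."""
    if len(s1) != len(s2):
        raise AlignmentError("sequences of unequal length")
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    if sites is not None:
        if len(sites) == 0:
            raise UndefinedDistanceError("empty site subset")
        a, b = a[sites], b[sites]
    if a.size == 0:
        raise UndefinedDistanceError("empty site subset")
    return float((a != b).mean())


def transition_transversion_proportions(
    s1: str, s2: str, sites: np.ndarray | None = None
) -> tuple[float, float]:
    """Observed transition (P) and transversion (Q) proportions."""
    if len(s1) != len(s2):
        raise AlignmentError("sequences of unequal length")
    if sites is not None:
        s1 = "".join(s1[i] for i in sites)
        s2 = "".join(s2[i] for i in sites)
    if not s1:
        raise UndefinedDistanceError("empty site subset")
    ts = tv = 0
    for x, y in zip(s1, s2):
        if x == y:
            continue
        if _is_transition(x, y):
            ts += 1
        else:
            tv += 1
    n = len(s1)
    return ts / n, tv / n


def k2p_from_pq(p: float, q: float) -> float:
    """Kimura's two-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for P={p}, Q={q}")
    return float(max(0.0, -0.5 * np.log(w1) - 0.25 * np.log(w2)))


def k2p_distance(s1: str, s2: str, sites: np.ndarray | None = None) -> float:
    p, q = transition_transversion_proportions(s1, s2, sites)
    return k2p_from_pq(p, q)


@dataclass(frozen=True)
class CodonProfile:
    """Fractional synonymous (S) and non-synonymous (N) site counts."""

    s_sites: float
    n_sites: float
    n_codons: int


@lru_cache(maxsize=None)
def _codon_fraction_synonymous(codon: str) -> float:
    """Per-codon synonymous site count s under the vertebrate mito code.

    Changes producing a stop codon count as non-synonymous in the
    denominator (the original pathway-method convention).
    """
    aa = VERTEBRATE_MITO_TABLE.forward_table[codon]
    s = 0.0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in _STOPS and VERTEBRATE_MITO_TABLE.forward_table[mutant] == aa:
                s += 1.0 / 3.0
    return s


def ng_site_counts(codon_sequence: str, lenient: bool = False) -> CodonProfile:
    """Nei–Gojobori S and N site counts for one codon sequence.

    S + N = 3 x (number of counted codons).  Internal stop codons raise
    :class:`InputError` unless ``lenient`` is set, in which case they are
    skipped.
    """
    if len(codon_sequence) % 3 != 0:
        raise InputError("sequence length not divisible by 3")
    s_total = 0.0
    n_codons = 0
    for i in range(0, len(codon_sequence), 3):
        codon = codon_sequence[i : i + 3]
        if any(b not in BASES for b in codon):
            raise InputError(f"ambiguous codon {codon!r}; apply complete deletion first")
        if codon in _STOPS:
            if lenient:
                continue
            raise InputError(f"internal stop codon {codon!r} at position {i + 1}")
        s_total += _codon_fraction_synonymous(codon)
        n_codons += 1
    return CodonProfile(s_total, 3.0 * n_codons - s_total, n_codons)


@lru_cache(maxsize=None)
def ng_differences(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/non-synonymous difference counts between two codons.

    For k differing positions the counts are averaged over all k!
    orderings of single-base steps; any ordering passing through a stop
    codon is excluded.  Returns (sd, nd) with sd + nd = k whenever at
    least one valid pathway exists.
    """
    if len(c1) != 3 or len(c2) != 3:
        raise InputError("codons must be length 3")
    if c1 in _STOPS or c2 in _STOPS:
        raise InputError("stop codon in pairwise codon comparison")
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0
    fwd = VERTEBRATE_MITO_TABLE.forward_table
    path_sd: list[float] = []
    path_nd: list[float] = []
    for order in itertools.permutations(diff_positions):
        current = c1
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                valid = False
                break
            if fwd[current] == fwd[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        if valid:
            path_sd.append(sd)
            path_nd.append(nd)
    if not path_sd:
        raise UndefinedDistanceError(
            f"all mutational pathways between {c1} and {c2} pass through stops"
        )
    return float(np.mean(path_sd)), float(np.mean(path_nd))


def ng_distance(s1: str, s2: str, lenient: bool = False) -> tuple[float, float]:
    """Nei–Gojobori (dS, dN) p-distances between two codon sequences.

    dS = sum(sd) / mean(S1, S2) and dN = sum(nd) / mean(N1, N2); on very
    short sequences dS can exceed 1 since no multiple-hit correction is
    applied.
    """
    if len(s1) != len(s2):
        raise AlignmentError("sequences of unequal length")
    prof1 = ng_site_counts(s1, lenient=lenient)
    prof2 = ng_site_counts(s2, lenient=lenient)
    sd_total = nd_total = 0.0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if lenient and (c1 in _STOPS or c2 in _STOPS):
            continue
        sd, nd = ng_differences(c1, c2)
        sd_total += sd
        nd_total += nd
    mean_s = 0.5 * (prof1.s_sites + prof2.s_sites)
    mean_n = 0.5 * (prof1.n_sites + prof2.n_sites)
    if mean_s == 0.0 or mean_n == 0.0:
        raise UndefinedDistanceError("zero synonymous or non-synonymous sites")
    return sd_total / mean_s, nd_total / mean_n


_METRICS = ("p", "k2p", "ds", "dn")


def _pair_metric(metric: str, s1: str, s2: str, sites: np.ndarray | None):
    if metric == "p":
        return p_distance(s1, s2, sites)
    if metric == "k2p":
        return k2p_distance(s1, s2, sites)
    if metric in ("ds", "dn"):
        # matrix-level dS/dN skips codons that are stops in either sequence
        ds, dn = ng_distance(s1, s2, lenient=True)
        return ds if metric == "ds" else dn
    raise InputError(f"unknown metric {metric!r}")


def pairwise_matrix(
    alignment: Alignment,
    metric: str = "k2p",
    subset: str = "all",
    scale_x100: bool = False,
    mask: CodonMask | None = None,
) -> DistanceMatrix:
    """All-pairs distance matrix (n(n-1)/2 unordered comparisons).

    The alignment is expected to be gap/ambiguity free (apply
    :func:`complete_deletion` first).  dS/dN metrics require ``subset``
    "all" since they are defined per codon.
    """
    if metric not in _METRICS:
        raise InputError(f"unknown metric {metric!r}")
    if metric in ("ds", "dn") and subset != "all":
        raise InputError("dS/dN are codon metrics; position subsets do not apply")
    n = alignment.n_sequences
    if n < 2:
        raise AlignmentError("need at least 2 sequences")
    sites = None if subset == "all" else _subset_indices(alignment.length, subset, mask)
    seqs = alignment.sequences
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = _pair_metric(metric, seqs[i], seqs[j], sites)
            except SaturationError:
                d = np.nan
                saturated[i, j] = saturated[j, i] = True
            values[i, j] = values[j, i] = d
    return DistanceMatrix(
        list(alignment.sample_ids), values, metric, subset, scale_x100, saturated
    )


@dataclass(frozen=True)
class BootstrapSE:
    estimate: float
    se: float
    replicates: int
    seed: int


def bootstrap_se(
    alignment: Alignment,
    metric: str = "k2p",
    subset: str = "all",
    replicates: int = 1000,
    seed: int = 0,
    mask: CodonMask | None = None,
) -> BootstrapSE:
    """Bootstrap standard error of the overall mean pairwise distance.

    Alignment columns are resampled with replacement (codon triplets for
    dS/dN so reading frame is preserved); the mean distance is recomputed
    per replicate and the SE is the standard deviation across replicates.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    base = pairwise_matrix(alignment, metric, subset, mask=mask)
    estimate = base.summary()["mean"]
    if subset != "all":
        # restrict to the codon-position sites once, then resample those
        sites = _subset_indices(alignment.length, subset, mask)
        alignment = Alignment(
            [(sid, "".join(seq[i] for i in sites)) for sid, seq in alignment.records]
        )
        subset = "all"
    length = alignment.length
    codon_units = metric in ("ds", "dn")
    n_units = length // 3 if codon_units else length
    means = np.empty(replicates)
    for r in range(replicates):
        picks = rng.integers(0, n_units, size=n_units)
        if codon_units:
            cols = np.concatenate([3 * picks + k for k in range(3)]).reshape(3, -1)
            cols = cols.T.ravel()
        else:
            cols = picks
        recs = [
            (sid, "".join(seq[c] for c in cols)) for sid, seq in alignment.records
        ]
        mat = pairwise_matrix(Alignment(recs), metric, subset)
        means[r] = mat.summary()["mean"]
    return BootstrapSE(estimate, float(means.std(ddof=1)), replicates, seed)
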