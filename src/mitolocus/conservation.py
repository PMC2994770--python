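"""Per-site sequence conservation in bits and sliding-window identity.

Conservation at an aligned site is measured as R_s = 2 - H, where H is the
Shannon uncertainty of the base frequencies at the site.  A site where all
sequences carry the same base has H = 0 and R_s = 2 bits (log2 4); a site
with all four bases at equal frequency has R_s = 0.

Heteroplasmy rule: an IUPAC ambiguity symbol (a heteroplasmic position in
one individual) contributes to the number of sequences at the site but is
not counted toward any base.  Out of 100 sequences with 99 A and one A/G
heteroplasmy, the site is scored as 99% A and 0% C, G, T — the frequencies
are deliberately NOT renormalised to sum to one.  Gap symbols are handled
by the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import BASES, Alignment
from .errors import AlignmentError, InputError

__all__ = [
    "BaseFrequencies",
    "ConservationTrack",
    "VariabilityCounts",
    "site_frequencies",
    "site_rs",
    "conservation_track",
    "sliding_window_identity",
    "variability_counts",
    "mean_conservation_percent",
]

#: Sliding-window sizes used throughout: 101 bp plus the approximate
#: fragment sizes sequenced in practice for cyt b (401) and COI (601).
DEFAULT_WINDOW_SIZES = (101, 401, 601)


@dataclass(frozen=True)
class BaseFrequencies:
    """Unambiguous-base frequencies at one aligned site.

    Frequencies are counts divided by ``n_sequences`` (every sequence,
    including gapped/ambiguous ones, is in the denominator) so their sum
    may be strictly below 1.
    """

    p_a: float
    p_c: float
    p_g: float
    p_t: float
    n_sequences: int

    def as_array(self) -> np.ndarray:
        return np.array([self.p_a, self.p_c, self.p_g, self.p_t])


@dataclass
class ConservationTrack:
    """Per-site R_s values (bits) and per-window identity fractions."""

    rs_values: np.ndarray
    window_fractions: dict[int, np.ndarray]

    @property
    def length(self) -> int:
        return len(self.rs_values)


@dataclass(frozen=True)
class VariabilityCounts:
    total_variable_sites: int
    singleton_variable_sites: int


def site_frequencies(column: str) -> BaseFrequencies:
    """Base frequencies of one alignment column under the heteroplasmy rule."""
    if not column:
        raise InputError("empty column")
    n = len(column)
    counts = {b: 0 for b in BASES}
    for sym in column:
        if sym in counts:
            counts[sym] += 1
    return BaseFrequencies(
        counts["A"] / n, counts["C"] / n, counts["G"] / n, counts["T"] / n, n
    )


def site_rs(freqs: BaseFrequencies) -> float:
    """Conservation R_s = 2 - H in bits, clamped to [0, 2]."""
    p = freqs.as_array()
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0
    return float(np.clip(2.0 - h, 0.0, 2.0))


def _rs_per_site(alignment: Alignment) -> np.ndarray:
    # vectorised: count A/C/G/T per column over a byte matrix
    mat = np.frombuffer(
        "".join(alignment.sequences).encode(), dtype=np.uint8
    ).reshape(alignment.n_sequences, alignment.length)
    n = alignment.n_sequences
    p = np.stack([(mat == ord(b)).sum(axis=0) / n for b in BASES])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return np.clip(2.0 - terms.sum(axis=0), 0.0, 2.0)


def sliding_window_identity(rs_values: np.ndarray, window: int) -> np.ndarray:
    """Identity fraction per window: sum of R_s over the window / (2 * window).

    Windows advance one site at a time; entry i is the window starting at
    1-based site i+1.  A fully conserved window scores 1.0.
    """
    rs_values = np.asarray(rs_values, dtype=float)
    if window > len(rs_values):
        raise AlignmentError(
            f"window {window} longer than track of {len(rs_values)} sites"
        )
    if window < 1:
        raise InputError("window must be >= 1")
    csum = np.concatenate([[0.0], np.cumsum(rs_values)])
    sums = csum[window:] - csum[:-window]
    return sums / (2.0 * window)


def conservation_track(
    alignment: Alignment, window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
) -> ConservationTrack:
    """Full conservation profile of an alignment."""
    rs = _rs_per_site(alignment)
    windows = {
        x: sliding_window_identity(rs, x) for x in window_sizes if x <= len(rs)
    }
    return ConservationTrack(rs, windows)


def variability_counts(alignment: Alignment) -> VariabilityCounts:
    """Count variable sites and singleton-variable sites.

    A site is variable when at least two distinct unambiguous bases occur.
    It is singleton-variable when exactly one sequence carries a minority
    base and every other base-bearing sequence shares a single base.
    """
    if alignment.n_sequences < 2:
        raise AlignmentError("need at least 2 sequences")
    total = 0
    singleton = 0
    for col in alignment.columns():
        counts = sorted(
            (col.count(b) for b in BASES if col.count(b) > 0), reverse=True
        )
        if len(counts) >= 2:
            total += 1
            if len(counts) == 2 and counts[1] == 1:
                singleton += 1
    return VariabilityCounts(total, singleton)


def mean_conservation_percent(rs_values: np.ndarray) -> float:
    """Average R_s as a percentage of a completely conserved gene."""
    rs_values = np.asarray(rs_values, dtype=float)
    if rs_values.size == 0:
        raise InputError("empty conservation track")
    return 100.0 * float(rs_values.mean()) / 2.0
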