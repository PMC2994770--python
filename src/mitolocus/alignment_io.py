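"""Alignment, taxonomy and tree I/O plus coordinate/codon utilities.

All downstream modules consume the types defined here.  Sequences are
stored as uppercase strings over the DNA alphabet plus IUPAC ambiguity
codes and the gap symbol ``-``.  Ambiguity codes are retained (the
conservation module's heteroplasmy rule needs them), never collapsed to N.
Coordinates are 1-based and inclusive on both ends, the convention used
for mitochondrial gene annotations (human cyt b spans 14,747–15,887,
COI spans 5,904–7,445).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, BoundsError, InputError, TreeError

#: Canonical bases.
BASES = ("A", "C", "G", "T")

#: IUPAC ambiguity codes mapped to the set of bases they stand for.
IUPAC_AMBIGUITY: Mapping[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

GAP = "-"

VALID_SYMBOLS = frozenset(BASES) | frozenset(IUPAC_AMBIGUITY) | {GAP}

#: Two-base ambiguity code for each unordered base pair (heteroplasmy encoding).
AMBIGUITY_FOR_PAIR: Mapping[frozenset[str], str] = {
    bases: code for code, bases in IUPAC_AMBIGUITY.items() if len(bases) == 2
}

TAXONOMY_COLUMNS = (
    "sample_id",
    "subspecies",
    "species",
    "genus",
    "family",
    "order",
    "superorder",
)


def normalise_sequence(seq: str) -> str:
    """Uppercase, map U->T and '.'->'-', and validate symbols."""
    s = seq.upper().replace("U", "T").replace(".", GAP)
    bad = set(s) - VALID_SYMBOLS
    if bad:
        raise InputError(f"non-IUPAC symbols in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class CoordinateRange:
    """1-based inclusive coordinate range on a sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise BoundsError(f"invalid range {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Alignment:
    """An aligned set of equal-length sequences with unique sample ids."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sample ids: {dupes}")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.records]

    def column(self, site: int) -> str:
        """Symbols at a 1-based site, in record order."""
        if not 1 <= site <= self.length:
            raise BoundsError(f"site {site} outside 1..{self.length}")
        return "".join(s[site - 1] for _, s in self.records)

    def columns(self) -> Iterable[str]:
        for site in range(1, self.length + 1):
            yield self.column(site)

    def subset_samples(self, ids: Sequence[str]) -> "Alignment":
        keep = set(ids)
        recs = [(sid, s) for sid, s in self.records if sid in keep]
        missing = keep - {sid for sid, _ in recs}
        if missing:
            raise InputError(f"unknown sample ids: {sorted(missing)}")
        return Alignment(recs)


def make_alignment(records: Iterable[tuple[str, str]]) -> Alignment:
    """Build an Alignment, normalising each sequence."""
    return Alignment([(sid, normalise_sequence(s)) for sid, s in records])


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file (wrapped or single-line)."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if len(records) < 2:
        raise InputError(f"{path}: need at least 2 records, found {len(records)}")
    return make_alignment(records)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in alignment.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def slice_gene(genome: str, coords: CoordinateRange) -> str:
    """Extract a gene from a genome string, 1-based inclusive both ends."""
    if coords.end > len(genome):
        raise BoundsError(
            f"range {coords.start}..{coords.end} outside genome of length {len(genome)}"
        )
    return genome[coords.start - 1 : coords.end]


@dataclass(frozen=True)
class CodonMask:
    """1st/2nd/3rd codon-position site sets (1-based alignment columns).

    Only complete in-frame codons contribute; trailing (and, for a nonzero
    frame offset, leading) sites belong to no set.
    """

    frame_offset: int
    position_sets: tuple[frozenset[int], frozenset[int], frozenset[int]]

    def positions(self, which: int) -> frozenset[int]:
        """Site set for codon position ``which`` in {1, 2, 3}."""
        return self.position_sets[which - 1]

    @property
    def n_codons(self) -> int:
        return len(self.position_sets[0])


def codon_mask(alignment_length: int, frame_offset: int = 0) -> CodonMask:
    """Partition sites into codon positions for a reading frame.

    The first complete codon starts at column ``frame_offset + 1``.
    """
    if alignment_length < 3:
        raise AlignmentError("alignment shorter than one codon")
    if frame_offset not in (0, 1, 2):
        raise InputError(f"frame_offset must be 0-2, got {frame_offset}")
    n_codons = (alignment_length - frame_offset) // 3
    sets: list[set[int]] = [set(), set(), set()]
    for c in range(n_codons):
        start = frame_offset + 3 * c + 1
        for pos in range(3):
            sets[pos].add(start + pos)
    return CodonMask(frame_offset, tuple(frozenset(s) for s in sets))


@dataclass
class TaxonomyTable:
    """Per-sample rank labels plus a subspecies-to-species collapsing map.

    ``collapse_map`` sends every sample id to its (collapsed) species name:
    named subspecies of one species all map to that species, so pairs of
    conspecific subspecies samples count as same-species comparisons.
    """

    table: pd.DataFrame
    collapse_map: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        missing = [c for c in TAXONOMY_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"taxonomy table missing columns: {missing}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            raise InputError(
                f"duplicate sample ids in taxonomy: {sorted(ids[ids.duplicated()])}"
            )
        self.table = self.table.set_index("sample_id", drop=False)
        self.collapse_map = {
            sid: row["species"] for sid, row in self.table.iterrows()
        }

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def species_of(self, sample_id: str) -> str:
        from .errors import TaxonomyError

        try:
            return self.collapse_map[sample_id]
        except KeyError:
            raise TaxonomyError(f"sample id {sample_id!r} not in taxonomy") from None

    def rank_of(self, sample_id: str, rank: str) -> str:
        from .errors import TaxonomyError

        if rank not in TAXONOMY_COLUMNS[1:]:
            raise InputError(f"unknown rank {rank!r}")
        if sample_id not in self.table.index:
            raise TaxonomyError(f"sample id {sample_id!r} not in taxonomy")
        return self.table.at[sample_id, rank]

    def groups(self, rank: str) -> dict[str, list[str]]:
        """Sample ids grouped by the label at ``rank`` (insertion order kept)."""
        if rank not in TAXONOMY_COLUMNS[1:]:
            raise InputError(f"unknown rank {rank!r}")
        out: dict[str, list[str]] = {}
        for sid, label in zip(self.table["sample_id"], self.table[rank]):
            out.setdefault(label, []).append(sid)
        return out


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a TSV taxonomy with the six rank columns.

    An empty subspecies field means the sample is a full species (it maps
    to its own species name in the collapse map).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return TaxonomyTable(df)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    taxonomy.table.to_csv(path, sep="\t", index=False)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree with leaf labels (branch lengths optional)."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"cannot parse Newick file {path}: {exc}") from exc
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise TreeError(f"{path}: unlabeled leaf in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    buf = io.StringIO()
    tree.write(
        file=buf,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    Path(path).write_text(buf.getvalue())
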